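"""Synthetic study generator: task design, neural encoding, epochs, behavior.

The generator emulates a three-phase Stroop experiment with an
item-specific proportion congruency (ISPC) manipulation that flips across
phases.  Within a phase one color set is mostly congruent (MC, 75%
congruent) and the other mostly incongruent (MI, 25% congruent); phase 2
flips the assignment of phase 1 and phase 3 restores it.  Trials are grouped
into mini-blocks of 16 whose stimulus counts follow the unique 3:1 template
compatible with the 75/25 per-set proportions and a 50% overall congruency.

The neural model writes factor-specific spatial patterns (color, word, set,
congruency, ISPC, and the 8-way SC and SR association classes) into a
multichannel epoch under latency-windowed envelopes.  A per-trial latent
gain can multiply both the SC and SR patterns (the integrated-representation
regime) and also speeds responses, producing the brain-behavior coupling the
downstream analyses are built to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .conditions import (
    COLORS,
    SETS,
    SET_OF_COLOR,
    STIMULI,
    condition_table,
)
from .containers import EpochSet

# ---------------------------------------------------------------------------
# Task design
# ---------------------------------------------------------------------------


@dataclass
class DesignConfig:
    """Parameters of the three-phase ISPC-flipping design."""

    n_subjects: int = 1
    miniblocks_per_phase: tuple[int, int, int] = (8, 50, 48)
    trials_per_miniblock: int = 16
    mc_proportion: float = 0.75
    #: per phase, which color set (A or B) is mostly congruent; the default
    #: is overridden per subject when counterbalance is on.
    phase_ispc_map: tuple[str, str, str] = ("A", "B", "A")
    counterbalance: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.trials_per_miniblock % 16 != 0:
            raise ValueError(
                "trials_per_miniblock must be a multiple of 16 (the 3/1 "
                "stimulus-count template has 16 slots)"
            )
        p1, p2, p3 = self.phase_ispc_map
        if p2 == p1:
            raise ValueError("phase 2 must flip the ISPC assignment of phase 1")
        if p3 != p1:
            raise ValueError("phase 3 must restore the ISPC assignment of phase 1")
        if not math.isclose(self.mc_proportion, 0.75):
            raise ValueError(
                "only the 75/25 proportion is expressible as the 16-trial template"
            )


def _miniblock_stimuli(mc_set: str, scale: int) -> list[tuple[str, str]]:
    """Stimulus list for one mini-block given which set is MC.

    The MC set contributes each of its 2 congruent stimuli 3x and each of
    its 2 incongruent stimuli 1x; the MI set the reverse.  ``scale``
    multiplies every count (16 * scale trials).
    """
    out: list[tuple[str, str]] = []
    for color, word in STIMULI:
        congruent = color == word
        in_mc = SET_OF_COLOR[color] == mc_set
        count = 3 if congruent == in_mc else 1
        out.extend([(color, word)] * (count * scale))
    return out


def generate_design(cfg: DesignConfig) -> pd.DataFrame:
    """Generate the full trial table (without RT/accuracy) for all subjects.

    Deterministic given ``cfg.seed``.  Trial order is shuffled within each
    mini-block.  With counterbalancing, odd subject indices run the flipped
    set-to-MC assignment in phase 1.
    """
    cfg.validate()
    scale = cfg.trials_per_miniblock // 16
    cond = condition_table().set_index(["ispc", "color", "word"])
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    rows = []
    for subj in range(cfg.n_subjects):
        rng = np.random.default_rng(streams[subj])
        phase_map = list(cfg.phase_ispc_map)
        if cfg.counterbalance and subj % 2 == 1:
            phase_map = ["B" if s == "A" else "A" for s in phase_map]
        for phase, (n_mb, mc_set) in enumerate(
            zip(cfg.miniblocks_per_phase, phase_map), start=1
        ):
            for mb in range(n_mb):
                stimuli = _miniblock_stimuli(mc_set, scale)
                order = rng.permutation(len(stimuli))
                for pos, k in enumerate(order):
                    color, word = stimuli[k]
                    ispc = "mc" if SET_OF_COLOR[color] == mc_set else "mi"
                    rows.append((subj, phase, mb, pos, color, word, ispc))
    trials = pd.DataFrame(
        rows,
        columns=["subject_id", "phase", "miniblock", "trial", "color", "word", "ispc"],
    )
    meta = cond.loc[
        pd.MultiIndex.from_frame(trials[["ispc", "color", "word"]])
    ].reset_index(drop=True)
    for c in [
        "set",
        "congruency",
        "condition_id",
        "sc_class",
        "most_likely_response",
        "sr_class",
        "frequency",
        "correct_response",
    ]:
        trials[c] = meta[c].to_numpy()
    return trials


# ---------------------------------------------------------------------------
# Neural encoding model
# ---------------------------------------------------------------------------

#: Default amplitudes (arbitrary sensor units at envelope peak) and latency
#: windows (ms after stimulus onset) per encoded factor.
DEFAULT_AMPLITUDES: dict[str, float] = {
    "color": 1.2,
    "word": 1.0,
    "set": 0.5,
    "congruency": 0.6,
    "ispc": 0.6,
    "sc": 1.5,
    "sr": 1.5,
}
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "color": (80.0, 1200.0),
    "word": (100.0, 1000.0),
    "set": (100.0, 800.0),
    "congruency": (150.0, 1000.0),
    "ispc": (150.0, 1000.0),
    "sc": (150.0, 900.0),
    "sr": (150.0, 900.0),
}

_FACTOR_LEVELS: dict[str, list] = {
    "color": list(COLORS),
    "word": list(COLORS),
    "set": list(SETS),
    "congruency": ["congruent", "incongruent"],
    "ispc": ["mc", "mi"],
    "sc": list(range(1, 9)),
    "sr": list(range(1, 9)),
}
_FACTOR_COLUMN: dict[str, str] = {
    "color": "color",
    "word": "word",
    "set": "set",
    "congruency": "congruency",
    "ispc": "ispc",
    "sc": "sc_class",
    "sr": "sr_class",
}


@dataclass
class EncodingConfig:
    n_channels: int = 64
    sfreq: float = 50.0
    tmin_ms: float = -200.0
    tmax_ms: float = 1500.0
    overlap_fraction: float = 0.5  # spatial dimensions shared by SC and SR families
    coupling: bool = True  # one latent gain multiplies both SC and SR amplitudes
    noise_sd: float = 1.0
    gain_sigma: float = 1.0  # log-normal sigma; the gain has mean 1
    amplitudes: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )

    @property
    def times(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        return np.arange(self.tmin_ms, self.tmax_ms + 0.5 * step, step)


@dataclass
class EncodingModel:
    """Factor-specific spatial patterns and latency windows."""

    cfg: EncodingConfig
    patterns: dict[str, np.ndarray]  # factor -> (n_levels, n_channels), unit rows
    shared_rank: int  # dimensions shared between SC and SR families

    def envelope(self, factor: str, times: np.ndarray) -> np.ndarray:
        """Nonnegative Hann envelope over the factor's latency window.

        Zero before stimulus onset and outside the window.
        """
        on, off = self.cfg.windows[factor]
        e = np.zeros_like(times, dtype=float)
        inside = (times >= on) & (times <= off)
        e[inside] = np.sin(np.pi * (times[inside] - on) / (off - on)) ** 2
        return e


def generate_encoding_model(cfg: EncodingConfig, seed: int = 0) -> EncodingModel:
    """Draw orthonormal spatial patterns for every encoded factor.

    All non-association factors get mutually orthogonal patterns.  The SC
    and SR families (8 patterns each) share exactly
    ``round(overlap_fraction * 8)`` basis directions; each family is then
    rotated within its own span so that individual SC and SR patterns do
    not coincide even at full overlap.
    """
    n_shared = int(round(cfg.overlap_fraction * 8))
    other = ["color", "word", "set", "congruency", "ispc"]
    n_other = sum(len(_FACTOR_LEVELS[f]) for f in other)
    total = n_other + 16 - n_shared
    if cfg.n_channels < total:
        raise ValueError(
            f"n_channels={cfg.n_channels} cannot hold {total} orthogonal pattern "
            "dimensions; increase channels or overlap_fraction"
        )
    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.standard_normal((cfg.n_channels, total)))
    patterns: dict[str, np.ndarray] = {}
    k = 0
    for f in other:
        n = len(_FACTOR_LEVELS[f])
        patterns[f] = basis[:, k : k + n].T.copy()
        k += n
    sc_basis = basis[:, k : k + 8]
    k += 8
    fresh = basis[:, k : k + 8 - n_shared]
    sr_basis = np.hstack([sc_basis[:, :n_shared], fresh])

    def rotate(fam: np.ndarray) -> np.ndarray:
        q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        return (fam @ q).T  # rows are unit-norm patterns

    patterns["sc"] = rotate(sc_basis)
    patterns["sr"] = rotate(sr_basis)
    return EncodingModel(cfg=cfg, patterns=patterns, shared_rank=n_shared)


def generate_epochs(
    design: pd.DataFrame, model: EncodingModel, seed: int = 0
) -> tuple[EpochSet, pd.DataFrame]:
    """Synthesize stimulus-locked epochs for every trial of *design*.

    Each trial's signal is the sum over factors of
    ``amplitude * envelope(t) * pattern(level)``, the SC and SR terms
    additionally multiplied by the trial's latent gain when coupling is on
    (when off, two independent gains are drawn).  Gaussian sensor noise is
    added everywhere, so pre-stimulus samples carry noise only.  The latent
    gain is written back into the returned copy of the trial table.
    """
    cfg = model.cfg
    times = cfg.times
    n_trials = len(design)
    design = design.reset_index(drop=True).copy()
    subjects = design["subject_id"].to_numpy()
    uniq = np.unique(subjects)
    streams = dict(zip(uniq, np.random.SeedSequence(seed).spawn(len(uniq))))

    data = np.empty((n_trials, cfg.n_channels, times.size))
    mu = -0.5 * cfg.gain_sigma**2  # log-normal location giving mean 1
    gain_sc = np.empty(n_trials)
    gain_sr = np.empty(n_trials)
    for s in uniq:
        m = subjects == s
        rng = np.random.default_rng(streams[s])
        data[m] = rng.standard_normal((int(m.sum()), cfg.n_channels, times.size))
        data[m] *= cfg.noise_sd
        g = rng.lognormal(mu, cfg.gain_sigma, size=int(m.sum()))
        gain_sc[m] = g
        gain_sr[m] = g if cfg.coupling else rng.lognormal(mu, cfg.gain_sigma, size=int(m.sum()))

    for f, levels in _FACTOR_LEVELS.items():
        amp = cfg.amplitudes.get(f, 0.0)
        if amp == 0.0:
            continue
        env = model.envelope(f, times)
        level_idx = design[_FACTOR_COLUMN[f]].map({lv: i for i, lv in enumerate(levels)})
        pat = model.patterns[f][level_idx.to_numpy()]  # (n_trials, n_channels)
        g = gain_sc if f == "sc" else gain_sr if f == "sr" else np.ones(n_trials)
        data += (amp * g)[:, None, None] * pat[:, :, None] * env[None, None, :]

    design["latent_gain"] = gain_sc
    if not cfg.coupling:
        design["latent_gain_sr"] = gain_sr
    epochs = EpochSet(data, cfg.sfreq, times, "stimulus")
    return epochs, design


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


@dataclass
class BehaviorConfig:
    """Reaction-time and accuracy model.

    RT = exp(log(base + conflict) + noise) + gain_slope * latent_gain, with
    the conflict cost shrunk by ``ispc_modulation`` on MI trials (producing
    the smaller MI congruency effect) and responses slower than the 1500 ms
    deadline marked missing.
    """

    rt_base: float = 720.0
    conflict_cost: float = 80.0
    ispc_modulation: float = 0.4
    gain_slope: float = -60.0  # ms per unit latent gain (negative: faster)
    rt_noise_sd: float = 0.15  # sd on the log scale
    deadline_ms: float = 1500.0
    gain_sigma: float = 1.0  # used only when the table has no latent_gain yet
    #: error probability per (congruency, ispc) cell
    error_rates: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("congruent", "mc"): 0.02,
            ("congruent", "mi"): 0.04,
            ("incongruent", "mc"): 0.10,
            ("incongruent", "mi"): 0.06,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.rt_base <= 0:
            raise ValueError("rt_base must be positive")
        if not all(0.0 <= p <= 1.0 for p in self.error_rates.values()):
            raise ValueError("error probabilities must lie in [0, 1]")


def generate_behavior(design: pd.DataFrame, cfg: BehaviorConfig) -> pd.DataFrame:
    """Sample RT and accuracy for every trial; returns an augmented copy.

    Uses the table's ``latent_gain`` column when present (so behavior and
    epochs share the same trial gain); otherwise draws gains from the
    configured log-normal.
    """
    cfg.validate()
    design = design.reset_index(drop=True).copy()
    n = len(design)
    subjects = design["subject_id"].to_numpy()
    uniq = np.unique(subjects)
    streams = dict(zip(uniq, np.random.SeedSequence(cfg.seed).spawn(len(uniq))))
    rngs = {s: np.random.default_rng(streams[s]) for s in uniq}

    if "latent_gain" not in design.columns:
        gains = np.empty(n)
        for s in uniq:
            m = subjects == s
            gains[m] = rngs[s].lognormal(
                -0.5 * cfg.gain_sigma**2, cfg.gain_sigma, int(m.sum())
            )
        design["latent_gain"] = gains

    incong = (design["congruency"] == "incongruent").to_numpy()
    mi = (design["ispc"] == "mi").to_numpy()
    conflict = cfg.conflict_cost * incong * np.where(mi, cfg.ispc_modulation, 1.0)
    rt = np.empty(n)
    acc = np.empty(n, dtype=int)
    err_p = np.array(
        [cfg.error_rates[(c, i)] for c, i in zip(design["congruency"], design["ispc"])]
    )
    for s in uniq:
        m = subjects == s
        rng = rngs[s]
        noise = rng.normal(0.0, cfg.rt_noise_sd, int(m.sum()))
        rt[m] = np.exp(np.log(cfg.rt_base + conflict[m]) + noise)
        rt[m] += cfg.gain_slope * design.loc[m, "latent_gain"].to_numpy()
        acc[m] = (rng.random(int(m.sum())) >= err_p[m]).astype(int)
    rt = np.maximum(rt, 1.0)  # truncate to (0, deadline]
    missed = rt > cfg.deadline_ms
    rt[missed] = np.nan
    acc[missed] = 0
    design["rt"] = rt
    design["accuracy"] = acc
    return design
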