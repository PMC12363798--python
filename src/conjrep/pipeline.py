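"""One-command reproduction of the full synthetic study.

Stages: simulate -> behavior -> decode (stimulus- and optionally
response-locked) -> subspace (+ overlap simulation) -> rsa (+ coupling) ->
lmm.  Every table goes to TSV, arrays to .npy/.npz with JSON sidecars, and
a run log records the seed and stage wall times.  Completed stages are
skipped on resume when their outputs already exist.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import brain_behavior as bb
from . import rsa as rsa_mod
from . import subspace as sub
from .containers import EpochSet, read_trials, to_response_locked, write_trials
from .decoding import CvScheme, decode_timecourse, group_significance
from .simulate import (
    BehaviorConfig,
    DesignConfig,
    EncodingConfig,
    generate_behavior,
    generate_design,
    generate_encoding_model,
    generate_epochs,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "conjrep_out"
    design: DesignConfig = field(default_factory=DesignConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    scheme: CvScheme = field(default_factory=CvScheme)
    overlap: sub.OverlapSimConfig = field(default_factory=sub.OverlapSimConfig)
    alpha_decoding: float = 0.001
    alpha_coupling: float = 0.05
    response_locked: bool = False
    run_cross_subspace: bool = True
    overlap_grid: tuple[int, ...] = (0, 4, 8)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key, sub_cls in [
            ("design", DesignConfig),
            ("encoding", EncodingConfig),
            ("behavior", BehaviorConfig),
            ("scheme", CvScheme),
            ("overlap", sub.OverlapSimConfig),
        ]:
            if key in kwargs and isinstance(kwargs[key], dict):
                section = dict(kwargs[key])
                for tup_key in ("miniblocks_per_phase", "phase_ispc_map"):
                    if tup_key in section and isinstance(section[tup_key], list):
                        section[tup_key] = tuple(section[tup_key])
                if "error_rates" in section and isinstance(section["error_rates"], dict):
                    section["error_rates"] = {
                        tuple(k.split("/")): v for k, v in section["error_rates"].items()
                    }
                kwargs[key] = sub_cls(**section)
        if "overlap_grid" in kwargs:
            kwargs["overlap_grid"] = tuple(kwargs["overlap_grid"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        for a in (self.alpha_decoding, self.alpha_coupling):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha levels must lie in (0, 1)")
        self.design.validate()


def round_trip(epochs: EpochSet, trials: pd.DataFrame, out_dir: str | Path) -> tuple[EpochSet, pd.DataFrame]:
    """Write both containers and read them back (bitwise for the array)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    epochs.save(out / "epochs")
    write_trials(trials, out / "trials.tsv")
    return EpochSet.load(out / "epochs"), read_trials(out / "trials.tsv")


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Execute the full synthetic study; returns the summary report dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"seed": cfg.seed, "stages": {}}
    current = "setup"

    def done(name: str, *files: str) -> bool:
        return resume and all((out / f).exists() for f in files)

    def tick(name: str) -> None:
        report["stages"][name] = round(time.time() - t0, 2)
        log.info("stage %s done at %.1fs", name, time.time() - t0)

    try:
        # -- simulate -------------------------------------------------------
        current = "simulate"
        if done(current, "trials.tsv", "epochs.npy", "epochs.json"):
            trials = read_trials(out / "trials.tsv")
            epochs = EpochSet.load(out / "epochs")
        else:
            cfg.design.seed = cfg.seed
            trials = generate_design(cfg.design)
            model = generate_encoding_model(cfg.encoding, seed=cfg.seed + 1)
            epochs, trials = generate_epochs(trials, model, seed=cfg.seed + 2)
            cfg.behavior.seed = cfg.seed + 3
            trials = generate_behavior(trials, cfg.behavior)
            write_trials(trials, out / "trials.tsv")
            epochs.save(out / "epochs")
        tick(current)

        # -- behavior -------------------------------------------------------
        current = "behavior"
        filtered = bhv.filter_rt_trials(trials)
        rows = []
        for phase in (1, 2, 3):
            anova = bhv.rm_anova_2x2(filtered, phase, "rt")
            contrast = bhv.ispc_conflict_contrast(filtered, phase, "rt")
            for r in anova.values():
                rows.append(
                    {
                        "phase": phase,
                        "effect": r.effect,
                        "F": r.F,
                        "df1": r.df[0],
                        "df2": r.df[1],
                        "p": r.p,
                        "partial_eta_sq": r.partial_eta_sq,
                    }
                )
            report.setdefault("behavior", {})[f"phase{phase}"] = {
                "interaction_F": anova["interaction"].F,
                "contrast_t": contrast.t,
                "contrast_d": contrast.cohens_d,
            }
        pd.DataFrame(rows).to_csv(out / "behavior_anova.tsv", sep="\t", index=False)
        tick(current)

        # -- decode ---------------------------------------------------------
        current = "decode"
        dec = decode_timecourse(epochs, trials, scheme=cfg.scheme)
        dec.accuracy_frame().to_csv(out / "decoding_accuracy.tsv", sep="\t", index=False)
        np.savez(
            out / "decoding_arrays.npz",
            trial_logit_probs=dec.trial_logit_probs,
            trial_index=dec.trial_index,
            confusion=dec.confusion,
            classes=dec.classes,
            times=dec.times,
        )
        mask = group_significance(dec.accuracy, dec.chance, cfg.alpha_decoding)
        report["decoding"] = {
            "chance": dec.chance,
            "mean_accuracy": float(dec.accuracy.mean()),
            "n_sig_timepoints": int(mask.sum()),
        }
        locks = {"stimulus": (dec, trials)}
        if cfg.response_locked:
            r_epochs, r_trials = to_response_locked(epochs, trials)
            r_dec = decode_timecourse(r_epochs, r_trials, scheme=cfg.scheme)
            r_dec.accuracy_frame().to_csv(
                out / "decoding_accuracy_resp.tsv", sep="\t", index=False
            )
            locks["response"] = (r_dec, r_trials)
        tick(current)

        # -- subspace -------------------------------------------------------
        current = "subspace"
        grid = sub.simulate_overlap(
            dataclasses.replace(cfg.overlap, seed=cfg.seed + 4), list(cfg.overlap_grid)
        )
        grid.to_csv(out / "overlap_simulation.tsv", sep="\t", index=False)
        mds = sub.classical_mds(dec.confusion.mean(axis=0))
        if not mds.empty:
            pd.DataFrame(
                mds.coordinates, columns=[f"dim{i+1}" for i in range(mds.coordinates.shape[1])]
            ).to_csv(out / "mds_coordinates.tsv", sep="\t", index=False)
            report["mds_cumulative_explained"] = mds.cumulative_explained.tolist()
        if cfg.run_cross_subspace:
            xres = sub.cross_subspace_decode(
                epochs, trials, scheme=cfg.scheme, alpha=cfg.alpha_decoding
            )
            xres.frame().to_csv(out / "cross_subspace.tsv", sep="\t", index=False)
            report["cross_subspace"] = {
                k: float(v.mean()) for k, v in xres.accuracy.items()
            }
        tick(current)

        # -- rsa ------------------------------------------------------------
        current = "rsa"
        for lock, (d, tr) in locks.items():
            suffix = "" if lock == "stimulus" else "_resp"
            cids = tr["condition_id"].to_numpy()[d.trial_index]
            subjects = tr["subject_id"].to_numpy()[d.trial_index]
            res = rsa_mod.trialwise_rsa(d.trial_logit_probs, cids, d.times)
            group = rsa_mod.group_rsa(res, subjects, alpha=cfg.alpha_decoding)
            group.to_csv(out / f"rsa_group{suffix}.tsv", sep="\t", index=False)
            coup = rsa_mod.sc_sr_coupling(
                res.strength("sc"),
                res.strength("sr"),
                subjects,
                d.times,
                alpha=cfg.alpha_coupling,
                condition_ids=cids,
            )
            coup.frame().to_csv(out / f"coupling{suffix}.tsv", sep="\t", index=False)
            if lock == "stimulus":
                stim_res, stim_subjects, stim_tr, stim_dec = res, subjects, tr, d
                report["rsa"] = {
                    "sc_sig_timepoints": int(
                        group.query("regressor == 'sc' and sig").shape[0]
                    ),
                    "sr_sig_timepoints": int(
                        group.query("regressor == 'sr' and sig").shape[0]
                    ),
                    "coupling_sig_timepoints": int(coup.mask.sum()),
                }
        tick(current)

        # -- lmm ------------------------------------------------------------
        current = "lmm"
        strengths = np.stack(
            [stim_res.strength("sc"), stim_res.strength("sr")], axis=2
        )
        lmm_trials = stim_tr.iloc[stim_dec.trial_index].reset_index(drop=True)
        results = bb.lmm_timecourse(
            strengths, ["sc", "sr"], lmm_trials, stim_dec.times, lock="stimulus"
        )
        bb.timecourse_frame(results).to_csv(out / "lmm_timecourse.tsv", sep="\t", index=False)
        if results:
            peaks = bb.timecourse_frame(results)
            sc_rows = peaks[peaks.predictor == "sc"]
            report["lmm"] = {
                "n_timepoints": len(results),
                "sc_min_b": float(sc_rows.b.min()) if len(sc_rows) else None,
            }
        tick(current)
    except Exception as e:
        report["failed_stage"] = current
        (out / "report.json").write_text(json.dumps(report, indent=2))
        raise RuntimeError(f"pipeline failed in stage {current!r}: {e}") from e

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
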