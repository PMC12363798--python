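"""Behavioral statistics: RT trial filtering, 2x2 repeated-measures ANOVA,
and the paired ISPC conflict contrast.

RTs are analyzed on correct trials within +/-3 SD of each subject's mean;
each phase is tested with a 2 (Congruency) x 2 (ISPC) within-subject ANOVA
on RT or error rate, and the ISPC effect (smaller conflict cost on mostly
incongruent items) is summarized by a paired t-test on the per-subject
difference between the MC and MI congruency effects.  For a 2x2
within-subject design the interaction F equals the square of that paired t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

log = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    effect: str
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float


@dataclass
class PairedContrast:
    t: float
    df: int
    p: float
    cohens_d: float


def filter_rt_trials(
    trials: pd.DataFrame, n_sd: float = 3.0, per_phase: bool = False
) -> pd.DataFrame:
    """Keep correct trials within ``n_sd`` SD of each subject's mean RT.

    Mean and SD are computed per subject over all correct responded trials
    before any removal (a single pass); with ``per_phase`` the bounds are
    computed within each phase instead of over the whole session.  Subjects
    with fewer than two correct trials are excluded with a warning.
    """
    correct = trials[(trials["accuracy"] == 1) & trials["rt"].notna()].copy()
    group_cols = ["subject_id", "phase"] if per_phase else ["subject_id"]
    counts = correct.groupby("subject_id")["rt"].size()
    bad = counts[counts < 2].index
    if len(bad):
        log.warning("excluding subjects with < 2 correct trials: %s", list(bad))
        correct = correct[~correct["subject_id"].isin(bad)]
    g = correct.groupby(group_cols)["rt"]
    mean = g.transform("mean")
    sd = g.transform("std").fillna(0.0)
    keep = (correct["rt"] - mean).abs() <= n_sd * sd
    return correct[keep].reset_index(drop=True)


def _cell_means(
    trials: pd.DataFrame, phase: int, measure: str
) -> pd.DataFrame:
    """Per-subject means of the 4 Congruency x ISPC cells in one phase.

    ``measure="rt"`` averages RT (caller supplies a filtered table);
    ``measure="error_rate"`` averages ``1 - accuracy`` over all trials.
    Subjects missing any cell are dropped with a warning.
    """
    sub = trials[trials["phase"] == phase].copy()
    if measure == "rt":
        sub["y"] = sub["rt"]
    elif measure == "error_rate":
        sub["y"] = 1 - sub["accuracy"]
    else:
        raise ValueError(f"unknown measure {measure!r}")
    cells = (
        sub.groupby(["subject_id", "congruency", "ispc"])["y"].mean().reset_index()
    )
    n_cells = cells.groupby("subject_id").size()
    bad = n_cells[n_cells < 4].index
    if len(bad):
        log.warning("dropping subjects with missing cells in phase %d: %s", phase, list(bad))
        cells = cells[~cells["subject_id"].isin(bad)]
    return cells


def rm_anova_2x2(
    trials: pd.DataFrame, phase: int, measure: str = "rt"
) -> dict[str, AnovaResult]:
    """2 (Congruency) x 2 (ISPC) within-subject ANOVA on one phase.

    Returns results keyed ``"congruency"``, ``"ispc"``, and
    ``"interaction"``; partial eta squared is F*df1 / (F*df1 + df2).
    """
    cells = _cell_means(trials, phase, measure)
    if cells["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 complete subjects")
    table = AnovaRM(
        cells, depvar="y", subject="subject_id", within=["congruency", "ispc"]
    ).fit().anova_table
    out = {}
    for key, row_name in [
        ("congruency", "congruency"),
        ("ispc", "ispc"),
        ("interaction", "congruency:ispc"),
    ]:
        F = float(table.loc[row_name, "F Value"])
        df1 = int(table.loc[row_name, "Num DF"])
        df2 = int(table.loc[row_name, "Den DF"])
        p = float(table.loc[row_name, "Pr > F"])
        out[key] = AnovaResult(
            effect=key,
            F=F,
            df=(df1, df2),
            p=p,
            partial_eta_sq=F * df1 / (F * df1 + df2),
        )
    return out


def ispc_conflict_contrast(
    trials: pd.DataFrame, phase: int, measure: str = "rt"
) -> PairedContrast:
    """Paired t on the MC-minus-MI difference of per-subject conflict effects.

    The conflict effect is the incongruent-minus-congruent cell-mean
    difference; a positive t means the MC conflict effect exceeds the MI
    one (the ISPC effect).  Cohen's d is the mean paired difference over
    its SD.
    """
    cells = _cell_means(trials, phase, measure)
    wide = cells.pivot_table(
        index="subject_id", columns=["ispc", "congruency"], values="y"
    )
    conflict_mc = wide[("mc", "incongruent")] - wide[("mc", "congruent")]
    conflict_mi = wide[("mi", "incongruent")] - wide[("mi", "congruent")]
    diffs = (conflict_mc - conflict_mi).to_numpy()
    n = diffs.size
    if n < 2:
        raise ValueError("need at least 2 complete subjects")
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if diffs.mean() == 0.0 else np.inf * np.sign(diffs.mean())
        p = 1.0 if diffs.mean() == 0.0 else 0.0
        d = 0.0 if diffs.mean() == 0.0 else np.inf * np.sign(diffs.mean())
    else:
        t, p = stats.ttest_1samp(diffs, 0.0)
        d = diffs.mean() / sd
    return PairedContrast(t=float(t), df=n - 1, p=float(p), cohens_d=float(d))


def anova_to_frame(results: dict[str, AnovaResult]) -> pd.DataFrame:
    """Flatten ANOVA results to the TSV layout used by the CLI."""
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "F": r.F,
                "df1": r.df[0],
                "df2": r.df[1],
                "p": r.p,
                "partial_eta_sq": r.partial_eta_sq,
            }
            for r in results.values()
        ]
    )
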