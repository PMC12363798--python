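"""Regression-based representational similarity analysis on decoding results.

The dependent variable at each trial and timepoint is the 16-vector of
logit-transformed classifier posteriors.  Model similarity patterns are
binary 16-cell regressors built from the factorial design: for each factor
(color, word, congruency, ISPC, SC, SR) a cell is 1 iff that condition
shares the factor's level with the condition of the current trial.  Two
nuisance regressors mark the trial's own condition (identity) and the
conditions sharing its frequent/infrequent status.  An ordinary least
squares fit per trial and timepoint yields trial-wise t values per
regressor (the "representational strength"), which feed group tests, the
collinearity (VIF) screen, and the SC-SR cross-trial coupling statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .conditions import sharing_matrix

#: fixed regressor order
REGRESSORS = ("color", "word", "congruency", "ispc", "sc", "sr", "identity", "frequency")


def build_regressors(
    condition_id: int, include: tuple[str, ...] = REGRESSORS
) -> pd.DataFrame:
    """16-row design matrix (intercept + binary sharing columns) for a trial.

    Deterministic in ``condition_id``; cell (row c, regressor f) is 1 iff
    condition c shares factor f's level with the trial's condition.
    """
    if not 1 <= int(condition_id) <= 16:
        raise ValueError(f"condition_id must be 1..16, got {condition_id}")
    cols = {"intercept": np.ones(16)}
    for f in include:
        cols[f] = sharing_matrix(f)[int(condition_id) - 1]
    return pd.DataFrame(cols)


def compute_vif(X: pd.DataFrame | np.ndarray, columns: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    R^2_j comes from regressing column j on the remaining columns with an
    intercept.  Perfectly collinear columns report +inf.
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if columns is None:
            columns = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    out = {}
    for j, name in enumerate(columns):
        others = sm.add_constant(np.delete(X, j, axis=1), has_constant="add")
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class RsaTrialResult:
    """Trial x timepoint x regressor OLS results (b, SE, t)."""

    b: np.ndarray
    se: np.ndarray
    t: np.ndarray
    regressors: tuple[str, ...]
    times: np.ndarray
    condition_ids: np.ndarray
    dropped: tuple[str, ...] = field(default=())

    def strength(self, regressor: str, kind: str = "t") -> np.ndarray:
        j = self.regressors.index(regressor)
        return {"t": self.t, "b": self.b}[kind][:, :, j]


def trialwise_rsa(
    logit_probs: np.ndarray,
    condition_ids: np.ndarray,
    times: np.ndarray,
    include: tuple[str, ...] = REGRESSORS,
    vif_threshold: float | None = None,
) -> RsaTrialResult:
    """OLS of the 16 logits on intercept + binary regressors, per trial/timepoint.

    Degrees of freedom are ``16 - n_parameters`` (7 with the full
    eight-regressor set).  With ``vif_threshold`` set, columns whose VIF
    exceeds it (computed on the trial's design) are dropped before fitting
    and recorded in ``dropped``; a rank-deficient design triggers the same
    policy at threshold 5.
    """
    logit_probs = np.asarray(logit_probs, dtype=float)
    if not np.all(np.isfinite(logit_probs)):
        raise ValueError("logit probabilities must be finite")
    n, T, _ = logit_probs.shape
    condition_ids = np.asarray(condition_ids)

    X0 = build_regressors(int(condition_ids[0]), include)
    keep = list(include)
    dropped: tuple[str, ...] = ()
    threshold = vif_threshold
    if threshold is None and np.linalg.matrix_rank(X0.to_numpy()) < X0.shape[1]:
        threshold = 5.0
    if threshold is not None:
        # flag at or above the threshold (the identity regressor sits exactly
        # at VIF = 5 on the enumerated 16-condition design)
        vif = compute_vif(X0[list(include)])
        dropped = tuple(r for r in include if vif[r] >= threshold - 1e-6)
        keep = [r for r in include if r not in dropped]

    R = len(keep)
    b = np.empty((n, T, R))
    se = np.empty((n, T, R))
    df = 16 - (R + 1)
    if df <= 0:
        raise ValueError("design has no residual degrees of freedom")
    for cid in np.unique(condition_ids):
        rows = np.flatnonzero(condition_ids == cid)
        X = build_regressors(int(cid), tuple(keep)).to_numpy()
        XtX_inv = np.linalg.inv(X.T @ X)
        A = XtX_inv @ X.T  # (R+1, 16)
        h = np.diag(XtX_inv)
        Y = logit_probs[rows].reshape(rows.size * T, 16).T  # (16, m*T)
        B = A @ Y
        resid = Y - X @ B
        sigma2 = (resid**2).sum(axis=0) / df
        SE = np.sqrt(np.outer(h, sigma2))
        b[rows] = B[1:].T.reshape(rows.size, T, R)
        se[rows] = SE[1:].T.reshape(rows.size, T, R)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, 0.0)
    return RsaTrialResult(
        b=b,
        se=se,
        t=t,
        regressors=tuple(keep),
        times=np.asarray(times),
        condition_ids=condition_ids,
        dropped=dropped,
    )


def group_rsa(
    result: RsaTrialResult,
    subjects: np.ndarray,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Group-level one-sample t of subject-mean trial t values, per regressor.

    Bonferroni correction across timepoints; returns a long frame with
    columns time_ms, regressor, mean_t, group_t, p, sig.
    """
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("need >= 2 subjects")
    T = result.times.size
    subj_means = np.stack(
        [result.t[subjects == s].mean(axis=0) for s in uniq]
    )  # (S, T, R)
    rows = []
    for ri, reg in enumerate(result.regressors):
        for ti, tm in enumerate(result.times):
            vals = subj_means[:, ti, ri]
            if vals.std(ddof=1) == 0.0:
                gt, p = (np.inf * np.sign(vals.mean()), 0.0) if vals.mean() != 0 else (0.0, 1.0)
            else:
                gt, p = stats.ttest_1samp(vals, 0.0)
            rows.append(
                {
                    "time_ms": tm,
                    "regressor": reg,
                    "mean_t": vals.mean(),
                    "group_t": float(gt),
                    "p": float(p),
                    "sig": bool(p < alpha / T),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CouplingResult:
    """Cross-trial SC-SR strength correlation vs a pre-stimulus baseline."""

    r: np.ndarray  # (n_subjects, n_times)
    baseline_z: np.ndarray  # (n_subjects,)
    times: np.ndarray
    mask: np.ndarray  # True where post-stimulus r is significantly above baseline
    subjects: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times,
                "mean_r": self.r.mean(axis=0),
                "sig_above_baseline": self.mask,
            }
        )


def _pearson_over_trials(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise Pearson r of two (n_trials, T) arrays."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a * b).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def sc_sr_coupling(
    sc_strength: np.ndarray,
    sr_strength: np.ndarray,
    subjects: np.ndarray,
    times: np.ndarray,
    baseline_window: tuple[float, float] = (-200.0, 0.0),
    alpha: float = 0.05,
    condition_ids: np.ndarray | None = None,
    method: str = "spearman",
) -> CouplingResult:
    """Cross-trial correlation of SC and SR strengths, tested against baseline.

    Per subject and timepoint, the correlation across trials between the
    SC and SR trial-wise strengths.  The default is Spearman (rank)
    correlation: trial-wise t values are heavy-tailed (near-perfect fits
    produce huge t), and a handful of such trials dominates a Pearson r;
    ranks keep the statistic monotone-invariant and outlier-robust.  Two
    further guards isolate genuine trial-wise covariation: with
    ``condition_ids`` given, strengths are centered within subject x
    condition first, so condition-level differences in decodability cannot
    masquerade as coupling; and the baseline is the mean Fisher-z
    correlation over pre-stimulus timepoints (inside *baseline_window*),
    absorbing the structural correlation that regression coefficients from
    one shared model carry even for pure noise.  Post-stimulus points are
    tested with a group one-sample t on z(r) - z(baseline),
    Bonferroni-corrected at *alpha*, flagged only when positive.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    subjects = np.asarray(subjects)
    times = np.asarray(times)
    uniq = np.unique(subjects)
    base_pts = (times >= baseline_window[0]) & (times <= baseline_window[1])
    post_pts = times > baseline_window[1]
    if not base_pts.any():
        raise ValueError("baseline window contains no timepoints")
    sc_strength = np.array(sc_strength, dtype=float)
    sr_strength = np.array(sr_strength, dtype=float)
    if condition_ids is not None:
        condition_ids = np.asarray(condition_ids)
        for s in uniq:
            for c in np.unique(condition_ids):
                m = (subjects == s) & (condition_ids == c)
                if m.any():
                    sc_strength[m] -= sc_strength[m].mean(axis=0)
                    sr_strength[m] -= sr_strength[m].mean(axis=0)
    r = np.empty((uniq.size, times.size))
    for si, s in enumerate(uniq):
        m = subjects == s
        if m.sum() < 3:
            raise ValueError(f"subject {s} has fewer than 3 trials")
        a, b = sc_strength[m], sr_strength[m]
        if method == "spearman":
            a = stats.rankdata(a, axis=0)
            b = stats.rankdata(b, axis=0)
        r[si] = _pearson_over_trials(a, b)
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    baseline_z = z[:, base_pts].mean(axis=1)
    mask = np.zeros(times.size, dtype=bool)
    n_post = int(post_pts.sum())
    if uniq.size >= 2 and n_post:
        for t in np.flatnonzero(post_pts):
            d = z[:, t] - baseline_z
            if d.std(ddof=1) == 0.0:
                mask[t] = d.mean() > 0
            else:
                tt, p = stats.ttest_1samp(d, 0.0)
                mask[t] = (tt > 0) and (p < alpha / n_post)
    return CouplingResult(r=r, baseline_z=baseline_z, times=times, mask=mask, subjects=uniq)
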