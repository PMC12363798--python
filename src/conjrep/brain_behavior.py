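"""Trial-wise brain-behavior linkage: mixed models predicting log RT.

At each analysis timepoint, a linear mixed model predicts log-transformed
reaction time from the trial-wise representational strengths (RSA t values,
z-scored within subject) with fixed per-class intercepts (the 8 SC or SR
trial types) and a random intercept per subject, estimated by REML.  For
stimulus-locked analysis only trials that have not yet generated a response
at that timepoint are included; for response-locked analysis only trials
whose stimulus has already appeared.  A negative strength coefficient means
stronger representations go with faster responses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)


@dataclass
class LmmResult:
    time_ms: float
    table: pd.DataFrame  # one row per fixed effect: predictor, b, se, t
    random_intercept_var: float
    n_trials: int

    def coef(self, predictor: str) -> tuple[float, float, float]:
        row = self.table.set_index("predictor").loc[predictor]
        return float(row.b), float(row.se), float(row.t)


def _included(trials: pd.DataFrame, t_ms: float, lock: str) -> np.ndarray:
    rt = trials["rt"].to_numpy(dtype=float)
    ok = np.isfinite(rt)
    if lock == "stimulus":
        return ok & (rt > t_ms)  # response not yet generated
    if lock == "response":
        return ok & (rt >= -t_ms)  # stimulus already on screen
    raise ValueError(f"unknown lock {lock!r}")


def fit_lmm_timepoint(
    strengths: pd.DataFrame,
    trials: pd.DataFrame,
    t_ms: float,
    lock: str = "stimulus",
    class_field: str = "sc_class",
    per_class_slopes: bool = False,
) -> LmmResult:
    """Fit the mixed model at one timepoint.

    ``strengths`` holds one column per strength predictor, row-aligned with
    ``trials``.  Fixed effects are dummy intercepts for the levels of
    ``class_field`` plus the (within-subject z-scored) strength predictors;
    with ``per_class_slopes`` each class gets its own strength slope
    instead of a shared one.  Random effect: subject intercept.  With a
    single subject the model degenerates to OLS with the same fixed design.
    """
    if len(strengths) != len(trials):
        raise ValueError("strengths and trials must be row-aligned")
    inc = _included(trials, t_ms, lock)
    if inc.sum() == 0:
        raise ValueError(f"no trials included at t={t_ms} ms ({lock}-locked)")
    df = trials.loc[inc, ["subject_id", "rt", class_field]].copy()
    y = np.log(df["rt"].to_numpy(dtype=float))
    Z = strengths.loc[inc].copy()
    for s, grp in Z.groupby(df["subject_id"].to_numpy()):
        sd = grp.std(ddof=0).replace(0.0, 1.0)
        Z.loc[grp.index] = (grp - grp.mean()) / sd

    dummies = pd.get_dummies(df[class_field].astype("category"), prefix=class_field)
    names: list[str] = list(dummies.columns)
    blocks = [dummies.to_numpy(dtype=float)]
    for col in Z.columns:
        if per_class_slopes:
            for cls in dummies.columns:
                blocks.append(
                    (Z[col].to_numpy() * dummies[cls].to_numpy(dtype=float))[:, None]
                )
                names.append(f"{col}:{cls}")
        else:
            blocks.append(Z[col].to_numpy()[:, None])
            names.append(col)
    X = np.hstack(blocks)
    groups = df["subject_id"].to_numpy()
    n_subj = np.unique(groups).size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n_subj >= 2:
            fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
            params, bse, tvals = fit.fe_params, fit.bse_fe, fit.tvalues[: X.shape[1]]
            re_var = float(np.asarray(fit.cov_re).ravel()[0])
        else:
            fit = sm.OLS(y, X).fit()
            params, bse, tvals = fit.params, fit.bse, fit.tvalues
            re_var = 0.0
    table = pd.DataFrame(
        {
            "predictor": names,
            "b": np.asarray(params)[: len(names)],
            "se": np.asarray(bse)[: len(names)],
            "t": np.asarray(tvals)[: len(names)],
        }
    )
    return LmmResult(
        time_ms=float(t_ms),
        table=table,
        random_intercept_var=re_var,
        n_trials=int(inc.sum()),
    )


def lmm_timecourse(
    strengths: np.ndarray,
    predictor_names: list[str],
    trials: pd.DataFrame,
    times: np.ndarray,
    lock: str = "stimulus",
    t_max: float | None = None,
    class_field: str = "sc_class",
    per_class_slopes: bool = False,
) -> list[LmmResult]:
    """Fit the mixed model at every analysis timepoint.

    ``strengths`` is trials x timepoints x predictors.  Stimulus-locked,
    only timepoints from 0 up to (but excluding) ``t_max`` are analyzed;
    ``t_max`` defaults to the grand-mean RT of the supplied trials.
    Response-locked, the full window is used.  Timepoints where the fit is
    impossible (e.g. all trials excluded) are skipped with a log entry.
    """
    times = np.asarray(times)
    if lock == "stimulus":
        if t_max is None:
            t_max = float(np.nanmean(trials["rt"].to_numpy(dtype=float)))
        use = (times >= 0) & (times < t_max)
    else:
        use = np.ones(times.size, dtype=bool)
    out: list[LmmResult] = []
    for ti in np.flatnonzero(use):
        S = pd.DataFrame(strengths[:, ti, :], columns=predictor_names)
        try:
            out.append(
                fit_lmm_timepoint(
                    S,
                    trials,
                    float(times[ti]),
                    lock=lock,
                    class_field=class_field,
                    per_class_slopes=per_class_slopes,
                )
            )
        except (ValueError, np.linalg.LinAlgError) as e:
            log.info("skipping timepoint %.0f ms: %s", times[ti], e)
    return out


def timecourse_frame(results: list[LmmResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for _, row in r.table.iterrows():
            rows.append(
                {
                    "time_ms": r.time_ms,
                    "predictor": row["predictor"],
                    "b": row["b"],
                    "se": row["se"],
                    "t": row["t"],
                    "n_trials": r.n_trials,
                }
            )
    return pd.DataFrame(rows)
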