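"""Time-resolved multiclass linear discriminant decoding.

The decoder is Gaussian LDA with a shared within-class covariance,
regularized by analytic (Ledoit-Wolf) shrinkage toward a scaled identity:
``(1 - lambda) S + lambda tr(S)/p I``.  With 64 sensor features and a few
hundred trials per class the raw pooled covariance is ill-conditioned, so
shrinkage is on by default.  Posteriors come from Bayes' rule with equal
priors (softmax over the linear discriminant scores).

Cross-validation follows a frequency-balanced scheme: the frequent trial
types (3x as many trials as the infrequent ones under the 75/25 ISPC
manipulation) are randomly split into three parts, and each part joined
with all infrequent trials forms one decoding subset.  Ten random
partitions times three parts give 30 repetitions of a stratified 4-fold CV.
The covariance/solve steps are vectorized across timepoints, which makes
the per-timepoint loop of the published procedure tractable at test scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

# Posterior clipping bound before the logit transform.  Kept small: sharp
# posteriors still carry condition structure in their tails, and a harsh
# bound flattens exactly the most informative (high-gain) trials.
LOGIT_CLIP = 1e-12


# ---------------------------------------------------------------------------
# Core LDA
# ---------------------------------------------------------------------------


def _ledoit_wolf_lambda(centered: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Analytic shrinkage intensity per timepoint.

    ``centered``: (n, p, T) class-centered samples; ``S``: (T, p, p) their
    biased pooled covariance.  Returns lambda in [0, 1] per timepoint.
    """
    n, p, _ = centered.shape
    mu = np.trace(S, axis1=1, axis2=2) / p  # (T,)
    s_norm2 = np.einsum("tpq,tpq->t", S, S)
    d2 = (s_norm2 - p * mu**2) / p
    sq_norms = np.einsum("npt,npt->nt", centered, centered)  # ||z_k||^2
    beta_num = (np.sum(sq_norms**2, axis=0) - n * s_norm2) / (n**2 * p)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(d2 > 0, np.minimum(beta_num, d2) / np.where(d2 > 0, d2, 1.0), 0.0)
    return np.clip(lam, 0.0, 1.0)


def _lda_train_predict(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    shrinkage: str | float = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Fit shared-covariance LDA per timepoint and return test posteriors.

    Xtr: (n, p, T), Xte: (m, p, T).  Returns (classes, probs (m, T, C)).
    """
    classes, inv = np.unique(ytr, return_inverse=True)
    C = classes.size
    n, p, T = Xtr.shape
    ind = np.zeros((n, C))
    ind[np.arange(n), inv] = 1.0
    counts = ind.sum(axis=0)
    means = np.einsum("nc,npt->cpt", ind, Xtr) / counts[:, None, None]
    centered = Xtr - means[inv]
    Z = centered.transpose(2, 0, 1)  # (T, n, p)
    S = Z.transpose(0, 2, 1) @ Z / n  # biased pooled covariance per timepoint
    if shrinkage == "auto":
        lam = _ledoit_wolf_lambda(centered, S)
    else:
        lam = np.full(T, float(shrinkage))
    mu = np.trace(S, axis1=1, axis2=2) / p
    S_sh = (1.0 - lam)[:, None, None] * S
    S_sh[:, np.arange(p), np.arange(p)] += (lam * mu)[:, None]
    try:
        W = np.linalg.solve(S_sh, means.transpose(2, 1, 0))  # (T, p, C)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "singular pooled covariance; use shrinkage > 0 (e.g. 'auto')"
        ) from e
    bias = -0.5 * np.einsum("cpt,tpc->tc", means, W)  # equal priors
    scores = np.einsum("mpt,tpc->mtc", Xte, W) + bias[None]
    scores -= scores.max(axis=2, keepdims=True)
    probs = np.exp(scores)
    probs /= probs.sum(axis=2, keepdims=True)
    return classes, probs


@dataclass
class LdaModel:
    """A fitted single-timepoint LDA (shared shrunk covariance, equal priors)."""

    classes: np.ndarray
    means: np.ndarray  # (C, p)
    covariance: np.ndarray  # (p, p), after shrinkage
    shrinkage: float
    priors: np.ndarray  # (C,), uniform
    weights: np.ndarray  # (C, p): Sigma^-1 mu_c
    biases: np.ndarray  # (C,): -0.5 mu_c' Sigma^-1 mu_c

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights.T + self.biases

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        s = self.decision_scores(X)
        s -= s.max(axis=1, keepdims=True)
        p = np.exp(s)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax takes the lowest class index on ties
        return self.classes[np.argmax(self.decision_scores(X), axis=1)]


def fit_lda(X: np.ndarray, y: np.ndarray, shrinkage: str | float = "auto") -> LdaModel:
    """Fit LDA on a samples x features matrix.

    Requires at least 2 samples per class and finite features.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")
    n, p = X.shape
    inv = np.searchsorted(classes, y)
    means = np.stack([X[inv == c].mean(axis=0) for c in range(classes.size)])
    centered = X - means[inv]
    S = centered.T @ centered / n
    if shrinkage == "auto":
        lam = float(_ledoit_wolf_lambda(centered[:, :, None], S[None])[0])
    else:
        lam = float(shrinkage)
    S_sh = (1.0 - lam) * S + lam * (np.trace(S) / p) * np.eye(p)
    try:
        W = np.linalg.solve(S_sh, means.T).T  # (C, p)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "singular pooled covariance; use shrinkage > 0 (e.g. 'auto')"
        ) from e
    biases = -0.5 * np.einsum("cp,cp->c", means, W)
    return LdaModel(
        classes=classes,
        means=means,
        covariance=S_sh,
        shrinkage=lam,
        priors=np.full(classes.size, 1.0 / classes.size),
        weights=W,
        biases=biases,
    )


# ---------------------------------------------------------------------------
# Cross-validation scheme
# ---------------------------------------------------------------------------


@dataclass
class CvScheme:
    n_folds: int = 4
    n_partitions: int = 10
    parts_per_partition: int = 3
    stratified: bool = True
    seed: int = 0

    @property
    def n_repetitions(self) -> int:
        return self.n_partitions * self.parts_per_partition


def balanced_partitions(
    trials: pd.DataFrame, scheme: CvScheme, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Frequency-balanced decoding subsets for one subject's trials.

    For each of ``n_partitions`` random partitions, the frequent trials of
    each condition are split into ``parts_per_partition`` near-equal parts
    (down-sampling each frequent type to roughly the infrequent count);
    each part plus all infrequent trials forms one subset (30 by default).
    Returned arrays index rows positionally into *trials*.
    """
    if rng is None:
        rng = np.random.default_rng(scheme.seed)
    freq = trials["frequency"].to_numpy()
    frequent = np.flatnonzero(freq == "frequent")
    infrequent = np.flatnonzero(freq == "infrequent")
    if frequent.size == 0 or infrequent.size == 0:
        raise ValueError("both frequent and infrequent trials are required")
    cond = (
        trials["condition_id"].to_numpy()
        if "condition_id" in trials.columns
        else np.zeros(len(trials), dtype=int)
    )
    subsets = []
    for _ in range(scheme.n_partitions):
        parts: list[list[np.ndarray]] = [[] for _ in range(scheme.parts_per_partition)]
        for c in np.unique(cond[frequent]):
            order = rng.permutation(frequent[cond[frequent] == c])
            for i, chunk in enumerate(np.array_split(order, scheme.parts_per_partition)):
                parts[i].append(chunk)
        for part in parts:
            pool = np.concatenate([infrequent, *part])
            # equalize class sizes exactly: unequal training counts bias the
            # per-class posteriors, which the trial-wise RSA would otherwise
            # pick up as spurious condition structure
            sizes = pd.Series(cond[pool]).value_counts()
            n_min = int(sizes.min())
            balanced = [
                rng.permutation(pool[cond[pool] == c])[:n_min] for c in sizes.index
            ]
            subsets.append(np.sort(np.concatenate(balanced)))
    return subsets


# ---------------------------------------------------------------------------
# Time-resolved decoding
# ---------------------------------------------------------------------------


@dataclass
class DecodingResult:
    """Accuracy timecourses plus trial-wise logit class probabilities."""

    accuracy: np.ndarray  # (n_subjects, n_times)
    subjects: list
    times: np.ndarray  # ms
    classes: np.ndarray
    trial_logit_probs: np.ndarray  # (n_trials_used, n_times, n_classes)
    trial_index: np.ndarray  # row positions into the trial table passed in
    confusion: np.ndarray  # (n_times, n_classes, n_classes) mean posterior by true class
    chance: float = field(default=0.0)

    def accuracy_frame(self) -> pd.DataFrame:
        rows = []
        for si, s in enumerate(self.subjects):
            for ti, t in enumerate(self.times):
                rows.append({"subject_id": s, "time_ms": t, "accuracy": self.accuracy[si, ti]})
        return pd.DataFrame(rows)

    def logit_frame(self) -> pd.DataFrame:
        n, T, C = self.trial_logit_probs.shape
        trial = np.repeat(self.trial_index, T * C)
        time = np.tile(np.repeat(self.times, C), n)
        cls = np.tile(self.classes, n * T)
        return pd.DataFrame(
            {
                "trial_id": trial,
                "time_ms": time,
                "class": cls,
                "logit_p": self.trial_logit_probs.ravel(),
            }
        )


def decode_timecourse(
    epochs,
    trials: pd.DataFrame,
    label_field: str = "condition_id",
    scheme: CvScheme | None = None,
    shrinkage: str | float = "auto",
    correct_only: bool = True,
) -> DecodingResult:
    """Balanced, repeated, stratified k-fold decoding at every timepoint.

    Accuracy is averaged over folds, parts and partitions per subject and
    timepoint.  Trial-wise posteriors are clipped, logit-transformed, and
    averaged over the repetitions in which the trial served as a test item.
    Each timepoint is processed independently.
    """
    if scheme is None:
        scheme = CvScheme()
    if label_field not in trials.columns:
        raise ValueError(f"label field {label_field!r} not in trial table")
    trials = trials.reset_index(drop=True)
    keep = np.arange(len(trials))
    if correct_only and "accuracy" in trials.columns:
        keep = np.flatnonzero((trials["accuracy"] == 1).to_numpy())
    labels_all = trials[label_field].to_numpy()
    classes = np.unique(labels_all[keep])
    C = classes.size
    subjects = sorted(trials["subject_id"].unique())
    T = epochs.times.size

    acc = np.zeros((len(subjects), T))
    logit_sum = np.zeros((keep.size, T, C))
    logit_cnt = np.zeros(keep.size)
    conf_sum = np.zeros((T, C, C))
    conf_cnt = np.zeros(C)
    subj_streams = np.random.SeedSequence(scheme.seed).spawn(len(subjects))

    pos_of = {g: i for i, g in enumerate(keep)}
    for si, subj in enumerate(subjects):
        rng = np.random.default_rng(subj_streams[si])
        rows = keep[trials["subject_id"].to_numpy()[keep] == subj]
        X = epochs.data[rows]  # (n, p, T)
        y = labels_all[rows]
        subsets = balanced_partitions(trials.iloc[rows], scheme, rng=rng)
        n_correct = np.zeros(T)
        n_total = 0
        for subset in subsets:
            ysub = y[subset]
            _, cnt = np.unique(ysub, return_counts=True)
            if cnt.min() < scheme.n_folds:
                raise ValueError(
                    f"a class has fewer than n_folds={scheme.n_folds} trials in a subset"
                )
            skf = StratifiedKFold(
                n_splits=scheme.n_folds,
                shuffle=True,
                random_state=int(rng.integers(2**31)),
            )
            for tr_idx, te_idx in skf.split(np.zeros(ysub.size), ysub):
                sub_classes, probs = _lda_train_predict(
                    X[subset[tr_idx]], ysub[tr_idx], X[subset[te_idx]], shrinkage
                )
                col = np.searchsorted(classes, sub_classes)
                full = np.zeros((te_idx.size, T, C))
                full[:, :, col] = probs
                pred = classes[np.argmax(full, axis=2)]  # (m, T)
                truth = ysub[te_idx][:, None]
                n_correct += (pred == truth).sum(axis=0)
                n_total += te_idx.size
                logit = np.log(
                    np.clip(full, LOGIT_CLIP, 1 - LOGIT_CLIP)
                    / (1 - np.clip(full, LOGIT_CLIP, 1 - LOGIT_CLIP))
                )
                g_rows = np.array([pos_of[g] for g in rows[subset[te_idx]]])
                logit_sum[g_rows] += logit
                logit_cnt[g_rows] += 1
                true_col = np.searchsorted(classes, ysub[te_idx])
                np.add.at(conf_sum, (slice(None), true_col), full.transpose(1, 0, 2))
                np.add.at(conf_cnt, true_col, 1)
        acc[si] = n_correct / n_total

    # trials never drawn into any balanced subset have no test posteriors;
    # they are dropped from the trial-wise outputs
    tested = logit_cnt > 0
    with np.errstate(invalid="ignore"):
        logits = logit_sum[tested] / logit_cnt[tested, None, None]
        confusion = conf_sum / conf_cnt[None, :, None]
    return DecodingResult(
        accuracy=acc,
        subjects=subjects,
        times=np.asarray(epochs.times),
        classes=classes,
        trial_logit_probs=logits,
        trial_index=keep[tested],
        confusion=confusion,
        chance=1.0 / C,
    )


def group_significance(
    accuracy: np.ndarray,
    chance: float,
    alpha: float = 0.001,
    n_tests: int | None = None,
) -> np.ndarray:
    """One-sample t vs chance per timepoint with Bonferroni correction.

    ``accuracy`` is subjects x timepoints; returns a boolean mask.  With
    zero between-subject variance the timepoint is significant iff the
    common value differs from chance.
    """
    accuracy = np.atleast_2d(np.asarray(accuracy, dtype=float))
    if accuracy.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    T = accuracy.shape[1]
    if n_tests is None:
        n_tests = T
    diffs = accuracy - chance
    sd = diffs.std(axis=0, ddof=1)
    mask = np.zeros(T, dtype=bool)
    for t in range(T):
        if sd[t] == 0.0:
            mask[t] = diffs[:, t].mean() != 0.0
        else:
            _, p = stats.ttest_1samp(diffs[:, t], 0.0)
            mask[t] = p < alpha / n_tests
    return mask
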