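"""Decoder subspaces, within/cross subspace decoding, overlap simulation, MDS.

The SC (stimulus-control: 4 colors x MC/MI) and SR (stimulus-response:
4 words x 2 possible responses) association decoders are 8-way LDAs.  A
decoder's subspace is the span of its centered class weight vectors
``Sigma^-1 (mu_c - mu_bar)`` (rank <= 7 for 8 classes), orthonormalized.
Projecting held-out data into the SC and SR subspaces and decoding both
label sets in each yields four accuracy timecourses whose within-vs-cross
pattern diagnoses whether the two associations live in identical,
disjoint, or partially overlapping subspaces.

A Gaussian cloud simulation makes that diagnosis quantitative: two 8-dim
layouts of 8 equidistant class centers, with the cross decoder given only
``n_shared`` informative dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa
from sklearn.model_selection import StratifiedKFold

from .decoding import CvScheme, _lda_train_predict, balanced_partitions, fit_lda

_KEYS = ("SC|SC", "SC|SR", "SR|SC", "SR|SR")  # "subspace | decoder"


@dataclass
class SubspaceModel:
    basis: np.ndarray  # (n_features, rank), orthonormal columns
    label_set: str  # "SC" | "SR"
    rank: int
    fold_id: int | None = None

    def project(self, X: np.ndarray) -> np.ndarray:
        return X @ self.basis


def fit_subspace(
    X: np.ndarray, labels8: np.ndarray, shrinkage: str | float = "auto", label_set: str = "SC"
) -> SubspaceModel:
    """Orthonormal basis of an 8-way LDA's discriminant weight span.

    The weights are computed against the grand mean of the class means, so
    the span has rank at most ``n_classes - 1``; merging two classes into
    one drops the rank accordingly.
    """
    model = fit_lda(X, labels8, shrinkage=shrinkage)
    demeaned = model.means - model.means.mean(axis=0)
    Wc = np.linalg.solve(model.covariance, demeaned.T).T  # (C, p)
    _, s, Vt = np.linalg.svd(Wc, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        raise ValueError("degenerate data: discriminant span has rank 0")
    rank = int(np.sum(s > s[0] * 1e-10))
    if rank == 0:
        raise ValueError("degenerate data: discriminant span has rank 0")
    return SubspaceModel(basis=Vt[:rank].T, label_set=label_set, rank=rank)


@dataclass
class CrossDecodingResult:
    """Four within/cross accuracy timecourses and within>cross masks."""

    accuracy: dict[str, np.ndarray]  # key -> (n_subjects, n_times)
    subjects: list
    times: np.ndarray
    masks: dict[str, np.ndarray]  # decoder ("SC"/"SR") -> within>cross mask
    chance: float = 1.0 / 8.0

    def frame(self) -> pd.DataFrame:
        rows = []
        for key, acc in self.accuracy.items():
            dec = key.split("|")[1]
            for ti, t in enumerate(self.times):
                rows.append(
                    {
                        "time_ms": t,
                        "key": key,
                        "accuracy": acc[:, ti].mean(),
                        "sig_within_gt_cross": bool(self.masks[dec][ti]),
                    }
                )
        return pd.DataFrame(rows)


def _subspace_bases(Xtr: np.ndarray, y: np.ndarray, shrinkage) -> list[np.ndarray]:
    """Per-timepoint discriminant-span bases from batched LDA statistics."""
    classes, inv = np.unique(y, return_inverse=True)
    C = classes.size
    n, p, T = Xtr.shape
    ind = np.zeros((n, C))
    ind[np.arange(n), inv] = 1.0
    counts = ind.sum(axis=0)
    means = np.einsum("nc,npt->cpt", ind, Xtr) / counts[:, None, None]
    centered = Xtr - means[inv]
    Z = centered.transpose(2, 0, 1)
    S = Z.transpose(0, 2, 1) @ Z / n
    from .decoding import _ledoit_wolf_lambda

    lam = (
        _ledoit_wolf_lambda(centered, S)
        if shrinkage == "auto"
        else np.full(T, float(shrinkage))
    )
    mu = np.trace(S, axis1=1, axis2=2) / p
    S_sh = (1.0 - lam)[:, None, None] * S
    S_sh[:, np.arange(p), np.arange(p)] += (lam * mu)[:, None]
    demeaned = means - means.mean(axis=0, keepdims=True)  # (C, p, T)
    Wc = np.linalg.solve(S_sh, demeaned.transpose(2, 1, 0))  # (T, p, C)
    bases = []
    for t in range(T):
        _, s, Vt = np.linalg.svd(Wc[t].T, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
        if rank == 0:
            raise ValueError("degenerate data: discriminant span has rank 0")
        bases.append(Vt[:rank].T)
    return bases


def cross_subspace_decode(
    epochs,
    trials: pd.DataFrame,
    scheme: CvScheme | None = None,
    shrinkage: str | float = "auto",
    alpha: float = 0.001,
    correct_only: bool = True,
) -> CrossDecodingResult:
    """Run the four within/cross subspace decoders with shared folds.

    Per fold, both subspaces are fit on training data only; training and
    test data are projected onto each basis, and 8-way SC and SR decoders
    are trained and tested in both.  All four decoders see identical
    subset/fold assignments.  The returned masks flag timepoints where the
    within-subspace decoder beats the cross-subspace one (paired t over
    subjects, Bonferroni-corrected at *alpha*).
    """
    if scheme is None:
        scheme = CvScheme()
    trials = trials.reset_index(drop=True)
    keep = np.arange(len(trials))
    if correct_only and "accuracy" in trials.columns:
        keep = np.flatnonzero((trials["accuracy"] == 1).to_numpy())
    labels = {"SC": trials["sc_class"].to_numpy(), "SR": trials["sr_class"].to_numpy()}
    subjects = sorted(trials["subject_id"].unique())
    T = epochs.times.size
    acc = {k: np.zeros((len(subjects), T)) for k in _KEYS}
    subj_streams = np.random.SeedSequence(scheme.seed).spawn(len(subjects))

    for si, subj in enumerate(subjects):
        rng = np.random.default_rng(subj_streams[si])
        rows = keep[trials["subject_id"].to_numpy()[keep] == subj]
        X = epochs.data[rows]
        y = {k: labels[k][rows] for k in labels}
        subsets = balanced_partitions(trials.iloc[rows], scheme, rng=rng)
        n_correct = {k: np.zeros(T) for k in _KEYS}
        n_total = 0
        for subset in subsets:
            strat = trials["condition_id"].to_numpy()[rows][subset]
            skf = StratifiedKFold(
                n_splits=scheme.n_folds,
                shuffle=True,
                random_state=int(rng.integers(2**31)),
            )
            for tr_idx, te_idx in skf.split(np.zeros(subset.size), strat):
                if np.intersect1d(subset[tr_idx], subset[te_idx]).size:
                    raise RuntimeError("leakage guard: train/test overlap")
                Xtr, Xte = X[subset[tr_idx]], X[subset[te_idx]]
                bases = {
                    sp: _subspace_bases(Xtr, y[sp][subset[tr_idx]], shrinkage)
                    for sp in ("SC", "SR")
                }
                for sp in ("SC", "SR"):
                    for dec in ("SC", "SR"):
                        ytr = y[dec][subset[tr_idx]]
                        yte = y[dec][subset[te_idx]]
                        for t in range(T):
                            B = bases[sp][t]
                            m = fit_lda(Xtr[:, :, t] @ B, ytr, shrinkage=shrinkage)
                            pred = m.predict(Xte[:, :, t] @ B)
                            n_correct[f"{sp}|{dec}"][t] += (pred == yte).sum()
                n_total += te_idx.size
        for k in _KEYS:
            acc[k][si] = n_correct[k] / n_total

    masks = {}
    for dec in ("SC", "SR"):
        within = acc[f"{dec}|{dec}"]
        cross = acc[("SR" if dec == "SC" else "SC") + f"|{dec}"]
        mask = np.zeros(T, dtype=bool)
        if len(subjects) >= 2:
            for t in range(T):
                d = within[:, t] - cross[:, t]
                if d.std(ddof=1) == 0.0:
                    mask[t] = d.mean() > 0
                else:
                    tt, p = stats.ttest_1samp(d, 0.0)
                    mask[t] = (tt > 0) and (p < alpha / T)
        masks[dec] = mask
    return CrossDecodingResult(
        accuracy=acc, subjects=subjects, times=np.asarray(epochs.times), masks=masks
    )


# ---------------------------------------------------------------------------
# Overlap simulation
# ---------------------------------------------------------------------------


@dataclass
class OverlapSimConfig:
    """Gaussian-cloud simulation of cross-decoding vs subspace overlap.

    Defaults: two 8-dimensional subspaces, 8 classes of 100 points each,
    pairwise-equidistant class centers.  ``center_distance`` and
    ``within_sd`` stand in for the between-center distance and within-class
    SD a real dataset would supply; the defaults put the own-subspace
    decoder at roughly 50% accuracy.
    """

    n_dims: int = 8
    n_classes: int = 8
    n_per_class: int = 100
    center_distance: float = 2.0
    within_sd: float = 1.0
    n_shared: int = 4
    n_reps: int = 40
    n_folds: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.center_distance <= 0:
            raise ValueError("center_distance must be positive")
        if not 0 <= self.n_shared <= self.n_dims:
            raise ValueError("n_shared must lie in 0..n_dims")


def _equidistant_centers(n_classes: int, n_dims: int, distance: float) -> np.ndarray:
    """Class centers with all pairwise distances equal to *distance*.

    Scaled coordinate vectors: ||d/sqrt(2) (e_i - e_j)|| = d for i != j.
    Requires n_dims >= n_classes.
    """
    if n_dims < n_classes:
        raise ValueError("need n_dims >= n_classes for equidistant centers")
    return (distance / np.sqrt(2.0)) * np.eye(n_classes, n_dims)


def _cv_accuracy(X, y, n_folds, rng) -> float:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    correct = 0
    for tr, te in skf.split(X, y):
        m = fit_lda(X[tr], y[tr], shrinkage="auto")
        correct += (m.predict(X[te]) == y[te]).sum()
    return correct / y.size


def generate_class_clouds(
    cfg: OverlapSimConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """One draw of the two Gaussian class layouts and their labels."""
    centers = _equidistant_centers(cfg.n_classes, cfg.n_dims, cfg.center_distance)
    y = np.repeat(np.arange(cfg.n_classes), cfg.n_per_class)
    X = {
        sp: centers[y] + rng.normal(0.0, cfg.within_sd, (y.size, cfg.n_dims))
        for sp in ("SC", "SR")
    }
    return X, y


def simulate_overlap(
    cfg: OverlapSimConfig, n_shared_grid: list[int] | None = None
) -> pd.DataFrame:
    """Decoding accuracy of own and cross decoders vs shared dimensions.

    Own decoders see all ``n_dims`` informative dimensions of their layout;
    a cross decoder sees ``n_shared`` randomly re-drawn informative
    dimensions, the remainder filled with the other layout's (label-
    independent) coordinates.  Returns mean +/- sd accuracy over
    repetitions for each key and grid value.
    """
    cfg.validate()
    if n_shared_grid is None:
        n_shared_grid = [cfg.n_shared]
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for n_shared in n_shared_grid:
        accs = {k: [] for k in _KEYS}
        for _ in range(cfg.n_reps):
            X, y = generate_class_clouds(cfg, rng)
            n = y.size
            for sp in ("SC", "SR"):
                accs[f"{sp}|{sp}"].append(_cv_accuracy(X[sp], y, cfg.n_folds, rng))
            for sp, dec in (("SC", "SR"), ("SR", "SC")):
                shared = rng.choice(cfg.n_dims, size=n_shared, replace=False)
                rest = np.setdiff1d(np.arange(cfg.n_dims), shared)
                Xc = np.empty((n, cfg.n_dims))
                Xc[:, shared] = X[dec][:, shared]  # informative for dec labels
                Xc[:, rest] = X[sp][rng.permutation(n)][:, rest]  # label-independent
                accs[f"{sp}|{dec}"].append(_cv_accuracy(Xc, y, cfg.n_folds, rng))
        for k in _KEYS:
            a = np.asarray(accs[k])
            rows.append(
                {
                    "n_shared": n_shared,
                    "key": k,
                    "mean_acc": a.mean(),
                    "sd_acc": a.std(ddof=1) if a.size > 1 else 0.0,
                    "n_reps": a.size,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------


@dataclass
class MdsEmbedding:
    coordinates: np.ndarray  # (n_conditions, n_dims)
    eigenvalues: np.ndarray
    cumulative_explained: np.ndarray  # per retained dimension

    @property
    def empty(self) -> bool:
        return self.coordinates.size == 0


def posterior_to_dissimilarity(P: np.ndarray) -> np.ndarray:
    """Dissimilarity from a mean-posterior confusion matrix.

    Symmetrize to s = (P + P')/2 and set
    d_ij = s_ii/2 + s_jj/2 - s_ij, floored at 0 with a zero diagonal, so
    conditions frequently confused with each other come out close.
    """
    P = np.asarray(P, dtype=float)
    s = 0.5 * (P + P.T)
    diag = np.diag(s)
    d = 0.5 * diag[:, None] + 0.5 * diag[None, :] - s
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def classical_mds(
    matrix: np.ndarray, n_dims: int = 3, input_kind: str = "posterior"
) -> MdsEmbedding:
    """Torgerson MDS of a confusion matrix (or precomputed dissimilarity).

    Coordinates come from the eigendecomposition of the double-centered
    squared-distance matrix; cumulative explained variance is the running
    share of the positive eigenvalues.
    """
    if input_kind == "posterior":
        d = posterior_to_dissimilarity(matrix)
    elif input_kind == "dissimilarity":
        d = 0.5 * (np.asarray(matrix, dtype=float) + np.asarray(matrix, dtype=float).T)
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown input_kind {input_kind!r}")
    if np.allclose(d, 0.0):
        warnings.warn("all conditions equidistant at 0: empty embedding")
        n = d.shape[0]
        return MdsEmbedding(
            coordinates=np.zeros((n, 0)),
            eigenvalues=np.zeros(n),
            cumulative_explained=np.zeros(0),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        res = pcoa(DistanceMatrix(d), number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    pos = np.clip(eig, 0.0, None)
    n_dims = min(n_dims, int(np.sum(pos > 0)))
    coords = res.samples.to_numpy()[:, :n_dims]
    cum = np.cumsum(pos[:n_dims]) / pos.sum()
    return MdsEmbedding(coordinates=coords, eigenvalues=eig, cumulative_explained=cum)
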