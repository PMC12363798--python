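"""Subspace construction, cross-decoding, overlap simulation, classical MDS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conjrep.containers import EpochSet
from conjrep.decoding import CvScheme, fit_lda
from conjrep.simulate import (
    DesignConfig,
    EncodingConfig,
    generate_design,
    generate_encoding_model,
    generate_epochs,
)
from conjrep.subspace import (
    OverlapSimConfig,
    classical_mds,
    cross_subspace_decode,
    fit_subspace,
    posterior_to_dissimilarity,
    simulate_overlap,
)


class TestFitSubspace:
    def test_eight_separated_classes_give_rank_7(self, rng):
        y = np.repeat(np.arange(8), 50)
        X = rng.standard_normal((400, 64))
        X[:, :8] += 6 * np.eye(8)[y]
        assert fit_subspace(X, y).rank == 7

    def test_basis_lies_in_the_generating_subspace(self, rng):
        # data confined to a known 3-dim subspace -> basis contained in it
        B = np.linalg.qr(rng.standard_normal((20, 3)))[0]
        y = np.repeat(np.arange(4), 40)
        latent = 4 * np.eye(4, 3)[y] + rng.standard_normal((160, 3))
        X = latent @ B.T
        m = fit_subspace(X, y)
        proj = B @ B.T  # projector onto the generating subspace
        assert np.linalg.norm(m.basis - proj @ m.basis) < 1e-8

    def test_merging_two_classes_drops_rank(self, rng):
        y = np.repeat(np.arange(8), 50)
        X = rng.standard_normal((400, 32))
        X[:, :8] += 6 * np.eye(8)[y]
        r_full = fit_subspace(X, y).rank
        y2 = np.where(y == 7, 6, y)
        assert fit_subspace(X, y2).rank == r_full - 1

    def test_orthonormal_columns(self, rng):
        y = np.repeat(np.arange(8), 30)
        X = rng.standard_normal((240, 16))
        X[:, :8] += 3 * np.eye(8)[y]
        m = fit_subspace(X, y)
        assert np.allclose(m.basis.T @ m.basis, np.eye(m.rank), atol=1e-10)


def _independent_label_study(overlap, seed, n_subjects=4, n_trials=320, n_times=3):
    """Epochs whose SC and SR labels are statistically independent.

    Isolates the subspace machinery from the task design, where SC and SR
    labels share the ISPC factor and can never be fully decoupled.
    """
    rng = np.random.default_rng(seed)
    model = generate_encoding_model(EncodingConfig(overlap_fraction=overlap), seed=seed)
    rows, data = [], []
    for s in range(n_subjects):
        sc = rng.integers(1, 9, n_trials)
        sr = rng.integers(1, 9, n_trials)
        X = rng.standard_normal((n_trials, 64, n_times))
        X += 1.5 * model.patterns["sc"][sc - 1][:, :, None]
        X += 1.5 * model.patterns["sr"][sr - 1][:, :, None]
        data.append(X)
        for i in range(n_trials):
            rows.append(
                {
                    "subject_id": s,
                    "sc_class": sc[i],
                    "sr_class": sr[i],
                    "condition_id": sc[i],  # stratification label
                    "frequency": "frequent" if i % 2 else "infrequent",
                }
            )
    trials = pd.DataFrame(rows)
    epochs = EpochSet(np.concatenate(data), 50.0, np.arange(n_times) * 20.0, "stimulus")
    return epochs, trials


class TestCrossSubspaceDecode:
    def test_overlap_regimes_with_independent_labels(self):
        """Cross accuracy tracks the pattern-family overlap.

        With labels independent by construction: near chance for disjoint
        families, near the within accuracy for identical families, strictly
        between for partial overlap.  Subspaces are estimated rank-7 spans
        fit on 64-channel data, so a small estimation leak above chance (at
        overlap 0) and below within (at overlap 1) is expected.
        """
        within, cross = {}, {}
        masks = {}
        for overlap in (0.0, 0.5, 1.0):
            epochs, trials = _independent_label_study(overlap, seed=61)
            res = cross_subspace_decode(
                epochs,
                trials,
                scheme=CvScheme(n_partitions=2, seed=62),
                correct_only=False,
                alpha=0.05,
            )
            within[overlap] = np.mean(
                [res.accuracy["SC|SC"].mean(), res.accuracy["SR|SR"].mean()]
            )
            cross[overlap] = np.mean(
                [res.accuracy["SR|SC"].mean(), res.accuracy["SC|SR"].mean()]
            )
            masks[overlap] = res.masks
        chance = 1 / 8
        assert all(w > 0.3 for w in within.values())
        assert cross[0.0] < cross[0.5] < cross[1.0]
        # disjoint: much closer to chance than to within
        assert cross[0.0] - chance < 0.35 * (within[0.0] - chance)
        assert masks[0.0]["SC"].all() and masks[0.0]["SR"].all()
        # full overlap: much closer to within than to chance
        assert within[1.0] - cross[1.0] < 0.35 * (within[1.0] - chance)

    def test_task_design_shows_partial_overlap_pattern(self, small_study):
        # on the real design SC/SR labels share ISPC, so cross-decoding sits
        # above chance but below within-subspace decoding
        eps = small_study["epochs"]
        keep = (eps.times >= 400) & (eps.times <= 560)
        sub = EpochSet(eps.data[:, :, keep], eps.sfreq, eps.times[keep], "stimulus")
        res = cross_subspace_decode(
            sub, small_study["trials"], scheme=CvScheme(n_partitions=2, seed=63)
        )
        within = np.mean([res.accuracy["SC|SC"].mean(), res.accuracy["SR|SR"].mean()])
        cross = np.mean([res.accuracy["SR|SC"].mean(), res.accuracy["SC|SR"].mean()])
        assert 1 / 8 + 0.03 < cross < within - 0.02


class TestSimulateOverlap:
    def test_default_points_per_class_is_100(self):
        cfg = OverlapSimConfig()
        assert cfg.n_per_class == 100

    def test_no_shared_dims_cross_at_chance(self):
        cfg = OverlapSimConfig(n_reps=8, seed=70)
        g = simulate_overlap(cfg, [0])
        cross = g[g.key.isin(["SC|SR", "SR|SC"])].mean_acc.mean()
        p = 1 / 8
        n = cfg.n_classes * cfg.n_per_class * cfg.n_reps * 2
        assert abs(cross - p) < 2.576 * np.sqrt(p * (1 - p) / n) + 0.005

    def test_all_shared_dims_cross_comparable_to_own(self):
        cfg = OverlapSimConfig(n_reps=8, seed=71)
        g = simulate_overlap(cfg, [8])
        own = g[g.key.isin(["SC|SC", "SR|SR"])]
        cross = g[g.key.isin(["SC|SR", "SR|SC"])]
        spread = g.sd_acc.max() / np.sqrt(cfg.n_reps)
        assert abs(own.mean_acc.mean() - cross.mean_acc.mean()) < 4 * spread

    def test_accuracy_monotone_in_shared_dims(self):
        g = simulate_overlap(OverlapSimConfig(n_reps=6, seed=72), list(range(9)))
        cross = (
            g[g.key == "SC|SR"].sort_values("n_shared").mean_acc.to_numpy()
        )
        rho, _ = stats.spearmanr(np.arange(9), cross)
        assert rho > 0.9

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="center_distance"):
            simulate_overlap(OverlapSimConfig(center_distance=0.0))
        with pytest.raises(ValueError, match="n_shared"):
            simulate_overlap(OverlapSimConfig(n_shared=9))

    def test_projection_never_beats_full_features(self, rng):
        # decoding in a discriminant subspace cannot exceed decoding on the
        # full feature set on average (data-processing inequality)
        y = np.repeat(np.arange(8), 60)
        accs_full, accs_proj = [], []
        for rep in range(5):
            X = rng.standard_normal((480, 24))
            X[:, :8] += 1.0 * np.eye(8)[y]
            half = 240
            perm = rng.permutation(480)
            tr, te = perm[:half], perm[half:]
            m_full = fit_lda(X[tr], y[tr])
            accs_full.append((m_full.predict(X[te]) == y[te]).mean())
            sub = fit_subspace(X[tr], y[tr])
            m_proj = fit_lda(X[tr] @ sub.basis, y[tr])
            accs_proj.append((m_proj.predict(X[te] @ sub.basis) == y[te]).mean())
        assert np.mean(accs_proj) <= np.mean(accs_full) + 0.02


class TestClassicalMds:
    def test_unit_square_distances_reproduced_exactly(self):
        s2 = np.sqrt(2.0)
        D = np.array(
            [[0, 1, 1, s2], [1, 0, s2, 1], [1, s2, 0, 1], [s2, 1, 1, 0]], dtype=float
        )
        e = classical_mds(D, n_dims=2, input_kind="dissimilarity")
        from scipy.spatial.distance import pdist, squareform

        assert np.abs(squareform(pdist(e.coordinates)) - D).max() < 1e-8
        assert e.cumulative_explained[-1] == pytest.approx(1.0)

    def test_identity_posterior_makes_conditions_equidistant(self):
        e = classical_mds(np.eye(8), n_dims=7)
        from scipy.spatial.distance import pdist

        d = pdist(np.column_stack([e.coordinates, np.zeros((8, 1))]))
        assert np.ptp(d) < 1e-8
        # symmetric configuration: leading eigenvalues all equal
        lead = e.eigenvalues[:7]
        assert np.allclose(lead, lead[0])

    def test_matches_double_centering_oracle(self, rng):
        P = rng.random((16, 16))
        P /= P.sum(axis=1, keepdims=True)
        e = classical_mds(P, n_dims=3)
        # independent Torgerson oracle
        D = posterior_to_dissimilarity(P)
        J = np.eye(16) - np.ones((16, 16)) / 16
        B = -0.5 * J @ (D**2) @ J
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        oracle = V[:, :3] * np.sqrt(np.clip(w[:3], 0, None))
        from scipy.spatial.distance import pdist

        r = np.corrcoef(pdist(e.coordinates), pdist(oracle))[0, 1]
        assert r > 0.999

    def test_cumulative_explained_nondecreasing_and_bounded(self, rng):
        P = rng.random((8, 8))
        e = classical_mds(P, n_dims=5)
        assert np.all(np.diff(e.cumulative_explained) >= -1e-12)
        assert e.cumulative_explained[-1] <= 1.0 + 1e-12

    def test_degenerate_matrix_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            e = classical_mds(np.full((6, 6), 0.25), n_dims=3)
        assert e.empty
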