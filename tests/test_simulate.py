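"""Synthetic generator: design template, encoding geometry, epochs, behavior."""

import numpy as np
import pandas as pd
import pytest

from conjrep.simulate import (
    BehaviorConfig,
    DesignConfig,
    EncodingConfig,
    generate_behavior,
    generate_design,
    generate_encoding_model,
    generate_epochs,
)


@pytest.fixture(scope="module")
def design():
    return generate_design(DesignConfig(n_subjects=2, miniblocks_per_phase=(2, 4, 4), seed=5))


class TestDesign:
    def test_miniblocks_of_16_with_half_congruent(self, design):
        sizes = design.groupby(["subject_id", "phase", "miniblock"]).size()
        assert set(sizes) == {16}
        frac = design.groupby(["subject_id", "phase", "miniblock"]).apply(
            lambda g: (g.congruency == "congruent").mean(), include_groups=False
        )
        assert set(frac) == {0.5}

    def test_mc_set_is_75_percent_congruent(self, design):
        mc = design[design.ispc == "mc"]
        mi = design[design.ispc == "mi"]
        assert (mc.congruency == "congruent").mean() == 0.75
        assert (mi.congruency == "congruent").mean() == 0.25

    def test_frequent_to_infrequent_is_3_within_each_phase(self, design):
        for (_, _), g in design.groupby(["subject_id", "phase"]):
            counts = g.frequency.value_counts()
            assert counts["frequent"] == 3 * counts["infrequent"]

    def test_same_seed_reproduces_table(self):
        cfg = DesignConfig(n_subjects=2, miniblocks_per_phase=(2, 4, 4), seed=9)
        a = generate_design(cfg)
        b = generate_design(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_phase_flip_populates_all_16_conditions_and_8_classes(self, design):
        for _, g in design.groupby("subject_id"):
            assert g.condition_id.nunique() == 16
            assert g.sc_class.nunique() == 8
            assert g.sr_class.nunique() == 8
            # every color serves as both MC and MI across the experiment
            assert g.groupby("color").ispc.nunique().eq(2).all()

    def test_counterbalance_alternates_phase1_assignment(self, design):
        p1 = design[design.phase == 1]
        mc_sets = p1.groupby("subject_id").apply(
            lambda g: g.loc[g.ispc == "mc", "set"].iloc[0], include_groups=False
        )
        assert mc_sets[0] != mc_sets[1]

    def test_rejects_bad_configs(self):
        with pytest.raises(ValueError, match="multiple of 16"):
            generate_design(DesignConfig(trials_per_miniblock=20))
        with pytest.raises(ValueError, match="flip"):
            generate_design(DesignConfig(phase_ispc_map=("A", "A", "A")))
        with pytest.raises(ValueError, match="restore"):
            generate_design(DesignConfig(phase_ispc_map=("A", "B", "B")))

    def test_scaled_miniblocks_keep_the_template(self):
        d = generate_design(
            DesignConfig(miniblocks_per_phase=(1, 2, 1), trials_per_miniblock=32, seed=0)
        )
        sizes = d.groupby(["phase", "miniblock"]).size()
        assert set(sizes) == {32}
        assert (d[d.ispc == "mc"].congruency == "congruent").mean() == 0.75


class TestEncodingModel:
    def test_zero_overlap_families_orthogonal(self):
        m = generate_encoding_model(EncodingConfig(overlap_fraction=0.0), seed=1)
        cos = np.abs(m.patterns["sc"] @ m.patterns["sr"].T)
        assert cos.max() < 1e-10

    def test_full_overlap_families_share_span(self):
        m = generate_encoding_model(EncodingConfig(overlap_fraction=1.0), seed=1)
        stacked = np.vstack([m.patterns["sc"], m.patterns["sr"]])
        assert np.linalg.matrix_rank(stacked, tol=1e-8) == 8

    def test_half_overlap_stacked_rank_is_12(self):
        m = generate_encoding_model(EncodingConfig(overlap_fraction=0.5), seed=1)
        stacked = np.vstack([m.patterns["sc"], m.patterns["sr"]])
        assert np.linalg.matrix_rank(stacked, tol=1e-8) == 12
        assert m.shared_rank == 4

    def test_insufficient_channels_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            generate_encoding_model(EncodingConfig(n_channels=20), seed=0)

    def test_envelopes_zero_before_onset(self):
        enc = EncodingConfig()
        m = generate_encoding_model(enc, seed=2)
        times = enc.times
        for f in m.patterns:
            assert np.all(m.envelope(f, times)[times < 0] == 0.0)


class TestEpochs:
    def test_single_factor_noiseless_epochs_identical_within_color(self):
        d = generate_design(DesignConfig(miniblocks_per_phase=(1, 1, 1), seed=3))
        enc = EncodingConfig(
            noise_sd=0.0,
            gain_sigma=0.0,
            tmax_ms=400.0,
            amplitudes={"color": 1.0},
        )
        eps, d = generate_epochs(d, generate_encoding_model(enc, seed=4), seed=5)
        for color in d.color.unique():
            idx = np.flatnonzero((d.color == color).to_numpy())
            assert np.allclose(eps.data[idx] - eps.data[idx[0]], 0.0)

    def test_zero_amplitudes_give_zero_mean_noise(self):
        d = generate_design(DesignConfig(miniblocks_per_phase=(2, 3, 3), seed=3))
        enc = EncodingConfig(tmax_ms=300.0, amplitudes={})
        eps, _ = generate_epochs(d, generate_encoding_model(enc, seed=4), seed=5)
        grand = eps.data.mean(axis=0)
        assert np.abs(grand).max() < 5.0 / np.sqrt(len(d))  # ~5 MC sigma

    def test_prestimulus_samples_are_noise_only(self, small_study):
        eps = small_study["epochs"]
        pre = eps.data[:, :, eps.times < 0]
        # variance of pre-stimulus samples equals the sensor noise variance
        assert abs(pre.var() - small_study["enc"].noise_sd ** 2) < 0.01

    def test_coupled_gains_shared_decoupled_independent(self):
        d = generate_design(DesignConfig(miniblocks_per_phase=(2, 4, 4), seed=6))
        enc_c = EncodingConfig(tmax_ms=200.0, coupling=True)
        _, dc = generate_epochs(d, generate_encoding_model(enc_c, seed=7), seed=8)
        assert "latent_gain_sr" not in dc.columns  # one shared gain
        enc_d = EncodingConfig(tmax_ms=200.0, coupling=False)
        _, dd = generate_epochs(d, generate_encoding_model(enc_d, seed=7), seed=8)
        r = np.corrcoef(dd.latent_gain, dd.latent_gain_sr)[0, 1]
        assert abs(r) < 0.1

    def test_epoch_rows_match_trial_rows(self, small_study):
        assert small_study["epochs"].n_trials == len(small_study["trials"])


class TestBehavior:
    def test_deterministic_cells_without_noise_or_gain(self):
        d = generate_design(DesignConfig(miniblocks_per_phase=(1, 1, 1), seed=1))
        cfg = BehaviorConfig(rt_noise_sd=0.0, gain_slope=0.0, seed=2)
        out = generate_behavior(d, cfg)
        cell = out[(out.congruency == "congruent") & (out.ispc == "mc")]
        assert cell.rt.nunique() == 1
        assert cell.rt.iloc[0] == pytest.approx(cfg.rt_base)

    def test_ispc_modulation_shrinks_mi_conflict(self):
        d = generate_design(DesignConfig(miniblocks_per_phase=(10, 60, 60), seed=3))
        assert len(d) >= 2000
        out = generate_behavior(d, BehaviorConfig(ispc_modulation=0.4, seed=4))
        cells = out.groupby(["ispc", "congruency"]).rt.mean()
        conflict_mc = cells["mc"]["incongruent"] - cells["mc"]["congruent"]
        conflict_mi = cells["mi"]["incongruent"] - cells["mi"]["congruent"]
        assert conflict_mc > conflict_mi > 0

    def test_negative_gain_slope_makes_rt_anticorrelate_with_gain(self):
        d = generate_design(DesignConfig(miniblocks_per_phase=(2, 5, 5), seed=5))
        out = generate_behavior(d, BehaviorConfig(gain_slope=-60.0, seed=6))
        ok = out.rt.notna()
        assert np.corrcoef(out.latent_gain[ok], out.rt[ok])[0, 1] < -0.3

    def test_deadline_marks_rt_missing(self):
        d = generate_design(DesignConfig(miniblocks_per_phase=(1, 2, 2), seed=7))
        out = generate_behavior(d, BehaviorConfig(rt_base=1400.0, rt_noise_sd=0.3, seed=8))
        missed = out.rt.isna()
        assert missed.any()
        assert (out.loc[missed, "accuracy"] == 0).all()
        assert out.rt.max() <= 1500.0

    def test_negative_rt_base_rejected(self):
        d = generate_design(DesignConfig(miniblocks_per_phase=(1, 1, 1), seed=9))
        with pytest.raises(ValueError, match="rt_base"):
            generate_behavior(d, BehaviorConfig(rt_base=-5.0))
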