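"""Shared fixtures: small synthetic studies generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from conjrep.decoding import CvScheme, decode_timecourse
from conjrep.simulate import (
    BehaviorConfig,
    DesignConfig,
    EncodingConfig,
    generate_behavior,
    generate_design,
    generate_encoding_model,
    generate_epochs,
)


@pytest.fixture(scope="session")
def small_study():
    """4 subjects, scaled-down phases, epochs to 800 ms, coupled gains."""
    design = generate_design(
        DesignConfig(n_subjects=4, miniblocks_per_phase=(2, 12, 10), seed=11)
    )
    enc = EncodingConfig(tmax_ms=800.0)
    model = generate_encoding_model(enc, seed=12)
    epochs, design = generate_epochs(design, model, seed=13)
    design = generate_behavior(design, BehaviorConfig(seed=14))
    return {"trials": design, "epochs": epochs, "model": model, "enc": enc}


@pytest.fixture(scope="session")
def small_decoding(small_study):
    """16-way decoding of the small study (shared by decoding/RSA/LMM tests)."""
    res = decode_timecourse(
        small_study["epochs"], small_study["trials"], scheme=CvScheme(seed=15)
    )
    trials = small_study["trials"]
    return {
        "result": res,
        "condition_ids": trials["condition_id"].to_numpy()[res.trial_index],
        "subjects": trials["subject_id"].to_numpy()[res.trial_index],
        "gains": trials["latent_gain"].to_numpy()[res.trial_index],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
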