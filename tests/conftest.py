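"""Shared fixtures: reference potential, trained dark model, dimer maps.

Everything is generated programmatically from the synthetic fixture
generators with fixed seeds; session scope keeps the expensive contact-map
computations shared across test modules.
"""

from __future__ import annotations

import pytest

from camqa.contacts import aggregate_residues, compute_contact_map
from camqa.experiments import default_potential, train_default_dark
from camqa.structures import make_dimer

N_SAMPLES = 128  # estimator lattice size used throughout the suite


@pytest.fixture(scope="session")
def potential():
    """Contact potential derived from six amphipathic dimer references."""
    return default_potential(seed=0, n_samples=N_SAMPLES)


@pytest.fixture(scope="session")
def dark_model(potential):
    """Per-residue quality predictor trained on four rigid-body decoy sets."""
    return train_default_dark(potential, seed=3, n_samples=N_SAMPLES)


@pytest.fixture(scope="session")
def dimer():
    return make_dimer(20, seed=42)


@pytest.fixture(scope="session")
def dimer_maps(dimer):
    cm = compute_contact_map(dimer, n_samples=N_SAMPLES, seed=0)
    return cm, aggregate_residues(cm, dimer)
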