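"""Shared fixtures: peptides and published distributions used across tests."""

import numpy as np
import pytest

from hypquant import GroundTruth, simulate_lcms_run
from hypquant.peptides import HINGE_PEPTIDE

# hydroxyproline distribution of the unperturbed plant-produced IgA1 hinge
# peptide (percent, 0..6 Hyp) — used as simulation ground truth throughout
CONTROL_PERCENT = (26.3, 27.9, 23.9, 16.0, 4.8, 1.1, 0.1)


@pytest.fixture(scope="session")
def control_fractions() -> np.ndarray:
    f = np.asarray(CONTROL_PERCENT, dtype=float)
    return f / f.sum()


@pytest.fixture(scope="session")
def noiseless_run(control_fractions):
    """One noiseless, adduct-free hinge-peptide run shared by read-only tests."""
    truth = GroundTruth(
        peptide=HINGE_PEPTIDE,
        stoichiometry=tuple(control_fractions),
        adduct_fraction=0.0,
        noise_cv=0.0,
        seed=7,
    )
    return truth, simulate_lcms_run(truth)
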