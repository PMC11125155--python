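"""Session fixtures built on the shared helpers."""
import pytest

import pdfshell as ps
from helpers import matched_monomer


@pytest.fixture(scope="session")
def headline_model():
    """The reference prolate test micelle (eps 1.4, R_sh 16 A, D_max 120 A)."""
    return ps.SpheroidModel((120.0 / 2 - 16.0) / 1.4, 1.4, 16.0, -0.03, 0.04)


@pytest.fixture(scope="session")
def headline_setup(headline_model):
    spec, k_const = matched_monomer(headline_model, 120)
    return headline_model, 120, spec, k_const


@pytest.fixture(scope="session")
def headline_profile(headline_setup):
    model, n_agg, _, k_const = headline_setup
    return ps.synthesize_pdf(
        model, n_agg, k_const, grid_step=0.25, n_pairs=2**23, seed=42
    )
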