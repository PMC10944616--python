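import numpy as np
import pytest

from soycanopy.synthetic import DEFAULT_REL_HEIGHTS, TrialDesign, TruthParams


@pytest.fixture
def rel_heights():
    return np.asarray(DEFAULT_REL_HEIGHTS)


@pytest.fixture
def small_design():
    """Six-accession version of the two-year RCBD for fast end-to-end tests."""
    return TrialDesign(n_accessions=6)


@pytest.fixture
def small_noise_free_trial(small_design):
    from soycanopy.synthetic import generate_trial

    truth = TruthParams.default(
        small_design, seed=11,
        cc_noise_sd=0.0, tpar_noise_sd=0.0,
        width_noise_frac=0.0, within_plot_frac=0.0,
    )
    return generate_trial(small_design, truth)
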