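import numpy as np
import pandas as pd
import pytest

import refcurve as rc


@pytest.fixture(scope="session")
def alp_boy_cohort():
    """Full-size synthetic ALP boys cohort from the calibrated preset."""
    return rc.generate_cohort(rc.table1_preset("ALP", "boy"), seed=5)


@pytest.fixture(scope="session")
def cleaned_alp_boy(alp_boy_cohort):
    cleaned, _ = rc.clean(alp_boy_cohort)
    return cleaned


@pytest.fixture(scope="session")
def smooth_truth():
    """Box-Cox normal ground truth with gently varying L/M/S curves."""
    return rc.LSSTruth(
        nu_fn=lambda t: 1.0 - 0.05 * (t - 10.0) / 9.0,
        mu_fn=lambda t: 100.0 + 8.0 * t - 0.15 * t**2,
        sigma_fn=lambda t: 0.12 + 0.002 * t,
        age_range=(1.0, 19.0),
    )


@pytest.fixture(scope="session")
def truth_cohort(smooth_truth):
    return rc.generate_from_truth(smooth_truth, 5000, seed=11)


@pytest.fixture()
def flat_gaussian():
    """Age-independent N(100, 10^2) cohort: known constant 95% limits."""
    rng = np.random.default_rng(17)
    n = 2000
    return pd.DataFrame({
        "age": rng.uniform(1, 19, n),
        "sex": "boy",
        "value": rng.normal(100.0, 10.0, n),
    })
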