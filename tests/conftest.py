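import numpy as np
import pytest

import sigcat as sc


@pytest.fixture(scope="session")
def times_equidistant() -> np.ndarray:
    """The benchmark observation grid: 3.0, 3.5, ..., 30.0."""
    return 3.0 + 0.5 * np.arange(55)


@pytest.fixture(scope="session")
def sig_params() -> sc.SigmoidalParams:
    return sc.SigmoidalParams(I_max=5.0, t_mid=14.0, a1=0.8)


@pytest.fixture(scope="session")
def dbl_params() -> sc.DoubleSigmoidalParams:
    return sc.DoubleSigmoidalParams(
        I_max=4.0, I_final=0.8, t_mid1_prime=10.0, t_mid2_prime=20.0,
        a1_prime=1.0, a2_prime=0.8,
    )


@pytest.fixture(scope="session")
def clean_sigmoidal_tc(times_equidistant, sig_params) -> sc.TimeCourse:
    return sc.TimeCourse(
        times_equidistant, sc.eval_sigmoidal(times_equidistant, sig_params)
    )


@pytest.fixture(scope="session")
def clean_double_tc(times_equidistant, dbl_params) -> sc.TimeCourse:
    return sc.TimeCourse(
        times_equidistant,
        sc.eval_double_sigmoidal(times_equidistant, dbl_params),
    )
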