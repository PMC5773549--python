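import pytest

from radioassay.aberrations import AberrationFitResult
from radioassay.survival import LQFitResult


@pytest.fixture
def mid_sobp_ref():
    """Published-scale LQ survival fit: protons alone at mid-SOBP."""
    return LQFitResult(
        alpha=0.314, sigma_alpha=0.022, beta=0.035, sigma_beta=0.007,
        model_form="linear_quadratic", n_points=6, residual_stat=0.0,
    )


@pytest.fixture
def mid_sobp_test():
    """Published-scale pure-exponential fit: protons + 80 ppm boron."""
    return LQFitResult(
        alpha=0.705, sigma_alpha=0.033, beta=0.0, sigma_beta=0.0,
        model_form="pure_exponential", n_points=6, residual_stat=0.0,
    )


@pytest.fixture
def distal_ref():
    return LQFitResult(
        alpha=0.541, sigma_alpha=0.027, beta=0.0, sigma_beta=0.0,
        model_form="pure_exponential", n_points=6, residual_stat=0.0,
    )


@pytest.fixture
def distal_test():
    return LQFitResult(
        alpha=0.952, sigma_alpha=0.053, beta=0.0, sigma_beta=0.0,
        model_form="pure_exponential", n_points=6, residual_stat=0.0,
    )


@pytest.fixture
def mfish_ref():
    """Purely quadratic aberration yield curve (no measurable linear term)."""
    return AberrationFitResult(
        y0=0.027, alpha=0.0, sigma_alpha=0.0, beta=0.051, sigma_beta=0.026,
        alpha_zero=True, n_points=3, residual_stat=0.0,
    )


@pytest.fixture
def mfish_test():
    """Linear-quadratic aberration yield curve for the sensitized condition."""
    return AberrationFitResult(
        y0=0.023, alpha=0.154, sigma_alpha=0.066, beta=0.034, sigma_beta=0.020,
        alpha_zero=False, n_points=3, residual_stat=0.0,
    )
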