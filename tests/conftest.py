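import numpy as np
import pytest

from stdcontrast import ContrastSpec, CovariateModel, DesignSpec, generate_dataset


# Learning-disabilities study summary statistics (three treatments for
# reading-test performance, baseline test score as covariate).
EXAMPLE = {
    "psih": 2.4823,
    "sigsqh": 3.2728,
    "v": 0.081437,
    "Q": 0.2131,
    "nu": 55,
    "nt": 59,
    "g": 3,
    "p": 1,
    "sizes": (19, 20, 20),
    "contrast": (-1.0, 0.5, 0.5),
}
EXAMPLE["psistar"] = EXAMPLE["psih"] / np.sqrt(EXAMPLE["sigsqh"])


@pytest.fixture(scope="session")
def example():
    return dict(EXAMPLE)


def make_design(p=1, theta=0.0, contrast=(1.0, -0.5, -0.5), ratios=(1, 1, 1),
                psi_star=0.5, sigma_sq=1.0, alpha=0.05, covariates=None):
    return DesignSpec(
        contrast=ContrastSpec(np.asarray(contrast, float)),
        ratios=np.asarray(ratios),
        psi_star=psi_star,
        covariates=covariates or CovariateModel(p=p, theta=theta),
        sigma_sq=sigma_sq,
        alpha=alpha,
    )


@pytest.fixture(scope="session")
def base_design():
    """The three-group planning design used throughout the numerical study."""
    return make_design()


@pytest.fixture
def small_dataset():
    """A small synthetic dataset: G = 3, P = 2, N_i = 6."""
    return generate_dataset(make_design(p=2, theta=0.25), 18, seed=42)
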