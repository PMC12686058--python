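import warnings

import numpy as np
import pytest

from aortauq import InputBounds, OgdenParams


@pytest.fixture(scope="session")
def bounds() -> InputBounds:
    """Reference epistemic bounds (the a2 nominal-outside-range warning is
    expected and silenced here)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return InputBounds.reference()


@pytest.fixture(scope="session")
def nominal_params() -> OgdenParams:
    return OgdenParams(5.0, 7.3, -0.4, 18.8)


def random_valid_params(rng: np.random.Generator) -> OgdenParams:
    """Ground-state-valid, identifiable Ogden parameter draws used by the
    oracle and recovery tests.

    The exponent ranges are kept disjoint: with alpha1 ~= alpha2 the two
    terms are collinear and only the curve — not the parameter split — is
    determined by data, so parameter-recovery checks are only meaningful
    for materials whose terms represent distinct response regimes.
    """
    return OgdenParams(
        mu1=float(rng.uniform(1.0, 8.0)),
        alpha1=float(rng.uniform(3.0, 9.0)),
        mu2=float(rng.uniform(-0.9, -0.05)),
        alpha2=float(rng.uniform(12.0, 20.0)),
    )
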