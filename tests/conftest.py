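import numpy as np
import pytest

import flexcif as fc


def make_constant_fit(lam1=0.2, lam2=0.1, sigma1=0.0, sigma2=0.0,
                      boundary=(0.0, 20.0)):
    """Two-cause constant-hazard fit built by hand.

    The degree-1 basis with equal coefficients gives a flat log-hazard, so
    exp(gamma) is the hazard.  The per-cause covariance is sigma^2 * 11'
    (perfectly correlated coefficients), which corresponds to a single
    underlying log-rate parameter with variance sigma^2.
    """
    models = []
    for cause, lam, sig in ((1, lam1, sigma1), (2, lam2, sigma2)):
        spec = fc.CauseModelSpec(cause, fc.SplineSpec(1, (), boundary))
        cov = sig ** 2 * np.ones((2, 2))
        models.append(fc.FittedCauseModel(spec, np.full(2, np.log(lam)),
                                          cov, 0.0, 0.0, True, 1))
    return fc.CompetingRisksFit(models)


@pytest.fixture(scope="session")
def const_fit():
    return make_constant_fit()


@pytest.fixture(scope="session")
def scenario1_data():
    """One moderate scenario-1 dataset shared across tests."""
    return fc.simulate_dataset(fc.scenario1_config(n=400), seed=11)


@pytest.fixture(scope="session")
def ref_fit(scenario1_data):
    """Cubic-spline two-cause fit on the shared scenario-1 dataset."""
    return fc.fit_competing(fc.study_model_specs("b"), scenario1_data,
                            fc.QuadratureRule(20))
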