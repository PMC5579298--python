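import logging
import warnings

import numpy as np
import pytest

import thermoburden as tb

logging.getLogger("thermoburden").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet():
    # basis clamping and missing-data warnings are expected in simulations
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_city():
    """One simulated 2-year city under the default truth."""
    cfg = tb.SimConfig(n_cities=1, years=2, rng_seed=424242)
    return cfg, tb.simulate_city(cfg, 0)


@pytest.fixture(scope="session")
def fitted_city(small_city):
    """Temperature + DTR fits for the small city (shared; fits are slow-ish)."""
    cfg, series = small_city
    tfit = tb.fit_temperature_model(series)
    dfit = tb.fit_dtr_model(series, tfit)
    return cfg, series, tfit, dfit


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_crossbasis_fit(rng, var_dim_knots=2, lag_knots=1, max_lag=4):
    """A random small cross-basis 'fit' for linear-algebra oracles."""
    var = tb.SplineSpec(kind="bspline_quadratic",
                        internal_knots=tuple(np.sort(rng.uniform(2, 8, var_dim_knots))),
                        boundary=(0.0, 10.0))
    lag = tb.SplineSpec(kind="natural_cubic",
                        internal_knots=tuple(np.sort(rng.uniform(0.5, max_lag - 0.5, lag_knots))),
                        boundary=(0.0, float(max_lag)), intercept=True)
    spec = tb.CrossBasisSpec(var_spec=var, lag_spec=lag, max_lag=max_lag)
    k = spec.dim
    A = rng.normal(size=(k, k))
    fit = tb.CityFit(
        coef=rng.normal(scale=0.05, size=k),
        vcov=A @ A.T * 1e-4,
        dispersion=1.0,
        fitted_log_mu=np.zeros(10),
        n_days_used=10,
        spec=spec,
    )
    return fit
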