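"""Shared fixtures: expensive global fits are computed once per session."""

import dataclasses

import numpy as np
import pytest

np.seterr(all="ignore")

from foldswitch import cest_fitting, realtime_kinetics, synthetic_data


@pytest.fixture(scope="session")
def fixtures():
    return synthetic_data.default_fixtures()


@pytest.fixture(scope="session")
def tjump_table(fixtures):
    return synthetic_data.simulate_realtime_dataset(fixtures["tjump20C"], seed=1)


@pytest.fixture(scope="session")
def tjump_fit(tjump_table):
    series = realtime_kinetics.series_from_table(tjump_table)
    keep, counts, fits = realtime_kinetics.filter_peaks(series)
    result = realtime_kinetics.global_fit_rates(keep)
    return {"series": keep, "counts": counts, "fits": fits, "result": result}


@pytest.fixture(scope="session")
def methyl_fit(fixtures):
    fx = fixtures["cestMethyl_20C"]
    table = synthetic_data.simulate_cest_dataset(fx, seed=1)
    profiles = cest_fitting.profiles_from_table(table, fx.scheme)
    fit = cest_fitting.fit_exchange_model(
        profiles, "two_state", r2_ties={"minor": "Ground"}, n_starts=2, seed=0
    )
    return fx, fit


@pytest.fixture(scope="session")
def cest20_fit(fixtures):
    fx = fixtures["cest15N_20C"]
    table = synthetic_data.simulate_cest_dataset(fx, seed=1)
    profiles = cest_fitting.profiles_from_table(table, fx.scheme)
    fit = cest_fitting.fit_exchange_model(
        profiles, "linear_three_state", r2_ties={"Enigma": "Ground"},
        n_starts=3, seed=0,
    )
    return fx, fit


@pytest.fixture(scope="session")
def cest4c_fit(fixtures):
    fx = fixtures["cest15N_4C"]
    table = synthetic_data.simulate_cest_dataset(fx, seed=1)
    profiles = cest_fitting.profiles_from_table(table, fx.scheme)
    fit = cest_fitting.fit_exchange_model(
        profiles, "linear_three_state", r2_ties={"Enigma": "Ground"},
        n_starts=2, seed=0, max_nfev=150,
    )
    return fx, fit


@pytest.fixture(scope="session")
def noiseless(fixtures):
    """Noise-free variant of any named fixture."""

    def make(name):
        return dataclasses.replace(fixtures[name], noise_sigma=0.0)

    return make
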