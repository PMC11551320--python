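"""CEST fitting: dip initialization, recovery, constraints, model ranking.

The unit tests here run on deliberately small synthetic setups (few
residues, coarse offset grids) so the whole module stays fast; the
full-size fixtures are exercised by the acceptance suite.
"""

import numpy as np
import pytest

from foldswitch.cest_fitting import (
    CESTProfile,
    TOPOLOGIES,
    compare_models,
    fit_exchange_model,
    initialize_from_dips,
    profiles_from_table,
)
from foldswitch.exchange_core import (
    AcquisitionScheme,
    ExchangeModel,
    cest_profiles,
)

np.seterr(all="ignore")

CARRIER = 119.0


def scheme(n_off=48, b1=20.0, t_relax=0.4):
    offsets = tuple(np.linspace(106.0, 132.0, n_off))
    return AcquisitionScheme(nucleus="N15", h1_freq_mhz=800.0, carrier_ppm=CARRIER,
                             b1_hz=b1, t_relax=t_relax, offsets_ppm=offsets)


def make_profiles(models_by_residue, sch, observed=("Ground",), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for res, model in models_by_residue.items():
        sims = cest_profiles(model, sch, observed)
        for obs, sim in zip(observed, sims):
            intensity = sim + rng.normal(0.0, noise, len(sim)) if noise else sim.copy()
            out.append(CESTProfile(
                residue=res, observed_state=obs,
                offsets_ppm=np.asarray(sch.offsets_ppm),
                intensity=intensity,
                sigma=np.full(len(sim), max(noise, 1e-4)),
                scheme=sch,
            ))
    return out


def two_state_models(dw_by_residue, kex=150.0, p_minor=0.08):
    return {
        res: ExchangeModel.two_state(
            kex=kex, p_minor=p_minor, dw_ppm=dw, r1=1.1, r2_major=9.0,
            labels=("Ground", "minor"), pos_major_ppm=pos - CARRIER,
        )
        for res, (pos, dw) in dw_by_residue.items()
    }


class TestDips:
    def test_slow_exchange_dips_recovered_within_grid_step(self):
        sch = scheme(n_off=120, b1=15.0)
        model = ExchangeModel.two_state(kex=25.0, p_minor=0.1, dw_ppm=5.3,
                                        r1=1.1, r2_major=9.0,
                                        labels=("Ground", "minor"),
                                        pos_major_ppm=117.0 - CARRIER)
        prof = make_profiles({1: model}, sch)[0]
        dips = initialize_from_dips(prof)
        step = np.diff(sch.offsets_ppm)[0]
        assert abs(dips[0] - 117.0) <= step + 1e-9
        assert any(abs(d - 122.3) <= step + 1e-9 for d in dips[1:])

    def test_flat_profile_returns_only_global_minimum(self):
        sch = scheme()
        prof = CESTProfile(1, "Ground", np.asarray(sch.offsets_ppm),
                           np.ones(len(sch.offsets_ppm)),
                           np.full(len(sch.offsets_ppm), 1e-3), sch)
        dips = initialize_from_dips(prof)
        assert len(dips) == 1

    def test_subthreshold_dip_not_reported(self):
        sch = scheme()
        off = np.asarray(sch.offsets_ppm)
        intensity = np.ones(len(off)) - 0.02 * np.exp(-((off - 124.0) / 0.5) ** 2)
        prof = CESTProfile(1, "Ground", off, intensity,
                           np.full(len(off), 1e-3), sch)
        dips = initialize_from_dips(prof, min_depth=0.05)
        assert not any(abs(d - 124.0) < 1.0 for d in dips[1:])


class TestTwoStateFit:
    def test_noiseless_fit_recovers_generator_exactly(self):
        sch = scheme()
        models = two_state_models({1: (114.0, 4.0), 2: (121.0, -3.4)})
        profiles = make_profiles(models, sch)
        fit = fit_exchange_model(profiles, "two_state",
                                 r2_ties={"minor": "Ground"}, n_starts=2, seed=0)
        assert fit.red_chi2 < 1e-4
        assert fit.edge_kex[("Ground", "minor")] == pytest.approx(150.0, rel=0.02)
        assert fit.populations["minor"] == pytest.approx(0.08, abs=0.002)

    def test_r2_tie_is_bit_exact(self):
        sch = scheme()
        models = two_state_models({1: (114.0, 4.0)})
        profiles = make_profiles(models, sch, noise=0.01, seed=3)
        fit = fit_exchange_model(profiles, "two_state",
                                 r2_ties={"minor": "Ground"}, n_starts=1, seed=0)
        row = fit.per_residue.iloc[0]
        assert row["r2_minor"] == row["r2_Ground"]

    def test_profiles_must_share_nucleus_and_carrier(self):
        sch_a = scheme()
        sch_b = AcquisitionScheme(nucleus="C13", h1_freq_mhz=800.0,
                                  carrier_ppm=16.5, b1_hz=20.0, t_relax=0.4,
                                  offsets_ppm=(10.0, 12.0))
        models = two_state_models({1: (114.0, 4.0)})
        profs = make_profiles(models, sch_a)
        bad = CESTProfile(2, "Ground", np.array([10.0, 12.0]),
                          np.ones(2), np.full(2, 1e-3), sch_b)
        with pytest.raises(ValueError):
            fit_exchange_model(profs + [bad], "two_state")


class TestModelComparison:
    @pytest.fixture(scope="class")
    def three_state_fits(self):
        """Fit three topologies to data generated from the linear chain."""
        sch = scheme(n_off=60, b1=15.0, t_relax=0.4)
        p = np.array([0.08, 0.87, 0.05])
        models = {}
        rng = np.random.default_rng(0)
        for res in (1, 2, 3):
            pos_g = float(rng.uniform(112.0, 126.0))
            rates = {
                ("Ground", "Enigma"): 12.0,
                ("Enigma", "Ground"): 12.0 * p[1] / p[0],
                ("Ground", "PD"): 6.0,
                ("PD", "Ground"): 6.0 * p[1] / p[2],
            }
            # the PD state resonates in the random-coil region (the
            # convention the fitter uses to name the two minors)
            pos_pd = float(rng.uniform(120.5, 122.5))
            pos_e = pos_g + 4.5 if pos_g < 124.0 else pos_g - 4.5
            models[res] = ExchangeModel(
                labels=("Enigma", "Ground", "PD"), populations=p, rates=rates,
                delta_omega=np.array([pos_e, pos_g, pos_pd]) - CARRIER,
                r1=np.full(3, 1.1), r2=np.full(3, 9.0),
            )
        profiles = make_profiles(models, sch, noise=0.01, seed=1)
        fits = {}
        fits["linear"] = fit_exchange_model(
            profiles, "linear_three_state", r2_ties={"Enigma": "Ground"},
            n_starts=2, seed=0, max_nfev=150,
        )
        fits["full"] = fit_exchange_model(
            profiles, "fully_connected_three_state", r2_ties={"Enigma": "Ground"},
            n_starts=1, seed=0, max_nfev=150, warm_start=fits["linear"],
        )
        fits["no_gpd"] = fit_exchange_model(
            profiles, "no_ground_pd_three_state", r2_ties={"Enigma": "Ground"},
            n_starts=2, seed=0, max_nfev=150,
        )
        return fits

    def test_removing_the_ground_pd_edge_fits_notably_worse(self, three_state_fits):
        fits = three_state_fits
        assert fits["no_gpd"].red_chi2 > 1.10 * fits["linear"].red_chi2

    def test_generating_model_and_superset_are_comparable(self, three_state_fits):
        fits = three_state_fits
        report = compare_models([fits["linear"], fits["full"], fits["no_gpd"]])
        assert report.best in ("linear_three_state", "fully_connected_three_state")
        assert ("fully_connected_three_state", "linear_three_state") in [
            tuple(sorted(pair)) for pair in report.indistinguishable
        ]
        assert report.ranking[-1] == "no_ground_pd_three_state"

    def test_superset_chi2_never_worse_than_nested(self, three_state_fits):
        fits = three_state_fits
        assert fits["full"].chi2 <= fits["linear"].chi2 * (1 + 1e-9)

    def test_superset_fit_keeps_populations_despite_flux_ambiguity(self, three_state_fits):
        # the extra minor-minor edge redistributes flux (it is famously
        # underdetermined between two sparse states) but the populations
        # stay pinned by the dip depths
        full = three_state_fits["full"]
        assert full.populations["Enigma"] == pytest.approx(0.08, abs=0.02)
        assert full.populations["PD"] == pytest.approx(0.05, abs=0.02)

    def test_rate_floor_flags_underdetermined_edges(self, three_state_fits):
        import dataclasses as dc

        a = three_state_fits["full"]
        tiny = dc.replace(a, edge_kex={**a.edge_kex, ("Enigma", "PD"): 1e-6})
        report = compare_models([tiny], rate_floor=1e-3)
        assert (tiny.topology, ("Enigma", "PD")) in report.underdetermined

    def test_identical_results_tie_with_stable_ordering(self, three_state_fits):
        a = three_state_fits["linear"]
        report = compare_models([a, a])
        assert report.ranking == ["linear_three_state", "linear_three_state"]
        assert report.indistinguishable

    def test_comparison_requires_same_data(self, three_state_fits):
        import dataclasses as dc

        a = three_state_fits["linear"]
        b = dc.replace(a, n_points=a.n_points + 7)
        with pytest.raises(ValueError):
            compare_models([a, b])


class TestTableRoundTrip:
    def test_profiles_from_table_normalizes_by_reference(self, fixtures, noiseless):
        import foldswitch.synthetic_data as sd

        fx = noiseless("cestMethyl_20C")
        table = sd.simulate_cest_dataset(fx)
        profs = profiles_from_table(table, fx.scheme)
        assert len(profs) == len(fx.cest_residues)
        for p in profs:
            assert p.intensity.max() <= 1.0 + 1e-9
            assert np.all(p.sigma > 0)
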