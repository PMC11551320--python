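"""Exchange-model algebra and Bloch-McConnell propagation."""

import numpy as np
import pytest

from foldswitch.exchange_core import (
    AcquisitionScheme,
    ConfigurationError,
    ExchangeModel,
    build_rate_matrix,
    carver_richards_r2eff,
    cest_profile,
    cest_profiles,
    cpmg_r2eff,
    rex_fast_limit,
    rex_slow_limit,
)

from helpers import euler_cest_profile


def nitrogen_cest(b1=20.0, t_relax=0.4, offsets=None, carrier=119.0):
    if offsets is None:
        offsets = tuple(np.arange(104.0, 135.0, 0.4))
    return AcquisitionScheme(
        nucleus="N15", h1_freq_mhz=800.0, carrier_ppm=carrier,
        b1_hz=b1, t_relax=t_relax, offsets_ppm=offsets,
    )


def cpmg_scheme(ncyc=(1, 2, 3, 4, 6, 8, 10, 15, 20, 25, 30, 40, 50, 60)):
    return AcquisitionScheme(
        nucleus="N15", h1_freq_mhz=600.0, t_ct=0.06, ncyc_values=ncyc,
    )


# an Enigma-like three-state chain used by several propagation tests
def enigma_chain():
    p = np.array([0.08, 0.89, 0.03])
    rates = {
        ("Ground", "Enigma"): 12.0,
        ("Enigma", "Ground"): 12.0 * p[1] / p[0],
        ("Ground", "PD"): 2.0,
        ("PD", "Ground"): 2.0 * p[1] / p[2],
    }
    return ExchangeModel(
        labels=("Enigma", "Ground", "PD"),
        populations=p,
        rates=rates,
        delta_omega=np.array([6.2, 0.0, 3.3]),
        r1=np.array([1.2, 1.2, 1.2]),
        r2=np.array([9.0, 9.0, 9.0]),
    )


class TestRateMatrix:
    def test_two_state_stationary_populations_follow_detailed_balance(self):
        model = ExchangeModel(
            labels=("A", "B"),
            populations=np.array([0.8, 0.2]),
            rates={("A", "B"): 1.0, ("B", "A"): 4.0},
            delta_omega=np.zeros(2), r1=np.ones(2), r2=np.ones(2),
        )
        K = build_rate_matrix(model)
        assert np.allclose(K.sum(axis=0), 0.0, atol=1e-12)
        assert np.allclose(K @ model.populations, 0.0, atol=1e-12)

    def test_symmetric_three_state_chain_is_uniform(self):
        p = np.full(3, 1.0 / 3.0)
        model = ExchangeModel(
            labels=("E", "G", "PD"),
            populations=p,
            rates={("E", "G"): 5.0, ("G", "E"): 5.0,
                   ("G", "PD"): 5.0, ("PD", "G"): 5.0},
            delta_omega=np.zeros(3), r1=np.ones(3), r2=np.ones(3),
        )
        K = build_rate_matrix(model)
        w, v = np.linalg.eig(K)
        i = int(np.argmin(np.abs(w)))
        stat = np.abs(v[:, i].real)
        stat /= stat.sum()
        assert np.allclose(stat, p, atol=1e-10)

    def test_enigma_chain_has_zero_eigenvalue_matching_populations(self):
        model = enigma_chain()
        K = build_rate_matrix(model)
        assert np.allclose(K.sum(axis=0), 0.0, atol=1e-10)
        w, v = np.linalg.eig(K)
        i = int(np.argmin(np.abs(w)))
        assert abs(w[i]) < 1e-10
        stat = np.abs(v[:, i].real)
        stat /= stat.sum()
        assert np.allclose(stat, model.populations, atol=1e-8)

    def test_unknown_state_in_rates_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            ExchangeModel(
                labels=("A", "B"),
                populations=np.array([0.5, 0.5]),
                rates={("A", "C"): 1.0},
                delta_omega=np.zeros(2), r1=np.ones(2), r2=np.ones(2),
            )

    def test_detailed_balance_violation_rejected(self):
        with pytest.raises(ConfigurationError):
            ExchangeModel(
                labels=("A", "B"),
                populations=np.array([0.5, 0.5]),
                rates={("A", "B"): 1.0, ("B", "A"): 3.0},
                delta_omega=np.zeros(2), r1=np.ones(2), r2=np.ones(2),
            )


class TestCestProfile:
    def test_single_populated_state_matches_one_state_profile(self):
        scheme = nitrogen_cest()
        two = ExchangeModel.two_state(kex=100.0, p_minor=0.0, dw_ppm=5.0,
                                      r1=1.2, r2_major=9.0, pos_major_ppm=-2.0)
        one = ExchangeModel(labels=("A",), populations=np.array([1.0]), rates={},
                            delta_omega=np.array([-2.0]), r1=np.array([1.2]),
                            r2=np.array([9.0]))
        assert np.allclose(cest_profile(two, scheme, "A"),
                           cest_profile(one, scheme, "A"), atol=1e-9)

    def test_slow_exchange_dips_at_both_state_positions(self):
        scheme = nitrogen_cest(offsets=tuple(np.arange(104.0, 135.0, 0.2)))
        model = ExchangeModel.two_state(kex=30.0, p_minor=0.1, dw_ppm=5.0,
                                        r1=1.2, r2_major=9.0, pos_major_ppm=-1.0)
        prof = cest_profile(model, scheme, "A")
        off = np.asarray(scheme.offsets_ppm)
        major_pos = 119.0 - 1.0
        minor_pos = major_pos + 5.0
        assert abs(off[np.argmin(prof)] - major_pos) <= 0.2 + 1e-9
        mask = np.abs(off - major_pos) > 2.0
        assert abs(off[mask][np.argmin(prof[mask])] - minor_pos) <= 0.2 + 1e-9

    def test_matrix_exponential_agrees_with_euler_integration(self):
        # offsets span the dip region; far off-resonance the explicit-Euler
        # oracle is amplitude-unstable (oscillatory modes) while the profile
        # is trivially ~1, so nothing would be tested there anyway
        model = enigma_chain()
        offsets = (115.5, 117.0, 119.0, 120.5, 122.3, 125.2)
        scheme = nitrogen_cest(offsets=offsets)
        fast = cest_profiles(model, scheme, ("Ground",))[0]
        slow = euler_cest_profile(model, scheme, "Ground", dt=1e-6)
        assert np.max(np.abs(fast - slow)) < 1e-3

    def test_zero_t_relax_returns_unit_reference(self):
        scheme = nitrogen_cest(t_relax=0.0, offsets=(110.0, 119.0, 128.0))
        model = enigma_chain()
        assert np.all(cest_profile(model, scheme, "Ground") == 1.0)

    def test_negative_b1_rejected(self):
        with pytest.raises(ConfigurationError):
            nitrogen_cest(b1=-5.0)

    def test_profile_bounded_and_near_one_far_off_resonance(self):
        model = enigma_chain()
        scheme = nitrogen_cest()
        prof = cest_profile(model, scheme, "Ground")
        assert np.all(prof > -0.05) and np.all(prof < 1.05)
        assert prof[0] > 0.98 and prof[-1] > 0.9

    def test_three_state_chain_reciprocity(self):
        """The Ground trace dips at both minors it exchanges with; the PD
        trace dips first-order at its direct partner (Ground) only.  At the
        Enigma offset the chain leaves just a weak Ground-relay response,
        which grows several-fold once a direct Enigma-PD edge is added."""
        # cold-condition populations: PD major, Enigma sparse
        p = np.array([0.02, 0.23, 0.75])
        positions = np.array([6.2, 0.0, 3.3])
        r1 = np.full(3, 1.2)
        r2 = np.full(3, 10.0)
        chain_rates = {
            ("Ground", "Enigma"): 6.0, ("Enigma", "Ground"): 6.0 * p[1] / p[0],
            ("Ground", "PD"): 2.0, ("PD", "Ground"): 2.0 * p[1] / p[2],
        }
        labels = ("Enigma", "Ground", "PD")
        chain = ExchangeModel(labels, p, chain_rates, positions, r1, r2)
        direct_rates = dict(chain_rates)
        direct_rates[("Enigma", "PD")] = 60.0
        direct_rates[("PD", "Enigma")] = 60.0 * p[0] / p[2]
        connected = ExchangeModel(labels, p, direct_rates, positions, r1, r2)

        off = np.arange(104.0, 135.0, 0.2)
        scheme = nitrogen_cest(b1=10.0, t_relax=0.5, offsets=tuple(off))
        pos = {lab: 119.0 + dw for lab, dw in zip(labels, positions)}

        def depth_at(prof, ppm, halfwidth=0.6):
            window = np.abs(off - ppm) <= halfwidth
            baseline = np.median(prof[np.abs(off - pos["Ground"]) > 6.0])
            return baseline - prof[window].min()

        g_prof, pd_prof = cest_profiles(chain, scheme, ("Ground", "PD"))
        assert depth_at(g_prof, pos["Enigma"]) > 0.05
        assert depth_at(g_prof, pos["PD"]) > 0.05
        assert depth_at(pd_prof, pos["Ground"]) > 0.05
        # no direct edge: only the (weaker) relay response remains
        relay = depth_at(pd_prof, pos["Enigma"])
        assert relay < 0.5 * depth_at(g_prof, pos["Enigma"])
        pd_direct = cest_profiles(connected, scheme, ("PD",))[0]
        assert depth_at(pd_direct, pos["Enigma"]) > 1.5 * relay

    def test_stationarity_without_b1(self):
        """With B1 = 0 and uniform R1, z-magnetization stays proportional to
        the stationary populations while decaying."""
        model = enigma_chain()
        scheme = nitrogen_cest(b1=0.0, t_relax=0.5, offsets=(110.0, 121.0))
        prof = cest_profiles(model, scheme, model.labels)
        # every state's normalized recovery is identical -> proportionality
        assert np.allclose(prof, 1.0, atol=1e-9)


class TestCpmg:
    def test_no_exchange_profile_is_flat_at_intrinsic_r2(self):
        model = ExchangeModel.two_state(kex=0.0, p_minor=0.0, dw_ppm=4.0,
                                        r1=1.2, r2_major=8.0)
        r2eff = cpmg_r2eff(model, cpmg_scheme(), "A")
        assert np.allclose(r2eff, 8.0, atol=1e-8)

    def test_two_state_dispersion_monotone_nonincreasing(self):
        model = ExchangeModel.two_state(kex=300.0, p_minor=0.06, dw_ppm=3.0,
                                        r1=1.2, r2_major=8.0)
        r2eff = cpmg_r2eff(model, cpmg_scheme(), "A")
        assert np.all(np.diff(r2eff) <= 1e-6)

    def test_fast_limit_matches_swift_connick_within_5_percent(self):
        scheme = cpmg_scheme()
        dw_ppm = 1.0
        dw_rad = dw_ppm * scheme.rad_per_ppm
        model = ExchangeModel.two_state(kex=10.0 * dw_rad, p_minor=0.05,
                                        dw_ppm=dw_ppm, r1=1.2, r2_major=8.0)
        r2eff = cpmg_r2eff(model, scheme, "A")
        rex_closed = rex_fast_limit(model, dw_rad)
        rex_numeric = r2eff[0] - 8.0
        assert rex_numeric == pytest.approx(rex_closed, rel=0.05)

    def test_slow_limit_rex_approaches_rate_of_leaving(self):
        """Deep slow exchange at low pulsing: Rex ~ k_AB within 10%."""
        scheme = cpmg_scheme(ncyc=(1, 2, 3))
        dw_ppm = 12.0  # dw = 6900 rad/s >> kex
        model = ExchangeModel.two_state(kex=90.0, p_minor=0.10, dw_ppm=dw_ppm,
                                        r1=1.2, r2_major=8.0)
        r2eff = cpmg_r2eff(model, scheme, "A")
        k_leave = rex_slow_limit(model, "A")
        assert r2eff[0] - 8.0 == pytest.approx(k_leave, rel=0.10)

    @pytest.mark.parametrize("kex", [150.0, 1000.0, 6000.0])
    @pytest.mark.parametrize("dw_ppm", [3.0, 4.0, 5.0])
    def test_dispersion_amplitude_matches_carver_richards(self, kex, dw_ppm):
        """Rex (dispersion amplitude) from the propagator agrees with the
        Carver-Richards closed form to 2% across exchange regimes."""
        scheme = cpmg_scheme()
        model = ExchangeModel.two_state(kex=kex, p_minor=0.08, dw_ppm=dw_ppm,
                                        r1=1.2, r2_major=8.0)
        bm = cpmg_r2eff(model, scheme, "A")
        nu = scheme.nu_cpmg(np.array(scheme.ncyc_values))
        cr = carver_richards_r2eff(kex, 0.08, dw_ppm * scheme.rad_per_ppm,
                                   8.0, 8.0, nu)
        rex_bm = bm.max() - bm.min()
        rex_cr = cr.max() - cr.min()
        assert rex_bm == pytest.approx(rex_cr, abs=0.02 * rex_bm)

    def test_ncyc_zero_is_reference_only(self):
        model = ExchangeModel.two_state(kex=100.0, p_minor=0.05, dw_ppm=3.0)
        scheme = cpmg_scheme(ncyc=(0, 10, 20))
        assert len(cpmg_r2eff(model, scheme, "A")) == 2


class TestClosedForms:
    def test_fast_limit_value(self):
        model = ExchangeModel.two_state(kex=10_000.0, p_minor=0.05, dw_ppm=1.0)
        assert rex_fast_limit(model, 1000.0) == pytest.approx(4.75)

    def test_fast_limit_zero_dw(self):
        model = ExchangeModel.two_state(kex=500.0, p_minor=0.05, dw_ppm=1.0)
        assert rex_fast_limit(model, 0.0) == 0.0

    def test_fast_limit_halves_when_kex_doubles(self):
        m1 = ExchangeModel.two_state(kex=500.0, p_minor=0.05, dw_ppm=1.0)
        m2 = ExchangeModel.two_state(kex=1000.0, p_minor=0.05, dw_ppm=1.0)
        assert rex_fast_limit(m1, 800.0) == pytest.approx(
            2.0 * rex_fast_limit(m2, 800.0)
        )

    def test_fast_limit_optional_dr2_correction(self):
        model = ExchangeModel.two_state(kex=5000.0, p_minor=0.05, dw_ppm=1.0,
                                        r2_major=10.0, r2_minor=30.0)
        base = rex_fast_limit(model, 1000.0)
        corrected = rex_fast_limit(model, 1000.0, include_dr2=True)
        assert corrected == pytest.approx(0.95 * 0.05 * (1000.0**2 - 400.0) / 5000.0)
        assert corrected < base

    def test_slow_limit_is_rate_of_leaving_each_side(self):
        model = ExchangeModel.two_state(kex=12.0 / 0.08, p_minor=0.08,
                                        dw_ppm=5.0, labels=("Ground", "Enigma"))
        assert rex_slow_limit(model, "Ground") == pytest.approx(12.0)
        assert rex_slow_limit(model, "Enigma") == pytest.approx(12.0 * 0.92 / 0.08)

    def test_slow_limit_zero_rate(self):
        model = ExchangeModel.two_state(kex=0.0, p_minor=0.0, dw_ppm=5.0)
        assert rex_slow_limit(model, "A") == 0.0

    def test_limit_formulas_require_two_states(self):
        model = enigma_chain()
        with pytest.raises(ValueError):
            rex_fast_limit(model, 100.0)
        with pytest.raises(ValueError):
            rex_slow_limit(model, "Ground")


class TestSerialization:
    def test_model_round_trip(self):
        model = enigma_chain()
        clone = ExchangeModel.from_dict(model.to_dict())
        assert clone.labels == model.labels
        assert np.allclose(clone.populations, model.populations)
        assert clone.rates == dict(model.rates)
        assert np.allclose(clone.delta_omega, model.delta_omega)

    def test_scheme_round_trip(self):
        for scheme in (nitrogen_cest(), cpmg_scheme()):
            clone = AcquisitionScheme.from_dict(scheme.to_dict())
            assert clone == scheme
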