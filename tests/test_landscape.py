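"""Populations, free energies, Eyring barriers, and landscape assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldswitch import synthetic_data as sd
from foldswitch.landscape import (
    R_KCAL,
    apply_temperature_offset,
    build_landscape,
    eyring_barrier,
    eyring_rate,
    merge_populations,
    populations_from_volumes,
    state_free_energies,
)


def volume_frame(volumes_by_residue_state, sigma=1.0):
    rows = []
    for (res, state), v in volumes_by_residue_state.items():
        rows.append({"peak_id": f"{state}_{res}", "residue": res, "state": state,
                     "volume": v, "sigma": sigma})
    return pd.DataFrame(rows)


class TestPopulationsFromVolumes:
    def test_simple_normalization(self):
        table = volume_frame({(1, "Ground"): 75.0, (1, "FS"): 15.0, (1, "PD"): 10.0})
        pops = populations_from_volumes(table)
        assert pops["Ground"].mean == pytest.approx(0.75)
        assert pops["FS"].mean == pytest.approx(0.15)
        assert pops["PD"].mean == pytest.approx(0.10)

    def test_scale_invariance(self):
        base = volume_frame({(1, "Ground"): 60.0, (1, "FS"): 40.0,
                             (2, "Ground"): 80.0, (2, "FS"): 20.0})
        doubled = base.copy()
        doubled["volume"] *= 2.0
        a = populations_from_volumes(base)
        b = populations_from_volumes(doubled)
        for state in a:
            assert a[state].mean == pytest.approx(b[state].mean)

    def test_noiseless_cold_fixture_returns_pd_three_quarters(self, noiseless):
        table = sd.simulate_volume_table(noiseless("volumes_4C"))
        pops = populations_from_volumes(table, temperature_k=277.15)
        assert pops["PD"].mean == pytest.approx(0.75, abs=1e-12)

    def test_incomplete_residues_excluded_from_average(self, caplog):
        table = volume_frame({(1, "Ground"): 80.0, (1, "FS"): 20.0,
                              (2, "Ground"): 99.0})
        with caplog.at_level("INFO"):
            pops = populations_from_volumes(table)
        assert pops["Ground"].n_residues == 1
        assert pops["Ground"].mean == pytest.approx(0.8)

    def test_round_trip_against_generator_populations(self, noiseless):
        fx = sd.default_fixtures()["volumes_4C"]
        table = sd.simulate_volume_table(noiseless("volumes_4C"))
        pops = populations_from_volumes(table)
        for state, p in fx.state_populations:
            assert pops[state].mean == pytest.approx(p, abs=1e-12)


class TestMergePopulations:
    def test_stated_rescaling_arithmetic(self):
        merged = merge_populations({"Ground": 0.92, "Enigma": 0.08},
                                   {"Ground": 0.80, "FS": 0.20})
        assert merged["Ground"] == pytest.approx(0.736)
        assert merged["Enigma"] == pytest.approx(0.064)
        assert merged["FS"] == pytest.approx(0.20)

    def test_missing_or_empty_anchor_rejected(self):
        with pytest.raises(ValueError):
            merge_populations({"Enigma": 1.0}, {"Ground": 0.8, "FS": 0.2})
        with pytest.raises(ValueError):
            merge_populations({"Ground": 0.0, "Enigma": 1.0},
                              {"Ground": 0.8, "FS": 0.2})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p_e=st.floats(0.01, 0.4),
        p_pd=st.floats(0.01, 0.4),
        p_fs=st.floats(0.01, 0.6),
    )
    def test_merged_set_always_sums_to_one(self, p_e, p_pd, p_fs):
        cest = {"Ground": 1.0 - p_e - p_pd, "Enigma": p_e, "PD": p_pd}
        if cest["Ground"] <= 0.01:
            return
        rt = {"Ground": 1.0 - p_fs, "FS": p_fs}
        merged = merge_populations(cest, rt)
        assert sum(merged.values()) == pytest.approx(1.0, abs=1e-12)


class TestFreeEnergies:
    def test_reference_state_sits_at_zero(self):
        dg = state_free_energies({"Ground": 0.8, "FS": 0.2}, 293.15)
        assert dg["Ground"] == 0.0

    def test_four_to_one_ratio_gives_0808_kcal(self):
        dg = state_free_energies({"Ground": 0.8, "FS": 0.2}, 293.15)
        assert dg["FS"] == pytest.approx(-R_KCAL * 293.15 * np.log(0.25), abs=1e-12)
        assert dg["FS"] == pytest.approx(0.808, abs=2e-3)

    def test_ordering_reverses_population_ordering(self):
        pops = {"A": 0.5, "B": 0.3, "C": 0.2}
        dg = state_free_energies(pops, 300.0, reference="A")
        order_p = sorted(pops, key=pops.get)
        order_g = sorted(dg, key=dg.get, reverse=True)
        assert order_p == order_g

    def test_unobserved_state_rejected(self):
        with pytest.raises(ValueError):
            state_free_energies({"Ground": 1.0, "FS": 0.0}, 293.15)


class TestEyring:
    def test_slow_rate_gives_23_kcal_barrier(self):
        assert eyring_barrier(0.09 / 3600.0, 293.15) == pytest.approx(23.3, abs=0.05)

    def test_prefactor_rate_gives_zero_barrier(self):
        from foldswitch.landscape import H_J, KB_J

        k = KB_J * 293.15 / H_J
        assert eyring_barrier(k, 293.15) == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_is_machine_precision(self):
        for k in (2.5e-5, 12.0, 173.0):
            back = eyring_rate(eyring_barrier(k, 293.15), 293.15)
            assert back == pytest.approx(k, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            eyring_barrier(0.0, 293.15)
        with pytest.raises(ValueError):
            eyring_barrier(1.0, 0.0)


class TestLandscapeAssembly:
    def build(self, temperature=293.15):
        pops = {"Ground": 0.736, "Enigma": 0.064, "PD": 0.027, "FS": 0.173}
        rates = {("Ground", "FS"): 0.09 / 3600.0,
                 ("Ground", "Enigma"): 12.0,
                 ("Ground", "PD"): 2.0}
        return build_landscape(pops, rates, temperature)

    def test_barriers_sit_above_their_end_states(self):
        scape = self.build()
        for (a, b), top in scape.barriers.items():
            assert top >= scape.free_energies[a]
            assert top >= scape.free_energies[b] - 1e-9

    def test_hour_scale_barrier_dominates_millisecond_barrier(self):
        """The Ground->FS step (0.09/h) towers over Ground->Enigma (12/s)."""
        scape = self.build()
        assert scape.barriers[("Ground", "FS")] > scape.barriers[("Ground", "Enigma")] + 5.0

    def test_cold_offset_shifts_everything_by_exactly_two(self):
        warm = self.build(293.15)
        cold = build_landscape(
            {"Ground": 0.23, "Enigma": 0.02, "PD": 0.75},
            {("Ground", "FS"): 1e-5, ("Ground", "Enigma"): 6.0, ("Ground", "PD"): 2.0},
            277.15,
        )
        shifted = apply_temperature_offset(cold, warm, offset_kcal=2.0,
                                           shared_transition=("Ground", "FS"))
        for state, g in cold.free_energies.items():
            assert shifted.free_energies[state] == pytest.approx(g + 2.0, abs=1e-12)
        for t, g in cold.barriers.items():
            assert shifted.barriers[t] == pytest.approx(g + 2.0, abs=1e-12)
        assert shifted.offset_applied == 2.0

    def test_zero_offset_is_identity(self):
        warm = self.build(293.15)
        cold = self.build(277.15)
        shifted = apply_temperature_offset(cold, warm, offset_kcal=0.0,
                                           shared_transition=("Ground", "FS"))
        assert shifted.free_energies == cold.free_energies

    def test_insufficient_offset_warns_with_minimal_compliant_value(self):
        warm = self.build(293.15)
        cold = build_landscape(
            {"Ground": 0.23, "Enigma": 0.02, "PD": 0.75},
            {("Ground", "FS"): 1e-3, ("Ground", "Enigma"): 6.0},
            277.15,
        )
        deficit = warm.barriers[("Ground", "FS")] - cold.barriers[("Ground", "FS")]
        assert deficit > 0.5  # premise: the cold barrier starts below
        with pytest.warns(UserWarning, match="minimal compliant offset"):
            shifted = apply_temperature_offset(cold, warm, offset_kcal=0.1,
                                               shared_transition=("Ground", "FS"))
        assert shifted.offset_applied == pytest.approx(0.1)

    def test_minimal_compliant_offset_equalizes_barriers(self):
        warm = self.build(293.15)
        cold = build_landscape(
            {"Ground": 0.23, "Enigma": 0.02, "PD": 0.75},
            {("Ground", "FS"): 1e-3, ("Ground", "Enigma"): 6.0},
            277.15,
        )
        minimal = warm.barriers[("Ground", "FS")] - cold.barriers[("Ground", "FS")]
        shifted = apply_temperature_offset(cold, warm, offset_kcal=minimal,
                                           shared_transition=("Ground", "FS"))
        assert shifted.barriers[("Ground", "FS")] == pytest.approx(
            warm.barriers[("Ground", "FS")], abs=1e-9
        )
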