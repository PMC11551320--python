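"""Stage 4: populations, state free energies, and Eyring barrier heights.

Populations come from two complementary measurements: peak-volume tables
(all states visible in slow exchange) and CEST fits (states invisible in
HSQC but exchanging on the millisecond scale).  The two are merged by
rescaling the CEST-visible ensemble to the real-time Ground-ensemble mass.

State free energies are Boltzmann inversions of populations relative to a
reference state, dG_i = -R T ln(p_i / p_ref); transition barriers come from
the Eyring equation dG' = -R T ln(k h / (kappa k_B T)) with transmission
coefficient kappa = 1.  Cross-temperature landscapes are aligned by a
constant offset applied to the cold-temperature free energies, chosen so
the absolute height of the shared rate-limiting barrier cannot decrease on
cooling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "R_KCAL",
    "KB_J",
    "H_J",
    "PopulationEstimate",
    "Landscape",
    "populations_from_volumes",
    "merge_populations",
    "state_free_energies",
    "eyring_barrier",
    "eyring_rate",
    "build_landscape",
    "apply_temperature_offset",
]

#: Gas constant in kcal/(mol K).
R_KCAL = 1.98720425e-3
#: Boltzmann constant (J/K) and Planck constant (J s), SI 2019 exact values.
KB_J = 1.380649e-23
H_J = 6.62607015e-34


@dataclass
class PopulationEstimate:
    state: str
    temperature_k: float
    mean: float
    per_residue: dict  # residue -> population
    n_residues: int


@dataclass
class Landscape:
    """Per-temperature free-energy landscape.

    ``free_energies`` are kcal/mol relative to the reference state;
    ``barriers`` maps directed transitions (a, b) to the absolute barrier
    top dG_a + dG'(k_ab), also relative to the reference state.
    """

    temperature_k: float
    populations: dict  # state -> fraction
    free_energies: dict  # state -> kcal/mol, reference state at 0
    barriers: dict  # (a, b) -> kcal/mol (barrier top above reference)
    reference: str
    offset_applied: float = 0.0

    def validate(self):
        total = sum(self.populations.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"populations sum to {total!r}, not 1")
        if abs(self.free_energies[self.reference] - self.offset_applied) > 1e-9:
            raise ValueError("reference state must sit at the applied offset")
        for (a, b), top in self.barriers.items():
            # the arrival state may be unresolved at this temperature (a
            # composite barrier drawn from the measured departing rate only)
            floor = max(self.free_energies.get(a, -np.inf),
                        self.free_energies.get(b, -np.inf))
            if top < floor - 1e-9:
                raise ValueError(
                    f"barrier {a}->{b} ({top:.3f}) below its end states ({floor:.3f})"
                )
        return self


def populations_from_volumes(table: pd.DataFrame,
                             temperature_k=293.15) -> dict:
    """Per-state populations from a multi-state peak-volume table.

    Per residue, populations are volumes normalized over that residue's
    assigned states (the per-residue response factor cancels); the estimate
    per state is the average across residues assigned to every state.
    Residues missing a state are excluded from the averages with a log
    entry (or, if no residue is complete, kept with a warning).
    """
    states = sorted(table["state"].unique())
    per_res = {}
    for res, grp in table.groupby("residue"):
        vols = grp.groupby("state")["volume"].mean()
        if (vols < 0).any():
            vols = vols.clip(lower=0.0)
        total = vols.sum()
        if total <= 0:
            logger.warning("residue %s: non-positive total volume, skipped", res)
            continue
        per_res[res] = (vols / total).to_dict()
    complete = {r: d for r, d in per_res.items() if set(d) == set(states)}
    if complete:
        skipped = sorted(set(per_res) - set(complete))
        if skipped:
            logger.info("residues without full state assignment excluded: %s", skipped)
        used = complete
    else:
        warnings.warn("no residue carries every state; averaging partial sets",
                      stacklevel=2)
        used = per_res
    out = {}
    for state in states:
        vals = {r: d[state] for r, d in used.items() if state in d}
        out[state] = PopulationEstimate(
            state=state,
            temperature_k=temperature_k,
            mean=float(np.mean(list(vals.values()))),
            per_residue=vals,
            n_residues=len(vals),
        )
    return out


def merge_populations(cest_pops: dict, realtime_pops: dict, anchor_state="Ground") -> dict:
    """Merge CEST populations with real-time populations via the anchor.

    The CEST experiment sees the anchor ensemble (e.g. Enigma/Ground/PD, all
    in fast-or-millisecond exchange) but not the slowly exchanging states
    (FS); the real-time experiment resolves the anchor ensemble's total
    share.  CEST fractions are therefore rescaled so their total equals the
    real-time anchor population, and real-time-only states pass through, so
    the merged set always sums to 1.
    """
    if anchor_state not in cest_pops or anchor_state not in realtime_pops:
        raise ValueError(f"anchor state {anchor_state!r} must appear in both inputs")
    if cest_pops[anchor_state] <= 0 or realtime_pops[anchor_state] <= 0:
        raise ValueError("anchor population must be positive in both inputs")
    cest_total = sum(cest_pops.values())
    scale = realtime_pops[anchor_state] / cest_total
    merged = {state: p * scale for state, p in cest_pops.items()}
    for state, p in realtime_pops.items():
        if state != anchor_state and state not in merged:
            merged[state] = p
    return merged


def state_free_energies(populations: dict, temperature_k, reference="Ground") -> dict:
    """Boltzmann inversion dG_i = -R T ln(p_i / p_ref), kcal/mol."""
    if reference not in populations:
        raise ValueError(f"reference state {reference!r} not in populations")
    p_ref = populations[reference]
    out = {}
    for state, p in populations.items():
        if p <= 0:
            raise ValueError(f"state {state!r} has non-positive population")
        out[state] = -R_KCAL * temperature_k * np.log(p / p_ref)
    return out


def eyring_barrier(k_s, temperature_k, kappa=1.0):
    """Activation free energy dG' = -R T ln(k h / (kappa k_B T)), kcal/mol."""
    if k_s <= 0:
        raise ValueError("rate constant must be positive")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return -R_KCAL * temperature_k * np.log(k_s * H_J / (kappa * KB_J * temperature_k))


def eyring_rate(dg_kcal, temperature_k, kappa=1.0):
    """Inverse of :func:`eyring_barrier`: k = kappa (k_B T / h) exp(-dG/RT)."""
    return (kappa * KB_J * temperature_k / H_J) * np.exp(
        -dg_kcal / (R_KCAL * temperature_k)
    )


def build_landscape(populations, rates_s, temperature_k, reference="Ground") -> Landscape:
    """Assemble a landscape from populations and directed rates (s^-1).

    Each transition's absolute barrier top is the departing state's free
    energy plus its Eyring activation energy.  Transitions measured in only
    one direction are drawn as a single effective barrier from the measured
    side.
    """
    dg = state_free_energies(populations, temperature_k, reference)
    barriers = {}
    for (a, b), k in rates_s.items():
        barriers[(a, b)] = dg[a] + eyring_barrier(k, temperature_k)
    return Landscape(
        temperature_k=temperature_k,
        populations=dict(populations),
        free_energies=dg,
        barriers=barriers,
        reference=reference,
    ).validate()


def apply_temperature_offset(landscape_cold: Landscape, landscape_warm: Landscape,
                             offset_kcal=2.0, shared_transition=None) -> Landscape:
    """Shift the cold-temperature landscape by a constant offset (kcal/mol).

    Free energies from population ratios are only defined up to a
    per-temperature constant; the cross-temperature alignment assumes the
    absolute height of the shared rate-limiting barrier cannot decrease on
    cooling.  All cold-temperature dG and barrier tops are shifted by
    ``offset_kcal``; if that still leaves the shared barrier below its
    warm-temperature height, a warning reports the minimal compliant offset.
    """
    if shared_transition is None:
        shared = set(landscape_cold.barriers) & set(landscape_warm.barriers)
        if not shared:
            raise ValueError("landscapes share no transition to align on")
        shared_transition = max(shared, key=lambda t: landscape_warm.barriers[t])
    elif (shared_transition not in landscape_cold.barriers
          or shared_transition not in landscape_warm.barriers):
        raise ValueError(f"transition {shared_transition} missing from a landscape")

    shifted = replace(
        landscape_cold,
        free_energies={s: g + offset_kcal for s, g in landscape_cold.free_energies.items()},
        barriers={t: g + offset_kcal for t, g in landscape_cold.barriers.items()},
        offset_applied=landscape_cold.offset_applied + offset_kcal,
    )
    deficit = landscape_warm.barriers[shared_transition] - shifted.barriers[shared_transition]
    if deficit > 1e-9:
        minimal = offset_kcal + deficit
        warnings.warn(
            f"offset {offset_kcal:g} kcal/mol leaves the shared barrier "
            f"{shared_transition} {deficit:.3f} kcal/mol below its warm-temperature "
            f"height; the minimal compliant offset is {minimal:.3f} kcal/mol",
            stacklevel=2,
        )
    return shifted
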