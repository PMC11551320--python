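"""Seeded generators for every input table the pipeline consumes.

The fixtures encode the reference conditions of a KaiB-style fold-switching
system: hour-timescale Ground <-> FS interconversion measured by real-time
HSQC series after a temperature jump, second-to-millisecond exchange with
the partially disordered (PD) and register-shifted (Enigma) states measured
by CEST and CPMG, and multi-state peak-volume tables for direct population
estimates.

Two seeds play different roles.  Each :class:`Fixture` carries a *structural*
seed that fixes the "sample": per-peak response factors, per-residue
chemical-shift positions and relaxation rates.  The ``seed`` argument of the
``simulate_*`` functions controls only the spectral noise, so changing it
re-draws the noise but never the noiseless signal.

All tables are tidy pandas DataFrames (one row per integrated peak volume)
with a fixed column set; :mod:`foldswitch.pipeline_io` writes and reads them
as tab-separated text.
"""

from __future__ import annotations

import warnings
import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from foldswitch.exchange_core import AcquisitionScheme, ExchangeModel, cest_profile, cpmg_r2eff

__all__ = [
    "Fixture",
    "default_fixtures",
    "simulate_realtime_dataset",
    "simulate_cest_dataset",
    "simulate_cpmg_dataset",
    "simulate_volume_table",
    "VOLUME_SCALE",
    "REALTIME_TIME_GRID_H",
]

#: Arbitrary-unit scale of a fully populated, unit-response peak volume.
#: Chosen so that the real-time amplitude filter threshold of 4e5 sits well
#: below every assigned switching peak and well above the weak decoys.
VOLUME_SCALE = 6.0e6

# Real-time series sampling: ~7 min dead time before the first HSQC, one
# spectrum every ~20 min, 16 h horizon.
_DEADTIME_H = 0.12
_SPACING_H = 0.33
_HORIZON_H = 16.0
REALTIME_TIME_GRID_H = _DEADTIME_H + _SPACING_H * np.arange(
    int((_HORIZON_H - _DEADTIME_H) / _SPACING_H) + 1
)


@dataclass(frozen=True)
class RealtimePeak:
    peak_id: str
    residue: int
    state: str
    response: float


@dataclass(frozen=True)
class CestResidue:
    residue: int
    positions_ppm: tuple  # absolute ppm, one per model state
    r1: float
    r2: float
    responses: tuple  # one per observed state


@dataclass(frozen=True)
class CpmgResidue:
    residue: int
    k_leave: float  # rate of leaving the observed (major) state, s^-1
    p_minor: float
    dw_ppm: float
    r2: float
    response: float


@dataclass(frozen=True)
class Fixture:
    """A fully specified synthetic experiment.

    The structural randomness (responses, positions, relaxation rates) is
    drawn once, at construction, from ``seed``; the object stores the
    realized values, so a fixture is reproducible from (name, seed) and the
    noiseless signal is independent of the simulation seed.
    """

    name: str
    kind: str  # realtime | cest | cpmg | volumes
    seed: int
    noise_sigma: float = 0.02
    temperature_c: float = 20.0
    # realtime
    realtime_rates: tuple | None = None  # (k_G->FS, k_FS->G) in h^-1
    initial_p_ground: float | None = None
    peaks: tuple = ()
    scale: float = 1.0  # cross-experiment intensity scale factor
    # cest / cpmg
    scheme: AcquisitionScheme | None = None
    extra_schemes: tuple = ()  # additional B1/t_relax conditions (CEST)
    labels: tuple | None = None
    populations: tuple | None = None
    rates_s: tuple = ()  # ((from, to, k_s), ...) directed, s^-1
    observed_states: tuple = ("Ground",)
    cest_residues: tuple = ()
    cpmg_residues: tuple = ()
    # volumes
    state_populations: tuple = ()  # ((state, p), ...)
    volume_residues: tuple = ()  # ((residue, response), ...)

    # -- derived models ----------------------------------------------------

    def residue_model(self, residue) -> ExchangeModel:
        """Exchange model of one CEST residue (positions relative to carrier)."""
        info = self._cest_residue(residue)
        return ExchangeModel(
            labels=self.labels,
            populations=np.asarray(self.populations, float),
            rates={(a, b): k for a, b, k in self.rates_s},
            delta_omega=np.asarray(info.positions_ppm, float) - self.scheme.carrier_ppm,
            r1=np.full(len(self.labels), info.r1),
            r2=np.full(len(self.labels), info.r2),
        )

    def cpmg_residue_model(self, residue) -> ExchangeModel:
        info = self._cpmg_residue(residue)
        kex = info.k_leave / info.p_minor
        return ExchangeModel.two_state(
            kex=kex,
            p_minor=info.p_minor,
            dw_ppm=info.dw_ppm,
            r1=1.2,
            r2_major=info.r2,
            labels=("Ground", "minor"),
        )

    def _cest_residue(self, residue) -> CestResidue:
        for info in self.cest_residues:
            if info.residue == residue:
                return info
        raise KeyError(f"fixture {self.name!r} has no CEST residue {residue}")

    def _cpmg_residue(self, residue) -> CpmgResidue:
        for info in self.cpmg_residues:
            if info.residue == residue:
                return info
        raise KeyError(f"fixture {self.name!r} has no CPMG residue {residue}")

    @property
    def all_schemes(self):
        return (self.scheme, *self.extra_schemes)

    @property
    def k_obs_h(self):
        return self.realtime_rates[0] + self.realtime_rates[1]

    @property
    def equilibrium_p_ground(self):
        k_gf, k_fg = self.realtime_rates
        return k_fg / (k_gf + k_fg)


# ---------------------------------------------------------------------------
# fixture construction helpers


def _realtime_fixture(name, seed, rates_h, scale=1.0, n_ground=45, n_fs=37, n_weak=4):
    rng = np.random.default_rng(seed)
    peaks = []
    # Residues 1..n_fs carry both a Ground and an FS peak (matched pairs for
    # the plateau-based population split); the remainder are Ground-only.
    for r in range(1, n_ground + 1):
        resp = float(np.clip(rng.lognormal(0.0, 0.3), 0.8, 2.5))
        peaks.append(RealtimePeak(f"G_{r}", r, "Ground", resp))
    for r in range(1, n_fs + 1):
        resp = float(np.clip(rng.lognormal(0.0, 0.3), 0.8, 2.5))
        peaks.append(RealtimePeak(f"FS_{r}", r, "FS", resp))
    # Weak unassigned peaks (integration artifacts / unassignable minor
    # cross peaks); they ride the Ground trajectory with a tiny response
    # and are dropped by the assignment clause of the peak filter.
    for j in range(n_weak):
        r = 100 + j
        peaks.append(RealtimePeak(f"u_{r}", r, "unassigned", float(rng.uniform(0.01, 0.03))))
    return Fixture(
        name=name,
        kind="realtime",
        seed=seed,
        realtime_rates=tuple(rates_h),
        initial_p_ground=0.6,
        peaks=tuple(peaks),
        scale=scale,
    )


def _ppm_grid(lo_ppm, hi_ppm, step_hz, larmor_mhz):
    step_ppm = step_hz / larmor_mhz
    n = int(np.floor((hi_ppm - lo_ppm) / step_ppm)) + 1
    return tuple(lo_ppm + step_ppm * np.arange(n))


def _cest_15n_scheme(b1_hz, t_relax):
    return AcquisitionScheme(
        nucleus="N15",
        h1_freq_mhz=800.0,
        carrier_ppm=119.0,
        b1_hz=b1_hz,
        t_relax=t_relax,
        offsets_ppm=_ppm_grid(104.0, 135.0, 25.0, 800.0 * 0.101329),
    )


def _three_state_rates(p, k_g_to_e, k_g_to_pd):
    """Directed rates of the linear Enigma <-> Ground <-> PD chain."""
    p_e, p_g, p_pd = p
    return (
        ("Ground", "Enigma", k_g_to_e),
        ("Enigma", "Ground", k_g_to_e * p_g / p_e),
        ("Ground", "PD", k_g_to_pd),
        ("PD", "Ground", k_g_to_pd * p_g / p_pd),
    )


def _cest_fixture_15n(name, seed, temperature_c, populations, k_g_to_e, k_g_to_pd,
                      residues, observed, b1_hz, t_relax, r2_range):
    rng = np.random.default_rng(seed)
    infos = []
    for r in residues:
        pos_g = float(rng.uniform(109.0, 130.0))
        sign = rng.choice([-1.0, 1.0])
        pos_e = float(np.clip(pos_g + sign * rng.uniform(2.5, 5.5), 105.5, 133.5))
        pos_pd = float(rng.uniform(119.5, 123.5))  # random-coil region
        infos.append(
            CestResidue(
                residue=r,
                positions_ppm=(pos_e, pos_g, pos_pd),
                r1=float(rng.uniform(1.0, 1.6)),
                r2=float(rng.uniform(*r2_range)),
                responses=tuple(float(np.clip(rng.lognormal(0.0, 0.3), 0.4, 3.0))
                                for _ in observed),
            )
        )
    return Fixture(
        name=name,
        kind="cest",
        seed=seed,
        temperature_c=temperature_c,
        scheme=_cest_15n_scheme(b1_hz, t_relax),
        labels=("Enigma", "Ground", "PD"),
        populations=tuple(populations),
        rates_s=_three_state_rates(populations, k_g_to_e, k_g_to_pd),
        observed_states=tuple(observed),
        cest_residues=tuple(infos),
    )


def _cest_fixture_two_state(name, seed, scheme, kex, p_minor, residue_dw, pos_range,
                            r1_range, r2_range, minor_label="Enigma"):
    rng = np.random.default_rng(seed)
    infos = []
    lo = min(scheme.offsets_ppm) + 0.8
    hi = max(scheme.offsets_ppm) - 0.8
    for r, dw in residue_dw:
        pos_g = float(rng.uniform(*pos_range))
        pos_b = float(np.clip(pos_g + dw, lo, hi))
        infos.append(
            CestResidue(
                residue=r,
                positions_ppm=(pos_g, pos_b),
                r1=float(rng.uniform(*r1_range)),
                r2=float(rng.uniform(*r2_range)),
                responses=(float(np.clip(rng.lognormal(0.0, 0.3), 0.4, 3.0)),),
            )
        )
    rates = (
        ("Ground", minor_label, kex * p_minor),
        (minor_label, "Ground", kex * (1.0 - p_minor)),
    )
    return Fixture(
        name=name,
        kind="cest",
        seed=seed,
        scheme=scheme,
        labels=("Ground", minor_label),
        populations=(1.0 - p_minor, p_minor),
        rates_s=rates,
        observed_states=("Ground",),
        cest_residues=tuple(infos),
    )


def _cpmg_fixture(name, seed, temperature_c, rate_scale, r2_scale):
    """Two-group CPMG fixture: Enigma-like residues with k_leave ~ 12 s^-1
    and PD-like residues with k_leave ~ 2 s^-1 (values at 25 degC, both
    doubling at 35 degC: slow-regime processes speed up with temperature).

    The CPMG acquisition is the high-sensitivity experiment of the set
    (32 scans per FID against 4 for the HSQC series, plus duplicate
    planes), so its spectral noise is set to 0.5% of the tallest peak."""
    rng = np.random.default_rng(seed)
    scheme = AcquisitionScheme(
        nucleus="N15",
        h1_freq_mhz=600.0,
        carrier_ppm=119.0,
        t_ct=0.06,
        ncyc_values=(0, 1, 2, 3, 4, 6, 8, 10, 15, 20, 25, 30, 40, 50, 60),
    )
    infos = []
    for j in range(8):  # Enigma-like group, Rex > 10 s^-1
        infos.append(
            CpmgResidue(
                residue=52 + j * 4,
                k_leave=12.0 * rate_scale,
                p_minor=0.08,
                dw_ppm=float(rng.uniform(3.0, 6.0) * rng.choice([-1, 1])),
                r2=float(rng.uniform(7.0, 13.0) * r2_scale),
                response=float(np.clip(rng.lognormal(0.0, 0.3), 0.7, 2.0)),
            )
        )
    for j in range(8):  # PD-like group, Rex ~ 2 s^-1
        infos.append(
            CpmgResidue(
                residue=10 + j * 4,
                k_leave=2.0 * rate_scale,
                p_minor=0.03,
                dw_ppm=float(rng.uniform(2.0, 5.0) * rng.choice([-1, 1])),
                r2=float(rng.uniform(7.0, 13.0) * r2_scale),
                response=float(np.clip(rng.lognormal(0.0, 0.3), 0.7, 2.0)),
            )
        )
    return Fixture(
        name=name,
        kind="cpmg",
        seed=seed,
        noise_sigma=0.005,
        temperature_c=temperature_c,
        scheme=scheme,
        observed_states=("Ground",),
        cpmg_residues=tuple(infos),
    )


def default_fixtures() -> dict:
    """The named experimental conditions.

    ========================= ====================================================
    name                      emulates
    ========================= ====================================================
    tjump20C                  40->20 degC temperature jump, k_G->FS = 0.09 h^-1,
                              k_FS->G = 0.36 h^-1, 45 Ground + 37 FS peaks
    tjump20C_cypa             same jump with the prolyl isomerase CypA added:
                              2.5x faster rates (0.24, 0.98 h^-1) and a 1.25x
                              higher intensity scale
    cest15N_4C                three-state Enigma<->Ground<->PD 15N CEST at 4 degC
                              (PD-dominant: p = 0.02/0.23/0.75), 11 residues
    cest15N_20C               same topology at 20 degC (p = 0.08/0.89/0.03,
                              k_G->E = 12 s^-1), 5 residues
    cestMethyl_20C            two-state 13C methyl CEST, kex = 173 s^-1,
                              p_b = 7%
    cest15N_beta1             two-state process of the beta1-strand residues
                              39-42: kex = 6.4 s^-1, p_b = 5%
    cpmg25C / cpmg35C         15N CPMG at two temperatures; Enigma-like group
                              (k_leave 12 s^-1) and PD-like group (2 s^-1),
                              rates doubling from 25 to 35 degC
    volumes_4C                peak-volume table at 4 degC, PD the major state
                              (p = 0.15/0.10/0.75 for Ground/FS/PD)
    ========================= ====================================================
    """
    fx = {}
    fx["tjump20C"] = _realtime_fixture("tjump20C", 101, (0.09, 0.36))
    fx["tjump20C_cypa"] = _realtime_fixture("tjump20C_cypa", 101, (0.24, 0.98), scale=1.25)
    fx["cest15N_4C"] = _cest_fixture_15n(
        "cest15N_4C", 104, 4.0,
        populations=(0.02, 0.23, 0.75),
        k_g_to_e=6.0, k_g_to_pd=2.0,
        residues=(52, 55, 58, 61, 64, 68, 72, 76, 80, 84, 88),
        observed=("Ground", "PD"),
        b1_hz=10.0, t_relax=0.5, r2_range=(8.0, 16.0),
    )
    fx["cest15N_20C"] = _cest_fixture_15n(
        "cest15N_20C", 105, 20.0,
        populations=(0.08, 0.89, 0.03),
        k_g_to_e=12.0, k_g_to_pd=2.0,
        residues=(81, 82, 84, 86, 88),
        observed=("Ground",),
        b1_hz=20.0, t_relax=0.4, r2_range=(6.0, 12.0),
    )
    methyl_scheme = AcquisitionScheme(
        nucleus="C13",
        h1_freq_mhz=800.0,
        carrier_ppm=16.5,
        b1_hz=20.0,
        t_relax=0.4,
        offsets_ppm=_ppm_grid(8.0, 25.0, 40.0, 800.0 * 0.251450),
    )
    fx["cestMethyl_20C"] = _cest_fixture_two_state(
        "cestMethyl_20C", 106, methyl_scheme,
        kex=173.0, p_minor=0.07,
        # half the probes with small methyl dw (< 0.7 ppm), half in the
        # larger group around the register-shifted strand, up to 4.1 ppm
        residue_dw=((17, 0.35), (46, -0.5), (60, 0.65), (69, -0.6), (74, 0.45),
                    (78, -0.3), (54, 1.6), (57, -1.2), (72, 2.0), (81, -2.4),
                    (85, 3.0), (82, 4.1)),
        pos_range=(11.0, 22.0), r1_range=(0.4, 0.8), r2_range=(4.0, 9.0),
    )
    rng_b1 = np.random.default_rng(107)
    fx["cest15N_beta1"] = dataclasses.replace(
        _cest_fixture_two_state(
            "cest15N_beta1", 107, _cest_15n_scheme(10.0, 0.5),
            kex=6.4, p_minor=0.05,
            residue_dw=tuple((r, float(rng_b1.uniform(2.5, 4.5) * rng_b1.choice([-1, 1])))
                             for r in (39, 40, 41, 42)),
            pos_range=(112.0, 127.0), r1_range=(1.0, 1.6), r2_range=(6.0, 12.0),
            minor_label="alt",
        ),
        # slow exchange needs both B1 fields to break the kex-p degeneracy
        extra_schemes=(_cest_15n_scheme(20.0, 0.4),),
    )
    fx["cpmg25C"] = _cpmg_fixture("cpmg25C", 108, 25.0, rate_scale=1.0, r2_scale=1.0)
    fx["cpmg35C"] = _cpmg_fixture("cpmg35C", 108, 35.0, rate_scale=2.0, r2_scale=0.85)
    rng_v = np.random.default_rng(109)
    fx["volumes_4C"] = Fixture(
        name="volumes_4C",
        kind="volumes",
        seed=109,
        temperature_c=4.0,
        state_populations=(("Ground", 0.15), ("FS", 0.10), ("PD", 0.75)),
        volume_residues=tuple(
            (r, float(np.clip(rng_v.lognormal(0.0, 0.3), 0.4, 3.0)))
            for r in (52, 55, 58, 61, 64, 68, 72, 76, 80, 84, 88, 90)
        ),
    )
    return fx


# ---------------------------------------------------------------------------
# simulators


def _noise_rng(fixture, seed):
    return np.random.default_rng(fixture.seed if seed is None else seed)


def simulate_realtime_dataset(fixture: Fixture, seed=None) -> pd.DataFrame:
    """Temperature-jump peak-volume time series.

    Each peak follows ``I(t) = response * VOLUME_SCALE * p_state(t)`` with
    the shared two-state relaxation ``p(t) = p_eq + (p0 - p_eq) e^(-k_obs t)``
    (k_obs = k_G->FS + k_FS->G), plus Gaussian spectral noise whose sd is
    ``noise_sigma`` times the largest noiseless volume.  Weak decoy peaks do
    not switch (their state populations still do; their responses are tiny).
    """
    if fixture.kind != "realtime":
        raise ValueError(f"fixture {fixture.name!r} is not a real-time fixture")
    rng = _noise_rng(fixture, seed)
    k_obs = fixture.k_obs_h
    p_g_eq = fixture.equilibrium_p_ground
    p_g0 = fixture.initial_p_ground
    if abs(p_g0 - p_g_eq) < 1e-12:
        warnings.warn(
            "initial populations equal equilibrium populations: no observable decay",
            stacklevel=2,
        )
    t = REALTIME_TIME_GRID_H
    decay = np.exp(-k_obs * t)
    p_g = p_g_eq + (p_g0 - p_g_eq) * decay
    traj = {"Ground": p_g, "FS": 1.0 - p_g, "unassigned": p_g}

    rows = []
    for pk in fixture.peaks:
        v = pk.response * VOLUME_SCALE * traj[pk.state]
        rows.append((pk.peak_id, pk.residue, pk.state, v))
    noiseless = np.stack([v for *_, v in rows])
    sigma = fixture.noise_sigma * noiseless.max()
    out = []
    for (peak_id, residue, state, v), noise in zip(
        rows, rng.normal(0.0, sigma, size=noiseless.shape)
    ):
        scaled = (v + noise) * fixture.scale
        sig = (sigma if sigma > 0 else 1.0) * fixture.scale
        for ti, vi in zip(t, scaled):
            out.append((peak_id, residue, state, ti, vi, sig))
    return pd.DataFrame(
        out, columns=["peak_id", "residue", "state", "time_h", "volume", "sigma"]
    )


def simulate_cest_dataset(fixture: Fixture, seed=None) -> pd.DataFrame:
    """CEST peak-volume table: one reference plane plus one row per offset,
    per residue and observed state.  Volumes are the forward-model profile
    times the reference volume, plus spectral noise."""
    if fixture.kind != "cest":
        raise ValueError(f"fixture {fixture.name!r} is not a CEST fixture")
    rng = _noise_rng(fixture, seed)
    scheme = fixture.scheme
    obs_index = {s: fixture.labels.index(s) for s in fixture.observed_states}
    rows = []
    for info in fixture.cest_residues:
        model = fixture.residue_model(info.residue)
        for sch in fixture.all_schemes:
            for j, obs in enumerate(fixture.observed_states):
                profile = cest_profile(model, sch, obs)
                ref = info.responses[j] * VOLUME_SCALE * model.populations[obs_index[obs]]
                peak_id = f"{obs}_{info.residue}"
                rows.append((peak_id, info.residue, obs, sch.b1_hz, np.nan, 1, ref))
                for off, rel in zip(sch.offsets_ppm, profile):
                    rows.append((peak_id, info.residue, obs, sch.b1_hz, off, 0, rel * ref))
    df = pd.DataFrame(
        rows,
        columns=["peak_id", "residue", "state", "b1_hz", "offset_ppm", "ref", "volume"],
    )
    sigma = fixture.noise_sigma * df["volume"].max()
    df["volume"] += rng.normal(0.0, sigma, size=len(df))
    df["sigma"] = sigma if sigma > 0 else 1.0
    return df


def simulate_cpmg_dataset(fixture: Fixture, seed=None) -> pd.DataFrame:
    """Constant-time CPMG volume table, duplicate planes at ncyc 0, 30, 60.

    Volumes are ``reference * exp(-R2eff * t_ct)`` from the Bloch-McConnell
    propagator, plus spectral noise; the repeats support duplicate-based
    uncertainty estimation downstream.
    """
    if fixture.kind != "cpmg":
        raise ValueError(f"fixture {fixture.name!r} is not a CPMG fixture")
    rng = _noise_rng(fixture, seed)
    scheme = fixture.scheme
    duplicated = (0, 30, 60)
    rows = []
    for info in fixture.cpmg_residues:
        model = fixture.cpmg_residue_model(info.residue)
        ncyc_pos = [n for n in scheme.ncyc_values if n > 0]
        r2eff = cpmg_r2eff(model, scheme, "Ground")
        ref = info.response * VOLUME_SCALE * model.populations[0]
        peak_id = f"G_{info.residue}"
        by_ncyc = dict(zip(ncyc_pos, ref * np.exp(-r2eff * scheme.t_ct)))
        by_ncyc[0] = ref
        for n in scheme.ncyc_values:
            reps = 2 if n in duplicated else 1
            for _ in range(reps):
                rows.append((peak_id, info.residue, "Ground", n, by_ncyc[n]))
    df = pd.DataFrame(rows, columns=["peak_id", "residue", "state", "ncyc", "volume"])
    sigma = fixture.noise_sigma * df["volume"].max()
    df["volume"] += rng.normal(0.0, sigma, size=len(df))
    df["sigma"] = sigma if sigma > 0 else 1.0
    return df


def simulate_volume_table(fixture: Fixture, seed=None) -> pd.DataFrame:
    """Multi-state peak-volume table: per residue, one volume per assigned
    state, proportional to population times the residue's response factor."""
    if fixture.kind != "volumes":
        raise ValueError(f"fixture {fixture.name!r} is not a volume fixture")
    rng = _noise_rng(fixture, seed)
    rows = []
    for residue, resp in fixture.volume_residues:
        for state, p in fixture.state_populations:
            rows.append((f"{state}_{residue}", residue, state, resp * VOLUME_SCALE * p))
    df = pd.DataFrame(rows, columns=["peak_id", "residue", "state", "volume"])
    sigma = fixture.noise_sigma * df["volume"].max()
    df["volume"] += rng.normal(0.0, sigma, size=len(df))
    df["sigma"] = sigma if sigma > 0 else 1.0
    return df
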