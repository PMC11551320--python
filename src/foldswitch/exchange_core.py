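"""Forward models of N-site chemical exchange.

This module owns the kinetic scheme (state labels, first-order rate
constants, stationary populations) and the Bloch-McConnell magnetization
propagation used to predict the two relaxation-dispersion observables:

* CEST: a weak B1 field is applied at a grid of offsets for a saturation
  period ``t_relax``; the longitudinal magnetization of the observed state,
  normalized by a no-saturation reference, dips wherever a state (major or
  exchange-connected minor) resonates.
* CPMG: transverse magnetization evolves for a constant time ``t_ct``
  interrupted by trains of ideal 180-degree pulses; the effective relaxation
  rate R2,eff(nu_cpmg) = -ln(I/I0)/t_ct decays from R2 + Rex toward the
  intrinsic R2 as the pulse rate outruns the exchange.

Closed-form limits (Swift-Connick fast limit, rate-of-leaving slow limit,
Carver-Richards two-state dispersion) are provided as oracles and
initializers; the numerical propagators are the reference implementation.

Unit conventions
----------------
Rates in s^-1, times in s, chemical shifts in ppm relative to the scheme's
carrier, B1 and nu_cpmg in Hz.  All ppm <-> rad/s conversions go through
``AcquisitionScheme.rad_per_ppm`` so that the gyromagnetic-ratio constants
live in exactly one place (``GAMMA_FRACTION``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "GAMMA_FRACTION",
    "ExchangeModel",
    "AcquisitionScheme",
    "build_rate_matrix",
    "cest_profile",
    "cest_profiles",
    "cpmg_r2eff",
    "carver_richards_r2eff",
    "rex_fast_limit",
    "rex_slow_limit",
]

#: Larmor frequency of each nucleus as a fraction of the 1H frequency at the
#: same field.  The spectrometer field is conventionally quoted as the 1H
#: frequency in MHz, so e.g. a "800 MHz" magnet detects 15N at
#: 800 * 0.101329 = 81.06 MHz and 1 ppm of 15N is 81.06 Hz.  Signs of the
#: gyromagnetic ratios are dropped; all profiles depend only on offset
#: differences.
GAMMA_FRACTION = {"H1": 1.0, "N15": 0.101329, "C13": 0.251450}

_POP_TOL = 1e-9
_STATIONARY_TOL = 1e-8


class ConfigurationError(ValueError):
    """Raised when an exchange topology or scheme is internally inconsistent."""


@dataclass(frozen=True)
class ExchangeModel:
    """An N-state exchange model with per-state NMR parameters.

    Parameters
    ----------
    labels:
        State names, e.g. ``("Ground", "Enigma")``.
    populations:
        Stationary fractions, one per state, summing to 1.
    rates:
        Directed first-order rate constants ``{(i_label, j_label): k_ij}``
        in s^-1 for every exchanging edge (both directions).  Detailed
        balance ``p_i * k_ij == p_j * k_ji`` must hold on every edge.
    delta_omega:
        Chemical-shift position of each state in ppm **relative to the
        acquisition carrier**.
    r1, r2:
        Per-state longitudinal / transverse relaxation rates (s^-1).
    """

    labels: tuple
    populations: np.ndarray
    rates: Mapping
    delta_omega: np.ndarray
    r1: np.ndarray
    r2: np.ndarray

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        n = len(labels)
        for name in ("populations", "delta_omega", "r1", "r2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ConfigurationError(
                    f"{name} must have one entry per state ({n}), got shape {arr.shape}"
                )
            object.__setattr__(self, name, arr)
        if n < 1:
            raise ConfigurationError("need at least one state")
        if abs(self.populations.sum() - 1.0) > _POP_TOL:
            raise ConfigurationError(
                f"populations must sum to 1 (got {self.populations.sum()!r})"
            )
        if np.any(self.populations < 0):
            raise ConfigurationError("populations must be non-negative")
        if np.any(self.r1 < 0) or np.any(self.r2 < 0):
            raise ConfigurationError("relaxation rates must be non-negative")
        rates = dict(self.rates)
        object.__setattr__(self, "rates", rates)
        idx = {lab: i for i, lab in enumerate(labels)}
        for (a, b), k in rates.items():
            if a not in idx or b not in idx:
                raise ConfigurationError(f"rate references unknown state: {(a, b)}")
            if k < 0:
                raise ConfigurationError(f"negative rate for edge {(a, b)}")
        # detailed balance on every edge
        for (a, b), k_ab in rates.items():
            k_ba = rates.get((b, a), 0.0)
            flux_ab = self.populations[idx[a]] * k_ab
            flux_ba = self.populations[idx[b]] * k_ba
            if abs(flux_ab - flux_ba) > _STATIONARY_TOL * max(1.0, flux_ab, flux_ba):
                raise ConfigurationError(
                    f"detailed balance violated on edge {a}<->{b}: "
                    f"{flux_ab!r} vs {flux_ba!r}"
                )

    # -- constructors ------------------------------------------------------

    @classmethod
    def two_state(
        cls,
        kex,
        p_minor,
        dw_ppm,
        r1=1.0,
        r2_major=10.0,
        r2_minor=None,
        labels=("A", "B"),
        pos_major_ppm=0.0,
    ):
        """Two-state model from the usual (kex, p_b, dw) parametrization.

        ``kex = k_AB + k_BA`` and detailed balance fix the directional
        rates: ``k_AB = kex * p_minor``, ``k_BA = kex * (1 - p_minor)``.
        """
        if not 0.0 <= p_minor < 1.0:
            raise ConfigurationError("p_minor must be in [0, 1)")
        a, b = labels
        p = np.array([1.0 - p_minor, p_minor])
        rates = {(a, b): kex * p_minor, (b, a): kex * (1.0 - p_minor)}
        r2b = r2_major if r2_minor is None else r2_minor
        return cls(
            labels=(a, b),
            populations=p,
            rates=rates,
            delta_omega=np.array([pos_major_ppm, pos_major_ppm + dw_ppm]),
            r1=np.array([r1, r1]),
            r2=np.array([r2_major, r2b]),
        )

    @classmethod
    def from_edges(cls, labels, populations, edge_kex, positions_ppm, r1, r2):
        """Build a model from undirected edge exchange rates.

        ``edge_kex`` maps unordered pairs ``(a, b)`` to the edge's total
        exchange rate ``k_ab + k_ba``; directional rates follow from the
        stationary populations via detailed balance.
        """
        labels = tuple(labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        p = np.asarray(populations, dtype=float)
        rates = {}
        for (a, b), kex in edge_kex.items():
            pa, pb = p[idx[a]], p[idx[b]]
            tot = pa + pb
            if tot <= 0:
                raise ConfigurationError(f"edge {a}<->{b} joins two empty states")
            rates[(a, b)] = kex * pb / tot
            rates[(b, a)] = kex * pa / tot
        r1 = np.broadcast_to(np.asarray(r1, dtype=float), (len(labels),)).copy()
        r2 = np.broadcast_to(np.asarray(r2, dtype=float), (len(labels),)).copy()
        return cls(labels, p, rates, np.asarray(positions_ppm, float), r1, r2)

    # -- helpers -----------------------------------------------------------

    @property
    def n_states(self):
        return len(self.labels)

    def index(self, label):
        try:
            return self.labels.index(label)
        except ValueError:
            raise ConfigurationError(
                f"unknown state {label!r}; states are {self.labels}"
            ) from None

    def rate(self, a, b):
        """Directed rate constant k_{a->b} (0 for non-edges)."""
        return self.rates.get((a, b), 0.0)

    def kex(self, a, b):
        """Edge exchange rate k_{a->b} + k_{b->a}."""
        return self.rate(a, b) + self.rate(b, a)

    def leaving_rate(self, label):
        """Total rate of leaving a state (sum of its outgoing edges)."""
        return sum(k for (a, _b), k in self.rates.items() if a == label)

    def to_dict(self):
        return {
            "labels": list(self.labels),
            "populations": [float(x) for x in self.populations],
            "rates": [[a, b, float(k)] for (a, b), k in sorted(self.rates.items())],
            "delta_omega": [float(x) for x in self.delta_omega],
            "r1": [float(x) for x in self.r1],
            "r2": [float(x) for x in self.r2],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            labels=tuple(d["labels"]),
            populations=np.asarray(d["populations"], float),
            rates={(a, b): float(k) for a, b, k in d["rates"]},
            delta_omega=np.asarray(d["delta_omega"], float),
            r1=np.asarray(d["r1"], float),
            r2=np.asarray(d["r2"], float),
        )


@dataclass(frozen=True)
class AcquisitionScheme:
    """Acquisition parameters for a CEST or CPMG experiment.

    A scheme is a CEST scheme when ``t_relax`` and ``offsets_ppm`` are set,
    and a CPMG scheme when ``t_ct`` and ``ncyc_values`` are set.  Offsets and
    the carrier are absolute ppm; state positions in :class:`ExchangeModel`
    are relative to ``carrier_ppm``.
    """

    nucleus: str
    h1_freq_mhz: float
    carrier_ppm: float = 0.0
    b1_hz: float | None = None
    t_relax: float | None = None
    offsets_ppm: tuple | None = None
    t_ct: float | None = None
    ncyc_values: tuple | None = None

    def __post_init__(self):
        if self.nucleus not in GAMMA_FRACTION:
            raise ConfigurationError(
                f"unknown nucleus {self.nucleus!r}; known: {sorted(GAMMA_FRACTION)}"
            )
        if self.offsets_ppm is not None:
            object.__setattr__(self, "offsets_ppm", tuple(float(o) for o in self.offsets_ppm))
        if self.ncyc_values is not None:
            object.__setattr__(self, "ncyc_values", tuple(int(n) for n in self.ncyc_values))
        if self.kind == "cest":
            if self.t_relax is None or self.t_relax < 0:
                raise ConfigurationError("CEST scheme needs t_relax >= 0")
            if self.b1_hz is None or self.b1_hz < 0:
                raise ConfigurationError("CEST scheme needs b1_hz >= 0")
        elif self.kind == "cpmg":
            if self.t_ct is None or self.t_ct <= 0:
                raise ConfigurationError("CPMG scheme needs t_ct > 0")
            if any(n < 0 for n in self.ncyc_values):
                raise ConfigurationError("ncyc values must be >= 0")
        else:
            raise ConfigurationError(
                "scheme must define either (t_relax, offsets_ppm) or (t_ct, ncyc_values)"
            )

    @property
    def kind(self):
        if self.offsets_ppm is not None and self.t_relax is not None:
            return "cest"
        if self.ncyc_values is not None and self.t_ct is not None:
            return "cpmg"
        return "invalid"

    @property
    def larmor_mhz(self):
        """Observed-nucleus Larmor frequency in MHz; also Hz per ppm."""
        return self.h1_freq_mhz * GAMMA_FRACTION[self.nucleus]

    @property
    def rad_per_ppm(self):
        return 2.0 * np.pi * self.larmor_mhz

    def nu_cpmg(self, ncyc):
        """CPMG refocusing frequency ncyc / t_ct in Hz."""
        ncyc = np.asarray(ncyc)
        if np.any(ncyc <= 0):
            raise ValueError("nu_cpmg is undefined for the ncyc = 0 reference")
        return ncyc / self.t_ct

    def to_dict(self):
        d = {
            "nucleus": self.nucleus,
            "h1_freq_mhz": float(self.h1_freq_mhz),
            "carrier_ppm": float(self.carrier_ppm),
        }
        if self.kind == "cest":
            d.update(
                b1_hz=float(self.b1_hz),
                t_relax=float(self.t_relax),
                offsets_ppm=[float(o) for o in self.offsets_ppm],
            )
        else:
            d.update(t_ct=float(self.t_ct), ncyc_values=[int(n) for n in self.ncyc_values])
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})


# ---------------------------------------------------------------------------
# rate matrix and propagation


def build_rate_matrix(model: ExchangeModel) -> np.ndarray:
    """Assemble the first-order exchange rate matrix K (s^-1).

    ``dp/dt = K @ p`` with ``K[j, i] = k_{i->j}`` off-diagonal; every column
    sums to zero and the model's stationary populations span the null space.
    """
    n = model.n_states
    idx = {lab: i for i, lab in enumerate(model.labels)}
    K = np.zeros((n, n))
    for (a, b), k in model.rates.items():
        K[idx[b], idx[a]] += k
        K[idx[a], idx[a]] -= k
    return K


def _bm_cest_matrix(model, scheme):
    """Offset-batched Bloch-McConnell evolution matrices, shape (m, 3n, 3n).

    Per-state block layout (Mx, My, Mz) with B1 along +x in the frame
    rotating at the saturation offset:

        dMx/dt = -R2 Mx - Omega My
        dMy/dt = +Omega Mx - R2 My + w1 Mz
        dMz/dt =           - w1 My - R1 Mz

    plus the exchange coupling kron(K, I3).  The longitudinal relaxation is
    homogeneous (decay toward zero); the no-saturation reference is
    propagated identically, so the normalized profile tends to 1 far
    off-resonance regardless of R1.
    """
    n = model.n_states
    K = build_rate_matrix(model)
    w1 = 2.0 * np.pi * scheme.b1_hz
    offsets = np.asarray(scheme.offsets_ppm, float) - scheme.carrier_ppm
    omega = (model.delta_omega[None, :] - offsets[:, None]) * scheme.rad_per_ppm

    A0 = np.kron(K, np.eye(3))
    for i in range(n):
        A0[3 * i + 0, 3 * i + 0] -= model.r2[i]
        A0[3 * i + 1, 3 * i + 1] -= model.r2[i]
        A0[3 * i + 2, 3 * i + 2] -= model.r1[i]
        A0[3 * i + 1, 3 * i + 2] += w1
        A0[3 * i + 2, 3 * i + 1] -= w1
    A = np.broadcast_to(A0, (len(offsets), 3 * n, 3 * n)).copy()
    for i in range(n):
        A[:, 3 * i + 0, 3 * i + 1] = -omega[:, i] + A0[3 * i, 3 * i + 1]
        A[:, 3 * i + 1, 3 * i + 0] = omega[:, i] + A0[3 * i + 1, 3 * i]
    return A


def _propagate_batched(A, M0, t):
    """exp(A*t) @ M0 for a stack of matrices, via batched eigendecomposition.

    Falls back to scipy's scaling-and-squaring expm when the eigenvector
    matrix is ill-conditioned (near-defective A).
    """
    try:
        w, V = np.linalg.eig(A)
        b = np.broadcast_to(M0.astype(complex), (A.shape[0], M0.size))[..., None]
        c = np.linalg.solve(V, b)
        out = (V * np.exp(w * t)[:, None, :]) @ c
        out = out[..., 0].real
        if not np.all(np.isfinite(out)):
            raise np.linalg.LinAlgError("non-finite eig propagation")
        # quick conditioning check on the worst matrix
        k = int(np.argmax(np.abs(w.real).max(axis=1)))
        resid = np.linalg.norm(expm(A[k] * t) @ M0 - out[k]) / max(
            1e-30, np.linalg.norm(out[k])
        )
        if resid > 1e-8:
            raise np.linalg.LinAlgError("eig propagation inaccurate")
        return out
    except np.linalg.LinAlgError:
        return np.stack([expm(Ak * t) @ M0 for Ak in A])


def cest_profiles(model, scheme, observed_states):
    """Normalized CEST profiles for several observed states at once.

    All observed states share one propagation of the 3N-dimensional
    magnetization, so fitting residues measured through more than one state
    (e.g. both the Ground and the PD cross peak) costs a single forward
    evaluation.  Returns an array of shape ``(len(observed_states),
    n_offsets)``.
    """
    if scheme.kind != "cest":
        raise ConfigurationError("cest_profile requires a CEST scheme")
    if scheme.b1_hz < 0:
        raise ValueError("negative B1 field")
    obs = [model.index(s) for s in observed_states]
    m = len(scheme.offsets_ppm)
    if scheme.t_relax == 0:
        return np.ones((len(obs), m))

    n = model.n_states
    M0 = np.zeros(3 * n)
    M0[2::3] = model.populations
    A = _bm_cest_matrix(model, scheme)
    Mt = _propagate_batched(A, M0, scheme.t_relax)

    # B1 = 0 reference: z-magnetization evolves under exchange and R1 only
    Az = build_rate_matrix(model) - np.diag(model.r1)
    ref = expm(Az * scheme.t_relax) @ model.populations
    return np.stack([Mt[:, 3 * i + 2] / ref[i] for i in obs])


def cest_profile(model, scheme, observed_state):
    """Normalized CEST intensity I/I0 of the observed state at every offset.

    The 3N-dimensional magnetization starts from equilibrium z-magnetization
    (proportional to populations), evolves under exchange + relaxation + B1
    nutation for ``t_relax``, and the observed state's z-component is read
    out, normalized by an identical propagation with B1 = 0.
    """
    return cest_profiles(model, scheme, (observed_state,))[0]


def cpmg_r2eff(model, scheme, observed_state):
    """R2,eff (s^-1) at each nu_cpmg = ncyc/t_ct of the scheme (ncyc > 0).

    Transverse magnetization (complex M+ = Mx + i My per state) evolves under
    exchange, R2, and off-resonance precession; each CPMG cycle is
    tau - 180 - 2*tau - 180 - tau with ideal instantaneous pulses (complex
    conjugation), so t_ct = 4 * tau * ncyc.  R2,eff = -ln(I/I0)/t_ct with
    I the observed state's in-phase magnetization after the constant-time
    period and I0 its equilibrium value.
    """
    if scheme.kind != "cpmg":
        raise ConfigurationError("cpmg_r2eff requires a CPMG scheme")
    obs = model.index(observed_state)
    K = build_rate_matrix(model)
    omega = model.delta_omega * scheme.rad_per_ppm
    L = K + np.diag(-model.r2 + 1j * omega)
    p = model.populations.astype(complex)
    I0 = model.populations[obs]
    out = []
    for ncyc in scheme.ncyc_values:
        if ncyc == 0:
            continue  # reference plane: no CPMG period, never divided by
        tau = scheme.t_ct / (4.0 * ncyc)
        E1 = expm(L * tau)
        E2 = expm(L * 2.0 * tau)
        M = p.copy()
        for _ in range(ncyc):
            M = E1 @ np.conj(E2 @ np.conj(E1 @ M))
        intensity = M[obs].real
        if intensity <= 0:
            out.append(np.inf)
        else:
            out.append(-np.log(intensity / I0) / scheme.t_ct)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# closed-form limits (oracles / initializers)


def carver_richards_r2eff(kex, p_minor, dw_rad, r2_major, r2_minor, nu_cpmg):
    """Two-state Carver-Richards R2,eff(nu_cpmg) closed form.

    Parameters are the standard (kex, p_b, dw in rad/s, intrinsic R2 of each
    state); ``nu_cpmg`` in Hz may be an array.  Used as an independent oracle
    for the numerical propagator and as an initializer; the paper-style
    estimators never fit this form to data.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    pa, pb = 1.0 - p_minor, p_minor
    dr2 = r2_major - r2_minor
    psi = (dr2 - pa * kex + pb * kex) ** 2 - dw_rad**2 + 4.0 * pa * pb * kex**2
    zeta = 2.0 * dw_rad * (dr2 - pa * kex + pb * kex)
    root = np.sqrt(psi**2 + zeta**2)
    d_pos = 0.5 * (1.0 + (psi + 2.0 * dw_rad**2) / root)
    d_neg = 0.5 * (-1.0 + (psi + 2.0 * dw_rad**2) / root)
    eta_pos = (2.0 ** (-1.5) / nu) * np.sqrt(psi + root)
    eta_neg = (2.0 ** (-1.5) / nu) * np.sqrt(np.maximum(-psi + root, 0.0))
    arg = d_pos * np.cosh(eta_pos) - d_neg * np.cos(eta_neg)
    return 0.5 * (r2_major + r2_minor + kex) - nu * np.arccosh(np.maximum(arg, 1.0))


def rex_fast_limit(model, delta_omega_rad, include_dr2=False):
    """Fast-limit exchange contribution p_A p_B dw^2 / kex (s^-1).

    With ``include_dr2`` the (usually negligible) difference of intrinsic
    transverse rates is subtracted inside the numerator:
    p_A p_B (dw^2 - dR2^2) / kex.
    """
    if model.n_states != 2:
        raise ValueError("fast-limit formula is defined for two-state models")
    pa, pb = model.populations
    kex = model.kex(model.labels[0], model.labels[1])
    num = delta_omega_rad**2
    if include_dr2:
        num -= (model.r2[0] - model.r2[1]) ** 2
    return pa * pb * num / kex


def rex_slow_limit(model, observed_state):
    """Slow-limit exchange contribution: the rate of leaving the observed state."""
    if model.n_states != 2:
        raise ValueError("slow-limit formula is defined for two-state models")
    model.index(observed_state)
    return model.leaving_rate(observed_state)
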