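"""Stage 2: global exchange-model fits to CEST saturation profiles.

Two- and three-state Bloch-McConnell models are fit across residues with the
kinetics (populations, edge exchange rates) global and the spectroscopic
nuisance parameters (state positions, R1, R2) per residue.  The paper-style
constraint of tying a sparsely populated state's R2 to the major state's R2
is supported, and competing topologies are compared by reduced chi-square.

The objective is multi-modal in the minor-state positions, so fits start
from dip candidates located on the measured profiles and from a handful of
seeded random restarts.  Rates are fit in log space and populations in logit
space to enforce positivity and bounds without constrained optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from foldswitch.exchange_core import (
    AcquisitionScheme,
    ExchangeModel,
    cest_profiles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CESTProfile",
    "Topology",
    "TOPOLOGIES",
    "CestFitResult",
    "profiles_from_table",
    "initialize_from_dips",
    "fit_exchange_model",
    "compare_models",
]


@dataclass
class CESTProfile:
    """One residue's reference-normalized CEST trace."""

    residue: int
    observed_state: str
    offsets_ppm: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    scheme: AcquisitionScheme

    def __post_init__(self):
        self.offsets_ppm = np.asarray(self.offsets_ppm, float)
        self.intensity = np.asarray(self.intensity, float)
        self.sigma = np.asarray(self.sigma, float)
        if np.any(self.sigma <= 0):
            raise ValueError("per-point sd must be positive")


@dataclass(frozen=True)
class Topology:
    """An exchange topology template: which states exist and which exchange.

    ``major`` is the reference state for population bookkeeping (its
    population is 1 minus the minors') and the default R2-tie target.
    """

    name: str
    labels: tuple
    edges: tuple
    major: str

    @property
    def minors(self):
        return tuple(lab for lab in self.labels if lab != self.major)


TOPOLOGIES = {
    "two_state": Topology("two_state", ("Ground", "minor"), (("Ground", "minor"),), "Ground"),
    "linear_three_state": Topology(
        "linear_three_state",
        ("Enigma", "Ground", "PD"),
        (("Ground", "Enigma"), ("Ground", "PD")),
        "Ground",
    ),
    "fully_connected_three_state": Topology(
        "fully_connected_three_state",
        ("Enigma", "Ground", "PD"),
        (("Ground", "Enigma"), ("Ground", "PD"), ("Enigma", "PD")),
        "Ground",
    ),
    # control topology: PD exchanges only through the Enigma state
    "no_ground_pd_three_state": Topology(
        "no_ground_pd_three_state",
        ("Enigma", "Ground", "PD"),
        (("Ground", "Enigma"), ("Enigma", "PD")),
        "Ground",
    ),
}


@dataclass
class CestFitResult:
    topology: str
    populations: dict
    edge_kex: dict  # (a, b) -> kex of the edge
    rates: dict  # (a, b) -> directional k
    per_residue: pd.DataFrame
    chi2: float
    red_chi2: float
    n_points: int
    n_params: int
    success: bool
    message: str = ""
    nfev: int = 0
    x: np.ndarray | None = None  # internal parameter vector (warm starts)

    def rate(self, a, b):
        return self.rates.get((a, b), 0.0)


# ---------------------------------------------------------------------------
# data preparation


def profiles_from_table(table: pd.DataFrame, schemes) -> list:
    """Normalize a CEST peak table by its reference planes.

    Per peak (and per saturation condition, when the table holds several B1
    fields), volumes at each offset are divided by the mean reference
    volume; per-point sds are the stated spectral noise divided by the same
    reference.  ``schemes`` is one :class:`AcquisitionScheme` or a sequence
    of them; multi-condition tables are matched to their scheme by the
    ``b1_hz`` column.
    """
    if isinstance(schemes, AcquisitionScheme):
        schemes = [schemes]
    by_b1 = {round(float(sch.b1_hz), 6): sch for sch in schemes}
    keys = ["peak_id"] + (["b1_hz"] if "b1_hz" in table.columns else [])
    out = []
    for key, grp in table.groupby(keys, sort=True):
        peak_id = key[0] if isinstance(key, tuple) else key
        if "b1_hz" in table.columns:
            sch = by_b1.get(round(float(grp["b1_hz"].iloc[0]), 6))
            if sch is None:
                raise ValueError(
                    f"peak {peak_id!r}: no scheme for B1 = {grp['b1_hz'].iloc[0]} Hz"
                )
        else:
            sch = schemes[0]
        refs = grp[grp["ref"] == 1]
        if refs.empty:
            raise ValueError(f"peak {peak_id!r} has no reference plane")
        ref = float(refs["volume"].mean())
        if ref <= 0:
            raise ValueError(f"peak {peak_id!r} has non-positive reference volume")
        sat = grp[grp["ref"] == 0].sort_values("offset_ppm")
        out.append(
            CESTProfile(
                residue=int(sat["residue"].iloc[0]),
                observed_state=str(sat["state"].iloc[0]),
                offsets_ppm=sat["offset_ppm"].to_numpy(),
                intensity=sat["volume"].to_numpy() / ref,
                sigma=sat["sigma"].to_numpy() / ref,
                scheme=sch,
            )
        )
    return out


def initialize_from_dips(profile: CESTProfile, min_depth=0.05, noise_mult=3.0):
    """Candidate state positions from local minima of a CEST trace.

    Returns offsets (ppm) ordered by dip depth, deepest first; the global
    minimum (the observed state's own resonance) is always included.  Minima
    shallower than ``max(min_depth, noise_mult * median sd)`` relative to
    the median intensity are discarded as noise.
    """
    y = profile.intensity
    if len(y) >= 5:  # 3-point box smoothing to suppress single-point noise
        y = np.convolve(y, np.ones(3) / 3.0, mode="same")
        y[0], y[-1] = profile.intensity[0], profile.intensity[-1]
    baseline = float(np.median(y))
    threshold = max(min_depth, noise_mult * float(np.median(profile.sigma)))
    candidates = []
    for i in range(1, len(y) - 1):
        if y[i] < y[i - 1] and y[i] <= y[i + 1] and baseline - y[i] > threshold:
            candidates.append((baseline - y[i], profile.offsets_ppm[i]))
    candidates.sort(reverse=True)
    out = [off for _depth, off in candidates]
    global_min = float(profile.offsets_ppm[int(np.argmin(profile.intensity))])
    if not any(abs(global_min - o) < 1e-9 for o in out):
        out.insert(0, global_min)
    return out


# ---------------------------------------------------------------------------
# parameter vector layout


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class _ParamLayout:
    """Bookkeeping between the flat optimizer vector and model quantities.

    Layout: [logit p_minor ...][log kex per edge][per residue:
    pos per state (ppm), log R1, log R2 per free-R2 state].
    """

    def __init__(self, topology, residues, r2_ties):
        self.top = topology
        self.residues = list(residues)
        self.r2_ties = dict(r2_ties or {})
        for minor, target in self.r2_ties.items():
            if minor not in topology.labels or target not in topology.labels:
                raise ValueError(f"R2 tie references unknown state: {minor}->{target}")
        self.free_r2 = [lab for lab in topology.labels if lab not in self.r2_ties]
        self.n_minor = len(topology.minors)
        self.n_edges = len(topology.edges)
        self.per_res = len(topology.labels) + 1 + len(self.free_r2)
        self.n_params = self.n_minor + self.n_edges + len(self.residues) * self.per_res

    def res_slice(self, j):
        start = self.n_minor + self.n_edges + j * self.per_res
        return slice(start, start + self.per_res)

    def unpack(self, x):
        top = self.top
        p_minor = _expit(x[: self.n_minor])
        kex = np.exp(x[self.n_minor : self.n_minor + self.n_edges])
        residues = {}
        n_lab = len(top.labels)
        for j, res in enumerate(self.residues):
            sl = x[self.res_slice(j)]
            pos = sl[:n_lab]
            r1 = np.exp(sl[n_lab])
            r2_free = np.exp(sl[n_lab + 1 :])
            r2 = {}
            for lab, val in zip(self.free_r2, r2_free):
                r2[lab] = val
            for minor, target in self.r2_ties.items():
                r2[minor] = r2[target]
            residues[res] = (pos, r1, r2)
        return p_minor, kex, residues

    def pack(self, p_minor, kex, residues):
        x = np.empty(self.n_params)
        x[: self.n_minor] = _logit(np.asarray(p_minor, float))
        x[self.n_minor : self.n_minor + self.n_edges] = np.log(np.asarray(kex, float))
        n_lab = len(self.top.labels)
        for j, res in enumerate(self.residues):
            pos, r1, r2 = residues[res]
            x[self.res_slice(j)] = np.concatenate(
                [np.asarray(pos, float), [np.log(r1)],
                 np.log([r2[lab] for lab in self.free_r2])]
            )
        return x

    def build_model(self, res, p_minor, kex, residues):
        top = self.top
        pos, r1, r2 = residues[res]
        p_major = 1.0 - float(np.sum(p_minor))
        if p_major <= 1e-4:
            return None
        pops = []
        mi = 0
        for lab in top.labels:
            if lab == top.major:
                pops.append(p_major)
            else:
                pops.append(float(p_minor[mi]))
                mi += 1
        return ExchangeModel.from_edges(
            labels=top.labels,
            populations=np.asarray(pops),
            edge_kex={edge: kex[i] for i, edge in enumerate(top.edges)},
            positions_ppm=pos,
            r1=r1,
            r2=np.array([r2[lab] for lab in top.labels]),
        )


def _simulate_residue(model, profs):
    """Forward profiles for one residue, one propagation per scheme."""
    by_scheme = {}
    for p in profs:
        by_scheme.setdefault(p.scheme, []).append(p)
    sims = {}
    for sch, group in by_scheme.items():
        out = cest_profiles(model, sch, tuple(q.observed_state for q in group))
        for q, row in zip(group, out):
            sims[id(q)] = row
    return [sims[id(p)] for p in profs]


def _residuals(x, layout, by_residue):
    p_minor, kex, residues = layout.unpack(x)
    chunks = []
    for res, profs in by_residue.items():
        model = layout.build_model(res, p_minor, kex, residues)
        if model is None:  # minors crowd out the major state: reject smoothly
            total = sum(len(p.intensity) + 1 for p in profs)
            chunks.append(np.full(total, 1e3 * (1.0 + float(np.sum(p_minor)))))
            continue
        for p, s in zip(profs, _simulate_residue(model, profs)):
            chunks.append(_scaled_profile_residuals(p, s))
    return np.concatenate(chunks)


def _scaled_profile_residuals(p, s):
    """Residuals of one profile with its reference scale as a nuisance.

    The measured reference plane is itself noisy, so the normalization of a
    profile carries a common scale error of relative sd ~ sigma/I0.  The
    scale is a linear nuisance constrained by that measurement; its
    weighted-least-squares optimum (including the (scale-1)/sd_ref prior
    from the reference plane) is closed-form, and the prior deviation is
    appended as an extra residual.
    """
    w = 1.0 / p.sigma**2
    sd_ref = float(np.median(p.sigma))  # relative sd of the reference plane
    wr = 1.0 / sd_ref**2
    denom = float(np.sum(w * s * s)) + wr
    scale = (float(np.sum(w * s * p.intensity)) + wr) / denom if denom > 0 else 1.0
    return np.concatenate([(scale * s - p.intensity) / p.sigma,
                           [(scale - 1.0) / sd_ref]])


def _jac_sparsity(layout, by_residue):
    rows = sum(len(p.intensity) + 1 for profs in by_residue.values() for p in profs)
    S = np.zeros((rows, layout.n_params), dtype=bool)
    S[:, : layout.n_minor + layout.n_edges] = True
    r0 = 0
    for j, res in enumerate(layout.residues):
        n = sum(len(p.intensity) + 1 for p in by_residue[res])
        S[r0 : r0 + n, layout.res_slice(j)] = True
        r0 += n
    return S


# ---------------------------------------------------------------------------
# start generation


def _starts(layout, by_residue, n_starts, seed, warm_start, pd_anchor=None):
    """Candidate starting vectors, each tagged with its start class
    (warm / anchored assignment / minor-permutation / random)."""
    top = layout.top
    rng = np.random.default_rng(seed)
    carrier = None
    dip_cache = {}
    for res, profs in by_residue.items():
        major_prof = next(
            (p for p in profs if p.observed_state == top.major), profs[0]
        )
        carrier = major_prof.scheme.carrier_ppm
        dip_cache[res] = (major_prof, initialize_from_dips(major_prof))

    def residue_block(res, perm, start_index, pd_anchor=None):
        major_prof, dips = dip_cache[res]
        pos_major = dips[0] if dips else float(np.median(major_prof.offsets_ppm))
        minors = list(dips[1:])
        # unresolved minors sit inside the major dip: start them one linewidth
        # to either side, alternating across starts
        near = [0.5, -0.5, 1.0, -1.0, 1.5, -1.5]
        j = start_index
        while len(minors) < len(top.minors):
            minors.append(pos_major + near[j % len(near)])
            j += 1
        if pd_anchor is not None and "PD" in top.minors and len(minors) >= 2:
            # assignment-style start: the candidate nearest the random-coil
            # region is PD, the deepest remaining dip is the other minor
            i_pd = int(np.argmin([abs(m - pd_anchor) for m in minors]))
            pd_pos = minors.pop(i_pd)
            ordered = []
            for lab in top.minors:
                ordered.append(pd_pos if lab == "PD" else minors.pop(0))
            minors = ordered
        elif perm:
            minors = [minors[i] for i in perm]
        pos = {}
        for lab in top.labels:
            if lab == top.major:
                pos[lab] = pos_major
            else:
                pos[lab] = minors.pop(0)
        # a state observed through its own cross peak anchors its position
        for p in by_residue[res]:
            if p.observed_state != top.major:
                d = initialize_from_dips(p)
                if d:
                    pos[p.observed_state] = d[0]
        pos_vec = [pos[lab] - carrier for lab in top.labels]
        r2 = {lab: 8.0 for lab in layout.free_r2}
        return (np.asarray(pos_vec), 1.0, r2)

    starts = []
    n_minor = len(top.minors)
    perms = [None]
    if n_minor == 2:
        perms = [(0, 1), (1, 0)]
    kex_grid = [50.0, 200.0, 10.0]
    anchored = pd_anchor is not None and "PD" in top.minors and n_minor >= 2
    if anchored:
        for i, kex0 in enumerate(kex_grid):
            residues = {res: residue_block(res, None, i, pd_anchor=pd_anchor)
                        for res in layout.residues}
            starts.append(("anchored", layout.pack(
                np.full(n_minor, 0.05), np.full(layout.n_edges, kex0), residues)))
    for i in range(max(n_starts, 2 * len(perms))):
        perm = perms[i % len(perms)]
        if i < len(kex_grid):
            kex = np.full(layout.n_edges, kex_grid[i])
            p_minor = np.full(n_minor, 0.05)
        else:
            kex = 10 ** rng.uniform(0.7, 2.6, size=layout.n_edges)
            p_minor = rng.uniform(0.02, 0.3, size=n_minor)
        residues = {res: residue_block(res, perm, i) for res in layout.residues}
        starts.append((f"perm{i % len(perms)}", layout.pack(p_minor, kex, residues)))
    if warm_start is not None:
        # two warm variants: edges absent from the previous topology start
        # either at a negligible rate (so a nested optimum is reproducible
        # and adding an edge can never fit worse) or at a moderate rate (so
        # a genuinely present new process can be found)
        for tag, fallback in (("warm_nested", 1e-3), ("warm_seeded", 30.0)):
            starts.insert(0, (tag, _adapt_warm_start(layout, warm_start, carrier,
                                                     fallback)))
    return starts


def _adapt_warm_start(layout, warm: CestFitResult, carrier_ppm, new_edge_kex=1e-3):
    """Map a previous fit's parameters into this layout; edges the previous
    topology lacked start at ``new_edge_kex``."""
    p_minor = [min(max(warm.populations.get(lab, 0.02), 1e-4), 0.98)
               for lab in layout.top.minors]
    kex = [max(warm.edge_kex.get(e, warm.edge_kex.get((e[1], e[0]), new_edge_kex)), 1e-3)
           for e in layout.top.edges]
    residues = {}
    pr = warm.per_residue.set_index("residue")
    for res in layout.residues:
        row = pr.loc[res]
        pos = [float(row.get(f"pos_{lab}", carrier_ppm)) - carrier_ppm
               for lab in layout.top.labels]
        r2 = {lab: float(row.get(f"r2_{lab}", 10.0)) for lab in layout.free_r2}
        residues[res] = (np.asarray(pos, float), float(row["r1"]), r2)
    return layout.pack(p_minor, kex, residues)


# ---------------------------------------------------------------------------
# fitting


def _residue_residuals(x, layout, by_residue, res):
    """Residual block of a single residue at the full parameter vector."""
    p_minor, kex, residues = layout.unpack(x)
    profs = by_residue[res]
    model = layout.build_model(res, p_minor, kex, residues)
    if model is None:
        total = sum(len(p.intensity) + 1 for p in profs)
        return np.full(total, 1e3)
    return np.concatenate([
        _scaled_profile_residuals(p, s)
        for p, s in zip(profs, _simulate_residue(model, profs))
    ])


def _polish_residues(x, layout, by_residue, misfit_factor=1.3):
    """Per-residue block refinement at fixed global parameters.

    The objective is near-symmetric in the sign of each minor state's offset
    from the major state, so individual residues can converge to the mirror
    solution; re-optimizing a misfitting residue's block (bounded, from its
    current and its mirrored minor positions) escapes those local minima
    cheaply.  Only residues whose per-point chi^2 exceeds ``misfit_factor``
    times the median are polished.
    """
    x = x.copy()
    top = layout.top
    n_lab = len(top.labels)
    major_idx = top.labels.index(top.major)
    minor_idx = [i for i, lab in enumerate(top.labels) if lab != top.major]

    per_point = {}
    for res in layout.residues:
        r = _residue_residuals(x, layout, by_residue, res)
        per_point[res] = float(r @ r) / len(r)
    cutoff = max(misfit_factor * float(np.median(list(per_point.values()))), 1.2)

    span = None
    for profs in by_residue.values():
        off = profs[0].offsets_ppm - profs[0].scheme.carrier_ppm
        span = (off.min() - 1.0, off.max() + 1.0)
        break
    lo = np.concatenate([np.full(n_lab, span[0]), [np.log(0.02)],
                         np.full(layout.per_res - n_lab - 1, np.log(0.2))])
    hi = np.concatenate([np.full(n_lab, span[1]), [np.log(30.0)],
                         np.full(layout.per_res - n_lab - 1, np.log(200.0))])

    for j, res in enumerate(layout.residues):
        if per_point[res] <= cutoff:
            continue
        sl = layout.res_slice(j)
        starts = [x[sl].copy()]
        for mi in minor_idx:
            flipped = x[sl].copy()
            flipped[mi] = 2.0 * flipped[major_idx] - flipped[mi]
            starts.append(flipped)
            swapped = x[sl].copy()  # major position caught in the minor dip
            swapped[major_idx], swapped[mi] = swapped[mi], swapped[major_idx]
            starts.append(swapped)
            # a collapsed minor (dw ~ 0) makes flip and swap no-ops: restart
            # from measured dip candidates and fixed offsets off the major
            major_pos = x[sl][major_idx]
            cands = []
            for p in by_residue[res]:
                cands += [d - p.scheme.carrier_ppm for d in initialize_from_dips(p)]
            cands = [c for c in cands if abs(c - major_pos) > 0.3]
            cands += [major_pos + d for d in (0.75, -0.75, 1.5, -1.5)]
            for c in cands[:4]:
                alt = x[sl].copy()
                alt[mi] = c
                starts.append(alt)

        def block_fun(xb, sl=sl, res=res):
            x2 = x.copy()
            x2[sl] = xb
            return _residue_residuals(x2, layout, by_residue, res)

        best_xb, best_cost = None, np.inf
        for xb0 in starts:
            try:
                r = least_squares(block_fun, np.clip(xb0, lo, hi), bounds=(lo, hi),
                                  method="trf", ftol=1e-7, xtol=1e-7, max_nfev=60)
            except Exception:  # pragma: no cover
                continue
            if np.isfinite(r.cost) and r.cost < best_cost:
                best_cost, best_xb = r.cost, r.x
        if best_xb is not None:
            x[sl] = best_xb
    return x


def fit_exchange_model(
    profiles,
    topology,
    r2_ties=None,
    n_starts=5,
    seed=0,
    warm_start=None,
    max_nfev=250,
    pd_anchor_ppm=121.5,
    cascade=True,
) -> CestFitResult:
    """Global weighted least-squares fit of an exchange topology to CEST data.

    Parameters
    ----------
    profiles:
        :class:`CESTProfile` objects sharing one acquisition scheme.  Profiles
        of the same residue (e.g. observed through two different states) share
        all their per-residue parameters.
    topology:
        Name in :data:`TOPOLOGIES` or a :class:`Topology`.
    r2_ties:
        Mapping ``{state: target_state}``; the tied state's R2 equals the
        target's bit-exactly in the fitted model (the paper-style Enigma-R2 =
        Ground-R2 constraint).
    n_starts:
        Number of optimization starts (dip-derived positions, varied rates).
    warm_start:
        A previous :class:`CestFitResult` on the same residues; its optimum
        is added as an extra start (useful to compare nested topologies).
    """
    top = TOPOLOGIES[topology] if isinstance(topology, str) else topology
    if len({(p.scheme.nucleus, p.scheme.carrier_ppm) for p in profiles}) != 1:
        raise ValueError("all profiles must share one nucleus and carrier")
    scheme = profiles[0].scheme

    if cascade and warm_start is None and len(top.labels) == 3:
        warm_start = _cascade_two_state(profiles, top, n_starts, seed, max_nfev,
                                        pd_anchor_ppm)
    for p in profiles:
        if p.observed_state not in top.labels:
            raise ValueError(
                f"profile observes {p.observed_state!r}, not a state of {top.name}"
            )
    by_residue = {}
    for p in profiles:
        by_residue.setdefault(p.residue, []).append(p)
    layout = _ParamLayout(top, sorted(by_residue), r2_ties)
    n_points = sum(len(p.intensity) for p in profiles)
    sparsity = _jac_sparsity(layout, by_residue)
    # natural parameter scales: ~1 for log/logit globals, ~0.3 ppm for
    # positions, ~0.5 for log relaxation rates
    x_scale = np.ones(layout.n_params)
    n_lab = len(top.labels)
    for j in range(len(layout.residues)):
        sl = layout.res_slice(j)
        x_scale[sl.start : sl.start + n_lab] = 0.3
        x_scale[sl.start + n_lab :  sl.stop] = 0.5

    # prescreen many cheap candidate starts by raw chi^2; optimize the best
    # few, keeping class diversity (warm start, PD-anchored assignment, and
    # each minor-permutation class stay represented)
    candidates = _starts(layout, by_residue, max(4 * n_starts, 12), seed,
                         warm_start, pd_anchor_ppm)
    scored = []
    for tag, x0 in candidates:
        try:
            r = _residuals(x0, layout, by_residue)
            scored.append((float(r @ r), tag, x0))
        except Exception:  # pragma: no cover
            continue
    scored.sort(key=lambda t: t[0])
    budget = max(n_starts, 4)
    chosen, seen_tags = [], set()
    # warm and assignment-anchored starts first, then the best of each
    # remaining class, then fill by score -- capped at the start budget
    priority = [t for t in ("warm_nested", "warm_seeded", "anchored")
                if any(tag == t for _s, tag, _x in scored)]
    for want in priority:
        for score, tag, x0 in scored:
            if tag == want:
                chosen.append((score, x0))
                seen_tags.add(tag)
                break
    for score, tag, x0 in scored:
        if len(chosen) >= budget:
            break
        if tag not in seen_tags:
            chosen.append((score, x0))
            seen_tags.add(tag)
    for score, tag, x0 in scored:
        if len(chosen) >= budget:
            break
        if not any(x0 is c for _s, c in chosen):
            chosen.append((score, x0))
    chosen = chosen[:budget]
    chosen.sort(key=lambda t: t[0])
    best = None
    for _score, x0 in chosen:
        try:
            res = least_squares(
                _residuals,
                x0,
                args=(layout, by_residue),
                jac_sparsity=sparsity,
                method="trf",
                x_scale=x_scale,
                ftol=1e-8,
                xtol=1e-8,
                max_nfev=max_nfev,
            )
        except Exception as err:  # pragma: no cover - optimizer edge cases
            logger.warning("fit start failed: %s", err)
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")

    # put the minor-state labels in canonical orientation (PD nearest the
    # random-coil anchor) before the final refinement, so the R2 tie binds
    # the intended state; then escape per-residue mirror minima and refine
    # globally while the polish keeps finding better local structure
    anchor_rel = None if pd_anchor_ppm is None else pd_anchor_ppm - scheme.carrier_ppm
    x_can = _canonical_orientation(layout, best.x, anchor_rel)
    if x_can is not best.x:
        try:
            refit = least_squares(
                _residuals, x_can, args=(layout, by_residue),
                jac_sparsity=sparsity, method="trf", x_scale=x_scale,
                ftol=1e-8, xtol=1e-8, max_nfev=max_nfev,
            )
            # accept the correctly-tied orientation unless it is clearly worse
            if np.isfinite(refit.cost) and refit.cost <= best.cost * 1.10:
                best = refit
        except Exception as err:  # pragma: no cover
            logger.warning("orientation refit failed: %s", err)

    for _round in range(2):
        x_pol = _polish_residues(best.x, layout, by_residue)
        if np.allclose(x_pol, best.x):
            break
        try:
            refit = least_squares(
                _residuals,
                x_pol,
                args=(layout, by_residue),
                jac_sparsity=sparsity,
                method="trf",
                x_scale=x_scale,
                ftol=1e-8,
                xtol=1e-8,
                max_nfev=max_nfev,
            )
        except Exception as err:  # pragma: no cover
            logger.warning("polish refit failed: %s", err)
            break
        if refit.cost < best.cost * (1.0 - 1e-3):
            best = refit
        else:
            break

    chi2 = float(2.0 * best.cost)
    dof = max(n_points - layout.n_params, 1)
    p_minor, kex, residues = layout.unpack(best.x)
    populations = {}
    mi = 0
    for lab in top.labels:
        if lab == top.major:
            populations[lab] = 1.0 - float(np.sum(p_minor))
        else:
            populations[lab] = float(p_minor[mi])
            mi += 1
    edge_kex = {edge: float(kex[i]) for i, edge in enumerate(top.edges)}
    rates = {}
    for (a, b), kx in edge_kex.items():
        tot = populations[a] + populations[b]
        rates[(a, b)] = kx * populations[b] / tot
        rates[(b, a)] = kx * populations[a] / tot
    rows = []
    for res in layout.residues:
        pos, r1, r2 = residues[res]
        row = {"residue": res, "r1": float(r1)}
        for lab, p_ in zip(top.labels, pos):
            row[f"pos_{lab}"] = float(p_) + scheme.carrier_ppm
            row[f"dw_{lab}"] = float(p_ - pos[top.labels.index(top.major)])
        for lab in top.labels:
            row[f"r2_{lab}"] = float(r2[lab])
        rows.append(row)
    success = bool(best.status > 0 and np.isfinite(chi2))
    if not success:  # pragma: no cover
        logger.warning("CEST fit did not converge cleanly: %s", best.message)
    result = CestFitResult(
        topology=top.name,
        populations=populations,
        edge_kex=edge_kex,
        rates=rates,
        per_residue=pd.DataFrame(rows),
        chi2=chi2,
        red_chi2=chi2 / dof,
        n_points=n_points,
        n_params=layout.n_params,
        success=success,
        message=str(best.message),
        nfev=int(best.nfev),
        x=best.x,
    )
    return _canonicalize_pd_label(result, top, pd_anchor_ppm)


def _swap_minor_states_in_x(layout, x, a, b):
    """Exchange two minor states' roles in the parameter vector.

    Populations, edge rates and positions travel with their state; a state
    moving into a tied-R2 slot drops its free R2 (the tie takes over) and a
    state moving out of one starts from the value it was tied to.
    """
    p_minor, kex, residues = layout.unpack(x)
    sw = {a: b, b: a}
    minors = list(layout.top.minors)
    ia, ib = minors.index(a), minors.index(b)
    p_new = p_minor.copy()
    p_new[ia], p_new[ib] = p_minor[ib], p_minor[ia]
    edges = list(layout.top.edges)
    kex_new = kex.copy()
    for i, e in enumerate(edges):
        target = frozenset(sw.get(s, s) for s in e)
        j = next(k for k, e2 in enumerate(edges) if frozenset(e2) == target)
        kex_new[j] = kex[i]
    idx = {lab: i for i, lab in enumerate(layout.top.labels)}
    res_new = {}
    for res, (pos, r1, r2) in residues.items():
        pos_new = np.array(pos, float)
        pos_new[idx[a]], pos_new[idx[b]] = pos[idx[b]], pos[idx[a]]
        r2_new = {f: r2[sw.get(f, f)] for f in layout.free_r2}
        res_new[res] = (pos_new, r1, r2_new)
    return layout.pack(p_new, kex_new, res_new)


def _canonical_orientation(layout, x, pd_anchor_rel):
    """Swap the two minors in ``x`` if the one labeled PD sits farther from
    the random-coil anchor than its sibling (returns ``x`` unchanged when
    the orientation is already canonical or the convention does not apply)."""
    top = layout.top
    if pd_anchor_rel is None or "PD" not in top.minors or len(top.minors) != 2:
        return x
    other = next(lab for lab in top.minors if lab != "PD")
    _pm, _kx, residues = layout.unpack(x)
    idx = {lab: i for i, lab in enumerate(top.labels)}
    d_pd = np.mean([abs(pos[idx["PD"]] - pd_anchor_rel) for pos, *_ in residues.values()])
    d_ot = np.mean([abs(pos[idx[other]] - pd_anchor_rel) for pos, *_ in residues.values()])
    if d_pd <= d_ot:
        return x
    return _swap_minor_states_in_x(layout, x, "PD", other)


def _cascade_two_state(profiles, top, n_starts, seed, max_nfev, pd_anchor_ppm):
    """Two-state prefit of the dominant process, used to warm-start a
    three-state fit (standard nested bootstrapping of exchange models).

    Only profiles observed through the major state enter; the fitted minor
    is relabeled to whichever three-state minor sits farther from the
    random-coil anchor (the dominant millisecond process in this system is
    the non-PD one).
    """
    major_profiles = [p for p in profiles if p.observed_state == top.major]
    if len(major_profiles) < 1:
        return None
    try:
        sub = fit_exchange_model(
            major_profiles,
            Topology("two_state_prefit", (top.major, "minor"),
                     ((top.major, "minor"),), top.major),
            r2_ties={"minor": top.major},
            n_starts=max(2, n_starts - 1),
            seed=seed,
            max_nfev=max_nfev,
            pd_anchor_ppm=None,
            cascade=False,
        )
    except Exception as err:  # pragma: no cover
        logger.warning("two-state prefit failed: %s", err)
        return None
    if pd_anchor_ppm is not None and "PD" in top.minors:
        dominant = next(lab for lab in top.minors if lab != "PD")
    else:
        dominant = top.minors[0]
    sub.populations = {top.major: sub.populations[top.major],
                       dominant: sub.populations["minor"]}
    sub.edge_kex = {(top.major, dominant): sub.edge_kex[(top.major, "minor")]}
    sub.rates = {}
    sub.per_residue = sub.per_residue.rename(columns={
        "pos_minor": f"pos_{dominant}", "dw_minor": f"dw_{dominant}",
        "r2_minor": f"r2_{dominant}"})
    return sub


def _canonicalize_pd_label(result: CestFitResult, top: Topology, pd_anchor_ppm):
    """Resolve the minor-state label permutation by chemical knowledge.

    A linear chain minor<->major<->minor likelihood is exactly symmetric
    under swapping the two minor states, so the fit alone cannot name them.
    The partially disordered state resonates in the random-coil region, so
    the minor state whose average fitted position is closest to the coil
    anchor is reported as PD (the same deduction the assignment-based
    analysis makes).
    """
    minors = [lab for lab in top.minors]
    if "PD" not in minors or len(minors) != 2 or pd_anchor_ppm is None:
        return result
    other = next(lab for lab in minors if lab != "PD")
    dist = {
        lab: float(np.mean(np.abs(result.per_residue[f"pos_{lab}"] - pd_anchor_ppm)))
        for lab in minors
    }
    if dist["PD"] <= dist[other]:
        return result
    swap = {other: "PD", "PD": other}

    def sw(lab):
        return swap.get(lab, lab)

    result.populations = {sw(k): v for k, v in result.populations.items()}
    result.edge_kex = {(sw(a), sw(b)): v for (a, b), v in result.edge_kex.items()}
    result.rates = {(sw(a), sw(b)): v for (a, b), v in result.rates.items()}
    rename = {}
    for lab in minors:
        for pref in ("pos", "dw", "r2"):
            rename[f"{pref}_{lab}"] = f"{pref}_{sw(lab)}"
    result.per_residue = result.per_residue.rename(columns=rename)
    return result


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ModelComparison:
    ranking: list  # topology names, best first
    red_chi2: dict
    indistinguishable: list  # pairs within the equivalence band
    underdetermined: dict  # (topology, edge) -> fitted kex
    best: str
    band: float


def compare_models(results, band=0.10, rate_floor=1e-3) -> ModelComparison:
    """Rank topology fits of the same data by reduced chi-square.

    Pairs whose reduced chi-squares differ by less than ``band`` (fraction
    of the smaller) are reported as indistinguishable; edges whose fitted
    exchange rate collapses below ``rate_floor`` (s^-1) are flagged as
    underdetermined.  Ties order alphabetically by topology name.
    """
    results = list(results)
    if len({r.n_points for r in results}) > 1:
        raise ValueError("model comparison requires fits of the same data")
    ranked = sorted(results, key=lambda r: (r.red_chi2, r.topology))
    red = {r.topology: r.red_chi2 for r in ranked}
    indist = []
    for i in range(len(ranked)):
        for j in range(i + 1, len(ranked)):
            a, b = ranked[i], ranked[j]
            lo = min(a.red_chi2, b.red_chi2)
            if lo <= 0 or abs(a.red_chi2 - b.red_chi2) / lo <= band:
                indist.append((a.topology, b.topology))
    under = {}
    for r in ranked:
        for edge, kx in r.edge_kex.items():
            if kx < rate_floor:
                under[(r.topology, edge)] = kx
    return ModelComparison(
        ranking=[r.topology for r in ranked],
        red_chi2=red,
        indistinguishable=indist,
        underdetermined=under,
        best=ranked[0].topology,
        band=band,
    )
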