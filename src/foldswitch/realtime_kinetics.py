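"""Stage 1: hour-timescale interconversion rates from real-time peak series.

A temperature jump perturbs the Ground/FS equilibrium; every cross peak then
relaxes as a single exponential with one shared observable rate

    I_i(t) = a_i + b_i * exp(-k_obs * t),        k_obs = k_G->FS + k_FS->G.

The global fit shares ``k_obs`` across all qualifying peaks (the per-peak
plateau ``a_i`` and amplitude ``b_i`` are conditionally linear and solved
exactly for each candidate rate, which makes the 1-D profile fit fast and
immune to starting values).  The observable rate is split into directional
rates through the equilibrium FS fraction estimated from matched-residue
plateau volumes: ``k_G->FS = k_obs * p_FS``, ``k_FS->G = k_obs * p_G``.

Uncertainty comes from a bootstrap that re-draws every point from its stated
spectral-noise sd and resamples peaks with replacement within each state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "IntensitySeries",
    "SingleFit",
    "GlobalFitResult",
    "series_from_table",
    "fit_single_exponential",
    "filter_peaks",
    "global_fit_rates",
    "bootstrap_uncertainty",
    "estimate_scale_factor",
]

#: Peak-amplitude threshold of the qualifying filter, in volume units.
AMPLITUDE_THRESHOLD = 4.0e5

# Search window for the observable rate (h^-1).  Outside it the [1, exp(-k t)]
# design degenerates on a ~20-min-resolution, ~16 h series: below the lower
# edge a decay is indistinguishable from a constant, above the upper edge it
# completes within the dead time; in both cases the amplitude is unbounded.
_K_LO, _K_HI = 0.05, 12.0


@dataclass
class IntensitySeries:
    """One peak's volume-versus-time trace."""

    peak_id: str
    state: str
    times: np.ndarray
    volumes: np.ndarray
    sigma: float
    residue: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.volumes.shape:
            raise ValueError("times and volumes must be matching 1-D arrays")
        if len(self.times) < 4:
            raise ValueError("need at least 4 points to fit an exponential")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class SingleFit:
    peak_id: str
    state: str
    a: float
    b: float
    k: float
    sd_a: float
    sd_b: float
    sd_k: float
    chi2: float
    converged: bool
    residue: int | None = None


@dataclass
class GlobalFitResult:
    k_obs: float
    k_g_to_fs: float | None
    k_fs_to_g: float | None
    p_ground: float | None
    p_fs: float | None
    per_peak: dict  # peak_id -> (a, b)
    n_ground: int
    n_fs: int
    chi2: float
    intervals: dict = field(default_factory=dict)  # rate -> (lo, hi, sd)

    @property
    def lifetimes_h(self):
        """Mean state lifetimes 1/k in hours, exact reciprocals of the rates."""
        out = {}
        if self.k_g_to_fs:
            out["Ground"] = 1.0 / self.k_g_to_fs
        if self.k_fs_to_g:
            out["FS"] = 1.0 / self.k_fs_to_g
        return out


def series_from_table(table: pd.DataFrame) -> list:
    """Split a real-time peak table into per-peak intensity series."""
    out = []
    for peak_id, grp in table.groupby("peak_id", sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            IntensitySeries(
                peak_id=str(peak_id),
                state=str(grp["state"].iloc[0]),
                times=grp["time_h"].to_numpy(),
                volumes=grp["volume"].to_numpy(),
                sigma=float(grp["sigma"].iloc[0]),
                residue=int(grp["residue"].iloc[0]) if "residue" in grp else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# exponential fitting machinery


def _design(times, k):
    return np.column_stack([np.ones_like(times), np.exp(-k * times)])


def _profile_chi2(k, groups):
    """chi^2 of the best (a_i, b_i) at fixed k, over grouped series.

    ``groups`` is a list of (times, Y, weights) with Y of shape
    (n_times, n_peaks): peaks sharing a time grid are solved in one lstsq.
    """
    chi2 = 0.0
    for times, Y, w in groups:
        X = _design(times, k)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        chi2 += float(np.sum(w * resid**2))
    return chi2


def _group_series(series_list):
    groups = {}
    for s in series_list:
        key = (len(s.times), round(float(s.times[0]), 9), round(float(s.times[-1]), 9))
        groups.setdefault(key, []).append(s)
    out = []
    for members in groups.values():
        times = members[0].times
        Y = np.stack([s.volumes for s in members], axis=1)
        w = np.array([1.0 / max(s.sigma, 1e-300) ** 2 for s in members])
        out.append((times, Y, w, members))
    return [(t, Y, w) for t, Y, w, _ in out], [m for *_, m in out]


def _fit_shared_k(series_list):
    groups, members = _group_series(series_list)
    # coarse log-grid bracket, then Brent refinement
    ks = np.geomspace(_K_LO, _K_HI, 60)
    chi = np.array([_profile_chi2(k, groups) for k in ks])
    i = int(np.argmin(chi))
    lo = ks[max(i - 1, 0)]
    hi = ks[min(i + 1, len(ks) - 1)]
    res = minimize_scalar(
        _profile_chi2, args=(groups,), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    k = float(res.x)
    chi2 = float(res.fun)
    per_peak = {}
    for (times, Y, w), mem in zip(groups, members):
        X = _design(times, k)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        for j, s in enumerate(mem):
            per_peak[s.peak_id] = (float(coef[0, j]), float(coef[1, j]))
    return k, per_peak, chi2


def fit_single_exponential(series: IntensitySeries) -> SingleFit:
    """Least-squares fit of a + b*exp(-k t) to one peak (k >= 0 enforced).

    The decay rate is profiled on a bounded grid with the linear parameters
    solved exactly, so the fit needs no starting values; parameter sds come
    from the Gauss-Newton covariance at the optimum.
    """
    try:
        k, per_peak, chi2 = _fit_shared_k([series])
        a, b = per_peak[series.peak_id]
        # covariance of (a, b, k) at the optimum
        t = series.times
        e = np.exp(-k * t)
        J = np.column_stack([np.ones_like(t), e, -b * t * e])
        cov = np.linalg.pinv(J.T @ J) * series.sigma**2
        sds = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return SingleFit(
            peak_id=series.peak_id,
            state=series.state,
            a=a, b=b, k=k,
            sd_a=float(sds[0]), sd_b=float(sds[1]), sd_k=float(sds[2]),
            chi2=chi2, converged=bool(np.isfinite([a, b, k]).all()),
            residue=series.residue,
        )
    except (np.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
        logger.warning("single-exponential fit failed for %s: %s", series.peak_id, err)
        return SingleFit(series.peak_id, series.state, np.nan, np.nan, np.nan,
                         np.nan, np.nan, np.nan, np.inf, False, series.residue)


def filter_peaks(series_list, amplitude_threshold=AMPLITUDE_THRESHOLD, fits=None):
    """Keep assigned Ground/FS peaks whose fitted amplitude exceeds the threshold.

    Returns ``(qualifying series, counts per state, fits by peak id)``.
    Non-converged fits are excluded and logged.
    """
    if fits is None:
        fits = {s.peak_id: fit_single_exponential(s) for s in series_list}
    keep = []
    counts = {"Ground": 0, "FS": 0}
    for s in series_list:
        f = fits[s.peak_id]
        if s.state not in counts:
            continue
        if not f.converged:
            logger.warning("excluding %s: fit did not converge", s.peak_id)
            continue
        if abs(f.b) > amplitude_threshold:
            keep.append(s)
            counts[s.state] += 1
    if not keep:
        raise RuntimeError(
            f"no peaks pass the amplitude filter at threshold {amplitude_threshold:g}"
        )
    return keep, counts, fits


def _plateau_p_fs(per_peak, series_list):
    """Equilibrium FS fraction from matched-residue plateau volumes.

    For every residue with both a Ground and an FS peak in the fit, the
    plateaus give p_FS(residue) = a_FS / (a_G + a_FS); the per-residue
    response factors enter as a ratio whose median is 1, so the median
    across residues is a robust estimate of the true fraction.
    """
    by_residue = {}
    for s in series_list:
        if s.residue is None:
            continue
        a = per_peak[s.peak_id][0]
        by_residue.setdefault(s.residue, {})[s.state] = a
    vals = []
    for r, d in sorted(by_residue.items()):
        if "Ground" in d and "FS" in d and d["Ground"] + d["FS"] > 0:
            vals.append(d["FS"] / (d["Ground"] + d["FS"]))
    if not vals:
        return None
    return float(np.median(vals))


def global_fit_rates(series_list, p_fs_eq=None) -> GlobalFitResult:
    """Shared-rate global fit across all qualifying peaks.

    One ``k_obs`` is fit jointly to the Ground and FS peak families; the
    directional split uses the plateau-based equilibrium FS fraction, or the
    user-supplied ``p_fs_eq`` when no residue carries both states.
    """
    states = {s.state for s in series_list}
    k_obs, per_peak, chi2 = _fit_shared_k(series_list)
    n_g = sum(1 for s in series_list if s.state == "Ground")
    n_f = sum(1 for s in series_list if s.state == "FS")
    p_fs = _plateau_p_fs(per_peak, series_list) if p_fs_eq is None else float(p_fs_eq)
    if p_fs is None:
        logger.warning(
            "no matched Ground/FS residues: directional split unavailable "
            "(states present: %s)", sorted(states),
        )
        return GlobalFitResult(k_obs, None, None, None, None, per_peak, n_g, n_f, chi2)
    return GlobalFitResult(
        k_obs=k_obs,
        k_g_to_fs=k_obs * p_fs,
        k_fs_to_g=k_obs * (1.0 - p_fs),
        p_ground=1.0 - p_fs,
        p_fs=p_fs,
        per_peak=per_peak,
        n_ground=n_g,
        n_fs=n_f,
        chi2=chi2,
    )


def bootstrap_uncertainty(series_list, n_boot=1000, seed=None,
                          resample_residues=True) -> dict:
    """Bootstrap intervals for the global rates.

    Each replicate (i) re-draws every data point from a Gaussian at its
    stated spectral-noise sd and (ii) resamples peaks with replacement
    within each state, then repeats the full global fit.  Returns, per rate,
    the 2.5/97.5 percentiles and the replicate sd.
    """
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    if n_boot < 50:
        warnings.warn(f"n_boot = {n_boot} is small; intervals will be unstable",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    by_state = {}
    for s in series_list:
        by_state.setdefault(s.state, []).append(s)
    samples = {"k_obs": [], "k_g_to_fs": [], "k_fs_to_g": []}
    for _ in range(n_boot):
        rep = []
        for state, members in by_state.items():
            if resample_residues:
                chosen = [members[i] for i in rng.integers(0, len(members), len(members))]
            else:
                chosen = members
            for j, s in enumerate(chosen):
                noisy = s.volumes + rng.normal(0.0, s.sigma, size=len(s.volumes))
                rep.append(
                    IntensitySeries(f"{s.peak_id}#{j}", s.state, s.times, noisy,
                                    s.sigma, s.residue)
                )
        fit = global_fit_rates(rep)
        samples["k_obs"].append(fit.k_obs)
        if fit.k_g_to_fs is not None:
            samples["k_g_to_fs"].append(fit.k_g_to_fs)
            samples["k_fs_to_g"].append(fit.k_fs_to_g)
    out = {}
    for name, vals in samples.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        out[name] = (
            float(np.percentile(arr, 2.5)),
            float(np.percentile(arr, 97.5)),
            float(arr.std(ddof=1)),
        )
    return out


def estimate_scale_factor(table_a: pd.DataFrame, table_b: pd.DataFrame,
                          state="Ground") -> float:
    """Robust intensity scale between two experiments sharing Ground peaks.

    Uses the median ratio of matched-peak volumes over the equilibrated tail
    (final quarter of the series), so a differing relaxation trajectory early
    in the experiment does not bias the factor and single outlier peaks
    cannot move it.
    """
    ratios = []
    a_peaks = {p: g for p, g in table_a[table_a["state"] == state].groupby("peak_id")}
    b_peaks = {p: g for p, g in table_b[table_b["state"] == state].groupby("peak_id")}
    shared = sorted(set(a_peaks) & set(b_peaks))
    if len(shared) < 5:
        warnings.warn(
            f"only {len(shared)} shared {state} peaks; scale factor is unreliable",
            stacklevel=2,
        )
    for p in shared:
        ga = a_peaks[p].sort_values("time_h")
        gb = b_peaks[p].sort_values("time_h")
        n = min(len(ga), len(gb))
        tail = max(n // 4, 1)
        va = ga["volume"].to_numpy()[n - tail:n]
        vb = gb["volume"].to_numpy()[n - tail:n]
        ratios.append(np.median(vb) / np.median(va))
    if not ratios:
        raise ValueError(f"no shared {state} peaks between the two tables")
    return float(np.median(ratios))
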