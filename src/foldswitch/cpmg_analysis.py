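"""Stage 3: CPMG relaxation dispersion — R2,eff, Rex estimation, and the
two-temperature exchange-regime classification.

Constant-time CPMG volumes convert to effective transverse relaxation rates
R2,eff = -ln(I/I0)/t_ct.  The exchange contribution Rex is estimated
non-parametrically as R2,eff at the lowest-frequency point minus the
high-frequency plateau (mean of the two largest-frequency points) — no
dispersion-curve model is fit, because for slow-to-intermediate exchange the
two-state closed forms cannot disentangle populations from rates at a single
field and temperature.  Instead the *direction* of the temperature response
separates regimes: Rex grows with temperature for slow exchange (Rex tracks
the rate of leaving the observed state) and shrinks for fast exchange
(Rex ~ pA pB dw^2 / kex).  Per residue, a Monte-Carlo resampling test on the
propagated uncertainties decides significance, Bonferroni-corrected across
residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from foldswitch.exchange_core import AcquisitionScheme

logger = logging.getLogger(__name__)

__all__ = [
    "CPMGProfile",
    "RexEstimate",
    "RexReport",
    "compute_r2eff_profile",
    "profiles_from_table",
    "estimate_rex",
    "classify_regime",
]


@dataclass
class CPMGProfile:
    """One residue's R2,eff dispersion profile (reference plane excluded)."""

    residue: int
    nu_cpmg: np.ndarray  # Hz, ncyc / t_ct
    r2eff: np.ndarray  # s^-1
    sigma: np.ndarray  # per-point sd, max(noise-based, duplicate-based)
    t_ct: float

    def __post_init__(self):
        self.nu_cpmg = np.asarray(self.nu_cpmg, float)
        self.r2eff = np.asarray(self.r2eff, float)
        self.sigma = np.asarray(self.sigma, float)
        order = np.argsort(self.nu_cpmg)
        self.nu_cpmg = self.nu_cpmg[order]
        self.r2eff = self.r2eff[order]
        self.sigma = self.sigma[order]


@dataclass
class RexEstimate:
    residue: int
    rex: float
    sd: float
    nu_low: float


@dataclass
class RexReport:
    """Per-residue regime classification across two temperatures."""

    table: pd.DataFrame  # residue, rex_t1, sd_t1, rex_t2, sd_t2, p_adj, regime, group
    alpha: float
    n_tested: int


def compute_r2eff_profile(table: pd.DataFrame, scheme: AcquisitionScheme,
                          residue=None) -> CPMGProfile:
    """R2,eff profile of one residue from a CPMG volume table.

    The ncyc = 0 planes average into the reference I0.  Duplicate planes are
    averaged and their half-range sd recorded; the reported per-point sd is
    the larger of the spectral-noise-based and the duplicate-based value.
    Non-positive volumes cannot enter the log and are dropped with a log
    entry.
    """
    if residue is not None:
        table = table[table["residue"] == residue]
    if table.empty:
        raise ValueError(f"no rows for residue {residue!r}")
    res = int(table["residue"].iloc[0])
    refs = table[table["ncyc"] == 0]
    if refs.empty:
        raise ValueError(f"residue {res}: no ncyc = 0 reference plane")
    i0 = float(refs["volume"].mean())
    sigma_vol = float(table["sigma"].iloc[0])
    # reference uncertainty: noise of the mean of the reference planes
    sd_i0_rel = sigma_vol / np.sqrt(len(refs)) / i0

    nu, r2, sd = [], [], []
    for ncyc, grp in table[table["ncyc"] > 0].groupby("ncyc"):
        vols = grp["volume"].to_numpy(float)
        good = vols > 0
        if not np.all(good):
            logger.warning(
                "residue %d ncyc %d: dropping %d non-positive volume(s)",
                res, int(ncyc), int((~good).sum()),
            )
            vols = vols[good]
            if vols.size == 0:
                continue
        mean_v = vols.mean()
        r2_planes = -np.log(vols / i0) / scheme.t_ct
        val = float(-np.log(mean_v / i0) / scheme.t_ct)
        # noise-based sd of the duplicate-averaged point
        noise_sd = np.hypot(sigma_vol / np.sqrt(len(vols)) / mean_v, sd_i0_rel) / scheme.t_ct
        if len(r2_planes) > 1:
            dup_sd = float(np.std(r2_planes, ddof=1) / np.sqrt(len(r2_planes)))
        else:
            dup_sd = 0.0
        nu.append(ncyc / scheme.t_ct)
        r2.append(val)
        sd.append(max(float(noise_sd), dup_sd))
    return CPMGProfile(residue=res, nu_cpmg=np.array(nu), r2eff=np.array(r2),
                       sigma=np.array(sd), t_ct=scheme.t_ct)


def profiles_from_table(table: pd.DataFrame, scheme: AcquisitionScheme) -> list:
    return [compute_r2eff_profile(grp, scheme)
            for _res, grp in table.groupby("residue", sort=True)]


def estimate_rex(profile: CPMGProfile, nu_low=50.0) -> RexEstimate:
    """Rex = R2,eff at the point nearest ``nu_low`` minus the mean of the two
    largest-frequency points (the nu -> infinity proxy), with propagated sd."""
    if len(profile.nu_cpmg) < 3:
        raise ValueError("need a low-frequency point and >= 2 high-frequency points")
    if nu_low > profile.nu_cpmg.max():
        raise ValueError(
            f"nu_low = {nu_low} Hz is above the largest measured frequency "
            f"({profile.nu_cpmg.max():.1f} Hz)"
        )
    i_low = int(np.argmin(np.abs(profile.nu_cpmg - nu_low)))
    plateau = profile.r2eff[-2:]
    plateau_sd = 0.5 * np.hypot(profile.sigma[-2], profile.sigma[-1])
    rex = float(profile.r2eff[i_low] - plateau.mean())
    sd = float(np.hypot(profile.sigma[i_low], plateau_sd))
    return RexEstimate(residue=profile.residue, rex=rex, sd=sd,
                       nu_low=float(profile.nu_cpmg[i_low]))


def _mc_pvalue(est1, est2, rng, n_mc):
    """Two-sided Monte-Carlo tail probability that the sign of
    Rex(T2) - Rex(T1) is due to measurement uncertainty alone."""
    d = rng.normal(est2.rex, est2.sd, n_mc) - rng.normal(est1.rex, est1.sd, n_mc)
    p_hi = float(np.mean(d <= 0.0))
    p_lo = float(np.mean(d >= 0.0))
    return min(1.0, 2.0 * min(p_hi, p_lo) + 1.0 / n_mc)


def classify_regime(rex_t1, rex_t2, alpha=0.05, n_mc=100_000, seed=0,
                    large_threshold=10.0, small_threshold=1.0) -> RexReport:
    """Classify each residue's exchange regime from two temperatures.

    ``rex_t1`` / ``rex_t2`` are :class:`RexEstimate` collections at the lower
    and higher temperature.  A residue is ``slow_intermediate`` when Rex
    rises significantly with temperature, ``fast`` when it falls
    significantly, otherwise ``undetermined``; significance is a two-sided
    Monte-Carlo resampling test at ``alpha``, Bonferroni-corrected by the
    number of residues measured at both temperatures.  The magnitude group
    (``large`` >= 10 s^-1, ``small`` >= 1 s^-1, else ``none``) uses the
    lower-temperature Rex.
    """
    rng = np.random.default_rng(seed)
    by1 = {e.residue: e for e in rex_t1}
    by2 = {e.residue: e for e in rex_t2}
    shared = sorted(set(by1) & set(by2))
    n_tests = len(shared)
    rows = []
    for res in sorted(set(by1) | set(by2)):
        if res not in by1 or res not in by2:
            rows.append({
                "residue": res,
                "rex_t1": by1[res].rex if res in by1 else np.nan,
                "sd_t1": by1[res].sd if res in by1 else np.nan,
                "rex_t2": by2[res].rex if res in by2 else np.nan,
                "sd_t2": by2[res].sd if res in by2 else np.nan,
                "p_adj": np.nan,
                "regime": "undetermined",
                "reason": "missing temperature",
                "group": "none",
            })
            continue
        e1, e2 = by1[res], by2[res]
        p_adj = min(1.0, _mc_pvalue(e1, e2, rng, n_mc) * n_tests)
        if p_adj < alpha:
            regime = "slow_intermediate" if e2.rex > e1.rex else "fast"
        else:
            regime = "undetermined"
        if e1.rex >= large_threshold:
            group = "large"
        elif e1.rex >= small_threshold:
            group = "small"
        else:
            group = "none"
        rows.append({
            "residue": res,
            "rex_t1": e1.rex, "sd_t1": e1.sd,
            "rex_t2": e2.rex, "sd_t2": e2.sd,
            "p_adj": p_adj, "regime": regime, "reason": "", "group": group,
        })
    return RexReport(table=pd.DataFrame(rows), alpha=alpha, n_tested=n_tests)
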