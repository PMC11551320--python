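"""Shared readers/writers, run configuration, and the end-to-end driver.

Peak tables travel as tab-separated text with a one-line header; unknown
extra columns are carried through untouched, malformed numerics are
reported with their line number.  Exchange models and acquisition schemes
round-trip through flat YAML blocks.

:func:`run_pipeline` chains the stages into the full analysis — simulate
the default fixtures, fit the real-time rates, fit the CEST exchange models,
classify CPMG regimes, and assemble the free-energy landscape — writing a
machine-readable JSON report plus a human-readable log under the configured
output directory.  Every stochastic stage takes an explicit seed from the
config, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from foldswitch import (
    cest_fitting,
    cpmg_analysis,
    landscape as landscape_mod,
    realtime_kinetics,
    synthetic_data,
)
from foldswitch.exchange_core import AcquisitionScheme, ExchangeModel

logger = logging.getLogger(__name__)

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "save_model",
    "load_model",
    "save_scheme",
    "load_scheme",
    "RunConfig",
    "run_pipeline",
]

_NUMERIC_COLUMNS = ("time_h", "offset_ppm", "ncyc", "volume", "sigma", "residue", "ref")


def write_peak_table(table: pd.DataFrame, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_peak_table(path, required=("peak_id", "volume")) -> pd.DataFrame:
    """Read a tab-separated peak table.

    Columns named in ``required`` must be present; the numeric columns the
    pipeline understands are validated value-by-value so a malformed entry
    is reported with its line number; unknown extra columns are carried
    through untouched.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col in df.columns:
        if col not in _NUMERIC_COLUMNS:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}: column {col!r} has a malformed numeric value at line {line}"
            )
        df[col] = parsed
    return df


def save_model(model: ExchangeModel, path):
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))


def load_model(path) -> ExchangeModel:
    return ExchangeModel.from_dict(yaml.safe_load(Path(path).read_text()))


def save_scheme(scheme: AcquisitionScheme, path):
    Path(path).write_text(yaml.safe_dump(scheme.to_dict(), sort_keys=False))


def load_scheme(path) -> AcquisitionScheme:
    return AcquisitionScheme.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run.

    Unknown keys are rejected at load time, and the seed is mandatory: a
    config fully determines the run.
    """

    seed: int
    outdir: str = "results/pipeline"
    temperature_k: float = 293.15
    amplitude_threshold: float = 4.0e5
    n_boot: int = 200
    cest_n_starts: int = 2
    cest_max_nfev: int = 250
    cest_residues: tuple | None = None  # subset of residues, None = all
    alpha: float = 0.05
    offset_cold_kcal: float = 2.0
    include_cpmg: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        if "cest_residues" in raw and raw["cest_residues"] is not None:
            raw["cest_residues"] = tuple(raw["cest_residues"])
        return cls(**raw)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis on the default fixtures.

    Stages: simulate -> real-time global fit (+bootstrap) -> three-state
    CEST fit at 20 degC -> CPMG regime classification -> merged populations
    and the four-state free-energy landscape.  Returns the report dict and
    writes ``report.json``, the input tables, and a stage log under
    ``config.outdir``.
    """
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(rng.integers(2**31))
                   for name in ("realtime", "cest", "cpmg25", "cpmg35", "boot", "fit")}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"pipeline seed={config.seed}"]
    fixtures = synthetic_data.default_fixtures()
    report = {"config": dataclasses.asdict(config), "stages": {}}

    # stage 1: real-time kinetics
    fx_rt = fixtures["tjump20C"]
    rt_table = synthetic_data.simulate_realtime_dataset(fx_rt, seed=stage_seeds["realtime"])
    write_peak_table(rt_table, outdir / "tjump20C.tsv")
    series = realtime_kinetics.series_from_table(rt_table)
    keep, counts, _fits = realtime_kinetics.filter_peaks(
        series, config.amplitude_threshold
    )
    rt_fit = realtime_kinetics.global_fit_rates(keep)
    rt_fit.intervals = realtime_kinetics.bootstrap_uncertainty(
        keep, n_boot=config.n_boot, seed=stage_seeds["boot"]
    )
    report["stages"]["realtime"] = {
        "seed": stage_seeds["realtime"],
        "counts": counts,
        "k_obs_h": rt_fit.k_obs,
        "k_g_to_fs_h": rt_fit.k_g_to_fs,
        "k_fs_to_g_h": rt_fit.k_fs_to_g,
        "p_ground": rt_fit.p_ground,
        "p_fs": rt_fit.p_fs,
        "lifetimes_h": rt_fit.lifetimes_h,
        "intervals": rt_fit.intervals,
    }
    log_lines.append(
        f"realtime: k_G->FS={rt_fit.k_g_to_fs:.4f}/h k_FS->G={rt_fit.k_fs_to_g:.4f}/h "
        f"({counts['Ground']} Ground + {counts['FS']} FS peaks)"
    )

    # stage 2: CEST exchange model at 20 degC
    fx_cest = fixtures["cest15N_20C"]
    cest_table = synthetic_data.simulate_cest_dataset(fx_cest, seed=stage_seeds["cest"])
    write_peak_table(cest_table, outdir / "cest15N_20C.tsv")
    profiles = cest_fitting.profiles_from_table(cest_table, fx_cest.scheme)
    if config.cest_residues is not None:
        profiles = [p for p in profiles if p.residue in set(config.cest_residues)]
    cest_fit = cest_fitting.fit_exchange_model(
        profiles,
        "linear_three_state",
        r2_ties={"Enigma": "Ground"},
        n_starts=config.cest_n_starts,
        seed=stage_seeds["fit"],
        max_nfev=config.cest_max_nfev,
    )
    report["stages"]["cest"] = {
        "seed": stage_seeds["cest"],
        "topology": cest_fit.topology,
        "populations": cest_fit.populations,
        "rates_s": {f"{a}->{b}": v for (a, b), v in cest_fit.rates.items()},
        "red_chi2": cest_fit.red_chi2,
        "n_residues": len({p.residue for p in profiles}),
    }
    log_lines.append(
        f"cest: p_E={cest_fit.populations['Enigma']:.3f} "
        f"k_G->E={cest_fit.rate('Ground', 'Enigma'):.2f}/s red_chi2={cest_fit.red_chi2:.2f}"
    )

    # stage 3: CPMG regime classification
    if config.include_cpmg:
        rexes = {}
        for name, seed_key in (("cpmg25C", "cpmg25"), ("cpmg35C", "cpmg35")):
            fx = fixtures[name]
            tab = synthetic_data.simulate_cpmg_dataset(fx, seed=stage_seeds[seed_key])
            write_peak_table(tab, outdir / f"{name}.tsv")
            profs = cpmg_analysis.profiles_from_table(tab, fx.scheme)
            rexes[name] = [cpmg_analysis.estimate_rex(p, nu_low=50.0) for p in profs]
        rex_report = cpmg_analysis.classify_regime(
            rexes["cpmg25C"], rexes["cpmg35C"], alpha=config.alpha,
            seed=stage_seeds["cpmg25"],
        )
        slow = rex_report.table[rex_report.table["regime"] == "slow_intermediate"]
        report["stages"]["cpmg"] = {
            "n_residues": int(len(rex_report.table)),
            "n_slow_intermediate": int(len(slow)),
            "table": rex_report.table.to_dict(orient="records"),
        }
        log_lines.append(
            f"cpmg: {len(slow)}/{len(rex_report.table)} residues slow-intermediate"
        )

    # stage 4: merged populations and the landscape
    cest_pops = cest_fit.populations
    rt_pops = {"Ground": rt_fit.p_ground, "FS": rt_fit.p_fs}
    merged = landscape_mod.merge_populations(cest_pops, rt_pops, anchor_state="Ground")
    rates_s = {
        ("Ground", "FS"): rt_fit.k_g_to_fs / 3600.0,
        ("FS", "Ground"): rt_fit.k_fs_to_g / 3600.0,
        ("Ground", "Enigma"): cest_fit.rate("Ground", "Enigma"),
        ("Ground", "PD"): cest_fit.rate("Ground", "PD"),
    }
    scape = landscape_mod.build_landscape(
        merged, rates_s, config.temperature_k, reference="Ground"
    )
    report["stages"]["landscape"] = {
        "temperature_k": scape.temperature_k,
        "populations": scape.populations,
        "free_energies_kcal": scape.free_energies,
        "barriers_kcal": {f"{a}->{b}": v for (a, b), v in scape.barriers.items()},
        "states": sorted(scape.populations),
    }
    log_lines.append(
        "landscape states: " + ", ".join(
            f"{s}={p:.3f}" for s, p in sorted(scape.populations.items())
        )
    )

    report_json = json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    (outdir / "report.json").write_text(report_json)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    report["report_sha256"] = hashlib.sha256(report_json.encode()).hexdigest()
    return report
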