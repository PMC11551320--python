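"""Stage 2: millisecond exchange from CEST saturation profiles.

Fits the two-state model to the methyl dataset and the linear three-state
Enigma<->Ground<->PD model to the 15N datasets (Enigma R2 tied to Ground),
then compares alternative topologies on the 20 degC data by reduced
chi-square.  Writes results/cest_fits.json.  The 4 degC fit is the slowest
stage (22 profiles); skip it with --fast.
"""

import argparse
import json
from pathlib import Path

import numpy as np

np.seterr(all="ignore")

from foldswitch import cest_fitting as cf, pipeline_io, synthetic_data as sd


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--fast", action="store_true",
                        help="skip the 11-residue 4 degC fit")
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/cest_fits.json"))
    args = parser.parse_args()

    fixtures = sd.default_fixtures()
    report = {}

    def load_profiles(name):
        fx = fixtures[name]
        table = pipeline_io.read_peak_table(args.data / f"{name}.tsv")
        return fx, cf.profiles_from_table(table, list(fx.all_schemes))

    fx, profiles = load_profiles("cestMethyl_20C")
    fit = cf.fit_exchange_model(profiles, "two_state", r2_ties={"minor": "Ground"},
                                n_starts=2, seed=args.seed)
    print(f"methyl CEST: kex = {fit.edge_kex[('Ground', 'minor')]:.0f}/s, "
          f"p_minor = {100 * fit.populations['minor']:.1f}%, "
          f"red chi2 = {fit.red_chi2:.2f}")
    report["cestMethyl_20C"] = {
        "kex_s": fit.edge_kex[("Ground", "minor")],
        "p_minor": fit.populations["minor"],
        "red_chi2": fit.red_chi2,
    }

    fx, profiles = load_profiles("cest15N_20C")
    fit20 = cf.fit_exchange_model(profiles, "linear_three_state",
                                  r2_ties={"Enigma": "Ground"},
                                  n_starts=3, seed=args.seed)
    print(f"15N CEST 20C: populations "
          + ", ".join(f"{s} {100 * p:.1f}%" for s, p in fit20.populations.items())
          + f"; k_G->E = {fit20.rate('Ground', 'Enigma'):.1f}/s, "
          f"k_G->PD = {fit20.rate('Ground', 'PD'):.1f}/s")
    report["cest15N_20C"] = {
        "populations": fit20.populations,
        "rates_s": {f"{a}->{b}": v for (a, b), v in fit20.rates.items()},
        "red_chi2": fit20.red_chi2,
    }

    # topology comparison: the fully connected superset fits comparably, a
    # model without direct Ground-PD exchange fits notably worse
    alt_full = cf.fit_exchange_model(profiles, "fully_connected_three_state",
                                     r2_ties={"Enigma": "Ground"}, n_starts=1,
                                     seed=args.seed, warm_start=fit20)
    alt_nogpd = cf.fit_exchange_model(profiles, "no_ground_pd_three_state",
                                      r2_ties={"Enigma": "Ground"}, n_starts=2,
                                      seed=args.seed)
    comparison = cf.compare_models([fit20, alt_full, alt_nogpd])
    print("topology ranking by reduced chi2: "
          + " < ".join(f"{t} ({comparison.red_chi2[t]:.2f})"
                       for t in comparison.ranking))
    report["topology_comparison"] = {
        "ranking": comparison.ranking,
        "red_chi2": comparison.red_chi2,
        "indistinguishable": [list(p) for p in comparison.indistinguishable],
    }

    if not args.fast:
        fx, profiles = load_profiles("cest15N_4C")
        fit4 = cf.fit_exchange_model(profiles, "linear_three_state",
                                     r2_ties={"Enigma": "Ground"},
                                     n_starts=2, seed=args.seed, max_nfev=150)
        print(f"15N CEST 4C: populations "
              + ", ".join(f"{s} {100 * p:.1f}%" for s, p in fit4.populations.items())
              + " (the partially disordered state dominates in the cold)")
        report["cest15N_4C"] = {
            "populations": fit4.populations,
            "rates_s": {f"{a}->{b}": v for (a, b), v in fit4.rates.items()},
            "red_chi2": fit4.red_chi2,
        }

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=2, sort_keys=True))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
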