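"""Stage 3: CPMG relaxation dispersion and the exchange-regime test.

Converts the two-temperature CPMG volume tables to R2,eff profiles,
estimates Rex per residue (low-frequency point minus high-frequency
plateau), and runs the Bonferroni-corrected resampling test on whether Rex
rises with temperature (slow-intermediate exchange) or falls (fast).
Writes results/cpmg_regimes.tsv.
"""

import argparse
from pathlib import Path

from foldswitch import cpmg_analysis as ca, pipeline_io, synthetic_data as sd


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/cpmg_regimes.tsv"))
    args = parser.parse_args()

    fixtures = sd.default_fixtures()
    rex = {}
    for name in ("cpmg25C", "cpmg35C"):
        table = pipeline_io.read_peak_table(args.data / f"{name}.tsv")
        profiles = ca.profiles_from_table(table, fixtures[name].scheme)
        rex[name] = [ca.estimate_rex(p, nu_low=50.0) for p in profiles]

    report = ca.classify_regime(rex["cpmg25C"], rex["cpmg35C"],
                                alpha=args.alpha, seed=args.seed)
    table = report.table
    n_slow = int((table["regime"] == "slow_intermediate").sum())
    large = table[table["group"] == "large"]
    print(f"{n_slow}/{len(table)} residues significantly slow-intermediate "
          f"(Rex rises with temperature) at alpha = {args.alpha}")
    print(f"large-Rex group (> 10/s): {len(large)} residues, "
          f"{int((large['regime'] == 'slow_intermediate').sum())} of them slow — "
          "consistent with the millisecond Ground->Enigma process")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False, float_format="%.6g")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
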