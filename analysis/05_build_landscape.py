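"""Stage 4: the four-state free-energy landscape.

Merges the CEST populations (Enigma/Ground/PD) with the real-time
populations (Ground ensemble vs FS), Boltzmann-inverts to state free
energies, converts every measured rate to an Eyring barrier, and aligns the
4 degC landscape to 20 degC with the constant cold-temperature offset.
Reads the stage reports of 02/03 and writes results/landscape.json + .tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from foldswitch.landscape import (
    apply_temperature_offset,
    build_landscape,
    merge_populations,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--offset-cold", type=float, default=2.0,
                        help="kcal/mol added to the 4 degC free energies")
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    rt = json.loads((args.results / "realtime_rates.json").read_text())
    cest = json.loads((args.results / "cest_fits.json").read_text())

    rt20 = rt["tjump20C"]
    cest20 = cest["cest15N_20C"]
    merged = merge_populations(
        cest20["populations"],
        {"Ground": rt20["p_ground"], "FS": 1.0 - rt20["p_ground"]},
    )
    rates20 = {
        ("Ground", "FS"): rt20["k_g_to_fs_h"] / 3600.0,
        ("FS", "Ground"): rt20["k_fs_to_g_h"] / 3600.0,
        ("Ground", "Enigma"): cest20["rates_s"]["Ground->Enigma"],
        ("Ground", "PD"): cest20["rates_s"]["Ground->PD"],
    }
    warm = build_landscape(merged, rates20, 293.15)
    print("20 degC landscape (kcal/mol relative to Ground):")
    for state, g in sorted(warm.free_energies.items(), key=lambda kv: kv[1]):
        print(f"  {state:7s} dG = {g:6.2f}   p = {warm.populations[state]:.3f}")
    for (a, b), top in sorted(warm.barriers.items(), key=lambda kv: kv[1]):
        print(f"  {a}->{b}: barrier top {top:.2f}")

    rows = [{"temperature_k": 293.15, "state": s, "population": warm.populations[s],
             "dG_kcal": g} for s, g in warm.free_energies.items()]

    if "cest15N_4C" in cest:
        cest4 = cest["cest15N_4C"]
        rates4 = {
            ("Ground", "Enigma"): cest4["rates_s"]["Ground->Enigma"],
            ("Ground", "PD"): cest4["rates_s"]["Ground->PD"],
        }
        cold = build_landscape(cest4["populations"], rates4, 277.15)
        cold = apply_temperature_offset(cold, warm, offset_kcal=args.offset_cold,
                                        shared_transition=("Ground", "Enigma"))
        print(f"4 degC landscape (+{args.offset_cold:g} kcal/mol offset so the "
              "shared barrier cannot drop on cooling):")
        for state, g in sorted(cold.free_energies.items(), key=lambda kv: kv[1]):
            print(f"  {state:7s} dG = {g:6.2f}   p = {cold.populations[state]:.3f}")
        rows += [{"temperature_k": 277.15, "state": s,
                  "population": cold.populations[s], "dG_kcal": g}
                 for s, g in cold.free_energies.items()]

    out_json = args.results / "landscape.json"
    out_json.write_text(json.dumps({
        "warm": {"free_energies": warm.free_energies,
                 "barriers": {f"{a}->{b}": v for (a, b), v in warm.barriers.items()},
                 "populations": warm.populations},
    }, indent=2, sort_keys=True))
    out_tsv = args.results / "landscape.tsv"
    pd.DataFrame(rows).to_csv(out_tsv, sep="\t", index=False, float_format="%.6g")
    print(f"wrote {out_json} and {out_tsv}")


if __name__ == "__main__":
    main()
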