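"""Generate every synthetic dataset of the analysis as plain TSV peak tables.

Writes one table per fixture under results/data/: the two temperature-jump
series, the 15N and methyl CEST datasets, the two-temperature CPMG pair,
and the 4 degC multi-state volume table.
"""

import argparse
from pathlib import Path

from foldswitch import pipeline_io, synthetic_data as sd

SIMULATORS = {
    "realtime": sd.simulate_realtime_dataset,
    "cest": sd.simulate_cest_dataset,
    "cpmg": sd.simulate_cpmg_dataset,
    "volumes": sd.simulate_volume_table,
}


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    for name, fixture in sd.default_fixtures().items():
        table = SIMULATORS[fixture.kind](fixture, seed=args.seed)
        path = pipeline_io.write_peak_table(table, args.out / f"{name}.tsv")
        print(f"{name:16s} -> {path} ({len(table)} rows, "
              f"{fixture.kind}, noise {fixture.noise_sigma:.1%})")


if __name__ == "__main__":
    main()
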