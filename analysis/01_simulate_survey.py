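#!/usr/bin/env python
"""Generate the synthetic household survey used by the downstream analyses.

The generator emulates the Malawi 2016/17 integrated household survey:
32 districts (rook lattice with one isolated lake district), covariate
margins matching the survey's descriptive table, per-capita expenditure
calibrated so the national poverty line sits at a 51.5% head count, and
an impoverishment process targeting the study's ~1.6% rate. District
random effects come from a Leroux CAR field with known (lambda, tau2).

Writes scratch/survey/{households.csv, districts.gal, truth.json}
(regenerable bulk data; the tables the later scripts derive from it go
under results/).
"""

from pathlib import Path

from impovmap import GeneratorConfig, generate, write_fixture

OUT = Path(__file__).resolve().parents[1] / "scratch" / "survey"
SEED = 1

# study conditions, at 120 households/district so every script re-runs in
# about a minute (the generator scales to the survey's ~389/district)
CONFIG = GeneratorConfig(households_per_district=120, seed=SEED)


def main() -> None:
    records, weights, truth = generate(CONFIG)
    paths = write_fixture(records, weights, truth, OUT)
    print(f"simulated {len(records)} households in {weights.n_districts} districts")
    print(f"  impoverishment rate: {records['impoverished'].mean():.4f}")
    print(f"  islands: {weights.islands}")
    print(f"  true lambda={truth['lambda']}, tau2={truth['tau2']}")
    for name, p in paths.items():
        print(f"  wrote {name}: {p}")


if __name__ == "__main__":
    main()
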