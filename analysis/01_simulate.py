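#!/usr/bin/env python
"""Generate the synthetic study: 3 regions x 2 years x 45 plots.

Writes the four raw input tables (landuse.csv, arthropods.csv,
vegetation.csv, traits.csv) plus the realized plot-level ground truth to
results/data/.  The ground truth follows the Resource Abundance graph, so
both model concepts can be fitted downstream.
"""

from pathlib import Path

from grasslandsem.io import AnalysisConfig
from grasslandsem.synth import default_truth, write_fixture_dir

SEED = 2026
OUT = Path("results/data")


def main() -> None:
    config = AnalysisConfig(seed=SEED)
    truth = default_truth("ra", seed=SEED)
    realized = write_fixture_dir(OUT, truth=truth, config=config, seed=SEED)
    n_records = sum(1 for _ in open(OUT / "arthropods.csv")) - 1
    print(f"wrote {len(realized)} plot-years ({realized['plot'].nunique()} plots) to {OUT}/")
    print(f"  arthropod occurrence records: {n_records}")
    print(f"  herbivore biomass per plot: median {realized['herbivore_biomass'].median():.1f} g")
    print(f"  predator biomass per plot:  median {realized['predator_biomass'].median():.2f} g")


if __name__ == "__main__":
    main()
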