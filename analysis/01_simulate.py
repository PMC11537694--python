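#!/usr/bin/env python
"""Generate the synthetic study landscape.

Writes the scenario definition, covariate rasters, land-use mosaic, species
occurrences and per-species true suitability surfaces under
``results/landscape/``. Later stages read from there.
"""

from pathlib import Path

import numpy as np

from priormap.geodata import write_raster
from priormap.occurrences import write_occurrences
from priormap.synth import (
    LandscapeScenario,
    gen_covariates,
    gen_lulc,
    gen_occurrences,
)

OUT = Path("results/landscape")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scenario = LandscapeScenario(seed=seed, forced_pair=(0, 1, 0.9))
    scenario.to_json(OUT / "scenario.json")

    cov = gen_covariates(scenario)
    for i, layer in enumerate(cov):
        write_raster(layer, OUT / f"cov{i + 1}.asc")
    lulc = gen_lulc(scenario, cov)
    write_raster(lulc, OUT / "lulc.asc")

    occ, truth = gen_occurrences(scenario, cov)
    write_occurrences(occ, OUT / "occurrences.csv")
    (OUT / "truth").mkdir(exist_ok=True)
    for sp, layer in truth.items():
        write_raster(layer, OUT / "truth" / f"{sp}.asc")

    classes, counts = np.unique(lulc.values, return_counts=True)
    print(f"landscape: {scenario.n_rows}x{scenario.n_cols} cells at "
          f"{scenario.cell_size:.0f} m ({scenario.n_covariates} covariates, "
          f"forced pair r=0.9 between cov1 and cov2)")
    print(f"land-use classes {classes.tolist()} with fractions "
          f"{np.round(counts / counts.sum(), 3).tolist()}")
    print(f"occurrences: {len(occ)} points over {len(scenario.species)} species "
          f"-> {OUT}")


if __name__ == "__main__":
    main()
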