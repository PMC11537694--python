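#!/usr/bin/env python
"""Fit one maxent SDM per species and aggregate richness.

Models use linear + quadratic + product features, RM = 1.1, 10,000
background points, and four replicate 75/25 split-sample validations.
Writes a per-species validation table, each suitability map, and the
equal-weight richness surface.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from priormap.geodata import read_raster, write_raster
from priormap.maxent import (
    FeatureExpansion,
    aggregate_richness,
    evaluate,
    fit_maxent,
    occurrence_cells,
    predict,
    sample_background,
    variable_importance,
)
from priormap.occurrences import read_occurrences
from priormap.synth import LandscapeScenario

LAND = Path("results/landscape")
OUT = Path("results")


def main() -> None:
    scenario = LandscapeScenario.from_json(LAND / "scenario.json")
    kept = pd.read_csv(OUT / "variable_selection.csv")
    kept_names = kept.loc[kept["status"] == "kept", "variable"].tolist()
    cov = [read_raster(LAND / f"{n}.asc") for n in kept_names]
    occ = read_occurrences(OUT / "occurrences_thinned.csv")

    bg = sample_background(cov, 10_000, seed=scenario.seed)
    expansion = FeatureExpansion.from_background(kept_names, bg)
    (OUT / "suitability").mkdir(parents=True, exist_ok=True)
    rows, maps = [], []
    for k, sp in enumerate(occ.species()):
        pres = occurrence_cells(occ.for_species(sp), cov)
        model = fit_maxent(pres, bg, expansion, rm=1.1)
        rep = evaluate(pres, bg, expansion, rm=1.1, split=0.75, replicates=4,
                       seed=scenario.seed * 100 + k)
        vi = variable_importance(model, pres, bg, seed=scenario.seed * 200 + k)
        smap = predict(model, cov)
        write_raster(smap, OUT / "suitability" / f"{sp}.asc")
        maps.append(smap)
        top = max(vi.permutation_importance, key=vi.permutation_importance.get)
        rows.append({
            "species": sp,
            "n_presences": len(pres),
            "train_auc": round(rep.mean_train_auc, 3),
            "test_auc": round(rep.mean_test_auc, 3),
            "top_variable": top,
            "top_permutation_importance": round(vi.permutation_importance[top], 1),
        })
    tab = pd.DataFrame(rows)
    tab.to_csv(OUT / "sdm_validation.csv", index=False)
    richness = aggregate_richness(maps)
    write_raster(richness, OUT / "richness.asc")
    print(tab.to_string(index=False))
    print(f"mean train AUC {tab['train_auc'].mean():.3f}, "
          f"mean test AUC {tab['test_auc'].mean():.3f}; richness surface "
          f"spans [{richness.values.min():.3f}, {richness.values.max():.3f}]")


if __name__ == "__main__":
    main()
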