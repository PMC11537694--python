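#!/usr/bin/env python
"""Overlay hotspots against protected areas and report conservation gaps.

Classifies the richness surface into the four suitability classes (with
built-up land and the 1-km road corridor excluded), places protected areas
over 60% of the constructed-truth hotspots, overlays both models' hotspots
with the PA raster into the six priority tiers plus over-protected cells,
and writes the area accounting, model-agreement metrics and per-PA actions.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from priormap.gap import (
    PRIORITY_LEGEND,
    area_report,
    classify_suitability,
    exclusion_mask,
    model_agreement,
    overlay_priorities,
    pa_actions,
    species_hotspots,
)
from priormap.geodata import (
    binary_layer,
    buffer_mask,
    rasterize,
    read_raster,
    write_polygons,
    write_raster,
)
from priormap.maxent import aggregate_richness
from priormap.synth import LULC_LEGEND, LandscapeScenario, gen_pas

LAND = Path("results/landscape")
OUT = Path("results")


def main() -> None:
    scenario = LandscapeScenario.from_json(LAND / "scenario.json")
    lulc = read_raster(LAND / "lulc.asc")
    richness = read_raster(OUT / "richness.asc")
    invest_hot = read_raster(OUT / "habitat_hotspots.asc")

    road_mask = buffer_mask(lulc, {LULC_LEGEND["road"]}, 1000.0)
    excl = exclusion_mask(lulc, road_mask, {LULC_LEGEND["town"]})
    classified = classify_suitability(richness, mask=excl)
    maxent_hot = species_hotspots(classified)
    write_raster(classified, OUT / "suitability_classes.asc")

    # constructed-truth hotspots drive PA placement (60% coverage)
    truth_maps = [read_raster(p) for p in sorted((LAND / "truth").glob("*.asc"))]
    rich_truth = aggregate_richness(truth_maps)
    hot_truth = species_hotspots(classify_suitability(rich_truth, mask=excl))
    union_truth = binary_layer(
        lulc.grid, (hot_truth.values != 0) | (invest_hot.values != 0)
    )
    pas = gen_pas(scenario, union_truth)
    write_polygons(pas, OUT / "pas.geojson")
    pa_raster = rasterize(pas, lulc.grid)

    priority = overlay_priorities(maxent_hot, invest_hot, pa_raster)
    write_raster(priority, OUT / "priority.asc")
    report = area_report(priority, legend=PRIORITY_LEGEND)
    report.to_csv(OUT / "priority_areas.csv", index=False)
    agreement = model_agreement(maxent_hot, invest_hot)
    pd.Series(agreement).to_csv(OUT / "model_agreement.csv")
    actions = pa_actions(priority, pas, lulc.grid)
    actions.to_csv(OUT / "pa_actions.csv", index=False)

    cell_km2 = lulc.grid.cell_area / 1e6
    union_model = (maxent_hot.values != 0) | (invest_hot.values != 0)
    outside = pa_raster.values == 0
    gap = float((union_model & outside).sum()) * cell_km2
    gap_truth = float(((union_truth.values != 0) & outside).sum()) * cell_km2

    print(report[["category", "area_km2", "pct_of_total"]].to_string(index=False))
    print(f"model agreement: {agreement}")
    print(f"conservation gap: {gap:.2f} km² (constructed truth {gap_truth:.2f} km², "
          f"relative error {(gap - gap_truth) / gap_truth * 100:+.1f}%)")
    print(f"PA action bins: {actions['bin'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
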