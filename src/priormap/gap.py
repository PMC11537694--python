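"""Conservation gap analysis: masking, classification, overlay, accounting.

The species-distribution and habitat-quality hotspot maps are overlaid with
protected-area (PA) boundaries to grade every cell into priority tiers:
cells flagged by both models form the core zone; cells flagged by one model
are second priority; PA cells flagged by neither model are over-protected.
Tier ordering (outside PAs): priority (habitat-quality only) < key priority
(species model only) < priority outside core zone (both). The same three
ranks repeat inside PAs. Area accounting reports km² and percentages of a
named reference area, rounded half-up to 2 decimals as in conventional
results tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geodata import (
    CategoricalLayer,
    ContinuousLayer,
    Grid,
    PolygonSet,
    binary_layer,
    rasterize,
)

__all__ = [
    "PRIORITY_LEGEND",
    "SuitabilityClasses",
    "exclusion_mask",
    "ten_percent_training_threshold",
    "classify_suitability",
    "species_hotspots",
    "overlay_priorities",
    "area_report",
    "percent_of",
    "model_agreement",
    "pa_actions",
]

# Priority-map legend. Codes 1-3 are outside PAs, 4-6 inside; 7 marks
# over-protected PA cells (neither model), 0 is unranked background.
PRIORITY_LEGEND: dict[int, str] = {
    0: "none",
    1: "priority_outside_pa",        # habitat-quality model only, outside
    2: "key_priority_outside_pa",    # species model only, outside
    3: "priority_outside_core",      # both models, outside
    4: "priority_inside_pa",
    5: "key_priority_inside_pa",
    6: "priority_inside_core",
    7: "over_protected",
}


@dataclass(frozen=True)
class SuitabilityClasses:
    """Fixed cut-offs for the four-class suitability map.

    Classes: 1 unsuitable (< t_unsuitable), 2 less suitable, 3 moderately
    suitable, 4 highly suitable (> t_moderate). Boundary values go to the
    higher class.
    """

    t_unsuitable: float = 0.25
    t_less: float = 0.55
    t_moderate: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.t_unsuitable < self.t_less < self.t_moderate < 1:
            raise ValueError("thresholds must be strictly increasing in (0, 1)")


def exclusion_mask(
    lulc: CategoricalLayer,
    road_mask: CategoricalLayer | None,
    excluded_codes: Iterable[int],
) -> CategoricalLayer:
    """Cells unusable as habitat: excluded land-use classes ∪ road buffer."""
    codes = sorted(set(int(c) for c in excluded_codes))
    present = set(np.unique(lulc.values).tolist())
    unknown = [c for c in codes if c not in present]
    if unknown:
        warnings.warn(f"excluded code(s) not present in land-use map: {unknown}")
    mask = np.isin(lulc.values, codes)
    if road_mask is not None:
        if not lulc.grid.same_geometry(road_mask.grid):
            raise ValueError("road mask not on the shared grid")
        mask = mask | (road_mask.values != 0)
    return binary_layer(lulc.grid, mask)


def ten_percent_training_threshold(
    suitability: ContinuousLayer, training_points: np.ndarray
) -> float:
    """Suitability cut below which 10% of training presences fall.

    ``training_points`` are suitability values at the training presences; the
    threshold is their 10th percentile, so 90% of training presences sit at
    or above it — the conservative binarization rule.
    """
    v = np.asarray(training_points, dtype=float)
    if v.size == 0:
        raise ValueError("no training presences")
    return float(np.quantile(v, 0.10))


def classify_suitability(
    richness: ContinuousLayer,
    classes: SuitabilityClasses | None = None,
    mask: CategoricalLayer | None = None,
) -> CategoricalLayer:
    """Four-class suitability map from an aggregated richness surface.

    Masked (excluded) cells are forced to class 1 (unsuitable). Boundaries
    go to the higher class: 0.25 -> less suitable, 0.55 -> moderately,
    0.90 -> moderately (highly requires > 0.90 strictly).
    """
    classes = classes or SuitabilityClasses()
    valid = richness.valid
    v = richness.values
    if np.any((v[valid] < 0) | (v[valid] > 1)):
        raise ValueError("richness values must lie in [0, 1]")
    out = np.zeros(richness.grid.shape, dtype=np.int64)
    out[valid] = 1
    out[valid & (v >= classes.t_unsuitable)] = 2
    out[valid & (v >= classes.t_less)] = 3
    out[valid & (v > classes.t_moderate)] = 4
    if mask is not None:
        if not richness.grid.same_geometry(mask.grid):
            raise ValueError("exclusion mask not on the shared grid")
        out[valid & (mask.values != 0)] = 1
    return CategoricalLayer(richness.grid, out)


def species_hotspots(
    classified: CategoricalLayer, min_class: int = 2
) -> CategoricalLayer:
    """Binary species-hotspot layer: all suitable classes by default
    (``min_class=2``); ``min_class=3`` restricts to moderate + high."""
    return binary_layer(classified.grid, classified.values >= min_class)


def overlay_priorities(
    maxent_hot: CategoricalLayer,
    invest_hot: CategoricalLayer,
    pa: CategoricalLayer,
) -> CategoricalLayer:
    """Grade every cell by model agreement and PA membership.

    ``pa`` is a rasterized PA layer (0 = outside). Cells outside PAs flagged
    by neither model stay 0; inside PAs they become over-protected (7).
    """
    for lyr in (invest_hot, pa):
        if not maxent_hot.grid.same_geometry(lyr.grid):
            raise ValueError("overlay layers must share a grid")
    me = maxent_hot.values != 0
    inv = invest_hot.values != 0
    inside = pa.values != 0
    out = np.zeros(maxent_hot.grid.shape, dtype=np.int64)
    out[~inside & inv & ~me] = 1
    out[~inside & me & ~inv] = 2
    out[~inside & me & inv] = 3
    out[inside & inv & ~me] = 4
    out[inside & me & ~inv] = 5
    out[inside & me & inv] = 6
    out[inside & ~me & ~inv] = 7
    return CategoricalLayer(maxent_hot.grid, out)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percent_of(area: float, reference: float) -> float:
    """Percentage of a reference area, rounded half-up to 2 decimals."""
    if reference <= 0:
        raise ValueError("reference area must be positive")
    return _round2(100.0 * area / reference)


def area_report(
    layer: CategoricalLayer,
    reference_areas: Mapping[str, float] | None = None,
    legend: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Per-category area (km²) and percentage of each reference area.

    Cell areas come from the grid (cell_size in meters → km² conversion);
    percentages are rounded half-up to 2 decimals. The default reference
    ("total") is the total valid-cell area.
    """
    grid = layer.grid
    cell_km2 = grid.cell_area / 1e6
    valid = layer.values != grid.nodata
    codes, counts = np.unique(layer.values[valid], return_counts=True)
    total_km2 = float(valid.sum()) * cell_km2
    refs = {"total": total_km2}
    if reference_areas:
        refs.update(reference_areas)
    for name, area in refs.items():
        if area <= 0:
            raise ValueError(f"reference area {name!r} must be positive")
    rows = []
    for code, count in zip(codes.tolist(), counts.tolist()):
        area = count * cell_km2
        row = {
            "category": legend.get(code, str(code)) if legend else str(code),
            "code": code,
            "cells": count,
            "area_km2": area,
        }
        for name, ref in refs.items():
            row[f"pct_of_{name}"] = percent_of(area, ref)
        rows.append(row)
    return pd.DataFrame(rows)


def model_agreement(
    maxent_hot: CategoricalLayer, invest_hot: CategoricalLayer
) -> dict[str, float | None]:
    """Agreement between the two hotspot maps under several definitions.

    Reports Jaccard |∩|/|∪|, overlap coefficient |∩|/min(|A|,|B|), and the
    intersection's share of each map, all as percentages rounded to 2
    decimals. No single definition is privileged. Both-empty → all None.
    """
    if not maxent_hot.grid.same_geometry(invest_hot.grid):
        raise ValueError("hotspot maps must share a grid")
    a = maxent_hot.values != 0
    b = invest_hot.values != 0
    na, nb = int(a.sum()), int(b.sum())
    inter = int((a & b).sum())
    union = int((a | b).sum())
    if union == 0:
        return {
            "jaccard": None, "overlap_coefficient": None,
            "share_of_maxent": None, "share_of_invest": None,
        }
    return {
        "jaccard": _round2(100.0 * inter / union),
        "overlap_coefficient": (
            _round2(100.0 * inter / min(na, nb)) if min(na, nb) > 0 else None
        ),
        "share_of_maxent": _round2(100.0 * inter / na) if na else None,
        "share_of_invest": _round2(100.0 * inter / nb) if nb else None,
    }


def pa_actions(
    priority: CategoricalLayer, pa: PolygonSet, grid: Grid | None = None
) -> pd.DataFrame:
    """Per-PA share of priority cells (tiers 4-6) and its action bin.

    Bins: ``>75%`` (p ≥ 0.75), ``25-75%`` (0.25 ≤ p < 0.75), ``<25%``
    (boundaries go to the higher bin). PAs that rasterize to zero cells are
    flagged and excluded from binning.
    """
    grid = grid or priority.grid
    pa_raster = rasterize(pa, grid)
    is_priority = np.isin(priority.values, [4, 5, 6])
    rows = []
    names = {pid: name for pid, name, *_ in pa.polygons}
    for pid in pa.ids():
        cells = pa_raster.values == pid
        n = int(cells.sum())
        if n == 0:
            rows.append(
                {"pa_id": pid, "name": names[pid], "cells": 0,
                 "priority_cells": 0, "proportion": np.nan, "bin": "no-cells"}
            )
            continue
        np_cells = int((cells & is_priority).sum())
        p = np_cells / n
        if p >= 0.75:
            b = ">75%"
        elif p >= 0.25:
            b = "25-75%"
        else:
            b = "<25%"
        rows.append(
            {"pa_id": pid, "name": names[pid], "cells": n,
             "priority_cells": np_cells, "proportion": p, "bin": b}
        )
    return pd.DataFrame(rows)
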