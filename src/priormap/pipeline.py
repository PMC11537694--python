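"""End-to-end composition of the analysis stages on one landscape.

Order of operations mirrors the study workflow: generate (or load) the
landscape; thin occurrences; screen covariates by pairwise correlation;
fit one maxent SDM per species and validate it; aggregate per-species
suitability into a richness surface and classify it; run the habitat-quality
model from the land-use map; overlay both hotspot sets against protected
areas; report priority tiers, model agreement, per-PA actions and the
conservation gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gap as gap_mod
from .geodata import CategoricalLayer, ContinuousLayer, binary_layer, buffer_mask, rasterize
from .habitat import HabitatConfig, degradation, quality, quality_hotspots
from .maxent import (
    FeatureExpansion,
    ValidationReport,
    aggregate_richness,
    evaluate,
    fit_maxent,
    occurrence_cells,
    predict,
    sample_background,
    variable_importance,
)
from .occurrences import OccurrenceSet, pearson_matrix, select_variables, thin_occurrences
from .synth import (
    LULC_LEGEND,
    LandscapeScenario,
    gen_covariates,
    gen_lulc,
    gen_occurrences,
    gen_pas,
    synthetic_sensitivity,
    threats_from_lulc,
    true_suitability,
)

__all__ = ["PipelineResult", "run_scenario"]


@dataclass
class PipelineResult:
    scenario: LandscapeScenario
    richness: ContinuousLayer
    richness_truth: ContinuousLayer
    species_hot: CategoricalLayer
    species_hot_truth: CategoricalLayer
    invest_hot: CategoricalLayer
    priority: CategoricalLayer
    pa_raster: CategoricalLayer
    validation: dict[str, ValidationReport]
    variable_selection: list[str]
    area_table: pd.DataFrame
    agreement: dict
    pa_table: pd.DataFrame
    gap_area_km2: float
    gap_area_truth_km2: float

    @property
    def mean_test_auc(self) -> float:
        return float(np.mean([v.mean_test_auc for v in self.validation.values()]))

    @property
    def mean_train_auc(self) -> float:
        return float(np.mean([v.mean_train_auc for v in self.validation.values()]))


def _union_hot(a: CategoricalLayer, b: CategoricalLayer) -> CategoricalLayer:
    return binary_layer(a.grid, (a.values != 0) | (b.values != 0))


def run_scenario(
    scenario: LandscapeScenario,
    rm: float = 1.1,
    replicates: int = 4,
    split: float = 0.75,
    n_background: int = 10_000,
    thin_min_dist: float = 1000.0,
    corr_threshold: float = 0.8,
    road_buffer: float = 1000.0,
    validate: bool = True,
) -> PipelineResult:
    """Run the whole prioritization pipeline on a synthetic scenario.

    Deterministic for a fixed scenario (every random stage derives its seed
    from ``scenario.seed``).
    """
    seed = scenario.seed
    grid = scenario.grid
    cov = gen_covariates(scenario)
    lulc = gen_lulc(scenario, cov)
    occ, truth = gen_occurrences(scenario, cov)
    names = [f"cov{i + 1}" for i in range(len(cov))]

    occ = thin_occurrences(occ, min_dist=thin_min_dist, max_per_neighborhood=2)

    # covariate screening: univariate gain scores, drop worst-pair partner
    bg = sample_background(cov, n_background, seed=seed + 10)
    r_mat, _ = pearson_matrix(cov, seed=seed + 11)
    pres_all = occurrence_cells(occ, cov)
    scores = {}
    for i, nm in enumerate(names):
        fe = FeatureExpansion.from_background([nm], bg[:, [i]], ("linear", "quadratic"))
        mod = fit_maxent(pres_all[:, [i]], bg[:, [i]], fe, rm=rm, track_contrib=False)
        scores[nm] = mod.training_gain(pres_all[:, [i]], bg[:, [i]])
    selection = select_variables(r_mat, names, scores, threshold=corr_threshold)
    kept_idx = [names.index(n) for n in selection.kept]
    cov_sel = [cov[i] for i in kept_idx]
    kept_names = selection.kept

    # per-species SDMs
    expansion = FeatureExpansion.from_background(
        kept_names, bg[:, kept_idx]
    )
    maps = []
    validation: dict[str, ValidationReport] = {}
    for sp_id in occ.species():
        sp_occ = occ.for_species(sp_id)
        pres = occurrence_cells(sp_occ, cov_sel)
        model = fit_maxent(pres, bg[:, kept_idx], expansion, rm=rm)
        maps.append(predict(model, cov_sel))
        if validate:
            validation[sp_id] = evaluate(
                pres, bg[:, kept_idx], expansion, rm=rm,
                split=split, replicates=replicates, seed=seed + 20,
            )

    # exclusion mask: built-up classes plus the road corridor
    road_mask = buffer_mask(lulc, {LULC_LEGEND["road"]}, road_buffer)
    excl = gap_mod.exclusion_mask(
        lulc, road_mask, excluded_codes={LULC_LEGEND["town"]}
    )

    richness = aggregate_richness(maps)
    classified = gap_mod.classify_suitability(richness, mask=excl)
    species_hot = gap_mod.species_hotspots(classified)

    richness_truth = aggregate_richness(
        [truth[sp] for sp in occ.species()]
    )
    classified_truth = gap_mod.classify_suitability(richness_truth, mask=excl)
    species_hot_truth = gap_mod.species_hotspots(classified_truth)

    # habitat-quality side
    threats = threats_from_lulc(lulc, distance_scale=scenario.threat_distance_scale)
    sens = synthetic_sensitivity()
    cfg = HabitatConfig()
    D = degradation(lulc, threats, sens, cfg)
    Q = quality(D, lulc, sens, cfg)
    invest_hot = quality_hotspots(Q)

    # PAs placed against the constructed-truth hotspots
    hot_truth_union = _union_hot(species_hot_truth, invest_hot)
    pas = gen_pas(scenario, hot_truth_union)
    pa_raster = rasterize(pas, grid) if len(pas) else binary_layer(
        grid, np.zeros(grid.shape)
    )

    priority = gap_mod.overlay_priorities(species_hot, invest_hot, pa_raster)
    area_table = gap_mod.area_report(priority, legend=gap_mod.PRIORITY_LEGEND)
    agreement = gap_mod.model_agreement(species_hot, invest_hot)
    pa_table = (
        gap_mod.pa_actions(priority, pas, grid) if len(pas) else pd.DataFrame()
    )

    cell_km2 = grid.cell_area / 1e6
    outside = pa_raster.values == 0
    hot_union = _union_hot(species_hot, invest_hot)
    gap_area = float(((hot_union.values != 0) & outside).sum()) * cell_km2
    gap_truth = float(((hot_truth_union.values != 0) & outside).sum()) * cell_km2

    return PipelineResult(
        scenario=scenario,
        richness=richness,
        richness_truth=richness_truth,
        species_hot=species_hot,
        species_hot_truth=species_hot_truth,
        invest_hot=invest_hot,
        priority=priority,
        pa_raster=pa_raster,
        validation=validation,
        variable_selection=kept_names,
        area_table=area_table,
        agreement=agreement,
        pa_table=pa_table,
        gap_area_km2=gap_area,
        gap_area_truth_km2=gap_truth,
    )
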