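# priormap

Spatial conservation prioritization for protected-area (PA) systems:
**priormap** combines a presence–background maximum-entropy species
distribution model (SDM) with an InVEST-style habitat-quality model, overlays
the two hotspot maps against existing PA boundaries, and reports conservation
gaps and priority tiers. Everything runs on synthetic landscapes generated by
the package itself, so the whole pipeline is testable end to end against a
known truth.

It is aimed at spatial ecologists and conservation planners who want the
model logic of a MaxEnt + habitat-quality gap analysis as a tested,
scriptable library rather than a chain of GIS operations.

## The models

**Species side.** For each species the landscape-use density over cells is a
Gibbs distribution

    q(x) ∝ exp(λ·f(x)),

with features f(x) built from standardized environmental covariates (linear,
quadratic and pairwise-product terms). The weights λ maximize the
L1-penalized log-likelihood

    mean_presence[λ·f] − log mean_background[exp(λ·f)] − RM · Σ_j β_j |λ_j|,

where RM is the regularization multiplier (default 1.1) and
β_j = sd_j/√m shrinks with the presence count m. Suitability is reported on
the conventional prevalence-0.5 logistic scale; validation uses repeated
random 75/25 presence splits with rank-based AUC against 10,000 background
points, plus jackknife gains, permutation importance and percent
contribution. Per-species maps are min–max normalized and averaged with
equal weights into a species-richness surface, classified at 0.25 / 0.55 /
0.90 into four suitability classes.

**Habitat side.** Each threat source r (cropland, towns, villages, roads,
railways, mines) degrades cell x of land-use class j as

    D_xj = Σ_r Σ_y (W_r / Σ W_r) · r_y · i_rxy · β_x · S_jr,

with linear decay i = 1 − d/d_rmax or exponential decay i = exp(−2.99
d/d_rmax), truncated beyond the maximum influence distance d_rmax. Quality
follows the half-saturation law

    Q_xj = H_j · (1 − D^z / (D^z + k^z)),     (defaults z = 2.5, k = 0.5)

so Q = H_j with no degradation and Q = H_j/2 at D = k.

**Overlay.** Cells flagged by both models form the core zone; single-model
cells are second priority; PA cells flagged by neither model are
over-protected. Crossing with PA membership yields six priority tiers plus
the over-protected class, with area accounting in km² and half-up-rounded
percentages, several model-agreement metrics (Jaccard, overlap coefficient,
per-model shares), and per-PA action bins at 25% / 75% priority coverage.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
10 × 10 km landscape (100 m cells, 5 autocorrelated covariates with one pair
forced to r = 0.9, a cropland-dominated land-use mosaic, 6 species with
known two-covariate niches, 300 occurrences each):

```bash
python analysis/01_simulate.py
python analysis/02_thin_and_select.py
python analysis/03_fit_sdms.py
python analysis/04_habitat_quality.py
python analysis/05_gap_analysis.py
```

which prints, among other things:

```
thinning: 1800 -> 160 records (1 km neighborhood, at most 2 kept)
screening at |r| > 0.8 kept ['cov2', 'cov3', 'cov4', 'cov5']; dropped [('cov1', 'cov2', 0.9)]
mean train AUC 0.882, mean test AUC 0.878
habitat hotspots: 2500 cells (25.0% of landscape, top quality quartile)
model agreement: {'jaccard': 33.88, 'overlap_coefficient': 99.2, ...}
conservation gap: 30.56 km² (constructed truth 27.41 km², relative error +11.5%)
PA action bins: {'>75%': 71, '25-75%': 8, '<25%': 2}
```

Reading: spatial thinning removes the strong pseudo-replication built into
the simulated survey; the forced-correlated covariate is dropped exactly at
the |r| > 0.8 rule; SDMs validate well (AUC ≈ 0.88); and because the
protected areas were constructed to cover only 60% of the true hotspot
cells, the pipeline finds a conservation gap close to the constructed truth
(here within 12%). Tables land under `results/`.

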