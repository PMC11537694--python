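# Methods

This note documents the models implemented in `priormap`, the choices made
where the published workflow left details open, what the synthetic-data
generator does and does not emulate, and the numerical decisions that affect
results.

## Occurrence filtering

Occurrence records are filtered in two steps. Exact same-species duplicate
coordinates are removed first (first record wins). Then a greedy pass in
input order keeps a record only while fewer than `max_per_neighborhood`
(default 2) already-kept records of the same species lie within `min_dist`
(default 1 km, inclusive). The published rule ("points within 1 km retained
if fewer than three") does not define a scan order; file order is canonical
here and the operation is deterministic, a subset of its input, and a fixed
point under re-application. Thinning is applied **per species**; whether the
original analysis thinned per species or jointly is not stated, and per
species is the conservative choice (it never discards a species' records
because of another species).

## Covariate screening

Pairwise Pearson correlations are computed over cells valid in every layer
(seeded subsample above 100,000 cells; default seed 42). While any retained
pair has |r| > 0.8, the pair with the largest |r| is found and its
lower-scored member dropped; ties break toward keeping the earlier variable.
The published workflow ranks by model contribution, which does not exist
before fitting; the default score here is the univariate training gain of a
quick linear+quadratic maxent fit per covariate, and any externally supplied
ranking can be passed instead. Constant layers get correlation 0 with a
warning flag rather than NaN.

## Maximum-entropy SDM

Features are linear, quadratic and pairwise-product transforms of
covariates standardized over the background sample ("LQP"); hinge and
threshold features are deliberately out of scope, which keeps the objective
small, smooth-plus-L1 and strictly convex in practice. The fitted weights
maximize

mean_pres(λ·f) − log mean_bg(exp(λ·f)) − RM·Σ_j β_j|λ_j|,
β_j = max(sd_j(presences), 10⁻⁶)/√m,

the classic per-feature penalty scaling with presence count m. RM defaults
to 1.1. The solver is monotone FISTA (accelerated proximal gradient with
backtracking and a descent safeguard): deterministic, objective
non-increasing by construction, convergence at relative objective change
≤ 1e−6, at most 500 iterations; exhausting the budget raises an error
carrying the objective trace rather than returning silently.

Prediction uses the conventional logistic output with prevalence parameter
τ = 0.5: `sigmoid(log q(x)/uniform + H)` where H is the entropy of the
fitted background distribution. This is monotone in the linear predictor
and lies in [0, 1], which the fixed suitability class cut-offs presuppose.

Validation refits the model on four independent random 75/25 presence
splits ("repeated split-sample"; the published description mixes a 75/25
split with a "cross-validation type", and independent splits are the
reading that honours both the split ratio and the replicate count). AUC is
rank-based (Mann–Whitney, ties counted half) of presences against the full
background. Variable importance is reported three ways:

- **jackknife**: unpenalized training gain with only a variable's features
  and without them (the "without" gain is absent for single-variable
  models);
- **permutation importance**: AUC drop after permuting one covariate's raw
  values across evaluation rows, negatives clipped, normalized to 100;
- **percent contribution**: per-feature credit for each iteration's
  objective improvement (proportional to |Δλ_j · grad_j|), aggregated to
  covariates with product features split evenly. Path accounting is
  solver-dependent — as it is in the original MaxEnt software — so only
  permutation importance should be compared across implementations.

Species maps are min–max normalized over valid cells and averaged with
equal weights into the richness surface. A constant map normalizes to zero
with a warning.

## Habitat quality

Implemented exactly as printed: weight-normalized degradation with linear
(1 − d/d_rmax) or exponential (exp(−2.99 d/d_rmax)) decay, and
half-saturation quality Q = H_j(1 − D^z/(D^z + k^z)). Choices:

- "Index" attenuation in the threat table is read as exponential decay —
  the only two printed kernels are linear and exponential.
- Exponential decay is truncated to 0 beyond d_rmax so every threat has
  compact support; the bare formula never reaches zero.
- z and k are not numerically specified in the source (its k sentence is
  garbled); defaults are the de-facto standards of this model family,
  z = 2.5 and k = 0.5, both configurable. Note k = 0.5 is calibrated for
  degradation scores in roughly [0, 1]; on threat-dense landscapes D can be
  much larger and quality then saturates near zero, which is why hotspot
  extraction uses a quantile rule rather than a fixed quality cut.
- Accessibility β_x defaults to 1 everywhere (no accessibility data in the
  source workflow).
- Degradation is computed by direct (not FFT) convolution of each threat's
  footprint with its decay kernel, so the fast path equals the naive
  quadruple-loop sum to float accumulation order (verified to 1e−10).
- The rule binarizing quality into "habitat hotspots" is unstated in the
  source; the default is the top quartile of valid cells, with a fixed-cut
  alternative. This is the single most consequential undocumented choice
  and is exposed as a parameter.

## Gap analysis

Cells are excluded (forced unsuitable) when they carry a built-up land-use
code or lie within the 1-km road corridor (Euclidean distance between cell
centers). The richness surface is classified at 0.25 / 0.55 / 0.90 with
boundaries going to the higher class ("highly suitable" requires > 0.90
strictly); the published interval notation overlaps at the boundaries, so
the half-open convention is documented here. A per-species
10%-training-presence threshold (10th percentile of suitability at training
presences) is available for conservative per-species binarization.
"Species hotspots" default to all three suitable classes — this matches the
published area accounting where the three class areas sum to the hotspot
total — with an option to restrict to moderate + high.

The overlay legend: outside PAs, habitat-only (1) < species-only (2) <
both = outside core (3); the same ordering inside PAs (4, 5, 6 = inside
core); PA cells identified by neither model are over-protected (7);
remaining cells 0. The categories partition the landscape exactly.

Area accounting is cell count × cell area, reported in km²; percentages are
rounded half-up to two decimals, the rule that reproduces the published
percentage figures from their printed areas. Three published figures are
arithmetically inconsistent under any rounding rule (a PA share printed as
12.17% that computes to 11.52%, 5.01% vs 5.00%, 12.57% vs 12.58%); they are
flagged here and not asserted anywhere. The "fit between models" definition
behind the published 72.11% is unstated, so agreement is reported under
Jaccard, overlap-coefficient and share-of-each definitions, none
privileged. Per-PA action bins cut priority-cell proportion at 25% and 75%,
boundaries to the higher bin.

## Synthetic landscapes

The generator emulates the *structure* the pipeline assumes, not any real
geography: covariates are kernel-smoothed white noise (standardized;
correlation length 8 cells by default; optionally one pair forced to a
target correlation, X₂ = rX₁ + √(1−r²)ε); land use is a mosaic from
latent-field quantiles (rank-transformed so requested class frequencies are
hit exactly, before 1-cell road/railway lines are burned in); species
occurrences are sampled without replacement from the true Gibbs density
exp(w·z); protected areas are rectangles greedily placed over true hotspot
cells until exactly ⌈f·n_hot⌉ of them are covered (final rectangles shrink
to avoid overshoot), so the constructed-truth gap is sharp.

Scale choices, made once:

- **Grid**: 100 × 100 cells of 100 m (10 × 10 km). Every oracle comparison
  and end-to-end run completes in seconds; the 30-m national-plain working
  resolution of the original study is a configuration, not a test
  condition.
- **Threat distances**: the published influence distances (5–12 km)
  describe a ~380-km-wide plain; on the 10-km landscape the scenario scales
  them by 0.1 so threats keep compact support relative to the map. The
  published values themselves remain the package defaults
  (`habitat.SONGNEN_THREATS`).
- **Species signal**: each species loads on two covariates, |w| = 3.5
  (strong) and 1.2 (weak), random signs. The magnitude matters because the
  τ = 0.5 logistic output depends on the niche concentration relative to
  log(number of cells) (≈ 9.2 here): much weaker signals saturate the
  logistic scale near 1 (every cell classifies as suitable), much stronger
  ones put the fixed class cut-offs on the steep part of the response where
  L1 shrinkage of fitted weights systematically inflates hotspot area.
  3.5/1.2 yields landscapes with all four suitability classes present and
  keeps the model inside its well-behaved regime.
- **Sensitivity table**: the per-land-use suitability/sensitivity values
  shipped in `synth.synthetic_sensitivity()` are synthetic and
  illustrative (natural classes good habitat and threat-sensitive,
  built classes non-habitat); the study's numeric table is supplementary
  material not reproduced in its main text.

What passing tests on these landscapes shows: the implementation satisfies
its analytic identities, matches brute-force oracles, recovers known
synthetic signals, and propagates a constructed protection shortfall
through to the reported gap. What they do not show: behaviour under real
survey bias, non-Gaussian covariates, strong niche interactions, or the
data volumes of a 144,200-km² study region — published real-data results
(core-zone area, AUC means, agreement percentage) are therefore not
reproduction targets, only their printed arithmetic is.

## End-to-end truth definition

The constructed-truth conservation gap applies the *same* exclusion,
classification and hotspot rules to the true (noise-free) suitability
surfaces that the pipeline applies to the fitted ones, and both sides share
the deterministic habitat-quality hotspots. Truth is thus "what an ideal
model would report", isolating estimation error from rule choices; PA
placement covers 60% of the union-hotspot truth cells by construction.

## Known limitations

- Percent contribution depends on the optimization path; compare only
  permutation importance across solvers.
- `rasterize` assigns cells by center containment with later-polygon-wins
  tie-breaking; overlapping PAs therefore partition, not double-count.
- The exponential-decay truncation introduces a discontinuity of size
  exp(−2.99) ≈ 0.05 at d_rmax, inherited from giving the printed kernel
  compact support.
- No reprojection: all layers must already share one equal-area projected
  grid, and mismatches are hard errors, never silent resampling.
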