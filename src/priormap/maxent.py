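"""Regularized maximum-entropy species distribution model.

A presence–background Gibbs model: the species' use of the landscape is the
density ``q(x) ∝ exp(λ·f(x))`` over background cells, with features f built
from environmental covariates (linear, quadratic and pairwise-product terms,
standardized over the background). The weights λ maximize the penalized
log-likelihood

    mean_presence[λ·f]  −  log mean_background[exp(λ·f)]  −  rm · Σ_j β_j |λ_j|

where ``rm`` is the regularization multiplier and the per-feature penalty
scale β_j = sd_j(presences)/√m shrinks with presence sample size m, as in
the classic maxent default. The problem is convex; a monotone accelerated
proximal-gradient method (FISTA with descent safeguard) solves it
deterministically.

Validation follows the usual presence–background protocol: repeated random
75/25 presence splits, rank-based AUC against background, jackknife gains,
permutation importance and optimization-path percent contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from .geodata import ContinuousLayer, Grid
from .occurrences import OccurrenceSet

__all__ = [
    "FeatureExpansion",
    "MaxentModel",
    "ValidationReport",
    "ConvergenceError",
    "auc_rank",
    "fit_maxent",
    "fit_maxent_layers",
    "predict",
    "evaluate",
    "variable_importance",
    "aggregate_richness",
    "sample_background",
    "occurrence_cells",
]


class ConvergenceError(RuntimeError):
    """Raised when the optimizer exhausts its iteration budget.

    Carries the objective trace so the failure can be diagnosed.
    """

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

@dataclass
class FeatureExpansion:
    """LQP feature map over named covariates.

    Covariates are standardized with the background mean/sd; features are
    the standardized covariates (linear), their squares (quadratic) and all
    pairwise products (product).
    """

    names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    classes: tuple[str, ...] = ("linear", "quadratic", "product")

    @classmethod
    def from_background(
        cls,
        names: Sequence[str],
        background: np.ndarray,
        classes: Sequence[str] = ("linear", "quadratic", "product"),
    ) -> "FeatureExpansion":
        bg = np.asarray(background, dtype=float)
        mean = bg.mean(axis=0)
        sd = bg.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)  # constant covariate -> zero feature
        return cls(list(names), mean, sd, tuple(classes))

    def feature_names(self) -> list[str]:
        out = []
        k = len(self.names)
        if "linear" in self.classes:
            out += [f"lin:{n}" for n in self.names]
        if "quadratic" in self.classes:
            out += [f"quad:{n}" for n in self.names]
        if "product" in self.classes:
            out += [
                f"prod:{self.names[i]}*{self.names[j]}"
                for i in range(k)
                for j in range(i + 1, k)
            ]
        return out

    def feature_variables(self) -> list[tuple[str, ...]]:
        """Covariate(s) each feature derives from, aligned with columns."""
        out: list[tuple[str, ...]] = []
        k = len(self.names)
        if "linear" in self.classes:
            out += [(n,) for n in self.names]
        if "quadratic" in self.classes:
            out += [(n,) for n in self.names]
        if "product" in self.classes:
            out += [
                (self.names[i], self.names[j])
                for i in range(k)
                for j in range(i + 1, k)
            ]
        return out

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Raw covariate rows (n × k, ordered as ``names``) -> feature rows."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.names):
            raise ValueError(f"expected {len(self.names)} covariate columns")
        Z = (X - self.mean) / self.sd  # constant covariates get sd=1, hence Z=0
        blocks = []
        if "linear" in self.classes:
            blocks.append(Z)
        if "quadratic" in self.classes:
            blocks.append(Z ** 2)
        if "product" in self.classes:
            k = Z.shape[1]
            if k >= 2:
                cols = [Z[:, i] * Z[:, j] for i in range(k) for j in range(i + 1, k)]
                blocks.append(np.column_stack(cols))
        return np.hstack(blocks) if blocks else np.empty((len(X), 0))


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    expansion: FeatureExpansion
    weights: np.ndarray
    rm: float
    log_z: float          # log mean_bg exp(eta), for density normalization
    entropy: float        # entropy of fitted background distribution (nats)
    objective_trace: list[float] = field(default_factory=list)
    contrib: np.ndarray | None = None  # per-feature objective-path contributions
    meta: dict = field(default_factory=dict)

    def eta(self, X: np.ndarray) -> np.ndarray:
        return self.expansion.transform(X) @ self.weights

    def logistic(self, X: np.ndarray) -> np.ndarray:
        """Logistic-scale suitability in [0, 1] (prevalence parameter 0.5)."""
        raw = self.eta(X) - self.log_z  # log q relative to uniform
        s = raw + self.entropy
        return 1.0 / (1.0 + np.exp(-s))

    def training_gain(self, pres_X: np.ndarray, bg_X: np.ndarray) -> float:
        """Unpenalized gain over the uniform model (nats)."""
        eta_p = self.eta(pres_X)
        eta_b = self.eta(bg_X)
        return float(np.mean(eta_p) - (logsumexp(eta_b) - np.log(len(eta_b))))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _objective(lam, Fp, Fb, pen):
    g = -float(Fp.mean(axis=0) @ lam) + float(logsumexp(Fb @ lam)) - np.log(len(Fb))
    return g + float(pen @ np.abs(lam))


def _grad(lam, fp_mean, Fb):
    eta_b = Fb @ lam
    w = np.exp(eta_b - logsumexp(eta_b))
    return -fp_mean + Fb.T @ w


def fit_maxent(
    pres_X: np.ndarray,
    bg_X: np.ndarray,
    expansion: FeatureExpansion,
    rm: float = 1.1,
    tol: float = 1e-6,
    max_iter: int = 500,
    track_contrib: bool = True,
) -> MaxentModel:
    """Fit λ by monotone FISTA on the L1-penalized maxent objective.

    ``pres_X``/``bg_X`` are raw covariate rows (columns ordered as
    ``expansion.names``). Deterministic: no randomness enters the solve.
    """
    if rm <= 0:
        raise ValueError("rm must be positive")
    Fp = expansion.transform(pres_X)
    Fb = expansion.transform(bg_X)
    m, p = Fp.shape
    if m < 5:
        raise ValueError("need at least 5 presence cells")
    if m < p:
        warnings.warn("fewer presences than features; relying on L1 shrinkage")
    sd_pres = Fp.std(axis=0)
    pen = rm * np.maximum(sd_pres, 1e-6) / np.sqrt(m)
    fp_mean = Fp.mean(axis=0)

    lam = np.zeros(p)
    y = lam.copy()
    t_mom = 1.0
    step = 1.0
    trace = [_objective(lam, Fp, Fb, pen)]
    contrib = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        g_y = _grad(y, fp_mean, Fb)
        gy_val = -float(fp_mean @ y) + float(logsumexp(Fb @ y)) - np.log(len(Fb))
        # backtracking proximal step from the extrapolated point
        while True:
            cand = np.sign(y - step * g_y) * np.maximum(
                np.abs(y - step * g_y) - step * pen, 0.0
            )
            diff = cand - y
            g_cand = -float(fp_mean @ cand) + float(logsumexp(Fb @ cand)) - np.log(len(Fb))
            if g_cand <= gy_val + g_y @ diff + (diff @ diff) / (2 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-14:
                break
        f_cand = g_cand + float(pen @ np.abs(cand))
        # monotone safeguard: fall back to the previous iterate if no descent
        if f_cand <= trace[-1]:
            new_lam = cand
            f_new = f_cand
        else:
            new_lam = lam
            f_new = trace[-1]
        if track_contrib:
            drop = max(0.0, trace[-1] - f_new)
            credit = np.abs((new_lam - lam) * g_y)
            tot = credit.sum()
            if drop > 0 and tot > 0:
                contrib += drop * credit / tot
        t_next = (1 + np.sqrt(1 + 4 * t_mom ** 2)) / 2
        y = new_lam + ((t_mom - 1) / t_next) * (new_lam - lam)
        lam, t_mom = new_lam, t_next
        trace.append(f_new)
        step *= 1.5  # allow the step to grow back
        if abs(trace[-2] - trace[-1]) <= tol * max(1.0, abs(trace[-2])):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"maxent optimizer did not converge in {max_iter} iterations", trace
        )
    eta_b = Fb @ lam
    log_z = float(logsumexp(eta_b) - np.log(len(eta_b)))
    q = np.exp(eta_b - logsumexp(eta_b))
    entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))
    return MaxentModel(
        expansion=expansion,
        weights=lam,
        rm=rm,
        log_z=log_z,
        entropy=entropy,
        objective_trace=trace,
        contrib=contrib if track_contrib else None,
        meta={"n_presence": m, "n_background": len(Fb), "iterations": len(trace) - 1},
    )


# ---------------------------------------------------------------------------
# Landscape helpers
# ---------------------------------------------------------------------------

def sample_background(
    env: Sequence[ContinuousLayer], n: int = 10_000, seed: int = 42
) -> np.ndarray:
    """Uniformly sample raw covariate rows from cells valid in every layer.

    Returns all valid cells when fewer than ``n`` exist.
    """
    valid = env[0].valid
    for lyr in env[1:]:
        valid &= lyr.valid
    idx = np.nonzero(valid.ravel())[0]
    if idx.size == 0:
        raise ValueError("no valid background cells")
    if idx.size > n:
        rng = np.random.default_rng(seed)
        idx = rng.choice(idx, size=n, replace=False)
    return np.column_stack([lyr.values.ravel()[idx] for lyr in env])


def occurrence_cells(
    occ: OccurrenceSet, env: Sequence[ContinuousLayer]
) -> np.ndarray:
    """Raw covariate rows at occurrence points (cell containing each point)."""
    grid = env[0].grid
    xy = occ.coords()
    cols = np.floor((xy[:, 0] - grid.origin_x) / grid.cell_size).astype(int)
    rows = np.floor((grid.origin_y - xy[:, 1]) / grid.cell_size).astype(int)
    inside = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    if not inside.all():
        raise ValueError("occurrence point(s) fall outside the grid")
    return np.column_stack([lyr.values[rows, cols] for lyr in env])


def fit_maxent_layers(
    occ: OccurrenceSet,
    env: Sequence[ContinuousLayer],
    names: Sequence[str],
    rm: float = 1.1,
    n_background: int = 10_000,
    seed: int = 42,
    classes: Sequence[str] = ("linear", "quadratic", "product"),
) -> tuple[MaxentModel, np.ndarray, np.ndarray]:
    """Convenience front end: build features from layers, sample background,
    fit. Returns (model, presence rows, background rows)."""
    bg = sample_background(env, n_background, seed)
    pres = occurrence_cells(occ, env)
    expansion = FeatureExpansion.from_background(names, bg, classes)
    model = fit_maxent(pres, bg, expansion, rm=rm)
    return model, pres, bg


def predict(model: MaxentModel, env: Sequence[ContinuousLayer]) -> ContinuousLayer:
    """Per-cell logistic suitability map in [0, 1]; nodata propagated."""
    if len(env) != len(model.expansion.names):
        raise ValueError(
            f"model needs covariates {model.expansion.names}, got {len(env)} layers"
        )
    grid = env[0].grid
    valid = env[0].valid
    for lyr in env[1:]:
        valid &= lyr.valid
    X = np.column_stack([lyr.values[valid] for lyr in env])
    out = np.full(grid.shape, grid.nodata, dtype=float)
    out[valid] = model.logistic(X)
    return ContinuousLayer(grid, out)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """Rank-based AUC (Mann–Whitney): P(pos > neg) + 0.5·P(tie)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


@dataclass
class ValidationReport:
    train_auc: list[float]
    test_auc: list[float]
    percent_contribution: dict[str, float] = field(default_factory=dict)
    permutation_importance: dict[str, float] = field(default_factory=dict)
    jackknife_only: dict[str, float] = field(default_factory=dict)
    jackknife_without: dict[str, float] = field(default_factory=dict)

    @property
    def mean_train_auc(self) -> float:
        return float(np.mean(self.train_auc))

    @property
    def mean_test_auc(self) -> float:
        return float(np.mean(self.test_auc))


def evaluate(
    pres_X: np.ndarray,
    bg_X: np.ndarray,
    expansion: FeatureExpansion,
    rm: float = 1.1,
    split: float = 0.75,
    replicates: int = 4,
    seed: int = 0,
) -> ValidationReport:
    """Repeated random split-sample validation.

    Per replicate: presences split ``split``/(1−``split``), model refit on the
    training part, train and test AUC computed against the background.
    """
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    m = len(pres_X)
    n_train = int(round(split * m))
    if n_train == 0 or n_train == m:
        raise ValueError("split leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    train_aucs, test_aucs = [], []
    for _ in range(replicates):
        perm = rng.permutation(m)
        tr, te = perm[:n_train], perm[n_train:]
        mod = fit_maxent(pres_X[tr], bg_X, expansion, rm=rm, track_contrib=False)
        s_bg = mod.eta(bg_X)
        train_aucs.append(auc_rank(mod.eta(pres_X[tr]), s_bg))
        test_aucs.append(auc_rank(mod.eta(pres_X[te]), s_bg))
    return ValidationReport(train_auc=train_aucs, test_auc=test_aucs)


def variable_importance(
    model: MaxentModel,
    pres_X: np.ndarray,
    bg_X: np.ndarray,
    seed: int = 0,
) -> ValidationReport:
    """Jackknife gains, permutation importance and percent contribution.

    - jackknife: per covariate, refit with only its features / without them;
      report unpenalized training gains (without-gain absent for a
      single-covariate model).
    - permutation importance: AUC drop after permuting one covariate's raw
      values across evaluation rows, negatives clipped, normalized to 100.
    - percent contribution: the optimizer-path credit accumulated per feature,
      aggregated to covariates (products split evenly), normalized to 100.
      Path accounting is solver-dependent; permutation importance is not.
    """
    names = model.expansion.names
    rng = np.random.default_rng(seed)
    report = ValidationReport(train_auc=[], test_auc=[])

    # --- percent contribution
    if model.contrib is not None:
        per_var = dict.fromkeys(names, 0.0)
        for feat_vars, c in zip(model.expansion.feature_variables(), model.contrib):
            for v in feat_vars:
                per_var[v] += c / len(feat_vars)
        total = sum(per_var.values())
        if total > 0:
            report.percent_contribution = {
                v: 100.0 * c / total for v, c in per_var.items()
            }
        else:
            report.percent_contribution = dict.fromkeys(names, 0.0)

    # --- permutation importance
    base_pres, base_bg = model.eta(pres_X), model.eta(bg_X)
    base_auc = auc_rank(base_pres, base_bg)
    drops = {}
    all_X = np.vstack([pres_X, bg_X])
    for i, v in enumerate(names):
        perm_X = all_X.copy()
        perm_X[:, i] = rng.permutation(perm_X[:, i])
        eta = model.eta(perm_X)
        drops[v] = max(0.0, base_auc - auc_rank(eta[: len(pres_X)], eta[len(pres_X):]))
    total = sum(drops.values())
    report.permutation_importance = {
        v: (100.0 * d / total if total > 0 else 0.0) for v, d in drops.items()
    }

    # --- jackknife
    for i, v in enumerate(names):
        only = FeatureExpansion(
            [v],
            model.expansion.mean[[i]],
            model.expansion.sd[[i]],
            tuple(c for c in model.expansion.classes if c != "product"),
        )
        mod_only = fit_maxent(
            pres_X[:, [i]], bg_X[:, [i]], only, rm=model.rm, track_contrib=False
        )
        report.jackknife_only[v] = mod_only.training_gain(
            pres_X[:, [i]], bg_X[:, [i]]
        )
        if len(names) > 1:
            rest = [j for j in range(len(names)) if j != i]
            without = FeatureExpansion(
                [names[j] for j in rest],
                model.expansion.mean[rest],
                model.expansion.sd[rest],
                model.expansion.classes,
            )
            mod_wo = fit_maxent(
                pres_X[:, rest], bg_X[:, rest], without, rm=model.rm,
                track_contrib=False,
            )
            report.jackknife_without[v] = mod_wo.training_gain(
                pres_X[:, rest], bg_X[:, rest]
            )
    return report


def aggregate_richness(maps: Sequence[ContinuousLayer]) -> ContinuousLayer:
    """Equal-weight richness: min–max normalize each suitability map over its
    valid cells, then average cell-wise. Output lies in [0, 1]."""
    if len(maps) == 0:
        raise ValueError("need at least one suitability map")
    grid = maps[0].grid
    for m in maps[1:]:
        if not grid.same_geometry(m.grid):
            raise ValueError("suitability maps must share a grid")
    valid = maps[0].valid
    for m in maps[1:]:
        valid &= m.valid
    acc = np.zeros(grid.shape, dtype=float)
    for m in maps:
        v = m.values[valid]
        lo, hi = v.min(), v.max()
        if hi == lo:
            warnings.warn("constant suitability map normalized to all-zero")
            norm = np.zeros_like(v)
        else:
            norm = (v - lo) / (hi - lo)
        acc[valid] += norm
    out = np.full(grid.shape, grid.nodata, dtype=float)
    out[valid] = acc[valid] / len(maps)
    return ContinuousLayer(grid, out)
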