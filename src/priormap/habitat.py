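"""Habitat-quality degradation model (InVEST habitat-quality style).

Each threat source r (cropland, towns, villages, roads, railways, mines)
occupies cells ``r_y ∈ {0,1}`` and degrades surrounding habitat with a
distance-decay kernel up to a maximum influence distance d_rmax:

    linear:       i_rxy = 1 − d_xy / d_rmax
    exponential:  i_rxy = exp(−2.99 · d_xy / d_rmax)

both truncated to 0 beyond d_rmax (the exponential form alone never reaches
zero; truncation gives every threat compact support). Total degradation of
cell x with land use j is the weight-normalized sum over threats and threat
cells:

    D_xj = Σ_r Σ_y (W_r / Σ_r W_r) · r_y · i_rxy · β_x · S_jr

with accessibility β_x ∈ [0,1] (default 1) and sensitivity S_jr of land-use
class j to threat r. Quality follows by half-saturation:

    Q_xj = H_j · (1 − D_xj^z / (D_xj^z + k^z))

so Q = H_j where D = 0 and Q = H_j/2 where D = k. Defaults z = 2.5, k = 0.5
(the de-facto standards for this model family); both configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .geodata import CategoricalLayer, ContinuousLayer, Grid, binary_layer

__all__ = [
    "ThreatSpec",
    "SensitivityTable",
    "HabitatConfig",
    "decay",
    "decay_kernel",
    "degradation",
    "quality",
    "quality_hotspots",
    "read_threats",
    "read_sensitivity",
    "SONGNEN_THREATS",
]


@dataclass
class ThreatSpec:
    """One threat source: its reach, weight, decay shape and footprint."""

    name: str
    d_rmax_km: float
    weight: float
    decay: str  # "linear" | "exponential"
    presence: CategoricalLayer | None = None

    def __post_init__(self) -> None:
        if self.d_rmax_km <= 0:
            raise ValueError(f"{self.name}: d_rmax must be positive")
        if not 0 <= self.weight <= 1:
            raise ValueError(f"{self.name}: weight must be in [0, 1]")
        if self.decay not in {"linear", "exponential"}:
            raise ValueError(f"{self.name}: decay must be linear or exponential")
        if self.presence is not None:
            vals = np.unique(self.presence.values)
            if not np.isin(vals, [0, 1]).all():
                raise ValueError(f"{self.name}: presence raster must be 0/1")


# Threat parameters for the Songnen Plain study system: distance (km),
# weight, decay shape ("index" attenuation read as exponential).
SONGNEN_THREATS: list[tuple[str, float, float, str]] = [
    ("field", 5.0, 0.3, "linear"),
    ("towns", 12.0, 1.0, "exponential"),
    ("villages", 10.0, 0.9, "exponential"),
    ("roads", 10.0, 0.8, "linear"),
    ("railways", 8.0, 0.7, "linear"),
    ("mines", 9.0, 0.8, "exponential"),
]


@dataclass
class SensitivityTable:
    """Per land-use class: habitat suitability H_j and sensitivities S_jr."""

    habitat: dict[int, float]                      # class code -> H_j
    sensitivity: dict[int, dict[str, float]]       # code -> threat -> S_jr

    def __post_init__(self) -> None:
        for j, h in self.habitat.items():
            if not 0 <= h <= 1:
                raise ValueError(f"H for class {j} outside [0, 1]")
        for j, row in self.sensitivity.items():
            for r, s in row.items():
                if not 0 <= s <= 1:
                    raise ValueError(f"S[{j},{r}] outside [0, 1]")

    def check_legend(self, codes: Sequence[int]) -> None:
        missing = [c for c in codes if c not in self.habitat]
        if missing:
            raise ValueError(f"land-use code(s) without table entry: {missing}")


@dataclass
class HabitatConfig:
    z: float = 2.5
    k: float = 0.5
    accessibility: ContinuousLayer | None = None  # beta_x, default 1 everywhere

    def __post_init__(self) -> None:
        if self.z <= 0 or self.k <= 0:
            raise ValueError("z and k must be positive")


def decay(d_xy: np.ndarray | float, d_rmax: float, kind: str) -> np.ndarray | float:
    """Distance-decay i_rxy in [0, 1]; zero beyond d_rmax. Total function."""
    d = np.asarray(d_xy, dtype=float)
    if d_rmax <= 0:
        raise ValueError("d_rmax must be positive")
    if kind == "linear":
        out = np.maximum(0.0, 1.0 - d / d_rmax)
    elif kind == "exponential":
        out = np.where(d <= d_rmax, np.exp(-2.99 * d / d_rmax), 0.0)
    else:
        raise ValueError(f"unknown decay kind {kind!r}")
    return float(out) if np.isscalar(d_xy) else out


def decay_kernel(d_rmax: float, cell_size: float, kind: str) -> np.ndarray:
    """Square convolution kernel of i_rxy over center-to-center distances."""
    reach = int(np.floor(d_rmax / cell_size))
    ax = np.arange(-reach, reach + 1)
    dy, dx = np.meshgrid(ax, ax, indexing="ij")
    d = np.hypot(dy, dx) * cell_size
    k = np.asarray(decay(d, d_rmax, kind))
    k[d > d_rmax] = 0.0
    return k


def degradation(
    lulc: CategoricalLayer,
    threats: Sequence[ThreatSpec],
    sens: SensitivityTable,
    cfg: HabitatConfig | None = None,
) -> ContinuousLayer:
    """Weighted, distance-decayed threat exposure D_xj per cell.

    Each threat's footprint is convolved with its decay kernel (direct
    convolution, so the result equals the naive sum over threat cells up to
    float accumulation order), then scaled by the normalized weight, the
    cell's sensitivity S_jr and accessibility β_x.
    """
    cfg = cfg or HabitatConfig()
    grid = lulc.grid
    codes = [int(c) for c in np.unique(lulc.values)]
    sens.check_legend(codes)
    for t in threats:
        if t.presence is None:
            raise ValueError(f"threat {t.name} has no presence raster")
        if not grid.same_geometry(t.presence.grid):
            raise ValueError(f"threat {t.name} not on the shared grid")
    if cfg.accessibility is not None and not grid.same_geometry(
        cfg.accessibility.grid
    ):
        raise ValueError("accessibility layer not on the shared grid")
    beta = (
        cfg.accessibility.values if cfg.accessibility is not None
        else np.ones(grid.shape)
    )
    w_total = sum(t.weight for t in threats)
    if w_total <= 0:
        raise ValueError("threat weights sum to zero")
    D = np.zeros(grid.shape, dtype=float)
    for t in threats:
        kern = decay_kernel(t.d_rmax_km * 1000.0, grid.cell_size, t.decay)
        exposure = ndimage.convolve(
            t.presence.values.astype(float), kern, mode="constant", cval=0.0
        )
        s_map = np.zeros(grid.shape)
        for j in codes:
            s_map[lulc.values == j] = sens.sensitivity.get(j, {}).get(t.name, 0.0)
        D += (t.weight / w_total) * exposure * s_map
    D *= beta
    return ContinuousLayer(grid, D)


def quality(
    D: ContinuousLayer,
    lulc: CategoricalLayer,
    sens: SensitivityTable,
    cfg: HabitatConfig | None = None,
) -> ContinuousLayer:
    """Half-saturation quality Q_xj = H_j (1 − D^z / (D^z + k^z)) ∈ [0, H_j]."""
    cfg = cfg or HabitatConfig()
    if not D.grid.same_geometry(lulc.grid):
        raise ValueError("degradation and land-use layers must share a grid")
    codes = [int(c) for c in np.unique(lulc.values)]
    sens.check_legend(codes)
    H = np.zeros(lulc.grid.shape)
    for j in codes:
        H[lulc.values == j] = sens.habitat[j]
    Dz = D.values ** cfg.z
    Q = H * (1.0 - Dz / (Dz + cfg.k ** cfg.z))
    return ContinuousLayer(D.grid, Q)


def quality_hotspots(
    Q: ContinuousLayer,
    rule: str = "quantile",
    value: float = 0.75,
) -> CategoricalLayer:
    """Binarize quality into habitat hotspots.

    ``rule='quantile'``: cells with Q at or above the ``value``-quantile of
    valid cells (default top 25%). ``rule='fixed'``: cells with Q ≥ value.
    A degenerate (constant) Q map yields an all-zero mask with a warning.
    """
    valid = Q.valid
    v = Q.values[valid]
    out = np.zeros(Q.grid.shape, dtype=np.int64)
    if v.size == 0 or v.min() == v.max():
        warnings.warn("degenerate quality map: no hotspots marked")
        return binary_layer(Q.grid, out)
    if rule == "quantile":
        cut = np.quantile(v, value)
        out[valid & (Q.values >= cut)] = 1
    elif rule == "fixed":
        out[valid & (Q.values >= value)] = 1
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return binary_layer(Q.grid, out)


# ---------------------------------------------------------------------------
# Parameter-table I/O (CSV layouts mirroring the published tables)
# ---------------------------------------------------------------------------

def read_threats(path: str | Path) -> list[ThreatSpec]:
    """Threat table CSV: columns THREAT, MAX_DIST_KM, WEIGHT, DECAY."""
    df = pd.read_csv(path)
    df.columns = [c.strip().upper() for c in df.columns]
    specs = []
    for _, row in df.iterrows():
        dec = str(row["DECAY"]).strip().lower()
        if dec == "index":
            dec = "exponential"
        specs.append(
            ThreatSpec(
                name=str(row["THREAT"]).strip(),
                d_rmax_km=float(row["MAX_DIST_KM"]),
                weight=float(row["WEIGHT"]),
                decay=dec,
            )
        )
    return specs


def read_sensitivity(path: str | Path, threat_names: Sequence[str]) -> SensitivityTable:
    """Sensitivity CSV: columns LULC_CODE, HABITAT, then one column per threat."""
    df = pd.read_csv(path)
    df.columns = [c.strip().upper() for c in df.columns]
    habitat = {}
    sensitivity = {}
    for _, row in df.iterrows():
        code = int(row["LULC_CODE"])
        habitat[code] = float(row["HABITAT"])
        sensitivity[code] = {
            t: float(row[t.upper()]) for t in threat_names if t.upper() in df.columns
        }
    return SensitivityTable(habitat=habitat, sensitivity=sensitivity)
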