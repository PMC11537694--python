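"""Occurrence filtering and environmental-variable decorrelation.

Occurrence records are spatially thinned to curb pseudo-replication and
spatial autocorrelation: exact same-species duplicates are dropped, then a
greedy pass keeps a record only while fewer than ``max_per_neighborhood``
already-kept conspecific records lie within ``min_dist``. Environmental
covariates are screened pairwise by Pearson correlation: while any pair
exceeds the threshold, the lower-ranked member of the worst pair is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geodata import ContinuousLayer

__all__ = [
    "OccurrenceSet",
    "VariableSelection",
    "read_occurrences",
    "write_occurrences",
    "thin_occurrences",
    "pearson_matrix",
    "select_variables",
]


@dataclass
class OccurrenceSet:
    """Presence points: one record per (species_id, x, y)."""

    records: pd.DataFrame  # columns: species, x, y (+ optional provenance)

    def __post_init__(self) -> None:
        missing = {"species", "x", "y"} - set(self.records.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def species(self) -> list:
        return list(pd.unique(self.records["species"]))

    def for_species(self, species_id) -> "OccurrenceSet":
        sub = self.records[self.records["species"] == species_id]
        return OccurrenceSet(sub.copy())

    def coords(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(dtype=float)


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read a CSV with header ``species,x,y``."""
    return OccurrenceSet(pd.read_csv(path))


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    occ.records.to_csv(path, index=False)


def thin_occurrences(
    occ: OccurrenceSet, min_dist: float, max_per_neighborhood: int = 2
) -> OccurrenceSet:
    """Spatially thin occurrences, per species, in input order.

    1. Exact same-species duplicate coordinates are removed (first kept).
    2. Greedy pass over the remaining records in input order: a record is
       kept only if fewer than ``max_per_neighborhood`` already-kept records
       of the same species lie within ``min_dist`` of it.

    Deterministic for a fixed input order; the output is always a subset of
    the input and re-thinning it is a fixed point.
    """
    if min_dist <= 0:
        raise ValueError("min_dist must be positive")
    if max_per_neighborhood < 1:
        raise ValueError("max_per_neighborhood must be >= 1")
    df = occ.records
    if df.empty:
        return OccurrenceSet(df.copy())
    df = df.drop_duplicates(subset=["species", "x", "y"], keep="first")
    keep_idx: list[int] = []
    for sp, sub in df.groupby("species", sort=False):
        kept_xy: list[tuple[float, float]] = []
        for idx, row in sub.iterrows():
            x, y = float(row["x"]), float(row["y"])
            if kept_xy:
                pts = np.asarray(kept_xy)
                d = np.hypot(pts[:, 0] - x, pts[:, 1] - y)
                if int(np.sum(d <= min_dist)) >= max_per_neighborhood:
                    continue
            kept_xy.append((x, y))
            keep_idx.append(idx)
    out = df.loc[sorted(keep_idx)]
    return OccurrenceSet(out.copy())


def pearson_matrix(
    env: Sequence[ContinuousLayer],
    sample_cells: int = 100_000,
    seed: int = 42,
) -> tuple[np.ndarray, list[bool]]:
    """Pairwise Pearson correlations among covariate layers.

    Sampled over cells valid in every layer; when more than ``sample_cells``
    valid cells exist, a seeded uniform subsample is used. Returns the
    symmetric correlation matrix and a per-layer flag marking constant
    layers (their correlations are reported as 0 with a warning).
    """
    if len(env) < 2:
        raise ValueError("need at least two layers")
    valid = env[0].valid
    for lyr in env[1:]:
        valid = valid & lyr.valid
    idx = np.nonzero(valid.ravel())[0]
    if idx.size == 0:
        raise ValueError("no cell is valid in every layer")
    if idx.size > sample_cells:
        rng = np.random.default_rng(seed)
        idx = rng.choice(idx, size=sample_cells, replace=False)
    data = np.column_stack([lyr.values.ravel()[idx] for lyr in env])
    sd = data.std(axis=0)
    constant = [s == 0 for s in sd]
    if any(constant):
        warnings.warn("constant layer(s): correlations reported as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    return r, constant


@dataclass
class VariableSelection:
    """Result of correlation screening."""

    kept: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)
    # (dropped name, retained partner, their r)

    def report(self) -> pd.DataFrame:
        rows = [{"variable": v, "status": "kept", "partner": "", "r": np.nan} for v in self.kept]
        rows += [
            {"variable": v, "status": "dropped", "partner": p, "r": r}
            for v, p, r in self.dropped
        ]
        return pd.DataFrame(rows)


def select_variables(
    r_matrix: np.ndarray,
    names: Sequence[str],
    scores: Mapping[str, float],
    threshold: float = 0.8,
) -> VariableSelection:
    """Iteratively drop the lower-scored member of the worst correlated pair.

    While some pair of retained variables has |r| > ``threshold``, the pair
    with the largest |r| is located and its lower-scored member removed
    (score ties: the variable appearing later in ``names`` is dropped).
    """
    names = list(names)
    r = np.asarray(r_matrix, dtype=float)
    if r.shape != (len(names), len(names)):
        raise ValueError("r_matrix shape does not match names")
    missing = [n for n in names if n not in scores]
    if missing:
        raise ValueError(f"scores missing for: {missing}")
    alive = list(range(len(names)))
    dropped: list[tuple[str, str, float]] = []
    while True:
        worst = None
        worst_abs = threshold
        for ii, i in enumerate(alive):
            for j in alive[ii + 1:]:
                a = abs(r[i, j])
                if a > worst_abs:
                    worst_abs = a
                    worst = (i, j)
        if worst is None:
            break
        i, j = worst
        # drop the lower-scored member; tie -> later in input order drops
        if scores[names[i]] < scores[names[j]]:
            loser, winner = i, j
        else:
            loser, winner = j, i
        dropped.append((names[loser], names[winner], float(r[loser, winner])))
        alive.remove(loser)
    return VariableSelection(kept=[names[i] for i in alive], dropped=dropped)
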