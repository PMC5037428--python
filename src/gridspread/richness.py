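"""Envelope species distribution models and richness stacking.

A minimal bioclimatic surface-range-envelope (SRE) model: per predictor,
presence is allowed between the empirical q and 1-q quantiles of the
training presences; a cell is predicted present iff every predictor
falls inside its bounds. Species with fewer than 5 records are not
modelled — their observed cells are used directly. Binary maps are
evaluated with sensitivity/specificity, the True Skill Statistic
(TSS = sensitivity + specificity - 1) and AUC, and stacked to a coarse
species-richness surface (a species counts in a coarse cell iff any
fine cell of its range lies inside it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .grids import LatticeGrid, Surface

__all__ = [
    "TooFewRecordsError",
    "OccurrenceSet",
    "EnvelopeModel",
    "fit_sre",
    "predict_sre",
    "evaluate_binary",
    "best_tss_threshold",
    "consensus_map",
    "stack_richness",
]

#: Minimum number of presence records for envelope fitting; species
#: below the floor fall back to their observed cells.
MIN_RECORDS = 5


class TooFewRecordsError(ValueError):
    """Raised when a species has too few records for envelope fitting;
    the caller should use the observed records only."""


@dataclass(frozen=True)
class OccurrenceSet:
    """Spatially unique presence cells of one species on the fine grid."""

    species: str
    cells: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        cells = tuple((int(r), int(c)) for r, c in self.cells)
        if len(set(cells)) != len(cells):
            raise ValueError(f"{self.species}: occurrence cells must be unique per cell")
        object.__setattr__(self, "cells", cells)

    @property
    def n_records(self) -> int:
        return len(self.cells)

    def mask(self, grid: LatticeGrid) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        for r, c in self.cells:
            m[r, c] = True
        return m


@dataclass(frozen=True)
class EnvelopeModel:
    """Per-predictor [lower, upper] bounds plus the envelope quantile."""

    bounds: Mapping[str, tuple[float, float]]
    q: float = 0.025

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"predictor {name!r}: lower bound exceeds upper")
        if not 0 <= self.q < 0.5:
            raise ValueError("q must lie in [0, 0.5)")


def fit_sre(
    presence_values: Mapping[str, np.ndarray], q: float = 0.025
) -> EnvelopeModel:
    """Fit envelope bounds as the empirical q and 1-q quantiles of the
    presence values, per predictor (linear-interpolation quantile rule).

    Raises :class:`TooFewRecordsError` below the 5-record modelling
    floor so the caller can fall back to observed records.
    """
    if not presence_values:
        raise ValueError("at least one predictor is required")
    if not 0 <= q < 0.5:
        raise ValueError("q must lie in [0, 0.5)")
    lengths = {name: len(np.asarray(v)) for name, v in presence_values.items()}
    n = next(iter(lengths.values()))
    if len(set(lengths.values())) != 1:
        raise ValueError("predictors have unequal record counts")
    if n < MIN_RECORDS:
        raise TooFewRecordsError(
            f"{n} records < modelling floor of {MIN_RECORDS}; use observed records only"
        )
    bounds = {}
    for name, vals in presence_values.items():
        vals = np.asarray(vals, dtype=float)
        lo, hi = np.quantile(vals, [q, 1.0 - q], method="linear")
        bounds[name] = (float(lo), float(hi))
    return EnvelopeModel(bounds=bounds, q=q)


def predict_sre(model: EnvelopeModel, predictors: Mapping[str, Surface]) -> Surface:
    """Binary range map: 1 where every predictor lies inside its bounds
    (inclusive), 0 elsewhere on observed cells, missing where any
    predictor is missing."""
    missing = [name for name in model.bounds if name not in predictors]
    if missing:
        raise KeyError(f"missing predictor surface(s): {missing}")
    surfaces = [predictors[name] for name in model.bounds]
    grid = surfaces[0].grid
    inside = np.ones(grid.shape, dtype=bool)
    any_nan = np.zeros(grid.shape, dtype=bool)
    for name, surf in zip(model.bounds, surfaces):
        if not surf.grid.same_geometry(grid):
            raise ValueError(f"predictor {name!r} is not on the common grid")
        lo, hi = model.bounds[name]
        any_nan |= surf.missing
        with np.errstate(invalid="ignore"):
            inside &= (surf.values >= lo) & (surf.values <= hi)
    out = inside.astype(float)
    out[any_nan] = np.nan
    return Surface(grid=grid, values=out, name="sre_prediction")


def evaluate_binary(
    predicted: np.ndarray,
    truth: np.ndarray,
    scores: np.ndarray | None = None,
) -> dict[str, float]:
    """Sensitivity, specificity, TSS and AUC of a binary prediction.

    ``predicted`` and ``truth`` are 0/1 label vectors over evaluation
    sites (presences plus absences); AUC uses the rank statistic over
    ``scores`` when a continuous score is available, else over the
    binary prediction itself.
    """
    predicted = np.asarray(predicted).astype(float).ravel()
    truth = np.asarray(truth).astype(float).ravel()
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth differ in length")
    pos = truth == 1
    neg = truth == 0
    if not pos.any() or not neg.any():
        raise ValueError("truth must contain both presences and absences")
    tp = float(np.sum(pos & (predicted == 1)))
    fn = float(np.sum(pos & (predicted == 0)))
    tn = float(np.sum(neg & (predicted == 0)))
    fp = float(np.sum(neg & (predicted == 1)))
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    auc_scores = predicted if scores is None else np.asarray(scores, dtype=float).ravel()
    auc = float(roc_auc_score(truth, auc_scores))
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "tss": sensitivity + specificity - 1.0,
        "auc": auc,
    }


def best_tss_threshold(scores: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Threshold on a continuous suitability score that maximizes TSS
    (ties broken toward the lowest threshold), for binarising SDM output."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    best_t, best_tss = np.nan, -np.inf
    for t in np.unique(scores):
        stats = evaluate_binary((scores >= t).astype(float), truth)
        if stats["tss"] > best_tss + 1e-12:
            best_t, best_tss = float(t), stats["tss"]
    return best_t, best_tss


def consensus_map(a: Surface, b: Surface) -> Surface:
    """Cellwise intersection of two binary maps (consensus prediction)."""
    if not a.grid.same_geometry(b.grid):
        raise ValueError("consensus inputs are not on the same grid")
    vals = a.values * b.values
    return a.with_values(vals, name="consensus")


def stack_richness(
    ranges: Sequence[Surface],
    observed_only: Sequence[OccurrenceSet],
    coarse: LatticeGrid,
    factor: int,
) -> Surface:
    """Stack fine-grid species ranges into coarse-grid species richness.

    A species contributes 1 to a coarse cell iff at least one fine cell
    of its binary range (or of its observed occurrence set, for
    unmodelled species) lies inside that coarse cell.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    richness = np.zeros(coarse.shape)

    def _add(fine_mask: np.ndarray, fine_grid: LatticeGrid) -> None:
        if -(-fine_grid.n_rows // factor) != coarse.n_rows or -(
            -fine_grid.n_cols // factor
        ) != coarse.n_cols:
            raise ValueError("fine grid does not aggregate to the coarse grid at this factor")
        rows, cols = np.nonzero(fine_mask)
        coarse_cells = set(zip(rows // factor, cols // factor))
        for r, c in coarse_cells:
            richness[r, c] += 1

    for surf in ranges:
        _add(np.nan_to_num(surf.values) > 0.5, surf.grid)
    for occ in observed_only:
        for r, c in {(r // factor, c // factor) for r, c in occ.cells}:
            if not (0 <= r < coarse.n_rows and 0 <= c < coarse.n_cols):
                raise ValueError(f"{occ.species}: occurrence outside the coarse grid")
            richness[r, c] += 1
    return Surface(grid=coarse, values=richness, name="richness")
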