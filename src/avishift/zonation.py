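"""Core-area zonation (CAZ) prioritization and reserve-gap statistics.

Cells are removed greedily, worst first: the marginal loss of cell *i* is
``max_j  w_j * p_ij / Q_j`` where ``p_ij`` is species *j*'s suitability in
the cell, ``Q_j`` the species' summed suitability over the not-yet-removed
cells, and ``w_j`` its conservation weight.  Each iteration removes the
``warp_factor`` cells with the smallest marginal loss (no recomputation
within a batch, matching warp semantics); a cell removed later gets a higher
rank, ``rank = removal position / number of land cells``, so the highest-
priority cells carry ranks near 1.

Species weights encode climate-change impact: range losers get high weights,
expanders low ones, with a +0.5 bonus for endemics —
``w = clamp(1 - pct_change / 100, 0.1, 2.0) + 0.5 * endemic``.

The masked ("outside reserves") scenario removes all reserve cells first in
their own CAZ-ordered phase, so the top of the ranking — and every top-30% /
top-50% selection — lies entirely outside existing reserves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import AlignmentError, KeyingError, UndefinedCoverageError
from .raster import RasterGrid

W_MIN, W_MAX = 0.1, 2.0
ENDEMIC_BONUS = 0.5


def compute_weights(records: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-species zonation weights from range-change records.

    ``records`` needs columns species_id and pct_change; ``meta`` the endemic
    flag.  Returns a WeightTable with columns species_id, pct_change,
    endemic, weight.
    """
    if "pct_change" not in records.columns:
        raise KeyingError("records lack a pct_change column")
    missing = set(records["species_id"]) - set(meta["species_id"])
    if missing:
        raise KeyingError(f"species missing from metadata: {sorted(missing)[:5]}")
    df = records[["species_id", "pct_change"]].merge(
        meta[["species_id", "endemic"]], on="species_id", how="left"
    )
    if df["pct_change"].isna().any():
        bad = df.loc[df["pct_change"].isna(), "species_id"].tolist()
        raise KeyingError(f"missing pct_change for {bad[:5]}")
    base = np.clip(1.0 - df["pct_change"].to_numpy(dtype=float) / 100.0, W_MIN, W_MAX)
    df["weight"] = base + ENDEMIC_BONUS * df["endemic"].astype(float)
    return df


@dataclass
class PriorityRanking:
    """CAZ ranking over land cells.

    ``rank_grid`` holds rank values in (0, 1] (1 = retained longest); cells
    off the land mask are NaN.  ``removal_order`` lists, per iteration, the
    flat (row-major) indices of the cells removed.
    """

    rank_grid: RasterGrid
    removal_order: list[np.ndarray]
    warp_factor: int
    masked: bool
    dropped_species: list[str]

    def ranks_flat(self) -> np.ndarray:
        return np.asarray(self.rank_grid.values, dtype=float).ravel()


class CoreAreaZonation(BaseEstimator):
    """Greedy CAZ cell-removal ranking as a fittable estimator.

    Parameters
    ----------
    warp_factor : int
        Cells removed per iteration without marginal-loss recomputation.

    Call :meth:`fit` with a ``(n_species, n_rows, n_cols)`` suitability
    stack (or a dict of single-band :class:`RasterGrid`), per-species
    weights, and optionally a reserve mask; the ranking is then available as
    ``ranking_`` / ``rank_grid_``.

    Tie-breaking is deterministic: smallest marginal loss first, then
    row-major cell index.  Species with zero total suitability are dropped
    with a warning.  Marginal losses are recomputed from scratch each
    iteration (Q summed over remaining cells), so a warp factor of 1
    reproduces the exact greedy algorithm.
    """

    def __init__(self, warp_factor: int = 1000):
        self.warp_factor = warp_factor

    def fit(self, species_layers, weights=None, mask: RasterGrid | None = None,
            land_mask: np.ndarray | None = None,
            reference: RasterGrid | None = None):
        if self.warp_factor < 1:
            raise ValueError("warp_factor must be >= 1")
        names, P3, ref = _coerce_layers(species_layers, reference)
        w = _coerce_weights(weights, names)
        n_rows, n_cols = P3.shape[1:]
        if land_mask is None:
            land_mask = np.isfinite(P3).all(axis=0)
        flat_land = np.flatnonzero(land_mask.ravel())
        n_land = flat_land.size
        P = np.nan_to_num(P3.reshape(len(names), -1)[:, flat_land], nan=0.0)

        keep = P.sum(axis=1) > 0
        dropped = [n for n, k in zip(names, keep) if not k]
        for n in dropped:
            warnings.warn(f"species {n!r} has zero total suitability; dropped",
                          stacklevel=2)
        P = P[keep]
        w = w[keep]

        if mask is not None:
            if isinstance(mask, RasterGrid):
                ref.require_aligned(mask, what="mask")
                mask_vals = np.asarray(mask.values)
            else:
                mask_vals = np.asarray(mask)
            masked_flags = np.nan_to_num(
                mask_vals.astype(float).ravel()[flat_land]) >= 0.5
        else:
            masked_flags = None

        remaining = np.ones(n_land, dtype=bool)
        position = np.empty(n_land, dtype=np.int64)
        removal_order: list[np.ndarray] = []
        pos = 0
        while remaining.any():
            if masked_flags is not None and (remaining & masked_flags).any():
                candidates = np.flatnonzero(remaining & masked_flags)
            else:
                candidates = np.flatnonzero(remaining)
            Q = P[:, remaining].sum(axis=1)
            active = Q > 0
            if active.any():
                delta = np.max(
                    (w[active, None] * P[np.ix_(active, candidates)])
                    / Q[active, None],
                    axis=0,
                )
            else:
                delta = np.zeros(candidates.size)
            order = np.lexsort((candidates, delta))
            batch = candidates[order[: self.warp_factor]]
            remaining[batch] = False
            position[batch] = np.arange(pos, pos + batch.size)
            removal_order.append(flat_land[batch])
            pos += batch.size

        ranks = np.full(n_rows * n_cols, np.nan)
        ranks[flat_land] = (position + 1) / n_land
        rank_grid = ref.with_values(ranks.reshape(n_rows, n_cols),
                                    band_names=("rank",))
        self.species_names_ = [n for n, k in zip(names, keep) if k]
        self.rank_grid_ = rank_grid
        self.ranking_ = PriorityRanking(
            rank_grid=rank_grid,
            removal_order=removal_order,
            warp_factor=self.warp_factor,
            masked=masked_flags is not None,
            dropped_species=dropped,
        )
        return self


def _coerce_layers(species_layers, reference):
    """Normalize layer input to (names, 3-D stack, reference grid)."""
    if isinstance(species_layers, dict):
        names = sorted(species_layers)
        ref = species_layers[names[0]]
        for n in names[1:]:
            ref.require_aligned(species_layers[n], what=f"layer {n}")
        P3 = np.stack([np.asarray(species_layers[n].values, dtype=float)
                       for n in names])
        return names, P3, ref
    P3 = np.asarray(species_layers, dtype=float)
    if P3.ndim != 3:
        raise AlignmentError("species_layers must be (n_species, n_rows, n_cols)")
    names = [f"sp{i}" for i in range(P3.shape[0])]
    if reference is None:
        reference = RasterGrid(P3[0], lon_west=0.0, lat_north=float(P3.shape[1]),
                               cell_size=1.0)
    return names, P3, reference


def _coerce_weights(weights, names) -> np.ndarray:
    if weights is None:
        return np.ones(len(names))
    if isinstance(weights, pd.DataFrame):
        table = dict(zip(weights["species_id"], weights["weight"]))
        missing = [n for n in names if n not in table]
        if missing:
            raise KeyingError(f"no weight for species {missing[:5]}")
        return np.asarray([float(table[n]) for n in names])
    if isinstance(weights, dict):
        return np.asarray([float(weights[n]) for n in names])
    w = np.asarray(weights, dtype=float)
    if w.size != len(names):
        raise KeyingError("one weight per species layer required")
    return w


def caz_rank(species_layers, weights=None, warp_factor: int = 1000,
             mask: RasterGrid | None = None,
             land_mask: np.ndarray | None = None,
             reference: RasterGrid | None = None) -> PriorityRanking:
    """Functional wrapper over :class:`CoreAreaZonation`."""
    est = CoreAreaZonation(warp_factor=warp_factor)
    est.fit(species_layers, weights=weights, mask=mask, land_mask=land_mask,
            reference=reference)
    return est.ranking_


def top_fraction(ranking: PriorityRanking, fraction: float) -> RasterGrid:
    """Binary grid of the top-``fraction`` priority cells (rank > 1 - fraction)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    ranks = np.asarray(ranking.rank_grid.values, dtype=float)
    sel = np.where(np.isnan(ranks), np.nan, (ranks > 1.0 - fraction).astype(float))
    return ranking.rank_grid.with_values(sel, band_names=("priority",))


def coverage_stats(priority: RasterGrid, reserves: RasterGrid) -> float:
    """Share of priority cells that fall inside reserves."""
    priority.require_aligned(reserves, what="reserves")
    p = np.nan_to_num(np.asarray(priority.values, dtype=float)) >= 0.5
    r = np.nan_to_num(np.asarray(reserves.values, dtype=float)) >= 0.5
    n_priority = int(p.sum())
    if n_priority == 0:
        raise UndefinedCoverageError("priority set is empty")
    return float((p & r).sum() / n_priority)
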