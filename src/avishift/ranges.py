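"""Binary range maps and range-shift analytics.

Continuous suitability surfaces are binarized at the threshold maximizing
test sensitivity plus specificity (MTSS) into per-species distribution range
maps (DRMs). From aligned current/future DRM pairs the module derives the
quantities a range-shift assessment reports: area change percentages,
median-centre displacement vectors (distance, bearing, compass quadrant),
stacked species-richness maps and their change, per-elevation-band species
diversity with a turning-point elevation, and group summary tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigurationError,
    InsufficientDataError,
    NoCenterError,
    KeyingError,
    UndefinedChangeError,
)
from .raster import RasterGrid, haversine_km

#: Fig-3-style elevation bands, metres; the last band is open above.
DEFAULT_BAND_EDGES = (0.0, 500.0, 1000.0, 1500.0, 2000.0, 2500.0,
                      3000.0, 3500.0, 4000.0, 5000.0, np.inf)
BAND_LABELS = tuple("ABCDEFGHIJ")


# ---------------------------------------------------------------------------
# thresholding and binary ranges
# ---------------------------------------------------------------------------

def mtss_threshold(test_presence_scores, background_scores) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the midpoints between adjacent distinct pooled scores plus
    one candidate below and one above every score; sensitivity is the share
    of presences scoring >= t, specificity the share of background scoring
    < t.  Among maximizers the smallest candidate is returned.
    """
    p = np.asarray(test_presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise InsufficientDataError("MTSS needs non-empty presence and background scores")
    pooled = np.unique(np.concatenate([p, b]))
    if pooled.size > 1:
        delta = 0.5 * np.min(np.diff(pooled))
        candidates = np.concatenate(
            [[pooled[0] - delta], (pooled[:-1] + pooled[1:]) / 2.0,
             [pooled[-1] + delta]]
        )
    else:
        candidates = np.array([pooled[0] - 0.5, pooled[0] + 0.5])
    best_t, best_obj = None, -np.inf
    for t in candidates:
        obj = np.mean(p >= t) + np.mean(b < t)
        if obj > best_obj:
            best_obj, best_t = obj, float(t)
    return best_t


@dataclass
class BinaryRange:
    """A species' predicted distribution range map (DRM) for one scenario."""

    grid: RasterGrid
    threshold: float
    species_id: str = ""
    scenario: str = ""

    def presence_mask(self) -> np.ndarray:
        return np.nan_to_num(self.grid.values, nan=0.0) >= 0.5

    @property
    def area_cells(self) -> int:
        return int(self.presence_mask().sum())

    @property
    def area_km2(self) -> float:
        return float((self.grid.cell_area_km2() * self.presence_mask()).sum())

    def median_center(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.presence_mask())
        if rows.size == 0:
            raise NoCenterError("empty range has no median centre",
                                species_id=self.species_id)
        lon, lat = self.grid.center_of(rows, cols)
        return geometric_median(lon, lat)


def binarize(suitability: RasterGrid, threshold: float,
             species_id: str = "", scenario: str = "") -> BinaryRange:
    """Binarize a suitability surface: presence iff suitability >= threshold.

    Missing (NaN) cells stay missing.  An all-absence result triggers a
    warning but is returned.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(f"threshold must be in (0, 1), got {threshold}")
    vals = np.asarray(suitability.values, dtype=float)
    out = np.where(np.isnan(vals), np.nan, (vals >= threshold).astype(float))
    if np.nansum(out) == 0:
        warnings.warn(
            f"threshold {threshold} exceeds every suitability value"
            f"{' for ' + species_id if species_id else ''}: empty range",
            stacklevel=2,
        )
    return BinaryRange(
        grid=suitability.with_values(out, band_names=("presence",)),
        threshold=float(threshold),
        species_id=species_id,
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# centres and displacement
# ---------------------------------------------------------------------------

def geometric_median(lon, lat, tol: float = 1e-8, max_iter: int = 2000
                     ) -> tuple[float, float]:
    """Point minimizing the summed Euclidean distance to the given points.

    Solved by Weiszfeld iterative reweighting in a local equirectangular
    frame about the centroid (x scaled by cos of the centroid latitude),
    with the Vardi–Zhang adjustment when an iterate lands on a data point.
    Convergence tolerance is in degrees.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lon.size == 0:
        raise NoCenterError("no points")
    if lon.size == 1:
        return float(lon[0]), float(lat[0])
    lon0, lat0 = lon.mean(), lat.mean()
    cosl = np.cos(np.deg2rad(lat0))
    if cosl <= 1e-9:
        cosl = 1e-9
    pts = np.column_stack([(lon - lon0) * cosl, lat - lat0])
    y = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - y, axis=1)
        on_point = d < 1e-12
        if on_point.any():
            # Vardi–Zhang: move off the coincident point only if the pull of
            # the remaining points exceeds its unit counter-pull
            others = ~on_point
            if not others.any():
                break
            r_vec = ((pts[others] - y) / d[others, None]).sum(axis=0)
            r = np.linalg.norm(r_vec)
            if r <= on_point.sum():
                break
            step = (r - on_point.sum()) / r
            t = (pts[others] / d[others, None]).sum(axis=0) / (1.0 / d[others]).sum()
            y_new = y + step * (t - y)
        else:
            w = 1.0 / d
            y_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            y = y_new
            break
        y = y_new
    return float(lon0 + y[0] / cosl), float(lat0 + y[1])


def shift_vector(center_current: tuple[float, float],
                 center_future: tuple[float, float]) -> dict:
    """Displacement between two range centres.

    Returns shift_km (great-circle, R = 6371 km), bearing_deg (clockwise
    from north), quadrant from the signs of (dlon, dlat) under the strict
    rule — north requires dlat > 0, east requires dlon > 0 — plus
    ``poleward`` ('north'/'south') and a ``boundary`` flag set when either
    component is exactly zero (including the zero vector, whose quadrant is
    None).
    """
    lon1, lat1 = center_current
    lon2, lat2 = center_future
    dlon = (lon2 - lon1 + 180.0) % 360.0 - 180.0
    dlat = lat2 - lat1
    km = float(haversine_km(lon1, lat1, lon2, lat2))
    phi1, phi2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dl = np.deg2rad(dlon)
    x = np.sin(dl) * np.cos(phi2)
    yb = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dl)
    bearing = float(np.degrees(np.arctan2(x, yb)) % 360.0)
    if dlon == 0.0 and dlat == 0.0:
        quadrant = None
    else:
        quadrant = ("N" if dlat > 0 else "S") + ("E" if dlon > 0 else "W")
    return {
        "shift_km": km,
        "bearing_deg": bearing,
        "quadrant": quadrant,
        "poleward": "north" if dlat > 0 else "south",
        "boundary": bool(dlon == 0.0 or dlat == 0.0),
    }


def range_change(current: BinaryRange, future: BinaryRange) -> dict:
    """Area accounting between two aligned DRMs.

    Percentage change uses cell counts; areas are also reported in km^2
    (cosine-latitude spherical cell areas).  A zero current area raises
    :class:`~avishift.errors.UndefinedChangeError`.
    """
    current.grid.require_aligned(future.grid, what="future DRM")
    a_c, a_f = current.area_cells, future.area_cells
    if a_c == 0:
        raise UndefinedChangeError(
            "current range empty: percentage change undefined",
            species_id=current.species_id,
        )
    return {
        "area_current_cells": a_c,
        "area_future_cells": a_f,
        "area_current_km2": current.area_km2,
        "area_future_km2": future.area_km2,
        "pct_change": 100.0 * (a_f - a_c) / a_c,
    }


def range_change_record(current: BinaryRange, future: BinaryRange) -> dict:
    """Full per-species record: area change plus displacement vector."""
    rec = {"species_id": current.species_id, "scenario": future.scenario}
    rec.update(range_change(current, future))
    c_cur = current.median_center()
    c_fut = future.median_center()
    rec.update(
        lon_current=c_cur[0], lat_current=c_cur[1],
        lon_future=c_fut[0], lat_future=c_fut[1],
    )
    rec.update(shift_vector(c_cur, c_fut))
    return rec


# ---------------------------------------------------------------------------
# richness
# ---------------------------------------------------------------------------

def stack_richness(drms: list[BinaryRange], scenario: str = "") -> RasterGrid:
    """Per-cell count of species present (missing cells count as absent)."""
    if not drms:
        raise ConfigurationError("stack_richness needs at least one DRM")
    ref = drms[0].grid
    total = np.zeros((ref.n_rows, ref.n_cols), dtype=np.int32)
    for d in drms:
        ref.require_aligned(d.grid, what=f"DRM {d.species_id}")
        total += d.presence_mask().astype(np.int32)
    return ref.with_values(total, band_names=(f"richness_{scenario}" if scenario
                                              else "richness",))


def richness_change(richness_current: RasterGrid,
                    richness_future: RasterGrid) -> RasterGrid:
    """Signed per-cell future - current species count."""
    richness_current.require_aligned(richness_future, what="future richness")
    diff = (np.asarray(richness_future.values, dtype=np.int64)
            - np.asarray(richness_current.values, dtype=np.int64))
    return richness_current.with_values(diff.astype(np.int32),
                                        band_names=("richness_change",))


# ---------------------------------------------------------------------------
# elevation profile
# ---------------------------------------------------------------------------

@dataclass
class ElevationProfile:
    """Per-band species diversity under two scenarios and the turning point."""

    band_edges: tuple[float, ...]
    labels: tuple[str, ...]
    diversity: pd.DataFrame  # index: label; columns: current, future, change
    turning_point: float | None = None


def _band_presence(drm: BinaryRange, elevation: RasterGrid,
                   edges: np.ndarray) -> np.ndarray:
    """Boolean vector: does the species occupy >= 1 cell in each band."""
    mask = drm.presence_mask()
    elev = np.asarray(elevation.values, dtype=float)
    out = np.zeros(len(edges) - 1, dtype=bool)
    if mask.any():
        e = elev[mask]
        for i in range(len(edges) - 1):
            out[i] = bool(np.any((e >= edges[i]) & (e < edges[i + 1])))
    return out


def elevation_profile(
    drms_current: list[BinaryRange],
    drms_future: list[BinaryRange],
    elevation: RasterGrid,
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES,
) -> ElevationProfile:
    """Species diversity per elevation band and its turning point.

    Diversity in a band is the number of species with at least one presence
    cell whose elevation lies in the half-open band [lo, hi).  The turning
    point is the lowest band edge e such that the diversity change
    (future - current) is <= 0 for every band entirely below e and >= 0 for
    every band at or above e; None when no such edge exists or when nothing
    changes.
    """
    edges = np.asarray(band_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ConfigurationError("band edges must be strictly increasing")
    n_bands = len(edges) - 1
    labels = tuple(BAND_LABELS[:n_bands]) if n_bands <= len(BAND_LABELS) else tuple(
        f"band{i}" for i in range(n_bands)
    )
    for d in drms_current + drms_future:
        elevation.require_aligned(d.grid, what=f"DRM {d.species_id}")
    cur = np.zeros(n_bands, dtype=int)
    fut = np.zeros(n_bands, dtype=int)
    for d in drms_current:
        cur += _band_presence(d, elevation, edges)
    for d in drms_future:
        fut += _band_presence(d, elevation, edges)
    change = fut - cur

    turning: float | None = None
    if np.any(change != 0):
        for k in range(n_bands):  # candidate edge: lower edge of band k
            below_ok = np.all(change[:k] <= 0)
            above_ok = np.all(change[k:] >= 0)
            if below_ok and above_ok:
                turning = float(edges[k])
                break
    div = pd.DataFrame(
        {"current": cur, "future": fut, "change": change},
        index=pd.Index(labels, name="band"),
    )
    div.insert(0, "lower_edge_m", edges[:-1])
    div.insert(1, "upper_edge_m", edges[1:])
    return ElevationProfile(
        band_edges=tuple(edges), labels=labels, diversity=div,
        turning_point=turning,
    )


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def summarize_groups(records: pd.DataFrame, meta: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group summary tables of range changes and shifts.

    ``records`` is one row per (species, scenario) as produced by
    :func:`range_change_record`; ``meta`` carries the migratory flag.  Returns
    dict with keys:

    * ``area_change`` — per (scenario, group, direction in {reduce, expand}):
      species count and mean percentage change;
    * ``shift`` — per (scenario, group, poleward): count and mean shift km;
    * ``quadrant`` — per (scenario, group, quadrant): count and mean shift km;
    * ``zero_change`` — species with exactly zero area change (in neither
      reduce nor expand class).
    """
    missing = set(records["species_id"]) - set(meta["species_id"])
    if missing:
        raise KeyingError(f"species missing from metadata: {sorted(missing)[:5]}")
    df = records.merge(meta[["species_id", "migratory"]], on="species_id", how="left")
    df["group_mr"] = np.where(df["migratory"], "migratory", "resident")
    if "scenario" not in df.columns:
        df["scenario"] = ""

    frames = {"area": [], "shift": [], "quad": []}
    for grp_name, sub in (("all", df),
                          ("migratory", df[df["group_mr"] == "migratory"]),
                          ("resident", df[df["group_mr"] == "resident"])):
        for scen, s in sub.groupby("scenario"):
            for direction, sel in (("reduce", s[s["pct_change"] < 0]),
                                   ("expand", s[s["pct_change"] > 0])):
                frames["area"].append({
                    "scenario": scen, "group": grp_name, "direction": direction,
                    "n": int(len(sel)),
                    "mean_pct_change": float(sel["pct_change"].mean()) if len(sel) else np.nan,
                })
            for pole, sel in s.groupby("poleward"):
                frames["shift"].append({
                    "scenario": scen, "group": grp_name, "poleward": pole,
                    "n": int(len(sel)),
                    "mean_shift_km": float(sel["shift_km"].mean()),
                })
            for quad, sel in s[s["quadrant"].notna()].groupby("quadrant"):
                frames["quad"].append({
                    "scenario": scen, "group": grp_name, "quadrant": quad,
                    "n": int(len(sel)),
                    "mean_shift_km": float(sel["shift_km"].mean()),
                })
    zero = df.loc[df["pct_change"] == 0, ["species_id", "scenario"]].copy()
    return {
        "area_change": pd.DataFrame(frames["area"]),
        "shift": pd.DataFrame(frames["shift"]),
        "quadrant": pd.DataFrame(frames["quad"]),
        "zero_change": zero,
    }
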