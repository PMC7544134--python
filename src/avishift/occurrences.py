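"""Occurrence cleaning, thinning and spatial-uniformity diagnostics.

Presence-only citizen-science records are spatially clustered around
accessible, well-birded places. Two cleaning rules reduce the resulting
overfitting risk before modelling: species with fewer than a minimum number
of independent (distinct) localities are excluded outright, and localities
packed closer than a minimum separation (default one arc-minute) are
randomly thinned so no conspecific pair remains within it.

The uniformity report quantifies how clustered a point set is: the offset
between its mean centre and its geometric-median centre, and the standard
distance (root-mean-square great-circle distance from the mean centre)
together with the share of points inside that radius.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InsufficientDataError
from .raster import RasterGrid, haversine_km
from .ranges import geometric_median

REQUIRED_COLUMNS = ("species_id", "lon", "lat")


def _check_table(points: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in points.columns]
    if missing:
        raise EmptyInputError(f"occurrence table lacks columns {missing}")


def validate_and_filter(
    points: pd.DataFrame,
    study_bbox: tuple[float, float, float, float],
    min_localities: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate coordinates, deduplicate, and drop data-poor species.

    Rows with missing or out-of-range coordinates (outside [-180, 180] x
    [-90, 90] or outside ``study_bbox`` = (lon_min, lat_min, lon_max,
    lat_max)) are dropped first; exact duplicate ``(species_id, lon, lat)``
    rows are then collapsed, so the minimum-locality rule counts independent
    localities.  Species left with fewer than ``min_localities`` distinct
    points are removed entirely.

    Returns ``(cleaned, exclusion_log)``; the log has one row per
    (species_id, reason, n_rows) event.  The retained set is independent of
    input row order.
    """
    if min_localities < 1:
        raise ValueError("min_localities must be >= 1")
    _check_table(points)
    if len(points) == 0:
        raise EmptyInputError("empty occurrence table")
    lon_min, lat_min, lon_max, lat_max = study_bbox
    df = points.loc[:, list(REQUIRED_COLUMNS)].copy()
    log: list[dict] = []

    coords_ok = (
        df["lon"].notna()
        & df["lat"].notna()
        & df["lon"].between(-180, 180)
        & df["lat"].between(-90, 90)
        & df["lon"].between(lon_min, lon_max)
        & df["lat"].between(lat_min, lat_max)
    )
    bad = df.loc[~coords_ok]
    for sp, n in bad.groupby("species_id").size().items():
        log.append({"species_id": sp, "reason": "invalid_coordinates", "n_rows": int(n)})
    df = df.loc[coords_ok]

    n_before = df.groupby("species_id").size()
    df = df.drop_duplicates(subset=["species_id", "lon", "lat"])
    n_after = df.groupby("species_id").size()
    for sp in n_before.index:
        dropped = int(n_before[sp] - n_after.get(sp, 0))
        if dropped:
            log.append({"species_id": sp, "reason": "duplicate", "n_rows": dropped})

    counts = df.groupby("species_id").size()
    too_few = counts[counts < min_localities].index
    for sp in too_few:
        log.append(
            {"species_id": sp, "reason": "too_few_localities", "n_rows": int(counts[sp])}
        )
    df = df[~df["species_id"].isin(too_few)]

    df = df.sort_values(["species_id", "lon", "lat"], kind="mergesort").reset_index(drop=True)
    log_df = pd.DataFrame(log, columns=["species_id", "reason", "n_rows"])
    return df, log_df


def _thin_one(lon: np.ndarray, lat: np.ndarray, sep_deg: float,
              rng: np.random.Generator) -> np.ndarray:
    """Greedy thinning of one species; returns indices kept.

    Points are visited in seeded random order; a point is kept iff no
    already-kept point lies within ``sep_deg`` (Euclidean in degree space).
    A coarse grid index keeps the scan local.
    """
    n = len(lon)
    order = rng.permutation(n)
    kept: list[int] = []
    grid: dict[tuple[int, int], list[int]] = {}
    for i in order:
        gx = int(np.floor(lon[i] / sep_deg))
        gy = int(np.floor(lat[i] / sep_deg))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in grid.get((gx + dx, gy + dy), ()):
                    if (lon[i] - lon[j]) ** 2 + (lat[i] - lat[j]) ** 2 < sep_deg**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            kept.append(i)
            grid.setdefault((gx, gy), []).append(i)
    return np.sort(np.asarray(kept, dtype=int))


def thin_presences(
    points: pd.DataFrame, min_sep_arcmin: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Randomly thin conspecific points closer than ``min_sep_arcmin``.

    Distances are Euclidean in degree space, matching the arc-minute
    criterion; removal among conflicting points is random under ``seed`` and
    the output is a subset of the input.  Thinning an already-thinned table
    leaves it unchanged.
    """
    if min_sep_arcmin <= 0:
        raise ValueError("min_sep_arcmin must be positive")
    _check_table(points)
    sep_deg = min_sep_arcmin / 60.0
    out = []
    for sp, grp in points.groupby("species_id", sort=True):
        sp_hash = zlib.crc32(str(sp).encode()) & 0x7FFFFFFF
        rng = np.random.default_rng(np.random.SeedSequence([seed, sp_hash]))
        grp = grp.reset_index(drop=True)
        keep = _thin_one(grp["lon"].to_numpy(), grp["lat"].to_numpy(), sep_deg, rng)
        out.append(grp.iloc[keep])
    if not out:
        return points.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)


@dataclass
class UniformityReport:
    """Clustering diagnostics of a point set."""

    mean_center: tuple[float, float]
    median_center: tuple[float, float]
    center_offset_km: float
    standard_distance_km: float
    fraction_within_one_sd: float
    n_points: int

    def to_dict(self) -> dict:
        return asdict(self)


def uniformity_stats(
    points: pd.DataFrame, land_mask: RasterGrid | None = None
) -> UniformityReport:
    """Mean/median centres and standard-distance statistics of all localities.

    ``land_mask`` is accepted for interface symmetry with gridded stages but
    the statistics are point-based and do not use it.
    """
    _check_table(points)
    if len(points) < 2:
        raise InsufficientDataError("uniformity statistics need at least 2 points")
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    mean_c = (float(lon.mean()), float(lat.mean()))
    med_c = geometric_median(lon, lat)
    offset = float(haversine_km(mean_c[0], mean_c[1], med_c[0], med_c[1]))
    d = haversine_km(lon, lat, mean_c[0], mean_c[1])
    sd = float(np.sqrt(np.mean(d**2)))
    frac = float(np.mean(d <= sd)) if sd > 0 else 1.0
    return UniformityReport(
        mean_center=mean_c,
        median_center=med_c,
        center_offset_km=offset,
        standard_distance_km=sd,
        fraction_within_one_sd=frac,
        n_points=int(len(points)),
    )
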