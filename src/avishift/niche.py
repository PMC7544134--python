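"""Presence-background niche models and the two-round modelling procedure.

The model is a MaxEnt-style presence-background fit: an L2-penalized
logistic log-linear model on standardized linear + quadratic climate
features, with suitability reported through the cloglog link
``p = 1 - exp(-exp(eta))``. Linear + quadratic features capture Gaussian
climatic niches exactly and keep every fit convex; hinge/product/threshold
feature classes are deliberately not implemented.

The surrounding procedure mirrors a national-scale presence-only workflow:

1. Pearson-correlation screening of climate variables at all presence sites
   (iteratively dropping the variable with the most |r| > 0.9 pairs);
2. round 1 — fit every species on all screened variables plus elevation with
   an unrestricted background, binarize at the MTSS threshold, drop species
   whose locality density falls below one point per 3-degree block of their
   predicted range, and prune variables with no coefficient mass;
3. round 2 — refit the survivors on their per-species variable sets with the
   background restricted to the regions (province analogues) where the
   species has presences, and project to each future scenario.

Cross-validation uses five replicates (80/20 presence splits against a
shared background); the species suitability map is the mean of the replicate
predictions, and the MTSS threshold is computed from the pooled held-out
presence scores against the background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegression

from .errors import (
    DegenerateModelError,
    FitError,
    InsufficientDataError,
    NoRegionError,
    ProjectionError,
    SpeciesError,
)
from .raster import RasterGrid
from .ranges import BinaryRange, binarize, mtss_threshold


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def evaluate_auc(scores_presence, scores_background) -> float:
    """Rank-based AUC: (concordant pairs + 0.5 * ties) / (n_p * n_b).

    A presence scoring above a background point is concordant.  Computed via
    midranks, which is algebraically identical to the all-pairs count.
    """
    p = np.asarray(scores_presence, dtype=float)
    b = np.asarray(scores_background, dtype=float)
    if p.size == 0 or b.size == 0:
        raise InsufficientDataError("AUC needs non-empty score lists")
    ranks = rankdata(np.concatenate([p, b]))
    return float((ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0)
                 / (p.size * b.size))


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    """Outcome of iterative collinearity screening."""

    retained_variables: list[str]
    removal_order: list[tuple[str, int]]  # (variable, high-pair count at removal)
    correlation_matrix: pd.DataFrame


class CorrelationScreener(BaseEstimator, TransformerMixin):
    """Iteratively drop the variable with the most high-correlation pairs.

    Pearson correlations are computed between all variable pairs at the
    presence sites passed to :meth:`fit`.  While any pair exceeds
    ``threshold`` in absolute value, the variable participating in the most
    such pairs is removed; ties go to the variable with the largest mean |r|
    against all others, then lexicographically by name.  Constant variables
    (undefined correlations) are removed first with a warning.

    Attributes
    ----------
    retained_variables_ : list of str
    removal_order_ : list of (variable, high-pair count)
    correlation_matrix_ : DataFrame of the initial Pearson r at presence sites
    """

    def __init__(self, threshold: float = 0.9):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 3:
            raise InsufficientDataError(
                "correlation screening needs at least 3 presence sites"
            )
        if X.shape[1] < 2:
            raise InsufficientDataError("correlation screening needs >= 2 variables")
        X.columns = [str(c) for c in X.columns]
        removal: list[tuple[str, int]] = []
        work = X.copy()
        for col in list(work.columns):
            if work[col].nunique() <= 1:
                warnings.warn(f"constant variable {col!r} removed before screening",
                              stacklevel=2)
                removal.append((col, 0))
                work = work.drop(columns=[col])
        corr0 = work.corr(method="pearson")
        self.correlation_matrix_ = corr0
        corr = corr0.abs()
        np.fill_diagonal(corr.values, 0.0)
        while True:
            high = corr > self.threshold
            counts = high.sum(axis=0)
            if counts.max() == 0:
                break
            top = counts[counts == counts.max()].index
            if len(top) > 1:
                mean_r = corr.loc[top].mean(axis=1)
                top = mean_r[mean_r == mean_r.max()].index
            victim = sorted(top)[0]
            removal.append((victim, int(counts[victim])))
            corr = corr.drop(index=victim, columns=victim)
        self.removal_order_ = removal
        removed = {v for v, _ in removal}
        self.retained_variables_ = [c for c in X.columns if c not in removed]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.retained_variables_]

    def result_(self) -> ScreeningResult:
        return ScreeningResult(
            retained_variables=list(self.retained_variables_),
            removal_order=list(self.removal_order_),
            correlation_matrix=self.correlation_matrix_,
        )


def correlation_screen(presence_values: pd.DataFrame,
                       threshold: float = 0.9) -> ScreeningResult:
    """Functional wrapper over :class:`CorrelationScreener`."""
    return CorrelationScreener(threshold=threshold).fit(presence_values).result_()


# ---------------------------------------------------------------------------
# the niche model estimator
# ---------------------------------------------------------------------------

def _cloglog(eta: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-np.exp(eta))


class MaxentNicheModel(BaseEstimator):
    """Presence-background niche model with replicate cross-validation.

    Fit on a design of raw variable values for presences (y = 1) and
    background cells (y = 0).  Internally each variable contributes a
    standardized linear and quadratic feature to an L2-penalized logistic
    fit; ``regularization`` is the penalty strength (sklearn C = 1 /
    regularization).  Presences are split into ``k_folds`` seeded folds;
    each replicate trains on the remaining presences plus the full shared
    background and is scored (train/test AUC) on the cloglog suitability.

    Attributes (after fit)
    ----------------------
    variables_ : list of str                  fitted variable names
    mean_, scale_ : per-variable standardization constants
    coef_ : ndarray (2 * n_vars,)             full-data linear/quadratic coefs
    intercept_ : float
    replicate_coefs_, replicate_intercepts_ : per-replicate parameters
    replicate_scores_ : DataFrame (replicate, train_auc, test_auc)
    cv_presence_scores_ : held-out suitability of every presence, pooled
    cv_background_scores_ : replicate-mean suitability of the background
    """

    def __init__(self, regularization: float = 1.0, k_folds: int = 5,
                 random_state: int = 0, species_id: str = ""):
        self.regularization = regularization
        self.k_folds = k_folds
        self.random_state = random_state
        self.species_id = species_id

    # -- feature machinery --------------------------------------------------
    def _design(self, X: pd.DataFrame) -> np.ndarray:
        cols = []
        for v in self.variables_:
            z = (X[v].to_numpy(dtype=float) - self.mean_[v]) / self.scale_[v]
            cols.extend([z, z * z])
        return np.column_stack(cols)

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=int)
        n_pres = int((y == 1).sum())
        if n_pres < max(5, self.k_folds):
            raise InsufficientDataError(
                f"need at least max(5, k_folds) presences, got {n_pres}",
                species_id=self.species_id,
            )
        if (y == 0).sum() == 0:
            raise InsufficientDataError("background is empty",
                                        species_id=self.species_id)
        self.variables_ = [str(c) for c in X.columns]
        X.columns = self.variables_
        self.mean_ = {}
        self.scale_ = {}
        for v in self.variables_:
            col = X[v].to_numpy(dtype=float)
            m, s = float(col.mean()), float(col.std())
            if s == 0 or not np.isfinite(s):
                raise FitError(f"constant feature: variable {v!r}",
                               species_id=self.species_id)
            self.mean_[v], self.scale_[v] = m, s
        F = self._design(X)

        def fit_one(mask: np.ndarray):
            # default penalty is L2; C is the inverse penalty strength
            lr = LogisticRegression(
                C=1.0 / self.regularization, solver="lbfgs", max_iter=2000,
            )
            lr.fit(F[mask], y[mask])
            return lr.coef_[0].copy(), float(lr.intercept_[0])

        # full-data fit
        self.coef_, self.intercept_ = fit_one(np.ones(len(y), dtype=bool))

        # replicate cross-validation on presences, shared background
        rng = np.random.default_rng(self.random_state)
        pres_idx = np.flatnonzero(y == 1)
        bg_idx = np.flatnonzero(y == 0)
        fold_of = np.empty(n_pres, dtype=int)
        perm = rng.permutation(n_pres)
        for k in range(self.k_folds):
            fold_of[perm[k::self.k_folds]] = k
        self.replicate_coefs_ = []
        self.replicate_intercepts_ = []
        rows = []
        cv_pres = np.empty(n_pres)
        bg_scores = np.zeros(bg_idx.size)
        for k in range(self.k_folds):
            test_p = pres_idx[fold_of == k]
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_p] = False
            coef, icpt = fit_one(train_mask)
            self.replicate_coefs_.append(coef)
            self.replicate_intercepts_.append(icpt)
            s_all = _cloglog(F @ coef + icpt)
            cv_pres[fold_of == k] = s_all[test_p]
            bg_scores += s_all[bg_idx]
            train_p = pres_idx[fold_of != k]
            rows.append({
                "replicate": k,
                "train_auc": evaluate_auc(s_all[train_p], s_all[bg_idx]),
                "test_auc": evaluate_auc(s_all[test_p], s_all[bg_idx])
                if test_p.size else np.nan,
            })
        self.replicate_scores_ = pd.DataFrame(rows)
        self.cv_presence_scores_ = cv_pres
        self.cv_background_scores_ = bg_scores / self.k_folds
        return self

    # -- prediction ---------------------------------------------------------
    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self._design(pd.DataFrame(X)) @ self.coef_ + self.intercept_

    def predict_suitability(self, X: pd.DataFrame,
                            mode: str = "replicate_mean") -> np.ndarray:
        """Cloglog suitability; ``mode`` is 'full' or 'replicate_mean'."""
        F = self._design(pd.DataFrame(X))
        if mode == "full":
            return _cloglog(F @ self.coef_ + self.intercept_)
        if mode == "replicate_mean":
            out = np.zeros(F.shape[0])
            for coef, icpt in zip(self.replicate_coefs_, self.replicate_intercepts_):
                out += _cloglog(F @ coef + icpt)
            return out / len(self.replicate_coefs_)
        raise ValueError(f"unknown mode {mode!r}")

    def fitted_optimum(self, variable: str) -> float:
        """Stationary point of the fitted univariate response, raw units.

        Defined when the quadratic coefficient is negative (concave
        response); otherwise NaN.
        """
        i = self.variables_.index(variable)
        lin, quad = self.coef_[2 * i], self.coef_[2 * i + 1]
        if quad >= 0:
            return float("nan")
        z_star = -lin / (2.0 * quad)
        return float(self.mean_[variable] + self.scale_[variable] * z_star)

    def coefficient_mass(self) -> dict[str, float]:
        """|linear| + |quadratic| coefficient mass per variable (full fit)."""
        return {
            v: float(abs(self.coef_[2 * i]) + abs(self.coef_[2 * i + 1]))
            for i, v in enumerate(self.variables_)
        }

    def mean_test_auc(self) -> float:
        return float(self.replicate_scores_["test_auc"].mean())

    def to_dict(self) -> dict:
        """JSON-serializable named-coefficient form."""
        return {
            "species_id": self.species_id,
            "variables": self.variables_,
            "regularization": self.regularization,
            "standardization": {
                v: {"mean": self.mean_[v], "scale": self.scale_[v]}
                for v in self.variables_
            },
            "coefficients": {
                v: {"linear": float(self.coef_[2 * i]),
                    "quadratic": float(self.coef_[2 * i + 1])}
                for i, v in enumerate(self.variables_)
            },
            "intercept": float(self.intercept_),
            "replicate_scores": self.replicate_scores_.to_dict(orient="records"),
            "replicate_coefficients": [c.tolist() for c in self.replicate_coefs_],
            "replicate_intercepts": [float(i) for i in self.replicate_intercepts_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaxentNicheModel":
        """Rebuild a fitted model from its JSON form (for projection)."""
        m = cls(regularization=d.get("regularization", 1.0),
                k_folds=len(d["replicate_coefficients"]),
                species_id=d.get("species_id", ""))
        m.variables_ = list(d["variables"])
        m.mean_ = {v: d["standardization"][v]["mean"] for v in m.variables_}
        m.scale_ = {v: d["standardization"][v]["scale"] for v in m.variables_}
        m.coef_ = np.array(
            [x for v in m.variables_
             for x in (d["coefficients"][v]["linear"],
                       d["coefficients"][v]["quadratic"])]
        )
        m.intercept_ = float(d["intercept"])
        m.replicate_coefs_ = [np.asarray(c, dtype=float)
                              for c in d["replicate_coefficients"]]
        m.replicate_intercepts_ = [float(i) for i in d["replicate_intercepts"]]
        m.replicate_scores_ = pd.DataFrame(d.get("replicate_scores", []))
        return m


def prune_zero_contribution(model: MaxentNicheModel,
                            tolerance: float = 1e-8) -> list[str]:
    """Variables whose coefficient mass exceeds ``tolerance`` (full fit)."""
    mass = model.coefficient_mass()
    kept = [v for v in model.variables_ if mass[v] > tolerance]
    if not kept:
        raise DegenerateModelError(
            "every variable pruned: no contributing variable remains",
            species_id=model.species_id,
        )
    return kept


# ---------------------------------------------------------------------------
# geographic plumbing
# ---------------------------------------------------------------------------

def land_cell_mask(climate: RasterGrid) -> np.ndarray:
    """Cells where every band is finite."""
    vals = np.asarray(climate.values, dtype=float)
    if vals.ndim == 2:
        return np.isfinite(vals)
    return np.isfinite(vals).all(axis=0)


def extract_values(climate: RasterGrid, rows, cols) -> pd.DataFrame:
    """Variable values at the given cells, one column per band."""
    return pd.DataFrame(
        {v: climate.band(v)[rows, cols] for v in climate.band_names}
    )


def points_to_cells(points: pd.DataFrame, grid: RasterGrid
                    ) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = grid.cell_of(points["lon"].to_numpy(), points["lat"].to_numpy())
    inside = (rows >= 0) & (cols >= 0)
    return rows[inside], cols[inside]


def build_background(
    species_points: pd.DataFrame,
    regions: RasterGrid,
    land_mask: np.ndarray,
    n_background: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample background cells restricted to regions holding presences.

    Cells are drawn uniformly without replacement from the land cells of
    every region containing at least one presence of the species; when fewer
    eligible cells exist than requested, all of them are returned.
    """
    rows, cols = points_to_cells(species_points, regions)
    reg = np.asarray(regions.values)
    occupied = np.unique(reg[rows, cols]) if rows.size else np.array([])
    occupied = occupied[np.isfinite(occupied.astype(float))]
    if occupied.size == 0:
        raise NoRegionError(
            "species presences fall outside every region",
            species_id=str(species_points["species_id"].iloc[0])
            if len(species_points) else None,
        )
    eligible = land_mask & np.isin(reg, occupied)
    er, ec = np.nonzero(eligible)
    n = min(n_background, er.size)
    rng = np.random.default_rng(seed)
    pick = rng.choice(er.size, size=n, replace=False)
    return er[pick], ec[pick]


def sample_background_anywhere(land_mask: np.ndarray, n_background: int,
                               seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Unrestricted background: uniform over all land cells."""
    er, ec = np.nonzero(land_mask)
    n = min(n_background, er.size)
    rng = np.random.default_rng(seed)
    pick = rng.choice(er.size, size=n, replace=False)
    return er[pick], ec[pick]


def fit_niche_model(
    presences: pd.DataFrame,
    background_cells: tuple[np.ndarray, np.ndarray],
    climate: RasterGrid,
    variables: list[str] | None = None,
    k_folds: int = 5,
    regularization: float = 1.0,
    seed: int = 0,
) -> MaxentNicheModel:
    """Fit the presence-background model from geography.

    ``presences`` is an occurrence table for one species; ``background_cells``
    is a (rows, cols) cell sample; ``climate`` supplies the variable bands
    (all bands are used unless ``variables`` restricts them).
    """
    variables = list(variables) if variables is not None else list(climate.band_names)
    prow, pcol = points_to_cells(presences, climate)
    if prow.size == 0:
        raise InsufficientDataError("no presence falls inside the climate grid")
    brow, bcol = background_cells
    Xp = extract_values(climate, prow, pcol)[variables]
    Xb = extract_values(climate, brow, bcol)[variables]
    X = pd.concat([Xp, Xb], ignore_index=True)
    y = np.concatenate([np.ones(len(Xp), dtype=int), np.zeros(len(Xb), dtype=int)])
    sp = str(presences["species_id"].iloc[0]) if "species_id" in presences else ""
    model = MaxentNicheModel(
        regularization=regularization, k_folds=k_folds, random_state=seed,
        species_id=sp,
    )
    return model.fit(X, y)


def predict_suitability(model: MaxentNicheModel, climate: RasterGrid,
                        mode: str = "replicate_mean") -> RasterGrid:
    """Project a fitted model onto a climate grid (cloglog suitability).

    Cells with any missing variable value stay missing.  Raises
    :class:`~avishift.errors.ProjectionError` when a model variable has no
    band in ``climate``.
    """
    for v in model.variables_:
        if v not in climate.band_names:
            raise ProjectionError(f"climate grid lacks band {v!r}",
                                  species_id=model.species_id)
    shape = (climate.n_rows, climate.n_cols)
    X = pd.DataFrame({v: climate.band(v).ravel() for v in model.variables_})
    finite = np.isfinite(X.to_numpy()).all(axis=1)
    out = np.full(X.shape[0], np.nan)
    if finite.any():
        out[finite] = model.predict_suitability(X.loc[finite], mode=mode)
    return climate.with_values(out.reshape(shape), band_names=("suitability",))


# ---------------------------------------------------------------------------
# density filter
# ---------------------------------------------------------------------------

def density_filter(species_drm: BinaryRange, n_localities: int,
                   block_size: float = 3.0) -> tuple[bool, float, str]:
    """Locality-density rule on the predicted range.

    The DRM is tiled with ``block_size``-degree blocks (anchored at 0 deg);
    density = n_localities / number of blocks intersecting at least one
    presence cell.  The species is excluded iff density < 1 (strict).
    Returns ``(keep, density, reason)``.
    """
    mask = species_drm.presence_mask()
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return False, 0.0, "no predicted range"
    lon, lat = species_drm.grid.center_of(rows, cols)
    blocks = {(int(np.floor(x / block_size)), int(np.floor(y / block_size)))
              for x, y in zip(lon, lat)}
    density = n_localities / len(blocks)
    if density < 1.0:
        return False, density, f"density {density:.3g} < 1 per {block_size}-degree block"
    return True, density, ""


# ---------------------------------------------------------------------------
# two-round batch
# ---------------------------------------------------------------------------

@dataclass
class TwoRoundResult:
    """Outputs of the two-round modelling batch."""

    models: dict[str, MaxentNicheModel]
    suitability: dict[str, dict[str, RasterGrid]]  # scenario -> species -> grid
    thresholds: dict[str, float]
    screening: ScreeningResult
    round1_variables: list[str]
    species_variables: dict[str, list[str]]
    exclusion_log: pd.DataFrame
    n_localities: dict[str, int] = field(default_factory=dict)


def _stage_seed(seed: int, *parts) -> int:
    import zlib
    h = zlib.crc32("/".join(str(p) for p in parts).encode())
    return int((seed * 2654435761 + h) % (2**31))


def run_two_rounds(
    occurrences: pd.DataFrame,
    climate_current: RasterGrid,
    elevation: RasterGrid,
    regions: RasterGrid,
    future_scenarios: dict[str, RasterGrid],
    n_background: int = 2000,
    k_folds: int = 5,
    regularization: float = 1.0,
    corr_threshold: float = 0.9,
    prune_tolerance: float = 1e-8,
    density_block_deg: float = 3.0,
    seed: int = 0,
) -> TwoRoundResult:
    """Run the full two-round modelling procedure over a species batch.

    Round 1 fits every species on all correlation-screened climate variables
    plus elevation with an unrestricted background, then applies the
    locality-density filter and zero-contribution pruning.  Round 2 refits
    the survivors on their per-species variable sets with region-restricted
    background and projects to the current and each future climate.
    Per-species failures are logged and skipped, never fatal.
    """
    climate_current.require_aligned(elevation, what="elevation")
    climate_current.require_aligned(regions, what="regions")
    for name, fut in future_scenarios.items():
        climate_current.require_aligned(fut, what=f"scenario {name}")

    def _with_elev(stack: RasterGrid) -> RasterGrid:
        vals = stack.values.reshape(-1, stack.n_rows, stack.n_cols)
        elev = np.asarray(elevation.values, dtype=vals.dtype)[None]
        return stack.with_values(
            np.concatenate([vals, elev]),
            band_names=list(stack.band_names) + ["elev"],
        )

    stack_cur = _with_elev(climate_current)
    land = land_cell_mask(stack_cur)
    log: list[dict] = []

    # --- pooled correlation screening at all presence sites ---------------
    prow, pcol = points_to_cells(occurrences, climate_current)
    presence_vals = extract_values(climate_current, prow, pcol)
    screening = correlation_screen(presence_vals, threshold=corr_threshold)
    round1_vars = screening.retained_variables + ["elev"]

    species_ids = sorted(occurrences["species_id"].unique())
    survivors: dict[str, list[str]] = {}
    n_loc: dict[str, int] = {}

    for sp in species_ids:
        pts = occurrences[occurrences["species_id"] == sp]
        n_loc[sp] = len(pts)
        try:
            bg = sample_background_anywhere(
                land, n_background, _stage_seed(seed, "bg1", sp))
            m1 = fit_niche_model(
                pts, bg, stack_cur, variables=round1_vars, k_folds=k_folds,
                regularization=regularization,
                seed=_stage_seed(seed, "fit1", sp),
            )
            t1 = mtss_threshold(m1.cv_presence_scores_, m1.cv_background_scores_)
            t1 = min(max(t1, 1e-9), 1 - 1e-9)
            suit1 = predict_suitability(m1, stack_cur)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                drm1 = binarize(suit1, t1, species_id=sp, scenario="round1")
            keep, density, reason = density_filter(
                drm1, len(pts), block_size=density_block_deg)
            if not keep:
                log.append({"species_id": sp, "stage": "round1",
                            "action": "excluded", "reason": reason})
                continue
            vars2 = prune_zero_contribution(m1, tolerance=prune_tolerance)
            survivors[sp] = vars2
        except SpeciesError as e:
            log.append({"species_id": sp, "stage": "round1",
                        "action": "excluded", "reason": str(e)})

    # --- round 2 -----------------------------------------------------------
    stack_fut = {name: _with_elev(fut) for name, fut in future_scenarios.items()}
    models: dict[str, MaxentNicheModel] = {}
    thresholds: dict[str, float] = {}
    suitability: dict[str, dict[str, RasterGrid]] = {
        "current": {}, **{name: {} for name in future_scenarios}
    }
    for sp, vars2 in survivors.items():
        pts = occurrences[occurrences["species_id"] == sp]
        try:
            bg = build_background(
                pts, regions, land, n_background,
                seed=_stage_seed(seed, "bg2", sp))
            m2 = fit_niche_model(
                pts, bg, stack_cur, variables=vars2, k_folds=k_folds,
                regularization=regularization,
                seed=_stage_seed(seed, "fit2", sp),
            )
            t2 = mtss_threshold(m2.cv_presence_scores_, m2.cv_background_scores_)
            t2 = min(max(t2, 1e-9), 1 - 1e-9)
            models[sp] = m2
            thresholds[sp] = t2
            suitability["current"][sp] = predict_suitability(m2, stack_cur)
            for name in future_scenarios:
                suitability[name][sp] = predict_suitability(m2, stack_fut[name])
            log.append({"species_id": sp, "stage": "round2",
                        "action": "modelled", "reason": ""})
        except SpeciesError as e:
            log.append({"species_id": sp, "stage": "round2",
                        "action": "excluded", "reason": str(e)})
    return TwoRoundResult(
        models=models,
        suitability=suitability,
        thresholds=thresholds,
        screening=screening,
        round1_variables=round1_vars,
        species_variables={sp: models[sp].variables_ for sp in models},
        exclusion_log=pd.DataFrame(
            log, columns=["species_id", "stage", "action", "reason"]),
        n_localities=n_loc,
    )
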