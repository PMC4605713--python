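"""Comparison and vulnerability-assessment layer.

Rank correlations between velocity metrics, smoothed latitudinal
profiles, zonal distribution summaries, a three-way variance
decomposition, bivariate quantile (3x3) classes of forward vs backward
velocity, and the protected-area four-quadrant assessment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ZoneMap",
    "LatProfile",
    "rank_correlation",
    "latitudinal_profile",
    "zonal_distribution",
    "bivariate_quantile_classes",
    "protected_area_assessment",
    "variance_decomposition",
]


@dataclass
class ZoneMap:
    """Per-cell zone labels (integers or strings); every cell has one."""

    cell_id: np.ndarray
    zone: np.ndarray

    def __post_init__(self) -> None:
        if len(self.cell_id) != len(self.zone):
            raise ValueError("one zone label per cell is required")


def rank_correlation(field_a: np.ndarray, field_b: np.ndarray) -> float:
    """Spearman rank correlation over cells defined in both fields.

    Cells that are NaN (e.g. flagged no-analog) in either field are
    dropped pairwise; average ranks are used for ties.
    """
    a = np.asarray(field_a, dtype=float)
    b = np.asarray(field_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fields must be congruent")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly defined cells")
    with warnings.catch_warnings():
        # constant input has no defined rank correlation; propagate NaN
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(a[ok], b[ok]).statistic
    return float(rho)


@dataclass
class LatProfile:
    """Smoothed mean velocity as a function of latitude."""

    lat_grid: np.ndarray
    fitted: np.ndarray
    df: int
    alpha: float

    def argmax_lat(self) -> float:
        return float(self.lat_grid[int(np.argmax(self.fitted))])


def latitudinal_profile(
    field: np.ndarray,
    lat: np.ndarray,
    df: int = 25,
    alpha: float | None = None,
    n_eval: int = 200,
) -> LatProfile:
    """Penalized B-spline smooth of a per-cell field on latitude.

    Fits a Gaussian generalized additive model with a ``df``-basis cubic
    B-spline smoother.  When ``alpha`` is None the penalty weight is
    chosen by generalized cross-validation over a log-spaced grid.  NaN
    cells are dropped.  The curve is evaluated on a regular latitude grid
    spanning the observed range only.
    """
    from statsmodels.gam.api import BSplines, GLMGam

    y = np.asarray(field, dtype=float)
    x = np.asarray(lat, dtype=float)
    ok = ~np.isnan(y)
    y, x = y[ok], x[ok]
    if len(y) < 20:
        raise ValueError("need at least 20 defined cells")
    if np.ptp(x) < 2.0:
        raise ValueError("latitude range must span at least 2 degrees")

    lat_grid = np.linspace(x.min(), x.max(), n_eval)
    if np.ptp(y) < 1e-12:  # constant response: smoother is the constant
        c = float(y.mean())
        return LatProfile(lat_grid=lat_grid, fitted=np.full(n_eval, c), df=df, alpha=0.0)

    df = min(df, max(4, len(np.unique(x)) - 1))
    bs = BSplines(x[:, None], df=[df], degree=[3], include_intercept=False)
    ones = np.ones((len(y), 1))

    def _fit(a: float):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return GLMGam(y, exog=ones, smoother=bs, alpha=[a]).fit()

    if alpha is None:
        best = None
        n = len(y)
        for a in 10.0 ** np.arange(-8.0, 5.0):
            res = _fit(a)
            edf = float(res.edf.sum())
            gcv = n * float(np.sum(res.resid_response**2)) / (n - edf) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, a, res)
        _, alpha, res = best
    else:
        res = _fit(alpha)
    fitted = res.predict(exog=np.ones((n_eval, 1)), exog_smooth=lat_grid[:, None])
    return LatProfile(lat_grid=lat_grid, fitted=np.asarray(fitted), df=df, alpha=float(alpha))


def zonal_distribution(
    field: np.ndarray,
    zones: ZoneMap,
    mode: str = "by_cell",
    kde_points: int = 128,
) -> pd.DataFrame:
    """Per-zone distribution summary (mean, sd, quartiles, Gaussian KDE).

    ``by_cell`` summarizes a 1-D per-cell field within each zone.
    ``by_species`` takes a 2-D (species x cells) field, averages each
    species over the zone's cells, and summarizes across species.  KDE
    uses Silverman's bandwidth; degenerate samples get no density.
    Empty zones are omitted with a warning.
    """
    f = np.asarray(field, dtype=float)
    if mode == "by_cell" and f.ndim != 1:
        raise ValueError("by_cell mode expects a 1-D per-cell field")
    if mode == "by_species" and f.ndim != 2:
        raise ValueError("by_species mode expects a 2-D species x cells field")
    if mode not in ("by_cell", "by_species"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for z in pd.unique(zones.zone):
        in_zone = zones.zone == z
        if mode == "by_cell":
            vals = f[in_zone]
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vals = np.nanmean(f[:, in_zone], axis=1)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            warnings.warn(f"zone {z!r} has no defined values; omitted", stacklevel=2)
            continue
        kde_x = kde_y = None
        if vals.size > 2 and np.ptp(vals) > 0:
            kde = stats.gaussian_kde(vals, bw_method="silverman")
            kde_x = np.linspace(vals.min(), vals.max(), kde_points)
            kde_y = kde(kde_x)
        rows.append(
            {
                "zone": z,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "q25": float(np.quantile(vals, 0.25)),
                "median": float(np.quantile(vals, 0.5)),
                "q75": float(np.quantile(vals, 0.75)),
                "kde_x": kde_x,
                "kde_y": kde_y,
            }
        )
    return pd.DataFrame(rows)


def _tercile(values: np.ndarray, k: int) -> np.ndarray:
    """Marginal quantile class (1..k), right-closed breaks, ties low."""
    qs = np.quantile(values, np.arange(1, k) / k)  # type-7 interpolation
    return 1 + np.searchsorted(qs, values, side="left").astype(np.int64)


def bivariate_quantile_classes(
    forward: np.ndarray,
    backward: np.ndarray,
    k: int = 3,
    log_transform: bool = True,
    log_offset: float = 1e-6,
) -> np.ndarray:
    """k x k joint quantile classes of forward vs backward velocity.

    Each axis is cut at its empirical 1/k ... (k-1)/k quantiles (computed
    on log-transformed values; class membership is invariant to the
    monotone log).  The class index is ``k * (row - 1) + column`` with
    row = forward class and column = backward class, i.e. 1..k**2.
    """
    f = np.asarray(forward, dtype=float)
    b = np.asarray(backward, dtype=float)
    if f.shape != b.shape:
        raise ValueError("fields must be congruent")
    ok = ~(np.isnan(f) | np.isnan(b))
    if ok.sum() < k:
        raise ValueError(f"need at least {k} jointly defined units")
    if log_transform:
        f = np.where(ok, np.log(np.maximum(f, 0.0) + log_offset), np.nan)
        b = np.where(ok, np.log(np.maximum(b, 0.0) + log_offset), np.nan)
    classes = np.full(f.shape, -1, dtype=np.int64)
    rf = _tercile(f[ok], k)
    rb = _tercile(b[ok], k)
    classes[ok] = k * (rf - 1) + rb
    return classes


def protected_area_assessment(
    metrics: dict[str, np.ndarray],
    pa_masks: list[np.ndarray],
    pa_areas: list[float] | np.ndarray,
    min_area_km2: float = 200.0,
    quadrant_pairs: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Mean velocity per protected area plus four-quadrant classes.

    PAs with area <= ``min_area_km2`` are excluded.  For every metric
    pair in ``quadrant_pairs`` (default: forward vs backward within each
    of the climatic and biotic metric families present), each retained PA
    is classed ``low``/``high`` on each axis against the median across
    retained PAs; a value at the median counts as low.
    """
    n_cells = len(next(iter(metrics.values())))
    for name, v in metrics.items():
        if len(v) != n_cells:
            raise ValueError(f"metric {name!r} is not on the analysis grid")
    rows = []
    for i, (mask, area) in enumerate(zip(pa_masks, pa_areas)):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n_cells,):
            raise ValueError(f"protected-area mask {i} is off-grid")
        if area <= min_area_km2:
            continue
        row = {"pa_id": i, "area_km2": float(area), "n_cells": int(mask.sum())}
        for name, v in metrics.items():
            vals = np.asarray(v, dtype=float)[mask]
            vals = vals[~np.isnan(vals)]
            row[name] = float(vals.mean()) if vals.size else np.nan
        rows.append(row)
    records = pd.DataFrame(rows)
    if records.empty:
        return records

    if quadrant_pairs is None:
        quadrant_pairs = {}
        for family in ("climatic", "biotic"):
            fa, ba = f"forward_{family}", f"backward_{family}"
            if fa in metrics and ba in metrics:
                quadrant_pairs[family] = (fa, ba)
    for pair_name, (xa, ya) in quadrant_pairs.items():
        mx = records[xa].median()
        my = records[ya].median()
        hx = records[xa] > mx
        hy = records[ya] > my
        records[f"quadrant_{pair_name}"] = [
            f"{'high' if a else 'low'}-{xa.split('_')[0]}/"
            f"{'high' if b else 'low'}-{ya.split('_')[0]}"
            for a, b in zip(hx, hy)
        ]
    return records


def variance_decomposition(velocity: np.ndarray) -> dict[str, float]:
    """Three variation scalars from a (species x GCM x cell) velocity stack.

    * ``mean_sd_across_species``: per-cell sample sd across species of
      their GCM-mean velocities, averaged over cells.
    * ``mean_sd_across_gcms``: per-cell sample sd across GCMs of the
      across-species mean, averaged over cells.
    * ``spatial_sd_of_means``: sample sd over cells of the per-cell
      across-species, across-GCM mean.

    NaN entries (cells outside a species' source range) are ignored; all
    sds use the n-1 estimator.
    """
    V = np.asarray(velocity, dtype=float)
    if V.ndim != 3:
        raise ValueError("expected a (n_species, n_gcms, n_cells) array")
    n_species = V.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sp_gcm_mean = np.nanmean(V, axis=1)  # (species, cells)
        n_sp = np.sum(~np.isnan(sp_gcm_mean), axis=0)
        if n_species < 2:
            sd_species = np.nan
        else:
            per_cell_sd = np.where(
                n_sp > 1, np.nanstd(sp_gcm_mean, axis=0, ddof=1), np.nan
            )
            sd_species = float(np.nanmean(per_cell_sd))
        gcm_mean = np.nanmean(V, axis=0)  # (gcms, cells)
        n_g = np.sum(~np.isnan(gcm_mean), axis=0)
        per_cell_sd_g = np.where(n_g > 1, np.nanstd(gcm_mean, axis=0, ddof=1), np.nan)
        sd_gcms = float(np.nanmean(per_cell_sd_g)) if np.any(n_g > 1) else np.nan
        cell_mean = np.nanmean(sp_gcm_mean, axis=0)
        defined = cell_mean[~np.isnan(cell_mean)]
        spatial = float(np.std(defined, ddof=1)) if defined.size > 1 else np.nan
    return {
        "mean_sd_across_species": sd_species,
        "mean_sd_across_gcms": sd_gcms,
        "spatial_sd_of_means": spatial,
    }
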