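"""Climate-space ordination and multivariate binning.

Climate analogs are defined in a reduced ordination space: bioclimatic
variables are standardized, projected onto principal components, and the
retained axes are cut into equal-width hyper-rectangular bins.  Two cells
are "the same climate type" when they fall in the same bin on every
retained axis.  The bin origin can be shifted by a fraction of the bin
width so that boundary artifacts can be averaged out over replicates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClimateGrid",
    "OrdinationModel",
    "ScoreMatrix",
    "BinAssignment",
    "fit_ordination",
    "project",
    "assign_bins",
]


@dataclass
class ClimateGrid:
    """Per-cell bioclimatic values for one period and one GCM.

    ``values`` is an ``(n_cells, n_vars)`` array in the original (mixed)
    units of the variables; ``var_names`` gives the column order shared by
    every grid in an analysis.  ``x_index``/``y_index`` are raster indices
    (column, row from the northwest corner) used for planar distances and
    raster export.
    """

    cell_id: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray
    var_names: list[str]
    period: str = "current"
    gcm_id: str = "obs"
    cell_size_km: float = 50.0
    x_index: np.ndarray | None = None
    y_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_id = np.asarray(self.cell_id)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (cells x variables) array")
        if self.values.shape[1] != len(self.var_names):
            raise ValueError("values column count does not match var_names")
        if len(np.unique(self.cell_id)) != len(self.cell_id):
            raise ValueError("cell_id values must be unique")
        if np.isnan(self.values).any():
            raise ValueError("missing values among included cells are not allowed")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def xy_km(self) -> np.ndarray | None:
        """Planar coordinates (km) from raster indices, if indices exist."""
        if self.x_index is None or self.y_index is None:
            return None
        return np.column_stack(
            (np.asarray(self.x_index) * self.cell_size_km,
             np.asarray(self.y_index) * self.cell_size_km)
        ).astype(float)


@dataclass
class OrdinationModel:
    """Fitted standardization + principal-components transform.

    ``loadings`` has one orthonormal column per component, in the order of
    decreasing ``variance_fraction``.  ``retained`` lists the component
    indices (0-based) kept by the minimum-variance-fraction rule.
    """

    var_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    retained: list[int]
    fit_basis: str = "pooled"
    min_fraction: float = 0.02
    dropped_vars: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_json(self, path) -> None:
        payload = {
            "var_names": list(self.var_names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "retained": list(self.retained),
            "fit_basis": self.fit_basis,
            "min_fraction": self.min_fraction,
            "dropped_vars": list(self.dropped_vars),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "OrdinationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            var_names=d["var_names"],
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            variance_fraction=np.asarray(d["variance_fraction"], dtype=float),
            retained=[int(i) for i in d["retained"]],
            fit_basis=d["fit_basis"],
            min_fraction=float(d["min_fraction"]),
            dropped_vars=d.get("dropped_vars", []),
        )


@dataclass
class ScoreMatrix:
    """Per-cell scores on the retained ordination axes, with coordinates."""

    cell_id: np.ndarray
    scores: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    cell_size_km: float = 50.0
    xy_km: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


@dataclass
class BinAssignment:
    """Integer bin codes per retained axis for every cell.

    ``codes[i, k] = floor((scores[i, k] - offset_fraction * w) / w)`` with
    ``w = bin_width``.  Cells share a bin iff all per-axis codes are equal.
    """

    cell_id: np.ndarray
    codes: np.ndarray
    bin_width: float
    offset_fraction: float


def _resolve_fit_values(grids: list[ClimateGrid], fit_basis: str) -> np.ndarray:
    if fit_basis == "pooled":
        chosen = grids
    elif fit_basis == "current_only":
        chosen = [g for g in grids if g.period == "current"]
        if not chosen:
            raise ValueError("fit_basis='current_only' but no grid has period='current'")
    else:
        raise ValueError(f"unknown fit_basis {fit_basis!r}")
    return np.vstack([g.values for g in chosen])


def fit_ordination(
    grids: ClimateGrid | list[ClimateGrid],
    min_fraction: float = 0.02,
    fit_basis: str = "pooled",
    standardize: bool = True,
) -> OrdinationModel:
    """Fit the standardization and PCA transform on one or more grids.

    Variables are centered and (by default) scaled to unit standard
    deviation on the fit basis, so that Euclidean distance on the scores
    approximates a Mahalanobis distance on the raw variables.  Components
    with a variance fraction above ``min_fraction`` are retained.
    Constant variables are dropped with a warning rather than erroring.
    """
    if isinstance(grids, ClimateGrid):
        grids = [grids]
    if not grids:
        raise ValueError("at least one grid is required")
    var_names = grids[0].var_names
    for g in grids[1:]:
        if g.var_names != var_names:
            raise ValueError("all grids must share the same variable list and order")
    X = _resolve_fit_values(grids, fit_basis)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    if n < 3:
        raise ValueError("need at least 3 cells to fit an ordination")

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [v for v, k in zip(var_names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant variables: {dropped}", stacklevel=2)
    if not keep.any():
        raise ValueError("all variables are constant; ordination is undefined")
    Xk = X[:, keep]
    kept_names = [v for v, k in zip(var_names, keep) if k]
    center = Xk.mean(axis=0)
    scale = sd[keep] if standardize else np.ones(keep.sum())
    Z = (Xk - center) / scale
    if n < Z.shape[1]:
        warnings.warn(
            f"fewer cells ({n}) than variables ({Z.shape[1]}): rank-deficient PCA",
            stacklevel=2,
        )

    # SVD of the standardized matrix; components ordered by singular value.
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt.T
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)

    # Sign convention: largest-magnitude loading positive in each column.
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0

    retained = [int(i) for i in np.nonzero(frac > min_fraction)[0]]
    if not retained:
        warnings.warn(
            "no component exceeds min_fraction; retaining the first axis",
            stacklevel=2,
        )
        retained = [0]
    return OrdinationModel(
        var_names=kept_names,
        center=center,
        scale=scale,
        loadings=loadings,
        variance_fraction=frac,
        retained=retained,
        fit_basis=fit_basis,
        min_fraction=min_fraction,
        dropped_vars=dropped,
    )


def project(grid: ClimateGrid, model: OrdinationModel) -> ScoreMatrix:
    """Project a grid onto the model's retained axes.

    The transform is linear: standardized values times the retained
    loading columns.  Grids whose variable list does not contain the
    model's (kept) variables are rejected.
    """
    try:
        cols = [grid.var_names.index(v) for v in model.var_names]
    except ValueError as exc:
        raise ValueError(
            f"grid is missing a variable required by the ordination: {exc}"
        ) from None
    Z = (grid.values[:, cols] - model.center) / model.scale
    scores = Z @ model.loadings[:, model.retained]
    return ScoreMatrix(
        cell_id=grid.cell_id,
        scores=scores,
        lon=np.asarray(grid.lon, dtype=float),
        lat=np.asarray(grid.lat, dtype=float),
        cell_size_km=grid.cell_size_km,
        xy_km=grid.xy_km(),
    )


def assign_bins(
    scores: ScoreMatrix | np.ndarray,
    bin_width: float = 2.0,
    offset_fraction: float = 0.0,
    cell_id: np.ndarray | None = None,
) -> BinAssignment:
    """Cut the score space into equal-width bins with a movable origin."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not 0.0 <= offset_fraction < 1.0:
        raise ValueError("offset_fraction must lie in [0, 1)")
    if isinstance(scores, ScoreMatrix):
        s = scores.scores
        ids = scores.cell_id
    else:
        s = np.atleast_2d(np.asarray(scores, dtype=float))
        ids = np.arange(s.shape[0]) if cell_id is None else np.asarray(cell_id)
    codes = np.floor((s - offset_fraction * bin_width) / bin_width).astype(np.int64)
    return BinAssignment(
        cell_id=ids, codes=codes, bin_width=bin_width, offset_fraction=offset_fraction
    )
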