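import numpy as np
import pytest

from climvelocity import ClimateGrid, ScoreMatrix, SuitabilityStack


def line_scores(n_cells, score_fn, cell_size_km=50.0, lat0=45.0, cell_id=None):
    """1-row ScoreMatrix along a west-east transect with planar coords."""
    x = np.arange(n_cells)
    xy = np.column_stack((x * cell_size_km, np.zeros(n_cells)))
    scores = np.atleast_2d(np.asarray(score_fn(x * cell_size_km), dtype=float))
    if scores.shape[0] == 1 and n_cells > 1:
        scores = scores.T
    return ScoreMatrix(
        cell_id=np.arange(n_cells) if cell_id is None else cell_id,
        scores=scores,
        lon=-120.0 + 0.45 * x,
        lat=np.full(n_cells, lat0),
        cell_size_km=cell_size_km,
        xy_km=xy,
    )


def grid_scores(nx, ny, score_fn, cell_size_km=50.0):
    """ScoreMatrix on a full nx x ny grid; score_fn(x_km, y_km, lat) -> (n, k)."""
    deg = cell_size_km / 111.19492664455873
    xi, yi = np.meshgrid(np.arange(nx), np.arange(ny))
    xi, yi = xi.ravel(), yi.ravel()
    lon = -100.0 + xi * deg
    lat = 50.0 - yi * deg
    scores = np.asarray(score_fn(xi * cell_size_km, yi * cell_size_km, lat), dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    return ScoreMatrix(
        cell_id=np.arange(nx * ny),
        scores=scores,
        lon=lon,
        lat=lat,
        cell_size_km=cell_size_km,
        xy_km=np.column_stack((xi * cell_size_km, yi * cell_size_km)),
    )


def stack_from_masks(masks, taxa=None, period="current", gcm_id="obs",
                     nx=None, cell_size_km=50.0):
    """SuitabilityStack on a 1-row transect (or given planar layout)."""
    masks = np.atleast_2d(np.asarray(masks, dtype=bool))
    n_sp, n_cells = masks.shape
    x = np.arange(n_cells)
    return SuitabilityStack(
        species_ids=[f"sp{i}" for i in range(n_sp)],
        taxa=list(taxa) if taxa is not None else ["bird"] * n_sp,
        period=period,
        gcm_id=gcm_id,
        mask=masks,
        cell_id=np.arange(n_cells),
        lon=-120.0 + 0.45 * x,
        lat=np.full(n_cells, 45.0),
        cell_size_km=cell_size_km,
        xy_km=np.column_stack((x * cell_size_km, np.zeros(n_cells))),
    )


@pytest.fixture
def toy_grid():
    """4-cell, 2-variable grid with a hand-checkable covariance."""
    values = np.array([[1.0, 2.0], [3.0, 6.0], [5.0, 7.0], [7.0, 13.0]])
    return ClimateGrid(
        cell_id=np.arange(4),
        lon=np.array([-100.0, -99.0, -98.0, -97.0]),
        lat=np.array([40.0, 40.0, 40.0, 40.0]),
        values=values,
        var_names=["a", "b"],
    )
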