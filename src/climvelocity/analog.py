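"""Forward and backward analog-based climatic velocity.

For every source cell the nearest target-period cell falling in the same
multivariate climate bin is found, and the great-circle distance to it,
divided by the number of years between the two period midpoints, is the
analog-based velocity.  "Forward" treats current cells as sources and
future cells as targets (exposure of resident organisms); "backward"
reverses the roles (difficulty of colonizing a site's future climate).
Cells whose bin has no occupant in the other period are no-analog —
disappearing climates in the forward direction, novel climates in the
backward direction — and are tabulated separately, never assigned a
sentinel velocity.  Bin boundaries are offset over replicate runs and the
per-cell distances averaged, which removes artifacts of the arbitrary
bin origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate_space import BinAssignment, ScoreMatrix, assign_bins

__all__ = [
    "EARTH_RADIUS_KM",
    "AnalogMatches",
    "VelocityField",
    "EnsembleField",
    "great_circle_distance",
    "nearest_analog",
    "climatic_velocity",
    "ensemble_average",
    "bin_width_sensitivity",
]

EARTH_RADIUS_KM = 6371.0


def great_circle_distance(a, b) -> np.ndarray | float:
    """Haversine distance in km between lon/lat points (degrees).

    ``a`` and ``b`` are (..., 2) arrays of (lon, lat) or single pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for p in (a, b):
        lon, lat = p[..., 0], p[..., 1]
        if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
            raise ValueError("coordinates outside [-180,180] x [-90,90]")
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    h = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return d if d.ndim else float(d)


def _embed_points(sm: ScoreMatrix, mode: str) -> np.ndarray:
    """Coordinates in a Euclidean embedding where nearest = nearest on the surface.

    Sphere mode embeds lon/lat on a sphere of radius R; chord distance is
    monotone in great-circle distance, so chord-nearest is arc-nearest.
    """
    if mode == "sphere":
        lon = np.radians(np.asarray(sm.lon, dtype=float))
        lat = np.radians(np.asarray(sm.lat, dtype=float))
        return EARTH_RADIUS_KM * np.column_stack(
            (np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat))
        )
    if mode == "planar":
        if sm.xy_km is None:
            raise ValueError("planar distance mode requires xy_km coordinates")
        return np.asarray(sm.xy_km, dtype=float)
    raise ValueError(f"unknown distance mode {mode!r}")


def _embedded_to_surface_km(d_embed: np.ndarray, mode: str) -> np.ndarray:
    if mode == "sphere":
        # chord -> arc length
        x = np.clip(d_embed / (2.0 * EARTH_RADIUS_KM), 0.0, 1.0)
        return 2.0 * EARTH_RADIUS_KM * np.arcsin(x)
    return d_embed


@dataclass
class AnalogMatches:
    """Vectorized nearest-analog result, one row per source cell."""

    source_cell: np.ndarray
    target_cell: np.ndarray  # -1 where no analog
    distance: np.ndarray  # km; NaN where no analog
    has_analog: np.ndarray


# Source-block size for the within-bin brute-force distance computation;
# bounds memory at ~ block * n_targets floats.
_BLOCK_ELEMS = 4_000_000


def _match_bins(
    src_codes: np.ndarray,
    tgt_codes: np.ndarray,
    src_pts: np.ndarray,
    tgt_pts: np.ndarray,
    tgt_order: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact within-bin nearest neighbour.

    Returns (target row index or -1, squared embedded distance or NaN) per
    source row.  ``tgt_order`` sorts targets by ascending cell_id so that
    ``argmin`` resolves exact distance ties to the lowest target cell_id.
    """
    n_src = src_codes.shape[0]
    out_idx = np.full(n_src, -1, dtype=np.int64)
    out_d2 = np.full(n_src, np.nan)

    tgt_codes_o = tgt_codes[tgt_order]
    tgt_pts_o = tgt_pts[tgt_order]

    # Group targets by bin via lexicographic sort of code rows.
    t_sort = np.lexsort(tgt_codes_o.T[::-1])
    tc = tgt_codes_o[t_sort]
    boundaries = np.nonzero(np.any(np.diff(tc, axis=0) != 0, axis=1))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [tc.shape[0]]))
    bin_index: dict[tuple, np.ndarray] = {
        tuple(tc[s]): t_sort[s:e] for s, e in zip(starts, ends)
    }

    # Group sources by bin the same way.
    s_sort = np.lexsort(src_codes.T[::-1])
    sc = src_codes[s_sort]
    sb = np.nonzero(np.any(np.diff(sc, axis=0) != 0, axis=1))[0] + 1
    s_starts = np.concatenate(([0], sb))
    s_ends = np.concatenate((sb, [sc.shape[0]]))

    for s, e in zip(s_starts, s_ends):
        key = tuple(sc[s])
        rows = s_sort[s:e]
        t_rows = bin_index.get(key)
        if t_rows is None:
            continue
        tp = tgt_pts_o[t_rows]
        block = max(1, _BLOCK_ELEMS // max(1, len(t_rows)))
        for b0 in range(0, len(rows), block):
            chunk = rows[b0 : b0 + block]
            sp = src_pts[chunk]
            d2 = ((sp[:, None, :] - tp[None, :, :]) ** 2).sum(axis=2)
            j = np.argmin(d2, axis=1)  # first minimum -> lowest cell_id tie-break
            out_idx[chunk] = t_rows[j]
            out_d2[chunk] = d2[np.arange(len(chunk)), j]
    # Map ordered-target rows back to original target rows.
    mask = out_idx >= 0
    out_idx[mask] = tgt_order[out_idx[mask]]
    return out_idx, out_d2


def nearest_analog(
    sources: BinAssignment,
    targets: BinAssignment,
    source_coords: ScoreMatrix,
    target_coords: ScoreMatrix,
    mode: str = "sphere",
) -> AnalogMatches:
    """Exact nearest same-bin target for every source cell.

    Distance ties are broken by the lowest target cell_id; sources whose
    bin is unoccupied among targets get ``has_analog = False``.
    """
    if sources.bin_width != targets.bin_width or (
        sources.offset_fraction != targets.offset_fraction
    ):
        raise ValueError("sources and targets must use identical bin parameters")
    if sources.codes.shape[1] != targets.codes.shape[1]:
        raise ValueError("sources and targets binned on different numbers of axes")
    src_pts = _embed_points(source_coords, mode)
    tgt_pts = _embed_points(target_coords, mode)
    tgt_order = np.argsort(targets.cell_id, kind="stable")
    idx, d2 = _match_bins(sources.codes, targets.codes, src_pts, tgt_pts, tgt_order)
    has = idx >= 0
    dist = np.full(len(idx), np.nan)
    dist[has] = _embedded_to_surface_km(np.sqrt(d2[has]), mode)
    target_cell = np.full(len(idx), -1, dtype=np.int64)
    target_cell[has] = np.asarray(targets.cell_id)[idx[has]]
    return AnalogMatches(
        source_cell=np.asarray(sources.cell_id),
        target_cell=target_cell,
        distance=dist,
        has_analog=has,
    )


@dataclass
class VelocityField:
    """Offset-averaged analog velocity for one direction and one GCM.

    ``velocity`` and ``mean_distance`` are NaN where no replicate found an
    analog; ``no_analog_prob`` is the fraction of replicates without one.
    """

    cell_id: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    mean_distance: np.ndarray
    velocity: np.ndarray
    no_analog_prob: np.ndarray
    direction: str
    n_replicates: int
    years_between: float
    gcm_id: str = ""


def _one_direction(
    src: ScoreMatrix,
    tgt: ScoreMatrix,
    bin_width: float,
    n_offsets: int,
    years_between: float,
    direction: str,
    mode: str,
    gcm_id: str,
) -> VelocityField:
    sum_d = np.zeros(src.n_cells)
    n_ok = np.zeros(src.n_cells, dtype=np.int64)
    for j in range(n_offsets):
        off = j / n_offsets
        sb = assign_bins(src, bin_width, off)
        tb = assign_bins(tgt, bin_width, off)
        m = nearest_analog(sb, tb, src, tgt, mode=mode)
        sum_d[m.has_analog] += m.distance[m.has_analog]
        n_ok += m.has_analog
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d = np.where(n_ok > 0, sum_d / np.maximum(n_ok, 1), np.nan)
    return VelocityField(
        cell_id=np.asarray(src.cell_id),
        lon=np.asarray(src.lon, dtype=float),
        lat=np.asarray(src.lat, dtype=float),
        mean_distance=mean_d,
        velocity=mean_d / years_between,
        no_analog_prob=1.0 - n_ok / n_offsets,
        direction=direction,
        n_replicates=n_offsets,
        years_between=years_between,
        gcm_id=gcm_id,
    )


def climatic_velocity(
    current: ScoreMatrix,
    future: ScoreMatrix,
    bin_width: float = 2.0,
    n_offsets: int = 100,
    years_between: float = 110.0,
    mode: str = "sphere",
    gcm_id: str = "",
    directions: tuple[str, ...] = ("forward", "backward"),
) -> dict[str, VelocityField]:
    """Offset-averaged forward and/or backward climatic velocity.

    Replicate ``j`` uses offset fraction ``j / n_offsets``, applied to all
    axes simultaneously; per-cell distances are averaged over replicates
    with an analog and divided by ``years_between``.
    """
    if current.n_axes != future.n_axes:
        raise ValueError("current and future scores are on different axes")
    if n_offsets < 1:
        raise ValueError("n_offsets must be >= 1")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    out: dict[str, VelocityField] = {}
    for d in directions:
        if d == "forward":
            out[d] = _one_direction(
                current, future, bin_width, n_offsets, years_between, d, mode, gcm_id
            )
        elif d == "backward":
            out[d] = _one_direction(
                future, current, bin_width, n_offsets, years_between, d, mode, gcm_id
            )
        else:
            raise ValueError(f"unknown direction {d!r}")
    return out


@dataclass
class EnsembleField:
    """Across-GCM mean velocity, its sd, and combined no-analog probability."""

    cell_id: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    velocity: np.ndarray
    sd_across_gcms: np.ndarray
    no_analog_prob: np.ndarray
    direction: str
    n_members: int


def ensemble_average(fields: list[VelocityField]) -> EnsembleField:
    """Per-cell mean over GCM members whose velocity is defined.

    sd is the sample standard deviation (ddof=1) over defined members; the
    combined no-analog probability is the mean of member probabilities.
    """
    if not fields:
        raise ValueError("at least one member field is required")
    d0 = fields[0].direction
    for f in fields[1:]:
        if f.direction != d0:
            raise ValueError("all members must share the same direction")
        if f.velocity.shape != fields[0].velocity.shape or not np.array_equal(
            f.cell_id, fields[0].cell_id
        ):
            raise ValueError("member fields are not congruent")
    V = np.vstack([f.velocity for f in fields])
    P = np.vstack([f.no_analog_prob for f in fields])
    n_def = np.sum(~np.isnan(V), axis=0)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.where(n_def > 0, np.nanmean(V, axis=0), np.nan)
        sd = np.full(V.shape[1], np.nan)
        ok2 = n_def > 1
        if ok2.any():
            sd[ok2] = np.nanstd(V[:, ok2], axis=0, ddof=1)
        sd[n_def == 1] = 0.0
    return EnsembleField(
        cell_id=fields[0].cell_id,
        lon=fields[0].lon,
        lat=fields[0].lat,
        velocity=mean,
        sd_across_gcms=sd,
        no_analog_prob=P.mean(axis=0),
        direction=d0,
        n_members=len(fields),
    )


def bin_width_sensitivity(
    current: ScoreMatrix,
    future: ScoreMatrix,
    widths,
    mode: str = "sphere",
):
    """Median forward match distance and no-analog proportion per bin width.

    One forward replicate at offset 0 per width; used to choose a width
    balancing loss of information (broad bins, many zero velocities)
    against domination by no-analog climates (narrow bins).
    """
    import pandas as pd

    rows = []
    for w in widths:
        if w <= 0:
            raise ValueError("bin widths must be positive")
        sb = assign_bins(current, float(w), 0.0)
        tb = assign_bins(future, float(w), 0.0)
        m = nearest_analog(sb, tb, current, future, mode=mode)
        n = len(m.has_analog)
        n_no = int(np.sum(~m.has_analog))
        med = float(np.median(m.distance[m.has_analog])) if n_no < n else np.nan
        rows.append(
            {
                "bin_width": float(w),
                "median_match_distance_km": med,
                "no_analog_proportion": n_no / n,
            }
        )
    return pd.DataFrame(rows)
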