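"""Analog-based biotic velocity from binary suitability grids.

Where climatic velocity asks "how far to the nearest cell with the same
climate type", biotic velocity asks, per species, "how far to the nearest
cell that the niche model projects as suitable".  Forward velocity is
defined on the species' current range (distance to the nearest
future-suitable cell), backward velocity on its projected future range
(distance to the nearest currently suitable cell).  A cell suitable in
both periods has velocity exactly zero.  Species whose projected future
suitable set is empty ("disappearing species") carry no finite distance
and are tabulated separately through the disappearance probability, never
given a sentinel velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SuitabilityStack",
    "SpeciesVelocityField",
    "TaxonSummary",
    "species_velocity",
    "disappearance_probability",
    "site_loss_probability",
    "aggregate_taxa",
]


@dataclass
class SuitabilityStack:
    """Binary suitability for many species on one grid, period and GCM.

    ``mask`` is ``(n_species, n_cells)`` boolean.  The current-period
    stack is independent of GCM; future stacks differ per GCM.
    """

    species_ids: list[str]
    taxa: list[str]
    period: str
    gcm_id: str
    mask: np.ndarray
    cell_id: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    cell_size_km: float = 50.0
    xy_km: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.species_ids), len(self.cell_id)):
            raise ValueError("mask shape must be (n_species, n_cells)")
        if len(self.taxa) != len(self.species_ids):
            raise ValueError("one taxon label per species is required")

    @property
    def n_species(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cells(self) -> int:
        return self.mask.shape[1]

    def range_size(self) -> np.ndarray:
        """Cells in each species' suitable set."""
        return self.mask.sum(axis=1)


@dataclass
class SpeciesVelocityField:
    """Per-cell analog distance and velocity for one species, direction, GCM.

    ``cell_index`` indexes the source-range cells into the master grid;
    ``distance``/``velocity`` align with it.  When ``range_disappears`` is
    True the target set was empty and no velocities exist.
    """

    species_id: str
    taxon: str
    gcm_id: str
    direction: str
    years_between: float
    cell_index: np.ndarray
    cell_id: np.ndarray
    distance: np.ndarray
    velocity: np.ndarray
    range_disappears: bool


def _stack_points(stack: SuitabilityStack, mode: str) -> np.ndarray:
    from .analog import EARTH_RADIUS_KM

    if mode == "planar":
        if stack.xy_km is None:
            raise ValueError("planar mode requires xy_km coordinates")
        return np.asarray(stack.xy_km, dtype=float)
    if mode == "sphere":
        lon = np.radians(stack.lon)
        lat = np.radians(stack.lat)
        return EARTH_RADIUS_KM * np.column_stack(
            (np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat))
        )
    raise ValueError(f"unknown distance mode {mode!r}")


def _chord_to_km(d: np.ndarray, mode: str) -> np.ndarray:
    from .analog import EARTH_RADIUS_KM

    if mode == "sphere":
        return 2.0 * EARTH_RADIUS_KM * np.arcsin(
            np.clip(d / (2.0 * EARTH_RADIUS_KM), 0.0, 1.0)
        )
    return d


def _check_congruent(a: SuitabilityStack, b: SuitabilityStack) -> None:
    if a.species_ids != b.species_ids:
        raise ValueError("stacks cover different species")
    if not np.array_equal(a.cell_id, b.cell_id):
        raise ValueError("stacks are on different grids")


def species_velocity(
    stack_current: SuitabilityStack,
    stack_future: SuitabilityStack,
    years_between: float = 110.0,
    direction: str = "forward",
    mode: str = "sphere",
) -> list[SpeciesVelocityField]:
    """Per-species analog velocity between two suitability stacks.

    Forward: every current-range cell gets the distance to the nearest
    future-suitable cell (zero if itself future-suitable).  Backward
    swaps the roles.  One field per species, in stack order.
    """
    _check_congruent(stack_current, stack_future)
    if direction == "forward":
        src_stack, tgt_stack = stack_current, stack_future
    elif direction == "backward":
        src_stack, tgt_stack = stack_future, stack_current
    else:
        raise ValueError(f"direction must be forward or backward, got {direction!r}")
    pts = _stack_points(stack_current, mode)
    gcm_id = stack_future.gcm_id
    fields: list[SpeciesVelocityField] = []
    for s in range(stack_current.n_species):
        src = np.nonzero(src_stack.mask[s])[0]
        tgt = np.nonzero(tgt_stack.mask[s])[0]
        disappears = tgt.size == 0
        if disappears or src.size == 0:
            dist = np.full(src.size, np.nan)
        else:
            tree = cKDTree(pts[tgt])
            d, _ = tree.query(pts[src], k=1)
            dist = _chord_to_km(np.asarray(d, dtype=float), mode)
        fields.append(
            SpeciesVelocityField(
                species_id=stack_current.species_ids[s],
                taxon=stack_current.taxa[s],
                gcm_id=gcm_id,
                direction=direction,
                years_between=years_between,
                cell_index=src,
                cell_id=np.asarray(stack_current.cell_id)[src],
                distance=dist,
                velocity=dist / years_between,
                range_disappears=bool(disappears),
            )
        )
    return fields


def disappearance_probability(
    stack_current: SuitabilityStack,
    future_stacks: list[SuitabilityStack],
    species_subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell probability that a resident species disappears range-wide.

    For each cell, over all (species currently suitable there) x (GCM)
    combinations, the fraction for which the species' future suitable set
    is empty anywhere on the grid.  A probability rather than a count is
    used so the metric does not track current species-richness gradients.
    Cells with no current species are NaN.
    """
    if not future_stacks:
        raise ValueError("at least one future stack is required")
    for f in future_stacks:
        _check_congruent(stack_current, f)
    sel = (
        np.arange(stack_current.n_species)
        if species_subset is None
        else np.asarray(species_subset)
    )
    cur = stack_current.mask[sel]
    # disappear[s, g]: species s has an empty future range under GCM g
    disappear = np.column_stack(
        [~f.mask[sel].any(axis=1) for f in future_stacks]
    )
    n_gcm = len(future_stacks)
    n_present = cur.sum(axis=0)  # species per cell
    n_disappear = disappear.sum(axis=1) @ cur  # sum over present species
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(n_present > 0, n_disappear / (n_present * n_gcm), np.nan)
    return prob


def site_loss_probability(
    stack_current: SuitabilityStack,
    future_stacks: list[SuitabilityStack],
) -> np.ndarray:
    """Per-cell probability that a resident species loses that site.

    Site-level variant: the fraction of (resident species x GCM)
    combinations for which the cell itself is not future-suitable,
    regardless of whether suitable habitat persists elsewhere.  Provided
    for comparison with the range-wide disappearance probability.
    """
    if not future_stacks:
        raise ValueError("at least one future stack is required")
    for f in future_stacks:
        _check_congruent(stack_current, f)
    cur = stack_current.mask
    n_present = cur.sum(axis=0)
    lost = np.zeros(stack_current.n_cells)
    for f in future_stacks:
        lost += (cur & ~f.mask).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_present > 0, lost / (n_present * len(future_stacks)), np.nan)


@dataclass
class TaxonSummary:
    """Across-species and across-GCM aggregates of biotic velocity."""

    taxon: str
    direction: str
    cell_id: np.ndarray
    mean_velocity: np.ndarray
    sd_across_species: np.ndarray
    sd_across_gcms: np.ndarray
    n_species: int


def _full_velocity(field: SpeciesVelocityField, n_cells: int) -> np.ndarray:
    v = np.full(n_cells, np.nan)
    if not field.range_disappears:
        v[field.cell_index] = field.velocity
    return v


def aggregate_taxa(
    fields_by_gcm: list[list[SpeciesVelocityField]],
    n_cells: int,
    cell_id: np.ndarray,
    taxa: tuple[str, ...] | None = None,
) -> dict[str, TaxonSummary]:
    """Per-taxon (and "all") across-species mean and variability per cell.

    ``fields_by_gcm`` holds one list of per-species fields per GCM, in
    the same species order.  Each species is first averaged over the GCMs
    for which its velocity at the cell is defined; the across-species
    mean and sample sd of those GCM means give the taxon maps.
    ``sd_across_gcms`` is the sample sd over GCMs of the per-GCM
    across-species mean.
    """
    if not fields_by_gcm or not fields_by_gcm[0]:
        raise ValueError("at least one GCM with at least one species is required")
    n_species = len(fields_by_gcm[0])
    species_taxa = [f.taxon for f in fields_by_gcm[0]]
    direction = fields_by_gcm[0][0].direction
    for per_gcm in fields_by_gcm:
        if len(per_gcm) != n_species:
            raise ValueError("species lists differ between GCMs")

    # (n_species, n_gcms, n_cells) stack of full-grid velocity vectors
    V = np.empty((n_species, len(fields_by_gcm), n_cells))
    for g, per_gcm in enumerate(fields_by_gcm):
        for s, f in enumerate(per_gcm):
            V[s, g] = _full_velocity(f, n_cells)

    requested = taxa if taxa is not None else tuple(sorted(set(species_taxa))) + ("all",)
    known = set(species_taxa) | {"all"}
    out: dict[str, TaxonSummary] = {}
    for t in requested:
        if t not in known:
            raise ValueError(f"unknown taxon label {t!r}")
        sel = (
            np.arange(n_species)
            if t == "all"
            else np.asarray([i for i, tx in enumerate(species_taxa) if tx == t])
        )
        Vt = V[sel]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gcm_mean = np.nanmean(Vt, axis=1)  # (n_sel, n_cells)
            n_def = np.sum(~np.isnan(gcm_mean), axis=0)
            mean = np.where(n_def > 0, np.nanmean(gcm_mean, axis=0), np.nan)
            sd_sp = np.full(n_cells, np.nan)
            many = n_def > 1
            if many.any():
                sd_sp[many] = np.nanstd(gcm_mean[:, many], axis=0, ddof=1)
            sd_sp[n_def == 1] = 0.0
            per_gcm_mean = np.nanmean(Vt, axis=0)  # (n_gcms, n_cells)
            g_def = np.sum(~np.isnan(per_gcm_mean), axis=0)
            sd_g = np.full(n_cells, np.nan)
            gmany = g_def > 1
            if gmany.any():
                sd_g[gmany] = np.nanstd(per_gcm_mean[:, gmany], axis=0, ddof=1)
            sd_g[g_def == 1] = 0.0
        out[t] = TaxonSummary(
            taxon=t,
            direction=direction,
            cell_id=np.asarray(cell_id),
            mean_velocity=mean,
            sd_across_species=sd_sp,
            sd_across_gcms=sd_g,
            n_species=len(sel),
        )
    return out
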