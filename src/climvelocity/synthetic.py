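"""Synthetic worlds for exercising the velocity pipeline end to end.

The generator builds the statistical structure the analysis assumes
without any external data: terrain with mountains, correlated bioclimatic
variables driven by latitude and a lapse rate, pseudo-GCM futures that
differ in mean warming and spatial noise, envelope-niche species whose
suitable ranges shift under warming, latitude-band zones, and random
connected protected-area masks.  Everything is bit-reproducible from a
seed, and key constructions (uniform warming on a linear gradient, niche
bands narrower than the imposed shift) have closed-form expected
velocities that downstream tests use as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biotic import SuitabilityStack
from .climate_space import ClimateGrid

__all__ = [
    "KM_PER_DEG",
    "TAXA",
    "TerrainGrid",
    "ScenarioConfig",
    "NicheSpec",
    "ProtectedArea",
    "make_terrain",
    "make_bioclim",
    "make_species",
    "sample_niches",
    "make_zones",
    "make_protected_areas",
]

# Mean length of one degree of a great circle on a sphere of radius 6371 km.
KM_PER_DEG = 111.19492664455873

TAXA = ("bird", "mammal", "amphibian")


@dataclass
class TerrainGrid:
    """Regular lon/lat grid with per-cell elevation.

    Cells are row-major from the northwest corner: latitude strictly
    decreases along rows (y), longitude strictly increases along columns
    (x).  ``elevation`` is in meters and never negative.
    """

    nx: int
    ny: int
    cell_id: np.ndarray
    x_index: np.ndarray
    y_index: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    elevation: np.ndarray
    cell_size_km: float = 50.0

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny


@dataclass
class ScenarioConfig:
    """Warming scenario shared by all pseudo-GCM futures.

    ``warming_mean`` (one entry per pseudo-GCM, in degrees C) and
    ``precip_change_frac`` (fractional precipitation change) are the only
    systematic differences between pseudo-GCMs; ``spatial_noise_sd`` adds
    GCM-specific spatially uncorrelated temperature noise.  No circulation
    realism is claimed.
    """

    n_pseudo_gcms: int = 1
    warming_mean: list[float] = field(default_factory=lambda: [3.0])
    spatial_noise_sd: float = 0.0
    precip_change_frac: list[float] = field(default_factory=lambda: [0.0])
    years_between: float = 110.0
    cell_size_km: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pseudo_gcms < 1:
            raise ValueError("n_pseudo_gcms must be >= 1")
        if self.years_between <= 0:
            raise ValueError("years_between must be positive")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if len(self.warming_mean) != self.n_pseudo_gcms:
            raise ValueError("warming_mean needs one entry per pseudo-GCM")
        if len(self.precip_change_frac) != self.n_pseudo_gcms:
            raise ValueError("precip_change_frac needs one entry per pseudo-GCM")


@dataclass
class NicheSpec:
    """Rectangular climate envelope: suitable iff every variable lies
    within ``center +/- halfwidth``."""

    species_id: str
    taxon: str
    center: np.ndarray
    halfwidth: np.ndarray

    def __post_init__(self) -> None:
        if self.taxon not in TAXA:
            raise ValueError(f"taxon must be one of {TAXA}")
        self.center = np.asarray(self.center, dtype=float)
        self.halfwidth = np.asarray(self.halfwidth, dtype=float)
        if self.center.shape != self.halfwidth.shape:
            raise ValueError("center and halfwidth must have the same length")
        if np.any(self.halfwidth <= 0):
            raise ValueError("halfwidth must be positive element-wise")


@dataclass
class ProtectedArea:
    """Connected set of grid cells treated as one protected area."""

    pa_id: int
    mask: np.ndarray  # boolean over cells
    area_km2: float


def make_terrain(
    nx: int,
    ny: int,
    n_mountains: int = 0,
    max_elev: float = 0.0,
    seed: int = 0,
    cell_size_km: float = 50.0,
    lat_max: float = 55.0,
    lon_min: float = -125.0,
) -> TerrainGrid:
    """Flat plain with optional Gaussian mountains.

    Elevation is the maximum over radially symmetric Gaussian bumps, so a
    single mountain decreases monotonically along any ray from its peak.
    The first mountain reaches exactly ``max_elev``.
    """
    if nx < 2 or ny < 2:
        raise ValueError("grid dimensions must be >= 2")
    if max_elev < 0:
        raise ValueError("max_elev must be >= 0")
    rng = np.random.default_rng(seed)
    xi, yi = np.meshgrid(np.arange(nx), np.arange(ny))
    xi = xi.ravel()
    yi = yi.ravel()
    deg = cell_size_km / KM_PER_DEG
    lon = lon_min + xi * deg
    lat = lat_max - yi * deg
    elev = np.zeros(nx * ny)
    for m in range(n_mountains):
        px = rng.integers(0, nx)
        py = rng.integers(0, ny)
        sigma = rng.uniform(min(nx, ny) / 10.0, min(nx, ny) / 4.0)
        amp = max_elev if m == 0 else max_elev * rng.uniform(0.4, 0.9)
        r2 = (xi - px) ** 2.0 + (yi - py) ** 2.0
        elev = np.maximum(elev, amp * np.exp(-r2 / (2.0 * sigma**2)))
    return TerrainGrid(
        nx=nx,
        ny=ny,
        cell_id=np.arange(nx * ny),
        x_index=xi,
        y_index=yi,
        lon=lon,
        lat=lat,
        elevation=elev,
        cell_size_km=cell_size_km,
    )


def _variable_fields(
    terrain: TerrainGrid,
    n_vars: int,
    lapse_rate: float,
    var_noise_sd: float,
    rng: np.random.Generator,
):
    """Fixed per-cell noise fields and derived-variable coefficients.

    These are drawn once and reused for current and future grids, so a
    null scenario reproduces the current grid exactly.
    """
    n = terrain.n_cells
    noise = rng.normal(0.0, var_noise_sd, size=(n_vars, n)) if var_noise_sd > 0 else np.zeros((n_vars, n))
    # Derived variables mix temperature, precipitation and latitude with
    # temperature-dominant weights, giving a dominant first PCA axis.
    coef = np.empty((max(n_vars - 2, 0), 3))
    coef[:, 0] = rng.uniform(0.6, 1.4, size=coef.shape[0])  # on temperature
    coef[:, 1] = rng.uniform(-0.5, 0.5, size=coef.shape[0])  # on scaled precip
    coef[:, 2] = rng.uniform(-0.2, 0.2, size=coef.shape[0])  # on latitude
    return noise, coef


def _assemble_values(
    temp: np.ndarray,
    precip: np.ndarray,
    lat: np.ndarray,
    noise: np.ndarray,
    coef: np.ndarray,
    n_vars: int,
) -> np.ndarray:
    vals = np.empty((temp.size, n_vars))
    vals[:, 0] = temp + noise[0]
    if n_vars >= 2:
        vals[:, 1] = precip + 10.0 * noise[1]
    for k in range(2, n_vars):
        a, b, c = coef[k - 2]
        vals[:, k] = a * temp + b * (precip / 50.0) + c * lat + noise[k]
    return vals


def make_bioclim(
    terrain: TerrainGrid,
    scenario: ScenarioConfig,
    n_vars: int = 8,
    lapse_rate: float = -6.5,
    lat_slope: float = 0.55,
    temp_base: float = 12.0,
    precip_base: float = 800.0,
    var_noise_sd: float = 0.1,
) -> tuple[ClimateGrid, list[ClimateGrid]]:
    """Current climate plus one future grid per pseudo-GCM.

    Variable 0 is temperature-like: base, minus ``lat_slope`` degC per
    degree of latitude above the grid's mean latitude, plus
    ``lapse_rate`` degC per km of elevation, plus fixed noise.  Variable 1
    is precipitation-like (orographic + zonal structure).  Remaining
    variables are fixed linear mixes of temperature, precipitation and
    latitude, so all variables are mutually correlated.  Future grids add
    per-GCM mean warming and spatial temperature noise and scale
    precipitation by ``1 + precip_change_frac``.
    """
    if n_vars < 2:
        raise ValueError("n_vars must be >= 2")
    if scenario.cell_size_km != terrain.cell_size_km:
        raise ValueError("scenario and terrain disagree on cell size")
    rng = np.random.default_rng(scenario.seed)
    noise, coef = _variable_fields(terrain, n_vars, lapse_rate, var_noise_sd, rng)
    lat = terrain.lat
    lat0 = float(lat.mean())
    elev_km = terrain.elevation / 1000.0
    temp_cur = temp_base - lat_slope * (lat - lat0) + lapse_rate * elev_km
    lon0 = float(terrain.lon.mean())
    precip_cur = (
        precip_base
        + 300.0 * elev_km
        + 8.0 * (terrain.lon - lon0)
        - 4.0 * (lat - lat0)
    )
    var_names = ["tmean", "precip"] + [f"bio{k + 1}" for k in range(2, n_vars)]
    common = dict(
        cell_id=terrain.cell_id,
        lon=terrain.lon,
        lat=terrain.lat,
        var_names=var_names,
        cell_size_km=terrain.cell_size_km,
        x_index=terrain.x_index,
        y_index=terrain.y_index,
    )
    current = ClimateGrid(
        values=_assemble_values(temp_cur, precip_cur, lat, noise, coef, n_vars),
        period="current",
        gcm_id="obs",
        **common,
    )
    futures = []
    for g in range(scenario.n_pseudo_gcms):
        gcm_noise = (
            rng.normal(0.0, scenario.spatial_noise_sd, size=terrain.n_cells)
            if scenario.spatial_noise_sd > 0
            else 0.0
        )
        temp_fut = temp_cur + scenario.warming_mean[g] + gcm_noise
        precip_fut = precip_cur * (1.0 + scenario.precip_change_frac[g])
        futures.append(
            ClimateGrid(
                values=_assemble_values(temp_fut, precip_fut, lat, noise, coef, n_vars),
                period="future",
                gcm_id=f"pgcm{g:02d}",
                **common,
            )
        )
    return current, futures


def sample_niches(
    current: ClimateGrid,
    n_species: int,
    seed: int = 0,
    halfwidth_range: tuple[float, float] = (0.3, 1.2),
    taxon_weights: tuple[float, float, float] = (0.6, 0.25, 0.15),
) -> list[NicheSpec]:
    """Draw envelope niches centered on the climates of random cells.

    Halfwidths are uniform multiples (``halfwidth_range``) of each
    variable's spatial standard deviation, so every species has a
    non-trivial current range.
    """
    rng = np.random.default_rng(seed)
    sds = current.values.std(axis=0, ddof=1)
    sds = np.where(sds > 0, sds, 1.0)
    cells = rng.integers(0, current.n_cells, size=n_species)
    taxa = rng.choice(TAXA, size=n_species, p=np.asarray(taxon_weights) / sum(taxon_weights))
    niches = []
    for i in range(n_species):
        u = rng.uniform(*halfwidth_range)
        niches.append(
            NicheSpec(
                species_id=f"sp{i:04d}",
                taxon=str(taxa[i]),
                center=current.values[cells[i]].copy(),
                halfwidth=u * sds,
            )
        )
    return niches


def _suitable_matrix(grid: ClimateGrid, niches: list[NicheSpec]) -> np.ndarray:
    out = np.empty((len(niches), grid.n_cells), dtype=bool)
    for i, nv in enumerate(niches):
        if nv.center.size != grid.n_vars:
            raise ValueError(
                f"niche {nv.species_id} has {nv.center.size} variables, grid has {grid.n_vars}"
            )
        out[i] = np.all(np.abs(grid.values - nv.center) <= nv.halfwidth, axis=1)
    return out


def make_species(
    current: ClimateGrid,
    futures: list[ClimateGrid],
    niches: list[NicheSpec],
) -> tuple[SuitabilityStack, list[SuitabilityStack]]:
    """Binary suitability per species for the current grid and each future.

    A cell is suitable iff every climate variable lies within the niche
    envelope; the current-period stack is shared by all pseudo-GCMs.
    """
    if not niches:
        raise ValueError("at least one niche is required")
    for f in futures:
        if not np.array_equal(f.cell_id, current.cell_id):
            raise ValueError("current and future grids must share the cell set")
    meta = dict(
        species_ids=[n.species_id for n in niches],
        taxa=[n.taxon for n in niches],
        cell_id=current.cell_id,
        lon=np.asarray(current.lon, dtype=float),
        lat=np.asarray(current.lat, dtype=float),
        cell_size_km=current.cell_size_km,
        xy_km=current.xy_km(),
    )
    cur = SuitabilityStack(period="current", gcm_id="obs",
                           mask=_suitable_matrix(current, niches), **meta)
    futs = [
        SuitabilityStack(period="future", gcm_id=f.gcm_id,
                         mask=_suitable_matrix(f, niches), **meta)
        for f in futures
    ]
    return cur, futs


def make_zones(terrain: TerrainGrid, band_edges) -> np.ndarray:
    """Latitude-band zone label (0-based integer) per cell.

    ``band_edges`` are strictly increasing latitude boundaries covering
    every cell; band k spans ``[edges[k], edges[k+1])`` (topmost band is
    closed above).
    """
    edges = np.asarray(band_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValueError("band_edges must list at least two latitudes")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("band_edges must be strictly increasing")
    lat = terrain.lat
    if lat.min() < edges[0] or lat.max() > edges[-1]:
        raise ValueError("band_edges do not cover the grid's latitudes")
    zone = np.digitize(lat, edges[1:-1], right=False)
    return zone.astype(np.int64)


def make_protected_areas(
    terrain: TerrainGrid,
    n_pa: int,
    radius_range: tuple[int, int] = (1, 3),
    seed: int = 0,
    max_tries: int = 2000,
) -> list[ProtectedArea]:
    """Random disjoint, connected protected-area cell masks.

    Each PA is a disc of cells (index distance <= radius) around a random
    center; overlapping candidates are rejected and redrawn.  Area is
    cell count times the cell area.
    """
    if n_pa < 0:
        raise ValueError("n_pa must be >= 0")
    rng = np.random.default_rng(seed)
    taken = np.zeros(terrain.n_cells, dtype=bool)
    xi, yi = terrain.x_index, terrain.y_index
    pas: list[ProtectedArea] = []
    tries = 0
    while len(pas) < n_pa and tries < max_tries:
        tries += 1
        cx = rng.integers(0, terrain.nx)
        cy = rng.integers(0, terrain.ny)
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        mask = ((xi - cx) ** 2 + (yi - cy) ** 2) <= r**2
        if not mask.any() or (mask & taken).any():
            continue
        taken |= mask
        pas.append(
            ProtectedArea(
                pa_id=len(pas),
                mask=mask,
                area_km2=float(mask.sum()) * terrain.cell_size_km**2,
            )
        )
    if len(pas) < n_pa:
        raise RuntimeError(
            f"could only place {len(pas)} of {n_pa} disjoint protected areas"
        )
    return pas
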