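"""Synthetic ocean world: environmental scenarios and species with known niches.

This module generates everything the pipeline consumes — a present-day stack of
ocean predictor layers, two warmed future stacks (2050, 2100), and species whose
*true* suitability functions are known — so parameter recovery, thresholding and
change accounting can all be validated against ground truth without downloading
any real climatology or occurrence data.

The world is deliberately simple but structured like a marine predictor stack:

* land is a set of smooth analytic "continents" on a global lon/lat grid;
* sea-surface temperature (SST) declines smoothly from equator to poles with a
  longitudinal wave and seeded noise; sea ice exists only where SST is below a
  freezing threshold; bottom temperature relaxes towards a cold deep-water value
  with depth;
* future scenarios apply a spatially uniform additive warming anomaly to the
  temperature layers and recompute ice from the warmed SST; depth and distance
  to land are scenario-invariant.

Species ("truth niches") are products of Gaussian or logistic response curves
over named predictors, zeroed on land and — for all groups except surface
phytoplankton — where the sea floor is deeper than the species' maximum depth.
Occurrences are sampled proportionally to true suitability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage

from ._seeding import derive_seed
from .grid import EnvStack, GridSpec, Layer, OccurrenceSet, condition_occurrences

Group = Literal["zoobenthos", "phytobenthos", "zooplankton", "phytoplankton"]

GROUPS: tuple[str, ...] = ("zoobenthos", "phytobenthos", "zooplankton", "phytoplankton")

#: Candidate predictors offered to screening, by ecological group. Benthic
#: groups carry bottom variables, plankton surface variables, phytoplankton
#: nutrients/iron.
GROUP_CANDIDATES: dict[str, tuple[str, ...]] = {
    "zoobenthos": (
        "bottom_temperature", "sst", "bottom_salinity", "surface_salinity",
        "ice_thickness", "depth", "land_distance",
    ),
    "phytobenthos": (
        "bottom_temperature", "sst", "bottom_salinity", "surface_salinity",
        "ice_thickness", "depth", "land_distance", "iron",
    ),
    "zooplankton": (
        "sst", "bottom_salinity", "surface_salinity", "ice_thickness",
        "depth", "land_distance",
    ),
    "phytoplankton": (
        "sst", "surface_salinity", "ice_thickness", "land_distance", "iron",
    ),
}

#: SST below this threshold grows sea ice, °C.
FREEZING_SST = -0.5

_DEFAULT_NOISE_SD = {
    "sst": 0.5,
    "bottom_temperature": 0.3,
    "surface_salinity": 0.3,
    "bottom_salinity": 0.1,
    "depth": 100.0,
    "iron": 0.05,
}


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic world.

    The default grid is a 0.5° global grid (360 × 720).  Warming anomalies are
    uniform additive shifts in °C (1.2 by 2050 and 2.4 by 2100, an intermediate
    stabilization pathway); ``arctic_lat_min`` delimits the pan-Arctic analysis
    extent used by the change summaries.
    """

    grid: GridSpec = field(default_factory=lambda: GridSpec(360, 720, -180.0, -90.0, 0.5))
    sst_anomaly_2050: float = 1.2
    sst_anomaly_2100: float = 2.4
    arctic_lat_min: float = 60.0
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sst_anomaly_2050 < 0 or self.sst_anomaly_2100 < 0:
            raise ValueError("warming anomalies must be non-negative")
        if not (self.grid.lat_min <= self.arctic_lat_min <= self.grid.lat_max):
            raise ValueError("arctic_lat_min outside grid latitude range")


@dataclass
class TruthNiche:
    """Known suitability function of a synthetic species.

    ``responses`` maps predictor name to ``("gaussian", optimum, breadth)``,
    ``("logistic", midpoint, slope)`` or the tolerance window
    ``("window", low, high, slope)`` — a product of a rising and a falling
    logistic edge, giving near-binary suitability inside [low, high].  True
    suitability is the product of the responses, zero on land, and zero where
    depth exceeds ``max_depth`` (skipped for phytoplankton, which are surface
    organisms).
    """

    species_id: str
    group: str
    responses: dict[str, tuple]
    max_depth: float | None = None
    prevalence: float = 1.0
    candidates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.group != "phytoplankton" and self.max_depth is None:
            raise ValueError(f"{self.species_id}: max_depth required for non-phytoplankton")
        if not self.candidates:
            self.candidates = GROUP_CANDIDATES[self.group]


# ---------------------------------------------------------------------------
# Scenario construction
# ---------------------------------------------------------------------------


def _continentality(grid: GridSpec) -> np.ndarray:
    """Smooth [0, 1]-ish field whose high values are land; analytic, seed-free."""
    lats = grid.row_lats("center")[:, None]
    lons = grid.col_lons()[None, :]
    blobs = [
        # (lon0, lat0, sig_lon, sig_lat, amplitude) — crude synthetic continents
        (-100.0, 45.0, 28.0, 22.0, 1.0),
        (-60.0, -15.0, 18.0, 25.0, 0.95),
        (20.0, 10.0, 25.0, 30.0, 1.0),
        (60.0, 50.0, 45.0, 18.0, 1.0),
        (135.0, -25.0, 20.0, 14.0, 0.9),
        (-40.0, 75.0, 25.0, 9.0, 0.85),
        (170.0, 65.0, 18.0, 10.0, 0.7),
    ]
    c = np.zeros(grid.shape)
    for lon0, lat0, sl, sp, amp in blobs:
        dlon = np.abs(lons - lon0)
        dlon = np.minimum(dlon, 360.0 - dlon)  # wrap-around
        c += amp * np.exp(-0.5 * ((dlon / sl) ** 2 + ((lats - lat0) / sp) ** 2))
    return c


def _ice_from_sst(sst: np.ndarray) -> np.ndarray:
    return np.clip(1.2 * (FREEZING_SST - sst), 0.0, None)


def make_scenarios(config: ScenarioConfig) -> dict[str, EnvStack]:
    """Generate the present, 2050 and 2100 predictor stacks.

    Future stacks differ from the present only in temperature, salinity and ice
    layers (temperatures shifted by the scenario anomaly, ice regrown from the
    warmed SST, salinity unchanged by default); depth and land distance are
    identical across scenarios.  Identical config (including seed) yields
    bit-identical stacks.
    """
    grid = config.grid
    rng = np.random.default_rng(derive_seed(config.seed, "world"))
    nsd = {**_DEFAULT_NOISE_SD, **dict(config.noise_sd)}

    cont = _continentality(grid)
    land = cont > 0.55
    if land.all() or not land.any():
        raise ValueError("degenerate land mask")
    sea = ~land

    lats = grid.row_lats("center")[:, None]
    lons = grid.col_lons()[None, :]
    coslat = np.cos(np.deg2rad(lats))

    sst = (
        -2.0
        + 30.0 * np.clip(coslat, 0, 1) ** 2.2
        + 1.5 * np.sin(np.deg2rad(2.0 * lons)) * coslat
        + rng.normal(0.0, nsd["sst"], grid.shape)
    )

    # cubic ramp: broad continental shelves, abyssal plains in the open ocean
    depth = np.clip(5000.0 * np.clip((0.55 - cont) / 0.55, 0.0, None) ** 3, 10.0, 5000.0)
    depth = depth + rng.normal(0.0, nsd["depth"], grid.shape)
    depth = np.clip(depth, 5.0, 5500.0)

    # planar distance transform in cell units, scaled to km at each row's latitude
    dist_cells = ndimage.distance_transform_edt(sea)
    land_distance = dist_cells * grid.cell_size * 111.19 * np.maximum(coslat, 0.2)

    relax = np.exp(-depth / 1200.0)
    bottom_temperature = (
        sst * relax + 1.5 * (1.0 - relax) + rng.normal(0.0, nsd["bottom_temperature"], grid.shape)
    )

    surface_salinity = (
        33.5
        + 1.5 * np.exp(-(((np.abs(lats) - 25.0) / 15.0) ** 2)) * np.ones_like(lons)
        + rng.normal(0.0, nsd["surface_salinity"], grid.shape)
    )
    bottom_salinity = 34.7 + rng.normal(0.0, nsd["bottom_salinity"], grid.shape)

    # coastal runoff plus longitudinal "dust / upwelling" basins: iron carries
    # information of its own instead of proxying land distance or temperature
    iron = (
        0.15
        + 0.45 * np.exp(-land_distance / 500.0)
        + 0.30 * (0.5 + 0.5 * np.sin(np.deg2rad(3.0 * lons) + 1.0)) * np.ones_like(lats)
        + rng.normal(0.0, nsd["iron"], grid.shape)
    )
    iron = np.clip(iron, 0.0, None)

    present_fields = {
        "sst": sst,
        "bottom_temperature": bottom_temperature,
        "surface_salinity": surface_salinity,
        "bottom_salinity": bottom_salinity,
        "ice_thickness": _ice_from_sst(sst),
        "depth": depth,
        "land_distance": land_distance,
        "iron": iron,
    }

    def build(fields: Mapping[str, np.ndarray], scenario: str) -> EnvStack:
        layers = {}
        for name, vals in fields.items():
            v = np.where(land, np.nan, vals)
            layers[name] = Layer(grid, v, land.copy())
        return EnvStack(layers=layers, scenario=scenario, sea_mask=sea.copy())

    stacks = {"present": build(present_fields, "present")}
    for scenario, anomaly in (("2050", config.sst_anomaly_2050), ("2100", config.sst_anomaly_2100)):
        fields = dict(present_fields)
        fields["sst"] = present_fields["sst"] + anomaly
        fields["bottom_temperature"] = present_fields["bottom_temperature"] + anomaly
        fields["ice_thickness"] = _ice_from_sst(fields["sst"])
        # salinity layers carried over unchanged (default future response)
        stacks[scenario] = build(fields, scenario)
    return stacks


def arctic_mask(stack: EnvStack, arctic_lat_min: float) -> np.ndarray:
    """Pan-Arctic analysis extent: sea cells at or above the given latitude."""
    lats = stack.grid.row_lats("center")
    return stack.sea_mask & (lats[:, None] >= arctic_lat_min)


# ---------------------------------------------------------------------------
# Truth suitability and occurrence sampling
# ---------------------------------------------------------------------------


def _response(kind_params: tuple, x: np.ndarray) -> np.ndarray:
    kind = kind_params[0]
    if kind == "gaussian":
        _, mu, sigma = kind_params
        return np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    if kind == "logistic":
        _, mid, slope = kind_params
        return 1.0 / (1.0 + np.exp(-slope * (x - mid)))
    if kind == "window":
        # tolerance window: product of a rising and a falling logistic edge
        _, low, high, slope = kind_params
        rise = 1.0 / (1.0 + np.exp(-slope * (x - low)))
        fall = 1.0 / (1.0 + np.exp(slope * (x - high)))
        return rise * fall
    raise ValueError(f"unknown response kind {kind!r}")


def true_suitability(niche: TruthNiche, stack: EnvStack) -> Layer:
    """True suitability S* ∈ [0, 1]: product of responses, sea/depth masked."""
    s = np.ones(stack.grid.shape)
    for name, spec in niche.responses.items():
        if name not in stack.layers:
            raise KeyError(f"niche predictor {name!r} missing from stack")
        with np.errstate(invalid="ignore"):
            s *= _response(spec, stack.layers[name].values)
    s = np.where(stack.sea_mask, s, 0.0)
    if niche.group != "phytoplankton":
        depth = stack.layers["depth"].values
        with np.errstate(invalid="ignore"):
            s = np.where(stack.sea_mask & (depth > niche.max_depth), 0.0, s)
    s = np.nan_to_num(s, nan=0.0)
    return Layer(stack.grid, s, ~stack.sea_mask)


def sample_occurrences(
    niche: TruthNiche,
    stack: EnvStack,
    n: int,
    seed: int,
    jitter_fraction: float = 0.5,
    contamination: float = 0.0,
) -> OccurrenceSet:
    """Draw ``n`` presence records proportionally to true suitability.

    Cells are drawn without replacement with probability ∝ S*; a fraction of the
    resulting points is jittered uniformly within its cell (the rest sit at cell
    centers).  ``contamination`` places ``round(contamination·n)`` of the records
    on random land cells, exercising the snap-to-sea conditioning downstream.
    If fewer than ``n`` cells have S* > 0, all of them are returned with a warning.
    """
    import warnings

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    grid = stack.grid
    s = true_suitability(niche, stack).values * niche.prevalence
    rows, cols = np.nonzero(s > 0)
    weights = s[rows, cols]

    n_land = int(round(contamination * n))
    n_sea = n - n_land
    if n_sea > len(rows):
        warnings.warn(
            f"{niche.species_id}: only {len(rows)} cells with positive suitability "
            f"(requested {n_sea}); returning all of them",
            stacklevel=2,
        )
        chosen = np.arange(len(rows))
    else:
        p = weights / weights.sum()
        chosen = rng.choice(len(rows), size=n_sea, replace=False, p=p)

    pts = []
    for idx in chosen:
        lon, lat = grid.cell_center(int(rows[idx]), int(cols[idx]))
        if rng.random() < jitter_fraction:
            lon += (rng.random() - 0.5) * grid.cell_size
            lat += (rng.random() - 0.5) * grid.cell_size
        pts.append((lon, lat))

    if n_land:
        land_rows, land_cols = np.nonzero(~stack.sea_mask)
        if len(land_rows) == 0:
            raise ValueError("contamination requested but world has no land")
        pick = rng.choice(len(land_rows), size=n_land, replace=True)
        for idx in pick:
            pts.append(grid.cell_center(int(land_rows[idx]), int(land_cols[idx])))

    points = np.asarray(pts, dtype=float)
    occ = condition_occurrences(niche.species_id, points, grid, stack.sea_mask)
    return occ


def default_roster() -> list[TruthNiche]:
    """Eight synthetic species spanning the four ecological groups.

    All are cool-temperate organisms with sharp tolerance windows whose warm
    edges lie above present Arctic temperatures — strongly environmentally
    determined niches, so pan-Arctic suitable habitat grows under warming (the
    directional behaviour the change-analysis stage must recover) and true
    suitability is close to binary (so threshold-based range maps are
    comparable against the truth region).
    """
    return [
        TruthNiche(
            "zb_barnacle", "zoobenthos",
            {"bottom_temperature": ("window", 4.0, 12.0, 4.0),
             "bottom_salinity": ("window", 34.2, 35.4, 8.0)},
            max_depth=200.0,
        ),
        TruthNiche(
            "zb_crab", "zoobenthos",
            {"bottom_temperature": ("window", 0.5, 7.0, 4.0),
             "sst": ("window", -1.0, 10.0, 3.0)},
            max_depth=500.0,
        ),
        TruthNiche(
            "pb_kelp", "phytobenthos",
            {"sst": ("window", 3.0, 14.0, 4.0),
             "bottom_temperature": ("window", 2.0, 14.0, 4.0)},
            max_depth=120.0,
        ),
        TruthNiche(
            "pb_redalga", "phytobenthos",
            {"sst": ("window", 1.0, 12.0, 4.0),
             "ice_thickness": ("logistic", 0.4, -8.0)},
            max_depth=100.0,
        ),
        TruthNiche(
            "zp_copepod", "zooplankton",
            {"sst": ("window", 6.0, 14.0, 4.0),
             "surface_salinity": ("window", 32.5, 35.5, 6.0)},
            max_depth=1000.0,
        ),
        TruthNiche(
            "zp_jelly", "zooplankton",
            {"sst": ("window", 1.0, 11.0, 4.0),
             "ice_thickness": ("logistic", 0.5, -6.0)},
            max_depth=1500.0,
        ),
        TruthNiche(
            "pp_dino_a", "phytoplankton",
            {"sst": ("window", 6.0, 15.0, 4.0),
             "iron": ("logistic", 0.3, 30.0)},
        ),
        TruthNiche(
            "pp_dino_b", "phytoplankton",
            {"sst": ("window", 5.0, 11.0, 4.0),
             "surface_salinity": ("window", 33.2, 34.8, 6.0)},
        ),
    ]


def roster_by_id(roster: Sequence[TruthNiche] | None = None) -> dict[str, TruthNiche]:
    return {n.species_id: n for n in (roster if roster is not None else default_roster())}
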