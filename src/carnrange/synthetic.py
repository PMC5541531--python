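"""Synthetic landscapes with known contraction ground truth.

Every stage of the pipeline can be exercised without external downloads:
this module simulates a land-masked world, three spatially autocorrelated
anthropogenic covariate fields (two right-skewed densities and a 0–100 %
fraction, matched loosely to global rural-population, cattle-density and
cropland statistics), overlapping species ranges, and cell-level range
contraction realized from the same model family the estimator fits —

    logit P(contract) = β₀ + b_species + x'β + spatial noise

with Gaussian species intercepts and an independent smoothed spatial field
on the logit scale.  The realized dataset, together with the parameters
that produced it (:class:`SyntheticTruth`), gives parameter-recovery and
calibration tests a known target.

The generator is deterministic given its seed: all randomness flows from a
single ``numpy`` SeedSequence spawned into per-component streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .grid import GridSpec, make_grid
from .harmonize import SpeciesRangePair, SpeciesTraits
from .model import (
    CovariateSpec,
    ModelParams,
    build_observation_table,
    transform_standardize,
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_land",
    "generate_covariate_field",
    "generate_species_historic",
    "generate_regions",
    "realize_contraction",
    "make_dataset",
]

_FAMILIES = ("Felidae", "Canidae", "Ursidae", "Hyaenidae")
_STATUSES = ("LC", "NT", "VU", "EN", "CR")
_TRENDS = ("decreasing", "stable", "increasing")

#: default covariate marginals — right-skewed densities (log-normal style:
#: median + log-s.d.) and a bounded cropland fraction (logit location/scale),
#: chosen to resemble global rural-population (~19 ± 48 people/km²), cattle
#: (~10 ± 26 head/km²) and cropland (~12 ± 19 %) summary statistics.
DEFAULT_COVARIATES = {
    "rural_pop_density": {"kind": "density", "median": 7.0, "log_sd": 1.4},
    "cattle_density": {"kind": "density", "median": 4.0, "log_sd": 1.35},
    "cropland": {"kind": "fraction", "loc": -3.0, "scale": 2.0},
}


@dataclass
class SimConfig:
    """Study conditions of the synthetic world.

    The default window is a 60°×120° band at 0.5° resolution (120×240
    fine cells) with a coarse aggregation factor of 5 — large enough for
    spatial structure, small enough for seconds-scale runs.
    """

    resolution: float = 0.5
    extent: tuple = (-60.0, 60.0, -30.0, 30.0)
    coarse_factor: int = 5
    land_fraction: float = 0.35
    land_length_scale_km: float = 1200.0
    elevation_relief_m: float = 2500.0
    n_species: int = 10
    species_n_disks: int = 3
    species_radius_frac: tuple = (0.10, 0.30)
    n_regions: int = 6
    covariates: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATES.items()})
    cov_length_scale_km: float = 800.0
    beta0: float = -0.5
    beta: dict = field(
        default_factory=lambda: {
            "rural_pop_density": 0.18,
            "cattle_density": 0.22,
            "cropland": 0.54,
        }
    )
    sigma_species: float = 1.0
    spatial_sd: float = 0.8
    spatial_length_km: float = 800.0
    membership_threshold: float = 0.5
    contraction_threshold: float = 0.5


@dataclass
class SyntheticTruth:
    """Parameters that generated a dataset; fully determine it with the seed."""

    seed: int
    beta0: float
    beta: dict
    sigma_species: float
    species_intercepts: list
    spatial_sd: float
    spatial_length_km: float
    membership_threshold: float
    contraction_threshold: float
    covariate_transforms: dict

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    """A complete synthetic world plus its generating truth.

    ``latent_obs`` holds one row per species × member coarse cell with the
    true contraction probability and the realized indicator.
    """

    fine_grid: GridSpec
    coarse_factor: int
    land: np.ndarray
    elevation: np.ndarray
    zones: np.ndarray
    covariates: dict
    pairs: list
    truth: SyntheticTruth
    latent_obs: pd.DataFrame

    @property
    def coarse_grid(self) -> GridSpec:
        return self.fine_grid.coarsen(self.coarse_factor)


# ---------------------------------------------------------------------------
# Field primitives
# ---------------------------------------------------------------------------

def _km_per_cell(grid: GridSpec) -> float:
    # nominal equatorial cell width; adequate for a noise length scale
    return 111.19 * grid.resolution


def _smooth_unit_field(rng: np.random.Generator, grid: GridSpec, length_scale_km: float) -> np.ndarray:
    """Gaussian-kernel-smoothed white noise, renormalized to mean 0, s.d. 1.

    Longitude wraps; latitude reflects.  A zero length scale returns the
    raw white noise (no spatial correlation).
    """
    z = rng.standard_normal(grid.shape)
    sigma = length_scale_km / _km_per_cell(grid)
    if sigma > 1e-6:
        z = ndimage.gaussian_filter(z, sigma=sigma, mode=["reflect", "wrap"])
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return z


def generate_land(
    rng: np.random.Generator,
    grid: GridSpec,
    land_fraction: float = 0.35,
    length_scale_km: float = 1200.0,
    relief_m: float = 2500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold a smoothed noise field into landmasses; derive elevation.

    The threshold is the field's (1 − land_fraction) quantile, so the
    realized land fraction matches the target up to grid granularity.
    Elevation is a second smooth field, shifted/rescaled to [0, relief_m]
    on land and 0 over ocean.
    """
    if not (0 < land_fraction < 1):
        raise ValueError("land_fraction must be in (0, 1)")
    f = _smooth_unit_field(rng, grid, length_scale_km)
    land = f >= np.quantile(f, 1.0 - land_fraction)
    e = _smooth_unit_field(rng, grid, length_scale_km / 2.0)
    lo, hi = e.min(), e.max()
    elevation = np.where(land, relief_m * (e - lo) / max(hi - lo, 1e-12), 0.0)
    return land, elevation


def generate_covariate_field(
    rng: np.random.Generator,
    grid: GridSpec,
    kind: str,
    length_scale_km: float,
    **marginal_params,
) -> np.ndarray:
    """A spatially autocorrelated covariate raster.

    ``kind="density"`` maps the smoothed Gaussian field through
    exp(log median + log_sd·z): positive and right-skewed, like gridded
    population or livestock densities.  ``kind="fraction"`` maps through
    100·logistic(loc + scale·z): bounded to [0, 100] %, like cropland
    cover.
    """
    z = _smooth_unit_field(rng, grid, length_scale_km)
    if kind == "density":
        median = marginal_params.get("median", 5.0)
        log_sd = marginal_params.get("log_sd", 1.5)
        return np.exp(np.log(median) + log_sd * z)
    if kind == "fraction":
        loc = marginal_params.get("loc", -2.0)
        scale = marginal_params.get("scale", 2.0)
        return 100.0 * expit(loc + scale * z)
    raise ValueError(f"unknown covariate kind {kind!r}")


def generate_species_historic(
    rng: np.random.Generator,
    n_species: int,
    land: np.ndarray,
    grid: GridSpec,
    n_disks: int = 3,
    radius_frac: tuple = (0.10, 0.30),
    max_retries: int = 10,
) -> list[np.ndarray]:
    """Historic ranges as smoothed unions of random disks clipped to land.

    Disk centres are drawn from land cells so ranges overlap where land
    is, producing composite richness > 1; each returned range is
    non-empty (retried, then an error).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    land = land.astype(bool)
    land_rows, land_cols = np.nonzero(land)
    if land_rows.size == 0:
        raise ValueError("land mask is empty")
    rr, cc = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    base = min(grid.n_rows, grid.n_cols)
    ranges = []
    for _ in range(n_species):
        for attempt in range(max_retries):
            mask = np.zeros(grid.shape, dtype=bool)
            for _ in range(n_disks):
                j = rng.integers(land_rows.size)
                r0, c0 = land_rows[j], land_cols[j]
                rad = rng.uniform(*radius_frac) * base
                mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
            # soften disk edges into an organic outline
            smooth = ndimage.gaussian_filter(mask.astype(float), sigma=1.5)
            rng_mask = (smooth > 0.35) & land
            if rng_mask.any():
                ranges.append(rng_mask)
                break
        else:
            raise RuntimeError("could not place a non-empty species range")
    return ranges


def generate_regions(rng: np.random.Generator, grid: GridSpec, n_regions: int) -> np.ndarray:
    """Contiguous integer-coded zones: nearest-seed (Voronoi) partition in
    grid coordinates."""
    seeds_r = rng.uniform(0, grid.n_rows, n_regions)
    seeds_c = rng.uniform(0, grid.n_cols, n_regions)
    rr, cc = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    d2 = (rr[..., None] - seeds_r) ** 2 + (cc[..., None] - seeds_c) ** 2
    return np.argmax(-d2, axis=-1).astype(np.int32)


def _covariate_specs(cov_config: dict) -> list[CovariateSpec]:
    """Model-side transform spec: densities are log1p'd, fractions are not."""
    specs = []
    for name, pars in cov_config.items():
        transform = "log1p" if pars.get("kind") == "density" else "none"
        units = {"density": "per km^2", "fraction": "%"}[pars.get("kind", "density")]
        specs.append(CovariateSpec(name=name, units=units, transform=transform))
    return specs


def realize_contraction(
    historic: list[np.ndarray],
    covariates: dict,
    land: np.ndarray,
    fine_grid: GridSpec,
    coarse_factor: int,
    config: SimConfig,
    rng_intercepts: np.random.Generator,
    rng_spatial: np.random.Generator,
    rng_bernoulli: np.random.Generator,
    traits: list[SpeciesTraits] | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame, np.ndarray]:
    """Draw per-(species, coarse cell) contraction from the logistic truth.

    Coarse membership and covariate aggregation reuse the pipeline's own
    observation builder (with current = historic), so the realized
    indicators land exactly on the observations the estimator will later
    rebuild.  A contracted coarse cell has *all* of its fine historic
    cells removed from the current range; a persisting cell keeps them
    all.

    Returns (current rasters, latent observation table with true
    probabilities, drawn species intercepts).
    """
    params = ModelParams(
        coarse_membership_threshold=config.membership_threshold,
        contraction_threshold=config.contraction_threshold,
    )
    if traits is None:
        traits = [SpeciesTraits(name=f"species_{i:02d}") for i in range(len(historic))]
    tmp_pairs = [
        SpeciesRangePair(traits=t, historic=h, current=h, grid=fine_grid)
        for t, h in zip(traits, historic)
    ]
    # observations the estimator will see (membership threshold applied)
    table, coarse = build_observation_table(
        tmp_pairs, covariates, land, fine_grid, coarse_factor, params=params
    )
    specs = _covariate_specs(config.covariates)
    table = transform_standardize(table, specs)
    # contraction is also drawn for fringe coarse cells below the membership
    # threshold (any historic coverage at all) so the realized rasters carry
    # no undrawn remnants; z-scoring uses the member-table constants so the
    # true coefficients live on the scale the estimator will reconstruct
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full, _ = build_observation_table(
            tmp_pairs, covariates, land, fine_grid, coarse_factor,
            params=ModelParams(
                coarse_membership_threshold=1e-9,
                contraction_threshold=config.contraction_threshold,
            ),
        )
    for spec in specs:
        x = full[spec.name].to_numpy(dtype=float)
        if spec.transform == "log1p":
            x = np.log1p(x)
        full[spec.name + "_z"] = (x - spec.mean) / spec.sd

    b_s = rng_intercepts.normal(0.0, config.sigma_species, size=len(historic))
    spatial = (
        config.spatial_sd
        * _smooth_unit_field(rng_spatial, coarse, config.spatial_length_km)
        if config.spatial_sd > 0
        else np.zeros(coarse.shape)
    )

    eta = np.full(len(full), config.beta0)
    for name, b in config.beta.items():
        eta += b * full[name + "_z"].to_numpy()
    eta += b_s[full["species_id"].to_numpy()]
    eta += spatial[full["row"].to_numpy(), full["col"].to_numpy()]
    p = expit(eta)
    y = (rng_bernoulli.random(len(full)) < p).astype(int)
    full = full.assign(eta_true=eta, p_true=p, y_true=y)

    member_keys = set(zip(table["species_id"], table["cell_id"]))
    is_member = np.fromiter(
        ((s, c) in member_keys for s, c in zip(full["species_id"], full["cell_id"])),
        dtype=bool,
        count=len(full),
    )
    latent = full.loc[
        is_member,
        ["species_id", "species", "cell_id", "row", "col", "lon", "lat",
         "eta_true", "p_true", "y_true"],
    ].rename(columns={"y_true": "y"}).reset_index(drop=True)

    current = []
    f = coarse_factor
    for sp_id, h in enumerate(historic):
        cur = h.copy()
        sub = full[(full["species_id"] == sp_id) & (full["y_true"] == 1)]
        for r, c in zip(sub["row"], sub["col"]):
            cur[r * f : (r + 1) * f, c * f : (c + 1) * f] = False
        current.append(cur)
    return current, latent, b_s


def _synthetic_traits(rng: np.random.Generator, n: int) -> list[SpeciesTraits]:
    return [
        SpeciesTraits(
            name=f"species_{i:02d}",
            family=_FAMILIES[i % len(_FAMILIES)],
            mass_kg=float(np.round(np.exp(rng.uniform(np.log(15), np.log(300))), 1)),
            iucn_status=_STATUSES[rng.integers(len(_STATUSES))],
            population_trend=_TRENDS[rng.integers(len(_TRENDS))],
        )
        for i in range(n)
    ]


def make_dataset(config: SimConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """End-to-end synthetic world: land, covariates, regions, species
    ranges and realized contraction, bit-reproducible given the seed."""
    config = config or SimConfig()
    grid = make_grid(config.resolution, config.extent)
    if grid.n_rows % config.coarse_factor or grid.n_cols % config.coarse_factor:
        raise ValueError("grid shape is not divisible by coarse_factor")

    streams = np.random.SeedSequence(seed).spawn(6)
    rng_land, rng_cov, rng_sp, rng_reg, rng_eff, rng_draw = (
        np.random.default_rng(s) for s in streams
    )

    land, elevation = generate_land(
        rng_land,
        grid,
        config.land_fraction,
        config.land_length_scale_km,
        config.elevation_relief_m,
    )
    covariates = {
        name: generate_covariate_field(
            rng_cov, grid, pars["kind"], config.cov_length_scale_km,
            **{k: v for k, v in pars.items() if k != "kind"},
        )
        for name, pars in config.covariates.items()
    }
    zones = generate_regions(rng_reg, grid, config.n_regions)
    historic = generate_species_historic(
        rng_sp,
        config.n_species,
        land,
        grid,
        config.species_n_disks,
        config.species_radius_frac,
    )
    traits = _synthetic_traits(rng_sp, config.n_species)
    rng_spatial = np.random.default_rng(streams[4].spawn(1)[0])
    current, latent, b_s = realize_contraction(
        historic,
        covariates,
        land,
        grid,
        config.coarse_factor,
        config,
        rng_intercepts=rng_eff,
        rng_spatial=rng_spatial,
        rng_bernoulli=rng_draw,
        traits=traits,
    )
    pairs = [
        SpeciesRangePair(traits=t, historic=h, current=c, grid=grid)
        for t, h, c in zip(traits, historic, current)
    ]
    for p in pairs:
        p.validate(land)
        if not p.current.any():
            warnings.warn(f"{p.traits.name}: fully extirpated in this realization")

    truth = SyntheticTruth(
        seed=seed,
        beta0=config.beta0,
        beta=dict(config.beta),
        sigma_species=config.sigma_species,
        species_intercepts=[float(b) for b in b_s],
        spatial_sd=config.spatial_sd,
        spatial_length_km=config.spatial_length_km,
        membership_threshold=config.membership_threshold,
        contraction_threshold=config.contraction_threshold,
        covariate_transforms={s.name: s.transform for s in _covariate_specs(config.covariates)},
    )
    return SyntheticDataset(
        fine_grid=grid,
        coarse_factor=config.coarse_factor,
        land=land,
        elevation=elevation,
        zones=zones,
        covariates=covariates,
        pairs=pairs,
        truth=truth,
        latent_obs=latent,
    )


def simulate_observation_table(
    seed: int,
    side: int = 18,
    n_species: int = 8,
    p_member: float = 0.6,
    beta=(0.2, 0.25, 0.55),
    beta0: float = -0.3,
    sigma_species: float = 1.0,
    cell_spacing_deg: float = 0.9,
    spatial_field=None,
) -> pd.DataFrame:
    """Directly simulate a model-ready observation table (no rasters).

    A ``side``×``side`` lattice of coarse cells (centroids ~100 km apart
    at the default spacing); each species occupies a random subset of
    cells; covariates ``x1..xk`` are iid standard normal and the binary
    response follows the logistic mixed model with Gaussian species
    intercepts.  ``spatial_field`` (a ``side``×``side`` array added to
    the logit) injects spatial structure; ``None`` leaves the response
    spatially independent — the null case for RAC calibration studies.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    rows, cols = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    lon = cols.ravel() * cell_spacing_deg
    lat = rows.ravel() * cell_spacing_deg
    cell_id = np.arange(lon.size)
    b_s = rng.normal(0.0, sigma_species, n_species)
    sf = np.zeros(side * side) if spatial_field is None else np.asarray(spatial_field).ravel()
    frames = []
    for s in range(n_species):
        sel = rng.random(lon.size) < p_member
        n = int(sel.sum())
        x = rng.standard_normal((n, beta.size))
        eta = beta0 + x @ beta + b_s[s] + sf[sel]
        y = (rng.random(n) < expit(eta)).astype(int)
        frame = {
            "species": s,
            "cell_id": cell_id[sel],
            "lon": lon[sel],
            "lat": lat[sel],
            "y": y,
        }
        for k in range(beta.size):
            frame[f"x{k + 1}"] = x[:, k]
        frames.append(pd.DataFrame(frame))
    return pd.concat(frames, ignore_index=True)


def fixture_config() -> SimConfig:
    """Tiny (20×40 fine cells) configuration used by unit tests."""
    return SimConfig(
        resolution=1.0,
        extent=(-20.0, 20.0, -10.0, 10.0),
        coarse_factor=2,
        land_fraction=0.5,
        land_length_scale_km=400.0,
        n_species=3,
        species_n_disks=2,
        species_radius_frac=(0.2, 0.5),
        n_regions=3,
        cov_length_scale_km=400.0,
        spatial_sd=0.3,
        spatial_length_km=400.0,
    )
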