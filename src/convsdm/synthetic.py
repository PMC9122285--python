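"""Synthetic landscapes with known ground truth.

This module builds small artificial "worlds" for exercising the whole
convolutional SDM pipeline end to end: smooth environmental fields, raster
channels derived from them (pseudo-RGB, near-IR, categorical land cover,
elevation), species with parameterized Gaussian niches whose optima double as
a trait table, and an opportunistic occurrence sample biased by habitat
suitability and observation effort.

Two latent-field archetypes mimic real covariate structure: a deterministic
monotone "temperature" gradient and Gaussian-smoothed random fields
("moisture", "elevation"). A configurable subset of species are *context*
species: their niche responds to a neighborhood statistic (the local standard
deviation of elevation, i.e. terrain ruggedness) rather than to the elevation
point value, so their habitat is invisible to any model that only sees
point-wise environment — the property the convolutional model is meant to
exploit.

Everything is deterministic given the configuration and seed, and the full
ground truth (field values at each occurrence, species parameters) is
exported so downstream stages can be tested against it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .rasters import CATEGORICAL, CONTINUOUS, RasterLayer, read_raster, write_raster

__all__ = [
    "LatentField",
    "SyntheticSpecies",
    "SyntheticWorld",
    "generate_fields",
    "derive_channels",
    "local_std",
    "suitability",
    "suitability_raster",
    "make_species",
    "sample_occurrences",
    "generate_world",
    "write_world",
    "read_world",
    "roughness",
]

CONTEXT_STAT = "elevation_local_std"


@dataclass
class LatentField:
    """A smooth environmental field on the world grid, scaled to [0, 1]."""

    name: str
    grid: np.ndarray
    role: str  # "gradient" | "random" | "smooth"


@dataclass
class SyntheticSpecies:
    """A species with a product-Gaussian niche over named niche dimensions.

    ``niche_optima[d]`` and ``niche_breadths[d]`` give the response optimum μ
    and breadth σ on dimension ``d``. Context species carry the neighborhood
    statistic name (``elevation_local_std``) among their dimensions instead of
    the elevation point value.
    """

    species_id: int
    niche_optima: dict[str, float]
    niche_breadths: dict[str, float]
    context_flag: bool
    prevalence: float

    def __post_init__(self) -> None:
        for d, s in self.niche_breadths.items():
            if s <= 0:
                raise ValueError(f"niche breadth on {d!r} must be > 0, got {s}")
        if self.prevalence <= 0:
            raise ValueError("prevalence must be positive")


@dataclass
class SyntheticWorld:
    """A generated world: fields, raster channels, species, occurrences, truth."""

    extent: float
    resolution: float
    patch_px: int
    fields: list[LatentField]
    layers: list[RasterLayer]
    env_rasters: list[RasterLayer]
    species: list[SyntheticSpecies]
    occurrences: pd.DataFrame
    truth: pd.DataFrame
    config: dict = dc_field(default_factory=dict)
    context_stat_grid: np.ndarray | None = None
    skipped_species: int = 0

    @property
    def n_px(self) -> int:
        return int(round(self.extent / self.resolution))

    def trait_table(self) -> pd.DataFrame:
        """Species traits = the niche optima used for sampling (exact)."""
        rows = []
        for sp in self.species:
            row: dict = {
                "species_id": sp.species_id,
                "prevalence": sp.prevalence,
                "context_flag": sp.context_flag,
            }
            for d, mu in sp.niche_optima.items():
                row[f"trait_{d}"] = mu
            rows.append(row)
        return pd.DataFrame(rows).set_index("species_id")


def roughness(grid: np.ndarray) -> float:
    """Mean absolute difference between 4-neighbors — the smoothness statistic."""
    g = np.asarray(grid, dtype=float)
    dv = np.abs(np.diff(g, axis=0)).mean()
    dh = np.abs(np.diff(g, axis=1)).mean()
    return 0.5 * (dv + dh)


def _minmax(g: np.ndarray) -> np.ndarray:
    lo, hi = g.min(), g.max()
    if hi == lo:
        return np.zeros_like(g)
    return (g - lo) / (hi - lo)


def generate_fields(
    extent: float,
    resolution: float,
    seed: int,
    moisture_kernel: float = 50.0,
    elevation_kernel: float = 120.0,
    roughness_kernel: float = 60.0,
    fine_kernel: float = 8.0,
    roughness_amp: float = 0.25,
) -> list[LatentField]:
    """Generate the three latent environmental fields, each scaled to [0, 1].

    * ``temperature`` — a deterministic gradient, strictly monotone along the
      x axis (column-wise means increase), with a smooth sinusoidal cross-term
      so it is genuinely two-dimensional.
    * ``moisture`` — seeded white noise convolved with a Gaussian kernel of
      width ``moisture_kernel`` (meters).
    * ``elevation`` — a two-scale terrain surface: a smooth macro-relief
      (kernel ``elevation_kernel``) plus fine-scale texture (kernel
      ``fine_kernel``) whose amplitude is modulated by an independent smooth
      "ruggedness" field (kernel ``roughness_kernel``). Real terrain is rough
      where there are mountains and smooth on plains; this makes the local
      standard deviation of elevation a genuine landscape property, visible
      in a patch but not in the point value.

    Deterministic given the seed. Kernel widths are Gaussian sigmas in meters.
    """
    if extent <= 0 or resolution <= 0:
        raise ValueError(
            f"extent and resolution must be positive, got {extent}, {resolution}"
        )
    n = int(round(extent / resolution))
    if n < 2:
        raise ValueError("world must be at least 2 pixels across")
    rng = np.random.default_rng(seed)

    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    u, v = xx / (n - 1), yy / (n - 1)
    temperature = _minmax(u + 0.1 * np.sin(2 * np.pi * v))

    def smooth_noise(sigma_m: float, standardize: bool = False) -> np.ndarray:
        sigma_px = max(sigma_m / resolution, 1.0)
        g = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma_px, mode="reflect")
        if standardize:
            return (g - g.mean()) / (g.std() or 1.0)
        return _minmax(g)

    moisture = smooth_noise(moisture_kernel)
    macro = smooth_noise(elevation_kernel)
    ruggedness = smooth_noise(roughness_kernel)
    fine = smooth_noise(fine_kernel, standardize=True)
    elevation = _minmax(macro + roughness_amp * ruggedness * fine)
    return [
        LatentField("temperature", temperature, "gradient"),
        LatentField("moisture", moisture, "random"),
        LatentField("elevation", elevation, "smooth"),
    ]


def _palette(class_count: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed per-class base colors and near-IR reflectances (independent of seed)."""
    prng = np.random.default_rng(12345)
    colors = 0.15 + 0.7 * prng.random((class_count, 3))
    reflect = 0.1 + 0.8 * prng.random(class_count)
    return colors, reflect


def derive_channels(
    fields: list[LatentField],
    class_count: int,
    seed: int,
    extent: float,
    resolution: float,
    noise_amp: float = 0.02,
) -> list[RasterLayer]:
    """Derive the six raster channels (R, G, B, near-IR, land cover, elevation).

    Land cover is the quantile band of a temperature/moisture mixture
    (categorical, classes ``0..class_count-1``). Pseudo-RGB is a per-class base
    color modulated continuously by the fields plus seeded Gaussian noise of
    amplitude ``noise_amp``; near-IR is an affine mix of moisture and the
    class base reflectance; the elevation channel is the elevation field.
    """
    if class_count < 2:
        raise ValueError(f"class_count must be >= 2, got {class_count}")
    by_name = {f.name: f.grid for f in fields}
    temp, moist, elev = by_name["temperature"], by_name["moisture"], by_name["elevation"]
    rng = np.random.default_rng(seed)

    mixture = 0.6 * temp + 0.4 * moist
    qs = np.quantile(mixture, np.linspace(0, 1, class_count + 1)[1:-1])
    land = np.digitize(mixture, qs).astype(np.int16)

    colors, reflect = _palette(class_count)
    mods = [0.25 * (temp - 0.5), 0.25 * (moist - 0.5), 0.25 * (elev - 0.5)]
    origin = (0.0, extent)
    layers = []
    for c, name in enumerate(["red", "green", "blue"]):
        band = colors[land, c] + mods[c]
        if noise_amp > 0:
            band = band + noise_amp * rng.standard_normal(band.shape)
        layers.append(
            RasterLayer(name, np.clip(band, 0, 1), resolution, origin, CONTINUOUS)
        )
    nir = np.clip(0.6 * moist + 0.4 * reflect[land], 0, 1)
    layers.append(RasterLayer("near_ir", nir, resolution, origin, CONTINUOUS))
    layers.append(RasterLayer("land_cover", land, resolution, origin, CATEGORICAL))
    layers.append(RasterLayer("elevation", elev, resolution, origin, CONTINUOUS))
    return layers


def local_std(grid: np.ndarray, radius_px: int) -> np.ndarray:
    """Neighborhood standard deviation in a (2r+1)-pixel square window."""
    size = 2 * radius_px + 1
    m = ndimage.uniform_filter(grid, size, mode="reflect")
    m2 = ndimage.uniform_filter(grid * grid, size, mode="reflect")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def suitability(
    species: SyntheticSpecies,
    field_values: dict[str, float],
    neighborhood_stats: dict[str, float] | None = None,
) -> float:
    """Habitat suitability in (0, 1]: product of Gaussian responses.

    ``prod_d exp(-(v_d - mu_d)^2 / (2 sigma_d^2))`` over the species' niche
    dimensions. Context species look one dimension up in
    ``neighborhood_stats`` (the neighborhood statistic) instead of the point
    values. Equals 1 exactly at the optimum on every dimension.
    """
    values = dict(field_values)
    if neighborhood_stats:
        values.update(neighborhood_stats)
    s = 1.0
    for d, mu in species.niche_optima.items():
        v = values[d]
        sig = species.niche_breadths[d]
        s *= float(np.exp(-((v - mu) ** 2) / (2.0 * sig**2)))
    return s


def suitability_raster(
    species: SyntheticSpecies, value_grids: dict[str, np.ndarray]
) -> np.ndarray:
    """Vectorized :func:`suitability` over the whole world grid."""
    out = None
    for d, mu in species.niche_optima.items():
        sig = species.niche_breadths[d]
        term = np.exp(-((value_grids[d] - mu) ** 2) / (2.0 * sig**2))
        out = term if out is None else out * term
    assert out is not None
    return out


def make_species(
    n_species: int,
    n_context: int,
    seed: int,
    context_stat_grid: np.ndarray,
) -> list[SyntheticSpecies]:
    """Draw species niches. The first ``n_context`` species are context species.

    Optima are uniform within the central part of each field's [0, 1] range
    (so they lie strictly inside it); breadths are uniform in [0.08, 0.18].
    Context species swap the elevation dimension for the local elevation
    standard deviation, with optima inside the 10–90% quantile range of that
    statistic. Prevalence is log-normal (sigma = 0.6), mimicking the
    right-skewed abundance of opportunistic records.
    """
    if n_context > n_species:
        raise ValueError("n_context cannot exceed n_species")
    rng = np.random.default_rng(seed)
    q10, q90 = np.quantile(context_stat_grid, [0.10, 0.90])
    stat_scale = max(q90 - q10, 1e-9)
    species = []
    for sid in range(n_species):
        is_context = sid < n_context
        optima = {
            "temperature": rng.uniform(0.15, 0.85),
            "moisture": rng.uniform(0.15, 0.85),
        }
        # context species are habitat-structure specialists but climate
        # generalists: their discriminating axis is the neighborhood statistic
        point_lo, point_hi = (0.2, 0.35) if is_context else (0.08, 0.18)
        breadths = {
            "temperature": rng.uniform(point_lo, point_hi),
            "moisture": rng.uniform(point_lo, point_hi),
        }
        if is_context:
            optima[CONTEXT_STAT] = rng.uniform(q10, q90)
            breadths[CONTEXT_STAT] = rng.uniform(0.12, 0.22) * stat_scale
        else:
            optima["elevation"] = rng.uniform(0.15, 0.85)
            breadths["elevation"] = rng.uniform(0.08, 0.18)
        prevalence = float(rng.lognormal(0.0, 0.6))
        species.append(SyntheticSpecies(sid, optima, breadths, is_context, prevalence))
    return species


def _value_grids(world_fields: list[LatentField], stat_grid: np.ndarray) -> dict[str, np.ndarray]:
    grids = {f.name: f.grid for f in world_fields}
    grids[CONTEXT_STAT] = stat_grid
    return grids


def sample_occurrences(
    fields: list[LatentField],
    species: list[SyntheticSpecies],
    context_stat_grid: np.ndarray,
    extent: float,
    resolution: float,
    patch_px: int,
    n_total: int,
    seed: int,
    effort_field: np.ndarray | None = None,
) -> tuple[pd.DataFrame, int]:
    """Species-then-location occurrence sampling with known truth.

    Species are drawn with probability proportional to prevalence; each
    occurrence location is drawn among valid pixels with probability
    proportional to suitability × effort. Coordinates are snapped to pixel
    centers, and a margin of half a patch width around the border is excluded
    so patches never cross the world boundary. Returns the occurrence table
    and the count of species skipped for having all-zero sampling intensity.
    """
    n = int(round(extent / resolution))
    # strict symmetric margin: occurrence pixel centers stay more than half a
    # patch width away from every border, so patches never cross it
    half = patch_px // 2
    lo, hi = half, n - half - 1  # inclusive valid pixel-index range
    if hi < lo:
        raise ValueError("patch size too large for the world extent")
    grids = _value_grids(fields, context_stat_grid)
    rng = np.random.default_rng(seed)

    if effort_field is None:
        effort = np.ones((n, n))
    else:
        effort = np.asarray(effort_field, dtype=float)
        if effort.shape != (n, n):
            raise ValueError("effort field shape must match the world grid")

    prev = np.array([sp.prevalence for sp in species], dtype=float)
    counts = rng.multinomial(n_total, prev / prev.sum()) if n_total > 0 else np.zeros(len(species), int)

    sub = np.s_[lo : hi + 1, lo : hi + 1]
    nv = hi - lo + 1
    records = []
    skipped = 0
    for sp, cnt in zip(species, counts):
        if cnt == 0:
            continue
        intensity = (suitability_raster(sp, grids)[sub] * effort[sub]).ravel()
        total = intensity.sum()
        if total <= 0:
            skipped += 1
            warnings.warn(
                f"species {sp.species_id} has all-zero sampling intensity; skipped"
            )
            continue
        idx = rng.choice(nv * nv, size=cnt, p=intensity / total, replace=True)
        rows, cols = np.unravel_index(idx, (nv, nv))
        rows, cols = rows + lo, cols + lo
        x = (cols + 0.5) * resolution
        y = extent - (rows + 0.5) * resolution  # row 0 is northmost
        for r, c, xi, yi in zip(rows, cols, x, y):
            records.append((sp.species_id, xi, yi, int(r), int(c)))

    df = pd.DataFrame(records, columns=["species_id", "x", "y", "_row", "_col"])
    df.insert(0, "occ_id", np.arange(len(df)))
    df["split"] = "train"
    return df, skipped


def generate_world(
    extent: float = 2000.0,
    resolution: float = 2.0,
    n_species: int = 20,
    n_context: int = 8,
    class_count: int = 5,
    patch_px: int = 32,
    n_occurrences: int = 4500,
    seed: int = 0,
    context_radius_px: int = 8,
    env_resolution: float = 50.0,
    effort_field: np.ndarray | None = None,
    moisture_kernel: float = 50.0,
    elevation_kernel: float = 120.0,
    noise_amp: float = 0.02,
) -> SyntheticWorld:
    """Build a complete synthetic world (the pipeline's default study system).

    Defaults give a 2 x 2 km landscape at 2 m/px with 20 species (8 of them
    context species) and 4,500 occurrences sampled over 32 x 32 px patches.
    Sub-seeds for fields, channels, species and sampling are derived from
    ``seed`` so the whole world is reproducible from one integer.
    """
    ss = np.random.SeedSequence(seed)
    s_fields, s_chan, s_species, s_occ = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )
    fields = generate_fields(extent, resolution, s_fields, moisture_kernel, elevation_kernel)
    layers = derive_channels(fields, class_count, s_chan, extent, resolution, noise_amp)
    elev = next(f.grid for f in fields if f.name == "elevation")
    stat_grid = local_std(elev, context_radius_px)
    species = make_species(n_species, n_context, s_species, stat_grid)
    occ, skipped = sample_occurrences(
        fields, species, stat_grid, extent, resolution, patch_px,
        n_occurrences, s_occ, effort_field,
    )

    grids = _value_grids(fields, stat_grid)
    truth = occ[["occ_id", "species_id", "x", "y"]].copy()
    r, c = occ["_row"].to_numpy(), occ["_col"].to_numpy()
    for name in ["temperature", "moisture", "elevation", CONTEXT_STAT]:
        truth[name] = grids[name][r, c]
    sp_by_id = {sp.species_id: sp for sp in species}
    truth["true_suitability"] = [
        suitability(sp_by_id[sid], {k: truth[k].iat[i] for k in grids})
        for i, sid in enumerate(occ["species_id"])
    ]

    env_rasters = [
        RasterLayer(f.name, f.grid, resolution, (0.0, extent), CONTINUOUS)
        for f in fields
    ]
    from .rasters import resample_layer

    env_rasters = [resample_layer(lyr, env_resolution) for lyr in env_rasters]

    config = dict(
        extent=extent, resolution=resolution, n_species=n_species,
        n_context=n_context, class_count=class_count, patch_px=patch_px,
        n_occurrences=n_occurrences, seed=seed, context_radius_px=context_radius_px,
        env_resolution=env_resolution, moisture_kernel=moisture_kernel,
        elevation_kernel=elevation_kernel, noise_amp=noise_amp,
    )
    occ = occ.drop(columns=["_row", "_col"])
    return SyntheticWorld(
        extent, resolution, patch_px, fields, layers, env_rasters, species,
        occ, truth, config, stat_grid, skipped,
    )


def roadside_effort(n: int, stripe_every: int = 100, stripe_width: int = 3, boost: float = 10.0) -> np.ndarray:
    """Optional citizen-science-style effort field: uniform plus boosted 'road' stripes."""
    effort = np.ones((n, n))
    for start in range(0, n, stripe_every):
        effort[:, start : start + stripe_width] *= boost
    return effort


def write_world(world: SyntheticWorld, directory) -> None:
    """Export the world: TIFF channels and environment rasters, CSV tables, JSON config."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for lyr in world.layers:
        write_raster(d / f"layer_{lyr.name}.tif", lyr)
    for lyr in world.env_rasters:
        write_raster(d / f"env_{lyr.name}.tif", lyr)
    world.occurrences.to_csv(d / "occurrences.csv", index=False)
    world.truth.to_csv(d / "truth.csv", index=False)
    world.trait_table().to_csv(d / "traits.csv")
    rows = []
    for sp in world.species:
        row = {"species_id": sp.species_id, "context_flag": sp.context_flag,
               "prevalence": sp.prevalence}
        for dim, mu in sp.niche_optima.items():
            row[f"mu_{dim}"] = mu
            row[f"sigma_{dim}"] = sp.niche_breadths[dim]
        rows.append(row)
    pd.DataFrame(rows).to_csv(d / "species.csv", index=False)
    (d / "config.json").write_text(json.dumps(world.config, indent=2))


def read_world_tables(directory) -> dict[str, pd.DataFrame]:
    """Read back the CSV ground-truth tables written by :func:`write_world`."""
    from pathlib import Path

    d = Path(directory)
    return {
        "occurrences": pd.read_csv(d / "occurrences.csv"),
        "truth": pd.read_csv(d / "truth.csv"),
        "traits": pd.read_csv(d / "traits.csv"),
        "species": pd.read_csv(d / "species.csv"),
    }


def read_world(directory) -> dict:
    """Read layers, environment rasters and tables from an exported world."""
    from pathlib import Path

    d = Path(directory)
    out: dict = read_world_tables(d)
    out["layers"] = [read_raster(p) for p in sorted(d.glob("layer_*.tif"))]
    out["env_rasters"] = [read_raster(p) for p in sorted(d.glob("env_*.tif"))]
    out["config"] = json.loads((d / "config.json").read_text())
    return out
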