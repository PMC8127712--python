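"""Synthetic landscapes, sampling sites and allele frequencies.

The generator emulates the study system the pipeline is designed for: a
tropical landscape with spatially autocorrelated environmental layers, a
modest number of sampled populations spanning the dominant gradient, and
a SNP panel that mixes environment-driven loci (logistic cline on one
driver predictor, by default minimum temperature of the coldest month)
with neutral loci.  The future scenario warms the driver layer by a
spatial delta ramping from 0 on the inland edge to ``warming_delta_max``
(default 2 °C) on the coastal edge.

Every quantity has a known ground truth (the :class:`TruthTable`), so
parameter-recovery of the downstream gradient-forest model is testable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .gea import AlleleFreqTable
from .grids import EnvStack, GridSpec, read_geotiff, write_geotiff

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "generate_env_stack",
    "place_sites",
    "simulate_allele_frequencies",
    "generate_bundle",
    "write_bundle",
    "read_bundle",
]

#: default layer value ranges, in the units of each predictor
_DEFAULT_RANGES = {
    "tmin": (14.0, 24.0),       # °C, minimum temperature of the coldest month
    "precip": (1200.0, 3200.0),  # mm, annual precipitation
    "seasonality": (35.0, 95.0),  # CV of monthly precipitation
    "cloud": (45.0, 90.0),       # % mean cloud cover
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the study conditions."""

    grid_rows: int = 60
    grid_cols: int = 60
    cell_size: float = 0.01  # degrees (~1.1 km)
    n_layers: int = 4
    autocorr_length: float = 6.0  # cells
    n_sites: int = 15
    n_snps: int = 500
    n_adaptive: int = 50
    driver_layer: str = "tmin"
    slope_b: float = 8.0  # logistic slope per env-unit
    intercept_a: float = 0.0  # logit units, offset at the cline centre
    noise_sd: float = 0.02  # frequency units
    warming_delta_max: float = 2.0  # env-units
    maf_threshold: float = 0.02
    seed: int = 0
    x_origin: float = 9.0
    y_origin: float = 7.0
    layer_ranges: tuple[tuple[str, tuple[float, float]], ...] = tuple(
        _DEFAULT_RANGES.items()
    )

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not 0 < self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must be in (0, 0.5)")
        if self.n_adaptive > self.n_snps:
            raise ValueError("n_adaptive must not exceed n_snps")
        if self.driver_layer not in self.layer_names:
            raise ValueError(
                f"driver_layer {self.driver_layer!r} is not among layers {self.layer_names}"
            )

    @property
    def layer_names(self) -> list[str]:
        names = [n for n, _ in self.layer_ranges]
        if self.n_layers <= len(names):
            return names[: self.n_layers]
        return names + [f"env{i}" for i in range(len(names), self.n_layers)]

    def range_of(self, layer: str) -> tuple[float, float]:
        for n, r in self.layer_ranges:
            if n == layer:
                return r
        return (0.0, 1.0)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            rows=self.grid_rows,
            cols=self.grid_cols,
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            cell_size=self.cell_size,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["layer_ranges"] = [[n, list(r)] for n, r in self.layer_ranges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "layer_ranges" in d:
            d["layer_ranges"] = tuple((n, tuple(r)) for n, r in d["layer_ranges"])
        return cls(**d)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian random field: white noise convolved with a Gaussian kernel."""
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    return noise


def _rescale(a: np.ndarray, lo: float, hi: float) -> np.ndarray:
    amin, amax = a.min(), a.max()
    if amax == amin:
        return np.full_like(a, (lo + hi) / 2)
    return lo + (a - amin) * (hi - lo) / (amax - amin)


def generate_env_stack(config: SyntheticConfig, seed: int | None = None) -> tuple[EnvStack, EnvStack]:
    """Generate the (current, future) environmental raster stacks.

    Each layer is a smoothed Gaussian random field blended with a
    deterministic spatial gradient (direction rotating per layer), then
    min–max rescaled to the layer's stated range.  The future stack is
    identical except that the driver layer gains a delta ramping
    linearly from 0 at the eastern edge to ``warming_delta_max`` at the
    western ("coastal") edge.
    """
    seed = config.seed if seed is None else seed
    grid = config.grid
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    rows, cols = grid.shape
    rr = np.linspace(0.0, 1.0, rows)[:, None] * np.ones((1, cols))
    cc = np.ones((rows, 1)) * np.linspace(0.0, 1.0, cols)[None, :]
    data = np.empty((config.n_layers, rows, cols))
    for i, name in enumerate(config.layer_names):
        field_part = _smooth_field(rng, grid.shape, config.autocorr_length)
        if field_part.std() > 0:
            field_part = (field_part - field_part.mean()) / field_part.std()
        # rotating deterministic gradient: W->E, N->S, and the two diagonals
        ramp = [cc, rr, 0.5 * (rr + cc), 0.5 * (rr + (1 - cc))][i % 4]
        combined = 0.55 * field_part + 0.45 * (ramp - 0.5) * 4.0
        lo, hi = config.range_of(name)
        data[i] = _rescale(combined, lo, hi)
    current = EnvStack(grid, config.layer_names, data)

    future = current.copy()
    d = config.driver_layer
    if cols > 1:
        delta = config.warming_delta_max * (1.0 - np.arange(cols) / (cols - 1))
        delta = np.broadcast_to(delta, grid.shape)
    else:
        delta = np.full(grid.shape, config.warming_delta_max)
    future.data[future.layer_names.index(d)] = future.layer(d) + delta
    return current, future


def place_sites(
    env_stack: EnvStack, n_sites: int = 15, seed: int = 0, driver_layer: str = "tmin"
) -> pd.DataFrame:
    """Place sampling sites at distinct cell centres, stratified across
    the driver-layer gradient (equal-count quantile bins, one site drawn
    per bin) so the environmental range is spanned.

    Returns a site table with columns site_id, lon, lat, row, col,
    habitat.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    grid = env_stack.grid
    valid = np.flatnonzero(env_stack.mask.ravel())
    if n_sites > len(valid):
        raise ValueError(f"n_sites={n_sites} exceeds the {len(valid)} available cells")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    driver = env_stack.layer(driver_layer).ravel()[valid]
    order = valid[np.argsort(driver, kind="stable")]
    bins = np.array_split(order, n_sites)
    chosen = np.array([b[rng.integers(len(b))] for b in bins])
    rows_idx, cols_idx = np.unravel_index(chosen, grid.shape)
    lon = grid.x_origin + (cols_idx + 0.5) * grid.cell_size
    lat = grid.y_origin - (rows_idx + 0.5) * grid.cell_size
    dvals = env_stack.layer(driver_layer)[rows_idx, cols_idx]
    q1, q2 = np.quantile(env_stack.layer(driver_layer)[env_stack.mask], [1 / 3, 2 / 3])
    habitat = np.where(dvals < q1, "montane", np.where(dvals < q2, "ecotone", "rainforest"))
    df = pd.DataFrame(
        {
            "site_id": [f"site{i:02d}" for i in range(n_sites)],
            "lon": lon,
            "lat": lat,
            "row": rows_idx,
            "col": cols_idx,
            "habitat": habitat,
        }
    )
    return df


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    env_current: EnvStack
    env_future: EnvStack
    sites: pd.DataFrame
    freqs: AlleleFreqTable
    truth: pd.DataFrame

    def env_at_sites(self, which: str = "current") -> pd.DataFrame:
        stack = self.env_current if which == "current" else self.env_future
        vals = stack.values_at(self.sites["lon"].to_numpy(), self.sites["lat"].to_numpy())
        return pd.DataFrame(vals, index=list(self.sites["site_id"]), columns=stack.layer_names)


def simulate_allele_frequencies(
    site_table: pd.DataFrame,
    env_stack: EnvStack,
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[AlleleFreqTable, pd.DataFrame]:
    """Simulate the sites × SNPs allele-frequency matrix.

    Adaptive SNP *j* follows a logistic cline on the driver value E at
    each site, ``p = clamp(logistic(a_j + b_j·E) + ε, 0, 1)`` with
    ``b_j = ±slope_b`` and the cline centre drawn inside the driver's
    observed range; neutral SNP *j* is ``clamp(p̄_j + ε, 0, 1)`` with
    ``p̄_j ~ U[0.01, 0.99]``.  ``ε ~ N(0, noise_sd)`` per site.

    Returns the frequency table and the ground-truth table.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    grid = env_stack.grid
    E = np.empty(len(site_table))
    for k, row in enumerate(site_table.itertuples(index=False)):
        try:
            r, c = grid.index_of(row.lon, row.lat)
        except ValueError:
            raise ValueError(f"site {row.site_id!r} lies outside the raster") from None
        if not env_stack.mask[r, c]:
            raise ValueError(f"site {row.site_id!r} falls on a nodata cell")
        E[k] = env_stack.layer(config.driver_layer)[r, c]

    n_sites, n_snps = len(site_table), config.n_snps
    n_adapt = config.n_adaptive
    # cline centres stay in the central 60% of the sampled gradient so each
    # cline is flanked by populations on both sides (identifiable at small n)
    lo, hi = np.quantile(E, [0.2, 0.8]) if n_sites > 1 else (E[0], E[0])
    freqs = np.empty((n_sites, n_snps))
    snp_ids = [f"snp{j:05d}" for j in range(n_snps)]
    is_adaptive = np.zeros(n_snps, dtype=bool)
    is_adaptive[:n_adapt] = True
    slopes = np.zeros(n_snps)
    intercepts = np.zeros(n_snps)
    for j in range(n_snps):
        if is_adaptive[j]:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            b = sign * config.slope_b
            center = rng.uniform(lo, hi)
            a = config.intercept_a - b * center
            p = special.expit(a + b * E)
            slopes[j] = b
            intercepts[j] = a
        else:
            p = np.full(n_sites, rng.uniform(0.01, 0.99))
        p = p + rng.normal(0.0, config.noise_sd, size=n_sites)
        freqs[:, j] = np.clip(p, 0.0, 1.0)

    table = AlleleFreqTable(
        site_ids=list(site_table["site_id"]),
        coordinates=site_table[["lon", "lat"]].to_numpy(),
        snp_ids=snp_ids,
        frequencies=freqs,
    )
    truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "is_adaptive": is_adaptive,
            "driver": np.where(is_adaptive, config.driver_layer, "none"),
            "slope": slopes,
            "intercept": intercepts,
        }
    )
    return table, truth


def generate_bundle(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticBundle:
    """Run the full generator: rasters, sites, frequencies, truth."""
    config = config or SyntheticConfig()
    if seed is not None and seed != config.seed:
        config = dataclasses.replace(config, seed=int(seed))
    cur, fut = generate_env_stack(config)
    sites = place_sites(cur, config.n_sites, config.seed, config.driver_layer)
    freqs, truth = simulate_allele_frequencies(sites, cur, config)
    return SyntheticBundle(config, cur, fut, sites, freqs, truth)


_FLOAT_FMT = "%.17g"


def write_bundle(bundle: SyntheticBundle, directory) -> dict[str, str]:
    """Write the bundle: one GeoTIFF per layer per time point, CSV site
    table, CSV frequency matrix, CSV truth table and a JSON manifest.

    Re-reading with :func:`read_bundle` reproduces the in-memory objects
    bit-for-bit for integers and to <= 1e-12 for floats.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for label, stack in (("current", bundle.env_current), ("future", bundle.env_future)):
        for name in stack.layer_names:
            fn = f"env_{label}_{name}.tif"
            write_geotiff(directory / fn, stack.layer(name), stack.grid, description=name)
            files[f"env_{label}_{name}"] = fn
    bundle.sites.to_csv(directory / "sites.csv", index=False, float_format=_FLOAT_FMT)
    files["sites"] = "sites.csv"
    bundle.freqs.to_frame().to_csv(directory / "frequencies.csv", float_format=_FLOAT_FMT)
    files["frequencies"] = "frequencies.csv"
    bundle.truth.to_csv(directory / "truth.csv", index=False, float_format=_FLOAT_FMT)
    files["truth"] = "truth.csv"
    manifest = {
        "seed": bundle.config.seed,
        "config": bundle.config.to_dict(),
        "files": files,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    files["manifest"] = "manifest.json"
    return files


def read_bundle(directory) -> SyntheticBundle:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    config = SyntheticConfig.from_dict(manifest["config"])
    stacks = {}
    for label in ("current", "future"):
        layers = []
        grid = None
        for name in config.layer_names:
            arr, grid, _ = read_geotiff(directory / manifest["files"][f"env_{label}_{name}"])
            layers.append(arr[0])
        stacks[label] = EnvStack(grid, config.layer_names, np.stack(layers))
    sites = pd.read_csv(directory / manifest["files"]["sites"], float_precision="round_trip")
    freq_df = pd.read_csv(
        directory / manifest["files"]["frequencies"], index_col=0, float_precision="round_trip"
    )
    freqs = AlleleFreqTable.from_frame(freq_df)
    truth = pd.read_csv(
        directory / manifest["files"]["truth"],
        float_precision="round_trip",
        dtype={"snp_id": str, "is_adaptive": bool, "driver": str, "slope": float, "intercept": float},
    )
    return SyntheticBundle(config, stacks["current"], stacks["future"], sites, freqs, truth)
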