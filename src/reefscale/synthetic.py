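"""Seeded generator of reef-like DEMs and synthetic coral cover layers.

A synthetic reefscape is the sum of a broad-scale relief (two orthogonal
sinusoids plus optional Gaussian bumps, wavelength much longer than the
wavelet smooth scale) and a fine-scale correlated Gaussian texture standing
in for biotic roughness, with an optional nodata margin.  Cover layers are
random disk-like colonies labeled with species codes drawn from the five
morphological groups.  Everything is reproducible from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point

from .dem_io import (
    AGRRA_GROUPS,
    CoralPolygonLayer,
    ElevationRaster,
    GridGeometry,
    GroupCodebook,
    default_codebook,
)

__all__ = ["SyntheticReefSpec", "SyntheticCoverSpec", "generate_reef_dem",
           "generate_cover_layer"]


@dataclass(frozen=True)
class SyntheticReefSpec:
    """Parameters of a two-scale synthetic reef surface."""

    n_rows: int = 500
    n_cols: int = 500
    pixel_size: float = 0.008           # meters
    base_depth: float = -10.0           # meters
    relief_amplitude: float = 0.3       # broad-scale relief half-height, m
    relief_wavelength: float = 1.2      # broad-scale wavelength, m
    roughness_sd: float = 0.02          # fine texture standard deviation, m
    roughness_corr_length: float = 0.02  # texture correlation length, m
    n_bumps: int = 0                    # optional Gaussian mounds
    bump_height: float = 0.2            # m
    bump_sigma: float = 0.3             # m
    nodata_margin: int = 0              # masked border, pixels
    seed: int = 0
    origin: tuple[float, float] = (500000.0, 2250000.0)
    crs_id: str = "EPSG:32616"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if min(self.relief_amplitude, self.roughness_sd,
               self.relief_wavelength, self.roughness_corr_length) < 0:
            raise ValueError("amplitudes and lengths must be >= 0")
        if self.nodata_margin < 0:
            raise ValueError("nodata_margin must be >= 0")
        if 2 * self.nodata_margin >= min(self.n_rows, self.n_cols):
            raise ValueError("nodata_margin swallows the whole grid")

    @property
    def grid(self) -> GridGeometry:
        return GridGeometry(self.n_rows, self.n_cols, self.pixel_size,
                            self.origin, self.crs_id)


@dataclass(frozen=True)
class SyntheticCoverSpec:
    """Parameters of a synthetic colony layer."""

    target_cover_fraction: float = 0.15
    group_mix: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    colony_radius_range: tuple[float, float] = (0.025, 0.25)  # meters
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_cover_fraction < 1.0:
            raise ValueError("target_cover_fraction must be in [0, 1)")
        if self.target_cover_fraction > 0.95:
            raise ValueError("cover targets above 0.95 are infeasible")
        if len(self.group_mix) != len(AGRRA_GROUPS):
            raise ValueError(f"group_mix needs {len(AGRRA_GROUPS)} weights")
        if not np.isclose(sum(self.group_mix), 1.0):
            raise ValueError("group_mix weights must sum to 1")
        rmin, rmax = self.colony_radius_range
        if rmin <= 0 or rmax < rmin:
            raise ValueError("colony radii must be positive and ordered")
        if rmin < 0.025:
            raise ValueError("minimum colony radius is 0.025 m "
                             "(5 cm minimum diameter)")


def _relief(spec: SyntheticReefSpec, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.meshgrid(
        np.arange(spec.n_rows, dtype=float) * spec.pixel_size,
        np.arange(spec.n_cols, dtype=float) * spec.pixel_size,
        indexing="ij",
    )
    if spec.relief_amplitude == 0 or spec.relief_wavelength == 0:
        relief = np.zeros((spec.n_rows, spec.n_cols))
    else:
        px, py = rng.uniform(0, 2 * np.pi, size=2)
        k = 2 * np.pi / spec.relief_wavelength
        relief = 0.5 * spec.relief_amplitude * (
            np.sin(k * xx + px) + np.sin(k * yy + py)
        )
    for _ in range(spec.n_bumps):
        cx = rng.uniform(0, spec.n_cols * spec.pixel_size)
        cy = rng.uniform(0, spec.n_rows * spec.pixel_size)
        relief += spec.bump_height * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * spec.bump_sigma ** 2)
        )
    return relief


def _texture(spec: SyntheticReefSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.roughness_sd == 0:
        return np.zeros((spec.n_rows, spec.n_cols))
    noise = rng.standard_normal((spec.n_rows, spec.n_cols))
    sigma_px = spec.roughness_corr_length / spec.pixel_size
    if sigma_px > 0:
        noise = ndimage.gaussian_filter(noise, sigma_px, mode="wrap")
    sd = noise.std()
    if sd == 0:
        return np.zeros_like(noise)
    return (noise - noise.mean()) / sd * spec.roughness_sd


def generate_reef_dem(spec: SyntheticReefSpec) -> ElevationRaster:
    """Synthesize a two-scale reef DEM; bit-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    values = spec.base_depth + _relief(spec, rng) + _texture(spec, rng)
    mask = np.zeros(values.shape, dtype=bool)
    m = spec.nodata_margin
    if m > 0:
        mask[:m, :] = mask[-m:, :] = True
        mask[:, :m] = mask[:, -m:] = True
    return ElevationRaster(
        values=values, nodata_mask=mask, pixel_size=spec.pixel_size,
        origin=spec.origin, crs_id=spec.crs_id,
    )


def generate_cover_layer(
    spec: SyntheticCoverSpec,
    grid: GridGeometry,
    seed: int | None = None,
    codebook: GroupCodebook | None = None,
    max_attempts: int = 100_000,
) -> CoralPolygonLayer:
    """Place random disk-like colonies until the rasterized cover fraction
    reaches the target.

    Species codes are drawn per colony from the codebook groups with the
    spec's mix weights.  The realized fraction slightly overshoots the
    target (the last colony is kept).
    """
    if codebook is None:
        codebook = default_codebook()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    layer = CoralPolygonLayer(records=[], crs_id=grid.crs_id)
    if spec.target_cover_fraction == 0:
        return layer

    species_by_group = {g: sorted(
        sp for sp, (grp, _) in codebook.mapping.items() if grp == g
    ) for g in AGRRA_GROUPS}
    for g, splist in species_by_group.items():
        if not splist:
            raise ValueError(f"codebook has no species for group {g!r}")

    xs, ys = grid.cell_centers()
    covered = np.zeros(grid.shape, dtype=bool)
    total = covered.size
    x0, x1 = xs[0], xs[-1]
    y0, y1 = ys[-1], ys[0]
    records: list[tuple[object, str]] = []
    for _ in range(max_attempts):
        frac = covered.sum() / total
        if frac >= spec.target_cover_fraction:
            break
        r = rng.uniform(*spec.colony_radius_range)
        cx = rng.uniform(x0, x1)
        cy = rng.uniform(y0, y1)
        group = AGRRA_GROUPS[rng.choice(len(AGRRA_GROUPS), p=spec.group_mix)]
        splist = species_by_group[group]
        sp = splist[int(rng.integers(len(splist)))]
        disk = Point(cx, cy).buffer(r, quad_segs=16)
        records.append((disk, sp))
        # incremental pixel-center rasterization of the new disk
        c_lo = int(np.searchsorted(xs, cx - r))
        c_hi = int(np.searchsorted(xs, cx + r, side="right"))
        r_lo = int(np.searchsorted(-ys, -(cy + r)))
        r_hi = int(np.searchsorted(-ys, -(cy - r), side="right"))
        if c_lo < c_hi and r_lo < r_hi:
            gx, gy = np.meshgrid(xs[c_lo:c_hi], ys[r_lo:r_hi])
            inside = ((gx - cx) ** 2 + (gy - cy) ** 2) <= r ** 2
            covered[r_lo:r_hi, c_lo:c_hi] |= inside
    else:
        raise RuntimeError(
            f"could not reach cover fraction {spec.target_cover_fraction} "
            f"in {max_attempts} colonies"
        )
    return CoralPolygonLayer(records=records, crs_id=grid.crs_id)
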