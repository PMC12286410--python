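"""Coral-cover rasterization and the DLC/DGC/cover stack.

Digitized colony polygons are burned onto the DEM grid with a
pixel-center-in-polygon rule, producing an integer cover raster (0 =
background) that forms the third layer of the complexity stack.  The stack
supports per-group extraction of paired DLC/DGC samples, cover-area
accounting, and a seeded rectangular crop used to standardize the analyzed
area between sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import shapely

from .dem_io import AGRRA_GROUPS, CoralPolygonLayer, GridGeometry, GroupCodebook
from .roughness import ComplexityRaster

logger = logging.getLogger(__name__)

__all__ = ["CoverRaster", "ComplexityStack", "rasterize_polygons",
           "filter_by_group", "cover_area", "crop_to_area"]


@dataclass
class CoverRaster:
    """Integer species-code grid co-registered with the complexity rasters."""

    codes: np.ndarray
    codebook: GroupCodebook
    grid: GridGeometry

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("cover codes must be integers")
        if self.codes.shape != self.grid.shape:
            raise ValueError("codes shape does not match grid")
        known = {rc for _, rc in self.codebook.mapping.values()}
        present = set(np.unique(self.codes).tolist()) - {0}
        unknown = present - known
        if unknown:
            raise ValueError(f"cover contains codes absent from codebook: "
                             f"{sorted(unknown)}")

    def group_mask(self, group_name: str) -> np.ndarray:
        if group_name == "all":
            return self.codes > 0
        codes = self.codebook.codes_for_group(group_name)
        return np.isin(self.codes, sorted(codes))


@dataclass
class ComplexityStack:
    """The three co-registered analysis layers: DLC, DGC and cover."""

    dlc: ComplexityRaster
    dgc: ComplexityRaster
    cover: CoverRaster

    def __post_init__(self) -> None:
        if self.dlc.layer != "DLC" or self.dgc.layer != "DGC":
            raise ValueError("stack layers must be tagged DLC and DGC")
        g = self.dlc.grid
        if not (g.same_geometry(self.dgc.grid) and g.same_geometry(self.cover.grid)):
            raise ValueError("stack layers are not co-registered")

    @property
    def grid(self) -> GridGeometry:
        return self.dlc.grid

    @property
    def valid_mask(self) -> np.ndarray:
        return ~(self.dlc.nodata_mask | self.dgc.nodata_mask)


def rasterize_polygons(layer: CoralPolygonLayer, codebook: GroupCodebook,
                       grid: GridGeometry) -> CoverRaster:
    """Burn coded colony polygons onto the grid.

    A pixel takes a polygon's raster code iff its center lies inside the
    polygon.  Overlapping polygons resolve later-record-wins, with a logged
    warning per overlap.  Unknown species codes raise, listing offenders.
    """
    if layer.crs_id != grid.crs_id:
        raise ValueError(
            f"polygon CRS {layer.crs_id!r} differs from grid CRS {grid.crs_id!r}"
        )
    unknown = sorted(layer.species_codes() - set(codebook.mapping))
    if unknown:
        raise ValueError(f"species codes missing from codebook: {unknown}")
    codes = np.zeros(grid.shape, dtype=np.int32)
    xs, ys = grid.cell_centers()
    for geom, sp in layer.records:
        rc = codebook.raster_code(sp)
        minx, miny, maxx, maxy = geom.bounds
        c0 = int(np.searchsorted(xs, minx, side="left"))
        c1 = int(np.searchsorted(xs, maxx, side="right"))
        # ys decreases with row index
        r0 = int(np.searchsorted(-ys, -maxy, side="left"))
        r1 = int(np.searchsorted(-ys, -miny, side="right"))
        if c0 >= c1 or r0 >= r1:
            continue
        gx, gy = np.meshgrid(xs[c0:c1], ys[r0:r1])
        inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
        inside = inside.reshape(gy.shape)
        target = codes[r0:r1, c0:c1]
        n_overlap = int(np.count_nonzero(target[inside]))
        if n_overlap:
            logger.warning(
                "polygon %s overwrites %d already-coded pixels "
                "(later record wins)", sp, n_overlap,
            )
        target[inside] = rc
    return CoverRaster(codes=codes, codebook=codebook, grid=grid)


def filter_by_group(stack: ComplexityStack, group_name: str
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Paired DLC and DGC samples at the pixels covered by one group."""
    if group_name != "all" and group_name not in AGRRA_GROUPS:
        raise KeyError(f"unknown group {group_name!r}; "
                       f"expected one of {AGRRA_GROUPS} or 'all'")
    sel = stack.cover.group_mask(group_name) & stack.valid_mask
    return stack.dlc.values[sel], stack.dgc.values[sel]


def cover_area(cover: CoverRaster, group_name: str = "all") -> float:
    """Covered area in square meters: coded pixel count times pixel area."""
    if group_name != "all" and group_name not in AGRRA_GROUPS:
        raise KeyError(f"unknown group {group_name!r}")
    return float(np.count_nonzero(cover.group_mask(group_name))
                 * cover.grid.pixel_area)


def _window_valid_counts(valid: np.ndarray, h: int, w: int) -> np.ndarray:
    """Count of valid cells in every h-by-w window (2-D sliding sum)."""
    padded = np.zeros((valid.shape[0] + 1, valid.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(valid, axis=0), axis=1, out=padded[1:, 1:])
    return (padded[h:, w:] - padded[:-h, w:] - padded[h:, :-w]
            + padded[:-h, :-w])


def crop_to_area(stack: ComplexityStack, target_area: float, seed: int = 0
                 ) -> ComplexityStack:
    """Restrict the stack to a rectangular window of about ``target_area``.

    Searches aspect-preserving rectangular windows at every position and
    keeps the one whose *unmasked* area is closest to the target; exact
    ties are broken by a seeded random choice.  This is a standardization
    convention for between-site comparisons, not a reproduction of any
    field subsetting protocol.
    """
    grid = stack.grid
    valid = stack.valid_mask
    pixel_area = grid.pixel_area
    total_area = float(valid.sum() * pixel_area)
    if target_area > total_area + 1e-9:
        raise ValueError(
            f"target area {target_area} m^2 exceeds available unmasked area "
            f"{total_area:.6g} m^2"
        )
    if np.isclose(target_area, total_area):
        return stack
    target_cells = target_area / pixel_area
    n_rows, n_cols = grid.shape
    aspect = n_cols / n_rows
    scales = [
        (h, min(max(1, round(h * aspect)), n_cols)) for h in range(1, n_rows + 1)
    ]
    # pass 1: best achievable |count - target| and tie multiplicity per scale
    best_diff = np.inf
    tied: list[tuple[int, int, int]] = []  # (h, w, n_tied_positions)
    for h, w in scales:
        diff = np.abs(_window_valid_counts(valid, h, w) - target_cells)
        local_best = float(diff.min())
        if local_best < best_diff - 1e-9:
            best_diff = local_best
            tied = []
        if local_best <= best_diff + 1e-9:
            tied.append((h, w, int(np.count_nonzero(diff <= best_diff + 1e-9))))
    # pass 2: seeded pick among all tied windows without materializing them
    rng = np.random.default_rng(seed)
    pick = int(rng.integers(sum(n for _, _, n in tied)))
    r0 = c0 = h = w = 0
    for h, w, n in tied:
        if pick < n:
            diff = np.abs(_window_valid_counts(valid, h, w) - target_cells)
            rr, cc = np.nonzero(diff <= best_diff + 1e-9)
            r0, c0 = int(rr[pick]), int(cc[pick])
            break
        pick -= n
    rows = slice(r0, r0 + h)
    cols = slice(c0, c0 + w)
    new_origin = (
        grid.origin[0] + c0 * grid.pixel_size,
        grid.origin[1] - r0 * grid.pixel_size,
    )

    def _crop_complexity(layer: ComplexityRaster) -> ComplexityRaster:
        return replace(
            layer,
            values=layer.values[rows, cols].copy(),
            nodata_mask=layer.nodata_mask[rows, cols].copy(),
            origin=new_origin,
        )

    new_grid = GridGeometry(
        n_rows=h, n_cols=w, pixel_size=grid.pixel_size,
        origin=new_origin, crs_id=grid.crs_id,
    )
    new_cover = CoverRaster(
        codes=stack.cover.codes[rows, cols].copy(),
        codebook=stack.cover.codebook,
        grid=new_grid,
    )
    return ComplexityStack(
        dlc=_crop_complexity(stack.dlc),
        dgc=_crop_complexity(stack.dgc),
        cover=new_cover,
    )


def extraction_table(stack: ComplexityStack):
    """Per-pixel long-format table: group, pixel_row, pixel_col, dlc, dgc."""
    import pandas as pd

    rows = []
    for group in AGRRA_GROUPS:
        sel = stack.cover.group_mask(group) & stack.valid_mask
        rr, cc = np.nonzero(sel)
        if rr.size == 0:
            continue
        rows.append(pd.DataFrame({
            "group": group,
            "pixel_row": rr,
            "pixel_col": cc,
            "dlc": stack.dlc.values[rr, cc],
            "dgc": stack.dgc.values[rr, cc],
        }))
    if not rows:
        return pd.DataFrame(
            columns=["group", "pixel_row", "pixel_col", "dlc", "dgc"]
        )
    return pd.concat(rows, ignore_index=True)
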