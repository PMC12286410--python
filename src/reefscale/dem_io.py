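"""Raster and vector I/O plus grid bookkeeping.

Rasters are single-band GeoTIFFs with a linear-unit (projected) CRS;
reading and writing go through :mod:`tifffile` with the standard GeoTIFF
tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA).
Polygon layers are GeoJSON FeatureCollections read with :mod:`shapely`.

Grid convention: north-up, row 0 at the top, pixel-center sampling with
half-open cell extents.  The map coordinate of the center of pixel
``(row, col)`` is ``(origin_x + (col + 0.5) * pixel_size,
origin_y - (row + 0.5) * pixel_size)``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

AGRRA_GROUPS = (
    "Branching",
    "Meandroid",
    "Flower and Solitary",
    "Agariciid",
    "Mound and Boulder",
)

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113

_MODEL_TYPE_PROJECTED = 1
_MODEL_TYPE_GEOGRAPHIC = 2

DEFAULT_NODATA = -9999.0


class RasterFormatError(ValueError):
    """Raised for rasters this package cannot consume."""


@dataclass(frozen=True)
class GridGeometry:
    """Shape, resolution and placement of a raster grid."""

    n_rows: int
    n_cols: int
    pixel_size: float
    origin: tuple[float, float]  # map (x, y) of the top-left raster corner
    crs_id: str = "EPSG:32616"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area(self) -> float:
        return self.pixel_size ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (xs per column, ys per row) of pixel centers."""
        xs = self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        ys = self.origin[1] - (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return xs, ys

    def same_geometry(self, other: "GridGeometry", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pixel_size, other.pixel_size, rtol=rtol)
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-9)
        )


@dataclass
class ElevationRaster:
    """Georeferenced elevation grid in meters with a nodata mask."""

    values: np.ndarray
    nodata_mask: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "EPSG:32616"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        # Non-finite cells are never valid data.
        self.nodata_mask = self.nodata_mask | ~np.isfinite(self.values)

    @property
    def grid(self) -> GridGeometry:
        return GridGeometry(
            n_rows=self.values.shape[0],
            n_cols=self.values.shape[1],
            pixel_size=self.pixel_size,
            origin=self.origin,
            crs_id=self.crs_id,
        )

    @property
    def valid_values(self) -> np.ndarray:
        """1-D array of unmasked cell values."""
        return self.values[~self.nodata_mask]

    def masked_like(self, values: np.ndarray, extra_mask: np.ndarray | None = None
                    ) -> "ElevationRaster":
        """New raster on the same grid with given values and widened mask."""
        mask = self.nodata_mask.copy()
        if extra_mask is not None:
            mask |= extra_mask
        return replace(self, values=np.asarray(values, dtype=float),
                       nodata_mask=mask)


@dataclass(frozen=True)
class RowSegment:
    """A contiguous run of valid cells within one raster row."""

    row_index: int
    start_col: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.row_index < 0 or self.start_col < 0:
            raise ValueError("row_index and start_col must be >= 0")
        vals = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("segment values must be finite")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def cols(self) -> slice:
        return slice(self.start_col, self.start_col + len(self.values))


@dataclass
class CoralPolygonLayer:
    """Digitized coral colony outlines with species codes."""

    records: list[tuple[object, str]]  # (shapely geometry, species_code)
    crs_id: str = "EPSG:32616"

    def __post_init__(self) -> None:
        repaired = []
        for geom, code in self.records:
            if not code:
                raise ValueError("species_code must be non-empty")
            if not geom.is_valid:
                geom = make_valid(geom)
            repaired.append((geom, str(code)))
        self.records = repaired

    def __len__(self) -> int:
        return len(self.records)

    def species_codes(self) -> set[str]:
        return {code for _, code in self.records}


@dataclass
class GroupCodebook:
    """species_code -> (AGRRA morphological group, positive raster code)."""

    mapping: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        codes = [rc for _, rc in self.mapping.values()]
        if any(rc < 1 for rc in codes):
            raise ValueError("raster codes must be >= 1 (0 is background)")
        if len(set(codes)) != len(codes):
            raise ValueError("raster codes must be unique per species_code")
        for sp, (group, _) in self.mapping.items():
            if group not in AGRRA_GROUPS:
                raise ValueError(
                    f"unknown morphological group {group!r} for {sp!r}; "
                    f"expected one of {AGRRA_GROUPS}"
                )

    def raster_code(self, species_code: str) -> int:
        return self.mapping[species_code][1]

    def group_of(self, species_code: str) -> str:
        return self.mapping[species_code][0]

    def codes_for_group(self, group_name: str) -> set[int]:
        if group_name not in AGRRA_GROUPS:
            raise KeyError(f"unknown group {group_name!r}")
        return {rc for g, rc in self.mapping.values() if g == group_name}

    def groups(self) -> set[str]:
        return {g for g, _ in self.mapping.values()}

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupCodebook":
        mapping: dict[str, tuple[str, int]] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"species_code", "group_name", "raster_code"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(
                    f"codebook must have columns {sorted(required)}, "
                    f"got {reader.fieldnames}"
                )
            for row in reader:
                mapping[row["species_code"]] = (
                    row["group_name"],
                    int(row["raster_code"]),
                )
        return cls(mapping=mapping)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["species_code", "group_name", "raster_code"])
            for sp, (group, rc) in sorted(self.mapping.items()):
                writer.writerow([sp, group, rc])


def default_codebook() -> GroupCodebook:
    """A small built-in codebook with two species per AGRRA group."""
    species = [
        ("PPOR", "Branching"), ("APAL", "Branching"),
        ("PSTR", "Meandroid"), ("DLAB", "Meandroid"),
        ("EFAS", "Flower and Solitary"), ("SCUB", "Flower and Solitary"),
        ("AAGA", "Agariciid"), ("ATEN", "Agariciid"),
        ("OANN", "Mound and Boulder"), ("MCAV", "Mound and Boulder"),
    ]
    return GroupCodebook(
        mapping={sp: (grp, i + 1) for i, (sp, grp) in enumerate(species)}
    )


# ---------------------------------------------------------------------------
# GeoTIFF read / write
# ---------------------------------------------------------------------------

def _epsg_code(crs_id: str) -> int | None:
    if crs_id.upper().startswith("EPSG:"):
        try:
            return int(crs_id.split(":", 1)[1])
        except ValueError:
            return None
    return None


def _build_geokeys(crs_id: str) -> tuple[list[int], str]:
    """Minimal projected-CRS GeoKeyDirectory plus ascii citation."""
    ascii_params = crs_id + "|"
    keys = [
        (1024, 0, 1, _MODEL_TYPE_PROJECTED),  # GTModelType
        (1025, 0, 1, 1),                       # GTRasterType = PixelIsArea
        (1026, _TAG_GEO_ASCII_PARAMS, len(ascii_params), 0),  # citation
    ]
    code = _epsg_code(crs_id)
    if code is not None:
        keys.append((3072, 0, 1, code))        # ProjectedCSType
    directory = [1, 1, 0, len(keys)]
    for entry in sorted(keys):
        directory.extend(entry)
    return directory, ascii_params


def write_raster(raster, path: str | Path, nodata: float = DEFAULT_NODATA) -> None:
    """Write an elevation or complexity raster as a single-band GeoTIFF.

    Masked cells are stored as the ``nodata`` sentinel and the sentinel is
    recorded in the GDAL_NODATA tag, so ``read_dem`` restores the mask.
    """
    import tifffile

    values = np.asarray(raster.values, dtype=np.float64)
    mask = np.asarray(raster.nodata_mask, dtype=bool)
    if np.any(values[~mask] == nodata):
        raise ValueError(
            f"unmasked cell equals the nodata sentinel {nodata}; "
            "choose a different sentinel"
        )
    out = values.copy()
    out[mask] = nodata
    geodir, ascii_params = _build_geokeys(raster.crs_id)
    px = float(raster.pixel_size)
    ox, oy = raster.origin
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(ox), float(oy), 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geodir), tuple(geodir)),
        (_TAG_GEO_ASCII_PARAMS, "s", len(ascii_params), ascii_params),
        (_TAG_GDAL_NODATA, "s", -1, str(nodata)),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


def read_dem(path: str | Path) -> ElevationRaster:
    """Read a single-band projected GeoTIFF as an :class:`ElevationRaster`.

    The GDAL_NODATA sentinel and any non-finite cells are masked.  Rasters
    in a geographic (degree-unit) CRS, with rotated geotransforms, or with
    pixels non-square beyond 1% are rejected.
    """
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such raster: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = {t.code: t.value for t in page.tags.values()}
    except (tifffile.TiffFileError, ValueError) as exc:
        raise RasterFormatError(f"unreadable GeoTIFF {path}: {exc}") from exc
    values = np.asarray(values, dtype=float)
    if values.ndim == 3 and values.shape[0] == 1:
        values = values[0]
    if values.ndim != 2:
        raise RasterFormatError(
            f"{path}: expected a single-band raster, got shape {values.shape}"
        )

    crs_id, model_type = _parse_geokeys(tags)
    if model_type == _MODEL_TYPE_GEOGRAPHIC:
        raise RasterFormatError(
            f"{path}: geographic (degree-unit) CRS; a projected CRS with "
            "linear units (meters) is required"
        )

    scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
    if scale is None:
        raise RasterFormatError(f"{path}: missing ModelPixelScale geotransform")
    sx, sy = float(scale[0]), float(scale[1])
    if sx <= 0 or sy <= 0:
        raise RasterFormatError(f"{path}: non-positive pixel scale {scale[:2]}")
    if abs(sx - sy) > 0.01 * max(sx, sy):
        raise RasterFormatError(
            f"{path}: non-square pixels ({sx} x {sy} m) beyond 1% tolerance"
        )
    tiepoint = tags.get(_TAG_MODEL_TIEPOINT, (0, 0, 0, 0.0, 0.0, 0.0))
    # Tiepoint maps raster (i, j) to map (x, y); shift back to corner (0, 0).
    i, j = float(tiepoint[0]), float(tiepoint[1])
    origin = (float(tiepoint[3]) - i * sx, float(tiepoint[4]) + j * sy)

    mask = ~np.isfinite(values)
    nodata_tag = tags.get(_TAG_GDAL_NODATA)
    if nodata_tag is not None:
        sentinel = float(str(nodata_tag).strip().strip("\x00"))
        if np.isfinite(sentinel):
            mask |= values == sentinel

    return ElevationRaster(
        values=values,
        nodata_mask=mask,
        pixel_size=(sx + sy) / 2.0,
        origin=origin,
        crs_id=crs_id,
    )


def _parse_geokeys(tags: dict) -> tuple[str, int | None]:
    directory = tags.get(_TAG_GEO_KEY_DIRECTORY)
    ascii_params = tags.get(_TAG_GEO_ASCII_PARAMS)
    model_type = None
    epsg = None
    if directory is not None:
        entries = list(directory)
        n_keys = entries[3]
        for k in range(n_keys):
            key_id, loc, _count, value = entries[4 + 4 * k: 8 + 4 * k]
            if key_id == 1024:
                model_type = value
            elif key_id == 3072 and loc == 0:
                epsg = value
            elif key_id == 2048 and loc == 0 and epsg is None:
                # geographic CRS code present without a projected one
                model_type = model_type or _MODEL_TYPE_GEOGRAPHIC
    if epsg is not None:
        crs_id = f"EPSG:{epsg}"
    elif ascii_params:
        crs_id = str(ascii_params).rstrip("|").split("|")[0]
    else:
        crs_id = "unknown"
    return crs_id, model_type


# ---------------------------------------------------------------------------
# GeoJSON polygon layers
# ---------------------------------------------------------------------------

def read_polygons(path: str | Path, species_field: str = "species_code"
                  ) -> CoralPolygonLayer:
    """Read a GeoJSON FeatureCollection of coded coral colony polygons."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    crs_id = doc.get("crs_id", "EPSG:32616")
    records = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        code = props.get(species_field)
        if not code:
            raise ValueError(
                f"{path}: feature missing {species_field!r} property"
            )
        records.append((shape(feat["geometry"]), str(code)))
    return CoralPolygonLayer(records=records, crs_id=crs_id)


def write_polygons(layer: CoralPolygonLayer, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"species_code": code},
        }
        for geom, code in layer.records
    ]
    doc = {"type": "FeatureCollection", "crs_id": layer.crs_id,
           "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Row segment extraction
# ---------------------------------------------------------------------------

def extract_row_segments(raster: ElevationRaster, min_length: int = 16
                         ) -> list[RowSegment]:
    """Maximal runs of consecutive valid cells per row, at least
    ``min_length`` pixels long.

    Shorter runs are skipped (counted in the log); a fully masked raster
    yields an empty list.  Segments are ordered by (row, start_col).
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    valid = ~raster.nodata_mask
    segments: list[RowSegment] = []
    n_skipped_runs = 0
    n_skipped_cells = 0
    for r in range(valid.shape[0]):
        row = valid[r]
        if not row.any():
            continue
        # Run boundaries from the padded difference of the validity mask.
        edges = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start >= min_length:
                segments.append(
                    RowSegment(
                        row_index=r,
                        start_col=int(start),
                        values=raster.values[r, start:stop],
                    )
                )
            else:
                n_skipped_runs += 1
                n_skipped_cells += int(stop - start)
    if n_skipped_runs:
        logger.info(
            "skipped %d runs (%d cells) shorter than %d pixels",
            n_skipped_runs, n_skipped_cells, min_length,
        )
    return segments


def count_short_run_cells(raster: ElevationRaster, min_length: int) -> int:
    """Number of valid cells that fall in runs shorter than ``min_length``."""
    segments = extract_row_segments(raster, min_length=2)
    short = sum(len(s) for s in segments if len(s) < min_length)
    # runs of length 1 are invisible to extract_row_segments(min_length=2)
    total_valid = int((~raster.nodata_mask).sum())
    covered = sum(len(s) for s in segments)
    return short + (total_valid - covered)
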