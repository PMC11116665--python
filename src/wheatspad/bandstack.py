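"""Multiband raster container, TIFF/GeoJSON I/O and plot extraction.

A :class:`BandStack` holds the five-band (B, G, R, RE, NIR) pixel grid of a
UAV multispectral image together with its value semantics — raw sensor
digital numbers (``"DN"``) or surface reflectance (``"reflectance"``) — a
nodata mask and an optional affine georeference.  Plot regions arrive as
polygons (GeoJSON or shapely geometries) and are rasterized with the
pixel-center rule: a pixel belongs to a plot iff its center lies inside the
polygon.

Band order is authoritative from the container/config, never from file page
order, to prevent silent blue/red swaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
import tifffile

BAND_NAMES: tuple[str, ...] = ("B", "G", "R", "RE", "NIR")
N_BANDS = len(BAND_NAMES)

#: reflectance above 1 is tolerated up to this value (sun glint / specular
#: pixels exist in field imagery); anything beyond is masked.
REFLECTANCE_CEILING = 1.2

DN = "DN"
REFLECTANCE = "reflectance"


class BandCountError(ValueError):
    """Raised when an image does not carry exactly the expected 5 bands."""


class SemanticsError(ValueError):
    """Raised when an operation receives DN where reflectance is required
    (or vice versa)."""


class EmptyRegionError(ValueError):
    """Raised when a plot polygon intersects no pixel centers."""


@dataclass
class BandStack:
    """Five-band pixel grid with value semantics and optional georeference.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 5)
        Pixel values, float.
    semantics : {"DN", "reflectance"}
    mask : ndarray of bool, shape (H, W)
        True where the pixel is valid.
    transform : 6-tuple, optional
        Affine map (a, b, c, d, e, f): x = a*col + b*row + c,
        y = d*col + e*row + f.  Identity-like default maps pixel indices
        to map units directly.
    crs : str, optional
        Free-form CRS tag carried through I/O, not interpreted.
    meta : dict
        Free-form metadata (e.g. clipping counts from DN encoding).
    """

    pixels: np.ndarray
    semantics: str = DN
    mask: np.ndarray | None = None
    band_names: tuple[str, ...] = BAND_NAMES
    transform: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)
    crs: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != N_BANDS:
            raise BandCountError(
                f"expected (H, W, {N_BANDS}) pixel array with bands "
                f"{list(BAND_NAMES)}, got shape {self.pixels.shape}"
            )
        if tuple(self.band_names) != BAND_NAMES:
            raise BandCountError(
                f"band order must be {list(BAND_NAMES)}, got {list(self.band_names)}"
            )
        if self.semantics not in (DN, REFLECTANCE):
            raise SemanticsError(f"unknown semantics {self.semantics!r}")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape[:2]:
                raise ValueError("mask shape must match pixel grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def band(self, name: str) -> np.ndarray:
        return self.pixels[:, :, BAND_NAMES.index(name)]

    def pixel_centers(self, rows: np.ndarray, cols: np.ndarray):
        """Map-space coordinates of pixel centers (half-integer offsets)."""
        a, b, c, d, e, f = self.transform
        col = cols + 0.5
        row = rows + 0.5
        return a * col + b * row + c, d * col + e * row + f


@dataclass
class PlotRegion:
    """A plot polygon plus its rasterized pixel mask for one image."""

    plot_id: str
    polygon: BaseGeometry

    def pixel_mask(self, stack: BandStack) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside the polygon."""
        h, w = stack.shape
        rows, cols = np.mgrid[0:h, 0:w]
        x, y = stack.pixel_centers(rows.ravel(), cols.ravel())
        inside = shapely.contains_xy(self.polygon, x, y)
        return inside.reshape(h, w)


@dataclass
class CalPanel:
    """One radiometric calibration panel: nominal reflectance + pixel region.

    ``region`` is (row0, row1, col0, col1), half-open, in pixel indices.
    The nominal reflectance applies to every band (grey panels).
    """

    nominal_reflectance: float
    region: tuple[int, int, int, int]

    def mean_dn(self, stack: BandStack) -> np.ndarray:
        r0, r1, c0, c1 = self.region
        patch = stack.pixels[r0:r1, c0:c1, :]
        m = stack.mask[r0:r1, c0:c1]
        if not m.any():
            raise EmptyRegionError("calibration panel region is fully masked")
        return patch[m].mean(axis=0)


@dataclass
class PlotImage:
    """Masked five-band sub-image of one plot (same grid as the source)."""

    plot_id: str
    pixels: np.ndarray  # (H, W, 5)
    mask: np.ndarray    # (H, W) bool, True inside the plot and valid
    semantics: str
    n_pixels: int = 0

    def __post_init__(self) -> None:
        self.n_pixels = int(self.mask.sum())

    def band(self, name: str) -> np.ndarray:
        return self.pixels[:, :, BAND_NAMES.index(name)]


# ---------------------------------------------------------------------------
# I/O


def write_stack(path, stack: BandStack) -> None:
    """Write a BandStack as a multiband TIFF.

    Pixel data is stored band-major (5, H, W) as float64 so DN and
    reflectance round-trip exactly; nodata is encoded as NaN.  Band
    order, semantics, affine transform and CRS travel in a JSON
    ImageDescription tag.
    """
    desc = json.dumps(
        {
            "bands": list(stack.band_names),
            "semantics": stack.semantics,
            "transform": list(stack.transform),
            "crs": stack.crs,
            "meta": stack.meta,
        }
    )
    data = np.moveaxis(stack.pixels, 2, 0).astype(np.float64).copy()
    data[:, ~stack.mask] = np.nan
    tifffile.imwrite(path, data, description=desc, photometric="minisblack")


def read_stack(path) -> BandStack:
    """Read a multiband TIFF written by :func:`write_stack`.

    Raises
    ------
    BandCountError
        If the file does not hold exactly 5 bands.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != N_BANDS:
        raise BandCountError(
            f"{path}: expected {N_BANDS} bands {list(BAND_NAMES)}, "
            f"found {data.shape[0]}"
        )
    info = json.loads(desc) if desc else {}
    pixels = np.moveaxis(data.astype(float), 0, 2)
    mask = ~np.isnan(pixels).any(axis=2)
    pixels = np.nan_to_num(pixels, nan=0.0)
    return BandStack(
        pixels=pixels,
        semantics=info.get("semantics", DN),
        mask=mask,
        band_names=tuple(info.get("bands", BAND_NAMES)),
        transform=tuple(info.get("transform", (1, 0, 0, 0, 1, 0))),
        crs=info.get("crs"),
        meta=info.get("meta", {}),
    )


def write_regions_geojson(path, regions: Sequence[PlotRegion]) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"plot_id": r.plot_id},
                "geometry": mapping(r.polygon),
            }
            for r in regions
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_regions_geojson(path) -> list[PlotRegion]:
    with open(path) as fh:
        fc = json.load(fh)
    return [
        PlotRegion(plot_id=str(feat["properties"]["plot_id"]),
                   polygon=shape(feat["geometry"]))
        for feat in fc["features"]
    ]


# ---------------------------------------------------------------------------
# plot extraction


def extract_plot(stack: BandStack, region: PlotRegion) -> PlotImage:
    """Mask a stack to one plot polygon (pixel-center containment rule).

    Raises
    ------
    EmptyRegionError
        If no valid pixel center falls inside the polygon.
    """
    inside = region.pixel_mask(stack)
    mask = inside & stack.mask
    if not mask.any():
        raise EmptyRegionError(
            f"plot {region.plot_id}: polygon contains no valid pixel centers"
        )
    return PlotImage(
        plot_id=region.plot_id,
        pixels=stack.pixels,
        mask=mask,
        semantics=stack.semantics,
    )
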