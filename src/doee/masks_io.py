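"""Reading, writing and rasterizing paired rater segmentations.

Two input forms are supported: binary mask volumes (NIfTI, or stacks of 2D
grayscale images) and per-slice closed-polygon contour sets in a small JSON
dialect.  Contours are rasterized onto a grid upsampled by a configurable
factor (default 5) in both in-plane directions, which keeps a single closed
path from fragmenting into several regions when it has a sub-pixel neck.
All areas downstream are physical (mm^2): a fine pixel contributes
(dx/f)*(dy/f) so total area is preserved under upsampling.

Contour JSON dialect::

    {"geometry": {"dx": float, "dy": float},
     "slices": [{"index": int, "polygons": [[[x, y], ...], ...]}]}

Coordinates are 0-based pixel coordinates with x = column and y = row,
measured at pixel centers.  Polygons are implicitly closed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import PairingError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_UPSAMPLE = 5

__all__ = [
    "PixelGeometry",
    "ContourSet",
    "ContourSlice",
    "RaterMaskPair",
    "rasterize_contours",
    "read_mask_volume",
    "write_mask_volume",
    "read_contours_json",
    "write_contours_json",
    "pair_masks",
    "DEFAULT_UPSAMPLE",
]


@dataclass(frozen=True)
class PixelGeometry:
    """In-plane pixel size in millimetres (analysis is per-slice 2D)."""

    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise ValidationError(
                f"pixel dimensions must be positive, got dx={self.dx}, dy={self.dy}"
            )

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in mm^2."""
        return self.dx * self.dy

    def upsampled(self, factor: int) -> "PixelGeometry":
        return PixelGeometry(self.dx / factor, self.dy / factor)


@dataclass
class ContourSlice:
    """One image slice: its index and the closed polygons drawn on it."""

    index: int
    polygons: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.index < 0 or int(self.index) != self.index:
            raise ValidationError(f"slice index must be a non-negative integer, got {self.index}")
        polys = []
        for i, poly in enumerate(self.polygons):
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise ValidationError(
                    f"polygon {i} on slice {self.index} must be an (n>=3, 2) vertex array"
                )
            polys.append(arr)
        self.polygons = polys


@dataclass
class ContourSet:
    """A rater's ROIs for one scan, as per-slice closed polygons."""

    slices: list[ContourSlice]
    geometry: PixelGeometry


@dataclass
class RaterMaskPair:
    """Aligned binary mask stacks (slices x rows x cols) for two raters."""

    rater1: np.ndarray
    rater2: np.ndarray
    geometry: PixelGeometry
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.rater1 = _as_binary_stack(self.rater1, "rater1")
        self.rater2 = _as_binary_stack(self.rater2, "rater2")
        if self.rater1.shape != self.rater2.shape:
            raise PairingError(
                f"scan {self.scan_id!r}: rater stacks have different shapes "
                f"{self.rater1.shape} vs {self.rater2.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.rater1.shape


def _as_binary_stack(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValidationError(f"{name}: mask stack must be 2D or 3D, got ndim={arr.ndim}")
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(f"{name}: mask values must be binary, found {vals[:5]}")
        arr = arr.astype(bool)
    return arr


# ---------------------------------------------------------------------------
# Rasterization

def _points_in_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon test; points on an edge count as inside.

    The even-odd (crossing-number) rule is part of the rasterization
    contract: it resolves self-intersecting outlines deterministically.
    """
    px, py = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    on_edge = np.zeros(len(points), dtype=bool)
    n = len(poly)
    eps = 1e-12
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # crossing test against the half-open edge
        crosses = (y1 > py) != (y2 > py)
        if crosses.any():
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (px < xint)
        # point-on-segment test
        dx, dy = x2 - x1, y2 - y1
        seg_len2 = dx * dx + dy * dy
        if seg_len2 < eps:
            on_edge |= (np.abs(px - x1) < eps) & (np.abs(py - y1) < eps)
            continue
        t = ((px - x1) * dx + (py - y1) * dy) / seg_len2
        cross = (px - x1) * dy - (py - y1) * dx
        on_edge |= (np.abs(cross) < eps * max(1.0, seg_len2)) & (t >= -eps) & (t <= 1 + eps)
    return inside | on_edge


def _cross2(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _segments_intersect(p: np.ndarray, q: np.ndarray, r: np.ndarray, s: np.ndarray) -> bool:
    d1 = _cross2(q - p, r - p)
    d2 = _cross2(q - p, s - p)
    d3 = _cross2(s - r, p - r)
    d4 = _cross2(s - r, q - r)
    return (d1 * d2 < 0) and (d3 * d4 < 0)


def _is_self_intersecting(poly: np.ndarray) -> bool:
    n = len(poly)
    for i in range(n):
        p, q = poly[i], poly[(i + 1) % n]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if _segments_intersect(p, q, poly[j], poly[(j + 1) % n]):
                return True
    return False


def rasterize_contours(
    contours: ContourSet,
    grid_shape: tuple[int, int],
    upsample: int = DEFAULT_UPSAMPLE,
    n_slices: int | None = None,
) -> tuple[np.ndarray, PixelGeometry]:
    """Rasterize a contour set to a binary mask stack at fine resolution.

    A fine pixel is set iff its center lies inside (or on the boundary of)
    any polygon of that slice, by the even-odd rule.  Output slices are
    ``(upsample*rows, upsample*cols)`` and the returned geometry is the
    input geometry divided by ``upsample``, so physical area is preserved.

    Parameters
    ----------
    contours : ContourSet
        Per-slice closed polygons, vertex coordinates in (coarse) pixel
        units with x = column, y = row.
    grid_shape : (rows, cols)
        Shape of the coarse image grid; all vertices must fall inside it.
    upsample : int
        Linear upsampling factor (default 5).
    n_slices : int, optional
        Number of slices in the output stack; defaults to max slice
        index + 1 (zero if the contour set is empty).
    """
    rows, cols = grid_shape
    if upsample < 1 or int(upsample) != upsample:
        raise ValidationError(f"upsample factor must be a positive integer, got {upsample}")
    if n_slices is None:
        n_slices = 1 + max((s.index for s in contours.slices), default=-1)
    stack = np.zeros((max(n_slices, 0), rows * upsample, cols * upsample), dtype=bool)

    # fine-pixel centers expressed in coarse pixel coordinates
    fine_y = (np.arange(rows * upsample) + 0.5) / upsample
    fine_x = (np.arange(cols * upsample) + 0.5) / upsample

    for sl in contours.slices:
        if sl.index >= stack.shape[0]:
            raise ValidationError(
                f"slice index {sl.index} exceeds requested stack depth {stack.shape[0]}"
            )
        for poly in sl.polygons:
            if (poly[:, 0] < 0).any() or (poly[:, 0] > cols).any() or (
                poly[:, 1] < 0
            ).any() or (poly[:, 1] > rows).any():
                raise ValidationError(
                    f"slice {sl.index}: polygon vertex outside grid bounds {grid_shape}"
                )
            if _is_self_intersecting(poly):
                logger.warning(
                    "slice %d: self-intersecting polygon resolved by even-odd rule", sl.index
                )
            # restrict the test to the polygon's bounding box of fine pixels
            xmin, xmax = poly[:, 0].min(), poly[:, 0].max()
            ymin, ymax = poly[:, 1].min(), poly[:, 1].max()
            ci = np.where((fine_x >= xmin - 1) & (fine_x <= xmax + 1))[0]
            ri = np.where((fine_y >= ymin - 1) & (fine_y <= ymax + 1))[0]
            if len(ci) == 0 or len(ri) == 0:
                continue
            cc, rr = np.meshgrid(ci, ri)
            pts = np.column_stack([fine_x[cc.ravel()], fine_y[rr.ravel()]])
            hit = _points_in_polygon(pts, poly)
            sub = stack[sl.index, ri[0] : ri[-1] + 1, ci[0] : ci[-1] + 1]
            sub |= hit.reshape(len(ri), len(ci))
    return stack, contours.geometry.upsampled(upsample)


# ---------------------------------------------------------------------------
# Mask volume IO

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


def read_mask_volume(
    path: str | Path, geometry: PixelGeometry | None = None
) -> tuple[np.ndarray, PixelGeometry]:
    """Read a single rater's mask stack from disk.

    Supports NIfTI volumes (``.nii``/``.nii.gz``), single 2D grayscale
    images, and directories of 2D images (slices sorted by file name).
    Values are thresholded at > 0.  Geometry is taken from the file header
    when present; an explicit ``geometry`` argument wins on conflict, with
    a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise PairingError(f"{path}: no such file or directory")
    header_geom: PixelGeometry | None = None
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise PairingError(f"{path}: no image files found in directory")
        from imageio.v3 import imread

        slices = [np.asarray(imread(f)) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise PairingError(f"{path}: slice images have inconsistent shapes {shapes}")
        data = np.stack(slices)
    elif path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        if len(zooms) >= 2 and zooms[0] > 0 and zooms[1] > 0:
            header_geom = PixelGeometry(float(zooms[0]), float(zooms[1]))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim == 2:
            arr = arr[..., np.newaxis]
        if arr.ndim != 3:
            raise ValidationError(f"{path}: expected a 2D or 3D volume, got ndim={arr.ndim}")
        data = np.moveaxis(arr, 2, 0)  # (slices, rows, cols)
    elif path.suffix.lower() in _IMAGE_SUFFIXES:
        from imageio.v3 import imread

        data = np.asarray(imread(str(path)))[np.newaxis]
    else:
        raise PairingError(f"{path}: unsupported mask format {path.suffix!r}")

    if data.ndim == 4:  # RGB(A) image stacks: any nonzero channel counts
        data = data.max(axis=-1)
    mask = np.asarray(data) > 0

    if geometry is not None and header_geom is not None:
        if not (
            np.isclose(geometry.dx, header_geom.dx) and np.isclose(geometry.dy, header_geom.dy)
        ):
            logger.warning(
                "%s: header pixel size (%.4g, %.4g) overridden by explicit (%.4g, %.4g)",
                path,
                header_geom.dx,
                header_geom.dy,
                geometry.dx,
                geometry.dy,
            )
        return mask, geometry
    if geometry is not None:
        return mask, geometry
    if header_geom is not None:
        return mask, header_geom
    raise ValidationError(f"{path}: no pixel geometry in header and none supplied")


def write_mask_volume(mask: np.ndarray, geometry: PixelGeometry, path: str | Path) -> None:
    """Write a binary stack as a NIfTI volume with pixdim from geometry."""
    import nibabel as nib

    mask = _as_binary_stack(np.asarray(mask), "mask")
    data = np.moveaxis(mask.astype(np.uint8), 0, 2)  # back to (rows, cols, slices)
    affine = np.diag([geometry.dx, geometry.dy, 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((geometry.dx, geometry.dy, 1.0))
    nib.save(img, str(path))


def pair_masks(
    rater1: np.ndarray,
    rater2: np.ndarray,
    geometry: PixelGeometry,
    scan_id: str = "",
) -> RaterMaskPair:
    """Pair two single-rater stacks, padding a shorter stack with empty
    slices (a slice one rater never annotated is all background)."""
    r1 = _as_binary_stack(rater1, "rater1")
    r2 = _as_binary_stack(rater2, "rater2")
    if r1.shape[1:] != r2.shape[1:]:
        raise PairingError(
            f"scan {scan_id!r}: in-plane shapes differ: {r1.shape[1:]} vs {r2.shape[1:]}"
        )
    n = max(r1.shape[0], r2.shape[0])
    if r1.shape[0] != r2.shape[0]:
        logger.warning(
            "scan %r: slice counts differ (%d vs %d); padding with background",
            scan_id,
            r1.shape[0],
            r2.shape[0],
        )

    def _pad(stack: np.ndarray) -> np.ndarray:
        if stack.shape[0] == n:
            return stack
        pad = np.zeros((n - stack.shape[0],) + stack.shape[1:], dtype=bool)
        return np.concatenate([stack, pad])

    return RaterMaskPair(_pad(r1), _pad(r2), geometry, scan_id)


# ---------------------------------------------------------------------------
# Contour JSON

def write_contours_json(contours: ContourSet, path: str | Path) -> None:
    """Serialize a contour set losslessly (float coordinates round-trip)."""
    doc = {
        "geometry": {"dx": contours.geometry.dx, "dy": contours.geometry.dy},
        "slices": [
            {
                "index": int(sl.index),
                "polygons": [poly.tolist() for poly in sl.polygons],
            }
            for sl in contours.slices
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_contours_json(path: str | Path) -> ContourSet:
    """Read the contour JSON dialect, validating structure field by field."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top-level value must be an object")
    for key in ("geometry", "slices"):
        if key not in doc:
            raise SchemaError(f"{path}: missing required key {key!r}")
    geom = doc["geometry"]
    for key in ("dx", "dy"):
        if not isinstance(geom, dict) or key not in geom:
            raise SchemaError(f"{path}: geometry missing required key {key!r}")
    try:
        geometry = PixelGeometry(float(geom["dx"]), float(geom["dy"]))
    except (TypeError, ValueError, ValidationError) as exc:
        raise SchemaError(f"{path}: invalid geometry: {exc}") from exc
    slices = []
    for i, rec in enumerate(doc["slices"]):
        if not isinstance(rec, dict) or "index" not in rec or "polygons" not in rec:
            raise SchemaError(f"{path}: slices[{i}] must have keys 'index' and 'polygons'")
        try:
            slices.append(ContourSlice(rec["index"], [np.asarray(p, float) for p in rec["polygons"]]))
        except (ValidationError, ValueError) as exc:
            raise SchemaError(f"{path}: slices[{i}]: {exc}") from exc
    return ContourSet(slices, geometry)
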