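"""Viable-tumor-area quantification from tiled calcein confocal stacks.

The pipeline mirrors standard practice for large mosaic viability imaging:

1. calibrate an intensity floor from live (untreated) vs dead (formalin)
   reference images — the floor sits midway between the two robust levels;
2. segment every Z-plane with a local-mean adaptive threshold AND the global
   floor (bright objects on dark background);
3. stitch the 13 x 3 tile grid (10% overlap, overlap fused by pixelwise
   maximum) per plane, OR the per-plane masks into a composite binarized
   mask, and form the maximum intensity projection (MIP);
4. label 8-connected components, convert areas to µm², drop objects below
   the minimum nodule size cut-off (2000 µm² by default, sweepable
   500-3000 µm²), and sum the surviving area;
5. normalize each sample to the mean of its internal no-treatment control.

Two execution modes produce identical results: whole-mosaic (stitch each
full plane) and streaming (process one tile-column band at a time, merging
objects across band seams with union-find), which bounds resident tiles to
two adjacent grid columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure


class CalibrationError(ValueError):
    """Live and dead intensity distributions are not separable."""


class PipelineUsageError(RuntimeError):
    """An operation was called outside its contract."""


class StitchingError(RuntimeError):
    """A tile required for stitching is missing or inconsistent."""


class NormalizationError(ValueError):
    """The control group cannot be used for normalization."""


# --------------------------------------------------------------------------
# calibration and segmentation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationParams:
    """Thresholding parameters derived from live/dead reference images."""

    background_level: float
    live_level: float
    global_floor: float
    adaptive_sensitivity: float = 0.35
    adaptive_window: int = 101

    def __post_init__(self) -> None:
        if self.live_level <= self.background_level:
            raise CalibrationError("live level must exceed background level")
        w = self.adaptive_window
        if w < 3 or w % 2 == 0:
            raise CalibrationError("adaptive window must be odd and >= 3")


def calibrate_threshold(live_images, dead_images,
                        adaptive_sensitivity: float = 0.5,
                        adaptive_window: int = 101) -> CalibrationParams:
    """Derive the global floor from live vs dead reference image sets.

    The floor is the midpoint of the robust (median) intensities of the two
    sets, i.e. the two-mode midpoint of the calcein dynamic range.
    """
    def as_list(images):
        if isinstance(images, (list, tuple)):
            return [np.asarray(im, dtype=float) for im in images]
        return [np.asarray(images, dtype=float)]

    live_images = as_list(live_images)
    dead_images = as_list(dead_images)
    if not live_images or not dead_images:
        raise PipelineUsageError("both live and dead image sets are required")
    live_level = float(np.median(np.concatenate([im.ravel() for im in live_images])))
    dead_level = float(np.median(np.concatenate([im.ravel() for im in dead_images])))
    if live_level <= dead_level:
        raise CalibrationError(
            f"live robust mean ({live_level:.3g}) does not exceed dead "
            f"robust mean ({dead_level:.3g})")
    floor = 0.5 * (live_level + dead_level)
    return CalibrationParams(background_level=dead_level, live_level=live_level,
                             global_floor=floor,
                             adaptive_sensitivity=adaptive_sensitivity,
                             adaptive_window=adaptive_window)


def _segment_array(image: np.ndarray, params: CalibrationParams) -> np.ndarray:
    """Boolean mask: local-mean adaptive pass AND the global intensity floor.

    A pixel is calcein-positive when it exceeds its local window mean by a
    sensitivity-scaled fraction of the calibrated dynamic range (bright
    objects on dark background; an inverted image segments to nothing) and
    also clears the live/dead floor.
    """
    img = np.asarray(image, dtype=float)
    local_mean = ndimage.uniform_filter(img, size=params.adaptive_window,
                                        mode="reflect")
    offset = params.adaptive_sensitivity * (params.live_level
                                            - params.background_level)
    return (img >= params.global_floor) & (img > local_mean + offset)


@dataclass
class BinaryMask:
    """A per-plane (or composite) segmentation mask on the mosaic grid."""

    pixels: np.ndarray           # bool array
    pixel_size_um: float
    origin: tuple[int, int] = (0, 0)

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size_um ** 2


def segment_plane(image: np.ndarray, params: CalibrationParams,
                  pixel_size_um: float = 1.0,
                  origin: tuple[int, int] = (0, 0)) -> BinaryMask:
    """Segment one intensity image into a calcein-positive BinaryMask."""
    return BinaryMask(pixels=_segment_array(image, params),
                      pixel_size_um=pixel_size_um, origin=origin)


# --------------------------------------------------------------------------
# stitching and projection
# --------------------------------------------------------------------------

def _mosaic_width(tiles) -> tuple[int, int]:
    stride = tiles.tile_size - tiles.overlap_px
    h = tiles.n_rows * tiles.tile_size - (tiles.n_rows - 1) * tiles.overlap_px
    w = tiles.n_cols * tiles.tile_size - (tiles.n_cols - 1) * tiles.overlap_px
    return h, w


def stitch_region(tiles, plane: int, x0: int, x1: int) -> np.ndarray:
    """Stitch the mosaic columns [x0, x1) of one plane (full height).

    Overlap strips are fused by pixelwise maximum, which is robust to
    per-tile illumination mismatch and idempotent for noiseless tiles.
    """
    H, W = _mosaic_width(tiles)
    if not (0 <= x0 < x1 <= W):
        raise StitchingError(f"column range [{x0}, {x1}) outside mosaic width {W}")
    stride = tiles.tile_size - tiles.overlap_px
    canvas = np.zeros((H, x1 - x0), dtype=float)
    filled = np.zeros((H, x1 - x0), dtype=bool)
    c_lo = max(0, (x0 - tiles.tile_size) // stride + 1)
    c_hi = min(tiles.n_cols - 1, (x1 - 1) // stride)
    for c in range(c_lo, c_hi + 1):
        tx0 = c * stride
        ov0, ov1 = max(tx0, x0), min(tx0 + tiles.tile_size, x1)
        if ov0 >= ov1:
            continue
        for r in range(tiles.n_rows):
            tile = tiles.get_tile(r, c, plane)
            if tile is None or tile.shape != (tiles.tile_size, tiles.tile_size):
                raise StitchingError(f"missing or malformed tile at grid ({r}, {c})")
            ry0 = r * stride
            sub = tile[:, ov0 - tx0:ov1 - tx0]
            dst = canvas[ry0:ry0 + tiles.tile_size, ov0 - x0:ov1 - x0]
            sel = filled[ry0:ry0 + tiles.tile_size, ov0 - x0:ov1 - x0]
            np.copyto(dst, np.where(sel, np.maximum(dst, sub), sub))
            sel[:] = True
    return canvas


def stitch_mosaic(tiles, plane: int) -> np.ndarray:
    """Stitch one full Z-plane of the tile grid into a mosaic image."""
    _, W = _mosaic_width(tiles)
    return stitch_region(tiles, plane, 0, W)


def max_intensity_projection(planes) -> np.ndarray:
    """Pixelwise maximum across Z-planes (MIP)."""
    planes = list(planes)
    if not planes:
        raise PipelineUsageError("MIP of an empty plane list")
    out = np.asarray(planes[0], dtype=float).copy()
    for pl in planes[1:]:
        if np.shape(pl) != out.shape:
            raise PipelineUsageError("MIP planes must share a shape")
        np.maximum(out, pl, out=out)
    return out


def composite_mask(per_plane_masks) -> BinaryMask:
    """Pixelwise logical OR of per-plane masks."""
    masks = list(per_plane_masks)
    if not masks:
        raise PipelineUsageError("composite of an empty mask list")
    arrays = [m.pixels if isinstance(m, BinaryMask) else np.asarray(m, bool)
              for m in masks]
    out = arrays[0].copy()
    for a in arrays[1:]:
        if a.shape != out.shape:
            raise PipelineUsageError("composite masks must share a shape")
        out |= a
    px = masks[0].pixel_size_um if isinstance(masks[0], BinaryMask) else 1.0
    return BinaryMask(pixels=out, pixel_size_um=px)


# --------------------------------------------------------------------------
# labeling, size filtering, quantification
# --------------------------------------------------------------------------

@dataclass
class LabeledObjects:
    """Size-filtered 8-connected objects of a composite mask."""

    table: pd.DataFrame          # label, area_um2, centroid, bbox, spans flag
    labels: np.ndarray           # label image (0 = background)
    min_size_um2: float
    pixel_size_um: float

    @property
    def total_area_um2(self) -> float:
        return float(self.table["area_um2"].sum())

    @property
    def count(self) -> int:
        return int(len(self.table))


def label_and_filter(mask: BinaryMask, min_size_um2: float,
                     seam_positions: tuple = ()) -> LabeledObjects:
    """Label 8-connected components and drop objects below the size cut-off."""
    if min_size_um2 <= 0:
        raise PipelineUsageError("min_size_um2 must be positive")
    px_area = mask.pixel_size_um ** 2
    labels = measure.label(mask.pixels, connectivity=2)
    rows = []
    for rp in measure.regionprops(labels):
        area = rp.area * px_area
        if area < min_size_um2:
            labels[labels == rp.label] = 0
            continue
        minr, minc, maxr, maxc = rp.bbox
        spans = any(minc < s < maxc for s in seam_positions)
        rows.append({"label": rp.label, "area_um2": area,
                     "centroid_row": rp.centroid[0],
                     "centroid_col": rp.centroid[1],
                     "bbox": rp.bbox, "spans_tile_boundary": spans})
    table = pd.DataFrame(rows, columns=["label", "area_um2", "centroid_row",
                                        "centroid_col", "bbox",
                                        "spans_tile_boundary"])
    return LabeledObjects(table=table, labels=labels,
                          min_size_um2=min_size_um2,
                          pixel_size_um=mask.pixel_size_um)


@dataclass
class QuantResult:
    """Total viable area of one channel at one size cut-off."""

    live_area_um2: float
    object_count: int
    min_size_cutoff_um2: float
    normalization_group: str | None = None
    normalized_area: float = float("nan")


class _DSU:
    """Union-find over streaming object fragments, accumulating pixel counts."""

    def __init__(self):
        self.parent: list[int] = []
        self.count: list[int] = []

    def make(self, pixels: int) -> int:
        self.parent.append(len(self.parent))
        self.count.append(pixels)
        return len(self.parent) - 1

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri
            self.count[ri] += self.count[rj]

    def root_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i in range(len(self.parent)):
            if self.find(i) == i:
                out[i] = self.count[i]
        return out


def _composite_band(tiles, params: CalibrationParams,
                    x0: int, x1: int) -> np.ndarray:
    """Composite (OR over planes) segmentation mask of mosaic columns [x0, x1).

    The band is segmented with a halo of half the adaptive window on each
    side so that the local-mean context matches the whole-mosaic computation
    exactly, then cropped back.
    """
    _, W = _mosaic_width(tiles)
    pad = params.adaptive_window // 2
    p0, p1 = max(0, x0 - pad), min(W, x1 + pad)
    comp = None
    for plane in range(tiles.n_planes):
        band = stitch_region(tiles, plane, p0, p1)
        m = _segment_array(band, params)[:, x0 - p0:x1 - p0]
        comp = m if comp is None else (comp | m)
    return comp


def _object_pixel_counts(tiles, params: CalibrationParams,
                         streaming: bool) -> np.ndarray:
    """Pixel counts of all 8-connected objects in the channel composite mask.

    Whole-mosaic mode stitches each full plane; streaming mode processes one
    tile-column band at a time (resident tiles bounded by two adjacent grid
    columns) and merges objects across band seams with union-find.  The two
    modes return identical counts.
    """
    px = tiles.pixel_size_um
    if not streaming:
        masks = [BinaryMask(_segment_array(stitch_mosaic(tiles, p), params), px)
                 for p in range(tiles.n_planes)]
        comp = composite_mask(masks)
        labels = measure.label(comp.pixels, connectivity=2)
        counts = np.bincount(labels.ravel())[1:]
        return np.sort(counts.astype(float))

    # --- streaming over tile-column bands --------------------------------
    H, W = _mosaic_width(tiles)
    stride = tiles.tile_size - tiles.overlap_px
    dsu = _DSU()
    prev_edge = np.full(H, -1, dtype=int)  # DSU node per row of previous band edge
    for c in range(tiles.n_cols):
        x0 = c * stride
        x1 = (c + 1) * stride if c < tiles.n_cols - 1 else W
        band = _composite_band(tiles, params, x0, x1)
        lab = measure.label(band, connectivity=2)
        nlab = lab.max()
        if nlab == 0:
            prev_edge = np.full(H, -1, dtype=int)
            continue
        counts = np.bincount(lab.ravel(), minlength=nlab + 1)
        nodes = np.full(nlab + 1, -1, dtype=int)
        for lb in range(1, nlab + 1):
            nodes[lb] = dsu.make(int(counts[lb]))
        # merge across the seam with 8-connectivity
        first = lab[:, 0]
        for r in np.nonzero(first)[0]:
            for rr in (r - 1, r, r + 1):
                if 0 <= rr < H and prev_edge[rr] >= 0:
                    dsu.union(prev_edge[rr], nodes[first[r]])
        last = lab[:, -1]
        prev_edge = np.where(last > 0, nodes[last], -1)
    return np.array(sorted(dsu.root_counts().values()), dtype=float)


def quantify_channel_sweep(tiles, params: CalibrationParams,
                           cutoffs_um2, streaming: bool = False,
                           ) -> dict[float, QuantResult]:
    """Quantify one channel at several size cut-offs, segmenting only once."""
    cutoffs = sorted(float(c) for c in cutoffs_um2)
    if not cutoffs or cutoffs[0] <= 0:
        raise PipelineUsageError("cut-offs must be positive")
    areas = _object_pixel_counts(tiles, params, streaming) \
        * tiles.pixel_size_um ** 2
    out = {}
    for co in cutoffs:
        keep = areas >= co
        out[co] = QuantResult(live_area_um2=float(areas[keep].sum()),
                              object_count=int(keep.sum()),
                              min_size_cutoff_um2=co)
    return out


def quantify_channel(tiles, params: CalibrationParams,
                     min_size_um2: float = 2000.0,
                     streaming: bool = False) -> QuantResult:
    """Total size-filtered calcein-positive area of a tiled Z-stack channel.

    Streaming and whole-mosaic modes return identical results; see
    ``_object_pixel_counts`` for the two execution strategies.
    """
    return quantify_channel_sweep(tiles, params, [min_size_um2],
                                  streaming=streaming)[float(min_size_um2)]


def quantify_static(image: np.ndarray, params: CalibrationParams,
                    pixel_size_um: float,
                    min_size_um2: float = 2000.0) -> QuantResult:
    """Single-focal-plane path used for static cultures: no Z projection."""
    mask = segment_plane(image, params, pixel_size_um)
    objs = label_and_filter(mask, min_size_um2)
    return QuantResult(live_area_um2=objs.total_area_um2,
                       object_count=objs.count,
                       min_size_cutoff_um2=min_size_um2)


def normalize_to_control(treated, control) -> np.ndarray:
    """Divide treated live areas by the mean control live area.

    Accepts sequences of QuantResult or plain areas; returns the normalized
    treated values.  By construction the control group normalizes to mean 1.
    """
    def areas(vals):
        return np.array([v.live_area_um2 if isinstance(v, QuantResult) else float(v)
                         for v in vals], dtype=float)

    ctrl = areas(control)
    if ctrl.size == 0:
        raise NormalizationError("control group is empty")
    mean = float(ctrl.mean())
    if mean <= 0:
        raise NormalizationError("control mean live area must be positive")
    return areas(treated) / mean


# --------------------------------------------------------------------------
# TIFF-backed tile source
# --------------------------------------------------------------------------

class TiffTileSource:
    """Tile source reading per-tile multi-page TIFFs via a JSON manifest.

    Keeps a small LRU cache of tile stacks and tracks the peak number of
    simultaneously resident tiles, which streaming mode bounds by two grid
    columns.
    """

    def __init__(self, manifest_path: str | Path, cache_tiles: int | None = None):
        import tifffile

        self._tifffile = tifffile
        self.dir = Path(manifest_path).parent
        m = json.loads(Path(manifest_path).read_text())
        self.n_rows = m["grid_rows"]
        self.n_cols = m["grid_cols"]
        self.tile_size = m["tile_size"]
        self.overlap_px = m["overlap_px"]
        self.n_planes = m["n_planes"]
        self.pixel_size_um = m["pixel_size_um"]
        self.pattern = m.get("tile_pattern", "tile_r{row:02d}_c{col:02d}.tif")
        self.cache_tiles = cache_tiles or 2 * self.n_rows
        self._cache: dict[tuple[int, int], np.ndarray] = {}
        self.peak_resident = 0

    def get_tile(self, row: int, col: int, plane: int) -> np.ndarray:
        key = (row, col)
        if key not in self._cache:
            path = self.dir / self.pattern.format(row=row, col=col)
            if not path.exists():
                raise StitchingError(f"missing tile at grid ({row}, {col}): {path}")
            stack = self._tifffile.imread(path)
            while len(self._cache) >= self.cache_tiles:
                self._cache.pop(next(iter(self._cache)))
            self._cache[key] = np.asarray(stack, dtype=float)
            self.peak_resident = max(self.peak_resident, len(self._cache))
        return self._cache[key][plane]
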