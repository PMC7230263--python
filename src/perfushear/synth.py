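"""Synthetic calcein-AM confocal datasets with exact ground truth.

Emulates the acquisition used for perfusion channels: a 13 x 3 grid of
512 x 512 tiles with 10% overlap, ~15-20 Z-planes at a 10 µm step.  Viable
nodules are bright filled ellipses on a dark background; non-viable nodules
sit at a dim "formalin-killed" level.  Axial structure is modelled by
spreading each nodule's intensity over 2-4 adjacent planes with a triangular
weight profile (peak weight 1 at the centre plane), and acquisition noise is
Poisson shot noise plus additive Gaussian read noise.

Rendering is lazy and deterministic: a tile is a pure function of
(scene, row, col, plane), with per-tile/per-plane random streams derived from
the master seed by fixed key splitting, so tile order and repeated reads
never change the data and full volumes are never held in memory.

The planted geometry is recorded exactly in a GroundTruthLedger (analytic
ellipse areas, pi*a*b), which is the oracle for every quantification test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd


class GenerationError(ValueError):
    """The requested scene cannot be generated (too crowded, bad fractions)."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic channel acquisition."""

    pixel_size_um: float = 2.5
    tile_size: int = 512
    grid_rows: int = 3
    grid_cols: int = 13
    overlap_fraction: float = 0.10
    nodule_count: int = 120
    area_median_um2: float = 3000.0   # log-normal median of nodule areas
    area_sigma: float = 0.45          # log-normal shape
    area_min_um2: float = 800.0
    area_max_um2: float = 12000.0
    background_level: float = 20.0
    live_level: float = 120.0
    dead_level: float = 30.0
    poisson_scale: float = 1.0        # photons per intensity unit; 0 = off
    gaussian_sd: float = 3.0          # read noise; 0 = off
    z_planes: int = 18
    z_step_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise GenerationError("pixel size and z step must be positive")
        if self.live_level <= self.background_level:
            raise GenerationError("live level must exceed background")
        if not (0 <= self.overlap_fraction < 1):
            raise GenerationError("overlap fraction must be in [0, 1)")

    @property
    def overlap_px(self) -> int:
        return int(round(self.overlap_fraction * self.tile_size))

    @property
    def stride_px(self) -> int:
        return self.tile_size - self.overlap_px

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        """(height, width) of the stitched mosaic in pixels."""
        h = self.grid_rows * self.tile_size - (self.grid_rows - 1) * self.overlap_px
        w = self.grid_cols * self.tile_size - (self.grid_cols - 1) * self.overlap_px
        return h, w

    @property
    def field_size_um(self) -> tuple[float, float]:
        h, w = self.mosaic_shape
        return w * self.pixel_size_um, h * self.pixel_size_um


@dataclass(frozen=True)
class Nodule:
    """One planted elliptical nodule (all lengths in µm, mosaic frame)."""

    id: int
    cx_um: float
    cy_um: float
    semi_x_um: float
    semi_y_um: float
    theta: float       # orientation, radians
    z_center: int
    z_extent: int      # number of planes carrying signal (2-4)
    viable: bool = True

    @property
    def area_um2(self) -> float:
        return float(np.pi * self.semi_x_um * self.semi_y_um)

    @property
    def radius_um(self) -> float:
        return float(max(self.semi_x_um, self.semi_y_um))

    def plane_weights(self, n_planes: int) -> dict[int, float]:
        """Triangular axial intensity profile, peak 1.0 at the centre plane."""
        profiles = {2: (0, 1), 3: (-1, 0, 1), 4: (-1, 0, 1, 2)}
        weights = {2: (1.0, 0.5), 3: (0.5, 1.0, 0.5), 4: (0.4, 1.0, 0.7, 0.3)}
        out = {}
        for off, wgt in zip(profiles[self.z_extent], weights[self.z_extent]):
            pl = self.z_center + off
            if 0 <= pl < n_planes:
                out[pl] = wgt
        return out


@dataclass
class Scene:
    """A planted field: spec plus the exact nodule geometry."""

    spec: SceneSpec
    nodules: list[Nodule]


@dataclass
class GroundTruthLedger:
    """Exact per-nodule truth; the oracle for segmentation recovery."""

    nodules: list[Nodule]

    @property
    def total_viable_area(self) -> float:
        return float(sum(n.area_um2 for n in self.nodules if n.viable))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"id": n.id, "cx_um": n.cx_um, "cy_um": n.cy_um,
                 "true_area_um2": n.area_um2, "z_center": n.z_center,
                 "z_extent": n.z_extent, "viable": n.viable}
                for n in self.nodules]
        return pd.DataFrame(rows)


def _sample_axes(rng: np.random.Generator, spec: SceneSpec) -> tuple[float, float]:
    area = np.exp(rng.normal(np.log(spec.area_median_um2), spec.area_sigma))
    area = float(np.clip(area, spec.area_min_um2, spec.area_max_um2))
    aspect = rng.uniform(1.0, 2.0)
    # area = pi * sx * sy with sx = aspect * sy
    sy = np.sqrt(area / (np.pi * aspect))
    return float(aspect * sy), float(sy)


def plant_nodules(spec: SceneSpec) -> tuple[Scene, GroundTruthLedger]:
    """Place non-overlapping elliptical nodules; return scene and exact truth.

    When ``nodule_count >= 10`` the first nodule is centred on an internal
    vertical tile seam so that cross-tile object merging is always exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    W_um, H_um = spec.field_size_um
    nodules: list[Nodule] = []
    placed: list[tuple[float, float, float]] = []  # (cx, cy, bounding radius)

    def fits(cx, cy, r):
        if not (r + 5 <= cx <= W_um - r - 5 and r + 5 <= cy <= H_um - r - 5):
            return False
        return all((cx - x) ** 2 + (cy - y) ** 2 > (r + rr + 10.0) ** 2
                   for x, y, rr in placed)

    attempts = 0
    while len(nodules) < spec.nodule_count:
        sx, sy = _sample_axes(rng, spec)
        theta = rng.uniform(0, np.pi)
        r = max(sx, sy)
        if len(nodules) == 0 and spec.nodule_count >= 10:
            # straddle the seam between the two central tile columns
            seam_col = spec.grid_cols // 2
            cx = seam_col * spec.stride_px * spec.pixel_size_um
            cy = H_um / 2.0
        else:
            cx = rng.uniform(0, W_um)
            cy = rng.uniform(0, H_um)
        if fits(cx, cy, r):
            zc = int(rng.integers(1, max(spec.z_planes - 2, 2)))
            ze = int(rng.integers(2, 5))
            nodules.append(Nodule(id=len(nodules), cx_um=cx, cy_um=cy,
                                  semi_x_um=sx, semi_y_um=sy, theta=theta,
                                  z_center=zc, z_extent=ze))
            placed.append((cx, cy, r))
        attempts += 1
        if attempts > 200 * max(spec.nodule_count, 1):
            raise GenerationError(
                f"could not place {spec.nodule_count} nodules in a "
                f"{W_um:.0f} x {H_um:.0f} µm field")
    scene = Scene(spec=spec, nodules=nodules)
    return scene, GroundTruthLedger(nodules=list(nodules))


def render_scene_plane(scene: Scene, plane: int,
                       region: tuple[int, int, int, int] | None = None) -> np.ndarray:
    """Noiseless intensity image of one Z-plane over a mosaic pixel region.

    ``region`` is (row0, row1, col0, col1) in mosaic pixel coordinates;
    default is the full mosaic.  This is the stitching/segmentation oracle:
    tiles are cut from exactly this field.
    """
    spec = scene.spec
    H, W = spec.mosaic_shape
    r0, r1, c0, c1 = region if region is not None else (0, H, 0, W)
    img = np.full((r1 - r0, c1 - c0), spec.background_level, dtype=float)
    px = spec.pixel_size_um
    # pixel centres in µm
    ys = (np.arange(r0, r1) + 0.5) * px
    xs = (np.arange(c0, c1) + 0.5) * px
    for nod in scene.nodules:
        wz = nod.plane_weights(spec.z_planes).get(plane)
        if wz is None:
            continue
        level = spec.live_level if nod.viable else spec.dead_level
        amp = (level - spec.background_level) * wz
        if amp <= 0:
            continue
        r = nod.radius_um
        ji = np.searchsorted(xs, [nod.cx_um - r - px, nod.cx_um + r + px])
        ii = np.searchsorted(ys, [nod.cy_um - r - px, nod.cy_um + r + px])
        if ji[0] >= ji[1] or ii[0] >= ii[1]:
            continue
        xl = xs[ji[0]:ji[1]] - nod.cx_um
        yl = ys[ii[0]:ii[1]] - nod.cy_um
        X, Y = np.meshgrid(xl, yl)
        ct, st = np.cos(nod.theta), np.sin(nod.theta)
        u = (X * ct + Y * st) / nod.semi_x_um
        v = (-X * st + Y * ct) / nod.semi_y_um
        inside = u * u + v * v <= 1.0
        sub = img[ii[0]:ii[1], ji[0]:ji[1]]
        np.maximum(sub, np.where(inside, spec.background_level + amp, 0.0), out=sub)
    return img


class ZStackMosaic:
    """Tiled multi-plane acquisition of a scene; tiles rendered on demand.

    Acts as the tile source for the quantification pipeline: exposes the grid
    layout and ``get_tile(row, col, plane)``.  Noise streams are keyed by
    (seed, row, col, plane), so reads are idempotent.
    """

    def __init__(self, scene: Scene):
        self.scene = scene
        spec = scene.spec
        self.n_rows = spec.grid_rows
        self.n_cols = spec.grid_cols
        self.n_planes = spec.z_planes
        self.tile_size = spec.tile_size
        self.overlap_px = spec.overlap_px
        self.pixel_size_um = spec.pixel_size_um

    @property
    def spec(self) -> SceneSpec:
        return self.scene.spec

    def tile_origin(self, row: int, col: int) -> tuple[int, int]:
        """Mosaic pixel coordinates of a tile's top-left corner."""
        s = self.spec.stride_px
        return row * s, col * s

    def get_tile(self, row: int, col: int, plane: int,
                 noiseless: bool = False) -> np.ndarray:
        spec = self.spec
        r0, c0 = self.tile_origin(row, col)
        t = spec.tile_size
        img = render_scene_plane(self.scene, plane, (r0, r0 + t, c0, c0 + t))
        if noiseless:
            return img
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 7, row, col, plane]))
        out = img
        if spec.poisson_scale > 0:
            out = rng.poisson(np.clip(out, 0, None) * spec.poisson_scale) \
                / spec.poisson_scale
        if spec.gaussian_sd > 0:
            out = out + rng.normal(0.0, spec.gaussian_sd, size=out.shape)
        return out.astype(float)

    def write(self, outdir: str | Path) -> Path:
        """Materialise the dataset: one multi-page TIFF per tile + manifest."""
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                stack = np.stack([self.get_tile(r, c, p)
                                  for p in range(self.n_planes)])
                tifffile.imwrite(outdir / f"tile_r{r:02d}_c{c:02d}.tif",
                                 stack.astype(np.float32),
                                 photometric="minisblack")
        manifest = {
            "grid_rows": self.n_rows, "grid_cols": self.n_cols,
            "tile_size": self.tile_size, "overlap_px": self.overlap_px,
            "n_planes": self.n_planes, "pixel_size_um": self.pixel_size_um,
            "z_step_um": self.spec.z_step_um, "seed": self.spec.seed,
            "tile_pattern": "tile_r{row:02d}_c{col:02d}.tif",
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return outdir / "manifest.json"


def render_tiles(scene: Scene) -> ZStackMosaic:
    """Tile the scene into the acquisition grid (lazy, deterministic)."""
    return ZStackMosaic(scene)


def render_calibration_pair(spec: SceneSpec, size: int = 256,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform live-level and dead-level calibration fields with noise.

    Emulates the untreated vs formalin-fixed calibration wells used to fix
    the calcein dynamic range: confluent viable signal vs killed signal.
    """
    out = []
    for key, level in ((11, spec.live_level), (12, spec.dead_level)):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, key]))
        img = np.full((size, size), float(level))
        if spec.poisson_scale > 0:
            img = rng.poisson(img * spec.poisson_scale) / spec.poisson_scale
        if spec.gaussian_sd > 0:
            img = img + rng.normal(0.0, spec.gaussian_sd, size=img.shape)
        out.append(img.astype(float))
    return out[0], out[1]


def simulate_experiment(
    doses: list[float],
    survival_fractions: list[float],
    replicates: int,
    spec: SceneSpec,
    replicate_cv: float = 0.08,
) -> tuple[dict[tuple[float, int], ZStackMosaic], pd.DataFrame]:
    """Per-dose, per-replicate datasets with planted survival fractions.

    Each replicate grows its own control scene; for a dose with survival
    fraction f, nodules are thinned (killed, i.e. flipped to the dead
    intensity level) and the survivors gently shrunk so that the planted
    viable area equals ``f * control_area`` times a replicate-level
    multiplicative noise factor of coefficient of variation ``replicate_cv``.
    The returned truth table records the exact planted areas.
    """
    if len(doses) != len(survival_fractions):
        raise GenerationError("doses and survival_fractions must align")
    fr = np.asarray(survival_fractions, dtype=float)
    if np.any((fr < 0) | (fr > 1)):
        raise GenerationError("survival fractions must lie in [0, 1]")
    if len(doses) and doses[0] == 0 and fr[0] != 1.0:
        raise GenerationError("the dose-0 survival fraction must be 1")

    datasets: dict[tuple[float, int], ZStackMosaic] = {}
    rows = []
    for rep in range(replicates):
        base_spec = replace(spec, seed=int(
            np.random.SeedSequence([spec.seed, 100, rep]).generate_state(1)[0]
            % (2 ** 31)))
        base_scene, base_ledger = plant_nodules(base_spec)
        a0 = base_ledger.total_viable_area
        for di, (dose, f) in enumerate(zip(doses, fr)):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 200, rep, di]))
            noise = 1.0 if replicate_cv == 0 else float(
                np.clip(rng.normal(1.0, replicate_cv), 0.5, 1.5))
            target = min(f * noise, 1.0) * a0
            scene = _thin_scene(base_scene, target, rng)
            planted = sum(n.area_um2 for n in scene.nodules if n.viable)
            datasets[(dose, rep)] = ZStackMosaic(scene)
            rows.append({"dose": dose, "replicate": rep,
                         "nominal_fraction": float(f),
                         "control_area_um2": a0,
                         "planted_viable_area_um2": planted,
                         "planted_fraction": planted / a0 if a0 > 0 else 0.0})
    return datasets, pd.DataFrame(rows)


def _thin_scene(base: Scene, target_area: float,
                rng: np.random.Generator) -> Scene:
    """Kill/shrink nodules so the viable planted area equals target exactly."""
    nodules = list(base.nodules)
    if target_area <= 0:
        new = [replace(n, viable=False) for n in nodules]
        return Scene(spec=base.spec, nodules=new)
    order = list(rng.permutation(len(nodules)))
    kept: list[int] = []
    total = 0.0
    for idx in order:
        if total >= target_area:
            break
        kept.append(idx)
        total += nodules[idx].area_um2
    # shrink survivors multiplicatively; keep the factor gentle by dropping
    # the last-added nodule if the overshoot is too large
    while kept:
        s = target_area / sum(nodules[i].area_um2 for i in kept)
        if s >= 0.7 or len(kept) == 1:
            break
        kept.pop()
    s = target_area / sum(nodules[i].area_um2 for i in kept)
    s = min(s, 1.0)
    root = np.sqrt(s)
    keep_set = set(kept)
    new = []
    for i, n in enumerate(nodules):
        if i in keep_set:
            new.append(replace(n, semi_x_um=n.semi_x_um * root,
                               semi_y_um=n.semi_y_um * root, viable=True))
        else:
            new.append(replace(n, viable=False))
    return Scene(spec=base.spec, nodules=new)
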