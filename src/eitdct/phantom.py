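"""Synthetic thorax phantoms for EIT simulation studies.

A scene is a smooth thorax-shaped domain with two dorsally flattened lung
regions, a CT-surrogate raster in Hounsfield units from which structural
priors are derived, per-region conductivities, and a ground-truth
conductivity-change raster.  Conductivities are in arbitrary units (AU):
baseline 0.5 inside the lungs and 1.0 elsewhere; full ventilation drops the
lung to 0.25.

Coordinates: ventral is +y, dorsal is -y; the thorax half-width is the
length unit.  All generation is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import UsageError
from .mesh import Mesh2D
from .raster import PixelImage

__all__ = [
    "PhantomScene",
    "ThoraxGeometry",
    "make_thorax_scene",
    "apply_pattern",
    "apply_atelectasis",
    "PATTERN_IDS",
]

BASELINE_LUNG_SIGMA = 0.5
BACKGROUND_SIGMA = 1.0
VENTILATED_SIGMA = 0.25
SIGMA_FLOOR = 1e-3  # stand-in for nominal sigma = 0 so the PDE stays elliptic
LUNG_HU = -700.0
TISSUE_HU = 40.0
ATELECTASIS_HU = 0.0
AIR_HU = -1000.0

PATTERN_IDS = ("a", "b", "c", "d", "e")


@dataclass
class ThoraxGeometry:
    """Analytic thorax-and-lungs geometry (ellipse-like, dorsally flattened)."""

    a: float  # thorax half-width
    b: float  # thorax half-height (ventral)
    dorsal_flatten: float  # relative reduction of the dorsal half-height
    lung_cx: float  # |x| of the lung centers
    lung_cy: float
    lung_rx: float
    lung_ry: float
    lung_dorsal_scale: float  # ry multiplier for the dorsal lung half

    def polygon(self, n_vertices: int = 256) -> np.ndarray:
        """Closed boundary ring starting at the ventral midline, clockwise."""
        th = np.pi / 2 - 2 * np.pi * np.arange(n_vertices) / n_vertices
        x = self.a * np.cos(th)
        s = np.sin(th)
        y = self.b * s * (1.0 - self.dorsal_flatten * np.clip(-s, 0.0, None))
        return np.column_stack([x, y])

    def _in_one_lung(self, x, y, cx):
        ry = np.where(y < self.lung_cy, self.lung_ry * self.lung_dorsal_scale,
                      self.lung_ry)
        return ((x - cx) / self.lung_rx) ** 2 + ((y - self.lung_cy) / ry) ** 2 <= 1.0

    def in_left_lung(self, x, y):
        return self._in_one_lung(np.asarray(x), np.asarray(y), -self.lung_cx)

    def in_right_lung(self, x, y):
        return self._in_one_lung(np.asarray(x), np.asarray(y), self.lung_cx)

    def in_lung(self, x, y):
        return self.in_left_lung(x, y) | self.in_right_lung(x, y)


@dataclass
class PhantomScene:
    """One simulation scene: geometry, CT surrogate, conductivities, truth."""

    thorax_polygon: np.ndarray
    extent: tuple
    lung_mask: np.ndarray  # (M, N) bool
    ct_surrogate: PixelImage  # hounsfield
    ground_truth: PixelImage  # conductivity change, zero outside the lungs
    geometry: ThoraxGeometry
    sigma_baseline_fn: Callable
    sigma_target_fn: Callable
    kind: str = "baseline"
    meta: dict = field(default_factory=dict)

    def element_conductivity(self, mesh: Mesh2D, which: str = "target"):
        """Per-element conductivity sampled at element centroids."""
        if which not in ("target", "baseline"):
            raise UsageError("which must be 'target' or 'baseline'")
        fn = self.sigma_target_fn if which == "target" else self.sigma_baseline_fn
        c = mesh.element_centroids()
        return np.asarray(fn(c[:, 0], c[:, 1]), dtype=float)


def _pixel_grid(M, N, extent):
    return PixelImage(np.zeros((M, N)), extent).pixel_centers()


def _scene_rasters(geom, M, N, extent):
    X, Y = _pixel_grid(M, N, extent)
    lung = geom.in_lung(X, Y)
    poly = Polygon(geom.polygon())
    thorax = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    return X, Y, lung, thorax


def _ct_from_weights(weights, lung, thorax):
    """CT surrogate whose HU/(-1000) detail weights equal ``weights`` in-lung."""
    hu = np.where(thorax, TISSUE_HU, AIR_HU)
    hu = np.where(lung, AIR_HU * np.clip(weights, 0.0, 1.0), hu)
    return hu


def make_thorax_scene(M: int, N: int, seed: int = 0) -> PhantomScene:
    """Baseline (reference-state) thorax scene on an M x N raster.

    The seed mildly perturbs the anatomy (thorax aspect, lung placement) so
    repeated studies do not share one fixed geometry; all randomness is
    confined to these shape parameters.
    """
    if M < 64 or N < 64:
        raise UsageError("raster must be at least 64 x 64")
    rng = np.random.default_rng(seed)
    geom = ThoraxGeometry(
        a=1.0,
        b=0.72 + 0.03 * rng.uniform(-1, 1),
        dorsal_flatten=0.22 + 0.04 * rng.uniform(-1, 1),
        lung_cx=0.42 + 0.02 * rng.uniform(-1, 1),
        lung_cy=-0.04 + 0.02 * rng.uniform(-1, 1),
        lung_rx=0.32 + 0.015 * rng.uniform(-1, 1),
        lung_ry=0.52 + 0.02 * rng.uniform(-1, 1),
        lung_dorsal_scale=0.7,
    )
    poly = geom.polygon()
    extent = (
        float(poly[:, 0].min()),
        float(poly[:, 0].max()),
        float(poly[:, 1].min()),
        float(poly[:, 1].max()),
    )
    X, Y, lung, thorax = _scene_rasters(geom, M, N, extent)

    ct = _ct_from_weights(np.full((M, N), 0.7), lung, thorax)

    def sigma_baseline(x, y):
        return np.where(geom.in_lung(x, y), BASELINE_LUNG_SIGMA, BACKGROUND_SIGMA)

    return PhantomScene(
        thorax_polygon=poly,
        extent=extent,
        lung_mask=lung,
        ct_surrogate=PixelImage(ct, extent, "hounsfield"),
        ground_truth=PixelImage(np.zeros((M, N)), extent, "conductivity"),
        geometry=geom,
        sigma_baseline_fn=sigma_baseline,
        sigma_target_fn=sigma_baseline,
        kind="baseline",
        meta={"seed": seed},
    )


def _lung_stats(scene):
    """Per-side and global lung-pixel statistics used by the patterns."""
    X, Y = _pixel_grid(*scene.lung_mask.shape, scene.extent)
    g = scene.geometry
    out = {}
    for side, member in (("left", g.in_left_lung), ("right", g.in_right_lung)):
        m = member(X, Y) & scene.lung_mask
        xs, ys = X[m], Y[m]
        cx, cy = xs.mean(), ys.mean()
        rmax = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2).max()
        out[side] = dict(
            cx=cx, cy=cy, rmax=rmax,
            xmin=xs.min(), xmax=xs.max(), ymin=ys.min(), ymax=ys.max(),
        )
    ys = Y[scene.lung_mask]
    xs = X[scene.lung_mask]
    out["bbox"] = (xs.min(), xs.max(), ys.min(), ys.max())
    return out


def _finish_target_scene(scene, nominal_fn, floored_fn, kind, weights=None,
                         meta=None):
    """Assemble a target scene from nominal/floored conductivity functions."""
    M, N = scene.lung_mask.shape
    X, Y, lung, thorax = _scene_rasters(scene.geometry, M, N, scene.extent)
    gt = np.where(lung, nominal_fn(X, Y) - BASELINE_LUNG_SIGMA, 0.0)
    if weights is None:
        amax = np.abs(gt[lung]).max()
        weights = np.abs(gt) / amax if amax > 0 else np.ones_like(gt)
    ct = _ct_from_weights(weights, lung, thorax)

    g = scene.geometry

    def sigma_target(x, y):
        inl = g.in_lung(x, y)
        return np.where(inl, floored_fn(x, y), BACKGROUND_SIGMA)

    return PhantomScene(
        thorax_polygon=scene.thorax_polygon,
        extent=scene.extent,
        lung_mask=scene.lung_mask,
        ct_surrogate=PixelImage(ct, scene.extent, "hounsfield"),
        ground_truth=PixelImage(gt, scene.extent, "conductivity"),
        geometry=scene.geometry,
        sigma_baseline_fn=scene.sigma_baseline_fn,
        sigma_target_fn=sigma_target,
        kind=kind,
        meta={**scene.meta, **(meta or {})},
    )


def apply_pattern(scene: PhantomScene, pattern_id: str) -> PhantomScene:
    """Target scene with one of the five lung conductivity patterns.

    a: uniform sigma = 0.25 over the whole lung;
    b: gravity-like gradient, sigma = 1 at the ventral lung edge decreasing
       linearly to 0.25 dorsally;
    c: radial gradient per lung, sigma = 1 at the lung centre decreasing
       linearly to 0.25 at the lung rim;
    d: four high-contrast circular patches (one ventral and one dorsal per
       lung) alternating sigma1 = 0 and sigma2 = 1, the rest unchanged;
    e: 8 x 8 chessboard over the lung bounding box alternating sigma1 = 0
       and sigma2 = 1.

    Nominal sigma = 0 is floored to 1e-3 in the forward conductivity; the
    ground truth keeps the nominal value.  The CT surrogate encodes the
    ventilation magnitude (|delta sigma| min-max normalized over the lung) as
    HU = -1000 * w, so the standard HU -> weight rule recovers the
    ground-truth-derived detail prior.
    """
    if scene.kind != "baseline":
        raise UsageError("patterns must be applied to a baseline scene")
    if pattern_id not in PATTERN_IDS:
        raise UsageError(f"unknown pattern id '{pattern_id}'")
    st = _lung_stats(scene)
    g = scene.geometry

    if pattern_id == "a":
        def nominal(x, y):
            return np.full(np.shape(x), VENTILATED_SIGMA)
        floored = nominal

    elif pattern_id == "b":
        ymin, ymax = st["bbox"][2], st["bbox"][3]

        def nominal(x, y):
            t = np.clip((np.asarray(y) - ymin) / (ymax - ymin), 0.0, 1.0)
            return VENTILATED_SIGMA + (1.0 - VENTILATED_SIGMA) * t
        floored = nominal

    elif pattern_id == "c":
        def nominal(x, y):
            x, y = np.asarray(x, float), np.asarray(y, float)
            left = g.in_left_lung(x, y)
            s = st["left"]
            r_l = np.sqrt((x - s["cx"]) ** 2 + (y - s["cy"]) ** 2) / s["rmax"]
            s = st["right"]
            r_r = np.sqrt((x - s["cx"]) ** 2 + (y - s["cy"]) ** 2) / s["rmax"]
            r = np.where(left, r_l, r_r)
            return 1.0 - (1.0 - VENTILATED_SIGMA) * np.clip(r, 0.0, 1.0)
        floored = nominal

    elif pattern_id == "d":
        patches = []  # (cx, cy, radius, sigma_nominal)
        for side, polarity in (("left", 0), ("right", 1)):
            s = st[side]
            ry = 0.5 * (s["ymax"] - s["ymin"])
            rad = 0.30 * 0.5 * (s["xmax"] - s["xmin"])  # 0.3 of the half-width
            sig_v, sig_d = (0.0, 1.0) if polarity == 0 else (1.0, 0.0)
            patches.append((s["cx"], s["cy"] + 0.5 * ry, rad, sig_v))
            patches.append((s["cx"], s["cy"] - 0.5 * ry, rad, sig_d))

        def make(floor):
            def fn(x, y):
                x, y = np.asarray(x, float), np.asarray(y, float)
                out = np.full(x.shape, BASELINE_LUNG_SIGMA)
                for cx, cy, rad, sig in patches:
                    hit = (x - cx) ** 2 + (y - cy) ** 2 <= rad ** 2
                    out = np.where(hit, max(sig, floor) if floor else sig, out)
                return out
            return fn

        nominal, floored = make(0.0), make(SIGMA_FLOOR)

    else:  # pattern e
        x0, x1, y0, y1 = st["bbox"]
        cw, ch = (x1 - x0) / 8.0, (y1 - y0) / 8.0

        def make(lo):
            def fn(x, y):
                x, y = np.asarray(x, float), np.asarray(y, float)
                ix = np.clip(np.floor((x - x0) / cw), 0, 7)
                iy = np.clip(np.floor((y - y0) / ch), 0, 7)
                odd = (ix + iy) % 2 == 1
                return np.where(odd, 1.0, lo)
            return fn

        nominal, floored = make(0.0), make(SIGMA_FLOOR)

    return _finish_target_scene(
        scene, nominal, floored, kind=f"pattern:{pattern_id}",
        meta={"pattern": pattern_id},
    )


def apply_atelectasis(
    scene: PhantomScene, fraction: float, ventilation_sigma: float = VENTILATED_SIGMA
) -> PhantomScene:
    """Target scene with a dorsal atelectatic slab in each lung.

    The dorsal-most horizontal slab holding ``fraction`` of each lung's area
    keeps the baseline conductivity (collapsed tissue: no ventilation signal)
    and is set to 0 HU in the CT surrogate; the remaining lung ventilates to
    ``ventilation_sigma`` and stays at -700 HU.
    """
    if scene.kind != "baseline":
        raise UsageError("atelectasis must be applied to a baseline scene")
    if not (0.0 <= fraction <= 0.5):
        raise UsageError("atelectasis fraction must be in [0, 0.5]")
    M, N = scene.lung_mask.shape
    X, Y, lung, thorax = _scene_rasters(scene.geometry, M, N, scene.extent)
    g = scene.geometry
    dy = (scene.extent[3] - scene.extent[2]) / M

    thresholds = {}
    for side, member in (("left", g.in_left_lung), ("right", g.in_right_lung)):
        m = member(X, Y) & lung
        counts = m.sum(axis=1)  # per raster row, row 0 = ventral
        total = counts.sum()
        if fraction == 0.0 or total == 0:
            thresholds[side] = -np.inf
            continue
        cum = np.cumsum(counts[::-1])[::-1]  # pixels at or dorsal of each row
        rows = np.nonzero(cum >= fraction * total)[0]
        m_star = rows.max()  # smallest slab with at least the requested area
        y_row_center = Y[m_star, 0]
        thresholds[side] = y_row_center + dy / 2.0  # top edge of the slab

    def in_atelectasis(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        left = g.in_left_lung(x, y)
        right = g.in_right_lung(x, y)
        return (left & (y < thresholds["left"])) | (
            right & (y < thresholds["right"])
        )

    def nominal(x, y):
        atel = in_atelectasis(x, y)
        return np.where(atel, BASELINE_LUNG_SIGMA, ventilation_sigma)

    atel_mask = in_atelectasis(X, Y) & lung
    weights = np.where(atel_mask, 0.0, 0.7)  # -700 HU ventilated, 0 HU collapsed
    return _finish_target_scene(
        scene, nominal, nominal, kind=f"atelectasis:{fraction:g}",
        weights=weights,
        meta={"fraction": float(fraction),
              "ventilation_sigma": float(ventilation_sigma),
              "atelectasis_mask": atel_mask},
    )
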