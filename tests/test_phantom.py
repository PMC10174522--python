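import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon

from eitdct import (
    apply_atelectasis,
    apply_pattern,
    build_mesh,
    make_detail_prior,
    make_thorax_scene,
)
from eitdct.errors import UsageError
from eitdct.phantom import BASELINE_LUNG_SIGMA, SIGMA_FLOOR
from eitdct.raster import PixelElementMap


def test_lungs_strictly_inside_thorax(scene128):
    X, Y = scene128.ground_truth.pixel_centers()
    poly = Polygon(scene128.thorax_polygon)
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    assert np.all(inside[scene128.lung_mask])


def test_lung_area_fraction(scene128):
    X, Y = scene128.ground_truth.pixel_centers()
    poly = Polygon(scene128.thorax_polygon)
    thorax = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    frac = scene128.lung_mask.sum() / thorax.sum()
    assert 0.30 <= frac <= 0.50


def test_baseline_scene(scene128):
    assert np.all(scene128.ground_truth.values == 0.0)
    hu = scene128.ct_surrogate.values
    assert np.all(hu[scene128.lung_mask] == -700.0)
    assert hu.min() >= -1000.0 and hu.max() <= 100.0
    prior = make_detail_prior(scene128.ct_surrogate, scene128.lung_mask)
    assert np.allclose(prior.weights[scene128.lung_mask], 0.7)


def test_scene_generation_deterministic():
    a = make_thorax_scene(96, 96, seed=7)
    b = make_thorax_scene(96, 96, seed=7)
    c = make_thorax_scene(96, 96, seed=8)
    assert np.array_equal(a.lung_mask, b.lung_mask)
    assert np.array_equal(a.thorax_polygon, b.thorax_polygon)
    assert not np.array_equal(a.thorax_polygon, c.thorax_polygon)


def test_pattern_a_uniform_change(scene128):
    scene = apply_pattern(scene128, "a")
    gt = scene.ground_truth.values
    assert np.allclose(gt[scene.lung_mask], -0.25)
    assert np.all(gt[~scene.lung_mask] == 0.0)
    mesh = build_mesh(scene.thorax_polygon, 16, 1000)
    sig = scene.element_conductivity(mesh, "target")
    in_lung = scene.element_conductivity(mesh, "baseline") == BASELINE_LUNG_SIGMA
    assert np.allclose(sig[in_lung], 0.25)


def test_pattern_b_ventral_edge_is_one(scene128):
    scene = apply_pattern(scene128, "b")
    gt = scene.ground_truth.values
    rows, cols = np.nonzero(scene.lung_mask)
    ventral_row = rows.min()  # row 0 is the ventral edge of the raster
    top = gt[rows[rows == ventral_row], cols[rows == ventral_row]]
    # sigma = 1 at the ventral lung edge -> change +0.5 against baseline 0.5
    assert np.all(top > 0.45)


def test_pattern_c_center_is_one(scene128):
    scene = apply_pattern(scene128, "c")
    g = scene.geometry
    X, Y = scene.ground_truth.pixel_centers()
    right = g.in_right_lung(X, Y) & scene.lung_mask
    cx, cy = X[right].mean(), Y[right].mean()  # radial gradient centre
    val = scene.sigma_target_fn(np.array([cx]), np.array([cy]))
    assert np.allclose(val, 1.0, atol=0.02)


def test_pattern_e_chessboard(scene128):
    scene = apply_pattern(scene128, "e")
    gt = scene.ground_truth.values
    lung_vals = gt[scene.lung_mask]
    assert set(np.round(np.unique(lung_vals), 3)) == {-0.5, 0.5}
    # adjacent cells differ: sample two neighbouring cell centers
    rows, cols = np.nonzero(scene.lung_mask)
    x0, x1 = cols.min(), cols.max()
    y0 = rows.min()
    cell = (x1 - x0) / 8.0
    r = int(y0 + cell / 2)
    c1, c2 = int(x0 + cell / 2), int(x0 + 3 * cell / 2)
    if scene.lung_mask[r, c1] and scene.lung_mask[r, c2]:
        assert gt[r, c1] != gt[r, c2]
    # the forward conductivity floors nominal 0 for solvability
    mesh = build_mesh(scene.thorax_polygon, 16, 1000)
    assert scene.element_conductivity(mesh, "target").min() >= SIGMA_FLOOR


def test_pattern_d_has_four_patches(scene128):
    scene = apply_pattern(scene128, "d")
    gt = scene.ground_truth.values
    assert (gt == -0.5).any() and (gt == 0.5).any()
    changed = scene.lung_mask & (gt != 0)
    unchanged = scene.lung_mask & (gt == 0)
    assert changed.sum() > 0 and unchanged.sum() > changed.sum()


def test_unknown_pattern_rejected(scene128):
    with pytest.raises(UsageError):
        apply_pattern(scene128, "z")


def test_atelectasis_zero_fraction_equals_pattern_a(scene128):
    atel = apply_atelectasis(scene128, 0.0, ventilation_sigma=0.25)
    pat = apply_pattern(scene128, "a")
    assert np.allclose(atel.ground_truth.values, pat.ground_truth.values)


@pytest.mark.parametrize("fraction", [0.25, 0.5])
def test_atelectasis_slab_area_and_location(scene128, fraction):
    scene = apply_atelectasis(scene128, fraction)
    atel = scene.meta["atelectasis_mask"]
    gt = scene.ground_truth.values
    assert np.all(gt[atel] == 0.0)  # no ventilation signal in the slab
    g = scene128.geometry
    X, Y = scene128.ground_truth.pixel_centers()
    for member in (g.in_left_lung, g.in_right_lung):
        side = member(X, Y) & scene128.lung_mask
        side_atel = atel & side
        rel = side_atel.sum() / side.sum()
        # dorsal-most slab by area, to within one raster-row of rounding
        max_row_px = side.sum(axis=1).max()
        assert abs(side_atel.sum() - fraction * side.sum()) <= max_row_px
        assert 0 < rel < 1
        # slab is dorsal: every atelectatic pixel lies below every ventilated one
        ventilated = side & ~atel
        assert Y[side_atel].max() < Y[ventilated].min() + 1e-9
    hu = scene.ct_surrogate.values
    assert np.all(hu[atel] == 0.0)
    assert np.all(hu[scene.lung_mask & ~atel] == -700.0)


def test_atelectasis_fraction_out_of_range(scene128):
    with pytest.raises(UsageError):
        apply_atelectasis(scene128, 0.6)


def test_element_and_raster_conductivity_agree(scene128, thorax_inverse_mesh):
    """Painting element conductivity changes matches the ground-truth raster."""
    scene = apply_pattern(scene128, "a")
    mesh = thorax_inverse_mesh
    delta = scene.element_conductivity(mesh, "target") - scene.element_conductivity(
        mesh, "baseline"
    )
    pmap = PixelElementMap(mesh, scene.extent, scene.lung_mask.shape)
    painted = pmap.paint(delta).values
    inside = pmap.element_of_pixel.reshape(scene.lung_mask.shape) >= 0
    differ = np.abs(painted - scene.ground_truth.values)[inside] > 0.05
    assert differ.mean() <= 0.02  # rasterization error confined to edges
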