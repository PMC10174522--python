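import numpy as np
import pytest

from eitdct import (
    ReconConfig,
    apply_atelectasis,
    build_dct_basis,
    calibrate_lambda,
    central_target_signal,
    make_contour_prior,
    make_detail_prior,
    make_subset_basis,
    normalized_jacobian,
    reconstruct,
    reconstruct_pipeline,
    restore_image,
    solve_forward,
    simulate_measurement,
)
from eitdct.errors import CalibrationError, ShapeError
from eitdct.solver import DctPipeline, _SvdOperator, noise_figure


def augmented_lstsq(J, y, lam, R=None):
    """Independent oracle: minimize ||Jx-y||^2 + lam^2 ||Rx||^2 by stacking."""
    n = J.shape[1]
    R = np.eye(n) if R is None else R
    A = np.vstack([J, lam * R])
    b = np.concatenate([y, np.zeros(R.shape[0])])
    return np.linalg.lstsq(A, b, rcond=None)[0]


@pytest.fixture(scope="module")
def small_problem(disk_mesh_small, protocol16):
    """<= 700-element disk, 6x6 DCT basis masked by a centred blob prior."""
    J, _ = normalized_jacobian(
        disk_mesh_small, np.ones(disk_mesh_small.n_elems), protocol16
    )
    M = N = 32
    yy, xx = np.meshgrid(np.arange(M), np.arange(N), indexing="ij")
    mask = (xx - 15.5) ** 2 + (yy - 15.5) ** 2 <= 10**2
    prior = make_contour_prior(mask)
    basis = build_dct_basis(M, N, 6, 6)
    extent = disk_mesh_small.bounding_box()
    sub = make_subset_basis(basis, prior, disk_mesh_small, extent, jacobian=J)
    return J, sub, mask


def test_closed_form_matches_augmented_lstsq(small_problem):
    J, sub, _ = small_problem
    rng = np.random.default_rng(0)
    y = rng.normal(size=J.shape[0])
    for lam in (1e-3, 0.1, 10.0):
        x = reconstruct(sub.J_dct, y, lam)
        ref = augmented_lstsq(sub.J_dct, y, lam)
        assert np.linalg.norm(x - ref) <= 1e-8 * np.linalg.norm(ref)


def test_reconstruct_zero_frame_and_linearity(small_problem):
    J, sub, _ = small_problem
    assert np.all(reconstruct(sub.J_dct, np.zeros(208), 0.1) == 0.0)
    rng = np.random.default_rng(3)
    y1, y2 = rng.normal(size=(2, 208))
    lhs = reconstruct(sub.J_dct, 2.0 * y1 - 0.5 * y2, 0.2)
    rhs = 2.0 * reconstruct(sub.J_dct, y1, 0.2) - 0.5 * reconstruct(
        sub.J_dct, y2, 0.2
    )
    assert np.allclose(lhs, rhs, atol=1e-12)


def test_solution_norm_vanishes_with_lambda(small_problem):
    J, sub, _ = small_problem
    y = np.random.default_rng(5).normal(size=208)
    norms = [
        np.linalg.norm(reconstruct(sub.J_dct, y, lam))
        for lam in (0.1, 1.0, 10.0, 100.0, 1e4)
    ]
    assert all(a > b for a, b in zip(norms, norms[1:]))
    assert norms[-1] < 1e-6 * norms[0]


def test_noise_figure_calibration(small_problem, disk_mesh_small):
    J, sub, _ = small_problem
    y_hom = central_target_signal(J, disk_mesh_small)
    lam, nf = calibrate_lambda(sub.J_dct, y_hom, 0.5)
    assert lam > 0
    assert 0.495 <= nf <= 0.505
    # NF(lambda) is monotone decreasing over the bracket
    op = _SvdOperator(sub.J_dct)
    uty, yn = op.U.T @ y_hom, np.linalg.norm(y_hom)
    grid = [op.nf(10.0**e, uty, yn) for e in np.linspace(-8, 8, 33)]
    assert all(a >= b - 1e-12 for a, b in zip(grid, grid[1:]))
    # matches the dense definition at the calibrated point
    B = (op.V * op.filter(lam)) @ op.U.T
    assert np.isclose(noise_figure(B, y_hom), nf, rtol=1e-10)


def test_unreachable_noise_figure_reports_range(small_problem, disk_mesh_small):
    J, sub, _ = small_problem
    y_hom = central_target_signal(J, disk_mesh_small)
    with pytest.raises(CalibrationError) as exc:
        calibrate_lambda(sub.J_dct, y_hom, 1e-9)
    lo, hi = exc.value.attainable_range
    assert lo < hi


def test_restore_image(small_problem):
    _, sub, mask = small_problem
    zero = restore_image(np.zeros(36), sub.C_stack)
    assert np.all(zero.values == 0.0)
    e1 = np.zeros(36)
    e1[0] = 1.0
    assert np.array_equal(restore_image(e1, sub.C_stack).values, sub.C_stack[0])
    rng = np.random.default_rng(9)
    H = restore_image(rng.normal(size=36), sub.C_stack)
    assert np.all(H.values[~mask] == 0.0)  # support confinement is exact
    with pytest.raises(ShapeError):
        restore_image(np.zeros(35), sub.C_stack)


@pytest.fixture(scope="module")
def thorax_setup(scene128, thorax_inverse_mesh, protocol16):
    sigma = scene128.element_conductivity(thorax_inverse_mesh, "baseline")
    J, _ = normalized_jacobian(thorax_inverse_mesh, sigma, protocol16)
    return J


def test_pipeline_caching_and_sign(scene128, thorax_inverse_mesh, protocol16,
                                   thorax_setup):
    J = thorax_setup
    prior = make_contour_prior(scene128.lung_mask)
    from eitdct import apply_pattern

    scene = apply_pattern(scene128, "a")
    target = thorax_inverse_mesh.with_conductivity(
        scene.element_conductivity(thorax_inverse_mesh, "target")
    )
    baseline = thorax_inverse_mesh.with_conductivity(
        scene.element_conductivity(thorax_inverse_mesh, "baseline")
    )
    vt = solve_forward(target, protocol16).values
    vb = solve_forward(baseline, protocol16).values
    y1 = simulate_measurement(None, None, protocol16, 0.0, 0,
                              v_target=vt, v_baseline=vb)
    y2 = simulate_measurement(None, None, protocol16, 0.25, 1,
                              v_target=vt, v_baseline=vb)
    r1 = reconstruct_pipeline(thorax_inverse_mesh, prior, J, y1,
                              extent=scene128.extent)
    r2 = reconstruct_pipeline(thorax_inverse_mesh, prior, J, y2,
                              extent=scene128.extent)
    # frames with the same prior reuse the cached reconstruction matrix
    assert r1.reconstruction_matrix_hash == r2.reconstruction_matrix_hash
    assert 0.495 <= r1.achieved_noise_figure <= 0.505
    # conductivity dropped in the lung -> noise-free image negative there
    H = r1.restored_image.values
    assert H[scene128.lung_mask].mean() < 0
    assert np.all(H[~scene128.lung_mask] == 0.0)


def test_detail_prior_inhibits_atelectatic_slab(scene128, thorax_inverse_mesh,
                                                protocol16, thorax_setup):
    J = thorax_setup
    scene = apply_atelectasis(scene128, 0.3)
    prior = make_detail_prior(scene.ct_surrogate, scene.lung_mask)
    atel = scene.meta["atelectasis_mask"]
    assert np.all(prior.weights[atel] == 0.0)
    basis = build_dct_basis(128, 128, 15, 15)
    pipe = DctPipeline(thorax_inverse_mesh, prior, J, basis, scene128.extent,
                       ReconConfig())
    y = np.random.default_rng(2).normal(size=208)  # any frame: support is exact
    H = pipe.reconstruct(y).restored_image.values
    assert np.all(H[atel] == 0.0)
    assert np.all(H[~scene.lung_mask] == 0.0)
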