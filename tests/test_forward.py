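import numpy as np
import pytest

from eitdct import (
    add_noise,
    adjacent_protocol,
    compute_jacobian,
    simulate_measurement,
    solve_forward,
)
from eitdct.errors import NormalizationError
from eitdct.forward import CEMSolver, _unique_pairs


# --------------------------------------------------------------------------
# Independent dense-matrix CEM assembly (oracle): different code path --
# per-triangle gradients from a 3x3 solve, boundary integrals by 2-point
# Gauss quadrature, grounded-node gauge instead of a zero-mean multiplier.


def dense_cem_frame(mesh, protocol):
    n, L = mesh.n_nodes, mesh.n_elec
    A = np.zeros((n + L, n + L))
    for e, tri in enumerate(mesh.elements):
        p = mesh.nodes[tri]
        M = np.column_stack([np.ones(3), p])
        coef = np.linalg.inv(M)  # rows: 1, x, y coefficients of each basis
        grads = coef[1:, :]  # (2, 3)
        area = 0.5 * abs(np.linalg.det(M))
        A[np.ix_(tri, tri)] += (
            mesh.element_conductivity[e] * area * grads.T @ grads
        )
    gauss = (np.array([-1, 1]) / np.sqrt(3) + 1) / 2  # points on [0, 1]
    for l, group in enumerate(mesh.electrodes):
        z = mesh.contact_impedance[l]
        for a, b in zip(group[:-1], group[1:]):
            pa, pb = mesh.nodes[a], mesh.nodes[b]
            ln = np.linalg.norm(pb - pa)
            for t in gauss:
                phi = np.array([1 - t, t])
                w = ln / 2.0 / z
                A[np.ix_([a, b], [a, b])] += w * np.outer(phi, phi)
                A[[a, b], n + l] -= w * phi
                A[n + l, [a, b]] -= w * phi
            A[n + l, n + l] += ln / z
    keep = np.arange(1, n + L)  # ground node 0
    vals = []
    for k, (ia, ib) in enumerate(protocol.injection_pairs):
        rhs = np.zeros(n + L)
        rhs[n + ia] = protocol.current_amplitude
        rhs[n + ib] = -protocol.current_amplitude
        u = np.zeros(n + L)
        u[keep] = np.linalg.solve(A[np.ix_(keep, keep)], rhs[keep])
        U = u[n:]
        pairs = protocol.measurement_pairs[k]
        vals.append(U[pairs[:, 0]] - U[pairs[:, 1]])
    return np.concatenate(vals)


def test_forward_matches_independent_dense_assembly(disk_mesh_small, protocol16):
    v = solve_forward(disk_mesh_small, protocol16).values
    v_ref = dense_cem_frame(disk_mesh_small, protocol16)
    assert np.allclose(v, v_ref, rtol=1e-9, atol=1e-12)


def test_reciprocity(disk_mesh_small, protocol16):
    """Drive/measure swap leaves the voltage unchanged (self-adjointness)."""
    pairs, _ = _unique_pairs(protocol16)
    _, U = CEMSolver(disk_mesh_small).solve_pairs(pairs)
    V = U[pairs[:, 0], :] - U[pairs[:, 1], :]
    assert np.abs(V - V.T).max() <= 1e-10 * np.abs(V).max()


def test_conductivity_scaling(disk_mesh_small, protocol16):
    from eitdct.mesh import Mesh2D

    v = solve_forward(disk_mesh_small, protocol16).values
    c = 2.7
    scaled = Mesh2D(
        disk_mesh_small.nodes,
        disk_mesh_small.elements,
        disk_mesh_small.element_conductivity * c,
        disk_mesh_small.electrodes,
        disk_mesh_small.contact_impedance / c,  # CEM homogeneity needs z/c
        disk_mesh_small.boundary_nodes,
    )
    v_scaled = solve_forward(scaled, protocol16).values
    assert np.allclose(v_scaled, v / c, rtol=1e-10)
    # with contact impedance held fixed the scaling still holds approximately
    v_fix = solve_forward(
        disk_mesh_small.with_conductivity(
            disk_mesh_small.element_conductivity * c
        ),
        protocol16,
    ).values
    assert np.allclose(v_fix, v / c, rtol=0.02)


def test_measurement_magnitude_decays_away_from_injection(disk_mesh_small,
                                                          protocol16):
    v = solve_forward(disk_mesh_small, protocol16).values
    first = np.abs(v[:13])  # injection (0, 1); meas pairs (2,3) .. (14,15)
    assert (np.diff(first[:7]) < 0).all()  # decreasing toward the far side
    assert (np.diff(first[6:]) > 0).all()  # increasing back toward the drive


def test_rotation_symmetry_of_disk_frame(disk_mesh_small, protocol16):
    """Electrode relabeling i -> i+1 permutes the frame (mesh-resolution tol)."""
    v = solve_forward(disk_mesh_small, protocol16).values
    full = np.full((16, 16), np.nan)  # (injection, measurement-pair start)
    i = 0
    for k, pairs in enumerate(protocol16.measurement_pairs):
        for a, _ in pairs:
            full[k, a] = v[i]
            i += 1
    rotated = np.roll(np.roll(full, 1, axis=0), 1, axis=1)
    mask = ~np.isnan(full) & ~np.isnan(rotated)
    err = np.linalg.norm(full[mask] - rotated[mask])
    assert err <= 0.05 * np.linalg.norm(full[mask])


def test_jacobian_matches_finite_differences(disk_mesh_small, protocol16):
    sigma = np.ones(disk_mesh_small.n_elems)
    J = compute_jacobian(disk_mesh_small, sigma, protocol16).entries
    assert J.shape == (208, disk_mesh_small.n_elems)
    rng = np.random.default_rng(0)
    eps = 1e-6
    for j in rng.choice(disk_mesh_small.n_elems, 12, replace=False):
        sp, sm = sigma.copy(), sigma.copy()
        sp[j] += eps
        sm[j] -= eps
        fd = (
            solve_forward(disk_mesh_small.with_conductivity(sp), protocol16).values
            - solve_forward(disk_mesh_small.with_conductivity(sm), protocol16).values
        ) / (2 * eps)
        assert np.abs(fd - J[:, j]).max() <= 1e-4 * np.abs(J[:, j]).max()


def test_jacobian_first_order_consistency(disk_mesh_small, protocol16):
    sigma = np.ones(disk_mesh_small.n_elems)
    J = compute_jacobian(disk_mesh_small, sigma, protocol16).entries
    v0 = solve_forward(disk_mesh_small, protocol16).values
    rng = np.random.default_rng(1)
    d = rng.normal(size=disk_mesh_small.n_elems)
    d /= np.abs(d).max()
    ratios = []
    for scale in (1e-2, 1e-3, 1e-4):
        delta = scale * d
        v1 = solve_forward(
            disk_mesh_small.with_conductivity(sigma + delta), protocol16
        ).values
        ratios.append(
            np.linalg.norm(v1 - v0 - J @ delta) / np.linalg.norm(J @ delta)
        )
    assert ratios[0] < 0.02
    # first-order convergence: error ratio shrinks ~linearly with the step
    assert ratios[1] < ratios[0] / 3
    assert ratios[2] < ratios[1] / 3


def test_simulated_measurement_noise_contract(disk_mesh_small, protocol16):
    mesh_t = disk_mesh_small.with_conductivity(
        disk_mesh_small.element_conductivity.copy()
    )
    y0 = simulate_measurement(mesh_t, disk_mesh_small, protocol16,
                              noise_fraction=0.0, seed=0)
    assert y0.is_normalized
    assert np.all(y0.values == 0.0)  # identical target and baseline

    y1 = simulate_measurement(mesh_t, disk_mesh_small, protocol16, 0.25, seed=42)
    y2 = simulate_measurement(mesh_t, disk_mesh_small, protocol16, 0.25, seed=42)
    assert np.array_equal(y1.values, y2.values)  # bit-identical per seed


def test_noise_std_matches_model():
    """Monte-Carlo: injected noise std is 25% of std(V - Vb) within 2%."""
    rng = np.random.default_rng(3)
    diff = rng.normal(size=208) * 0.05
    target = 0.25 * diff.std()
    draws = np.array(
        [add_noise(diff, 0.25, np.random.default_rng(s)) - diff
         for s in range(10_000)]
    )
    assert abs(draws.std() - target) <= 0.02 * target


def test_tiny_baseline_voltage_rejected(disk_mesh_small, protocol16):
    v = solve_forward(disk_mesh_small, protocol16).values
    bad = v.copy()
    bad[5] = 1e-13
    with pytest.raises(NormalizationError):
        simulate_measurement(None, None, protocol16, 0.1, 0,
                             v_target=v, v_baseline=bad)
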