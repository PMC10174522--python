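"""Complete-electrode-model forward solver, adjoint Jacobian and simulation.

The forward problem is the 2D elliptic PDE div(sigma grad u) = 0 with the
complete electrode model (CEM): finite-width electrodes with contact
impedance z_l, current I_l driven through electrode l, and the electrode
potentials U_l as extra unknowns.  Linear (P1) triangles are used.  The
system is gauged by constraining the node potentials to zero mean, which
leaves all measured voltage differences unchanged.

Measurements follow the adjacent (neighbouring-pair) stimulation and
measurement pattern common in commercial thoracic EIT devices: for 16
electrodes with measurements on driven electrodes excluded this yields
16 x 13 = 208 values per frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import NormalizationError, ShapeError, SolverError, UsageError
from .mesh import Mesh2D

__all__ = [
    "StimulationProtocol",
    "VoltageFrame",
    "JacobianMatrix",
    "adjacent_protocol",
    "solve_forward",
    "compute_jacobian",
    "normalized_jacobian",
    "add_noise",
    "simulate_measurement",
]


@dataclass
class StimulationProtocol:
    """Current-injection and voltage-measurement schedule.

    ``measurement_pairs[k]`` lists the electrode pairs measured while
    ``injection_pairs[k]`` is driven.
    """

    n_elec: int
    injection_pairs: np.ndarray  # (n_inj, 2) int
    measurement_pairs: list  # list of (n_k, 2) int arrays
    current_amplitude: float = 1.0
    exclude_driven: bool = True

    @property
    def n_meas(self) -> int:
        return sum(len(m) for m in self.measurement_pairs)


def adjacent_protocol(
    n_elec: int = 16, current_amplitude: float = 1.0, exclude_driven: bool = True
) -> StimulationProtocol:
    """Adjacent stimulation with adjacent measurement.

    With ``exclude_driven`` (the commercial convention) every pair touching a
    driven electrode is skipped, giving ``n_elec * (n_elec - 3)`` measurements.
    """
    if n_elec < 4:
        raise UsageError("adjacent protocol needs at least 4 electrodes")
    inj = np.array([(k, (k + 1) % n_elec) for k in range(n_elec)], dtype=int)
    meas = []
    for a, b in inj:
        pairs = []
        for m in range(n_elec):
            pair = (m, (m + 1) % n_elec)
            if exclude_driven and ({a, b} & set(pair)):
                continue
            pairs.append(pair)
        meas.append(np.array(pairs, dtype=int))
    return StimulationProtocol(
        n_elec=n_elec,
        injection_pairs=inj,
        measurement_pairs=meas,
        current_amplitude=float(current_amplitude),
        exclude_driven=exclude_driven,
    )


@dataclass
class VoltageFrame:
    """One frame of boundary voltages (raw or normalized differences)."""

    values: np.ndarray
    is_normalized: bool = False
    noise_seed: int | None = None


@dataclass
class JacobianMatrix:
    """Sensitivity of boundary measurements to per-element conductivity."""

    entries: np.ndarray  # (n_meas, n_elems)
    linearization: np.ndarray  # per-element sigma at which J was evaluated


# ---------------------------------------------------------------------------
# FEM assembly


def _element_gradients(nodes, elements):
    """Per-element gradient operators of P1 basis functions.

    Returns ``(bx, by, area)``, each row e giving coefficients so that for a
    nodal field u the constant element gradient is
    ``(bx[e] @ u[elements[e]], by[e] @ u[elements[e]])``.
    """
    p = nodes[elements]  # (m, 3, 2)
    x, y = p[..., 0], p[..., 1]
    det = (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0]) - (x[:, 2] - x[:, 0]) * (
        y[:, 1] - y[:, 0]
    )
    area = 0.5 * np.abs(det)
    bx = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    by = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    bx = bx / det[:, None]
    by = by / det[:, None]
    return bx, by, area


def _stiffness(nodes, elements, sigma):
    bx, by, area = _element_gradients(nodes, elements)
    n = len(nodes)
    w = (sigma * area)[:, None, None]
    local = w * (bx[:, :, None] * bx[:, None, :] + by[:, :, None] * by[:, None, :])
    rows = np.repeat(elements, 3, axis=1).ravel()
    cols = np.tile(elements, (1, 3)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def _electrode_edges(mesh: Mesh2D):
    """Boundary edges (node pairs + lengths) under each electrode."""
    edges = []
    for group in mesh.electrodes:
        a = np.asarray(group[:-1])
        b = np.asarray(group[1:])
        ln = np.linalg.norm(mesh.nodes[b] - mesh.nodes[a], axis=1)
        edges.append((a, b, ln))
    return edges


def _cem_system(mesh: Mesh2D):
    """Assemble the gauged CEM system matrix (nodes + electrodes + 1)."""
    n, L = mesh.n_nodes, mesh.n_elec
    K = _stiffness(mesh.nodes, mesh.elements, mesh.element_conductivity).tolil()

    rows, cols, vals = [], [], []
    ew_rows, ew_cols, ew_vals = [], [], []
    diag_e = np.zeros(L)
    for l, (a, b, ln) in enumerate(_electrode_edges(mesh)):
        z = mesh.contact_impedance[l]
        # Node-node boundary mass: (len/6) [[2,1],[1,2]] / z per edge.
        for i, j, e_len in zip(a, b, ln):
            m = e_len / (6.0 * z)
            rows += [i, j, i, j]
            cols += [i, j, j, i]
            vals += [2 * m, 2 * m, m, m]
            # Node-electrode coupling: -(1/z) int phi ds = -len/(2z).
            ew_rows += [i, j]
            ew_cols += [l, l]
            ew_vals += [-e_len / (2 * z), -e_len / (2 * z)]
        diag_e[l] = ln.sum() / z

    A_zz = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    A_w = sp.coo_matrix((ew_vals, (ew_rows, ew_cols)), shape=(n, L))
    top = sp.hstack([K.tocsr() + A_zz.tocsr(), A_w.tocsr()])
    bottom = sp.hstack([A_w.T.tocsr(), sp.diags(diag_e)])
    A = sp.vstack([top, bottom]).tolil()

    # Gauge: zero-mean node potential via a Lagrange multiplier row/col.
    g = np.zeros(n + L)
    g[:n] = 1.0
    A = sp.bmat(
        [[A.tocsr(), sp.csr_matrix(g[:, None])], [sp.csr_matrix(g[None, :]), None]]
    )
    return A.tocsc()


class CEMSolver:
    """Factorized CEM system reusable across injection patterns."""

    def __init__(self, mesh: Mesh2D):
        mesh.validate()
        self.mesh = mesh
        try:
            self._lu = splu(_cem_system(mesh))
        except RuntimeError as exc:  # singular factorization
            raise SolverError(f"CEM system factorization failed: {exc}") from exc

    def solve_pairs(self, pairs, current=1.0):
        """Solve for unit-pair injections.

        Returns ``(U_nodes, U_elec)`` with one column per pair: current
        ``+current`` into the first electrode of the pair, ``-current`` out
        of the second.
        """
        n, L = self.mesh.n_nodes, self.mesh.n_elec
        pairs = np.asarray(pairs, dtype=int)
        rhs = np.zeros((n + L + 1, len(pairs)))
        rhs[n + pairs[:, 0], np.arange(len(pairs))] = current
        rhs[n + pairs[:, 1], np.arange(len(pairs))] = -current
        sol = self._lu.solve(rhs)
        if not np.all(np.isfinite(sol)):
            raise SolverError("CEM solve returned non-finite potentials")
        return sol[:n], sol[n : n + L]


def _unique_pairs(protocol: StimulationProtocol):
    """All distinct electrode pairs appearing as injections or measurements."""
    seen = {}
    order = []
    for a, b in protocol.injection_pairs:
        key = (int(a), int(b))
        if key not in seen:
            seen[key] = len(order)
            order.append(key)
    for pairs in protocol.measurement_pairs:
        for a, b in pairs:
            key = (int(a), int(b))
            if key not in seen:
                seen[key] = len(order)
                order.append(key)
    return np.array(order, dtype=int), seen


def solve_forward(mesh: Mesh2D, protocol: StimulationProtocol) -> VoltageFrame:
    """Simulate one raw boundary-voltage frame.

    Measurement i is ``U_a - U_b`` of its measurement pair under the
    corresponding injection, for ``current_amplitude`` injected current.
    """
    if protocol.n_elec != mesh.n_elec:
        raise ShapeError("mesh and protocol electrode counts disagree")
    solver = CEMSolver(mesh)
    _, U = solver.solve_pairs(protocol.injection_pairs, protocol.current_amplitude)
    vals = []
    for k, pairs in enumerate(protocol.measurement_pairs):
        vals.append(U[pairs[:, 0], k] - U[pairs[:, 1], k])
    return VoltageFrame(values=np.concatenate(vals), is_normalized=False)


def compute_jacobian(
    mesh: Mesh2D, sigma_baseline, protocol: StimulationProtocol
) -> JacobianMatrix:
    """Adjoint-method Jacobian of raw measurements w.r.t. element conductivity.

    For drive field u_d and measurement-pair lead field u_m (unit current
    through the measured pair), dV/dsigma_e = -area_e * grad(u_d).grad(u_m),
    exact for the P1 discretization.
    """
    sigma_baseline = np.asarray(sigma_baseline, dtype=float)
    if sigma_baseline.shape != (mesh.n_elems,):
        raise ShapeError("sigma_baseline length must equal the element count")
    if np.any(sigma_baseline <= 0):
        raise UsageError("sigma_baseline must be strictly positive")
    work = mesh.with_conductivity(sigma_baseline)
    solver = CEMSolver(work)

    pairs, index = _unique_pairs(protocol)
    U_nodes, _ = solver.solve_pairs(pairs, current=1.0)

    bx, by, area = _element_gradients(work.nodes, work.elements)
    # Per-pair constant element gradients: (n_pairs, n_elems)
    u_loc = U_nodes[work.elements]  # (m, 3, n_pairs)
    gx = np.einsum("mk,mkp->pm", bx, u_loc)
    gy = np.einsum("mk,mkp->pm", by, u_loc)

    amp = protocol.current_amplitude
    rows = []
    for k, (a, b) in enumerate(protocol.injection_pairs):
        d = index[(int(a), int(b))]
        for ma, mb in protocol.measurement_pairs[k]:
            m = index[(int(ma), int(mb))]
            rows.append(-amp * area * (gx[d] * gx[m] + gy[d] * gy[m]))
    return JacobianMatrix(entries=np.array(rows), linearization=sigma_baseline)


def normalized_jacobian(
    mesh: Mesh2D, sigma_baseline, protocol: StimulationProtocol
):
    """Jacobian of normalized voltage changes y = (V - Vb)/Vb.

    Returns ``(J_norm, v_baseline)`` where row i of the raw Jacobian is
    divided by the baseline voltage of measurement i.
    """
    jac = compute_jacobian(mesh, sigma_baseline, protocol)
    vb = solve_forward(mesh.with_conductivity(np.asarray(sigma_baseline, float)),
                       protocol).values
    if np.any(np.abs(vb) < 1e-12):
        raise NormalizationError("baseline voltage below 1e-12 on some channel")
    return jac.entries / vb[:, None], vb


def add_noise(diff: np.ndarray, noise_fraction: float, rng: np.random.Generator):
    """Gaussian noise scaled to the std of the raw voltage difference.

    n_i ~ Normal(0, (noise_fraction * std(diff))^2), added to ``diff``.
    """
    if noise_fraction < 0:
        raise UsageError("noise_fraction must be non-negative")
    if noise_fraction == 0:
        return diff.copy()
    scale = noise_fraction * float(np.std(diff))
    return diff + rng.normal(0.0, scale, size=diff.shape)


def simulate_measurement(
    mesh_target: Mesh2D,
    mesh_baseline: Mesh2D,
    protocol: StimulationProtocol,
    noise_fraction: float = 0.25,
    seed: int | None = None,
    v_target: np.ndarray | None = None,
    v_baseline: np.ndarray | None = None,
) -> VoltageFrame:
    """Simulate a normalized, noisy voltage-change frame.

    Noise scaled to ``noise_fraction * std(V - V_baseline)`` is added to the
    raw difference, then the frame is normalized by the (noise-free)
    baseline: ``y = (V - Vb + n) / Vb``.  Precomputed raw frames may be
    passed to avoid repeated forward solves.
    """
    if v_target is None:
        v_target = solve_forward(mesh_target, protocol).values
    if v_baseline is None:
        v_baseline = solve_forward(mesh_baseline, protocol).values
    if v_target.shape != v_baseline.shape:
        raise ShapeError("target and baseline frames differ in length")
    if np.any(np.abs(v_baseline) < 1e-12):
        raise NormalizationError("baseline voltage below 1e-12 on some channel")
    rng = np.random.default_rng(seed)
    diff = add_noise(v_target - v_baseline, noise_fraction, rng)
    return VoltageFrame(values=diff / v_baseline, is_normalized=True, noise_seed=seed)
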