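"""Structural priors and the masked DCT subset basis.

The reconstruction is constrained to a low-frequency cosine subspace that is
masked by a structural prior P derived from a morphological (CT-like) image:

* contour prior P^cp: binary lung mask — support restriction only;
* detail prior P^dp: graded weights HU/(-1000) in [0, 1] inside the lung
  (pure air -1000 HU -> 1, atelectasis/edema ~0 HU -> 0), 0 outside.

Each masked basis raster C(p,q) = P * D(p,q) is projected onto the inverse
FEM mesh by the pixel-to-element map T, giving one column K_j of the subset
matrix; the reduced Jacobian is J_DCT = J K.  Column ordering follows
j(p,q) = q * n_xDCT + p + 1 (1-based; the x-frequency p varies fastest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError, UsageError
from .mesh import Mesh2D
from .raster import PixelElementMap, PixelImage

__all__ = [
    "StructuralPrior",
    "DCTBasis",
    "SubsetBasis",
    "make_contour_prior",
    "make_detail_prior",
    "build_dct_basis",
    "mask_basis",
    "build_K",
    "reduce_jacobian",
    "make_subset_basis",
]


@dataclass
class StructuralPrior:
    """M x N weight field in [0, 1]; binary for kind='contour'."""

    weights: np.ndarray
    kind: str  # "contour" | "detail"
    source_extent: tuple


@dataclass
class DCTBasis:
    """Stack of 2D DCT-II basis rasters D(p,q), p < order_x, q < order_y."""

    order_x: int  # number of x (column-direction) frequencies, n_xDCT
    order_y: int  # number of y (row-direction) frequencies, n_yDCT
    stack: np.ndarray  # (order_x * order_y, M, N), index j0 = q * order_x + p

    @property
    def n_dct(self) -> int:
        return self.order_x * self.order_y

    def column_of(self, p: int, q: int, one_based: bool = False) -> int:
        """Stack index of frequency pair (p, q): j(p,q) = q*n_xDCT + p (+1)."""
        if not (0 <= p < self.order_x and 0 <= q < self.order_y):
            raise UsageError("frequency pair out of range")
        j = q * self.order_x + p
        return j + 1 if one_based else j


@dataclass
class SubsetBasis:
    """Masked basis stack with its element-space projection and reduced Jacobian."""

    C_stack: np.ndarray  # (n_dct, M, N)
    K: np.ndarray  # (n_elems, n_dct)
    J_dct: np.ndarray | None  # (n_meas, n_dct)
    basis: DCTBasis
    prior: StructuralPrior

    def column_of(self, p: int, q: int, one_based: bool = False) -> int:
        return self.basis.column_of(p, q, one_based)


def make_contour_prior(lung_mask, extent=None) -> StructuralPrior:
    """Binary prior: 1 inside the lung, 0 outside."""
    mask = np.asarray(lung_mask)
    if not mask.any():
        raise UsageError("lung mask is empty")
    return StructuralPrior(
        weights=mask.astype(float), kind="contour", source_extent=extent
    )


def make_detail_prior(ct: PixelImage, lung_mask) -> StructuralPrior:
    """Graded prior HU/(-1000), clamped to [0, 1], zero outside the lung."""
    mask = np.asarray(lung_mask)
    hu = np.asarray(ct.values, dtype=float)
    if hu.shape != mask.shape:
        raise ShapeError("CT raster and lung mask dimensions differ")
    w = np.clip(hu / -1000.0, 0.0, 1.0)
    return StructuralPrior(
        weights=np.where(mask, w, 0.0), kind="detail", source_extent=ct.extent
    )


def build_dct_basis(M: int, N: int, n_x: int = 15, n_y: int = 15) -> DCTBasis:
    """Orthonormal 2D DCT-II basis rasters.

    D(p,q)[m,n] = a_p a_q cos((2m+1) q pi / 2M) cos((2n+1) p pi / 2N) with
    a_0 = 1/sqrt(M) and a_k = sqrt(2/M) otherwise (likewise for N); p counts
    x-direction (column) frequencies and q y-direction (row) frequencies.
    At full order the stack is orthonormal under the pixelwise inner product
    and inverts exactly.
    """
    if not (1 <= n_x <= N and 1 <= n_y <= M):
        raise UsageError("DCT order exceeds the image size")
    m = np.arange(M)
    n = np.arange(N)
    cos_q = np.cos((2 * m[None, :] + 1) * np.arange(n_y)[:, None] * np.pi / (2 * M))
    cos_p = np.cos((2 * n[None, :] + 1) * np.arange(n_x)[:, None] * np.pi / (2 * N))
    a_q = np.where(np.arange(n_y) == 0, np.sqrt(1.0 / M), np.sqrt(2.0 / M))
    a_p = np.where(np.arange(n_x) == 0, np.sqrt(1.0 / N), np.sqrt(2.0 / N))
    rows = a_q[:, None] * cos_q  # (n_y, M)
    cols = a_p[:, None] * cos_p  # (n_x, N)
    stack = np.einsum("qm,pn->qpmn", rows, cols).reshape(n_y * n_x, M, N)
    return DCTBasis(order_x=n_x, order_y=n_y, stack=stack)


def mask_basis(basis: DCTBasis, prior: StructuralPrior) -> np.ndarray:
    """Pixelwise product C(p,q) = P * D(p,q) for every stack member."""
    if prior.weights.shape != basis.stack.shape[1:]:
        raise ShapeError("prior raster and basis dimensions differ")
    return basis.stack * prior.weights[None, :, :]


def build_K(
    C_stack: np.ndarray,
    inverse_mesh: Mesh2D,
    extent,
    aggregation: str = "mean",
    pixel_map: PixelElementMap | None = None,
) -> np.ndarray:
    """Project each masked basis raster onto the inverse-mesh elements.

    Element value = mean of the C-values of the pixels whose centers the
    element covers (elements covering no pixel center take the nearest
    pixel); ``aggregation='nearest'`` samples one pixel per element instead.
    """
    if pixel_map is None:
        pixel_map = PixelElementMap(
            inverse_mesh, extent, C_stack.shape[1:], aggregation
        )
    return pixel_map.to_elements(C_stack)


def reduce_jacobian(J, K: np.ndarray) -> np.ndarray:
    """Structural-prior-reduced Jacobian J_DCT = J K, shape (n_meas, n_dct)."""
    entries = getattr(J, "entries", J)
    if entries.shape[1] != K.shape[0]:
        raise ShapeError("Jacobian columns must equal K rows")
    return entries @ K


def make_subset_basis(
    basis: DCTBasis,
    prior: StructuralPrior,
    inverse_mesh: Mesh2D,
    extent,
    jacobian=None,
    aggregation: str = "mean",
    pixel_map: PixelElementMap | None = None,
) -> SubsetBasis:
    """Convenience: mask the basis, build K, and (optionally) reduce J."""
    C = mask_basis(basis, prior)
    K = build_K(C, inverse_mesh, extent, aggregation, pixel_map)
    J_dct = None if jacobian is None else reduce_jacobian(jacobian, K)
    return SubsetBasis(C_stack=C, K=K, J_dct=J_dct, basis=basis, prior=prior)
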