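"""Pixel rasters registered to mesh coordinates, and pixel<->element maps.

Orientation convention: pixel (0, 0) is the top-left corner of the physical
extent; row index m increases downward, i.e. from ymax toward ymin.  The
phantom module places "ventral" at +y, so row 0 is the ventral edge.  Pixel
centers sit at half-integer offsets inside the extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.tri import Triangulation, TrapezoidMapTriFinder
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

from .errors import RegistrationError, ShapeError
from .mesh import Mesh2D

__all__ = ["PixelImage", "PixelElementMap", "extent_of_mesh"]


@dataclass
class PixelImage:
    """M x N scalar raster with a physical bounding box.

    semantics is one of {"hounsfield", "conductivity", "prior_weight",
    "eit_image"} and is informational only.
    """

    values: np.ndarray
    extent: tuple  # (xmin, xmax, ymin, ymax)
    semantics: str = "eit_image"

    @property
    def shape(self):
        return self.values.shape

    def pixel_centers(self):
        """(X, Y) arrays of shape (M, N) with physical pixel-center coords."""
        M, N = self.values.shape
        xmin, xmax, ymin, ymax = self.extent
        dx = (xmax - xmin) / N
        dy = (ymax - ymin) / M
        x = xmin + (np.arange(N) + 0.5) * dx
        y = ymax - (np.arange(M) + 0.5) * dy
        return np.meshgrid(x, y)

    def copy_with(self, values, semantics=None):
        return PixelImage(
            values=np.asarray(values, dtype=float),
            extent=self.extent,
            semantics=semantics or self.semantics,
        )


def extent_of_mesh(mesh: Mesh2D) -> tuple:
    """Physical extent matching the mesh bounding box."""
    return mesh.bounding_box()


def pixel_grid(shape, extent):
    """Pixel-center coordinate arrays for a raster of given shape/extent."""
    return PixelImage(np.zeros(shape), extent).pixel_centers()


class PixelElementMap:
    """Bidirectional map between an M x N raster and mesh elements.

    Implements the assignment T of pixels to the covering FEM element and its
    reverse (painting element values onto the pixel grid).  When an element
    covers several pixel centers their mean is taken ("mean" aggregation); an
    element covering no pixel center takes the value of the pixel center
    nearest its centroid.  "nearest" aggregation samples one pixel per
    element (the one nearest the centroid).
    """

    def __init__(self, mesh: Mesh2D, extent, shape, aggregation: str = "mean"):
        if aggregation not in ("mean", "nearest"):
            raise ShapeError(f"unknown aggregation '{aggregation}'")
        self.mesh = mesh
        self.extent = tuple(float(v) for v in extent)
        self.shape = tuple(shape)
        self.aggregation = aggregation

        X, Y = pixel_grid(shape, self.extent)
        tri = Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.elements)
        finder = TrapezoidMapTriFinder(tri)
        self.element_of_pixel = finder(X.ravel(), Y.ravel())  # -1 outside mesh
        if not np.any(self.element_of_pixel >= 0):
            raise RegistrationError("raster and mesh do not overlap")

        n_pix = X.size
        centroids = mesh.element_centroids()
        tree = cKDTree(np.column_stack([X.ravel(), Y.ravel()]))
        nearest_pix = tree.query(centroids)[1]

        if aggregation == "nearest":
            rows = np.arange(mesh.n_elems)
            cols = nearest_pix
            data = np.ones(mesh.n_elems)
        else:
            inside = self.element_of_pixel >= 0
            pix_idx = np.nonzero(inside)[0]
            elem_idx = self.element_of_pixel[inside]
            counts = np.bincount(elem_idx, minlength=mesh.n_elems)
            covered = counts > 0
            data = 1.0 / counts[elem_idx]
            rows = elem_idx
            cols = pix_idx
            empty = np.nonzero(~covered)[0]
            rows = np.concatenate([rows, empty])
            cols = np.concatenate([cols, nearest_pix[empty]])
            data = np.concatenate([data, np.ones(len(empty))])
        self._gather = csr_matrix(
            (data, (rows, cols)), shape=(mesh.n_elems, n_pix)
        )

    def to_elements(self, raster) -> np.ndarray:
        """Map raster values (M, N) or a stack (k, M, N) to element values."""
        arr = np.asarray(raster, dtype=float)
        if arr.shape[-2:] != self.shape:
            raise ShapeError("raster shape does not match the registered grid")
        flat = arr.reshape(-1, self.shape[0] * self.shape[1]).T
        out = self._gather @ flat
        return out[:, 0] if arr.ndim == 2 else out

    def paint(self, element_values, semantics="eit_image") -> PixelImage:
        """Nearest-element lookup of element values at each pixel center."""
        element_values = np.asarray(element_values, dtype=float)
        if element_values.shape != (self.mesh.n_elems,):
            raise ShapeError("element value vector has wrong length")
        flat = np.zeros(self.shape[0] * self.shape[1])
        inside = self.element_of_pixel >= 0
        flat[inside] = element_values[self.element_of_pixel[inside]]
        return PixelImage(flat.reshape(self.shape), self.extent, semantics)
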