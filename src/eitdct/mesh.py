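"""2D triangular meshes of a thorax cross-section with boundary electrodes.

The mesher triangulates a simple closed polygon with a Delaunay triangulation
of equidistant boundary samples plus a hexagonal interior point lattice, and
places ``n_elec`` electrodes equidistantly by boundary arc length.  Each
electrode is a short ordered run of boundary nodes, so the complete electrode
model can integrate over the electrode's boundary edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .errors import GeometryError, MeshError

__all__ = ["Mesh2D", "build_mesh"]


@dataclass
class Mesh2D:
    """Triangulated 2D domain carrying per-element conductivity.

    Attributes
    ----------
    nodes : (n_nodes, 2) float array
        Node coordinates in arbitrary length units.
    elements : (n_elems, 3) int array
        Counter-clockwise node-index triples.
    element_conductivity : (n_elems,) float array
        Conductivity per element, arbitrary units, strictly positive.
    electrodes : list of int arrays
        Ordered boundary-node groups, one per electrode, each ordered along
        the boundary so consecutive entries form boundary edges.
    contact_impedance : (n_elec,) float array
        Effective contact impedance per electrode (AU * length).
    boundary_nodes : (n_bound,) int array
        All boundary nodes ordered as a ring around the domain.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_conductivity: np.ndarray
    electrodes: list
    contact_impedance: np.ndarray
    boundary_nodes: np.ndarray = field(default=None)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elements.shape[0]

    @property
    def n_elec(self) -> int:
        return len(self.electrodes)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def bounding_box(self):
        """(xmin, xmax, ymin, ymax) of the node cloud."""
        return (
            float(self.nodes[:, 0].min()),
            float(self.nodes[:, 0].max()),
            float(self.nodes[:, 1].min()),
            float(self.nodes[:, 1].max()),
        )

    def with_conductivity(self, sigma) -> "Mesh2D":
        """Copy of the mesh with a different per-element conductivity."""
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (self.n_elems,):
            raise MeshError(
                f"conductivity has shape {sigma.shape}, expected ({self.n_elems},)"
            )
        if np.any(sigma <= 0):
            raise MeshError("element conductivity must be strictly positive")
        return Mesh2D(
            self.nodes,
            self.elements,
            sigma,
            self.electrodes,
            self.contact_impedance,
            self.boundary_nodes,
        )

    def validate(self) -> None:
        """Check mesh invariants; raise :class:`MeshError` on violation."""
        p = self.nodes[self.elements]
        signed = 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )
        if np.any(signed <= 0):
            raise MeshError("found triangles with non-positive signed area")
        if np.any(self.element_conductivity <= 0):
            raise MeshError("element conductivity must be strictly positive")
        seen = set()
        bset = set(self.boundary_nodes.tolist())
        for group in self.electrodes:
            for n in group:
                if int(n) in seen:
                    raise MeshError("electrodes are not disjoint")
                seen.add(int(n))
                if int(n) not in bset:
                    raise MeshError("electrode node off the domain boundary")


def _hex_lattice(bbox, h):
    xmin, ymin, xmax, ymax = bbox
    dy = h * np.sqrt(3.0) / 2.0
    ys = np.arange(ymin + 0.5 * dy, ymax, dy)
    pts = []
    for i, y in enumerate(ys):
        off = 0.25 * h if i % 2 == 0 else -0.25 * h
        xs = np.arange(xmin + 0.5 * h + off, xmax, h)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    if not pts:
        return np.empty((0, 2))
    return np.vstack(pts)


def build_mesh(
    boundary_polygon,
    n_elec: int,
    target_element_count: int,
    contact_impedance: float = 1e-2,
    electrode_width_fraction: float = 0.25,
) -> Mesh2D:
    """Triangulate the interior of a simple polygon and attach electrodes.

    Parameters
    ----------
    boundary_polygon : (V, 2) array
        Vertices of a simple (non-self-intersecting) closed polygon.  The
        first vertex anchors electrode 0; electrodes follow the polygon's
        own orientation at equal arc-length spacing.
    n_elec : int
        Number of boundary electrodes (>= 4).
    target_element_count : int
        Requested triangle count (>= 500); the result is within +-30%.
    contact_impedance : float
        Uniform effective contact impedance assigned to every electrode.
    electrode_width_fraction : float
        Electrode arc width as a fraction of the inter-electrode spacing.

    Returns
    -------
    Mesh2D
        With homogeneous unit conductivity; use
        :meth:`Mesh2D.with_conductivity` to assign a distribution.
    """
    ring = np.asarray(boundary_polygon, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2 or ring.shape[0] < 3:
        raise GeometryError("boundary polygon must be a (V, 2) vertex array")
    if n_elec < 4:
        raise GeometryError("need at least 4 electrodes")
    if target_element_count < 500:
        raise GeometryError("target element count must be at least 500")

    poly = Polygon(ring)
    if (not poly.is_valid) or (not poly.is_simple):
        raise GeometryError("boundary polygon is self-intersecting or invalid")

    area = poly.area
    perim = poly.exterior.length
    spacing_e = perim / n_elec
    width_e = electrode_width_fraction * spacing_e

    h = np.sqrt(2.0 * area / target_element_count)
    for _attempt in range(4):
        # Boundary sampling fine enough for >= 2 nodes under each electrode,
        # and commensurate with the electrode spacing so electrodes are
        # geometrically identical up to the boundary curvature.
        h_b = min(h, width_e / 2.2)
        n_b = n_elec * int(np.ceil(perim / (h_b * n_elec)))
        arc = np.arange(n_b) * perim / n_b
        bpts = np.array(
            [poly.exterior.interpolate(s).coords[0] for s in arc]
        )

        interior = _hex_lattice(poly.bounds, h)
        if len(interior):
            keep = shapely.contains_xy(
                poly.buffer(-0.55 * h), interior[:, 0], interior[:, 1]
            )
            interior = interior[keep]

        pts = np.vstack([bpts, interior])
        tri = Delaunay(pts)
        simplices = tri.simplices
        cent = pts[simplices].mean(axis=1)
        inside = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        p = pts[simplices]
        signed = 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )
        good = inside & (np.abs(signed) > 1e-10 * area)
        simplices = simplices[good]
        count = len(simplices)
        if abs(count - target_element_count) <= 0.3 * target_element_count:
            break
        # One corrective resize of the lattice spacing.
        h *= np.sqrt(count / target_element_count)
    else:
        raise MeshError(
            f"element count {count} not within 30% of {target_element_count}"
        )

    # Consistent CCW orientation.
    p = pts[simplices]
    signed = 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    flip = signed < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]

    # Drop unused nodes, keep boundary nodes first (they come first in pts).
    used = np.unique(simplices)
    remap = -np.ones(len(pts), dtype=int)
    remap[used] = np.arange(len(used))
    if np.any(remap[:n_b] < 0):
        raise MeshError("a boundary node is not part of any triangle")
    nodes = pts[used]
    elements = remap[simplices]
    boundary_nodes = remap[np.arange(n_b)]

    # Verify consecutive boundary samples are actual mesh edges.
    edge_set = set()
    for a, b, c in elements:
        edge_set.update(
            {(min(a, b), max(a, b)), (min(b, c), max(b, c)), (min(a, c), max(a, c))}
        )
    for i in range(n_b):
        a, b = boundary_nodes[i], boundary_nodes[(i + 1) % n_b]
        if (min(a, b), max(a, b)) not in edge_set:
            raise MeshError("boundary ring is not conforming with the triangulation")

    # Electrodes: boundary nodes within +- width/2 of equidistant anchors.
    electrodes = []
    for k in range(n_elec):
        anchor = k * spacing_e
        d = np.abs(arc - anchor)
        d = np.minimum(d, perim - d)
        idx = np.where(d <= width_e / 2.0)[0]
        if len(idx) < 2:
            raise MeshError("electrode covers fewer than 2 boundary nodes")
        # Order along the boundary, unwrapping across the arc origin.
        rel = arc[idx] - anchor
        rel[rel > perim / 2] -= perim
        rel[rel < -perim / 2] += perim
        idx = idx[np.argsort(rel)]
        electrodes.append(boundary_nodes[idx].copy())

    mesh = Mesh2D(
        nodes=nodes,
        elements=elements,
        element_conductivity=np.ones(len(elements)),
        electrodes=electrodes,
        contact_impedance=np.full(n_elec, float(contact_impedance)),
        boundary_nodes=boundary_nodes,
    )
    mesh.validate()
    return mesh
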