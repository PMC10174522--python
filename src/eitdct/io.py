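"""Serialization: meshes, voltage frames, scenes, priors and run manifests.

Arrays travel in single ``.npz`` archives; meshes can additionally be dumped
as OFF-style plain text for eyeballing, voltage frames as headered CSV, and
the CT surrogate as 16-bit PGM.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .mesh import Mesh2D
from .raster import PixelImage

__all__ = [
    "save_mesh",
    "load_mesh",
    "export_mesh_off",
    "save_frames",
    "load_frames",
    "save_scene_archive",
    "save_prior",
    "load_prior",
    "export_pgm",
    "write_manifest",
]


def save_mesh(path, mesh: Mesh2D) -> None:
    np.savez_compressed(
        path,
        nodes=mesh.nodes,
        elements=mesh.elements,
        element_conductivity=mesh.element_conductivity,
        contact_impedance=mesh.contact_impedance,
        boundary_nodes=mesh.boundary_nodes,
        electrode_sizes=np.array([len(e) for e in mesh.electrodes]),
        electrode_nodes=np.concatenate(mesh.electrodes),
    )


def load_mesh(path) -> Mesh2D:
    with np.load(path) as z:
        sizes = z["electrode_sizes"]
        flat = z["electrode_nodes"]
        electrodes, k = [], 0
        for s in sizes:
            electrodes.append(flat[k : k + s].copy())
            k += s
        return Mesh2D(
            nodes=z["nodes"],
            elements=z["elements"],
            element_conductivity=z["element_conductivity"],
            electrodes=electrodes,
            contact_impedance=z["contact_impedance"],
            boundary_nodes=z["boundary_nodes"],
        )


def export_mesh_off(path, mesh: Mesh2D) -> None:
    """OFF-style plain-text dump (z = 0) for external viewers."""
    with open(path, "w") as f:
        f.write("OFF\n")
        f.write(f"{mesh.n_nodes} {mesh.n_elems} 0\n")
        for x, y in mesh.nodes:
            f.write(f"{x:.9g} {y:.9g} 0\n")
        for a, b, c in mesh.elements:
            f.write(f"3 {a} {b} {c}\n")


def save_frames(path, frames, protocol_name: str = "adjacent", seed=None) -> None:
    """Voltage frames as CSV, one frame per row, with a describing header."""
    arr = np.atleast_2d(np.asarray(frames, dtype=float))
    header = f"protocol={protocol_name} seed={seed} n_meas={arr.shape[1]}"
    np.savetxt(path, arr, delimiter=",", header=header)


def load_frames(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def save_scene_archive(path, scene) -> None:
    """Polygon, masks, HU raster and ground truth of a phantom scene."""
    np.savez_compressed(
        path,
        thorax_polygon=scene.thorax_polygon,
        extent=np.array(scene.extent),
        lung_mask=scene.lung_mask,
        ct_hu=scene.ct_surrogate.values,
        ground_truth=scene.ground_truth.values,
        kind=np.array(scene.kind),
    )


def save_prior(path, prior) -> None:
    np.savez_compressed(
        path,
        weights=prior.weights,
        kind=np.array(prior.kind),
        extent=np.array(
            prior.source_extent if prior.source_extent is not None else np.nan
        ),
    )


def load_prior(path):
    from .priors import StructuralPrior

    with np.load(path) as z:
        extent = z["extent"]
        return StructuralPrior(
            weights=z["weights"],
            kind=str(z["kind"]),
            source_extent=tuple(extent) if extent.shape == (4,) else None,
        )


def export_pgm(path, image: PixelImage) -> None:
    """16-bit binary PGM of a raster, min-max scaled, for visual inspection."""
    v = np.asarray(image.values, dtype=float)
    lo, hi = v.min(), v.max()
    scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    data = (scaled * 65535).astype(">u2")
    with open(path, "wb") as f:
        f.write(f"P5\n{v.shape[1]} {v.shape[0]}\n65535\n".encode())
        f.write(data.tobytes())


def write_manifest(path, manifest: dict) -> None:
    """Plain-text key = value manifest (nested dicts flattened by dots)."""
    def flatten(d, prefix=""):
        for k, v in d.items():
            key = f"{prefix}{k}"
            if isinstance(v, dict):
                yield from flatten(v, key + ".")
            else:
                yield key, v

    with open(path, "w") as f:
        for k, v in flatten(manifest):
            if isinstance(v, (list, tuple, np.ndarray)):
                v = json.dumps(np.asarray(v).tolist())
            f.write(f"{k} = {v}\n")
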