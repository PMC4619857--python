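"""Triangulated surface meshes and seed regions.

Vertex-wise cortical statistics live on a triangulated 2-manifold. This
module provides the mesh container, a synthetic spherical template built by
recursive icosahedral subdivision (the same construction that yields the
40962-vertex / 81920-triangle hemispheric templates used in surface
morphometry), geometric quantities needed downstream (edge lengths,
triangle areas, adjacency), and geodesic seed patches standing in for
atlas-delineated seed regions.

Vertex indices are 0-based everywhere, including all TSV interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra


class MeshValidationError(ValueError):
    """Raised when a mesh violates manifold/triangulation invariants."""


@dataclass(frozen=True)
class SurfaceMesh:
    """A triangulated surface: vertex coordinates (mm) and triangle indices.

    Validated on construction: indices in range, no degenerate (zero-area)
    triangles, every undirected edge shared by at most two triangles.
    Non-manifold input is rejected, not repaired.
    """

    vertex_coords: np.ndarray  # (V, 3) float, mm
    triangles: np.ndarray      # (F, 3) int

    def __post_init__(self) -> None:
        coords = np.asarray(self.vertex_coords, dtype=float)
        tris = np.asarray(self.triangles, dtype=np.int64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise MeshValidationError("vertex_coords must be (V, 3)")
        if tris.ndim != 2 or tris.shape[1] != 3:
            raise MeshValidationError("triangles must be (F, 3)")
        object.__setattr__(self, "vertex_coords", coords)
        object.__setattr__(self, "triangles", tris)
        if tris.size and (tris.min() < 0 or tris.max() >= len(coords)):
            raise MeshValidationError("triangle indices out of range")
        areas = self.triangle_areas()
        bad = np.flatnonzero(areas <= 0)
        if bad.size:
            raise MeshValidationError(
                f"degenerate (zero-area) triangle(s): indices {bad[:5].tolist()}"
            )
        # manifold check: each undirected edge in <= 2 triangles
        e = self._directed_edges()
        und = np.sort(e, axis=1)
        _, counts = np.unique(und, axis=0, return_counts=True)
        if counts.size and counts.max() > 2:
            raise MeshValidationError("non-manifold edge shared by >2 triangles")

    # -- derived geometry ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_coords)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def _directed_edges(self) -> np.ndarray:
        t = self.triangles
        return np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])

    def edges(self) -> np.ndarray:
        """Deduplicated undirected edge list, shape (E, 2), i < j."""
        und = np.sort(self._directed_edges(), axis=1)
        return np.unique(und, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        d = self.vertex_coords[e[:, 0]] - self.vertex_coords[e[:, 1]]
        return np.linalg.norm(d, axis=1)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertex_coords[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_triangles

    def boundary_edges(self) -> np.ndarray:
        """Edges belonging to exactly one triangle (empty for closed meshes)."""
        und = np.sort(self._directed_edges(), axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        return uniq[counts == 1]

    def is_closed(self) -> bool:
        return len(self.boundary_edges()) == 0

    def vertex_neighbors(self) -> list[np.ndarray]:
        """Per-vertex sorted neighbor index arrays (1-ring)."""
        e = self.edges()
        both = np.concatenate([e, e[:, ::-1]])
        order = np.argsort(both[:, 0], kind="stable")
        both = both[order]
        splits = np.searchsorted(both[:, 0], np.arange(1, self.n_vertices))
        return [np.sort(a) for a in np.split(both[:, 1], splits)]

    def adjacency(self, weighted: bool = True) -> csr_matrix:
        """Sparse symmetric vertex adjacency; weights are edge lengths in mm."""
        e = self.edges()
        w = self.edge_lengths() if weighted else np.ones(len(e))
        i = np.concatenate([e[:, 0], e[:, 1]])
        j = np.concatenate([e[:, 1], e[:, 0]])
        return csr_matrix((np.concatenate([w, w]), (i, j)),
                          shape=(self.n_vertices, self.n_vertices))


@dataclass(frozen=True)
class SeedRegion:
    """A named set of vertex indices acting as a covariance seed."""

    name: str
    vertex_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.vertex_indices, dtype=np.int64)
        if idx.size == 0:
            raise ValueError(f"seed region {self.name!r} is empty")
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"seed region {self.name!r} has duplicate vertices")
        object.__setattr__(self, "vertex_indices", np.sort(idx))

    def validate_against(self, mesh: SurfaceMesh) -> None:
        if self.vertex_indices.min() < 0 or self.vertex_indices.max() >= mesh.n_vertices:
            raise ValueError(
                f"seed region {self.name!r} has indices outside the mesh")

    def __len__(self) -> int:
        return len(self.vertex_indices)


def build_icosphere(subdivisions: int, radius: float = 70.0) -> SurfaceMesh:
    """Closed triangulated sphere from recursive 4-fold icosahedral subdivision.

    Each level splits every triangle into four and projects new vertices to
    the sphere, giving V = 10·4**s + 2 vertices and F = 20·4**s triangles.
    Six levels yield the 40962-vertex, 81920-triangle hemispheric template
    convention of surface-based cortical morphometry.

    Parameters
    ----------
    subdivisions : int
        Number of subdivision levels s >= 0; capped at 8 (memory guard).
    radius : float
        Sphere radius in mm. A 70 mm radius gives a surface area on the
        order of a human hemisphere.
    """
    if not isinstance(subdivisions, (int, np.integer)) or subdivisions < 0:
        raise ValueError("subdivisions must be a non-negative integer")
    if subdivisions > 8:
        raise ValueError("subdivisions > 8 refused (memory guard)")
    if radius <= 0:
        raise ValueError("radius must be positive")
    ico = trimesh.creation.icosphere(subdivisions=int(subdivisions), radius=radius)
    return SurfaceMesh(np.asarray(ico.vertices, dtype=float),
                       np.asarray(ico.faces, dtype=np.int64))


def seed_patch(mesh: SurfaceMesh, center: int, geodesic_radius: float,
               name: str = "patch") -> SeedRegion:
    """Seed region of all vertices within graph-geodesic distance of a center.

    Distance is the edge-length-weighted shortest path along mesh edges
    (not an exact polyhedral geodesic). The center is always included, so a
    radius below the shortest incident edge yields a singleton region.
    """
    if not (0 <= center < mesh.n_vertices):
        raise ValueError(f"center vertex {center} outside mesh")
    if geodesic_radius <= 0:
        raise ValueError("geodesic_radius must be positive")
    dist = dijkstra(mesh.adjacency(weighted=True), directed=False,
                    indices=center, limit=geodesic_radius * (1 + 1e-12))
    idx = np.flatnonzero(np.isfinite(dist) & (dist <= geodesic_radius))
    idx = np.union1d(idx, [center])
    return SeedRegion(name=name, vertex_indices=idx)


def mesh_metrics(mesh: SurfaceMesh) -> dict:
    """Edge lengths (mm), total area (mm²), and 1-ring neighbor sets."""
    return {
        "edge_lengths": mesh.edge_lengths(),
        "total_area": mesh.total_area(),
        "vertex_neighbors": mesh.vertex_neighbors(),
    }


# -- I/O ---------------------------------------------------------------------

def write_obj(mesh: SurfaceMesh, path) -> None:
    """ASCII Wavefront OBJ (v/f records; f written 1-based per convention)."""
    with open(path, "w") as fh:
        for x, y, z in mesh.vertex_coords:
            fh.write(f"v {x:.9g} {y:.9g} {z:.9g}\n")
        for a, b, c in mesh.triangles + 1:
            fh.write(f"f {a} {b} {c}\n")


def read_obj(path) -> SurfaceMesh:
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(p) for p in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    return SurfaceMesh(np.array(verts, dtype=float), np.array(faces, dtype=np.int64))


def write_gifti_surface(mesh: SurfaceMesh, path) -> None:
    import nibabel as nib
    coords = nib.gifti.GiftiDataArray(
        mesh.vertex_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET")
    tris = nib.gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE")
    nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), str(path))


def read_gifti_surface(path) -> SurfaceMesh:
    import nibabel as nib
    img = nib.load(str(path))
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return SurfaceMesh(np.asarray(coords, dtype=float),
                       np.asarray(tris, dtype=np.int64))


def write_labels(seeds: list[SeedRegion], path) -> None:
    """Label TSV: `vertex_index<TAB>label`, 0-based vertex indices."""
    with open(path, "w") as fh:
        fh.write("vertex_index\tlabel\n")
        for seed in seeds:
            for v in seed.vertex_indices:
                fh.write(f"{v}\t{seed.name}\n")


def read_labels(path) -> list[SeedRegion]:
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["vertex_index", "label"]:
        raise ValueError("label file must have header 'vertex_index\\tlabel'")
    return [SeedRegion(name=str(name), vertex_indices=grp["vertex_index"].to_numpy())
            for name, grp in df.groupby("label", sort=True)]
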