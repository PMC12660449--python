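"""Tetrahedral mesh container and geometric queries.

All meshes in this package are 4-node (constant-strain) tetrahedra in a
millimetre coordinate frame.  Named element sets partition the assembly into
bone fragments, implant hardware and callus; named node sets anchor loads and
boundary conditions.  Meshes generated internally come from a structured
voxel lattice (each hexahedral cell split into six positively oriented
tetrahedra), which makes conforming implant carving and face adjacency cheap
and exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MeshModel", "StructureError", "box_mesh", "tet_volumes", "tet_aspect_ratios"]


class StructureError(ValueError):
    """A mesh violates a structural contract (sets, adjacency, orientation)."""


# Split of a hexahedron into 6 tetrahedra sharing the main diagonal (0,6),
# with local corner numbering 0..7 = (i,j,k) bits (x fastest).  Every tet has
# positive signed volume for an axis-aligned right-handed cell.
_HEX_TO_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 1, 7, 5],
        [0, 5, 7, 4],
        [0, 3, 2, 7],
        [0, 2, 6, 7],
        [0, 6, 4, 7],
    ],
    dtype=np.int64,
)

# Faces of a tet in local indices (opposite each vertex).
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]], dtype=np.int64)


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes (mm^3) of each tetrahedron."""
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def tet_aspect_ratios(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Longest-edge / inradius quality measure (regular tet ~ 4.9)."""
    p = nodes[tets]  # (m, 4, 3)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edge = np.stack([np.linalg.norm(p[:, i] - p[:, j], axis=1) for i, j in pairs], axis=1)
    lmax = edge.max(axis=1)
    vol = np.abs(tet_volumes(nodes, tets))
    # total face area
    area = np.zeros(len(tets))
    for f in _TET_FACES:
        u = p[:, f[1]] - p[:, f[0]]
        v = p[:, f[2]] - p[:, f[0]]
        area += 0.5 * np.linalg.norm(np.cross(u, v), axis=1)
    inradius = 3.0 * vol / area
    return lmax / inradius


@dataclass
class MeshModel:
    """Tetrahedral mesh with named element/node sets.

    Attributes
    ----------
    nodes : (n, 3) float array, mm.
    tets : (m, 4) int array, 0-based connectivity, positive orientation.
    element_sets : name -> sorted int array of element indices.
    node_sets : name -> sorted int array of node indices.
    """

    nodes: np.ndarray
    tets: np.ndarray
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    # voxel-lattice provenance (spacing, origin, cell index per element);
    # present on generated meshes, enables conforming implant carving.
    lattice: dict | None = None
    _face_adjacency: list[np.ndarray] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def copy(self) -> "MeshModel":
        return MeshModel(
            nodes=self.nodes.copy(),
            tets=self.tets.copy(),
            element_sets={k: v.copy() for k, v in self.element_sets.items()},
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            lattice=dict(self.lattice) if self.lattice is not None else None,
        )

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    # ------------------------------------------------------------------
    # adjacency
    # ------------------------------------------------------------------
    def face_adjacency(self) -> list[np.ndarray]:
        """For each element, the indices of elements sharing a full face.

        Symmetric by construction: faces are matched by their sorted node
        triple, and an interior face is shared by exactly two tets.
        """
        if self._face_adjacency is None:
            m = self.n_elements
            faces = self.tets[:, _TET_FACES]  # (m, 4, 3)
            faces = np.sort(faces.reshape(m * 4, 3), axis=1)
            order = np.lexsort((faces[:, 2], faces[:, 1], faces[:, 0]))
            fs = faces[order]
            owner = order // 4
            neigh: list[list[int]] = [[] for _ in range(m)]
            same = np.all(fs[1:] == fs[:-1], axis=1)
            for i in np.nonzero(same)[0]:
                a, b = owner[i], owner[i + 1]
                neigh[a].append(b)
                neigh[b].append(a)
            self._face_adjacency = [np.array(sorted(s), dtype=np.int64) for s in neigh]
        return self._face_adjacency

    def shared_faces(self, set_a: str, set_b: str) -> list[tuple[int, int]]:
        """Pairs (ea, eb) of elements from two sets sharing a face (tie pairs)."""
        a = set(self.element_sets[set_a].tolist())
        b = set(self.element_sets[set_b].tolist())
        adj = self.face_adjacency()
        pairs = []
        for ea in sorted(a):
            for eb in adj[ea]:
                if int(eb) in b:
                    pairs.append((ea, int(eb)))
        return pairs

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        vol = self.volumes()
        if not np.all(vol > 0):
            raise StructureError(
                f"{int(np.sum(vol <= 0))} tetrahedra have non-positive volume"
            )
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= self.n_nodes:
            raise StructureError("connectivity index out of range")
        for name, els in self.element_sets.items():
            if len(els) and (els.min() < 0 or els.max() >= self.n_elements):
                raise StructureError(f"element set {name!r} index out of range")
        for name, nds in self.node_sets.items():
            if len(nds) and (nds.min() < 0 or nds.max() >= self.n_nodes):
                raise StructureError(f"node set {name!r} index out of range")
        bp = self.element_sets.get("bone_proximal", np.empty(0, np.int64))
        bd = self.element_sets.get("bone_distal", np.empty(0, np.int64))
        if len(np.intersect1d(bp, bd)):
            raise StructureError("bone_proximal and bone_distal overlap")

    def bone_elements(self) -> np.ndarray:
        bp = self.element_sets.get("bone_proximal", np.empty(0, np.int64))
        bd = self.element_sets.get("bone_distal", np.empty(0, np.int64))
        return np.union1d(bp, bd)


def _lattice_nodes(nx: int, ny: int, nz: int, h: np.ndarray, origin: np.ndarray):
    """Full lattice node coordinates and an (nx+1,ny+1,nz+1) index grid."""
    xs = origin[0] + h[0] * np.arange(nx + 1)
    ys = origin[1] + h[1] * np.arange(ny + 1)
    zs = origin[2] + h[2] * np.arange(nz + 1)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    idx = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)
    return coords, idx


def voxels_to_mesh(
    cells: np.ndarray, dims: tuple[int, int, int], h: np.ndarray, origin: np.ndarray
) -> tuple[MeshModel, np.ndarray]:
    """Build a tet mesh from selected voxel cells of a regular lattice.

    Parameters
    ----------
    cells : (c, 3) int array of (i, j, k) cell indices to keep.
    dims : lattice cell counts (nx, ny, nz).
    h : (3,) spacing per axis, mm.
    origin : (3,) lattice origin, mm.

    Returns the mesh (nodes compacted to those actually used) and the
    per-element cell index row in `cells` (6 tets per cell).
    """
    nx, ny, nz = dims
    coords, idx = _lattice_nodes(nx, ny, nz, h, origin)
    i, j, k = cells[:, 0], cells[:, 1], cells[:, 2]
    # hex corner node ids, local numbering by (di, dj, dk) bits, x fastest
    corners = np.stack(
        [
            idx[i + di, j + dj, k + dk]
            for dk in (0, 1)
            for dj in (0, 1)
            for di in (0, 1)
        ],
        axis=1,
    )
    # reorder: our bit order above is (dk, dj, di) loops -> col index = di + 2*dj + 4*dk
    # loops produce order di fastest? cols are [dk,dj,di] nested with di innermost:
    # col c corresponds to di = c % 2, dj = (c // 2) % 2, dk = c // 4  -> matches
    tets = corners[:, _HEX_TO_TETS].reshape(-1, 4)
    used, inv = np.unique(tets, return_inverse=True)
    tets = inv.reshape(-1, 4).astype(np.int64)
    nodes = coords[used]
    cell_of_elem = np.repeat(np.arange(len(cells)), 6)
    mesh = MeshModel(
        nodes=nodes,
        tets=tets,
        lattice={
            "dims": dims,
            "h": h.copy(),
            "origin": origin.copy(),
            "cells": cells.copy(),
            "node_ids_global": used,
        },
    )
    return mesh, cell_of_elem


def box_mesh(
    lengths: tuple[float, float, float],
    divisions: tuple[int, int, int],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> MeshModel:
    """Structured tet mesh of an axis-aligned box (test and oracle geometry)."""
    nx, ny, nz = divisions
    h = np.array([lengths[0] / nx, lengths[1] / ny, lengths[2] / nz])
    cells = np.array(
        [(i, j, k) for i in range(nx) for j in range(ny) for k in range(nz)],
        dtype=np.int64,
    )
    mesh, _ = voxels_to_mesh(cells, (nx, ny, nz), h, np.asarray(origin, float))
    return mesh
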