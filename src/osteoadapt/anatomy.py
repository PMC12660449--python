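"""Synthetic femur-implant anatomy generator.

Stands in for CT-derived geometry: an idealised femur (cylindrical shaft +
angled neck + spherical head) is voxelised on a regular lattice and each
kept voxel is split into six tetrahedra, giving a watertight conforming
mesh on which the lateral blade plate, screws and blade are either added
(plate: extra lattice cells on the lateral cortex) or carved (screws/blade:
bone cells reassigned to implant sets).  Because every part lives on the
same lattice, all interfaces are node-conforming, i.e. tied, and tie pairs
are exactly the shared faces between sets.

Frame: +x anterior, +y lateral, +z superior; knee centre at the origin.
Units: mm, g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import MeshModel, StructureError, voxels_to_mesh

__all__ = [
    "FemurParams",
    "DensityFieldParams",
    "ImplantParams",
    "GeometryError",
    "generate_femur_mesh",
    "generate_density_field",
    "build_assembly",
]

_LATERAL_PAD = 8.0  # mm of lattice beyond the cortex reserved for the plate


class GeometryError(ValueError):
    """Requested implant/osteotomy geometry cannot be realised on the bone."""


@dataclass(frozen=True)
class FemurParams:
    shaft_length: float = 160.0
    shaft_outer_radius: float = 12.0
    cortical_thickness: float = 3.0
    neck_angle: float = 130.0  # degrees between shaft and neck axes
    neck_length: float = 35.0  # 0 disables neck and head (plain cylinder)
    head_radius: float = 14.0
    target_edge_length: float = 4.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "shaft_length",
            "shaft_outer_radius",
            "cortical_thickness",
            "head_radius",
            "target_edge_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"FemurParams.{name} must be positive")
        if self.neck_length < 0:
            raise ValueError("FemurParams.neck_length must be >= 0")
        if self.cortical_thickness >= self.shaft_outer_radius:
            raise ValueError(
                "FemurParams.cortical_thickness must be smaller than shaft_outer_radius"
            )
        if not 90.0 <= self.neck_angle <= 150.0:
            raise ValueError("FemurParams.neck_angle must lie in [90, 150] degrees")

    @property
    def neck_radius(self) -> float:
        return 0.75 * self.head_radius

    def neck_axis(self) -> np.ndarray:
        alpha = np.radians(180.0 - self.neck_angle)
        return np.array([0.0, -np.sin(alpha), np.cos(alpha)])

    def head_centre(self) -> np.ndarray:
        base = np.array([0.0, 0.0, self.shaft_length])
        if self.neck_length == 0:
            return base
        return base + self.neck_length * self.neck_axis()


@dataclass(frozen=True)
class DensityFieldParams:
    cortical_density: float = 1.8
    trabecular_density_mean: float = 0.30
    trabecular_density_sd: float = 0.08
    rho_min: float = 0.05
    rho_max: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.rho_min <= 0:
            raise ValueError("rho_min must be positive")
        if not (
            self.rho_min
            <= self.trabecular_density_mean
            <= self.cortical_density
            <= self.rho_max
        ):
            raise ValueError(
                "require rho_min <= trabecular mean <= cortical <= rho_max"
            )
        if self.trabecular_density_sd < 0:
            raise ValueError("trabecular_density_sd must be >= 0")


@dataclass(frozen=True)
class ImplantParams:
    plate_length: float = 80.0
    plate_width: float = 12.0
    plate_thickness: float = 4.0
    blade_angle: float = 130.0  # degrees; 90 = horizontal blade
    n_screws: int = 4
    screw_radius: float = 2.5
    osteotomy_height: float = 120.0  # mm above the distal (knee) end

    def __post_init__(self):
        if self.n_screws < 1:
            raise ValueError("ImplantParams.n_screws must be >= 1")
        for name in ("plate_length", "plate_width", "plate_thickness", "screw_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ImplantParams.{name} must be positive")


# ----------------------------------------------------------------------
# implicit solid
# ----------------------------------------------------------------------
def _solid_depth(points: np.ndarray, p: FemurParams) -> np.ndarray:
    """Approximate inside-distance to the femur surface (<= 0 outside).

    Union of shaft cylinder, neck cylinder and head sphere; the depth of a
    point is the largest of the member depths, a standard approximation of
    the union's signed distance.
    """
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    r_xy = np.hypot(x, y)
    depth = np.minimum(p.shaft_outer_radius - r_xy, z)
    if p.neck_length == 0:
        depth = np.minimum(depth, p.shaft_length - z)
        return depth
    depth = np.minimum(depth, p.shaft_length + p.neck_length - z)  # loose proximal cap
    base = np.array([0.0, 0.0, p.shaft_length])
    d = p.neck_axis()
    rel = points - base
    t = rel @ d
    radial = np.linalg.norm(rel - np.outer(t, d), axis=1)
    neck_depth = np.where(
        (t >= -p.shaft_outer_radius) & (t <= p.neck_length),
        p.neck_radius - radial,
        -np.inf,
    )
    head_depth = p.head_radius - np.linalg.norm(points - p.head_centre(), axis=1)
    return np.maximum.reduce([depth, neck_depth, head_depth])


def _nearest_node(mesh: MeshModel, point: np.ndarray) -> int:
    return int(np.argmin(np.linalg.norm(mesh.nodes - point, axis=1)))


def _attach_node_sets(mesh: MeshModel, p: FemurParams) -> None:
    head = _nearest_node(mesh, p.head_centre())
    knee = _nearest_node(mesh, np.zeros(3))
    gt_anchor = np.array([0.0, p.shaft_outer_radius, p.shaft_length])
    d = np.linalg.norm(mesh.nodes - gt_anchor, axis=1)
    gt = np.nonzero(d <= 1.6 * p.target_edge_length)[0]
    if len(gt) == 0:
        gt = np.argsort(d)[:4]
    gt = np.setdiff1d(np.sort(gt), [head, knee])
    if len(gt) == 0:  # pathological coarse mesh; keep the nearest node
        gt = np.array([int(np.argmin(d))])
    mesh.node_sets["head_centre"] = np.array([head], dtype=np.int64)
    mesh.node_sets["knee_centre"] = np.array([knee], dtype=np.int64)
    mesh.node_sets["greater_trochanter"] = gt.astype(np.int64)
    mesh.node_sets["abductor"] = gt.astype(np.int64)


def _femur_lattice(p: FemurParams):
    """Lattice dims/spacing/origin covering the femur plus lateral plate pad."""
    h = p.target_edge_length
    R = p.shaft_outer_radius
    head = p.head_centre()
    x_max = R + h
    if p.neck_length > 0:
        x_max = max(x_max, p.head_radius + h)
    y_lo = -R - h
    if p.neck_length > 0:
        y_lo = min(y_lo, head[1] - p.head_radius - h)
    y_hi = R + _LATERAL_PAD + h
    z_hi = p.shaft_length if p.neck_length == 0 else max(
        p.shaft_length, head[2] + p.head_radius
    ) + h
    nx = int(np.ceil(2 * x_max / h))
    ny = int(np.ceil((y_hi - y_lo) / h))
    nz = int(np.ceil(z_hi / h)) if p.neck_length > 0 else max(int(round(z_hi / h)), 1)
    hx = 2 * x_max / nx
    hy = (y_hi - y_lo) / ny
    hz = z_hi / nz
    spacing = np.array([hx, hy, hz])
    origin = np.array([-x_max, y_lo, 0.0])
    return (nx, ny, nz), spacing, origin


def _cell_centres(dims, spacing, origin):
    nx, ny, nz = dims
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cells = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centres = origin + (cells + 0.5) * spacing
    return cells, centres


def generate_femur_mesh(params: FemurParams = FemurParams()) -> MeshModel:
    """Voxelise the idealised femur into a conforming tetrahedral mesh.

    The mesh carries node sets ``head_centre``, ``knee_centre``,
    ``greater_trochanter`` (= abductor attachment) and the element set
    ``bone`` covering all elements.  Output is deterministic for identical
    parameters.
    """
    dims, spacing, origin = _femur_lattice(params)
    cells, centres = _cell_centres(dims, spacing, origin)
    inside = _solid_depth(centres, params) > 0
    if not inside.any():
        raise ValueError("FemurParams produce an empty solid (target_edge_length too large?)")
    mesh, _ = voxels_to_mesh(cells[inside], dims, spacing, origin)
    mesh.element_sets["bone"] = np.arange(mesh.n_elements, dtype=np.int64)
    for name in ("bone_proximal", "bone_distal", "plate", "screws", "callus"):
        mesh.element_sets.setdefault(name, np.empty(0, dtype=np.int64))
    # the whole femur is one fragment until an osteotomy is applied
    mesh.element_sets["bone_distal"] = np.arange(mesh.n_elements, dtype=np.int64)
    mesh.lattice["femur_params"] = params
    _attach_node_sets(mesh, params)
    mesh.validate()
    return mesh


# ----------------------------------------------------------------------
# density field
# ----------------------------------------------------------------------
def generate_density_field(
    mesh: MeshModel, params: DensityFieldParams = DensityFieldParams()
) -> np.ndarray:
    """Per-element apparent density (g/cm^3) with cortical shell + smooth core.

    Elements whose centroid lies within the cortical thickness of the
    surface receive the cortical density; deeper (trabecular) elements get
    a spatially smoothed Gaussian random field rescaled to the requested
    mean/sd and clipped to [rho_min, rho_max].  Non-bone elements (implant
    cells) receive the cortical value as an inert placeholder; their
    stiffness is always overridden by the implant material.
    """
    if mesh.lattice is None or "femur_params" not in mesh.lattice:
        raise StructureError("mesh does not carry femur lattice provenance")
    fp: FemurParams = mesh.lattice["femur_params"]
    depth = _solid_depth(mesh.centroids(), fp)
    bone = mesh.bone_elements()
    rho = np.full(mesh.n_elements, params.cortical_density, dtype=float)
    interior_mask = np.zeros(mesh.n_elements, dtype=bool)
    interior_mask[bone] = depth[bone] > fp.cortical_thickness
    interior = np.nonzero(interior_mask)[0]
    if len(interior) == 0:
        raise StructureError(
            "mesh has no interior (trabecular) elements; refine the lattice"
        )
    rng = np.random.default_rng(params.seed)
    v = rng.standard_normal(len(interior))
    # diffuse over the interior face-adjacency graph for spatial smoothness
    pos = -np.ones(mesh.n_elements, dtype=np.int64)
    pos[interior] = np.arange(len(interior))
    adj = mesh.face_adjacency()
    neighbour_lists = [
        pos[adj[e]][pos[adj[e]] >= 0] for e in interior
    ]
    for _ in range(8):
        means = np.array(
            [v[nb].mean() if len(nb) else v[i] for i, nb in enumerate(neighbour_lists)]
        )
        v = 0.5 * v + 0.5 * means
    sd = v.std()
    if sd > 0 and params.trabecular_density_sd > 0:
        v = (v - v.mean()) / sd * params.trabecular_density_sd
    else:
        v = np.zeros_like(v)
    rho[interior] = params.trabecular_density_mean + v
    return np.clip(rho, params.rho_min, params.rho_max)


# ----------------------------------------------------------------------
# assembly
# ----------------------------------------------------------------------
def _carve_cylinder(centres, start, direction, length, radius):
    rel = centres - start
    t = rel @ direction
    radial = np.linalg.norm(rel - np.outer(t, direction), axis=1)
    return (t >= 0) & (t <= length) & (radial <= radius)


def build_assembly(
    mesh: MeshModel,
    implant: ImplantParams = ImplantParams(),
    scenario_kind: str = "retained",
) -> MeshModel:
    """Split the femur at the osteotomy and (for implanted scenarios) fit the
    lateral blade plate, blade and screws as conforming element sets.

    ``scenario_kind``: ``intact`` returns the unsplit bone regions with
    empty implant sets; ``retained`` and ``removed`` share the same
    implanted geometry (removal is a simulation event, not a geometry
    change).  A one-element-thick ``callus`` layer spans the osteotomy gap
    in implanted assemblies.
    """
    if scenario_kind not in ("intact", "retained", "removed"):
        raise ValueError(f"unknown scenario_kind {scenario_kind!r}")
    if mesh.lattice is None or "femur_params" not in mesh.lattice:
        raise StructureError("build_assembly requires a lattice-generated femur mesh")
    fp: FemurParams = mesh.lattice["femur_params"]
    z_ost = implant.osteotomy_height
    if not 0.0 < z_ost < fp.shaft_length:
        raise GeometryError(
            f"osteotomy_height {z_ost} mm does not intersect the shaft "
            f"(0..{fp.shaft_length} mm)"
        )

    dims = mesh.lattice["dims"]
    spacing = mesh.lattice["h"]
    origin = mesh.lattice["origin"]
    R = fp.shaft_outer_radius

    if scenario_kind == "intact":
        out = mesh.copy()
        cz = out.centroids()[:, 2]
        bone = np.arange(out.n_elements, dtype=np.int64)
        out.element_sets = {
            "bone_proximal": bone[cz > z_ost],
            "bone_distal": bone[cz <= z_ost],
            "plate": np.empty(0, dtype=np.int64),
            "screws": np.empty(0, dtype=np.int64),
            "callus": np.empty(0, dtype=np.int64),
        }
        out.lattice["scenario_kind"] = "intact"
        out.validate()
        return out

    # --- lateral plate: lattice cells between the cortex staircase and the
    # plate outer face, spanning the osteotomy ---
    all_cells, all_centres = _cell_centres(dims, spacing, origin)
    in_bone = _solid_depth(all_centres, fp) > 0
    z0p = max(z_ost - implant.plate_length / 2.0, spacing[2])
    z1p = min(z_ost + implant.plate_length / 2.0, fp.shaft_length - spacing[2])
    if z1p <= z0p:
        raise GeometryError("plate_length leaves no usable span on the shaft")
    y_outer = R + implant.plate_thickness
    if y_outer > origin[1] + dims[1] * spacing[1]:
        raise GeometryError("plate_thickness exceeds the lateral lattice pad")
    plate_sel = (
        ~in_bone
        & (np.abs(all_centres[:, 0]) <= implant.plate_width / 2.0)
        & (all_centres[:, 1] > 0)
        & (all_centres[:, 1] <= y_outer)
        & (all_centres[:, 2] >= z0p)
        & (all_centres[:, 2] <= z1p)
    )
    if not plate_sel.any():
        raise GeometryError("plate does not contact the lateral surface")

    bone_cells = mesh.lattice["cells"]
    cells = np.vstack([bone_cells, all_cells[plate_sel]])
    kind = np.concatenate(
        [np.zeros(len(bone_cells), np.int64), np.ones(int(plate_sel.sum()), np.int64)]
    )  # 0 = bone, 1 = plate
    out, cell_of_elem = voxels_to_mesh(cells, dims, spacing, origin)
    elem_kind = kind[cell_of_elem]
    cent = out.centroids()

    # --- screws: horizontal cylinders along -y, carved from bone and plate ---
    r_eff = max(implant.screw_radius, 0.71 * float(spacing.max()))
    margin = max(2.0 * implant.screw_radius, 1.5 * float(spacing[2]))
    lo, hi = z0p + margin, z1p - margin
    if hi <= lo:
        raise GeometryError("plate too short for the requested screws")
    z_screws = np.linspace(lo, hi, implant.n_screws)
    # keep clear of the osteotomy/callus layer
    for i, zi in enumerate(z_screws):
        if abs(zi - z_ost) < 1.5 * spacing[2]:
            z_screws[i] = zi + np.sign(zi - z_ost or 1.0) * 1.5 * spacing[2]
    # snap to cell-centre planes so coarse lattices always capture a column
    kz = np.clip(np.round((z_screws - origin[2]) / spacing[2] - 0.5), 0, dims[2] - 1)
    z_screws = origin[2] + (kz + 0.5) * spacing[2]
    screw_sets: dict[str, np.ndarray] = {}
    claimed = np.zeros(out.n_elements, dtype=bool)
    for i, zi in enumerate(z_screws):
        start = np.array([0.0, y_outer, zi])
        sel = _carve_cylinder(
            cent, start, np.array([0.0, -1.0, 0.0]), y_outer + 0.7 * R, r_eff
        )
        sel &= ~claimed
        if not sel.any():
            raise GeometryError(f"screw {i + 1} does not intersect the assembly")
        claimed |= sel
        screw_sets[f"screw_{i + 1}"] = np.nonzero(sel)[0].astype(np.int64)

    # --- blade: angled prong from the plate top toward the neck ---
    blade_sel = np.zeros(out.n_elements, dtype=bool)
    gamma = np.radians(implant.blade_angle - 90.0)
    blade_dir = np.array([0.0, -np.cos(gamma), np.sin(gamma)])
    blade_start = np.array([0.0, R, z1p - 2.0 * spacing[2]])
    blade_sel = _carve_cylinder(
        cent, blade_start, blade_dir, 1.8 * R, max(1.6 * implant.screw_radius, r_eff)
    )
    blade_sel &= ~claimed
    claimed |= blade_sel

    screws_all = np.sort(np.concatenate([v for v in screw_sets.values()]))
    plate_elems = np.nonzero(((elem_kind == 1) & ~claimed) | blade_sel)[0]
    bone_mask = (elem_kind == 0) & ~claimed
    bone_idx = np.nonzero(bone_mask)[0]
    cz = cent[:, 2]
    prox = bone_idx[cz[bone_idx] > z_ost]
    dist = bone_idx[cz[bone_idx] <= z_ost]

    # --- callus: the one-cell-thick bone layer containing the plane ---
    kz_ost = int(np.clip((z_ost - origin[2]) // spacing[2], 0, dims[2] - 1))
    layer_lo = origin[2] + kz_ost * spacing[2]
    layer_hi = layer_lo + spacing[2]
    callus = bone_idx[(cz[bone_idx] >= layer_lo) & (cz[bone_idx] <= layer_hi)]

    out.element_sets = {
        "bone_proximal": prox.astype(np.int64),
        "bone_distal": dist.astype(np.int64),
        "plate": plate_elems.astype(np.int64),
        "screws": screws_all.astype(np.int64),
        "callus": callus.astype(np.int64),
        **screw_sets,
    }
    out.lattice["femur_params"] = fp
    out.lattice["scenario_kind"] = scenario_kind
    out.lattice["osteotomy_z"] = z_ost
    _attach_node_sets(out, fp)
    if not out.shared_faces("plate", "bone_proximal") and not out.shared_faces(
        "plate", "bone_distal"
    ):
        raise GeometryError("plate is not contactable with the lateral bone surface")
    out.validate()
    return out
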