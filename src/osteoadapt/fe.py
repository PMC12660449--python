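"""Small-strain linear-elastic solver on 4-node tetrahedra.

Standard constant-strain tet assembly with heterogeneous isotropic
properties, the isolated-femur boundary-condition set (fixed knee centre,
transversely locked greater trochanter, head centre free only along the
head-knee axis) and a direct sparse LU factorisation that is reused across
the seven load steps of a simulated month.  Element outputs are the strain
tensor, strain energy density U = 1/2 sigma:eps (MPa = J/cm^3 in the
mm-N-MPa system) and the von Mises stress, all evaluated at the element's
single integration point.

Deactivated elements (removed hardware) contribute no stiffness and carry
zero fields; degrees of freedom no longer attached to any active element
are removed from the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .loads import BoundaryConditionSpec, LoadStep
from .mesh import MeshModel, tet_volumes

__all__ = [
    "AssemblyError",
    "NumericalError",
    "ElementFieldSet",
    "LinearSystem",
    "element_matrices",
    "assemble_system",
    "solve_load_step",
]


class AssemblyError(RuntimeError):
    """The constrained system is singular (rigid-body mode left)."""


class NumericalError(RuntimeError):
    """The sparse solve failed or produced non-finite results."""


@dataclass
class ElementFieldSet:
    """Per-element fields from one static solve."""

    strain: np.ndarray  # (m, 6) engineering strains [xx, yy, zz, yz, xz, xy]
    stress: np.ndarray  # (m, 6) MPa
    energy_density: np.ndarray  # (m,) MPa == J/cm^3, >= 0
    von_mises: np.ndarray  # (m,) MPa, >= 0


def _elastic_matrix(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Isotropic elasticity matrices, (m, 6, 6), engineering-shear convention."""
    m = len(E)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((m, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


def element_matrices(mesh: MeshModel, E: np.ndarray, nu: np.ndarray):
    """Per-element stiffness (m,12,12), strain-displacement B (m,6,12), volumes."""
    vol = tet_volumes(mesh.nodes, mesh.tets)
    p = mesh.nodes[mesh.tets]  # (m, 4, 3)
    # gradients of the four linear shape functions
    J = np.stack([p[:, i] - p[:, 0] for i in (1, 2, 3)], axis=1)  # (m, 3, 3)
    Jinv = np.linalg.inv(J)
    grads = np.zeros((len(vol), 4, 3))
    grads[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    B = np.zeros((len(vol), 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 1] = gz
        B[:, 3, c + 2] = gy
        B[:, 4, c] = gz
        B[:, 4, c + 2] = gx
        B[:, 5, c] = gy
        B[:, 5, c + 1] = gx
    D = _elastic_matrix(np.asarray(E, float), np.asarray(nu, float))
    Ke = np.einsum("eji,ejk,ekl->eil", B, D, B) * vol[:, None, None]
    return Ke, B, D, vol


@dataclass
class LinearSystem:
    """Constrained sparse system for one assembly state."""

    mesh: MeshModel
    bc: BoundaryConditionSpec
    K_reduced: sp.csc_matrix
    T: sp.csc_matrix  # full-dof x reduced-dof transformation
    B: np.ndarray
    D: np.ndarray
    volumes: np.ndarray
    active: np.ndarray  # (m,) bool
    head_node: int
    _lu: spla.SuperLU | None = field(default=None, repr=False)

    @property
    def n_dofs(self) -> int:
        return self.K_reduced.shape[0]

    def factor(self) -> spla.SuperLU:
        if self._lu is None:
            try:
                self._lu = spla.splu(self.K_reduced.tocsc())
            except RuntimeError as exc:  # exactly singular
                raise AssemblyError(
                    "constrained stiffness is singular; a rigid-body mode remains "
                    "(check knee/trochanter/head constraints)"
                ) from exc
        return self._lu

    def is_positive_definite(self) -> bool:
        """Dense smallest-eigenvalue check; intended for coarse meshes."""
        Kd = self.K_reduced.toarray()
        w = np.linalg.eigvalsh(0.5 * (Kd + Kd.T))
        return bool(w.min() > 0)


def _resolve_active(mesh: MeshModel, active_sets) -> np.ndarray:
    if active_sets is None:
        return np.ones(mesh.n_elements, dtype=bool)
    mask = np.asarray(active_sets)
    if mask.dtype == bool:
        return mask.copy()
    out = np.zeros(mesh.n_elements, dtype=bool)
    for name in active_sets:
        out[mesh.element_sets[name]] = True
    return out


def assemble_system(
    assembly: MeshModel,
    E: np.ndarray,
    nu: np.ndarray,
    bc: BoundaryConditionSpec,
    active_sets=None,
) -> LinearSystem:
    """Assemble and constrain the global stiffness.

    Parameters
    ----------
    E, nu : per-element Young's modulus (MPa) and Poisson ratio.
    bc : boundary-condition specification; ``head_axis`` must be set.
    active_sets : None (all active), a boolean element mask, or an iterable
        of element-set names.  Inactive elements contribute zero stiffness.

    The head-centre node is condensed to a single generalised DOF along the
    head-knee axis via the transformation u = T q; the reduced operator is
    T^T K T, which stays symmetric positive definite when the constraint
    set removes every rigid-body mode.
    """
    E = np.asarray(E, float)
    nu = np.asarray(nu, float)
    if len(E) != assembly.n_elements or len(nu) != assembly.n_elements:
        raise AssemblyError("every element needs a material (E, nu)")
    if not np.all(np.isfinite(E)) or np.any(E <= 0):
        raise AssemblyError("element moduli must be positive and finite")
    active = _resolve_active(assembly, active_sets)

    Ke, B, D, vol = element_matrices(assembly, E, nu)
    act = np.nonzero(active)[0]
    dofs = (3 * assembly.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    rows = np.repeat(dofs[act], 12, axis=1).ravel()
    cols = np.tile(dofs[act], 12).ravel()
    vals = Ke[act].ravel()
    n = 3 * assembly.n_nodes
    K = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    # --- constraints ---
    for name in ("head_centre", "knee_centre", "greater_trochanter"):
        if name not in assembly.node_sets or len(assembly.node_sets[name]) == 0:
            raise AssemblyError(f"boundary-condition node set {name!r} missing")
    axis = bc.head_axis
    if axis is None:
        raise AssemblyError("BoundaryConditionSpec.head_axis is not set")
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)

    head = int(assembly.node_sets["head_centre"][0])
    knee = int(assembly.node_sets["knee_centre"][0])
    fixed = np.zeros(n, dtype=bool)
    for i, on in enumerate(bc.knee_centre_fixed_translations):
        if on:
            fixed[3 * knee + i] = True
    for tn in assembly.node_sets["greater_trochanter"]:
        for d in bc.trochanter_locked_directions:
            fixed[3 * int(tn) + d] = True
    # orphan dofs: nodes not attached to any active element
    attached = np.zeros(assembly.n_nodes, dtype=bool)
    attached[np.unique(assembly.tets[act])] = True
    fixed[np.repeat(~attached, 3)] = True
    head_dofs = [3 * head, 3 * head + 1, 3 * head + 2]
    if fixed[head_dofs].any():
        raise AssemblyError("head_centre node is fixed or detached; cannot attach connector")

    free = np.nonzero(~fixed)[0]
    free = free[~np.isin(free, head_dofs)]
    n_red = len(free) + 1
    t_rows = np.concatenate([free, head_dofs])
    t_cols = np.concatenate([np.arange(len(free)), np.full(3, len(free))])
    t_vals = np.concatenate([np.ones(len(free)), axis])
    T = sp.coo_matrix((t_vals, (t_rows, t_cols)), shape=(n, n_red)).tocsc()

    K_red = (T.T @ K @ T).tocsc()
    return LinearSystem(
        mesh=assembly,
        bc=bc,
        K_reduced=K_red,
        T=T,
        B=B,
        D=D,
        volumes=vol,
        active=active,
        head_node=head,
    )


def _assemble_full(assembly: MeshModel, E, nu, active: np.ndarray):
    Ke, B, D, vol = element_matrices(assembly, np.asarray(E, float), np.asarray(nu, float))
    act = np.nonzero(active)[0]
    dofs = (3 * assembly.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    rows = np.repeat(dofs[act], 12, axis=1).ravel()
    cols = np.tile(dofs[act], 12).ravel()
    n = 3 * assembly.n_nodes
    K = sp.coo_matrix((Ke[act].ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K, B, D, vol


def solve_dirichlet(
    mesh: MeshModel,
    E,
    nu,
    fixed_mask: np.ndarray,
    fixed_values: np.ndarray | None = None,
    f: np.ndarray | None = None,
    active_sets=None,
):
    """General static solve with (possibly inhomogeneous) Dirichlet DOFs.

    ``fixed_mask`` is a (3n,) boolean over DOFs; ``fixed_values`` the
    prescribed displacements on those DOFs (zero if omitted); ``f`` a full
    nodal force vector.  Returns ``(u, fields)``.  This is the workhorse
    behind patch/bar/cantilever verification problems that do not use the
    femur boundary-condition set.
    """
    active = _resolve_active(mesh, active_sets)
    K, B, D, vol = _assemble_full(mesh, E, nu, active)
    n = K.shape[0]
    u = np.zeros(n)
    if fixed_values is not None:
        fixed_values = np.asarray(fixed_values, float)
        u[fixed_mask] = fixed_values[fixed_mask] if len(fixed_values) == n else fixed_values
    rhs = np.zeros(n) if f is None else np.asarray(f, float).copy()
    free = ~fixed_mask
    rhs_free = rhs[free] - K[free][:, fixed_mask] @ u[fixed_mask]
    try:
        lu = spla.splu(K[free][:, free].tocsc())
    except RuntimeError as exc:
        raise AssemblyError("free-free stiffness block is singular") from exc
    u[free] = lu.solve(rhs_free)
    if not np.all(np.isfinite(u)):
        raise NumericalError("Dirichlet solve produced non-finite displacements")
    shell = LinearSystem(
        mesh=mesh,
        bc=BoundaryConditionSpec(head_axis=np.array([0.0, 0.0, 1.0])),
        K_reduced=K[free][:, free].tocsc(),
        T=sp.identity(n, format="csc"),
        B=B,
        D=D,
        volumes=vol,
        active=active,
        head_node=-1,
    )
    return u, element_fields(shell, u)


def surface_traction_loads(
    mesh: MeshModel, node_mask: np.ndarray, total_force: np.ndarray
) -> np.ndarray:
    """Nodal force vector equivalent to a uniform traction on a surface.

    ``node_mask`` selects the loaded surface's nodes; the total force is
    split in proportion to each node's tributary area (one third of every
    boundary face whose three nodes all lie on the surface), the consistent
    lumping for linear triangles.
    """
    from .mesh import _TET_FACES

    weights = np.zeros(mesh.n_nodes)
    faces = mesh.tets[:, _TET_FACES].reshape(-1, 3)
    on = node_mask[faces].all(axis=1)
    for tri in faces[on]:
        p = mesh.nodes[tri]
        area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        weights[tri] += area / 3.0
    total = weights.sum()
    if total == 0:
        raise ValueError("no boundary face lies fully on the loaded surface")
    f = np.zeros(3 * mesh.n_nodes)
    tf = np.asarray(total_force, float)
    for d in range(3):
        f[d::3] = weights / total * tf[d]
    return f


def total_strain_energy(system: LinearSystem, u: np.ndarray, fields: ElementFieldSet) -> float:
    """Volume integral of the element SED (N*mm)."""
    return float(np.sum(fields.energy_density * system.volumes * system.active))


def build_load_vector(system: LinearSystem, step: LoadStep) -> np.ndarray:
    """Full-DOF nodal force vector for one load step.

    The hip contact force acts on the head-centre node (only its component
    along the connector axis does work); muscle bundle forces are divided
    equally over their attachment node set.
    """
    mesh = system.mesh
    n = 3 * mesh.n_nodes
    f = np.zeros(n)
    hv = np.asarray(step.hip_contact_force, float)
    if not np.all(np.isfinite(hv)):
        raise ValueError("non-finite hip contact force")
    f[3 * system.head_node : 3 * system.head_node + 3] += hv
    for set_name, force in step.muscle_forces:
        force = np.asarray(force, float)
        if not np.all(np.isfinite(force)):
            raise ValueError(f"non-finite muscle force on {set_name!r}")
        nodes = mesh.node_sets[set_name]
        share = force / len(nodes)
        for nd in nodes:
            f[3 * int(nd) : 3 * int(nd) + 3] += share
    return f


def element_fields(system: LinearSystem, u: np.ndarray) -> ElementFieldSet:
    """Strain, stress, SED and von Mises per element for a displacement field."""
    mesh = system.mesh
    ue = u.reshape(-1, 3)[mesh.tets].reshape(mesh.n_elements, 12)
    strain = np.einsum("eij,ej->ei", system.B, ue)
    stress = np.einsum("eij,ej->ei", system.D, strain)
    inactive = ~system.active
    strain[inactive] = 0.0
    stress[inactive] = 0.0
    U = 0.5 * np.einsum("ei,ei->e", stress, strain)
    U = np.maximum(U, 0.0)
    s = stress
    vm = np.sqrt(
        0.5
        * (
            (s[:, 0] - s[:, 1]) ** 2
            + (s[:, 1] - s[:, 2]) ** 2
            + (s[:, 2] - s[:, 0]) ** 2
        )
        + 3.0 * (s[:, 3] ** 2 + s[:, 4] ** 2 + s[:, 5] ** 2)
    )
    return ElementFieldSet(strain=strain, stress=stress, energy_density=U, von_mises=vm)


def solve_load_step(system: LinearSystem, step: LoadStep):
    """Direct sparse solve of one load step.

    Returns ``(u, fields)`` where ``u`` is the full (3n,) displacement
    vector (mm) and ``fields`` the per-element :class:`ElementFieldSet`.
    The LU factorisation is computed once per system and reused.
    """
    f = build_load_vector(system, step)
    lu = system.factor()
    q = lu.solve(np.asarray(system.T.T @ f).ravel())
    if not np.all(np.isfinite(q)):
        raise NumericalError(
            "sparse solve returned non-finite displacements; the system may be "
            "ill-conditioned (check constraints and element moduli)"
        )
    u = np.asarray(system.T @ q).ravel()
    return u, element_fields(system, u)
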