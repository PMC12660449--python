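import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from osteoadapt.anatomy import (
    DensityFieldParams,
    FemurParams,
    ImplantParams,
    build_assembly,
    generate_density_field,
    generate_femur_mesh,
)
from osteoadapt.loads import LoadProgram, LoadStep
from osteoadapt.mesh import MeshModel, box_mesh
from osteoadapt.remodelling import AssemblyState

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

# coarse anatomy: fast enough for 36-month runs inside unit tests
COARSE_FEMUR = FemurParams(
    shaft_length=120.0,
    shaft_outer_radius=12.0,
    cortical_thickness=4.0,
    neck_angle=130.0,
    neck_length=28.0,
    head_radius=13.0,
    target_edge_length=6.0,
    seed=0,
)
COARSE_IMPLANT = ImplantParams(
    plate_length=60.0,
    plate_width=12.0,
    plate_thickness=5.0,
    n_screws=3,
    screw_radius=2.5,
    osteotomy_height=85.0,
)


@pytest.fixture(scope="session")
def coarse_femur() -> MeshModel:
    return generate_femur_mesh(COARSE_FEMUR)


@pytest.fixture(scope="session")
def coarse_retained(coarse_femur) -> MeshModel:
    return build_assembly(coarse_femur, COARSE_IMPLANT, "retained")


@pytest.fixture(scope="session")
def coarse_intact(coarse_femur) -> MeshModel:
    return build_assembly(coarse_femur, COARSE_IMPLANT, "intact")


@pytest.fixture(scope="session")
def coarse_density(coarse_retained) -> np.ndarray:
    return generate_density_field(coarse_retained, DensityFieldParams(seed=0))


def make_bar_assembly(
    lengths=(10.0, 10.0, 50.0),
    divisions=(2, 2, 10),
    steel_strip=False,
) -> AssemblyState:
    """Vertical bar dressed up with the femur node sets (head on top,
    knee at the bottom centre, 'trochanter' at a bottom corner) so the
    standard boundary-condition set and scenario machinery apply.
    Optionally the lateral-most element column becomes a bonded steel
    'plate' strip for stress-shielding experiments.
    """
    m = box_mesh(lengths, divisions)
    centre_top = np.array([lengths[0] / 2, lengths[1] / 2, lengths[2]])
    centre_bot = np.array([lengths[0] / 2, lengths[1] / 2, 0.0])
    head = int(np.argmin(np.linalg.norm(m.nodes - centre_top, axis=1)))
    knee = int(np.argmin(np.linalg.norm(m.nodes - centre_bot, axis=1)))
    corner = int(np.argmin(np.linalg.norm(m.nodes - np.array([0.0, 0.0, 0.0]), axis=1)))
    if corner == knee:
        corner = int(
            np.argmin(np.linalg.norm(m.nodes - np.array([lengths[0], 0, 0]), axis=1))
        )
    m.node_sets = {
        "head_centre": np.array([head]),
        "knee_centre": np.array([knee]),
        "greater_trochanter": np.array([corner]),
    }
    all_e = np.arange(m.n_elements, dtype=np.int64)
    if steel_strip:
        hy = lengths[1] / divisions[1]
        strip = all_e[m.centroids()[:, 1] > lengths[1] - hy]
        bone = np.setdiff1d(all_e, strip)
        m.element_sets = {
            "bone_proximal": bone[m.centroids()[bone, 2] > lengths[2] / 2],
            "bone_distal": bone[m.centroids()[bone, 2] <= lengths[2] / 2],
            "plate": strip,
            "screws": np.empty(0, np.int64),
            "callus": np.empty(0, np.int64),
        }
    else:
        m.element_sets = {
            "bone_proximal": all_e[m.centroids()[:, 2] > lengths[2] / 2],
            "bone_distal": all_e[m.centroids()[:, 2] <= lengths[2] / 2],
            "plate": np.empty(0, np.int64),
            "screws": np.empty(0, np.int64),
            "callus": np.empty(0, np.int64),
        }
    return AssemblyState.from_mesh(m)


def make_single_tet_assembly() -> AssemblyState:
    """One tetrahedral 'bone' element with the femur node-set roles, the
    smallest system on which every stimulus can be steered into the lazy
    zone (multi-element meshes always contain lightly loaded elements that
    shed their remaining load as they soften, so their stimulus cannot be
    raised into the zone)."""
    nodes = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [3.0, 3.0, 10.0]])
    m = MeshModel(nodes=nodes, tets=np.array([[0, 1, 2, 3]]))
    m.node_sets = {
        "head_centre": np.array([3]),
        "knee_centre": np.array([0]),
        "greater_trochanter": np.array([1]),
    }
    m.element_sets = {
        "bone_proximal": np.empty(0, np.int64),
        "bone_distal": np.array([0]),
        "plate": np.empty(0, np.int64),
        "screws": np.empty(0, np.int64),
        "callus": np.empty(0, np.int64),
    }
    return AssemblyState.from_mesh(m)


def adapt_to_lazy_zone(asm, loads, p, iters=120):
    """Iterate element densities until every stimulus of the assembly's own
    solve sits inside the lazy zone (S is monotone decreasing in rho)."""
    from osteoadapt import fe
    from osteoadapt.loads import default_bcs

    m = asm.mesh
    rho = np.full(m.n_elements, 1.0)
    bc = default_bcs(m)
    for _ in range(iters):
        E, nu = asm.element_properties(rho)
        sys_ = fe.assemble_system(m, E, nu, bc)
        _, fields = fe.solve_load_step(sys_, loads.steps[0])
        S = fields.energy_density / rho
        if np.all((S >= (1 - 0.9 * p.x) * p.S_ref) & (S <= (1 + 0.9 * p.x) * p.S_ref)):
            return rho
        rho = np.clip(rho * (S / p.S_ref) ** (1.0 / 2.49), p.rho_min, p.rho_max)
    raise AssertionError("could not steer all stimuli into the lazy zone")


def constant_load_program(force_z: float, n_equal: int = 7) -> LoadProgram:
    """Seven identical axial steps (head force along -z)."""
    step = LoadStep(hip_contact_force=np.array([0.0, 0.0, -force_z]))
    return LoadProgram(steps=tuple([step] * n_equal), body_weight=1.0)
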