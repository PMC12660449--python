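"""Strain-energy-density adaptive bone remodelling.

The mechanical stimulus of an element is its strain energy density per
unit apparent density, S = U / rho (J/g).  Around the homeostatic
reference S_ref there is a lazy (dead) zone of half-width x*S_ref inside
which nothing happens; outside it the apparent density evolves at

    drho/dt = C1*[S - (1+x)*S_ref] - C2*[S - (1+x)*S_ref]^2   for S >= (1+x)*S_ref
    drho/dt = C1*[S - (1-x)*S_ref]                            for S <= (1-x)*S_ref
    drho/dt = 0                                               otherwise

with rho clamped to [rho_min, rho_max].  One time step is one month of
gait loading, discretised into seven load steps; the default update
averages the rate over the seven steps (a per-step sequential mode with
dt/7 sub-steps is available).  Element moduli are refreshed from density
once per month so the stiffness factorisation is reused across the seven
solves.

Scenario events at the union month: the implant-retained model upgrades
the callus layer to the bone material law (solid union); the
implant-removed model additionally deactivates all plate and screw
elements.  The intact model has no event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .fe import assemble_system, solve_load_step
from .loads import LoadProgram, default_bcs
from .materials import (
    BoneMaterialLaw,
    CallusMaterial,
    ImplantMaterial,
    bin_materials,
    density_to_modulus,
)
from .mesh import MeshModel, StructureError

__all__ = [
    "RemodellingParams",
    "DensityState",
    "ScenarioConfig",
    "AssemblyState",
    "SimulationResult",
    "StateError",
    "remodelling_stimulus",
    "remodelling_rate",
    "step_month",
    "check_convergence",
    "apply_scenario_event",
    "run_scenario",
]


class StateError(RuntimeError):
    """Scenario/state machine misuse (e.g. union event applied twice)."""


@dataclass(frozen=True)
class RemodellingParams:
    """Rate-law constants and numerical controls.

    C1/C2 are the linear and quadratic rate constants in rate-consistent
    units (density change per month per unit stimulus excess); x the lazy
    zone half-width as a fraction of S_ref; S_ref the homeostatic stimulus
    (J/g); dt the time step in months.
    """

    C1: float = 60.0
    C2: float = 120.0
    x: float = 0.10
    S_ref: float = 3.6e-5
    dt: float = 1.0
    rho_min: float = 0.05
    rho_max: float = 2.0
    convergence_tol: float = 0.0005
    update_mode: str = "monthly-average"  # or "per-step"
    stimulus_aggregate: str = "mean"  # or "max" (monthly-average mode)
    roy_step: str = "max"  # "max" over the 7 steps, or "last"

    def __post_init__(self):
        if min(self.C1, self.C2, self.S_ref, self.dt) <= 0:
            raise ValueError("C1, C2, S_ref, dt must be positive")
        if not 0.0 <= self.x < 1.0:
            raise ValueError("lazy-zone half-width x must lie in [0, 1)")
        if self.rho_min >= self.rho_max:
            raise ValueError("rho_min must be below rho_max")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.update_mode not in ("monthly-average", "per-step"):
            raise ValueError("update_mode must be 'monthly-average' or 'per-step'")
        if self.roy_step not in ("max", "last"):
            raise ValueError("roy_step must be 'max' or 'last'")


@dataclass
class DensityState:
    """Per-element density state after month ``month`` (0 = initial)."""

    month: int
    rho: np.ndarray
    rho_start: np.ndarray
    converged: bool = False

    def copy(self) -> "DensityState":
        return DensityState(self.month, self.rho.copy(), self.rho_start, self.converged)


@dataclass(frozen=True)
class ScenarioConfig:
    scenario_kind: str = "retained"  # intact | retained | removed
    event_month: int = 12
    total_months: int = 36
    seed: int = 0
    remodelling: RemodellingParams = field(default_factory=RemodellingParams)
    bin_initial_field: bool = True

    def __post_init__(self):
        if self.scenario_kind not in ("intact", "retained", "removed"):
            raise ValueError(f"unknown scenario_kind {self.scenario_kind!r}")
        if not 1 <= self.event_month < self.total_months:
            raise ValueError("require 1 <= event_month < total_months")


@dataclass
class AssemblyState:
    """Mesh plus the mutable simulation aspects of the assembly."""

    mesh: MeshModel
    active: np.ndarray  # (m,) bool
    union: bool = False  # callus upgraded to bone law
    event_applied: bool = False
    bone_law: BoneMaterialLaw = field(default_factory=BoneMaterialLaw)
    implant: ImplantMaterial = field(default_factory=ImplantMaterial)
    callus: CallusMaterial = field(default_factory=CallusMaterial)

    @classmethod
    def from_mesh(cls, mesh: MeshModel, **kw) -> "AssemblyState":
        return cls(mesh=mesh, active=np.ones(mesh.n_elements, dtype=bool), **kw)

    def remodelling_elements(self) -> np.ndarray:
        """Bone elements currently subject to the rate law.

        The callus layer is provisional tissue until union and does not
        remodel while soft.
        """
        bone = self.mesh.bone_elements()
        if self.union or "callus" not in self.mesh.element_sets:
            return bone
        return np.setdiff1d(bone, self.mesh.element_sets["callus"])

    def element_properties(self, rho: np.ndarray):
        """Per-element (E, nu) for the current state."""
        m = self.mesh
        E = density_to_modulus(np.maximum(rho, 1e-6), self.bone_law)
        nu = np.full(m.n_elements, self.bone_law.poisson_ratio)
        callus = m.element_sets.get("callus", np.empty(0, np.int64))
        if not self.union and len(callus):
            E[callus] = self.callus.youngs_modulus
            nu[callus] = self.callus.poisson_ratio
        for name in ("plate", "screws"):
            idx = m.element_sets.get(name, np.empty(0, np.int64))
            E[idx] = self.implant.youngs_modulus
            nu[idx] = self.implant.poisson_ratio
        return E, nu


def remodelling_stimulus(U, rho):
    """Remodelling stimulus S = U / rho (J/g) from SED (J/cm^3) and density."""
    U = np.asarray(U, float)
    rho = np.asarray(rho, float)
    if np.any(rho <= 0):
        raise ValueError("apparent density must be positive")
    return U / rho


def remodelling_rate(S, p: RemodellingParams = RemodellingParams()):
    """Lazy-zone rate law drho/dt (g/cm^3 per month); total on S >= 0."""
    S = np.asarray(S, float)
    hi = (1.0 + p.x) * p.S_ref
    lo = (1.0 - p.x) * p.S_ref
    rate = np.zeros_like(S)
    above = S >= hi
    below = S <= lo
    d_hi = S - hi
    d_lo = S - lo
    rate = np.where(above, p.C1 * d_hi - p.C2 * d_hi**2, rate)
    rate = np.where(below & ~above, p.C1 * d_lo, rate)
    return rate if rate.ndim else float(rate)


@dataclass
class MonthDiagnostics:
    """Solver outputs of one simulated month."""

    month: int
    total_sed: float  # N*mm, at the final load step
    mean_stimulus: dict[str, float]  # per bone region, averaged over steps
    vm_field: np.ndarray | None = None  # per-element von Mises envelope (MPa)
    energy_density: np.ndarray | None = None  # last-step per-element SED


def step_month(
    state: DensityState,
    assembly: AssemblyState,
    loads: LoadProgram,
    p: RemodellingParams = RemodellingParams(),
    bc=None,
) -> tuple[DensityState, MonthDiagnostics]:
    """Advance the density field by one month of gait loading.

    Solves the seven load steps at the current (month-frozen) moduli, maps
    each element's SED to a stimulus and a remodelling rate, and applies
    either the step-averaged rate over dt (default) or seven sequential
    dt/7 sub-updates.  Densities are clamped to [rho_min, rho_max];
    elements outside the remodelling set (implant, soft callus, inactive)
    are untouched.
    """
    mesh = assembly.mesh
    if len(state.rho) != mesh.n_elements:
        raise StructureError("density state does not match the assembly mesh")
    if bc is None:
        bc = default_bcs(mesh)
    E, nu = assembly.element_properties(state.rho)
    system = assemble_system(mesh, E, nu, bc, assembly.active)

    remod = assembly.remodelling_elements()
    remod = remod[assembly.active[remod]]
    U_steps = []
    vm_steps = []
    total_sed = 0.0
    for step in loads.steps:
        u, fields = solve_load_step(system, step)
        U_steps.append(fields.energy_density)
        vm_steps.append(fields.von_mises)
        total_sed = float(np.sum(fields.energy_density * system.volumes))
    last_fields_energy = U_steps[-1]

    rho_new = state.rho.copy()
    if p.update_mode == "monthly-average":
        S_steps = np.stack(
            [remodelling_stimulus(U[remod], state.rho[remod]) for U in U_steps]
        )
        S_agg = S_steps.max(axis=0) if p.stimulus_aggregate == "max" else S_steps.mean(axis=0)
        if p.stimulus_aggregate == "max":
            rate = remodelling_rate(S_agg, p)
        else:
            rate = np.stack([remodelling_rate(s, p) for s in S_steps]).mean(axis=0)
        rho_new[remod] = np.clip(
            state.rho[remod] + p.dt * rate, p.rho_min, p.rho_max
        )
        mean_S = S_steps.mean(axis=0)
    else:  # per-step sequential
        acc = []
        for U in U_steps:
            S = remodelling_stimulus(U[remod], rho_new[remod])
            acc.append(S)
            rho_new[remod] = np.clip(
                rho_new[remod] + (p.dt / 7.0) * remodelling_rate(S, p),
                p.rho_min,
                p.rho_max,
            )
        mean_S = np.mean(acc, axis=0)

    # regional stimulus bookkeeping (step-averaged); remod is sorted
    mean_stim = {}
    for region in ("bone_proximal", "bone_distal"):
        els = mesh.element_sets.get(region, np.empty(0, np.int64))
        inset = els[np.isin(els, remod)]
        idx = np.searchsorted(remod, inset)
        mean_stim[region] = float(np.mean(mean_S[idx])) if len(idx) else float("nan")

    stack = np.stack(vm_steps)
    vm_field = stack.max(axis=0) if p.roy_step == "max" else stack[-1]

    new_state = DensityState(
        month=state.month + 1, rho=rho_new, rho_start=state.rho_start
    )
    diag = MonthDiagnostics(
        month=new_state.month,
        total_sed=total_sed,
        mean_stimulus=mean_stim,
        vm_field=vm_field,
        energy_density=last_fields_energy,
    )
    return new_state, diag


def check_convergence(prev, curr, tol: float = 0.0005) -> bool:
    """Stability test between successive months.

    ``prev``/``curr`` are ``(DensityState, total_strain_energy)`` pairs on
    the same mesh.  Converged when the relative change of both the total
    strain energy and the mean density is at or below ``tol`` (default
    0.05%).
    """
    (s0, e0), (s1, e1) = prev, curr
    if len(s0.rho) != len(s1.rho):
        raise StructureError("density states live on different meshes")
    r0, r1 = float(np.mean(s0.rho)), float(np.mean(s1.rho))
    drho = abs(r1 - r0) / max(abs(r0), 1e-300)
    dsed = abs(e1 - e0) / max(abs(e0), 1e-300)
    return bool(drho <= tol and dsed <= tol)


def apply_scenario_event(assembly: AssemblyState, scenario_kind: str) -> AssemblyState:
    """Apply the union-month event in place and return the assembly.

    retained: callus takes the bone material law (solid union).
    removed: plate and screws are deactivated and the cut surfaces unite.
    intact: no-op.
    """
    if scenario_kind == "intact":
        return assembly
    if assembly.event_applied:
        raise StateError("scenario event already applied")
    if scenario_kind not in ("retained", "removed"):
        raise ValueError(f"unknown scenario_kind {scenario_kind!r}")
    assembly.union = True
    if scenario_kind == "removed":
        for name in ("plate", "screws"):
            idx = assembly.mesh.element_sets.get(name, np.empty(0, np.int64))
            assembly.active[idx] = False
    assembly.event_applied = True
    return assembly


@dataclass
class SimulationResult:
    """Monthly output series of one scenario run."""

    config: ScenarioConfig
    months: list[int]
    delta_rho: dict[str, list[float]]  # region -> monthly Eq.-style mean change
    roy: list[dict]  # RoY records (month, component, pvms, roy, flags)
    mean_stimulus: dict[str, list[float]]
    converged: list[bool]
    total_sed: list[float]
    rho_start: np.ndarray
    rho_final: np.ndarray
    mesh: MeshModel
    final_active: np.ndarray
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    seed: int = 0


def run_scenario(
    config: ScenarioConfig,
    assembly: AssemblyState | MeshModel,
    loads: LoadProgram,
    rho_start: np.ndarray | None = None,
    snapshot_months: tuple[int, ...] = (1, 12, 13, 36),
) -> SimulationResult:
    """Simulate ``total_months`` months of remodelling for one scenario.

    The union/removal event fires after ``event_month`` for non-intact
    scenarios.  Regional average density change (proximal/distal), implant
    risk of yield while hardware is active, regional mean stimulus,
    convergence status and total strain energy are recorded monthly.
    """
    if isinstance(assembly, MeshModel):
        assembly = AssemblyState.from_mesh(assembly)
    if rho_start is None:
        from .anatomy import DensityFieldParams, generate_density_field

        rho_start = generate_density_field(
            assembly.mesh, DensityFieldParams(seed=config.seed)
        )
    rho0 = np.asarray(rho_start, float).copy()
    if config.bin_initial_field:
        bone = assembly.mesh.bone_elements()
        ids, table = bin_materials(rho0[bone], assembly.bone_law)
        rho0[bone] = table[ids, 0]
    p = config.remodelling
    state = DensityState(month=0, rho=rho0.copy(), rho_start=rho0.copy())
    bc = default_bcs(assembly.mesh)

    result = SimulationResult(
        config=config,
        months=[],
        delta_rho={"proximal": [], "distal": []},
        roy=[],
        mean_stimulus={"proximal": [], "distal": []},
        converged=[],
        total_sed=[],
        rho_start=rho0.copy(),
        rho_final=rho0.copy(),
        mesh=assembly.mesh,
        final_active=assembly.active.copy(),
        seed=config.seed,
    )
    prev = None
    for month in range(1, config.total_months + 1):
        if month == config.event_month + 1 and config.scenario_kind != "intact":
            apply_scenario_event(assembly, config.scenario_kind)
        try:
            state, diag = step_month(state, assembly, loads, p, bc=bc)
        except Exception as exc:
            raise RuntimeError(
                f"scenario {config.scenario_kind!r} failed at month {month}"
            ) from exc
        result.months.append(month)
        for region, key in (("bone_proximal", "proximal"), ("bone_distal", "distal")):
            result.delta_rho[key].append(
                _metrics.average_density_change(state, assembly.mesh.element_sets[region])
            )
            result.mean_stimulus[key].append(diag.mean_stimulus[region])
        hardware_active = bool(
            len(assembly.mesh.element_sets.get("plate", ()))
            and assembly.active[assembly.mesh.element_sets["plate"]].any()
        )
        if hardware_active:
            for comp in ("plate", "screws"):
                els = assembly.mesh.element_sets.get(comp, np.empty(0, np.int64))
                if len(els) == 0 or not assembly.active[els].any():
                    continue
                pvms = _metrics.filtered_pvms(
                    diag.vm_field,
                    assembly.mesh.face_adjacency(),
                    assembly.mesh.element_sets[comp],
                )
                result.roy.append(
                    _metrics.make_roy_record(
                        month, comp, pvms, assembly.implant.yield_strength
                    )
                )
        curr = (state, diag.total_sed)
        result.converged.append(
            check_convergence(prev, curr, p.convergence_tol) if prev else False
        )
        result.total_sed.append(diag.total_sed)
        prev = (state.copy(), diag.total_sed)
        if month in snapshot_months:
            result.snapshots[month] = state.rho.copy()
    state.converged = result.converged[-1] if result.converged else False
    result.rho_final = state.rho.copy()
    result.final_active = assembly.active.copy()
    return result
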