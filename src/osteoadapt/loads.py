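"""Gait-cycle load programs and the boundary-condition set.

One simulated month of walking is represented by seven static load steps
spanning the stance phase.  Each step carries a hip joint contact force
applied at the femoral-head centre plus muscle force bundles applied over
attachment node sets (a single hip-abductor bundle on the greater
trochanter in the default profile).  The assembly is restrained by the
standard isolated-femur set: knee centre fixed in all translations, the
most lateral point of the greater trochanter fixed in the anterior-
posterior and medial-lateral directions, and the head centre free to
translate only along the head-to-knee axis (an axial connector realised as
a rotated single-DOF constraint).

Coordinate frame: +x anterior, +y lateral, +z superior (knee to head).
Units: N, mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LoadStep",
    "LoadProgram",
    "BoundaryConditionSpec",
    "ConfigurationError",
    "generate_load_program",
    "default_bcs",
    "PROFILES",
]


class ConfigurationError(ValueError):
    """Unknown profile or invalid load-program configuration."""


@dataclass(frozen=True)
class LoadStep:
    """One static load step: hip contact force + muscle bundles."""

    hip_contact_force: np.ndarray  # (3,) N, applied at head_centre
    muscle_forces: tuple[tuple[str, np.ndarray], ...] = ()  # (node_set, (3,) N)


@dataclass(frozen=True)
class LoadProgram:
    steps: tuple[LoadStep, ...]
    body_weight: float  # N
    profile_name: str = "walking"
    seed: int = 0

    def __post_init__(self):
        if len(self.steps) != 7:
            raise ConfigurationError(
                f"a load program has exactly 7 gait load steps, got {len(self.steps)}"
            )
        for s in self.steps:
            if not np.all(np.isfinite(s.hip_contact_force)):
                raise ConfigurationError("non-finite hip contact force")
            for _, f in s.muscle_forces:
                if not np.all(np.isfinite(f)):
                    raise ConfigurationError("non-finite muscle force")


@dataclass(frozen=True)
class BoundaryConditionSpec:
    """Constraint set removing all rigid-body modes of the assembly."""

    knee_centre_fixed_translations: tuple[bool, bool, bool] = (True, True, True)
    trochanter_locked_directions: tuple[int, ...] = (0, 1)  # x (AP), y (ML)
    head_axis: np.ndarray | None = None  # unit vector head -> knee; from mesh if None


# stance-phase magnitude fractions per step; the hip profile peaks mid-stance
_WALK_HIP = np.array([0.40, 0.75, 1.00, 0.85, 0.75, 0.90, 0.50])
_WALK_ABD = np.array([0.35, 0.70, 1.00, 0.80, 0.70, 0.85, 0.45])

# force directions in the femur frame (unit vectors)
_HIP_DIR = np.array([0.0, -np.sin(np.radians(13.0)), -np.cos(np.radians(13.0))])
_ABD_DIR = np.array([0.0, -np.sin(np.radians(20.0)), np.cos(np.radians(20.0))])

PROFILES = {
    "walking": {
        "hip_fractions": _WALK_HIP,
        "abductor_fractions": _WALK_ABD,
        "hip_peak_multiple": 3.0,  # x body weight, mid-stance
        "abductor_peak_multiple": 1.5,
    },
}


def generate_load_program(
    body_weight: float,
    profile_name: str = "walking",
    seed: int = 0,
    hip_peak_multiple: float | None = None,
    abductor_peak_multiple: float | None = None,
) -> LoadProgram:
    """Build the seven-step gait load program for one simulated month.

    The hip contact force magnitude follows a stance-phase-like profile
    peaking at ``hip_peak_multiple`` x body weight; a single abductor bundle
    acts on the ``greater_trochanter`` node set.  All magnitudes scale
    linearly with body weight.
    """
    if body_weight <= 0:
        raise ConfigurationError("body_weight must be positive")
    if profile_name not in PROFILES:
        raise ConfigurationError(
            f"unknown load profile {profile_name!r}; available: {sorted(PROFILES)}"
        )
    prof = PROFILES[profile_name]
    hp = prof["hip_peak_multiple"] if hip_peak_multiple is None else hip_peak_multiple
    ap = (
        prof["abductor_peak_multiple"]
        if abductor_peak_multiple is None
        else abductor_peak_multiple
    )
    steps = []
    for fh, fa in zip(prof["hip_fractions"], prof["abductor_fractions"]):
        hip = fh * hp * body_weight * _HIP_DIR
        abd = fa * ap * body_weight * _ABD_DIR
        steps.append(
            LoadStep(
                hip_contact_force=hip,
                muscle_forces=(("greater_trochanter", abd),),
            )
        )
    return LoadProgram(
        steps=tuple(steps), body_weight=float(body_weight), profile_name=profile_name, seed=seed
    )


def default_bcs(mesh) -> BoundaryConditionSpec:
    """Boundary-condition spec with the head-knee axis taken from the mesh."""
    head = mesh.nodes[mesh.node_sets["head_centre"][0]]
    knee = mesh.nodes[mesh.node_sets["knee_centre"][0]]
    axis = knee - head
    n = np.linalg.norm(axis)
    if n == 0:
        raise ConfigurationError("head and knee centres coincide")
    return BoundaryConditionSpec(head_axis=axis / n)
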