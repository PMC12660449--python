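"""Output measures: regional average density change and implant risk of yield.

The regional measure is the mean, over a fragment's elements, of the
difference between the current and baseline apparent density.  The implant
measure is the peak von Mises stress (PVMS) of a hardware component
expressed as a percentage of the steel yield strength (792 MPa); before
taking the peak, singularity-driven outliers are rejected by requiring a
candidate maximum to lie within 10% of the stresses of its face-adjacent
neighbours within the same component.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionSeries",
    "RoYRecord",
    "average_density_change",
    "filtered_pvms",
    "risk_of_yield",
    "make_roy_record",
    "export_results",
]

YIELD_FLAG_PERCENT = 100.0
REHAB_FLAG_PERCENT = 50.0


@dataclass(frozen=True)
class RegionSeries:
    region: str  # proximal | distal
    delta_rho: tuple[float, ...]  # g/cm^3 per month
    n_elements: int

    def __post_init__(self):
        if self.n_elements <= 0:
            raise ValueError("region must contain elements")


@dataclass(frozen=True)
class RoYRecord:
    month: int
    component: str  # plate | screws
    pvms: float  # MPa, filtered
    roy: float  # percent
    exceeds_yield: bool  # >= 100%
    within_rehab_threshold: bool  # <= 50%


def average_density_change(state, region_elements) -> float:
    """Mean density change (g/cm^3) of a region relative to baseline."""
    region = np.asarray(region_elements, dtype=np.int64)
    if region.size == 0:
        raise ValueError("empty region")
    return float(np.mean(state.rho[region] - state.rho_start[region]))


def filtered_pvms(
    von_mises: np.ndarray,
    face_adjacency,
    component_elements,
    rel_tol: float = 0.10,
) -> float:
    """Peak von Mises stress after rejecting singularity-driven outliers.

    Component elements are visited in descending stress order; a candidate
    is accepted when its stress does not exceed ``(1 + rel_tol)`` times the
    maximum stress among its face-adjacent neighbours *inside the
    component*.  An element with no in-component neighbours is compared
    against the component's next-highest stress instead.  If every
    candidate is rejected the raw maximum is returned with a warning.
    """
    comp = np.asarray(component_elements, dtype=np.int64)
    if comp.size == 0:
        raise ValueError("empty component set")
    vm = np.asarray(von_mises, float)
    values = vm[comp]
    order = np.argsort(values)[::-1]
    in_comp = set(comp.tolist())
    for rank, oi in enumerate(order):
        e = comp[oi]
        v = values[oi]
        neighbours = [n for n in face_adjacency[e] if int(n) in in_comp]
        if neighbours:
            ref = max(vm[int(n)] for n in neighbours)
        elif rank + 1 < len(order):
            ref = values[order[rank + 1]]  # isolated element: next-highest value
        else:
            return float(v)  # single-element component
        if v <= (1.0 + rel_tol) * ref:
            return float(v)
    warnings.warn(
        "no stress peak passed the neighbour filter; returning the raw maximum",
        RuntimeWarning,
        stacklevel=2,
    )
    return float(values.max())


def risk_of_yield(pvms: float, yield_strength: float = 792.0) -> float:
    """Risk of yield (percent): filtered PVMS over material yield strength."""
    if yield_strength <= 0:
        raise ValueError("yield_strength must be positive")
    if pvms < 0:
        raise ValueError("pvms must be non-negative")
    return pvms / yield_strength * 100.0


def make_roy_record(month: int, component: str, pvms: float, yield_strength: float = 792.0) -> dict:
    roy = risk_of_yield(pvms, yield_strength)
    return {
        "month": month,
        "component": component,
        "pvms": float(pvms),
        "roy": roy,
        "exceeds_yield": bool(roy >= YIELD_FLAG_PERCENT),
        "within_rehab_threshold": bool(roy <= REHAB_FLAG_PERCENT),
    }


def export_results(result, out_dir, manifest_extra: dict | None = None):
    """Write the monthly series, VTK snapshots and run manifest of a scenario.

    Produces ``density_change.csv`` (month, scenario, region, value, units),
    ``risk_of_yield.csv``, ``convergence.csv``, VTK snapshots with density /
    delta-density / final von Mises cell fields, and ``manifest.json``.
    Returns the list of written paths.
    """
    from pathlib import Path

    from . import __version__
    from .vtkio import write_vtk

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written = []

    rows = []
    for key in ("proximal", "distal"):
        for month, val in zip(result.months, result.delta_rho[key]):
            rows.append(
                {
                    "month": month,
                    "scenario": result.config.scenario_kind,
                    "region": key,
                    "value": val,
                    "units": "g/cm^3",
                }
            )
    path = out / "density_change.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)

    roy_rows = [
        {
            "month": r["month"],
            "scenario": result.config.scenario_kind,
            "component": r["component"],
            "value": r["roy"],
            "units": "percent",
            "pvms_mpa": r["pvms"],
            "exceeds_yield": r["exceeds_yield"],
            "within_rehab_threshold": r["within_rehab_threshold"],
        }
        for r in result.roy
    ]
    path = out / "risk_of_yield.csv"
    pd.DataFrame(roy_rows).to_csv(path, index=False)
    written.append(path)

    path = out / "convergence.csv"
    pd.DataFrame(
        {
            "month": result.months,
            "converged": result.converged,
            "total_strain_energy_nmm": result.total_sed,
        }
    ).to_csv(path, index=False)
    written.append(path)

    set_id = np.zeros(result.mesh.n_elements, dtype=np.int64)
    set_names = {}
    for i, name in enumerate(sorted(result.mesh.element_sets), start=1):
        set_id[result.mesh.element_sets[name]] = i
        set_names[str(i)] = name
    for month, rho in sorted(result.snapshots.items()):
        path = out / f"snapshot_month_{month:02d}.vtk"
        write_vtk(
            path,
            result.mesh,
            cell_data={
                "density": rho,
                "delta_density": rho - result.rho_start,
                "element_set_id": set_id.astype(float),
                "active": result.final_active.astype(float),
            },
        )
        written.append(path)

    manifest = {
        "scenario": result.config.scenario_kind,
        "event_month": result.config.event_month,
        "total_months": result.config.total_months,
        "seed": result.seed,
        "version": __version__,
        "element_set_names": set_names,
        "converged_final": bool(result.converged[-1]) if result.converged else False,
        "convergence_log": [bool(c) for c in result.converged],
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    written.append(path)
    return written
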