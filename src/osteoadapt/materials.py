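"""Density-to-stiffness mapping for bone and implant steel properties.

Bone is treated as isotropic linear elastic with a power-law dependence of
Young's modulus on apparent density, E = a * rho^b (MPa, rho in g/cm^3),
defaulting to the femoral relation E = 6850 * rho^1.49 with a constant
Poisson ratio of 0.3.  The initial CT-style density field is discretised
into ten equal-width density-modulus layers, mirroring common FE bone-model
practice; remodelling thereafter updates element moduli continuously from
the evolving density unless per-month re-binning is requested.

The implant is medical-grade stainless steel: E = 190 GPa, nu = 0.33,
yield strength 792 MPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoneMaterialLaw",
    "ImplantMaterial",
    "CallusMaterial",
    "density_to_modulus",
    "bin_materials",
]


@dataclass(frozen=True)
class BoneMaterialLaw:
    """E = a * rho^b power law with constant Poisson ratio."""

    a: float = 6850.0  # MPa * (g/cm^3)^-b
    b: float = 1.49
    poisson_ratio: float = 0.3
    n_bins: int = 10

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("power-law coefficients a, b must be positive")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in (0, 0.5)")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


@dataclass(frozen=True)
class ImplantMaterial:
    youngs_modulus: float = 190000.0  # MPa
    poisson_ratio: float = 0.33
    yield_strength: float = 792.0  # MPa

    def __post_init__(self):
        if min(self.youngs_modulus, self.poisson_ratio, self.yield_strength) <= 0:
            raise ValueError("implant material properties must be positive")


@dataclass(frozen=True)
class CallusMaterial:
    """Soft provisional tissue bridging the osteotomy gap pre-union."""

    youngs_modulus: float = 50.0  # MPa
    poisson_ratio: float = 0.3


def density_to_modulus(rho, law: BoneMaterialLaw = BoneMaterialLaw()):
    """Young's modulus (MPa) from apparent density (g/cm^3), E = a*rho^b."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("apparent density must be positive")
    return law.a * rho**law.b


def bin_materials(density_field, law: BoneMaterialLaw = BoneMaterialLaw()):
    """Discretise a density field into n_bins equal-width material layers.

    Returns ``(material_id, table)`` where ``material_id[k]`` indexes the
    per-bin ``table`` of ``(rho_mid, E_mid)`` rows.  Fields with at most
    n_bins distinct values keep each value as its own material, which makes
    the operation exactly idempotent (a binned field re-bins to itself) and
    covers the constant-field case with a single layer.
    """
    rho = np.asarray(density_field, dtype=float)
    if rho.size == 0:
        raise ValueError("empty density field")
    if np.any(rho <= 0):
        raise ValueError("density field must be positive")
    distinct = np.unique(rho)
    if len(distinct) <= law.n_bins:
        mids = distinct
        ids = np.searchsorted(distinct, rho)
    else:
        lo, hi = rho.min(), rho.max()
        width = (hi - lo) / law.n_bins
        ids = np.minimum((rho - lo) // width, law.n_bins - 1).astype(np.int64)
        mids = lo + (np.arange(law.n_bins) + 0.5) * width
    table = np.column_stack([mids, density_to_modulus(mids, law)])
    return ids.astype(np.int64), table
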