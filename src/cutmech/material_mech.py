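"""Derive E, UTS and tearing energy from stress-strain records.

Young's modulus is the least-squares slope over the initial linear region
(engineering stress/strain, default window 0-5% strain); the ultimate tensile
strength is the maximum engineering stress; and the tearing energy comes from
the pure-shear (trousers-free) specimen geometry via the Rivlin-Thomas
relation

    Gc = W(lambda_c) * h0,

where W is the strain energy density of the unnotched twin specimen,
integrated (trapezoidal) up to the stretch lambda_c at which the crack in the
notched twin propagates, and h0 the unstrained specimen height in the loading
direction.  For a pure-shear specimen the energy release rate is independent
of crack length, which is what makes this simple product exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_model import MaterialProperties, material_length_scale
from .errors import InvalidInputError

__all__ = [
    "StressStrainCurve",
    "PureShearTestPair",
    "young_modulus",
    "ultimate_tensile_strength",
    "tearing_energy_pure_shear",
    "summarize_material",
    "characterize_batch",
    "DOGBONE_TENSION",
    "PURE_SHEAR_NOTCHED",
    "PURE_SHEAR_UNNOTCHED",
]

DOGBONE_TENSION = "dogbone_tension"
PURE_SHEAR_NOTCHED = "pure_shear_notched"
PURE_SHEAR_UNNOTCHED = "pure_shear_unnotched"

_TEST_TYPES = {DOGBONE_TENSION, PURE_SHEAR_NOTCHED, PURE_SHEAR_UNNOTCHED}


@dataclass
class StressStrainCurve:
    """Engineering stress-strain record of one specimen."""

    strain: np.ndarray  # dimensionless, non-decreasing from 0
    stress: np.ndarray  # Pa
    gauge_length: float = 10e-3  # m
    width: float = 5e-3  # m
    thickness: float = 0.3e-3  # m
    test_type: str = DOGBONE_TENSION
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.size < 2:
            raise InvalidInputError("strain and stress must be equal-length, n >= 2")
        if self.strain[0] < 0 or np.any(np.diff(self.strain) < 0):
            raise InvalidInputError("strain must be non-decreasing from 0")
        if not np.all(np.isfinite(self.stress)):
            raise InvalidInputError("stress must be finite")
        if min(self.gauge_length, self.width, self.thickness) <= 0:
            raise InvalidInputError("specimen geometry must be positive")
        if self.test_type not in _TEST_TYPES:
            raise InvalidInputError(f"unknown test_type {self.test_type!r}")


@dataclass
class PureShearTestPair:
    """Unnotched pure-shear record + critical stretch of its notched twin."""

    unnotched: StressStrainCurve
    critical_stretch: float  # stretch at crack propagation in the notched twin
    specimen_height: float  # m, unstrained, in the loading direction

    def __post_init__(self) -> None:
        if self.critical_stretch <= 1:
            raise InvalidInputError("critical_stretch must exceed 1")
        if self.specimen_height <= 0:
            raise InvalidInputError("specimen_height must be > 0")


def young_modulus(
    curve: StressStrainCurve, strain_window: tuple[float, float] = (0.0, 0.05)
) -> float:
    """Least-squares slope (Pa) of the initial linear region.

    The window is a fixed strain interval rather than an automated knee
    detection — simpler and deterministic; widen or narrow it for materials
    whose linear region ends before 5% strain.
    """
    lo, hi = strain_window
    mask = (curve.strain >= lo) & (curve.strain <= hi)
    if int(mask.sum()) < 2:
        raise InvalidInputError(
            f"strain window [{lo}, {hi}] contains {int(mask.sum())} point(s); "
            "need at least 2 (>= 5 recommended)"
        )
    slope, _ = np.polyfit(curve.strain[mask], curve.stress[mask], 1)
    return float(slope)


def ultimate_tensile_strength(curve: StressStrainCurve) -> float:
    """Maximum engineering stress (Pa) the specimen withstood."""
    return float(np.max(curve.stress))


def tearing_energy_pure_shear(pair: PureShearTestPair) -> float:
    """Tearing energy Gc = W(lambda_c) * h0 (J m^-2), Rivlin-Thomas pure shear."""
    curve = pair.unnotched
    eps_c = pair.critical_stretch - 1.0
    if curve.strain[-1] < eps_c - 1e-12:
        raise InvalidInputError(
            f"unnotched curve ends at strain {curve.strain[-1]:.4f}, before the "
            f"critical stretch (strain {eps_c:.4f})"
        )
    # Integrate stress d(strain) up to eps_c, interpolating the endpoint.
    mask = curve.strain < eps_c
    eps = np.append(curve.strain[mask], eps_c)
    sig = np.append(curve.stress[mask], np.interp(eps_c, curve.strain, curve.stress))
    W = float(np.trapezoid(sig, eps))  # J m^-3
    return W * pair.specimen_height


def summarize_material(
    name: str,
    Gc_replicates: Sequence[float],
    sigma_c_replicates: Sequence[float],
    E_replicates: Sequence[float],
) -> MaterialProperties:
    """Pool replicate estimates into a material (mean and sample sd).

    Fewer than 2 replicates for a quantity yields sd 0 with a warning.
    """

    def _pool(values: Sequence[float], label: str) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise InvalidInputError(f"no {label} replicates supplied")
        if arr.size < 2:
            warnings.warn(
                f"{label}: single replicate, reporting sd = 0", stacklevel=3
            )
            return float(arr[0]), 0.0
        return float(arr.mean()), float(arr.std(ddof=1))

    Gc, Gc_sd = _pool(Gc_replicates, "Gc")
    sc, sc_sd = _pool(sigma_c_replicates, "sigma_c")
    E, E_sd = _pool(E_replicates, "E")
    return MaterialProperties(
        name=name, Gc=Gc, Gc_sd=Gc_sd, sigma_c=sc, sigma_c_sd=sc_sd, E=E, E_sd=E_sd
    )


def characterize_batch(
    name: str,
    tensile_curves: Sequence[StressStrainCurve],
    shear_pairs: Sequence[PureShearTestPair],
    strain_window: tuple[float, float] = (0.0, 0.05),
) -> tuple[MaterialProperties, tuple[float, float]]:
    """Characterize a specimen batch end to end.

    Returns the pooled material and its length scale Gc/sigma_c (m, sd).
    """
    E = [young_modulus(c, strain_window) for c in tensile_curves]
    sigma = [ultimate_tensile_strength(c) for c in tensile_curves]
    Gc = [tearing_energy_pure_shear(p) for p in shear_pairs]
    material = summarize_material(name, Gc, sigma, E)
    return material, material_length_scale(material)
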