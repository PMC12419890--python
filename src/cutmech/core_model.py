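"""Fracture-mechanics model of cutting a thin sheet with a blade of finite sharpness.

Cutting is treated as a fracture process: advancing a cut through a sheet of
thickness ``t`` creates new surface area at an energetic cost set by the tearing
energy ``Gc`` (J m^-2), so the steady-state fracture force is bounded from below
by ``F >= Gc*t``.  A blunt blade incurs an additional, geometry-dependent cost
near the crack tip, parametrized by the cutting-edge radius ``R`` and a
characteristic stress ``sigma_c`` (taken as the ultimate tensile strength):

    Ff = Gc*t + C*sigma_c*R*t,        Ff/(Gc*t) = 1 + Omega,

with ``C`` a dimensionless contact constant of order unity and

    Omega = C*sigma_c*R/Gc

the sharpness number.  Omega compares the edge radius with the material length
scale ``Gc/sigma_c``: for Omega << 1 the blade is "ideally sharp" and the force
depends only on sheet properties; for Omega >~ 1 tool geometry dominates.

All quantities are SI internally (N, m, Pa, J m^-2).  Uncertainties are
propagated to first order assuming independent Gaussian errors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import InvalidInputError

__all__ = [
    "MaterialProperties",
    "BladeGeometry",
    "SheetSpec",
    "CutModelConfig",
    "CutForcePrediction",
    "IDEALLY_SHARP",
    "TRANSITIONAL",
    "GEOMETRY_DOMINATED",
    "lower_bound_force",
    "omega",
    "predict_cutting_force",
    "classify_sharpness",
    "critical_radius",
    "material_length_scale",
    "material_from_dict",
    "blade_from_dict",
    "sheet_from_dict",
    "load_material",
    "PDMS_4_TO_1",
    "PDMS_10_TO_1",
    "JAPANESE_LAUREL",
]

#: Sharpness regimes, assigned by :func:`classify_sharpness`.
IDEALLY_SHARP = "ideally_sharp"
TRANSITIONAL = "transitional"
GEOMETRY_DOMINATED = "geometry_dominated"


@dataclass(frozen=True)
class MaterialProperties:
    """Mechanical characterization of a sheet material.

    Parameters
    ----------
    name
        Label, e.g. ``"4:1 PDMS"``.
    Gc
        Tearing energy (critical surface energy per unit crack area), J m^-2.
    sigma_c
        Characteristic stress, Pa.  Identified with the ultimate tensile
        strength by default; the field is a plain number, so callers may
        substitute a yield stress or modulus where more appropriate.
    E
        Young's modulus, Pa.
    Gc_sd, sigma_c_sd, E_sd
        One-standard-deviation uncertainties (same units as the mean).
    """

    name: str
    Gc: float
    sigma_c: float
    E: float
    Gc_sd: float = 0.0
    sigma_c_sd: float = 0.0
    E_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.Gc > 0 and self.sigma_c > 0 and self.E > 0):
            raise InvalidInputError(
                f"material {self.name!r}: Gc, sigma_c and E must be positive "
                f"(got Gc={self.Gc}, sigma_c={self.sigma_c}, E={self.E})"
            )
        if min(self.Gc_sd, self.sigma_c_sd, self.E_sd) < 0:
            raise InvalidInputError(
                f"material {self.name!r}: standard deviations must be >= 0"
            )


@dataclass(frozen=True)
class BladeGeometry:
    """Cutting-edge radius and wedge angle of a tool (mandible or scalpel)."""

    edge_radius: float  # m
    wedge_angle: float = 90.0  # degrees
    label: str = "custom"  # pristine | forager | scalpel | custom

    def __post_init__(self) -> None:
        if self.edge_radius < 0:
            raise InvalidInputError(f"edge_radius must be >= 0, got {self.edge_radius}")
        if not 0 < self.wedge_angle < 180:
            raise InvalidInputError(
                f"wedge_angle must lie in (0, 180) degrees, got {self.wedge_angle}"
            )


@dataclass(frozen=True)
class SheetSpec:
    """Thickness (m) of the cut sheet, with measurement uncertainty."""

    thickness: float
    thickness_sd: float = 0.0
    substrate_label: str = ""

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise InvalidInputError(f"thickness must be > 0, got {self.thickness}")
        if self.thickness_sd < 0:
            raise InvalidInputError("thickness_sd must be >= 0")


@dataclass(frozen=True)
class CutModelConfig:
    """Model constants: contact constant C and the ideal-sharpness cutoff.

    ``C = 2`` follows the empirical choice for insect-mandible cutting;
    ``omega_sharp_threshold = 0.05`` is the largest Omega at which measured
    fracture forces are indistinguishable from the lower bound.
    """

    C: float = 2.0
    omega_sharp_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise InvalidInputError(f"C must be > 0, got {self.C}")
        if self.omega_sharp_threshold <= 0:
            raise InvalidInputError("omega_sharp_threshold must be > 0")


@dataclass(frozen=True)
class CutForcePrediction:
    """Model output for one blade/material/sheet combination.

    ``F_min = Gc*t`` is the sharp-blade lower bound; ``F_pred = Gc*t*(1+Omega)``
    the finite-sharpness prediction; ``normalized_force = F_pred/(Gc*t)``.
    """

    F_min: float  # N
    F_min_sd: float  # N
    omega: float
    F_pred: float  # N
    normalized_force: float
    regime: str

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise InvalidInputError("omega must be >= 0")
        if self.F_pred < self.F_min * (1 - 1e-12):
            raise InvalidInputError("F_pred must be >= F_min")
        if not math.isclose(self.normalized_force, 1.0 + self.omega, rel_tol=1e-9):
            raise InvalidInputError("normalized_force must equal 1 + omega")


def lower_bound_force(
    material: MaterialProperties, sheet: SheetSpec
) -> tuple[float, float]:
    """Sharp-blade lower bound ``Gc*t`` and its propagated uncertainty.

    Returns
    -------
    (F_min, F_min_sd)
        Force in N; sd from first-order propagation of independent errors,
        ``sqrt((t*Gc_sd)^2 + (Gc*t_sd)^2)``.
    """
    F = material.Gc * sheet.thickness
    sd = math.hypot(sheet.thickness * material.Gc_sd, material.Gc * sheet.thickness_sd)
    return F, sd


def omega(
    config: CutModelConfig, material: MaterialProperties, blade: BladeGeometry
) -> float:
    """Dimensionless sharpness number ``Omega = C*sigma_c*R/Gc``."""
    return config.C * material.sigma_c * blade.edge_radius / material.Gc


def classify_sharpness(omega_value: float, config: CutModelConfig) -> str:
    """Assign the sharpness regime for a given Omega.

    ``ideally_sharp`` for Omega strictly below the threshold (default 0.05;
    the threshold itself is *not* ideally sharp), ``geometry_dominated`` for
    Omega >= 1, ``transitional`` in between.
    """
    if omega_value < 0:
        raise InvalidInputError(f"omega must be >= 0, got {omega_value}")
    if omega_value < config.omega_sharp_threshold:
        return IDEALLY_SHARP
    if omega_value >= 1.0:
        return GEOMETRY_DOMINATED
    return TRANSITIONAL


def predict_cutting_force(
    config: CutModelConfig,
    material: MaterialProperties,
    blade: BladeGeometry,
    sheet: SheetSpec,
) -> CutForcePrediction:
    """Predict the steady-state fracture force ``Gc*t*(1 + Omega)``."""
    F_min, F_min_sd = lower_bound_force(material, sheet)
    om = omega(config, material, blade)
    F_pred = F_min * (1.0 + om)
    return CutForcePrediction(
        F_min=F_min,
        F_min_sd=F_min_sd,
        omega=om,
        F_pred=F_pred,
        normalized_force=1.0 + om,
        regime=classify_sharpness(om, config),
    )


def critical_radius(
    config: CutModelConfig, material: MaterialProperties, tolerance: float
) -> float:
    """Largest edge radius elevating the predicted force by at most `tolerance`.

    Inverts Omega = C*sigma_c*R/Gc at Omega = tolerance:
    ``R_crit = tolerance*Gc/(C*sigma_c)`` (m).  A blade with R below this
    returns a cutting-derived toughness estimate within `tolerance` of truth.
    """
    if tolerance < 0:
        raise InvalidInputError(f"tolerance must be >= 0, got {tolerance}")
    return tolerance * material.Gc / (config.C * material.sigma_c)


def material_length_scale(material: MaterialProperties) -> tuple[float, float]:
    """Material length scale ``Gc/sigma_c`` (m) with propagated uncertainty.

    Edge geometry is irrelevant to the cutting force when the edge radius is
    far below this length.
    """
    L = material.Gc / material.sigma_c
    sd = L * math.hypot(
        material.Gc_sd / material.Gc, material.sigma_c_sd / material.sigma_c
    )
    return L, sd


# ---------------------------------------------------------------------------
# Reference substrates (laboratory characterization means +/- sd).

#: 4:1 base:curing-agent PDMS pseudoleaf — stiff, brittle, low toughness.
PDMS_4_TO_1 = MaterialProperties(
    name="4:1 PDMS",
    Gc=98.0,
    Gc_sd=9.0,
    sigma_c=6.0e6,
    sigma_c_sd=2.0e6,
    E=4.1e6,
    E_sd=0.3e6,
)

#: 10:1 PDMS pseudoleaf — compliant and roughly twice as tough as the 4:1 mix.
PDMS_10_TO_1 = MaterialProperties(
    name="10:1 PDMS",
    Gc=197.0,
    Gc_sd=25.0,
    sigma_c=5.5e6,
    sigma_c_sd=2.0e6,
    E=1.6e6,
    E_sd=0.3e6,
)

#: Japanese laurel (Aucuba japonica) leaf lamina, pure-shear toughness.
JAPANESE_LAUREL = MaterialProperties(
    name="Japanese laurel",
    Gc=746.0,
    Gc_sd=210.0,
    sigma_c=1.63e6,
    sigma_c_sd=0.3e6,
    E=31.0e6,
    E_sd=4.0e6,
)


# ---------------------------------------------------------------------------
# Config-file I/O.  Canonical keys use explicit unit tags (MPa, J/m^2, um, nm);
# values are converted to SI on load.


def material_from_dict(d: dict) -> MaterialProperties:
    """Build a material from canonical unit-tagged keys.

    Expected keys: ``name``, ``Gc_J_per_m2``, ``sigma_c_MPa``, ``E_MPa`` and
    optional ``*_sd`` twins.
    """
    try:
        return MaterialProperties(
            name=str(d.get("name", "custom")),
            Gc=float(d["Gc_J_per_m2"]),
            Gc_sd=float(d.get("Gc_sd_J_per_m2", 0.0)),
            sigma_c=float(d["sigma_c_MPa"]) * 1e6,
            sigma_c_sd=float(d.get("sigma_c_sd_MPa", 0.0)) * 1e6,
            E=float(d["E_MPa"]) * 1e6,
            E_sd=float(d.get("E_sd_MPa", 0.0)) * 1e6,
        )
    except KeyError as exc:  # pragma: no cover - message detail only
        raise InvalidInputError(f"material config missing key {exc}") from exc


def blade_from_dict(d: dict) -> BladeGeometry:
    """Build a blade from ``edge_radius_nm`` / ``wedge_angle_deg`` keys."""
    try:
        return BladeGeometry(
            edge_radius=float(d["edge_radius_nm"]) * 1e-9,
            wedge_angle=float(d.get("wedge_angle_deg", 90.0)),
            label=str(d.get("label", "custom")),
        )
    except KeyError as exc:
        raise InvalidInputError(f"blade config missing key {exc}") from exc


def sheet_from_dict(d: dict) -> SheetSpec:
    """Build a sheet spec from ``thickness_um`` (+ optional sd) keys."""
    try:
        return SheetSpec(
            thickness=float(d["thickness_um"]) * 1e-6,
            thickness_sd=float(d.get("thickness_sd_um", 0.0)) * 1e-6,
            substrate_label=str(d.get("substrate_label", "")),
        )
    except KeyError as exc:
        raise InvalidInputError(f"sheet config missing key {exc}") from exc


def load_material(path: str | Path) -> MaterialProperties:
    """Read a material definition from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return material_from_dict(data)
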