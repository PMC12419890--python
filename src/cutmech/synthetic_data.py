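"""Generate every input the pipeline consumes, with known ground truth.

The generator emulates a cutting-force study on leaf-cutter ant mandibles:

* worker populations — body masses evenly spaced in log10 over the foraging
  range; "callow" (pristine) blades with size-invariant edge radii (truncated
  normal, mean 162 nm, sd 120 nm) and "forager" (worn) blades whose radii
  follow R = a * m^-0.87 with lognormal scatter, clamped to 89-11712 nm;
* two-pass force traces — a cut-initiation ramp to an overshoot peak followed
  by exponential settling onto the steady-state plateau Fc (first pass) and a
  lower spacing-force plateau Fs (second pass), with additive Gaussian noise,
  5 mm of travel at 0.3 mm/s;
* tip cross-section contours — wedge flanks joined by a tangent circular arc
  of prescribed radius, discretized at 0.5 px;
* stress-strain records — linear/Hermite tensile curves with exact initial
  slope E and peak sigma_c, and pure-shear pairs constructed so that
  W(lambda_c)*h0 equals the material's Gc exactly at zero noise.

Plateau levels satisfy the cutting model by construction
(Ff_true = Gc*t*(1+Omega) with Omega from :mod:`cutmech.core_model`), so every
processing stage can be tested against exact ground truth.  All draws go
through one :class:`numpy.random.Generator`; outputs are byte-identical under
a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .core_model import (
    PDMS_4_TO_1,
    PDMS_10_TO_1,
    BladeGeometry,
    CutModelConfig,
    MaterialProperties,
    omega,
)
from .edge_geometry import CrossSectionContour
from .errors import InvalidInputError
from .material_mech import (
    DOGBONE_TENSION,
    PURE_SHEAR_UNNOTCHED,
    PureShearTestPair,
    StressStrainCurve,
)
from .trace_processing import ForceTrace, write_trace

__all__ = [
    "WearModel",
    "SyntheticStudyConfig",
    "WorkerSample",
    "GroundTruthRecord",
    "generate_worker_population",
    "generate_force_trace",
    "generate_cross_section",
    "generate_stress_strain",
    "generate_pure_shear_pair",
    "generate_material_batch",
    "write_study_dir",
    "CALLOW",
    "FORAGER",
]

CALLOW = "callow"
FORAGER = "forager"


def _geometric_midpoint_prefactor(
    mass_range_mg: tuple[float, float],
    radius_range_m: tuple[float, float],
    exponent: float,
) -> float:
    """Prefactor mapping the log-midpoint of the mass range onto the
    log-midpoint of the radius range (the deterministic wear line cannot span
    the full observed radius range; lognormal scatter supplies the tails)."""
    m_mid = math.sqrt(mass_range_mg[0] * mass_range_mg[1])
    r_mid = math.sqrt(radius_range_m[0] * radius_range_m[1])
    return r_mid / m_mid**exponent


@dataclass
class WearModel:
    """Edge-radius model: size-invariant pristine radii, power-law wear."""

    pristine_radius_mean: float = 162e-9  # m
    pristine_radius_sd: float = 120e-9  # m
    forager_exponent: float = -0.87  # R ~ m^exponent, m in mg
    forager_prefactor: float | None = None  # m at m = 1 mg; None = derived
    forager_scatter_log10_sd: float = 0.4  # dex, lognormal wear scatter
    radius_min: float = 89e-9  # m
    radius_max: float = 11712e-9  # m

    def __post_init__(self) -> None:
        if min(self.pristine_radius_mean, self.radius_min, self.radius_max) <= 0:
            raise InvalidInputError("radii must be positive")
        if self.pristine_radius_sd < 0 or self.forager_scatter_log10_sd < 0:
            raise InvalidInputError("dispersions must be >= 0")
        if self.radius_min >= self.radius_max:
            raise InvalidInputError("radius_min must be below radius_max")


@dataclass
class SyntheticStudyConfig:
    """Study conditions for the simulated experiment.

    Defaults reproduce the laboratory conditions: 15 workers per group with
    masses spanning the foraging range, the two characterized PDMS pseudoleaf
    materials at 200 and 400 um nominal thickness (5% sheet-to-sheet sd),
    0.3 mm/s stage speed with 5 mm travel, 1 mN plateau noise, and spacing
    forces drawn at 12-22% of the total cutting force (use 9-14% for
    plant-tissue profiles).
    """

    seed: int = 0
    n_per_group: int = 15
    callow_mass_range_mg: tuple[float, float] = (1.9, 55.5)
    forager_mass_range_mg: tuple[float, float] = (2.3, 54.8)
    materials: tuple[MaterialProperties, ...] = (PDMS_4_TO_1, PDMS_10_TO_1)
    thicknesses_m: tuple[float, ...] = (200e-6, 400e-6)
    thickness_rel_sd: float = 0.05
    wear: WearModel = field(default_factory=WearModel)
    trace_noise_sd: float = 1e-3  # N
    spacing_fraction_range: tuple[float, float] = (0.12, 0.22)
    stage_speed: float = 0.3e-3  # m/s
    sampling_rate: float = 300.0  # Hz
    travel: float = 5e-3  # m
    peak_overshoot: float = 1.33  # initiation peak / plateau
    peak_displacement: float = 0.8e-3  # m
    settle_length: float = 0.1e-3  # m, exponential settling scale
    callow_wedge_angle: tuple[float, float] = (77.0, 15.0)  # mean, sd (deg)
    forager_wedge_angle: tuple[float, float] = (93.0, 9.0)
    model: CutModelConfig = field(default_factory=CutModelConfig)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise InvalidInputError("n_per_group must be >= 2")
        if self.trace_noise_sd < 0 or self.thickness_rel_sd < 0:
            raise InvalidInputError("dispersions must be >= 0")
        lo, hi = self.spacing_fraction_range
        if not 0 <= lo <= hi < 1:
            raise InvalidInputError("spacing_fraction_range must lie in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class WorkerSample:
    """One worker: body mass, group, and the true geometry of its blade."""

    sample_id: str
    mass: float  # mg
    group: str  # callow | forager
    blade: BladeGeometry

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise InvalidInputError("mass must be > 0")
        if self.group not in (CALLOW, FORAGER):
            raise InvalidInputError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Per-trial truth, consistent with the cutting model by construction."""

    trial_id: str
    sample_id: str
    group: str
    mass: float  # mg
    material_name: str
    thickness: float  # m, actual sampled sheet thickness
    edge_radius: float  # m
    omega: float
    Fc: float  # N
    Fs: float  # N
    Ff: float  # N


def generate_worker_population(
    config: SyntheticStudyConfig,
    rng: np.random.Generator | None = None,
    groups: tuple[str, ...] = (CALLOW, FORAGER),
) -> list[WorkerSample]:
    """Draw both worker groups with ground-truth blade geometry.

    Masses are evenly spaced in log10 across each group's range.  Callow
    radii are size-invariant truncated-normal draws; forager radii follow the
    wear power law with lognormal scatter, clamped to the configured range.
    """
    rng = config.rng() if rng is None else rng
    wear = config.wear
    workers: list[WorkerSample] = []
    for group in groups:
        lo, hi = (
            config.callow_mass_range_mg
            if group == CALLOW
            else config.forager_mass_range_mg
        )
        masses = np.logspace(np.log10(lo), np.log10(hi), config.n_per_group)
        ang_mean, ang_sd = (
            config.callow_wedge_angle if group == CALLOW else config.forager_wedge_angle
        )
        angles = np.clip(rng.normal(ang_mean, ang_sd, config.n_per_group), 5.0, 175.0)
        if group == CALLOW:
            mu, sd = wear.pristine_radius_mean, wear.pristine_radius_sd
            if sd > 0:
                a = (0.0 - mu) / sd  # truncate at zero radius
                radii = truncnorm.rvs(
                    a, np.inf, loc=mu, scale=sd, size=config.n_per_group,
                    random_state=rng,
                )
            else:
                radii = np.full(config.n_per_group, mu)
        else:
            prefactor = wear.forager_prefactor
            if prefactor is None:
                prefactor = _geometric_midpoint_prefactor(
                    (lo, hi), (wear.radius_min, wear.radius_max), wear.forager_exponent
                )
            line = prefactor * masses**wear.forager_exponent
            if wear.forager_scatter_log10_sd > 0:
                scatter = 10.0 ** rng.normal(
                    0.0, wear.forager_scatter_log10_sd, config.n_per_group
                )
            else:
                scatter = 1.0
            radii = np.clip(line * scatter, wear.radius_min, wear.radius_max)
        for i, (m, r, ang) in enumerate(zip(masses, radii, angles)):
            workers.append(
                WorkerSample(
                    sample_id=f"{group[0]}{i:02d}",
                    mass=float(m),
                    group=group,
                    blade=BladeGeometry(
                        edge_radius=float(r),
                        wedge_angle=float(ang),
                        label="pristine" if group == CALLOW else "forager",
                    ),
                )
            )
    return workers


def _trace_grid(config: SyntheticStudyConfig) -> np.ndarray:
    n = int(round(config.travel / config.stage_speed * config.sampling_rate)) + 1
    return np.arange(n) / config.sampling_rate


def generate_force_trace(
    worker: WorkerSample,
    material: MaterialProperties,
    thickness: float,
    config: SyntheticStudyConfig,
    rng: np.random.Generator | None = None,
    trial_id: str = "",
) -> tuple[ForceTrace, ForceTrace, GroundTruthRecord]:
    """Simulate the two passes of one cutting trial.

    The first-pass plateau is ``Fc = Ff_true + Fs_true`` with
    ``Ff_true = Gc*t*(1+Omega)``; the spacing force is drawn so that Fs/Fc
    falls uniformly within the configured spacing-fraction range.  The
    initiation peak is a linear ramp to ``peak_overshoot * Fc`` followed by
    exponential settling — an invented shape whose parameters only matter
    through the plateau statistics.
    """
    rng = config.rng() if rng is None else rng
    if thickness <= 0:
        raise InvalidInputError("thickness must be > 0")
    om = omega(config.model, material, worker.blade)
    Ff_true = material.Gc * thickness * (1.0 + om)
    f_lo, f_hi = config.spacing_fraction_range
    f = float(rng.uniform(f_lo, f_hi))
    Fs_true = Ff_true * f / (1.0 - f)
    Fc_true = Ff_true + Fs_true

    time = _trace_grid(config)
    disp = time * config.stage_speed
    peak = config.peak_overshoot * Fc_true

    first = np.where(
        disp <= config.peak_displacement,
        peak * disp / config.peak_displacement,
        Fc_true
        + (peak - Fc_true)
        * np.exp(-(disp - config.peak_displacement) / config.settle_length),
    )
    second = np.full_like(disp, Fs_true)
    if config.trace_noise_sd > 0:
        first = first + rng.normal(0.0, config.trace_noise_sd, first.size)
        second = second + rng.normal(0.0, config.trace_noise_sd, second.size)

    trial_id = trial_id or f"{worker.sample_id}-{material.name}-{thickness * 1e6:.0f}um"
    mk = lambda force, pass_id: ForceTrace(
        time=time,
        force=force,
        stage_speed=config.stage_speed,
        pass_id=pass_id,
        trial_id=trial_id,
    )
    truth = GroundTruthRecord(
        trial_id=trial_id,
        sample_id=worker.sample_id,
        group=worker.group,
        mass=worker.mass,
        material_name=material.name,
        thickness=thickness,
        edge_radius=worker.blade.edge_radius,
        omega=om,
        Fc=Fc_true,
        Fs=Fs_true,
        Ff=Ff_true,
    )
    return mk(first, "first"), mk(second, "second"), truth


def generate_cross_section(
    radius: float,
    wedge_angle_deg: float,
    scale: float,
    noise_px: float = 0.0,
    rng: np.random.Generator | int | None = None,
    flank_extra_px: float = 300.0,
    point_spacing_px: float = 0.5,
    specimen_id: str = "",
) -> CrossSectionContour:
    """Wedge flanks joined by a tangent circular arc of the given tip radius.

    The apex of the ideal wedge sits at the origin with the interior bisector
    along +y; the contour runs from one flank's outer end, around the arc tip,
    to the other flank's outer end, discretized at ``point_spacing_px``.
    Optional isotropic Gaussian jitter (``noise_px``) emulates digitization
    noise.
    """
    if radius < 0:
        raise InvalidInputError("radius must be >= 0")
    if not 0 < wedge_angle_deg < 180:
        raise InvalidInputError("wedge angle must lie in (0, 180)")
    if scale <= 0:
        raise InvalidInputError("scale must be > 0")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    gamma = math.radians(wedge_angle_deg) / 2.0
    r_px = radius / scale
    u_left = np.array([-math.sin(gamma), math.cos(gamma)])
    u_right = np.array([math.sin(gamma), math.cos(gamma)])

    tangent_len = r_px / math.tan(gamma) if r_px > 0 else 0.0
    outer_len = tangent_len + flank_extra_px

    def _flank(u: np.ndarray, frm: float, to: float) -> np.ndarray:
        length = abs(to - frm)
        n = max(int(math.ceil(length / point_spacing_px)), 2)
        ts = np.linspace(frm, to, n)
        return ts[:, None] * u[None, :]

    parts: list[np.ndarray] = []
    # Left flank: outer end -> tangent point (exclusive of the arc join).
    parts.append(_flank(u_left, outer_len, tangent_len)[:-1])
    if r_px > 0:
        center = np.array([0.0, r_px / math.sin(gamma)])
        # Arc from the left tangent point, through the tip at angle -pi/2,
        # to the right tangent point.  Seen from the arc centre the left
        # tangent direction is gamma - pi and the right one -gamma; since the
        # half-angle gamma < pi/2 the sweep passes -pi/2 without wrapping.
        a0 = gamma - math.pi
        a1 = -gamma
        arc_len = abs(a1 - a0) * r_px
        n_arc = max(int(math.ceil(arc_len / point_spacing_px)), 3)
        angs = np.linspace(a0, a1, n_arc)
        arc = center + r_px * np.column_stack([np.cos(angs), np.sin(angs)])
        parts.append(arc)
        parts.append(_flank(u_right, tangent_len, outer_len)[1:])
    else:
        parts.append(np.array([[0.0, 0.0]]))
        parts.append(_flank(u_right, 0.0, outer_len)[1:])

    points = np.vstack(parts)
    if noise_px > 0:
        points = points + gen.normal(0.0, noise_px, points.shape)
    return CrossSectionContour(points=points, scale=scale, specimen_id=specimen_id)


def generate_stress_strain(
    material: MaterialProperties,
    test_type: str = DOGBONE_TENSION,
    noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
    n_points: int = 200,
    linear_limit: float = 0.05,
    strain_at_peak: float = 0.8,
    failure_strain: float = 1.0,
    E: float | None = None,
    sigma_c: float | None = None,
) -> StressStrainCurve:
    """Tensile curve with exact initial slope E and exact peak stress sigma_c.

    Piecewise construction: linear (slope E) to ``linear_limit`` strain, a
    monotone cubic Hermite rise to the peak (sigma_c, zero slope) at
    ``strain_at_peak``, then linear softening to 85% of the peak.  The strain
    grid contains the section boundaries, so the peak stress is exactly
    sigma_c at zero noise.  ``noise`` is a multiplicative Gaussian sd (the
    recorded stress is ``true * (1 + N(0, noise))``), emulating a sensor
    whose error scales with the signal.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    E = material.E if E is None else E
    sigma_c = material.sigma_c if sigma_c is None else sigma_c
    # Keep the linear region below half the peak so the Hermite rise exists.
    lin = min(linear_limit, 0.5 * sigma_c / E)
    n_lin = max(n_points // 4, 5)
    n_soft = max(n_points // 4, 3)
    n_rise = max(n_points - n_lin - n_soft, 5)
    eps = np.concatenate([
        np.linspace(0.0, lin, n_lin, endpoint=False),
        np.linspace(lin, strain_at_peak, n_rise, endpoint=False),
        np.linspace(strain_at_peak, failure_strain, n_soft),
    ])

    s_lin = E * lin
    span = strain_at_peak - lin
    delta = (sigma_c - s_lin) / span
    m0 = min(E, 3.0 * delta)  # Fritsch-Carlson bound keeps the rise monotone
    t = np.clip((eps - lin) / span, 0.0, 1.0)
    h = (
        (2 * t**3 - 3 * t**2 + 1) * s_lin
        + (t**3 - 2 * t**2 + t) * span * m0
        + (-2 * t**3 + 3 * t**2) * sigma_c
    )
    rise = eps <= lin
    soften = eps > strain_at_peak
    sig = np.where(rise, E * eps, h)
    if np.any(soften):
        soft_span = max(failure_strain - strain_at_peak, 1e-9)
        sig = np.where(
            soften,
            sigma_c - 0.15 * sigma_c * (eps - strain_at_peak) / soft_span,
            sig,
        )
    if noise > 0:
        sig = sig * (1.0 + gen.normal(0.0, noise, sig.size))
    return StressStrainCurve(strain=eps, stress=sig, test_type=test_type)


def generate_pure_shear_pair(
    material: MaterialProperties,
    noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
    critical_stretch: float = 1.5,
    specimen_height: float = 10e-3,
    n_points: int = 200,
    Gc: float | None = None,
) -> PureShearTestPair:
    """Pure-shear pair whose zero-noise tearing energy equals the material Gc.

    The unnotched record is linear, with stiffness chosen so that the strain
    energy density integrated to the critical stretch times the specimen
    height reproduces Gc exactly (the trapezoid rule is exact on a line).
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    Gc = material.Gc if Gc is None else Gc
    eps_c = critical_stretch - 1.0
    W_target = Gc / specimen_height  # J m^-3
    k = 2.0 * W_target / eps_c**2  # linear stiffness, Pa per unit strain
    eps = np.linspace(0.0, 1.1 * eps_c, n_points)
    sig = k * eps
    if noise > 0:
        sig = sig * (1.0 + gen.normal(0.0, noise, sig.size))
    curve = StressStrainCurve(strain=eps, stress=sig, test_type=PURE_SHEAR_UNNOTCHED)
    return PureShearTestPair(
        unnotched=curve,
        critical_stretch=critical_stretch,
        specimen_height=specimen_height,
    )


def generate_material_batch(
    material: MaterialProperties,
    n: int = 8,
    noise: float = 0.01,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[StressStrainCurve], list[PureShearTestPair]]:
    """Replicate specimens whose true E, sigma_c, Gc scatter as the material's sd."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tensile: list[StressStrainCurve] = []
    pairs: list[PureShearTestPair] = []
    for _ in range(n):
        E_i = max(gen.normal(material.E, material.E_sd), 0.05 * material.E)
        s_i = max(gen.normal(material.sigma_c, material.sigma_c_sd), 0.05 * material.sigma_c)
        G_i = max(gen.normal(material.Gc, material.Gc_sd), 0.05 * material.Gc)
        tensile.append(
            generate_stress_strain(material, noise=noise, rng=gen, E=E_i, sigma_c=s_i)
        )
        pairs.append(generate_pure_shear_pair(material, noise=noise, rng=gen, Gc=G_i))
    return tensile, pairs


def write_study_dir(config: SyntheticStudyConfig, out_dir: str | Path) -> Path:
    """Simulate a full study and write it in the formats the pipeline reads.

    Produces per-trial trace CSVs (``<trial>_first.csv`` / ``_second.csv``),
    a ``metadata.csv`` join table, ``materials.json`` and a
    ``ground_truth.csv`` (the oracle, not consumed by the pipeline).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces_dir = out / "traces"
    traces_dir.mkdir(exist_ok=True)
    rng = config.rng()
    workers = generate_worker_population(config, rng)

    meta_rows = []
    truth_rows = []
    for material in config.materials:
        for t_nom in config.thicknesses_m:
            for worker in workers:
                t_actual = max(
                    rng.normal(t_nom, config.thickness_rel_sd * t_nom), 0.2 * t_nom
                )
                first, second, truth = generate_force_trace(
                    worker, material, t_actual, config, rng
                )
                safe = truth.trial_id.replace(":", "").replace(" ", "_")
                write_trace(first, traces_dir / f"{safe}_first.csv")
                write_trace(second, traces_dir / f"{safe}_second.csv")
                meta_rows.append(
                    {
                        "trial_id": truth.trial_id,
                        "sample_id": worker.sample_id,
                        "group": worker.group,
                        "mass_mg": worker.mass,
                        "material_name": material.name,
                        "substrate": f"{material.name}-{t_nom * 1e6:.0f}um",
                        "thickness_nominal_um": t_nom * 1e6,
                        "thickness_um": t_actual * 1e6,
                        "biological": False,
                        "edge_radius_nm": worker.blade.edge_radius * 1e9,
                        "wedge_angle_deg": worker.blade.wedge_angle,
                        "first_trace": f"traces/{safe}_first.csv",
                        "second_trace": f"traces/{safe}_second.csv",
                        "flags": "",
                    }
                )
                truth_rows.append(
                    {
                        "trial_id": truth.trial_id,
                        "Fc_mN": truth.Fc * 1e3,
                        "Fs_mN": truth.Fs * 1e3,
                        "Ff_mN": truth.Ff * 1e3,
                        "omega": truth.omega,
                    }
                )

    import pandas as pd

    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    mats = {
        m.name: {
            "name": m.name,
            "Gc_J_per_m2": m.Gc,
            "Gc_sd_J_per_m2": m.Gc_sd,
            "sigma_c_MPa": m.sigma_c / 1e6,
            "sigma_c_sd_MPa": m.sigma_c_sd / 1e6,
            "E_MPa": m.E / 1e6,
            "E_sd_MPa": m.E_sd / 1e6,
        }
        for m in config.materials
    }
    (out / "materials.json").write_text(json.dumps(mats, indent=2))
    return out
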