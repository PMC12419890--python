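"""Turn raw two-pass cutting force recordings into Fc, Fs and Ff.

Each cutting trial consists of two passes of the blade through the sheet at
constant stage speed: the first pass cuts intact material and its steady-state
plateau is the total cutting force Fc; the second pass re-runs the open cut and
its plateau is the spacing force Fs (sidewall friction plus elastic sheet
deformation).  The fracture force is Ff = Fc - Fs.

Steady-state extraction follows the protocol of averaging a fixed-length
(default 2 mm) displacement window after the cut-initiation peak.  The exact
settling rule after the peak is a package decision (the experimental
supplement leaves it open): the window starts at the first post-peak sample
whose 5-sample rolling median lies within ``settle_fraction`` (default 10%) of
the median force over the trailing 2 mm of travel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import (
    InsufficientSteadyStateError,
    InvalidInputError,
    TraceFormatError,
)

__all__ = [
    "ForceTrace",
    "SteadyStateWindow",
    "CutMeasurement",
    "TraceFormat",
    "read_trace",
    "write_trace",
    "detect_steady_state",
    "decompose_passes",
    "thickness_correct",
    "spacing_fraction",
    "NEGATIVE_FRACTURE_FORCE",
]

#: Flag set on a measurement whose spacing force exceeds the total force.
NEGATIVE_FRACTURE_FORCE = "negative_fracture_force"

DEFAULT_STAGE_SPEED = 0.3e-3  # m/s
DEFAULT_WINDOW_LENGTH = 2e-3  # m


@dataclass
class ForceTrace:
    """One pass of a cutting trial: force versus time at constant stage speed.

    Displacement is derived as ``time * stage_speed`` unless an explicit
    displacement array is supplied (which then takes precedence).
    """

    time: np.ndarray  # s, strictly increasing
    force: np.ndarray  # N
    stage_speed: float = DEFAULT_STAGE_SPEED  # m/s
    pass_id: str = "first"  # "first" | "second"
    trial_id: str = ""
    displacement: np.ndarray | None = None  # m, optional override

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.size < 2:
            raise InvalidInputError("a trace needs at least 2 samples")
        if self.time.shape != self.force.shape:
            raise InvalidInputError("time and force must have equal length")
        if not np.all(np.diff(self.time) > 0):
            bad = int(np.flatnonzero(np.diff(self.time) <= 0)[0]) + 1
            raise InvalidInputError(f"time must be strictly increasing (row {bad})")
        if self.stage_speed <= 0:
            raise InvalidInputError("stage_speed must be > 0")
        if self.pass_id not in ("first", "second"):
            raise InvalidInputError("pass_id must be 'first' or 'second'")
        if self.displacement is not None:
            self.displacement = np.asarray(self.displacement, dtype=float)
            if self.displacement.shape != self.time.shape:
                raise InvalidInputError("displacement length must match time")

    @property
    def disp(self) -> np.ndarray:
        """Blade travel (m)."""
        if self.displacement is not None:
            return self.displacement
        return self.time * self.stage_speed


@dataclass(frozen=True)
class SteadyStateWindow:
    """Displacement window over which the force plateau was averaged."""

    start_displacement: float  # m
    end_displacement: float  # m
    mean_force: float  # N
    force_sd: float  # N


@dataclass(frozen=True)
class CutMeasurement:
    """Derived forces of one trial: total (Fc), spacing (Fs), fracture (Ff)."""

    Fc: float  # N
    Fs: float  # N
    Ff: float  # N
    trial_id: str = ""
    thickness_corrected: bool = False
    sample_thickness: float | None = None  # m
    reference_thickness: float | None = None  # m
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if abs(self.Ff - (self.Fc - self.Fs)) > 1e-12 * max(1.0, abs(self.Fc)):
            raise InvalidInputError("Ff must equal Fc - Fs")


@dataclass(frozen=True)
class TraceFormat:
    """Dialect of a trace file.  Defaults match ``time_s,force_mN`` CSV."""

    delimiter: str = ","
    time_column: str | None = None  # auto-detected from unit-tagged header
    force_column: str | None = None
    displacement_column: str | None = None


_TIME_UNITS = {"s": 1.0, "ms": 1e-3}
_FORCE_UNITS = {"N": 1.0, "mN": 1e-3, "uN": 1e-6}
_DISP_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6}


def _split_unit(column: str) -> tuple[str, str]:
    stem, _, unit = column.rpartition("_")
    return stem, unit


def read_trace(
    path: str | Path,
    format_spec: TraceFormat | None = None,
    stage_speed: float = DEFAULT_STAGE_SPEED,
    pass_id: str = "first",
    trial_id: str = "",
) -> ForceTrace:
    """Read a delimited trace file into an SI-normalized :class:`ForceTrace`.

    Columns are recognized by unit-tagged headers: ``time_s``/``time_ms``,
    ``force_mN``/``force_N``/``force_uN`` and optionally
    ``displacement_mm``/``displacement_um``/``displacement_m``.  If a
    displacement column is present it takes precedence over ``time *
    stage_speed``; if only displacement is given, time is reconstructed from
    the (constant) stage speed.
    """
    fmt = format_spec or TraceFormat()
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=fmt.delimiter)
    except Exception as exc:
        raise TraceFormatError(f"{path}: cannot parse delimited text: {exc}") from exc

    time = force = disp = None
    for col in df.columns:
        name = str(col).strip()
        stem, unit = _split_unit(name)
        if (fmt.time_column and name == fmt.time_column) or (
            not fmt.time_column and stem == "time"
        ):
            if unit not in _TIME_UNITS:
                raise TraceFormatError(f"{path}: unknown time unit in column {name!r}")
            time = df[col].to_numpy(dtype=float) * _TIME_UNITS[unit]
        elif (fmt.force_column and name == fmt.force_column) or (
            not fmt.force_column and stem == "force"
        ):
            if unit not in _FORCE_UNITS:
                raise TraceFormatError(f"{path}: unknown force unit in column {name!r}")
            force = df[col].to_numpy(dtype=float) * _FORCE_UNITS[unit]
        elif (fmt.displacement_column and name == fmt.displacement_column) or (
            not fmt.displacement_column and stem == "displacement"
        ):
            if unit not in _DISP_UNITS:
                raise TraceFormatError(
                    f"{path}: unknown displacement unit in column {name!r}"
                )
            disp = df[col].to_numpy(dtype=float) * _DISP_UNITS[unit]

    if force is None:
        raise TraceFormatError(f"{path}: no force column found")
    if time is None and disp is None:
        raise TraceFormatError(f"{path}: no time or displacement column found")
    if time is None:
        time = disp / stage_speed
    if not np.all(np.diff(time) > 0):
        bad = int(np.flatnonzero(np.diff(time) <= 0)[0]) + 2  # 1-based + header
        raise TraceFormatError(f"{path}: time not strictly increasing at row {bad}")

    return ForceTrace(
        time=time,
        force=force,
        stage_speed=stage_speed,
        pass_id=pass_id,
        trial_id=trial_id or path.stem,
        displacement=disp,
    )


def write_trace(trace: ForceTrace, path: str | Path) -> None:
    """Write a trace as ``time_s,force_mN`` CSV at full float precision."""
    df = pd.DataFrame({"time_s": trace.time, "force_mN": trace.force * 1e3})
    df.to_csv(path, index=False, float_format="%.17g")


def detect_steady_state(
    trace: ForceTrace,
    window_length: float = DEFAULT_WINDOW_LENGTH,
    settle_fraction: float = 0.1,
    start_displacement: float | None = None,
    guard_length: float = 0.4e-3,
) -> SteadyStateWindow:
    """Locate the steady-state plateau and average the force across it.

    First-pass traces: the cut-initiation peak is the global force maximum;
    settling is reached at the first post-peak sample within
    ``settle_fraction`` of the trailing median (median force over the final
    ``window_length`` of travel), judged on a 5-sample rolling median to
    resist noise spikes; the averaging window then starts ``guard_length``
    of travel later, so that the exponentially decaying initiation transient
    (still at up to ``settle_fraction`` of the plateau when settling
    triggers) has died off before any sample is averaged.  Second-pass
    traces skip peak detection.  Passing ``start_displacement`` pins the
    window to a given travel position (used to align the second pass to the
    first-pass window; it bypasses settling and guard).

    Raises
    ------
    InsufficientSteadyStateError
        If less than ``window_length`` of travel remains after the window
        start (the trial-validity rule for short steady states).
    """
    disp = trace.disp
    force = trace.force
    n = force.size
    spacing = float(np.median(np.diff(disp)))

    if start_displacement is not None:
        start = int(np.searchsorted(disp, start_displacement - 0.5 * spacing))
    else:
        if trace.pass_id == "first":
            peak = int(np.argmax(force))
            search_from = min(peak + 1, n - 1)
        else:
            search_from = 0
        trailing = force[disp >= disp[-1] - window_length]
        ref = float(np.median(trailing))
        tol = settle_fraction * abs(ref) + 1e-12
        smooth = median_filter(force, size=5, mode="nearest")
        settled = np.abs(smooth - ref) <= tol
        candidates = np.flatnonzero(settled[search_from:])
        if candidates.size == 0:
            raise InsufficientSteadyStateError(
                f"trial {trace.trial_id!r} ({trace.pass_id} pass): "
                "force never settles after the initiation peak"
            )
        settled_idx = search_from + int(candidates[0])
        start = int(
            np.searchsorted(disp, disp[settled_idx] + guard_length - 0.5 * spacing)
        )
        start = min(start, n - 1)

    if disp[-1] - disp[start] < window_length - 0.5 * spacing:
        raise InsufficientSteadyStateError(
            f"trial {trace.trial_id!r} ({trace.pass_id} pass): only "
            f"{(disp[-1] - disp[start]) * 1e3:.2f} mm of steady-state travel, "
            f"need {window_length * 1e3:.2f} mm"
        )

    end = int(np.searchsorted(disp, disp[start] + window_length - 0.5 * spacing))
    end = min(end, n - 1)
    window = force[start : end + 1]
    return SteadyStateWindow(
        start_displacement=float(disp[start]),
        end_displacement=float(disp[end]),
        mean_force=float(np.mean(window)),
        force_sd=float(np.std(window, ddof=1)) if window.size > 1 else 0.0,
    )


def decompose_passes(
    first: SteadyStateWindow, second: SteadyStateWindow, trial_id: str = ""
) -> CutMeasurement:
    """Combine the two pass plateaus: Fc from pass 1, Fs from pass 2, Ff = Fc - Fs.

    A spacing force exceeding the total force yields a negative fracture
    force; this is retained (never clipped) and flagged for pipeline-level
    policy to handle.
    """
    Fc = first.mean_force
    Fs = second.mean_force
    flags: tuple[str, ...] = ()
    if Fs > Fc:
        flags = (NEGATIVE_FRACTURE_FORCE,)
    return CutMeasurement(Fc=Fc, Fs=Fs, Ff=Fc - Fs, trial_id=trial_id, flags=flags)


def thickness_correct(
    measurement: CutMeasurement,
    sample_thickness: float,
    reference_thickness: float,
    force: bool = False,
) -> CutMeasurement:
    """Rescale forces to a reference lamina thickness.

    Biological laminae vary in thickness between samples; forces are made
    comparable by scaling with ``reference_thickness / sample_thickness``.
    Applying the correction twice is an error unless ``force=True`` (which
    also permits inverting a correction by swapping the thickness arguments).
    """
    if sample_thickness <= 0 or reference_thickness <= 0:
        raise InvalidInputError("thicknesses must be > 0")
    if measurement.thickness_corrected and not force:
        raise InvalidInputError(
            f"measurement {measurement.trial_id!r} is already thickness-corrected"
        )
    k = reference_thickness / sample_thickness
    Fc = measurement.Fc * k
    Fs = measurement.Fs * k
    return replace(
        measurement,
        Fc=Fc,
        Fs=Fs,
        Ff=Fc - Fs,
        thickness_corrected=True,
        sample_thickness=sample_thickness,
        reference_thickness=reference_thickness,
    )


def spacing_fraction(measurement: CutMeasurement) -> float:
    """Fraction of the total cutting force due to spacing, Fs/Fc."""
    if measurement.Fc <= 0:
        raise InvalidInputError(f"Fc must be > 0, got {measurement.Fc}")
    return measurement.Fs / measurement.Fc
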