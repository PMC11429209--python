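"""Metrological feature extraction from compression curves and fatigue series.

A compression cycle of a monofilament against a force platform shows two
regimes: a linear force ramp while the filament is in pure axial
compression, then a buckling regime in which the force holds a plateau —
sometimes after an overshoot above it.  ``extract_features`` reduces one
sampled cycle to its critical force (peak), plateau force, overshoot index,
initial stiffness and the breakpoint displacement where the ramp ends.

Repeated cycling softens the filament: the first-cycle critical force is
highest and decays toward a plateau over a handful of cycles.
``analyze_fatigue`` summarises a per-cycle critical-force series.

``verify_monofilament`` turns either summary into a pass/fail verdict
against the nominal 10 gf rating, and ``display_round`` reproduces the
instrument's display resolution (0.1 gf below 100 gf, 1 gf above, hard
abort above the 500 gf load limit).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .exceptions import DomainError, NoBucklingWarning, OverloadError

__all__ = [
    "MIN_CURVE_SAMPLES",
    "ForceDisplacementCurve",
    "CurveFeatures",
    "FatigueSeries",
    "FatigueSummary",
    "VerificationReport",
    "extract_features",
    "analyze_fatigue",
    "verify_monofilament",
    "display_round",
]

#: Minimum samples a curve must have before feature extraction is meaningful.
MIN_CURVE_SAMPLES = 8


@dataclass(frozen=True)
class ForceDisplacementCurve:
    """One compression cycle: force (gf) sampled against displacement (mm).

    Displacement must be non-decreasing with positive span; forces are
    non-negative.  ``speed`` is the compression speed in mm/s, ``cycle_index``
    the 1-based cycle number within a fatigue sequence.
    """

    displacement: np.ndarray  # mm
    force: np.ndarray  # gf
    speed: Optional[float] = None  # mm/s
    device_id: str = ""
    cycle_index: int = 1

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement, dtype=float)
        force = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "displacement", disp)
        object.__setattr__(self, "force", force)
        if disp.ndim != 1 or force.shape != disp.shape:
            raise DomainError("displacement and force must be 1-D of equal length")
        if disp.size >= 2 and np.any(np.diff(disp) < 0):
            raise DomainError("displacement must be non-decreasing")
        if disp.size >= 2 and not disp[-1] > disp[0]:
            raise DomainError("displacement span must be positive")
        if np.any(force < 0):
            raise DomainError("forces must be >= 0")
        if self.cycle_index < 1:
            raise DomainError(f"cycle_index must be >= 1, got {self.cycle_index!r}")

    def __len__(self) -> int:
        return int(self.displacement.size)


@dataclass(frozen=True)
class CurveFeatures:
    """Scalar summary of one compression cycle.

    ``overshoot_index = (critical_force - plateau_force) / plateau_force``:
    0 for a curve that ramps straight onto its plateau, positive when the
    peak transiently exceeds it.  ``breakpoint_displacement`` is None when
    no buckling transition was detected.
    """

    critical_force: float  # gf
    plateau_force: float  # gf
    overshoot_index: float
    breakpoint_displacement: Optional[float]  # mm
    initial_stiffness: float  # gf/mm
    buckling_detected: bool = True

    def to_dict(self) -> dict:
        return {
            "critical_force_gf": self.critical_force,
            "plateau_force_gf": self.plateau_force,
            "overshoot_index": self.overshoot_index,
            "breakpoint_displacement_mm": self.breakpoint_displacement,
            "initial_stiffness_gf_mm": self.initial_stiffness,
            "buckling_detected": self.buckling_detected,
        }


@dataclass(frozen=True)
class FatigueSeries:
    """Critical forces (gf) for consecutive compression cycles 1..n."""

    critical_forces: np.ndarray  # gf
    speed: Optional[float] = None  # mm/s
    inter_cycle_interval: Optional[float] = None  # s

    def __post_init__(self) -> None:
        forces = np.asarray(self.critical_forces, dtype=float)
        object.__setattr__(self, "critical_forces", forces)
        if forces.ndim != 1 or forces.size < 2:
            raise DomainError("fatigue series needs >= 2 cycles")
        if np.any(forces <= 0):
            raise DomainError("critical forces must be > 0")

    def __len__(self) -> int:
        return int(self.critical_forces.size)


@dataclass(frozen=True)
class FatigueSummary:
    """First-cycle force, plateau statistics and total decay of a series."""

    first_cycle_force: float  # gf
    plateau_mean: float  # gf
    plateau_sd: float  # gf
    decay_percent: float
    monotone_decay: bool

    def to_dict(self) -> dict:
        return {
            "first_cycle_force_gf": self.first_cycle_force,
            "plateau_mean_gf": self.plateau_mean,
            "plateau_sd_gf": self.plateau_sd,
            "decay_percent": self.decay_percent,
            "monotone_decay": self.monotone_decay,
        }


def extract_features(
    curve: ForceDisplacementCurve,
    plateau_fraction: float = 0.2,
    slope_window: int = 5,
    slope_drop: float = 0.2,
) -> CurveFeatures:
    """Extract critical force, plateau, stiffness and breakpoint from a cycle.

    - critical force: global maximum of the cycle's force trace;
    - plateau force: mean force over the final ``plateau_fraction`` of the
      displacement span;
    - initial stiffness: least-squares slope over the first
      ``max(slope_window, 10% of samples)`` points;
    - breakpoint: first displacement where the centred-difference local
      slope falls below ``slope_drop`` times the initial stiffness.

    A curve whose slope never drops (pure ramp) carries no buckling
    transition: ``buckling_detected`` is False, the breakpoint is None and
    a :class:`NoBucklingWarning` is emitted.
    """
    n = len(curve)
    if n < MIN_CURVE_SAMPLES:
        raise DomainError(
            f"curve has {n} samples; need >= {MIN_CURVE_SAMPLES} for analysis"
        )
    if not (0.0 < plateau_fraction < 1.0):
        raise DomainError(f"plateau_fraction must be in (0, 1), got {plateau_fraction!r}")
    if slope_window < 2:
        raise DomainError(f"slope_window must be >= 2, got {slope_window!r}")
    if not (0.0 < slope_drop < 1.0):
        raise DomainError(f"slope_drop must be in (0, 1), got {slope_drop!r}")

    x = curve.displacement
    f = curve.force
    critical = float(np.max(f))

    span = x[-1] - x[0]
    plateau_mask = x >= x[-1] - plateau_fraction * span
    plateau = float(np.mean(f[plateau_mask]))

    n_fit = min(n, max(slope_window, math.ceil(0.1 * n)))
    stiffness = float(np.polyfit(x[:n_fit], f[:n_fit], 1)[0])

    breakpoint = None
    if stiffness > 0:
        local = np.gradient(f, x)  # centred differences, one-sided at ends
        below = np.flatnonzero(local < slope_drop * stiffness)
        # ignore a flat start before the ramp engages
        below = below[below >= n_fit - 1]
        if below.size:
            breakpoint = float(x[below[0]])
    if breakpoint is None:
        warnings.warn(
            "no buckling detected: local slope never fell below "
            f"{slope_drop:g} x initial stiffness",
            NoBucklingWarning,
            stacklevel=2,
        )
    if plateau <= 0:
        overshoot = float("inf") if critical > 0 else 0.0
    else:
        overshoot = (critical - plateau) / plateau
    return CurveFeatures(
        critical_force=critical,
        plateau_force=plateau,
        overshoot_index=overshoot,
        breakpoint_displacement=breakpoint,
        initial_stiffness=stiffness,
        buckling_detected=breakpoint is not None,
    )


def analyze_fatigue(
    series: FatigueSeries,
    plateau_from_cycle: int = 3,
    noise_tolerance: float = 0.03,
) -> FatigueSummary:
    """Summarise the cycle-to-cycle decay of a critical-force series.

    ``decay_percent = 100 * (F_1 - plateau_mean) / F_1`` where the plateau
    statistics are computed over cycles ``plateau_from_cycle..n``.
    ``monotone_decay`` is true when no cycle exceeds its predecessor by more
    than ``noise_tolerance`` gf (default 0.03 gf, the instrument precision
    in the 10 gf range).
    """
    forces = series.critical_forces
    n = forces.size
    if plateau_from_cycle < 1:
        raise DomainError(f"plateau_from_cycle must be >= 1, got {plateau_from_cycle!r}")
    if n < plateau_from_cycle + 1:
        raise DomainError(
            f"series of {n} cycles too short for plateau_from_cycle={plateau_from_cycle}"
        )
    first = float(forces[0])
    plateau = forces[plateau_from_cycle - 1 :]
    plateau_mean = float(np.mean(plateau))
    plateau_sd = float(np.std(plateau, ddof=1)) if plateau.size > 1 else 0.0
    decay = 100.0 * (first - plateau_mean) / first
    monotone = bool(np.all(np.diff(forces) <= noise_tolerance))
    return FatigueSummary(
        first_cycle_force=first,
        plateau_mean=plateau_mean,
        plateau_sd=plateau_sd,
        decay_percent=decay,
        monotone_decay=monotone,
    )


@dataclass(frozen=True)
class VerificationReport:
    """Pass/fail verdict of a measured force against the nominal rating."""

    nominal_force: float  # gf
    measured_force: float  # gf
    measured_from: str  # which summary statistic was compared
    deviation_percent: float
    tolerance_band: float  # +/- %
    verdict: str  # "pass" | "fail"

    def to_dict(self) -> dict:
        return {
            "nominal_force_gf": self.nominal_force,
            "measured_force_gf": self.measured_force,
            "measured_from": self.measured_from,
            "deviation_percent": self.deviation_percent,
            "tolerance_band_percent": self.tolerance_band,
            "verdict": self.verdict,
        }


def verify_monofilament(
    measured: Union[CurveFeatures, FatigueSummary, float],
    nominal_force: float = 10.0,
    tolerance_band: float = 10.0,
    use: str = "plateau",
) -> VerificationReport:
    """Compare a measured force against the nominal rating.

    ``measured`` may be a bare force in gf, a :class:`CurveFeatures`
    (``use="plateau"`` compares the plateau force, ``use="first_cycle"`` the
    peak) or a :class:`FatigueSummary` (plateau mean vs first-cycle force).
    The verdict is "pass" iff ``|deviation| <= tolerance_band`` (band edge
    inclusive).  The band is a convention of this tool, not a standard;
    every report carries it.
    """
    if not (nominal_force > 0):
        raise DomainError(f"nominal_force must be > 0, got {nominal_force!r}")
    if tolerance_band < 0:
        raise DomainError(f"tolerance_band must be >= 0, got {tolerance_band!r}")
    if use not in ("plateau", "first_cycle"):
        raise DomainError(f"use must be 'plateau' or 'first_cycle', got {use!r}")

    if isinstance(measured, CurveFeatures):
        if use == "plateau":
            value, source = measured.plateau_force, "curve plateau force"
        else:
            value, source = measured.critical_force, "curve critical force"
    elif isinstance(measured, FatigueSummary):
        if use == "plateau":
            value, source = measured.plateau_mean, "fatigue plateau mean"
        else:
            value, source = measured.first_cycle_force, "fatigue first-cycle force"
    else:
        value, source = float(measured), "measured force"

    deviation = 100.0 * (value - nominal_force) / nominal_force
    verdict = "pass" if abs(deviation) <= tolerance_band else "fail"
    return VerificationReport(
        nominal_force=nominal_force,
        measured_force=value,
        measured_from=source,
        deviation_percent=deviation,
        tolerance_band=tolerance_band,
        verdict=verdict,
    )


def display_round(force: float) -> float:
    """Round a force (gf) to the instrument's display resolution.

    Values below 100 gf display with one decimal, values from 100 to
    500 gf to the nearest unit; rounding is half-away-from-zero and the
    range classification applies after rounding (99.96 displays as 100).
    Above the 500 gf admissible load the instrument aborts, which surfaces
    here as :class:`OverloadError`.
    """
    if not math.isfinite(force) or force < 0:
        raise DomainError(f"force must be finite and >= 0, got {force!r}")
    if force > 500:
        raise OverloadError(
            f"{force:g} gf exceeds the 500 gf admissible load; operation aborted"
        )

    def _half_away(x: float, ndigits: int) -> float:
        factor = 10.0 ** ndigits
        return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor

    one_dp = _half_away(force, 1)
    if one_dp < 100.0:
        return one_dp
    return _half_away(force, 0)
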