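"""Synthetic bench-instrument data with known ground truth.

The generators here stand in for the physical calibration bench, emitting
the same three shapes its measurements take:

- one compression cycle's force-displacement curve: a linear ramp at the
  pre-buckling stiffness up to the critical force, then exponential
  relaxation onto the buckling plateau (a zero-overshoot spec ramps
  straight onto a flat plateau);
- a fatigue series: per-cycle critical forces decaying exponentially from
  a first-cycle maximum toward a plateau over 20 cycles;
- paired reference/candidate force readings with a known bias for
  agreement analysis.

Every generator is a pure function of its spec: the same spec (including
the seed) reproduces the output bit for bit.  Noise is additive Gaussian
clipped at zero; the default noise SD of 0.03 gf matches the instrument's
stated precision in the sub-100 gf range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .curves import FatigueSeries, ForceDisplacementCurve, display_round
from .exceptions import DomainError, GenerationError
from .agreement import PairedMeasurements

__all__ = [
    "DEFAULT_NOISE_SD",
    "CurveGenSpec",
    "FatigueGenSpec",
    "generate_curve",
    "generate_fatigue",
    "generate_pairs",
]

#: Default measurement noise SD (gf); the instrument precision below 100 gf.
DEFAULT_NOISE_SD = 0.03


@dataclass(frozen=True)
class CurveGenSpec:
    """Ground truth for one synthetic compression cycle.

    ``plateau_force`` is derived: critical_force / (1 + overshoot).  The
    10 mm span and 0.08 mm step are the bench's compression stroke and
    displacement resolution.  ``relaxation_fraction`` sets the exponential
    decay constant of the post-peak relaxation as a fraction of the span.
    """

    critical_force: float  # gf
    initial_stiffness: float  # gf/mm
    overshoot: float = 0.0
    displacement_span: float = 10.0  # mm
    sample_step: float = 0.08  # mm
    relaxation_fraction: float = 0.10
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    speed: float = 4.0  # mm/s
    device_id: str = "synthetic"
    cycle_index: int = 1
    apply_display_rounding: bool = False

    def __post_init__(self) -> None:
        if not (self.critical_force > 0):
            raise DomainError(f"critical_force must be > 0, got {self.critical_force!r}")
        if not (self.initial_stiffness > 0):
            raise DomainError(
                f"initial_stiffness must be > 0, got {self.initial_stiffness!r}"
            )
        if self.overshoot < 0:
            raise DomainError(f"overshoot must be >= 0, got {self.overshoot!r}")
        if not (self.sample_step > 0):
            raise DomainError(f"sample_step must be > 0, got {self.sample_step!r}")
        if self.displacement_span / self.sample_step < 8:
            raise DomainError("span/step must give at least 8 samples")
        if not (0 < self.relaxation_fraction <= 1):
            raise DomainError(
                f"relaxation_fraction must be in (0, 1], got {self.relaxation_fraction!r}"
            )
        if self.noise_sd < 0:
            raise DomainError(f"noise_sd must be >= 0, got {self.noise_sd!r}")

    @property
    def plateau_force(self) -> float:
        return self.critical_force / (1.0 + self.overshoot)


def generate_curve(spec: CurveGenSpec) -> ForceDisplacementCurve:
    """Synthesise one compression cycle from a :class:`CurveGenSpec`.

    Noiseless profile: force rises linearly at ``initial_stiffness`` until
    it reaches ``critical_force`` at the breakpoint x_c, then relaxes as

        F(x) = plateau + (critical - plateau) * exp(-(x - x_c) / lambda)

    with lambda = ``relaxation_fraction`` * span.  Gaussian noise of SD
    ``noise_sd`` is added pointwise, the result clipped at zero, and
    optionally passed through :func:`monofil.curves.display_round`.
    """
    x_peak = spec.critical_force / spec.initial_stiffness
    if x_peak > spec.displacement_span:
        raise GenerationError(
            f"peak unreachable: critical force {spec.critical_force:g} gf needs "
            f"{x_peak:.2f} mm of travel at stiffness {spec.initial_stiffness:g} gf/mm "
            f"but the span is {spec.displacement_span:g} mm"
        )
    x = np.arange(0.0, spec.displacement_span + spec.sample_step / 2, spec.sample_step)
    lam = spec.relaxation_fraction * spec.displacement_span
    plateau = spec.plateau_force
    ramp = spec.initial_stiffness * x
    # anchor the relaxation at the first grid point at/after the peak so the
    # sampled trace attains the critical force exactly
    x_crit = spec.sample_step * math.ceil(x_peak / spec.sample_step - 1e-9)
    relax = plateau + (spec.critical_force - plateau) * np.exp(
        -np.maximum(x - x_crit, 0.0) / lam
    )
    force = np.where(x < x_crit, np.minimum(ramp, spec.critical_force), relax)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        force = force + rng.normal(0.0, spec.noise_sd, size=force.shape)
    force = np.clip(force, 0.0, None)
    if spec.apply_display_rounding:
        force = np.array([display_round(f) for f in force])
    return ForceDisplacementCurve(
        displacement=x,
        force=force,
        speed=spec.speed,
        device_id=spec.device_id,
        cycle_index=spec.cycle_index,
    )


@dataclass(frozen=True)
class FatigueGenSpec:
    """Ground truth for a synthetic fatigue series.

    Per-cycle critical force F(n) = plateau + (first - plateau) *
    exp(-decay_rate * (n - 1)) + noise, n = 1..cycles.  20 cycles at 3 s
    intervals mirror the bench's stress-test protocol.
    """

    first_cycle_force: float  # gf
    plateau_force: float  # gf
    decay_rate: float = 1.5  # per cycle
    cycles: int = 20
    inter_cycle_interval: float = 3.0  # s
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    speed: float = 4.0  # mm/s

    def __post_init__(self) -> None:
        if not (self.plateau_force > 0):
            raise DomainError(f"plateau_force must be > 0, got {self.plateau_force!r}")
        if self.first_cycle_force < self.plateau_force:
            raise DomainError("first_cycle_force must be >= plateau_force")
        if not (self.decay_rate > 0):
            raise DomainError(f"decay_rate must be > 0, got {self.decay_rate!r}")
        if self.cycles < 2:
            raise DomainError(f"cycles must be >= 2, got {self.cycles!r}")
        if self.noise_sd < 0:
            raise DomainError(f"noise_sd must be >= 0, got {self.noise_sd!r}")


def generate_fatigue(spec: FatigueGenSpec) -> FatigueSeries:
    """Synthesise a per-cycle critical-force series from a :class:`FatigueGenSpec`."""
    n = np.arange(1, spec.cycles + 1, dtype=float)
    forces = spec.plateau_force + (
        spec.first_cycle_force - spec.plateau_force
    ) * np.exp(-spec.decay_rate * (n - 1.0))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        forces = forces + rng.normal(0.0, spec.noise_sd, size=forces.shape)
    forces = np.clip(forces, np.finfo(float).tiny, None)
    return FatigueSeries(
        critical_forces=forces,
        speed=spec.speed,
        inter_cycle_interval=spec.inter_cycle_interval,
    )


def generate_pairs(
    true_forces: Sequence[float],
    bias: float = 0.0,
    noise_ref: float = 0.0,
    noise_cand: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    jitter: bool = False,
) -> PairedMeasurements:
    """Paired reference/candidate readings of the same true forces.

    reference = true + N(0, noise_ref^2); candidate = true + bias +
    N(0, noise_cand^2).  With ``jitter=True`` each true force is first
    scaled by an independent uniform factor on [1, 1.25], emulating the
    validation protocol's random up-to-25% increase of each reference
    point.  Labels carry the original true forces.
    """
    if noise_ref < 0 or noise_cand < 0:
        raise DomainError("noise SDs must be >= 0")
    true = np.asarray(true_forces, dtype=float)
    if true.ndim != 1 or true.size < 2:
        raise DomainError("need at least 2 true forces")
    rng = np.random.default_rng(seed)
    applied = true.copy()
    if jitter:
        applied = applied * rng.uniform(1.0, 1.25, size=applied.shape)
    reference = applied + rng.normal(0.0, noise_ref, size=applied.shape)
    candidate = applied + bias + rng.normal(0.0, noise_cand, size=applied.shape)
    return PairedMeasurements(
        reference=reference, candidate=candidate, labels=true.copy()
    )
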