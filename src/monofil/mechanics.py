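"""Closed-form mechanics of a Semmes-Weinstein monofilament (SWM).

The monofilament is a slender nylon column of diameter ``d`` and length
``L``.  Pressed axially against the skin it buckles at the Euler critical
load

    F_c = pi^2 * E * I / L_e^2,    I = pi * d^4 / 64,    L_e = k * L,

where ``E`` is Young's modulus, ``I`` the second moment of area of the
circular cross-section and ``k`` the effective-length factor encoding the
end conditions (0.7 for clamped-pinned contact, 2.0 when the skin contact
slides).  Held horizontally, the filament is a cantilever deflecting under
its own distributed weight:

    delta = w * L^3 / (8 * E * I),    w = (pi d^2 / 4) * L * rho * g.

Young's modulus of nylon drifts with temperature and relative humidity,
modelled to first order as E = E0 * (1 - alpha*(T - T0)) and
E = E0 * (1 - beta*(H - H0)).

All quantities are stored in SI units (m, N, Pa, kg m^-3); constructors and
helpers accept the mm / gf / GPa units in which monofilaments are specified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from .exceptions import ConfigurationError, DomainError, EulerSlendernessWarning

#: Standard gravity used for all gf <-> N conversions (m s^-2). Not configurable.
STANDARD_GRAVITY = 9.80665

#: Default density of extruded Nylon 6.6 (kg m^-3).
NYLON66_DENSITY = 1140.0

#: Effective slenderness ratio below which the Euler-validity warning fires.
SLENDERNESS_LIMIT = 30.0

__all__ = [
    "STANDARD_GRAVITY",
    "NYLON66_DENSITY",
    "SLENDERNESS_LIMIT",
    "MonofilamentGeometry",
    "MaterialProperties",
    "BoundaryCondition",
    "Environment",
    "DeflectionResult",
    "CLAMPED_PINNED",
    "CLAMPED_PINNED_SLIDING",
    "second_moment_area",
    "effective_length",
    "critical_buckling_force",
    "estimate_young_modulus",
    "newton_to_gramforce",
    "gramforce_to_newton",
    "modulus_at_temperature",
    "modulus_at_humidity",
    "modulus_at_environment",
    "self_weight",
    "tip_deflection",
]


@dataclass(frozen=True)
class MonofilamentGeometry:
    """Filament geometry in SI units.

    Parameters
    ----------
    diameter : float
        Filament diameter in metres.
    length : float
        Filament length in metres.
    """

    diameter: float
    length: float

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise DomainError(f"diameter must be > 0, got {self.diameter!r}")
        if not (self.length > 0):
            raise DomainError(f"length must be > 0, got {self.length!r}")

    @classmethod
    def from_mm(cls, diameter_mm: float, length_mm: float) -> "MonofilamentGeometry":
        """Build a geometry from the millimetre values printed on devices."""
        return cls(diameter=diameter_mm * 1e-3, length=length_mm * 1e-3)

    @property
    def diameter_mm(self) -> float:
        return self.diameter * 1e3

    @property
    def length_mm(self) -> float:
        return self.length * 1e3

    @property
    def radius_of_gyration(self) -> float:
        """Radius of gyration of the circular section, d/4 (m)."""
        return self.diameter / 4.0

    def slenderness(self, bc: "BoundaryCondition") -> float:
        """Effective slenderness ratio L_e / (d/4) for the given end conditions."""
        return effective_length(self, bc) / self.radius_of_gyration


@dataclass(frozen=True)
class MaterialProperties:
    """Nylon material parameters.

    ``young_modulus_ref`` (Pa) and ``density`` (kg m^-3) are always required.
    The environmental coefficients are manufacturer-supplied and optional;
    each coefficient must come with its reference condition.

    Parameters
    ----------
    young_modulus_ref : float
        Reference Young's modulus E0 in Pa.
    density : float
        Material density rho in kg m^-3.
    temp_coefficient : float, optional
        alpha in 1/degC; rate of modulus loss per degree above ``ref_temperature``.
    humidity_coefficient : float, optional
        beta in 1/%RH; rate of modulus loss per %RH above ``ref_humidity``.
    ref_temperature, ref_humidity : float, optional
        Reference conditions T0 (degC) and H0 (%RH) for the coefficients.
    """

    young_modulus_ref: float
    density: float = NYLON66_DENSITY
    temp_coefficient: Optional[float] = None
    humidity_coefficient: Optional[float] = None
    ref_temperature: Optional[float] = None
    ref_humidity: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.young_modulus_ref > 0):
            raise DomainError(
                f"young_modulus_ref must be > 0, got {self.young_modulus_ref!r}"
            )
        if not (self.density > 0):
            raise DomainError(f"density must be > 0, got {self.density!r}")
        if self.temp_coefficient is not None and self.ref_temperature is None:
            raise ConfigurationError(
                "temp_coefficient given without ref_temperature"
            )
        if self.humidity_coefficient is not None and self.ref_humidity is None:
            raise ConfigurationError(
                "humidity_coefficient given without ref_humidity"
            )

    @classmethod
    def from_gpa(cls, young_modulus_gpa: float, **kwargs) -> "MaterialProperties":
        return cls(young_modulus_ref=young_modulus_gpa * 1e9, **kwargs)


_PRESET_K = {"clamped_pinned": 0.7, "clamped_pinned_sliding": 2.0}


@dataclass(frozen=True)
class BoundaryCondition:
    """End-support conditions of the buckling column via the k factor.

    Two named presets cover the clinical contact regimes: ``clamped_pinned``
    (k = 0.7; firm skin contact, no slip) and ``clamped_pinned_sliding``
    (k = 2.0; the contact point slides on oily/sweaty skin). ``custom``
    accepts any positive k.
    """

    name: str
    k_factor: float

    def __post_init__(self) -> None:
        if self.name in _PRESET_K:
            if self.k_factor != _PRESET_K[self.name]:
                raise DomainError(
                    f"preset {self.name!r} requires k={_PRESET_K[self.name]}, "
                    f"got {self.k_factor!r}"
                )
        elif self.name != "custom":
            raise DomainError(
                f"unknown boundary condition {self.name!r}; "
                "use clamped_pinned, clamped_pinned_sliding or custom"
            )
        if not (self.k_factor > 0):
            raise DomainError(f"k_factor must be > 0, got {self.k_factor!r}")

    @classmethod
    def clamped_pinned(cls) -> "BoundaryCondition":
        return cls("clamped_pinned", 0.7)

    @classmethod
    def clamped_pinned_sliding(cls) -> "BoundaryCondition":
        return cls("clamped_pinned_sliding", 2.0)

    @classmethod
    def custom(cls, k_factor: float) -> "BoundaryCondition":
        return cls("custom", k_factor)

    @classmethod
    def from_name(cls, name: str, k_factor: Optional[float] = None) -> "BoundaryCondition":
        if name in _PRESET_K:
            return cls(name, _PRESET_K[name])
        if name == "custom":
            if k_factor is None:
                raise ConfigurationError("custom boundary condition needs k_factor")
            return cls("custom", k_factor)
        raise DomainError(f"unknown boundary condition {name!r}")


CLAMPED_PINNED = BoundaryCondition.clamped_pinned()
CLAMPED_PINNED_SLIDING = BoundaryCondition.clamped_pinned_sliding()


@dataclass(frozen=True)
class Environment:
    """Ambient conditions: temperature in degC, relative humidity in %RH."""

    temperature: float
    humidity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.humidity <= 100.0):
            raise DomainError(f"humidity must be in [0, 100], got {self.humidity!r}")


def second_moment_area(geometry: MonofilamentGeometry) -> float:
    """Second moment of area of the circular section, I = pi d^4 / 64 (m^4)."""
    return math.pi * geometry.diameter ** 4 / 64.0


def effective_length(geometry: MonofilamentGeometry, bc: BoundaryCondition) -> float:
    """Effective column length L_e = k * L (m)."""
    return bc.k_factor * geometry.length


def critical_buckling_force(
    geometry: MonofilamentGeometry,
    young_modulus: float,
    bc: BoundaryCondition = CLAMPED_PINNED,
) -> float:
    """Euler critical buckling force F_c = pi^2 E I / L_e^2 (N).

    Emits :class:`EulerSlendernessWarning` (value still returned) when the
    effective slenderness L_e/(d/4) drops below :data:`SLENDERNESS_LIMIT`,
    where the slender-column assumption becomes questionable.
    """
    if not (young_modulus > 0):
        raise DomainError(f"young_modulus must be > 0, got {young_modulus!r}")
    slend = geometry.slenderness(bc)
    if slend < SLENDERNESS_LIMIT:
        warnings.warn(
            f"effective slenderness {slend:.1f} < {SLENDERNESS_LIMIT:g}; "
            "Euler buckling theory may not apply",
            EulerSlendernessWarning,
            stacklevel=2,
        )
    le = effective_length(geometry, bc)
    return math.pi ** 2 * young_modulus * second_moment_area(geometry) / le ** 2


def estimate_young_modulus(
    geometry: MonofilamentGeometry,
    critical_force: float,
    bc: BoundaryCondition = CLAMPED_PINNED,
) -> float:
    """Invert the Euler formula: E = F_c L_e^2 / (pi^2 I) (Pa).

    Given a measured critical force (N) and the geometry, recover the
    Young's modulus of the (unknown) filament material.  Exact algebraic
    inverse of :func:`critical_buckling_force`.
    """
    if not (critical_force > 0):
        raise DomainError(f"critical_force must be > 0, got {critical_force!r}")
    le = effective_length(geometry, bc)
    return critical_force * le ** 2 / (math.pi ** 2 * second_moment_area(geometry))


def newton_to_gramforce(force: float) -> float:
    """Convert newtons to gram-force (1 gf = g_0 * 1 g = 9.80665e-3 N)."""
    if not math.isfinite(force):
        raise DomainError(f"force must be finite, got {force!r}")
    return force / STANDARD_GRAVITY * 1e3


def gramforce_to_newton(force_gf: float) -> float:
    """Convert gram-force to newtons; inverse of :func:`newton_to_gramforce`."""
    if not math.isfinite(force_gf):
        raise DomainError(f"force must be finite, got {force_gf!r}")
    return force_gf * STANDARD_GRAVITY * 1e-3


def _linear_correction(e0: float, coeff: float, delta: float, what: str) -> float:
    e = e0 * (1.0 - coeff * delta)
    if not (e > 0):
        raise DomainError(
            f"{what} correction drives Young's modulus non-positive "
            f"(E0={e0:g}, coeff={coeff:g}, delta={delta:g}); outside model validity"
        )
    return e


def modulus_at_temperature(material: MaterialProperties, temperature: float) -> float:
    """E(T) = E0 * (1 - alpha * (T - T0)) (Pa); requires alpha and T0."""
    if material.temp_coefficient is None or material.ref_temperature is None:
        raise ConfigurationError(
            "temp_coefficient/ref_temperature not set on material"
        )
    return _linear_correction(
        material.young_modulus_ref,
        material.temp_coefficient,
        temperature - material.ref_temperature,
        "temperature",
    )


def modulus_at_humidity(material: MaterialProperties, humidity: float) -> float:
    """E(H) = E0 * (1 - beta * (H - H0)) (Pa); requires beta and H0."""
    if material.humidity_coefficient is None or material.ref_humidity is None:
        raise ConfigurationError(
            "humidity_coefficient/ref_humidity not set on material"
        )
    return _linear_correction(
        material.young_modulus_ref,
        material.humidity_coefficient,
        humidity - material.ref_humidity,
        "humidity",
    )


def modulus_at_environment(material: MaterialProperties, env: Environment) -> float:
    """Combined correction E0 * (1 - alpha dT) * (1 - beta dH) (Pa).

    The two first-order corrections compose multiplicatively, which is
    consistent with applying either alone and symmetric in the order of
    application.  Both coefficient pairs must be present.
    """
    e_t = modulus_at_temperature(material, env.temperature)
    factor_h = modulus_at_humidity(material, env.humidity) / material.young_modulus_ref
    return e_t * factor_h


def self_weight(geometry: MonofilamentGeometry, density: float) -> float:
    """Filament weight w = V rho g with V = (pi d^2/4) L (N)."""
    if density < 0:
        raise DomainError(f"density must be >= 0, got {density!r}")
    volume = math.pi * geometry.diameter ** 2 / 4.0 * geometry.length
    return volume * density * STANDARD_GRAVITY


@dataclass(frozen=True)
class DeflectionResult:
    """Self-weight tip deflection of the horizontal filament.

    Attributes
    ----------
    deflection : float
        Tip deflection delta in metres.
    percent_of_diameter : float
        100 * delta / d; how far the tip droops relative to the filament
        thickness (the quantity that drives pre-buckling curve shape).
    small_deflection_valid : bool
        True when delta < L/10, the validity bound of the linearised
        elastic-line solution.
    """

    deflection: float
    percent_of_diameter: float
    small_deflection_valid: bool

    @property
    def deflection_um(self) -> float:
        return self.deflection * 1e6


def tip_deflection(
    geometry: MonofilamentGeometry,
    young_modulus: float,
    density: float = NYLON66_DENSITY,
) -> DeflectionResult:
    """Cantilever tip deflection under self-weight, delta = w L^3 / (8 E I).

    This is the classical uniformly-distributed-load closed form
    q L^4 / (8 E I) with line load q = w / L.  Valid in the linear regime
    delta < L/10; the result carries a validity flag rather than raising.
    """
    if not (young_modulus > 0):
        raise DomainError(f"young_modulus must be > 0, got {young_modulus!r}")
    w = self_weight(geometry, density)
    delta = w * geometry.length ** 3 / (
        8.0 * young_modulus * second_moment_area(geometry)
    )
    return DeflectionResult(
        deflection=delta,
        percent_of_diameter=100.0 * delta / geometry.diameter,
        small_deflection_valid=delta < geometry.length / 10.0,
    )
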