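"""Parameter sweeps: critical-force grids and manufacturing-tolerance tables.

Because F_c = pi^2 E I / (kL)^2 with I proportional to d^4, and the
self-weight deflection delta = 2 rho g L^4 / (E d^2), small manufacturing
variations in d and L move both quantities by large factors.  The sweeps
here quantify that: a critical-force grid over (L, d) and a 3x3 table of
deflection changes under +/-10% geometry variations.  The relative
deflection change is purely geometric,

    delta(+dd, +dL) / delta(ref) = (1 + dL)^4 / (1 + dd)^2,

independent of material, which the tolerance table exploits as an internal
consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .mechanics import (
    CLAMPED_PINNED,
    CLAMPED_PINNED_SLIDING,
    STANDARD_GRAVITY,
    BoundaryCondition,
    MaterialProperties,
    MonofilamentGeometry,
    critical_buckling_force,
    estimate_young_modulus,
    gramforce_to_newton,
    newton_to_gramforce,
    second_moment_area,
    tip_deflection,
)

__all__ = [
    "ParameterGrid",
    "ToleranceTable",
    "BoundaryComparison",
    "critical_force_grid",
    "deflection_tolerance_table",
    "boundary_condition_comparison",
]


def _round_half_away(x: float, ndigits: int = 0) -> float:
    factor = 10.0 ** ndigits
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


@dataclass(frozen=True)
class ParameterGrid:
    """Critical force (gf) over a rectangular (length, diameter) grid.

    ``values_gf`` has shape ``(len(diameters), len(lengths))``: rows are
    indexed by diameter, columns by length.
    """

    lengths: np.ndarray  # m, ascending
    diameters: np.ndarray  # m, ascending
    young_modulus: float  # Pa
    k_factor: float
    values_gf: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        """Grid as a DataFrame labelled in mm (index: d, columns: L)."""
        return pd.DataFrame(
            self.values_gf,
            index=pd.Index(np.round(self.diameters * 1e3, 6), name="d_mm"),
            columns=pd.Index(np.round(self.lengths * 1e3, 6), name="L_mm"),
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def to_dict(self) -> dict:
        return {
            "lengths_mm": (self.lengths * 1e3).tolist(),
            "diameters_mm": (self.diameters * 1e3).tolist(),
            "young_modulus_gpa": self.young_modulus / 1e9,
            "k_factor": self.k_factor,
            "values_gf": self.values_gf.tolist(),
        }


def _parse_range(rng: Sequence[float], what: str) -> np.ndarray:
    try:
        lo, hi, steps = rng
    except (TypeError, ValueError) as exc:
        raise DomainError(f"{what} range must be (min, max, steps)") from exc
    steps = int(steps)
    if not (lo > 0 and hi > lo):
        raise DomainError(f"{what} range must satisfy 0 < min < max, got {rng!r}")
    if steps < 2:
        raise DomainError(f"{what} range needs steps >= 2, got {steps}")
    return np.linspace(lo, hi, steps)


def critical_force_grid(
    length_range: Sequence[float],
    diameter_range: Sequence[float],
    young_modulus: float,
    bc: BoundaryCondition = CLAMPED_PINNED,
) -> ParameterGrid:
    """Evaluate F_c (in gf) on a linear (L, d) grid.

    Parameters
    ----------
    length_range, diameter_range : (min_m, max_m, steps)
        Linearly sampled axis specifications in metres, steps >= 2.
    young_modulus : float
        Young's modulus in Pa, shared by every cell.
    bc : BoundaryCondition
        End conditions (k factor) shared by every cell.
    """
    if not (young_modulus > 0):
        raise DomainError(f"young_modulus must be > 0, got {young_modulus!r}")
    lengths = _parse_range(length_range, "length")
    diameters = _parse_range(diameter_range, "diameter")
    le = bc.k_factor * lengths[np.newaxis, :]
    i = np.pi * diameters[:, np.newaxis] ** 4 / 64.0
    fc_n = np.pi ** 2 * young_modulus * i / le ** 2
    return ParameterGrid(
        lengths=lengths,
        diameters=diameters,
        young_modulus=young_modulus,
        k_factor=bc.k_factor,
        values_gf=fc_n / (STANDARD_GRAVITY * 1e-3),
    )


@dataclass(frozen=True)
class ToleranceTable:
    """Self-weight deflection under signed fractional geometry variations.

    A 3x3 table over diameter variations (rows) and length variations
    (columns), each drawn from ``(-variation, 0, +variation)``.  Per cell:

    - ``deflection_um``: absolute tip deflection in micrometres;
    - ``percent_vs_reference``: 100 * (delta/delta_ref - 1), material-free;
    - ``percent_of_diameter``: 100 * delta / d for that cell's own diameter.
    """

    geometry: MonofilamentGeometry
    material: MaterialProperties
    variation: float
    variations: tuple  # signed fractions, (-v, 0, +v)
    deflection_um: np.ndarray  # (3, 3), rows d, cols L
    percent_vs_reference: np.ndarray
    percent_of_diameter: np.ndarray

    def to_dataframe(self, rounded: bool = True) -> pd.DataFrame:
        """Layout with one row per diameter variation and a three-column
        block (delta um, delta %, delta %d) per length variation.

        With ``rounded=True``, micrometres carry two decimals and percents
        are integers, the precision at which such tables are printed.
        """
        cols = {}
        for j, dl in enumerate(self.variations):
            tag = f"L({dl:+.0%})" if dl else "L(0%)"
            um = self.deflection_um[:, j]
            pref = self.percent_vs_reference[:, j]
            pdia = self.percent_of_diameter[:, j]
            if rounded:
                um = np.array([_round_half_away(v, 2) for v in um])
                pref = np.array([_round_half_away(v) for v in pref])
                pdia = np.array([_round_half_away(v, 1) for v in pdia])
            cols[f"{tag} delta_um"] = um
            cols[f"{tag} delta_pct"] = pref
            cols[f"{tag} delta_pct_d"] = pdia
        index = pd.Index(
            [f"d({dd:+.0%})" if dd else "d(0%)" for dd in self.variations],
            name="d variation",
        )
        return pd.DataFrame(cols, index=index)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def to_dict(self) -> dict:
        return {
            "reference": {
                "d_mm": self.geometry.diameter_mm,
                "L_mm": self.geometry.length_mm,
                "young_modulus_gpa": self.material.young_modulus_ref / 1e9,
                "density_kg_m3": self.material.density,
            },
            "variations": list(self.variations),
            "deflection_um": self.deflection_um.tolist(),
            "percent_vs_reference": self.percent_vs_reference.tolist(),
            "percent_of_diameter": self.percent_of_diameter.tolist(),
        }


def deflection_tolerance_table(
    geometry: MonofilamentGeometry,
    material: MaterialProperties,
    variation: float = 0.10,
) -> ToleranceTable:
    """Tabulate tip deflection under +/-``variation`` changes of d and L."""
    if not (0.0 < variation < 1.0):
        raise DomainError(f"variation must be in (0, 1), got {variation!r}")
    variations = (-variation, 0.0, +variation)
    e = material.young_modulus_ref
    rho = material.density
    ref = tip_deflection(geometry, e, rho).deflection

    um = np.empty((3, 3))
    pct_ref = np.empty((3, 3))
    pct_d = np.empty((3, 3))
    for i_d, dd in enumerate(variations):
        for j_l, dl in enumerate(variations):
            g = MonofilamentGeometry(
                diameter=geometry.diameter * (1.0 + dd),
                length=geometry.length * (1.0 + dl),
            )
            res = tip_deflection(g, e, rho)
            um[i_d, j_l] = res.deflection_um
            pct_ref[i_d, j_l] = 100.0 * (res.deflection / ref - 1.0)
            pct_d[i_d, j_l] = res.percent_of_diameter
    # centre cell is the reference by construction; pin it to exactly zero
    pct_ref[1, 1] = 0.0
    return ToleranceTable(
        geometry=geometry,
        material=material,
        variation=variation,
        variations=variations,
        deflection_um=um,
        percent_vs_reference=pct_ref,
        percent_of_diameter=pct_d,
    )


@dataclass(frozen=True)
class BoundaryComparison:
    """Per-device modulus estimates and both-regime critical forces."""

    table: pd.DataFrame
    mean_young_modulus: float  # Pa

    @property
    def mean_young_modulus_gpa(self) -> float:
        return self.mean_young_modulus / 1e9

    def to_dict(self) -> dict:
        return {
            "devices": self.table.to_dict(orient="records"),
            "mean_young_modulus_gpa": self.mean_young_modulus_gpa,
        }


def boundary_condition_comparison(
    devices: Sequence[tuple[MonofilamentGeometry, float]],
) -> BoundaryComparison:
    """From clamped-pinned critical-force measurements, estimate each
    device's Young's modulus and recompute its force for the sliding case.

    Parameters
    ----------
    devices : sequence of (geometry, critical_force_gf)
        Forces measured under clamped-pinned conditions (k = 0.7), in gf.

    Returns
    -------
    BoundaryComparison
        One row per device with d, L, I, E and F_c at k = 0.7 and k = 2.0,
        plus the mean modulus across devices.  F_c(k=2)/F_c(k=0.7) is
        (0.7/2)^2 = 0.1225 for every row.
    """
    if len(devices) == 0:
        raise DomainError("boundary_condition_comparison needs at least one device")
    rows = []
    for geom, fc_gf in devices:
        if not (fc_gf > 0):
            raise DomainError(f"critical force must be > 0 gf, got {fc_gf!r}")
        e = estimate_young_modulus(geom, gramforce_to_newton(fc_gf), CLAMPED_PINNED)
        fc_sliding = newton_to_gramforce(
            critical_buckling_force(geom, e, CLAMPED_PINNED_SLIDING)
        )
        rows.append(
            {
                "d_mm": geom.diameter_mm,
                "L_mm": geom.length_mm,
                "E_gpa": e / 1e9,
                "I_m4": second_moment_area(geom),
                "fc_clamped_pinned_gf": fc_gf,
                "fc_clamped_sliding_gf": fc_sliding,
            }
        )
    table = pd.DataFrame(rows)
    return BoundaryComparison(
        table=table, mean_young_modulus=float(table["E_gpa"].mean() * 1e9)
    )
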