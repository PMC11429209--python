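"""Instrument-agreement and repeatability statistics.

Validating a new force-measurement system against a calibrated reference
bench is a method-comparison problem: the same applied force is read by
both instruments and the question is how far, and how consistently, they
disagree.  The standard summary is the Bland-Altman analysis — mean of the
pairwise differences (bias) and limits of agreement at +/-1.96 sample
standard deviations, the interval expected to contain ~95% of differences —
supplemented here by per-reference-point mean +/- SD summaries and the mean
relative error across the measurement range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "bland_altman",
    "reference_point_summary",
    "mean_relative_error",
]

#: Normal quantile for the ~95% limits of agreement; fixed by convention.
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired readings (gf) of the same stimuli by two instruments.

    ``reference`` is the calibrated bench, ``candidate`` the instrument
    under validation.  ``labels`` optionally groups pairs by reference
    point (e.g. the nominal force of each measurement round).
    """

    reference: np.ndarray  # gf
    candidate: np.ndarray  # gf
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        cand = np.asarray(self.candidate, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "candidate", cand)
        if ref.ndim != 1 or cand.shape != ref.shape:
            raise DomainError("reference and candidate must be 1-D of equal length")
        if ref.size < 2:
            raise DomainError("need at least 2 pairs")
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != ref.shape:
                raise DomainError("labels must match the number of pairs")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.reference.size)


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary: bias and limits of agreement (all gf).

    Differences are taken as candidate - reference; a positive
    ``mean_difference`` means the candidate reads high.  ``points`` holds
    the plot-ready (pair mean, difference) table.
    """

    n: int
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    points: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "difference_direction": "candidate - reference",
            "mean_difference_gf": self.mean_difference,
            "sd_difference_gf": self.sd_difference,
            "loa_lower_gf": self.loa_lower,
            "loa_upper_gf": self.loa_upper,
            "loa_multiplier": LOA_MULTIPLIER,
        }


def bland_altman(pairs: PairedMeasurements) -> AgreementResult:
    """Bland-Altman agreement between two instruments.

    Bias is the mean of candidate - reference; the limits of agreement are
    bias +/- 1.96 sample standard deviations (n-1 denominator).
    """
    diff = pairs.candidate - pairs.reference
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    points = pd.DataFrame(
        {
            "mean_gf": (pairs.candidate + pairs.reference) / 2.0,
            "difference_gf": diff,
        }
    )
    return AgreementResult(
        n=len(pairs),
        mean_difference=mean_diff,
        sd_difference=sd_diff,
        loa_lower=mean_diff - LOA_MULTIPLIER * sd_diff,
        loa_upper=mean_diff + LOA_MULTIPLIER * sd_diff,
        points=points,
    )


def reference_point_summary(
    measurements: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Per-group mean and sample SD, in input order.

    ``measurements`` maps a group label (typically the reference force of a
    measurement round) to that round's readings.  Returns a DataFrame with
    columns group, n, mean, sd; SD uses the n-1 denominator and is 0 for
    singleton groups.
    """
    rows = []
    for group, values in measurements.items():
        vals = np.asarray(values, dtype=float)
        if vals.size == 0:
            raise DomainError(f"group {group!r} is empty")
        rows.append(
            {
                "group": group,
                "n": int(vals.size),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sd"])


def mean_relative_error(pairs: PairedMeasurements) -> float:
    """Mean of 100 * |candidate - reference| / reference over all pairs (%)."""
    if np.any(pairs.reference == 0):
        raise DomainError("mean relative error undefined for zero reference values")
    return float(
        np.mean(100.0 * np.abs(pairs.candidate - pairs.reference) / pairs.reference)
    )
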