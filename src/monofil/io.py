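"""CSV dialects and JSON reports shared by the analysis modules and the CLI.

Three plain-text formats are read and written:

- curve CSV: header ``displacement_mm,force_gf`` (a ``cycle`` column turns
  it into long format holding several cycles), with optional ``#``-prefixed
  metadata lines ``# device_id=...``, ``# speed_mm_s=...``, ``# cycle=...``;
- fatigue CSV: header ``cycle,critical_force_gf``;
- pairs CSV: header ``reference_gf,measured_gf[,group]``.

Writers prepend a ``#`` metadata header (tool version, parameters, seed)
so every artifact records how it was produced.
"""

from __future__ import annotations

import io as _stdio
import json
import sys
from contextlib import contextmanager
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .agreement import PairedMeasurements
from .curves import FatigueSeries, ForceDisplacementCurve
from .exceptions import CsvFormatError

PathLike = Union[str, Path]

__all__ = [
    "read_curves_csv",
    "write_curve_csv",
    "read_fatigue_csv",
    "write_fatigue_csv",
    "read_pairs_csv",
    "write_pairs_csv",
    "write_json_report",
    "metadata_header",
]


def metadata_header(params: Optional[Mapping] = None) -> str:
    """`#`-comment header recording the tool version and run parameters."""
    lines = [f"# monofil={__version__}"]
    for key, value in (params or {}).items():
        lines.append(f"# {key}={value}")
    return "\n".join(lines) + "\n"


@contextmanager
def _open_out(path: PathLike):
    """Open a path for writing; '-' means stdout (left open)."""
    if str(path) == "-":
        yield sys.stdout
    else:
        with open(path, "w") as fh:
            yield fh


def _read_csv_with_metadata(path: PathLike, what: str):
    """Read a CSV, splitting `# key=value` metadata lines from the table."""
    meta: dict[str, str] = {}
    body_lines = []
    try:
        if str(path) == "-":
            text = sys.stdin.read()
        else:
            text = Path(path).read_text()
    except OSError as exc:
        raise CsvFormatError(f"cannot read {what} CSV {path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if line.strip():
            body_lines.append((lineno, line))
    if not body_lines:
        raise CsvFormatError(f"{what} CSV {path} has no data rows")
    try:
        frame = pd.read_csv(_stdio.StringIO("\n".join(l for _, l in body_lines)))
    except Exception as exc:
        raise CsvFormatError(f"malformed {what} CSV {path}: {exc}") from exc
    # pandas drops malformed rows silently only with special options; check NaNs
    if frame.isna().any().any():
        bad = int(frame.isna().any(axis=1).idxmax())
        lineno = body_lines[bad + 1][0] if bad + 1 < len(body_lines) else "?"
        raise CsvFormatError(f"malformed {what} CSV {path}: bad value near line {lineno}")
    return frame, meta


def read_curves_csv(path: PathLike) -> list[ForceDisplacementCurve]:
    """Read one or more compression cycles from a curve CSV.

    A file without a ``cycle`` column yields a single curve (cycle index
    from ``# cycle=`` metadata, default 1); a long-format file with a
    ``cycle`` column yields one curve per cycle, ordered by cycle number.
    """
    frame, meta = _read_csv_with_metadata(path, "curve")
    required = {"displacement_mm", "force_gf"}
    if not required.issubset(frame.columns):
        raise CsvFormatError(
            f"curve CSV {path} must have columns displacement_mm,force_gf; "
            f"got {list(frame.columns)}"
        )
    speed = float(meta["speed_mm_s"]) if "speed_mm_s" in meta else None
    device_id = meta.get("device_id", "")

    def _build(sub: pd.DataFrame, cycle: int) -> ForceDisplacementCurve:
        return ForceDisplacementCurve(
            displacement=sub["displacement_mm"].to_numpy(float),
            force=sub["force_gf"].to_numpy(float),
            speed=speed,
            device_id=device_id,
            cycle_index=cycle,
        )

    if "cycle" in frame.columns:
        return [
            _build(sub, int(cycle))
            for cycle, sub in frame.groupby("cycle", sort=True)
        ]
    return [_build(frame, int(meta.get("cycle", 1)))]


def write_curve_csv(
    path: PathLike,
    curve: ForceDisplacementCurve,
    params: Optional[Mapping] = None,
) -> None:
    meta = {
        "device_id": curve.device_id,
        "cycle": curve.cycle_index,
        **({"speed_mm_s": curve.speed} if curve.speed is not None else {}),
        **(params or {}),
    }
    frame = pd.DataFrame(
        {"displacement_mm": curve.displacement, "force_gf": curve.force}
    )
    with _open_out(path) as fh:
        fh.write(metadata_header(meta))
        frame.to_csv(fh, index=False)


def read_fatigue_csv(path: PathLike) -> FatigueSeries:
    """Read a per-cycle critical-force series (``cycle,critical_force_gf``)."""
    frame, meta = _read_csv_with_metadata(path, "fatigue")
    required = {"cycle", "critical_force_gf"}
    if not required.issubset(frame.columns):
        raise CsvFormatError(
            f"fatigue CSV {path} must have columns cycle,critical_force_gf; "
            f"got {list(frame.columns)}"
        )
    frame = frame.sort_values("cycle")
    return FatigueSeries(
        critical_forces=frame["critical_force_gf"].to_numpy(float),
        speed=float(meta["speed_mm_s"]) if "speed_mm_s" in meta else None,
        inter_cycle_interval=(
            float(meta["inter_cycle_interval_s"])
            if "inter_cycle_interval_s" in meta
            else None
        ),
    )


def write_fatigue_csv(
    path: PathLike,
    series: FatigueSeries,
    params: Optional[Mapping] = None,
) -> None:
    meta = dict(params or {})
    if series.speed is not None:
        meta.setdefault("speed_mm_s", series.speed)
    if series.inter_cycle_interval is not None:
        meta.setdefault("inter_cycle_interval_s", series.inter_cycle_interval)
    frame = pd.DataFrame(
        {
            "cycle": np.arange(1, len(series) + 1),
            "critical_force_gf": series.critical_forces,
        }
    )
    with _open_out(path) as fh:
        fh.write(metadata_header(meta))
        frame.to_csv(fh, index=False)


def read_pairs_csv(path: PathLike) -> PairedMeasurements:
    """Read paired readings (``reference_gf,measured_gf[,group]``)."""
    frame, _ = _read_csv_with_metadata(path, "pairs")
    required = {"reference_gf", "measured_gf"}
    if not required.issubset(frame.columns):
        raise CsvFormatError(
            f"pairs CSV {path} must have columns reference_gf,measured_gf; "
            f"got {list(frame.columns)}"
        )
    labels = frame["group"].to_numpy() if "group" in frame.columns else None
    return PairedMeasurements(
        reference=frame["reference_gf"].to_numpy(float),
        candidate=frame["measured_gf"].to_numpy(float),
        labels=labels,
    )


def write_pairs_csv(
    path: PathLike,
    pairs: PairedMeasurements,
    params: Optional[Mapping] = None,
) -> None:
    data = {"reference_gf": pairs.reference, "measured_gf": pairs.candidate}
    if pairs.labels is not None:
        data["group"] = pairs.labels
    with _open_out(path) as fh:
        fh.write(metadata_header(params))
        pd.DataFrame(data).to_csv(fh, index=False)


def write_json_report(path: PathLike, payload: Mapping, params: Optional[Mapping] = None) -> None:
    """Write a JSON artifact with an embedded ``_meta`` provenance block."""
    doc = {"_meta": {"monofil": __version__, **(params or {})}, **payload}
    Path(path).write_text(json.dumps(doc, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
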