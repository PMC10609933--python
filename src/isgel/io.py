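"""Delimited-text I/O with embedded provenance.

All tabular outputs are comma-delimited with a mandatory header row;
times in days, release in % of dose.  Provenance (tool version, config
hash, seed) is embedded as ``# key: value`` comment lines above the
header so every file is self-describing yet still parses with any CSV
reader that skips comments.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import InvalidInputError
from .release_core import ReleaseSeries
from .sphere_transport import SphereSpec, SphereState

__all__ = [
    "config_hash",
    "write_release_series",
    "read_release_series",
    "write_key_value",
    "read_key_value",
    "write_sweep_table",
    "write_sphere_fields",
]


def config_hash(params: Mapping) -> str:
    """Short deterministic hash of a parameter mapping."""
    blob = json.dumps(
        {k: params[k] for k in sorted(params)}, sort_keys=True, default=str
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance_lines(metadata: Optional[Mapping]) -> list[str]:
    lines = [f"# tool: isgel {__version__}"]
    if metadata:
        lines.append(f"# config_hash: {config_hash(metadata)}")
        for k in sorted(metadata):
            lines.append(f"# {k}: {metadata[k]}")
    return lines


def write_release_series(
    path: str | Path,
    series: ReleaseSeries,
    metadata: Optional[Mapping] = None,
) -> None:
    """Write a release series as ``time_days,release_pct`` with provenance."""
    path = Path(path)
    lines = _provenance_lines(metadata)
    lines.append("time_days,release_pct")
    for t, v in zip(series.times, series.values):
        lines.append(f"{t:.10g},{v:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_release_series(path: str | Path) -> ReleaseSeries:
    """Read a ``time_days,release_pct`` file, skipping ``#`` comments."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise InvalidInputError(f"cannot parse {path}: {exc}") from exc
    for col in ("time_days", "release_pct"):
        if col not in df.columns:
            raise InvalidInputError(
                f"{path}: missing required column {col!r} "
                f"(found {list(df.columns)})"
            )
    return ReleaseSeries(
        times=df["time_days"].to_numpy(dtype=float),
        values=df["release_pct"].to_numpy(dtype=float),
        t0=0.0,
    )


def write_key_value(
    path: str | Path, record: Mapping, metadata: Optional[Mapping] = None
) -> None:
    """Write a flat ``key: value`` report (one pair per line)."""
    path = Path(path)
    lines = _provenance_lines(metadata)
    for k in record:
        lines.append(f"{k}: {record[k]}")
    path.write_text("\n".join(lines) + "\n")


def read_key_value(path: str | Path) -> dict[str, str]:
    """Read a flat ``key: value`` report, skipping ``#`` comments."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        out[key.strip()] = value.strip()
    return out


def write_sweep_table(
    path: str | Path,
    profiles: Sequence[tuple[float, float, ReleaseSeries]],
    metadata: Optional[Mapping] = None,
) -> None:
    """Write sweep output in long format.

    Columns: ``K32_per_day, C2_pct, time_days, release_pct``; one row per
    (parameter pair, time point).
    """
    path = Path(path)
    lines = _provenance_lines(metadata)
    lines.append("K32_per_day,C2_pct,time_days,release_pct")
    for k32, c2, series in profiles:
        for t, v in zip(series.times, series.values):
            lines.append(f"{k32:.10g},{c2:.10g},{t:.10g},{v:.10g}")
    path.write_text("\n".join(lines) + "\n")


def write_sphere_fields(
    path: str | Path,
    spec: SphereSpec,
    states: Sequence[SphereState],
    metadata: Optional[Mapping] = None,
) -> None:
    """Write radial fields in long format.

    Columns: ``time_days, phase, r_mm, concentration`` with phase one of
    ``core | matrix | bath`` (bath rows carry ``r_mm = r2``).
    """
    path = Path(path)
    lines = _provenance_lines(metadata)
    lines.append("time_days,phase,r_mm,concentration")
    rc = spec.core_centers
    rm = spec.matrix_centers
    for s in states:
        for r, c in zip(rc, s.C1_field):
            lines.append(f"{s.time:.10g},core,{r:.10g},{c:.10g}")
        for r, c in zip(rm, s.C2_field):
            lines.append(f"{s.time:.10g},matrix,{r:.10g},{c:.10g}")
        lines.append(f"{s.time:.10g},bath,{spec.r2:.10g},{s.C3:.10g}")
    path.write_text("\n".join(lines) + "\n")
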