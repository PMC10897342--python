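"""File formats: reflectivity ASCII tables, run configs, QCM-D traces.

Reflectivity files are plain text with 3-4 numeric columns
(Q, R, dR[, dQ]), whitespace or comma separated, ``#`` comment lines
and blank lines ignored.  The writer emits the same dialect.  Run
configuration is a single YAML document; QCM-D traces are delimited
text with a header naming the harmonic columns (``f3``, ``d3``, ...).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .reflectivity import ReflectivityCurve

__all__ = ["read_reflectivity", "write_reflectivity", "load_config",
           "read_qcmd_trace", "write_json_report"]


class FormatError(ValueError):
    """A data file violates the expected dialect."""


def read_reflectivity(path, dq_over_q: float = 0.0) -> ReflectivityCurve:
    """Parse a Q, R, dR[, dQ] text file into a curve.

    A 4th column is read as per-point dQ (absolute, same convention as
    the file's producer); otherwise ``dq_over_q`` from the config is
    attached.  Malformed rows and non-monotone Q raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                values = [float(p) for p in parts]
            except ValueError:
                raise FormatError(f"{path.name}:{lineno}: non-numeric row {line!r}")
            if len(values) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: expected >= 3 columns (Q, R, dR), "
                    f"got {len(values)}")
            if ncols is None:
                ncols = min(len(values), 4)
            rows.append(values[:ncols])
            if len(rows) >= 2 and rows[-1][0] <= rows[-2][0]:
                raise FormatError(
                    f"{path.name}:{lineno}: Q not strictly increasing")
    if not rows:
        raise FormatError(f"{path.name}: no data rows")
    data = np.array(rows)
    dq = data[:, 3] if data.shape[1] == 4 else None
    return ReflectivityCurve(q=data[:, 0], r=data[:, 1], dr=data[:, 2],
                             dq_over_q=dq_over_q, dq=dq)


def write_reflectivity(path, curve: ReflectivityCurve,
                       header: str | None = None) -> None:
    """Write a curve in the same ASCII dialect the reader accepts."""
    path = Path(path)
    dr = curve.dr if curve.dr is not None else np.zeros_like(curve.r)
    cols = [curve.q, curve.r, dr]
    names = ["Q(1/Angstrom)", "R", "dR"]
    if curve.dq is not None:
        cols.append(curve.dq)
        names.append("dQ")
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# " + "  ".join(names) + "\n")
        for row in zip(*cols):
            fh.write("  ".join(f"{v:.8e}" for v in row) + "\n")


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def read_qcmd_trace(path, delimiter=None):
    """Read a QCM-D trace from delimited text.

    The header row names the columns: ``time`` then ``f<n>`` and
    optionally ``d<n>`` per odd harmonic n (e.g. ``time f3 f5 d3 d5``).
    Returns a :class:`~pqinr.qcmd.QCMDTrace`.
    """
    import pandas as pd

    from .qcmd import QCMDTrace

    df = pd.read_csv(path, sep=delimiter or r"[,\s]+", engine="python",
                     comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    if "time" not in cols:
        raise FormatError(f"{path}: missing 'time' column")
    delta_f = {}
    delta_d = {}
    for low, orig in cols.items():
        if low.startswith("f") and low[1:].isdigit():
            delta_f[int(low[1:])] = df[orig].to_numpy(dtype=float)
        elif low.startswith("d") and low[1:].isdigit():
            delta_d[int(low[1:])] = df[orig].to_numpy(dtype=float)
    if not delta_f:
        raise FormatError(f"{path}: no frequency columns (f3, f5, ...)")
    return QCMDTrace(time=df[cols["time"]].to_numpy(dtype=float),
                     delta_f=delta_f, delta_d=delta_d or None)


def write_json_report(path, report: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
        fh.write("\n")
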