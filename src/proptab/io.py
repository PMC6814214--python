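"""Readers and writers for tables, reports, and scans.

2x2 CSV/TSV cell order is row-major: first row ``a,b``, second row ``c,d``.
JSON tables are objects with keys ``a, b, c, d``.  Reports serialize with
deterministic key order and floats at 12 significant digits; metadata
(package version, seed, conventions) is embedded in JSON reports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import DomainError
from .tables import CountTable2x2, make_table

__all__ = ["read_table", "read_table_any", "read_samples", "write_report", "round_floats"]

_CONVENTIONS = {
    "table_order": "row-major a,b/c,d",
    "delta": "halved difference (p_beta - p_alpha)/2",
    "csum_rows_orientation": "c-element minus a-element",
}


def _parse_matrix(path: Path, sep: str) -> np.ndarray:
    rows = []
    width = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        cells = [c.strip() for c in line.split(sep)]
        try:
            row = [float(c) for c in cells]
        except ValueError:
            if lineno == 1:  # tolerate a header line
                continue
            raise DomainError(f"{path}:{lineno}: non-numeric cell in {cells!r}")
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise DomainError(
                f"{path}:{lineno}: ragged row ({len(row)} cells, expected {width})"
            )
        rows.append(row)
    if not rows:
        raise DomainError(f"{path}: no numeric rows found")
    return np.array(rows)


def read_table_any(path: Union[str, Path], fmt: Optional[str] = None) -> np.ndarray:
    """Read an r x c numeric matrix from CSV/TSV/JSON."""
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".json": "json"}.get(
            path.suffix.lower(), "csv"
        )
    if fmt == "json":
        obj = json.loads(path.read_text())
        if isinstance(obj, dict):
            try:
                return np.array([[obj["a"], obj["b"]], [obj["c"], obj["d"]]], dtype=float)
            except KeyError as exc:
                raise DomainError(f"{path}: JSON table needs keys a,b,c,d") from exc
        return np.array(obj, dtype=float)
    sep = "\t" if fmt == "tsv" else ","
    return _parse_matrix(path, sep)


def read_table(path: Union[str, Path], fmt: Optional[str] = None) -> CountTable2x2:
    """Read and validate a 2x2 table."""
    m = read_table_any(path, fmt)
    if m.shape != (2, 2):
        raise DomainError(f"{path}: expected a 2x2 block, got shape {m.shape}")
    return make_table(m[0, 0], m[0, 1], m[1, 0], m[1, 1])


def read_samples(path: Union[str, Path], x_col: str = "x", y_col: str = "y"):
    """Read labeled (x, y) samples from a CSV/TSV with a header."""
    from .cart import LabeledSample

    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    if x_col not in df.columns or y_col not in df.columns:
        # headerless two-column fallback
        df = pd.read_csv(path, sep=sep, header=None, names=[x_col, y_col])
    return [LabeledSample(float(r), int(v)) for r, v in zip(df[x_col], df[y_col])]


def round_floats(obj, sig: int = 12):
    """Recursively round floats to ``sig`` significant digits."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    return obj


def write_report(
    result,
    path: Union[str, Path],
    fmt: str = "json",
    seed: Optional[int] = None,
) -> None:
    """Serialize a result (anything with ``to_dict``/``to_frame``, or a plain
    dict/DataFrame) to JSON or CSV."""
    from . import __version__

    path = Path(path)
    if fmt == "csv":
        if hasattr(result, "to_frame"):
            df = result.to_frame()
        elif isinstance(result, pd.DataFrame):
            df = result
        else:
            raise DomainError(f"cannot write {type(result).__name__} as CSV")
        df.to_csv(path, index=False, float_format="%.12g")
        return
    if fmt != "json":
        raise ValueError(f"format must be 'json' or 'csv', got {fmt!r}")
    payload = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    doc = {
        "metadata": {
            "version": __version__,
            "seed": seed,
            "conventions": _CONVENTIONS,
        },
        "result": round_floats(payload),
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
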