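"""CSV and JSON I/O with reproducibility headers.

Every tabular artifact the pipeline emits is an RFC-4180 CSV preceded by
comment lines of the form ``# key: value`` carrying the generator name,
package version, seed and parameters, so any output can be traced back to
the exact invocation that produced it. Values are JSON-encoded so the
header round-trips without loss.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__

_HEADER_PREFIX = "# "


def write_table(df: pd.DataFrame, path: str | Path, meta: dict[str, Any] | None = None) -> None:
    """Write ``df`` as CSV with a commented metadata header.

    ``meta`` values must be JSON-serializable. The package version is always
    recorded under ``sterolfilm_version``.
    """
    path = Path(path)
    meta = dict(meta or {})
    meta.setdefault("sterolfilm_version", __version__)
    with open(path, "w", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"{_HEADER_PREFIX}{key}: {json.dumps(value)}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Read a CSV written by :func:`write_table`; returns (frame, metadata)."""
    path = Path(path)
    meta: dict[str, Any] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line.lstrip("#").strip()
            if ": " in body:
                key, _, raw = body.partition(": ")
                try:
                    meta[key] = json.loads(raw)
                except json.JSONDecodeError:
                    meta[key] = raw
    df = pd.read_csv(path, skiprows=n_header)
    return df, meta


def write_report(obj: dict[str, Any], path: str | Path) -> None:
    """Write a JSON report (fit results, index summaries, ...)."""
    obj = dict(obj)
    obj.setdefault("sterolfilm_version", __version__)
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def _jsonify(value):
    try:
        import numpy as np

        if isinstance(value, np.generic):
            return value.item()
        if isinstance(value, np.ndarray):
            return value.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(value)!r}")
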