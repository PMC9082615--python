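"""Plain-text I/O for profiles, RDFs and isotherm tables.

Density profiles and radial distribution functions travel as two-column
whitespace-delimited text (``z[nm]  density[nm^-3]`` or ``r[nm]  g(r)``), with
``#`` comment headers.  Lines starting with ``@`` (xmgrace/XVG metadata, as
written by common MD post-processing tools) are tolerated and skipped on read.
Isotherm series travel as CSV with columns ``c0_mol_l, gamma_nm2, sd_c0, sd_gamma``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

ISOTHERM_COLUMNS = ["c0_mol_l", "gamma_nm2", "sd_c0", "sd_gamma"]


def read_xy(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a two-column text file, skipping ``#`` and ``@`` lines.

    Returns (x, y, metadata) where metadata holds any ``# key: value`` header lines.
    """
    xs, ys, meta = [], [], {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("@"):
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: expected two columns, got line {line!r}")
        xs.append(float(parts[0]))
        ys.append(float(parts[1]))
    if not xs:
        raise ValueError(f"{path}: no data rows found")
    return np.asarray(xs), np.asarray(ys), meta


def write_xy(path, x, y, metadata: dict | None = None) -> None:
    """Write a two-column text file with ``# key: value`` headers."""
    lines = []
    for key, val in (metadata or {}).items():
        lines.append(f"# {key}: {val}")
    for xi, yi in zip(np.asarray(x), np.asarray(y)):
        lines.append(f"{xi:.10g} {yi:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_isotherm_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ISOTHERM_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing isotherm columns {missing}")
    for col in ISOTHERM_COLUMNS[2:]:
        if col not in df.columns:
            df[col] = 0.0
    return df[ISOTHERM_COLUMNS]


def write_isotherm_csv(path, df: pd.DataFrame) -> None:
    df[ISOTHERM_COLUMNS].to_csv(path, index=False)


def write_sidecar(path, payload: dict) -> None:
    """Write a JSON metadata sidecar next to an artifact (``<path>.meta.json``)."""
    side = Path(str(path) + ".meta.json")
    side.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
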