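"""STAR-style metadata tables: one named data block with a loop of columns.

The dialect written here is the single-block subset used by particle
alignment files: ``data_<name>``, ``loop_``, one ``_column #i`` line per
field, then whitespace-separated rows.  Round trips are lossless (floats
written with 17 significant digits); extra user columns pass through
untouched.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd


def write_star(df: pd.DataFrame, path, block: str = "particles") -> None:
    lines = [f"data_{block}", "", "loop_"]
    for i, col in enumerate(df.columns, start=1):
        lines.append(f"_{col} #{i}")

    def fmt(v):
        if isinstance(v, (float, np.floating)):
            return "nan" if np.isnan(v) else f"{v:.17g}"
        return str(v)

    for _, row in df.iterrows():
        lines.append(" ".join(fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_star(path) -> pd.DataFrame:
    text = Path(path).read_text()
    columns, rows = [], []
    in_loop = False
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith("data_"):
            if columns:          # only the first data block is read
                break
            continue
        if s == "loop_":
            in_loop = True
            continue
        if in_loop and s.startswith("_"):
            columns.append(s.split()[0].lstrip("_"))
            continue
        if in_loop and columns:
            rows.append(s)
    if not columns:
        raise ValueError(f"{path}: no loop_ data block found")
    buf = io.StringIO("\n".join(rows))
    df = pd.read_csv(buf, sep=r"\s+", names=columns, header=None)
    return df


def require_columns(df: pd.DataFrame, columns, context: str = "") -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        where = f" for {context}" if context else ""
        raise ValueError(f"missing required metadata column(s){where}: {missing}")
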