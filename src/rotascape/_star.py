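"""Minimal reader/writer for the RELION dialect of the STAR format.

Covers what particle metadata needs: named ``data_`` blocks containing
either a ``loop_`` table (returned as a :class:`pandas.DataFrame`) or bare
``_tag value`` pairs (returned as a :class:`pandas.Series`).  Both the
legacy single-block layout and the RELION >= 3.1 ``data_optics`` +
``data_particles`` layout round-trip; unknown blocks and columns pass
through untouched.
"""

from __future__ import annotations

from collections import OrderedDict
from pathlib import Path

import pandas as pd


def _coerce(series: pd.Series) -> pd.Series:
    """Numeric conversion where the whole column parses; strings otherwise."""
    out = pd.to_numeric(series, errors="coerce")
    if out.notna().all():
        # preserve integer columns (class numbers, optics groups)
        if (out % 1 == 0).all() and not series.str.contains(r"[.eE]").any():
            return out.astype(int)
        return out
    return series


def read_star(path: str | Path) -> "OrderedDict[str, pd.DataFrame | pd.Series]":
    """Parse a STAR file into an ordered mapping of block name -> table.

    Loop blocks become DataFrames (empty loops give empty DataFrames with
    the declared columns); key-value blocks become Series.
    """
    path = Path(path)
    blocks: OrderedDict[str, pd.DataFrame | pd.Series] = OrderedDict()
    name = None
    columns: list[str] = []
    rows: list[list[str]] = []
    pairs: "OrderedDict[str, str]" = OrderedDict()
    in_loop = False

    def flush() -> None:
        nonlocal columns, rows, pairs, in_loop
        if name is None:
            return
        if columns:
            df = pd.DataFrame(rows, columns=columns)
            blocks[name] = df.apply(_coerce) if len(df) else df
        elif pairs:
            blocks[name] = pd.Series(pairs).map(lambda v: _coerce(pd.Series([v]))[0])
        columns, rows, pairs, in_loop = [], [], OrderedDict(), False

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                flush()
                name = line[len("data_"):] or "root"
                continue
            if line == "loop_":
                in_loop = True
                continue
            if line.startswith("_"):
                tokens = line.split(None, 1)
                tag = tokens[0].lstrip("_")
                if in_loop:
                    columns.append(tag)
                else:
                    pairs[tag] = tokens[1].split("#")[0].strip() if len(tokens) > 1 else ""
                continue
            if in_loop and columns:
                values = line.split()
                if len(values) != len(columns):
                    raise ValueError(
                        f"{path}: row with {len(values)} fields under "
                        f"{len(columns)} declared columns in data_{name}"
                    )
                rows.append(values)
    flush()
    return blocks


def _format_cell(value) -> str:
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)


def write_star(blocks: "dict[str, pd.DataFrame | pd.Series]", path: str | Path) -> None:
    """Write blocks back out; floats use 6 decimals (RELION's precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# Written by rotascape\n")
        for name, table in blocks.items():
            fh.write(f"\ndata_{name}\n\n")
            if isinstance(table, pd.Series):
                width = max((len(k) for k in table.index), default=0) + 1
                for key, value in table.items():
                    fh.write(f"_{key:<{width}} {_format_cell(value)}\n")
                continue
            fh.write("loop_\n")
            for i, col in enumerate(table.columns, start=1):
                fh.write(f"_{col} #{i}\n")
            for row in table.itertuples(index=False):
                fh.write(" ".join(_format_cell(v) for v in row) + "\n")
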