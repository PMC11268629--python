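"""Minimal STAR (Self-defining Text Archive and Retrieval) table parser.

Handles the subset used by Relion and CrYOLO: ``data_`` blocks containing
either ``loop_`` tables (``_name`` headers followed by whitespace-separated
rows) or simple ``_name value`` pairs.  Values are converted to numeric
columns where possible.  Quoting and multi-line values are not needed by
these dialects and are not supported.
"""

from __future__ import annotations

import pandas as pd

from tomogeom.io_formats.errors import FormatError

__all__ = ["parse_star", "write_star_blocks"]


def parse_star(path) -> dict[str, pd.DataFrame]:
    """Parse a STAR file into ``{block name: DataFrame}``.

    Loop tables become multi-row frames; key-value blocks become one-row
    frames.  Block names keep their ``data_`` suffix stripped.
    """
    blocks: dict[str, pd.DataFrame] = {}
    name = None
    headers: list[str] = []
    rows: list[list[str]] = []
    pairs: dict[str, str] = {}
    in_loop = False

    def flush():
        nonlocal headers, rows, pairs, in_loop
        if name is not None and (headers or pairs):
            if headers:
                if rows and any(len(r) != len(headers) for r in rows):
                    bad = next(i for i, r in enumerate(rows) if len(r) != len(headers))
                    raise FormatError(
                        f"row {bad} of block data_{name} has {len(rows[bad])} fields, "
                        f"expected {len(headers)}"
                    )
                df = pd.DataFrame(rows, columns=headers)
            else:
                df = pd.DataFrame([pairs])
            for col in df.columns:
                converted = pd.to_numeric(df[col], errors="coerce")
                if not converted.isna().any():
                    df[col] = converted
            blocks[name] = df
        headers, rows, pairs, in_loop = [], [], {}, False

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                flush()
                name = line[len("data_") :]
            elif line == "loop_":
                in_loop = True
            elif line.startswith("_"):
                token = line.split()
                key = token[0].lstrip("_")
                if in_loop:
                    headers.append(key)
                else:
                    if len(token) < 2:
                        raise FormatError(f"key {token[0]} has no value")
                    pairs[key] = token[1]
            else:
                rows.append(line.split())
    flush()
    return blocks


def write_star_blocks(blocks: dict[str, pd.DataFrame], path, float_format: str = "%.6f"):
    """Write ``{block name: DataFrame}`` as loop_ tables."""
    with open(path, "w") as fh:
        for name, df in blocks.items():
            fh.write(f"\ndata_{name}\n\nloop_\n")
            for i, col in enumerate(df.columns, start=1):
                fh.write(f"_{col} #{i}\n")
            for _, row in df.iterrows():
                fields = []
                for value in row:
                    if isinstance(value, float):
                        fields.append(float_format % value)
                    else:
                        fields.append(str(value))
                fh.write(" ".join(fields) + "\n")
            fh.write("\n")
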