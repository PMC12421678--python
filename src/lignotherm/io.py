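"""Tabular IO with commented key=value headers, plus XVG interoperability.

Analysis inputs and synthetic outputs travel as plain CSV files whose leading
lines of the form ``# key = value`` carry metadata (units, generator ground
truth, box dimensions).  Two-column XVG tables (``@``/``#`` comment lines, as
produced by common MD post-processing tools) are read and written for
interoperability.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_table", "read_table", "write_xvg", "read_xvg"]


def _format_value(value):
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_value(text: str):
    text = text.strip()
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            pass
    return text


def write_table(path, frame: pd.DataFrame, header: dict | None = None) -> None:
    """Write ``frame`` as CSV preceded by ``# key = value`` header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key} = {_format_value(value)}\n")
        frame.to_csv(fh, index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_table`; returns (frame, metadata)."""
    path = Path(path)
    meta: dict = {}
    body_lines = []
    with path.open() as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                content = stripped.lstrip("#").strip()
                if "=" in content:
                    key, _, value = content.partition("=")
                    meta[key.strip()] = _parse_value(value)
                continue
            body_lines.append(line)
    frame = pd.read_csv(_io.StringIO("".join(body_lines)))
    return frame, meta


def write_xvg(path, x, y, title: str = "", xaxis: str = "", yaxis: str = "",
              comments: dict | None = None) -> None:
    """Write a two-column XVG table (``@`` directives, ``#`` comments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (comments or {}).items():
            fh.write(f"# {key} = {_format_value(value)}\n")
        if title:
            fh.write(f'@    title "{title}"\n')
        if xaxis:
            fh.write(f'@    xaxis  label "{xaxis}"\n')
        if yaxis:
            fh.write(f'@    yaxis  label "{yaxis}"\n')
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.10g} {yi:.10g}\n")


def read_xvg(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a two-column XVG table; returns (x, y, metadata)."""
    xs, ys = [], []
    meta: dict = {}
    with Path(path).open() as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("@"):
                continue
            if stripped.startswith("#"):
                content = stripped.lstrip("#").strip()
                if "=" in content:
                    key, _, value = content.partition("=")
                    meta[key.strip()] = _parse_value(value)
                continue
            parts = stripped.split()
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
    return np.asarray(xs), np.asarray(ys), meta
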