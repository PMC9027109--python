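"""Reading and writing signals as plain text or CSV.

Plain-text format is one value per line (blank lines tolerated); CSV
files are read with pandas and a column selected by name or 0-based
position.  Long records can be truncated — entropy protocols commonly
cap series at 10^6 samples.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import Signal

__all__ = ["read_signal", "write_signal"]


def read_signal(path, column=None, max_length: int | None = None) -> Signal:
    """Read a signal from a plain-text or CSV file.

    Parameters
    ----------
    path : file path.  Files with suffix ``.csv`` (or any file when
        ``column`` is given) are parsed as CSV; otherwise one value
        per line.
    column : CSV column to use — a name (str) or 0-based position
        (int).
    max_length : optional truncation; only the first ``max_length``
        values are kept.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError``
    (with the line number, for plain text) for unparsable content or
    an empty file.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"signal file not found: {p}")
    if max_length is not None and max_length < 1:
        raise ValueError(f"max_length must be positive, got {max_length}")
    if column is not None or p.suffix.lower() == ".csv":
        values = _read_csv(p, column)
    else:
        values = _read_plain(p, max_length)
    if max_length is not None:
        values = values[:max_length]
    if values.size == 0:
        raise ValueError(f"{p}: no values found")
    return Signal(values)


def _read_csv(p: Path, column) -> np.ndarray:
    df = pd.read_csv(p)
    if df.shape[1] == 0:
        raise ValueError(f"{p}: no columns in CSV")
    if column is None:
        column = 0
    if isinstance(column, int):
        if not 0 <= column < df.shape[1]:
            raise ValueError(
                f"{p}: column index {column} out of range (file has {df.shape[1]} columns)"
            )
        series = df.iloc[:, column]
    else:
        if column not in df.columns:
            raise ValueError(
                f"{p}: no column named {column!r}; available: {list(df.columns)}"
            )
        series = df[column]
    values = pd.to_numeric(series, errors="coerce").to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        bad = int(np.flatnonzero(np.isnan(values))[0])
        raise ValueError(f"{p}: non-numeric value in column {column!r} at row {bad}")
    return values


def _read_plain(p: Path, max_length: int | None) -> np.ndarray:
    values: list[float] = []
    with open(p, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                values.append(float(token))
            except ValueError:
                raise ValueError(
                    f"{p}: line {lineno}: not a number: {token!r}"
                ) from None
            if max_length is not None and len(values) >= max_length:
                break
    return np.asarray(values, dtype=np.float64)


def write_signal(path, signal, fmt: str = "%.17g") -> None:
    """Write a signal as plain text, one value per line."""
    sig = signal if isinstance(signal, Signal) else Signal(np.asarray(signal, float))
    np.savetxt(path, sig.values, fmt=fmt)
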