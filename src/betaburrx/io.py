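"""Reading and writing univariate samples (one-column CSV or whitespace text)."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .inference import SampleVector

__all__ = ["read_sample", "write_sample"]


class SampleParseError(ValueError):
    """Raised with the offending line number and content on bad input."""


def _parse_tokens(lines: list[tuple[int, list[str]]]) -> SampleVector:
    values = []
    for lineno, tokens in lines:
        for tok in tokens:
            try:
                v = float(tok)
            except ValueError as exc:
                raise SampleParseError(f"line {lineno}: non-numeric value {tok!r}") from exc
            if not np.isfinite(v) or v <= 0:
                raise SampleParseError(f"line {lineno}: value {tok!r} is not a positive finite real")
            values.append(v)
    if not values:
        raise SampleParseError("no numeric values found in input")
    return SampleVector(np.array(values))


def read_sample(path, format: str = "auto") -> SampleVector:
    """Read a positive-real sample from ``path``.

    ``format``: 'csv' (one column, optional header), 'whitespace'
    (any whitespace-delimited layout), or 'auto' (csv for .csv paths,
    whitespace otherwise).  Raises :class:`SampleParseError` naming the
    offending line for non-numeric or non-positive entries.
    """
    path = Path(path)
    if format == "auto":
        format = "csv" if path.suffix.lower() == ".csv" else "whitespace"
    if format not in {"csv", "whitespace"}:
        raise ValueError(f"unknown format {format!r}")
    text = path.read_text()
    lines: list[tuple[int, list[str]]] = []
    if format == "csv":
        rows = list(csv.reader(text.splitlines()))
        start = 0
        if rows:
            # optional single header row
            try:
                float(rows[0][0])
            except (ValueError, IndexError):
                start = 1
        for idx, row in enumerate(rows[start:], start=start + 1):
            tokens = [cell.strip() for cell in row if cell.strip()]
            if tokens:
                lines.append((idx, tokens))
    else:
        for idx, line in enumerate(text.splitlines(), start=1):
            tokens = line.split()
            if tokens:
                lines.append((idx, tokens))
    return _parse_tokens(lines)


def write_sample(sample: SampleVector, path) -> None:
    """Write one value per line at full round-trip precision."""
    Path(path).write_text("\n".join(repr(float(v)) for v in sample.values) + "\n")
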