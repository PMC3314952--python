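"""Shared TSV dialect.

Tab-separated, UTF-8, '.' decimal; metadata travels in leading ``#key=value``
lines so that every numeric output file round-trips through the package's own
readers and remains bit-stable across runs.
"""

from __future__ import annotations

from typing import Any

import pandas as pd


def write_tsv(path, frame: pd.DataFrame, metadata: dict[str, Any] | None = None,
              float_format: str = "%.6g") -> None:
    """Write ``frame`` with optional ``#key=value`` metadata header lines."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for key, value in (metadata or {}).items():
            handle.write(f"#{key}={value}\n")
        frame.to_csv(handle, sep="\t", index=False, float_format=float_format)


def read_tsv(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_tsv`; returns (frame, metadata)."""
    metadata: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        lines = handle.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            metadata[key] = value
            body_start = i + 1
        else:
            break
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    return frame, metadata


def parse_float(value: str | None, default: float | None = None) -> float | None:
    if value is None or value == "":
        return default
    return float(value)
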