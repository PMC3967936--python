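"""Tab-separated grid matrices and JSON run manifests.

Every component field is written as one integer matrix per file (row-major:
one grid row per line, columns tab-separated).  Round trips are lossless and
dimensions/level ranges are validated on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .epithelium import Epithelium

__all__ = ["write_field", "read_field", "write_epithelium", "write_manifest"]


class GridFileError(ValueError):
    pass


def write_field(field: np.ndarray, path: str | Path) -> None:
    field = np.asarray(field)
    if field.ndim != 2:
        raise GridFileError(f"field must be 2-D, got shape {field.shape}")
    lines = ["\t".join(str(int(v)) for v in row) for row in field]
    Path(path).write_text("\n".join(lines) + "\n")


def read_field(
    path: str | Path,
    shape: tuple[int, int] | None = None,
    max_level: int | None = None,
) -> np.ndarray:
    rows = []
    width = None
    for k, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        try:
            row = [int(tok) for tok in line.split("\t")]
        except ValueError as e:
            raise GridFileError(f"{path}, line {k + 1}: non-integer entry") from e
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise GridFileError(f"{path}, line {k + 1}: ragged row ({len(row)} != {width})")
        rows.append(row)
    arr = np.array(rows, dtype=np.int8)
    if shape is not None and arr.shape != tuple(shape):
        raise GridFileError(f"{path}: shape {arr.shape} does not match expected {shape}")
    if arr.min(initial=0) < 0:
        raise GridFileError(f"{path}: negative level")
    if max_level is not None and arr.max(initial=0) > max_level:
        raise GridFileError(f"{path}: level {arr.max()} above maximum {max_level}")
    return arr


def write_epithelium(epi: Epithelium, outdir: str | Path, prefix: str = "") -> list[Path]:
    """One TSV per component field; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in epi.model.names:
        p = outdir / f"{prefix}{name}.tsv"
        write_field(epi.fields[name], p)
        written.append(p)
    return written


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
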