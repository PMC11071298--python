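"""Serialization of identity matrices: pairwise BED and binary containers.

The BED dialect is a 7-column pairwise layout (query name/start/end,
reference name/start/end, percent identity), 0-based half-open base
coordinates, gzip-compressed, with a ``#`` header line naming the columns
and embedding all sketching parameters as JSON for provenance.  Self-plot
files keep only the upper triangle (i <= j) by default since the matrix is
symmetric.

Binary save/load uses a numpy .npz container with a JSON metadata entry;
loading validates the format version and, when requested, k/seed
compatibility before the matrix can be reused.
"""

from __future__ import annotations

import gzip
import json
import zipfile
from pathlib import Path

import numpy as np

from .identity import IdentityMatrix
from .kmers import ValidationError

_FORMAT_VERSION = 1
_BED_COLUMNS = ("query_name", "query_start", "query_end",
                "reference_name", "reference_start", "reference_end", "perID")


def _cell_bounds(idx: int, offset: int, w: int, seq_len: int) -> tuple[int, int]:
    start = offset + idx * w
    return start, min(start + w, offset + seq_len)


def _header_meta(matrix: IdentityMatrix) -> dict:
    meta = dict(matrix.metadata)
    meta.update(
        {
            "version": _FORMAT_VERSION,
            "x_name": matrix.x_name,
            "y_name": matrix.y_name,
            "window_size": matrix.window_size,
            "x_offset": matrix.x_offset,
            "y_offset": matrix.y_offset,
            "self_plot": matrix.self_plot,
            "threshold": matrix.threshold,
            "shape": list(matrix.values.shape),
        }
    )
    return meta


def write_bed(matrix: IdentityMatrix, path: str | Path, full: bool = False) -> Path:
    """Write cells >= threshold as gzip-compressed pairwise BED.

    Self matrices emit the upper triangle only (symmetric rows are
    redundant) unless ``full`` is set.
    """
    path = Path(path)
    n_rows, n_cols = matrix.values.shape
    x_len = int(matrix.metadata.get("x_len", n_cols * matrix.window_size))
    y_len = int(matrix.metadata.get("y_len", n_rows * matrix.window_size))
    w = matrix.window_size
    with gzip.open(path, "wt") as fh:
        fh.write("#" + "\t".join(_BED_COLUMNS) + "\t" + json.dumps(_header_meta(matrix)) + "\n")
        for i in range(n_rows):
            ys, ye = _cell_bounds(i, matrix.y_offset, w, y_len)
            j_start = i if (matrix.self_plot and not full) else 0
            for j in range(j_start, n_cols):
                v = matrix.values[i, j]
                if v < matrix.threshold:
                    continue
                xs, xe = _cell_bounds(j, matrix.x_offset, w, x_len)
                # shortest round-trip repr keeps the file lossless
                fh.write(
                    f"{matrix.x_name}\t{xs}\t{xe}\t{matrix.y_name}\t{ys}\t{ye}\t{float(v)!r}\n"
                )
    return path


def read_bed(path: str | Path) -> IdentityMatrix:
    """Reconstruct a matrix from a pairwise BED file written by write_bed.

    Cells absent from the file (below threshold) come back as 0.
    """
    path = Path(path)
    with gzip.open(path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValidationError(f"{path}: missing header line")
        meta = json.loads(header.rsplit("\t", 1)[-1])
        if meta.get("version") != _FORMAT_VERSION:
            raise ValidationError(f"{path}: unsupported format version {meta.get('version')}")
        shape = tuple(meta.pop("shape"))
        w = meta["window_size"]
        values = np.zeros(shape, dtype=np.float64)
        for lineno, line in enumerate(fh, 2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise ValidationError(f"{path}: line {lineno}: expected 7 columns")
            xs, ys, v = int(fields[1]), int(fields[4]), float(fields[6])
            j = (xs - meta["x_offset"]) // w
            i = (ys - meta["y_offset"]) // w
            values[i, j] = v
            if meta["self_plot"]:
                values[j, i] = v
    matrix = IdentityMatrix(
        values=values,
        x_name=meta.pop("x_name"),
        y_name=meta.pop("y_name"),
        window_size=meta.pop("window_size"),
        x_offset=meta.pop("x_offset"),
        y_offset=meta.pop("y_offset"),
        self_plot=meta.pop("self_plot"),
        threshold=meta.pop("threshold"),
    )
    meta.pop("version", None)
    matrix.metadata = meta
    return matrix


def save_matrix(matrix: IdentityMatrix, path: str | Path) -> Path:
    """Save as a binary .npz container with embedded JSON metadata."""
    path = Path(path)
    np.savez_compressed(
        path,
        values=matrix.values,
        meta=np.frombuffer(json.dumps(_header_meta(matrix)).encode(), dtype=np.uint8),
    )
    # np.savez appends .npz when missing; normalize the return path
    return path if path.suffix == ".npz" else path.with_name(path.name + ".npz")


def load_matrix(
    path: str | Path,
    expect_k: int | None = None,
    expect_seed: int | None = None,
) -> IdentityMatrix:
    """Load a saved matrix, validating version and optional k/seed match."""
    path = Path(path)
    try:
        with np.load(path) as npz:
            values = npz["values"]
            meta = json.loads(npz["meta"].tobytes().decode())
    except (OSError, KeyError, ValueError, zipfile.BadZipFile) as exc:
        raise ValidationError(f"{path}: not a valid matrix container ({exc})") from exc
    if meta.get("version") != _FORMAT_VERSION:
        raise ValidationError(f"{path}: unsupported format version {meta.get('version')}")
    if expect_k is not None and meta.get("k") != expect_k:
        raise ValidationError(f"{path}: built with k={meta.get('k')}, expected k={expect_k}")
    if expect_seed is not None and meta.get("seed") != expect_seed:
        raise ValidationError(
            f"{path}: built with seed={meta.get('seed')}, expected seed={expect_seed}"
        )
    meta.pop("shape", None)
    meta.pop("version", None)
    matrix = IdentityMatrix(
        values=values,
        x_name=meta.pop("x_name"),
        y_name=meta.pop("y_name"),
        window_size=meta.pop("window_size"),
        x_offset=meta.pop("x_offset"),
        y_offset=meta.pop("y_offset"),
        self_plot=meta.pop("self_plot"),
        threshold=meta.pop("threshold"),
        metadata=meta,
    )
    return matrix
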