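"""Labelled-matrix round-tripping: TSV values plus a JSON sidecar of metadata.

Matrices are stored as tab-separated text with row and column label headers.
The sidecar records orientation ("column->row"), the reversed flag, band and
lag parameters, and a digest of the configuration that produced the matrix.
On reload, rows and columns are reindexed by label into the requested order,
so files whose columns were shuffled still load correctly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import ECMatrix


def write_matrix(values: np.ndarray, labels: Sequence[str], path: str | Path,
                 sidecar: dict | None = None) -> None:
    """Write a labelled square matrix as TSV (+ optional JSON sidecar)."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.shape != (len(labels), len(labels)):
        raise ValueError("matrix shape does not match labels")
    df = pd.DataFrame(values, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.12g", index_label="region")
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_matrix(path: str | Path,
                labels: Sequence[str] | None = None) -> tuple[np.ndarray, list[str], dict]:
    """Read a labelled matrix TSV; reindex to ``labels`` if given.

    Returns (values, labels, sidecar); the sidecar is {} when absent.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if labels is not None:
        missing = set(labels).symmetric_difference(df.index)
        if missing or list(df.index) != list(df.columns) and set(df.index) != set(df.columns):
            if missing:
                raise ValueError(f"matrix labels do not match scheme: {sorted(missing)}")
        df = df.reindex(index=list(labels), columns=list(labels))
        if df.isna().any().any():
            raise ValueError("matrix could not be reindexed to the requested labels")
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return df.to_numpy(dtype=float), list(df.index), sidecar


def write_ec(ec: ECMatrix, path: str | Path, extra: dict | None = None) -> None:
    sidecar = {"orientation": ec.orientation, "reversed": ec.reversed,
               "lag_samples": ec.diagnostics.get("lag_samples"),
               "best_error": ec.diagnostics.get("best_error"),
               "n_iterations": ec.diagnostics.get("n_iterations")}
    if extra:
        sidecar.update(extra)
    write_matrix(ec.values, ec.labels, path, sidecar)


def read_ec(path: str | Path, labels: Sequence[str] | None = None) -> ECMatrix:
    values, labs, sidecar = read_matrix(path, labels)
    return ECMatrix(values=values, labels=labs,
                    reversed=bool(sidecar.get("reversed", False)),
                    diagnostics={k: sidecar[k] for k in ("lag_samples", "best_error",
                                                         "n_iterations") if k in sidecar})
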