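"""File I/O and the run manifest.

Matrices are stored probes-as-rows in TSV/CSV: first column the probe
id, header row of sample ids.  Floats are written with 17 significant
digits so write -> read round-trips are bit-exact.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .matrix import MethylationMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_svs",
    "write_weights",
    "RunManifest",
    "file_digest",
]

FLOAT_FMT = "%.17g"


def _detect_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_matrix(path, scale: str = "M") -> MethylationMatrix:
    """Read a probes x samples TSV/CSV matrix (dialect auto-detected).

    The first column holds probe ids, the header row sample ids.  Scale
    invariants are validated on load; non-numeric cells are reported
    with their coordinates.
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"non-numeric cell at probe {df.index[i]!r}, sample {col!r}"
                )
        values = df.apply(pd.to_numeric).to_numpy()
    return MethylationMatrix(
        values=values.astype(float),
        probe_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        scale=scale,
    )


def write_matrix(matrix: MethylationMatrix, path, sep: str = "\t") -> None:
    df = pd.DataFrame(matrix.values, index=matrix.probe_ids, columns=matrix.sample_ids)
    df.index.name = "probe_id"
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    """Read a phenotype/covariate table keyed by a sample-id column."""
    return pd.read_csv(path, sep=_detect_sep(path))


def write_svs(sv: np.ndarray, sample_ids, path) -> None:
    df = pd.DataFrame(
        sv, index=sample_ids, columns=[f"SV{k + 1}" for k in range(sv.shape[1])]
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_weights(weights: np.ndarray, probe_ids, path) -> None:
    df = pd.DataFrame({"probe_id": probe_ids, "weight": weights})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


@dataclass
class RunManifest:
    """Reproducibility record written once per CLI run."""

    command: str
    config: dict
    seed: Optional[int] = None
    version: str = __version__
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    convergence: Optional[dict] = None
    started: str = ""
    finished: str = ""

    def write(self, path) -> None:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_json_default)
            fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
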