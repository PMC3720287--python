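"""Plain-text readers and writers for the pipeline's artifacts.

Chromatograms travel as per-sample CSV (``rt_min,intensity``); matrices
(aligned peaks, probe intensities, expression) as TSV with row and
column identifiers; run manifests and ground truth as JSON. No binary
chip or vendor formats are read or written.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chrom import AlignedPeakMatrix, Chromatogram
from .exprproc import ExpressionMatrix, ProbeMatrix, ProbesetMap

__all__ = [
    "write_chromatogram",
    "read_chromatogram",
    "write_peak_matrix",
    "read_peak_matrix",
    "write_probe_matrix",
    "read_probe_matrix",
    "write_probeset_map",
    "read_probeset_map",
    "write_expression",
    "read_expression",
    "write_json",
    "read_json",
]


def write_chromatogram(c: Chromatogram, path: str | Path) -> None:
    pd.DataFrame({"rt_min": c.rt, "intensity": c.intensity}).to_csv(path, index=False)


def read_chromatogram(
    path: str | Path,
    sample_id: str | None = None,
    technique: str = "synthetic",
    group: str | None = None,
) -> Chromatogram:
    df = pd.read_csv(path)
    if not {"rt_min", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns rt_min,intensity")
    sid = sample_id if sample_id is not None else Path(path).stem
    return Chromatogram(df["rt_min"].to_numpy(), df["intensity"].to_numpy(), sid, technique, group)


def write_peak_matrix(m: AlignedPeakMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_peak_matrix(path: str | Path, technique: str = "synthetic") -> AlignedPeakMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    rts = np.array([float(c.removeprefix("rt_")) for c in df.columns])
    return AlignedPeakMatrix(df.to_numpy(), rts, list(df.index), technique)


def write_probe_matrix(m: ProbeMatrix, path: str | Path) -> None:
    pd.DataFrame(m.values, index=m.probe_ids, columns=m.array_ids).to_csv(
        path, sep="\t", index_label="probe_id"
    )


def read_probe_matrix(path: str | Path, condition: list[str] | None = None) -> ProbeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    return ProbeMatrix(df.to_numpy(), list(df.index), list(df.columns), condition)


def write_probeset_map(pm: ProbesetMap, path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(pm.mapping), "probeset_id": list(pm.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_probeset_map(path: str | Path) -> ProbesetMap:
    df = pd.read_csv(path, sep="\t")
    return ProbesetMap(dict(zip(df["probe_id"], df["probeset_id"])))


def write_expression(e: ExpressionMatrix, path: str | Path) -> None:
    e.to_frame().to_csv(path, sep="\t", index_label="probeset_id")


def read_expression(path: str | Path, condition: list[str] | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probeset_id")
    return ExpressionMatrix(df.to_numpy(), list(df.index), list(df.columns), condition)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
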