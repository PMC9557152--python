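"""Readers and writers for recordings, segments and result tables.

Signal matrices travel as a data file plus a JSON sidecar named after it
(``rec.csv`` + ``rec.json``).  Two data layouts are supported:

* delimited text: one row per sample, one column per lead;
* flat binary: float64 little-endian, row-major ``(m, n)``.

The sidecar declares at least ``fs_hz`` and ``n_leads``; optional fields are
``lead_labels`` and ``bad_leads`` (1-based vest labels).  WFDB records are
recognised but delegated to the optional ``wfdb`` package.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, InsufficientDataError
from .geometry import VestGeometry
from .types import AASegment, BspmRecording, SegmentIndices

__all__ = [
    "read_recording",
    "write_recording",
    "read_segment",
    "write_segment",
    "write_segment_indices",
    "read_segment_indices",
]

_INDEX_COLUMNS = [
    "patient_id",
    "segment_id",
    "subset_kind",
    "k",
    "er_nrmse",
    "er_abse",
    "ndi",
    "outcome",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_sidecar(path: Path) -> dict:
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing JSON sidecar {side}")
    try:
        doc = json.loads(side.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {side} is not valid JSON: {exc}") from exc
    for key in ("fs_hz", "n_leads"):
        if key not in doc:
            raise FormatError(f"sidecar {side} is missing required field '{key}'")
    return doc


def _load_matrix(path: Path, n_leads: int) -> np.ndarray:
    if path.suffix in {".csv", ".tsv", ".txt"}:
        delim = "\t" if path.suffix == ".tsv" else ","
        x = np.loadtxt(path, delimiter=delim, ndmin=2)
    elif path.suffix in {".f64", ".bin", ".dat"}:
        flat = np.fromfile(path, dtype="<f8")
        if flat.size % n_leads:
            raise DimensionError(
                f"{path} holds {flat.size} float64 values, not a multiple of "
                f"n_leads={n_leads}"
            )
        x = flat.reshape(-1, n_leads)
    else:
        raise FormatError(f"unsupported data file extension {path.suffix!r}")
    if x.shape[1] != n_leads:
        raise DimensionError(
            f"{path} has {x.shape[1]} columns but sidecar declares n_leads={n_leads}"
        )
    return x


def read_recording(
    path: str | Path,
    format: str = "matrix",
    geometry: Optional[VestGeometry] = None,
) -> BspmRecording:
    """Read a multichannel recording.

    Parameters
    ----------
    path
        Data file (``.csv``/``.tsv``/``.txt`` delimited or ``.f64``/``.bin``
        flat binary) with a JSON sidecar, or a WFDB record name.
    format
        ``"matrix"`` (default) or ``"wfdb"``.
    geometry
        Vest geometry; inferred from the lead count when omitted.
    """
    if format == "wfdb":
        try:
            import wfdb  # noqa: F401
        except ImportError as exc:  # pragma: no cover - depends on extras
            raise FormatError(
                "WFDB reading requires the optional 'wfdb' package (pip install wfdb)"
            ) from exc
        rec = wfdb.rdrecord(str(path))  # pragma: no cover
        x = np.asarray(rec.p_signal, dtype=float)  # pragma: no cover
        geo = geometry or VestGeometry.for_n_leads(x.shape[1])  # pragma: no cover
        return BspmRecording(samples=x, fs=float(rec.fs), geometry=geo)  # pragma: no cover
    if format != "matrix":
        raise FormatError(f"unknown recording format {format!r}")

    path = Path(path)
    if not path.exists():
        raise FormatError(f"recording data file {path} does not exist")
    doc = _read_sidecar(path)
    n_leads = int(doc["n_leads"])
    x = _load_matrix(path, n_leads)
    geo = geometry or VestGeometry.for_n_leads(n_leads)
    quality = np.ones(n_leads, dtype=bool)
    for label in doc.get("bad_leads", []):
        i = int(label) - 1
        if not 0 <= i < n_leads:
            raise FormatError(f"bad_leads entry {label} outside 1..{n_leads}")
        quality[i] = False
    return BspmRecording(samples=x, fs=float(doc["fs_hz"]), geometry=geo, lead_quality=quality)


def write_recording(rec: BspmRecording, path: str | Path) -> None:
    """Write a recording in the sidecar format chosen by the file extension."""
    path = Path(path)
    if path.suffix in {".csv", ".tsv", ".txt"}:
        delim = "\t" if path.suffix == ".tsv" else ","
        np.savetxt(path, rec.samples, delimiter=delim, fmt="%.17e")
    elif path.suffix in {".f64", ".bin", ".dat"}:
        rec.samples.astype("<f8").tofile(path)
    else:
        raise FormatError(f"unsupported data file extension {path.suffix!r}")
    doc = {
        "fs_hz": rec.fs,
        "n_leads": rec.n_leads,
        "lead_labels": [str(i + 1) for i in range(rec.n_leads)],
        "bad_leads": [int(i) + 1 for i in np.flatnonzero(~rec.lead_quality)],
    }
    _sidecar_path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_segment(path: str | Path, geometry: Optional[VestGeometry] = None) -> AASegment:
    """Read an atrial-activity segment written by :func:`write_segment`."""
    path = Path(path)
    doc = _read_sidecar(path)
    x = _load_matrix(path, int(doc["n_leads"]))
    return AASegment(
        samples=x,
        fs=float(doc["fs_hz"]),
        window_len_s=float(doc.get("window_len_s", 5.0)),
        normalized=bool(doc.get("normalized", False)),
    )


def write_segment(seg: AASegment, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".csv", ".tsv", ".txt"}:
        delim = "\t" if path.suffix == ".tsv" else ","
        np.savetxt(path, seg.samples, delimiter=delim, fmt="%.17e")
    elif path.suffix in {".f64", ".bin", ".dat"}:
        seg.samples.astype("<f8").tofile(path)
    else:
        raise FormatError(f"unsupported data file extension {path.suffix!r}")
    doc = {
        "fs_hz": seg.fs,
        "n_leads": seg.n_leads,
        "window_len_s": seg.window_len_s,
        "normalized": seg.normalized,
    }
    _sidecar_path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def write_segment_indices(results: Sequence[SegmentIndices], path: str | Path) -> None:
    """Write one delimited row per (segment, subset kind), stable column order."""
    if not results:
        raise InsufficientDataError("write_segment_indices requires at least one result")
    rows = [
        {
            "patient_id": r.patient_id,
            "segment_id": r.segment_id,
            "subset_kind": r.subset_kind,
            "k": r.k,
            "er_nrmse": np.nan if r.er_nrmse is None else r.er_nrmse,
            "er_abse": np.nan if r.er_abse is None else r.er_abse,
            "ndi": np.nan if r.ndi is None else r.ndi,
            "outcome": r.outcome,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=_INDEX_COLUMNS).to_csv(path, index=False, float_format="%.12g")


def read_segment_indices(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "segment_id": str})
    missing = set(_INDEX_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"index table {path} is missing columns {sorted(missing)}")
    return df
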