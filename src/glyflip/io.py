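"""Readers and writers for traces, dwell lists, clusters and CRC tables.

Traces travel either as CSV (``time_s,current_pA`` with ``# key=value``
metadata comment lines) or as an HDF5 layout with ``/trace/current`` plus
``sample_rate_hz``-style attributes; both round-trip values exactly.
Dwell and cluster lists are plain CSV; comparison results and study
summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .concentration_response import CRCCell, CRCStudy
from .idealization import Cluster, DwellSequence, clusters_to_frame
from .synthetic_data import TraceRecord

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_trace_hdf5", "read_trace_hdf5",
    "read_trace",
    "write_dwells_csv", "read_dwells_csv",
    "write_clusters_csv",
    "write_crc_csv", "read_crc_csv",
    "write_json",
]


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_trace_csv(trace: TraceRecord, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={trace.sample_rate!r}\n")
        fh.write(f"# start_s={trace.start!r}\n")
        if trace.labels:
            fh.write(f"# labels={json.dumps(trace.labels)}\n")
        fh.write("time_s,current_pA\n")
        t = trace.times
        for ti, xi in zip(t, trace.current):
            fh.write(f"{ti:.17g},{xi:.17g}\n")


def read_trace_csv(path) -> TraceRecord:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        current = df["current_pA"].to_numpy(float)
    except (KeyError, ValueError, pd.errors.ParserError) as err:
        raise ValueError(f"{path}: malformed trace CSV ({err})") from err
    labels = json.loads(meta["labels"]) if "labels" in meta else {}
    return TraceRecord(current=current,
                       sample_rate=float(meta["sample_rate_hz"]),
                       start=float(meta.get("start_s", 0.0)),
                       labels=labels)


def write_trace_hdf5(trace: TraceRecord, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("trace")
        d = g.create_dataset("current", data=np.asarray(trace.current, dtype=np.float64))
        d.attrs["sample_rate_hz"] = trace.sample_rate
        d.attrs["start_s"] = trace.start
        if trace.acquisition is not None and trace.acquisition.filter_corner:
            d.attrs["filter_corner_hz"] = trace.acquisition.filter_corner
        g.create_dataset("labels", data=json.dumps(trace.labels))


def read_trace_hdf5(path) -> TraceRecord:
    with h5py.File(path, "r") as f:
        d = f["trace/current"]
        labels = json.loads(f["trace/labels"][()])
        return TraceRecord(current=d[:].astype(float),
                           sample_rate=float(d.attrs["sample_rate_hz"]),
                           start=float(d.attrs.get("start_s", 0.0)),
                           labels=labels)


def read_trace(path) -> TraceRecord:
    """Dispatch on extension: .h5/.hdf5 to HDF5, otherwise CSV."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return read_trace_hdf5(path)
    return read_trace_csv(path)


# ---------------------------------------------------------------------------
# dwells and clusters
# ---------------------------------------------------------------------------

def write_dwells_csv(dwells: DwellSequence, path) -> None:
    dwells.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_dwells_csv(path) -> DwellSequence:
    df = pd.read_csv(path)
    missing = {"start_s", "duration_s", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: dwell CSV missing columns {sorted(missing)}")
    return DwellSequence.from_frame(df)


def write_clusters_csv(clusters: list[Cluster], path) -> None:
    clusters_to_frame(clusters).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# concentration-response tables
# ---------------------------------------------------------------------------

def write_crc_csv(study: CRCStudy, path) -> None:
    rows = []
    for cell in study.cells:
        for c, r in zip(cell.concentrations, cell.peak_responses):
            rows.append((cell.cell_id, cell.agonist, cell.ph, c, r, 0))
        if cell.reference_saturating_response is not None:
            rows.append((cell.cell_id, cell.agonist, cell.ph, np.nan,
                         cell.reference_saturating_response, 1))
    pd.DataFrame(rows, columns=["cell_id", "agonist", "ph", "concentration_m",
                                "response_na", "is_reference"]) \
        .to_csv(path, index=False, float_format="%.17g")


def read_crc_csv(path) -> CRCStudy:
    df = pd.read_csv(path)
    required = {"cell_id", "agonist", "ph", "concentration_m",
                "response_na", "is_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: CRC CSV missing columns {sorted(missing)}")
    cells = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        data = grp[grp["is_reference"] == 0]
        refs = grp[grp["is_reference"] == 1]
        reference = float(refs["response_na"].iloc[0]) if len(refs) else None
        cells.append(CRCCell(
            cell_id=str(cell_id),
            agonist=str(grp["agonist"].iloc[0]),
            ph=str(grp["ph"].iloc[0]),
            concentrations=data["concentration_m"].to_numpy(float),
            peak_responses=data["response_na"].to_numpy(float),
            reference_saturating_response=reference))
    return CRCStudy(cells=cells)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_json(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
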