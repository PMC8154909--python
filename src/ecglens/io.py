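"""Plain-text record bundles and dataset manifests.

One record is stored as a CSV of samples (one column per lead, in LSB
counts) plus a JSON sidecar with the sampling metadata, fiducials and
measurements; a dataset is a directory of bundles plus a ``manifest.csv``
listing record ids and labels.  Everything round-trips exactly (signals
are integers, times/amplitudes are floats).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .records import ECGRecord, FiducialSet, LEAD_NAMES, MeasurementSet
from .synth import LabeledECG

__all__ = ["write_bundle", "read_bundle", "write_dataset", "read_dataset"]


def _fid_to_dict(fid: FiducialSet) -> dict:
    d = dataclasses.asdict(fid)
    if d.get("beat_times") is not None:
        d["beat_times"] = list(map(float, d["beat_times"]))
    return d


def write_bundle(directory, labeled: LabeledECG) -> Path:
    """Write one record bundle; returns the directory written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rec = labeled.record
    lead_names = LEAD_NAMES[:rec.n_leads] if rec.n_leads <= 12 else \
        [f"ch{i}" for i in range(rec.n_leads)]
    pd.DataFrame(rec.voltages.T, columns=lead_names).to_csv(
        directory / "signal.csv", index=False)
    meta = {
        "fs": rec.fs, "lsb": rec.lsb, "record_kind": rec.record_kind,
        "record_id": rec.record_id,
        "fiducials": _fid_to_dict(labeled.fiducials),
        "measurements": dataclasses.asdict(labeled.measurements),
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_bundle(directory) -> LabeledECG:
    directory = Path(directory)
    sig = pd.read_csv(directory / "signal.csv")
    meta = json.loads((directory / "meta.json").read_text())
    rec = ECGRecord(sig.to_numpy().T.astype(np.int32), fs=meta["fs"],
                    lsb=meta["lsb"], record_kind=meta["record_kind"],
                    record_id=meta["record_id"])
    fid = FiducialSet(**meta["fiducials"])
    meas = MeasurementSet(**meta["measurements"])
    return LabeledECG(rec, fid, meas, params=None)


def write_dataset(directory, dataset: Sequence[LabeledECG]) -> Path:
    """Write bundles ``rec00000/ ...`` plus a label manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, d in enumerate(dataset):
        sub = directory / f"rec{i:05d}"
        write_bundle(sub, d)
        row = {"record_id": d.record.record_id or sub.name, "path": sub.name}
        row.update(dataclasses.asdict(d.measurements))
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    return directory


def read_dataset(directory) -> List[LabeledECG]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    return [read_bundle(directory / p) for p in manifest["path"]]
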