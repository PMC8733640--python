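"""Reading and writing cohort tables and examination containers.

Cohorts travel as tidy CSV (one row per subject).  Examinations are
columnar arrays; two interchangeable containers are supported: an HDF5 file
(datasets ``time_grid``, ``x_grid``, ``surface``; truth as a JSON attribute)
and a plain-text CSV bundle directory (same arrays as CSV plus
``truth.json``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Examination, subject_from_row


def write_cohort_csv(subjects, path) -> None:
    pd.DataFrame([s.to_row() for s in subjects]).to_csv(path, index=False)


def read_cohort_csv(path):
    df = pd.read_csv(path)
    return [subject_from_row(row) for row in df.to_dict("records")]


def _truth_to_json(truth: dict) -> str:
    enc = {}
    for k, v in truth.items():
        enc[k] = v.tolist() if isinstance(v, np.ndarray) else v
    return json.dumps(enc)


def _truth_from_json(text: str) -> dict:
    dec = json.loads(text)
    for k in ("delta_true", "force"):
        if k in dec and dec[k] is not None:
            dec[k] = np.asarray(dec[k])
    return dec


def write_examination_h5(exam: Examination, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("time_grid", data=exam.time_grid)
        f.create_dataset("x_grid", data=exam.x_grid)
        f.create_dataset("surface", data=exam.surface)
        f.attrs["subject_id"] = exam.subject_id
        f.attrs["truth"] = _truth_to_json(exam.truth)


def read_examination_h5(path) -> Examination:
    import h5py

    with h5py.File(path, "r") as f:
        return Examination(
            subject_id=str(f.attrs["subject_id"]),
            time_grid=f["time_grid"][:],
            x_grid=f["x_grid"][:],
            surface=f["surface"][:],
            truth=_truth_from_json(f.attrs["truth"]),
        )


def write_examination_bundle(exam: Examination, dirpath) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "time_grid.csv", exam.time_grid, delimiter=",")
    np.savetxt(d / "x_grid.csv", exam.x_grid, delimiter=",")
    np.savetxt(d / "surface.csv", exam.surface, delimiter=",")
    meta = {"subject_id": exam.subject_id, "truth": json.loads(_truth_to_json(exam.truth))}
    (d / "truth.json").write_text(json.dumps(meta, indent=2))


def read_examination_bundle(dirpath) -> Examination:
    d = Path(dirpath)
    meta = json.loads((d / "truth.json").read_text())
    return Examination(
        subject_id=meta["subject_id"],
        time_grid=np.loadtxt(d / "time_grid.csv", delimiter=","),
        x_grid=np.loadtxt(d / "x_grid.csv", delimiter=","),
        surface=np.loadtxt(d / "surface.csv", delimiter=","),
        truth=_truth_from_json(json.dumps(meta["truth"])),
    )
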