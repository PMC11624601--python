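"""Flat-binary + JSON-sidecar export layout for evoked data.

A directory holds ``evoked.bin`` (float64, C order), ``evoked.json`` (shape,
axes, labels, epoch counts), ``space.json`` (vertices, edges, labels) and
``subjects.csv``; ``win_responses.csv`` is written when behavior exists.
The same layout is accepted for real exported source estimates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import EvokedSet, SourceSpace, SubjectRecord, records_to_frame

__all__ = ["export_dataset", "ingest_real"]


def export_dataset(
    out_dir,
    ev: EvokedSet,
    space: SourceSpace,
    records: list[SubjectRecord] | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(ev.data, dtype=np.float64).tofile(out / "evoked.bin")
    sidecar = {
        "shape": list(ev.data.shape),
        "dtype": "float64",
        "axes": ["subject", "condition", "vertex", "time"],
        "conditions": list(ev.conditions),
        "times_ms": ev.times_ms.tolist(),
        "fs": ev.fs,
        "n_epochs": ev.n_epochs.tolist(),
    }
    (out / "evoked.json").write_text(json.dumps(sidecar))
    (out / "space.json").write_text(
        json.dumps(
            {
                "hemi": space.hemi.tolist(),
                "region": space.region.tolist(),
                "edges": space.edges.tolist(),
            }
        )
    )
    if records is not None:
        records_to_frame(records).to_csv(out / "subjects.csv", index=False)
        frames = [
            r.win_responses.assign(subject=r.subject)
            for r in records
            if r.win_responses is not None
        ]
        if frames:
            pd.concat(frames).to_csv(out / "win_responses.csv", index=False)
    return out


def ingest_real(export_dir) -> tuple[EvokedSet, SourceSpace, pd.DataFrame | None]:
    """Load and validate a dataset directory in the export layout.

    Raises ValueError naming the first schema violation found.
    """
    d = Path(export_dir)
    for fname in ("evoked.json", "evoked.bin", "space.json"):
        if not (d / fname).exists():
            raise ValueError(f"missing {fname} in {d}")
    meta = json.loads((d / "evoked.json").read_text())
    for key in ("shape", "conditions", "times_ms", "fs", "n_epochs"):
        if key not in meta:
            raise ValueError(f"evoked.json missing key {key!r}")
    shape = tuple(meta["shape"])
    if len(shape) != 4:
        raise ValueError(f"evoked array must be 4-D, got shape {shape}")
    raw = np.fromfile(d / "evoked.bin", dtype=np.float64)
    if raw.size != int(np.prod(shape)):
        raise ValueError(
            f"evoked.bin holds {raw.size} values, sidecar shape {shape} "
            f"needs {int(np.prod(shape))}"
        )
    data = raw.reshape(shape)
    if len(meta["conditions"]) != shape[1]:
        raise ValueError("condition labels do not match axis 1 length")
    times = np.asarray(meta["times_ms"], float)
    if len(times) != shape[3]:
        raise ValueError("times_ms length does not match axis 3 length")
    n_epochs = np.asarray(meta["n_epochs"], int)
    if n_epochs.shape != (shape[0], shape[1]):
        raise ValueError("n_epochs shape does not match (subjects, conditions)")
    if np.any(n_epochs <= 0):
        raise ValueError("n_epochs must be positive")

    sp = json.loads((d / "space.json").read_text())
    hemi = np.asarray(sp["hemi"])
    region = np.asarray(sp["region"], dtype=object)
    edges = np.asarray(sp["edges"], int)
    if len(hemi) != shape[2]:
        raise ValueError("space vertex count does not match evoked axis 2")
    if edges.size and np.any(hemi[edges[:, 0]] != hemi[edges[:, 1]]):
        raise ValueError("adjacency contains a cross-hemisphere edge")
    space = SourceSpace(hemi=hemi, region=region, edges=edges)

    ev = EvokedSet(
        data=data,
        conditions=tuple(meta["conditions"]),
        times_ms=times,
        n_epochs=n_epochs,
        fs=float(meta["fs"]),
    )
    subjects = None
    if (d / "subjects.csv").exists():
        subjects = pd.read_csv(d / "subjects.csv")
        if len(subjects) != shape[0]:
            raise ValueError("subjects.csv row count does not match evoked axis 0")
    return ev, space, subjects
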