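"""Epoch container: a directory with one array file per subject plus a manifest.

Each subject is stored as ``<subject_id>.npz`` holding the epochs array
(``n_epochs x ch x T``, float64), the integer labels, and the sample rate;
``manifest.json`` lists the subjects and carries free-form provenance
metadata. Round trips are bit-exact (npz stores raw float64).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .alignment import EpochSet

__all__ = ["save_dataset", "load_dataset"]

MANIFEST = "manifest.json"


def save_dataset(subjects: list[EpochSet], out_dir, provenance: dict | None = None) -> Path:
    """Write a multi-subject dataset to ``out_dir``; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = []
    for s in subjects:
        if s.subject_id in ids:
            raise ValueError(f"duplicate subject id {s.subject_id!r}")
        ids.append(s.subject_id)
        np.savez(
            out / f"{s.subject_id}.npz",
            epochs=s.epochs,
            labels=s.labels,
            sample_rate=np.float64(s.sample_rate),
        )
    manifest = {"subjects": ids, "provenance": provenance or {}}
    (out / MANIFEST).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def load_dataset(in_dir) -> list[EpochSet]:
    """Read every subject listed in the manifest, in manifest order."""
    root = Path(in_dir)
    manifest = json.loads((root / MANIFEST).read_text())
    subjects = []
    for sid in manifest["subjects"]:
        with np.load(root / f"{sid}.npz") as f:
            subjects.append(
                EpochSet(
                    subject_id=sid,
                    epochs=f["epochs"],
                    labels=f["labels"],
                    sample_rate=float(f["sample_rate"]),
                )
            )
    return subjects
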