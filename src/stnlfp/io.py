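"""Readers/writers for signal containers (HDF5/NPZ) and trial-table CSVs.

The on-disk layout is a clean-room design: one HDF5 group per
(subject, hemisphere, depth) holding three channel datasets plus a
JSON-serialized metadata attribute, or an NPZ file with the same content for
lightweight use. Trial tables are UTF-8 CSVs with the fixed header of
:data:`stnlfp.datamodel.TRIAL_COLUMNS`. Both containers carry a schema
version tag and round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datamodel import (
    NO_RESPONSE,
    TRIAL_COLUMNS,
    Recording,
    SchemaError,
    validate_trials,
)

RECORDING_SCHEMA = "stnlfp-recording/1"
TRIALS_SCHEMA = "stnlfp-trials/1"


def recording_key(rec: Recording) -> str:
    return f"{rec.subject_id}/{rec.hemisphere}/{rec.subregion}"


def _meta(rec: Recording) -> str:
    return json.dumps(
        {
            "schema": RECORDING_SCHEMA,
            "subject_id": rec.subject_id,
            "hemisphere": rec.hemisphere,
            "subregion": rec.subregion,
            "fs_raw": rec.fs_raw,
            "t0": rec.t0,
        }
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to an HDF5 (``.h5``) or NPZ (``.npz``) container.

    HDF5 files are opened in append mode, so several recordings of one
    cohort can share a file (one group per subject/hemisphere/depth).
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            ch0=rec.channels[0],
            ch1=rec.channels[1],
            ch2=rec.channels[2],
            meta=np.bytes_(_meta(rec).encode()),
        )
        return
    with h5py.File(path, "a") as f:
        grp = f.require_group(recording_key(rec))
        for i in range(3):
            name = f"ch{i}"
            if name in grp:
                del grp[name]
            grp.create_dataset(name, data=rec.channels[i])
        grp.attrs["meta"] = _meta(rec)


def _from_meta(meta: dict, channels: list[np.ndarray]) -> Recording:
    if meta.get("schema") != RECORDING_SCHEMA:
        raise SchemaError(f"unknown recording schema version: {meta.get('schema')!r}")
    lengths = {len(c) for c in channels}
    if len(lengths) != 1:
        raise SchemaError(f"channel-length mismatch: {sorted(lengths)}")
    return Recording(
        subject_id=meta["subject_id"],
        hemisphere=meta["hemisphere"],
        subregion=meta["subregion"],
        channels=np.stack(channels),
        fs_raw=meta["fs_raw"],
        t0=meta["t0"],
    )


def read_recording(path: str | Path, key: str | None = None) -> Recording:
    """Read one recording from an HDF5/NPZ container.

    ``key`` selects the ``subject/hemisphere/depth`` group within an HDF5
    file; it may be omitted when the file holds exactly one recording.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            names = [n for n in z.files if n.startswith("ch")]
            if sorted(names) != ["ch0", "ch1", "ch2"]:
                raise SchemaError(f"expected channels ch0..ch2, found {sorted(names)}")
            meta = json.loads(bytes(z["meta"]).decode())
            return _from_meta(meta, [z[n] for n in ("ch0", "ch1", "ch2")])
    with h5py.File(path, "r") as f:
        if key is None:
            keys = list_recordings(path)
            if len(keys) != 1:
                raise SchemaError(
                    f"container holds {len(keys)} recordings; pass key= to select one"
                )
            key = keys[0]
        grp = f[key]
        names = sorted(n for n in grp.keys() if n.startswith("ch"))
        if names != ["ch0", "ch1", "ch2"]:
            raise SchemaError(f"group {key!r}: expected channels ch0..ch2, found {names}")
        meta = json.loads(grp.attrs["meta"])
        return _from_meta(meta, [grp[n][()] for n in names])


def list_recordings(path: str | Path) -> list[str]:
    """List the subject/hemisphere/depth keys stored in an HDF5 container."""
    keys: list[str] = []
    with h5py.File(path, "r") as f:

        def visit(name, obj):
            if isinstance(obj, h5py.Group) and "meta" in obj.attrs:
                keys.append(name)

        f.visititems(visit)
    return sorted(keys)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a validated trial table as a UTF-8 CSV with a schema-tag header."""
    t = validate_trials(trials)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema: {TRIALS_SCHEMA}\n")
        t.to_csv(fh, index=False, float_format="%.6f")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV (enforces the Cs/NC invariant)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# schema:"):
            raise SchemaError("trial CSV missing schema tag line")
        schema = first.split(":", 1)[1].strip()
        if schema != TRIALS_SCHEMA:
            raise SchemaError(f"unknown trial-table schema version: {schema!r}")
        t = pd.read_csv(fh, keep_default_na=False, na_values=[""])
    t["response_side"] = t["response_side"].replace({"": NO_RESPONSE})
    return validate_trials(t)


__all__ = [
    "RECORDING_SCHEMA",
    "TRIALS_SCHEMA",
    "read_recording",
    "write_recording",
    "list_recordings",
    "read_trials",
    "write_trials",
    "recording_key",
    "TRIAL_COLUMNS",
]
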