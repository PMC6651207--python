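"""Reading and writing recordings and cohorts.

Cohorts are written as one CSV per subject-task (first column ``time_s``,
one column per channel, header = AES labels) plus a ``manifest.json``
carrying subject_id, task, fs, seed and the sub-task script. EDF files
are read through MNE; writing uses the CSV dialect.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS
from .recording import Recording
from .task import TaskScript, script_for


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    """One recording as time + channel columns."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for name in rec.channel_names:
        df[name] = rec.channel(name)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def _script_from_json(obj: dict) -> TaskScript:
    return TaskScript(obj["task"], tuple((l, float(d)) for l, d in obj["intervals"]))


def _script_to_json(script: TaskScript) -> dict:
    return {"task": script.task, "intervals": [[l, d] for l, d in script.intervals]}


def write_cohort(recordings: list[Recording], out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Write a cohort as CSVs + manifest.json; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        fname = f"{rec.subject_id}_{rec.task}.csv"
        write_recording_csv(rec, out / fname)
        entries.append({
            "file": fname,
            "subject_id": rec.subject_id,
            "task": rec.task,
            "fs": rec.fs,
            "script": _script_to_json(rec.script),
        })
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"seed": seed, "recordings": entries}, indent=2))
    return manifest


def read_cohort(manifest_path: str | Path) -> list[Recording]:
    """Load every recording listed in a cohort manifest."""
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    out = []
    for e in meta["recordings"]:
        out.append(read_recording(
            manifest_path.parent / e["file"],
            subject_id=e["subject_id"], task=e["task"],
            script=_script_from_json(e["script"]), expected_fs=e["fs"],
        ))
    return out


def read_recording(path: str | Path, fmt: str | None = None,
                   subject_id: str | None = None, task: str | None = None,
                   script: TaskScript | None = None,
                   expected_fs: float | None = None) -> Recording:
    """Read one recording from CSV or EDF.

    Channels are reordered to montage order; a file missing montage
    channels is rejected naming the absentees. If ``expected_fs`` is
    given, a sampling-rate mismatch is a hard error — no silent
    resampling.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
        missing = [c for c in CHANNELS if c not in df.columns]
        if missing:
            raise ValueError(f"missing channel(s) in {path.name}: {', '.join(missing)}")
        if "time_s" in df.columns and len(df) > 1:
            t = df["time_s"].to_numpy()
            fs = (len(t) - 1) / float(t[-1] - t[0])
            if abs(fs - round(fs)) < 1e-3:  # absorb printed-precision error
                fs = float(round(fs))
        elif expected_fs is not None:
            fs = expected_fs
        else:
            raise ValueError("CSV has no time_s column and no expected_fs given")
        data = df[list(CHANNELS)].to_numpy().T
    elif fmt == "edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        missing = [c for c in CHANNELS if c not in raw.ch_names]
        if missing:
            raise ValueError(f"missing channel(s) in {path.name}: {', '.join(missing)}")
        fs = float(raw.info["sfreq"])
        data = np.stack([raw.get_data(picks=[c])[0] for c in CHANNELS])
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'edf'")

    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        raise ValueError(
            f"sampling rate {fs} in {path.name} does not match expected "
            f"{expected_fs}; refusing to resample"
        )
    if task is None or subject_id is None:
        # conventional file name: <subject>_<task>.<ext>
        stem_parts = path.stem.split("_")
        subject_id = subject_id or stem_parts[0]
        task = task or (stem_parts[1] if len(stem_parts) > 1 else "unknown")
    if script is None:
        try:
            script = script_for(task)
        except ValueError:
            script = None
        if script is not None and \
                abs(data.shape[1] - fs * script.total_duration) > 0.5:
            script = None
        if script is None:
            script = TaskScript(task, (("all", data.shape[1] / fs),))
    return Recording(subject_id=subject_id, task=task, fs=fs, data=data,
                     channel_names=CHANNELS, script=script)
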