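"""Trajectory and manifest file I/O.

On-disk layout:

* trajectory CSV: header ``t,x,y`` (``t`` optional, seconds), comma
  separated, '.' decimal, UTF-8;
* manifest CSV: one row per sample with columns
  ``file,label,subject_id,trial_index``; ``file`` is resolved relative to
  the manifest's directory.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import DatasetBundle, Provenance, Sample, Trajectory

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "load_manifest",
    "save_bundle",
]

PathLike = Union[str, Path]


class TrajectoryFormatError(ValueError):
    """A trajectory or manifest file violates the expected format."""


def read_trajectory_csv(path: PathLike) -> Trajectory:
    """Read a trajectory from a ``t,x,y`` / ``x,y`` CSV file.

    When a ``t`` column is present and uniformly spaced, the sampling rate
    is inferred as the reciprocal of the median spacing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TrajectoryFormatError(f"{path}: empty trajectory file") from None
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise TrajectoryFormatError(
            f"{path}: missing required column(s) {sorted(missing)}")
    if len(df) == 0:
        raise TrajectoryFormatError(f"{path}: no data rows")
    for col in ("x", "y") + (("t",) if "t" in df.columns else ()):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # 1-based + header
            raise TrajectoryFormatError(
                f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = numeric

    sampling_rate = None
    if "t" in df.columns and len(df) >= 2:
        dt = np.diff(df["t"].to_numpy())
        if np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            sampling_rate = 1.0 / float(np.median(dt))
    points = df[["x", "y"]].to_numpy(dtype=float)
    return Trajectory(points=points, sampling_rate=sampling_rate)


def write_trajectory_csv(traj: Trajectory, path: PathLike) -> None:
    """Write a trajectory as CSV, preserving full float precision.

    A ``t`` column is emitted only when the trajectory has a sampling rate.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if traj.sampling_rate is not None:
            writer.writerow(["t", "x", "y"])
            dt = 1.0 / traj.sampling_rate
            for i, (x, y) in enumerate(traj.points):
                writer.writerow([repr(i * dt), repr(float(x)), repr(float(y))])
        else:
            writer.writerow(["x", "y"])
            for x, y in traj.points:
                writer.writerow([repr(float(x)), repr(float(y))])


def load_manifest(path: PathLike, name: str | None = None) -> DatasetBundle:
    """Load a dataset bundle from a manifest CSV.

    Every referenced trajectory file must exist and every
    ``(subject_id, label, trial_index)`` key must be unique.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"label": str, "subject_id": str})
    except pd.errors.EmptyDataError:
        raise TrajectoryFormatError(f"{path}: empty manifest") from None
    required = {"file", "label", "subject_id", "trial_index"}
    missing = required - set(df.columns)
    if missing:
        raise TrajectoryFormatError(
            f"{path}: manifest missing column(s) {sorted(missing)}")

    # optional 5th column written by save_bundle for augmented sets
    prov_col = df["provenance"] if "provenance" in df.columns else ["raw"] * len(df)
    keys = list(zip(df["subject_id"], df["label"], df["trial_index"], prov_col))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise TrajectoryFormatError(
            f"{path}: duplicate (subject, label, trial) key(s): {dupes[:5]}")

    base = path.parent
    samples = []
    for row, prov in zip(df.itertuples(index=False), prov_col):
        traj_path = base / str(row.file)
        if not traj_path.exists():
            raise TrajectoryFormatError(
                f"{path}: referenced trajectory file not found: {traj_path}")
        traj = read_trajectory_csv(traj_path)
        samples.append(Sample(trajectory=traj, label=str(row.label),
                              subject_id=str(row.subject_id),
                              trial_index=int(row.trial_index),
                              provenance=Provenance(str(prov))))
    return DatasetBundle(samples=samples, name=name or path.stem)


def save_bundle(bundle: DatasetBundle, out_dir: PathLike,
                manifest_name: str = "manifest.csv") -> Path:
    """Write every trajectory of a bundle as CSV plus a manifest.

    Returns the manifest path.  File names encode subject, label and trial
    so the directory is diff-friendly and self-describing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    any_augmented = any(s.provenance is not Provenance.RAW for s in bundle.samples)
    rows = []
    used: set[str] = set()
    for s in bundle.samples:
        stem = f"{s.subject_id}_{s.label}_{s.trial_index}_{s.provenance.value}"
        fname, k = f"{stem}.csv", 0
        while fname in used:  # augmented copies can share all key fields
            k += 1
            fname = f"{stem}_{k}.csv"
        used.add(fname)
        write_trajectory_csv(s.trajectory, out_dir / fname)
        row = {"file": fname, "label": s.label,
               "subject_id": s.subject_id, "trial_index": s.trial_index}
        if any_augmented:
            row["provenance"] = s.provenance.value
        rows.append(row)
    manifest = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
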