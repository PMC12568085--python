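"""Core domain types for eye-writing recognition.

An eye-writing sample is a variable-length sequence of gaze coordinates
(x, y) traced while the user "writes" a character-shaped pattern with eye
movements.  These types carry the bookkeeping that the rest of the package
relies on: who wrote the sample (for user-independent evaluation), which
pattern it is (the class label), and whether it is an original recording or
an augmented copy (augmented data must never leak into a test fold).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "Provenance",
    "Sample",
    "DatasetBundle",
    "SubjectSplit",
    "loso_splits",
]


class Provenance(str, enum.Enum):
    """Whether a sample is an original recording or an augmented copy."""

    RAW = "raw"
    AUGMENTED = "augmented"


@dataclass(frozen=True)
class Trajectory:
    """An ordered 2-D point sequence: the raw eye-movement signal.

    Parameters
    ----------
    points
        Array of shape ``(N, 2)``; column 0 is x, column 1 is y, row index
        is time (0-based).  Position units are arbitrary (screen pixels,
        EOG amplitude, ...).
    sampling_rate
        Sampling rate in Hz, or ``None`` when unknown (e.g. webcam capture
        without timestamps).
    """

    points: np.ndarray
    sampling_rate: Optional[float] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must have shape (N, 2), got {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("a trajectory needs at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("trajectory coordinates must be finite")
        if self.sampling_rate is not None and not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        """Number of samples N (the signal length L)."""
        return int(self.points.shape[0])

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def with_points(self, points: np.ndarray) -> "Trajectory":
        """A copy of this trajectory with new coordinates."""
        return Trajectory(points=np.asarray(points, dtype=float),
                          sampling_rate=self.sampling_rate)


@dataclass(frozen=True)
class Sample:
    """A trajectory plus the labels that make it a classification example."""

    trajectory: Trajectory
    label: str
    subject_id: str
    trial_index: int = 0
    provenance: Provenance = Provenance.RAW

    def __post_init__(self) -> None:
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")

    def with_trajectory(self, traj: Trajectory, *,
                        provenance: Optional[Provenance] = None) -> "Sample":
        prov = self.provenance if provenance is None else provenance
        return replace(self, trajectory=traj, provenance=prov)


@dataclass
class DatasetBundle:
    """A named collection of samples with an explicit ordered class set.

    The class set is the lexicographically sorted set of labels, fixing the
    logit ordering without hidden state.
    """

    samples: list[Sample]
    class_set: list[str] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        if not self.class_set:
            self.class_set = sorted({s.label for s in self.samples})
        if len(self.class_set) < 2:
            raise ValueError("a dataset needs at least 2 classes")
        missing = {s.label for s in self.samples} - set(self.class_set)
        if missing:
            raise ValueError(f"labels outside the declared class set: {sorted(missing)}")
        if len(self.subject_ids) < 2:
            raise ValueError("a dataset needs at least 2 distinct subjects "
                             "(leave-one-subject-out requires >= 2)")

    @property
    def subject_ids(self) -> list[str]:
        """Distinct subject ids, sorted."""
        return sorted({s.subject_id for s in self.samples})

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class SubjectSplit:
    """One leave-one-subject-out fold: held-out subject vs everyone else."""

    test_subject: str
    train: list[Sample]
    test: list[Sample]

    def __post_init__(self) -> None:
        if any(s.subject_id == self.test_subject for s in self.train):
            raise ValueError("train fold contains the held-out subject")
        if any(s.subject_id != self.test_subject for s in self.test):
            raise ValueError("test fold contains other subjects")
        if any(s.provenance is Provenance.AUGMENTED for s in self.test):
            raise ValueError("augmented samples must never appear in a test fold")


def loso_splits(bundle: DatasetBundle) -> list[SubjectSplit]:
    """Build all leave-one-subject-out splits of a bundle.

    One split per distinct subject, ordered by subject id.  Each split
    tests on exactly that subject's samples and trains on all others, so
    evaluation is strictly user-independent.
    """
    subjects = bundle.subject_ids
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    splits = []
    for subject in subjects:
        train = [s for s in bundle.samples if s.subject_id != subject]
        test = [s for s in bundle.samples if s.subject_id == subject]
        splits.append(SubjectSplit(test_subject=subject, train=train, test=test))
    return splits
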