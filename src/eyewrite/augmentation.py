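"""Training-set augmentation: segmental scaling distortion and window warping.

Both techniques operate on raw trajectories, before any preprocessing, and
only ever on training data — augmented copies are tagged so that split
construction can refuse them in test folds.

*Distortion* draws fresh per-axis scale factors from N(mu, sigma^2) at
segment boundaries spaced ``gap`` samples apart and multiplies them into
every point from the boundary onward, so the factors compound along the
sequence.  It emulates within-pattern variations of writing amplitude and
drift of gain.

*Window warping* picks a random contiguous window covering a fraction
``r`` of the sequence, stretches or compresses its time axis by a factor
``s`` drawn from a small set (e.g. {0.25, 4.0}), then rescales the whole
sequence back to its original length.  It emulates local speed changes of
the writer's eye movements.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import Provenance, Sample, Trajectory

__all__ = [
    "DistortionConfig",
    "WarpConfig",
    "distort",
    "window_warp",
    "augment_training_set",
    "DISTORTION_I",
    "DISTORTION_II",
    "DEFAULT_WARP",
]

_SCALE_FLOOR = 0.01  # negative draws would mirror the pattern; clip instead


@dataclass(frozen=True)
class DistortionConfig:
    """Parameters of the segmental scaling distortion."""

    mean: float = 1.0
    variance: float = 0.1
    gap: int = 32
    mode: Literal["compound", "per_segment"] = "compound"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.gap < 1:
            raise ValueError("gap must be >= 1")


@dataclass(frozen=True)
class WarpConfig:
    """Parameters of window warping."""

    window_ratio: float = 0.3
    scale_choices: tuple[float, ...] = (0.25, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.window_ratio <= 1:
            raise ValueError("window_ratio must lie in (0, 1]")
        if not self.scale_choices or any(s <= 0 for s in self.scale_choices):
            raise ValueError("every scale choice must be > 0")


# presets matching the two distortion variants used for training
DISTORTION_I = DistortionConfig(mean=1.0, variance=0.1)
DISTORTION_II = DistortionConfig(mean=1.01, variance=0.01)
DEFAULT_WARP = WarpConfig()


def distort(traj: Trajectory, cfg: DistortionConfig,
            rng: np.random.Generator | None = None) -> Trajectory:
    """Apply segmental scaling distortion to a trajectory.

    Boundaries sit at i = 0, gap, 2*gap, ... while i < N (one per
    segment).  In ``compound`` mode each boundary's fresh (s_x, s_y) pair
    multiplies all coordinates from that boundary to the end, so factors
    accumulate; in ``per_segment`` mode each pair applies only within its
    own segment.  With sigma^2 = 0 and mu = 1 the map is the identity.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pts = traj.points.copy()
    n = pts.shape[0]
    sd = np.sqrt(cfg.variance)
    for start in range(0, n, cfg.gap):
        sx, sy = rng.normal(cfg.mean, sd, size=2)
        sx = max(sx, _SCALE_FLOOR)
        sy = max(sy, _SCALE_FLOOR)
        stop = n if cfg.mode == "compound" else min(start + cfg.gap, n)
        pts[start:stop, 0] *= sx
        pts[start:stop, 1] *= sy
    return traj.with_points(pts)


def _resample_linear(seg: np.ndarray, m: int) -> np.ndarray:
    """Linearly interpolate a (n, 2) segment onto m evenly spaced samples."""
    n = seg.shape[0]
    if m == n:
        return seg.copy()
    pos = np.linspace(0.0, n - 1.0, m)
    return np.column_stack([np.interp(pos, np.arange(n), seg[:, c])
                            for c in range(seg.shape[1])])


def window_warp(traj: Trajectory, cfg: WarpConfig,
                rng: np.random.Generator | None = None) -> Trajectory:
    """Warp the time axis of a random window, then restore the length.

    A window of ceil(N*r) samples at a uniform-random start is linearly
    interpolated to ceil(N*r*s) samples with s drawn uniformly from
    ``scale_choices``; the warped window is concatenated with the
    untouched flanks and the whole sequence is linearly rescaled back to
    N samples.  s = 1 therefore gives the identity.
    """
    n = traj.n
    if n < 4:
        raise ValueError("window warping needs at least 4 samples")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    w = int(np.ceil(n * cfg.window_ratio))
    w = min(max(w, 2), n)
    start = int(rng.integers(0, n - w + 1))
    choices = list(cfg.scale_choices)
    rng.shuffle(choices)
    for s in choices:
        warped_len = int(np.ceil(w * s))
        if warped_len >= 2:
            break
    else:
        raise ValueError(
            f"every scale in {cfg.scale_choices} collapses the {w}-sample "
            "window below 2 samples")
    window = _resample_linear(traj.points[start:start + w], warped_len)
    stitched = np.vstack([traj.points[:start], window,
                          traj.points[start + w:]])
    return traj.with_points(_resample_linear(stitched, n))


def _sample_stream(master_seed: int, sample: Sample, technique: str
                   ) -> np.random.Generator:
    """Per-sample RNG derived by stable hashing, so results do not depend
    on processing order."""
    key = f"{sample.subject_id}|{sample.label}|{sample.trial_index}|{technique}"
    digest = hashlib.sha256(key.encode()).digest()
    child = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([master_seed, child]))


def augment_training_set(train: Sequence[Sample],
                         distortion1: DistortionConfig = DISTORTION_I,
                         distortion2: DistortionConfig = DISTORTION_II,
                         warp: WarpConfig = DEFAULT_WARP,
                         seed: int = 0) -> list[Sample]:
    """Expand a training fold: originals plus one copy per technique (4x).

    Each original contributes one distortion-I copy, one distortion-II
    copy and one window-warp copy, all tagged ``augmented`` and inheriting
    label/subject/trial.  Refuses already-augmented input so augmentation
    cannot be applied twice.
    """
    out: list[Sample] = []
    for s in train:
        if s.provenance is not Provenance.AUGMENTED:
            continue
        raise ValueError("augment_training_set expects raw samples only "
                         f"(got an augmented sample for subject {s.subject_id})")
    for s in train:
        out.append(s)
        for technique, fn, cfg in (
                ("distortion1", distort, distortion1),
                ("distortion2", distort, distortion2),
                ("window_warp", window_warp, warp)):
            rng = _sample_stream(seed, s, technique)
            traj = fn(s.trajectory, cfg, rng=rng)
            out.append(s.with_trajectory(traj, provenance=Provenance.AUGMENTED))
    return out
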