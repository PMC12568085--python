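"""Seeded synthetic eye-writing dataset generator.

Real eye-writing corpora are collected by having subjects trace
character-shaped patterns with their eyes while gaze (or EOG) coordinates
are recorded.  This module emulates the statistical structure of such
recordings so that every pipeline stage — filtering, length
normalization, augmentation, the classifier, and the LOSO harness — can
be exercised without downloading anything:

* class structure: 10 single-stroke numeral-like patterns or 12
  Katakana-style strokes, each an idealised polyline in the unit square;
* per-subject variability: a subject-specific affine (position offset and
  axis scaling) plus per-segment speed jitter, mimicking how writing
  position, size and pace differ between users;
* recording-length variability: durations drawn uniformly from a wide
  range (default 1.69-23.51 s), so sample lengths vary by an order of
  magnitude;
* sensor artifacts: i.i.d. Gaussian fixation noise and, for EOG-style
  configurations, sporadic large spikes that the median filter is meant
  to remove.

The polyline geometry is package-defined, not a reproduction of any
published glyph set; it only needs to give the classes the same kind of
mutual distinctness that real patterns have.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import DatasetBundle, Provenance, Sample, Trajectory

__all__ = [
    "GeneratorConfig",
    "PatternTemplate",
    "SubjectParams",
    "builtin_templates",
    "generate_sample",
    "generate_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and noise parameters of the generator.

    Defaults emulate the webcam-style protocol: 19 subjects x 10 numeral
    patterns x 5 repetitions at 30 Hz, clean signals (no spikes), with
    recording durations spanning 1.69-23.51 s.
    """

    n_subjects: int = 19
    patterns: Literal["digits10", "katakana12"] = "digits10"
    trials_per_pattern: int = 5
    sampling_rate_hz: float = 30.0
    duration_range_s: tuple[float, float] = (1.69, 23.51)
    noise_sd: float = 0.01
    spike_prob: float = 0.0
    spike_scale: float = 1.0
    subject_offset_sd: float = 0.15
    subject_scale_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.trials_per_pattern < 1:
            raise ValueError("trials_per_pattern must be >= 1")
        lo, hi = self.duration_range_s
        if not 0 < lo <= hi:
            raise ValueError("duration range must satisfy 0 < min <= max")
        if not 0 <= self.spike_prob <= 0.05:
            raise ValueError("spike_prob must lie in [0, 0.05]")

    @classmethod
    def eog_style(cls, **overrides) -> "GeneratorConfig":
        """EOG-like recordings: higher rate, offset, noise and spikes."""
        defaults = dict(n_subjects=6, patterns="katakana12",
                        trials_per_pattern=10, sampling_rate_hz=125.0,
                        noise_sd=0.02, spike_prob=0.01, spike_scale=2.0,
                        subject_offset_sd=0.5)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class PatternTemplate:
    """An idealised single-stroke pattern: a polyline in the unit square."""

    label: str
    polyline: np.ndarray  # (V, 2)

    def __post_init__(self) -> None:
        poly = np.asarray(self.polyline, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
            raise ValueError("polyline needs at least 2 (x, y) vertices")
        if np.any(np.all(np.diff(poly, axis=0) == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        if poly.min() < 0 or poly.max() > 1:
            raise ValueError("polyline must lie in the unit square")
        object.__setattr__(self, "polyline", poly)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject affine writing style."""

    offset: tuple[float, float]
    scale: tuple[float, float]


_DIGITS = {
    "0": [(0.5, 1), (0, 0.5), (0.5, 0), (1, 0.5), (0.5, 1)],
    "1": [(0.35, 0.8), (0.55, 1), (0.55, 0)],
    "2": [(0, 0.8), (0.5, 1), (1, 0.8), (0, 0), (1, 0)],
    "3": [(0, 1), (1, 1), (0.4, 0.55), (1, 0.3), (0.4, 0), (0, 0.1)],
    "4": [(0.7, 1), (0, 0.3), (1, 0.3), (0.7, 0.55), (0.7, 0)],
    "5": [(1, 1), (0, 1), (0, 0.55), (0.8, 0.55), (1, 0.3), (0.8, 0), (0, 0)],
    "6": [(0.9, 1), (0.1, 0.45), (0.1, 0.1), (0.9, 0.1), (0.9, 0.45), (0.1, 0.45)],
    "7": [(0, 1), (1, 1), (0.35, 0)],
    "8": [(0.5, 0.5), (0.1, 0.75), (0.5, 1), (0.9, 0.75), (0.5, 0.5),
          (0.1, 0.25), (0.5, 0), (0.9, 0.25), (0.5, 0.5)],
    "9": [(0.9, 0.6), (0.1, 0.9), (0.1, 1), (0.9, 1), (0.9, 0.6), (0.9, 0)],
}

# 12 rectilinear Katakana-style strokes; "k00" is the
# left-up-right-down-left stroke.
_KATAKANA = {
    "k00": [(1, 0.7), (0, 0.7), (0, 1), (1, 1), (1, 0.2), (0, 0.2)],
    "k01": [(0, 1), (1, 1)],
    "k02": [(0.5, 1), (0.5, 0)],
    "k03": [(0, 1), (1, 0)],
    "k04": [(1, 1), (0, 0)],
    "k05": [(0, 1), (1, 1), (1, 0)],
    "k06": [(0, 0), (0, 1), (1, 1)],
    "k07": [(1, 1), (0, 1), (0, 0), (1, 0)],
    "k08": [(0, 1), (1, 1), (1, 0), (0, 0)],
    "k09": [(0, 1), (0.5, 0), (1, 1)],
    "k10": [(0, 0.5), (1, 0.5), (0.5, 1), (0.5, 0)],
    "k11": [(0, 1), (1, 1), (0, 0.5), (1, 0.5), (0, 0), (1, 0)],
}


def builtin_templates(patterns: str) -> list[PatternTemplate]:
    """The built-in pattern sets: 10 numeral-like or 12 Katakana-style."""
    if patterns == "digits10":
        table = _DIGITS
    elif patterns == "katakana12":
        table = _KATAKANA
    else:
        raise ValueError(f"unknown pattern set {patterns!r}")
    return [PatternTemplate(label=k, polyline=np.array(v, dtype=float))
            for k, v in sorted(table.items())]


def _trace_polyline(poly: np.ndarray, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Sample n points along a polyline at roughly constant speed.

    Each segment's traversal time is proportional to its length times a
    smooth per-segment jitter factor, emulating uneven writing pace.
    """
    seg = np.diff(poly, axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    jitter = rng.uniform(0.7, 1.3, size=lengths.size)
    times = np.concatenate([[0.0], np.cumsum(lengths * jitter)])
    times /= times[-1]
    t = np.linspace(0.0, 1.0, n)
    if n > 2 * times.size:
        # snap the nearest grid instant to each vertex time so corner
        # points are sampled exactly, not straddled
        for tv in times[1:-1]:
            t[int(np.argmin(np.abs(t - tv)))] = tv
        t.sort()
    x = np.interp(t, times, poly[:, 0])
    y = np.interp(t, times, poly[:, 1])
    return np.column_stack([x, y])


def generate_sample(template: PatternTemplate, subject: SubjectParams,
                    cfg: GeneratorConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """One synthetic recording of a subject tracing a pattern.

    Returns the (N, 2) coordinate array; N is set by a random duration
    within ``cfg.duration_range_s`` at the configured sampling rate.
    """
    lo, hi = cfg.duration_range_s
    duration = rng.uniform(lo, hi)
    n = max(2, int(round(duration * cfg.sampling_rate_hz)))
    pts = _trace_polyline(template.polyline, n, rng)
    pts = pts * np.asarray(subject.scale) + np.asarray(subject.offset)
    if cfg.noise_sd > 0:
        pts = pts + rng.normal(0.0, cfg.noise_sd, size=pts.shape)
    if cfg.spike_prob > 0:
        hits = rng.random(n) < cfg.spike_prob
        if hits.any():
            direction = rng.normal(size=(int(hits.sum()), 2))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            magnitude = rng.uniform(0.5, 1.5, size=(int(hits.sum()), 1))
            pts[hits] += cfg.spike_scale * magnitude * direction
    return pts


def generate_dataset(cfg: GeneratorConfig) -> DatasetBundle:
    """A balanced bundle: n_subjects x patterns x trials_per_pattern.

    Fully deterministic under ``cfg.seed``; every (subject, label) cell
    holds exactly ``trials_per_pattern`` samples.
    """
    templates = builtin_templates(cfg.patterns)
    samples: list[Sample] = []
    for si in range(cfg.n_subjects):
        subject_id = f"S{si + 1:02d}"
        srng = np.random.default_rng(np.random.SeedSequence(
            entropy=cfg.seed, spawn_key=(si,)))
        subject = SubjectParams(
            offset=tuple(srng.normal(0.0, cfg.subject_offset_sd, size=2)),
            scale=tuple(srng.normal(1.0, cfg.subject_scale_sd, size=2)))
        for pi, template in enumerate(templates):
            for trial in range(cfg.trials_per_pattern):
                rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=cfg.seed, spawn_key=(si, pi, trial)))
                pts = generate_sample(template, subject, cfg, rng)
                traj = Trajectory(points=pts,
                                  sampling_rate=cfg.sampling_rate_hz)
                samples.append(Sample(trajectory=traj, label=template.label,
                                      subject_id=subject_id,
                                      trial_index=trial,
                                      provenance=Provenance.RAW))
    name = f"synthetic-{cfg.patterns}-{cfg.n_subjects}x{cfg.trials_per_pattern}"
    return DatasetBundle(samples=samples, name=name)
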