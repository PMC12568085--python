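"""Fourier-domain length normalization and initial-point normalization.

Eye-writing recordings vary widely in duration (seconds to tens of
seconds), while convolutional models want a fixed input length M.  Rather
than time-domain resampling, the signal is taken to the frequency domain,
its spectrum is truncated (L > M) or zero-padded (L < M), and the inverse
transform of length M is taken.  Truncation keeps the M lowest-frequency
bins, which simultaneously resamples and denoises: high-frequency jitter
is discarded while the written shape, carried by the low-frequency
content, survives.

Initial-point normalization then translates the trajectory so that it
starts at the origin, removing absolute-position variability between
users and trials.

A naive zero-padding baseline (append (0,0) points up to a fixed length,
no spectral processing) is also provided for ablation comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .core import Sample, Trajectory
from .filtering import FilterConfig, apply_filter_chain

__all__ = [
    "NormalizationConfig",
    "dft",
    "truncate_spectrum",
    "pad_spectrum",
    "normalize_length",
    "initial_point_normalize",
    "zero_pad_baseline",
    "preprocess",
]


@dataclass(frozen=True)
class NormalizationConfig:
    """Length-normalization settings.

    ``target_length`` is M, the fixed model input length (default 64).
    ``amplitude_mode='preserve'`` rescales by M/L so that amplitude is
    independent of the original length L (a constant channel c maps to the
    constant c for any L); ``'literal'`` keeps the bare 1/M inverse
    transform, whose amplitude scales with L/M.
    ``baseline_pad_length``, when set, switches the whole preprocessing
    path to the naive zero-padding baseline.
    ``truncation_convention='lowpass'`` keeps the lowest-frequency bins of
    the standard-order spectrum; ``'centered_literal'`` applies the
    centered block selection X[(k + ceil((L-M)/2)) mod L], which assumes a
    zero-centered spectrum ordering.
    """

    target_length: int = 64
    amplitude_mode: Literal["preserve", "literal"] = "preserve"
    baseline_pad_length: Optional[int] = None
    apply_initial_point: bool = True
    truncation_convention: Literal["lowpass", "centered_literal"] = "lowpass"

    def __post_init__(self) -> None:
        if self.target_length < 2:
            raise ValueError("target_length must be >= 2")
        if self.baseline_pad_length is not None and self.baseline_pad_length < 1:
            raise ValueError("baseline_pad_length must be >= 1")


def dft(x: np.ndarray) -> np.ndarray:
    """Discrete Fourier transform X(k) = sum_n x(n) exp(-j 2 pi k n / L).

    For real input the spectrum is Hermitian-symmetric:
    X(L-k) = conj(X(k)).
    """
    x = np.asarray(x)
    if x.shape[-1] < 1:
        raise ValueError("cannot transform an empty signal")
    return np.fft.fft(x)


def truncate_spectrum(X: np.ndarray, M: int,
                      convention: str = "lowpass") -> np.ndarray:
    """Shorten a length-L spectrum to M bins, keeping low frequencies.

    In the default ``lowpass`` convention the retained bins are
    Xd(k) = X(k) for 0 <= k < ceil(M/2) and Xd(k) = X(k + L - M) for
    ceil(M/2) <= k < M — the lowest positive and negative frequencies in
    standard DFT order, and the exact inverse of :func:`pad_spectrum`'s
    bin placement.
    """
    X = np.asarray(X)
    L = X.shape[-1]
    if M < 1:
        raise ValueError("target length must be >= 1")
    if M >= L:
        raise ValueError(f"truncation requires M < L (got M={M}, L={L}); "
                         "use pad_spectrum to extend")
    k = np.arange(M)
    if convention == "lowpass":
        src = np.where(k < -(-M // 2), k, k + L - M)
    elif convention == "centered_literal":
        src = (k + (L - M + 1) // 2) % L
    else:
        raise ValueError(f"unknown truncation convention {convention!r}")
    return X[..., src]


def pad_spectrum(X: np.ndarray, M: int) -> np.ndarray:
    """Extend a length-L spectrum to M bins by symmetric zero-padding.

    Xd(k) = X(k) for k < ceil(L/2), zero in the middle, and
    X(k - (M - L)) for k >= M - floor(L/2), i.e. the low positive and
    negative frequencies keep their standard-order positions.
    """
    X = np.asarray(X)
    L = X.shape[-1]
    if M <= L:
        raise ValueError(f"padding requires M > L (got M={M}, L={L}); "
                         "use truncate_spectrum to shorten")
    head = -(-L // 2)  # ceil(L/2)
    tail = L // 2
    Xd = np.zeros(X.shape[:-1] + (M,), dtype=complex)
    Xd[..., :head] = X[..., :head]
    if tail:
        Xd[..., M - tail:] = X[..., L - tail:]
    return Xd


def normalize_length(traj: Trajectory, cfg: NormalizationConfig) -> Trajectory:
    """Resample a trajectory to exactly ``cfg.target_length`` samples.

    Per channel: forward DFT, spectrum truncation or zero-padding to M,
    inverse DFT of length M (1/M convention), real part.  In ``preserve``
    mode the result is additionally scaled by M/L so amplitude does not
    depend on the original length.  M = L returns the input unchanged (to
    numerical precision).
    """
    L = traj.n
    M = cfg.target_length
    if L < 2:
        raise ValueError("length normalization needs at least 2 samples")
    channels = traj.points.T  # (2, L)
    if M == L:
        out = channels.astype(float)
    else:
        X = dft(channels)
        if M < L:
            Xd = truncate_spectrum(X, M, cfg.truncation_convention)
        else:
            Xd = pad_spectrum(X, M)
        out = np.fft.ifft(Xd).real
        if cfg.amplitude_mode == "preserve":
            out = out * (M / L)
    return Trajectory(points=out.T, sampling_rate=None)


def initial_point_normalize(traj: Trajectory) -> Trajectory:
    """Translate a trajectory so its first point is exactly the origin.

    All displacement vectors between points are unchanged; applying the
    operation twice equals applying it once.
    """
    return traj.with_points(traj.points - traj.points[0])


def zero_pad_baseline(traj: Trajectory, pad_length: int) -> Trajectory:
    """Append (0, 0) points up to ``pad_length`` samples, never truncating."""
    if traj.n > pad_length:
        raise ValueError(
            f"trajectory of length {traj.n} exceeds the baseline pad length "
            f"{pad_length}; the baseline pads without truncation")
    if traj.n == pad_length:
        return traj
    pad = np.zeros((pad_length - traj.n, 2))
    return Trajectory(points=np.vstack([traj.points, pad]),
                      sampling_rate=traj.sampling_rate)


def preprocess(sample: Sample, filter_cfg: FilterConfig,
               norm_cfg: NormalizationConfig) -> Sample:
    """Full preprocessing of one sample; metadata is untouched.

    The standard path runs filter chain -> DFT length normalization ->
    initial-point normalization.  When ``baseline_pad_length`` is set the
    spectral and initial-point steps are replaced by naive zero-padding
    (the ablation baseline); the filter chain still applies.
    """
    traj = apply_filter_chain(sample.trajectory, filter_cfg)
    if norm_cfg.baseline_pad_length is not None:
        traj = zero_pad_baseline(traj, norm_cfg.baseline_pad_length)
    else:
        traj = normalize_length(traj, norm_cfg)
        if norm_cfg.apply_initial_point:
            traj = initial_point_normalize(traj)
    return sample.with_trajectory(traj)
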