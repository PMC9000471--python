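"""Bulk mixing time from dual-indicator (DISMT) video.

A pH-driven red→yellow color change is recorded; spatial homogeneity is
tracked through the population standard deviation σ_G of the normalized
green channel G/(R+G+B) over a rectangular mask.  The mixing time t₉₅%
is the earliest time at which σ_G stays within 5% of its fully mixed
asymptote (estimated from the final frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "FrameSequence",
    "MaskRegion",
    "MixingTrace",
    "MixingTimeResult",
    "default_mask",
    "normalize_green",
    "sigma_trace",
    "fully_mixed_baseline",
    "mixing_time_t95",
]


class FrameSequence:
    """Ordered RGB frames with a frame rate.

    Frames may be held in memory (``FrameSequence(frames, fps)``), built
    on demand from a per-index callable (:meth:`from_callable`, used by
    the synthetic generator so long videos never materialize), or read
    from a directory of images in lexicographic filename order
    (:meth:`from_directory`; the frame rate must be given explicitly —
    container metadata is not trusted).
    """

    def __init__(self, frames: Sequence[np.ndarray], frame_rate: float):
        if frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        frames = list(frames)
        if not frames:
            raise ValueError("empty frame sequence")
        shape = frames[0].shape
        for f in frames:
            if f.shape != shape:
                raise ValueError("all frames must share one shape")
        self._frames: Sequence[np.ndarray] | None = frames
        self._builder: Callable[[int], np.ndarray] | None = None
        self._n = len(frames)
        self.frame_rate = float(frame_rate)
        self.frame_shape = shape

    @classmethod
    def from_callable(
        cls,
        builder: Callable[[int], np.ndarray],
        n_frames: int,
        frame_rate: float,
    ) -> "FrameSequence":
        if n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        obj = cls.__new__(cls)
        if frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        obj._frames = None
        obj._builder = builder
        obj._n = int(n_frames)
        obj.frame_rate = float(frame_rate)
        obj.frame_shape = builder(0).shape
        return obj

    @classmethod
    def from_directory(
        cls,
        path: str | Path,
        frame_rate: float,
        suffixes: tuple[str, ...] = (".png", ".tif", ".tiff"),
    ) -> "FrameSequence":
        import imageio.v3 as iio

        files = sorted(
            p for p in Path(path).iterdir() if p.suffix.lower() in suffixes
        )
        if not files:
            raise FileNotFoundError(f"no image frames under {path}")
        return cls([np.asarray(iio.imread(f)) for f in files], frame_rate)

    def __len__(self) -> int:
        return self._n

    def __getitem__(self, index: int) -> np.ndarray:
        if not 0 <= index < self._n:
            raise IndexError(index)
        if self._frames is not None:
            return self._frames[index]
        assert self._builder is not None
        return self._builder(index)

    def __iter__(self) -> Iterator[np.ndarray]:
        for i in range(self._n):
            yield self[i]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self._n) / self.frame_rate


@dataclass(frozen=True)
class MaskRegion:
    """Half-open rectangular pixel region [row0, row1) × [col0, col1)."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("mask bounds must be non-negative")
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("mask region is empty")

    @property
    def area(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def validate_for(self, frame_shape: tuple[int, ...]) -> None:
        if self.row1 > frame_shape[0] or self.col1 > frame_shape[1]:
            raise ValueError(
                f"mask {self} exceeds frame shape {frame_shape[:2]}"
            )

    def slice(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


def default_mask(frame_shape: tuple[int, ...], area: int = 18000) -> MaskRegion:
    """Centered rectangular mask of exactly ``area`` pixels (default
    18,000, the area used for 1080p DISMT recordings), with aspect ratio
    as close to the frame's as the divisors of ``area`` allow."""
    h, w = frame_shape[0], frame_shape[1]
    if area > h * w:
        raise ValueError(f"mask area {area} exceeds frame ({h}x{w})")
    target = np.sqrt(area * h / w)
    best = None
    for rows in range(1, area + 1):
        if area % rows:
            continue
        cols = area // rows
        if rows <= h and cols <= w:
            score = abs(rows - target)
            if best is None or score < best[0]:
                best = (score, rows, cols)
    if best is None:
        raise ValueError(f"no {area}-px rectangle fits a {h}x{w} frame")
    _, rows, cols = best
    r0 = (h - rows) // 2
    c0 = (w - cols) // 2
    return MaskRegion(r0, r0 + rows, c0, c0 + cols)


@dataclass(frozen=True)
class MixingTrace:
    """σ_G(t): per-frame SD of the normalized green channel."""

    times: np.ndarray
    sigma_g: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.sigma_g, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and sigma_g must be equal-length 1-D")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("sigma_g must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sigma_g", s)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class MixingTimeResult:
    t95: float
    sigma_fully_mixed: float
    converged: bool


def normalize_green(frame: np.ndarray) -> np.ndarray:
    """Per-pixel normalized green G/(R+G+B); zero-intensity pixels map
    to 0.  Invariant to uniform scaling of all channels."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected H×W×3 RGB frame, got shape {frame.shape}")
    frame = frame.astype(np.float64)
    total = frame.sum(axis=2)
    out = np.zeros(frame.shape[:2])
    np.divide(frame[:, :, 1], total, out=out, where=total > 0)
    return out


def sigma_trace(
    seq: FrameSequence,
    mask: MaskRegion | None = None,
) -> MixingTrace:
    """Population SD of normalized green over the mask, per frame."""
    if mask is None:
        mask = default_mask(seq.frame_shape)
    mask.validate_for(seq.frame_shape)
    rs, cs = mask.slice()
    sigma = np.empty(len(seq))
    for i, frame in enumerate(seq):
        g = normalize_green(frame[rs, cs, :])
        sigma[i] = g.std()  # population SD
    return MixingTrace(times=seq.times, sigma_g=sigma)


def fully_mixed_baseline(trace: MixingTrace, n_final: int = 10) -> float:
    """σ∞ estimate: mean σ_G over the final ``n_final`` frames."""
    if n_final < 1:
        raise ValueError("n_final must be >= 1")
    if len(trace) < n_final:
        raise ValueError(
            f"trace of length {len(trace)} shorter than n_final={n_final}"
        )
    return float(trace.sigma_g[-n_final:].mean())


def mixing_time_t95(
    trace: MixingTrace,
    baseline: float | None = None,
    n_final: int = 10,
    criterion: str = "sustained",
) -> MixingTimeResult:
    """Mixing time t₉₅%: earliest time from which σ_G stays within the
    ±5% band around σ∞ (band width 5% of the initial deviation).

    ``criterion="sustained"`` (default) requires the trace to remain in
    the band for the rest of the record, so transient crossings do not
    count as mixed; ``"first"`` takes the first entry.  ``converged`` is
    False when the band is only reached inside the final ``n_final``
    baseline window (or never).
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if criterion not in ("sustained", "first"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if baseline is None:
        baseline = fully_mixed_baseline(trace, n_final)
    band = 0.05 * abs(trace.sigma_g[0] - baseline)
    inside = np.abs(trace.sigma_g - baseline) <= band
    if criterion == "sustained":
        # earliest index from which every later frame is inside the band
        ok = np.logical_and.accumulate(inside[::-1])[::-1]
        hits = np.flatnonzero(ok)
    else:
        hits = np.flatnonzero(inside)
    if hits.size == 0:
        return MixingTimeResult(float("nan"), baseline, False)
    idx = int(hits[0])
    converged = idx <= max(len(trace) - n_final - 1, 0) or idx == 0
    t95 = float(trace.times[idx]) if converged else float("nan")
    return MixingTimeResult(t95, baseline, converged)
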