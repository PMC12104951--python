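"""Frame screening, axial-only registration and averaging of B-scan stacks.

A capture arrives as up to 50 B-scan frames of the same scene.  Low-signal
frames are screened out, the survivors are aligned in the axial direction
only by cross-correlating their laterally averaged depth profiles, and the
aligned frames are averaged into a single B-scan.  Lateral registration is
deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "BScanStack",
    "AveragedBScan",
    "ScreeningPolicy",
    "CaptureFailure",
    "screen_frames",
    "axial_align",
    "average_frames",
    "preprocess_stack",
]


class CaptureFailure(RuntimeError):
    """A capture yields no usable data (e.g. every frame screened out)."""


@dataclass
class BScanStack:
    """Raw multi-frame capture.

    ``frames`` has shape ``(n_frames, n_rows, n_cols)`` with axial index
    z increasing with depth.  Spacings are per-pixel: axial in
    optical-path micrometres, lateral in geometric micrometres.
    """

    frames: np.ndarray
    axial_px_um_optical: float
    lateral_px_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, z, x) array")
        if self.frames.shape[0] > 50:
            raise ValueError("a capture holds at most 50 frames")
        if self.axial_px_um_optical <= 0 or self.lateral_px_um <= 0:
            raise ValueError("pixel spacings must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class AveragedBScan:
    """One averaged B-scan plus the provenance of how it was made.

    ``row_offset`` maps image coordinates back to the reference (first
    kept) frame: row ``z`` of ``image`` is row ``z + row_offset`` of that
    frame.
    """

    image: np.ndarray
    axial_px_um_optical: float
    lateral_px_um: float
    n_frames_used: int
    n_frames_screened_out: int
    shifts_px: np.ndarray
    row_offset: int = 0
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ScreeningPolicy:
    """Keep frames whose signal statistic clears a stack-relative bar.

    The statistic is the 99th-percentile intensity minus the median
    (background) level.  A frame is kept when its statistic reaches
    ``rel_fraction`` of the stack's median statistic and an absolute
    floor; the relative bar is what rejects uniformly attenuated frames,
    whose internal contrast scales down with the signal.
    """

    rel_fraction: float = 0.25
    abs_floor: float = 1e-9
    percentile: float = 99.0


def _signal_statistic(frame: np.ndarray, percentile: float) -> float:
    return float(np.percentile(frame, percentile) - np.median(frame))


def screen_frames(
    stack: BScanStack, policy: ScreeningPolicy | None = None
) -> list[int]:
    """Indices of frames passing the signal screen, in original order."""
    policy = policy or ScreeningPolicy()
    if stack.n_frames == 0:
        raise CaptureFailure("empty stack")
    stats = np.array(
        [_signal_statistic(f, policy.percentile) for f in stack.frames]
    )
    bar = max(policy.abs_floor, policy.rel_fraction * float(np.median(stats)))
    kept = [i for i, s in enumerate(stats) if s >= bar and s > 0]
    if not kept:
        raise CaptureFailure("all frames below the signal threshold")
    return kept


def _profile_shift(profile: np.ndarray, reference: np.ndarray, max_shift: int) -> float:
    """Axial shift of ``profile`` relative to ``reference``.

    Positive means the profile sits deeper than the reference.  The
    cross-correlation of mean-subtracted profiles is evaluated over
    ``[-max_shift, max_shift]`` on the overlapping support and the peak
    refined by a parabolic fit.
    """
    p = profile - profile.mean()
    r = reference - reference.mean()
    if p.std() == 0 or r.std() == 0:
        warnings.warn("flat axial profile: assuming zero shift", stacklevel=3)
        return 0.0
    # circular correlation: exact (and parabola-symmetric) for pure integer
    # shifts; wrap-around is negligible for small jitter on profiles whose
    # ends are flat (air above, bulk stroma below)
    lags = np.arange(-max_shift, max_shift + 1)
    cc = np.array([np.dot(np.roll(p, -k), r) for k in lags])
    i = int(np.argmax(cc))
    return float(lags[i]) + _parabolic_subpeak(cc, i)


def _parabolic_subpeak(y: np.ndarray, i: int) -> float:
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def axial_align(frames: np.ndarray, max_shift: int = 30) -> np.ndarray:
    """Per-frame axial shifts against a running-average reference.

    The first frame seeds the reference (its shift is 0 by construction);
    each subsequent frame is correlated against the running average of
    the already-aligned profiles, which damps reference bias relative to
    aligning everything to one arbitrary frame.  Only the laterally
    averaged axial profile is used, so pure lateral translations cannot
    influence the estimate.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("need a (n_frames, z, x) array with >= 1 frame")
    profiles = frames.mean(axis=2)
    shifts = np.zeros(frames.shape[0])
    reference = profiles[0].copy()
    n_in_ref = 1
    for f in range(1, frames.shape[0]):
        s = _profile_shift(profiles[f], reference, max_shift)
        shifts[f] = s
        aligned = ndimage.shift(profiles[f], -s, order=1, mode="nearest")
        reference = (reference * n_in_ref + aligned) / (n_in_ref + 1)
        n_in_ref += 1
    return shifts


def average_frames(
    frames: np.ndarray,
    shifts: np.ndarray,
    axial_px_um_optical: float = 1.0,
    lateral_px_um: float = 1.0,
    n_frames_screened_out: int = 0,
    metadata: dict | None = None,
) -> AveragedBScan:
    """Shift each frame by minus its estimated shift and average.

    Rows that lack contributions from every frame after shifting are
    cropped, so the average is unbiased everywhere it is reported;
    ``row_offset`` records the top crop.
    """
    frames = np.asarray(frames, dtype=float)
    shifts = np.asarray(shifts, dtype=float)
    if frames.shape[0] != shifts.shape[0]:
        raise ValueError("one shift per frame required")
    aligned = np.empty_like(frames)
    for f in range(frames.shape[0]):
        if shifts[f] == 0.0:
            aligned[f] = frames[f]
        else:
            aligned[f] = ndimage.shift(frames[f], (-shifts[f], 0.0), order=1, mode="nearest")
    applied = -shifts
    top = int(np.ceil(max(0.0, float(applied.max(initial=0.0)))))
    bottom = int(np.ceil(max(0.0, float((-applied).max(initial=0.0)))))
    img = aligned.mean(axis=0)
    if bottom > 0:
        img = img[top : img.shape[0] - bottom]
    elif top > 0:
        img = img[top:]
    return AveragedBScan(
        image=img,
        axial_px_um_optical=axial_px_um_optical,
        lateral_px_um=lateral_px_um,
        n_frames_used=frames.shape[0],
        n_frames_screened_out=n_frames_screened_out,
        shifts_px=shifts,
        row_offset=top,
        metadata=metadata or {},
    )


def preprocess_stack(
    stack: BScanStack, policy: ScreeningPolicy | None = None, max_shift: int = 30
) -> AveragedBScan:
    """Screen, align and average one capture."""
    kept = screen_frames(stack, policy)
    frames = stack.frames[kept]
    shifts = axial_align(frames, max_shift=max_shift)
    return average_frames(
        frames,
        shifts,
        axial_px_um_optical=stack.axial_px_um_optical,
        lateral_px_um=stack.lateral_px_um,
        n_frames_screened_out=stack.n_frames - len(kept),
        metadata=dict(stack.metadata),
    )
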