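"""Geometric layer thicknesses from labelled boundaries.

Optical path lengths measured along the beam are converted to geometric
tissue distances with the corneal group refractive index.  The central
Bowman's-layer thickness (BT) and epithelial thickness (ET) of a capture
are quasi-point values: per-column separations averaged over a 450 um
lateral window centred on the image.  Captures are aggregated per eye
with quality weighting (scores 3/4/5 weigh 1/2/3; scores below 3 are
excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graphseg import SegmentationResult

__all__ = [
    "ThicknessMeasurement",
    "EyeSummary",
    "optical_to_geometric",
    "quasi_point_thickness",
    "aggregate_eye",
    "SCORE_WEIGHTS",
]

#: Quality score -> averaging weight; scores below 3 are excluded.
SCORE_WEIGHTS = {3: 1, 4: 2, 5: 3}


@dataclass
class ThicknessMeasurement:
    """Capture-level quasi-point thicknesses over the central window."""

    bt_um: float
    et_um: float
    window_center_x: int
    window_len_um: float
    local_sd_um: float
    quality_score: int
    weight: int
    excluded: bool
    capture_id: str = ""
    failed: bool = False


@dataclass
class EyeSummary:
    """Per-eye aggregate of capture measurements."""

    eye_id: str
    bt_um: float
    et_um: float
    n_captures_used: int
    mode: str
    failed: bool = False


def optical_to_geometric(d_optical_um: float, n_g: float = 1.387) -> float:
    """Convert an optical path length to geometric tissue distance."""
    if d_optical_um < 0:
        raise ValueError("negative optical distance: ordering violation upstream")
    if n_g <= 1.0:
        if n_g == 1.0:
            return float(d_optical_um)
        raise ValueError("group refractive index must be >= 1")
    return float(d_optical_um) / n_g


def _failed_measurement(capture_id: str) -> ThicknessMeasurement:
    return ThicknessMeasurement(
        bt_um=float("nan"),
        et_um=float("nan"),
        window_center_x=-1,
        window_len_um=450.0,
        local_sd_um=float("nan"),
        quality_score=1,
        weight=0,
        excluded=True,
        capture_id=capture_id,
        failed=True,
    )


def quasi_point_thickness(
    seg: SegmentationResult,
    axial_px_um_optical: float,
    lateral_px_um: float,
    n_g: float = 1.387,
    window_len_um: float = 450.0,
    capture_id: str = "",
) -> ThicknessMeasurement:
    """Mean BT and ET over the centred lateral window, in geometric um.

    Per-column separations of the labelled boundaries are converted
    optical->geometric and averaged across the window; the SD of the
    per-column BT within the window is reported as ``local_sd_um``.
    """
    if seg.failed or not {"epi_bowman", "bowman_stroma"} <= set(seg.paths):
        return _failed_measurement(capture_id)

    eb = seg.paths["epi_bowman"].z
    bs = seg.paths["bowman_stroma"].z
    n_cols = len(eb)
    half_cols = int(round(window_len_um / lateral_px_um / 2))
    center = n_cols // 2
    lo, hi = center - half_cols, center + half_cols
    if lo < 0 or hi > n_cols:
        raise ValueError("quasi-point window exceeds the image width")

    bt_cols = (bs[lo:hi] - eb[lo:hi]) * axial_px_um_optical / n_g
    bt = float(bt_cols.mean())
    if bt <= 0:
        raise ValueError("non-positive thickness: ordering violation upstream")
    local_sd = float(bt_cols.std(ddof=1))

    if "tear_film" in seg.paths:
        tf = seg.paths["tear_film"].z
        et = float(((eb[lo:hi] - tf[lo:hi]) * axial_px_um_optical / n_g).mean())
    else:
        et = float("nan")

    score = int(seg.quality_score)
    weight = SCORE_WEIGHTS.get(score, 0)
    return ThicknessMeasurement(
        bt_um=bt,
        et_um=et,
        window_center_x=center,
        window_len_um=window_len_um,
        local_sd_um=local_sd,
        quality_score=score,
        weight=weight,
        excluded=score < 3,
        capture_id=capture_id,
    )


def aggregate_eye(
    measurements: Sequence[ThicknessMeasurement],
    mode: str = "weighted",
    eye_id: str = "",
) -> EyeSummary:
    """Aggregate a single eye's captures into one BT (and ET).

    ``weighted``: quality-weighted mean over captures scoring >= 3 with
    weights 1/2/3 for scores 3/4/5.  ``best``: the single highest-score
    capture, ties broken by the lowest within-window SD.  An eye whose
    captures are all excluded is a failed eye.
    """
    if not measurements:
        raise ValueError("no measurements to aggregate")
    if mode not in ("weighted", "best"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    usable = [m for m in measurements if not m.excluded and not m.failed]
    if not usable:
        return EyeSummary(
            eye_id=eye_id,
            bt_um=float("nan"),
            et_um=float("nan"),
            n_captures_used=0,
            mode=mode,
            failed=True,
        )
    if mode == "weighted":
        w = np.array([m.weight for m in usable], dtype=float)
        bt = float(np.average([m.bt_um for m in usable], weights=w))
        ets = np.array([m.et_um for m in usable])
        et_ok = ~np.isnan(ets)
        et = float(np.average(ets[et_ok], weights=w[et_ok])) if et_ok.any() else float("nan")
        return EyeSummary(eye_id, bt, et, len(usable), mode)
    best = max(usable, key=lambda m: (m.quality_score, -m.local_sd_um))
    return EyeSummary(eye_id, best.bt_um, best.et_um, 1, mode)
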