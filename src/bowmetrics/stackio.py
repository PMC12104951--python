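"""Readers and writers for the pipeline's on-disk formats.

Stacks travel as multi-page 16-bit grayscale TIFFs with a JSON sidecar
holding pixel spacings, the seed, the intensity scale used for
quantisation and (for synthetic data) the ground-truth interface depths
per column.  Tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import AveragedBScan, BScanStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_averaged",
    "read_averaged",
    "write_json",
    "read_json",
]

UINT16_MAX = 65535


def _quantise(frames: np.ndarray) -> tuple[np.ndarray, float]:
    scale = float(frames.max()) or 1.0
    q = np.clip(frames / scale * UINT16_MAX, 0, UINT16_MAX).astype(np.uint16)
    return q, scale


def write_stack(
    stack: BScanStack, tiff_path: str | Path, ground_truth: dict | None = None
) -> Path:
    """Write a capture as multi-page TIFF + ``<name>.json`` sidecar."""
    tiff_path = Path(tiff_path)
    q, scale = _quantise(stack.frames)
    tifffile.imwrite(tiff_path, q, photometric="minisblack")
    sidecar = {
        "axial_px_um_optical": stack.axial_px_um_optical,
        "lateral_px_um": stack.lateral_px_um,
        "n_frames": stack.n_frames,
        "intensity_scale": scale,
        "metadata": stack.metadata,
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth
    write_json(sidecar, tiff_path.with_suffix(".json"))
    return tiff_path


def read_stack(tiff_path: str | Path) -> tuple[BScanStack, dict]:
    """Read a capture written by :func:`write_stack`; returns (stack, sidecar)."""
    tiff_path = Path(tiff_path)
    sidecar = read_json(tiff_path.with_suffix(".json"))
    frames = tifffile.imread(tiff_path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    frames = frames / UINT16_MAX * sidecar.get("intensity_scale", 1.0)
    stack = BScanStack(
        frames=frames,
        axial_px_um_optical=sidecar["axial_px_um_optical"],
        lateral_px_um=sidecar["lateral_px_um"],
        metadata=sidecar.get("metadata", {}),
    )
    return stack, sidecar


def write_averaged(avg: AveragedBScan, tiff_path: str | Path) -> Path:
    tiff_path = Path(tiff_path)
    q, scale = _quantise(avg.image)
    tifffile.imwrite(tiff_path, q, photometric="minisblack")
    write_json(
        {
            "axial_px_um_optical": avg.axial_px_um_optical,
            "lateral_px_um": avg.lateral_px_um,
            "n_frames_used": avg.n_frames_used,
            "n_frames_screened_out": avg.n_frames_screened_out,
            "shifts_px": np.asarray(avg.shifts_px).tolist(),
            "row_offset": avg.row_offset,
            "intensity_scale": scale,
            "metadata": avg.metadata,
        },
        tiff_path.with_suffix(".json"),
    )
    return tiff_path


def read_averaged(tiff_path: str | Path) -> AveragedBScan:
    tiff_path = Path(tiff_path)
    side = read_json(tiff_path.with_suffix(".json"))
    img = tifffile.imread(tiff_path).astype(float) / UINT16_MAX * side["intensity_scale"]
    return AveragedBScan(
        image=img,
        axial_px_um_optical=side["axial_px_um_optical"],
        lateral_px_um=side["lateral_px_um"],
        n_frames_used=side["n_frames_used"],
        n_frames_screened_out=side["n_frames_screened_out"],
        shifts_px=np.asarray(side["shifts_px"], dtype=float),
        row_offset=side["row_offset"],
        metadata=side.get("metadata", {}),
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path
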