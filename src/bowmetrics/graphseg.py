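"""Graph-search segmentation of corneal interfaces in an averaged B-scan.

Each interface is modelled as a left-to-right path through the image,
one node per column, with a hard smoothness constraint on the axial step
between neighbouring columns.  Minimum-cost paths are found by dynamic
programming over a per-pixel energy map; paths are extracted iteratively
with an exclusion band blocked around each one, and a deterministic
labelling policy assigns the tear-film, epithelium-Bowman and
Bowman-stroma interfaces by depth order, strength and anatomically
plausible separations.  The human supervisor of the original acquisition
protocol is replaced by this policy plus configuration overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import AveragedBScan

__all__ = [
    "EnergyMap",
    "BoundaryPath",
    "SegmentationResult",
    "SegmentationPolicy",
    "build_energy",
    "find_path",
    "segment_interfaces",
    "grade_segmentation",
]

EPS = 1e-3  # floor so flat regions still carry cost

INTERFACE_LABELS = ("tear_film", "epi_bowman", "bowman_stroma")


@dataclass
class EnergyMap:
    """Per-pixel transition cost plus the polarity it encodes.

    Polarities: ``dark_bright`` / ``bright_dark`` penalise the absence of
    a signed vertical intensity step; ``ridge`` penalises the absence of
    a bright line.  Resolution-limited corneal interfaces image as bright
    lines, so the pipeline segments on ``ridge`` energy; the signed-step
    polarities serve edge-type boundaries.
    """

    cost: np.ndarray
    polarity: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.cost)):
            raise ValueError("energy must be finite (blocking is applied separately)")


@dataclass
class BoundaryPath:
    """One interface as per-column subpixel axial positions."""

    z: np.ndarray  # float, len n_cols
    cost: float
    z_int: np.ndarray  # integer DP path the refinement started from
    interface_label: str | None = None
    strength: float = 0.0  # mean image intensity along the path

    def mean_depth(self) -> float:
        return float(self.z.mean())


@dataclass
class SegmentationResult:
    """Labelled interface paths and quality grade for one averaged B-scan."""

    paths: dict[str, BoundaryPath]
    quality_score: int = 0
    failed: bool = False
    flags: list[str] = field(default_factory=list)
    unassigned: list[BoundaryPath] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.failed and len(self.paths) == len(INTERFACE_LABELS):
            tf = self.paths["tear_film"].z
            eb = self.paths["epi_bowman"].z
            bs = self.paths["bowman_stroma"].z
            if not (np.all(tf < eb) and np.all(eb < bs)):
                raise ValueError("interfaces out of depth order")


def build_energy(image: np.ndarray, polarity: str = "ridge") -> EnergyMap:
    """Energy map for boundary search, min-max normalised to [eps, 1+eps].

    ``dark_bright`` uses the negative signed vertical gradient (cheap
    where intensity increases with depth), ``bright_dark`` its mirror,
    and ``ridge`` the negative intensity (cheap on bright lines).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if polarity == "ridge":
        raw = -image
    elif polarity in ("dark_bright", "bright_dark"):
        grad = np.gradient(image, axis=0)
        raw = -grad if polarity == "dark_bright" else grad
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        import warnings

        warnings.warn("constant image: energy is uniform", stacklevel=2)
        cost = np.full_like(raw, EPS)
    else:
        cost = (raw - lo) / (hi - lo) + EPS
    return EnergyMap(cost=cost, polarity=polarity)


def _refine_subpixel(cost: np.ndarray, z_int: np.ndarray) -> np.ndarray:
    """Per-column parabolic refinement of the path around the energy minimum."""
    n_rows = cost.shape[0]
    cols = np.arange(cost.shape[1])
    z = z_int.astype(float)
    interior = (z_int > 0) & (z_int < n_rows - 1)
    zi = z_int[interior]
    ci = cols[interior]
    y0 = cost[zi - 1, ci]
    y1 = cost[zi, ci]
    y2 = cost[zi + 1, ci]
    denom = y0 - 2.0 * y1 + y2
    delta = np.zeros_like(y1)
    ok = denom > 1e-300
    delta[ok] = 0.5 * (y0[ok] - y2[ok]) / denom[ok]
    z[interior] += np.clip(delta, -0.5, 0.5)
    return z


def find_path(
    energy: EnergyMap,
    blocked: np.ndarray | None = None,
    max_step: int = 2,
) -> BoundaryPath:
    """Minimum-cost left-to-right path by dynamic programming.

    The path visits one node per column and may move at most ``max_step``
    pixels axially between columns; its cost is the sum of node energies.
    ``blocked`` nodes are unavailable.  The integer optimum is refined
    per column by a parabolic fit of the energy, clamped to half a pixel.
    Raises ``RuntimeError`` when no unblocked path exists.
    """
    cost = energy.cost
    n_rows, n_cols = cost.shape
    c = cost.copy()
    if blocked is not None:
        c[blocked] = np.inf

    acc = np.empty_like(c)
    step = np.zeros((n_rows, n_cols), dtype=np.int16)
    acc[:, 0] = c[:, 0]
    offsets = np.arange(-max_step, max_step + 1)
    for x in range(1, n_cols):
        prev = acc[:, x - 1]
        # candidate predecessor cost for each offset, padded with inf
        cand = np.full((len(offsets), n_rows), np.inf)
        for j, dz in enumerate(offsets):
            if dz >= 0:
                cand[j, dz:] = prev[: n_rows - dz] if dz > 0 else prev
            else:
                cand[j, :dz] = prev[-dz:]
        best = np.argmin(cand, axis=0)
        acc[:, x] = cand[best, np.arange(n_rows)] + c[:, x]
        step[:, x] = offsets[best]

    z_end = int(np.argmin(acc[:, -1]))
    total = float(acc[z_end, -1])
    if not np.isfinite(total):
        raise RuntimeError("no feasible unblocked path")
    z_int = np.empty(n_cols, dtype=int)
    z_int[-1] = z_end
    for x in range(n_cols - 1, 0, -1):
        z_int[x - 1] = z_int[x] - step[z_int[x], x]
    z = _refine_subpixel(cost, z_int)
    return BoundaryPath(z=z, cost=total, z_int=z_int)


@dataclass(frozen=True)
class SegmentationPolicy:
    """Deterministic stand-in for the human supervisor.

    Candidate paths are extracted in order of increasing cost; labels are
    then assigned by depth and anatomy: the shallowest strong path is the
    tear film, the strongest path an epithelium's depth below it is the
    epithelium-Bowman interface, and the strongest (possibly faint) path
    within the plausible Bowman thickness range below that is the
    Bowman-stroma interface.  Separations are geometric micrometres.
    """

    max_paths: int = 6
    block_band_px: int = 3
    max_step_px: int = 2
    strong_fraction: float = 0.5  # of the brightest path's strength
    et_range_um: tuple[float, float] = (20.0, 100.0)
    bt_range_um: tuple[float, float] = (5.0, 25.0)
    min_score_override: int | None = None


def _extract_paths(
    image: np.ndarray, policy: SegmentationPolicy, extra_blocked: np.ndarray | None
) -> list[BoundaryPath]:
    energy = build_energy(image, polarity="ridge")
    blocked = np.zeros(image.shape, dtype=bool)
    if extra_blocked is not None:
        blocked |= extra_blocked
    paths: list[BoundaryPath] = []
    cols = np.arange(image.shape[1])
    for _ in range(policy.max_paths):
        try:
            p = find_path(energy, blocked=blocked, max_step=policy.max_step_px)
        except RuntimeError:
            break
        p.strength = float(image[p.z_int, cols].mean())
        paths.append(p)
        for dz in range(-policy.block_band_px, policy.block_band_px + 1):
            zz = np.clip(p.z_int + dz, 0, image.shape[0] - 1)
            blocked[zz, cols] = True
    return paths


def segment_interfaces(
    avg: AveragedBScan,
    policy: SegmentationPolicy | None = None,
    group_index: float = 1.387,
    blocked: np.ndarray | None = None,
) -> SegmentationResult:
    """Iteratively extract low-energy paths and label the three interfaces.

    ``blocked`` optionally masks regions the caller wants excluded,
    emulating a supervisor striking out an incorrect path.
    """
    policy = policy or SegmentationPolicy()
    image = avg.image
    paths = _extract_paths(image, policy, blocked)
    flags: list[str] = []
    labelled: dict[str, BoundaryPath] = {}

    px_to_um = avg.axial_px_um_optical / group_index  # axial px -> geometric um

    if paths:
        ref_strength = max(p.strength for p in paths)
        strong = [p for p in paths if p.strength >= policy.strong_fraction * ref_strength]
        if strong:
            tf = min(strong, key=lambda p: p.mean_depth())
            tf.interface_label = "tear_film"
            labelled["tear_film"] = tf

            def sep_um(p: BoundaryPath, q: BoundaryPath) -> float:
                return float((p.z - q.z).mean()) * px_to_um

            eb_cands = [
                p
                for p in strong
                if p is not tf
                and policy.et_range_um[0] <= sep_um(p, tf) <= policy.et_range_um[1]
            ]
            if eb_cands:
                eb = max(eb_cands, key=lambda p: p.strength)
                eb.interface_label = "epi_bowman"
                labelled["epi_bowman"] = eb
                bs_cands = [
                    p
                    for p in paths
                    if p.interface_label is None
                    and policy.bt_range_um[0] <= sep_um(p, eb) <= policy.bt_range_um[1]
                    and np.all(p.z > eb.z)
                ]
                if bs_cands:
                    bs = max(bs_cands, key=lambda p: p.strength)
                    bs.interface_label = "bowman_stroma"
                    labelled["bowman_stroma"] = bs

    failed = set(labelled) != set(INTERFACE_LABELS)
    if failed:
        missing = sorted(set(INTERFACE_LABELS) - set(labelled))
        flags.append(f"unassigned interfaces: {', '.join(missing)}")
    else:
        order_ok = np.all(labelled["tear_film"].z < labelled["epi_bowman"].z) and np.all(
            labelled["epi_bowman"].z < labelled["bowman_stroma"].z
        )
        if not order_ok:
            failed = True
            flags.append("depth ordering violated")
            labelled = {}

    result = SegmentationResult(
        paths=labelled,
        failed=failed,
        flags=flags,
        unassigned=[p for p in paths if p.interface_label is None],
    )
    result.quality_score = grade_segmentation(result, image, policy)
    return result


def grade_segmentation(
    result: SegmentationResult,
    image: np.ndarray,
    policy: SegmentationPolicy | None = None,
) -> int:
    """Quality grade 1-5 from boundary contrast-to-noise and roughness.

    The grade proxies a human interpretability rating: 5 exceptional,
    4 good, 3 moderate, 1-2 not interpretable.  A failed segmentation is
    capped at 2 regardless of image quality.  The contrast-to-noise ratio
    is the weakest interface's mean path intensity over the image's
    robust noise scale (median absolute deviation of the axial
    derivative); roughness penalises column-to-column jitter beyond what
    a smooth interface allows.
    """
    policy = policy or SegmentationPolicy()
    if policy.min_score_override is not None and not result.failed:
        return int(np.clip(policy.min_score_override, 1, 5))
    if result.failed or not result.paths:
        return min(2, 1 + len(result.paths))

    noise = float(np.median(np.abs(np.diff(image, axis=0)))) * 1.4826 + 1e-9
    cnr = min(p.strength for p in result.paths.values()) / noise
    roughness = max(
        float(np.std(np.diff(p.z))) for p in result.paths.values()
    )

    if cnr >= 200 and roughness < 0.3:
        score = 5
    elif cnr >= 80 and roughness < 0.6:
        score = 4
    elif cnr >= 30 and roughness < 1.2:
        score = 3
    elif cnr >= 10:
        score = 2
    else:
        score = 1
    return score
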