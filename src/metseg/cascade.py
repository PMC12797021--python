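"""Two-stage inference cascade over serial MRI.

Per session: the locator's whole-volume tumor probability map is binarized at
0.5; 26-connected components above a voxel-count floor become lesion ROIs,
each defining a fixed-size crop (default 128^3, shifted inward near borders).
The segmenter then refines each lesion on a 3-channel crop (T1c, FLAIR,
probability map); within a crop its output is restricted to the connected
component overlapping the ROI's seed, so two nearby lesions sharing a crop
are segmented independently. Per-lesion masks are fused back into the full
grid by logical OR, and the lesion's longest diameter is measured from its
own mask.

Across sessions, lesions are cross-checked against the previous scan: each
previous lesion is greedily matched to the nearest current ROI within a
radius; a previous lesion with no match is carried forward at its previous
coordinates and still cropped and segmented, so a vanished tumor is reported
with LD 0 (distinguishing complete disappearance from shrinkage to a small
remnant).

``OracleLocator`` / ``OracleSegmenter`` substitute ground-truth-derived
probability maps for network inference, separating pipeline correctness from
model quality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from . import metrics
from .volume import Volume

__all__ = [
    "LesionROI",
    "SessionResult",
    "OracleLocator",
    "OracleSegmenter",
    "localize",
    "crop_inputs",
    "fuse",
    "track_lesions",
    "run_session",
    "run_series",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class LesionROI:
    """One localized lesion: id, crop geometry and provenance."""

    lesion_id: int
    center: tuple[int, int, int]  # voxel coordinates
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None  # [lo, hi)
    source: str = "detected"  # or "carried_forward"
    n_voxels: int = 0

    def with_box(self, box) -> "LesionROI":
        return replace(self, box=tuple((int(lo), int(hi)) for lo, hi in box))


@dataclass
class SessionResult:
    session_index: int
    fused_mask: Volume
    rois: list[LesionROI]
    lesion_masks: dict[int, np.ndarray]  # per-lesion binary crop at roi.box
    ld_mm: dict[int, float]  # per-lesion longest diameter


class OracleLocator:
    """Stands in for the locator network: probability = ground-truth mask."""

    def __init__(self, truth: Volume):
        self.truth = truth

    def predict_prob(self, channels: np.ndarray) -> np.ndarray:
        return (np.asarray(self.truth.data) > 0).astype(np.float32)


class OracleSegmenter:
    """Stands in for the segmenter: crop probabilities from the truth mask."""

    def __init__(self, truth: Volume):
        self.truth = truth

    def predict_prob(self, channels: np.ndarray) -> np.ndarray:
        # the caller supplies the crop box through predict_prob_box
        raise NotImplementedError("OracleSegmenter requires the crop box")

    def predict_prob_box(self, channels: np.ndarray, box) -> np.ndarray:
        sl = tuple(slice(lo, hi) for lo, hi in box)
        return (np.asarray(self.truth.data[sl]) > 0).astype(np.float32)


def localize(prob: Volume, threshold: float = 0.5, min_voxels: int = 2) -> list[LesionROI]:
    """Threshold the probability map and return ROIs, largest component first."""
    p = np.asarray(prob.data)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    binary = p > threshold
    labels, n = ndimage.label(binary, structure=_STRUCT26)
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]
    centroids = ndimage.center_of_mass(binary, labels, index=np.arange(1, n + 1))
    order = np.argsort(-counts, kind="stable")
    rois = []
    next_id = 1
    for comp in order:
        if counts[comp] < min_voxels:
            continue
        center = tuple(int(round(c)) for c in np.atleast_2d(centroids)[comp])
        rois.append(LesionROI(next_id, center, n_voxels=int(counts[comp])))
        next_id += 1
    return rois


def _crop_box(center, grid, extent) -> tuple[tuple[int, int], ...]:
    box = []
    for c, n, e in zip(center, grid, extent):
        if e > n:
            raise ValueError(f"crop extent {e} exceeds grid axis {n}")
        lo = int(c) - e // 2
        lo = max(0, min(lo, n - e))
        box.append((lo, lo + e))
    return tuple(box)


def crop_inputs(
    t1c: Volume, flair: Volume, prob: Volume, roi: LesionROI, extent: int | tuple = 128
) -> tuple[np.ndarray, LesionROI]:
    """Extract the (t1c, flair, prob) crop for one ROI; records the box on the ROI."""
    if not (t1c.shape == flair.shape == prob.shape):
        raise ValueError("volumes must share the grid")
    ext = (extent,) * 3 if isinstance(extent, int) else tuple(extent)
    box = _crop_box(roi.center, t1c.shape, ext)
    sl = tuple(slice(lo, hi) for lo, hi in box)
    crop = np.stack(
        [np.asarray(t1c.data[sl]), np.asarray(flair.data[sl]), np.asarray(prob.data[sl])]
    ).astype(np.float32)
    return crop, roi.with_box(box)


def fuse(crop_masks: list[tuple[LesionROI, np.ndarray]], grid) -> Volume:
    """Voxelwise OR of per-lesion crop masks placed at their boxes."""
    out = np.zeros(tuple(grid), dtype=np.uint8)
    for roi, m in crop_masks:
        if roi.box is None:
            raise ValueError("ROI has no crop box")
        m = np.asarray(m).astype(bool)
        for (lo, hi), n, e in zip(roi.box, grid, m.shape):
            if lo < 0 or hi > n or hi - lo != e:
                raise ValueError(f"crop box {roi.box} incompatible with grid {tuple(grid)}")
        sl = tuple(slice(lo, hi) for lo, hi in roi.box)
        out[sl] |= m.astype(np.uint8)
    return Volume(out, (1.0, 1.0, 1.0))


def track_lesions(
    current: list[LesionROI],
    previous: SessionResult,
    spacing_mm,
    match_radius_mm: float = 10.0,
) -> list[LesionROI]:
    """Cross-check current ROIs against the previous session.

    Greedy nearest-first one-to-one matching within ``match_radius_mm``
    (ties broken toward the lower previous id). Matched ROIs inherit the
    previous lesion id; unmatched previous lesions are appended as
    carried-forward ROIs at their previous centers; unmatched current ROIs
    get fresh ids.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    prev_rois = sorted(previous.rois, key=lambda r: r.lesion_id)
    if not prev_rois:
        return list(current)

    cur_centers = np.array([r.center for r in current], dtype=float).reshape(-1, 3) * spacing
    prev_centers = np.array([r.center for r in prev_rois], dtype=float).reshape(-1, 3) * spacing

    pairs = []  # (distance, prev_idx, cur_idx)
    for i, pc in enumerate(prev_centers):
        for j, cc in enumerate(cur_centers):
            d = float(np.linalg.norm(pc - cc))
            if d <= match_radius_mm:
                pairs.append((d, i, j))
    pairs.sort(key=lambda t: (t[0], t[1]))

    matched_prev: dict[int, int] = {}
    matched_cur: set[int] = set()
    for d, i, j in pairs:
        if i in matched_prev or j in matched_cur:
            continue
        matched_prev[i] = j
        matched_cur.add(j)

    out: list[LesionROI] = []
    for i, prev_roi in enumerate(prev_rois):
        if i in matched_prev:
            cur_roi = current[matched_prev[i]]
            out.append(replace(cur_roi, lesion_id=prev_roi.lesion_id))
        else:
            out.append(
                LesionROI(prev_roi.lesion_id, prev_roi.center, source="carried_forward")
            )
    next_id = max((r.lesion_id for r in prev_rois), default=0) + 1
    for j, cur_roi in enumerate(current):
        if j not in matched_cur:
            out.append(replace(cur_roi, lesion_id=next_id))
            next_id += 1
    return out


def _seed_component(
    crop_mask: np.ndarray, roi: LesionROI, spacing_mm, claim_radius_mm: float
) -> np.ndarray:
    """Restrict a crop mask to the component belonging to this ROI.

    The component overlapping the ROI center wins; if the center sits on no
    component (carried-forward lesion, or a centroid just off a non-convex
    blob) the nearest component within ``claim_radius_mm`` is taken. A
    carried-forward lesion with nothing nearby keeps an empty mask — another
    lesion sharing the crop must not be claimed.
    """
    labels, n = ndimage.label(crop_mask, structure=_STRUCT26)
    if n == 0:
        return crop_mask
    center_local = tuple(
        int(np.clip(roi.center[a] - roi.box[a][0], 0, crop_mask.shape[a] - 1)) for a in range(3)
    )
    lab = labels[center_local]
    if lab == 0:
        spacing = np.asarray(spacing_mm, dtype=float)
        best, best_d = 0, np.inf
        for comp in range(1, n + 1):
            idx = np.argwhere(labels == comp)
            d = np.sqrt((((idx - np.asarray(center_local)) * spacing) ** 2).sum(1)).min()
            if d < best_d:
                best, best_d = comp, d
        if best_d > claim_radius_mm:
            return np.zeros_like(crop_mask)
        lab = best
    return labels == lab


def run_session(
    t1c: Volume,
    flair: Volume,
    locator,
    segmenter,
    previous: SessionResult | None = None,
    session_index: int = 0,
    threshold: float = 0.5,
    min_voxels: int = 2,
    crop_extent: int | tuple = 128,
    match_radius_mm: float = 10.0,
    seg_threshold: float = 0.5,
) -> SessionResult:
    """Run the full cascade on one session's preprocessed volumes."""
    prob_map = locator.predict_prob(np.stack([t1c.data, flair.data]).astype(np.float32))
    prob_vol = Volume(prob_map, t1c.spacing_mm, t1c.origin)
    rois = localize(prob_vol, threshold=threshold, min_voxels=min_voxels)
    if previous is not None:
        rois = track_lesions(rois, previous, t1c.spacing_mm, match_radius_mm)

    ext = (crop_extent,) * 3 if isinstance(crop_extent, int) else tuple(crop_extent)
    ext = tuple(min(e, n) for e, n in zip(ext, t1c.shape))

    crop_masks: list[tuple[LesionROI, np.ndarray]] = []
    lesion_masks: dict[int, np.ndarray] = {}
    ld_mm: dict[int, float] = {}
    placed: list[LesionROI] = []
    claimed = np.zeros(t1c.shape, dtype=bool)
    # detected ROIs segment first; carried-forward ROIs may not claim voxels
    # that already belong to a detected lesion sharing the crop
    for roi in sorted(rois, key=lambda r: r.source == "carried_forward"):
        crop, roi = crop_inputs(t1c, flair, prob_vol, roi, extent=ext)
        if hasattr(segmenter, "predict_prob_box"):
            prob_crop = segmenter.predict_prob_box(crop, roi.box)
        else:
            prob_crop = segmenter.predict_prob(crop)
        mask = prob_crop > seg_threshold
        sl = tuple(slice(lo, hi) for lo, hi in roi.box)
        if roi.source == "carried_forward":
            mask &= ~claimed[sl]
        if mask.any():
            mask = _seed_component(mask, roi, t1c.spacing_mm, match_radius_mm)
        claimed[sl] |= mask
        crop_masks.append((roi, mask))
        lesion_masks[roi.lesion_id] = mask
        ld_mm[roi.lesion_id] = metrics.longest_diameter(mask, t1c.spacing_mm)
        placed.append(roi)
    placed.sort(key=lambda r: r.lesion_id)

    fused = fuse(crop_masks, t1c.shape)
    fused = Volume(fused.data, t1c.spacing_mm, t1c.origin)
    return SessionResult(session_index, fused, placed, lesion_masks, ld_mm)


def run_series(sessions, locators, segmenters, **kwargs) -> list[SessionResult]:
    """Run the cascade over an ordered series of (t1c, flair) sessions.

    ``locators``/``segmenters`` are either single models reused per session
    or per-session sequences (the oracle models are per-session since they
    wrap that session's ground truth).
    """
    results: list[SessionResult] = []
    prev = None
    for s, (t1c, flair) in enumerate(sessions):
        loc = locators[s] if isinstance(locators, (list, tuple)) else locators
        seg = segmenters[s] if isinstance(segmenters, (list, tuple)) else segmenters
        res = run_session(t1c, flair, loc, seg, previous=prev, session_index=s, **kwargs)
        results.append(res)
        prev = res
    return results
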