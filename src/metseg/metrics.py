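"""Segmentation loss and evaluation metrics.

Implements the soft Dice loss used for training, plus the evaluation metrics
reported per lesion: Dice similarity coefficient (DSC, %), Hausdorff distance
(HD, mm), volume estimation error (VEE, cc), and the RANO-style longest
diameter (LD, mm) measured in-plane on a 3D mask. Size categories (small
<=1 cm, medium 1-2 cm, large >2 cm) are assigned from the baseline LD.

Conventions stated openly: LD is the maximum voxel-center pairwise distance
within any single axial, coronal or sagittal slice (a 2D, in-plane
measurement, matching how the longest diameter is read clinically); a lesion
occupying a single voxel therefore has LD 0 and is flagged. The Hausdorff
distance is the full (not 95th-percentile) symmetric distance between surface
voxel sets, in physical mm.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree, ConvexHull, QhullError

from .volume import Volume

__all__ = [
    "dice_loss",
    "dsc",
    "hausdorff",
    "vee",
    "longest_diameter",
    "size_category",
    "lesion_metrics",
    "metrics_table",
]

_SMOOTH_EPS = 1e-7


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, Volume) else np.asarray(x)


def _spacing(x, default=(1.0, 1.0, 1.0)) -> np.ndarray:
    return np.asarray(x.spacing_mm if isinstance(x, Volume) else default, dtype=float)


def dice_loss(G, P) -> float:
    """Soft Dice loss L = 1 - 2*sum(G*P) / (sum(G^2) + sum(P^2)).

    ``G`` is the one-hot (binary) ground truth and ``P`` the predicted tumor
    probability, over the same voxel grid. A smoothing epsilon enters the
    denominator only when both sums vanish (empty truth and prediction).
    """
    G = _as_array(G).astype(np.float64)
    P = _as_array(P).astype(np.float64)
    if G.shape != P.shape:
        raise ValueError(f"shape mismatch: {G.shape} vs {P.shape}")
    if ((G != 0) & (G != 1)).any():
        raise ValueError("ground truth must be binary")
    if P.min() < 0 or P.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    inter = float((G * P).sum())
    denom = float((G * G).sum() + (P * P).sum())
    if denom == 0.0:
        denom = _SMOOTH_EPS
    return 1.0 - 2.0 * inter / denom


def dsc(A, B) -> float:
    """Dice similarity coefficient in percent; 100 when both masks are empty."""
    A = _as_array(A).astype(bool)
    B = _as_array(B).astype(bool)
    if A.shape != B.shape:
        raise ValueError(f"grid mismatch: {A.shape} vs {B.shape}")
    sa, sb = int(A.sum()), int(B.sum())
    if sa + sb == 0:
        return 100.0
    return 100.0 * 2.0 * int((A & B).sum()) / (sa + sb)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (N, 3) of mask voxels with at least one 6-neighbor outside."""
    mask = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return np.argwhere(mask & ~eroded)


def hausdorff(A, B, spacing_mm=None) -> float:
    """Symmetric Hausdorff distance between two masks' surfaces, in mm."""
    spacing = _spacing(A) if spacing_mm is None else np.asarray(spacing_mm, dtype=float)
    a = _as_array(A).astype(bool)
    b = _as_array(B).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    pa = surface_voxels(a) * spacing
    pb = surface_voxels(b) * spacing
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def vee(A, B, spacing_mm=None) -> float:
    """Absolute volume difference between two masks, in cc (cm^3)."""
    spacing = _spacing(A) if spacing_mm is None else np.asarray(spacing_mm, dtype=float)
    a = _as_array(A).astype(bool)
    b = _as_array(B).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    voxel_cc = float(np.prod(spacing)) / 1000.0
    return abs(int(a.sum()) - int(b.sum())) * voxel_cc


def _max_pairwise(points: np.ndarray) -> float:
    """Maximum pairwise Euclidean distance among 2D points."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 16:
        try:
            pts = points[ConvexHull(points).vertices]
        except QhullError:  # degenerate (collinear) slice
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def longest_diameter(mask, spacing_mm=None) -> float:
    """In-plane longest diameter of a mask, in mm.

    Maximum over the three orthogonal slice families (planes normal to each
    grid axis) of the maximum pairwise voxel-center distance within a single
    slice. An empty mask has LD 0 (the CR convention); so does a single voxel.
    """
    spacing = _spacing(mask) if spacing_mm is None else np.asarray(spacing_mm, dtype=float)
    m = _as_array(mask).astype(bool)
    if not m.any():
        return 0.0
    idx = np.argwhere(m).astype(float)
    best = 0.0
    for normal_axis in range(3):
        in_plane = [ax for ax in range(3) if ax != normal_axis]
        coords = idx[:, in_plane] * spacing[in_plane]
        slices = idx[:, normal_axis]
        for s in np.unique(slices):
            best = max(best, _max_pairwise(coords[slices == s]))
    return best


def size_category(baseline_ld_mm: float) -> str:
    """RANO size stratum from the baseline LD: small <=1 cm, medium (1,2] cm, large >2 cm."""
    if baseline_ld_mm <= 10.0:
        return "small"
    if baseline_ld_mm <= 20.0:
        return "medium"
    return "large"


def lesion_metrics(pred, truth, spacing_mm=None, reference_ld_mm=None, baseline_ld_mm=None) -> dict:
    """Bundle of per-lesion evaluation metrics for one (pred, truth) mask pair."""
    spacing = _spacing(pred) if spacing_mm is None else np.asarray(spacing_mm, dtype=float)
    p = _as_array(pred).astype(bool)
    t = _as_array(truth).astype(bool)
    ld = longest_diameter(p, spacing)
    out = {
        "dsc": dsc(p, t),
        "vee_cc": vee(p, t, spacing),
        "ld_mm": ld,
        "single_voxel": bool(p.sum() == 1),
    }
    out["hd_mm"] = hausdorff(p, t, spacing) if (p.any() and t.any()) else float("nan")
    ref = reference_ld_mm if reference_ld_mm is not None else longest_diameter(t, spacing)
    out["ld_error_mm"] = abs(ld - ref)
    if baseline_ld_mm is not None:
        out["size_category"] = size_category(baseline_ld_mm)
    return out


def metrics_table(sessions, spacing_mm=None, patient: str = ""):
    """Per-lesion, per-session metrics table.

    ``sessions`` is a sequence of (session_index, pred_labels, truth_labels)
    where the label volumes share lesion ids (lesion k -> label k). Baseline
    LDs (session of first appearance in the truth) assign the size category.
    Returns a pandas DataFrame with one row per lesion and session.
    """
    import pandas as pd

    rows = []
    baseline_ld: dict[int, float] = {}
    for session, pred, truth in sessions:
        sp = _spacing(pred) if spacing_mm is None else np.asarray(spacing_mm, dtype=float)
        pred_l = _as_array(pred)
        truth_l = _as_array(truth)
        ids = sorted((set(np.unique(pred_l)) | set(np.unique(truth_l))) - {0})
        for k in ids:
            if k == 0:
                continue
            t = truth_l == k
            if k not in baseline_ld and t.any():
                baseline_ld[k] = longest_diameter(t, sp)
            m = lesion_metrics(
                pred_l == k, t, spacing_mm=sp, baseline_ld_mm=baseline_ld.get(k)
            )
            rows.append(
                {
                    "patient": patient,
                    "lesion_id": int(k),
                    "session": session,
                    "dsc": m["dsc"],
                    "hd_mm": m["hd_mm"],
                    "vee_cc": m["vee_cc"],
                    "ld_mm": m["ld_mm"],
                    "ld_error_mm": m["ld_error_mm"],
                    "size_category": m.get("size_category"),
                }
            )
    return pd.DataFrame(rows)
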