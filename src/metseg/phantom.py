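"""Longitudinal multi-channel 3D phantoms with ground-truth lesion masks.

The generator emulates the serial-MRI monitoring setting at desk scale:
skull-stripped brain volumes (two channels, T1c-like and FLAIR-like)
containing 1-10 ellipsoidal enhancing lesions of 2-56 mm longest diameter,
each following a prescribed longitudinal size trajectory (shrink / steady /
enlarge / regrow), on a smooth low-frequency background with additive
Gaussian noise. Geometry is frozen by the spec seed, so repeated calls are
bit-identical and sessions are mutually co-registered; only the noise field
differs between sessions.

Lesions are axis-aligned ellipsoids with the longest axis drawn at random and
the other two semi-axes scaled by ratios in [0.7, 1]. Lesion centers are
snapped to voxel centers and the voxelization rule includes voxels whose
center lies within the ellipsoid inflated by half a voxel per axis, so the
longest diameter measured on the mask tracks the prescribed diameter to
within one voxel spacing.

Ground-truth per-session longest diameters are the prescribed ones
(diameter x trajectory factor), and ground-truth status/outcome labels are
obtained by running the response-assessment automaton on that noiseless LD
series, making the simulator self-consistent with the outcome module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import metrics, rano
from .volume import Volume

__all__ = [
    "PhantomSpec",
    "PhantomSession",
    "PhantomSeries",
    "PlacementError",
    "generate_session",
    "generate_series",
    "write_series",
    "random_trajectory",
    "random_spec",
    "threshold_margin",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping lesion placement fails after bounded retries."""


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic longitudinal case.

    ``trajectory[k][s]`` is the LD scale factor of lesion ``k`` at session
    ``s`` (session 0 is the baseline, factor 1.0; factor 0 means the lesion
    has vanished at that session).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lesions: int = 1
    lesion_diameters_mm: tuple[float, ...] = (10.0,)
    trajectory: tuple[tuple[float, ...], ...] = ((1.0, 0.6),)
    contrast: float = 2.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(
            self, "lesion_diameters_mm", tuple(float(d) for d in self.lesion_diameters_mm)
        )
        object.__setattr__(
            self, "trajectory", tuple(tuple(float(f) for f in t) for t in self.trajectory)
        )
        if any(n <= 0 for n in self.grid_shape) or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("grid shape and spacing must be positive")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be positive")
        if len(self.lesion_diameters_mm) != self.n_lesions:
            raise ValueError("one diameter per lesion required")
        if len(self.trajectory) != self.n_lesions:
            raise ValueError("one trajectory per lesion required")
        if any(not (2.0 <= d <= 56.0) for d in self.lesion_diameters_mm):
            raise ValueError("lesion diameters must lie in [2, 56] mm")
        lengths = {len(t) for t in self.trajectory}
        if len(lengths) != 1:
            raise ValueError("all trajectories must have the same number of sessions")
        if any(t[0] != 1.0 for t in self.trajectory):
            raise ValueError("baseline trajectory factor must be 1.0")
        if any(f < 0 for t in self.trajectory for f in t):
            raise ValueError("trajectory factors must be nonnegative")
        if self.contrast <= 1.0:
            raise ValueError("contrast must exceed 1 (enhancing lesions)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def n_sessions(self) -> int:
        return len(self.trajectory[0])


@dataclass
class PhantomSession:
    index: int
    t1c: Volume
    flair: Volume
    truth: Volume  # labeled mask: lesion k -> label k+1


@dataclass
class PhantomSeries:
    spec: PhantomSpec
    sessions: list[PhantomSession]
    gt_ld_mm: np.ndarray  # (n_lesions, n_sessions) LDs measured on the truth masks
    prescribed_ld_mm: np.ndarray  # (n_lesions, n_sessions) diameter x factor
    timelines: list[rano.LesionTimeline]  # ground-truth labels per lesion


# ----------------------------------------------------------------- geometry


@dataclass(frozen=True)
class _LesionGeometry:
    center_vox: tuple[int, int, int]
    axis_ratios: tuple[float, float, float]  # 1.0 on the longest axis


def _brain_params(spec: PhantomSpec):
    shape = np.asarray(spec.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = 0.46 * shape  # in voxel units
    return center, semi


def _max_semi_axes_mm(spec: PhantomSpec, k: int, geo_ratios) -> np.ndarray:
    max_factor = max(spec.trajectory[k])
    return np.asarray(geo_ratios) * spec.lesion_diameters_mm[k] * max_factor / 2.0


@lru_cache(maxsize=256)
def _plan_geometry(spec: PhantomSpec, max_attempts: int = 500) -> list[_LesionGeometry]:
    """Place lesions inside the brain with pairwise-disjoint inflated bounds."""
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing_mm)
    shape = np.asarray(spec.grid_shape)
    brain_c, brain_semi = _brain_params(spec)

    geoms: list[_LesionGeometry] = []
    placed_centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    for k in range(spec.n_lesions):
        long_axis = int(rng.integers(3))
        ratios = rng.uniform(0.7, 1.0, size=3)
        ratios[long_axis] = 1.0
        semi_mm = _max_semi_axes_mm(spec, k, ratios)
        semi_vox = semi_mm / spacing + 1.0  # snapping can grow the lesion by <= 1 voxel
        bound_mm = float((semi_vox * spacing).max())

        ok = False
        for _ in range(max_attempts):
            # uniform center inside the brain ellipsoid core
            u = rng.uniform(-1.0, 1.0, size=3)
            if (u**2).sum() > 1.0:
                continue
            center = brain_c + u * 0.78 * brain_semi
            center_vox = np.round(center).astype(int)
            lo = center_vox - np.ceil(semi_vox).astype(int) - 1
            hi = center_vox + np.ceil(semi_vox).astype(int) + 1
            if (lo < 1).any() or (hi > shape - 2).any():
                continue
            # keep the whole (max-size) lesion within the brain support
            if (((center_vox - brain_c) / (brain_semi - semi_vox - 1)) ** 2).sum() > 1.0:
                continue
            c_mm = center_vox * spacing
            sep = float(spacing.max())
            if all(
                np.linalg.norm(c_mm - pc) > bound_mm + pr + sep
                for pc, pr in zip(placed_centers, placed_radii)
            ):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place lesion {k} ({spec.lesion_diameters_mm[k]} mm) "
                f"without overlap in grid {spec.grid_shape}"
            )
        placed_centers.append(center_vox * spacing)
        placed_radii.append(bound_mm)
        geoms.append(
            _LesionGeometry(tuple(int(c) for c in center_vox), tuple(float(r) for r in ratios))
        )
    return geoms


def _lesion_mask(
    spec: PhantomSpec, geo: _LesionGeometry, diameter_mm: float
) -> tuple[tuple[slice, ...], np.ndarray] | None:
    """Boolean mask of one lesion within its bounding-box slices.

    The semi-axis along the longest axis is snapped to the nearest whole
    voxel (minimum one), the other axes scaled along, so the rendered
    in-plane longest diameter is exactly twice the snapped semi-axis and
    within one voxel spacing of the prescribed diameter; the mask never
    extends beyond the realized ellipsoid (voxel centers on the boundary are
    included).
    """
    if diameter_mm <= 0:
        return None
    spacing = np.asarray(spec.spacing_mm)
    semi_mm = np.asarray(geo.axis_ratios) * diameter_mm / 2.0
    semi_vox = semi_mm / spacing
    long_axis = int(np.argmax(geo.axis_ratios))
    a_long = semi_vox[long_axis]
    a_eff = max(int(np.floor(a_long + 0.5)), 1)
    semi_vox = semi_vox * (a_eff / a_long)
    center = np.asarray(geo.center_vox, dtype=float)
    lo = np.floor(center - semi_vox).astype(int)
    hi = np.ceil(center + semi_vox).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(spec.grid_shape))
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    q = sum(((grids[a] - center[a]) / semi_vox[a]) ** 2 for a in range(3))
    mask = q <= 1.0 + 1e-9
    if not mask.any():
        return None
    return tuple(slice(lo[a], hi[a]) for a in range(3)), mask


def _background(spec: PhantomSpec, channel: int) -> np.ndarray:
    """Smooth low-frequency field on the brain support, zero outside."""
    rng = np.random.default_rng([spec.seed, 77 + channel])
    field = rng.standard_normal(spec.grid_shape)
    sigma = max(min(spec.grid_shape) / 8.0, 2.0)
    field = ndimage.gaussian_filter(field, sigma=sigma)
    field /= max(np.abs(field).max(), 1e-12)
    brain_c, brain_semi = _brain_params(spec)
    grids = np.meshgrid(*[np.arange(n) for n in spec.grid_shape], indexing="ij")
    brain = sum(((grids[a] - brain_c[a]) / brain_semi[a]) ** 2 for a in range(3)) <= 1.0
    bg = (1.0 + 0.15 * field) * brain
    return bg.astype(np.float32)


# ----------------------------------------------------------------- public API


def generate_session(
    spec: PhantomSpec, session_index: int
) -> tuple[Volume, Volume, Volume]:
    """Render one imaging session: (t1c, flair, labeled truth mask).

    Identical ``(spec, session_index)`` arguments produce bit-identical
    output. Lesion ``k`` carries label ``k + 1`` in the truth mask.
    """
    if not (0 <= session_index < spec.n_sessions):
        raise ValueError(f"session_index {session_index} outside trajectory length")
    geoms = _plan_geometry(spec)
    truth = np.zeros(spec.grid_shape, dtype=np.uint16)
    t1c = _background(spec, 0)
    flair = _background(spec, 1)
    brain = t1c > 0

    for k, geo in enumerate(geoms):
        d = spec.lesion_diameters_mm[k] * spec.trajectory[k][session_index]
        box = _lesion_mask(spec, geo, d)
        if box is None:
            continue
        sl, m = box
        truth[sl][m] = k + 1
        t1c[sl][m] = spec.contrast
        flair[sl][m] = 1.0 + 0.6 * (spec.contrast - 1.0)

    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 1000 + session_index])
        noise = rng.standard_normal(spec.grid_shape).astype(np.float32) * spec.noise_sd
        t1c = np.where(brain, t1c + noise, 0.0).astype(np.float32)
        rng2 = np.random.default_rng([spec.seed, 2000 + session_index])
        noise2 = rng2.standard_normal(spec.grid_shape).astype(np.float32) * spec.noise_sd
        flair = np.where(brain, flair + noise2, 0.0).astype(np.float32)

    mk = lambda d: Volume(d, spec.spacing_mm)
    return mk(t1c), mk(flair), mk(truth)


def generate_series(spec: PhantomSpec) -> PhantomSeries:
    """Render all sessions plus ground-truth LDs and outcome labels.

    Ground-truth LDs are measured on the rendered truth masks (what is
    actually in the image) with the same in-plane longest-diameter rule used
    for evaluation; they agree with the prescribed ``diameter x factor``
    values to within one voxel spacing. Status/outcome labels come from the
    response automaton applied to that noiseless LD series, making the
    simulator self-consistent with the outcome module.
    """
    if spec.n_sessions < 2:
        raise ValueError("a series needs a baseline and at least one follow-up")
    sessions = [
        PhantomSession(s, *generate_session(spec, s)) for s in range(spec.n_sessions)
    ]
    prescribed = np.array(
        [
            [spec.lesion_diameters_mm[k] * f for f in spec.trajectory[k]]
            for k in range(spec.n_lesions)
        ]
    )
    gt_ld = np.zeros_like(prescribed)
    for s, sess in enumerate(sessions):
        labels = np.asarray(sess.truth.data)
        for k in range(spec.n_lesions):
            gt_ld[k, s] = metrics.longest_diameter(labels == k + 1, spec.spacing_mm)
    timelines = [
        rano.assess_timeline(gt_ld[k], lesion_id=k + 1) for k in range(spec.n_lesions)
    ]
    return PhantomSeries(spec, sessions, gt_ld, prescribed, timelines)


def lesion_centers_mm(spec: PhantomSpec) -> np.ndarray:
    """Planned lesion centers in mm, one row per lesion (deterministic)."""
    spacing = np.asarray(spec.spacing_mm)
    return np.array([np.asarray(g.center_vox) * spacing for g in _plan_geometry(spec)])


def write_series(spec: PhantomSpec, out_dir) -> Path:
    """Write per-session NIfTI files plus a JSON manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = generate_series(spec)
    manifest = {
        "grid_shape": list(spec.grid_shape),
        "spacing_mm": list(spec.spacing_mm),
        "seed": spec.seed,
        "sessions": [],
        "lesions": [],
    }
    for sess in series.sessions:
        d = out / f"session_{sess.index:02d}"
        d.mkdir(exist_ok=True)
        sess.t1c.save(d / "t1c.nii.gz")
        sess.flair.save(d / "flair.nii.gz")
        sess.truth.save(d / "truth.nii.gz")
        # paths are stored relative to the manifest so the directory is portable
        manifest["sessions"].append(
            {
                "index": sess.index,
                "t1c": f"{d.name}/t1c.nii.gz",
                "flair": f"{d.name}/flair.nii.gz",
                "truth": f"{d.name}/truth.nii.gz",
            }
        )
    for k, tl in enumerate(series.timelines):
        manifest["lesions"].append(
            {
                "id": k + 1,
                "ld_mm": [float(x) for x in series.gt_ld_mm[k]],
                "prescribed_ld_mm": [float(x) for x in series.prescribed_ld_mm[k]],
                "status_series": tl.status_series,
                "outcome": tl.outcome,
                "are": tl.are_flag,
                "lf_time": tl.lf_time,
                "are_time": tl.are_time,
            }
        )
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


# ------------------------------------------------- randomized study cohorts


def random_trajectory(
    rng: np.random.Generator, n_follow_ups: int, diameter_mm: float
) -> tuple[float, ...]:
    """Draw a clinically-shaped LD trajectory (factors relative to baseline).

    Patterns cover the outcomes seen after radiosurgery: sustained shrinkage
    (LC, possibly to complete disappearance), stable disease, confirmed
    progression (LF), and transient post-treatment enlargement that settles
    (ARE). Progression steps are sized so the >1 mm LF confirmation is
    satisfied in absolute mm for the given baseline diameter.
    """
    pattern = rng.choice(["shrink", "cr", "steady", "lf", "are"])
    f = [1.0]
    confirm_frac = 2.0 / diameter_mm  # factor step worth ~2 mm

    if pattern == "shrink":
        level = 1.0
        for _ in range(n_follow_ups):
            level *= rng.uniform(0.55, 0.85)
            f.append(round(max(level, 0.05), 3))
    elif pattern == "cr":
        vanish_at = int(rng.integers(1, n_follow_ups + 1))
        level = 1.0
        for j in range(1, n_follow_ups + 1):
            if j >= vanish_at:
                f.append(0.0)
            else:
                level *= rng.uniform(0.45, 0.6)
                f.append(round(level, 3))
    elif pattern == "steady":
        level = 1.0
        for _ in range(n_follow_ups):
            level *= rng.uniform(0.96, 1.0)
            f.append(round(level, 3))
    else:  # lf / are: shrink or stay, enlarge, then confirm or settle
        enlarge_at = int(rng.integers(1, max(n_follow_ups - 1, 1) + 1))
        level = 1.0
        for j in range(1, n_follow_ups + 1):
            if j < enlarge_at:
                level *= rng.uniform(0.75, 0.95)
            elif j == enlarge_at:
                level = min(level, 1.0) * rng.uniform(1.35, 1.6)
            elif j == enlarge_at + 1:
                if pattern == "lf":
                    level = level + max(rng.uniform(0.15, 0.3), 1.6 * confirm_frac)
                else:
                    level = level * rng.uniform(0.75, 0.95)
            else:
                if pattern == "lf":
                    level *= rng.uniform(1.0, 1.1)
                else:
                    level *= rng.uniform(0.85, 1.0)
            f.append(round(level, 3))
    return tuple(f)


def random_spec(
    rng: np.random.Generator,
    grid_shape=(64, 64, 64),
    n_sessions: int = 4,
    max_lesions: int = 3,
    diameter_range=(6.0, 18.0),
    noise_sd: float = 0.05,
) -> PhantomSpec:
    """Draw a random desk-scale longitudinal spec (geometry seed from rng)."""
    n = int(rng.integers(1, max_lesions + 1))
    diameters = tuple(float(rng.uniform(*diameter_range)) for _ in range(n))
    traj = tuple(random_trajectory(rng, n_sessions - 1, d) for d in diameters)
    return PhantomSpec(
        grid_shape=grid_shape,
        n_lesions=n,
        lesion_diameters_mm=diameters,
        trajectory=traj,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )


def threshold_margin(ld_series, cfg: rano.OutcomeConfig = rano.OutcomeConfig()) -> float:
    """Smallest relative distance of a noiseless LD series to a decision boundary.

    Measures, over all follow-ups, how far each measurement sits from the 30%
    baseline-shrinkage and 20% nadir-enlargement thresholds (as a fraction of
    the threshold LD) and how far each LF confirmation comparison sits from
    the 1 mm rule (as a fraction of the enlargement-scan LD). Series whose
    margin is small can flip labels under sub-voxel measurement error.
    """
    lds = [float(x) for x in ld_series]
    baseline = lds[0]
    margin = np.inf
    nadir = baseline
    for j in range(1, len(lds)):
        cur = lds[j]
        shrink_bound = baseline * (1.0 - cfg.shrink_threshold)
        enlarge_bound = nadir * (1.0 + cfg.enlarge_threshold)
        margin = min(margin, abs(cur - shrink_bound) / max(shrink_bound, 1e-9))
        if enlarge_bound > 0:
            margin = min(margin, abs(cur - enlarge_bound) / max(enlarge_bound, 1e-9))
        if j + 1 < len(lds):
            confirm_bound = lds[j] + cfg.lf_confirm_mm
            margin = min(margin, abs(lds[j + 1] - confirm_bound) / max(lds[j], 1e-9))
        nadir = min(nadir, cur)
    return float(margin)
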