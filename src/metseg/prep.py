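"""Volume preparation: grid resampling, intensity normalization, augmentation.

Inputs are assumed co-registered and skull-stripped; registration and brain
extraction are delegated to upstream tools and not reimplemented here.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = ["resample", "znorm_nonzero", "augment"]


def resample(v: Volume, target_shape, is_mask: bool = False) -> Volume:
    """Resample a volume to ``target_shape`` preserving its physical extent.

    Trilinear interpolation for intensity volumes, nearest-neighbor when
    ``is_mask``. The voxel spacing is rescaled so ``shape * spacing`` is
    unchanged per axis.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if len(target_shape) != 3 or any(n <= 0 for n in target_shape):
        raise ValueError(f"target shape must be 3 positive integers, got {target_shape}")
    src_shape = v.shape
    new_spacing = tuple(
        v.spacing_mm[a] * src_shape[a] / target_shape[a] for a in range(3)
    )
    if target_shape == src_shape:
        return Volume(v.data.copy(), v.spacing_mm, v.origin)
    zoom = [target_shape[a] / src_shape[a] for a in range(3)]
    order = 0 if is_mask else 1
    data = ndimage.zoom(v.data, zoom, order=order, mode="nearest", grid_mode=True)
    # grid_mode can be off by one voxel for awkward ratios; enforce the contract
    data = data[tuple(slice(0, n) for n in target_shape)]
    if data.shape != target_shape:
        pad = [(0, target_shape[a] - data.shape[a]) for a in range(3)]
        data = np.pad(data, pad, mode="edge")
    return Volume(data, new_spacing, v.origin)


def znorm_nonzero(v: Volume) -> Volume:
    """Z-score the volume using mean/sd of its non-zero voxels only.

    Zero voxels (the stripped background) stay exactly zero; non-zero voxels
    are transformed to zero mean and unit standard deviation.
    """
    data = np.asarray(v.data, dtype=np.float64)
    nz = data != 0
    vals = data[nz]
    if vals.size == 0:
        raise ValueError("cannot normalize an all-zero volume")
    mu = vals.mean()
    sd = vals.std()
    if sd == 0:
        raise ValueError("cannot normalize a volume with zero variance on its non-zero support")
    out = np.zeros_like(data, dtype=np.float32)
    out[nz] = ((vals - mu) / sd).astype(np.float32)
    return Volume(out, v.spacing_mm, v.origin)


_ROT_AXES = ((0, 1), (0, 2), (1, 2))


def augment(
    channels: list[Volume],
    mask: Volume,
    seed: int,
    p_spatial: float = 0.5,
    p_intensity: float = 0.5,
) -> tuple[list[Volume], Volume]:
    """Random training-time augmentation, deterministic given ``seed``.

    Spatial transforms (axis flips and in-plane 90-degree rotations) are
    applied identically to every channel and the mask; intensity transforms
    (gain in [0.9, 1.1], offset in [-0.1, 0.1], gamma in [0.8, 1.2]) apply to
    the channels only. Gamma acts on the volume min-max rescaled to [0, 1]
    and is mapped back, so it is monotone regardless of intensity range.
    """
    for c in channels:
        if c.shape != mask.shape or c.spacing_mm != mask.spacing_mm:
            raise ValueError("channels and mask must share grid and spacing")
    rng = np.random.default_rng(seed)

    ops: list = []
    for axis in range(3):
        if rng.random() < p_spatial:
            ops.append(("flip", axis))
    # 90-degree rotations are only shape-preserving on square axis pairs
    for axes in _ROT_AXES:
        if mask.shape[axes[0]] == mask.shape[axes[1]] and rng.random() < p_spatial:
            ops.append(("rot90", axes, int(rng.integers(1, 4))))

    def spatial(d: np.ndarray) -> np.ndarray:
        for op in ops:
            if op[0] == "flip":
                d = np.flip(d, axis=op[1])
            else:
                d = np.rot90(d, k=op[2], axes=op[1])
        return d

    out_channels = []
    for c in channels:
        d = spatial(np.asarray(c.data, dtype=np.float32)).copy()
        if rng.random() < p_intensity:
            d = d * rng.uniform(0.9, 1.1)
        if rng.random() < p_intensity:
            d = d + rng.uniform(-0.1, 0.1)
        if rng.random() < p_intensity:
            gamma = rng.uniform(0.8, 1.2)
            lo, hi = float(d.min()), float(d.max())
            if hi > lo:
                d = ((d - lo) / (hi - lo)) ** gamma * (hi - lo) + lo
        out_channels.append(Volume(d.astype(np.float32), c.spacing_mm, c.origin))
    out_mask = Volume(spatial(mask.data).copy(), mask.spacing_mm, mask.origin)
    return out_channels, out_mask
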