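"""Scar-to-MRA fusion for volumetric display.

The scar-enhanced and angiographic volumes come from the same session on
the same grid (inherently co-registered), so fusion is a voxel overwrite:
scar voxels are set to a sentinel intensity 5% above the MRA maximum,
keeping the fused image a plain scalar volume any viewer can render with
scar saturated white.  No registration is performed — a grid mismatch is
a hard error, never a silent resample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CoRegistrationError, ScarflowError
from .volio import LabelMap, Volume3D

SENTINEL_FACTOR = 1.05


@dataclass
class FusedVolume:
    base: Volume3D
    overlay: np.ndarray          # binary scar mask
    fused: Volume3D
    sentinel: float


def fuse(mra: Volume3D, scar: LabelMap | np.ndarray) -> FusedVolume:
    """Overwrite scar voxels in the MRA with a sentinel intensity."""
    scar_mask = (scar.data if isinstance(scar, LabelMap) else np.asarray(scar)) > 0
    if scar_mask.shape != mra.data.shape:
        raise CoRegistrationError(
            f"MRA grid {mra.data.shape} and scar grid {scar_mask.shape} differ; "
            "this tool performs no registration — resample upstream")
    if isinstance(scar, LabelMap) and not np.allclose(scar.spacing_mm, mra.spacing_mm):
        raise CoRegistrationError("MRA and scar voxel spacings differ")
    sentinel = float(mra.data.max()) * SENTINEL_FACTOR
    fused = np.asarray(mra.data, dtype=np.float32).copy()
    fused[scar_mask] = sentinel
    return FusedVolume(
        base=mra,
        overlay=scar_mask,
        fused=Volume3D(fused, mra.spacing_mm, affine=mra.affine, units=mra.units),
        sentinel=sentinel,
    )


def mip_png(fused: FusedVolume, axis: int, path: str | Path) -> Path:
    """Maximum-intensity projection to an 8-bit grayscale PNG.

    The sentinel maps to the top of the gray scale, so scar renders white.
    """
    import imageio.v3 as iio

    if axis not in (0, 1, 2):
        raise ScarflowError(f"axis must be 0, 1 or 2, got {axis}")
    mip = fused.fused.data.max(axis=axis)
    lo = float(fused.fused.data.min())
    hi = fused.sentinel if fused.sentinel > lo else float(fused.fused.data.max())
    if hi <= lo:
        img = np.zeros(mip.shape, dtype=np.uint8)
    else:
        img = np.clip((mip - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
    path = Path(path)
    iio.imwrite(path, img)
    return path
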