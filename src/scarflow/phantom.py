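"""Synthetic 3D LGE / MRA cardiac phantom.

Builds a parametric-analytic thin-walled two-ventricle heart on an
isotropic voxel grid: nested ellipsoidal shells give an ~8 mm thick left
ventricle and a 3-4 mm thick right-ventricular crescent; curved
hyperenhanced scar patches are embedded in the right-ventricular outflow
wall (and optionally the basal septum, emulating a ventricular-septal-
defect repair).  Intensities follow a four-class mixture (dark
fat-suppressed background, bright blood pool, nulled myocardium,
hyperenhanced scar) with partial-volume mixing modeled by Gaussian
blurring of per-class indicator fractions, and Rician noise modeled as
the magnitude of the noisy complex signal.

The geometry is analytic rather than atlas-based so ground truth is
exact, generation is dependency-free, and identical spec + seed yields
bit-identical output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import MissingClassError, SizingError
from .volio import LabelMap, TISSUE_CODES, TISSUE_NAMES, Volume3D

log = logging.getLogger(__name__)

_DEFAULT_LGE_MEANS = {"background": 10.0, "blood": 70.0, "myocardium": 30.0, "scar": 100.0}
# blood-bright companion channel (angiography): blood dominates, wall and
# scar share unremarkable soft-tissue signal
_DEFAULT_MRA_MEANS = {"background": 12.0, "blood": 160.0, "myocardium": 45.0, "scar": 45.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    ``scar_volume_ml=None`` means "draw uniformly from ``scar_volume_range``"
    so cohorts bracket a realistic surgical-scar burden (a few mL up to
    ~25 mL).  All randomness flows from ``rng_seed``.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 1.3
    tissue_means: dict = field(default_factory=lambda: dict(_DEFAULT_LGE_MEANS))
    mra_means: dict = field(default_factory=lambda: dict(_DEFAULT_MRA_MEANS))
    noise_sigma: float = 5.0
    pv_blur_sigma_mm: float = 1.0
    scar_volume_ml: float | None = None
    scar_volume_range: tuple[float, float] = (2.0, 25.0)
    include_septal_patch: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        m = self.tissue_means
        if min(m.values()) < 0:
            raise ValueError("tissue means must be non-negative")
        if not (m["scar"] > m["blood"] > m["myocardium"] > m["background"]):
            warnings.warn(
                "tissue mean ordering scar > blood > myocardium > background is broken; "
                "the segmentation priors assume it", stacklevel=2)


@dataclass
class PhantomCase:
    """A generated case: LGE volume, matched MRA, exact truth labels."""

    lge: Volume3D
    mra: Volume3D
    truth: LabelMap
    true_scar_volume_ml: float
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _world_coords(shape: Sequence[int], spacing: float):
    """Millimetre coordinates of voxel centres, origin at the grid centre."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * spacing for n in shape]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(coords, center, semi):
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


# fixed anatomical layout (mm, relative to grid centre): LV on the left,
# RV crescent wrapping it anteriorly/rightward, long axis along z
_LV_CENTER = (-8.0, 0.0, -2.0)
_LV_EPI_SEMI = (24.0, 24.0, 32.0)
_LV_WALL_MM = 8.0
_RV_CENTER = (10.0, 2.0, 0.0)
_RV_EPI_SEMI = (28.0, 25.0, 31.0)
_RV_WALL_MM = 3.5


def _build_anatomy(shape, spacing):
    """Return (truth uint8 array without scar, masks dict)."""
    # feasibility: the heart plus one blur margin must fit inside the grid
    extent = np.asarray(shape) * spacing
    need = {
        "x": max(abs(_LV_CENTER[0]) + _LV_EPI_SEMI[0], abs(_RV_CENTER[0]) + _RV_EPI_SEMI[0]),
        "y": max(abs(_LV_CENTER[1]) + _LV_EPI_SEMI[1], abs(_RV_CENTER[1]) + _RV_EPI_SEMI[1]),
        "z": max(abs(_LV_CENTER[2]) + _LV_EPI_SEMI[2], abs(_RV_CENTER[2]) + _RV_EPI_SEMI[2]),
    }
    for axis, (half_extent, needed) in enumerate(zip(extent / 2.0, need.values())):
        if needed + 2 * spacing > half_extent:
            name = "xyz"[axis]
            raise SizingError(
                f"grid too small along {name}: heart needs ±{needed + 2 * spacing:.1f} mm, "
                f"grid provides ±{half_extent:.1f} mm")

    coords = _world_coords(shape, spacing)
    lv_epi = _ellipsoid(coords, _LV_CENTER, _LV_EPI_SEMI)
    lv_endo = _ellipsoid(coords, _LV_CENTER, tuple(s - _LV_WALL_MM for s in _LV_EPI_SEMI))
    rv_epi = _ellipsoid(coords, _RV_CENTER, _RV_EPI_SEMI)
    rv_endo = _ellipsoid(coords, _RV_CENTER, tuple(s - _RV_WALL_MM for s in _RV_EPI_SEMI))

    lv_wall = lv_epi & ~lv_endo
    rv_wall = rv_epi & ~rv_endo & ~lv_epi
    blood = lv_endo | (rv_endo & ~lv_epi)
    myo = lv_wall | rv_wall

    truth = np.full(shape, TISSUE_NAMES["background"], dtype=np.uint8)
    truth[blood] = TISSUE_NAMES["blood"]
    truth[myo] = TISSUE_NAMES["myocardium"]
    return truth, {"lv_wall": lv_wall, "rv_wall": rv_wall, "blood": blood,
                   "rv_endo": rv_endo & ~lv_epi, "coords": coords}


def _grow_patch(eligible: np.ndarray, anchor: tuple[int, int, int], n_voxels: int,
                spacing: float) -> np.ndarray:
    """Grow a connected patch of exactly ``n_voxels`` voxels from ``anchor``.

    Grassfire expansion restricted to ``eligible`` guarantees connectivity;
    within the last generation, voxels closest (Euclidean) to the anchor are
    preferred, with a lexicographic index as the final deterministic tie-break.
    """
    if not eligible[anchor]:
        raise SizingError("patch anchor fell outside the eligible wall region")
    struct = ndimage.generate_binary_structure(3, 1)
    current = np.zeros_like(eligible)
    current[anchor] = True
    generation = np.full(eligible.shape, np.iinfo(np.int32).max, dtype=np.int32)
    generation[anchor] = 0
    g = 0
    while current.sum() < n_voxels:
        grown = ndimage.binary_dilation(current, structure=struct) & eligible
        new = grown & ~current
        if not new.any():
            raise SizingError(
                f"scar patch of {n_voxels} voxels does not fit: wall region exhausted "
                f"at {int(current.sum())} voxels (reduce scar_volume_ml)")
        g += 1
        generation[new] = g
        current = grown
    idx = np.argwhere(current)
    dist = np.linalg.norm((idx - np.asarray(anchor)) * spacing, axis=1)
    gen = generation[tuple(idx.T)]
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], dist, gen))
    keep = idx[order[:n_voxels]]
    patch = np.zeros_like(eligible)
    patch[tuple(keep.T)] = True
    return patch


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: |(S + g1) + i g2| with iid zero-mean Gaussians."""
    if sigma == 0:
        return signal
    g1 = rng.normal(0.0, sigma, size=signal.shape)
    g2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + g1) ** 2 + g2 ** 2)


def _mix_intensities(truth: np.ndarray, means: dict, blur_sigma_vox: float) -> np.ndarray:
    """Partial-volume mixing: blur per-class indicator fractions, then
    intensity = sum(fraction * class mean)."""
    out = np.zeros(truth.shape, dtype=np.float64)
    for code, name in TISSUE_CODES.items():
        frac = (truth == code).astype(np.float64)
        if blur_sigma_vox > 0:
            frac = ndimage.gaussian_filter(frac, sigma=blur_sigma_vox)
        out += frac * means[name]
    return out


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one synthetic LGE/MRA case with exact ground-truth labels."""
    shape = tuple(spec.grid_shape)
    s = spec.spacing_mm
    truth, masks = _build_anatomy(shape, s)
    rng = np.random.default_rng(spec.rng_seed)

    target_ml = spec.scar_volume_ml
    if target_ml is None:
        lo, hi = spec.scar_volume_range
        target_ml = float(rng.uniform(lo, hi))
    n_target = int(round(target_ml * 1000.0 / s ** 3))
    if n_target < 1:
        raise SizingError(f"scar_volume_ml={target_ml} is below one voxel at {s} mm")

    # RVOT patch: anchored at the superior/anterior extreme of the RV free
    # wall; transmural, thickening toward the cavity (surgical patch and
    # adjacent fibrosis replace the wall and indent the blood pool) so its
    # outer face is the epicardial surface, as in repaired outflow tracts
    rv_wall = masks["rv_wall"]
    bulge = ndimage.binary_dilation(rv_wall, iterations=2) & (truth == TISSUE_NAMES["blood"])
    eligible_rvot = rv_wall | bulge
    idx = np.argwhere(rv_wall)
    score = idx[:, 2] + 0.3 * idx[:, 0]  # superior, slightly rightward
    anchor_rvot = tuple(idx[np.argmax(score)])

    if spec.include_septal_patch and n_target >= 8:
        n_rvot = int(round(0.65 * n_target))
        n_sept = n_target - n_rvot
    else:
        n_rvot, n_sept = n_target, 0

    scar = _grow_patch(eligible_rvot, anchor_rvot, n_rvot, s)
    if n_sept:
        # basal septum: LV wall adjacent to the RV cavity, near the top
        septum = masks["lv_wall"] & ndimage.binary_dilation(masks["rv_endo"], iterations=2)
        if not septum.any():
            septum = masks["lv_wall"]
        # anchor mid-septum (well below the RVOT patch so patches stay distinct)
        sidx = np.argwhere(septum)
        z_ref = np.percentile(sidx[:, 2], 40)
        lo_x = sidx[np.abs(sidx[:, 2] - z_ref) <= 2]
        anchor_sept = tuple(lo_x[np.argmin(lo_x[:, 0])]) if len(lo_x) else tuple(sidx[0])
        scar |= _grow_patch(masks["lv_wall"], anchor_sept, n_sept, s)

    truth = truth.copy()
    truth[scar] = TISSUE_NAMES["scar"]
    n_scar = int(scar.sum())
    true_ml = n_scar * s ** 3 / 1000.0

    blur_vox = spec.pv_blur_sigma_mm / s
    lge_clean = _mix_intensities(truth, spec.tissue_means, blur_vox)
    mra_clean = _mix_intensities(truth, spec.mra_means, blur_vox)
    lge = _rician(lge_clean, spec.noise_sigma, rng).astype(np.float32)
    mra = _rician(mra_clean, spec.noise_sigma, rng).astype(np.float32)

    spacing3 = (s, s, s)
    return PhantomCase(
        lge=Volume3D(lge, spacing3, units="a.u."),
        mra=Volume3D(mra, spacing3, units="a.u."),
        truth=LabelMap(truth, spacing3),
        true_scar_volume_ml=true_ml,
        spec=replace(spec, scar_volume_ml=target_ml),
    )


# ---------------------------------------------------------------------------
# automatic seed strokes
# ---------------------------------------------------------------------------

def auto_seeds(truth: LabelMap, erosion_radius_vox: int | dict = 2, strokes_per_class: int = 200,
               rng_seed: int | Sequence[int] = 0, placement: str = "center",
               stroke_shape: str = "scribble") -> LabelMap:
    """Emulate a user's brush stroke per tissue class.

    Each class region is eroded (keeping strokes away from ambiguous
    boundaries, as a careful user would), then a connected stroke of
    ``strokes_per_class`` voxels is grown from a randomly jittered start.
    ``placement`` is the brush habit: a ``"center"`` brusher starts near
    the middle of each region, an ``"edge"`` brusher near its margin.
    ``stroke_shape`` selects the stroke type: a ``"scribble"`` wanders
    across the region by randomized flood fill (samples the region's
    intensity variation broadly), a ``"dab"`` is a compact patch whose
    shape is deterministic given its start (highly repeatable).
    ``erosion_radius_vox`` may be a single radius or a per-class-name
    mapping (e.g. a habit of brushing blood close to the wall).
    If erosion would leave too little room for the stroke the radius is
    reduced for that class and a log record is emitted.  Seeded voxels
    are always a subset of the truth labels.
    """
    rng = np.random.default_rng(rng_seed)
    seeds = np.zeros(truth.shape, dtype=np.uint8)
    struct = ndimage.generate_binary_structure(3, 1)
    for code in sorted(truth.codes):
        mask = truth.data == code
        if not mask.any():
            raise MissingClassError(f"class {code} ({truth.codes[code]}) absent from label map")
        n = int(min(strokes_per_class, mask.sum()))
        if n >= mask.sum():
            seeds[mask] = code
            continue
        if isinstance(erosion_radius_vox, dict):
            r = int(erosion_radius_vox.get(truth.codes[code], 2))
        else:
            r = int(erosion_radius_vox)
        eroded = mask
        if r > 0:
            eroded = ndimage.binary_erosion(mask, structure=struct, iterations=r)
        # thin structures may erode below the requested stroke size; back
        # the radius off per class until the stroke fits (a careful user
        # brushes closer to the boundary when the region is small)
        while eroded.sum() < n and r > 0:
            r -= 1
            eroded = mask if r == 0 else ndimage.binary_erosion(mask, structure=struct, iterations=r)
            log.info("auto_seeds: erosion radius reduced to %d for class %s", r, truth.codes[code])
        stroke = _random_stroke(eroded, n, rng, placement=placement,
                                stroke_shape=stroke_shape)
        seeds[stroke] = code
    return LabelMap(seeds, truth.spacing_mm, affine=truth.affine, codes=truth.codes)


def _random_stroke(region: np.ndarray, n_voxels: int, rng: np.random.Generator,
                   placement: str = "center", stroke_shape: str = "scribble") -> np.ndarray:
    """A brush-like stroke of ``n_voxels`` voxels inside ``region``.

    The start voxel is drawn among the tenth of the region where the
    brush habit puts it (``"center"``: closest to the region centroid;
    ``"edge"``: farthest from it).  A ``"scribble"`` stroke then spreads
    by randomized flood fill, wandering across the region; a ``"dab"``
    grows a compact patch in deterministic order of distance from the
    start.  The largest still-unseeded blob is always brushed first (the
    obvious target), and if a connected component is exhausted a fresh
    stroke is started in the remainder (the region may be split across,
    e.g., two scar patches).
    """
    if placement not in ("center", "edge"):
        raise ValueError(f"unknown stroke placement {placement!r}")
    if stroke_shape not in ("scribble", "dab"):
        raise ValueError(f"unknown stroke shape {stroke_shape!r}")
    import heapq

    shape = region.shape
    remaining = region.copy()
    chosen: list[tuple[int, int, int]] = []
    offsets = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
    while len(chosen) < n_voxels and remaining.any():
        comp, n_comp = ndimage.label(remaining)
        if n_comp > 1:
            sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                       index=np.arange(1, n_comp + 1))
            idx = np.argwhere(comp == (int(np.argmax(sizes)) + 1))
        else:
            idx = np.argwhere(remaining)
        dist = np.linalg.norm(idx - idx.mean(axis=0), axis=1)
        order = np.argsort(dist if placement == "center" else -dist)
        near = order[:max(1, len(idx) // 10)]
        start = tuple(int(v) for v in idx[near[rng.integers(len(near))]])
        remaining[start] = False
        if stroke_shape == "dab":
            heap = [(0.0, start)]
            while len(chosen) < n_voxels and heap:
                _, vx = heapq.heappop(heap)
                chosen.append(vx)
                for off in offsets:
                    nb = (vx[0] + off[0], vx[1] + off[1], vx[2] + off[2])
                    if not (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                            and 0 <= nb[2] < shape[2]):
                        continue
                    if remaining[nb]:
                        remaining[nb] = False
                        d = ((nb[0] - start[0]) ** 2 + (nb[1] - start[1]) ** 2
                             + (nb[2] - start[2]) ** 2)
                        heapq.heappush(heap, (float(d), nb))
            continue
        frontier = [start]
        chosen.append(start)
        while len(chosen) < n_voxels and frontier:
            i = int(rng.integers(len(frontier)))
            vx = frontier.pop(i)
            for off in offsets:
                nb = (vx[0] + off[0], vx[1] + off[1], vx[2] + off[2])
                if not (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1] and 0 <= nb[2] < shape[2]):
                    continue
                if remaining[nb]:
                    remaining[nb] = False
                    frontier.append(nb)
                    chosen.append(nb)
                    if len(chosen) >= n_voxels:
                        break
    out = np.zeros(shape, dtype=bool)
    out[tuple(np.array(chosen).T)] = True
    return out


# ---------------------------------------------------------------------------
# anisotropic degradation (thick-slice 2D-protocol emulation)
# ---------------------------------------------------------------------------

def resample_anisotropic(case: PhantomCase, slice_thickness_mm: float = 8.0,
                         gap_mm: float = 2.0,
                         inplane_mm: tuple[float, float] = (1.6, 1.3)) -> PhantomCase:
    """Degrade an isotropic case into a thick-slice anisotropic stack.

    Along z the volume is block-averaged over each ``slice_thickness_mm``
    slab and inter-slab ``gap_mm`` voxels are dropped; in-plane the images
    are linearly resampled to ``inplane_mm`` (truth by nearest neighbour,
    slabs by per-class majority vote).  Used for the 3D-vs-2D partial-volume
    comparison.
    """
    s = case.spec.spacing_mm
    if slice_thickness_mm < s:
        raise ValueError("slice thickness must be >= native spacing")
    shape = case.lge.data.shape
    period = slice_thickness_mm + gap_mm
    extent_z = shape[2] * s
    n_out = int(np.floor(extent_z / period)) if period > s else shape[2]
    if slice_thickness_mm == s and gap_mm == 0:
        n_out = shape[2]
    if n_out < 1:
        raise ValueError("volume thinner than one slab")

    z_centers = (np.arange(shape[2]) + 0.5) * s
    lge_sl = np.empty(shape[:2] + (n_out,), dtype=np.float64)
    mra_sl = np.empty_like(lge_sl)
    truth_sl = np.empty(shape[:2] + (n_out,), dtype=np.uint8)
    for k in range(n_out):
        z0, z1 = k * period, k * period + slice_thickness_mm
        sel = (z_centers >= z0) & (z_centers < z1)
        if not sel.any():
            sel = np.zeros_like(sel)
            sel[min(int(z0 / s), shape[2] - 1)] = True
        lge_sl[:, :, k] = case.lge.data[:, :, sel].mean(axis=2)
        mra_sl[:, :, k] = case.mra.data[:, :, sel].mean(axis=2)
        block = case.truth.data[:, :, sel]
        counts = np.stack([(block == c).sum(axis=2) for c in sorted(case.truth.codes)], axis=0)
        truth_sl[:, :, k] = np.asarray(sorted(case.truth.codes), dtype=np.uint8)[counts.argmax(axis=0)]

    zoom_xy = (s / inplane_mm[0], s / inplane_mm[1], 1.0)
    lge_d = ndimage.zoom(lge_sl, zoom_xy, order=1)
    mra_d = ndimage.zoom(mra_sl, zoom_xy, order=1)
    truth_d = ndimage.zoom(truth_sl, zoom_xy, order=0)

    spacing_d = (float(inplane_mm[0]), float(inplane_mm[1]), float(period))
    truth_map = LabelMap(truth_d, spacing_d, codes=case.truth.codes)
    n_scar = int((truth_d == TISSUE_NAMES["scar"]).sum())
    true_ml = n_scar * float(np.prod(spacing_d)) / 1000.0
    return PhantomCase(
        lge=Volume3D(lge_d.astype(np.float32), spacing_d),
        mra=Volume3D(mra_d.astype(np.float32), spacing_d),
        truth=truth_map,
        true_scar_volume_ml=true_ml,
        spec=case.spec,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def make_cohort(n: int, spec_template: PhantomSpec | None = None,
                rng_seed: int = 0) -> list[PhantomCase]:
    """Generate ``n`` cases with scar volumes drawn from the template range.

    Child RNG streams are derived deterministically from ``rng_seed`` via
    ``numpy.random.SeedSequence`` spawning, so the same seed reproduces the
    same cohort and different cases are statistically independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec_template is None:
        spec_template = PhantomSpec()
    children = np.random.SeedSequence(rng_seed).spawn(n)
    cases = []
    for child in children:
        case_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cases.append(make_phantom(replace(spec_template, rng_seed=case_seed)))
    return cases
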