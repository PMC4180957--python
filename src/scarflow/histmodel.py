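"""Seed-stroke intensity likelihoods and per-voxel data costs.

A single brush stroke per tissue class provides a sample of that class's
signal intensities.  Each sample is turned into a Parzen-smoothed
histogram (64 bins spanning the volume's robust 1st-99th percentile
range, Gaussian kernel with Silverman bandwidth) and every voxel then
receives one negative-log-likelihood cost per class::

    D_l(x) = -log(P_l(I(x)) + eps),   clipped to [0, -log eps]

where ``P_l`` is the per-bin probability mass of class ``l``.  Smoothing
prevents zero-probability holes from a single stroke; the epsilon floor
and clip keep all costs finite so the downstream max-flow energy is
bounded.  Seeds inform the histograms only — they are not hard
constraints unless ``pin_seeds`` is requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, SeedingError
from .volio import LabelMap, Volume3D

N_BINS = 64
EPS = 1e-8
MIN_SEEDS_PER_CLASS = 10


@dataclass
class ClassDensity:
    """Smoothed intensity density of one tissue class."""

    density: np.ndarray          # per-bin density, integrates to 1 over the range
    seed_count: int
    seed_range: tuple[float, float]


@dataclass
class IntensityModel:
    """Per-class Parzen histograms over one shared intensity binning."""

    bin_centers: np.ndarray
    classes: dict[int, ClassDensity]
    intensity_range: tuple[float, float]   # robust (1st, 99th pctile) range

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    def prob_mass(self, code: int) -> np.ndarray:
        """Per-bin probability mass (density x bin width); sums to 1."""
        return self.classes[code].density * self.bin_width

    def to_dict(self) -> dict:
        return {
            "bin_centers": self.bin_centers.tolist(),
            "intensity_range": list(self.intensity_range),
            "classes": {
                str(code): {
                    "density": cd.density.tolist(),
                    "seed_count": cd.seed_count,
                    "seed_range": list(cd.seed_range),
                }
                for code, cd in self.classes.items()
            },
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, payload: dict) -> "IntensityModel":
        return cls(
            bin_centers=np.asarray(payload["bin_centers"], dtype=float),
            intensity_range=tuple(payload["intensity_range"]),
            classes={
                int(code): ClassDensity(
                    density=np.asarray(entry["density"], dtype=float),
                    seed_count=int(entry["seed_count"]),
                    seed_range=tuple(entry["seed_range"]),
                )
                for code, entry in payload["classes"].items()
            },
        )


@dataclass
class DataCostField:
    """Per-voxel, per-class negative-log-likelihood costs.

    ``cost`` has shape ``(n_classes, *grid)``; channel ``c`` corresponds to
    tissue code ``c + 1`` (background, blood, myocardium, scar).
    """

    cost: np.ndarray
    spacing_mm: tuple[float, float, float]
    eps: float = EPS
    clip: float = field(default=-np.log(EPS))

    @property
    def n_classes(self) -> int:
        return self.cost.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.cost.shape[1:]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


def _silverman_bandwidth(x: np.ndarray, fallback: float) -> float:
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return fallback
    return 0.9 * spread * n ** (-0.2)


def fit_intensity_model(volume: Volume3D, seeds: LabelMap) -> IntensityModel:
    """Build per-class Parzen-smoothed intensity histograms from seed strokes.

    Every class listed in ``seeds.codes`` must have at least
    ``MIN_SEEDS_PER_CLASS`` seeded voxels.  The shared binning spans the
    volume's robust (1st-99th percentile) intensity range.
    """
    from .volio import check_same_grid

    check_same_grid(volume, seeds, "volume and seed map")
    lo, hi = np.percentile(volume.data, [1.0, 99.0])
    if hi <= lo:
        raise DegenerateInputError("volume has no intensity contrast (constant robust range)")
    # widen the robust range to cover every seed sample: sparse bright
    # classes (scar) occupy far less than 1% of the voxels, so a pure
    # volume percentile range would exclude them entirely
    seeded = volume.data[seeds.data > 0]
    if seeded.size:
        lo = min(lo, float(seeded.min()))
        hi = max(hi, float(seeded.max()))
    edges = np.linspace(lo, hi, N_BINS + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = float(centers[1] - centers[0])

    classes: dict[int, ClassDensity] = {}
    for code in sorted(seeds.codes):
        vals = np.asarray(volume.data[seeds.data == code], dtype=float)
        if vals.size < MIN_SEEDS_PER_CLASS:
            raise SeedingError(
                f"class {code} ({seeds.codes[code]}) has {vals.size} seed voxels; "
                f"at least {MIN_SEEDS_PER_CLASS} are required")
        h = _silverman_bandwidth(vals, fallback=width)
        # Parzen estimate evaluated at the bin centers (chunked: exhaustive
        # seeding can supply hundreds of thousands of samples)
        acc = np.zeros(N_BINS)
        for block in np.array_split(vals, max(1, vals.size // 65536)):
            z = (centers[:, None] - block[None, :]) / h
            acc += np.exp(-0.5 * z ** 2).sum(axis=1)
        dens = acc / (vals.size * h * np.sqrt(2 * np.pi))
        dens = np.maximum(dens, EPS)
        dens = dens / (dens.sum() * width)  # renormalize after flooring
        classes[code] = ClassDensity(density=dens, seed_count=int(vals.size),
                                     seed_range=(float(vals.min()), float(vals.max())))
    return IntensityModel(bin_centers=centers, classes=classes, intensity_range=(float(lo), float(hi)))


def data_costs(model: IntensityModel, volume: Volume3D, *,
               pin_seeds: LabelMap | None = None) -> DataCostField:
    """Evaluate per-voxel, per-class costs ``-log(P_l(I) + eps)``.

    Intensities outside the binned range fall to the epsilon floor for all
    classes (a cost tie at the clip value).  If ``pin_seeds`` is given,
    seeded voxels are made hard constraints: zero cost for the seeded class
    and the clip value for all others.
    """
    clip = -np.log(EPS)
    flat = np.asarray(volume.data, dtype=float).ravel()
    n_classes = len(model.classes)
    cost = np.empty((n_classes,) + volume.data.shape, dtype=np.float32)
    # interpolation nodes: bin centers, extended flat to the outer bin edges
    # so intensities inside the first/last bin keep that bin's mass; beyond
    # the binned range the probability drops to zero (cost ties at the clip)
    half = model.bin_width / 2.0
    for ch, code in enumerate(sorted(model.classes)):
        mass = model.prob_mass(code)
        xp = np.concatenate(([model.bin_centers[0] - half], model.bin_centers,
                             [model.bin_centers[-1] + half]))
        fp = np.concatenate(([mass[0]], mass, [mass[-1]]))
        p = np.interp(flat, xp, fp, left=0.0, right=0.0)
        c = -np.log(p + EPS)
        cost[ch] = np.clip(c, 0.0, clip).reshape(volume.data.shape).astype(np.float32)
    if pin_seeds is not None:
        for ch, code in enumerate(sorted(model.classes)):
            hit = pin_seeds.data == code
            cost[:, hit] = clip
            cost[ch, hit] = 0.0
    return DataCostField(cost=cost, spacing_mm=volume.spacing_mm, eps=EPS, clip=float(clip))
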