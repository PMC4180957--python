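"""Segmentation-agreement statistics.

Implements the validation battery used for scar segmentations: Dice
overlap, symmetric surface RMSE between 0.5-isolevel surfaces, volumes
in mL, Bland-Altman bias with limits of agreement, Pearson correlation,
cohort summaries, and the seed-perturbation observer-variability
battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import stats

from .errors import EmptySurfaceError, GridMismatchError, ScarflowError
from .volio import mask_to_mesh


# ---------------------------------------------------------------------------
# voxel-overlap and surface metrics
# ---------------------------------------------------------------------------

def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)``.

    Two empty masks agree perfectly on absence and score 1.0 (conventions
    differ; this one is documented).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (na + nb)


def _directed_rms(src: np.ndarray, tree: cKDTree) -> float:
    d, _ = tree.query(src, workers=1)
    return float(np.sqrt(np.mean(d ** 2)))


def surface_rmse(a: np.ndarray, b: np.ndarray, spacing_mm) -> float:
    """Symmetric surface RMSE in mm.

    Both masks are triangulated at the 0.5 isolevel in world mm; the RMS
    of vertex-to-nearest-surface-vertex Euclidean distances is computed in
    both directions and the two directed values are averaged.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise EmptySurfaceError("surface RMSE undefined for an empty mask")
    va, _ = mask_to_mesh(a, spacing_mm)
    vb, _ = mask_to_mesh(b, spacing_mm)
    rms_ab = _directed_rms(va, cKDTree(vb))
    rms_ba = _directed_rms(vb, cKDTree(va))
    return 0.5 * (rms_ab + rms_ba)


def mask_volume_ml(mask: np.ndarray, spacing_mm) -> float:
    """Voxel count times voxel volume, in mL (exact integer count, one multiply)."""
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
    return int(np.count_nonzero(mask)) * float(np.prod(spacing)) / 1000.0


# ---------------------------------------------------------------------------
# paired-measurement statistics
# ---------------------------------------------------------------------------

def bland_altman(pairs: Sequence[tuple[float, float]]):
    """Bland-Altman agreement of paired measurements (a - b).

    Returns ``(bias, loa_low, loa_high, ci_low, ci_high)`` where the limits
    of agreement are ``bias ± 1.96 sd`` and the confidence interval of the
    bias is ``bias ± 1.96 sd / sqrt(n)``.  Both dispersion measures are
    reported because published "95% CI" bands around a Bland-Altman bias
    are frequently limits of agreement under another name.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ScarflowError("bland_altman needs at least 2 (a, b) pairs")
    diff = arr[:, 0] - arr[:, 1]
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    n = len(diff)
    return (bias, bias - 1.96 * sd, bias + 1.96 * sd,
            bias - 1.96 * sd / np.sqrt(n), bias + 1.96 * sd / np.sqrt(n))


def pearson_r(pairs: Sequence[tuple[float, float]]) -> float:
    """Product-moment correlation of paired measurements."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ScarflowError("pearson_r needs at least 3 (a, b) pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ScarflowError("correlation undefined: one side has zero variance")
    return float(stats.pearsonr(arr[:, 0], arr[:, 1]).statistic)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

@dataclass
class CaseAgreement:
    case_id: str
    volume_a_ml: float
    volume_b_ml: float
    dice: float = np.nan
    surface_rmse_mm: float = np.nan

    @property
    def difference_ml(self) -> float:
        return self.volume_a_ml - self.volume_b_ml


@dataclass
class AgreementReport:
    """Per-case agreement rows plus cohort summary statistics."""

    cases: list[CaseAgreement] = field(default_factory=list)

    def add(self, case_id: str, volume_a_ml: float, volume_b_ml: float,
            dice: float = np.nan, surface_rmse_mm: float = np.nan) -> None:
        self.cases.append(CaseAgreement(case_id, float(volume_a_ml), float(volume_b_ml),
                                        float(dice), float(surface_rmse_mm)))

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def volume_pairs(self) -> list[tuple[float, float]]:
        return [(c.volume_a_ml, c.volume_b_ml) for c in self.cases]

    def summary(self) -> dict:
        if not self.cases:
            return {"n": 0}
        d = np.array([c.dice for c in self.cases])
        r = np.array([c.surface_rmse_mm for c in self.cases])
        va = np.array([c.volume_a_ml for c in self.cases])
        vb = np.array([c.volume_b_ml for c in self.cases])
        out = {
            "n": len(self.cases),
            "dice_mean": float(np.nanmean(d)) if not np.all(np.isnan(d)) else None,
            "dice_sd": float(np.nanstd(d, ddof=1)) if len(d) > 1 and not np.all(np.isnan(d)) else None,
            "surface_rmse_mean_mm": float(np.nanmean(r)) if not np.all(np.isnan(r)) else None,
            "surface_rmse_sd_mm": float(np.nanstd(r, ddof=1)) if len(r) > 1 and not np.all(np.isnan(r)) else None,
            "volume_a_mean_ml": float(va.mean()),
            "volume_a_sd_ml": float(va.std(ddof=1)) if len(va) > 1 else None,
            "volume_b_mean_ml": float(vb.mean()),
            "volume_b_sd_ml": float(vb.std(ddof=1)) if len(vb) > 1 else None,
        }
        if len(self.cases) >= 2:
            bias, lo, hi, ci_lo, ci_hi = bland_altman(self.volume_pairs)
            out.update({"bias_ml": bias, "loa_low_ml": lo, "loa_high_ml": hi,
                        "bias_ci_low_ml": ci_lo, "bias_ci_high_ml": ci_hi})
        if len(self.cases) >= 3:
            try:
                out["pearson_r"] = pearson_r(self.volume_pairs)
            except ScarflowError:
                out["pearson_r"] = None
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = ["case_id", "volume_a_ml", "volume_b_ml", "difference_ml",
                "dice", "surface_rmse_mm"]
        rows = [{"case_id": c.case_id, "volume_a_ml": c.volume_a_ml,
                 "volume_b_ml": c.volume_b_ml, "difference_ml": c.difference_ml,
                 "dice": c.dice, "surface_rmse_mm": c.surface_rmse_mm}
                for c in self.cases]
        return pd.DataFrame(rows, columns=cols)

    def to_dict(self) -> dict:
        return {"cases": self.to_frame().to_dict(orient="records"),
                "summary": self.summary()}

    @classmethod
    def from_dict(cls, payload: dict) -> "AgreementReport":
        rep = cls()
        for row in payload.get("cases", []):
            rep.add(row["case_id"], row["volume_a_ml"], row["volume_b_ml"],
                    row.get("dice", np.nan), row.get("surface_rmse_mm", np.nan))
        return rep


# ---------------------------------------------------------------------------
# observer-variability battery
# ---------------------------------------------------------------------------

def observer_battery(cases, n_observers: int = 2, n_repeats: int = 2,
                     seed_params: dict | None = None, rng_seed: int = 0,
                     **segment_kwargs) -> tuple[AgreementReport, AgreementReport]:
    """Simulate repeated seeded segmentations by independent observers.

    An *observer* is a persistent seeding style (stroke size and erosion
    depth drawn once per observer); a *repeat* re-runs the same style with
    fresh random stroke placement.  Each (case, observer, repeat) triplet
    is segmented end to end; scar volumes are then paired into an
    intra-observer report (same observer, consecutive repeats) and an
    inter-observer report (first repeat of each observer pair).

    Mirroring the clinical protocol, the intra-observer report pairs the
    reference observer's first run against each of their repeats, and the
    inter-observer report pairs the reference observer's first run against
    each other observer's first run.  With ``n_repeats - 1`` equal to
    ``n_observers - 1`` the two reports have the same number of pairs, so
    their correlations are compared at equal n.  Only the runs a report
    needs are segmented.

    ``cases`` may be one phantom case or a list; correlations need at
    least 3 pairs.  Returns ``(intra_report, inter_report)``.
    """
    from .pipeline import segment_case
    from .phantom import auto_seeds

    if n_observers < 2 or n_repeats < 2:
        raise ScarflowError("observer battery needs >= 2 observers and >= 2 repeats")
    if not isinstance(cases, (list, tuple)):
        cases = [cases]
    seed_params = dict(seed_params or {})
    # brush-habit styles (placement, erosion depth, stroke size): observers
    # differ systematically, so distinct styles are drawn without
    # replacement.  The default pool spans three habits with clearly
    # different intensity sampling: a deep-core brusher, an
    # along-the-margin brusher, and a near-boundary brusher; erosion depth
    # and placement set per-observer offsets that interact with case
    # geometry, which is what separates inter- from intra-observer
    # variation
    # observers place strokes with the repeatable "dab" shape: an observer's
    # hand repeats its own gesture closely, which is exactly what separates
    # intra- from inter-observer variation
    style_pool = [tuple(s) for s in seed_params.get(
        "styles", [("center", 5, 300), ("edge", 2, 300), ("center", 1, 300)])]
    style_rng = np.random.default_rng([rng_seed, 7919])
    if len(style_pool) >= n_observers:
        chosen = style_rng.choice(len(style_pool), size=n_observers, replace=False)
    else:
        chosen = style_rng.choice(len(style_pool), size=n_observers, replace=True)
    styles = [{"placement": style_pool[i][0],
               "erosion_radius_vox": style_pool[i][1],
               "strokes_per_class": style_pool[i][2],
               "stroke_shape": style_pool[i][3] if len(style_pool[i]) > 3 else "dab"}
              for i in chosen]

    def run(ci, case, obs, rep):
        seeds = auto_seeds(case.truth,
                           erosion_radius_vox=styles[obs]["erosion_radius_vox"],
                           strokes_per_class=styles[obs]["strokes_per_class"],
                           placement=styles[obs]["placement"],
                           stroke_shape=styles[obs]["stroke_shape"],
                           rng_seed=[rng_seed, ci, obs, rep])
        _, scar = segment_case(case.lge, seeds, **segment_kwargs)
        return mask_volume_ml(scar.data, case.truth.spacing_mm)

    intra = AgreementReport()
    inter = AgreementReport()
    for ci, case in enumerate(cases):
        ref = run(ci, case, 0, 0)
        for rep in range(1, n_repeats):
            intra.add(f"case{ci}_rep{rep}", ref, run(ci, case, 0, rep))
        for obs in range(1, n_observers):
            inter.add(f"case{ci}_obs0v{obs}", ref, run(ci, case, obs, 0))
    return intra, inter
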