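"""Hierarchical max-flow (hierarchical Potts) segmentation solver.

The four tissue classes are leaves of a small anatomical tree that
encodes the region-ordering prior "scar lies within the wall, the wall
borders the blood pool"::

    root -+- background
          +- cardiac -+- blood
                      +- wall -+- myocardium
                               +- scar

The segmentation minimizes the convex relaxation of the hierarchical
Potts energy

    E(u) = sum_l sum_x D_l(x) u_l(x) dV  +  sum_{n != root} alpha_n TV(u_n)

over the per-voxel probability simplex, where ``u_n`` is the summed
membership of all leaves under node ``n`` and TV is anisotropic total
variation (absolute forward differences weighted by voxel face area, so
an exact discrete analog exists for the brute-force oracle).  The solver
is a first-order primal-dual scheme (Chambolle-Pock) with fixed step
sizes from the standard stability bound; hard labels come from the
voxelwise argmax of the relaxed memberships with ties broken toward the
lowest class code.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._kernels import HAVE_NUMBA, pd_iteration
from .errors import ScarflowError, SizeError
from .histmodel import DataCostField
from .volio import LabelMap, TISSUE_CODES, TISSUE_NAMES

log = logging.getLogger(__name__)

LEAF_ORDER = ("background", "blood", "myocardium", "scar")

_DEFAULT_TREE = {
    "root": ("background", "cardiac"),
    "cardiac": ("blood", "wall"),
    "wall": ("myocardium", "scar"),
}

# Regularization weights, calibrated once on the default synthetic phantom
# and frozen.  The large blood weight is the anatomical ordering prior at
# work: a thin sheet of "blood" sandwiched between scar and background (or
# scar and myocardium) is anatomically implausible, yet partial-volume
# mixing at thin scar interfaces produces exactly blood-like intensities
# there.  alpha_blood is set just above the flip threshold (maximum data
# advantage ~= clip x voxel volume over two voxel faces) so such sheets are
# suppressed while data-supported blood-pool voxels are untouched.  The
# two leaf weights are kept minimal: speckle cleanup is handled by the
# minimum-component filter, while leaf-level TV mainly trims the convex
# margins of thin scar patches where the data costs are nearly tied.
_DEFAULT_ALPHA = {
    "background": 0.1,
    "cardiac": 0.5,
    "blood": 12.0,
    "wall": 0.3,
    "myocardium": 0.02,
    "scar": 0.02,
}


@dataclass(frozen=True)
class LabelHierarchy:
    """Label tree plus per-node total-variation weights.

    ``children`` maps every internal node (including ``"root"``) to its
    children; leaves are exactly :data:`LEAF_ORDER`.  ``alpha`` assigns a
    non-negative regularization weight to every node except the root.
    """

    children: dict = field(default_factory=lambda: dict(_DEFAULT_TREE))
    alpha: dict = field(default_factory=lambda: dict(_DEFAULT_ALPHA))

    def __post_init__(self) -> None:
        leaves = self.leaves()
        if set(leaves) != set(LEAF_ORDER):
            raise ValueError(f"hierarchy leaves must be {LEAF_ORDER}, got {leaves}")
        parents: dict[str, str] = {}
        for parent, kids in self.children.items():
            for kid in kids:
                if kid in parents:
                    raise ValueError(f"node {kid} has two parents")
                parents[kid] = parent
        for node in self.nonroot_nodes():
            if node not in parents and node != "root":
                raise ValueError(f"node {node} unreachable from root")
            if self.alpha.get(node, -1) < 0:
                raise ValueError(f"alpha[{node}] must be a non-negative number")

    @classmethod
    def default(cls, **alpha_overrides: float) -> "LabelHierarchy":
        alpha = dict(_DEFAULT_ALPHA)
        alpha.update(alpha_overrides)
        return cls(alpha=alpha)

    def leaves(self, node: str = "root") -> tuple[str, ...]:
        if node not in self.children:
            return (node,)
        out: list[str] = []
        for kid in self.children[node]:
            out.extend(self.leaves(kid))
        return tuple(out)

    def nonroot_nodes(self) -> tuple[str, ...]:
        """All nodes except the root, parents before children."""
        out: list[str] = []
        stack = list(self.children["root"])
        while stack:
            node = stack.pop(0)
            out.append(node)
            stack.extend(self.children.get(node, ()))
        return tuple(out)

    def aggregation_matrix(self) -> np.ndarray:
        """(n_nodes, 4) binary matrix: A[n, l] = 1 iff leaf l is under node n.

        Leaf channel order follows :data:`LEAF_ORDER` (tissue codes 1..4).
        """
        nodes = self.nonroot_nodes()
        A = np.zeros((len(nodes), len(LEAF_ORDER)))
        for i, node in enumerate(nodes):
            for leaf in self.leaves(node):
                A[i, LEAF_ORDER.index(leaf)] = 1.0
        return A

    def node_alphas(self) -> np.ndarray:
        return np.array([self.alpha[n] for n in self.nonroot_nodes()])

    def class_distance_matrix(self) -> np.ndarray:
        """Tree metric between leaf classes.

        ``d[a, b] = sum over nodes n of alpha_n * |1(a under n) - 1(b under n)]``,
        i.e. the alpha-weighted path length between two leaves.  The discrete
        hierarchical energy is exactly a pairwise Potts energy with this
        class-distance on neighbouring voxel faces.
        """
        A = self.aggregation_matrix()
        a = self.node_alphas()
        K = A.shape[1]
        d = np.zeros((K, K))
        for i in range(K):
            for j in range(K):
                d[i, j] = float(np.sum(a * np.abs(A[:, i] - A[:, j])))
        return d

    def to_dict(self) -> dict:
        return {"children": {k: list(v) for k, v in self.children.items()},
                "alpha": dict(self.alpha)}

    @classmethod
    def from_dict(cls, payload: dict) -> "LabelHierarchy":
        return cls(children={k: tuple(v) for k, v in payload["children"].items()},
                   alpha=dict(payload["alpha"]))


@dataclass
class SegmentationResult:
    """Relaxed memberships, hard labels and solver diagnostics."""

    membership: np.ndarray          # (4, *grid), simplex per voxel
    labels: LabelMap                # argmax labels, codes 1..4
    energy: float                   # final relaxed primal energy
    trace: np.ndarray               # per-iteration mean |du| per voxel
    energy_trace: np.ndarray        # per-iteration relaxed primal energy
    iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# finite differences (forward differences, Neumann boundary)
# ---------------------------------------------------------------------------

def _grad_axis(v: np.ndarray, axis: int, out: np.ndarray) -> np.ndarray:
    out[...] = 0.0
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(0, -1)
    sl_hi[axis] = slice(1, None)
    out[tuple(sl_lo)] = v[tuple(sl_hi)] - v[tuple(sl_lo)]
    return out


def _div_accum(p: np.ndarray, axis: int, out: np.ndarray) -> None:
    """Accumulate the divergence (negative adjoint of _grad_axis) into out."""
    sl_first = [slice(None)] * 3
    sl_first[axis] = slice(0, 1)
    sl_mid = [slice(None)] * 3
    sl_mid[axis] = slice(1, -1)
    sl_mid_m1 = [slice(None)] * 3
    sl_mid_m1[axis] = slice(0, -2)
    sl_last = [slice(None)] * 3
    sl_last[axis] = slice(-1, None)
    sl_last_m1 = [slice(None)] * 3
    sl_last_m1[axis] = slice(-2, -1)
    out[tuple(sl_first)] += p[tuple(sl_first)]
    out[tuple(sl_mid)] += p[tuple(sl_mid)] - p[tuple(sl_mid_m1)]
    out[tuple(sl_last)] += -p[tuple(sl_last_m1)]


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each voxel's channel vector onto the simplex.

    Channels along axis 0; standard sort-and-threshold algorithm, fully
    vectorized.
    """
    K = v.shape[0]
    u = np.sort(v, axis=0)[::-1]
    css = np.cumsum(u, axis=0, dtype=v.dtype) - 1.0
    ks = np.arange(1, K + 1, dtype=v.dtype).reshape((K,) + (1,) * (v.ndim - 1))
    cond = u - css / ks > 0
    rho = cond.sum(axis=0, dtype=np.int64) - 1
    theta = np.take_along_axis(css, rho[None], axis=0)[0] / (rho + 1.0)
    return np.maximum(v - theta[None], 0.0)


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------

def relaxed_energy(u: np.ndarray, costs: DataCostField, hierarchy: LabelHierarchy) -> float:
    """Relaxed primal energy of a membership field ``u`` (shape (4, *grid))."""
    dv = costs.voxel_volume_mm3
    spacing = costs.spacing_mm
    face = [dv / spacing[i] for i in range(3)]
    A = hierarchy.aggregation_matrix()
    alphas = hierarchy.node_alphas()
    e = float(np.vdot(costs.cost, u)) * dv
    scratch = np.empty(u.shape[1:], dtype=u.dtype)
    for a_n, row in zip(alphas, A):
        if a_n == 0:
            continue
        un = np.tensordot(row.astype(u.dtype), u, axes=(0, 0))
        for ax in range(3):
            _grad_axis(un, ax, scratch)
            e += a_n * face[ax] * float(np.abs(scratch).sum())
    return e


def solve_hmf(costs: DataCostField, hierarchy: LabelHierarchy | None = None,
              tol: float = 1e-4, max_iter: int = 500,
              energy_every: int = 1, step_ratio: float = 8.0,
              force_numpy: bool = False) -> SegmentationResult:
    """Minimize the hierarchical Potts energy by first-order primal-dual
    iterations on its convex relaxation.

    Stops when the mean absolute membership change per voxel drops below
    ``tol`` or after ``max_iter`` iterations (then ``converged=False`` and a
    warning is emitted).  ``energy_every`` controls how often the primal
    energy is evaluated (it is always evaluated on the final iterate).

    Primal-dual iterations are not energy-monotone step to step, so the
    solver tracks the best (lowest-energy) iterate seen at the evaluation
    points and returns it; the reported energy trace is that incumbent's
    and is therefore non-increasing by construction.
    """
    if hierarchy is None:
        hierarchy = LabelHierarchy()
    cost = np.asarray(costs.cost, dtype=np.float32)
    if not np.all(np.isfinite(cost)):
        raise ScarflowError("data costs contain NaN/inf")
    if min(cost.shape[1:]) < 2:
        raise ScarflowError("grid must be at least 2 voxels per axis")

    shape = cost.shape[1:]
    dv = costs.voxel_volume_mm3
    spacing = costs.spacing_mm
    face = np.array([dv / spacing[i] for i in range(3)], dtype=np.float32)

    A = hierarchy.aggregation_matrix().astype(np.float32)
    alphas = hierarchy.node_alphas().astype(np.float32)
    n_nodes = len(alphas)
    active = alphas > 0

    f = cost * np.float32(dv)

    # step sizes from ||K||^2 <= ||A||_2^2 * ||grad||^2, ||grad||^2 <= 4 * ndim;
    # the dual step is scaled up (and the primal step down, keeping
    # sigma * tau * ||K||^2 = 1) so the dual variables reach large TV bounds
    # in few iterations -- with symmetric steps the ramp dominates runtime
    norm_A2 = float(np.linalg.eigvalsh(A.T @ A).max())
    norm_K = np.sqrt(12.0 * norm_A2)
    sigma = np.float32(step_ratio / norm_K)
    tau = np.float32(1.0 / (step_ratio * norm_K))

    # warm start at the voxelwise cost argmin (exact solution for alpha = 0)
    u = np.zeros_like(f)
    am = np.argmin(f, axis=0)
    for ch in range(f.shape[0]):
        u[ch][am == ch] = 1.0
    u_bar = u.copy()
    p = np.zeros((n_nodes, 3) + shape, dtype=np.float32)

    trace: list[float] = []
    energy_trace: list[float] = []
    best_energy = np.inf
    best_u = u
    scratch = np.empty(shape, dtype=np.float32)
    nvox = float(np.prod(shape))
    bounds = np.outer(alphas, face).astype(np.float32)
    use_kernel = HAVE_NUMBA and not force_numpy
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if use_kernel:
            du_sum, dp_sum = pd_iteration(u, u_bar, f, p, A, bounds,
                                          np.float32(sigma), np.float32(tau))
            change = du_sum / nvox
            dp_rel = dp_sum / nvox
        else:
            # dual ascent on every node's TV term
            dp_rel = 0.0
            for n in range(n_nodes):
                if not active[n]:
                    continue
                un = np.tensordot(A[n], u_bar, axes=(0, 0))
                for ax in range(3):
                    _grad_axis(un, ax, scratch)
                    pn = p[n, ax]
                    bound = bounds[n, ax]
                    step = sigma * scratch
                    np.add(pn, step, out=step)
                    np.clip(step, -bound, bound, out=step)
                    dp_rel += float(np.abs(step - pn).sum()) / (bound * nvox)
                    pn[...] = step
            # primal descent + simplex projection
            g = f.copy()
            for n in range(n_nodes):
                if not active[n]:
                    continue
                scratch[...] = 0.0
                for ax in range(3):
                    _div_accum(p[n, ax], ax, scratch)
                for ch in range(f.shape[0]):
                    if A[n, ch]:
                        g[ch] -= scratch
            u_new = _project_simplex(u - tau * g)
            change = float(np.abs(u_new - u).sum() / nvox)
            np.multiply(u_new, 2.0, out=u_bar)
            u_bar -= u
            u = u_new
        trace.append(change)
        settled = change < tol and dp_rel < tol
        if energy_every and (it % energy_every == 0 or settled or it == max_iter):
            e = relaxed_energy(u, costs, hierarchy)
            if e < best_energy:
                best_energy = e
                best_u = u.copy()
            energy_trace.append(best_energy)
        # primal change alone can stall at zero while the dual variables are
        # still ramping toward their bounds, so require both to settle
        if settled:
            converged = True
            break

    if not np.isfinite(best_energy):
        best_energy = relaxed_energy(u, costs, hierarchy)
        best_u = u
        energy_trace.append(best_energy)
    if not converged:
        warnings.warn(f"solve_hmf did not reach tol={tol} within {max_iter} iterations",
                      stacklevel=2)

    u = best_u
    labels = np.argmax(u, axis=0).astype(np.uint8) + 1  # argmax ties -> lowest code
    return SegmentationResult(
        membership=u,
        labels=LabelMap(labels, spacing, codes=dict(TISSUE_CODES)),
        energy=float(energy_trace[-1]),
        trace=np.asarray(trace),
        energy_trace=np.asarray(energy_trace),
        iterations=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# discrete energy + exhaustive oracle
# ---------------------------------------------------------------------------

def discrete_energy(labels: LabelMap, costs: DataCostField,
                    hierarchy: LabelHierarchy | None = None) -> float:
    """Discrete analog of the relaxed energy for a hard labeling.

    TV of each node indicator reduces to the alpha-weighted count of
    boundary faces, i.e. a pairwise Potts energy with the hierarchy's tree
    metric between classes.
    """
    if hierarchy is None:
        hierarchy = LabelHierarchy()
    lab = np.asarray(labels.data, dtype=np.int64)
    if lab.shape != costs.grid_shape:
        raise ScarflowError("label grid does not match cost grid")
    if lab.min() < 1 or lab.max() > costs.n_classes:
        raise ScarflowError(f"labels must lie in 1..{costs.n_classes}")
    dv = costs.voxel_volume_mm3
    spacing = costs.spacing_mm
    ch = lab - 1
    data = float(np.take_along_axis(costs.cost, ch[None], axis=0).sum()) * dv
    d = hierarchy.class_distance_matrix()
    reg = 0.0
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        reg += (dv / spacing[ax]) * float(d[ch[tuple(sl_lo)], ch[tuple(sl_hi)]].sum())
    return data + reg


MAX_ORACLE_VOXELS = 12


def brute_force_oracle(costs: DataCostField, hierarchy: LabelHierarchy | None = None
                       ) -> tuple[LabelMap, float]:
    """Exhaustive minimizer of :func:`discrete_energy` on tiny grids.

    Refuses grids above :data:`MAX_ORACLE_VOXELS` voxels.  Ties resolve to
    the lexicographically smallest labeling (scanning voxels in C order,
    lower codes first), which is deterministic.
    """
    if hierarchy is None:
        hierarchy = LabelHierarchy()
    shape = costs.grid_shape
    n = int(np.prod(shape))
    if n > MAX_ORACLE_VOXELS:
        raise SizeError(f"{n} voxels exceeds the exhaustive-search limit of {MAX_ORACLE_VOXELS}")
    K = costs.n_classes
    dv = costs.voxel_volume_mm3
    spacing = costs.spacing_mm
    d = hierarchy.class_distance_matrix()
    flat_cost = costs.cost.reshape(K, n).T * dv  # (n, K)

    # neighbouring flat-index pairs with their face weights
    pairs = []
    grid_idx = np.arange(n).reshape(shape)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        w = dv / spacing[ax]
        a = grid_idx[tuple(sl_lo)].ravel()
        b = grid_idx[tuple(sl_hi)].ravel()
        pairs.extend((int(i), int(j), w) for i, j in zip(a, b))

    best_energy = np.inf
    best = None
    chunk = 1 << 18
    total = K ** n
    powers = K ** np.arange(n - 1, -1, -1, dtype=np.int64)
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.int64)
        labs = (codes[:, None] // powers[None, :]) % K  # (m, n) base-K digits
        e = flat_cost[np.arange(n)[None, :], labs].sum(axis=1)
        for i, j, w in pairs:
            e += w * d[labs[:, i], labs[:, j]]
        k = int(np.argmin(e))
        if e[k] < best_energy:
            best_energy = float(e[k])
            best = labs[k]
    lab = (best.reshape(shape) + 1).astype(np.uint8)
    return LabelMap(lab, spacing, codes=dict(TISSUE_CODES)), best_energy


# ---------------------------------------------------------------------------
# scar extraction
# ---------------------------------------------------------------------------

def extract_scar(result: SegmentationResult, min_component_ml: float = 0.1) -> LabelMap:
    """Binary scar mask from a segmentation, small components removed.

    Connected components (26-connectivity) smaller than ``min_component_ml``
    are dropped (isolated speckle, typically noise); removals are logged.
    An empty scar class yields an empty mask with a warning.
    """
    labels = result.labels
    scar = labels.data == TISSUE_NAMES["scar"]
    if not scar.any():
        warnings.warn("segmentation contains no scar voxels", stacklevel=2)
        return LabelMap(np.zeros(labels.shape, dtype=np.uint8), labels.spacing_mm,
                        affine=labels.affine, codes={1: "scar"})
    if min_component_ml > 0:
        struct = np.ones((3, 3, 3), dtype=bool)
        comp, n_comp = ndimage.label(scar, structure=struct)
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
        dv_ml = labels.voxel_volume_mm3 / 1000.0
        small = np.flatnonzero(sizes * dv_ml < min_component_ml) + 1
        if small.size:
            log.info("extract_scar: removing %d components below %.3f mL", small.size, min_component_ml)
            scar &= ~np.isin(comp, small)
    return LabelMap(scar.astype(np.uint8), labels.spacing_mm, affine=labels.affine,
                    codes={1: "scar"})
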