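import itertools

import numpy as np
import pytest

from scarflow.errors import ScarflowError, SizeError
from scarflow.histmodel import DataCostField
from scarflow.hmfsolver import (LabelHierarchy, SegmentationResult,
                                brute_force_oracle, discrete_energy,
                                extract_scar, solve_hmf)
from scarflow.volio import LabelMap


def _costs(arr, spacing=1.0):
    return DataCostField(np.asarray(arr, dtype=np.float32), (spacing,) * 3)


def _zero_alpha():
    return LabelHierarchy.default(background=0.0, cardiac=0.0, blood=0.0,
                                  wall=0.0, myocardium=0.0, scar=0.0)


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------

def test_default_hierarchy_structure():
    h = LabelHierarchy()
    assert set(h.leaves()) == {"background", "blood", "myocardium", "scar"}
    A = h.aggregation_matrix()
    nodes = h.nonroot_nodes()
    # every leaf is under itself and all its ancestors
    assert A[nodes.index("cardiac")].tolist() == [0, 1, 1, 1]
    assert A[nodes.index("wall")].tolist() == [0, 0, 1, 1]
    assert A[nodes.index("scar")].tolist() == [0, 0, 0, 1]


def test_class_distance_is_alpha_weighted_tree_metric():
    h = LabelHierarchy.default(background=0.1, cardiac=0.5, blood=0.3,
                               wall=0.3, myocardium=0.15, scar=0.15)
    d = h.class_distance_matrix()
    np.testing.assert_allclose(np.diag(d), 0)
    np.testing.assert_allclose(d, d.T)
    # hand-computed path lengths for these alphas
    assert d[0, 1] == pytest.approx(0.1 + 0.5 + 0.3)          # bg <-> blood
    assert d[0, 3] == pytest.approx(0.1 + 0.5 + 0.3 + 0.15)   # bg <-> scar
    assert d[2, 3] == pytest.approx(0.15 + 0.15)              # myo <-> scar
    assert d[1, 2] == pytest.approx(0.3 + 0.3 + 0.15)         # blood <-> myo


def test_bad_hierarchy_rejected():
    with pytest.raises(ValueError):
        LabelHierarchy(children={"root": ("background", "blood")})
    with pytest.raises(ValueError):
        LabelHierarchy.default(blood=-1.0)


# ---------------------------------------------------------------------------
# solver limits
# ---------------------------------------------------------------------------

def test_zero_alpha_limit_equals_voxelwise_argmin_exactly():
    rng = np.random.default_rng(0)
    costs = _costs(rng.uniform(0, 5, (4, 5, 4, 3)))
    res = solve_hmf(costs, _zero_alpha())
    np.testing.assert_array_equal(res.labels.data,
                                  np.argmin(costs.cost, axis=0) + 1)


def test_zero_alpha_tie_breaks_to_lowest_code():
    arr = np.full((4, 2, 2, 2), 3.0, dtype=np.float32)
    arr[1] = 1.0
    arr[3] = 1.0  # blood and scar tie
    res = solve_hmf(_costs(arr), _zero_alpha())
    assert (res.labels.data == 2).all()


def test_tv_dominated_limit_gives_constant_labeling():
    rng = np.random.default_rng(1)
    # two-class toy: myocardium and scar priced out everywhere
    arr = rng.uniform(0, 2, (4, 3, 3, 3)).astype(np.float32)
    arr[2:] = 50.0
    total = arr.reshape(4, -1).sum(axis=1)
    h = LabelHierarchy.default(background=1e6, cardiac=1e6, blood=1e6,
                               wall=1e6, myocardium=1e6, scar=1e6)
    res = solve_hmf(_costs(arr), h, max_iter=2000)
    assert len(np.unique(res.labels.data)) == 1
    assert int(np.unique(res.labels.data)[0]) == int(np.argmin(total)) + 1


# ---------------------------------------------------------------------------
# discrete energy
# ---------------------------------------------------------------------------

def test_uniform_labeling_energy_is_pure_data_term():
    rng = np.random.default_rng(2)
    costs = _costs(rng.uniform(0, 3, (4, 3, 2, 2)), spacing=1.3)
    for code in (1, 2, 3, 4):
        lab = LabelMap(np.full((3, 2, 2), code, dtype=np.uint8), 1.3)
        expected = costs.cost[code - 1].sum() * 1.3 ** 3
        assert discrete_energy(lab, costs) == pytest.approx(expected, rel=1e-6)


def test_single_flip_energy_delta_hand_computed():
    h = LabelHierarchy.default(background=0.1, cardiac=0.5, blood=0.3,
                               wall=0.3, myocardium=0.15, scar=0.15)
    rng = np.random.default_rng(3)
    cost = rng.uniform(0, 3, (4, 2, 1, 1)).astype(np.float32)
    costs = _costs(cost, spacing=2.0)
    base = LabelMap(np.full((2, 1, 1), 1, dtype=np.uint8), 2.0)
    flipped = LabelMap(np.array([1, 4], dtype=np.uint8).reshape(2, 1, 1), 2.0)
    dv, face = 8.0, 4.0
    d_bg_scar = 0.1 + 0.5 + 0.3 + 0.15
    delta = (cost[3, 1, 0, 0] - cost[0, 1, 0, 0]) * dv + d_bg_scar * face
    assert (discrete_energy(flipped, costs, h) - discrete_energy(base, costs, h)
            == pytest.approx(delta, rel=1e-5))


def test_energy_invariant_under_symmetric_class_swap():
    # myocardium and scar have equal alphas; swapping their costs and labels
    # leaves the energy unchanged
    rng = np.random.default_rng(4)
    cost = rng.uniform(0, 3, (4, 3, 3, 2)).astype(np.float32)
    lab = rng.integers(1, 5, (3, 3, 2)).astype(np.uint8)
    swapped_cost = cost.copy()
    swapped_cost[[2, 3]] = cost[[3, 2]]
    swapped_lab = lab.copy()
    swapped_lab[lab == 3] = 4
    swapped_lab[lab == 4] = 3
    h = LabelHierarchy()
    e1 = discrete_energy(LabelMap(lab, 1.0), _costs(cost), h)
    e2 = discrete_energy(LabelMap(swapped_lab, 1.0), _costs(swapped_cost), h)
    assert e1 == pytest.approx(e2, rel=1e-6)


def test_discrete_energy_rejects_bad_labels():
    costs = _costs(np.zeros((4, 2, 2, 2)))
    with pytest.raises(ScarflowError):
        discrete_energy(LabelMap(np.zeros((2, 2, 2), dtype=np.uint8), 1.0), costs)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def test_oracle_equals_argmin_without_regularization():
    rng = np.random.default_rng(5)
    costs = _costs(rng.uniform(0, 3, (4, 2, 2, 2)))
    lab, energy = brute_force_oracle(costs, _zero_alpha())
    np.testing.assert_array_equal(lab.data, np.argmin(costs.cost, axis=0) + 1)


def test_oracle_matches_independent_enumeration_on_2x2x1():
    """Cross-check against a from-scratch enumeration that recomputes the
    hierarchical boundary term from node indicators, not the tree metric."""
    h = LabelHierarchy.default(background=0.2, cardiac=0.4, blood=0.25,
                               wall=0.3, myocardium=0.1, scar=0.12)
    cost = np.array([[[[2.0], [0.5]], [[1.0], [1.5]]],
                     [[[0.3], [2.5]], [[0.7], [0.2]]],
                     [[[1.2], [0.4]], [[2.2], [0.9]]],
                     [[[0.8], [1.1]], [[0.1], [2.0]]]], dtype=np.float32)
    costs = _costs(cost, spacing=1.3)
    nodes = h.nonroot_nodes()
    A = h.aggregation_matrix()
    alphas = h.node_alphas()
    dv = 1.3 ** 3
    face = dv / 1.3
    neighbors = [((0, 0, 0), (1, 0, 0)), ((0, 1, 0), (1, 1, 0)),
                 ((0, 0, 0), (0, 1, 0)), ((1, 0, 0), (1, 1, 0))]

    best, best_e = None, np.inf
    for combo in itertools.product(range(4), repeat=4):
        lab = np.array(combo).reshape(2, 2, 1)
        e = sum(cost[lab[x], x[0], x[1], x[2]]
                for x in np.ndindex(2, 2, 1)) * dv
        for va, vb in neighbors:
            for n in range(len(nodes)):
                ia = A[n, lab[va]]
                ib = A[n, lab[vb]]
                e += alphas[n] * face * abs(ia - ib)
        if e < best_e:
            best_e, best = e, lab + 1
    lab_pkg, e_pkg = brute_force_oracle(costs, h)
    assert e_pkg == pytest.approx(best_e, rel=1e-6)
    np.testing.assert_array_equal(lab_pkg.data, best)


def test_oracle_beats_heuristic_labelings():
    rng = np.random.default_rng(6)
    costs = _costs(rng.uniform(0, 3, (4, 2, 2, 2)), spacing=1.3)
    h = LabelHierarchy()
    _, e_opt = brute_force_oracle(costs, h)
    argmin_lab = LabelMap((np.argmin(costs.cost, axis=0) + 1).astype(np.uint8), 1.3)
    assert e_opt <= discrete_energy(argmin_lab, costs, h) + 1e-6
    for _ in range(10):
        lab = LabelMap(rng.integers(1, 5, (2, 2, 2)).astype(np.uint8), 1.3)
        assert e_opt <= discrete_energy(lab, costs, h) + 1e-6


def test_oracle_refuses_large_grids():
    with pytest.raises(SizeError):
        brute_force_oracle(_costs(np.zeros((4, 3, 3, 2))))


# ---------------------------------------------------------------------------
# relaxation quality, conservation, convergence
# ---------------------------------------------------------------------------

def test_relaxed_solution_within_5pct_of_discrete_optimum():
    rng = np.random.default_rng(7)
    h = LabelHierarchy()
    worst = 0.0
    for _ in range(50):
        costs = _costs(rng.uniform(0, 3, (4, 2, 2, 2)).astype(np.float32), spacing=1.3)
        _, e_opt = brute_force_oracle(costs, h)
        res = solve_hmf(costs, h, tol=1e-6, max_iter=3000)
        e_rel = discrete_energy(res.labels, costs, h)
        worst = max(worst, e_rel / e_opt)
    assert worst <= 1.05


def test_simplex_conservation_and_energy_monotone(small_case, small_seeds):
    from scarflow.histmodel import data_costs, fit_intensity_model

    model = fit_intensity_model(small_case.lge, small_seeds)
    costs = data_costs(model, small_case.lge)
    res = solve_hmf(costs, energy_every=5)
    total = res.membership.sum(axis=0)
    assert np.abs(total - 1.0).max() <= 1e-4
    assert (res.membership >= -1e-6).all()
    assert (np.diff(res.energy_trace) <= 1e-6 * abs(res.energy_trace[0])).all()
    assert res.converged
    assert res.trace[-1] < 1e-4


def test_kernel_and_numpy_paths_agree():
    from scarflow._kernels import HAVE_NUMBA

    if not HAVE_NUMBA:
        return  # single path; nothing to cross-check
    rng = np.random.default_rng(8)
    costs = _costs(rng.uniform(0, 6, (4, 12, 10, 8)), spacing=1.3)
    a = solve_hmf(costs, max_iter=80, energy_every=0, tol=0.0)
    b = solve_hmf(costs, max_iter=80, energy_every=0, tol=0.0, force_numpy=True)
    assert (a.labels.data == b.labels.data).mean() > 0.999
    assert np.abs(a.membership - b.membership).max() < 1e-4


def test_nan_costs_rejected_and_nonconvergence_warns():
    bad = np.zeros((4, 2, 2, 2), dtype=np.float32)
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ScarflowError):
        solve_hmf(_costs(bad))
    rng = np.random.default_rng(9)
    costs = _costs(rng.uniform(0, 3, (4, 4, 4, 4)))
    with pytest.warns(UserWarning, match="did not reach"):
        res = solve_hmf(costs, max_iter=2)
    assert not res.converged


# ---------------------------------------------------------------------------
# scar extraction
# ---------------------------------------------------------------------------

def _result_from_labels(lab: np.ndarray, spacing=1.3) -> SegmentationResult:
    u = np.zeros((4,) + lab.shape, dtype=np.float32)
    for ch in range(4):
        u[ch][lab == ch + 1] = 1.0
    return SegmentationResult(
        membership=u, labels=LabelMap(lab.astype(np.uint8), spacing),
        energy=0.0, trace=np.zeros(1), energy_trace=np.zeros(1),
        iterations=1, converged=True)


def test_extract_scar_identity_without_threshold():
    lab = np.ones((6, 6, 6), dtype=np.uint8)
    lab[2:4, 2:4, 2:4] = 4
    res = _result_from_labels(lab)
    mask = extract_scar(res, min_component_ml=0.0)
    np.testing.assert_array_equal(mask.data.astype(bool), lab == 4)


def test_extract_scar_removes_subthreshold_speckle():
    lab = np.ones((10, 10, 10), dtype=np.uint8)
    lab[2:5, 2:5, 2:5] = 4           # 27 voxels = 0.059 mL at 1.3 mm -> removed
    lab[8, 8, 8] = 4                 # isolated speckle -> removed
    res = _result_from_labels(lab)
    assert not extract_scar(res, min_component_ml=0.1).data.any()
    # a 1 mL component survives
    lab2 = np.ones((12, 12, 12), dtype=np.uint8)
    lab2[1:9, 1:9, 1:8] = 4
    kept = extract_scar(_result_from_labels(lab2), min_component_ml=0.1)
    assert kept.data.sum() == (lab2 == 4).sum()


def test_extract_scar_empty_warns():
    lab = np.ones((4, 4, 4), dtype=np.uint8)
    with pytest.warns(UserWarning, match="no scar"):
        mask = extract_scar(_result_from_labels(lab))
    assert not mask.data.any()
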