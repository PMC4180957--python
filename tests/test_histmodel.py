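import numpy as np
import pytest

from scarflow.errors import DegenerateInputError, SeedingError
from scarflow.histmodel import IntensityModel, data_costs, fit_intensity_model
from scarflow.phantom import auto_seeds
from scarflow.volio import LabelMap, Volume3D


def _flat_seeds(shape, spacing, layout):
    """Build a seed map from {code: flat index array}."""
    data = np.zeros(shape, dtype=np.uint8)
    for code, idx in layout.items():
        data.reshape(-1)[idx] = code
    return LabelMap(data, spacing, codes={c: f"class_{c}" for c in layout})


def test_densities_integrate_to_one(small_case, small_seeds):
    model = fit_intensity_model(small_case.lge, small_seeds)
    for code in (1, 2, 3, 4):
        mass = model.prob_mass(code)
        assert mass.sum() == pytest.approx(1.0, abs=1e-6)
        assert (model.classes[code].density >= 0).all()


def test_noise_free_exhaustive_seeds_give_point_masses(clean_case):
    seeds = auto_seeds(clean_case.truth, 0, clean_case.truth.data.size, rng_seed=0)
    model = fit_intensity_model(clean_case.lge, seeds)
    means = clean_case.spec.tissue_means
    from scarflow.volio import TISSUE_CODES
    for code, name in TISSUE_CODES.items():
        dens = model.classes[code].density
        mode = model.bin_centers[np.argmax(dens)]
        width = model.bin_width
        assert abs(mode - means[name]) <= width
        # near-point-mass: the bins nearest the class mean hold almost all
        # probability (the zero-variance bandwidth fallback is one bin width)
        mass = dens * width
        assert mass[np.abs(model.bin_centers - means[name]) <= 2 * width].sum() > 0.95


def test_constant_seed_intensities_put_mode_at_value():
    rng = np.random.default_rng(0)
    vol = Volume3D(rng.uniform(0, 120, (8, 8, 8)).astype(np.float32), 1.0)
    vol.data.reshape(-1)[:12] = 100.0
    seeds = _flat_seeds((8, 8, 8), 1.0, {1: np.arange(12), 2: np.arange(100, 120)})
    model = fit_intensity_model(vol, seeds)
    mode = model.bin_centers[np.argmax(model.classes[1].density)]
    assert abs(mode - 100.0) <= model.bin_width


def test_undersized_class_raises_naming_it(small_case):
    # classes 1..3 get 20 seeds, scar only 9
    data = np.zeros(small_case.truth.shape, dtype=np.uint8)
    flat = data.reshape(-1)
    flat[:20] = 1
    flat[20:40] = 2
    flat[40:60] = 3
    flat[60:69] = 4
    seeds = LabelMap(data, small_case.truth.spacing_mm)
    with pytest.raises(SeedingError, match="scar"):
        fit_intensity_model(small_case.lge, seeds)


def test_degenerate_volume_rejected():
    vol = Volume3D(np.full((8, 8, 8), 7.0, dtype=np.float32), 1.0)
    seeds = _flat_seeds((8, 8, 8), 1.0, {c: np.arange(c * 20, c * 20 + 15)
                                         for c in (1, 2, 3, 4)})
    with pytest.raises(DegenerateInputError):
        fit_intensity_model(vol, seeds)


def test_cost_argmin_matches_seed_class_at_mode(small_case, small_seeds):
    model = fit_intensity_model(small_case.lge, small_seeds)
    costs = data_costs(model, small_case.lge)
    for ch, code in enumerate((1, 2, 3, 4)):
        mode = model.bin_centers[np.argmax(model.classes[code].density)]
        probe = Volume3D(np.full((2, 2, 2), mode, dtype=np.float32),
                         small_case.lge.spacing_mm)
        c = data_costs(model, probe)
        assert int(np.argmin(c.cost[:, 0, 0, 0])) == ch
    assert costs.cost.min() >= 0
    assert costs.cost.max() <= costs.clip + 1e-6


def test_out_of_support_intensity_hits_clip_tie(small_case, small_seeds):
    model = fit_intensity_model(small_case.lge, small_seeds)
    probe = Volume3D(np.full((2, 2, 2), 1.0e4, dtype=np.float32),
                     small_case.lge.spacing_mm)
    c = data_costs(model, probe)
    np.testing.assert_allclose(c.cost, c.clip, rtol=1e-6)


def test_noise_free_argmin_classification_reproduces_truth(clean_case):
    seeds = auto_seeds(clean_case.truth, 0, clean_case.truth.data.size, rng_seed=0)
    model = fit_intensity_model(clean_case.lge, seeds)
    costs = data_costs(model, clean_case.lge)
    labels = np.argmin(costs.cost, axis=0) + 1
    np.testing.assert_array_equal(labels, clean_case.truth.data)


def test_cost_monotone_in_probability(small_case, small_seeds):
    model = fit_intensity_model(small_case.lge, small_seeds)
    # float64 probe: a float32 cast would land between interpolation nodes
    probe = Volume3D(model.bin_centers.astype(float).reshape(-1, 1, 1),
                     small_case.lge.spacing_mm)
    c = data_costs(model, probe)
    for ch, code in enumerate((1, 2, 3, 4)):
        mass = model.prob_mass(code)
        cost = c.cost[ch, :, 0, 0]
        order = np.argsort(mass)
        assert (np.diff(cost[order]) <= 1e-5).all()


def test_channel_permutation_equivariance(small_case):
    seeds = auto_seeds(small_case.truth, 2, 100, rng_seed=7)
    model = fit_intensity_model(small_case.lge, seeds)
    costs = data_costs(model, small_case.lge)
    # swap codes blood (2) <-> scar (4) in the seed map
    swapped = seeds.data.copy()
    swapped[seeds.data == 2] = 4
    swapped[seeds.data == 4] = 2
    seeds_sw = LabelMap(swapped, seeds.spacing_mm, codes=seeds.codes)
    costs_sw = data_costs(fit_intensity_model(small_case.lge, seeds_sw), small_case.lge)
    np.testing.assert_allclose(costs_sw.cost[1], costs.cost[3], atol=1e-5)
    np.testing.assert_allclose(costs_sw.cost[3], costs.cost[1], atol=1e-5)
    np.testing.assert_allclose(costs_sw.cost[0], costs.cost[0], atol=1e-5)


def test_model_json_roundtrip(tmp_path, small_case, small_seeds):
    model = fit_intensity_model(small_case.lge, small_seeds)
    model.save(tmp_path / "model.json")
    import json
    back = IntensityModel.from_dict(json.loads((tmp_path / "model.json").read_text()))
    np.testing.assert_allclose(back.bin_centers, model.bin_centers)
    for code in (1, 2, 3, 4):
        np.testing.assert_allclose(back.classes[code].density,
                                   model.classes[code].density)
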