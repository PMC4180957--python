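import pytest

from scarflow.phantom import PhantomSpec, auto_seeds, make_phantom
from scarflow.pipeline import run_cohort


@pytest.fixture(scope="session")
def small_case():
    """A 64^3 default-statistics phantom shared by fast unit tests."""
    return make_phantom(PhantomSpec(grid_shape=(64, 64, 64), scar_volume_ml=12.0,
                                    rng_seed=5))


@pytest.fixture(scope="session")
def small_seeds(small_case):
    return auto_seeds(small_case.truth, erosion_radius_vox=2, strokes_per_class=200,
                      rng_seed=11)


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free, blur-free phantom: intensities are exact class means."""
    return make_phantom(PhantomSpec(grid_shape=(64, 64, 64), noise_sigma=0.0,
                                    pv_blur_sigma_mm=0.0, scar_volume_ml=10.0,
                                    rng_seed=3))


@pytest.fixture(scope="session")
def default_cohort_run():
    """The 14-case default-condition cohort run used by the validation loop.

    Session-scoped: it is by far the most expensive fixture (~3 min) and
    several accuracy checks share it.
    """
    return run_cohort(n=14, rng_seed=1, keep_cases=True)

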