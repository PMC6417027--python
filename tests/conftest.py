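import numpy as np
import pytest

import seedspectra as ss


@pytest.fixture(scope="session")
def noise_free_profiles():
    """Two-class (Non-aged vs Aged) profiles with all variability switched off."""
    base = ss.default_seed_profile(seed_level_sd=0.0, pixel_noise_sd=0.0)
    aged96 = ss.make_ageing_profiles(base)["AA96"]
    return {
        "Non-aged": base,
        "Aged": ss.ClassSpectralProfile(
            "Aged", aged96.mean_reflectance, 0.0, 0.0
        ),
    }


@pytest.fixture(scope="session")
def noise_free_scene(noise_free_profiles):
    """A deterministic 10-seed dish with zero noise and known ground truth."""
    spec = ss.SceneSpec(
        image_size=(320, 320),
        n_seeds=10,
        seed_radius_px=(10, 14),
        # background/dish noise off too, so thresholding is exact
        background_profile=ss.ClassSpectralProfile("background", (0.04,) * 20, 0, 0),
        dish_profile=ss.ClassSpectralProfile("dish", (0.22,) * 20, 0, 0),
        seed_classes=("Non-aged", "Aged") * 5,
        rng_seed=42,
    )
    cube, truth = ss.render_scene(spec, noise_free_profiles)
    return cube, truth


@pytest.fixture(scope="session")
def gaussian_fixture():
    """60-point, 3-class, 5-band Gaussian clusters for oracle comparisons."""
    rng = np.random.default_rng(7)
    centers = np.array(
        [
            [0.0, 0.0, 0.0, 0.0, 0.0],
            [3.0, 1.0, -1.0, 2.0, 0.5],
            [-2.0, 2.5, 1.5, -1.0, 1.0],
        ]
    )
    n_per = 20
    X = np.vstack([c + rng.normal(0, 1.0, (n_per, 5)) for c in centers])
    y = np.repeat(np.arange(3), n_per)
    return X, y
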