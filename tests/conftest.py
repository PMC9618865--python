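import numpy as np
import pytest

from dfnckit import default_cohort_config, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast structural tests (6 subjects, T=80)."""
    return simulate_cohort(default_cohort_config(n_per_group=3,
                                                 n_timepoints=80, seed=42))


@pytest.fixture(scope="session")
def default_cohort():
    """The shipped study conditions (19+19 subjects, 21 components, T=230)."""
    return simulate_cohort(default_cohort_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_phantom(seed: int = 7, shape=(12, 12, 6), n_components: int = 5,
                 n_timepoints: int = 150, n_subjects: int = 4,
                 snr: float = 5.0):
    """Blob-map phantom cohort: shared spatial maps, subject timecourses.

    Returns (flattened maps, per-subject true timecourses, per-subject
    noisy voxel data). The maps are compact Gaussian blobs (sparse,
    super-Gaussian sources for spatial ICA); the timecourses are
    smoothed unit-variance noise.
    """
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    centers = [(2, 2, 2), (9, 2, 3), (2, 9, 3), (9, 9, 2), (5, 5, 4),
               (5, 2, 1), (2, 5, 4)][:n_components]
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    maps = np.stack([
        np.exp(-(sum((g - c) ** 2 for g, c in zip(grids, ctr))) / (2 * 2.0 ** 2))
        for ctr in centers
    ])
    flat = maps.reshape(n_components, -1)
    tcs, data = [], []
    for _ in range(n_subjects):
        tc = gaussian_filter1d(
            rng.standard_normal((n_components, n_timepoints)), 2.0, axis=1)
        tc = (tc - tc.mean(1, keepdims=True)) / tc.std(1, keepdims=True)
        sig = flat.T @ tc
        y = sig + (sig.std() / snr) * rng.standard_normal(sig.shape)
        tcs.append(tc)
        data.append(y)
    return maps, tcs, data


@pytest.fixture(scope="session")
def phantom():
    return make_phantom()
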