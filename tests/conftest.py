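import numpy as np
import pytest
from hypothesis import settings

import dopapet as dp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort0():
    """Reconstructed 112-patient cohort, seed 0."""
    return dp.reconstructed_cohort(seed=0)


@pytest.fixture(scope="session")
def reference_model():
    """Synthetic normal reference fitted from simulated healthy phantoms."""
    return dp.fit_reference_model(n_subjects=6, noise_sd=0.08, seed=500)


@pytest.fixture
def small_grid():
    """16³ grid, 2 mm isotropic, centred on the origin."""
    return dp.VoxelGrid((16, 16, 16), (2.0, 2.0, 2.0), (-15.0, -15.0, -15.0))


def auc_bruteforce(scores, labels):
    """Pairwise-concordance (Mann–Whitney) AUC, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


def cutoff_bruteforce(scores, labels):
    """Exhaustive Youden search over observed thresholds plus +inf.

    Tie-breaks mirror the implementation contract: highest specificity,
    then lowest cutoff.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    candidates = sorted(set(scores)) + [np.inf]
    best = None
    for t in candidates:
        calls = scores >= t
        sens = (calls & labels).sum() / labels.sum()
        spec = (~calls & ~labels).sum() / (~labels).sum()
        key = (sens + spec, spec, -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]


def voi_stats_bruteforce(volume, voi):
    """SUVmax/SUVmean by enumerating every voxel center."""
    grid = volume.grid
    r = voi.radius_mm
    vals = []
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                c = [grid.origin_mm[d] + idx * grid.spacing_mm[d]
                     for d, idx in enumerate((i, j, k))]
                d2 = sum((c[d] - voi.center_mm[d]) ** 2 for d in range(3))
                if d2 <= r * r:
                    vals.append(volume.values[i, j, k])
    return max(vals), sum(vals) / len(vals), len(vals)
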