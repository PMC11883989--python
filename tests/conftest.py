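import numpy as np
import pytest

from optiregen import phantoms


@pytest.fixture
def nerve_phantom():
    spec = phantoms.NervePhantomSpec(seed=1)
    image, truth = phantoms.make_nerve_phantom(spec)
    return spec, image, truth


@pytest.fixture
def puncta_forced():
    spec = phantoms.PunctaPhantomSpec(n_cells=5, forced_counts=[0, 1, 2, 3, 4],
                                      seed=5)
    image, truth = phantoms.make_puncta_field(spec)
    return spec, image, truth


@pytest.fixture
def count_phantom_spiked():
    spec = phantoms.CountPhantomSpec(n_genes=800, seed=9, spiked_log2fc=2.0)
    counts, truth = phantoms.make_count_matrix(spec)
    groups = [truth["groups"][s] for s in counts.columns]
    return counts, groups, truth


def decoy_sets(genes, spiked, n_sets, size, seed):
    """Null gene sets drawn from the non-spiked complement."""
    rng = np.random.default_rng(seed)
    pool = np.array([g for g in genes if g not in set(spiked)])
    return {f"DECOY_{d:02d}": list(pool[rng.choice(len(pool), size,
                                                   replace=False)])
            for d in range(n_sets)}
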