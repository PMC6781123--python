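import numpy as np
import pytest

from treegs.pedigree import Pedigree, build_A
from treegs.synthetic_data import SimulationConfig, build_study_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced two-generation study used by several integration tests."""
    cfg = SimulationConfig(
        f1_site_sizes=(60, 60, 60),
        f2_size=60,
        f2_genotyped=40,
        n_markers=400,
        n_qtl=50,
        n_f1_families=20,
        n_f2_families=12,
        n_f2_parents=8,
        seed=7,
    )
    return build_study_bundle(cfg)


@pytest.fixture(scope="session")
def small_relmat(small_bundle):
    return build_A(small_bundle.pedigree)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pedigree(rng, n=20, n_founders=6):
    """Random valid pedigree: founders first, then offspring of earlier ids."""
    ids = [f"i{k}" for k in range(n)]
    rows = [(ids[k], None, None) for k in range(n_founders)]
    for k in range(n_founders, n):
        s, d = rng.choice(k, size=2, replace=False)
        rows.append((ids[k], ids[s], ids[d]))
    return Pedigree.from_records(rows)
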