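import dendropy
import numpy as np
import pytest

from parabias.effect_sizes import EffectSize
from parabias.synthetic_data import SimConfig, simulate_tree


def make_effect(yi, vi, species="sp", study="s1", category="Combined",
                pclass="blood", period="breeding", detection="microscopy"):
    return EffectSize(
        study_id=study,
        species=species,
        parasite_class=pclass,
        parasite_category=category,
        yi=yi,
        vi=vi,
        corrected=False,
        period=period,
        detection=detection,
    )


@pytest.fixture
def three_tip_tree():
    t = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
    t.is_rooted = True
    return t


@pytest.fixture
def tree20():
    return simulate_tree(SimConfig(seed=5, n_species=20))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_correlation(ns, rng):
    A = rng.normal(size=(ns, ns))
    R = A @ A.T + ns * np.eye(ns)
    d = np.sqrt(np.diag(R))
    return R / np.outer(d, d)
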