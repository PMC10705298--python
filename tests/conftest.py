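import numpy as np
import pytest

import phylopower as pp


@pytest.fixture(scope="session")
def default_fixture():
    """One default synthetic dataset shared across tests."""
    return pp.make_fixture(pp.SimulationConfig(seed=0))


@pytest.fixture()
def small_tree():
    return pp.parse_newick("((A:1,B:1):1,C:2);")


def random_tree(seed, n=10):
    return pp.simulate_yule_tree(n, 0.5, seed=seed)


def brute_force_patristic(tree):
    """Independent pairwise path-length computation via ancestor chains."""
    depths = tree.depths()
    tips = tree.tip_indices()
    anc = {int(i): set(tree.ancestors(int(i))) | {int(i)} for i in tips}
    out = {}
    for a in range(len(tips)):
        for b in range(a + 1, len(tips)):
            ia, ib = int(tips[a]), int(tips[b])
            m = max(anc[ia] & anc[ib], key=lambda j: depths[j])
            la, lb = tree.label[ia], tree.label[ib]
            out[frozenset((la, lb))] = depths[ia] + depths[ib] - 2 * depths[m]
    return out
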