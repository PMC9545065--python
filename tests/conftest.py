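import numpy as np
import pytest

import elevolve as ev


@pytest.fixture(scope="session")
def tree3():
    """The worked 3-tip ultrametric example ((A:1,B:1):1,C:2)."""
    return ev.parse_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture(scope="session")
def tree5():
    return ev.simulate_tree(5, 10.0, seed=101)


@pytest.fixture(scope="session")
def tree100():
    return ev.simulate_tree(100, 30.0, seed=202)


def random_tree(rng, n_tips, height=10.0):
    """Random ultrametric tree via the Yule simulator (fresh seed)."""
    return ev.simulate_tree(n_tips, height, seed=int(rng.integers(2**31)))


def mixed_regimes(tree, rng, q_lh=0.1, q_hl=0.1, max_tries=50):
    """A simulated regime history with both states present among the tips."""
    for _ in range(max_tries):
        smap, reg = ev.simulate_regime_history(
            tree, q_lh, q_hl, seed=int(rng.integers(2**31))
        )
        if len(set(reg.states.values())) == 2:
            return smap, reg
    raise RuntimeError("could not obtain a two-state history")
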