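import numpy as np
import pytest

from amorthmm.signal_sim import _random_window_vocabulary


@pytest.fixture(scope="session")
def window_vocab():
    """200 distinct valid methyl windows for selection/novelty tests."""
    rng = np.random.default_rng(1234)
    return _random_window_vocabulary(rng, 200, 6)


def random_selection_problem(rng, n_windows, p, vocab):
    """A small coherent-selection instance with random integer counts."""
    from amorthmm.panel_design import build_selection_problem

    take = rng.choice(len(vocab), size=n_windows, replace=False)
    wwc = [(vocab[i], float(rng.integers(1, 10))) for i in take]
    return build_selection_problem(wwc, p=p)
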