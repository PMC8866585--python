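import itertools

import numpy as np
import pytest

from biocomp.rules import Branch, GeneralRule, TableGuard


def make_table_rule(rng: np.random.Generator, n_inputs: int = 2,
                    n_states: int = 2) -> tuple[GeneralRule, dict]:
    """Random fully specified decision-table rule over binary input axes and
    the given number of states, plus its lookup-table oracle."""
    axes = tuple(f"x{k}" for k in range(n_inputs))
    states = tuple(f"s{k}" for k in range(n_states))
    alphabet = tuple(dict(zip(axes, vals))
                     for vals in itertools.product((0, 1), repeat=n_inputs))
    outputs = ("alpha", "beta", "gamma")
    table = {}
    branches = []
    for inp in alphabet:
        for s in states:
            image = (outputs[rng.integers(len(outputs))], (),
                     states[rng.integers(n_states)])
            table[(tuple(sorted(inp.items())), s)] = image
            guard = TableGuard({a: (v,) for a, v in inp.items()}, states=(s,))
            branches.append(Branch(guard, image[0], image[1], image[2]))
    rule = GeneralRule("random-table", axes, frozenset(states),
                       tuple(branches), alphabet)
    return rule, table


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
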