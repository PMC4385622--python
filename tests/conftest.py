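import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from seedpath import (
    CHEMICAL,
    PROTEIN,
    InteractionRecord,
    NodeRef,
    build_graph,
)


def P(node_id):
    return NodeRef(node_id, PROTEIN)


def C(node_id):
    return NodeRef(node_id, CHEMICAL)


def rec(a, b, score):
    return InteractionRecord(a, b, score)


def graph_from_scores(scores, kinds=None):
    """Build a HybridGraph from {frozenset({u, v}): score}; nodes are
    proteins unless listed in ``kinds`` as 'chemical'."""
    kinds = kinds or {}
    records = []
    for key, score in scores.items():
        u, v = sorted(key)
        ru = C(u) if kinds.get(u) == CHEMICAL else P(u)
        rv = C(v) if kinds.get(v) == CHEMICAL else P(v)
        records.append(rec(ru, rv, score))
    return build_graph(records)


@pytest.fixture
def line_graph():
    """a - b - c with scores 999 (weight 1 each)."""
    return graph_from_scores({frozenset("ab"): 999, frozenset("bc"): 999})


@pytest.fixture
def square_graph():
    """a-b-d and a-c-d, all scores 999: two tied shortest a->d paths."""
    return graph_from_scores(
        {
            frozenset("ab"): 999,
            frozenset("bd"): 999,
            frozenset("ac"): 999,
            frozenset("cd"): 999,
        }
    )


@pytest.fixture
def star_graph():
    """Hub h with leaves s1..s4, scores 999."""
    return graph_from_scores({frozenset((f"s{i}", "h")): 999 for i in range(1, 5)})


@pytest.fixture
def toy_hybrid_graph():
    """Small mixed graph: 3 chemicals (a, b, c) and 4 proteins (d, e, f, g)."""
    kinds = {n: CHEMICAL for n in "abc"}
    scores = {
        frozenset("ad"): 800,
        frozenset("ab"): 700,
        frozenset("bc"): 650,
        frozenset("de"): 900,
        frozenset("ef"): 850,
        frozenset("cf"): 600,
        frozenset("fg"): 750,
    }
    return graph_from_scores(scores, kinds)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
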