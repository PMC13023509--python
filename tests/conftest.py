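import itertools

import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from netprior import SyntheticSpec, gen_ppi


@pytest.fixture
def star5() -> nx.Graph:
    """Star with center C and four leaves."""
    G = nx.Graph()
    G.add_edges_from([("C", f"L{i}") for i in range(1, 5)])
    return G


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3() -> nx.Graph:
    return nx.Graph([("A", "B"), ("B", "C")])


def feasible_hub_seeds(start: int, count: int, **spec_kwargs) -> list[int]:
    """First `count` seeds >= start for which the planted-hub generator admits
    a feasible realization (rare degenerate degree sequences are skipped)."""
    out = []
    for s in itertools.count(start):
        try:
            gen_ppi(SyntheticSpec(seed=s, **spec_kwargs))
        except ValueError:
            continue
        out.append(s)
        if len(out) == count:
            return out
    raise RuntimeError("unreachable")
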