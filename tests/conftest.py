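import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from netpharm.simulate import SyntheticSpec, make_input_bundle


@pytest.fixture
def barbell() -> nx.Graph:
    """Two 5-cliques joined by a single bridge edge (21 edges)."""
    g = nx.Graph()
    left = [f"A{i}" for i in range(5)]
    right = [f"B{i}" for i in range(5)]
    for clique in (left, right):
        for i, u in enumerate(clique):
            for v in clique[i + 1:]:
                g.add_edge(u, v)
    g.add_edge(left[0], right[0])
    return g


@pytest.fixture
def chain() -> nx.Graph:
    return nx.path_graph(["A", "B", "C", "D"])


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A full synthetic input bundle on disk (default planted-structure spec)."""
    out = tmp_path_factory.mktemp("bundle")
    paths = make_input_bundle(SyntheticSpec(seed=3), out)
    return paths


def write_lines(path: Path, lines) -> Path:
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
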