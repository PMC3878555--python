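import io

import pytest

import spgenes as sp


@pytest.fixture()
def triangle_net():
    """A-B-C path plus a costlier direct A-C edge."""
    text = "protein1 protein2 combined_score\nA B 900\nB C 900\nA C 700\n"
    return sp.build_network(sp.parse_edge_list(io.StringIO(text)))


@pytest.fixture()
def star_net():
    """Hub H with leaves L0..L3, uniform score 900."""
    from _oracles import net_from_edges

    return net_from_edges({("H", f"L{i}"): 900 for i in range(4)})


def network_from_text(text: str) -> "sp.WeightedNetwork":
    return sp.build_network(sp.parse_edge_list(io.StringIO(text)))
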