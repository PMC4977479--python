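"""Shared construction helpers for the test suite."""

from stericrules.geometry import (
    RegionPairDistance,
    StericAdjacency,
    StrandGeometry,
)
from stericrules.rulegen import RateParameters

DEMO_RATES = RateParameters(k_f1=1.0, k_f2=0.005, k_r=0.01)


def uniform_geometry(distance: float = 5.0, strand: str = "I") -> StrandGeometry:
    """Six regions, all 15 pairwise distances equal (single threshold)."""
    regions = list("ABCDEF")
    pairs = [
        RegionPairDistance(a, b, distance, "negative")
        for i, a in enumerate(regions)
        for b in regions[i + 1 :]
    ]
    return StrandGeometry(strand, regions, pairs)


def adjacency_from_edges(edges, regions="ABCDEF", strand="I"):
    neighbors = {r: set() for r in regions}
    for a, b in edges:
        neighbors[a].add(b)
        neighbors[b].add(a)
    return StericAdjacency(
        strand, {r: frozenset(ns) for r, ns in neighbors.items()}
    )


CHAIN = adjacency_from_edges(
    [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F")]
)
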