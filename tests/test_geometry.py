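"""Strand geometry, effective distances, and steric adjacency."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stericrules.geometry import (
    GeometryError,
    RegionPairDistance,
    StrandGeometry,
    StericAdjacency,
    adjacency_breakpoints,
    build_adjacency,
    cutoff_grid,
    effective_distance,
)

from helpers import uniform_geometry


@pytest.mark.parametrize(
    "linear,path,curvature,expected",
    [
        (5.5, 9.0, "negative", 5.5),
        (4.0, 4.0, "nonnegative", 4.0),
        (3.0, 7.2, "nonnegative", 7.2),
        (2.0, None, "negative", 2.0),
    ],
)
def test_effective_distance_follows_curvature(linear, path, curvature, expected):
    pair = RegionPairDistance("A", "B", linear, curvature, path)
    assert effective_distance(pair) == expected


def test_missing_path_for_nonnegative_curvature_names_the_pair():
    pair = RegionPairDistance("C", "D", 3.0, "nonnegative")
    with pytest.raises(GeometryError, match=r"\(C, D\)"):
        effective_distance(pair)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(region_a="A", region_b="A", linear_nm=1.0, curvature="negative"),
        dict(region_a="A", region_b="B", linear_nm=0.0, curvature="negative"),
        dict(region_a="A", region_b="B", linear_nm=-1.0, curvature="negative"),
        dict(region_a="A", region_b="B", linear_nm=5.0, curvature="sideways"),
        dict(
            region_a="A", region_b="B", linear_nm=5.0,
            curvature="nonnegative", path_nm=4.0,
        ),
    ],
)
def test_invalid_pair_definitions_rejected(kwargs):
    with pytest.raises(GeometryError):
        RegionPairDistance(**kwargs)


def test_strand_geometry_requires_all_pairs():
    regions = list("ABC")
    pairs = [
        RegionPairDistance("A", "B", 1.0, "negative"),
        RegionPairDistance("B", "C", 1.0, "negative"),
    ]
    with pytest.raises(GeometryError, match="A-C"):
        StrandGeometry("I", regions, pairs)


def test_strand_geometry_rejects_duplicates_and_unknown_regions():
    with pytest.raises(GeometryError, match="duplicate"):
        StrandGeometry(
            "I",
            ["A", "B"],
            [
                RegionPairDistance("A", "B", 1.0, "negative"),
                RegionPairDistance("B", "A", 2.0, "negative"),
            ],
        )
    with pytest.raises(GeometryError, match="unknown region"):
        StrandGeometry(
            "I", ["A", "B"], [RegionPairDistance("A", "Z", 1.0, "negative")]
        )


class TestBuildAdjacency:
    def test_half_resolution_worked_example(self, native_geometry):
        """At a 5.5 nm cutoff, strand I is hindered on exactly
        {A-B, B-C, C-D, E-F}; on strand II the C-D pair (5.6 nm) drops out."""
        strand_i, strand_ii = native_geometry
        edges_i = {
            "".join(sorted(e)) for e in build_adjacency(strand_i, 5.5).edges()
        }
        assert edges_i == {"AB", "BC", "CD", "EF"}
        edges_ii = {
            "".join(sorted(e)) for e in build_adjacency(strand_ii, 5.5).edges()
        }
        assert edges_ii == {"AB", "BC", "EF"}

    def test_boundary_distance_counts_as_hindered(self, native_geometry):
        # C-D on strand I sits exactly at 5.5 nm and r <= d_c applies.
        strand_i, _ = native_geometry
        assert strand_i.effective_distance("C", "D") == 5.5
        adj = build_adjacency(strand_i, 5.5)
        assert "D" in adj.neighbors["C"]

    def test_tiny_cutoff_gives_empty_adjacency(self, native_geometry):
        adj = build_adjacency(native_geometry[0], 1e-9)
        assert all(not ns for ns in adj.neighbors.values())

    def test_nonpositive_cutoff_rejected(self, native_geometry):
        with pytest.raises(GeometryError):
            build_adjacency(native_geometry[0], 0.0)

    def test_geometry_derived_adjacency_is_symmetric(self, native_geometry):
        for geometry in native_geometry:
            for d_c in (4.0, 5.5, 8.0, 12.0, 25.0):
                build_adjacency(geometry, d_c).require_symmetric()


@st.composite
def random_geometries(draw):
    regions = list("WXYZ")
    pairs = []
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            dist = draw(
                st.floats(0.5, 20.0, allow_nan=False, allow_infinity=False)
            )
            pairs.append(RegionPairDistance(a, b, dist, "negative"))
    return StrandGeometry("I", regions, pairs)


@settings(max_examples=50, deadline=None)
@given(
    geometry=random_geometries(),
    d_small=st.floats(0.1, 25.0),
    delta=st.floats(0.0, 10.0),
)
def test_adjacency_monotone_in_cutoff(geometry, d_small, delta):
    smaller = build_adjacency(geometry, d_small)
    larger = build_adjacency(geometry, d_small + delta)
    assert smaller.issubset(larger)


class TestBreakpoints:
    def test_single_threshold_partitions_grid_in_two(self):
        regions = ["A", "B"]
        geometry = StrandGeometry(
            "I", regions, [RegionPairDistance("A", "B", 5.0, "negative")]
        )
        intervals = adjacency_breakpoints(geometry, 3.0, 20.0, 0.1)
        assert [iv for iv, _ in intervals] == [(3.0, 4.9), (5.0, 20.0)]
        assert not intervals[0][1].edges()
        assert intervals[1][1].edges() == frozenset({frozenset("AB")})

    def test_native_chain_interval_is_7_0_to_8_7(self, native_geometry):
        chain = {
            frozenset(p)
            for p in [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F")]
        }
        for geometry in native_geometry:
            matches = [
                iv
                for iv, adj in adjacency_breakpoints(geometry, 3.0, 20.0, 0.1)
                if set(adj.edges()) == chain
            ]
            assert matches == [(7.0, 8.7)]

    def test_agrees_with_per_grid_point_brute_force(self, native_geometry):
        geometry = native_geometry[0]
        intervals = adjacency_breakpoints(geometry, 3.0, 20.0, 0.1)
        for d_c in cutoff_grid(3.0, 20.0, 0.1):
            direct = build_adjacency(geometry, d_c)
            containing = next(
                adj for (lo, hi), adj in intervals if lo <= d_c <= hi
            )
            assert direct.neighbors == containing.neighbors

    def test_equal_distances_share_a_breakpoint(self):
        geometry = uniform_geometry(distance=6.0)
        intervals = adjacency_breakpoints(geometry, 3.0, 20.0, 0.1)
        assert len(intervals) == 2
        assert intervals[1][0][0] == 6.0
        # all 15 pairs flip together
        assert len(intervals[1][1].edges()) == 15

    def test_empty_grid_rejected(self, native_geometry):
        with pytest.raises(GeometryError):
            adjacency_breakpoints(native_geometry[0], 5.0, 4.0, 0.1)


def test_directed_hindrance_map_allowed_but_flagged():
    adjacency = StericAdjacency(
        "I", {"A": frozenset("B"), "B": frozenset(), "C": frozenset()}
    )
    assert not adjacency.is_symmetric
    with pytest.raises(GeometryError, match="not symmetric"):
        adjacency.require_symmetric()


def test_self_neighbor_rejected():
    with pytest.raises(GeometryError, match="own steric neighbor"):
        StericAdjacency("I", {"A": frozenset("A")})
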