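"""Antigen strand geometry and steric adjacency.

The antigen is modeled as a rigid two-stranded rod carrying a small number of
antibody-binding regions per strand (six in the standard tropomyosin model).
Whether two regions on the same strand sterically interfere with each other is
decided by a single length scale, the *cutoff distance* ``d_c``: a pair of
regions whose effective separation is at most ``d_c`` is considered mutually
hindering, and the hindrance is later encoded into the binding rules.

The effective separation between two regions depends on the local molecular
curvature.  In a region of negative curvature the molecule folds back on
itself, so a straight-line (linear) distance is the relevant measure; anywhere
else the shortest path *along* the molecule is used.  Curvature labels are
per-pair inputs measured from structural models; no automatic classification
is attempted.

All distances are in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeometryError",
    "BindingRegion",
    "RegionPairDistance",
    "StrandGeometry",
    "StericAdjacency",
    "effective_distance",
    "build_adjacency",
    "adjacency_breakpoints",
    "cutoff_grid",
]

#: Allowed curvature labels for a region pair.
CURVATURE_NEGATIVE = "negative"
CURVATURE_NONNEGATIVE = "nonnegative"
CURVATURES = (CURVATURE_NEGATIVE, CURVATURE_NONNEGATIVE)


class GeometryError(ValueError):
    """Invalid strand geometry or adjacency configuration."""


@dataclass(frozen=True)
class BindingRegion:
    """A single antibody-binding region on one antigen strand."""

    id: str
    strand: str


@dataclass(frozen=True)
class RegionPairDistance:
    """Measured distances between two binding regions on one strand.

    Parameters
    ----------
    region_a, region_b
        Region labels; the pair is unordered.
    linear_nm
        Straight-line distance between the regions, nm (> 0).
    curvature
        ``"negative"`` if the pair lies in an area of negative curvature
        (molecule folding back on itself), else ``"nonnegative"``.
    path_nm
        Distance of a free-form path along the molecule, nm.  Required when
        ``curvature`` is ``"nonnegative"``; must be >= ``linear_nm``.
    """

    region_a: str
    region_b: str
    linear_nm: float
    curvature: str
    path_nm: float | None = None

    def __post_init__(self) -> None:
        if self.region_a == self.region_b:
            raise GeometryError(
                f"pair ({self.region_a}, {self.region_b}): a region cannot "
                "pair with itself"
            )
        if not (self.linear_nm > 0):
            raise GeometryError(
                f"pair ({self.region_a}, {self.region_b}): linear distance "
                f"must be > 0 nm, got {self.linear_nm!r}"
            )
        if self.curvature not in CURVATURES:
            raise GeometryError(
                f"pair ({self.region_a}, {self.region_b}): unknown curvature "
                f"label {self.curvature!r}; expected one of {CURVATURES}"
            )
        if self.path_nm is not None and self.path_nm < self.linear_nm:
            raise GeometryError(
                f"pair ({self.region_a}, {self.region_b}): path distance "
                f"{self.path_nm} nm is shorter than linear distance "
                f"{self.linear_nm} nm"
            )

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.region_a, self.region_b))

    @property
    def effective_nm(self) -> float:
        return effective_distance(self)


def effective_distance(pair: RegionPairDistance) -> float:
    """Distance used for the steric-cutoff comparison, nm.

    Negative curvature pulls the two regions toward each other, so the linear
    distance governs whether a bound antibody at one region can block the
    other.  For nonnegative curvature the regions only communicate along the
    molecule, so the path distance is used.
    """
    if pair.curvature == CURVATURE_NEGATIVE:
        return pair.linear_nm
    if pair.path_nm is None:
        raise GeometryError(
            f"pair ({pair.region_a}, {pair.region_b}) has nonnegative "
            "curvature but no path distance; supply path_nm"
        )
    return pair.path_nm


@dataclass(frozen=True)
class StericAdjacency:
    """Per-region map of which regions exert steric effects on it.

    ``neighbors[r]`` is the set of regions whose occupancy reduces the
    accessibility of region ``r``.  Adjacencies derived from a distance table
    are symmetric by construction.  Hindrance maps transcribed from published
    rule tables may be directed (a bulky complex at a recessed region can
    block a neighbor whose converse effect is negligible), so symmetry is not
    forced at construction; call :meth:`require_symmetric` to assert it.
    """

    strand: str
    neighbors: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        frozen = {r: frozenset(ns) for r, ns in self.neighbors.items()}
        object.__setattr__(self, "neighbors", frozen)
        for region, ns in frozen.items():
            if region in ns:
                raise GeometryError(
                    f"region {region!r} listed as its own steric neighbor"
                )
            unknown = ns - frozen.keys()
            if unknown:
                raise GeometryError(
                    f"region {region!r} lists unknown neighbors "
                    f"{sorted(unknown)}"
                )

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.neighbors.keys())

    @property
    def is_symmetric(self) -> bool:
        return all(
            a in self.neighbors[b]
            for a, ns in self.neighbors.items()
            for b in ns
        )

    def require_symmetric(self) -> "StericAdjacency":
        if not self.is_symmetric:
            bad = [
                (a, b)
                for a, ns in self.neighbors.items()
                for b in ns
                if a not in self.neighbors[b]
            ]
            raise GeometryError(
                f"adjacency for strand {self.strand!r} is not symmetric: "
                f"directed pairs {bad}"
            )
        return self

    def edges(self) -> frozenset[frozenset[str]]:
        """Unordered adjacent pairs (only meaningful for symmetric maps)."""
        return frozenset(
            frozenset((a, b)) for a, ns in self.neighbors.items() for b in ns
        )

    def issubset(self, other: "StericAdjacency") -> bool:
        return all(
            ns <= other.neighbors.get(r, frozenset())
            for r, ns in self.neighbors.items()
        )


class StrandGeometry:
    """All pairwise region distances for one antigen strand.

    Parameters
    ----------
    strand
        Strand label, conventionally ``"I"`` or ``"II"``.
    regions
        Ordered region labels (e.g. ``"A".."F"``); order fixes the canonical
        ordering of rules and state bit-vectors downstream.
    pairs
        One :class:`RegionPairDistance` for every unordered pair of regions;
        all C(m, 2) pairs must be present.
    """

    def __init__(
        self,
        strand: str,
        regions: Sequence[str],
        pairs: Iterable[RegionPairDistance],
    ) -> None:
        self.strand = str(strand)
        self.regions: tuple[str, ...] = tuple(str(r) for r in regions)
        if len(set(self.regions)) != len(self.regions):
            raise GeometryError(
                f"strand {strand!r}: region ids must be unique, got "
                f"{self.regions}"
            )
        self._pairs: dict[frozenset[str], RegionPairDistance] = {}
        for pair in pairs:
            for r in (pair.region_a, pair.region_b):
                if r not in self.regions:
                    raise GeometryError(
                        f"strand {strand!r}: pair references unknown region "
                        f"{r!r}"
                    )
            if pair.key in self._pairs:
                raise GeometryError(
                    f"strand {strand!r}: duplicate pair "
                    f"({pair.region_a}, {pair.region_b})"
                )
            self._pairs[pair.key] = pair
        expected = {frozenset(c) for c in combinations(self.regions, 2)}
        missing = expected - self._pairs.keys()
        if missing:
            names = sorted("-".join(sorted(m)) for m in missing)
            raise GeometryError(
                f"strand {strand!r}: missing distance for pair(s) {names}"
            )
        extra = self._pairs.keys() - expected
        if extra:
            raise GeometryError(
                f"strand {strand!r}: unexpected pair(s) "
                f"{sorted('-'.join(sorted(e)) for e in extra)}"
            )
        # Fail fast on pairs whose effective distance is unresolvable.
        for pair in self._pairs.values():
            effective_distance(pair)

    @property
    def pairs(self) -> tuple[RegionPairDistance, ...]:
        return tuple(self._pairs.values())

    def pair(self, a: str, b: str) -> RegionPairDistance:
        try:
            return self._pairs[frozenset((a, b))]
        except KeyError:
            raise GeometryError(
                f"strand {self.strand!r}: no pair ({a}, {b})"
            ) from None

    def effective_distance(self, a: str, b: str) -> float:
        return effective_distance(self.pair(a, b))

    def build_adjacency(self, d_c: float) -> StericAdjacency:
        return build_adjacency(self, d_c)

    def adjacency_breakpoints(
        self, d_min: float, d_max: float, step: float
    ) -> list[tuple[tuple[float, float], StericAdjacency]]:
        return adjacency_breakpoints(self, d_min, d_max, step)


def build_adjacency(geometry: StrandGeometry, d_c: float) -> StericAdjacency:
    """Steric adjacency of a strand at cutoff distance ``d_c``.

    A pair is adjacent iff its effective distance is <= ``d_c``.  The boundary
    case ``r == d_c`` counts as hindered: the rate-assignment rule is stated
    for ``r <= d_c``, and a region pair sitting exactly at the cutoff is
    treated as hindered in the published worked example.
    """
    if not (d_c > 0):
        raise GeometryError(f"cutoff distance must be > 0 nm, got {d_c!r}")
    neighbors: dict[str, set[str]] = {r: set() for r in geometry.regions}
    for pair in geometry.pairs:
        if effective_distance(pair) <= d_c:
            neighbors[pair.region_a].add(pair.region_b)
            neighbors[pair.region_b].add(pair.region_a)
    return StericAdjacency(
        strand=geometry.strand,
        neighbors={r: frozenset(ns) for r, ns in neighbors.items()},
    )


def cutoff_grid(d_min: float, d_max: float, step: float) -> list[float]:
    if not (d_min < d_max):
        raise GeometryError(
            f"need d_min < d_max, got d_min={d_min}, d_max={d_max}"
        )
    if not (step > 0):
        raise GeometryError(f"grid step must be > 0, got {step!r}")
    points = []
    k = 0
    while True:
        value = round(d_min + k * step, 9)
        if value > d_max + 1e-9:
            break
        points.append(value)
        k += 1
    if not points:
        raise GeometryError("empty cutoff-distance grid")
    return points


def adjacency_breakpoints(
    geometry: StrandGeometry, d_min: float, d_max: float, step: float
) -> list[tuple[tuple[float, float], StericAdjacency]]:
    """Partition a cutoff grid into intervals of constant adjacency.

    Scans the grid ``d_min, d_min + step, ..., <= d_max`` and groups maximal
    runs of consecutive grid points whose adjacency (hence whose rule set) is
    identical.  Returns ``[((lo, hi), adjacency), ...]`` ordered by cutoff,
    where ``lo`` and ``hi`` are the first and last grid points of each run.
    Because the rule set is constant within a run, any downstream fit needs
    one optimization per interval rather than one per grid point.
    """
    points = cutoff_grid(d_min, d_max, step)
    intervals: list[tuple[tuple[float, float], StericAdjacency]] = []
    current_adj: StericAdjacency | None = None
    lo = points[0]
    prev = points[0]
    for value in points:
        adj = build_adjacency(geometry, value)
        if current_adj is None:
            current_adj, lo = adj, value
        elif adj.neighbors != current_adj.neighbors:
            intervals.append(((lo, prev), current_adj))
            current_adj, lo = adj, value
        prev = value
    assert current_adj is not None
    intervals.append(((lo, prev), current_adj))
    return intervals
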