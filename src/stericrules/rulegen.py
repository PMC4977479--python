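"""Construction of steric-hindrance-aware binding rule sets.

Each binding region of a strand gets one forward (binding) rule per occupancy
pattern of its steric neighbors: with ``s`` neighbors that is ``2**s`` rules.
The single all-neighbors-free pattern binds at the unhindered rate ``k_f1``;
every other pattern binds at the reduced rate ``k_f2 < k_f1`` (steric
hindrance).  Unbinding is uniform at ``k_r`` regardless of neighbors.  The
older "no binding when hindered" variant is the special case ``k_f2 = 0``.

Rules are emitted in a canonical order — regions in strand order, neighbor
patterns in binary counting order with the first neighbor as the lowest bit —
so exports are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from .geometry import StericAdjacency

__all__ = [
    "RateParameters",
    "BindingRule",
    "RuleSet",
    "RuleGenerationError",
    "generate_rules",
    "rule_count",
    "MAX_NEIGHBORS",
]

FREE = "free"
BOUND = "bound"
UNHINDERED = "unhindered"
HINDERED = "hindered"

#: Refuse rule generation for regions with more steric neighbors than this
#: (2**s rules per region grows too fast to be useful).
MAX_NEIGHBORS = 12


class RuleGenerationError(ValueError):
    """Invalid inputs to rule-set construction."""


@dataclass(frozen=True)
class RateParameters:
    """Forward and reverse rate constants of the binding rules.

    ``k_f1`` (molecule^-1 s^-1) applies when all steric neighbors of the
    target region are free; ``k_f2`` (molecule^-1 s^-1, ``0 <= k_f2 < k_f1``)
    when at least one is bound; ``k_r`` (s^-1) is the uniform unbinding rate.
    """

    k_f1: float = 1.0
    k_f2: float = 0.0
    k_r: float = 0.01

    def __post_init__(self) -> None:
        for name in ("k_f1", "k_f2", "k_r"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise RuleGenerationError(f"{name} must be finite, got {value!r}")
        if not (0 <= self.k_f2 < self.k_f1):
            raise RuleGenerationError(
                f"need 0 <= k_f2 < k_f1, got k_f2={self.k_f2}, k_f1={self.k_f1}"
            )
        if self.k_r < 0:
            raise RuleGenerationError(f"k_r must be >= 0, got {self.k_r}")


@dataclass(frozen=True)
class BindingRule:
    """One forward binding rule for a target region.

    ``neighbor_pattern`` maps each steric neighbor of the target to ``"free"``
    or ``"bound"``; the keys are exactly the target's neighbor set.  The rule
    is ``"unhindered"`` (rate ``k_f1``) iff every neighbor is free, else
    ``"hindered"`` (rate ``k_f2``).
    """

    target_region: str
    neighbor_pattern: tuple[tuple[str, str], ...]
    rate_class: str

    def __post_init__(self) -> None:
        states = dict(self.neighbor_pattern)
        if len(states) != len(self.neighbor_pattern):
            raise RuleGenerationError(
                f"rule for {self.target_region!r}: duplicate neighbor in "
                f"pattern {self.neighbor_pattern}"
            )
        for region, state in states.items():
            if state not in (FREE, BOUND):
                raise RuleGenerationError(
                    f"rule for {self.target_region!r}: neighbor {region!r} "
                    f"has invalid state {state!r}"
                )
        all_free = all(s == FREE for s in states.values())
        expected = UNHINDERED if all_free else HINDERED
        if self.rate_class != expected:
            raise RuleGenerationError(
                f"rule for {self.target_region!r}: pattern {states} implies "
                f"rate class {expected!r}, got {self.rate_class!r}"
            )

    @property
    def pattern(self) -> dict[str, str]:
        return dict(self.neighbor_pattern)

    @property
    def bound_neighbors(self) -> frozenset[str]:
        return frozenset(r for r, s in self.neighbor_pattern if s == BOUND)

    def rate(self, rates: RateParameters) -> float:
        return rates.k_f1 if self.rate_class == UNHINDERED else rates.k_f2


@dataclass(frozen=True)
class RuleSet:
    """Complete forward rule set for one strand plus its rate parameters."""

    strand: str
    regions: tuple[str, ...]
    forward_rules: tuple[BindingRule, ...]
    rates: RateParameters

    @property
    def reverse_rate(self) -> float:
        return self.rates.k_r

    def rules_for(self, region: str) -> tuple[BindingRule, ...]:
        return tuple(
            r for r in self.forward_rules if r.target_region == region
        )

    def neighbor_map(self) -> dict[str, tuple[str, ...]]:
        """Steric neighbors of each region, in pattern order."""
        out: dict[str, tuple[str, ...]] = {}
        for rule in self.forward_rules:
            names = tuple(r for r, _ in rule.neighbor_pattern)
            prev = out.setdefault(rule.target_region, names)
            if prev != names:
                raise RuleGenerationError(
                    f"inconsistent neighbor sets in rules for "
                    f"{rule.target_region!r}: {prev} vs {names}"
                )
        for region in self.regions:
            out.setdefault(region, ())
        return out

    def rate_table(self) -> dict[str, dict[frozenset[str], float]]:
        """Per region: bound-neighbor set -> forward rate constant.

        Raises if some occupancy pattern of a region's neighbor set has no
        rule (cannot happen for :func:`generate_rules` output; guards
        hand-written rule files).
        """
        table: dict[str, dict[frozenset[str], float]] = {
            r: {} for r in self.regions
        }
        for rule in self.forward_rules:
            table[rule.target_region][rule.bound_neighbors] = rule.rate(
                self.rates
            )
        for region, patterns in table.items():
            n_neighbors = (
                len(self.rules_for(region)[0].neighbor_pattern)
                if patterns
                else 0
            )
            if len(patterns) != 2**n_neighbors:
                raise RuleGenerationError(
                    f"rule set for strand {self.strand!r} does not cover all "
                    f"neighbor patterns of region {region!r}: "
                    f"{len(patterns)} rules for {n_neighbors} neighbors"
                )
        return table


def _ordered_neighbors(
    adjacency: StericAdjacency, region: str
) -> tuple[str, ...]:
    order = {r: i for i, r in enumerate(adjacency.regions)}
    return tuple(sorted(adjacency.neighbors[region], key=order.__getitem__))


def rule_count(adjacency: StericAdjacency) -> int:
    """Number of forward rules the adjacency generates: sum of 2**s."""
    return sum(2 ** len(ns) for ns in adjacency.neighbors.values())


def generate_rules(
    adjacency: StericAdjacency, rates: RateParameters
) -> RuleSet:
    """Expand a steric adjacency into the full forward rule set.

    For each region with neighbors ``(n_1, ..., n_s)`` (strand order), emits
    ``2**s`` rules covering every free/bound pattern, in binary counting order
    (``n_1`` is the lowest bit, pattern 0 = all free).  Exactly one rule per
    region — the all-free one — is unhindered.
    """
    rules: list[BindingRule] = []
    for region in adjacency.regions:
        neighbors = _ordered_neighbors(adjacency, region)
        if len(neighbors) > MAX_NEIGHBORS:
            raise RuleGenerationError(
                f"region {region!r} has {len(neighbors)} steric neighbors; "
                f"refusing to expand more than {MAX_NEIGHBORS} "
                f"(2**{len(neighbors)} rules)"
            )
        for pattern_index in range(2 ** len(neighbors)):
            pattern = tuple(
                (n, BOUND if (pattern_index >> j) & 1 else FREE)
                for j, n in enumerate(neighbors)
            )
            rate_class = UNHINDERED if pattern_index == 0 else HINDERED
            rules.append(
                BindingRule(
                    target_region=region,
                    neighbor_pattern=pattern,
                    rate_class=rate_class,
                )
            )
    return RuleSet(
        strand=adjacency.strand,
        regions=adjacency.regions,
        forward_rules=tuple(rules),
        rates=rates,
    )
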