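"""Plain-text BioNetGen-language (BNGL) export of rule sets, and a reader.

A strand with regions ``A..F`` becomes a molecule type ``TI(A,...,F)`` whose
components carry bonds to a monovalent ``IgE(fab)`` receptor molecule.  A
forward rule conditions on the occupancy of the target's steric neighbors
using BNGL bond wildcards (``B!+`` = bound to anything, plain ``B`` = free),
for example::

    TI(A,B!+) + IgE(fab) -> TI(A!1,B!+).IgE(fab!1) kf2

Unbinding is one rule per region at ``kr``.  The export is canonical (fixed
section order, region order, pattern order) so it is bit-reproducible, and
:func:`parse_bngl` reads it back into identical :class:`~stericrules.rulegen.RuleSet`
objects.  The reader is intentionally limited to this exported dialect; it is
not a general BNGL parser.
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

from .rulegen import (
    BOUND,
    FREE,
    HINDERED,
    UNHINDERED,
    BindingRule,
    RateParameters,
    RuleSet,
)

__all__ = ["export_bngl", "parse_bngl", "BNGLError"]

RECEPTOR = "IgE"
RECEPTOR_SITE = "fab"


class BNGLError(ValueError):
    """Malformed BNGL text (for this package's exported dialect)."""


def _molecule_name(strand: str) -> str:
    sanitized = re.sub(r"\W", "_", strand)
    return f"T{sanitized}"


def _fmt(value: float) -> str:
    return repr(float(value))


def _forward_line(ruleset: RuleSet, rule: BindingRule) -> str:
    pattern = rule.pattern
    order = [rule.target_region] + [r for r, _ in rule.neighbor_pattern]
    # List components in strand-region order for readability.
    order.sort(key=ruleset.regions.index)
    reactant, product = [], []
    for region in order:
        if region == rule.target_region:
            reactant.append(region)
            product.append(f"{region}!1")
        elif pattern[region] == BOUND:
            reactant.append(f"{region}!+")
            product.append(f"{region}!+")
        else:
            reactant.append(region)
            product.append(region)
    mol = _molecule_name(ruleset.strand)
    rate = "kf1" if rule.rate_class == UNHINDERED else "kf2"
    return (
        f"{mol}({','.join(reactant)}) + {RECEPTOR}({RECEPTOR_SITE}) -> "
        f"{mol}({','.join(product)}).{RECEPTOR}({RECEPTOR_SITE}!1) {rate}"
    )


def export_bngl(
    rulesets: RuleSet | Sequence[RuleSet],
    copy_numbers: Mapping[str, float] | None = None,
) -> str:
    """Render one or more strand rule sets as a BNGL model.

    ``copy_numbers`` maps strand labels (and ``"IgE"`` for the receptor) to
    initial molecule counts; unmentioned species seed at 0.  All rule sets
    must share the same rate parameters (one ``kf1/kf2/kr`` parameter block).
    """
    if isinstance(rulesets, RuleSet):
        rulesets = [rulesets]
    if not rulesets:
        raise BNGLError("no rule sets to export")
    rates = rulesets[0].rates
    for rs in rulesets[1:]:
        if rs.rates != rates:
            raise BNGLError(
                "all exported rule sets must share one RateParameters block"
            )
    copy_numbers = dict(copy_numbers or {})

    lines = ["begin model", "begin parameters"]
    lines += [
        f"  kf1 {_fmt(rates.k_f1)}",
        f"  kf2 {_fmt(rates.k_f2)}",
        f"  kr {_fmt(rates.k_r)}",
    ]
    lines.append("end parameters")

    lines.append("begin molecule types")
    for rs in rulesets:
        lines.append(f"  {_molecule_name(rs.strand)}({','.join(rs.regions)})")
    lines.append(f"  {RECEPTOR}({RECEPTOR_SITE})")
    lines.append("end molecule types")

    lines.append("begin seed species")
    for rs in rulesets:
        count = copy_numbers.get(rs.strand, 0)
        lines.append(
            f"  {_molecule_name(rs.strand)}({','.join(rs.regions)}) "
            f"{_fmt(count)}"
        )
    lines.append(
        f"  {RECEPTOR}({RECEPTOR_SITE}) {_fmt(copy_numbers.get(RECEPTOR, 0))}"
    )
    lines.append("end seed species")

    lines.append("begin reaction rules")
    for rs in rulesets:
        lines.append(f"  # strand {rs.strand} => {_molecule_name(rs.strand)}")
        for rule in rs.forward_rules:
            lines.append(f"  {_forward_line(rs, rule)}")
        mol = _molecule_name(rs.strand)
        for region in rs.regions:
            lines.append(
                f"  {mol}({region}!1).{RECEPTOR}({RECEPTOR_SITE}!1) -> "
                f"{mol}({region}) + {RECEPTOR}({RECEPTOR_SITE}) kr"
            )
    lines.append("end reaction rules")
    lines.append("end model")
    return "\n".join(lines) + "\n"


_FORWARD_RE = re.compile(
    rf"^(\w+)\(([^)]*)\) \+ {RECEPTOR}\({RECEPTOR_SITE}\) -> "
    rf"(\w+)\(([^)]*)\)\.{RECEPTOR}\({RECEPTOR_SITE}!1\) (kf1|kf2)$"
)
_REVERSE_RE = re.compile(
    rf"^(\w+)\((\w+)!1\)\.{RECEPTOR}\({RECEPTOR_SITE}!1\) -> "
    rf"(\w+)\(\w+\) \+ {RECEPTOR}\({RECEPTOR_SITE}\) kr$"
)
_STRAND_COMMENT_RE = re.compile(r"^# strand (\S+) => (\w+)$")


def _sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line in ("begin model", "end model"):
            continue
        if line.startswith("begin "):
            current = line[len("begin ") :]
            sections[current] = []
        elif line.startswith("end "):
            current = None
        elif current is not None:
            sections[current].append(line)
        else:
            raise BNGLError(f"unexpected line outside any section: {raw!r}")
    return sections


def parse_bngl(
    text: str,
) -> tuple[list[RuleSet], dict[str, float]]:
    """Read a model previously written by :func:`export_bngl`.

    Returns the per-strand rule sets (in file order) and the seed copy
    numbers keyed by strand label plus ``"IgE"``.
    """
    sections = _sections(text)
    for required in ("parameters", "molecule types", "seed species", "reaction rules"):
        if required not in sections:
            raise BNGLError(f"missing section {required!r}")

    params: dict[str, float] = {}
    for line in sections["parameters"]:
        name, value = line.split()
        params[name] = float(value)
    try:
        rates = RateParameters(
            k_f1=params["kf1"], k_f2=params["kf2"], k_r=params["kr"]
        )
    except KeyError as exc:
        raise BNGLError(f"missing rate parameter {exc}") from None

    regions_by_mol: dict[str, tuple[str, ...]] = {}
    for line in sections["molecule types"]:
        m = re.match(r"^(\w+)\(([^)]*)\)$", line)
        if not m:
            raise BNGLError(f"bad molecule type line: {line!r}")
        if m.group(1) != RECEPTOR:
            regions_by_mol[m.group(1)] = tuple(m.group(2).split(","))

    copy_numbers: dict[str, float] = {}
    seed_by_mol: dict[str, float] = {}
    for line in sections["seed species"]:
        m = re.match(r"^(\w+)\([^)]*\) (\S+)$", line)
        if not m:
            raise BNGLError(f"bad seed species line: {line!r}")
        seed_by_mol[m.group(1)] = float(m.group(2))

    strand_by_mol: dict[str, str] = {}
    forward: dict[str, list[BindingRule]] = {m: [] for m in regions_by_mol}
    reverse_seen: dict[str, set[str]] = {m: set() for m in regions_by_mol}
    for line in sections["reaction rules"]:
        cm = _STRAND_COMMENT_RE.match(line)
        if cm:
            strand_by_mol[cm.group(2)] = cm.group(1)
            continue
        if line.startswith("#"):
            continue
        fm = _FORWARD_RE.match(line)
        if fm:
            mol, reactant, _, product, rate_name = fm.groups()
            if mol not in regions_by_mol:
                raise BNGLError(f"rule references unknown molecule {mol!r}")
            r_components = reactant.split(",")
            p_components = product.split(",")
            target: str | None = None
            pattern: list[tuple[str, str]] = []
            for rc, pc in zip(r_components, p_components):
                name = rc.split("!")[0]
                if rc == name and pc == f"{name}!1":
                    target = name
                elif rc.endswith("!+"):
                    pattern.append((name, BOUND))
                else:
                    pattern.append((name, FREE))
            if target is None:
                raise BNGLError(f"cannot identify target region in: {line!r}")
            rate_class = UNHINDERED if rate_name == "kf1" else HINDERED
            forward[mol].append(
                BindingRule(
                    target_region=target,
                    neighbor_pattern=tuple(pattern),
                    rate_class=rate_class,
                )
            )
            continue
        rm = _REVERSE_RE.match(line)
        if rm:
            reverse_seen[rm.group(1)].add(rm.group(2))
            continue
        raise BNGLError(f"unrecognized reaction rule line: {line!r}")

    rulesets = []
    for mol, regions in regions_by_mol.items():
        missing = set(regions) - reverse_seen[mol]
        if missing:
            raise BNGLError(
                f"molecule {mol!r}: missing unbinding rules for "
                f"{sorted(missing)}"
            )
        strand = strand_by_mol.get(mol, mol[1:] if mol.startswith("T") else mol)
        rulesets.append(
            RuleSet(
                strand=strand,
                regions=regions,
                forward_rules=tuple(forward[mol]),
                rates=rates,
            )
        )
        copy_numbers[strand] = seed_by_mol.get(mol, 0.0)
    copy_numbers[RECEPTOR] = seed_by_mol.get(RECEPTOR, 0.0)
    return rulesets, copy_numbers
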