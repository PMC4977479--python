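"""Readers and writers for the package's plain-text formats.

Geometry and hindrance maps travel as JSON, histograms and error bars as CSV
(sizes 0..12 everywhere, zero-filled), run configuration as YAML, and rule
sets as BNGL text (see :mod:`stericrules.bngl`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .aggregate import N_SIZES, AggregateSizeDistribution, HistogramSet
from .dynamics import ReactionNetwork, SteadyState
from .geometry import (
    GeometryError,
    RegionPairDistance,
    StericAdjacency,
    StrandGeometry,
)

__all__ = [
    "SchemaError",
    "read_geometry",
    "read_adjacency",
    "read_histogram",
    "write_histogram",
    "write_histogram_set",
    "write_error_bars",
    "write_steady_state",
    "write_network_edges",
    "RunConfig",
    "load_run_config",
]


class SchemaError(ValueError):
    """A file does not conform to the expected schema."""


# ---------------------------------------------------------------------------
# geometry JSON
# ---------------------------------------------------------------------------

def _strand_geometry(doc: Mapping[str, Any]) -> StrandGeometry:
    try:
        strand = doc["strand"]
        regions = doc["regions"]
        raw_pairs = doc["pairs"]
    except KeyError as exc:
        raise SchemaError(f"geometry strand missing field {exc}") from None
    pairs = []
    for item in raw_pairs:
        try:
            pairs.append(
                RegionPairDistance(
                    region_a=item["a"],
                    region_b=item["b"],
                    linear_nm=float(item["linear_nm"]),
                    curvature=item["curvature"],
                    path_nm=(
                        float(item["path_nm"])
                        if item.get("path_nm") is not None
                        else None
                    ),
                )
            )
        except KeyError as exc:
            raise SchemaError(
                f"pair entry {item!r} missing field {exc}"
            ) from None
        except GeometryError as exc:
            raise SchemaError(str(exc)) from None
    try:
        return StrandGeometry(strand, regions, pairs)
    except GeometryError as exc:
        raise SchemaError(str(exc)) from None


def read_geometry(path) -> tuple[StrandGeometry, StrandGeometry]:
    """Load a two-strand geometry JSON file.

    The two strands must carry the same region id set; their distances may
    differ (curvature differs between strands of one antigen).
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("type") not in (None, "geometry"):
        raise SchemaError(
            f"{path}: expected a geometry file, got type={doc.get('type')!r}"
        )
    strands = doc.get("strands")
    if not isinstance(strands, list) or len(strands) != 2:
        raise SchemaError(f"{path}: expected exactly 2 strands")
    first, second = (_strand_geometry(s) for s in strands)
    if set(first.regions) != set(second.regions):
        raise SchemaError(
            f"{path}: strands carry different region id sets: "
            f"{first.regions} vs {second.regions}"
        )
    return first, second


def read_adjacency(path) -> tuple[StericAdjacency, ...]:
    """Load an explicit hindrance-map JSON file (one adjacency per strand)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "adjacency":
        raise SchemaError(
            f"{path}: expected an adjacency file, got type={doc.get('type')!r}"
        )
    out = []
    for strand_doc in doc["strands"]:
        regions = strand_doc["regions"]
        raw = strand_doc["neighbors"]
        try:
            adjacency = StericAdjacency(
                strand=strand_doc["strand"],
                neighbors={
                    r: frozenset(raw.get(r, ())) for r in regions
                },
            )
        except GeometryError as exc:
            raise SchemaError(str(exc)) from None
        out.append(adjacency)
    return tuple(out)


# ---------------------------------------------------------------------------
# histogram CSV
# ---------------------------------------------------------------------------

def _zero_filled(sizes: np.ndarray, values: np.ndarray) -> np.ndarray:
    if np.any((sizes < 0) | (sizes > N_SIZES - 1)):
        bad = sizes[(sizes < 0) | (sizes > N_SIZES - 1)]
        raise SchemaError(
            f"aggregate sizes must lie in 0..{N_SIZES - 1}, got {bad.tolist()}"
        )
    out = np.zeros(N_SIZES)
    out[sizes] = values
    return out


def read_histogram(path) -> AggregateSizeDistribution | HistogramSet:
    """Read an aggregate-size histogram CSV.

    Expected columns: ``size`` plus either a single ``probability`` or
    ``count`` column (returns a distribution; counts are normalized;
    probabilities must sum to 1), or several ``run_*`` columns (returns a
    :class:`HistogramSet` with one histogram per run column).  Missing sizes
    are zero-filled.
    """
    frame = pd.read_csv(path)
    if "size" not in frame.columns:
        raise SchemaError(f"{path}: missing required column 'size'")
    sizes = frame["size"].to_numpy(dtype=int)
    run_cols = [c for c in frame.columns if str(c).startswith("run")]
    if run_cols:
        rows = []
        for col in run_cols:
            values = frame[col].to_numpy(dtype=float)
            h = _zero_filled(sizes, values)
            total = h.sum()
            if total <= 0:
                raise SchemaError(f"{path}: run column {col!r} is empty")
            rows.append(h / total)
        return HistogramSet(runs=np.asarray(rows))
    if "probability" in frame.columns:
        p = _zero_filled(sizes, frame["probability"].to_numpy(dtype=float))
        if abs(p.sum() - 1.0) > 1e-6:
            raise SchemaError(
                f"{path}: probabilities sum to {p.sum():.6f}, expected 1"
            )
        return AggregateSizeDistribution(p / p.sum())
    if "count" in frame.columns:
        counts = _zero_filled(sizes, frame["count"].to_numpy(dtype=float))
        total = counts.sum()
        if total <= 0:
            raise SchemaError(f"{path}: counts sum to zero")
        return AggregateSizeDistribution(counts / total)
    raise SchemaError(
        f"{path}: expected a 'probability', 'count' or 'run_*' column"
    )


def write_histogram(path, dist: AggregateSizeDistribution) -> None:
    frame = pd.DataFrame(
        {"size": np.arange(N_SIZES), "probability": dist.probabilities}
    )
    frame.to_csv(path, index=False)


def write_histogram_set(path, runs: HistogramSet) -> None:
    data: dict[str, Any] = {"size": np.arange(N_SIZES)}
    for i, row in enumerate(runs.runs):
        data[f"run_{i + 1}"] = row
    pd.DataFrame(data).to_csv(path, index=False)


def write_error_bars(path, error_bars: pd.DataFrame) -> None:
    error_bars.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# steady-state / network dumps
# ---------------------------------------------------------------------------

def write_steady_state(path, ss: SteadyState) -> None:
    """Species counts (one row per occupancy state plus receptor pools)."""
    rows = []
    for strand in ss.strands:
        regions = ss.regions_by_strand[strand]
        counts = ss.counts_by_strand[strand]
        for state, count in enumerate(counts):
            occupied = "".join(
                regions[i] if state & (1 << i) else "-"
                for i in range(len(regions))
            )
            rows.append(
                {"species": f"{strand}:{occupied}", "count": count}
            )
    for pool, count in ss.free_receptors.items():
        rows.append({"species": f"receptor[{pool}]", "count": count})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_network_edges(path, network: ReactionNetwork) -> None:
    frame = pd.DataFrame(
        network.reactions(),
        columns=["reactant", "product", "receptor_delta", "rate_constant"],
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration (YAML)
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parsed YAML run configuration for the command-line workflows."""

    geometry: str | None = None
    target_histogram: str | None = None
    output_dir: str = "."
    seed: int = 0
    cutoff_nm: float | None = None
    k_f2: float | None = None
    optimizer: dict[str, Any] = field(default_factory=dict)
    dynamics: dict[str, Any] = field(default_factory=dict)
    mc: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"


def load_run_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = doc.keys() - known
    if unknown:
        raise SchemaError(
            f"{path}: unknown configuration keys {sorted(unknown)}"
        )
    config = RunConfig(**doc)
    for name in ("geometry", "target_histogram"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            raise SchemaError(f"{path}: {name} path does not exist: {value}")
    return config
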