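"""Built-in geometry and hindrance-map fixtures plus standard parameters.

Five named fixtures cover the demonstration molecules:

``native``, ``s_shaped``, ``u_shaped``
    Full-resolution conformations of the two-strand antigen.  Distance
    tables are synthetic reconstructions chosen so the nearest-neighbor
    chain adjacency A-B-C-D-E-F appears exactly over each conformation's
    published cutoff interval (native 7.0-8.7 nm, S-shaped 6.8-8.3 nm,
    U-shaped 6.8-8.6 nm).  The native table also encodes the half-resolution
    worked example (strand I C-D = 5.5 nm, strand II C-D = 5.6 nm).
``rotated45``
    U-shaped molecule with both ends rotated inward by 45 degrees; distance
    table reconstructed to give the published six-edge adjacency at the
    demonstration cutoff 8.1 nm.
``rotated60``
    Ends rotated inward by 60 degrees.  Ships as an explicit hindrance map
    (the published rule table is directional for the pair B-D, which no
    symmetric distance table can reproduce).

Regenerating rule sets from these fixtures is byte-reproducible.
"""

from __future__ import annotations

from importlib import resources

from .dynamics import SimulationConfig
from .geometry import StericAdjacency, StrandGeometry, build_adjacency
from .io import read_adjacency, read_geometry
from .rulegen import RateParameters

__all__ = [
    "GEOMETRY_FIXTURES",
    "ADJACENCY_FIXTURES",
    "list_fixtures",
    "load_geometry",
    "load_adjacency",
    "default_rates",
    "default_simulation",
    "DEMO_CUTOFF_NM",
    "DEMO_KF2",
]

GEOMETRY_FIXTURES = ("native", "s_shaped", "u_shaped", "rotated45")
ADJACENCY_FIXTURES = ("rotated60",)

#: Demonstration parameters of the curvature study: the cutoff distance is
#: fixed at 8.1 nm and the hindered rate constant at 0.005 molecule^-1 s^-1.
DEMO_CUTOFF_NM = 8.1
DEMO_KF2 = 0.005

#: Standard fixed rate constants: unhindered binding 1.0 molecule^-1 s^-1,
#: unbinding 0.01 s^-1.
DEFAULT_KF1 = 1.0
DEFAULT_KR = 0.01


def list_fixtures() -> tuple[str, ...]:
    return GEOMETRY_FIXTURES + ADJACENCY_FIXTURES


def _data_path(name: str):
    if name not in list_fixtures():
        raise KeyError(
            f"unknown fixture {name!r}; available: {list_fixtures()}"
        )
    return resources.files("stericrules.data").joinpath(f"{name}.json")


def load_geometry(name: str) -> tuple[StrandGeometry, StrandGeometry]:
    """Two-strand geometry of a distance-table fixture."""
    if name in ADJACENCY_FIXTURES:
        raise KeyError(
            f"fixture {name!r} is an explicit hindrance map with no distance "
            "table; use load_adjacency"
        )
    with resources.as_file(_data_path(name)) as path:
        return read_geometry(path)


def load_adjacency(
    name: str, d_c: float | None = None
) -> tuple[StericAdjacency, ...]:
    """Per-strand steric adjacency of a fixture.

    For geometry fixtures a cutoff distance ``d_c`` is required and the
    adjacency is derived from the distance table.  For hindrance-map
    fixtures the stored map is returned as-is (``d_c`` is ignored; the map
    is nominally valid at the demonstration cutoff).
    """
    if name in ADJACENCY_FIXTURES:
        with resources.as_file(_data_path(name)) as path:
            return read_adjacency(path)
    if d_c is None:
        raise ValueError(
            f"fixture {name!r} is a distance table; pass a cutoff distance"
        )
    return tuple(build_adjacency(g, d_c) for g in load_geometry(name))


def default_rates(k_f2: float) -> RateParameters:
    """Standard rates with a chosen hindered constant."""
    return RateParameters(k_f1=DEFAULT_KF1, k_f2=k_f2, k_r=DEFAULT_KR)


def default_simulation(**overrides) -> SimulationConfig:
    """Standard copy numbers and horizon (100/100 strands, 1000 receptors,
    1000 x 0.01 s)."""
    return SimulationConfig(**overrides)
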