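"""Reaction-network expansion and deterministic/stochastic simulation.

Because one antibody-receptor complex occupies one binding region and
antigen-antigen crosslinking is forbidden, the configuration space of a
strand with ``m`` regions is exactly its ``2**m`` occupancy states.  The
network is therefore enumerated exhaustively (generate-then-integrate): every
(state, free region) pair yields one binding reaction consuming a receptor at
``k_f1`` or ``k_f2`` according to the unique matching rule, and every
(state, bound region) pair yields one unbinding reaction releasing a receptor
at ``k_r``.  Mass-action ODEs in raw molecule-count units (bimolecular
constants in molecule^-1 s^-1, no volume factor) are integrated with a
stiff-safe method to a fixed horizon, with a residual check for steady state.
A Gillespie stochastic simulator over the same network serves as an exact
finite-copy-number oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .rulegen import UNHINDERED, RuleSet

__all__ = [
    "SimulationConfig",
    "ReactionNetwork",
    "SteadyState",
    "IntegrationError",
    "build_network",
    "integrate_to_steady_state",
    "simulate",
    "ssa_oracle",
    "strand_size_distribution",
    "region_binding_probabilities",
    "mean_strand_size",
]

#: Hard cap on regions per strand (2**m states must stay enumerable).
MAX_REGIONS = 16


class IntegrationError(RuntimeError):
    """ODE integration failed or produced non-finite state."""


@dataclass
class SimulationConfig:
    """Copy numbers and integration settings.

    Defaults follow the standard in-solution experiment: 100 copies of each
    strand, 1000 receptors, integrated for 1000 steps of 0.01 s (10 s total).
    ``convergence_tol`` bounds the residual max|dy/dt| at the horizon,
    measured relative to the total strand copy number (fractional drift per
    second); the default 1e-3 tolerates the slow k_r-scale redistribution
    mode, which moves the reported probabilities only in the fourth decimal
    beyond the standard horizon.
    ``shared_receptor_pool=True`` places both strand types in one system
    competing for the same receptors; ``False`` runs each strand type alone
    against the full receptor count.
    """

    strand_I_count: float = 100.0
    strand_II_count: float = 100.0
    receptor_count: float = 1000.0
    t_end: float = 10.0
    dt: float = 0.01
    shared_receptor_pool: bool = True
    seed: int | None = None
    counts: Mapping[str, float] | None = None
    rtol: float = 1e-8
    atol: float = 1e-10
    convergence_tol: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("strand_I_count", "strand_II_count", "receptor_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.counts is not None and any(v < 0 for v in self.counts.values()):
            raise ValueError("strand counts must be >= 0")
        if not (self.t_end > 0 and self.dt > 0):
            raise ValueError("t_end and dt must be > 0")

    def count_for(self, strand: str) -> float:
        if self.counts is not None and strand in self.counts:
            return float(self.counts[strand])
        if strand == "I":
            return float(self.strand_I_count)
        if strand == "II":
            return float(self.strand_II_count)
        raise ValueError(
            f"no copy number configured for strand {strand!r}; pass counts="
            "{...} for non-standard strand labels"
        )


class ReactionNetwork:
    """Exhaustively enumerated reaction network over strand occupancy states.

    Species are ordered strand by strand (states in binary counting order,
    bit ``i`` = region ``i`` of the strand bound) with the free receptor as
    the final species.
    """

    def __init__(self, rulesets: Sequence[RuleSet]) -> None:
        if not rulesets:
            raise ValueError("need at least one rule set")
        labels = [rs.strand for rs in rulesets]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate strand labels: {labels}")
        self.rulesets = tuple(rulesets)
        self.strands: tuple[str, ...] = tuple(labels)
        self.regions_by_strand = {rs.strand: rs.regions for rs in rulesets}
        self.k_f1 = rulesets[0].rates.k_f1
        self.k_f2 = rulesets[0].rates.k_f2
        self.k_r = rulesets[0].rates.k_r

        self._offsets: dict[str, int] = {}
        self._n_states: dict[str, int] = {}
        offset = 0
        for rs in rulesets:
            m = len(rs.regions)
            if m > MAX_REGIONS:
                raise ValueError(
                    f"strand {rs.strand!r} has {m} regions; at most "
                    f"{MAX_REGIONS} supported"
                )
            self._offsets[rs.strand] = offset
            self._n_states[rs.strand] = 2**m
            offset += 2**m
        self.n_species = offset + 1
        self.receptor_index = offset

        fwd_src: list[int] = []
        fwd_dst: list[int] = []
        fwd_hindered: list[bool] = []
        rev_src: list[int] = []
        rev_dst: list[int] = []
        for rs in rulesets:
            off = self._offsets[rs.strand]
            regions = rs.regions
            index_of = {r: i for i, r in enumerate(regions)}
            class_table = _rate_class_table(rs)
            neighbor_bits = {
                region: [index_of[n] for n in neighbors]
                for region, neighbors in rs.neighbor_map().items()
            }
            for state in range(2 ** len(regions)):
                for i, region in enumerate(regions):
                    bit = 1 << i
                    if state & bit:
                        rev_src.append(off + state)
                        rev_dst.append(off + (state & ~bit))
                    else:
                        bound = frozenset(
                            regions[j]
                            for j in neighbor_bits[region]
                            if state & (1 << j)
                        )
                        fwd_src.append(off + state)
                        fwd_dst.append(off + (state | bit))
                        fwd_hindered.append(
                            class_table[region][bound] != UNHINDERED
                        )
        self.fwd_src = np.asarray(fwd_src, dtype=np.intp)
        self.fwd_dst = np.asarray(fwd_dst, dtype=np.intp)
        self.fwd_hindered = np.asarray(fwd_hindered, dtype=bool)
        self.rev_src = np.asarray(rev_src, dtype=np.intp)
        self.rev_dst = np.asarray(rev_dst, dtype=np.intp)
        self.fwd_k = np.where(self.fwd_hindered, self.k_f2, self.k_f1)
        self.rev_k = np.full(len(rev_src), self.k_r)

    # -- species bookkeeping -------------------------------------------------
    def strand_slice(self, strand: str) -> slice:
        off = self._offsets[strand]
        return slice(off, off + self._n_states[strand])

    def n_states(self, strand: str) -> int:
        return self._n_states[strand]

    def bound_counts(self, strand: str) -> np.ndarray:
        """Number of bound regions of each occupancy state of a strand."""
        states = np.arange(self._n_states[strand], dtype=np.uint64)
        return np.bitwise_count(states).astype(np.intp)

    def species_names(self) -> list[str]:
        names = []
        for rs in self.rulesets:
            m = len(rs.regions)
            for state in range(2**m):
                occupied = "".join(
                    rs.regions[i] if state & (1 << i) else "-"
                    for i in range(m)
                )
                names.append(f"{rs.strand}:{occupied}")
        names.append("receptor")
        return names

    def set_kf2(self, k_f2: float) -> "ReactionNetwork":
        """Re-rate the hindered reactions in place (structure unchanged)."""
        if not (0 <= k_f2 < self.k_f1):
            raise ValueError(f"need 0 <= k_f2 < k_f1={self.k_f1}, got {k_f2}")
        self.k_f2 = float(k_f2)
        self.fwd_k = np.where(self.fwd_hindered, self.k_f2, self.k_f1)
        return self

    # -- mass-action right-hand side and Jacobian ----------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        R = y[self.receptor_index]
        fw = self.fwd_k * y[self.fwd_src] * R
        rv = self.rev_k * y[self.rev_src]
        dy = np.zeros_like(y)
        np.subtract.at(dy, self.fwd_src, fw)
        np.add.at(dy, self.fwd_dst, fw)
        np.subtract.at(dy, self.rev_src, rv)
        np.add.at(dy, self.rev_dst, rv)
        dy[self.receptor_index] = rv.sum() - fw.sum()
        return dy

    def jacobian(self, t: float, y: np.ndarray) -> np.ndarray:
        n, iR = self.n_species, self.receptor_index
        R = y[iR]
        kR = self.fwd_k * R
        kx = self.fwd_k * y[self.fwd_src]
        J = np.zeros((n, n))
        np.subtract.at(J, (self.fwd_src, self.fwd_src), kR)
        np.add.at(J, (self.fwd_dst, self.fwd_src), kR)
        np.subtract.at(J, (self.fwd_src, np.full_like(self.fwd_src, iR)), kx)
        np.add.at(J, (self.fwd_dst, np.full_like(self.fwd_dst, iR)), kx)
        np.subtract.at(J, (np.full_like(self.fwd_src, iR), self.fwd_src), kR)
        J[iR, iR] -= kx.sum()
        np.subtract.at(J, (self.rev_src, self.rev_src), self.rev_k)
        np.add.at(J, (self.rev_dst, self.rev_src), self.rev_k)
        np.add.at(J, (np.full_like(self.rev_src, iR), self.rev_src), self.rev_k)
        return J

    def reactions(self) -> list[tuple[str, str, int, float]]:
        """Edge list: (reactant, product, receptor delta, rate constant)."""
        names = self.species_names()
        out = []
        for s, d, k in zip(self.fwd_src, self.fwd_dst, self.fwd_k):
            out.append((names[s], names[d], -1, float(k)))
        for s, d, k in zip(self.rev_src, self.rev_dst, self.rev_k):
            out.append((names[s], names[d], +1, float(k)))
        return out


def _rate_class_table(ruleset: RuleSet) -> dict[str, dict[frozenset[str], str]]:
    ruleset.rate_table()  # validates full pattern coverage
    table: dict[str, dict[frozenset[str], str]] = {
        r: {} for r in ruleset.regions
    }
    for rule in ruleset.forward_rules:
        table[rule.target_region][rule.bound_neighbors] = rule.rate_class
    return table


def build_network(rulesets: RuleSet | Sequence[RuleSet]) -> ReactionNetwork:
    """Expand rule set(s) into the exhaustive occupancy-state network."""
    if isinstance(rulesets, RuleSet):
        rulesets = [rulesets]
    return ReactionNetwork(rulesets)


@dataclass
class SteadyState:
    """End-of-integration species counts with conservation bookkeeping.

    ``counts_by_strand[s]`` is the expected molecule count of every occupancy
    state of strand ``s``; ``free_receptors`` is keyed by receptor pool (one
    pool named after the joined strand labels in shared mode, one pool per
    strand otherwise).  For stochastic means, ``sem_by_strand`` carries the
    per-state standard error over runs.
    """

    strands: tuple[str, ...]
    regions_by_strand: dict[str, tuple[str, ...]]
    counts_by_strand: dict[str, np.ndarray]
    strand_totals: dict[str, float]
    free_receptors: dict[str, float]
    receptor_totals: dict[str, float]
    pool_by_strand: dict[str, str]
    converged: bool
    residual: float
    trajectory: tuple[np.ndarray, dict[str, np.ndarray]] | None = None
    sem_by_strand: dict[str, np.ndarray] | None = None
    size_class_runs: dict[str, np.ndarray] | None = None
    n_runs: int | None = None

    def bound_receptors(self, strand: str) -> float:
        counts = self.counts_by_strand[strand]
        states = np.arange(len(counts), dtype=np.uint64)
        return float((counts * np.bitwise_count(states)).sum())

    def conservation_errors(self) -> dict[str, float]:
        """Relative conservation defects for each strand and receptor pool."""
        errors: dict[str, float] = {}
        for strand in self.strands:
            total = self.strand_totals[strand]
            got = float(self.counts_by_strand[strand].sum())
            scale = max(abs(total), 1.0)
            errors[f"strand:{strand}"] = abs(got - total) / scale
        for pool, total in self.receptor_totals.items():
            bound = sum(
                self.bound_receptors(s)
                for s in self.strands
                if self.pool_by_strand[s] == pool
            )
            got = self.free_receptors[pool] + bound
            scale = max(abs(total), 1.0)
            errors[f"receptors:{pool}"] = abs(got - total) / scale
        return errors


def _initial_state(
    network: ReactionNetwork, config: SimulationConfig
) -> np.ndarray:
    y0 = np.zeros(network.n_species)
    for strand in network.strands:
        y0[network.strand_slice(strand).start] = config.count_for(strand)
    y0[network.receptor_index] = config.receptor_count
    return y0


def integrate_to_steady_state(
    network: ReactionNetwork,
    config: SimulationConfig,
    t_eval: Sequence[float] | None = None,
) -> SteadyState:
    """Integrate the mass-action ODEs to ``t_end`` and report the end state.

    Uses LSODA with an analytic Jacobian (the binding transient is stiff:
    per-site binding propensities are ~1e3/s against k_r = 0.01/s).  The
    horizon is fixed (default 1000 x 0.01 s); if the residual max|dy/dt| at
    ``t_end`` exceeds ``convergence_tol`` the state is returned with
    ``converged=False`` and a warning rather than silently extending.
    """
    y0 = _initial_state(network, config)
    times = None if t_eval is None else np.asarray(t_eval, dtype=float)
    sol = solve_ivp(
        network.rhs,
        (0.0, config.t_end),
        y0,
        method="LSODA",
        jac=network.jacobian,
        rtol=config.rtol,
        atol=config.atol,
        t_eval=times,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    y_end = sol.y[:, -1]
    if not np.all(np.isfinite(y_end)):
        bad = np.flatnonzero(~np.isfinite(y_end))
        names = network.species_names()
        raise IntegrationError(
            f"non-finite state at t_end for species "
            f"{[names[i] for i in bad[:5]]}"
        )
    residual = float(np.max(np.abs(network.rhs(config.t_end, y_end))))
    strand_total = sum(config.count_for(s) for s in network.strands)
    converged = residual < config.convergence_tol * max(strand_total, 1.0)
    if not converged:
        warnings.warn(
            f"steady state not reached at t_end={config.t_end}: "
            f"max|dy/dt| = {residual:.3g} molecules/s against "
            f"{strand_total:g} strand molecules "
            f"(relative tol {config.convergence_tol:.3g})",
            stacklevel=2,
        )
    pool = "+".join(network.strands)
    trajectory = None
    if times is not None:
        trajectory = (
            sol.t,
            {s: sol.y[network.strand_slice(s), :] for s in network.strands}
            | {"receptor": sol.y[network.receptor_index, :]},
        )
    return SteadyState(
        strands=network.strands,
        regions_by_strand=dict(network.regions_by_strand),
        counts_by_strand={
            s: y_end[network.strand_slice(s)].copy() for s in network.strands
        },
        strand_totals={
            s: config.count_for(s) for s in network.strands
        },
        free_receptors={pool: float(y_end[network.receptor_index])},
        receptor_totals={pool: config.receptor_count},
        pool_by_strand={s: pool for s in network.strands},
        converged=converged,
        residual=residual,
        trajectory=trajectory,
    )


def simulate(
    rulesets: RuleSet | Sequence[RuleSet],
    config: SimulationConfig,
) -> SteadyState:
    """Steady state of one or more strand types under the configured pool.

    With ``shared_receptor_pool=True`` (default) all strand types compete in
    one ODE system for ``receptor_count`` receptors.  Otherwise each strand
    type is integrated alone against the full receptor count and the results
    are merged (one receptor pool per strand).
    """
    if isinstance(rulesets, RuleSet):
        rulesets = [rulesets]
    if config.shared_receptor_pool or len(rulesets) == 1:
        return integrate_to_steady_state(build_network(rulesets), config)
    parts = [
        integrate_to_steady_state(build_network([rs]), config)
        for rs in rulesets
    ]
    merged = parts[0]
    for part in parts[1:]:
        merged = SteadyState(
            strands=merged.strands + part.strands,
            regions_by_strand={
                **merged.regions_by_strand,
                **part.regions_by_strand,
            },
            counts_by_strand={
                **merged.counts_by_strand,
                **part.counts_by_strand,
            },
            strand_totals={**merged.strand_totals, **part.strand_totals},
            free_receptors={**merged.free_receptors, **part.free_receptors},
            receptor_totals={
                **merged.receptor_totals,
                **part.receptor_totals,
            },
            pool_by_strand={**merged.pool_by_strand, **part.pool_by_strand},
            converged=merged.converged and part.converged,
            residual=max(merged.residual, part.residual),
        )
    return merged


def ssa_oracle(
    network: ReactionNetwork,
    config: SimulationConfig,
    n_runs: int,
) -> SteadyState:
    """Exact Gillespie simulation of the same network; mean over runs.

    Initial copy numbers must be integers.  Returns the sample mean of every
    species count at ``t_end`` with the standard error over runs in
    ``sem_by_strand`` (and the receptor pool).  This is the stochastic
    counterpart of the ODE system and serves as an independent oracle for it.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    y0 = _initial_state(network, config)
    if np.any(np.abs(y0 - np.round(y0)) > 1e-9):
        raise ValueError("SSA requires integer initial copy numbers")
    rng = np.random.default_rng(config.seed)
    iR = network.receptor_index
    finals = np.empty((n_runs, network.n_species))
    for run in range(n_runs):
        x = np.round(y0).astype(np.int64)
        t = 0.0
        while True:
            R = x[iR]
            a_f = network.fwd_k * x[network.fwd_src] * R
            a_r = network.rev_k * x[network.rev_src]
            a0 = a_f.sum() + a_r.sum()
            if a0 <= 0:
                break
            t += rng.exponential(1.0 / a0)
            if t >= config.t_end:
                break
            u = rng.random() * a0
            cum = np.cumsum(np.concatenate((a_f, a_r)))
            j = int(np.searchsorted(cum, u, side="right"))
            if j < len(a_f):
                x[network.fwd_src[j]] -= 1
                x[network.fwd_dst[j]] += 1
                x[iR] -= 1
            else:
                k = j - len(a_f)
                x[network.rev_src[k]] -= 1
                x[network.rev_dst[k]] += 1
                x[iR] += 1
        finals[run] = x
    size_class_runs = {}
    for s in network.strands:
        block = finals[:, network.strand_slice(s)]
        sizes = network.bound_counts(s)
        m = len(network.regions_by_strand[s])
        per_run = np.zeros((n_runs, m + 1))
        for n in range(m + 1):
            per_run[:, n] = block[:, sizes == n].sum(axis=1)
        size_class_runs[s] = per_run
    mean = finals.mean(axis=0)
    sem = finals.std(axis=0, ddof=1) / np.sqrt(n_runs) if n_runs > 1 else (
        np.zeros(network.n_species)
    )
    pool = "+".join(network.strands)
    return SteadyState(
        strands=network.strands,
        regions_by_strand=dict(network.regions_by_strand),
        counts_by_strand={
            s: mean[network.strand_slice(s)].copy() for s in network.strands
        },
        strand_totals={s: config.count_for(s) for s in network.strands},
        free_receptors={pool: float(mean[iR])},
        receptor_totals={pool: config.receptor_count},
        pool_by_strand={s: pool for s in network.strands},
        converged=True,
        residual=float("nan"),
        sem_by_strand={
            s: sem[network.strand_slice(s)].copy() for s in network.strands
        }
        | {"receptor": sem[iR : iR + 1]},
        size_class_runs=size_class_runs,
        n_runs=n_runs,
    )


def _require_converged(ss: SteadyState) -> None:
    if not ss.converged:
        warnings.warn(
            "steady state flagged as not converged; derived distributions "
            "may reflect a transient",
            stacklevel=3,
        )


def strand_size_distribution(ss: SteadyState, strand: str) -> np.ndarray:
    """P(n bound regions) for one strand, vector over n = 0..m.

    Sums the expected counts of all occupancy states with exactly ``n``
    regions bound and normalizes by the strand copy number.
    """
    _require_converged(ss)
    counts = ss.counts_by_strand[strand]
    total = ss.strand_totals[strand]
    if total <= 0:
        raise ValueError(
            f"strand {strand!r} has zero copy number; size distribution "
            "undefined"
        )
    m = len(ss.regions_by_strand[strand])
    states = np.arange(len(counts), dtype=np.uint64)
    sizes = np.bitwise_count(states).astype(np.intp)
    dist = np.bincount(sizes, weights=counts, minlength=m + 1) / float(
        counts.sum()
    )
    return dist


def region_binding_probabilities(
    ss: SteadyState, strand: str
) -> dict[str, float]:
    """Marginal occupancy probability of each region of a strand."""
    _require_converged(ss)
    counts = ss.counts_by_strand[strand]
    regions = ss.regions_by_strand[strand]
    total = float(counts.sum())
    states = np.arange(len(counts), dtype=np.intp)
    probs = {}
    for i, region in enumerate(regions):
        mask = (states & (1 << i)) != 0
        probs[region] = float(counts[mask].sum()) / total if total > 0 else 0.0
    return probs


def mean_strand_size(ss: SteadyState, strand: str) -> float:
    dist = strand_size_distribution(ss, strand)
    return float(np.dot(np.arange(len(dist)), dist))
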