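"""Simplified rigid-body membrane Monte Carlo aggregation simulator.

Generates target aggregate-size histograms with the statistical structure the
fitting stage expects: one rigid multivalent antigen and a population of
antibody-receptor complexes diffusing on a 2D membrane patch, with
distance-triggered stochastic binding and first-order unbinding.

Molecules are disks, not polygon meshes: the receptor complex is a disk of
fixed radius and each antigen binding site carries a small exclusion radius.
Steric hindrance then emerges mechanically — a receptor parked at one site
excludes other receptors from a neighborhood of receptor-diameter scale, so
closely spaced sites compete for access while widely spaced sites fill
independently.  Shrinking the exclusion radii emulates, abstractly, the
volume loss of reduced-resolution molecular models.

Defaults reproduce the standard membrane experiment: a 200 nm x 200 nm
non-periodic box, one antigen, 24 receptors (600 receptors/um^2), binding and
unbinding rates 1.0 molecule^-1 s^-1 and 0.01 s^-1, monomer diffusion
coefficient 0.09 um^2/s, 10 us time steps, 5e5 steps per run, 60 runs per
campaign.  An aggregate of n receptors diffuses at 1/n of the monomer
coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .aggregate import N_SIZES, HistogramSet

__all__ = [
    "MCConfig",
    "MCRunResult",
    "default_site_layout",
    "run_mc",
    "run_campaign",
]


def default_site_layout(
    spacing: float = 7.0, strand_gap: float = 2.0
) -> np.ndarray:
    """Twelve binding-site coordinates (nm) in the antigen frame.

    Two parallel strands of six sites each along the rod axis, ``spacing``
    nm apart within a strand and ``strand_gap`` nm between strands.
    """
    x = (np.arange(6) - 2.5) * spacing
    upper = np.column_stack([x, np.full(6, strand_gap / 2)])
    lower = np.column_stack([x, np.full(6, -strand_gap / 2)])
    return np.vstack([upper, lower])


@dataclass
class MCConfig:
    """Membrane Monte Carlo parameters (lengths nm, times s).

    ``D0`` is the monomer diffusion coefficient in um^2/s; an aggregate of
    ``n`` receptors diffuses at ``D0 / n``.  ``binding_distance`` is the
    maximum site-to-receptor-center separation at which a binding attempt is
    made, with per-step success probability ``min(1, k_on * dt)``; it must
    exceed the hard-core contact distance ``receptor_radius +
    site_exclusion_radius`` or no receptor could ever reach a site.
    """

    box: tuple[float, float] = (200.0, 200.0)
    antigen_count: int = 1
    receptor_count: int = 24
    site_layout: np.ndarray = field(default_factory=default_site_layout)
    site_exclusion_radius: float = 0.5
    receptor_radius: float = 5.0
    binding_distance: float = 6.0
    k_on: float = 1.0
    k_off: float = 0.01
    D0: float = 0.09
    rot_D0: float = 0.5
    dt: float = 1e-5
    steps: int = 500_000
    seed: int | None = None
    antigen_mobile: bool = True
    record_every: int = 1000
    max_init_tries: int = 20_000
    check_invariants_every: int | None = None

    def __post_init__(self) -> None:
        self.site_layout = np.asarray(self.site_layout, dtype=float)
        if self.site_layout.ndim != 2 or self.site_layout.shape[1] != 2:
            raise ValueError("site_layout must be an (n_sites, 2) array")
        if self.antigen_count != 1:
            raise ValueError("exactly one antigen per run is supported")
        for name in (
            "site_exclusion_radius",
            "receptor_radius",
            "binding_distance",
            "dt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_on < 0 or self.k_off < 0 or self.D0 < 0 or self.rot_D0 < 0:
            raise ValueError("rates and diffusion coefficients must be >= 0")
        if self.k_off * self.dt > 1:
            raise ValueError("dt * k_off must be <= 1")
        if self.binding_distance <= self.contact_distance:
            raise ValueError(
                f"binding_distance ({self.binding_distance} nm) must exceed "
                f"the contact distance receptor_radius + "
                f"site_exclusion_radius ({self.contact_distance} nm)"
            )
        if self.steps < 1 or self.receptor_count < 0:
            raise ValueError("steps >= 1 and receptor_count >= 0 required")

    @property
    def n_sites(self) -> int:
        return int(self.site_layout.shape[0])

    @property
    def contact_distance(self) -> float:
        return self.receptor_radius + self.site_exclusion_radius

    @property
    def receptor_density_per_um2(self) -> float:
        """Implied receptor surface density, receptors per square micron."""
        area_um2 = (self.box[0] / 1000.0) * (self.box[1] / 1000.0)
        return self.receptor_count / area_um2

    def diffusion_coefficient(self, size: int) -> float:
        """Aggregate diffusion coefficient, um^2/s; inverse-size scaling."""
        return self.D0 / max(int(size), 1)

    @classmethod
    def test_profile(cls, seed: int | None = None, **overrides) -> "MCConfig":
        """Scaled-down profile for fast tests: smaller box, fewer receptors,
        boosted on-rate, far fewer steps."""
        params = dict(
            box=(80.0, 80.0),
            receptor_count=10,
            k_on=500.0,
            steps=4000,
            record_every=200,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class MCRunResult:
    """Outcome of one membrane run."""

    final_size: int
    edge_counts: np.ndarray
    record_times: np.ndarray

    def histogram(self) -> np.ndarray:
        h = np.zeros(N_SIZES)
        h[min(self.final_size, N_SIZES - 1)] = 1.0
        return h


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class _State:
    """Mutable simulation state with invariant checks for testing."""

    def __init__(self, config: MCConfig, rng: np.random.Generator) -> None:
        self.cfg = config
        self.rng = rng
        bx, by = config.box
        self.antigen_pos = np.array([bx / 2, by / 2])
        self.antigen_theta = float(rng.uniform(0, 2 * np.pi))
        self.receptor_pos = np.zeros((config.receptor_count, 2))
        self.receptor_site = np.full(config.receptor_count, -1, dtype=int)
        self.site_receptor = np.full(config.n_sites, -1, dtype=int)
        # Receptor offsets in the antigen frame, valid while bound.
        self.bond_offset = np.zeros((config.receptor_count, 2))
        self._place_receptors()

    # -- geometry ------------------------------------------------------------
    def site_positions(
        self, pos: np.ndarray | None = None, theta: float | None = None
    ) -> np.ndarray:
        pos = self.antigen_pos if pos is None else pos
        theta = self.antigen_theta if theta is None else theta
        return self.cfg.site_layout @ _rot(theta).T + pos

    def _place_receptors(self) -> None:
        cfg = self.cfg
        bx, by = cfg.box
        r = cfg.receptor_radius
        sites = self.site_positions()
        placed = 0
        for _ in range(cfg.max_init_tries):
            if placed == cfg.receptor_count:
                break
            p = self.rng.uniform([r, r], [bx - r, by - r])
            if placed and (
                np.min(
                    np.linalg.norm(self.receptor_pos[:placed] - p, axis=1)
                )
                < 2 * r
            ):
                continue
            if np.min(np.linalg.norm(sites - p, axis=1)) < cfg.contact_distance:
                continue
            self.receptor_pos[placed] = p
            placed += 1
        if placed < cfg.receptor_count:
            raise RuntimeError(
                f"could not place {cfg.receptor_count} receptors of radius "
                f"{r} nm in a {bx} x {by} nm box without overlap"
            )

    # -- moves ---------------------------------------------------------------
    @property
    def n_bound(self) -> int:
        return int(np.count_nonzero(self.receptor_site >= 0))

    def move_aggregate(self) -> None:
        cfg = self.cfg
        size = max(self.n_bound, 1)
        d_nm2 = cfg.diffusion_coefficient(size) * 1e6  # um^2/s -> nm^2/s
        sigma = np.sqrt(2 * d_nm2 * cfg.dt)
        sigma_rot = np.sqrt(2 * (cfg.rot_D0 / size) * cfg.dt)
        dpos = self.rng.normal(0.0, sigma, 2)
        dtheta = float(self.rng.normal(0.0, sigma_rot))
        new_pos = self.antigen_pos + dpos
        new_theta = self.antigen_theta + dtheta
        bx, by = cfg.box
        sites = self.site_positions(new_pos, new_theta)
        margin = cfg.site_exclusion_radius
        if np.any(sites < margin) or np.any(
            sites > [bx - margin, by - margin]
        ):
            return
        bound = np.flatnonzero(self.receptor_site >= 0)
        free = np.flatnonzero(self.receptor_site < 0)
        new_bound_pos = (
            self.bond_offset[bound] @ _rot(new_theta).T + new_pos
            if len(bound)
            else np.zeros((0, 2))
        )
        r = cfg.receptor_radius
        if len(bound) and (
            np.any(new_bound_pos < r)
            or np.any(new_bound_pos > [bx - r, by - r])
        ):
            return
        if len(free):
            free_pos = self.receptor_pos[free]
            if len(bound):
                d = np.linalg.norm(
                    new_bound_pos[:, None, :] - free_pos[None, :, :], axis=2
                )
                if np.min(d) < 2 * r:
                    return
            d = np.linalg.norm(
                sites[:, None, :] - free_pos[None, :, :], axis=2
            )
            if np.min(d) < cfg.contact_distance:
                return
        self.antigen_pos = new_pos
        self.antigen_theta = new_theta
        if len(bound):
            self.receptor_pos[bound] = new_bound_pos

    def move_free_receptors(self) -> None:
        cfg = self.cfg
        bx, by = cfg.box
        r = cfg.receptor_radius
        sigma = np.sqrt(2 * cfg.D0 * 1e6 * cfg.dt)
        sites = self.site_positions()
        free = np.flatnonzero(self.receptor_site < 0)
        for i in free:
            p = self.receptor_pos[i] + self.rng.normal(0.0, sigma, 2)
            if np.any(p < r) or p[0] > bx - r or p[1] > by - r:
                continue
            others = np.delete(self.receptor_pos, i, axis=0)
            if len(others) and np.min(
                np.linalg.norm(others - p, axis=1)
            ) < 2 * r:
                continue
            if np.min(np.linalg.norm(sites - p, axis=1)) < cfg.contact_distance:
                continue
            self.receptor_pos[i] = p

    def unbind(self) -> None:
        cfg = self.cfg
        p_off = min(1.0, cfg.k_off * cfg.dt)
        if p_off <= 0:
            return
        bound = np.flatnonzero(self.receptor_site >= 0)
        for i in bound:
            if self.rng.random() < p_off:
                self.site_receptor[self.receptor_site[i]] = -1
                self.receptor_site[i] = -1

    def bind(self) -> None:
        cfg = self.cfg
        p_on = min(1.0, cfg.k_on * cfg.dt)
        if p_on <= 0:
            return
        free_r = np.flatnonzero(self.receptor_site < 0)
        free_s = np.flatnonzero(self.site_receptor < 0)
        if not len(free_r) or not len(free_s):
            return
        sites = self.site_positions()
        d = np.linalg.norm(
            sites[free_s][:, None, :] - self.receptor_pos[free_r][None, :, :],
            axis=2,
        )
        pairs = np.argwhere(d <= cfg.binding_distance)
        if not len(pairs):
            return
        self.rng.shuffle(pairs, axis=0)
        inv_rot = _rot(-self.antigen_theta)
        for si, ri in pairs:
            site = int(free_s[si])
            rec = int(free_r[ri])
            if self.site_receptor[site] >= 0 or self.receptor_site[rec] >= 0:
                continue
            if self.rng.random() < p_on:
                self.site_receptor[site] = rec
                self.receptor_site[rec] = site
                self.bond_offset[rec] = inv_rot @ (
                    self.receptor_pos[rec] - self.antigen_pos
                )

    # -- invariants (exercised by the test suite) ---------------------------
    def check_invariants(self) -> None:
        cfg = self.cfg
        bound = self.receptor_site >= 0
        sites_of_bound = self.receptor_site[bound]
        assert len(set(sites_of_bound)) == len(sites_of_bound)
        for site, rec in enumerate(self.site_receptor):
            if rec >= 0:
                assert self.receptor_site[rec] == site
        pos = self.receptor_pos
        if len(pos) > 1:
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
            np.fill_diagonal(d, np.inf)
            assert np.min(d) >= 2 * cfg.receptor_radius - 1e-6


def run_mc(config: MCConfig, rng: np.random.Generator | None = None) -> MCRunResult:
    """One membrane run; returns the final aggregate size (bound receptors)
    and the recorded bond-count series.

    Per step: the antigen aggregate and every free receptor take Gaussian
    diffusive moves (rejected on overlap or boundary exit), bound receptors
    may unbind with probability ``k_off * dt``, and free receptors within
    ``binding_distance`` of a free site bind with probability
    ``min(1, k_on * dt)``.  Warns if the bond count was still drifting over
    the final quarter of the run.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    state = _State(config, rng)
    edge_counts = []
    record_times = []
    for step in range(1, config.steps + 1):
        if config.antigen_mobile:
            state.move_aggregate()
        state.move_free_receptors()
        state.unbind()
        state.bind()
        if (
            config.check_invariants_every
            and step % config.check_invariants_every == 0
        ):
            state.check_invariants()
        if step % config.record_every == 0 or step == config.steps:
            edge_counts.append(state.n_bound)
            record_times.append(step * config.dt)
    edges = np.asarray(edge_counts)
    tail = edges[-max(1, len(edges) // 4) :]
    if tail.max() - tail.min() > 1:
        warnings.warn(
            "bond count still drifting in the final quarter of the run; "
            "consider more steps for a steady state",
            stacklevel=2,
        )
    return MCRunResult(
        final_size=int(edges[-1]),
        edge_counts=edges,
        record_times=np.asarray(record_times),
    )


def run_campaign(config: MCConfig, n_runs: int = 60) -> HistogramSet:
    """Repeated runs with per-run seeds derived from the master seed.

    Each run contributes a one-hot histogram of its final aggregate size;
    the result feeds :func:`stericrules.aggregate.sem_error_bars` (default
    plan: 60 runs binned into 10 sets of 6).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = np.random.SeedSequence(config.seed).spawn(n_runs)
    rows = []
    for child in seeds:
        result = run_mc(config, rng=np.random.default_rng(child))
        rows.append(result.histogram())
    return HistogramSet(runs=np.asarray(rows))
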