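"""Metropolis-Hastings rate fitting and the cutoff scan."""

import numpy as np
import pytest

import stericrules.fit as fit_module
from stericrules.aggregate import AggregateSizeDistribution
from stericrules.fit import (
    FitResult,
    OptimizerConfig,
    interval_model,
    metropolis_optimize_kf2,
    paired_breakpoints,
    scan_cutoff,
)


def analytic_model(k_f2):
    """Cheap smooth surrogate: binomial occupancy over the 13 sizes with a
    success probability that saturates in k_f2."""
    from math import comb

    p = k_f2 / (k_f2 + 0.01)
    probs = np.array(
        [comb(12, n) * p**n * (1 - p) ** (12 - n) for n in range(13)]
    )
    return AggregateSizeDistribution(probs / probs.sum())


class TestMetropolis:
    def test_equal_sigma_proposals_always_accepted(self):
        # A constant model makes every delta-sigma zero: the third case of
        # the acceptance rule applies with probability one.
        target = analytic_model(0.005)
        result = metropolis_optimize_kf2(
            lambda k: target,
            target,
            OptimizerConfig(max_iterations=50, no_improve_limit=1000, seed=0),
        )
        assert all(step.accepted for step in result.trace)
        assert result.sigma == 0.0

    def test_cold_temperature_rejects_every_worse_proposal(self):
        target = analytic_model(0.005)
        result = metropolis_optimize_kf2(
            analytic_model,
            target,
            OptimizerConfig(
                temperature=1e-300, max_iterations=300,
                no_improve_limit=300, seed=1,
            ),
        )
        sigma_cur = result.trace[0].sigma
        for step in result.trace[1:]:
            if step.accepted:
                assert step.sigma <= sigma_cur
                sigma_cur = step.sigma

    def test_best_sigma_is_non_increasing_and_trace_reproducible(self):
        target = analytic_model(0.004)
        config = OptimizerConfig(max_iterations=150, seed=7)
        first = metropolis_optimize_kf2(analytic_model, target, config)
        second = metropolis_optimize_kf2(analytic_model, target, config)
        assert first.trace == second.trace
        best = np.array([step.best_sigma for step in first.trace])
        assert np.all(np.diff(best) <= 0)
        other = metropolis_optimize_kf2(
            analytic_model, target, OptimizerConfig(max_iterations=150, seed=8)
        )
        assert other.trace != first.trace

    def test_recovers_generating_rate_on_surrogate(self):
        target = analytic_model(0.005)
        result = metropolis_optimize_kf2(
            analytic_model,
            target,
            OptimizerConfig(
                temperature=1e-8, k_f2_init=0.0, sigma_stop=1e-9,
                max_iterations=1000, no_improve_limit=400, seed=2,
            ),
        )
        assert abs(result.k_f2 - 0.005) <= 5e-4
        assert result.sigma < 1e-6

    def test_evaluations_are_memoized_on_the_step_grid(self):
        calls = []

        def counting_model(k):
            calls.append(k)
            return analytic_model(k)

        target = analytic_model(0.005)
        result = metropolis_optimize_kf2(
            counting_model,
            target,
            OptimizerConfig(max_iterations=200, seed=3),
        )
        assert len(calls) == result.n_evaluations == len(set(calls))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(temperature=0.0),
            dict(step_small=1e-4, step_large=1e-5),
            dict(k_f2_min=0.5, k_f2_max=0.4),
            dict(k_f2_init=0.9),
            dict(max_iterations=0),
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OptimizerConfig(**kwargs)


RECOVERY_OPT = OptimizerConfig(
    temperature=1e-8, k_f2_init=0.0, sigma_stop=1e-7,
    max_iterations=300, no_improve_limit=60, seed=0,
)


class TestScan:
    def test_single_threshold_geometry_runs_two_optimizations(
        self, single_threshold_geometry
    ):
        target = interval_model(
            [single_threshold_geometry.build_adjacency(3.0)]
        )(0.005)
        result = scan_cutoff(
            single_threshold_geometry,
            target,
            grid=(3.0, 20.0, 0.1),
            opt=OptimizerConfig(
                max_iterations=5, no_improve_limit=5, seed=0
            ),
        )
        assert len(result.interval_results) == 2
        assert [iv for iv, _, _ in result.interval_results] == [
            (3.0, 4.9),
            (5.0, 20.0),
        ]

    def test_recovery_of_cutoff_interval_and_rate(
        self, single_threshold_geometry
    ):
        # Target built above the 5.0 nm threshold: the full 15-edge
        # adjacency with k_f2 = 0.005 should win with near-zero sigma.
        adjacency = single_threshold_geometry.build_adjacency(6.0)
        target = interval_model([adjacency])(0.005)
        result = scan_cutoff(
            single_threshold_geometry, target,
            grid=(3.0, 20.0, 0.1), opt=RECOVERY_OPT,
        )
        assert result.d_c_interval == (5.0, 20.0)
        assert abs(result.k_f2 - 0.005) <= 5e-4
        assert result.sigma < 1e-6

    def test_sigma_ties_resolve_to_the_smallest_cutoff_interval(
        self, single_threshold_geometry, monkeypatch
    ):
        def stub_optimize(model, target, config):
            return FitResult(
                k_f2=0.01, sigma=0.5, d_c_interval=None, trace=[],
                n_evaluations=1, seed=config.seed,
            )

        monkeypatch.setattr(
            fit_module, "metropolis_optimize_kf2", stub_optimize
        )
        target = AggregateSizeDistribution(np.eye(13)[0])
        result = scan_cutoff(single_threshold_geometry, target)
        assert result.d_c_interval == (3.0, 4.9)

    def test_per_point_mode_agrees_on_winning_interval(
        self, single_threshold_geometry
    ):
        adjacency = single_threshold_geometry.build_adjacency(6.0)
        target = interval_model([adjacency])(0.005)
        opt = OptimizerConfig(
            temperature=1e-8, k_f2_init=0.0, sigma_stop=1e-7,
            max_iterations=60, no_improve_limit=30, seed=4,
        )
        literal = scan_cutoff(
            single_threshold_geometry, target, grid=(4.7, 5.3, 0.2),
            opt=opt, per_point=True,
        )
        grouped = scan_cutoff(
            single_threshold_geometry, target, grid=(4.7, 5.3, 0.2), opt=opt
        )
        assert literal.d_c_interval == grouped.d_c_interval == (5.1, 5.3)
        assert len(literal.interval_results) == len(grouped.interval_results)

    def test_search_range_must_stay_below_kf1(self, single_threshold_geometry):
        target = AggregateSizeDistribution(np.eye(13)[0])
        with pytest.raises(ValueError, match="k_f1"):
            scan_cutoff(
                single_threshold_geometry, target,
                opt=OptimizerConfig(k_f2_max=1.5),
            )


def test_paired_breakpoints_merge_thresholds_of_both_strands(native_geometry):
    intervals = paired_breakpoints(native_geometry, 5.0, 6.0, 0.1)
    boundaries = [iv[0] for iv, _ in intervals]
    # strand I gains C-D at 5.5 and strand II at 5.6: both are breakpoints
    assert 5.5 in boundaries and 5.6 in boundaries
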