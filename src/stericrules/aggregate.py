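"""Whole-antigen aggregate-size distributions and histogram scoring.

The two strands of the antigen bind independently, so the probability of a
whole-antigen aggregate of size ``n`` (total bound receptors, 0..12) is the
discrete convolution of the per-strand distributions over 0..6:

    P(n) = sum_m P_I(m) * P_II(n - m)

with the summation limits restricted to the strand supports.  Model/target
histograms are compared by the residual sum of squares normalized by the
number of possible aggregate sizes (N = 13):

    sigma = sum_i (P_target_i - P_model_i)**2 / 13

Note that for two probability vectors the largest attainable value of this
statistic is 2/13 (disjoint point masses), not 1.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

__all__ = [
    "N_SIZES",
    "AggregateSizeDistribution",
    "HistogramSet",
    "combine_strands",
    "normalized_sigma",
    "sem_error_bars",
    "mean_size",
]

#: Possible whole-antigen aggregate sizes: 0..12 receptors, 13 bins.
N_SIZES = 13

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class AggregateSizeDistribution:
    """Probability vector over whole-antigen aggregate sizes 0..12."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (N_SIZES,):
            raise ValueError(
                f"expected {N_SIZES} aggregate-size bins (sizes 0..12), got "
                f"shape {p.shape}"
            )
        if np.any(p < -_NORM_TOL):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"probabilities must sum to 1, got {p.sum():.9f}"
            )

    @property
    def n_sizes(self) -> int:
        return N_SIZES

    def mean(self) -> float:
        return float(np.dot(np.arange(N_SIZES), self.probabilities))

    def __eq__(self, other) -> bool:  # dataclass default breaks on arrays
        if not isinstance(other, AggregateSizeDistribution):
            return NotImplemented
        return bool(np.array_equal(self.probabilities, other.probabilities))


def _as_vector(dist, length: int | None = None) -> np.ndarray:
    if isinstance(dist, AggregateSizeDistribution):
        return dist.probabilities
    p = np.asarray(dist, dtype=float)
    if length is not None and p.shape != (length,):
        raise ValueError(f"expected length-{length} vector, got {p.shape}")
    return p


def combine_strands(p_I, p_II) -> AggregateSizeDistribution:
    """Convolve two per-strand size distributions (supports 0..6) into the
    13-bin whole-antigen distribution.

    Inputs must be normalized (error beyond 1e-9 tolerance); the output is
    renormalized to absorb floating-point drift.
    """
    a = _as_vector(p_I, 7)
    b = _as_vector(p_II, 7)
    for name, v in (("p_I", a), ("p_II", b)):
        if np.any(v < -_NORM_TOL):
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > _NORM_TOL:
            raise ValueError(
                f"{name} is not normalized: sum = {v.sum():.12f}"
            )
    full = np.convolve(a, b)  # length 13, exactly the two-limit summation
    return AggregateSizeDistribution(full / full.sum())


def normalized_sigma(p_target, p_model) -> float:
    """Residual sum of squares between two 13-bin histograms, divided by 13.

    Zero iff the histograms are identical; symmetric in its arguments.
    """
    a = _as_vector(p_target)
    b = _as_vector(p_model)
    if a.shape != b.shape:
        raise ValueError(
            f"histogram length mismatch: {a.shape} vs {b.shape}"
        )
    if a.shape != (N_SIZES,):
        raise ValueError(
            f"expected {N_SIZES}-bin histograms, got length {a.shape[0]}"
        )
    return float(np.sum((a - b) ** 2) / N_SIZES)


@dataclass(frozen=True)
class HistogramSet:
    """Per-run aggregate-size histograms from repeated simulations.

    ``runs`` has shape (run_count, 13); each row is one run's size histogram
    (probabilities or one-hot final sizes).  The default bin plan for error
    bars splits 60 runs into 10 sets of 6.
    """

    runs: np.ndarray
    bin_plan: tuple[int, int] = (10, 6)

    def __post_init__(self) -> None:
        runs = np.atleast_2d(np.asarray(self.runs, dtype=float))
        if runs.shape[1] != N_SIZES:
            raise ValueError(
                f"each run histogram needs {N_SIZES} bins, got "
                f"{runs.shape[1]}"
            )
        object.__setattr__(self, "runs", runs)

    @property
    def run_count(self) -> int:
        return int(self.runs.shape[0])

    def to_distribution(self) -> AggregateSizeDistribution:
        """Pooled distribution: mean of the per-run histograms, normalized."""
        mean = self.runs.mean(axis=0)
        total = mean.sum()
        if total <= 0:
            raise ValueError("histogram set is empty")
        return AggregateSizeDistribution(mean / total)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HistogramSet):
            return NotImplemented
        return (
            np.array_equal(self.runs, other.runs)
            and self.bin_plan == other.bin_plan
        )


def sem_error_bars(
    runs: HistogramSet, n_bins: int | None = None
) -> pd.DataFrame:
    """Mean and standard error per aggregate size by run binning.

    The runs are split into ``n_bins`` consecutive sets of equal size; the
    per-size mean is the mean of the bin means and the SEM is their standard
    deviation (ddof=1) divided by sqrt(n_bins).  The run count must be
    divisible by ``n_bins``.
    """
    if n_bins is None:
        n_bins = runs.bin_plan[0]
    n_runs = runs.run_count
    if n_bins < 2:
        raise ValueError("need at least 2 bins for a standard error")
    if n_runs % n_bins != 0:
        divisors = [d for d in range(2, n_runs + 1) if n_runs % d == 0]
        raise ValueError(
            f"{n_runs} runs cannot be split into {n_bins} equal bins; "
            f"valid bin counts: {divisors}"
        )
    per_bin = n_runs // n_bins
    bin_means = runs.runs.reshape(n_bins, per_bin, N_SIZES).mean(axis=1)
    mean = bin_means.mean(axis=0)
    sem = bin_means.std(axis=0, ddof=1) / np.sqrt(n_bins)
    return pd.DataFrame(
        {"size": np.arange(N_SIZES), "mean": mean, "sem": sem}
    )


def mean_size(dist) -> float:
    """Expected aggregate size of a 13-bin distribution."""
    p = _as_vector(dist, N_SIZES)
    return float(np.dot(np.arange(N_SIZES), p))
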