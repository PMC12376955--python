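"""Simulation-based significance for neutrality statistics.

The observed statistic is ranked against R (default 1000) constant-size
neutral coalescent simulations matched to the data, and a deviation is
called significant when the observation falls among the ``floor(0.05 R)``
(or ``floor(0.10 R)``) most extreme simulated values in the matching tail —
the ms-style rank rule.  Both tails are always computed; ties count as
as-extreme (the conservative choice), and no two-tailed correction is
applied (the rule is per-tail).

Matching modes: ``fixed_S`` conditions every replicate on the observed
number of segregating sites (the default; removes dependence on theta
estimation error), ``theta_W`` simulates with theta set to Watterson's
estimate so S varies.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import coalsim, sumstats

__all__ = ["NullDistribution", "build_null", "empirical_p", "STATISTICS"]


def _stat_tajima(counts: np.ndarray, n: int) -> np.ndarray:
    return sumstats.tajimas_d_from_classes(counts, n)


def _stat_dstar(counts: np.ndarray, n: int) -> np.ndarray:
    return sumstats.fu_li_from_classes(counts, n)[0]


def _stat_fstar(counts: np.ndarray, n: int) -> np.ndarray:
    return sumstats.fu_li_from_classes(counts, n)[1]


STATISTICS = {
    "tajima_d": _stat_tajima,
    "fu_li_dstar": _stat_dstar,
    "fu_li_fstar": _stat_fstar,
}


@dataclasses.dataclass
class NullDistribution:
    """R simulated values of one neutrality statistic under the null."""

    statistic: str
    R: int
    values: np.ndarray
    mode: str
    n: int
    observed_S: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def build_null(
    n: int,
    observed_S: int,
    statistic: str = "tajima_d",
    mode: str = "fixed_S",
    R: int = 1000,
    seed: int | None = None,
) -> NullDistribution:
    """Simulate the neutral null distribution of a neutrality statistic.

    ``n`` is the number of sampled alleles.  Replicates with S = 0 (possible
    only in theta mode) yield NaN and are ignored by the rank machinery.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if observed_S < 1:
        raise ValueError("test undefined for observed_S = 0")
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if mode not in ("fixed_S", "theta_W"):
        raise ValueError("mode must be 'fixed_S' or 'theta_W'")
    rng = np.random.default_rng(seed)
    lengths = coalsim.batch_class_lengths(n, R, rng)
    if mode == "fixed_S":
        counts = coalsim.sample_site_classes(lengths, rng, fixed_s=observed_S)
    else:
        theta = sumstats.watterson_theta(observed_S, n)
        counts = coalsim.sample_site_classes(lengths, rng, theta=theta)
    values = STATISTICS[statistic](counts, n)
    return NullDistribution(statistic, R, values, mode, n, observed_S)


def empirical_p(observed: float, null: NullDistribution) -> dict:
    """Rank-based empirical p-values and significance flags.

    ``lower_rank`` counts null values <= observed, ``upper_rank`` counts
    >= observed (ties as-extreme).  Flags use the tail matching the sign of
    the deviation implicitly through the min rank: ``p<0.05`` when the more
    extreme rank is at most ``floor(0.05 R)`` and ``p<0.1`` at
    ``floor(0.10 R)`` (50 and 100 of 1000 at the default R).
    """
    vals = null.values[np.isfinite(null.values)]
    lower = int((vals <= observed).sum())
    upper = int((vals >= observed).sum())
    r = null.R
    k05 = math.floor(0.05 * r)
    k10 = math.floor(0.10 * r)
    min_rank = min(lower, upper)
    return {
        "statistic": null.statistic,
        "observed": observed,
        "R": r,
        "lower_rank": lower,
        "upper_rank": upper,
        "p_lower": lower / r,
        "p_upper": upper / r,
        "significant_05": min_rank <= k05,
        "significant_10": min_rank <= k10,
        "tail": "lower" if lower <= upper else "upper",
        "mode": null.mode,
    }
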