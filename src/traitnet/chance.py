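"""Monte-Carlo chance null for criterion-based maze learning.

A subject choosing randomly between the two maze arms produces daily correct
counts distributed Binomial(6, 1/2). The null asks how often such random
choosers would reach the learning criterion (>= 10 correct of 12 over any two
consecutive days) within the observed day horizon. The simulation draws
replicate cohorts of random choosers and records, per replicate, the
percentage of subjects reaching criterion; an exact dynamic-programming
oracle computes the same per-subject probability in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats

from .scoring import days_to_criterion  # shared criterion rule

__all__ = [
    "NullDistribution",
    "simulate_chance_experiment",
    "pvalue_observed",
    "exact_criterion_probability",
    "criterion_chi_square",
]


@dataclass
class NullDistribution:
    """Replicate-level null distribution of criterion-reaching percentages."""

    replicate_percentages: np.ndarray
    n_subjects: int
    n_days: int
    trials_per_day: int
    n_replicates: int
    seed: int

    @property
    def mean_percentage(self) -> float:
        return float(np.mean(self.replicate_percentages))

    @property
    def sd_percentage(self) -> float:
        return float(np.std(self.replicate_percentages, ddof=1))

    def summary(self) -> dict:
        return {
            "mean_percentage": self.mean_percentage,
            "sd_percentage": self.sd_percentage,
            "n_subjects": self.n_subjects,
            "n_days": self.n_days,
            "trials_per_day": self.trials_per_day,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
        }


def simulate_chance_experiment(
    n_subjects: int,
    n_days: int,
    trials_per_day: int = 6,
    n_replicates: int = 10_000,
    seed: int = 0,
    threshold: int = 10,
) -> NullDistribution:
    """Simulate replicate cohorts of random choosers against the criterion.

    Each replicate draws ``n_subjects x n_days`` daily correct counts from
    Binomial(trials_per_day, 1/2); a subject succeeds if any two consecutive
    days sum to at least ``threshold`` correct choices. Returns the
    replicate-level percentages of successful subjects.
    """
    if n_subjects < 1 or n_replicates < 1 or trials_per_day < 1 or n_days < 1:
        raise ValueError("all counts must be positive")
    rng = np.random.default_rng(seed)
    if n_days < 2:
        warnings.warn(
            "criterion spans two consecutive days; with n_days < 2 no "
            "simulated subject can reach it",
            stacklevel=2,
        )
        pct = np.zeros(n_replicates)
    else:
        counts = rng.binomial(
            trials_per_day, 0.5, size=(n_replicates, n_subjects, n_days)
        )
        window = counts[..., :-1] + counts[..., 1:]
        success = (window >= threshold).any(axis=-1)
        pct = success.mean(axis=1) * 100.0
    return NullDistribution(
        replicate_percentages=pct,
        n_subjects=n_subjects,
        n_days=n_days,
        trials_per_day=trials_per_day,
        n_replicates=n_replicates,
        seed=seed,
    )


def pvalue_observed(null: NullDistribution, observed_successes: int) -> float:
    """Monte-Carlo p-value for an observed number of criterion-reachers.

    Uses the add-one convention (1 + #{replicates >= observed}) /
    (n_replicates + 1), which never returns exactly zero from a finite run;
    when no replicate reaches the observed count the result is the bound
    1 / (n_replicates + 1).
    """
    if not (0 <= observed_successes <= null.n_subjects):
        raise ValueError(
            f"observed_successes must lie in [0, {null.n_subjects}]"
        )
    successes = np.round(
        null.replicate_percentages * null.n_subjects / 100.0
    ).astype(int)
    k = int(np.sum(successes >= observed_successes))
    return (1 + k) / (null.n_replicates + 1)


def exact_criterion_probability(
    n_days: int, trials_per_day: int = 6, threshold: int = 10
) -> float:
    """Exact P(random chooser reaches the two-day criterion within n_days).

    Dynamic programming over the previous day's correct count: the state
    after day d is the day-d count among subjects not yet at criterion;
    each day marginalizes a Binomial(trials_per_day, 1/2) draw. Computed in
    exact rational arithmetic and returned as a float.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if n_days < 2:
        return 0.0
    denom = 2**trials_per_day
    pmf = [Fraction(comb(trials_per_day, k), denom)
           for k in range(trials_per_day + 1)]
    alive = list(pmf)  # state distribution after day 1
    success = Fraction(0)
    for _ in range(2, n_days + 1):
        new = [Fraction(0)] * (trials_per_day + 1)
        for prev, mass in enumerate(alive):
            if mass == 0:
                continue
            for k, q in enumerate(pmf):
                if prev + k >= threshold:
                    success += mass * q
                else:
                    new[k] += mass * q
        alive = new
    return float(success)


def criterion_chi_square(correct: int, incorrect: int) -> tuple[float, float]:
    """Pearson goodness-of-fit of correct/incorrect counts vs equal split.

    One degree of freedom, no continuity correction — the test used to show
    that the criterion performance departs from random arm choice.
    """
    if correct < 0 or incorrect < 0:
        raise ValueError("counts must be non-negative")
    if correct + incorrect == 0:
        raise ValueError("at least one observation required")
    res = stats.chisquare([correct, incorrect])
    return float(res.statistic), float(res.pvalue)
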