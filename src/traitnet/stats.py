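"""Univariate and repeated-measures statistics for the trait pipeline.

Wraps the standard tests (one-sample and paired t, Brown-Forsythe Levene,
exact binomial with Clopper-Pearson interval, Spearman rank correlation)
and implements the two model-based procedures:

* repeatability (intraclass correlation) of repeated trials under a one-way
  random-intercept model, with a parametric-bootstrap confidence interval
  and a likelihood-ratio test of the between-subject variance;
* the grouped-binomial learning-curve fit — daily error counts regressed on
  testing day with a per-subject random intercept, maximized by
  Gauss-Hermite quadrature.

Missing values are dropped pairwise; imputation belongs to the network
stage only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "RepeatabilityResult",
    "LearningCurveFit",
    "one_sample_t",
    "paired_t",
    "variance_homogeneity",
    "spearman",
    "exact_binomial",
    "repeatability",
    "learning_curve_fit",
    "univariate_report",
]


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def one_sample_t(values: Sequence[float], mu0: float) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of the mean against ``mu0``.

    Returns (t, df, p). A zero-variance sample gives t = 0 (p = 1) when the
    common value equals mu0 and a signed infinite t (p = 0) otherwise.
    """
    x = _clean(values)
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    df = x.size - 1
    if np.ptp(x) == 0:
        if x[0] == mu0:
            return 0.0, df, 1.0
        return float(np.sign(x[0] - mu0) * np.inf), df, 0.0
    res = stats.ttest_1samp(x, mu0)
    return float(res.statistic), df, float(res.pvalue)


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided paired-samples t-test; incomplete pairs are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("need at least 2 complete pairs")
    return one_sample_t(x[ok] - y[ok], 0.0)


def variance_homogeneity(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Levene's test in the Brown-Forsythe (median-centered) form."""
    x, y = _clean(x), _clean(y)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per group")
    res = stats.levene(x, y, center="median")
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties, p by t-approximation.

    Pairs with a missing member are dropped; constant input leaves the
    correlation undefined -> (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("spearman undefined for constant input", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def exact_binomial(
    successes: int,
    trials: int,
    p0: float = 0.5,
    alternative: str = "two-sided",
    ci_level: float = 0.95,
) -> tuple[float, float, float]:
    """Exact binomial test with a Clopper-Pearson interval.

    Returns (p, ci_low, ci_high). ``alternative="greater"`` is the one-sided
    form used for first-day memory performance above chance.
    """
    if not (0 <= successes <= trials):
        raise ValueError("successes must lie in [0, trials]")
    res = stats.binomtest(successes, trials, p0, alternative=alternative)
    ci = res.proportion_ci(confidence_level=ci_level, method="exact")
    return float(res.pvalue), float(ci.low), float(ci.high)


# --------------------------------------------------------------------------
# repeatability (one-way random-intercept intraclass correlation)
# --------------------------------------------------------------------------

@dataclass
class RepeatabilityResult:
    """Intraclass-correlation repeatability with bootstrap uncertainty."""

    R: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    var_between: float
    var_within: float


def _anova_components(values: np.ndarray, codes: np.ndarray, n_groups: int):
    """ANOVA variance components (Searle's n0 for unbalanced designs)."""
    N = values.size
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    means = sums / counts
    grand = values.mean()
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((values - means[codes]) ** 2))
    msb = ssb / (n_groups - 1)
    msw = ssw / (N - n_groups)
    n0 = (N - np.sum(counts**2) / N) / (n_groups - 1)
    var_between = max(0.0, (msb - msw) / n0)
    return var_between, msw, means, counts


def _icc_from_components(vb: float, vw: float) -> float:
    tot = vb + vw
    return 0.0 if tot == 0 else float(np.clip(vb / tot, 0.0, 1.0))


def _ml_loglik(sa2, se2, values, codes, n_groups):
    """Gaussian ML log-likelihood of the one-way random-intercept model."""
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    means = sums / counts
    ssw_i = np.bincount(codes, weights=values**2, minlength=n_groups) - counts * means**2
    lam = se2 + counts * sa2
    mu = float(np.sum(counts * means / lam) / np.sum(counts / lam))
    ll = -0.5 * (
        values.size * np.log(2 * np.pi)
        + np.sum((counts - 1) * np.log(se2))
        + np.sum(np.log(lam))
        + np.sum(ssw_i) / se2
        + np.sum(counts * (means - mu) ** 2 / lam)
    )
    return float(ll)


def repeatability(
    values: Sequence[float],
    subjects: Sequence,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    ci_level: float = 0.95,
) -> RepeatabilityResult:
    """Repeatability R = sigma2_subject / (sigma2_subject + sigma2_residual).

    The point estimate uses the one-way ANOVA variance components; the
    confidence interval is a percentile parametric bootstrap (Gaussian
    simulation from the fitted components with the observed group sizes,
    refit per draw); the p-value is a likelihood-ratio test of the
    between-subject variance against the 0.5*chi2(0) + 0.5*chi2(1) mixture.
    """
    values = np.asarray(values, dtype=float)
    subjects = np.asarray(subjects)
    ok = ~np.isnan(values)
    values, subjects = values[ok], subjects[ok]
    uniq, codes = np.unique(subjects, return_inverse=True)
    n_groups = uniq.size
    counts = np.bincount(codes, minlength=n_groups)
    if n_groups < 2 or np.max(counts) < 2:
        raise ValueError("need >= 2 subjects and repeated trials")

    vb, vw, means, cts = _anova_components(values, codes, n_groups)
    R = _icc_from_components(vb, vw)

    # likelihood-ratio test of sigma2_subject = 0
    def nll(params):
        sa2, se2 = np.exp(np.clip(params, -60.0, 60.0))
        return -_ml_loglik(sa2, max(se2, 1e-26), values, codes, n_groups)

    start = np.log([max(vb, 1e-8), max(vw, 1e-8)])
    fit = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10})
    ll1 = -fit.fun
    resid = values - values.mean()
    se2_null = max(float(np.mean(resid**2)), 1e-12)
    ll0 = -0.5 * values.size * (np.log(2 * np.pi * se2_null) + 1)
    lr = max(0.0, 2 * (ll1 - ll0))
    p = 0.5 * float(stats.chi2.sf(lr, 1)) + (0.5 if lr <= 1e-10 else 0.0)

    # vectorized parametric bootstrap with the observed group sizes
    rng = np.random.default_rng(seed)
    mu = float(values.mean())
    a = rng.normal(0.0, np.sqrt(vb), (n_boot, n_groups))
    e = rng.normal(0.0, np.sqrt(vw), (n_boot, values.size))
    yb = mu + a[:, codes] + e
    gsum = np.zeros((n_boot, n_groups))
    np.add.at(gsum.T, codes, yb.T)  # accumulate per group across boots
    gmean = gsum / cts
    grand = yb.mean(axis=1, keepdims=True)
    ssb = np.sum(cts * (gmean - grand) ** 2, axis=1)
    ssw = np.sum((yb - gmean[:, codes]) ** 2, axis=1)
    msb = ssb / (n_groups - 1)
    msw = ssw / (values.size - n_groups)
    n0 = (values.size - np.sum(cts**2) / values.size) / (n_groups - 1)
    vb_b = np.maximum(0.0, (msb - msw) / n0)
    r_b = np.where(vb_b + msw > 0, vb_b / (vb_b + msw), 0.0)
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(r_b, [alpha, 1 - alpha])
    return RepeatabilityResult(
        R=R, ci_low=float(lo), ci_high=float(hi), p=p, n_boot=n_boot,
        var_between=vb, var_within=vw,
    )


# --------------------------------------------------------------------------
# grouped-binomial learning curve (random-intercept logistic regression)
# --------------------------------------------------------------------------

@dataclass
class LearningCurveFit:
    """Day effect on the log-odds of committing an error in the maze."""

    slope: float
    intercept: float
    subject_sd: float
    chi_square: float
    p: float
    separation: bool
    converged: bool


def _glmm_nll(day, errors, trials, starts, log_w, nodes, slope_free):
    gl = special.gammaln
    const = gl(trials + 1) - gl(errors + 1) - gl(trials - errors + 1)

    def nll(params):
        if slope_free:
            b0, b1, log_sig = params
        else:
            b0, log_sig = params
            b1 = 0.0
        sig = np.exp(log_sig)
        eta = b0 + b1 * day[:, None] + np.sqrt(2.0) * sig * nodes[None, :]
        lp = (const[:, None] + errors[:, None] * eta
              - trials[:, None] * np.logaddexp(0.0, eta))
        per_subj = np.add.reduceat(lp, starts, axis=0)
        return -float(np.sum(special.logsumexp(per_subj + log_w[None, :], axis=1)))

    return nll


def learning_curve_fit(
    daily_correct: Mapping,
    trials_per_day: int = 6,
    n_quad: int = 25,
) -> LearningCurveFit:
    """Fit the grouped-binomial GLMM of daily errors on testing day.

    ``daily_correct`` maps subject -> sequence of daily correct counts.
    Errors per day are Binomial(trials_per_day, p) with
    logit(p) = intercept + slope*day + u_subject, u ~ N(0, sd^2). The
    marginal likelihood integrates the random intercept with Gauss-Hermite
    quadrature; the day effect is tested by likelihood ratio (1 df).

    Degenerate all-correct or all-error data is flagged as separation and
    returned without estimates.
    """
    subj_idx, day, correct = [], [], []
    for i, (_, seq) in enumerate(sorted(daily_correct.items(), key=lambda kv: str(kv[0]))):
        for d, c in enumerate(seq, start=1):
            subj_idx.append(i)
            day.append(d)
            correct.append(c)
    if len(set(subj_idx)) < 2 or max(day) < 2:
        raise ValueError("need >= 2 days for >= 2 subjects")
    subj_idx = np.asarray(subj_idx)
    day = np.asarray(day, dtype=float)
    correct = np.asarray(correct, dtype=float)
    if np.any(correct < 0) or np.any(correct > trials_per_day):
        raise ValueError(f"daily correct counts must lie in [0, {trials_per_day}]")
    errors = trials_per_day - correct
    trials = np.full_like(errors, trials_per_day)

    if errors.sum() == 0 or errors.sum() == trials.sum():
        warnings.warn("complete separation: all-correct or all-error data",
                      stacklevel=2)
        return LearningCurveFit(
            slope=float("nan"), intercept=float("nan"), subject_sd=float("nan"),
            chi_square=float("nan"), p=float("nan"),
            separation=True, converged=False,
        )

    # rows are already grouped by subject (sorted insertion order)
    starts = np.flatnonzero(np.r_[1, np.diff(subj_idx)])
    x, w = special.roots_hermite(n_quad)
    log_w = np.log(w) - 0.5 * np.log(np.pi)

    p_bar = errors.sum() / trials.sum()
    b0_start = float(special.logit(p_bar))
    full = optimize.minimize(
        _glmm_nll(day, errors, trials, starts, log_w, x, True),
        np.array([b0_start, 0.0, np.log(0.5)]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    null = optimize.minimize(
        _glmm_nll(day, errors, trials, starts, log_w, x, False),
        np.array([b0_start, np.log(0.5)]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    chi2 = max(0.0, 2 * (null.fun - full.fun))
    p = float(stats.chi2.sf(chi2, 1))
    b0, b1, log_sig = full.x
    return LearningCurveFit(
        slope=float(b1), intercept=float(b0),
        subject_sd=float(np.exp(log_sig)),
        chi_square=float(chi2), p=p,
        separation=False, converged=bool(full.success and null.success),
    )


# --------------------------------------------------------------------------
# batch driver
# --------------------------------------------------------------------------

def univariate_report(cohort, trait_table) -> "pd.DataFrame":
    """Tidy table of the standard univariate tests for one cohort.

    One row per (test, trait): one-sample t-tests of scores against their
    chance expectations, paired t-tests plus Levene companions between the
    two trials of the repeated assays, and trial repeatability.
    """
    import pandas as pd

    from .scoring import chance_level, lateralization_indices, zone_percentage

    rows = []

    chance = {
        "thigmotaxis": chance_level("open_field"),
        "scototaxis": chance_level("scototaxis"),
        "sociability": chance_level("sociability"),
        "motor_lat_rel": 0.0,
        "visual_lat_rel": 0.0,
        "flexibility": 0.0,
        "memory": 0.0,
    }
    for trait, mu0 in chance.items():
        vals = trait_table[trait].to_numpy()
        if np.sum(~np.isnan(vals)) >= 2:
            t, df, p = one_sample_t(vals, mu0)
            rows.append(("one_sample_t", trait, t, df, p, mu0))

    def trial_scores(df, score):
        per = {}
        for trial, grp in df.groupby("trial"):
            per[trial] = grp.set_index("subject").apply(score, axis=1)
        return per

    paired_specs = {
        "thigmotaxis": (cohort.open_field,
                        lambda r: zone_percentage(r.time_outer_s, r.time_total_s)),
        "activity": (cohort.open_field, lambda r: r.distance_cm),
        "scototaxis": (cohort.scototaxis,
                       lambda r: zone_percentage(r.time_dark_s, r.time_total_s)),
        "sociability": (cohort.sociability,
                        lambda r: zone_percentage(
                            r.time_near_mirror_s, r.time_total_s - r.time_center_s)),
    }
    for test in ("motor", "visual"):
        sub = cohort.lateralization[cohort.lateralization.test == test]
        paired_specs[f"{test}_lat_rel"] = (
            sub, lambda r: lateralization_indices(r.time_cw_s, r.time_ccw_s)[0])
        paired_specs[f"{test}_lat_abs"] = (
            sub, lambda r: lateralization_indices(r.time_cw_s, r.time_ccw_s)[1])

    for trait, (df, score) in paired_specs.items():
        per = trial_scores(df, score)
        if len(per) < 2:
            continue
        t1, t2 = per[1], per[2]
        common = t1.index.intersection(t2.index)
        if len(common) < 2:
            continue
        t, dfree, p = paired_t(t1[common], t2[common])
        rows.append(("paired_t", trait, t, dfree, p, np.nan))
        w, pw = variance_homogeneity(t1[common], t2[common])
        rows.append(("levene", trait, w, np.nan, pw, np.nan))
        stacked = pd.concat([t1[common], t2[common]])
        rpt = repeatability(stacked.to_numpy(),
                            stacked.index.to_numpy(), n_boot=500, seed=0)
        rows.append(("repeatability", trait, rpt.R, np.nan, rpt.p, np.nan))

    return pd.DataFrame(
        rows, columns=["test", "trait", "statistic", "df", "p", "reference"]
    )
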