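"""Study-level statistics.

Covers the a-priori two-sample power calculation, trapezoidal AUCs, the
percent-gain / fold-change / percent-reduction summary arithmetic, the
simulated-subject non-inferiority analysis of oral glucose absorption, and
rank-based group comparisons (delegated to scipy).

The non-inferiority procedure mirrors a design where only group-mean
absorption is available: ``n`` subject-level values per group are simulated
as mean * exp(eps) with eps ~ Normal(0, sigma^2) on the log scale and
sigma = sqrt(ln(1 + cv^2)), so the multiplicative coefficient of variation
equals ``cv`` exactly.  Each treatment is compared to the comparator on the
log scale (Welch t intervals); one-sided 95% lower confidence bounds on the
treatment/comparator ratio are Holm-adjusted across the simultaneous
tests, and a treatment is non-inferior when its adjusted lower bound
reaches the margin (default ratio >= 0.80).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PowerSpec",
    "NiResult",
    "sample_size_two_means",
    "auc_trapezoid",
    "percent_change",
    "percent_reduction",
    "fold_change",
    "round_half_up",
    "simulate_noninferiority",
    "replicate_noninferiority",
    "compare_groups",
]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the two-sample normal-approximation sample-size formula."""

    mu1: float
    mu2: float
    sigma: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.mu1 == self.mu2:
            raise ValueError("mu1 == mu2 implies an infinite sample size")


def sample_size_two_means(spec: PowerSpec) -> dict:
    """Per-group n for a two-sample t-test, normal approximation:

        n = 2 sigma^2 (z_{1-alpha/2} + z_{1-beta})^2 / delta^2

    with exact standard-normal quantiles.  Returns the raw (real) n and the
    integer per-group n (ceiling, minimum 2).
    """
    delta = spec.mu2 - spec.mu1
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    n_raw = 2 * spec.sigma**2 * (z_a + z_b) ** 2 / delta**2
    return {"n_raw": float(n_raw), "n_per_group": max(2, math.ceil(n_raw - 1e-12))}


def auc_trapezoid(time, values) -> float:
    """Composite trapezoidal area under ``values`` over ``time``."""
    t = np.asarray(time, float)
    v = np.asarray(values, float)
    if t.size < 2:
        raise ValueError("need at least 2 samples for an AUC")
    if v.shape != t.shape:
        raise ValueError("time and values must match")
    if not np.all(np.diff(t) > 0):
        raise ValueError("time must be strictly increasing")
    return float(np.trapezoid(v, t))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Display rounding with ties away from zero (so 2.5% -> 3%)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def percent_change(initial: float, final: float) -> float:
    """100 * (final - initial) / initial (display: round half-up to int)."""
    if initial <= 0:
        raise ValueError("initial value must be positive")
    return 100.0 * (final - initial) / initial


def percent_reduction(a: float, b: float) -> float:
    """How much lower ``a`` is than the reference ``b``: 100 * (1 - a/b)."""
    if b <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (1.0 - a / b)


def fold_change(a: float, b: float) -> float:
    """Ratio a / b (displayed to 1 decimal place in reports)."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    return a / b


@dataclass(frozen=True)
class NiResult:
    """Non-inferiority outcome for one treatment vs the comparator."""

    treatment: str
    ratio: float
    ci_two_sided: tuple
    one_sided_lower: float
    holm_adjusted_lower: float
    p_one_sided: float
    margin: float
    non_inferior: bool


def _log_ratio_interval(log_t: np.ndarray, log_c: np.ndarray, level: float):
    """Welch t interval for the difference of log means; returns the point
    estimate, SE, df, and the one-sided lower bound at ``level``."""
    nt, nc = log_t.size, log_c.size
    diff = log_t.mean() - log_c.mean()
    vt, vc = log_t.var(ddof=1) / nt, log_c.var(ddof=1) / nc
    se = math.sqrt(vt + vc)
    if se == 0.0:
        return diff, 0.0, float(nt + nc - 2), diff
    df = (vt + vc) ** 2 / (vt**2 / (nt - 1) + vc**2 / (nc - 1))
    lower = diff - stats.t.ppf(level, df) * se
    return diff, se, df, lower


def simulate_noninferiority(group_means: dict, cv: float, n_per_group: int,
                            margin: float = 0.80,
                            alpha_one_sided: float = 0.05,
                            comparator: str = "sham",
                            seed: int | np.random.Generator = 0) -> dict:
    """One realisation of the simulated-subject non-inferiority analysis.

    Parameters
    ----------
    group_means : dict
        Mean endpoint per group (must include ``comparator``); every other
        key is tested against the comparator.
    cv : float
        Multiplicative coefficient of variation of the simulated subjects.
    n_per_group : int
        Simulated subjects per group.
    margin : float
        Non-inferiority threshold on the treatment/comparator ratio.
    alpha_one_sided : float
        Level of the one-sided bounds before Holm adjustment.
    seed : int or Generator
        Source of randomness; fixed seed gives identical output.

    Returns
    -------
    dict mapping treatment name -> :class:`NiResult`.
    """
    if not 0 <= cv < 1:
        raise ValueError("cv must lie in [0, 1)")
    if margin <= 0:
        raise ValueError("margin must be positive")
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    if comparator not in group_means:
        raise ValueError(f"comparator {comparator!r} missing from group_means")
    if any(m <= 0 for m in group_means.values()):
        raise ValueError("group means must be positive")

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sigma = math.sqrt(math.log(1.0 + cv**2))
    log_values = {
        g: math.log(mu) + sigma * rng.standard_normal(n_per_group)
        for g, mu in group_means.items()
    }
    treatments = [g for g in group_means if g != comparator]

    raw = {}
    for g in treatments:
        diff, se, df, lower = _log_ratio_interval(
            log_values[g], log_values[comparator], 1 - alpha_one_sided)
        lo2, hi2 = (diff, diff) if se == 0.0 else (
            diff - stats.t.ppf(0.975, df) * se,
            diff + stats.t.ppf(0.975, df) * se,
        )
        # one-sided p for H0: ratio <= margin vs H1: ratio > margin
        if se == 0.0:
            p = 0.0 if diff > math.log(margin) else 1.0
        else:
            p = float(stats.t.sf((diff - math.log(margin)) / se, df))
        raw[g] = (diff, se, df, lower, (lo2, hi2), p)

    # Holm step-down across the simultaneous one-sided tests: the k-th
    # smallest p is tested at alpha/(m-k+1); the adjusted lower bound uses
    # the same sharpened level, and testing stops at the first failure.
    m = len(treatments)
    order = sorted(treatments, key=lambda g: raw[g][5])
    results = {}
    rejected_so_far = True
    for k, g in enumerate(order):
        diff, se, df, lower, ci2, p = raw[g]
        level = 1 - alpha_one_sided / (m - k) if rejected_so_far else \
            1 - alpha_one_sided / m
        adj_lower = diff if se == 0.0 else diff - stats.t.ppf(level, df) * se
        verdict = math.exp(adj_lower) >= margin if se > 0.0 else \
            math.exp(diff) >= margin
        if not verdict:
            rejected_so_far = False
        results[g] = NiResult(
            treatment=g,
            ratio=math.exp(diff),
            ci_two_sided=(math.exp(ci2[0]), math.exp(ci2[1])),
            one_sided_lower=math.exp(lower),
            holm_adjusted_lower=math.exp(adj_lower),
            p_one_sided=p,
            margin=margin,
            non_inferior=verdict,
        )
    return {g: results[g] for g in treatments}


def replicate_noninferiority(group_means: dict, cv: float, n_per_group: int,
                             margin: float = 0.80, n_reps: int = 1000,
                             comparator: str = "sham",
                             seed: int = 0) -> dict:
    """Average the non-inferiority analysis over seeded replicates.

    Point ratios are averaged on the log scale (geometric mean across
    replicates), matching the log-scale analysis; verdict rates are the
    fraction of replicates declaring non-inferiority.  Returns per
    treatment: ``ratio`` (seed-averaged), ``verdict_rate``,
    ``mean_holm_lower`` (geometric mean of adjusted lower bounds) and the
    majority ``non_inferior`` call.
    """
    rng = np.random.default_rng(seed)
    treatments = [g for g in group_means if g != comparator]
    log_ratios = {g: np.empty(n_reps) for g in treatments}
    log_lowers = {g: np.empty(n_reps) for g in treatments}
    verdicts = {g: np.empty(n_reps, bool) for g in treatments}
    for r in range(n_reps):
        res = simulate_noninferiority(group_means, cv, n_per_group,
                                      margin=margin, comparator=comparator,
                                      seed=rng)
        for g in treatments:
            log_ratios[g][r] = math.log(res[g].ratio)
            log_lowers[g][r] = math.log(max(res[g].holm_adjusted_lower, 1e-300))
            verdicts[g][r] = res[g].non_inferior
    out = {}
    for g in treatments:
        rate = float(verdicts[g].mean())
        out[g] = {
            "ratio": float(np.exp(log_ratios[g].mean())),
            "mean_holm_lower": float(np.exp(log_lowers[g].mean())),
            "verdict_rate": rate,
            "non_inferior": rate >= 0.5,
            "n_reps": n_reps,
        }
    return out


def compare_groups(values_by_group: dict, design: str = "independent") -> dict:
    """Rank-based group comparison (reporting glue).

    ``independent`` runs Kruskal-Wallis across groups with Bonferroni-
    adjusted pairwise Mann-Whitney follow-ups; ``repeated`` runs the
    Friedman test on aligned subjects with Bonferroni-adjusted pairwise
    Wilcoxon signed-rank follow-ups.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(values_by_group[g], float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if design == "independent":
        stat, p = stats.kruskal(*arrays)
        pair_test = lambda a, b: stats.mannwhitneyu(a, b).pvalue
    elif design == "repeated":
        if len({a.size for a in arrays}) != 1:
            raise ValueError("repeated design requires aligned subjects")
        stat, p = stats.friedmanchisquare(*arrays)
        pair_test = lambda a, b: stats.wilcoxon(a, b).pvalue
    else:
        raise ValueError(f"unknown design {design!r}")
    pairs = [(groups[i], groups[j]) for i in range(len(groups))
             for j in range(i + 1, len(groups))]
    mcorr = len(pairs)
    pairwise = {
        f"{a} vs {b}": min(1.0, mcorr * pair_test(values_by_group[a],
                                                  values_by_group[b]))
        for a, b in pairs
    }
    return {"statistic": float(stat), "p_value": float(p),
            "design": design, "pairwise_bonferroni": pairwise}
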