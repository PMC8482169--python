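"""Between-mode comparison battery: normality triage, then multiple comparisons.

Each parameter is first triaged for normality: a parameter is treated as
normally distributed (class "P") only when every group passes both the
Shapiro-Wilk test and the Kolmogorov-Smirnov test at the chosen alpha;
otherwise it is "NP". Because group means and SDs are estimated from the
data, the KS test is run with the Lilliefors correction — the plain KS
test against a fitted normal is anti-conservative at these sample sizes.

"P" parameters get a one-way ANOVA omnibus plus pairwise Welch t tests with
Bonferroni adjustment (p × number of pairs, capped at 1). "NP" parameters
get a tie-corrected Kruskal-Wallis omnibus plus Steel-Dwass all-pairs
comparisons: for each pair of groups the pooled-rank Mann-Whitney statistic
is standardised with the tie-corrected variance and referred to the
studentized range distribution with k groups (the q/√2 convention). An
exact permutation mode is available for very small groups and serves as
the reference implementation in the test suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ComparisonResult",
    "classify_normality",
    "compare_modes_parametric",
    "compare_modes_nonparametric",
    "compare_parameter",
    "steel_dwass",
]


@dataclass
class ComparisonResult:
    parameter: str
    groups: tuple[str, ...]
    means: dict[str, float]
    sds: dict[str, float]
    normality: str  # "P" or "NP"
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]
    method: str  # "bonferroni-anova" or "steel-dwass"


def _as_groups(samples: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in samples.items()}


def classify_normality(samples: dict[str, np.ndarray], alpha: float = 0.05) -> str:
    """"P" iff Shapiro-Wilk and Lilliefors-KS both fail to reject in every group.

    A degenerate (constant) group cannot be tested and is classed "NP".
    """
    for name, x in _as_groups(samples).items():
        if x.size < 3:
            raise ValueError(f"group {name!r} needs at least 3 observations")
        if np.ptp(x) == 0:
            warnings.warn(f"group {name!r} is constant; classing parameter as NP")
            return "NP"
        if stats.shapiro(x).pvalue < alpha:
            return "NP"
        # the Lilliefors table starts at n = 4; Shapiro-Wilk alone decides below that
        if x.size >= 4 and lilliefors(x, dist="norm")[1] < alpha:
            return "NP"
    return "P"


def _summaries(groups: dict[str, np.ndarray]):
    means = {k: float(np.mean(v)) for k, v in groups.items()}
    sds = {k: float(np.std(v, ddof=1)) for k, v in groups.items()}
    return means, sds


def compare_modes_parametric(samples: dict[str, np.ndarray], parameter: str = "") -> ComparisonResult:
    """One-way ANOVA omnibus with Bonferroni-adjusted pairwise t tests."""
    groups = _as_groups(samples)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = tuple(groups)
    omnibus = stats.f_oneway(*groups.values()).pvalue
    pairs = list(itertools.combinations(names, 2))
    pairwise = {}
    for a, b in pairs:
        if np.ptp(groups[a]) == 0 and np.ptp(groups[b]) == 0 and groups[a][0] == groups[b][0]:
            p = 1.0
        else:
            p = stats.ttest_ind(groups[a], groups[b]).pvalue
        pairwise[(a, b)] = min(1.0, float(p) * len(pairs))
    means, sds = _summaries(groups)
    return ComparisonResult(parameter, names, means, sds, "P", float(omnibus), pairwise, "bonferroni-anova")


def steel_dwass(
    x: np.ndarray, y: np.ndarray, k_groups: int, exact: bool = False
) -> tuple[float, float]:
    """Steel-Dwass pairwise statistic and p value for one pair out of k groups.

    Returns (t, p) where t is the standardised Mann-Whitney rank statistic
    on the pooled pair and p refers |t|·√2 to the studentized range
    distribution with ``k_groups`` groups and infinite df. With
    ``exact=True`` the p value is instead the exact permutation tail
    probability of |t| (feasible for small pooled sizes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    t_obs = _sd_statistic(x, y)
    if exact:
        pooled = np.concatenate([x, y])
        n = x.size
        stats_all = [
            _sd_statistic(pooled[list(idx)], np.delete(pooled, list(idx)))
            for idx in itertools.combinations(range(pooled.size), n)
        ]
        p = float(np.mean(np.abs(stats_all) >= abs(t_obs) - 1e-12))
    else:
        p = float(stats.studentized_range.sf(abs(t_obs) * np.sqrt(2.0), k_groups, np.inf))
    return float(t_obs), p


def _sd_statistic(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    expect = n1 * (n + 1) / 2.0
    var = n1 * n2 / (n * (n - 1.0)) * (np.sum(ranks**2) - n * (n + 1.0) ** 2 / 4.0)
    if var <= 0:  # all observations tied
        return 0.0
    return (w - expect) / np.sqrt(var)


def compare_modes_nonparametric(
    samples: dict[str, np.ndarray], parameter: str = "", exact: bool = False
) -> ComparisonResult:
    """Kruskal-Wallis omnibus with Steel-Dwass all-pairs comparisons."""
    groups = _as_groups(samples)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(v.size == 0 for v in groups.values()):
        raise ValueError("all groups must be non-empty")
    names = tuple(groups)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        # no variation anywhere: nothing to detect
        omnibus = 1.0
        pairwise = {pair: 1.0 for pair in itertools.combinations(names, 2)}
    else:
        omnibus = float(stats.kruskal(*groups.values()).pvalue)
        pairwise = {
            (a, b): steel_dwass(groups[a], groups[b], len(groups), exact=exact)[1]
            for a, b in itertools.combinations(names, 2)
        }
    means, sds = _summaries(groups)
    return ComparisonResult(parameter, names, means, sds, "NP", omnibus, pairwise, "steel-dwass")


def compare_parameter(
    samples: dict[str, np.ndarray], parameter: str = "", alpha: float = 0.05
) -> ComparisonResult:
    """Full battery for one parameter: triage, then the matching comparison."""
    if classify_normality(samples, alpha=alpha) == "P":
        return compare_modes_parametric(samples, parameter)
    return compare_modes_nonparametric(samples, parameter)
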