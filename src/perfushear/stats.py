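"""Group summaries and hypothesis tests over normalized viable tumor areas.

Implements the comparisons used for dose-response readouts in perfusion and
static 3D cultures: mean ± SEM summaries, Welch's t and Mann-Whitney U for
two-group comparisons, one-way ANOVA with Dunnett-style many-to-one control
comparisons (adjusted p-values from a seeded Monte-Carlo sample of the
multivariate t distribution of the control contrasts), a rank-based
alternative (Kruskal-Wallis with Dunn's test, Bonferroni-adjusted), fold
changes and percent tumoricidal effect, and a repeated-measures ANOVA over
the minimum-nodule-size cut-off factor (the 500-3000 µm² sensitivity sweep).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsUsageError(ValueError):
    """Inputs violate a statistical operation's contract."""


@dataclass(frozen=True)
class GroupSummary:
    group_id: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    comparison: str = ""
    adjustment: str = "none"

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise StatsUsageError("p-value outside [0, 1]")


def summarize(values, group_id: str = "") -> GroupSummary:
    """Mean and standard error of the mean (sd with n-1 denominator)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise StatsUsageError("cannot summarize an empty group")
    if v.size == 1:
        warnings.warn("SEM undefined for n=1; reporting 0", stacklevel=2)
        return GroupSummary(group_id, 1, float(v[0]), 0.0)
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size))
    return GroupSummary(group_id, int(v.size), float(v.mean()), sem)


def fold_change(numerator_mean: float, denominator_mean: float) -> tuple[float, float]:
    """Ratio of group means: (full precision, rounded to 2 significant figures)."""
    if denominator_mean <= 0:
        raise StatsUsageError("fold change requires a positive denominator")
    ratio = float(numerator_mean) / float(denominator_mean)
    if ratio == 0:
        return 0.0, 0.0
    ndigits = 1 - int(np.floor(np.log10(abs(ratio))))
    return ratio, float(round(ratio, ndigits))


def percent_reduction(normalized_mean: float) -> float:
    """Tumoricidal effect: 100 x (1 - normalized area). Negative = growth."""
    if normalized_mean < 0:
        raise StatsUsageError("normalized area cannot be negative")
    return 100.0 * (1.0 - float(normalized_mean))


def welch_t(a, b) -> TestResult:
    """Two-sided Welch's t test (unequal variances)."""
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size < 2 or b.size < 2:
        raise StatsUsageError("Welch's t requires n >= 2 per group")
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return TestResult("welch_t", 0.0 if p == 1.0 else np.inf, p)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(t), float(p))


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U; exact null distribution for small samples."""
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size < 1 or b.size < 1:
        raise StatsUsageError("Mann-Whitney requires non-empty groups")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) else "asymptotic"
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("mann_whitney", float(u), float(min(p, 1.0)))


# --------------------------------------------------------------------------
# one-way ANOVA with Monte-Carlo Dunnett many-to-one comparisons
# --------------------------------------------------------------------------

class DunnettMC:
    """Seeded Monte-Carlo reference distribution for Dunnett's max-|t|.

    For k treatment groups compared with one control, the vector of contrast
    t statistics follows a k-variate t distribution with correlation
    rho_ij = lambda_i lambda_j, lambda_i = sqrt(n_i / (n_i + n_0)), and the
    pooled-variance degrees of freedom.  The adjusted p-value for contrast i
    is P(max_j |T_j| >= |t_i|), estimated from ``draws`` samples.

    The sample depends only on the group sizes, so it can be reused across
    datasets of the same design (used for type-I-error calibration).
    """

    def __init__(self, n_groups: list[int], n_control: int,
                 draws: int = 100_000, seed: int = 0):
        n_groups = [int(n) for n in n_groups]
        df = sum(n_groups) + n_control - len(n_groups) - 1
        if df < 1:
            raise StatsUsageError("not enough replication for Dunnett contrasts")
        self.df = df
        lam = np.sqrt(np.array(n_groups) / (np.array(n_groups) + n_control))
        k = len(n_groups)
        rho = np.outer(lam, lam)
        np.fill_diagonal(rho, 1.0)
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(rho)
        z = rng.standard_normal((draws, k)) @ L.T
        s = np.sqrt(rng.chisquare(df, size=draws) / df)
        self.max_abs_t = np.sort(np.max(np.abs(z / s[:, None]), axis=1))

    def adjusted_p(self, t_stat: float) -> float:
        idx = np.searchsorted(self.max_abs_t, abs(t_stat))
        return float(1.0 - idx / self.max_abs_t.size)


def anova_dunnett(groups, control_index: int = 0, draws: int = 100_000,
                  seed: int = 0, rank: bool = False,
                  mc: DunnettMC | None = None) -> list[TestResult]:
    """One-way ANOVA plus per-group-vs-control adjusted comparisons.

    Returns the omnibus test first (ANOVA F, or Kruskal-Wallis H with
    ``rank=True``), followed by one TestResult per non-control group with the
    multiplicity-adjusted p-value (Monte-Carlo Dunnett, or Dunn's rank test
    with Bonferroni adjustment).
    """
    groups = [np.asarray(list(g), float) for g in groups]
    if len(groups) < 2:
        raise StatsUsageError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise StatsUsageError("each group needs n >= 2")
    if not (0 <= control_index < len(groups)):
        raise StatsUsageError("control index out of range")
    ctrl = groups[control_index]
    if ctrl.size == 0:
        raise StatsUsageError("control group is empty")
    others = [(i, g) for i, g in enumerate(groups) if i != control_index]

    if rank:
        h, p = sps.kruskal(*groups)
        results = [TestResult("kruskal_wallis", float(h), float(p))]
        results += _dunn_vs_control(groups, control_index)
        return results

    f, p = sps.f_oneway(*groups)
    results = [TestResult("one_way_anova", float(f), float(p))]
    # pooled variance over all groups
    df = sum(g.size for g in groups) - len(groups)
    sp2 = sum((g.size - 1) * np.var(g, ddof=1) for g in groups) / df
    if mc is None:
        mc = DunnettMC([g.size for _, g in others], ctrl.size,
                       draws=draws, seed=seed)
    for i, g in others:
        se = np.sqrt(sp2 * (1.0 / g.size + 1.0 / ctrl.size))
        t = (g.mean() - ctrl.mean()) / se if se > 0 else 0.0
        results.append(TestResult("dunnett_mc", float(t), mc.adjusted_p(t),
                                  comparison=f"group{i}-vs-control",
                                  adjustment="dunnett_mc"))
    return results


def _dunn_vs_control(groups, control_index: int) -> list[TestResult]:
    """Dunn's rank-based many-to-one z tests with Bonferroni adjustment."""
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    # tie correction to the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks, start = [], 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    k = len(groups) - 1
    out = []
    for i in range(len(groups)):
        if i == control_index:
            continue
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[control_index]))
        z = (mean_ranks[i] - mean_ranks[control_index]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * k)
        out.append(TestResult("dunn", float(z), float(p),
                              comparison=f"group{i}-vs-control",
                              adjustment="bonferroni"))
    return out


# --------------------------------------------------------------------------
# size cut-off sensitivity
# --------------------------------------------------------------------------

@dataclass
class ThresholdSensitivityResult:
    per_group: pd.DataFrame     # group, F, p
    threshold_stable: bool


def threshold_sensitivity(table: pd.DataFrame,
                          alpha: float = 0.05) -> ThresholdSensitivityResult:
    """Repeated-measures ANOVA of normalized area over the cut-off factor.

    ``table`` must have columns (group, replicate, cutoff_um2,
    normalized_area) with every replicate quantified at every cut-off.  For
    each treatment group the cut-off is treated as a within-replicate factor;
    the channel is flagged threshold-stable when no group shows a
    significant cut-off effect (all p > alpha), mirroring the finding that
    results are insensitive to cut-offs in the 500-3000 µm² range.
    """
    from statsmodels.stats.anova import AnovaRM

    required = {"group", "replicate", "cutoff_um2", "normalized_area"}
    if not required.issubset(table.columns):
        raise StatsUsageError(f"table must have columns {sorted(required)}")
    cutoffs = sorted(table["cutoff_um2"].unique())
    rows = []
    for grp, sub in table.groupby("group"):
        pivot = sub.pivot_table(index="replicate", columns="cutoff_um2",
                                values="normalized_area")
        if pivot.isna().any().any() or set(pivot.columns) != set(cutoffs):
            raise StatsUsageError(
                f"group {grp!r}: unequal replicate sets across cut-offs")
        within_var = float(pivot.sub(pivot.mean(axis=1), axis=0).var().sum())
        scale = float(max(np.abs(pivot.values).max(), 1e-30)) ** 2
        if within_var <= 1e-20 * scale:
            # identical areas at all cut-offs: no cut-off effect by definition
            rows.append({"group": grp, "F": 0.0, "p": 1.0})
            continue
        res = AnovaRM(sub, depvar="normalized_area", subject="replicate",
                      within=["cutoff_um2"]).fit()
        rows.append({"group": grp,
                     "F": float(res.anova_table["F Value"].iloc[0]),
                     "p": float(res.anova_table["Pr > F"].iloc[0])})
    per_group = pd.DataFrame(rows)
    return ThresholdSensitivityResult(
        per_group=per_group,
        threshold_stable=bool((per_group["p"] > alpha).all()))
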