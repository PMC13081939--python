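"""Genotype comparisons: one-way ANOVA with Tukey HSD, and cell-count tests.

Per-fish gains are compared across genotype groups (e.g. wildtype,
heterozygote, homozygous mutant) with a fixed-effects one-way ANOVA
followed by all-pairs Tukey HSD.  Adjusted p-values come from the
studentized-range distribution with the Tukey-Kramer standard error for
unequal group sizes.  Subnucleus cell counts are compared per region with
a Welch two-sample t-test by default (Mann-Whitney optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GenotypeGroup",
    "PairwiseComparison",
    "AnovaTukeyResult",
    "anova_tukey",
    "compare_counts",
]


@dataclass(frozen=True)
class GenotypeGroup:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_difference: float
    q: float
    adjusted_p: float
    alpha: float


@dataclass(frozen=True)
class AnovaTukeyResult:
    F: float
    p_anova: float
    comparisons: list[PairwiseComparison]
    df_within: int


def anova_tukey(groups: list[GenotypeGroup],
                alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA plus all-pairs Tukey HSD.

    For groups i, j with means m_i, m_j and sizes n_i, n_j,

        q_ij = |m_i - m_j| / sqrt( MSE/2 * (1/n_i + 1/n_j) )

    where MSE is the pooled within-group variance; the adjusted p is the
    survival function of the studentized range with k groups and N - k
    degrees of freedom (Tukey-Kramer for unequal n).

    If every group has zero variance: equal means give the degenerate
    p = 1 family; unequal means give q = inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.values.size < 2:
            raise ValueError(f"group {g.label!r} has n < 2")
    k = len(groups)
    ns = np.array([g.values.size for g in groups])
    means = np.array([g.values.mean() for g in groups])
    N = int(ns.sum())
    df_within = N - k
    sse = sum(float(((g.values - m) ** 2).sum())
              for g, m in zip(groups, means))
    mse = sse / df_within

    F, p_anova = sps.f_oneway(*[g.values for g in groups])
    comparisons = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        if mse > 0:
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_within))
        elif diff == 0:
            q, p = 0.0, 1.0
        else:
            q, p = np.inf, 0.0
        comparisons.append(PairwiseComparison(
            group_a=groups[i].label, group_b=groups[j].label,
            mean_difference=float(diff), q=float(q),
            adjusted_p=min(max(p, 0.0), 1.0), alpha=alpha))
    if mse == 0 and np.allclose(means, means[0]):
        F, p_anova = 0.0, 1.0
    return AnovaTukeyResult(F=float(F), p_anova=float(p_anova),
                            comparisons=comparisons, df_within=df_within)


def compare_counts(counts: pd.DataFrame, regions: list[str] | None = None,
                   test: str = "welch") -> pd.DataFrame:
    """Per-region two-genotype comparison of per-fish cell counts.

    ``counts`` is tidy: columns fish_id, genotype, region, count, with
    exactly two genotypes.  Returns one row per region with the mean
    difference (first genotype minus second, in label order) and the
    p-value of the chosen test ("welch" or "mannwhitney").
    """
    if test not in ("welch", "mannwhitney"):
        raise ValueError(f"unknown test {test!r}")
    genotypes = sorted(counts["genotype"].unique())
    if len(genotypes) != 2:
        raise ValueError(f"expected exactly 2 genotypes, got {genotypes}")
    if regions is None:
        regions = list(counts["region"].unique())
    rows = []
    for region in regions:
        sub = counts[counts["region"] == region]
        if sub.empty:
            raise ValueError(f"region {region!r} absent from count table")
        a = sub.loc[sub["genotype"] == genotypes[0], "count"].to_numpy(float)
        b = sub.loc[sub["genotype"] == genotypes[1], "count"].to_numpy(float)
        for label, v in ((genotypes[0], a), (genotypes[1], b)):
            if v.size < 2:
                raise ValueError(
                    f"genotype {label!r} has < 2 fish in region {region!r}")
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0  # identical samples: no evidence of a difference
        elif test == "welch":
            p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float(sps.mannwhitneyu(a, b,
                                       alternative="two-sided").pvalue)
        rows.append({"region": region, "genotype_a": genotypes[0],
                     "genotype_b": genotypes[1],
                     "mean_a": a.mean(), "mean_b": b.mean(),
                     "mean_difference": a.mean() - b.mean(),
                     "test": test, "p_value": p,
                     "n_a": a.size, "n_b": b.size})
    return pd.DataFrame(rows)
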