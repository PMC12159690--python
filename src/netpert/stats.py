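"""Nonparametric group statistics for SED/RED comparisons.

Implements the analysis battery used on the deviation metrics: Wilcoxon
rank-sum with Cohen's d for two unpaired groups, one-tailed Wilcoxon
signed-rank for baseline/follow-up pairs, Kruskal-Wallis with Dunn's
post-hoc z-tests for three groups, Benjamini-Hochberg FDR adjustment,
region-wise testing over RED matrices, and top-decile region selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .metrics import REDMatrix

__all__ = [
    "ComparisonResult",
    "RegionwiseReport",
    "OmnibusReport",
    "compare_unpaired",
    "compare_paired_one_tailed",
    "omnibus_three_group",
    "fdr_adjust",
    "regionwise_tests",
    "top_decile_regions",
    "significance_marker",
]

#: maximum per-group size for exact rank-sum p-values (ties permitting)
EXACT_N_MAX = 25


def significance_marker(p: float) -> str:
    """Conventional star markers: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return ""


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with plain pooled standard deviation; sign follows
    mean(a) - mean(b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    effect_size_d: float
    alternative: str
    n_a: int
    n_b: int

    @property
    def marker(self) -> str:
        return significance_marker(self.p_value)

    def summary(self) -> str:
        return (
            f"statistic={self.statistic:.4g}, p={self.p_value:.4g}{self.marker}, "
            f"d={self.effect_size_d:.3f} ({self.alternative}; "
            f"n={self.n_a}/{self.n_b})"
        )


def compare_unpaired(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> ComparisonResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test plus Cohen's d.

    Exact p-values for small tie-free samples (both groups <= 25),
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("combined sample is constant; rank test undefined")
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (max(a.size, b.size) <= EXACT_N_MAX and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size_d=cohens_d(a, b),
        alternative=alternative,
        n_a=a.size,
        n_b=b.size,
    )


def compare_paired_one_tailed(before: np.ndarray, after: np.ndarray) -> ComparisonResult:
    """One-tailed Wilcoxon signed-rank test of after < before.

    Zero differences are dropped before ranking; requires at least 5
    informative pairs.  The effect size is Cohen's d_z of the paired
    differences (mean difference / sd of differences).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must have equal length")
    diff = after - before
    informative = diff[diff != 0]
    if informative.size == 0:
        raise ValueError("all paired differences are zero; no informative pairs")
    if informative.size < 5:
        raise ValueError(
            f"only {informative.size} informative pairs; need at least 5"
        )
    res = sps.wilcoxon(after, before, alternative="less", zero_method="wilcox")
    sd = informative.std(ddof=1)
    dz = 0.0 if sd == 0 else float(-informative.mean() / sd)
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size_d=dz,
        alternative="less",
        n_a=before.size,
        n_b=after.size,
    )


@dataclass
class PairwiseDunn:
    pair: tuple[str, str]
    dunn_z: float
    raw_p: float
    adj_p: float


@dataclass
class OmnibusReport:
    kw_statistic: float
    kw_p: float
    pairwise: list[PairwiseDunn]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": d.pair[0],
                    "group_b": d.pair[1],
                    "dunn_z": d.dunn_z,
                    "raw_p": d.raw_p,
                    "adj_p": d.adj_p,
                    "marker": significance_marker(d.adj_p),
                }
                for d in self.pairwise
            ]
        )


def _dunn_z(groups: dict[str, np.ndarray]) -> list[PairwiseDunn]:
    """Dunn's pairwise z statistics on pooled ranks with tie correction."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    mean_ranks = {}
    start = 0
    for g in names:
        size = groups[g].size
        mean_ranks[g] = ranks[start : start + size].mean()
        start += size
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ga, gb = names[i], names[j]
            na, nb = groups[ga].size, groups[gb].size
            se = np.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
            )
            z = (mean_ranks[ga] - mean_ranks[gb]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            out.append(PairwiseDunn(pair=(ga, gb), dunn_z=float(z), raw_p=float(p), adj_p=np.nan))
    return out


def omnibus_three_group(
    g1: np.ndarray,
    g2: np.ndarray,
    g3: np.ndarray,
    names: tuple[str, str, str] = ("group1", "group2", "group3"),
) -> OmnibusReport:
    """Kruskal-Wallis omnibus test followed by Dunn's pairwise post-hoc
    z-tests, FDR-adjusted across the three pairs."""
    arrays = [np.asarray(g, dtype=float) for g in (g1, g2, g3)]
    if any(a.size < 3 for a in arrays):
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("pooled sample is constant; rank tests undefined")
    kw_stat, kw_p = sps.kruskal(*arrays)
    pairwise = _dunn_z(dict(zip(names, arrays)))
    adj = fdr_adjust(np.array([d.raw_p for d in pairwise]))
    for d, p in zip(pairwise, adj):
        d.adj_p = float(p)
    return OmnibusReport(kw_statistic=float(kw_stat), kw_p=float(kw_p), pairwise=pairwise)


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class RegionwiseReport:
    region_labels: list[str]
    raw_p: np.ndarray
    adj_p: np.ndarray
    effect_size_d: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05

    def summary(self) -> str:
        n_sig = int(self.significant.sum())
        lines = [
            f"Region-wise rank-sum tests: {n_sig}/{len(self.region_labels)} "
            f"significant at FDR {self.alpha}"
        ]
        for i in np.flatnonzero(self.significant):
            lines.append(
                f"  {self.region_labels[i]}: adj p={self.adj_p[i]:.4g}"
                f"{significance_marker(self.adj_p[i])}, d={self.effect_size_d[i]:.3f}"
            )
        return "\n".join(lines)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_labels,
                "raw_p": self.raw_p,
                "adj_p": self.adj_p,
                "cohens_d": self.effect_size_d,
                "significant": self.significant,
                "marker": [significance_marker(p) for p in self.adj_p],
            }
        )


def regionwise_tests(
    red_a: REDMatrix, red_b: REDMatrix, alpha: float = 0.05
) -> RegionwiseReport:
    """Per-region two-sided rank-sum tests between two RED matrices,
    FDR-adjusted across all regions.

    A region that is constant across both groups carries no rank
    information; it is assigned p = 1 (and d = 0) rather than aborting
    the scan.
    """
    if red_a.region_labels != red_b.region_labels:
        raise ValueError("RED matrices must share region labels")
    m = red_a.n_regions
    raw = np.ones(m)
    d = np.zeros(m)
    for i in range(m):
        a, b = red_a.red[:, i], red_b.red[:, i]
        if np.ptp(np.concatenate([a, b])) == 0:
            continue
        res = compare_unpaired(a, b, alternative="two-sided")
        raw[i] = res.p_value
        d[i] = res.effect_size_d
    adj = fdr_adjust(raw)
    return RegionwiseReport(
        region_labels=list(red_a.region_labels),
        raw_p=raw,
        adj_p=adj,
        effect_size_d=d,
        significant=adj < alpha,
        alpha=alpha,
    )


def top_decile_regions(red: REDMatrix, fraction: float = 0.10) -> list[str]:
    """Regions ranked by mean RED, returning the top ``floor(fraction*m)``
    labels in descending order (ties broken by lower region index)."""
    if red.n_subjects < 1:
        raise ValueError("RED matrix must contain at least one subject")
    means = red.column_means()
    k = int(np.floor(fraction * red.n_regions))
    # stable sort on negated means keeps the lower index first on ties
    order = np.argsort(-means, kind="stable")
    return [red.region_labels[i] for i in order[:k]]
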