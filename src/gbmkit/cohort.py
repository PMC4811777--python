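"""Cohort-level z-score comparisons and cross-platform concordance.

Reproduces the structure of TCGA-style analyses: per-gene expression
z-scores against a control distribution, two-sided Wilcoxon/Mann-Whitney
rank-sum comparisons between genotype or subtype groups (e.g. TP53 mutant
vs wild-type, or {G-CIMP, Proneural} vs {Neural, Classical, Mesenchymal}),
and Spearman rank concordance of z-scores measured on two platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "compute_zscores",
    "rank_sum_test",
    "group_contrast",
    "platform_concordance",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


def compute_zscores(values: pd.Series, reference_ids) -> pd.Series:
    """z-scores of per-sample expression against a control distribution.

    ``z = (x - mean(reference)) / sd(reference)`` with the unbiased (ddof=1)
    standard deviation. Requires >= 2 reference samples with nonzero spread.
    """
    reference_ids = list(reference_ids)
    missing = set(reference_ids) - set(values.index)
    if missing:
        raise ValueError(f"reference samples absent from values: {sorted(missing)[:5]}")
    ref = values.loc[reference_ids].astype(float)
    if len(ref) < 2:
        raise ValueError("need at least 2 reference samples")
    sd = float(ref.std(ddof=1))
    if sd == 0:
        raise ValueError("reference samples have zero spread")
    return (values.astype(float) - float(ref.mean())) / sd


def rank_sum_test(group_a, group_b, exact_cutoff: int = 12) -> TestResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum comparison of two groups.

    Uses exact enumeration when the combined sample size is at most
    ``exact_cutoff`` and the data are tie-free; otherwise the normal
    approximation with mid-rank tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size + b.size <= exact_cutoff and not has_ties:
        method = "rank-sum exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "rank-sum normal-approx"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def group_contrast(
    table: pd.DataFrame,
    grouping="mutation_status",
    exact_cutoff: int = 12,
) -> tuple[TestResult, pd.DataFrame]:
    """Rank-sum contrast of two cohort groups plus per-group summaries.

    ``grouping="mutation_status"`` contrasts mutant vs wild-type. Otherwise
    pass a pair of label collections partitioning the subtype labels, e.g.
    ``({"GCiMP", "Proneural"}, {"Neural", "Classical", "Mesenchymal"})``.
    Returns the test result and a summary frame (group, n, median z-score).
    """
    if isinstance(grouping, str):
        if grouping != "mutation_status":
            raise ValueError("string grouping must be 'mutation_status'")
        if "mutation_status" not in table.columns:
            raise ValueError("table has no mutation_status column")
        a = table.loc[table["mutation_status"] == "mutant", "zscore"]
        b = table.loc[table["mutation_status"] == "wild-type", "zscore"]
        names = ("mutant", "wild-type")
    else:
        set_a, set_b = (set(grouping[0]), set(grouping[1]))
        if "subtype" not in table.columns:
            raise ValueError("table has no subtype column")
        known = set(table["subtype"].dropna())
        unknown = (set_a | set_b) - known if known else set()
        bad = known - (set_a | set_b)
        if bad:
            raise ValueError(
                f"subtype labels {sorted(bad)} not covered by the partition; "
                f"valid labels: {sorted(set_a | set_b)}"
            )
        if unknown:
            raise ValueError(
                f"partition names unknown subtype labels {sorted(unknown)}; "
                f"table has: {sorted(known)}"
            )
        a = table.loc[table["subtype"].isin(set_a), "zscore"]
        b = table.loc[table["subtype"].isin(set_b), "zscore"]
        names = ("+".join(sorted(set_a)), "+".join(sorted(set_b)))
    if a.empty or b.empty:
        raise ValueError("both partition cells must be non-empty")
    result = rank_sum_test(a, b, exact_cutoff=exact_cutoff)
    summary = pd.DataFrame(
        {
            "group": names,
            "n": [len(a), len(b)],
            "median_zscore": [float(a.median()), float(b.median())],
        }
    )
    return result, summary


def platform_concordance(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> TestResult:
    """Spearman rank concordance of z-scores over the shared samples.

    Both tables need ``sample_id`` and ``zscore`` columns; at least 3
    overlapping samples are required. Mid-ranks handle ties.
    """
    a = table_a.set_index("sample_id")["zscore"]
    b = table_b.set_index("sample_id")["zscore"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 overlapping samples, found {len(shared)}"
        )
    rho, p = stats.spearmanr(a.loc[shared], b.loc[shared])
    return TestResult(
        statistic=float(rho),
        p_value=float(min(max(p, np.nextafter(0, 1)), 1.0)),
        method="spearman",
        n_a=len(shared),
        n_b=len(shared),
    )
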