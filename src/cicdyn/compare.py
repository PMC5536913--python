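"""Pairwise statistical comparison of per-embryo metrics across genotypes.

Scalar metrics (cycle-14 mean amplitude, boundary position lambda,
recovery tau) are compared between genotypes with a two-tailed Student's
t-test (pooled variance by default, Welch by flag) and annotated with the
conventional significance codes:

    n.s.  p >= 0.05
    *     p < 0.05
    **    p < 0.005
    ***   p < 0.0005

No multiple-testing correction is applied by default; a Bonferroni flag
is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

SIGNIFICANCE_THRESHOLDS = (0.05, 0.005, 0.0005)


def significance_code(p: float) -> str:
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass
class ComparisonResult:
    metric: str
    genotype_a: str
    genotype_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    code: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def two_tailed_t_test(
    sample_a,
    sample_b,
    metric: str = "",
    genotype_a: str = "a",
    genotype_b: str = "b",
    variance_mode: str = "pooled",
) -> ComparisonResult:
    """Two-tailed Student's t-test between two per-embryo samples.

    variance_mode "pooled" (classic Student) or "welch".  Two samples with
    zero variance and equal means are reported as t=0, p=1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if variance_mode not in ("pooled", "welch"):
        raise ValueError("variance_mode must be 'pooled' or 'welch'")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=(variance_mode == "pooled"))
        t_stat, p = float(t_stat), float(p)
        if np.isnan(p):
            t_stat, p = 0.0, 1.0
    return ComparisonResult(
        metric=metric,
        genotype_a=genotype_a,
        genotype_b=genotype_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
        t_statistic=t_stat,
        p_value=p,
        code=significance_code(p),
    )


def compare_all(
    metrics_by_genotype: dict[str, np.ndarray],
    metric: str = "",
    variance_mode: str = "pooled",
    bonferroni: bool = False,
) -> list[ComparisonResult]:
    """All unordered pairwise comparisons between genotypes.

    With ``bonferroni=True`` p-values are multiplied by the number of
    pairs (capped at 1) before coding; the default applies no correction.
    """
    names = list(metrics_by_genotype)
    if len(names) < 2:
        raise ValueError("need at least 2 genotypes")
    pairs = list(combinations(names, 2))
    results = []
    for ga, gb in pairs:
        res = two_tailed_t_test(
            metrics_by_genotype[ga],
            metrics_by_genotype[gb],
            metric=metric,
            genotype_a=ga,
            genotype_b=gb,
            variance_mode=variance_mode,
        )
        if bonferroni:
            p = min(1.0, res.p_value * len(pairs))
            res.p_value = p
            res.code = significance_code(p)
        results.append(res)
    return results


def comparison_table(results: list[ComparisonResult]):
    """Results as a pandas DataFrame, one row per pair."""
    import pandas as pd

    return pd.DataFrame([r.as_dict() for r in results])
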