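"""Group-level statistical battery for scored cohorts.

Covers the analyses applied to switch rates and percept durations:
Kruskal-Wallis group comparisons with chi-squared post-hocs, two-sample
Kolmogorov-Smirnov tests on pooled duration distributions, Spearman
symptom and metabolite correlations with Bonferroni correction,
test–retest reliability via ICC(3,k), Cohen's d effect sizes on log10
rates, the inclusion/exclusion contingency analysis, and a
repeated-measures ANOVA for the block-order effect.

Standard tests are delegated to scipy / pingouin / statsmodels; this
module fixes the exact conventions (tie handling, analysis scale,
correction families) and returns uniformly structured results.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "StatsReport",
    "kruskal_wallis",
    "posthoc_pairwise",
    "ks_two_sample",
    "spearman",
    "icc_3k",
    "cohens_d",
    "exclusion_contingency",
    "block_effect",
    "duration_histogram",
    "metabolite_correlations",
    "bonferroni",
    "DurationHistogram",
]


@dataclass(frozen=True)
class TestResult:
    """One named test: statistic, degrees of freedom / sample sizes, p values."""

    test_name: str
    statistic: float
    df: Optional[float] = None
    n: Optional[tuple[int, ...]] = None
    p: float = float("nan")
    p_bonferroni: Optional[float] = None
    effect_size: Optional[float] = None
    note: str = ""


@dataclass
class StatsReport:
    """Ordered collection of named test results, JSON-serializable."""

    entries: dict[str, TestResult] = field(default_factory=dict)

    def add(self, result: TestResult) -> None:
        self.entries[result.test_name] = result

    def __getitem__(self, name: str) -> TestResult:
        return self.entries[name]

    def to_dict(self) -> dict:
        return {name: asdict(r) for name, r in self.entries.items()}

    def to_json(self, path=None, indent: int = 1) -> str:
        text = json.dumps(self.to_dict(), indent=indent, allow_nan=True)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p value: min(1, m * p). Never smaller than p."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return min(1.0, m * p)


def _as_clean_arrays(groups: Sequence[Sequence[float]], min_n: int = 2) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size < min_n:
            raise ValueError(f"group {i} has n = {a.size} < {min_n}")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {i} contains non-finite values")
    return arrays


def kruskal_wallis(*groups: Sequence[float], name: str = "kruskal_wallis") -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square(k-1) p value."""
    arrays = _as_clean_arrays(groups)
    h, p = sps.kruskal(*arrays)
    return TestResult(
        test_name=name,
        statistic=float(h),
        df=len(arrays) - 1,
        n=tuple(a.size for a in arrays),
        p=float(p),
    )


def posthoc_pairwise(
    a: Sequence[float], b: Sequence[float], name: str = "posthoc", m: int = 3
) -> TestResult:
    """Two-group Kruskal-Wallis (chi-square, 1 df) with Bonferroni over ``m`` pairs."""
    res = kruskal_wallis(a, b, name=name)
    return TestResult(
        test_name=name,
        statistic=res.statistic,
        df=1,
        n=res.n,
        p=res.p,
        p_bonferroni=bonferroni(res.p, m),
    )


def ks_two_sample(
    a: Sequence[float], b: Sequence[float], name: str = "ks", exact: bool = False
) -> TestResult:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_a - ECDF_b|.

    The p value is asymptotic by default; ``exact=True`` switches to the
    exact small-sample distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, method="exact" if exact else "asymp")
    return TestResult(
        test_name=name,
        statistic=float(res.statistic),
        n=(a.size, b.size),
        p=float(res.pvalue),
    )


def spearman(
    x: Sequence[float], y: Sequence[float], name: str = "spearman", m: int = 1
) -> TestResult:
    """Tie-aware (average-rank) Spearman correlation with a t-approximation p.

    Constant input leaves rho undefined: flagged in ``note`` with NaN
    statistic rather than raising, since screening batteries routinely hit
    degenerate covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 4:
        raise ValueError("need n >= 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(
            test_name=name, statistic=float("nan"), n=(x.size,), note="undefined: constant input"
        )
    rho, p = sps.spearmanr(x, y)
    return TestResult(
        test_name=name,
        statistic=float(rho),
        df=x.size - 2,
        n=(x.size,),
        p=float(p),
        p_bonferroni=bonferroni(float(p), m) if m > 1 else None,
        effect_size=float(rho),
    )


def icc_3k(matrix: np.ndarray | pd.DataFrame, name: str = "icc_3k") -> TestResult:
    """ICC(3,k): two-way mixed, consistency, average measures.

    ``matrix`` is subjects x sessions; rows with missing values are dropped
    (the count is recorded in ``note``). Computed as (BMS - EMS) / BMS from
    the two-way ANOVA decomposition via pingouin.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("matrix must be subjects x k sessions with k >= 2")
    complete = np.all(np.isfinite(m), axis=1)
    dropped = int((~complete).sum())
    m = m[complete]
    if m.shape[0] < 2:
        raise ValueError("need at least 2 complete subjects")

    import pingouin as pg

    n, k = m.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": m.ravel(),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # degenerate inputs (zero residual MS) trip divide-by-zero in the
        # confidence-interval arithmetic we do not use
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
    # "ICC(C,k)": consistency, average of k measures == ICC(3,k); older
    # pingouin releases label the same row "ICC3k".
    key = "ICC(C,k)" if "ICC(C,k)" in table.index else "ICC3k"
    row = table.loc[key]
    return TestResult(
        test_name=name,
        statistic=float(row["ICC"]),
        df=n - 1,
        n=(n, k),
        p=float(row["pval"]),
        note=f"dropped {dropped} incomplete rows" if dropped else "",
    )


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation.

    By convention applied here to log10 switch rates, the analysis scale.
    Returns NaN when the pooled SD is zero.
    """
    a, b = _as_clean_arrays([a, b])
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def exclusion_contingency(table: np.ndarray, name: str = "exclusion") -> TestResult:
    """Pearson chi-square on the included/excluded x group contingency table."""
    t = np.asarray(table, dtype=float)
    if np.any(t < 0) or not np.all(t == np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(test_name=name, statistic=float(chi2), df=float(df), p=float(p))


def block_effect(
    per_block: np.ndarray | pd.DataFrame, name: str = "block_effect"
) -> TestResult:
    """Repeated-measures ANOVA for the within-subject block-order effect.

    ``per_block`` is subjects x blocks (log10 rates). Rows with missing
    blocks are dropped. No sphericity correction by default.
    """
    m = np.asarray(per_block, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("per_block must be subjects x blocks")
    complete = np.all(np.isfinite(m), axis=1)
    dropped = int((~complete).sum())
    m = m[complete]
    if m.shape[0] < 2:
        raise ValueError("need at least 2 complete subjects")

    from statsmodels.stats.anova import AnovaRM

    n, k = m.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "block": np.tile(np.arange(k), n),
            "value": m.ravel(),
        }
    )
    res = AnovaRM(long, depvar="value", subject="subject", within=["block"]).fit()
    row = res.anova_table.iloc[0]
    return TestResult(
        test_name=name,
        statistic=float(row["F Value"]),
        df=float(row["Num DF"]),
        n=(n, k),
        p=float(row["Pr > F"]),
        note=(f"den df = {row['Den DF']:g}" + (f"; dropped {dropped} rows" if dropped else "")),
    )


@dataclass(frozen=True)
class DurationHistogram:
    """Per-group percept-duration histograms normalized to unit mass."""

    bin_edges: np.ndarray
    proportions: dict[str, np.ndarray]


def duration_histogram(
    durations_by_group: Mapping[str, Sequence[float]], bin_edges: Sequence[float]
) -> DurationHistogram:
    """Histogram of pooled durations per group, normalized by the group's
    total number of responses; out-of-range durations fall in the end bins.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with at least 2 entries")
    props: dict[str, np.ndarray] = {}
    for g, d in durations_by_group.items():
        d = np.asarray(d, dtype=float)
        if d.size == 0:
            raise ValueError(f"group {g} has no durations")
        clipped = np.clip(d, edges[0], np.nextafter(edges[-1], -np.inf))
        counts, _ = np.histogram(clipped, bins=edges)
        props[g] = counts / d.size
    return DurationHistogram(bin_edges=edges, proportions=props)


def metabolite_correlations(
    rates: pd.Series | Sequence[float],
    concentrations: pd.DataFrame,
    groups: Optional[pd.Series] = None,
    metabolites: Sequence[str] = ("GABA", "glutamate", "glutamine"),
) -> StatsReport:
    """Spearman correlations between switch rates and metabolite levels.

    One pooled test per metabolite plus per-group tests when ``groups`` is
    given; Bonferroni is applied within the pooled family (m = number of
    metabolites) and within each group's family separately.
    """
    rates = pd.Series(np.asarray(rates, dtype=float)).reset_index(drop=True)
    conc = concentrations.reset_index(drop=True)
    report = StatsReport()
    m = len(metabolites)
    for met in metabolites:
        pair = pd.DataFrame({"rate": rates, "conc": conc[met]}).dropna()
        report.add(
            spearman(pair["rate"], pair["conc"], name=f"{met}_pooled", m=m)
        )
        if groups is not None:
            gser = pd.Series(groups).reset_index(drop=True)
            for g in gser.unique():
                sel = gser == g
                pair = pd.DataFrame({"rate": rates[sel], "conc": conc.loc[sel.values, met]}).dropna()
                if len(pair) >= 4:
                    report.add(spearman(pair["rate"], pair["conc"], name=f"{met}_{g}", m=m))
    return report
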