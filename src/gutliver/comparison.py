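"""Per-feature three-group screening and cohort summary-statistic tests.

The screening machinery mirrors the standard nonparametric workflow for
small clinical cohorts: a tie-corrected Kruskal-Wallis test across cohorts,
Dunn's rank-based post hoc z tests for each cohort pair with multiplicity
adjustment, and an enriched-group call (the cohort with the highest mean)
for features that clear both hurdles.  Summary-level tests (pooled-variance
t-test from mean/SD/n, chi-square on 2x2 tables, Mann-Whitney) recompute the
cohort-characteristics comparisons that clinical tables report.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import MultiOmicsDataset, SampleMetadata

AdjustMethod = Literal["bh", "bonferroni", "holm"]

_ADJUST = {"bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    With every observation identical the tie correction degenerates; the
    test then carries no information and (H, p) = (0, 1) is returned.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups: Mapping[str, Sequence[float]],
                 adjust: AdjustMethod = "bh") -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's post hoc z tests on pooled ranks for every group pair.

    z_jk = (Rbar_j - Rbar_k) / sqrt([N(N+1)/12 - sum(t^3 - t)/(12(N-1))]
    (1/n_j + 1/n_k)); two-sided p-values are adjusted across the pairs
    (Benjamini-Hochberg by default; ``bonferroni`` and ``holm`` available).
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for name, a in zip(names, arrays):
        mean_ranks[name] = ranks[start:start + a.size].mean()
        sizes[name] = a.size
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var_core = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    zs, raw = [], []
    pairs = list(combinations(names, 2))
    for a, b in pairs:
        se2 = var_core * (1.0 / sizes[a] + 1.0 / sizes[b])
        if se2 <= 0:  # all observations tied: no rank information
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(se2)
        zs.append(z)
        raw.append(2 * stats.norm.sf(abs(z)))
    adj = multipletests(raw, method=_ADJUST[adjust])[1] if raw else []
    return {pair: (float(z), float(p)) for pair, z, p in zip(pairs, zs, adj)}


@dataclass
class DiffTestResult:
    """Kruskal-Wallis + Dunn outcome for one feature of one layer."""

    feature: str
    layer: str
    kw_H: float
    kw_p: float
    dunn: dict[tuple[str, str], tuple[float, float]]
    group_means: dict[str, float]
    significant: bool
    enriched_group: str | None = None


def screen_features(dataset: MultiOmicsDataset, alpha: float = 0.05,
                    adjust: AdjustMethod = "bh",
                    center: Literal["mean", "median"] = "mean") -> list[DiffTestResult]:
    """Screen every feature of every layer for cohort differences.

    A feature is significant when the Kruskal-Wallis p is below ``alpha``
    and at least one Dunn pair survives adjustment; significant features
    get an enriched-group call, the cohort with the maximal mean (or
    median) on the analysed scale.  With two cohorts present the screen
    reduces to a two-group rank test with a single Dunn pair.
    """
    cohorts = [c for c in ("Ctrl", "LC", "HCC") if c in set(dataset.metadata.cohorts)]
    cols = {c: dataset.metadata.samples_in([c]) for c in cohorts}
    centre = np.mean if center == "mean" else np.median
    results: list[DiffTestResult] = []
    for layer_id, table in dataset.layers.items():
        vals = table.values
        for feat in vals.index:
            groups = {c: vals.loc[feat, cols[c]].to_numpy(dtype=float) for c in cohorts}
            h, p = kruskal_wallis(list(groups.values()))
            dunn = dunn_posthoc(groups, adjust=adjust)
            means = {c: float(centre(g)) for c, g in groups.items()}
            sig = bool(p < alpha and any(padj < alpha for _, padj in dunn.values()))
            enriched = max(means, key=means.get) if sig else None
            results.append(DiffTestResult(
                feature=feat, layer=layer_id, kw_H=h, kw_p=p, dunn=dunn,
                group_means=means, significant=sig, enriched_group=enriched,
            ))
    return results


def screen_to_frame(results: Sequence[DiffTestResult]) -> pd.DataFrame:
    """Flatten screen results into one row per feature for TSV export."""
    rows = []
    for r in results:
        row = {"feature": r.feature, "layer": r.layer, "kw_H": r.kw_H,
               "kw_p": r.kw_p, "significant": r.significant,
               "enriched_group": r.enriched_group or ""}
        for (a, b), (z, padj) in r.dunn.items():
            row[f"dunn_z_{a}-{b}"] = z
            row[f"dunn_p_{a}-{b}"] = padj
        for c, m in r.group_means.items():
            row[f"mean_{c}"] = m
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Summary-statistic tests (cohort characteristics tables)
# ---------------------------------------------------------------------------

@dataclass
class SummaryGroup:
    """Mean, standard deviation and size of one cohort's measurements."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("need n >= 2 per group")


def t_test_from_summary(a: SummaryGroup, b: SummaryGroup) -> tuple[float, int, float]:
    """Two-sided pooled-variance t-test from summary statistics.

    Returns (t, df, p) with df = n_a + n_b - 2.  When both SDs are zero and
    the means coincide the statistic carries no information and p = 1.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return 0.0, a.n + b.n - 2, 1.0
        raise ValueError("zero variance in both groups with unequal means: t undefined")
    t, p = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                      equal_var=True)
    return float(t), a.n + b.n - 2, float(p)


def load_cohort_characteristics() -> pd.DataFrame:
    """Packaged cohort-characteristics summary (mean/SD/n per pair).

    One row per parameter and cohort pair for every normally-distributed
    clinical parameter, as printed in the study's characteristics table,
    with the printed p-value alongside.
    """
    from importlib import resources
    with resources.files("gutliver.data").joinpath("cohort_characteristics.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def characteristics_table(fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute the pooled t-test p for every summary row.

    Returns the fixture with ``t``, ``df`` and ``computed_p`` columns; the
    printed p-values are reproduced at 3-decimal rounding for the rows
    whose original comparison was a pooled t-test.
    """
    df = load_cohort_characteristics() if fixture is None else fixture.copy()
    out = []
    for _, row in df.iterrows():
        a = SummaryGroup(row["mean_a"], row["sd_a"], int(row["n_a"]))
        b = SummaryGroup(row["mean_b"], row["sd_b"], int(row["n_b"]))
        out.append(t_test_from_summary(a, b))
    df["t"] = [t for t, _, _ in out]
    df["df"] = [d for _, d, _ in out]
    df["computed_p"] = [p for _, _, p in out]
    return df


def chi2_2x2(table, correction: bool = True) -> tuple[float, float]:
    """Chi-square test on a 2x2 contingency table (Yates correction optional)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("table entries must be nonnegative integers")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=correction)
    return float(chi2), float(p)


def mann_whitney(x, y, exact_max: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when both sides have at most ``exact_max``
    observations and no ties cross the samples; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("need nonempty samples")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2.0), 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and x.size <= exact_max and y.size <= exact_max) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)
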