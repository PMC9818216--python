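"""LDA effect-size biomarker scoring (LEfSe-style), implemented from scratch.

The procedure: (1) scale every sample to a total of 1e6 so scores land on
the familiar log10 range where the conventional "score >= 3" biomarker
cutoff is meaningful; (2) filter features with a Kruskal-Wallis test across
classes at ``alpha``; (3) for each of ``n_boot`` bootstrap rounds, subsample
a fraction of each class and fit a linear discriminant; the per-feature
effect size blends the raw between-class difference with the feature's
coefficient-weighted displacement along the discriminant axis,
0.5 * (|d_raw| + |w_f d_raw|), reported as log10(1 + effect); (4) average
over rounds.  The within-class (subclass) consistency stage is a no-op when
no subclass labels exist, which matches a plain cohort design.  With more
than two classes the default one-against-all strategy scores each feature's
winning class against the rest; all-against-all scores the extreme pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .comparison import kruskal_wallis
from .tables import FeatureTable

SCALE_TOTAL = 1e6


@dataclass
class LefseResult:
    """Per-feature biomarker call."""

    feature: str
    winning_class: str
    lda_score: float
    kw_p: float
    passed_filters: bool

    def is_biomarker(self, threshold: float = 3.0) -> bool:
        return self.passed_filters and self.lda_score >= threshold


def _lda_axis(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """First discriminant axis, scaled to unit within-class variance."""
    lda = LinearDiscriminantAnalysis(solver="svd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear features are expected
        lda.fit(x, y)
    return lda.scalings_[:, 0]


def lefse(table: FeatureTable, classes: Sequence[str], alpha: float = 0.05,
          n_boot: int = 30, subsample: float = 2 / 3, threshold: float = 3.0,
          strategy: Literal["one_against_all", "all_against_all"] = "one_against_all",
          seed: int | np.random.Generator | None = None) -> list[LefseResult]:
    """Score features for class-discriminating effect size.

    Returns one :class:`LefseResult` per feature that survives the
    Kruskal-Wallis filter (features failing it never receive a score).
    ``classes`` gives the class label per sample, aligned with the table's
    sample order; every class needs at least 4 samples.
    """
    classes = np.asarray([str(c) for c in classes])
    if classes.size != len(table.sample_ids):
        raise ValueError("classes length does not match the table's samples")
    labels, counts = np.unique(classes, return_counts=True)
    if labels.size < 2:
        raise ValueError("need >= 2 classes")
    if (counts < 4).any():
        small = labels[counts < 4][0]
        raise ValueError(f"class {small!r} has fewer than 4 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # per-sample scaling to a fixed total
    x_all = table.values.to_numpy(dtype=float)
    totals = x_all.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("all-zero sample column")
    x_all = x_all / totals * SCALE_TOTAL  # features x samples

    # Kruskal-Wallis filter
    kw_p = np.array([
        kruskal_wallis([x_all[i, classes == g] for g in labels])[1]
        for i in range(x_all.shape[0])
    ])
    surviving = np.flatnonzero(kw_p < alpha)
    if surviving.size == 0:
        return []

    x = x_all[surviving].T  # samples x surviving features
    feats = [table.feature_ids[i] for i in surviving]
    class_means = {g: x[classes == g].mean(axis=0) for g in labels}
    winners = [max(labels, key=lambda g: class_means[g][j]) for j in range(len(feats))]
    losers = [min(labels, key=lambda g: class_means[g][j]) for j in range(len(feats))]

    scores = np.zeros((n_boot, len(feats)))
    for b in range(n_boot):
        idx: list[int] = []
        for g in labels:
            members = np.flatnonzero(classes == g)
            k = max(int(np.ceil(subsample * members.size)), 2)
            idx.extend(rng.choice(members, size=k, replace=False))
        xb, yb = x[idx], classes[idx]
        axes: dict[str, np.ndarray] = {}
        for j in range(len(feats)):
            if strategy == "one_against_all" and labels.size > 2:
                key = winners[j]
                if key not in axes:
                    axes[key] = _lda_axis(xb, np.where(yb == key, key, "rest"))
                w = axes[key]
                in_a = yb == key
                d_raw = xb[in_a, j].mean() - xb[~in_a, j].mean()
            else:
                a, c = winners[j], losers[j]
                key = f"{a}|{c}"
                if key not in axes:
                    pair = (yb == a) | (yb == c)
                    axes[key] = np.zeros(len(feats))
                    axes[key][:] = _lda_axis(xb[pair], yb[pair]) \
                        if labels.size > 2 else _lda_axis(xb, yb)
                w = axes[key]
                d_raw = xb[yb == a, j].mean() - xb[yb == c, j].mean()
            effect = 0.5 * (abs(d_raw) + abs(w[j] * d_raw))
            scores[b, j] = np.log10(1.0 + effect)
    mean_scores = scores.mean(axis=0)

    results = [
        LefseResult(feature=f, winning_class=winners[j],
                    lda_score=float(mean_scores[j]), kw_p=float(kw_p[surviving[j]]),
                    passed_filters=True)
        for j, f in enumerate(feats)
    ]
    return results


def lefse_to_frame(results: Sequence[LefseResult], threshold: float = 3.0) -> pd.DataFrame:
    """Long-format table of scores, histogram-ready."""
    return pd.DataFrame([
        {"feature": r.feature, "class": r.winning_class, "lda_score": r.lda_score,
         "kw_p": r.kw_p, "biomarker": r.is_biomarker(threshold)}
        for r in results
    ])
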