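"""Alpha diversity, Bray-Curtis beta diversity, PCoA, PERMANOVA, Venn overlap.

Alpha estimators follow the conventions of the common amplicon toolchains:
Shannon entropy in natural log, Simpson as the Gini-Simpson index 1 - sum
p_i^2, Chao1 in its bias-corrected form, and ACE with a rare-species cutoff
of 10.  The richness estimators extrapolate unseen taxa from singleton and
doubleton counts and are only defined on integer count vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .tables import COHORTS, FeatureTable, SampleMetadata


def _as_counts(counts) -> np.ndarray:
    v = np.asarray(counts, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D vector of counts")
    if (v < 0).any():
        raise ValueError("counts must be nonnegative")
    return v


def _proportions(counts) -> np.ndarray:
    v = _as_counts(counts)
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero vector: diversity undefined")
    return v / total


def observed_richness(counts) -> int:
    """Number of features with a nonzero count."""
    return int(np.count_nonzero(_as_counts(counts)))


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i over nonzero proportions.

    Natural log by default; pass ``base=2`` for bits.
    """
    p = _proportions(counts)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson(counts, kind: str = "gini") -> float:
    """Simpson diversity.

    ``gini`` (default) returns the Gini-Simpson index 1 - sum p_i^2;
    ``inverse`` returns 1 / sum p_i^2; ``dominance`` returns sum p_i^2.
    """
    p = _proportions(counts)
    d = float((p ** 2).sum())
    if kind == "gini":
        return 1.0 - d
    if kind == "inverse":
        return 1.0 / d
    if kind == "dominance":
        return d
    raise ValueError(f"unknown Simpson variant {kind!r}")


def _require_integer(counts) -> np.ndarray:
    v = _as_counts(counts)
    if not np.allclose(v, np.round(v)):
        raise ValueError("richness estimators require integer counts")
    return np.round(v).astype(np.int64)


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton (F1) and doubleton (F2) counts.

    Bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) by default; the classic
    form S_obs + F1^2/(2 F2) is available but undefined at F2 = 0.
    """
    v = _require_integer(counts)
    s_obs = int(np.count_nonzero(v))
    f1 = int((v == 1).sum())
    f2 = int((v == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ZeroDivisionError("classic Chao1 undefined with no doubletons")
    return s_obs + f1 * f1 / (2.0 * f2)


def ace(counts, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    Species with counts <= ``rare_threshold`` form the rare group.  With
    sample coverage C = 1 - F1/N_rare and the coefficient of variation
    gamma^2, the estimate is S_abund + S_rare/C + (F1/C) gamma^2.
    Degenerate inputs: if every rare species is a singleton (C = 0) the
    estimator is undefined and bias-corrected Chao1 is returned with a
    warning; if N_rare <= 1 the observed richness is returned.
    """
    v = _require_integer(counts)
    s_obs = int(np.count_nonzero(v))
    rare = v[(v > 0) & (v <= rare_threshold)]
    s_abund = int((v > rare_threshold).sum())
    s_rare = rare.size
    n_rare = int(rare.sum())
    if s_rare == 0:
        return float(s_obs)
    if n_rare <= 1:
        return float(s_obs)
    f1 = int((rare == 1).sum())
    coverage = 1.0 - f1 / n_rare
    if coverage == 0.0:
        warnings.warn("ACE undefined (all rare species are singletons); "
                      "falling back to bias-corrected Chao1", stacklevel=2)
        return chao1(v)
    sum_term = sum(i * (i - 1) * int((rare == i).sum())
                   for i in range(1, rare_threshold + 1))
    gamma2 = max(s_rare * sum_term / (coverage * n_rare * (n_rare - 1)) - 1.0, 0.0)
    return s_abund + s_rare / coverage + (f1 / coverage) * gamma2


def rarefy(counts, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement."""
    v = _require_integer(counts)
    total = int(v.sum())
    if depth > total:
        raise ValueError(f"cannot rarefy {total} reads to depth {depth}")
    pool = np.repeat(np.arange(v.size), v)
    picked = rng.choice(pool, size=depth, replace=False)
    return np.bincount(picked, minlength=v.size)


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Per-sample alpha diversity table (one row per sample).

    Columns: observed_richness, shannon (nats), simpson (Gini-Simpson),
    chao1, ace.  Richness estimators require a counts table.
    """
    rows = {}
    for s in table.sample_ids:
        v = table.values[s].to_numpy()
        row = {
            "observed_richness": observed_richness(v),
            "shannon": shannon(v),
            "simpson": simpson(v),
        }
        if table.semantics == "counts":
            row["chao1"] = chao1(v)
            row["ace"] = ace(v)
        rows[s] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric nonnegative sample-by-sample distances with zero diagonal."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} sample ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (m < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(x, y) = sum|x-y| / sum(x+y) between samples."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    x = table.values.to_numpy(dtype=float).T  # samples x features
    sums = x.sum(axis=1)
    if (sums == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined for a pair of all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


@dataclass
class PCoAResult:
    """Principal-coordinates embedding of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray      # samples x axes, positive-eigenvalue axes only
    eigenvalues: np.ndarray      # all eigenvalues, non-increasing
    explained_fraction: np.ndarray  # per retained axis, over positive eigenvalues

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Classical multidimensional scaling (Gower centering + eigendecomposition).

    Coordinates are eigenvectors scaled by sqrt(eigenvalue), kept for
    positive eigenvalues only; non-Euclidean inputs (Bray-Curtis) may
    produce negative eigenvalues, which are reported but never embedded.
    """
    n = len(d.sample_ids)
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    a = -0.5 * d.matrix ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(eigvals.max(), 0) * 1e-12
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    frac = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    if n_axes is not None:
        coords = coords[:, :n_axes]
        frac = frac[:n_axes]
    return PCoAResult(d.sample_ids, coords, eigvals, frac)


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    # pseudo-F from squared distances: SS_total = sum_{i<j} d2 / N,
    # SS_within = per-group sum of within-pair d2 / n_g
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    k = groups.size
    denom = ss_within / (n - k)
    if denom == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (k - 1)) / denom


def permanova(d: DistanceMatrix, labels: Sequence[str], n_perm: int = 999,
              seed: int | np.random.Generator | None = None) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Returns the pseudo-F statistic and the permutation p-value
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    labels = np.asarray(labels)
    if labels.size != len(d.sample_ids):
        raise ValueError("labels length does not match the distance matrix")
    groups, sizes = np.unique(labels, return_counts=True)
    if groups.size < 2 or (sizes < 2).any():
        raise ValueError("PERMANOVA needs >= 2 groups with >= 2 samples each")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d2 = d.matrix ** 2
    f_obs = _permanova_f(d2, labels)
    if not np.isfinite(f_obs):
        return f_obs, 1.0 / (1 + n_perm)
    hits = 0
    for _ in range(n_perm):
        if _permanova_f(d2, rng.permutation(labels)) >= f_obs:
            hits += 1
    return f_obs, (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Venn / OTU overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapCounts:
    """Venn-region feature counts across cohorts plus per-cohort presence sets."""

    presence: dict[str, frozenset[str]]      # cohort -> present features
    regions: dict[frozenset, int]            # exact region (cohort combo) -> count

    @property
    def union_size(self) -> int:
        u: set[str] = set()
        for s in self.presence.values():
            u |= s
        return len(u)

    def shared_all(self) -> int:
        sets = list(self.presence.values())
        inter = set(sets[0])
        for s in sets[1:]:
            inter &= s
        return len(inter)

    def shared(self, a: str, b: str) -> int:
        return len(self.presence[a] & self.presence[b])

    def pair_union(self, a: str, b: str) -> int:
        return len(self.presence[a] | self.presence[b])

    def unique(self, cohort: str) -> int:
        others: set[str] = set()
        for c, s in self.presence.items():
            if c != cohort:
                others |= s
        return len(self.presence[cohort] - others)

    def summary(self) -> dict:
        """Counts in the style 'shared X of Y' for all cohorts and pairs."""
        cohorts = list(self.presence)
        out = {
            "shared_all": self.shared_all(),
            "union_all": self.union_size,
            "unique": {c: self.unique(c) for c in cohorts},
            "pairs": {
                f"{a}-{b}": {"shared": self.shared(a, b), "union": self.pair_union(a, b)}
                for a, b in combinations(cohorts, 2)
            },
        }
        return out


def overlap_counts(table: FeatureTable, metadata: SampleMetadata,
                   min_count: float = 0, min_prevalence: int = 1) -> OverlapCounts:
    """Feature presence per cohort and counts for every Venn region.

    A feature is "present" in a cohort when it exceeds ``min_count`` in at
    least ``min_prevalence`` of that cohort's samples.
    """
    cohorts = [c for c in COHORTS if c in set(metadata.cohorts)]
    presence: dict[str, frozenset[str]] = {}
    for c in cohorts:
        cols = metadata.samples_in([c])
        mask = (table.values[cols] > min_count).sum(axis=1) >= min_prevalence
        presence[c] = frozenset(table.values.index[mask])
    regions: dict[frozenset, int] = {}
    for r in range(1, len(cohorts) + 1):
        for combo in combinations(cohorts, r):
            inside = set.intersection(*(set(presence[c]) for c in combo))
            for c in cohorts:
                if c not in combo:
                    inside -= presence[c]
            regions[frozenset(combo)] = len(inside)
    return OverlapCounts(presence=presence, regions=regions)
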