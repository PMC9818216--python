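"""Joint Pearson correlation networks across omics layers, per subject subset.

Candidate features (those passing the differential screen in a given
subject subset) from all four layers are correlated pairwise; pairs with a
two-sided correlation p-value below the edge threshold form an undirected
network.  "The network centered on X" is formalised as the star (radius-1
ego graph) of X, and the composition filter keeps stars whose members span
a required number of layers - four, by default, with the center's own layer
counting toward coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comparison import AdjustMethod, DiffTestResult
from .tables import MultiOmicsDataset

#: Feature reference: (layer_id, feature_id).
FeatureRef = tuple[str, str]

#: The four subject subsets the analysis is repeated on.
SUBSETS: dict[str, tuple[str, ...]] = {
    "ALL": ("Ctrl", "LC", "HCC"),
    "CTRL_LC": ("Ctrl", "LC"),
    "CTRL_HCC": ("Ctrl", "HCC"),
    "LC_HCC": ("LC", "HCC"),
}


def pearson_with_p(x, y) -> tuple[float, float, int] | None:
    """Pearson r with its two-sided t-test p-value and the n used.

    Returns ``None`` (a missing correlation, not zero) when either vector
    is constant; requires n >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors differ in length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson p-value needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


@dataclass(frozen=True)
class CorrelationEdge:
    """Undirected significant correlation between two layer-tagged features."""

    a: FeatureRef
    b: FeatureRef
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-correlation is not an edge")
        if self.a > self.b:  # canonical ordering so each pair is stored once
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    def touches(self, node: FeatureRef) -> bool:
        return node in (self.a, self.b)

    def other(self, node: FeatureRef) -> FeatureRef:
        if node == self.a:
            return self.b
        if node == self.b:
            return self.a
        raise ValueError(f"{node} is not an endpoint of this edge")


def candidate_set(screen_results: Sequence[DiffTestResult]) -> list[FeatureRef]:
    """Layer-tagged union of features called significant by the screen."""
    out: list[FeatureRef] = []
    seen: set[FeatureRef] = set()
    for r in screen_results:
        ref = (r.layer, r.feature)
        if r.significant and ref not in seen:
            seen.add(ref)
            out.append(ref)
    return out


def build_network(dataset: MultiOmicsDataset, candidates: Sequence[FeatureRef],
                  subset: str = "ALL", alpha_edge: float = 0.05,
                  r_min: float = 0.0, adjust: AdjustMethod | None = None,
                  log_transform: bool = False,
                  pseudocount: float = 1e-6) -> list[CorrelationEdge]:
    """Correlate all candidate pairs on the subset's samples; keep significant edges.

    Edges require p < ``alpha_edge`` (unadjusted by default, matching the
    usual practice of reporting raw correlation p-values; pass ``adjust``
    for a BH/Bonferroni/Holm-corrected screen) and |r| >= ``r_min``.
    Constant candidate columns are dropped with a warning.
    ``log_transform`` applies log10(x + pseudocount) to abundance layers
    before correlating.
    """
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {list(SUBSETS)}")
    if not candidates:
        return []
    samples = dataset.metadata.samples_in(SUBSETS[subset])
    if len(samples) < 4:
        raise ValueError(f"subset {subset} has fewer than 4 samples")
    vectors: dict[FeatureRef, np.ndarray] = {}
    for layer, feat in candidates:
        v = dataset.layers[layer].values.loc[feat, samples].to_numpy(dtype=float)
        if log_transform and dataset.layers[layer].semantics in ("counts", "relative_abundance"):
            v = np.log10(v + pseudocount)
        vectors[(layer, feat)] = v

    constant = [ref for ref, v in vectors.items() if np.ptp(v) == 0]
    if constant:
        warnings.warn(f"dropped {len(constant)} constant candidate column(s): "
                      f"{constant[:3]}", stacklevel=2)
        for ref in constant:
            del vectors[ref]
    raw: list[tuple[FeatureRef, FeatureRef, float, float, int]] = []
    for a, b in combinations(vectors, 2):
        res = pearson_with_p(vectors[a], vectors[b])
        if res is None:
            continue
        raw.append((a, b, *res))
    if not raw:
        return []

    pvals = np.array([p for _a, _b, _r, p, _n in raw])
    if adjust is not None and raw:
        from statsmodels.stats.multitest import multipletests
        method = {"bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}[adjust]
        pvals = multipletests(pvals, method=method)[1]

    edges = []
    for (a, b, r, p, n), p_eff in zip(raw, pvals):
        if p_eff < alpha_edge and abs(r) >= r_min:
            edges.append(CorrelationEdge(a=a, b=b, r=r, p=float(p_eff), n=n))
    return edges


@dataclass
class StarNetwork:
    """A center feature plus its directly correlated neighbors."""

    center: FeatureRef
    edges: list[CorrelationEdge]

    def __post_init__(self) -> None:
        for e in self.edges:
            if not e.touches(self.center):
                raise ValueError(f"edge {e.a}-{e.b} does not touch center {self.center}")

    @property
    def neighbors(self) -> list[FeatureRef]:
        return [e.other(self.center) for e in self.edges]

    @property
    def layer_coverage(self) -> frozenset[str]:
        return frozenset([self.center[0]] + [n[0] for n in self.neighbors])

    def neighbor_layer_coverage(self) -> frozenset[str]:
        """Coverage counting neighbors only (the center-exclusive reading)."""
        return frozenset(n[0] for n in self.neighbors)


def extract_stars(edges: Iterable[CorrelationEdge], min_layers: int = 4,
                  count_center: bool = True) -> list[StarNetwork]:
    """Stars around every connected node, filtered by layer coverage.

    ``count_center`` controls whether the center's own layer counts toward
    coverage (the default reading: a four-dataset star may have neighbors
    in only three other layers).
    """
    edges = list(edges)
    incident: dict[FeatureRef, list[CorrelationEdge]] = {}
    for e in edges:
        incident.setdefault(e.a, []).append(e)
        incident.setdefault(e.b, []).append(e)
    stars = []
    for node in sorted(incident):
        star = StarNetwork(center=node, edges=incident[node])
        coverage = star.layer_coverage if count_center else star.neighbor_layer_coverage()
        if len(coverage) >= min_layers:
            stars.append(star)
    return stars


def edges_to_frame(edges: Sequence[CorrelationEdge], subset: str = "ALL") -> pd.DataFrame:
    """Edge list as a flat table (one row per unordered pair)."""
    cols = ["feature_a", "layer_a", "feature_b", "layer_b", "r", "p", "n", "subset"]
    return pd.DataFrame([
        {"feature_a": e.a[1], "layer_a": e.a[0], "feature_b": e.b[1],
         "layer_b": e.b[0], "r": e.r, "p": e.p, "n": e.n, "subset": subset}
        for e in edges
    ], columns=cols)


def stars_to_records(stars: Sequence[StarNetwork]) -> list[dict]:
    """JSON-ready star summaries."""
    return [
        {"center": list(s.center),
         "neighbors": [[*n] for n in s.neighbors],
         "layer_coverage": sorted(s.layer_coverage)}
        for s in stars
    ]
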