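"""Seeded synthetic multi-omics cohorts with known ground truth.

Emulates the statistical structure the downstream analysis assumes: three
cohorts (healthy controls, cirrhosis, carcinoma; default sizes 17/18/10),
two compositional count layers (gut bacterial genera, gut viral species)
drawn per sample from a Dirichlet-multinomial, and two continuous
concentration layers (plasma metabolites, plasma cytokines/chemokines)
drawn from zero-truncated normals.  Cohort effects enter as multiplicative
shifts on the Dirichlet concentrations of count layers and additive shifts
on the means of concentration layers.  Cross-layer dependence is planted as
latent-factor "stars": one Gaussian factor per star, added on the log scale
to count-layer concentrations and on the linear scale (in units of the
feature's noise SD) to concentration layers, with signed loadings that set
the correlation signs.  Every draw
flows through one seeded generator, so a spec determines its dataset
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import COHORTS, LAYERS, FeatureTable, MultiOmicsDataset, SampleMetadata

#: Count layers use a multiplicative shift (1 = no effect); concentration
#: layers use an additive shift (0 = no effect).
COUNT_LAYERS = ("bacteria", "virus")

#: Default sequencing depth per sample, on the order of the cleaned read
#: counts typical of 16S amplicon runs.
DEFAULT_DEPTH = 70_000

#: Default cohort sizes of the study design this generator emulates.
DEFAULT_GROUP_SIZES = {"Ctrl": 17, "LC": 18, "HCC": 10}


@dataclass
class PlantedStarSpec:
    """A latent-factor star: one center plus signed-loading neighbors.

    ``center`` and each neighbor are (layer_id, feature_id); neighbor
    entries carry a loading in [-1, 1] whose sign sets the correlation
    sign with the center (the center itself loads at +1).
    """

    center: tuple[str, str]
    neighbors: list[tuple[str, str, float]]
    latent_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be positive")
        for layer, feat, loading in self.neighbors:
            if not -1.0 <= loading <= 1.0:
                raise ValueError(f"loading {loading} for {layer}/{feat} outside [-1, 1]")

    def loadings(self) -> dict[tuple[str, str], float]:
        out = {self.center: 1.0}
        for layer, feat, loading in self.neighbors:
            out[(layer, feat)] = loading
        return out

    def layer_coverage(self) -> frozenset[str]:
        return frozenset([self.center[0]] + [layer for layer, _, _ in self.neighbors])


@dataclass
class LayerSpec:
    """Value model for one synthetic layer.

    Count layers (``bacteria``, ``virus``): per-sample Dirichlet-multinomial
    with feature base concentrations ``base_concentrations`` (drawn
    log-normally when omitted, giving the skewed abundance profile of real
    amplicon tables) and sequencing ``depth``.  Concentration layers
    (``metabolite``, ``cytokine``): independent normals with per-feature
    ``means``/``sds`` (also log-normal by default, coefficient of variation
    0.6, matching the large relative SDs of plasma panels), truncated at 0.

    ``group_shift`` maps feature id -> cohort -> effect: a concentration
    multiplier for count layers (1 = null), an additive mean offset for
    concentration layers (0 = null).
    """

    layer_id: str
    n_features: int
    depth: int = DEFAULT_DEPTH
    base_concentrations: np.ndarray | None = None
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    group_shift: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer_id not in LAYERS:
            raise ValueError(f"unknown layer id {self.layer_id!r}")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.layer_id in COUNT_LAYERS and self.depth <= 0:
            raise ValueError("depth must be positive")

    @property
    def is_count_layer(self) -> bool:
        return self.layer_id in COUNT_LAYERS

    def feature_ids(self) -> list[str]:
        return [f"{self.layer_id}_{i:03d}" for i in range(self.n_features)]

    def null_shift(self) -> float:
        return 1.0 if self.is_count_layer else 0.0


@dataclass
class CohortSpec:
    """Full recipe for one synthetic dataset."""

    layer_specs: list[LayerSpec]
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    planted_stars: list[PlantedStarSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.group_sizes) - set(COHORTS):
            raise ValueError(f"cohort labels must be among {COHORTS}")
        for label, n in self.group_sizes.items():
            if n < 3:
                raise ValueError(f"cohort {label!r} needs >= 3 samples, got {n}")
        known = {(ls.layer_id, f) for ls in self.layer_specs for f in ls.feature_ids()}
        for star in self.planted_stars:
            for ref in star.loadings():
                if ref not in known:
                    raise ValueError(f"planted star refers to unknown feature {ref}")


def generate_cohort(spec: CohortSpec) -> MultiOmicsDataset:
    """Draw one dataset from a :class:`CohortSpec`; the seed fixes the output."""
    rng = np.random.default_rng(spec.seed)
    sample_ids: list[str] = []
    cohort_of: list[str] = []
    for label in COHORTS:
        if label in spec.group_sizes:
            n = spec.group_sizes[label]
            sample_ids += [f"{label}_{i + 1:02d}" for i in range(n)]
            cohort_of += [label] * n
    n_samples = len(sample_ids)

    # One latent Gaussian factor per planted star, shared by all layers.
    latent = {id(star): rng.normal(0.0, star.latent_sd, size=n_samples)
              for star in spec.planted_stars}

    layers: dict[str, FeatureTable] = {}
    truncation_fraction: dict[str, float] = {}
    for ls in spec.layer_specs:
        feats = ls.feature_ids()
        # per-feature latent loadings for this layer
        load = np.zeros((len(spec.planted_stars), ls.n_features))
        for k, star in enumerate(spec.planted_stars):
            for (layer, feat), loading in star.loadings().items():
                if layer == ls.layer_id:
                    load[k, feats.index(feat)] = loading
        z = np.stack([latent[id(s)] for s in spec.planted_stars]) \
            if spec.planted_stars else np.zeros((0, n_samples))
        latent_effect = load.T @ z  # features x samples

        shift = np.full((ls.n_features, n_samples), ls.null_shift())
        for feat, per_cohort in ls.group_shift.items():
            i = feats.index(feat)
            for j, label in enumerate(cohort_of):
                if label in per_cohort:
                    shift[i, j] = per_cohort[label]

        if ls.is_count_layer:
            base = ls.base_concentrations
            if base is None:
                base = rng.lognormal(mean=0.0, sigma=1.0, size=ls.n_features)
            base = np.asarray(base, dtype=float)
            alpha = base[:, None] * shift * np.exp(latent_effect)
            counts = np.empty((ls.n_features, n_samples), dtype=np.int64)
            for j in range(n_samples):
                p = rng.dirichlet(alpha[:, j])
                counts[:, j] = rng.multinomial(ls.depth, p)
            values = pd.DataFrame(counts, index=feats, columns=sample_ids)
            layers[ls.layer_id] = FeatureTable(ls.layer_id, values, "counts")
        else:
            means = ls.means
            if means is None:
                means = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=ls.n_features)
            means = np.asarray(means, dtype=float)
            sds = np.asarray(0.6 * means if ls.sds is None else ls.sds, dtype=float)
            # the latent factor enters in units of the feature's noise SD so
            # a loading is a comparable effect size across layers and units
            raw = (means[:, None] + shift + latent_effect * sds[:, None]
                   + rng.normal(0.0, 1.0, size=(ls.n_features, n_samples)) * sds[:, None])
            truncated = raw < 0
            truncation_fraction[ls.layer_id] = float(truncated.mean())
            values = pd.DataFrame(np.where(truncated, 0.0, raw),
                                  index=feats, columns=sample_ids)
            layers[ls.layer_id] = FeatureTable(ls.layer_id, values, "concentration")

    truth = {
        "planted_stars": [
            {"center": list(star.center),
             "neighbors": [[l, f, float(w)] for l, f, w in star.neighbors],
             "latent_sd": star.latent_sd}
            for star in spec.planted_stars
        ],
        "shifted_features": {
            ls.layer_id: {
                feat: dict(per_cohort)
                for feat, per_cohort in ls.group_shift.items()
                if any(eff != ls.null_shift() for eff in per_cohort.values())
            }
            for ls in spec.layer_specs
        },
        "truncation_fraction": truncation_fraction,
        "seed": spec.seed,
    }
    metadata = SampleMetadata(pd.Series(cohort_of, index=sample_ids))
    return MultiOmicsDataset(layers=layers, metadata=metadata, truth=truth)


def demo_spec(seed: int = 0, depth: int = DEFAULT_DEPTH,
              star_loading: float = 0.9, count_shift: float = 8.0,
              conc_shift_sd: float = 2.5, latent_sd: float = 1.0,
              group_sizes: dict[str, int] | None = None) -> CohortSpec:
    """A ready-made spec with one shared-disease star and one LC-only star.

    The "common" star (center ``virus_000``) spans all four layers and its
    members are shifted equally in both disease cohorts, so it should
    surface in the all-subjects, Ctrl-LC and Ctrl-HCC analyses.  The
    "LC-only" star (center ``metabolite_001``) has members shifted in the
    LC cohort alone.  Concentration layers use fixed means (100) and SDs
    (20) so ``conc_shift_sd`` is an effect size in within-group SD units;
    count-layer shifts are fold changes of the Dirichlet concentration.
    """
    conc_mean, conc_sd = 100.0, 20.0
    conc_shift = conc_shift_sd * conc_sd

    def count_layer(layer_id: str, n: int, shifted: dict[str, dict[str, float]]):
        # symmetric Dirichlet concentration 5 per feature: overdispersed
        # but not so noisy that an 8-fold shift is invisible at n = 10
        return LayerSpec(layer_id=layer_id, n_features=n, depth=depth,
                         base_concentrations=np.full(n, 5.0), group_shift=shifted)

    def conc_layer(layer_id: str, n: int, shifted: dict[str, dict[str, float]]):
        return LayerSpec(layer_id=layer_id, n_features=n,
                         means=np.full(n, conc_mean), sds=np.full(n, conc_sd),
                         group_shift=shifted)

    layer_specs = [
        count_layer("bacteria", 20, {
            "bacteria_000": {"LC": count_shift, "HCC": count_shift},
            "bacteria_001": {"LC": count_shift},
        }),
        count_layer("virus", 20, {
            "virus_000": {"LC": count_shift, "HCC": count_shift},
            "virus_001": {"LC": count_shift},
        }),
        conc_layer("metabolite", 15, {
            "metabolite_000": {"LC": conc_shift, "HCC": conc_shift},
            "metabolite_001": {"LC": conc_shift},
        }),
        # cytokine_000 is shifted downward, matching its negative loading on
        # the shared latent factor (a marker suppressed in disease)
        conc_layer("cytokine", 12, {
            "cytokine_000": {"LC": -conc_shift, "HCC": -conc_shift},
            "cytokine_001": {"LC": conc_shift},
        }),
    ]
    stars = [
        PlantedStarSpec(
            center=("virus", "virus_000"),
            neighbors=[("bacteria", "bacteria_000", star_loading),
                       ("metabolite", "metabolite_000", star_loading),
                       ("cytokine", "cytokine_000", -star_loading)],
            latent_sd=latent_sd,
        ),
        PlantedStarSpec(
            center=("metabolite", "metabolite_001"),
            neighbors=[("bacteria", "bacteria_001", star_loading),
                       ("virus", "virus_001", star_loading),
                       ("cytokine", "cytokine_001", star_loading)],
            latent_sd=latent_sd,
        ),
    ]
    return CohortSpec(layer_specs=layer_specs,
                      group_sizes=dict(group_sizes or DEFAULT_GROUP_SIZES),
                      planted_stars=stars, seed=seed)


def planted_truth(dataset: MultiOmicsDataset) -> dict:
    """Return the planted-star list and shifted-feature flags for scoring."""
    if dataset.truth is None:
        raise ValueError("dataset carries no truth record (not produced by generate_cohort)")
    return dataset.truth
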