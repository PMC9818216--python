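"""End-to-end orchestration: screen -> correlate -> star networks -> signatures.

``run_all`` executes every stage on a loaded (or simulated) dataset and
writes all results under a parameter-stamped directory: alpha/beta
diversity, per-subset differential screens, candidate correlation networks
and their four-layer stars, the center membership matrix, and the final
signature report, plus a JSON manifest recording parameters, seed and the
config hash.  Stage seeds are spawned from the single user seed via
``numpy.random.SeedSequence`` so any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import comparison, diversity, network, signatures
from .lefse import lefse as lefse_scores, lefse_to_frame
from .tables import (COHORTS, MultiOmicsDataset, load_dataset, to_relative_abundance,
                     prevalence_filter, write_feature_table, write_metadata)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and paths of one pipeline run."""

    layer_paths: dict[str, str] = field(default_factory=dict)
    metadata_path: str = ""
    outdir: str = "gutliver_out"
    seed: int = 0
    alpha_screen: float = 0.05
    alpha_edge: float = 0.05
    r_min: float = 0.0
    dunn_adjust: str = "bh"
    min_mean_rel_abund: float = 1e-4
    min_layers: int = 4
    count_center_layer: bool = True
    log_transform: bool = False
    lefse_alpha: float = 0.05
    lefse_n_boot: int = 30
    lefse_threshold: float = 3.0
    n_perm: int = 999

    def __post_init__(self) -> None:
        for name in ("alpha_screen", "alpha_edge"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:10]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: derived from (seed, stage name)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


def prepare_analysis_dataset(dataset: MultiOmicsDataset,
                             min_mean_rel_abund: float = 1e-4) -> MultiOmicsDataset:
    """Put every layer on its analysis scale.

    Count layers become relative abundances and drop features whose mean
    relative abundance does not exceed the prevalence threshold (0.01% by
    default); concentration layers pass through unchanged.
    """
    layers = {}
    for lid, table in dataset.layers.items():
        if table.semantics == "counts":
            rel = to_relative_abundance(table)
            table = prevalence_filter(rel, min_mean_rel_abund)
            logger.info("layer %s: %d of %d features pass the %.2g abundance filter",
                        lid, table.shape[0], rel.shape[0], min_mean_rel_abund)
        layers[lid] = table
    return MultiOmicsDataset(layers=layers, metadata=dataset.metadata,
                             truth=dataset.truth)


def subset_analysis(analysis: MultiOmicsDataset, subset: str, config: RunConfig
                    ) -> tuple[list, list, list]:
    """Screen, correlate and extract stars within one subject subset."""
    cohorts = network.SUBSETS[subset]
    sub = analysis.subset(analysis.metadata.samples_in(cohorts))
    screen = comparison.screen_features(sub, alpha=config.alpha_screen,
                                        adjust=config.dunn_adjust)
    candidates = network.candidate_set(screen)
    edges = network.build_network(
        sub, candidates, subset=subset, alpha_edge=config.alpha_edge,
        r_min=config.r_min, log_transform=config.log_transform,
    ) if candidates else []
    stars = network.extract_stars(edges, min_layers=config.min_layers,
                                  count_center=config.count_center_layer)
    logger.info("subset %s: %d candidates, %d edges, %d four-layer stars",
                subset, len(candidates), len(edges), len(stars))
    return screen, edges, stars


def run_all(config: RunConfig, dataset: MultiOmicsDataset | None = None) -> Path:
    """Run every stage; returns the parameter-stamped output directory."""
    if dataset is None:
        dataset = load_dataset(config.layer_paths, config.metadata_path)
    outdir = Path(config.outdir) / f"run-{config.config_hash()}"
    outdir.mkdir(parents=True, exist_ok=True)

    # --- diversity on count layers -------------------------------------
    rng = np.random.default_rng(config.stage_seed("permanova"))
    labels = [dataset.metadata.cohorts[s] for s in dataset.sample_ids]
    diversity_report: dict = {}
    for lid, table in dataset.layers.items():
        if table.semantics != "counts":
            continue
        alpha = diversity.alpha_diversity(table)
        alpha.to_csv(outdir / f"alpha_{lid}.tsv", sep="\t", index_label="sample_id")
        rel = to_relative_abundance(table)
        dm = diversity.bray_curtis(rel)
        dm.to_frame().to_csv(outdir / f"braycurtis_{lid}.tsv", sep="\t",
                             index_label="sample_id")
        coords = diversity.pcoa(dm, n_axes=2)
        coords.to_frame().to_csv(outdir / f"pcoa_{lid}.tsv", sep="\t",
                                 index_label="sample_id")
        f_stat, p = diversity.permanova(dm, labels, n_perm=config.n_perm, seed=rng)
        venn = diversity.overlap_counts(table, dataset.metadata)
        diversity_report[lid] = {"permanova_F": f_stat, "permanova_p": p,
                                 "venn": venn.summary()}
    (outdir / "diversity.json").write_text(json.dumps(diversity_report, indent=2))

    # --- per-subset screens, networks, stars ----------------------------
    analysis = prepare_analysis_dataset(dataset, config.min_mean_rel_abund)
    stars_by_subset = {}
    screens = {}
    for subset in network.SUBSETS:
        screen, edges, stars = subset_analysis(analysis, subset, config)
        screens[subset] = screen
        stars_by_subset[subset] = stars
        comparison.screen_to_frame(screen).to_csv(
            outdir / f"screen_{subset}.tsv", sep="\t", index=False)
        network.edges_to_frame(edges, subset).to_csv(
            outdir / f"edges_{subset}.tsv", sep="\t", index=False)
        (outdir / f"stars_{subset}.json").write_text(
            json.dumps(network.stars_to_records(stars), indent=2))

    # --- LDA effect sizes on the abundance layers ------------------------
    lefse_rng = np.random.default_rng(config.stage_seed("lefse"))
    for lid in ("bacteria", "virus"):
        if lid not in analysis.layers:
            continue
        res = lefse_scores(analysis.layers[lid], labels, alpha=config.lefse_alpha,
                           n_boot=config.lefse_n_boot,
                           threshold=config.lefse_threshold, seed=lefse_rng)
        lefse_to_frame(res, config.lefse_threshold).to_csv(
            outdir / f"lefse_{lid}.tsv", sep="\t", index=False)

    # --- signature classification ---------------------------------------
    memberships = signatures.membership_matrix(stars_by_subset)
    means = {
        (lid, feat): {
            c: float(np.mean(
                analysis.layers[lid].values.loc[
                    feat, analysis.metadata.samples_in([c])]))
            for c in COHORTS if c in set(analysis.metadata.cohorts)
        }
        for (lid, feat) in memberships
    }
    calls = signatures.classify_all(memberships, means)
    report = signatures.calls_to_frame(calls, memberships)
    report.to_csv(outdir / "signature_report.tsv", sep="\t", index=False)

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": len(dataset.sample_ids),
        "group_sizes": dataset.metadata.group_sizes(),
        "stage_counts": {
            subset: {"screened": len(screens[subset]),
                     "significant": sum(r.significant for r in screens[subset]),
                     "stars": len(stars_by_subset[subset])}
            for subset in network.SUBSETS
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def write_dataset(dataset: MultiOmicsDataset, outdir: str | Path) -> Path:
    """Write a dataset's layer tables, metadata and truth record as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for lid, table in dataset.layers.items():
        write_feature_table(table, outdir / f"{lid}.tsv")
    write_metadata(dataset.metadata, outdir / "metadata.tsv")
    if dataset.truth is not None:
        (outdir / "truth.json").write_text(json.dumps(dataset.truth, indent=2))
    return outdir
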