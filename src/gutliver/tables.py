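"""Feature tables, sample metadata, and TSV input/output.

The in-memory containers for one omics layer (a features x samples matrix
with value semantics) and for an aligned multi-layer dataset.  All tables
travel as tab-separated UTF-8 text with a '.' decimal point: the header row
holds sample ids and the first column holds feature ids.  Feature ids are
free text (virus species names legitimately contain spaces, colons and
dots); only tabs and newlines are forbidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four omics layers of the study design.
LAYERS = ("bacteria", "virus", "metabolite", "cytokine")

#: Value semantics a FeatureTable can carry.
SEMANTICS = ("counts", "relative_abundance", "concentration")

#: The three cohort labels, in display order.
COHORTS = ("Ctrl", "LC", "HCC")

_FORBIDDEN = ("\t", "\n", "\r")


def _check_ids(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if any(c in i for c in _FORBIDDEN):
            raise ValueError(f"{what} id {i!r} contains a tab or newline")
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class FeatureTable:
    """One omics layer: a nonnegative features x samples matrix.

    Parameters
    ----------
    layer_id:
        One of :data:`LAYERS`.
    values:
        DataFrame with feature ids as the index and sample ids as columns.
    semantics:
        One of :data:`SEMANTICS`.  ``relative_abundance`` columns must each
        sum to 1 (within 1e-6); ``counts`` are nonnegative integers.
    units:
        Free-text unit annotation (e.g. ``pg/mL``); informational only.
    """

    layer_id: str
    values: pd.DataFrame
    semantics: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.layer_id not in LAYERS:
            raise ValueError(f"unknown layer id {self.layer_id!r}; expected one of {LAYERS}")
        if self.semantics not in SEMANTICS:
            raise ValueError(f"unknown semantics {self.semantics!r}; expected one of {SEMANTICS}")
        vals = self.values
        if not isinstance(vals, pd.DataFrame):
            vals = pd.DataFrame(vals)
        vals = vals.copy()
        vals.index = _check_ids(vals.index, "feature")
        vals.columns = _check_ids(vals.columns, "sample")
        arr = vals.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at feature {vals.index[r]!r}, sample {vals.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value {arr[r, c]} at feature {vals.index[r]!r}, "
                f"sample {vals.columns[c]!r}"
            )
        if self.semantics == "counts":
            if not np.allclose(arr, np.round(arr)):
                r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValueError(
                    f"count table has non-integer value {arr[r, c]} at feature "
                    f"{vals.index[r]!r}, sample {vals.columns[c]!r}"
                )
            vals = vals.round().astype(np.int64)
        if self.semantics == "relative_abundance":
            # Filtered subsets of a composition may sum to less than 1, so
            # only the upper bound is a hard invariant here; freshly
            # normalised tables sum to 1 by construction.
            sums = arr.sum(axis=0)
            bad = np.flatnonzero(sums - 1.0 > 1e-6)
            if bad.size:
                raise ValueError(
                    f"relative-abundance column {vals.columns[bad[0]]!r} sums to "
                    f"{sums[bad[0]]:.8g} > 1"
                )
        self.values = vals

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        """Return a copy restricted to ``sample_ids`` (given order kept)."""
        return replace(self, values=self.values.loc[:, list(sample_ids)])


@dataclass
class SampleMetadata:
    """Cohort assignment (and optional covariates) per sample."""

    cohorts: pd.Series  # sample id -> label in COHORTS
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        s = pd.Series(self.cohorts)
        s.index = _check_ids(s.index, "sample")
        bad = set(s.unique()) - set(COHORTS)
        if bad:
            raise ValueError(f"unknown cohort labels {sorted(bad)}; expected {COHORTS}")
        self.cohorts = s.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cohorts.index)

    def samples_in(self, cohort_labels: Iterable[str]) -> list[str]:
        labels = set(cohort_labels)
        return [s for s, c in self.cohorts.items() if c in labels]

    def group_sizes(self) -> dict[str, int]:
        vc = self.cohorts.value_counts()
        return {c: int(vc.get(c, 0)) for c in COHORTS if c in vc.index}


@dataclass
class MultiOmicsDataset:
    """Aligned multi-layer dataset: every layer shares one ordered sample set."""

    layers: dict[str, FeatureTable]
    metadata: SampleMetadata
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ref: list[str] | None = None
        for lid, table in self.layers.items():
            if table.layer_id != lid:
                raise ValueError(f"layer key {lid!r} does not match table layer {table.layer_id!r}")
            if ref is None:
                ref = table.sample_ids
            elif table.sample_ids != ref:
                raise ValueError("layers do not share an identical ordered sample set")
        if ref is not None and ref != self.metadata.sample_ids:
            missing = set(ref) - set(self.metadata.sample_ids)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
            # reorder metadata to the layer order
            self.metadata = SampleMetadata(
                self.metadata.cohorts.loc[ref],
                None if self.metadata.covariates is None else self.metadata.covariates.loc[ref],
            )

    @property
    def sample_ids(self) -> list[str]:
        return next(iter(self.layers.values())).sample_ids

    def subset(self, sample_ids: Iterable[str]) -> "MultiOmicsDataset":
        ids = list(sample_ids)
        return MultiOmicsDataset(
            layers={lid: t.select_samples(ids) for lid, t in self.layers.items()},
            metadata=SampleMetadata(
                self.metadata.cohorts.loc[ids],
                None if self.metadata.covariates is None else self.metadata.covariates.loc[ids],
            ),
            truth=self.truth,
        )


# ---------------------------------------------------------------------------
# TSV input / output
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, layer_id: str, semantics: str,
                       units: str = "") -> FeatureTable:
    """Read a features x samples TSV into a validated :class:`FeatureTable`.

    The first row is the header of sample ids, the first column holds
    feature ids, the body is numeric.  Duplicate ids, negative values,
    non-numeric cells and ragged rows are rejected with row/column context.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        n_cols = len(header)
        feats: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {n_cols})"
                )
            feats.append(parts[0])
            row = []
            for j, cell in enumerate(parts[1:]):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column "
                        f"{sample_ids[j]!r} (feature {parts[0]!r})"
                    ) from None
            rows.append(row)
    values = pd.DataFrame(rows, index=feats, columns=sample_ids, dtype=float)
    return FeatureTable(layer_id=layer_id, values=values, semantics=semantics, units=units)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table as TSV; the full float repr is kept so read/write round-trips."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.values.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata TSV with columns ``sample_id`` and ``cohort``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "cohort" not in df.columns:
        raise ValueError(f"{path}: metadata needs 'sample_id' and 'cohort' columns")
    cov_cols = [c for c in df.columns if c not in ("sample_id", "cohort")]
    cov = df.set_index("sample_id")[cov_cols] if cov_cols else None
    return SampleMetadata(df.set_index("sample_id")["cohort"], cov)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = metadata.cohorts.rename("cohort").to_frame()
    if metadata.covariates is not None:
        df = df.join(metadata.covariates)
    df.to_csv(path, sep="\t", index_label="sample_id")


def load_dataset(layer_paths: Mapping[str, str | Path], metadata_path: str | Path,
                 semantics: Mapping[str, str] | None = None) -> MultiOmicsDataset:
    """Load layers + metadata, aligning all on the intersection of sample sets.

    Samples missing from any layer or from the metadata are dropped with a
    warning listing the ids.
    """
    default_sem = {"bacteria": "counts", "virus": "counts",
                   "metabolite": "concentration", "cytokine": "concentration"}
    semantics = dict(default_sem, **(semantics or {}))
    metadata = read_metadata(metadata_path)
    tables = {
        lid: read_feature_table(p, lid, semantics[lid]) for lid, p in layer_paths.items()
    }
    common = [s for s in metadata.sample_ids
              if all(s in t.sample_ids for t in tables.values())]
    dropped = (set(metadata.sample_ids) | {s for t in tables.values() for s in t.sample_ids}) - set(common)
    if dropped:
        logger.warning("dropping %d samples absent from some layer: %s",
                       len(dropped), sorted(dropped))
    if not common:
        raise ValueError("no samples shared by all layers and the metadata")
    return MultiOmicsDataset(
        layers={lid: t.select_samples(common) for lid, t in tables.items()},
        metadata=SampleMetadata(metadata.cohorts.loc[common],
                                None if metadata.covariates is None
                                else metadata.covariates.loc[common]),
    )


# ---------------------------------------------------------------------------
# Compositional transforms
# ---------------------------------------------------------------------------

def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Divide each sample column by its total, turning counts into proportions."""
    if table.semantics != "counts":
        raise ValueError(f"expected counts, got {table.semantics!r}")
    totals = table.values.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero)}")
    return FeatureTable(
        layer_id=table.layer_id,
        values=table.values / totals,
        semantics="relative_abundance",
        units="",
    )


def prevalence_filter(table: FeatureTable, min_mean_rel_abund: float = 1e-4,
                      metadata: SampleMetadata | None = None) -> FeatureTable:
    """Keep features whose mean relative abundance exceeds the threshold.

    The inequality is strict.  By default the mean is taken across all
    samples; passing ``metadata`` switches to a per-cohort screen that keeps
    a feature if its mean within *any* cohort exceeds the threshold.
    """
    if table.semantics != "relative_abundance":
        raise ValueError("prevalence_filter expects a relative-abundance table")
    if metadata is None:
        keep = table.values.mean(axis=1) > min_mean_rel_abund
    else:
        keep = pd.Series(False, index=table.values.index)
        for cohort in metadata.cohorts.unique():
            cols = metadata.samples_in([cohort])
            keep |= table.values[cols].mean(axis=1) > min_mean_rel_abund
    return replace(table, values=table.values.loc[keep])
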