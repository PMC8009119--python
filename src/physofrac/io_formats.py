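"""Readers, writers and validated containers for the pipeline's file formats.

Canonical on-disk formats are TSV for tables (samples as rows, ASVs as
columns, sample id in the first column) and Newick for the phylogeny.
Fraction and treatment labels are case-sensitive closed vocabularies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .exceptions import DataError, FormatError, SchemaError

logger = logging.getLogger(__name__)

#: Closed vocabulary of physiological fraction labels.
FRACTIONS = ("Whole", "HNA", "LNA", "BONCATpos", "BONCATneg", "PIpos", "Sheath")

#: Sorted (gated) fractions, i.e. everything that passes through the sorter.
SORTED_FRACTIONS = ("HNA", "LNA", "BONCATpos", "BONCATneg", "PIpos")

#: Closed vocabulary of treatment labels. "NA" marks untreated baseline samples.
TREATMENTS = ("Control", "Digoxin", "Nizatidine", "Glucose", "NA")

METADATA_COLUMNS = ("individual", "fraction", "treatment", "replicate")


@dataclass
class CountTable:
    """An ASV count matrix (samples x ASVs) with per-sample metadata.

    counts: integer DataFrame indexed by sample id, columns are ASV ids.
    metadata: DataFrame indexed by sample id with columns
        individual, fraction, treatment, replicate.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        counts, meta = self.counts, self.metadata
        if counts.index.has_duplicates:
            raise SchemaError("duplicate sample ids in count table")
        if counts.columns.has_duplicates:
            raise SchemaError("duplicate ASV ids in count table")
        missing = counts.index.difference(meta.index)
        if len(missing):
            raise SchemaError(f"samples missing from metadata: {list(missing)[:5]}")
        for col in METADATA_COLUMNS:
            if col not in meta.columns:
                raise SchemaError(f"metadata lacks required column {col!r}")
        bad_frac = set(meta.loc[counts.index, "fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise DataError(f"unknown fraction labels: {sorted(bad_frac)}")
        bad_treat = set(meta.loc[counts.index, "treatment"].astype(str)) - set(TREATMENTS)
        if bad_treat:
            raise DataError(f"unknown treatment labels: {sorted(bad_treat)}")
        arr = counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise DataError("counts must be integers")
                self.counts = counts.astype(np.int64)
                arr = self.counts.to_numpy()
            if (arr < 0).any():
                raise DataError("counts must be non-negative")
        # keep metadata aligned and restricted to table samples
        self.metadata = meta.loc[counts.index].copy()
        self.counts.index.name = None
        self.counts.columns.name = None
        self.metadata.index.name = None

    # -- convenience -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def fraction_of(self, sample_id: str) -> str:
        return self.metadata.at[sample_id, "fraction"]

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose metadata matches every given column=value pair."""
        mask = pd.Series(True, index=self.metadata.index)
        for col, val in conditions.items():
            mask &= self.metadata[col] == val
        return list(self.metadata.index[mask])

    def subset_samples(self, sample_ids) -> "CountTable":
        ids = list(sample_ids)
        return CountTable(self.counts.loc[ids].copy(), self.metadata.loc[ids].copy())

    def drop_asvs(self, asv_ids) -> "CountTable":
        keep = [a for a in self.counts.columns if a not in set(asv_ids)]
        return CountTable(self.counts[keep].copy(), self.metadata.copy())

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized proportions; zero-total rows stay all-zero."""
        totals = self.counts.sum(axis=1).to_numpy(dtype=float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts.div(safe, axis=0)

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.metadata.copy())


@dataclass
class CytometryCounts:
    """Per-sample gated event tallies from flow cytometry.

    One row per (sample_id, gate): columns sample_id, individual, treatment,
    replicate, gate, events, total_events.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "gate", "events", "total_events")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise SchemaError(f"cytometry table lacks column {col!r}")
        t = self.table
        if (t["events"] > t["total_events"]).any():
            raise DataError("gate events exceed total events")
        bad = set(t["gate"]) - set(FRACTIONS)
        if bad:
            raise DataError(f"unknown gate labels: {sorted(bad)}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_count_table(path, metadata_path) -> CountTable:
    """Read a samples-x-ASVs TSV and its sample metadata TSV."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0,
                       keep_default_na=False, na_values=[])
    if "replicate" in meta.columns:
        meta["replicate"] = pd.to_numeric(meta["replicate"], errors="coerce").fillna(1).astype(int)
    try:
        return CountTable(counts, meta)
    except (SchemaError, DataError):
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise FormatError(f"could not parse count table: {exc}") from exc


def read_cytometry(path) -> CytometryCounts:
    return CytometryCounts(pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[]))


def read_taxonomy(path) -> pd.DataFrame:
    """Taxonomy TSV: index = ASV id, columns = ranks (domain..genus)."""
    return pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, na_values=[])


def read_newick(path) -> TreeNode:
    """Read a rooted Newick tree, requiring labeled leaves and branch lengths."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"malformed Newick: {exc}") from exc
    return _validate_tree(tree)


def _validate_tree(tree: TreeNode) -> TreeNode:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError(f"branch without length under {node.parent.name or 'root'}")
        if node.length < 0:
            raise FormatError("negative branch length")
        if node.is_tip() and not node.name:
            raise FormatError("unlabeled leaf")
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise FormatError("duplicate leaf labels")
    return tree


def prune_tree_to_table(tree: TreeNode, asv_ids) -> TreeNode:
    """Prune tree leaves that are absent from the count table (warn); error
    if the table has ASVs missing from the tree."""
    leaf_names = {t.name for t in tree.tips()}
    asv_set = set(asv_ids)
    missing = asv_set - leaf_names
    if missing:
        raise SchemaError(f"ASVs absent from tree: {sorted(missing)[:5]}")
    extra = leaf_names - asv_set
    if extra:
        logger.warning("pruning %d tree leaves absent from count table", len(extra))
        tree = tree.shear(sorted(leaf_names & asv_set))
        tree.prune()
    return tree


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_count_table(table: CountTable, counts_path, metadata_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
    table.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def write_results(tables: dict[str, pd.DataFrame], out_dir, run_info: dict | None = None) -> list[str]:
    """Write each result table to <out_dir>/<name>.tsv with 6-significant-digit
    floats, plus run.log echoing configuration and versions."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", float_format="%.6g")
        written.append(str(path))
    if run_info is not None:
        import json
        import time

        import physofrac

        log = dict(run_info)
        log["physofrac_version"] = physofrac.__version__
        log["numpy_version"] = np.__version__
        log["pandas_version"] = pd.__version__
        log["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(out / "run.log", "w") as fh:
            json.dump(log, fh, indent=2, default=str)
        written.append(str(out / "run.log"))
    return written
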