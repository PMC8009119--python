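"""Contaminant removal, abundance filtering, count transform and rarefaction.

The filter chain runs in a fixed order: sheath decontamination, removal of
ASVs without a phylum assignment, prevalence filtering, then removal of
individually named contaminants. Every rule returns a FilterReport that
reconciles read totals exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidArgument
from .io_formats import CountTable

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """What a single filter rule removed."""

    rule: str
    removed_asvs: list[str]
    reads_removed: pd.Series  # per sample
    samples_dropped: list[str] = field(default_factory=list)

    @property
    def n_asvs_removed(self) -> int:
        return len(self.removed_asvs)

    @property
    def total_reads_removed(self) -> int:
        return int(self.reads_removed.sum())


def _report(rule: str, before: CountTable, after_counts: pd.DataFrame,
            removed: list[str], samples_dropped: list[str] | None = None) -> FilterReport:
    reads_before = before.counts.sum(axis=1)
    reads_after = after_counts.sum(axis=1).reindex(reads_before.index, fill_value=0)
    return FilterReport(rule=rule, removed_asvs=list(removed),
                        reads_removed=reads_before - reads_after,
                        samples_dropped=list(samples_dropped or []))


def remove_sheath_contaminants(table: CountTable) -> tuple[CountTable, FilterReport]:
    """Drop ASVs seen in any sheath-fluid control but in no unsorted (Whole)
    sample, then exclude the sheath controls themselves.

    Whole samples of all individuals are pooled: an ASV must be absent from
    every Whole sample to be called a contaminant.
    """
    sheath = table.samples_where(fraction="Sheath")
    whole = table.samples_where(fraction="Whole")
    if not whole:
        raise DataError("decontamination requires at least one Whole sample")
    if not sheath:
        logger.warning("no Sheath samples: decontamination skipped")
        report = FilterReport("sheath_decontamination", [],
                              pd.Series(0, index=table.counts.index))
        return table.copy(), report
    in_sheath = table.counts.loc[sheath].sum(axis=0) > 0
    in_whole = table.counts.loc[whole].sum(axis=0) > 0
    contaminants = list(table.counts.columns[in_sheath & ~in_whole])
    kept_samples = [s for s in table.sample_ids if s not in set(sheath)]
    new_counts = table.counts.drop(columns=contaminants).loc[kept_samples]
    new = CountTable(new_counts, table.metadata.loc[kept_samples].copy())
    report = _report("sheath_decontamination", table, new_counts,
                     contaminants, samples_dropped=sheath)
    return new, report


def drop_unassigned_phylum(table: CountTable, taxonomy: pd.DataFrame) -> tuple[CountTable, FilterReport]:
    """Remove ASVs whose taxonomy lacks a phylum-level assignment.

    An ASV missing from the taxonomy table counts as unassigned.
    """
    phylum = taxonomy["phylum"] if "phylum" in taxonomy.columns else pd.Series(dtype=object)
    removed = []
    for asv in table.counts.columns:
        val = phylum.get(asv, "")
        if val is None or (isinstance(val, float) and np.isnan(val)) or str(val).strip() == "":
            removed.append(asv)
    new_counts = table.counts.drop(columns=removed)
    new = CountTable(new_counts, table.metadata.copy())
    return new, _report("unassigned_phylum", table, new_counts, removed)


def prevalence_filter(table: CountTable, min_reads: int = 6,
                      min_samples: int = 2) -> tuple[CountTable, FilterReport]:
    """Keep an ASV iff it has >= min_reads in each of >= min_samples samples."""
    if min_reads < 1 or min_samples < 1:
        raise InvalidArgument("thresholds must be >= 1")
    hits = (table.counts >= min_reads).sum(axis=0)
    removed = list(table.counts.columns[hits < min_samples])
    new_counts = table.counts.drop(columns=removed)
    new = CountTable(new_counts, table.metadata.copy())
    return new, _report(f"prevalence(min_reads={min_reads},min_samples={min_samples})",
                        table, new_counts, removed)


def remove_named_taxa(table: CountTable, asv_ids) -> tuple[CountTable, FilterReport]:
    """Drop an explicit list of contaminant ASVs; unknown ids are warned about."""
    present, missing = [], []
    cols = set(table.counts.columns)
    for asv in asv_ids:
        (present if asv in cols else missing).append(asv)
    if missing:
        logger.warning("named taxa not in table, skipped: %s", missing)
    new_counts = table.counts.drop(columns=present)
    new = CountTable(new_counts, table.metadata.copy())
    return new, _report("named_taxa", table, new_counts, present)


def apply_filters(table: CountTable, taxonomy: pd.DataFrame | None = None,
                  min_reads: int = 6, min_samples: int = 2,
                  named_taxa=(), decontaminate: bool = True
                  ) -> tuple[CountTable, list[FilterReport]]:
    """Run the full filter chain in its fixed order."""
    reports = []
    if decontaminate:
        table, rep = remove_sheath_contaminants(table)
        reports.append(rep)
    if taxonomy is not None:
        table, rep = drop_unassigned_phylum(table, taxonomy)
        reports.append(rep)
    table, rep = prevalence_filter(table, min_reads=min_reads, min_samples=min_samples)
    reports.append(rep)
    if named_taxa:
        table, rep = remove_named_taxa(table, named_taxa)
        reports.append(rep)
    return table, reports


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over ASVs with nonzero geometric mean of count_ij / geomean_i.
    Falls back to library size / mean library size when no ASV is nonzero in
    every sample.
    """
    X = counts.to_numpy(dtype=float).T  # ASVs x samples
    all_nonzero = (X > 0).all(axis=1)
    if not all_nonzero.any():
        logger.warning("no ASV nonzero in all samples: library-size size factors")
        lib = counts.sum(axis=1).astype(float)
        if lib.mean() == 0:
            raise InvalidArgument("all-empty count table")
        return lib / lib.mean()
    logs = np.log(X[all_nonzero])
    geomean_log = logs.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logs - geomean_log, axis=0))
    return pd.Series(s, index=counts.index)


def vst_transform(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing transform: log2(count_ij / s_j + 1) with
    median-of-ratios size factors s_j."""
    counts = table.counts if isinstance(table, CountTable) else table
    if counts.shape[0] < 2:
        raise InvalidArgument("VST needs at least two samples")
    s = size_factors(counts)
    return np.log2(counts.div(s, axis=0) + 1.0)


def rarefy(table: CountTable, depth: int = 10534, seed: int | None = None) -> CountTable:
    """Subsample each sample without replacement to exactly `depth` reads.

    Samples with fewer than `depth` total reads are dropped with a warning.
    """
    if depth < 1:
        raise InvalidArgument("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = list(totals.index[totals >= depth])
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning("dropping %d samples below rarefaction depth %d: %s",
                       len(dropped), depth, dropped[:5])
    if not keep:
        raise DataError(f"all samples below rarefaction depth {depth}")
    rows = []
    for s in keep:
        vec = table.counts.loc[s].to_numpy(dtype=np.int64)
        if vec.sum() == depth:
            rows.append(vec)
        else:
            rows.append(rng.multivariate_hypergeometric(vec, depth))
    new_counts = pd.DataFrame(np.vstack(rows), index=keep, columns=table.counts.columns)
    return CountTable(new_counts, table.metadata.loc[keep].copy())
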