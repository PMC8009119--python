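"""Fraction-proportion statistics and core/unique/shared taxon partitioning.

A "fraction proportion" is the percent of total quantified cells falling in
one physiological gate (HNA, LNA, BONCAT+, PI+) for one sample. Core taxa
are ASVs present in all sampled individuals, unique taxa in exactly one, and
shared taxa the remainder; the threshold for "core" can be relaxed (e.g.
8 of 10 individuals).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as pf_stats
from .exceptions import InvalidArgument, InvalidDesign
from .io_formats import CountTable, CytometryCounts

PROPORTION_GATES = ("HNA", "LNA", "BONCATpos", "PIpos")


def fraction_proportions(cytometry: CytometryCounts | pd.DataFrame) -> pd.DataFrame:
    """Percent of quantified cells per gate and sample.

    HNA and LNA are the two modes of the same SYBR-stained acquisition, so
    their percentages are computed from their joint event count and sum to
    100 exactly. BONCAT+ and PI+ are separate stains scored against their own
    acquisition totals.
    """
    t = cytometry.table if isinstance(cytometry, CytometryCounts) else cytometry
    if (pd.to_numeric(t["total_events"]) <= 0).any():
        raise InvalidArgument("zero total events in cytometry table")
    rows = {}
    carry_cols = [c for c in ("individual", "treatment", "replicate") if c in t.columns]
    for sample_id, grp in t.groupby("sample_id", sort=True):
        events = dict(zip(grp["gate"], grp["events"].astype(float)))
        row = {}
        if "HNA" in events or "LNA" in events:
            hna = events.get("HNA", 0.0)
            lna = events.get("LNA", 0.0)
            if hna + lna <= 0:
                raise InvalidArgument(f"sample {sample_id}: SYBR gates empty")
            row["HNA"] = 100.0 * hna / (hna + lna)
            row["LNA"] = 100.0 - row["HNA"]
        for gate in ("BONCATpos", "PIpos"):
            sub = grp[grp["gate"] == gate]
            if len(sub):
                row[gate] = 100.0 * float(sub["events"].iloc[0]) / float(sub["total_events"].iloc[0])
        for c in carry_cols:
            row[c] = grp[c].iloc[0]
        rows[sample_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def proportion_correlations(props: pd.DataFrame,
                            pairs=(("HNA", "PIpos"), ("HNA", "BONCATpos"))) -> pd.DataFrame:
    """Pearson correlation (r, p) between fraction proportions across samples."""
    if len(props) < 3:
        raise InvalidArgument("need at least 3 samples for correlation")
    rows = []
    for a, b in pairs:
        r, p = pf_stats.pearson_test(props[a].to_numpy(), props[b].to_numpy())
        rows.append({"x": a, "y": b, "r": r, "p": p, "n": len(props)})
    return pd.DataFrame(rows)


@dataclass
class CorePartition:
    """Partition of the ASV universe by prevalence across individuals."""

    threshold: int
    n_individuals: int
    core: list[str]
    unique: list[str]
    shared: list[str]
    prevalence: pd.Series  # ASV -> number of individuals with presence

    @property
    def n_total(self) -> int:
        return len(self.core) + len(self.unique) + len(self.shared)

    def percentages(self) -> dict[str, float]:
        """Category percentages of total ASVs, one decimal, round-half-even."""
        tot = self.n_total
        return {cat: round(100.0 * len(getattr(self, cat)) / tot, 1)
                for cat in ("core", "unique", "shared")}

    def category_of(self) -> pd.Series:
        cat = pd.Series("shared", index=self.prevalence.index)
        cat.loc[self.core] = "core"
        cat.loc[self.unique] = "unique"
        return cat

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"category": self.category_of(),
                             "n_individuals_present": self.prevalence})


def partition_core(table: CountTable, threshold: int | None = None,
                   pool_all_samples: bool = False) -> CorePartition:
    """Classify every ASV as core / unique / shared by per-individual presence.

    Presence defaults to >= 1 read in the individual's Whole (unsorted)
    sample; pool_all_samples=True instead pools presence over all of an
    individual's samples. threshold defaults to "all individuals".
    """
    if pool_all_samples:
        samples = [s for s in table.sample_ids if table.fraction_of(s) != "Sheath"]
    else:
        samples = table.samples_where(fraction="Whole")
    if not samples:
        raise InvalidDesign("no Whole samples available for core calling")
    meta = table.metadata.loc[samples]
    individuals = sorted(meta["individual"].unique())
    n_ind = len(individuals)
    if threshold is None:
        threshold = n_ind
    if threshold < 2:
        raise InvalidArgument("threshold must be >= 2")
    if threshold > n_ind:
        raise InvalidArgument(f"threshold {threshold} exceeds {n_ind} individuals")
    presence = pd.DataFrame(0, index=individuals, columns=table.counts.columns, dtype=bool)
    for ind in individuals:
        ids = list(meta.index[meta["individual"] == ind])
        presence.loc[ind] = (table.counts.loc[ids].sum(axis=0) > 0).to_numpy()
    prevalence = presence.sum(axis=0)
    core = list(prevalence.index[prevalence >= threshold])
    unique = list(prevalence.index[prevalence == 1])
    shared = [a for a in prevalence.index if a not in set(core) and a not in set(unique)]
    return CorePartition(threshold=threshold, n_individuals=n_ind, core=core,
                         unique=unique, shared=shared, prevalence=prevalence)


def category_counts(table: CountTable, partition: CorePartition) -> pd.DataFrame:
    """Per-sample summed reads over the core / unique / shared ASV sets."""
    out = pd.DataFrame(index=table.counts.index)
    for cat in ("core", "unique", "shared"):
        ids = [a for a in getattr(partition, cat) if a in table.counts.columns]
        out[cat] = table.counts[ids].sum(axis=1) if ids else 0
    out["total"] = table.counts.sum(axis=1)
    return out


def fraction_core_enrichment(table: CountTable, partition: CorePartition,
                             reference: str = "Whole") -> pd.DataFrame:
    """Beta-binomial tests of core-set and unique-set read proportions in each
    sorted fraction against the reference (Whole) community."""
    cats = category_counts(table, partition)
    meta = table.metadata
    fractions = [f for f in meta["fraction"].unique() if f not in (reference, "Sheath")]
    ref_ids = table.samples_where(fraction=reference)
    if not ref_ids:
        raise InvalidDesign(f"no {reference} samples")
    rows = []
    for frac in fractions:
        ids = table.samples_where(fraction=frac)
        for cat in ("core", "unique"):
            sel = ref_ids + ids
            y = cats.loc[sel, cat].to_numpy()
            n = cats.loc[sel, "total"].to_numpy()
            labels = np.array([reference] * len(ref_ids) + [frac] * len(ids))
            if y.sum() == 0:
                rows.append({"fraction": frac, "category": cat, "p_abundance": np.nan,
                             "p_dispersion": np.nan, "direction": np.nan})
                continue
            res = pf_stats.fit_betabinom_test(y, n, labels, taxon=f"{frac}:{cat}")
            direction = res.mu.get(frac, np.nan) - res.mu.get(reference, np.nan) \
                if res.converged else np.nan
            rows.append({"fraction": frac, "category": cat,
                         "mu_fraction": res.mu.get(frac), "mu_reference": res.mu.get(reference),
                         "p_abundance": res.p_abundance, "p_dispersion": res.p_dispersion,
                         "direction": direction})
    out = pd.DataFrame(rows)
    for col in ("p_abundance", "p_dispersion"):
        out["q" + col[1:]] = pf_stats.bh_adjust(out[col].to_numpy())
    return out


def interindividual_distance_groups(dm, metadata: pd.DataFrame,
                                    fractions=None) -> dict[str, np.ndarray]:
    """Between-individual distances within each fraction.

    For fraction f with one sample per individual, returns the I(I-1)/2
    pairwise distances between distinct individuals' f-samples.
    """
    import itertools
    import logging

    logger = logging.getLogger(__name__)
    ids = list(dm.ids)
    meta = metadata.loc[[i for i in ids if i in metadata.index]]
    if fractions is None:
        fractions = [f for f in meta["fraction"].unique() if f != "Sheath"]
    out = {}
    for frac in fractions:
        sub = meta[meta["fraction"] == frac]
        by_ind = {}
        for sid, row in sub.iterrows():
            if row["individual"] in by_ind:
                raise InvalidDesign(f"multiple {frac} samples for individual {row['individual']}")
            by_ind[row["individual"]] = sid
        inds = sorted(by_ind)
        dists = []
        for a, b in itertools.combinations(inds, 2):
            dists.append(dm[by_ind[a], by_ind[b]])
        if len(inds) < len(meta["individual"].unique()):
            logger.warning("fraction %s missing samples for some individuals", frac)
        out[frac] = np.asarray(dists)
    return out
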