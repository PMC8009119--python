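"""End-to-end orchestration: simulate/load -> filter -> diversity -> stats.

run_full performs the baseline-cohort analysis (decontamination, filtering,
fraction proportions and correlations, VST, beta diversity, PCoA, PERMANOVA,
per-taxon beta-binomial tests, core partitioning and enrichment,
inter-individual distance comparisons, rarefied alpha diversity).
run_xenobiotic performs the per-individual treatment analysis (PCoA,
single-term and nested PERMANOVA, proportion ANOVAs against control).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diversity, fractions, preprocess, simdata
from . import stats as pf_stats
from .exceptions import InvalidArgument
from .io_formats import (
    CountTable,
    CytometryCounts,
    prune_tree_to_table,
    read_count_table,
    read_cytometry,
    read_newick,
    read_taxonomy,
    write_results,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    sim_config: simdata.SimConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    taxonomy_path: str | None = None
    cytometry_path: str | None = None
    metric: str = "weighted_unifrac"
    normalized: bool = False
    n_perm: int = 999
    rarefy_depth: int | None = 10534
    min_reads: int = 6
    min_samples: int = 2
    named_taxa: tuple = ()
    decontaminate: bool = True
    betabinom_tests: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        have_paths = self.counts_path is not None
        if self.sim_config is None and not have_paths:
            raise InvalidArgument("provide either sim_config or input paths")
        if self.sim_config is not None and have_paths:
            raise InvalidArgument("provide sim_config or input paths, not both")


def _load_inputs(config: RunConfig):
    if config.sim_config is not None:
        bundle = simdata.simulate_cohort(config.sim_config)
        return bundle.counts, bundle.taxonomy, bundle.tree, bundle.cytometry
    table = read_count_table(config.counts_path, config.metadata_path)
    taxonomy = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    tree = read_newick(config.tree_path) if config.tree_path else None
    cyto = read_cytometry(config.cytometry_path) if config.cytometry_path else None
    return table, taxonomy, tree, cyto


def run_full(config: RunConfig) -> dict:
    """Execute the baseline analysis; returns a dict of result tables.

    Writes TSVs, summary.md and run.log when config.out_dir is set.
    """
    rng = np.random.default_rng(config.seed)
    table, taxonomy, tree, cytometry = _load_inputs(config)
    results: dict = {}

    # ---- filtering ------------------------------------------------------
    filtered, reports = preprocess.apply_filters(
        table, taxonomy=taxonomy, min_reads=config.min_reads,
        min_samples=config.min_samples, named_taxa=config.named_taxa,
        decontaminate=config.decontaminate)
    results["filter_report"] = pd.DataFrame(
        [{"rule": r.rule, "n_asvs_removed": r.n_asvs_removed,
          "reads_removed": r.total_reads_removed,
          "samples_dropped": ",".join(r.samples_dropped)} for r in reports])

    # ---- fraction proportions ------------------------------------------
    if cytometry is not None:
        props = fractions.fraction_proportions(cytometry)
        results["proportions"] = props
        if len(props) >= 3:
            results["correlations"] = fractions.proportion_correlations(props)

    # ---- transforms and distances --------------------------------------
    results["vst"] = preprocess.vst_transform(filtered)
    rel = filtered.relative_abundance()
    if tree is not None:
        tree = prune_tree_to_table(tree.copy(), filtered.asv_ids)
    dm = diversity.distance_matrix(rel, config.metric, tree=tree,
                                   normalized=config.normalized)
    results["distances"] = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    pcoa_res = diversity.pcoa(dm)
    results["pcoa"] = pcoa_res.coordinates
    results["eigenvalues"] = pd.DataFrame(
        {"eigenvalue": pcoa_res.eigenvalues})

    # ---- PERMANOVA ------------------------------------------------------
    meta = filtered.metadata
    perm_rows = []
    for term, labels in (("individual", meta["individual"]),
                         ("physiology", meta["fraction"])):
        if labels.nunique() >= 2:
            res = pf_stats.permanova(dm, labels.to_numpy(), n_perm=config.n_perm,
                                     seed=int(rng.integers(2 ** 31)), term=term)
            row = res.table.loc[term]
            perm_rows.append({"term": term, "df": row["df"], "SS": row["SS"],
                              "R2": row["R2"], "F": row["F"], "p": row["p"]})
    results["permanova"] = pd.DataFrame(perm_rows)
    if meta["fraction"].nunique() >= 2:
        results["pairwise_permanova"] = pf_stats.pairwise_permanova(
            dm, meta["fraction"].to_numpy(), n_perm=config.n_perm,
            seed=int(rng.integers(2 ** 31)))

    # ---- per-taxon beta-binomial tests (fraction vs Whole) --------------
    if config.betabinom_tests and meta["fraction"].nunique() >= 2:
        results["taxa_tests"] = pf_stats.betabinom_test_table(
            filtered.counts, meta["fraction"].to_numpy())

    # ---- core partition and enrichment ----------------------------------
    partition = fractions.partition_core(filtered)
    results["core_partition"] = partition.to_frame()
    results["core_summary"] = pd.DataFrame([{
        "threshold": partition.threshold, "n_total": partition.n_total,
        "n_core": len(partition.core), "n_unique": len(partition.unique),
        "n_shared": len(partition.shared), **{
            f"pct_{k}": v for k, v in partition.percentages().items()}}])
    results["core_enrichment"] = fractions.fraction_core_enrichment(filtered, partition)

    # ---- inter-individual distances -------------------------------------
    groups = fractions.interindividual_distance_groups(dm, meta)
    labels = list(groups)
    if len(labels) >= 2:
        H, p = pf_stats.kruskal_wallis([groups[k] for k in labels])
        results["distance_groups"] = pd.DataFrame(
            [{"fraction": k, "mean_distance": groups[k].mean(),
              "n_pairs": groups[k].size} for k in labels])
        results["distance_groups"].attrs["kruskal_H"] = H
        results["distance_groups"].attrs["kruskal_p"] = p
        results["distance_posthoc"] = pf_stats.dunn_posthoc(
            [groups[k] for k in labels], labels=labels)

    # ---- alpha diversity -------------------------------------------------
    depth = config.rarefy_depth
    totals = filtered.counts.sum(axis=1)
    if depth is None or depth > totals.max():
        depth = int(totals.min())
    results["alpha"] = diversity.alpha_diversity(filtered, rarefy_depth=depth,
                                                 seed=int(rng.integers(2 ** 31)))

    if config.out_dir:
        _write(results, config)
    return results


def table1_models(dm, physiology, treatment, n_perm: int = 999,
                  seed: int | None = None) -> pd.DataFrame:
    """Three single-term PERMANOVA models: physiology, treatment, and
    treatment-within-physiology (the combination factor), each fit alone.

    R-squared values of separate models can exceed 1 in sum; this mirrors the
    convention of reporting each model's own R-squared.
    """
    physiology = np.asarray(physiology)
    treatment = np.asarray(treatment)
    combo = np.array([f"{p}\x1f{t}" for p, t in zip(physiology, treatment)])
    rng = np.random.default_rng(seed)
    rows = []
    for name, labels in (("Physiology", physiology), ("Treatment", treatment),
                         ("Treatment %in% Physiology", combo)):
        res = pf_stats.permanova(dm, labels, n_perm=n_perm,
                                 seed=int(rng.integers(2 ** 31)), term="group")
        row = res.table.loc["group"]
        rows.append({"term": name, "df": row["df"], "R2": row["R2"],
                     "F": row["F"], "p": row["p"]})
    return pd.DataFrame(rows)


def run_xenobiotic(config: RunConfig, bundle=None) -> dict:
    """Per-individual xenobiotic analysis on a treatment experiment.

    bundle: optional (CountTable, CytometryCounts, truth) triple as returned
    by simdata.simulate_treatments; simulated from config.sim_config otherwise.
    """
    rng = np.random.default_rng(config.seed)
    if bundle is None:
        if config.sim_config is None:
            raise InvalidArgument("run_xenobiotic needs sim_config or a bundle")
        cohort = simdata.Cohort.make(config.sim_config)
        table, cytometry, truth = simdata.simulate_treatments(
            cohort, config.sim_config, seed=int(rng.integers(2 ** 31)))
        tree, taxonomy = cohort.tree, pd.concat(
            [cohort.taxonomy, simdata.contaminant_taxonomy(config.sim_config)])
    else:
        table, cytometry, truth = bundle
        tree = taxonomy = None
        if config.sim_config is not None:
            cohort = simdata.Cohort.make(config.sim_config)
            tree, taxonomy = cohort.tree, pd.concat(
                [cohort.taxonomy, simdata.contaminant_taxonomy(config.sim_config)])

    filtered, _ = preprocess.apply_filters(
        table, taxonomy=taxonomy, min_reads=config.min_reads,
        min_samples=config.min_samples, decontaminate=config.decontaminate)
    results: dict = {}
    props = fractions.fraction_proportions(cytometry)
    results["proportions"] = props

    table1_frames, anova_frames = [], []
    for ind in sorted(filtered.metadata["individual"].unique()):
        ids = filtered.samples_where(individual=ind)
        sub = filtered.subset_samples(ids)
        rel = sub.relative_abundance()
        sub_tree = prune_tree_to_table(tree.copy(), sub.asv_ids) if tree is not None else None
        metric = config.metric if sub_tree is not None else "bray_curtis"
        dm = diversity.distance_matrix(rel, metric, tree=sub_tree,
                                       normalized=config.normalized)
        t1 = table1_models(dm, sub.metadata["fraction"].to_numpy(),
                           sub.metadata["treatment"].to_numpy(),
                           n_perm=config.n_perm, seed=int(rng.integers(2 ** 31)))
        t1.insert(0, "individual", ind)
        table1_frames.append(t1)
        nested = pf_stats.nested_permanova(
            dm, sub.metadata["fraction"].to_numpy(), sub.metadata["treatment"].to_numpy(),
            n_perm=config.n_perm, seed=int(rng.integers(2 ** 31)),
            outer_name="Physiology", inner_name="Treatment")
        nested_tbl = nested.table.reset_index()
        nested_tbl.insert(0, "individual", ind)
        results.setdefault("nested_permanova", []).append(nested_tbl)

        sub_props = props[props["individual"] == ind]
        for frac in ("HNA", "LNA", "BONCATpos", "PIpos"):
            if frac not in sub_props.columns:
                continue
            res = pf_stats.anova_vs_control(
                sub_props[frac].to_numpy(), sub_props["treatment"].to_numpy())
            res.insert(0, "individual", ind)
            res.insert(1, "fraction", frac)
            anova_frames.append(res)

    results["table1"] = pd.concat(table1_frames, ignore_index=True)
    results["nested_permanova"] = pd.concat(results["nested_permanova"], ignore_index=True)
    anova = pd.concat(anova_frames, ignore_index=True)
    anova["q"] = anova.groupby(["individual", "fraction"])["p"].transform(
        lambda p: pf_stats.bh_adjust(p.to_numpy()))
    results["proportion_anova"] = anova
    results["treatment_truth"] = truth

    if config.out_dir:
        _write(results, config)
    return results


def _write(results: dict, config: RunConfig) -> None:
    tables = {k: v for k, v in results.items() if isinstance(v, pd.DataFrame)}
    info = {"seed": config.seed, "metric": config.metric, "n_perm": config.n_perm,
            "rarefy_depth": config.rarefy_depth,
            "simulated": config.sim_config is not None}
    write_results(tables, config.out_dir, run_info=info)
    lines = ["# physofrac run summary", ""]
    for name, df in tables.items():
        lines.append(f"## {name}")
        lines.append(f"rows: {len(df)}")
        lines.append("")
    import pathlib

    (pathlib.Path(config.out_dir) / "summary.md").write_text("\n".join(lines))
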