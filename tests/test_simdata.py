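"""Synthetic cohort generator: structure, moments, calibration, conservation."""
import io as _io

import numpy as np
import pandas as pd
import pytest
from scipy import special

from physofrac import simdata
from physofrac.exceptions import (
    DegenerateFraction,
    InvalidArgument,
    UnreachableTarget,
)


class TestSimConfig:
    def test_defaults_valid(self):
        cfg = simdata.SimConfig()
        assert cfg.n_taxa == 838 and cfg.sort_events == 180_000

    @pytest.mark.parametrize("kwargs", [
        dict(core_count=500, unique_count=500),          # exceeds n_taxa
        dict(relaxed_core_count=5),                      # below core_count
        dict(sheath_read_range=(10, 5)),
        dict(seq_depth=0),
        dict(gate_error={"HNA": 1.5}),
        dict(calibration="other"),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidArgument):
            simdata.SimConfig(**kwargs)

    def test_non_psd_correlation_rejected(self):
        corr = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(InvalidArgument):
            simdata.SimConfig(fraction_corr=corr)


class TestSimulateTree:
    def test_smallest_tree(self):
        tree = simdata.simulate_tree(2, seed=1)
        tips = list(tree.tips())
        assert len(tips) == 2
        assert all(t.length > 0 for t in tips)

    def test_leaf_and_split_counts(self):
        tree = simdata.simulate_tree(838, seed=7)
        tips = [t for t in tree.traverse(include_self=True) if t.is_tip()]
        internal = [t for t in tree.traverse(include_self=True) if not t.is_tip()]
        assert len(tips) == 838
        assert len(internal) == 837  # binary tree identity

    def test_seeded_determinism_byte_identical(self):
        a, b = _io.StringIO(), _io.StringIO()
        simdata.simulate_tree(50, seed=3).write(a)
        simdata.simulate_tree(50, seed=3).write(b)
        assert a.getvalue() == b.getvalue()

    def test_rejects_single_taxon(self):
        with pytest.raises(InvalidArgument):
            simdata.simulate_tree(1, seed=0)

    def test_phyla_are_monophyletic(self):
        tree = simdata.simulate_tree(100, seed=5)
        tax = simdata.taxonomy_from_tree(tree)
        for phylum, members in tax.groupby("phylum").groups.items():
            if len(members) < 2:
                continue
            lca = tree.lca(list(members))
            assert {t.name for t in lca.tips()} >= set(members)


class TestSimulateAbundances:
    def test_prevalence_structure_exact(self):
        cfg = simdata.SimConfig(seed=4)
        ab = simdata.simulate_abundances(cfg, seed=4)
        prev = (ab > 0).sum(axis=0)
        assert (prev == 10).sum() == cfg.core_count
        assert (prev == 1).sum() == cfg.unique_count
        assert (prev >= 8).sum() == cfg.relaxed_core_count
        rest = prev[(prev > 1) & (prev < 8)]
        assert len(rest) == cfg.n_taxa - cfg.relaxed_core_count - cfg.unique_count

    def test_rows_sum_to_one(self):
        ab = simdata.simulate_abundances(simdata.SimConfig.small(seed=2), seed=2)
        assert np.allclose(ab.sum(axis=1), 1.0, atol=1e-9)

    def test_all_core_all_present(self):
        cfg = simdata.SimConfig.small(n_taxa=20, core_count=20, unique_count=0,
                                      relaxed_core_count=20, seed=0)
        ab = simdata.simulate_abundances(cfg, seed=0)
        assert ((ab > 0).sum(axis=0) == cfg.n_individuals).all()

    def test_presence_fixture_preserves_structure(self):
        cfg = simdata.SimConfig(seed=9)
        table = simdata.presence_fixture_table(cfg, seed=9)
        prev = (table.counts > 0).sum(axis=0)
        assert (prev == 10).sum() == cfg.core_count
        assert (prev == 1).sum() == cfg.unique_count


class TestFractionProportions:
    def test_zero_sds_give_exact_means(self):
        cfg = simdata.SimConfig(fraction_sds={"HNA": 0.0, "BONCATpos": 0.0, "PIpos": 0.0})
        props = simdata.draw_fraction_proportions(cfg, seed=1, n=5)
        assert np.allclose(props["HNA"], 51.73)
        assert np.allclose(props["BONCATpos"], 49.01)
        assert np.allclose(props["LNA"], 100 - 51.73)

    def test_lna_complements_hna(self):
        props = simdata.draw_fraction_proportions(simdata.SimConfig(), seed=2, n=50)
        assert np.allclose(props["HNA"] + props["LNA"], 100.0, atol=1e-9)

    def test_all_within_bounds(self):
        props = simdata.draw_fraction_proportions(simdata.SimConfig(), seed=3, n=2000)
        vals = props[["HNA", "LNA", "BONCATpos", "PIpos"]].to_numpy()
        assert (vals >= 0).all() and (vals <= 100).all()

    def test_moment_recovery_large_cohort(self):
        """Monte-Carlo check: configured means/sds/correlations recovered."""
        cfg = simdata.SimConfig()
        props = simdata.draw_fraction_proportions(cfg, seed=42, n=10000)
        for frac in ("HNA", "BONCATpos", "PIpos"):
            assert props[frac].mean() == pytest.approx(cfg.fraction_means[frac], abs=0.5)
            assert props[frac].std(ddof=1) == pytest.approx(cfg.fraction_sds[frac], abs=0.5)
        r_hp = np.corrcoef(props["HNA"], props["PIpos"])[0, 1]
        r_hb = np.corrcoef(props["HNA"], props["BONCATpos"])[0, 1]
        assert r_hp == pytest.approx(0.74, abs=0.05)
        assert r_hb == pytest.approx(-0.62, abs=0.05)

    def test_seeded_determinism(self):
        cfg = simdata.SimConfig()
        a = simdata.draw_fraction_proportions(cfg, seed=8, n=20)
        b = simdata.draw_fraction_proportions(cfg, seed=8, n=20)
        pd.testing.assert_frame_equal(a, b)


class TestCalibration:
    def test_logit_identity_when_target_equals_baseline(self):
        a = np.full(10, 0.1)
        theta = np.full(10, 0.3)
        delta = simdata.calibrate_propensities(a, theta, 30.0)
        assert delta == pytest.approx(0.0, abs=1e-8)

    def test_logit_closed_form_under_equal_propensities(self):
        a = np.array([0.2, 0.3, 0.5])
        theta = np.full(3, 0.4)
        for pi in (10.0, 50.0, 90.0):
            delta = simdata.calibrate_propensities(a, theta, pi)
            expected = special.logit(pi / 100) - special.logit(0.4)
            assert delta == pytest.approx(expected, abs=1e-8)

    def test_logit_residual_below_tolerance(self):
        rng = np.random.default_rng(1)
        a = rng.dirichlet(np.ones(50))
        theta = rng.uniform(0.05, 0.95, 50)
        delta = simdata.calibrate_propensities(a, theta, 50.0)
        agg = float(a @ special.expit(special.logit(theta) + delta))
        assert agg == pytest.approx(0.5, abs=1e-8)

    def test_scale_residual_below_tolerance(self):
        rng = np.random.default_rng(2)
        a = rng.dirichlet(np.ones(50))
        theta = rng.uniform(0.05, 0.95, 50)
        c = simdata.calibrate_activity_scale(a, theta, 50.0)
        agg = float(a @ np.minimum(1.0, c * theta))
        assert agg == pytest.approx(0.5, abs=1e-8)

    def test_unreachable_targets_rejected(self):
        a = np.array([0.5, 0.5])
        theta = np.array([0.3, 0.4])
        with pytest.raises(UnreachableTarget):
            simdata.calibrate_propensities(a, theta, 100.0)
        with pytest.raises(UnreachableTarget):
            simdata.calibrate_activity_scale(a, theta, 0.0)

    def test_cohort_aggregate_membership_matches_pi(self, small_bundle):
        """Calibration correctness across every individual x fraction."""
        cohort = small_bundle.cohort
        for ind in cohort.individuals:
            a = cohort.abundance.loc[ind].to_numpy()
            for frac in simdata.BASE_FRACTIONS:
                theta = cohort.calibrated_theta(ind, frac)
                target = cohort.proportions.at[ind, frac] / 100.0
                assert float(a @ theta) == pytest.approx(target, abs=1e-8)


class TestSorting:
    def test_zero_gate_error_perfect_purity(self, small_config):
        cohort = simdata.Cohort.make(small_config)
        cfg = simdata.SimConfig.small(seed=11)
        cfg.gate_error = {g: 0.0 for g in ("HNA", "LNA", "BONCATpos", "BONCATneg", "PIpos")}
        pool = simdata.simulate_sorting(cohort, cfg, seed=1,
                                        individuals=cohort.individuals[:2])
        for rec in pool.records.values():
            assert rec.purity == 1.0

    def test_tallies_conserve_sort_events(self, small_bundle, small_config):
        pool = simdata.simulate_sorting(small_bundle.cohort, small_config, seed=2,
                                        individuals=["I01"])
        for rec in pool.records.values():
            assert rec.tallies.sum() == small_config.sort_events
            assert rec.n_in + rec.n_leak == small_config.sort_events

    def test_boncat_purity_near_configured(self, small_bundle):
        """180,000 events at gate error 0.20 give re-acquired purity 0.80 +/- 0.01."""
        cfg = simdata.SimConfig(seed=11)
        pool = simdata.simulate_sorting(small_bundle.cohort, cfg, seed=42,
                                        gates=("BONCATpos",), individuals=["I01"])
        assert pool.purity("I01", "BONCATpos") == pytest.approx(0.80, abs=0.01)

    def test_degenerate_gate_rejected(self, small_config):
        cohort = simdata.Cohort.make(small_config)
        broken = cohort.propensities.copy()
        cohort2 = simdata.Cohort(config=small_config, tree=cohort.tree,
                                 taxonomy=cohort.taxonomy, abundance=cohort.abundance,
                                 proportions=cohort.proportions,
                                 propensities=broken, offsets=cohort.offsets * 0.0)
        with pytest.raises(DegenerateFraction):
            simdata.simulate_sorting(cohort2, small_config, seed=0,
                                     individuals=["I01"], gates=("HNA",))


class TestSequencing:
    def test_whole_samples_have_no_contaminants(self, small_bundle):
        contam = small_bundle.truth["contaminant_asvs"]
        whole = small_bundle.counts.samples_where(fraction="Whole")
        assert (small_bundle.counts.counts.loc[whole, contam] == 0).all().all()

    def test_sheath_totals_within_configured_range(self, small_bundle, small_config):
        lo, hi = small_config.sheath_read_range
        sheath = small_bundle.counts.samples_where(fraction="Sheath")
        totals = small_bundle.counts.counts.loc[sheath].sum(axis=1)
        assert ((totals >= lo) & (totals <= hi)).all()

    def test_sheath_contains_only_contaminants(self, small_bundle):
        contam = set(small_bundle.truth["contaminant_asvs"])
        sheath = small_bundle.counts.samples_where(fraction="Sheath")
        others = [c for c in small_bundle.counts.asv_ids if c not in contam]
        assert small_bundle.counts.counts.loc[sheath, others].sum().sum() == 0

    def test_sorted_sample_community_reads_equal_depth(self, small_bundle, small_config):
        contam = small_bundle.truth["contaminant_asvs"]
        sorted_ids = [s for s in small_bundle.counts.sample_ids
                      if small_bundle.counts.fraction_of(s) in simdata._GATE_COMPLEMENTS
                      or small_bundle.counts.fraction_of(s) in ("HNA", "BONCATpos", "PIpos")]
        community = small_bundle.counts.counts.drop(columns=contam)
        assert (community.loc[sorted_ids].sum(axis=1) == small_config.seq_depth).all()

    def test_depth_must_be_positive(self, small_bundle, small_config):
        import copy

        cfg = copy.deepcopy(small_config)
        cfg.seq_depth = -5
        pool = simdata.simulate_sorting(small_bundle.cohort, small_config, seed=3,
                                        individuals=["I01"])
        with pytest.raises(InvalidArgument):
            simdata.simulate_sequencing(pool, small_bundle.cohort.abundance, cfg, seed=3)


class TestTreatments:
    def test_replicate_counts(self, small_bundle, small_config):
        table, cyto, truth = simdata.simulate_treatments(
            small_bundle.cohort, small_config, seed=5)
        meta = table.metadata
        for (ind, treat), grp in meta[meta["fraction"] == "BONCATpos"].groupby(
                ["individual", "treatment"]):
            assert len(grp) == small_config.n_replicates

    def test_unknown_treatment_rejected(self, small_bundle, small_config):
        import copy

        cfg = copy.deepcopy(small_config)
        cfg.treatment_effects = {1: {"Control": {}, "Espresso": {}}}
        with pytest.raises(InvalidArgument):
            simdata.simulate_treatments(small_bundle.cohort, cfg, seed=0)

    def test_missing_control_rejected(self, small_bundle, small_config):
        import copy

        cfg = copy.deepcopy(small_config)
        cfg.treatment_effects = {1: {"Glucose": {}}}
        with pytest.raises(InvalidArgument):
            simdata.simulate_treatments(small_bundle.cohort, cfg, seed=0)

    def test_zero_effect_treatment_matches_control(self, small_bundle):
        """With identical means/SDs, treatment and Control replicate
        proportions are draws from one distribution."""
        import copy

        cfg = copy.deepcopy(small_bundle.cohort.config)
        base = {"HNA": (50.0, 5.0), "BONCATpos": (40.0, 5.0), "PIpos": (12.0, 2.0)}
        cfg.treatment_effects = {1: {"Control": base, "Glucose": dict(base)}}
        cfg.n_replicates = 40
        _, cyto, truth = simdata.simulate_treatments(small_bundle.cohort, cfg, seed=6)
        from scipy import stats as sps

        g = truth[truth["treatment"] == "Glucose"]["BONCATpos"]
        c = truth[truth["treatment"] == "Control"]["BONCATpos"]
        _, p = sps.ttest_ind(g, c, equal_var=False)
        assert p > 0.01

    def test_glucose_individual2_mean_near_configured(self, small_bundle, small_config):
        table, cyto, truth = simdata.simulate_treatments(
            small_bundle.cohort, small_config, seed=7)
        g2 = truth[(truth["individual"] == "I02") & (truth["treatment"] == "Glucose")]
        # mean of 3 replicates around 67 with replicate SD 3.5
        assert g2["BONCATpos"].mean() == pytest.approx(67.0, abs=8.0)


class TestCohortBundle:
    def test_deterministic_given_seed(self, small_config):
        a = simdata.simulate_cohort(small_config)
        b = simdata.simulate_cohort(small_config)
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
        pd.testing.assert_frame_equal(a.cytometry.table, b.cytometry.table)
        assert str(a.tree) == str(b.tree)

    def test_sample_layout(self, small_bundle, small_config):
        meta = small_bundle.counts.metadata
        counts = meta["fraction"].value_counts()
        for frac in ("Whole", "HNA", "LNA", "BONCATpos", "BONCATneg", "PIpos", "Sheath"):
            assert counts[frac] == small_config.n_individuals

    def test_firmicutes_enriched_in_hna(self, default_bundle):
        """Phylum propensity offsets skew HNA toward Firmicutes vs Whole."""
        tax = default_bundle.taxonomy
        firm = tax.index[tax["phylum"] == "Firmicutes"]
        rel = default_bundle.counts.relative_abundance()
        meta = default_bundle.counts.metadata
        hna = rel.loc[meta["fraction"] == "HNA", rel.columns.intersection(firm)].sum(axis=1)
        whole = rel.loc[meta["fraction"] == "Whole", rel.columns.intersection(firm)].sum(axis=1)
        assert hna.mean() > whole.mean()

    def test_write_bundle_files(self, tmp_path, small_bundle):
        small_bundle.write(tmp_path)
        for name in ("counts.tsv", "metadata.tsv", "taxonomy.tsv", "tree.nwk",
                     "cytometry.tsv", "truth.tsv", "config.yaml"):
            assert (tmp_path / name).exists()
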