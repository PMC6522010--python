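import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from ciliabayes import synthetic
from ciliabayes.bayes import estimate_likelihoods
from ciliabayes.containers import RunConfig
from ciliabayes.dollo import SpeciesTree, ddp_against_reference, infer_dollo_events


def small_config(**overrides):
    spec_a = synthetic.DatasetSpec(
        dataset_id="a",
        categories=("found", "not_found"),
        p_pos={"found": 0.6, "not_found": 0.4},
        p_neg={"found": 0.1, "not_found": 0.9},
    )
    spec_b = synthetic.DatasetSpec(
        dataset_id="b",
        categories=("found", "not_found"),
        p_pos={"found": 0.3, "not_found": 0.7},
        p_neg={"found": 0.05, "not_found": 0.95},
    )
    kwargs = dict(
        n_genes=4000,
        prior_true=0.2,
        dataset_specs=(spec_a, spec_b),
        n_train_pos=100,
        n_train_neg=300,
        seed=7,
    )
    kwargs.update(overrides)
    return synthetic.SyntheticConfig(**kwargs)


class TestDatasetSpec:
    def test_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            synthetic.DatasetSpec(
                dataset_id="d",
                categories=("x", "y"),
                p_pos={"x": 0.5, "y": 0.4},
                p_neg={"x": 0.5, "y": 0.5},
            )

    def test_distribution_keys_must_match_categories(self):
        with pytest.raises(ValueError, match="keys"):
            synthetic.DatasetSpec(
                dataset_id="d",
                categories=("x", "y"),
                p_pos={"x": 0.5, "z": 0.5},
                p_neg={"x": 0.5, "y": 0.5},
            )

    def test_schema_round_trip(self):
        cfg = small_config()
        schema = cfg.dataset_specs[0].schema()
        assert schema.dataset_id == "a"
        assert schema.default_category == "not_found"


class TestSyntheticConfig:
    def test_coupling_to_unknown_dataset_rejected(self):
        spec = synthetic.DatasetSpec(
            dataset_id="a",
            categories=("x", "y"),
            p_pos={"x": 0.5, "y": 0.5},
            p_neg={"x": 0.5, "y": 0.5},
            couple_to="zzz",
            couple_share=0.5,
        )
        with pytest.raises(ValueError, match="zzz"):
            synthetic.SyntheticConfig(dataset_specs=(spec,))

    def test_flip_rate_above_half_rejected(self):
        with pytest.raises(ValueError, match="flip"):
            small_config(profile_flip_pos=0.6)

    def test_with_seed_changes_only_the_seed(self):
        cfg = small_config()
        cfg2 = synthetic.with_seed(cfg, 99)
        assert cfg2.seed == 99
        assert cfg2.dataset_specs == cfg.dataset_specs
        assert cfg2.n_genes == cfg.n_genes


class TestGenerate:
    def test_same_seed_reproduces_bundle_exactly(self):
        b1 = synthetic.generate(small_config())
        b2 = synthetic.generate(small_config())
        pd.testing.assert_frame_equal(b1.evidence.cells, b2.evidence.cells)
        pd.testing.assert_series_equal(b1.truth, b2.truth)
        assert b1.training.positives == b2.training.positives
        assert b1.training.negatives == b2.training.negatives

    def test_different_seed_changes_the_draw(self):
        b1 = synthetic.generate(small_config(seed=7))
        b2 = synthetic.generate(small_config(seed=8))
        assert not b1.evidence.cells.equals(b2.evidence.cells)
        assert b1.training.positives != b2.training.positives

    def test_zero_prior_plants_no_positives(self):
        cfg = small_config(prior_true=0.0, n_train_pos=0, n_train_neg=50)
        b = synthetic.generate(cfg)
        assert b.n_planted == 0
        assert (b.truth == "neg").all()

    def test_planted_count_near_prior_expectation(self):
        b = synthetic.generate(small_config())
        n, p = b.config.n_genes, b.config.prior_true
        sd = np.sqrt(n * p * (1 - p))
        assert abs(b.n_planted - n * p) <= 3 * sd

    def test_training_sets_are_class_pure_and_sized(self):
        b = synthetic.generate(small_config())
        assert len(b.training.positives) == 100
        assert len(b.training.negatives) == 300
        assert (b.truth.loc[list(b.training.positives)] == "pos").all()
        assert (b.truth.loc[list(b.training.negatives)] == "neg").all()

    def test_infeasible_training_sizes_rejected(self):
        cfg = small_config(n_genes=300, n_train_pos=200, n_train_neg=50)
        with pytest.raises(ValueError, match="infeasible"):
            synthetic.generate(cfg)

    def test_class_conditional_marginals_within_3_sd(self):
        b = synthetic.generate(small_config())
        is_pos = (b.truth == "pos").to_numpy()
        for spec in b.config.dataset_specs:
            col = b.evidence.cells[spec.dataset_id].to_numpy()
            for cls_mask, dist in ((is_pos, spec.p_pos), (~is_pos, spec.p_neg)):
                n_cls = cls_mask.sum()
                for cat, p in dist.items():
                    obs = (col[cls_mask] == cat).mean()
                    sd = np.sqrt(p * (1 - p) / n_cls)
                    assert abs(obs - p) <= 3 * sd + 1e-12, (
                        spec.dataset_id,
                        cat,
                        obs,
                        p,
                    )

    def test_columns_conditionally_independent_given_class(self):
        b = synthetic.generate(small_config())
        neg = b.truth == "neg"
        sub = b.evidence.cells.loc[neg.to_numpy()]
        table = pd.crosstab(sub["a"], sub["b"])
        _, p, _, _ = ss.chi2_contingency(table)
        assert p > 0.001

    def test_coupling_induces_dependence_but_keeps_marginals(self):
        spec_b = synthetic.DatasetSpec(
            dataset_id="b",
            categories=("found", "not_found"),
            p_pos={"found": 0.3, "not_found": 0.7},
            p_neg={"found": 0.05, "not_found": 0.95},
            couple_to="a",
            couple_share=0.9,
        )
        base = small_config()
        cfg = small_config(
            dataset_specs=(base.dataset_specs[0], spec_b), n_genes=8000
        )
        b = synthetic.generate(cfg)
        neg = (b.truth == "neg").to_numpy()
        sub = b.evidence.cells.loc[neg]
        table = pd.crosstab(sub["a"], sub["b"])
        _, p, _, _ = ss.chi2_contingency(table)
        assert p < 1e-6
        # comonotone copula: the per-column marginals are untouched
        obs = (sub["b"] == "found").mean()
        sd = np.sqrt(0.05 * 0.95 / neg.sum())
        assert abs(obs - 0.05) <= 3 * sd + 1e-12


class TestBaits:
    def test_baits_forced_into_bait_category_and_registered(self):
        spec = synthetic.DatasetSpec(
            dataset_id="a",
            categories=("found", "not_found"),
            p_pos={"found": 0.6, "not_found": 0.4},
            p_neg={"found": 0.1, "not_found": 0.9},
            n_baits=20,
        )
        cfg = small_config(dataset_specs=(spec,))
        b = synthetic.generate(cfg)
        baits = b.training.bait_exclusions["a"]
        assert len(baits) == 20
        assert baits <= b.training.positives
        assert (b.evidence.cells.loc[list(baits), "a"] == "found").all()

    def test_more_baits_than_training_positives_rejected(self):
        spec = synthetic.DatasetSpec(
            dataset_id="a",
            categories=("found", "not_found"),
            p_pos={"found": 0.6, "not_found": 0.4},
            p_neg={"found": 0.1, "not_found": 0.9},
            n_baits=200,
        )
        cfg = small_config(dataset_specs=(spec,), n_train_pos=100)
        with pytest.raises(ValueError, match="baits"):
            synthetic.generate(cfg)


class TestProfilesAndDdpColumn:
    def test_ddp_column_matches_recomputation_from_profiles(self, paperlike_bundle):
        b = paperlike_bundle
        vals = ddp_against_reference(b.tree, b.profiles, b.reference_profile)
        t = b.config.ddp_threshold
        expected = np.where(vals <= t, f"DDP<={t}", f"DDP>{t}")
        assert (b.evidence.cells["coevolution"].to_numpy() == expected).all()

    def test_reference_profile_must_cover_tree(self):
        cfg = small_config(
            tree_newick="((A,B),(C,D));", reference_profile={"A": 1, "B": 1}
        )
        with pytest.raises(ValueError, match="cover"):
            synthetic.generate(cfg)

    def test_zero_flip_rates_copy_the_reference(self):
        cfg = small_config(
            tree_newick="((A,B),(C,D));",
            reference_profile={"A": 1, "B": 1, "C": 1, "D": 0},
            profile_flip_pos=0.0,
            profile_flip_neg=0.0,
            ddp_dataset_id="coev",
        )
        b = synthetic.generate(cfg)
        assert (b.profiles["A"] == 1).all() and (b.profiles["D"] == 0).all()
        assert (b.evidence.cells["coev"] == "DDP<=9").all()


class TestDefaultTree:
    def test_tree_has_52_species_and_8_independent_losses(self):
        newick, reference = synthetic.build_default_tree()
        tree = SpeciesTree.from_newick(newick)
        assert len(tree.leaves) == 52
        assert set(reference) == set(tree.leaves)
        rec = infer_dollo_events(tree, reference)
        assert rec.origin == tree.root
        assert len(rec.losses) == 8

    def test_loss_clades_have_2_to_6_species(self):
        newick, reference = synthetic.build_default_tree()
        tree = SpeciesTree.from_newick(newick)
        rec = infer_dollo_events(tree, reference)
        assert all(2 <= len(c) <= 6 for c in rec.losses)


class TestPaperlikeDefaults:
    def test_study_scale_constants(self):
        cfg = synthetic.default_paperlike_config()
        assert cfg.n_genes == 22_000
        assert cfg.prior_true == 0.05
        assert cfg.n_train_pos == 302 and cfg.n_train_neg == 1275
        ids = {s.dataset_id for s in cfg.dataset_specs}
        assert len(cfg.dataset_specs) == 7 and cfg.ddp_dataset_id == "coevolution"
        assert "tap_ms" in ids and "expression_2007" in ids

    def test_genome_coverage_matches_mixture_targets(self, paperlike_bundle):
        # genome-wide "found" fraction must equal the class mixture
        # prior*covP + (1-prior)*covN by construction
        b = paperlike_bundle
        n = b.config.n_genes
        prior = b.config.prior_true
        for spec in b.config.dataset_specs:
            found = spec.categories[:-1]  # all but the not-found category
            cov_mix = sum(
                prior * spec.p_pos[c] + (1 - prior) * spec.p_neg[c] for c in found
            )
            obs = b.evidence.cells[spec.dataset_id].isin(found).mean()
            sd = np.sqrt(cov_mix * (1 - cov_mix) / n)
            assert abs(obs - cov_mix) <= 3 * sd + 1e-12, spec.dataset_id

    def test_estimated_llrs_recover_generating_values(self, paperlike_bundle):
        """Training-set estimates agree with the spec llrs within 5 SE."""
        b = paperlike_bundle
        cfg = RunConfig(smoothing=0.5)
        lik = estimate_likelihoods(b.evidence, b.training, cfg)
        for spec in b.config.dataset_specs:
            truth = synthetic.true_llr(spec)
            n_pos, n_neg = lik.training_summary[spec.dataset_id]
            for cat, true_val in truth.items():
                p, q = spec.p_pos[cat], spec.p_neg[cat]
                if min(n_pos * p, n_neg * q) < 5:
                    continue  # too few expected counts for a stable estimate
                se = (
                    np.sqrt((1 - p) / (p * n_pos) + (1 - q) / (q * n_neg))
                    / np.log(2)
                )
                est = lik.llr(spec.dataset_id, cat)
                assert abs(est - true_val) <= 5 * se, (spec.dataset_id, cat)

    def test_ddp_column_coverage_in_target_regime(self, paperlike_bundle):
        # the co-evolution bin was calibrated to ~30% of organelle genes
        # and ~5% of the genome
        b = paperlike_bundle
        is_pos = (b.truth == "pos").to_numpy()
        low = (b.evidence.cells["coevolution"] == "DDP<=9").to_numpy()
        assert 0.22 <= low[is_pos].mean() <= 0.38
        assert 0.035 <= low.mean() <= 0.07

    def test_true_likelihood_table_matches_population_fractions(
        self, paperlike_bundle
    ):
        b = paperlike_bundle
        oracle = synthetic.true_likelihood_table(b)
        is_pos = (b.truth == "pos").to_numpy()
        col = b.evidence.cells["tap_ms"].to_numpy()
        fp = (col[is_pos] == "found").mean()
        entry = next(
            e
            for e in oracle.entries
            if e.dataset_id == "tap_ms" and e.category == "found"
        )
        assert entry.frac_pos == pytest.approx(fp, abs=1e-12)
        assert entry.llr == pytest.approx(
            np.log2(entry.frac_pos / entry.frac_neg), abs=1e-12
        )
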