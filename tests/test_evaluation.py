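"""Scenario construction, masking, accuracy statistics and aggregation."""

import numpy as np
import pandas as pd
import pytest

from bovimpute import (
    MISSING,
    AccuracyReport,
    BenchmarkConfig,
    ScenarioConfig,
    aggregate,
    build_scenarios,
    centered_correlation,
    eligible_sites,
    genotype_concordance,
    ld_r2,
    maf_class,
    maf_class_label,
    mask_validation,
    per_class_accuracy,
    run_benchmark,
    simulate_founder_haplotypes,
    simulate_pedigree,
)
from bovimpute.evaluation import MAF_BOUNDARIES, evaluate_scenario, simulate_population


@pytest.fixture(scope="module")
def population():
    cfg = BenchmarkConfig(
        seed=17, n_founders=16, n_generations=2, n_sires_per_gen=3,
        offspring_per_dam=3, n_sites=1500, chrom_length_bp=5_000_000, n_hd=60,
    )
    truth, pedigree, chip = simulate_population(cfg)
    return cfg, truth, pedigree, chip


class TestBuildScenarios:
    def test_key_ancestors_split_sizes(self, population):
        _, truth, ped, _ = population
        n = truth.n_individuals
        scens = build_scenarios(truth, ped, "key_ancestors", {"n": 20}, seed=1)
        assert len(scens) == 1
        sc = scens[0]
        assert len(sc.reference_ids) == 20
        assert len(sc.validation_ids) == n - 20
        assert not set(sc.reference_ids) & set(sc.validation_ids)

    def test_random_cv_folds_disjoint_reference_validation(self, population):
        _, truth, ped, _ = population
        scens = build_scenarios(truth, ped, "random_cv", {"n": 20, "folds": 10}, seed=2)
        assert len(scens) == 10
        for sc in scens:
            assert not set(sc.reference_ids) & set(sc.validation_ids)
            assert len(sc.reference_ids) == 20

    def test_random_cv_partitions_pool_when_it_fits(self, population):
        _, truth, ped, _ = population
        scens = build_scenarios(truth, ped, "random_cv", {"n": 10, "folds": 5}, seed=3)
        refs = [frozenset(sc.reference_ids) for sc in scens]
        allref = set().union(*refs)
        assert len(allref) == 50  # 5 disjoint folds of 10

    def test_nested_references_are_nested(self, population):
        _, truth, ped, _ = population
        scens = build_scenarios(
            truth, ped, "nested_reference", {"sizes": [10, 30, 60], "n_validation": 12}, seed=4
        )
        refs = [set(sc.reference_ids) for sc in scens]
        assert refs[0] < refs[1] < refs[2]
        vals = [tuple(sc.validation_ids) for sc in scens]
        assert len(set(vals)) == 1  # same validation set throughout
        assert all(not r & set(vals[0]) for r in refs)

    def test_oversized_request_rejected(self, population):
        _, truth, ped, _ = population
        with pytest.raises(ValueError):
            build_scenarios(truth, ped, "key_ancestors", {"n": 10_000}, seed=0)

    def test_overlapping_split_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ScenarioConfig("bad", ["a", "b"], ["b", "c"])


class TestMasking:
    def test_validation_reduced_to_chip_sites(self, population):
        _, truth, ped, chip = population
        sc = ScenarioConfig("s", list(truth.samples)[:10], list(truth.samples)[10:20])
        masked = mask_validation(truth, sc, chip)
        assert masked.haplotypes.shape == (20, len(chip))
        assert masked.genotypes.shape == (10, len(chip))
        # typed content equals truth at chip sites
        val = truth.take_individuals(sc.validation_ids)
        assert np.array_equal(masked.genotypes, val.genotypes()[:, masked.typed_site_index])

    def test_hidden_site_count(self, population):
        _, truth, _, chip = population
        sc = ScenarioConfig("s", list(truth.samples)[:5], list(truth.samples)[5:10])
        masked = mask_validation(truth, sc, chip)
        assert truth.n_sites - masked.typed_site_index.size == truth.n_sites - len(chip)

    def test_reference_untouched(self, population):
        _, truth, _, chip = population
        before = truth.alleles.copy()
        sc = ScenarioConfig("s", list(truth.samples)[:5], list(truth.samples)[5:10])
        mask_validation(truth, sc, chip)
        assert np.array_equal(truth.alleles, before)

    def test_empty_chip_rejected(self, population):
        _, truth, _, _ = population
        sc = ScenarioConfig("s", list(truth.samples)[:5], list(truth.samples)[5:10])
        with pytest.raises(ValueError, match="chip"):
            mask_validation(truth, sc, [])


class TestEligibleSites:
    def test_rules(self):
        #               chip  mono-both  mono-ref-only  mono-val-only  plain
        ref = np.array([[1, 0, 0, 1, 0], [1, 0, 0, 2, 1]])
        val = np.array([[0, 2, 1, 0, 2], [2, 2, 0, 1, 1]])
        chip_idx = np.array([0])
        kept = eligible_sites(chip_idx, ref, val)
        assert kept.tolist() == [2, 3, 4]

    def test_monomorphic_for_different_alleles_still_excluded(self):
        ref = np.array([[0, 0], [0, 1]])
        val = np.array([[2, 0], [2, 2]])
        kept = eligible_sites(np.array([], dtype=int), ref, val)
        assert kept.tolist() == [1]


class TestConcordance:
    def test_perfect_and_partial(self):
        truth = np.tile(np.arange(10) % 3, (2, 1)).astype(np.int8)
        imputed = truth.copy()
        sites = np.arange(10)
        assert genotype_concordance(truth, imputed, sites).tolist() == [1.0, 1.0]
        imputed[0, 3] = (imputed[0, 3] + 1) % 3
        assert genotype_concordance(truth, imputed, sites).tolist() == [0.9, 1.0]

    def test_missing_imputed_counts_as_mismatch(self):
        truth = np.zeros((1, 4), dtype=np.int8)
        imputed = np.full((1, 4), MISSING, dtype=np.int8)
        assert genotype_concordance(truth, imputed, np.arange(4))[0] == 0.0

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError):
            genotype_concordance(np.zeros((1, 2), dtype=np.int8),
                                 np.zeros((1, 2), dtype=np.int8), np.array([], dtype=int))

    def test_missing_truth_rejected(self):
        t = np.array([[0, MISSING]], dtype=np.int8)
        with pytest.raises(ValueError, match="truth"):
            genotype_concordance(t, t, np.arange(2))


class TestCenteredCorrelation:
    def test_identity_gives_one(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        r = centered_correlation(t, t, np.arange(30))
        assert np.allclose(r[~np.isnan(r)], 1.0)

    def test_sign_flip_gives_minus_one(self):
        rng = np.random.default_rng(1)
        t = rng.integers(0, 3, size=(3, 30)).astype(np.int8)
        r = centered_correlation(t, 2 - t, np.arange(30))
        assert np.allclose(r[~np.isnan(r)], -1.0)

    def test_matches_textbook_pearson_after_centering(self):
        # 3 animals x 4 sites fixture against an explicit hand computation
        truth = np.array([[0, 1, 2, 1], [1, 1, 0, 2], [2, 0, 1, 0]], dtype=np.int8)
        imputed = np.array([[0, 1, 1, 1], [1, 2, 0, 2], [2, 0, 1, 1]], dtype=np.int8)
        sites = np.arange(4)
        p = truth.mean(axis=0) / 2.0
        tc = truth - 2 * p
        ic = imputed - imputed.mean(axis=0)  # imputed centered by its own frequency
        for i in range(3):
            x, y = tc[i], ic[i]
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            expected = num / den
            got = centered_correlation(truth, imputed, sites)[i]
            assert got == pytest.approx(expected, abs=1e-12)
        pooled = centered_correlation(truth, imputed, sites, unit="pooled")
        x, y = tc.ravel(), ic.ravel()
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pooled == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_flagged_as_nan_with_warning(self):
        truth = np.array([[0, 1, 2]], dtype=np.int8)
        flat = np.ones((1, 3), dtype=np.int8)
        with pytest.warns(UserWarning, match="zero-variance"):
            r = centered_correlation(truth, flat, np.arange(3))
        assert np.isnan(r[0])


class TestMafClasses:
    def test_thirteen_classes_with_half_open_membership(self):
        assert len(MAF_BOUNDARIES) == 13
        assert maf_class(0.0) == 0
        assert maf_class(0.025) == 1  # boundary belongs to the class below
        assert maf_class(0.0251) == 2
        assert maf_class(0.5) == 12
        assert maf_class(1e-9) == 1
        assert maf_class_label(1) == "(0,0.025]"
        assert maf_class_label(0) == "0"

    def test_out_of_range_rejected(self):
        for bad in (-0.01, 0.51):
            with pytest.raises(ValueError):
                maf_class(bad)

    def test_vectorised_classification(self):
        vals = np.array([0.0, 0.01, 0.025, 0.3, 0.45, 0.5])
        assert np.array_equal(maf_class(vals), [0, 1, 1, 8, 11, 12])


class TestPerClassAccuracy:
    def test_single_class_matches_pooled_correlation(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 3, size=(5, 20)).astype(np.int8)
        noisy = truth.copy()
        noisy[0, ::3] = (noisy[0, ::3] + 1) % 3
        freqs = np.full(20, 0.3)  # every site in class (0.25, 0.3]
        sites = np.arange(20)
        table = per_class_accuracy(truth, noisy, None, freqs, sites)
        assert len(table) == 1
        assert table["maf_class"].iloc[0] == 8
        expected = centered_correlation(truth, noisy, sites, unit="pooled")
        assert table["genotype_corr"].iloc[0] == pytest.approx(expected)

    def test_empty_classes_absent(self):
        truth = np.array([[0, 1], [1, 2]], dtype=np.int8)
        freqs = np.array([0.02, 0.4])
        table = per_class_accuracy(truth, truth, None, freqs, np.arange(2))
        assert set(table["maf_class"]) == {1, 10}  # (0, 0.025] and (0.35, 0.4]
        assert len(table) == 2


class TestAggregate:
    def _report(self, label, fold, values):
        df = pd.DataFrame(
            {"id": [f"i{k}" for k in range(len(values))],
             "concordance": values, "genotype_corr": values, "dosage_corr": values}
        )
        return AccuracyReport(label, fold, df, pd.DataFrame(), 10)

    def test_single_fold_equals_its_mean(self):
        r = self._report("s", 0, [0.8, 0.9])
        s = aggregate([r])
        assert s.mean_concordance == pytest.approx(0.85)
        assert s.range_concordance == (pytest.approx(0.85), pytest.approx(0.85))

    def test_mean_and_range_across_folds(self):
        s = aggregate([self._report("s", 0, [0.8]), self._report("s", 1, [0.9])])
        assert s.mean_genotype_corr == pytest.approx(0.85)
        assert s.range_genotype_corr == (pytest.approx(0.8), pytest.approx(0.9))

    def test_unweighted_fold_averaging_differs_from_pooled(self):
        # fold 0: 3 individuals at 0.6; fold 1: one individual at 0.9
        r0 = self._report("s", 0, [0.6, 0.6, 0.6])
        r1 = self._report("s", 1, [0.9])
        s = aggregate([r0, r1])
        assert s.mean_concordance == pytest.approx(0.75)  # (0.6 + 0.9) / 2
        pooled = np.mean([0.6, 0.6, 0.6, 0.9])  # 0.675: what pooling would give
        assert s.mean_concordance != pytest.approx(pooled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestLdR2:
    def test_identical_and_complementary_columns(self):
        x = np.array([[0, 2, 1], [1, 1, 0], [2, 0, 2], [0, 2, 0]], dtype=float)
        cols = np.column_stack([x[:, 0], x[:, 0], 2 - x[:, 0]])
        assert ld_r2(cols, 0, 1) == pytest.approx(1.0)
        assert ld_r2(cols, 0, 2) == pytest.approx(1.0)

    def test_independent_sites_near_zero(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(200):
            a = rng.integers(0, 2, size=400).astype(float)
            b = rng.integers(0, 2, size=400).astype(float)
            vals.append(ld_r2(np.column_stack([a, b]), 0, 1))
        assert np.mean(vals) == pytest.approx(1 / 400, rel=0.5)

    def test_monomorphic_rejected(self):
        cols = np.column_stack([np.zeros(4), np.arange(4)])
        with pytest.raises(ValueError):
            ld_r2(cols, 0, 1)


class TestEndToEnd:
    def test_identity_imputer_scores_one_everywhere(self, population):
        cfg, truth, ped, chip = population
        sc = ScenarioConfig("id", list(truth.samples)[:20], list(truth.samples)[20:40])
        report = evaluate_scenario(truth, sc, chip, imputer="identity")
        assert np.allclose(report.per_individual["concordance"], 1.0)
        gc = report.per_individual["genotype_corr"]
        assert np.allclose(gc[~np.isnan(gc)], 1.0)
        dc = report.per_individual["dosage_corr"]
        assert np.allclose(dc[~np.isnan(dc)], 1.0)
        assert np.allclose(report.per_class["genotype_corr"], 1.0)

    def test_chip_sites_never_evaluated(self, population):
        cfg, truth, ped, chip = population
        sc = ScenarioConfig("id", list(truth.samples)[:20], list(truth.samples)[20:40])
        report = evaluate_scenario(truth, sc, chip, imputer="identity")
        assert report.n_eligible_sites <= truth.n_sites - len(chip)

    def test_benchmark_deterministic_given_seed(self):
        cfg = BenchmarkConfig(
            seed=5, n_founders=8, n_generations=1, n_sires_per_gen=2,
            offspring_per_dam=3, n_sites=400, chrom_length_bp=1_000_000, n_hd=30,
            scheme_params={"sizes": [4, 8], "n_validation": 4},
        )
        a = run_benchmark(cfg)
        b = run_benchmark(cfg)
        pd.testing.assert_frame_equal(a.summary_frame(), b.summary_frame())
        assert np.array_equal(a.truth.alleles, b.truth.alleles)

    def test_accuracy_nondecreasing_with_nested_reference(self):
        """Larger reference panels yield higher genotype correlation (3 seeds here)."""
        gains = []
        for seed in range(3):
            cfg = BenchmarkConfig(
                seed=seed, n_founders=16, n_generations=2, n_sires_per_gen=3,
                offspring_per_dam=3, n_sites=1200, chrom_length_bp=5_000_000, n_hd=60,
                scheme_params={"sizes": [10, 40], "n_validation": 10},
            )
            frame = run_benchmark(cfg).summary_frame().set_index("scenario")
            gains.append(
                frame.loc["nested_40", "genotype_corr"] - frame.loc["nested_10", "genotype_corr"]
            )
        assert np.mean(gains) > 0

    def test_dosage_correlation_at_least_genotype_correlation_on_average(self):
        diffs = []
        for seed in range(3):
            cfg = BenchmarkConfig(
                seed=100 + seed, n_founders=16, n_generations=2, n_sires_per_gen=3,
                offspring_per_dam=3, n_sites=1200, chrom_length_bp=5_000_000, n_hd=60,
                scheme_params={"sizes": [20], "n_validation": 10},
            )
            frame = run_benchmark(cfg).summary_frame()
            diffs.append(frame["dosage_corr"].iloc[0] - frame["genotype_corr"].iloc[0])
        assert np.mean(diffs) >= 0
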