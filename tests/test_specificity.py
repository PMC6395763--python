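import numpy as np
import pandas as pd
import pytest

from adipoatlas import specificity as sp
from adipoatlas.config import AnalysisConfig, OMENTAL, SUBCUTANEOUS
from adipoatlas.io_formats import ExpressionMatrix

from conftest import make_matrix


def make_profile(medians: dict[str, list[float]], genes=None) -> sp.MedianProfile:
    df = pd.DataFrame(medians, index=genes or [f"g{i}" for i in range(len(next(iter(medians.values()))))])
    return sp.MedianProfile(df.astype(float), (SUBCUTANEOUS, OMENTAL))


class TestSelectSamples:
    def _inputs(self, rows):
        samples = pd.DataFrame(rows, columns=["sample_id", "donor_id", "tissue", "rin"])
        values = pd.DataFrame(
            np.ones((3, len(samples))), index=["g0", "g1", "g2"], columns=samples["sample_id"]
        )
        return ExpressionMatrix(values), samples

    def test_rin_boundary_is_inclusive(self, config):
        rows = [[f"S{i}", f"D{i}", "Liver", rin] for i, rin in enumerate([5.9, 6.0, 9.0] * 15)]
        matrix, samples = self._inputs(rows)
        out = sp.select_samples(matrix, samples, config)
        kept_rins = samples.set_index("sample_id").loc[out.sample_ids, "rin"]
        assert (kept_rins >= 6.0).all()
        assert len(out.sample_ids) == 30  # the 5.9 third is gone

    def test_tissue_with_29_donors_removed_entirely(self, config):
        rows = [[f"S{i}", f"D{i}", "Liver", 9.0] for i in range(29)]
        rows += [[f"T{i}", f"E{i}", "Lung", 9.0] for i in range(30)]
        matrix, samples = self._inputs(rows)
        out = sp.select_samples(matrix, samples, config)
        assert set(out.tissue_of.values()) == {"Lung"}

    def test_excluded_tissue_labels_dropped(self, config):
        rows = [[f"S{i}", f"D{i}", "Breast - Mammary Tissue", 9.0] for i in range(40)]
        rows += [[f"T{i}", f"E{i}", "Lung", 9.0] for i in range(40)]
        matrix, samples = self._inputs(rows)
        out = sp.select_samples(matrix, samples, config)
        assert set(out.tissue_of.values()) == {"Lung"}

    def test_matches_bruteforce_refilter(self, config):
        # 3 tissues x 40 donors; one tissue loses 15 samples to low RIN
        rng = np.random.default_rng(5)
        rows = []
        for t_i, tissue in enumerate(["Liver", "Lung", "Spleen"]):
            for d in range(40):
                rin = 5.0 if tissue == "Spleen" and d < 15 else float(rng.uniform(6, 10))
                rows.append([f"S{t_i}_{d}", f"D{t_i}_{d}", tissue, rin])
        matrix, samples = self._inputs(rows)
        out = sp.select_samples(matrix, samples, config)
        # independent re-filter
        ok = samples[samples["rin"] >= 6.0]
        donors = ok.groupby("tissue")["donor_id"].nunique()
        expected = set(ok[ok["tissue"].isin(donors[donors >= 30].index)]["sample_id"])
        assert set(out.sample_ids) == expected
        # Spleen retains only 25 donors after the RIN filter, so it is gone
        assert ("Spleen" in set(out.tissue_of.values())) == (donors["Spleen"] >= 30)

    def test_sample_absent_from_table_raises(self, config):
        matrix, samples = self._inputs([["S0", "D0", "Liver", 9.0]])
        with pytest.raises(KeyError):
            sp.select_samples(matrix, samples.iloc[0:0], config)


class TestFilterExpressed:
    def test_all_zero_gene_excluded_constant_gene_retained(self, config):
        matrix = make_matrix({"Liver": [0.0, 1.0], "Lung": [0.0, 0.0]}, n_samples=10)
        kept = sp.filter_expressed(matrix, config)
        assert kept == {"g1"}

    def test_median_exactly_at_floor_is_excluded(self, config):
        matrix = make_matrix({"Liver": [0.5, 0.51]}, n_samples=10)
        assert sp.filter_expressed(matrix, config) == {"g1"}

    def test_single_passing_tissue_suffices(self, config):
        # the any-tissue rule: expressed in Liver only is enough
        matrix = make_matrix({"Liver": [1.0], "Lung": [0.0], "Spleen": [0.0]}, n_samples=6)
        assert sp.filter_expressed(matrix, config) == {"g0"}

    def test_unlabelled_matrix_raises(self, config):
        values = pd.DataFrame(np.ones((1, 3)), index=["g0"], columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            sp.filter_expressed(ExpressionMatrix(values), config)


class TestTissueMedians:
    def test_odd_and_even_sample_counts(self, config):
        values = pd.DataFrame(
            {"a": [1.0], "b": [2.0], "c": [3.0], "d": [1.0], "e": [2.0], "f": [3.0], "g": [10.0]},
            index=["g0"],
        )
        tissue_of = {"a": "X", "b": "X", "c": "X", "d": "Y", "e": "Y", "f": "Y", "g": "Y"}
        profile = sp.tissue_medians(ExpressionMatrix(values, tissue_of), config)
        assert profile.medians.at["g0", "X"] == 2.0
        assert profile.medians.at["g0", "Y"] == 2.5  # even n: mean of central pair

    def test_matches_numpy_median_on_random_matrix(self, config, small_atlas):
        matrix, *_ = small_atlas
        profile = sp.tissue_medians(matrix, config)
        for tissue in matrix.tissues:
            cols = matrix.samples_of_tissue(tissue)
            expected = np.median(matrix.values[cols].to_numpy(), axis=1)
            np.testing.assert_allclose(profile.medians[tissue].to_numpy(), expected)


class TestRelativeMedian:
    def test_hand_cases(self):
        profile = make_profile(
            {SUBCUTANEOUS: [10.0, 1.0], OMENTAL: [3.0, 1.0], "Liver": [1.0, 1.0], "Lung": [1.0, 1.0]}
        )
        assert sp.relative_median_value(profile, "g0", "subcutaneous") == 10.0
        assert sp.relative_median_value(profile, "g1", "subcutaneous") == 1.0

    def test_toy_two_tissue_denominator(self):
        profile = make_profile({SUBCUTANEOUS: [4.0], OMENTAL: [0.0], "T1": [1.0], "T2": [3.0]})
        assert sp.relative_median_value(profile, "g0", "subcutaneous") == pytest.approx(2.0)

    def test_zero_conventions(self):
        profile = make_profile({SUBCUTANEOUS: [4.0, 0.0], OMENTAL: [0.0, 0.0],
                                "T1": [0.0, 0.0], "T2": [0.0, 0.0]})
        assert sp.relative_median_value(profile, "g0", "subcutaneous") == np.inf
        assert sp.relative_median_value(profile, "g1", "subcutaneous") == 0.0

    def test_invariant_under_global_scaling(self):
        rng = np.random.default_rng(1)
        med = {SUBCUTANEOUS: rng.gamma(2, 5, 5).tolist(), OMENTAL: rng.gamma(2, 5, 5).tolist(),
               "T1": rng.gamma(2, 5, 5).tolist(), "T2": rng.gamma(2, 5, 5).tolist()}
        p1 = make_profile(med)
        p2 = make_profile({t: [7.3 * v for v in vals] for t, vals in med.items()})
        for g in p1.medians.index:
            assert sp.relative_median_value(p1, g, "omental") == pytest.approx(
                sp.relative_median_value(p2, g, "omental")
            )

    def test_unknown_gene_raises(self):
        profile = make_profile({SUBCUTANEOUS: [1.0], OMENTAL: [1.0], "T1": [1.0]})
        with pytest.raises(KeyError):
            sp.relative_median_value(profile, "nope", "subcutaneous")


class TestPairwiseFolds:
    def test_boundary_and_zero_conventions(self):
        profile = make_profile({SUBCUTANEOUS: [10.0, 10.0, 0.0], OMENTAL: [1.0, 1.0, 1.0],
                                "T1": [2.0, 0.0, 5.0]})
        folds = sp.pairwise_folds(profile, "g0", "subcutaneous")
        assert folds["T1"] == 5.0  # exactly 5: will NOT pass the strict threshold
        assert sp.pairwise_folds(profile, "g1", "subcutaneous")["T1"] == np.inf
        assert sp.pairwise_folds(profile, "g2", "subcutaneous")["T1"] == 0.0

    def test_matches_elementwise_division(self):
        rng = np.random.default_rng(9)
        med = {SUBCUTANEOUS: rng.gamma(2, 5, 30).tolist(), OMENTAL: rng.gamma(2, 5, 30).tolist()}
        for j in range(18):
            med[f"T{j}"] = rng.gamma(2, 5, 30).tolist()
        profile = make_profile(med)
        table = sp.pairwise_fold_table(profile, "subcutaneous")
        for g in profile.medians.index[:5]:
            folds = sp.pairwise_folds(profile, g, "subcutaneous")
            for t in profile.non_depot_tissues:
                expected = profile.medians.at[g, SUBCUTANEOUS] / profile.medians.at[g, t]
                assert folds[t] == pytest.approx(expected)
                assert table.at[g, t] == pytest.approx(expected)


class TestPairwiseTests:
    def test_identical_constant_groups_give_q_one(self, config):
        matrix = make_matrix({SUBCUTANEOUS: [2.0], OMENTAL: [2.0], "Liver": [2.0]}, n_samples=5)
        q = sp.pairwise_tests(matrix, "subcutaneous", config)
        assert q.at["g0", "Liver"] == 1.0

    def test_strong_separation_is_significant(self, config):
        rng = np.random.default_rng(2)
        n = 30
        cols, tissue_of = {}, {}
        for i in range(n):
            cols[f"a{i}"] = [10.0 + rng.normal(0, 0.01)]
            tissue_of[f"a{i}"] = SUBCUTANEOUS
            cols[f"b{i}"] = [abs(rng.normal(0, 0.01))]
            tissue_of[f"b{i}"] = "Liver"
            cols[f"c{i}"] = [2.0]
            tissue_of[f"c{i}"] = OMENTAL
        values = pd.DataFrame(cols, index=["g0"], dtype=float)
        q = sp.pairwise_tests(ExpressionMatrix(values, tissue_of), "subcutaneous", config)
        assert q.at["g0", "Liver"] < 0.01

    def test_null_simulation_controls_fdr(self, config):
        # 200 null genes, identical distributions: the fraction called at
        # q < 0.01 should stay within 3 binomial SEs of 0.01
        rng = np.random.default_rng(13)
        n_genes, n = 200, 30
        cols, tissue_of = {}, {}
        for i in range(n):
            for label, key in [(SUBCUTANEOUS, f"a{i}"), (OMENTAL, f"o{i}"), ("Liver", f"b{i}")]:
                cols[key] = rng.gamma(4.0, 2.5, n_genes)
                tissue_of[key] = label
        values = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
        q = sp.pairwise_tests(ExpressionMatrix(values, tissue_of), "subcutaneous", config)
        frac = float((q["Liver"] < 0.01).mean())
        se = np.sqrt(0.01 * 0.99 / n_genes)
        assert frac <= 0.01 + 3 * se

    def test_group_below_two_samples_raises(self, config):
        matrix = make_matrix({SUBCUTANEOUS: [1.0], OMENTAL: [1.0], "Liver": [1.0]}, n_samples=1)
        with pytest.raises(ValueError):
            sp.pairwise_tests(matrix, "subcutaneous", config)


def classify_one(medians, qrow, config, depot="subcutaneous"):
    profile = make_profile(medians, genes=["g0"])
    folds = sp.pairwise_fold_table(profile, depot)
    q = pd.DataFrame({t: [qrow.get(t, 0.0)] for t in profile.non_depot_tissues}, index=["g0"])
    return sp.classify_genes(profile, folds, q, depot, config)


class TestClassifyGenes:
    def test_passing_all_tissues_is_specific_all(self, config):
        medians = {SUBCUTANEOUS: [100.0], OMENTAL: [1.0]}
        medians.update({f"T{j}": [1.0] for j in range(44)})
        calls = classify_one(medians, {}, config)
        assert len(calls) == 1
        assert calls[0].category == "specific_all" and calls[0].exception_tissues == []

    def test_single_sub_threshold_tissue_is_enhanced_except1(self, config):
        # one tissue at 26% of the depot median: a 3.8-fold ratio below the
        # 5-fold bar, but still below the depot -> tolerated exception
        medians = {SUBCUTANEOUS: [100.0], OMENTAL: [1.0], "Testis": [26.0]}
        medians.update({f"T{j}": [1.0] for j in range(43)})
        calls = classify_one(medians, {}, config)
        assert calls[0].category == "enhanced_except1"
        assert calls[0].exception_tissues == ["Testis"]

    def test_exception_above_depot_median_yields_no_call(self, config):
        medians = {SUBCUTANEOUS: [100.0], OMENTAL: [1.0], "Testis": [130.0]}
        medians.update({f"T{j}": [1.0] for j in range(43)})
        assert classify_one(medians, {}, config) == []

    def test_fold_exactly_five_counts_as_exception(self, config):
        medians = {SUBCUTANEOUS: [100.0], OMENTAL: [1.0], "Liver": [20.0]}
        medians.update({f"T{j}": [1.0] for j in range(43)})
        calls = classify_one(medians, {}, config)
        assert calls[0].category == "enhanced_except1"
        assert calls[0].exception_tissues == ["Liver"]

    def test_nonsignificant_q_counts_as_exception(self, config):
        medians = {SUBCUTANEOUS: [100.0], OMENTAL: [1.0], "Liver": [2.0]}
        medians.update({f"T{j}": [1.0] for j in range(43)})
        calls = classify_one(medians, {"Liver": 0.5}, config)
        assert calls[0].category == "enhanced_except1"

    def test_three_failing_tissues_yield_no_call(self, config):
        medians = {SUBCUTANEOUS: [100.0], OMENTAL: [1.0]}
        medians.update({f"T{j}": [50.0] for j in range(3)})
        medians.update({f"U{j}": [1.0] for j in range(41)})
        assert classify_one(medians, {}, config) == []

    def test_matches_bruteforce_rederivation(self, config):
        rng = np.random.default_rng(21)
        n_genes, tissues = 60, [f"T{j}" for j in range(12)]
        med = {SUBCUTANEOUS: rng.gamma(2, 20, n_genes), OMENTAL: rng.gamma(2, 20, n_genes)}
        med.update({t: rng.gamma(2, 5, n_genes) for t in tissues})
        profile = make_profile({k: list(v) for k, v in med.items()})
        folds = sp.pairwise_fold_table(profile, "subcutaneous")
        q = pd.DataFrame(rng.random((n_genes, len(tissues))) * 0.05,
                         index=profile.medians.index, columns=tissues)
        calls = {c.gene_id: c for c in sp.classify_genes(profile, folds, q, "subcutaneous", config)}
        for i, g in enumerate(profile.medians.index):
            failing = [
                t for t in tissues
                if not (folds.at[g, t] > 5.0 and q.at[g, t] < 0.01)
            ]
            depot_med = profile.medians.at[g, SUBCUTANEOUS]
            expected = None
            if len(failing) == 0:
                expected = "specific_all"
            elif len(failing) <= 2 and all(profile.medians.at[g, t] < depot_med for t in failing):
                expected = f"enhanced_except{len(failing)}"
            got = calls.get(g)
            assert (got.category if got else None) == expected
            if got and expected != "specific_all":
                assert got.exception_tissues == sorted(failing)

    def test_monotone_in_other_tissue_medians(self, config):
        # raising a non-depot median can only weaken or keep the call
        rank = {None: 0, "enhanced_except2": 1, "enhanced_except1": 2, "specific_all": 3}
        rng = np.random.default_rng(31)
        for _ in range(25):
            base = {SUBCUTANEOUS: [50.0], OMENTAL: [1.0]}
            base.update({f"T{j}": [float(rng.gamma(2, 4))] for j in range(8)})
            before = classify_one(base, {}, config)
            bumped = dict(base)
            t = f"T{int(rng.integers(8))}"
            bumped[t] = [base[t][0] * float(rng.uniform(1.5, 10))]
            after = classify_one(bumped, {}, config)
            cat_b = before[0].category if before else None
            cat_a = after[0].category if after else None
            assert rank[cat_a] <= rank[cat_b]


class TestPlantedRecoverySmall:
    def test_small_atlas_roles_recovered(self, config, small_sim, small_atlas):
        from adipoatlas import pipeline as pl
        matrix, samples, annotation, truth = small_atlas
        table, summary = pl.run_specificity(config, matrix, samples, annotation)
        merged = table.merge(truth, on="gene_id")
        spec = merged[merged["category"] == "specific_all"]
        assert set(spec[spec["depot"] == "subcutaneous"]["role"]) <= {"specific_sub", "specific_both"}
        # every planted specific gene is found in its depot
        for role, depot in [("specific_sub", "subcutaneous"), ("specific_om", "omental")]:
            planted = set(truth.loc[truth["role"] == role, "gene_id"])
            called = set(table.loc[(table["depot"] == depot) & (table["category"] == "specific_all"), "gene_id"])
            assert len(planted & called) / len(planted) >= 0.95
        # planted exceptions identified exactly
        enh = merged[merged["role"].str.startswith("enhanced")]
        assert len(enh) > 0
        assert (enh["exception_tissues_x"] == enh["exception_tissues_y"]).all()
        # nulls essentially never called
        nulls = set(truth.loc[truth["role"] == "null", "gene_id"])
        false_calls = nulls & set(table["gene_id"])
        assert len(false_calls) / len(nulls) <= 0.01
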