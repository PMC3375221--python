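import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from regdiverge import expression as ex
from regdiverge import synthetic_data as sd


@pytest.fixture(scope="module")
def design():
    return sd.standard_expression_design()


@pytest.fixture(scope="module")
def null_matrix(design):
    matrix, _ = sd.simulate_expression_matrix(1_500, design, seed=71)
    return matrix


class TestQpcr:
    @staticmethod
    def simulate_records(fold, bias, seed):
        rng = np.random.default_rng(seed)
        rows, het = [], []
        for plate in ("p1", "p2"):
            for primer, level in (("C", fold), ("P", 1.0)):
                apparent = level * (bias if primer == "C" else 1.0)
                for i in range(6):
                    ct_ref = 15 + rng.normal(0, 0.05)
                    rows.append({
                        "sample": f"{plate}{primer}{i}", "gene": "target",
                        "primer": primer, "ct_target": ct_ref - np.log2(apparent)
                        + rng.normal(0, 0.05),
                        "ct_reference": ct_ref, "plate": plate,
                    })
            for primer in "CP":
                apparent = bias if primer == "C" else 1.0
                het.append({"plate": plate, "primer": primer,
                            "ct_target": 15.0 - np.log2(apparent),
                            "ct_reference": 15.0})
        return pd.DataFrame(rows), pd.DataFrame(het)

    def test_equal_cts_give_unit_expression(self):
        rec = pd.DataFrame([{"sample": "s", "gene": "g", "ct_target": 20.0,
                             "ct_reference": 20.0, "plate": "p"}])
        out = ex.plate_corrected_relative_expression(rec)
        assert out["relative_expression"].iloc[0] == pytest.approx(1.0)

    def test_heterozygote_ratio_corrected_to_unity(self):
        records, het = self.simulate_records(fold=1.0, bias=1.3, seed=0)
        # noiseless heterozygote measurements run through the correction
        noiseless = het.copy()
        noiseless["sample"] = [f"h{i}" for i in range(len(het))]
        noiseless["gene"] = "target"
        out = ex.plate_corrected_relative_expression(noiseless, het)
        by = out.groupby("primer")["relative_expression"].mean()
        assert by["C"] / by["P"] == pytest.approx(1.0, abs=1e-9)

    def test_primer_bias_removed_from_fold_change(self):
        folds = []
        for seed in range(30):
            records, het = self.simulate_records(fold=2.0, bias=1.3, seed=seed)
            out = ex.plate_corrected_relative_expression(records, het)
            by = out.groupby("primer")["relative_expression"].mean()
            folds.append(by["C"] / by["P"])
        assert np.mean(folds) == pytest.approx(2.0, rel=0.10)

    def test_missing_calibration_is_error(self):
        records, het = self.simulate_records(fold=2.0, bias=1.3, seed=1)
        with pytest.raises(ValueError, match="calibration"):
            ex.plate_corrected_relative_expression(records, None)
        with pytest.raises(ValueError, match="plate"):
            ex.plate_corrected_relative_expression(
                records, het[het["plate"] == "p1"]
            )

    def test_missing_reference_is_error(self):
        rec = pd.DataFrame([{"sample": "s", "gene": "g", "ct_target": 20.0,
                             "ct_reference": np.nan, "plate": "p"}])
        with pytest.raises(ValueError, match="ACT1"):
            ex.plate_corrected_relative_expression(rec)


class TestMedianNormalize:
    def test_constant_array_becomes_zero(self):
        m = pd.DataFrame({"a": [3.0, 3.0, 3.0], "b": [1.0, 2.0, 3.0]})
        out = ex.median_normalize(m)
        assert (out["a"] == 0).all()

    def test_idempotent_and_offset_removal(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame({"a": rng.normal(size=101)})
        m["b"] = m["a"] + 5.0
        out = ex.median_normalize(m)
        pd.testing.assert_series_equal(out["a"], out["b"], check_names=False)
        pd.testing.assert_frame_equal(ex.median_normalize(out), out)

    def test_all_missing_array_is_error(self):
        m = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="'a'"):
            ex.median_normalize(m)


class TestGeneAnova:
    def test_null_pvalues_uniform(self, null_matrix, design):
        res = ex.gene_anova(null_matrix, design)
        for col in ("p_allele", "p_time", "p_allele_time"):
            assert stats.kstest(res[col], "uniform").pvalue > 0.01

    def test_single_gene_matches_statsmodels_anova(self, null_matrix, design):
        res = ex.gene_anova(null_matrix, design)
        df = design.copy()
        df["y"] = null_matrix.iloc[7][design["sample"]].to_numpy()
        fit = smf.ols("y ~ C(allele)*C(time) + C(tech_replicate)", df).fit()
        table = anova_lm(fit, typ=2)
        assert res["p_allele"].iloc[7] == pytest.approx(
            table.loc["C(allele)", "PR(>F)"], abs=1e-10
        )
        assert res["p_allele_time"].iloc[7] == pytest.approx(
            table.loc["C(allele):C(time)", "PR(>F)"], abs=1e-10
        )

    def test_constant_gene_is_degenerate_not_crash(self, design):
        matrix = pd.DataFrame(
            np.ones((3, len(design))), columns=design["sample"].tolist(),
            index=["g1", "g2", "g3"],
        )
        res = ex.gene_anova(matrix, design)
        assert (res["p_allele"] == 1.0).all()

    def test_empty_design_cell_is_error(self, null_matrix, design):
        broken = design[~((design["allele"] == "C.C") & (design["time"] == 0))]
        with pytest.raises(ValueError, match="<2 replicates"):
            ex.gene_anova(null_matrix, broken)

    def test_coding_spikes_classified_as_coding(self, design):
        matrix, truth = sd.simulate_expression_matrix(
            400, design, {"coding": (40, 2.0)}, seed=5
        )
        res = ex.gene_anova(matrix, design)
        spiked = truth[truth == "coding"].index
        called = res.loc[spiked, "source"]
        assert (called == "coding").mean() >= 0.90

    def test_classification_invariant_to_reference_species(self, design):
        matrix, truth = sd.simulate_expression_matrix(
            200, design, {"coding": (20, 2.0), "noncoding": (20, 2.0),
                          "interaction": (20, 2.0)}, seed=6
        )
        res1 = ex.gene_anova(matrix, design)
        flipped = design.copy()
        flipped["noncoding_origin"] = 1 - flipped["noncoding_origin"]
        flipped["coding_origin"] = 1 - flipped["coding_origin"]
        res2 = ex.gene_anova(matrix, flipped)
        spiked = truth[truth != "null"].index
        assert (res1.loc[spiked, "source"] == res2.loc[spiked, "source"]).all()


class TestPermutationFdr:
    def test_deterministic_given_seed(self, design):
        matrix, _ = sd.simulate_expression_matrix(
            300, design, {"coding": (30, 2.0)}, seed=8
        )
        f1 = ex.permutation_fdr(matrix, design, nperm=25, seed=9)
        f2 = ex.permutation_fdr(matrix, design, nperm=25, seed=9)
        assert f1 == f2

    def test_null_matrix_fdr_near_one(self, null_matrix, design):
        f = ex.permutation_fdr(null_matrix, design, alpha=0.05, nperm=40, seed=10)
        # observed and permuted significant counts are both chance-level
        assert f.n_observed > 0
        se = np.sqrt(f.n_observed) / f.n_observed * 3
        assert abs(f.fdr - 1.0) < max(3 * se, 0.75)

    def test_spiked_matrix_fdr_small(self, design):
        matrix, _ = sd.simulate_expression_matrix(
            2_000, design, {"coding": (100, 3.0), "noncoding": (100, 3.0)},
            seed=11,
        )
        f = ex.permutation_fdr(matrix, design, alpha=0.01, nperm=40, seed=12)
        assert f.fdr < 0.25

    def test_zero_observed_reports_undefined(self, design):
        matrix = pd.DataFrame(
            np.zeros((2, len(design))), columns=design["sample"].tolist(),
            index=["g1", "g2"],
        )
        f = ex.permutation_fdr(matrix, design, alpha=1e-6, nperm=20, seed=1)
        assert f.fdr is None and f.fdr_capped is None

    def test_nperm_floor_and_test_names(self, null_matrix, design):
        with pytest.raises(ValueError):
            ex.permutation_fdr(null_matrix, design, nperm=5, seed=0)
        with pytest.raises(ValueError):
            ex.permutation_fdr(null_matrix, design, nperm=25, seed=0, test="bogus")


class TestFoldChangeSets:
    def test_rule_application_and_strict_boundary(self):
        res = pd.DataFrame(
            {
                "p_time": [0.005, 0.005, 0.005, 0.5],
                "log2fc_sulfite": [1.1, 1.0, -1.4, 3.0],
            },
            index=["up_gene", "boundary", "down_gene", "ns_gene"],
        )
        sets = ex.fold_change_sets(res)
        assert sets["up"] == ["up_gene"]
        assert sets["down"] == ["down_gene"]  # exactly 2-fold excluded

    def test_null_set_size_matches_chance_expectation(self, null_matrix, design):
        res = ex.gene_anova(null_matrix, design)
        sets = ex.fold_change_sets(res, fc_threshold=1.05, p_threshold=0.05)
        n = len(null_matrix)
        # p<0.05 and |log2fc| > tiny threshold: close to 5% in each tail
        assert len(sets["up"]) + len(sets["down"]) < 0.10 * n
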