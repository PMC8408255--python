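"""TPM, expressed filter, NB Wald DE test, categories, and chromosome grouping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from homoevol.bias import (BiasError, CountMatrix, DEResult, BIAS_CATEGORIES,
                           chi_square_gof, chromosome_bias_grouping,
                           classify_bias_category, compute_tpm, flag_expressed,
                           high_confidence_pairs, is_significant_twofold,
                           size_factors, te_stratified_bias)
from homoevol.bias import test_homoeolog_de as run_de
from homoevol.synteny import HomoeologPair


def _simple_cm(counts, lengths=None, n=None):
    n = n or counts.shape[1]
    idx = list(counts.columns)
    design = pd.DataFrame({"tissue": ["t"] * n, "variety": ["v"] * n,
                           "replicate": range(n)}, index=idx)
    lengths = lengths if lengths is not None else pd.Series(1000.0, index=counts.index)
    return CountMatrix(counts=counts, design=design, gene_lengths=lengths)


class TestTPM:
    def test_single_gene_gets_full_million(self):
        counts = pd.DataFrame({"s1": [7]}, index=["g"])
        tpm = compute_tpm(counts, pd.Series({"g": 500}))
        assert tpm.loc["g", "s1"] == pytest.approx(1e6)

    def test_length_normalization_two_to_one(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["short", "long"])
        tpm = compute_tpm(counts, pd.Series({"short": 1000, "long": 2000}))
        assert tpm.loc["short", "s1"] / tpm.loc["long", "s1"] == pytest.approx(2.0)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, (30, 4)),
                              columns=list("abcd"))
        tpm = compute_tpm(counts, pd.Series(rng.integers(200, 3000, 30),
                                            index=counts.index))
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_sample_is_an_error(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        with pytest.raises(BiasError, match="zero total"):
            compute_tpm(counts, pd.Series({"a": 100, "b": 100}))


class TestExpressedFilter:
    def test_threshold_is_strictly_exceeded(self):
        tpm = pd.DataFrame({"s1": [0.4, 0.5, 0.6]}, index=["a", "b", "c"])
        assert flag_expressed(tpm, 0.5) == {"c"}

    def test_pair_with_one_silent_member_is_not_high_confidence(self):
        pairs = [HomoeologPair("a", "b", "c1", "c2"),
                 HomoeologPair("c", "d", "c1", "c2")]
        assert high_confidence_pairs(pairs, {"a", "c", "d"}) == [pairs[1]]

    def test_zero_threshold_keeps_all_nonzero(self):
        tpm = pd.DataFrame({"s1": [0.0, 0.01]}, index=["a", "b"])
        assert flag_expressed(tpm, 0.0) == {"b"}


class TestWaldTest:
    def test_identical_count_vectors_are_a_clear_null(self):
        counts = pd.DataFrame([[10, 20, 30, 25], [10, 20, 30, 25]],
                              index=["gA", "gB"], columns=list("wxyz"))
        cm = _simple_cm(counts)
        res = run_de(cm, HomoeologPair("gA", "gB", "c1", "c2"),
                                sf=pd.Series(1.0, index=list("wxyz")))
        assert abs(res.log2fc) < 1e-9
        assert res.p_value > 0.9
        assert classify_bias_category(res) == "no_difference"

    def test_fewer_than_two_samples_is_an_error(self):
        counts = pd.DataFrame([[10], [12]], index=["gA", "gB"], columns=["s1"])
        cm = _simple_cm(counts)
        with pytest.raises(BiasError, match="need >= 2"):
            run_de(cm, HomoeologPair("gA", "gB", "c1", "c2"))

    def test_type_one_error_calibrated_under_null(self):
        """With no planted effect the p <= 0.05 rate stays near 5%."""
        rng = np.random.default_rng(10)
        n, alpha, hits, runs = 30, 0.05, 0, 400
        idx = [f"s{i}" for i in range(n)]
        sf = pd.Series(1.0, index=idx)
        for _ in range(runs):
            mu = float(np.exp(rng.normal(np.log(150), 1.0)))
            r = 1 / alpha
            counts = pd.DataFrame(
                rng.negative_binomial(r, r / (r + mu), (2, n)),
                index=["gA", "gB"], columns=idx)
            res = run_de(_simple_cm(counts),
                                    HomoeologPair("gA", "gB", "c1", "c2"), sf=sf)
            hits += res.p_value <= 0.05
        rate = hits / runs
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / runs)

    def test_planted_eightfold_effect_is_detected(self):
        rng = np.random.default_rng(11)
        idx = ["s1", "s2", "s3"]
        sf = pd.Series(1.0, index=idx)
        det = 0
        for _ in range(200):
            r = 1 / 0.05
            a = rng.negative_binomial(r, r / (r + 100.0), 3)
            b = rng.negative_binomial(r, r / (r + 800.0), 3)
            counts = pd.DataFrame([a, b], index=["gA", "gB"], columns=idx)
            res = run_de(_simple_cm(counts),
                                    HomoeologPair("gA", "gB", "c1", "c2"), sf=sf)
            det += is_significant_twofold(res)
        assert det / 200 >= 0.9


class TestCategories:
    @pytest.mark.parametrize("p,fc,expected", [
        (0.2, 10.0, "no_difference"),
        (0.01, 1.5, "lower"),
        (0.01, 2.0, "lower"),
        (0.01, 2.01, "medium"),
        (0.01, 7.99, "medium"),
        (0.01, 8.0, "higher"),
        (0.05, 3.0, "medium"),   # boundary p = 0.05 is significant
        (0.0501, 3.0, "no_difference"),
    ])
    def test_printed_inequalities(self, p, fc, expected):
        res = DEResult(pair=HomoeologPair("a", "b", "c1", "c2"),
                       log2fc=np.log2(fc), p_value=p, higher_copy="b")
        assert classify_bias_category(res) == expected

    def test_partition_is_exhaustive_and_exclusive(self):
        """Every (fc, p) grid point lands in exactly one category."""
        pair = HomoeologPair("a", "b", "c1", "c2")
        for fc in np.concatenate([np.linspace(1, 16, 301), [2.0, 8.0]]):
            for p in np.concatenate([np.linspace(0, 1, 101), [0.05]]):
                res = DEResult(pair=pair, log2fc=np.log2(fc), p_value=p,
                               higher_copy="b")
                cats = [c for c in BIAS_CATEGORIES
                        if classify_bias_category(res) == c]
                assert len(cats) == 1


class TestChiSquare:
    def test_balanced_counts_give_zero_statistic(self):
        chi2, df, p = chi_square_gof([50, 50], [1, 1])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_seventy_thirty_closed_form(self):
        chi2, df, p = chi_square_gof([70, 30], [50, 50])
        assert chi2 == pytest.approx(16.0)
        assert df == 1
        assert p == pytest.approx(6.33e-5, rel=1e-2)

    def test_matches_monte_carlo_multinomial_null(self):
        rng = np.random.default_rng(12)
        obs = [530, 470]
        chi2, _, p = chi_square_gof(obs, [1, 1])
        draws = rng.multinomial(1000, [0.5, 0.5], size=100_000)
        stat = ((draws - 500.0) ** 2 / 500.0).sum(axis=1)
        mc_p = (stat >= chi2 - 1e-12).mean()
        # allow MC sampling error plus the discreteness of the multinomial tail
        assert abs(p - mc_p) <= 0.1 * p + 3 * np.sqrt(mc_p * (1 - mc_p) / 1e5)

    def test_zero_expected_cell_is_an_error(self):
        with pytest.raises(BiasError):
            chi_square_gof([10, 10], [1, 0])


def _de(ga, gb, ca, cb, log2fc, p):
    pair = HomoeologPair(ga, gb, ca, cb)
    return DEResult(pair=pair, log2fc=log2fc, p_value=p,
                    higher_copy=gb if log2fc > 0 else ga)


class TestGrouping:
    def test_balanced_split_gives_sc_sd(self):
        des = [_de(f"a{i}", f"b{i}", "c1", "c2", 1.5 if i < 25 else -1.5, 0.01)
               for i in range(50)]
        res = chromosome_bias_grouping(des, [("c1", "c2")],
                                       {f"a{i}": "c1" for i in range(50)} |
                                       {f"b{i}": "c2" for i in range(50)})
        assert set(res.groups.values()) == {"SC", "SD"}

    def test_seventy_thirty_split_gives_sa_sb(self):
        des = [_de(f"a{i}", f"b{i}", "c1", "c2", -1.5 if i < 70 else 1.5, 0.01)
               for i in range(100)]
        gmap = {f"a{i}": "c1" for i in range(100)} | {f"b{i}": "c2" for i in range(100)}
        res = chromosome_bias_grouping(des, [("c1", "c2")], gmap)
        assert res.groups == {"c1": "SA", "c2": "SB"}
        assert res.table.loc[0, "chi2"] == pytest.approx(16.0)

    def test_swapping_chromosomes_swaps_labels_keeps_chi2(self):
        des = [_de(f"a{i}", f"b{i}", "c1", "c2", 1.5 if i < 70 else -1.5, 0.01)
               for i in range(100)]
        gmap = {f"a{i}": "c1" for i in range(100)} | {f"b{i}": "c2" for i in range(100)}
        r1 = chromosome_bias_grouping(des, [("c1", "c2")], gmap)
        r2 = chromosome_bias_grouping(des, [("c2", "c1")], gmap)
        assert r1.groups["c1"] == r2.groups["c1"] == "SB"
        assert r1.groups["c2"] == r2.groups["c2"] == "SA"
        assert r1.table.loc[0, "chi2"] == pytest.approx(r2.table.loc[0, "chi2"])

    def test_pair_without_significant_genes_is_unclassifiable(self):
        des = [_de("a1", "b1", "c1", "c2", 0.1, 0.9)]
        res = chromosome_bias_grouping(des, [("c1", "c2")], {"a1": "c1", "b1": "c2"})
        assert res.unclassifiable == [("c1", "c2")]


class TestTEStratified:
    def _setup(self, d_dom, d_rec):
        des = [_de(f"a{i}", f"b{i}", "c1", "c2", -1.5, 0.01) for i in range(40)]
        gmap = {f"a{i}": "c1" for i in range(40)} | {f"b{i}": "c2" for i in range(40)}
        grouping = chromosome_bias_grouping(des, [("c1", "c2")], gmap)
        dist = {f"a{i}": d_dom for i in range(40)}
        dist |= {f"b{i}": d_rec for i in range(40)}
        return grouping, des, dist, gmap

    def test_two_kb_window_is_strict(self):
        grouping, des, dist, gmap = self._setup(1500, 2500)
        out = te_stratified_bias(grouping, des, dist, gmap)
        assert list(out["stratum"]) == ["SAyes_SBno"]

    def test_distance_exactly_2000_counts_as_no(self):
        grouping, des, dist, gmap = self._setup(2000, 2000)
        out = te_stratified_bias(grouping, des, dist, gmap)
        assert list(out["stratum"]) == ["SAno_SBno"]

    def test_missing_distances_are_excluded_and_counted(self):
        grouping, des, dist, gmap = self._setup(100, 100)
        del dist["a0"]
        out = te_stratified_bias(grouping, des, dist, gmap)
        assert out.attrs["n_missing"] == 1
        assert out["n_dominant_side"].sum() + out["n_recessive_side"].sum() == 39


class TestPlantedRecovery:
    def test_planted_category_proportions_recovered(self, small_truth, small_config):
        """Planted category shares stay within 3 binomial SDs of the config."""
        cats = [p.category for p in small_truth.homoeolog_pairs]
        n = len(cats)
        for frac, cat in zip(small_config.bias_fractions,
                             ("no_difference", "lower", "medium", "higher")):
            got = sum(c == cat for c in cats)
            sd = np.sqrt(n * frac * (1 - frac))
            assert abs(got - n * frac) <= 3 * sd + 1e-9

    def test_size_factors_track_library_depth(self, small_counts):
        sf = size_factors(small_counts)
        assert (sf > 0).all()
        # doubling one library doubles its size factor relative to the rest
        doubled = small_counts.copy()
        col = doubled.columns[0]
        doubled[col] = doubled[col] * 2
        sf2 = size_factors(doubled)
        rel = (sf2 / sf2.drop(col).mean()) / (sf / sf.drop(col).mean())
        assert rel[col] == pytest.approx(2.0, rel=0.05)
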