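import numpy as np
import pandas as pd
import pytest

from introscan import diffexpr as de
from tests.conftest import make_matrix, unit_factors


class TestCpm:
    def test_definition(self):
        cm = make_matrix([[10], [0]], ["A"])
        f = unit_factors(cm, lib_size=1e7)
        table = de.cpm(cm, f)
        assert table.iloc[0, 0] == pytest.approx(1.0)
        assert table.iloc[1, 0] == 0.0

    def test_hand_computation_with_factors(self):
        cm = make_matrix([[100, 50], [200, 100], [700, 850]], ["A", "B"])
        lib = cm.lib_sizes.astype(float)  # 1000, 1000
        factors = de.NormFactors(
            lib_size=lib, factor=pd.Series([2.0, 0.5], index=cm.counts.columns)
        )
        table = de.cpm(cm, factors)
        assert table.iloc[0, 0] == pytest.approx(100 / (1000 * 2.0) * 1e6)
        assert table.iloc[1, 1] == pytest.approx(100 / (1000 * 0.5) * 1e6)

    def test_zero_library_errors(self):
        cm = make_matrix([[1]], ["A"])
        f = de.NormFactors(
            lib_size=pd.Series(0.0, index=cm.counts.columns),
            factor=pd.Series(1.0, index=cm.counts.columns),
        )
        with pytest.raises(ValueError):
            de.cpm(cm, f)


class TestFilterTranscribed:
    def fixture(self, rows):
        cm = make_matrix(rows, ["A", "A", "B", "B"])
        return cm, unit_factors(cm, lib_size=1e6)  # CPM == count

    def test_all_zero_excluded(self):
        cm, f = self.fixture([[0, 0, 0, 0], [10, 10, 10, 10]])
        kept = de.filter_transcribed(cm, f, "A", "B")
        assert list(kept) == ["g2"]

    def test_either_group_suffices(self):
        cm, f = self.fixture([[5, 5, 0, 0]])
        kept = de.filter_transcribed(cm, f, "A", "B")
        assert list(kept) == ["g1"]

    def test_boundary_is_strict(self):
        cm, f = self.fixture([[1, 1, 1, 1]])
        assert len(de.filter_transcribed(cm, f, "A", "B")) == 0

    def test_unknown_group_errors(self):
        cm, f = self.fixture([[1, 1, 1, 1]])
        with pytest.raises(KeyError, match="nope"):
            de.filter_transcribed(cm, f, "A", "nope")


class TestTmm:
    def test_identical_samples_factor_one(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 1000, 100)
        cm = make_matrix(np.column_stack([col, col]), ["A", "B"])
        f = de.tmm_factors(cm)
        assert np.allclose(f.factor, 1.0)

    def test_scale_invariance(self):
        # M and A values are exactly invariant to scaling one sample's counts;
        # only the (count-level) precision weights move, so the factors agree
        # to well under a percent
        rng = np.random.default_rng(2)
        y = rng.integers(1, 500, size=(200, 3))
        cm1 = make_matrix(y, ["A", "B", "C"])
        y2 = y.copy()
        y2[:, 1] *= 2
        cm2 = make_matrix(y2, ["A", "B", "C"])
        f1 = de.tmm_factors(cm1, reference="A_r1")
        f2 = de.tmm_factors(cm2, reference="A_r1")
        assert np.allclose(f1.factor, f2.factor, atol=1e-2)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        cm = make_matrix(rng.integers(0, 2000, size=(300, 4)), ["A", "A", "B", "B"])
        f = de.tmm_factors(cm)
        assert np.exp(np.mean(np.log(f.factor))) == pytest.approx(1.0, abs=1e-8)

    def test_worked_example_matches_independent_computation(self):
        # 6 genes, 2 samples; the oracle below redoes the standard recipe
        # step by step with explicit sorting, no shared code
        counts = np.array(
            [[100, 320], [200, 230], [300, 610], [400, 390], [500, 1500], [600, 610]]
        )
        cm = make_matrix(counts, ["A", "B"])
        got = de.tmm_factors(cm, reference="A_r1")

        n_a, n_b = counts[:, 0].sum(), counts[:, 1].sum()
        obs, ref = counts[:, 1] / n_b, counts[:, 0] / n_a
        m = np.log2(obs / ref)
        a = 0.5 * np.log2(obs * ref)
        w = (n_b - counts[:, 1]) / (n_b * counts[:, 1]) + (n_a - counts[:, 0]) / (
            n_a * counts[:, 0]
        )
        n = 6
        lo_m, hi_m = np.floor(n * 0.3) + 1, n + 1 - (np.floor(n * 0.3) + 1)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n + 1 - (np.floor(n * 0.05) + 1)
        rank_m = np.argsort(np.argsort(m)) + 1
        rank_a = np.argsort(np.argsort(a)) + 1
        keep = (
            (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        )
        log_f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        expected_b = 2 ** (log_f - log_f / 2)  # after geometric-mean rescale
        expected_a = 2 ** (0.0 - log_f / 2)
        assert got.factor["B_r1"] == pytest.approx(expected_b, abs=1e-10)
        assert got.factor["A_r1"] == pytest.approx(expected_a, abs=1e-10)


class TestDispersion:
    def test_poisson_data_small_common(self):
        rng = np.random.default_rng(10)
        base = rng.lognormal(5.0, 1.0, 500)
        y = rng.poisson(np.tile(base[:, None], (1, 6)))
        cm = make_matrix(y, ["A"] * 3 + ["B"] * 3)
        est = de.estimate_dispersion(cm)
        assert est.common < 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(11)
        base = rng.lognormal(5.0, 1.0, 1000)
        mu = np.tile(base[:, None], (1, 12))
        y = rng.poisson(rng.gamma(1 / 0.4, 0.4 * mu))
        cm = make_matrix(y, ["A"] * 6 + ["B"] * 6)
        est = de.estimate_dispersion(cm)
        assert 0.3 < est.common < 0.5

    def test_constant_gene_shrinks_to_floor(self):
        # with a weak prior the zero-variance gene's own likelihood wins and
        # its tagwise estimate drops to the floor; with the default prior it
        # is still the smallest estimate in the matrix
        rng = np.random.default_rng(12)
        base = rng.lognormal(6.0, 0.5, 200)
        mu = np.tile(base[:, None], (1, 30))
        y = rng.poisson(rng.gamma(1 / 0.4, 0.4 * mu))
        y[0, :] = 500  # identical counts in every sample
        cm = make_matrix(y, ["A"] * 15 + ["B"] * 15)
        weak = de.estimate_dispersion(cm, prior_df=0.01)
        assert weak.tagwise.iloc[0] < 1e-4
        default = de.estimate_dispersion(cm)
        assert default.tagwise.iloc[0] == default.tagwise.min()

    def test_single_replicate_everywhere_errors(self):
        cm = make_matrix([[1, 2], [3, 4]], ["A", "B"])
        with pytest.raises(ValueError, match="fixed dispersion"):
            de.estimate_dispersion(cm)


class TestTestDt:
    def test_sign_convention_up(self):
        rng = np.random.default_rng(20)
        mu = np.full((50, 12), 500.0)
        mu[0, 6:] *= 8.0  # logFC = 3 in the test group
        y = rng.poisson(rng.gamma(1 / 0.05, 0.05 * mu))
        cm = make_matrix(y, ["ref"] * 6 + ["tst"] * 6)
        f = de.tmm_factors(cm)
        dt = de.test_dt(cm, f, 0.05, "ref", "tst")
        assert dt.iloc[0]["dt_class"] == "up"
        assert dt.iloc[0]["logFC"] == pytest.approx(3.0, abs=0.5)

    def test_q_at_least_p_and_partition(self, nb_null_matrix):
        cm = nb_null_matrix
        f = de.tmm_factors(cm)
        est = de.estimate_dispersion(cm)
        dt = de.test_dt(cm, f, est, "A", "B")
        assert (dt["qvalue"] >= dt["pvalue"] - 1e-12).all()
        assert set(dt["dt_class"]).issubset(set(de.DT_CLASSES))
        counts = dt["dt_class"].value_counts()
        assert counts.sum() == len(dt)
        up = dt[dt["dt_class"] == "up"]
        down = dt[dt["dt_class"] == "down"]
        assert (up["logFC"] > 0).all() and (up["qvalue"] < 0.05).all()
        assert (down["logFC"] < 0).all() and (down["qvalue"] < 0.05).all()

    def test_null_calibration_small(self, nb_null_matrix):
        cm = nb_null_matrix
        f = de.tmm_factors(cm)
        est = de.estimate_dispersion(cm)
        dt = de.test_dt(cm, f, est, "A", "B")
        assert 0.01 < (dt["pvalue"] < 0.05).mean() < 0.10

    def test_structural_zero_group_gets_large_negative_logfc(self):
        rng = np.random.default_rng(21)
        y = rng.poisson(300.0, size=(20, 8))
        y[0, 4:] = 0
        cm = make_matrix(y, ["ref"] * 4 + ["tst"] * 4)
        f = unit_factors(cm)
        dt = de.test_dt(cm, f, 0.1, "ref", "tst")
        assert dt.iloc[0]["dt_class"] == "down"
        assert np.isfinite(dt.iloc[0]["logFC"])
        assert dt.iloc[0]["logFC"] < -8

    def test_requires_two_replicates(self):
        cm = make_matrix([[1, 2, 3]], ["A", "B", "B"])
        f = unit_factors(cm)
        with pytest.raises(ValueError, match="replicates"):
            de.test_dt(cm, f, 0.1, "A", "B")


class TestFpkm:
    def test_definition(self):
        cm = make_matrix([[100]], ["A"])
        f = unit_factors(cm, lib_size=1e7)
        lengths = pd.Series([1000], index=["g1"])
        assert de.fpkm(cm, f, lengths).iloc[0, 0] == pytest.approx(10.0)

    def test_zero_counts(self):
        cm = make_matrix([[0], [5]], ["A"])
        f = unit_factors(cm, lib_size=1e6)
        lengths = pd.Series([1000, 1000], index=["g1", "g2"])
        assert de.fpkm(cm, f, lengths).iloc[0, 0] == 0.0

    def test_length_scaling(self):
        cm = make_matrix([[100], [100]], ["A"])
        f = unit_factors(cm, lib_size=1e6)
        lengths = pd.Series([1000, 2000], index=["g1", "g2"])
        table = de.fpkm(cm, f, lengths)
        assert table.iloc[0, 0] / table.iloc[1, 0] == pytest.approx(2.0)

    def test_missing_length_lists_genes(self):
        cm = make_matrix([[1], [2]], ["A"])
        f = unit_factors(cm)
        with pytest.raises(ValueError, match="g2"):
            de.fpkm(cm, f, pd.Series([100], index=["g1"]))


class TestSummaries:
    def make_dt(self, n_up, n_down, n_not):
        cls = ["up"] * n_up + ["down"] * n_down + ["not_DT"] * n_not
        return pd.DataFrame(
            {"dt_class": cls, "logFC": 0.0, "pvalue": 0.5, "qvalue": 0.5},
            index=[f"g{i}" for i in range(len(cls))],
        )

    def test_reference_donor_contrast_counts(self):
        s = de.summarize_contrast(self.make_dt(156, 233, 534))
        assert s["transcribed"] == 923
        assert s["DT"] == 389
        assert s["pct_DT"] == 42.15  # 389/923, 2 dp
        assert s["pct_up"] == 16.90
        assert s["pct_down"] == 25.24

    def test_no_dt(self):
        s = de.summarize_contrast(self.make_dt(0, 0, 50))
        assert s["pct_DT"] == 0.0 and s["pct_not_DT"] == 100.0

    def test_partition(self):
        s = de.summarize_contrast(self.make_dt(3, 4, 5))
        assert s["up"] + s["down"] + s["not_DT"] == s["transcribed"]


class TestSilencedAndBins:
    def test_count_silenced(self):
        cm = make_matrix([[0, 0, 5, 1], [0, 1, 2, 2]], ["A", "A", "B", "B"])
        f = unit_factors(cm, lib_size=1e6)
        table = de.fpkm(cm, f, pd.Series([1000, 1000], index=["g1", "g2"]))
        silenced = de.count_silenced(table, cm.samples, "A")
        assert list(silenced) == ["g1"]

    def test_count_silenced_empty_group(self):
        cm = make_matrix([[1]], ["A"])
        f = unit_factors(cm)
        table = de.fpkm(cm, f, pd.Series([100], index=["g1"]))
        with pytest.raises(ValueError, match="no samples"):
            de.count_silenced(table, cm.samples, "Z")

    def test_bin_assignment(self):
        values = pd.Series([3.0, 0.0, 5.0, 25.0, 0.5], index=list("abcde"))
        labels, counts = de.expression_bins(values)
        assert labels["a"] == "1-5"
        assert labels["b"] == de.NOT_DETECTABLE
        assert labels["c"] == "5-20"  # exactly 5 goes to the upper bin
        assert labels["d"] == ">=20"
        assert counts[de.NOT_DETECTABLE] == 2
        assert counts.sum() == 5

    def test_unsorted_edges_error(self):
        with pytest.raises(ValueError, match="increasing"):
            de.expression_bins(pd.Series([1.0]), edges=(5, 1))
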