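import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from zoocomm.association import (
    PresenceMatrix,
    classify_pairs,
    contingency_2x2,
    export_network,
    overall_variance_ratio,
    pearson_pair_summary,
    point_correlation,
    presence_absence,
    stability_summary,
    to_graph,
)
from zoocomm.errors import UndefinedStatisticError, ValidationError

# chi-square critical value at 1 df, alpha 0.05, from published tables
CHI2_CRIT_1DF = 3.841


def _pm(rows, index=None):
    arr = np.asarray(rows)
    idx = index or [f"e{i}" for i in range(arr.shape[0])]
    return PresenceMatrix(values=pd.DataFrame(arr, index=idx))


class TestPresenceAbsence:
    def test_binarize_default_threshold(self):
        mat = pd.DataFrame([[0.0, 0.3], [1.0, 0.0]])
        pm = presence_absence(mat)
        assert pm.values.iloc[0].tolist() == [0, 1]

    def test_custom_threshold(self):
        mat = pd.DataFrame([[0.3, 0.8], [0.6, 0.0]])
        pm = presence_absence(mat, threshold=0.5)
        assert pm.values.iloc[0].tolist() == [0, 1]

    def test_all_present(self):
        mat = pd.DataFrame(np.ones((3, 4)))
        assert (presence_absence(mat).values == 1).all().all()

    def test_too_few_entities_or_sites(self):
        with pytest.raises(ValidationError):
            presence_absence(pd.DataFrame([[1.0, 2.0]]))
        with pytest.raises(ValidationError):
            presence_absence(pd.DataFrame([[1.0], [2.0]]))


class TestOverallVarianceRatio:
    def test_complementary_pair_closed_form(self):
        pm = _pm([[1, 0], [0, 1]])
        res = overall_variance_ratio(pm)
        assert res.sigma_T2 == pytest.approx(0.5)
        assert res.S_T2 == 0.0
        assert res.VR == 0.0
        assert res.verdict == "negative"

    def test_co_occurring_pair_positive(self):
        pm = _pm([[1, 1, 0, 0], [1, 1, 0, 0]])
        res = overall_variance_ratio(pm)
        assert res.VR > 1
        assert res.verdict == "positive"

    def test_w_equals_n_times_vr(self):
        rng = np.random.default_rng(0)
        pm = _pm(rng.integers(0, 2, size=(6, 12)))
        res = overall_variance_ratio(pm)
        assert res.W == res.VR * pm.n_sites

    def test_degenerate_occupancy_flagged(self):
        pm = _pm([[1, 1, 1], [1, 1, 1]])
        with pytest.raises(UndefinedStatisticError):
            overall_variance_ratio(pm)

    def test_chi2_bounds_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        pm = _pm(rng.integers(0, 2, size=(5, 10)))
        r1 = overall_variance_ratio(pm, alpha=0.05)
        r2 = overall_variance_ratio(pm, alpha=0.10)
        assert r2.chi2_lower > r1.chi2_lower
        assert r2.chi2_upper < r1.chi2_upper

    def test_first_principles_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            vals = rng.integers(0, 2, size=(8, 15))
            if vals.sum() == 0 or (vals.std(axis=1) == 0).all():
                continue
            pm = _pm(vals)
            res = overall_variance_ratio(pm)
            # two-pass variance computation, no vectorized shortcuts
            N = vals.shape[1]
            p = [row.sum() / N for row in vals]
            sigma = sum(pi * (1 - pi) for pi in p)
            T = [int(vals[:, j].sum()) for j in range(N)]
            mean_T = sum(T) / N
            st2 = sum((t - mean_T) ** 2 for t in T) / N
            assert res.VR == pytest.approx(st2 / sigma, abs=1e-12)


class TestContingency:
    def test_enumeration(self):
        pm = _pm([[1, 1, 0, 0], [1, 0, 1, 0]], index=["A", "B"])
        assert contingency_2x2(pm, "A", "B") == (1, 1, 1, 1)

    def test_identical_patterns(self):
        pm = _pm([[1, 1, 0], [1, 1, 0]], index=["A", "B"])
        assert contingency_2x2(pm, "A", "B") == (2, 0, 0, 1)

    def test_complementary_patterns(self):
        pm = _pm([[1, 1, 0], [0, 0, 1]], index=["A", "B"])
        a, _, _, d = contingency_2x2(pm, "A", "B")
        assert a == 0 and d == 0

    def test_cells_sum_to_n(self):
        rng = np.random.default_rng(4)
        pm = _pm(rng.integers(0, 2, size=(2, 20)), index=["A", "B"])
        assert sum(contingency_2x2(pm, "A", "B")) == 20


class TestPointCorrelation:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((2, 0, 0, 2), 1.0),
            ((0, 2, 2, 0), -1.0),
            ((1, 1, 1, 1), 0.0),
            ((6, 2, 1, 6), 34 / 56),  # hand arithmetic: (36-2)/sqrt(8*7*8*7)
        ],
    )
    def test_values(self, cells, expected):
        assert point_correlation(*cells) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_marginal_nan_not_inf(self):
        phi = point_correlation(3, 0, 2, 0)  # b+d == 0
        assert np.isnan(phi)

    def test_phi_equals_pearson_on_binary_vectors(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(8)
        checked = 0
        while checked < 100:
            x = rng.integers(0, 2, 25)
            y = rng.integers(0, 2, 25)
            if x.std() == 0 or y.std() == 0:
                continue
            pm = _pm(np.vstack([x, y]), index=["A", "B"])
            phi = point_correlation(*contingency_2x2(pm, "A", "B"))
            assert phi == pytest.approx(pearsonr(x, y).statistic, abs=1e-12)
            checked += 1

    def test_complement_symmetry(self):
        rng = np.random.default_rng(12)
        x = rng.integers(0, 2, 30)
        y = rng.integers(0, 2, 30)

        def phi_of(u, v):
            pm = _pm(np.vstack([u, v]), index=["A", "B"])
            return point_correlation(*contingency_2x2(pm, "A", "B"))

        base = phi_of(x, y)
        assert phi_of(1 - x, 1 - y) == pytest.approx(base, abs=1e-12)
        assert phi_of(1 - x, y) == pytest.approx(-base, abs=1e-12)


class TestClassifyPairs:
    def test_perfect_cooccurrence_sig_positive(self):
        row = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        pm = _pm([row, row], index=["A", "B"])
        pairs = classify_pairs(pm)
        assert pairs.loc[0, "chi2"] == pytest.approx(10.0)
        assert pairs.loc[0, "chi2"] > CHI2_CRIT_1DF
        assert pairs.loc[0, "class"] == "sig_positive"

    def test_zero_phi_positive_by_convention(self):
        pm = _pm([[1, 1, 0, 0], [1, 0, 1, 0]], index=["A", "B"])  # (1,1,1,1)
        pairs = classify_pairs(pm)
        assert pairs.loc[0, "phi"] == 0.0
        assert pairs.loc[0, "class"] == "positive"
        assert bool(pairs.loc[0, "zero_phi"])

    def test_undefined_pair_class(self):
        pm = _pm([[1, 1, 1], [1, 0, 1]], index=["A", "B"])  # A ubiquitous
        pairs = classify_pairs(pm)
        assert pairs.loc[0, "class"] == "undefined"

    def test_all_unordered_pairs_enumerated(self):
        rng = np.random.default_rng(3)
        pm = _pm(rng.integers(0, 2, size=(6, 10)))
        assert len(classify_pairs(pm)) == 15

    def test_critical_value_against_independent_table(self):
        # independent source for the 1-df critical value (published table)
        assert chi2.ppf(0.95, 1) == pytest.approx(CHI2_CRIT_1DF, abs=5e-4)


class TestStabilitySummary:
    def _pairs(self, classes):
        return pd.DataFrame({"class": classes})

    def test_stable(self):
        s = stability_summary(self._pairs(["positive"] * 3 + ["negative"]))
        assert s["verdict"] == "stable" and s["positive"] == 3

    def test_successional(self):
        s = stability_summary(self._pairs(["positive"] + ["negative"] * 3))
        assert s["verdict"] == "successional"

    def test_network_total_structure(self):
        classes = ["positive"] * 17 + ["sig_positive"] * 4 + ["negative"] * 5 + ["sig_negative"] * 2
        s = stability_summary(self._pairs(classes))
        assert s["positive"] == 21 and s["negative"] == 7
        assert s["verdict"] == "stable"

    def test_tie_is_successional(self):
        s = stability_summary(self._pairs(["positive", "negative"]))
        assert s["verdict"] == "successional"


class TestPearsonPairSummary:
    def test_duplicate_entity_strong(self):
        mat = pd.DataFrame([[1, 5, 9, 2], [1, 5, 9, 2]], index=["A", "B"], dtype=float)
        s = pearson_pair_summary(mat)
        assert s["strong"] == 1
        assert s["pairs"].loc[0, "r"] == pytest.approx(1.0)

    def test_negated_entity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        mat = pd.DataFrame([x, 2 * x.mean() - x], index=["A", "B"])
        s = pearson_pair_summary(mat, log_transform=False)
        assert s["pairs"].loc[0, "r"] == pytest.approx(-1.0)

    def test_zero_variance_entity_skipped(self):
        mat = pd.DataFrame([[1, 1, 1], [1, 2, 3]], index=["A", "B"], dtype=float)
        s = pearson_pair_summary(mat)
        assert s["skipped"] == [("A", "B")]
        assert len(s["pairs"]) == 0

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            pearson_pair_summary(pd.DataFrame([[1, 2], [3, 4]], dtype=float))

    def test_independent_vectors_rarely_strong(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.random((46, 20)))  # 1035 pairs
        s = pearson_pair_summary(mat, log_transform=False)
        assert s["strong"] / len(s["pairs"]) < 0.01  # far below 0.05 at n=20


class TestExportNetwork:
    def test_round_trip(self, tmp_path):
        pm = _pm([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]], index=["A", "B", "C"])
        pairs = classify_pairs(pm)
        path = tmp_path / "edges.tsv"
        export_network(pairs, path)
        back = pd.read_csv(path, sep="\t")
        assert set(back.columns) == {"a_entity", "b_entity", "phi", "chi2", "class"}
        merged = back.merge(pairs, on=["a_entity", "b_entity"], suffixes=("_f", ""))
        assert np.allclose(merged["phi_f"], merged["phi"].astype(float), rtol=1e-5)

    def test_empty_edge_list_keeps_header(self, tmp_path):
        pairs = pd.DataFrame(columns=["a_entity", "b_entity", "phi", "chi2", "class"])
        path = tmp_path / "empty.tsv"
        export_network(pairs, path)
        assert path.read_text().startswith("a_entity\tb_entity")

    def test_classes_partition_edges(self, tmp_path):
        rng = np.random.default_rng(7)
        pm = _pm(rng.integers(0, 2, size=(8, 12)))
        pairs = classify_pairs(pm)
        path = tmp_path / "edges.tsv"
        export_network(pairs, path)
        back = pd.read_csv(path, sep="\t")
        valid = {"sig_positive", "positive", "sig_negative", "negative"}
        assert set(back["class"]).issubset(valid)
        assert len(back) == (pairs["class"] != "undefined").sum()

    def test_to_graph(self):
        pm = _pm([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]], index=["A", "B", "C"])
        g = to_graph(classify_pairs(pm))
        assert g.number_of_edges() == 3
        assert g["A"]["B"]["phi"] == pytest.approx(1.0)
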