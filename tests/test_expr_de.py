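import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senecon import expr_de as de
from senecon.synthdata import ExpressionTruth, simulate_expression


class TestExpressionMatrixIO:
    def test_round_trip(self, small_matrix, tmp_path):
        m_path, d_path = tmp_path / "m.tsv", tmp_path / "d.csv"
        de.write_expression_matrix(small_matrix, m_path, d_path)
        loaded = de.read_expression_matrix(m_path, d_path)
        pd.testing.assert_frame_equal(loaded.values, small_matrix.values)
        pd.testing.assert_frame_equal(loaded.design, small_matrix.design)

    def test_missing_design_sample_names_it(self, small_matrix):
        design = small_matrix.design[small_matrix.design["sample_id"] != "c1_r2"]
        with pytest.raises(ValueError, match="c1_r2"):
            de.ExpressionMatrix(values=small_matrix.values, design=design)

    def test_duplicate_probe_ids_rejected(self, small_matrix):
        values = pd.concat([small_matrix.values, small_matrix.values.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            de.ExpressionMatrix(values=values, design=small_matrix.design)

    def test_non_numeric_rejected(self, small_matrix, tmp_path):
        m_path, d_path = tmp_path / "m.tsv", tmp_path / "d.csv"
        de.write_expression_matrix(small_matrix, m_path, d_path)
        txt = m_path.read_text().replace("8.", "x8.", 1)
        m_path.write_text(txt)
        with pytest.raises(ValueError, match="non-numeric"):
            de.read_expression_matrix(m_path, d_path)

    def test_simulated_output_loads(self, tmp_path):
        truth = ExpressionTruth(n_probes=50, seed=7)
        matrix, labels = simulate_expression(truth)
        de.write_expression_matrix(matrix, tmp_path / "m.tsv", tmp_path / "d.csv")
        loaded = de.read_expression_matrix(tmp_path / "m.tsv", tmp_path / "d.csv")
        assert loaded.values.shape == (50, 9)
        assert len(labels) == 50


class TestPairwiseDE:
    def test_identical_groups(self):
        values = pd.DataFrame(
            {"a1": [1.0], "a2": [2.0], "a3": [3.0], "b1": [1.0], "b2": [2.0], "b3": [3.0]},
            index=pd.Index(["p1"], name="probe_id"),
        )
        design = pd.DataFrame(
            {"sample_id": values.columns, "condition": ["A"] * 3 + ["B"] * 3}
        )
        res = de.pairwise_de(de.ExpressionMatrix(values, design), "A", "B")
        assert res.lfc.iloc[0] == 0.0
        assert res.p.iloc[0] == 1.0

    def test_antisymmetry(self, small_matrix):
        ab = de.pairwise_de(small_matrix, "c1", "base")
        ba = de.pairwise_de(small_matrix, "base", "c1")
        np.testing.assert_allclose(ab.lfc, -ba.lfc, atol=1e-12)
        np.testing.assert_allclose(ab.p, ba.p, atol=1e-12)

    def test_closed_form_t_oracle(self):
        # pooled-variance t computed by hand arithmetic, not via ttest_ind
        first, second = [8.0, 8.2, 8.4], [7.0, 7.2, 7.4]
        values = pd.DataFrame(
            [first + second],
            index=pd.Index(["p1"], name="probe_id"),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        design = pd.DataFrame(
            {"sample_id": values.columns, "condition": ["A"] * 3 + ["B"] * 3}
        )
        res = de.pairwise_de(de.ExpressionMatrix(values, design), "A", "B")
        sp2 = (np.var(first, ddof=1) + np.var(second, ddof=1)) / 2
        t = (np.mean(first) - np.mean(second)) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_expected = 2 * stats.t.sf(abs(t), df=4)
        assert res.lfc.iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert res.p.iloc[0] == pytest.approx(p_expected, rel=1e-12)

    def test_unknown_condition(self, small_matrix):
        with pytest.raises(KeyError):
            de.pairwise_de(small_matrix, "c1", "nope")

    def test_too_few_replicates(self, small_matrix):
        design = small_matrix.design.copy()
        design.loc[design["sample_id"].isin(["c1_r2", "c1_r3"]), "condition"] = "other"
        m = de.ExpressionMatrix(small_matrix.values, design)
        with pytest.raises(ValueError, match="replicates"):
            de.pairwise_de(m, "c1", "base")

    def test_degenerate_zero_variance(self):
        values = pd.DataFrame(
            {"a1": [5.0], "a2": [5.0], "b1": [4.0], "b2": [4.0]},
            index=pd.Index(["p1"], name="probe_id"),
        )
        design = pd.DataFrame({"sample_id": values.columns, "condition": ["A", "A", "B", "B"]})
        res = de.pairwise_de(de.ExpressionMatrix(values, design), "A", "B")
        assert res.table["degenerate"].iloc[0]
        assert res.p.iloc[0] == np.finfo(float).tiny

    def test_welch_variant_runs(self, small_matrix):
        res = de.pairwise_de(small_matrix, "c1", "base", equal_var=False)
        assert ((res.p > 0) & (res.p <= 1)).all()


def _result_from_rows(rows):
    table = pd.DataFrame(rows).set_index("probe_id")
    table["degenerate"] = False
    return de.DEResult(contrast=("A", "B"), table=table)


class TestSelectSignificant:
    def test_boundary_lfc_inclusive_p_strict(self):
        res = _result_from_rows(
            [
                {"probe_id": "at_lfc", "lfc": 0.5, "p": 1e-5},
                {"probe_id": "at_p", "lfc": 0.8, "p": 1e-4},
                {"probe_id": "under_lfc", "lfc": 0.49, "p": 1e-6},
            ]
        )
        sig = de.select_significant(res, lfc_cut=0.5, p_cut=1e-4)
        assert set(sig.members) == {"at_lfc"}
        assert sig.members["at_lfc"] == 1

    def test_direction_is_sign_of_lfc(self):
        res = _result_from_rows(
            [
                {"probe_id": "up", "lfc": 1.0, "p": 1e-6},
                {"probe_id": "dn", "lfc": -1.0, "p": 1e-6},
            ]
        )
        sig = de.select_significant(res)
        assert sig.members == {"up": 1, "dn": -1}

    def test_invalid_cutoffs(self):
        res = _result_from_rows([{"probe_id": "p", "lfc": 1.0, "p": 0.5}])
        with pytest.raises(ValueError):
            de.select_significant(res, lfc_cut=0.0)
        with pytest.raises(ValueError):
            de.select_significant(res, p_cut=-1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_monotonicity_in_cutoffs(self, seed):
        rng = np.random.default_rng(seed)
        res = _result_from_rows(
            [
                {"probe_id": f"p{i}", "lfc": rng.normal(0, 1), "p": rng.random()}
                for i in range(200)
            ]
        )
        tight = de.select_significant(res, lfc_cut=0.5, p_cut=0.01)
        loose_p = de.select_significant(res, lfc_cut=0.5, p_cut=0.1)
        loose_lfc = de.select_significant(res, lfc_cut=0.2, p_cut=0.01)
        assert set(tight.members) <= set(loose_p.members)
        assert set(tight.members) <= set(loose_lfc.members)

    def test_planted_signal_sensitivity(self):
        # cutoffs chosen for n=3 triplicates: a plain t-test with df=4 cannot
        # reach p < 1e-4 at moderate effects, so recovery is checked at 0.01
        truth = ExpressionTruth(
            n_probes=5000, de_fraction_per_contrast=0.1,
            effect_range=(1.5, 2.5), noise_sd=0.25, seed=11,
        )
        matrix, labels = simulate_expression(truth)
        sig = de.select_significant(
            de.pairwise_de(matrix, "c1", "base"), lfc_cut=0.5, p_cut=0.01
        )
        planted = labels.index[labels["dir_c1"] != 0]
        hits = [p for p in planted if p in sig.members]
        sensitivity = len(hits) / len(planted)
        sign_acc = np.mean([sig.members[p] == labels.loc[p, "dir_c1"] for p in hits])
        assert sensitivity >= 0.9
        assert sign_acc >= 0.99

    def test_type_i_control_under_global_null(self):
        truth = ExpressionTruth(n_probes=20000, de_fraction_per_contrast=0.0, seed=5)
        matrix, _ = simulate_expression(truth)
        res = de.pairwise_de(matrix, "c1", "base")
        p_cut = 0.01
        frac = (res.p < p_cut).mean()
        se = np.sqrt(p_cut * (1 - p_cut) / 20000)
        assert frac <= p_cut + 3 * se


class TestUnionSignificant:
    def test_disjoint_sizes(self):
        uni = frozenset(f"p{i}" for i in range(10))
        a = de.SignificantSet(("a", "b"), 0.5, 1e-4, {"p0": 1, "p1": 1, "p2": -1}, uni)
        b = de.SignificantSet(("c", "b"), 0.5, 1e-4, {"p3": 1, "p4": -1, "p5": 1, "p6": -1}, uni)
        union = de.union_significant([a, b])
        assert len(union) == 7

    def test_idempotence(self):
        uni = frozenset(["p1", "p2", "p3"])
        a = de.SignificantSet(("a", "b"), 0.5, 1e-4, {"p1": 1, "p2": -1}, uni)
        union = de.union_significant([a, a])
        assert len(union) == 2
        assert set(union.index) == {"p1", "p2"}

    def test_mismatched_universe(self):
        a = de.SignificantSet(("a", "b"), 0.5, 1e-4, {"p1": 1}, frozenset(["p1"]))
        b = de.SignificantSet(("c", "b"), 0.5, 1e-4, {"p2": 1}, frozenset(["p2"]))
        with pytest.raises(ValueError, match="universe"):
            de.union_significant([a, b])

    def test_directions_recorded_per_contrast(self):
        uni = frozenset(["p1", "p2"])
        a = de.SignificantSet(("a", "b"), 0.5, 1e-4, {"p1": 1}, uni)
        b = de.SignificantSet(("c", "b"), 0.5, 1e-4, {"p1": -1, "p2": 1}, uni)
        union = de.union_significant([a, b])
        assert union.loc["p1", "a-b"] == 1
        assert union.loc["p1", "c-b"] == -1
        assert union.loc["p2", "a-b"] == 0


class TestCollapseToGenes:
    def test_keeps_largest_lfc_and_drops_unannotated(self):
        res = _result_from_rows(
            [
                {"probe_id": "p1", "lfc": 0.5, "p": 0.01},
                {"probe_id": "p2", "lfc": -2.0, "p": 0.01},
                {"probe_id": "p3", "lfc": 1.0, "p": 0.01},
            ]
        )
        ann = pd.DataFrame(
            {"probe_id": ["p1", "p2"], "gene": ["g1", "g1"]}
        )
        collapsed = de.collapse_to_genes(res, ann)
        assert list(collapsed.table.index) == ["p2"]
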