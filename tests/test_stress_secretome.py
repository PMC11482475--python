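import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanopotency import (
    filter_responders,
    gsh_gssg_fc,
    hierarchical_cluster,
    oxidative_stress_table,
    protein_fold_change,
)
from nanopotency.errors import DegenerateRowError, KeyingError, ValidationError


class TestGshGssgFc:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((100, 25, 100, 25), 1.0),       # treated == control
            ((50, 50, 100, 25), 0.25),       # GSH halved, GSSG doubled
            ((80, 40, 100, 25), 0.5),
        ],
    )
    def test_ratio_of_ratios(self, args, expected):
        assert gsh_gssg_fc(*args) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            gsh_gssg_fc(0.0, 40, 100, 25)

    def test_table_control_fc_is_one(self):
        df = pd.DataFrame(
            {
                "treatment": ["control", "control", "NP", "NP"],
                "gsh": [100.0, 110.0, 40.0, 44.0],
                "gssg": [25.0, 25.0, 50.0, 50.0],
            }
        )
        out = oxidative_stress_table(df).set_index("treatment")
        assert out.loc["control", "ratio_fc"] == pytest.approx(1.0)
        assert out.loc["NP", "ratio_fc"] < 1.0  # oxidative stress


class TestProteinFoldChange:
    def test_treated_equal_control_gives_ones(self):
        s = pd.Series({"IL-6": 10.0, "TNF-a": 20.0})
        assert (protein_fold_change(s, s) == 1.0).all()

    def test_per_protein_ratio(self):
        treated = pd.Series({"IL-6": 5.0, "TNF-a": 60.0})
        control = pd.Series({"IL-6": 10.0, "TNF-a": 20.0})
        fc = protein_fold_change(treated, control)
        assert fc["IL-6"] == pytest.approx(0.5)
        assert fc["TNF-a"] == pytest.approx(3.0)

    def test_mismatched_protein_sets_rejected(self):
        with pytest.raises(KeyingError):
            protein_fold_change(
                pd.Series({"IL-6": 1.0}), pd.Series({"IL-8": 1.0})
            )


class TestFilterResponders:
    def matrix(self, values):
        return pd.DataFrame({"t1": values}, index=[f"P{i}" for i in range(len(values))])

    def test_boundary_inclusive_two_sided(self):
        m = self.matrix([1.5, 1.49, 0.60, 0.67, 1.0])
        kept = filter_responders(m, cutoff=1.5)
        # 1.5 on the boundary kept; 0.60 < 1/1.5 kept; 0.67 and 1.49 inside band
        assert list(kept.index) == ["P0", "P2"]

    def test_cutoff_must_exceed_one(self):
        with pytest.raises(ValidationError):
            filter_responders(self.matrix([2.0]), cutoff=1.0)

    @settings(deadline=None, max_examples=25)
    @given(
        c1=st.floats(min_value=1.1, max_value=3.0),
        c2=st.floats(min_value=1.1, max_value=3.0),
    )
    def test_monotone_in_cutoff(self, c1, c2):
        lo, hi = sorted((c1, c2))
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            np.exp(rng.normal(0, 0.7, size=(12, 3))),
            index=[f"P{i}" for i in range(12)],
            columns=list("abc"),
        )
        assert set(filter_responders(m, hi).index) <= set(filter_responders(m, lo).index)


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero_height(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 4.0], [1.0, 2.0, 4.0], [4.0, 2.0, 1.0]],
            index=["a", "b", "c"],
            columns=["t1", "t2", "t3"],
        )
        res = hierarchical_cluster(m, distance="euclidean")
        first = res.merge_table("rows").iloc[0]
        assert {first["member_a"], first["member_b"]} == {0, 1}
        assert first["height"] == pytest.approx(0.0)

    def test_perfectly_correlated_rows_merge_first_under_pearson(self):
        # log2 of rows (1,2,3) and (2,4,6) differ by a constant => r = 1,
        # distance 0; the reversed row sits at distance 2 from both
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]],
            index=["a", "b", "c"],
            columns=["t1", "t2", "t3"],
        )
        res = hierarchical_cluster(m, distance="pearson")
        first = res.merge_table("rows").iloc[0]
        assert {first["member_a"], first["member_b"]} == {0, 1}
        assert first["height"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_row_rejected_by_name_under_pearson(self):
        m = pd.DataFrame(
            [[2.0, 2.0, 2.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]],
            index=["flat", "x", "y"],
            columns=["t1", "t2", "t3"],
        )
        with pytest.raises(DegenerateRowError, match="flat"):
            hierarchical_cluster(m, distance="pearson")

    def test_merge_heights_nondecreasing_and_leaf_order_permutes(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(
            np.exp(rng.normal(size=(10, 6))),
            index=[f"P{i}" for i in range(10)],
            columns=[f"T{j}" for j in range(6)],
        )
        for linkage in ("average", "complete"):
            res = hierarchical_cluster(m, linkage=linkage)
            heights = res.merge_table("rows")["height"].to_numpy()
            assert np.all(np.diff(heights) >= -1e-12)
            assert sorted(res.row_order) == sorted(m.index)
            assert sorted(res.col_order) == sorted(m.columns)

    def test_pearson_clustering_invariant_to_row_scaling_of_log_matrix(self):
        rng = np.random.default_rng(8)
        log2 = rng.normal(size=(6, 5))
        scales = rng.uniform(0.5, 3.0, size=(6, 1))
        m1 = pd.DataFrame(2.0**log2)
        m2 = pd.DataFrame(2.0 ** (log2 * scales))
        r1 = hierarchical_cluster(m1, distance="pearson")
        r2 = hierarchical_cluster(m2, distance="pearson")
        assert np.allclose(r1.row_linkage[:, 2], r2.row_linkage[:, 2])
        assert r1.row_order == r2.row_order
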