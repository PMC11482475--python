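import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from nanopotency import holm_sidak, one_way_anova, pairwise_contrasts, two_way_anova
from nanopotency.errors import DesignError, ValidationError


def balanced_2x2(values):
    """Factorial frame from four cells x two replicates, row-major."""
    rows = []
    cells = [("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2")]
    for (a, b), pair in zip(cells, values):
        for v in pair:
            rows.append({"A": a, "B": b, "fe": float(v)})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_constant_responses_give_zero_f(self):
        df = balanced_2x2([(5, 5), (5, 5), (5, 5), (5, 5)])
        res = two_way_anova(df, factor_a="A", factor_b="B", transform="none")
        assert all(t.F == 0.0 for t in res.terms)

    def test_matches_hand_computed_sums_of_squares(self):
        # cells {10,12 | 20,22 | 30,32 | 40,42}: SSA=800, SSB=200, SSAB=0,
        # SSE=8 on 4 df => F_A=400, F_B=100, F_AB=0
        df = balanced_2x2([(10, 12), (20, 22), (30, 32), (40, 42)])
        res = two_way_anova(df, factor_a="A", factor_b="B", transform="none")
        assert res.term("A").F == pytest.approx(400.0)
        assert res.term("B").F == pytest.approx(100.0)
        assert res.term("A:B").F == pytest.approx(0.0, abs=1e-10)
        assert res.term("A").df == 1 and res.term("A").df_resid == 4

    def test_rank_path_equals_none_path_on_ranks(self):
        rng = np.random.default_rng(5)
        df = balanced_2x2(rng.normal(size=(4, 2)))
        ranked = df.assign(fe=stats.rankdata(df["fe"]))
        via_transform = two_way_anova(df, factor_a="A", factor_b="B", transform="rank")
        direct = two_way_anova(ranked, factor_a="A", factor_b="B", transform="none")
        for t1, t2 in zip(via_transform.terms, direct.terms):
            assert t1.F == pytest.approx(t2.F)

    def test_auto_transform_switches_on_non_normal_residuals(self):
        rng = np.random.default_rng(11)
        # heavy-tailed residuals in a bigger balanced design trip Shapiro-Wilk
        rows = []
        for a in ("a1", "a2", "a3"):
            for b in ("b1", "b2", "b3"):
                for _ in range(6):
                    rows.append({"A": a, "B": b, "fe": float(rng.standard_cauchy())})
        res = two_way_anova(pd.DataFrame(rows), factor_a="A", factor_b="B",
                            transform="auto")
        assert res.transform == "rank"

    def test_unbalanced_design_rejected(self):
        df = balanced_2x2([(10, 12), (20, 22), (30, 32), (40, 42)]).iloc[:-1]
        with pytest.raises(DesignError, match="balanced"):
            two_way_anova(df, factor_a="A", factor_b="B")

    def test_single_replicate_rejected(self):
        df = balanced_2x2([(10,), (20,), (30,), (40,)])
        with pytest.raises(DesignError, match="replicates"):
            two_way_anova(df, factor_a="A", factor_b="B")

    def test_shift_invariance_and_monotone_rank_invariance(self):
        rng = np.random.default_rng(9)
        df = balanced_2x2(rng.normal(size=(4, 2)))
        base = two_way_anova(df, factor_a="A", factor_b="B", transform="none")
        shifted = two_way_anova(
            df.assign(fe=df["fe"] + 100.0), factor_a="A", factor_b="B",
            transform="none",
        )
        scaled = two_way_anova(
            df.assign(fe=df["fe"] * 7.5), factor_a="A", factor_b="B",
            transform="none",
        )
        monotone = two_way_anova(
            df.assign(fe=np.exp(df["fe"])), factor_a="A", factor_b="B",
            transform="rank",
        )
        rank_base = two_way_anova(df, factor_a="A", factor_b="B", transform="rank")
        for t_base, t_shift, t_scale in zip(base.terms, shifted.terms, scaled.terms):
            assert t_base.F == pytest.approx(t_shift.F)
            assert t_base.F == pytest.approx(t_scale.F)
        for t_rank, t_mono in zip(rank_base.terms, monotone.terms):
            assert t_rank.F == pytest.approx(t_mono.F)


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([[3.0, 3.0], [3.0, 3.0]])
        assert res.term("group").F == 0.0

    def test_hand_computed_f(self):
        # MSB = 13.5, MSW = 1 => F = 13.5
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert res.term("group").F == pytest.approx(13.5)
        assert res.term("group").df == 1
        assert res.term("group").df_resid == 4

    def test_small_group_rejected(self):
        with pytest.raises(DesignError):
            one_way_anova([[1.0, 2.0], [3.0]])


class TestHolmSidak:
    def test_single_comparison_unchanged(self):
        assert holm_sidak([0.03]).adjusted_p[0] == pytest.approx(0.03)

    def test_two_step_formula(self):
        adj = holm_sidak([0.01, 0.04]).adjusted_p
        assert adj[0] == pytest.approx(1 - 0.99**2)  # 0.0199
        assert adj[1] == pytest.approx(0.04)

    def test_monotonicity_propagates_through_ties(self):
        adj = holm_sidak([0.02, 0.02, 0.02]).adjusted_p
        assert np.allclose(adj, 1 - 0.98**3)  # 0.058808

    def test_matches_reference_implementation_on_random_inputs(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 12))
            ours = holm_sidak(p).adjusted_p
            theirs = multipletests(p, method="holm-sidak")[1]
            assert np.allclose(ours, theirs)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            holm_sidak([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10)
    )
    def test_dominated_by_bonferroni_and_above_raw(self, p):
        p = np.asarray(p)
        adj = holm_sidak(p).adjusted_p
        bonf = np.minimum(p * p.size, 1.0)
        assert np.all(adj <= bonf + 1e-12)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestPairwiseContrasts:
    def test_vs_control_family_size_and_labels(self):
        rng = np.random.default_rng(2)
        groups = {name: rng.normal(size=6) for name in ("control", "t1", "t2", "t3")}
        out = pairwise_contrasts(groups, control="control")
        assert len(out.labels) == 3
        assert all("control" in lab for lab in out.labels)

    def test_all_pairs_family(self):
        rng = np.random.default_rng(2)
        groups = {name: rng.normal(size=5) for name in ("a", "b", "c")}
        out = pairwise_contrasts(groups, family="all_pairs")
        assert len(out.labels) == 3
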