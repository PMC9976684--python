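import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import capomics as c
from capomics.differential import UntestableError

from conftest import make_metadata, make_table


def brute_force_bh(p):
    """Independent step-up oracle: sort, scale, suffix-min, unsort."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestWelchT:
    def test_matches_closed_form_on_worked_example(self):
        # t = (11-2)/sqrt(1/3 + 1/3) = 9/sqrt(2/3); Welch-Satterthwaite df = 4
        t, df, p = c.welch_t([10, 11, 12], [1, 2, 3])
        t_expected = 9 / np.sqrt(2 / 3)
        assert t == pytest.approx(t_expected, abs=1e-8)
        assert df == pytest.approx(4.0, abs=1e-8)
        assert p == pytest.approx(2 * stats.t.sf(t_expected, 4), abs=1e-12)

    def test_identical_samples_give_t_zero_p_one(self):
        t, _, p = c.welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == 1.0

    def test_p_symmetric_under_swap(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 2, 6)
        t1, df1, p1 = c.welch_t(x, y)
        t2, df2, p2 = c.welch_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("x,y", [([1.0], [1, 2, 3]), ([1, 1, 1], [2, 2, 2])])
    def test_untestable_inputs_raise_typed_error(self, x, y):
        with pytest.raises(UntestableError):
            c.welch_t(x, y)


class TestBhFdr:
    def test_worked_step_up_example(self):
        np.testing.assert_allclose(
            c.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_is_its_own_q(self):
        assert c.bh_fdr([0.3]) == pytest.approx([0.3])

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(c.bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            c.bh_fdr([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.randoms())
    def test_permutation_invariance(self, ps, rand):
        q = c.bh_fdr(ps)
        perm = list(range(len(ps)))
        rand.shuffle(perm)
        q_perm = c.bh_fdr([ps[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.data())
    def test_monotonicity_raising_a_p_never_lowers_any_q(self, ps, data):
        idx = data.draw(st.integers(0, len(ps) - 1))
        bumped = list(ps)
        bumped[idx] = data.draw(st.floats(ps[idx], 1.0))
        assert (c.bh_fdr(bumped) >= c.bh_fdr(ps) - 1e-12).all()


class TestCallDifferential:
    def _table_with_known_fc(self, fc, n=6, base=100.0, spread=1.0):
        rng = np.random.default_rng(5)
        x = base * fc + spread * rng.standard_normal(n)
        y = base + spread * rng.standard_normal(n)
        vals = np.concatenate([x, y])[None, :]
        table = make_table(vals, features=["F"], samples=[f"S{i}" for i in range(2 * n)])
        meta = make_metadata(["S_CAP"] * n + ["CON"] * n)
        return table, meta

    def test_up_call_requires_fc_and_p(self):
        table, meta = self._table_with_known_fc(1.8)
        rec = c.call_differential(table, meta, ("S_CAP", "CON"))
        assert rec.loc["F", "status"] == "up"
        assert rec.loc["F", "p"] < 0.05
        assert rec.loc["F", "q"] >= rec.loc["F", "p"]

    def test_exact_threshold_fc_is_not_significant(self):
        # FC exactly 1.5 fails the strict > rule regardless of p
        x = np.array([1.5, 3.0, 4.5, 6.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        table = make_table(np.concatenate([x, y])[None, :], features=["F"],
                           samples=[f"S{i}" for i in range(8)])
        meta = make_metadata(["S_CAP"] * 4 + ["CON"] * 4)
        rec = c.call_differential(table, meta, ("S_CAP", "CON"))
        assert rec.loc["F", "fc"] == pytest.approx(1.5)
        assert rec.loc["F", "status"] == "ns"

    def test_down_call_and_fc_uses_raw_group_means(self):
        table, meta = self._table_with_known_fc(0.5)
        rec = c.call_differential(table, meta, ("S_CAP", "CON"))
        assert rec.loc["F", "status"] == "down"
        assert rec.loc["F", "fc"] == pytest.approx(
            rec.loc["F", "mean_num"] / rec.loc["F", "mean_den"]
        )

    def test_significant_implies_p_below_alpha(self, small_cohort):
        tables, meta, _ = small_cohort
        rec = c.call_differential(tables["protein"], meta, ("S_CAP", "CON"), cohort="train")
        sig = rec[rec.status != "ns"]
        assert (sig.p < 0.05).all()
        assert ((sig.fc > 1.5) | (sig.fc < 0.67)).all()

    def test_untestable_features_are_flagged_not_nan_status(self):
        vals = np.array([[np.nan, np.nan, np.nan, 2.0, 3.0, 4.0],
                         [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]])
        table = make_table(vals, features=["BAD", "OK"],
                           samples=[f"S{i}" for i in range(6)])
        meta = make_metadata(["S_CAP"] * 3 + ["CON"] * 3)
        rec = c.call_differential(table, meta, ("S_CAP", "CON"))
        assert not rec.loc["BAD", "testable"]
        assert rec.loc["BAD", "status"] == "ns"
        assert rec.loc["BAD", "skip_reason"]
        assert rec.loc["OK", "testable"]

    def test_q_gate_option_uses_adjusted_p(self, small_cohort):
        tables, meta, _ = small_cohort
        rec_p = c.call_differential(tables["metabolite"], meta, ("S_CAP", "CON"), cohort="train")
        rec_q = c.call_differential(tables["metabolite"], meta, ("S_CAP", "CON"),
                                    cohort="train", gate="q")
        called_p = set(rec_p.index[rec_p.status != "ns"])
        called_q = set(rec_q.index[rec_q.status != "ns"])
        assert called_q <= called_p


class TestVennPartition:
    def test_hand_enumerated_example(self):
        part = c.venn_partition({"ab": {"A", "B"}, "bc": {"B", "C"}, "b": {"B"}})
        assert part.triple_overlap == 1
        assert part.regions == {
            "100": 1, "010": 1, "001": 0, "110": 0, "101": 0, "011": 0, "111": 1,
        }
        assert part.union_size == 3

    def test_empty_sets_give_zero_regions(self):
        part = c.venn_partition({"a": set(), "b": set(), "c": set()})
        assert all(v == 0 for v in part.regions.values())

    def test_regions_partition_the_union(self, rng):
        for _ in range(25):
            sets = {
                name: set(rng.choice(40, size=rng.integers(0, 25), replace=False).tolist())
                for name in ("x", "y", "z")
            }
            part = c.venn_partition(sets)
            assert part.union_size == len(sets["x"] | sets["y"] | sets["z"])
            for name, bit in zip(("x", "y", "z"), range(3)):
                total = sum(v for k, v in part.regions.items() if k[bit] == "1")
                assert total == part.set_sizes[name]

    def test_mixed_layers_rejected(self, small_cohort):
        tables, meta, _ = small_cohort
        rec_p = c.call_differential(tables["protein"], meta, ("S_CAP", "CON"), cohort="train")
        rec_m = c.call_differential(tables["metabolite"], meta, ("S_CAP", "CON"), cohort="train")
        rec_p2 = c.call_differential(tables["protein"], meta, ("NS_CAP", "CON"), cohort="train")
        with pytest.raises(ValueError, match="universe"):
            c.venn_partition({"a": rec_p, "b": rec_m, "c": rec_p2})


class TestSpearmanClinical:
    def _setup(self):
        vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        table = make_table(vals, features=["F"], samples=[f"S{i}" for i in range(5)])
        meta = make_metadata(["CON"] * 5)
        return table, meta

    def test_feature_identical_to_index_gives_rho_one(self):
        table, meta = self._setup()
        meta["IDX"] = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, p, n = c.spearman_clinical(table, meta, ["F"], ["IDX"])
        assert rho.loc["F", "IDX"] == pytest.approx(1.0)

    def test_negated_index_gives_rho_minus_one(self):
        table, meta = self._setup()
        meta["IDX"] = [-1.0, -2.0, -3.0, -4.0, -5.0]
        rho, _, _ = c.spearman_clinical(table, meta, ["F"], ["IDX"])
        assert rho.loc["F", "IDX"] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 1.0, 2.0])
        y = np.array([3.0, 5.0, 4.0])
        table = make_table(x[None, :], features=["F"], samples=["S0", "S1", "S2"])
        meta = make_metadata(["CON"] * 3)
        meta["IDX"] = y
        rho, _, _ = c.spearman_clinical(table, meta, ["F"], ["IDX"])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["F", "IDX"] == pytest.approx(oracle)

    def test_too_few_pairs_marked_untestable(self):
        table, meta = self._setup()
        meta["IDX"] = [1.0, 2.0, np.nan, np.nan, np.nan]
        rho, p, n = c.spearman_clinical(table, meta, ["F"], ["IDX"])
        assert n.loc["F", "IDX"] == 2
        assert np.isnan(rho.loc["F", "IDX"]) and np.isnan(p.loc["F", "IDX"])
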