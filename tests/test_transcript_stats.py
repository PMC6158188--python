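"""Expression filtering, fuzzy clustering, differential statistics,
directional gene-set analysis and over-representation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fluxomix.synthetic_data import make_synthetic_expression
from fluxomix.transcript_stats import (
    ExpressionMatrix,
    annotate_clusters,
    bh_adjust,
    differential_stats,
    estimate_fuzzifier,
    fcm_objective,
    filter_low_expression,
    fuzzy_cmeans,
    gene_set_analysis,
    ora_hypergeometric,
    read_gmt,
    standardize_profiles,
    write_gmt,
)

from oracles import bh_stepup_by_hand, hypergeom_tail_exact


def make_expression(values, times, reps=None, phases=None):
    values = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(np.shape(values)[0])],
        columns=[f"s{j}" for j in range(np.shape(values)[1])],
    )
    samples = pd.DataFrame(
        {
            "time_h": times,
            "replicate": reps if reps is not None else [1] * len(times),
        },
        index=values.columns,
    )
    if phases is not None:
        samples["phase"] = phases
    return ExpressionMatrix(values=values, samples=samples)


class TestFilter:
    def test_gene_silent_at_two_of_four_timepoints_removed(self):
        mat = make_expression(
            [[0.0, 0.0, 5.0, 5.0], [3.0, 3.0, 3.0, 3.0]], times=[1, 2, 3, 4]
        )
        out = filter_low_expression(mat)
        assert list(out.values.index) == ["g1"]

    def test_all_expressed_genes_pass_through_unchanged(self):
        mat = make_expression(np.full((4, 4), 7.0), times=[1, 2, 3, 4])
        out = filter_low_expression(mat)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_planted_low_gene_count(self):
        vals = np.full((10, 4), 10.0)
        vals[[2, 5, 7], :2] = 0.2  # low at 2 of 4 time points
        mat = make_expression(vals, times=[1, 2, 3, 4])
        out = filter_low_expression(mat, fpkm_threshold=1.0, min_low_timepoints=2)
        assert out.values.shape[0] == 7

    def test_replicates_averaged_before_thresholding(self):
        # replicate means straddle the threshold: (0.4 + 1.8)/2 = 1.1 > 1
        vals = np.array([[0.4, 1.8, 0.4, 1.8]])
        mat = make_expression(vals, times=[1, 1, 2, 2], reps=[1, 2, 1, 2])
        out = filter_low_expression(mat)
        assert out.values.shape[0] == 1

    def test_negative_threshold_rejected(self):
        mat = make_expression(np.full((2, 4), 5.0), times=[1, 2, 3, 4])
        with pytest.raises(ValueError):
            filter_low_expression(mat, fpkm_threshold=-1.0)


class TestStandardize:
    def test_rows_are_zscores_and_constant_genes_dropped(self):
        vals = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
        mat = make_expression(vals, times=[1, 2, 3, 4])
        prof = standardize_profiles(mat)
        assert list(prof.index) == ["g0"]
        expect = (vals[0] - vals[0].mean()) / vals[0].std()
        np.testing.assert_allclose(prof.loc["g0"].to_numpy(), expect)


class TestFuzzifier:
    def test_formula_evaluates_as_direct_substitution(self):
        prof = pd.DataFrame(np.zeros((1000, 4)))
        N, D = 1000, 4
        expect = (
            1
            + (1418 / N + 22.05) * D**-2
            + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
        )
        assert estimate_fuzzifier(prof) == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("N", [10, 100, 5000])
    def test_exceeds_one_and_decreases_with_profile_length(self, N):
        ms = [
            estimate_fuzzifier(pd.DataFrame(np.zeros((N, D))))
            for D in (3, 5, 9, 17)
        ]
        assert all(m > 1 for m in ms)
        assert all(a > b for a, b in zip(ms, ms[1:]))


class TestFuzzyCmeans:
    def test_memberships_rows_sum_to_one(self, rng):
        prof = pd.DataFrame(rng.normal(size=(40, 4)))
        fc = fuzzy_cmeans(prof, k=3, m=1.8, seed=0)
        np.testing.assert_allclose(
            fc.memberships.sum(axis=1).to_numpy(), 1.0, atol=1e-9
        )

    def test_two_separated_shapes_give_confident_memberships(self, rng):
        up = np.tile([-1.0, -0.3, 0.3, 1.0], (20, 1))
        down = -up
        prof = pd.DataFrame(
            np.vstack([up, down]) + rng.normal(0, 0.05, (40, 4))
        )
        fc = fuzzy_cmeans(prof, k=2, m=1.2, seed=1)
        own = fc.memberships.to_numpy().max(axis=1)
        assert own.min() > 0.95
        hard = fc.assignment(min_membership=0.0).to_numpy()
        assert len(set(hard[:20])) == 1 and len(set(hard[20:])) == 1
        assert hard[0] != hard[-1]

    def test_point_coincident_with_center_gets_full_membership(self):
        base = np.array(
            [[0.0, 1.0, 0.0, -1.0], [1.0, -1.0, 1.0, -1.0], [0.5, 0.5, -0.5, -0.5]]
        )
        prof = pd.DataFrame(np.vstack([base, base, base[:1]]))
        fc = fuzzy_cmeans(prof, k=3, m=2.0, seed=2)
        d2 = ((prof.to_numpy()[:, None, :] - fc.centers[None]) ** 2).sum(axis=2)
        coincident = np.where(d2.min(axis=1) < 1e-30)[0]
        for i in coincident:
            assert fc.memberships.to_numpy()[i].max() == pytest.approx(1.0)

    def test_objective_non_increasing_across_iterations(self, rng):
        prof = pd.DataFrame(rng.normal(size=(60, 4)))
        X = prof.to_numpy()
        objs = []
        # re-run with increasing iteration caps; FCM's alternating updates
        # must never increase the objective
        for it in (1, 2, 4, 8, 16):
            fc = fuzzy_cmeans(prof, k=3, m=2.0, max_iter=it, seed=5)
            objs.append(
                fcm_objective(X, fc.memberships.to_numpy(), fc.centers, 2.0)
            )
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_k_larger_than_gene_count_rejected(self, rng):
        prof = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError, match="exceeds"):
            fuzzy_cmeans(prof, k=5, m=2.0)

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_planted_pattern_recovery(self, seed):
        """Four planted temporal patterns at noise sd 0.2: the thresholded
        hard assignment recovers the planted partition (unassigned genes
        counting as their own group)."""
        from sklearn.metrics import adjusted_rand_score

        mat, _, truth = make_synthetic_expression(seed=seed)
        prof = standardize_profiles(filter_low_expression(mat))
        fc = fuzzy_cmeans(prof, k=4, m=estimate_fuzzifier(prof), seed=seed)
        hard = fc.assignment()
        labels_true = [truth["pattern_of"][g] for g in hard.index]
        assert adjusted_rand_score(labels_true, hard.to_numpy()) >= 0.9

    def test_reproducible_given_seed(self, rng):
        prof = pd.DataFrame(rng.normal(size=(30, 4)))
        a = fuzzy_cmeans(prof, k=3, m=2.0, seed=9)
        b = fuzzy_cmeans(prof, k=3, m=2.0, seed=9)
        pd.testing.assert_frame_equal(a.memberships, b.memberships)

    def test_cluster_annotation_counts(self, rng):
        up = np.tile([-1.0, 0.0, 0.0, 1.0], (10, 1))
        prof = pd.DataFrame(
            np.vstack([up, -up]) + rng.normal(0, 0.05, (20, 4)),
            index=[f"g{i}" for i in range(20)],
        )
        fc = fuzzy_cmeans(prof, k=2, m=1.3, seed=0)
        ann = annotate_clusters(fc, ["g0", "g1", "g15"])
        assert ann["n_annotated"].sum() == 3
        assert ann["n_genes"].sum() == 20


class TestDifferentialStats:
    def test_identical_phases_are_null(self):
        vals = np.tile([4.0, 4.0, 4.0, 4.0], (3, 1))
        mat = make_expression(
            vals, times=[1, 1, 2, 2], reps=[1, 2, 1, 2],
            phases=["a", "a", "b", "b"],
        )
        st = differential_stats(mat, "a", "b")
        assert np.allclose(st.table["log2fc"], 0.0)
        assert np.allclose(st.table["p"], 1.0)

    def test_fourfold_increase_on_offset_scale(self):
        # means 3 -> 15: log2(16/4) = 2 exactly on the +1 offset scale
        vals = np.array([[3.0, 3.0, 15.0, 15.0]])
        mat = make_expression(
            vals, times=[1, 1, 2, 2], reps=[1, 2, 1, 2],
            phases=["a", "a", "b", "b"],
        )
        st = differential_stats(mat, "a", "b")
        assert st.table["log2fc"].iloc[0] == pytest.approx(2.0)
        assert st.table["direction"].iloc[0] == 1

    def test_single_replicate_gives_fold_change_only(self):
        vals = np.array([[2.0, 6.0]])
        mat = make_expression(vals, times=[1, 2], phases=["a", "b"])
        st = differential_stats(mat, "a", "b")
        assert np.isnan(st.table["p"].iloc[0])
        assert st.table["log2fc"].iloc[0] == pytest.approx(np.log2(7 / 3))

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_null_pvalues_uniform(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(3.0, 1.0, size=(2000, 6))
        mat = make_expression(
            vals, times=[1, 1, 1, 2, 2, 2], reps=[1, 2, 3, 1, 2, 3],
            phases=["a", "a", "a", "b", "b", "b"],
        )
        st = differential_stats(mat, "a", "b")
        ks = sps.kstest(st.table["p"], "uniform").statistic
        assert ks < 0.05


class TestGeneSetAnalysis:
    @staticmethod
    def _stats_from(t_values, gene_ids=None):
        from fluxomix.transcript_stats import GeneLevelStats

        gene_ids = gene_ids or [f"g{i}" for i in range(len(t_values))]
        t = np.asarray(t_values, dtype=float)
        table = pd.DataFrame(
            {
                "log2fc": t,
                "t": t,
                "p": np.full(len(t), 0.5),
                "direction": np.sign(t).astype(int),
            },
            index=gene_ids,
        )
        return GeneLevelStats(table=table, phase_a="a", phase_b="b")

    def test_top_positive_set_attains_minimal_empirical_p(self, rng):
        t = rng.normal(size=500)
        st = self._stats_from(t)
        top = list(st.table["t"].nlargest(20).index)
        res = gene_set_analysis(st, {"top": top}, n_perm=999, seed=0)
        assert res.table.loc["top", "p_distinct_up"] == pytest.approx(1 / 1000)

    def test_all_zero_statistics_give_p_one(self):
        st = self._stats_from(np.zeros(100))
        res = gene_set_analysis(
            st, {"s": [f"g{i}" for i in range(10)]}, n_perm=199, seed=0
        )
        row = res.table.loc["s"]
        for cls in ("distinct_up", "distinct_down", "non_directional"):
            assert row[f"p_{cls}"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_half_up_half_down_set_is_mixed_not_distinct(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(scale=1.0, size=400)
        t[:10] = rng.normal(4.0, 0.3, 10)    # strong up subset
        t[10:20] = rng.normal(-4.0, 0.3, 10)  # strong down subset
        st = self._stats_from(t)
        mixed = [f"g{i}" for i in range(20)]
        res = gene_set_analysis(st, {"mixed": mixed}, n_perm=999, seed=seed)
        row = res.table.loc["mixed"]
        assert row["p_mixed_up"] < 0.01
        assert row["p_mixed_down"] < 0.01
        assert row["p_distinct_up"] > 0.1
        assert row["p_distinct_down"] > 0.1

    def test_uncovered_and_empty_sets_skipped_with_notice(self, rng):
        st = self._stats_from(rng.normal(size=50))
        sets = {
            "ok": [f"g{i}" for i in range(10)],
            "alien": ["x1", "x2", "x3"],
            "thin": ["g1", "x9", "x10", "x11", "x12"],
        }
        res = gene_set_analysis(st, sets, n_perm=99, seed=0)
        assert list(res.table.index) == ["ok"]
        assert {s for s, _ in res.skipped} == {"alien", "thin"}

    def test_deterministic_given_seed(self, rng):
        st = self._stats_from(rng.normal(size=200))
        sets = {"s1": [f"g{i}" for i in range(15)], "s2": [f"g{i}" for i in range(30, 60)]}
        a = gene_set_analysis(st, sets, n_perm=199, seed=42).table
        b = gene_set_analysis(st, sets, n_perm=199, seed=42).table
        pd.testing.assert_frame_equal(a, b)


class TestOra:
    def test_complete_overlap_probability_closed_form(self):
        universe = [f"g{i}" for i in range(10)]
        sets = {"s": universe[:4]}
        res = ora_hypergeometric(universe[:4], universe, sets)
        from math import comb

        assert res.loc["s", "p"] == pytest.approx(1 / comb(10, 4))

    def test_zero_overlap_boundary(self):
        universe = [f"g{i}" for i in range(10)]
        res = ora_hypergeometric(
            universe[5:7], universe, {"s": universe[:3]}
        )
        assert res.loc["s", "overlap"] == 0
        assert res.loc["s", "p"] == pytest.approx(1.0)

    def test_matches_exact_pmf_tail_summation(self):
        universe = [f"g{i}" for i in range(20)]
        selected = universe[:5]
        sets = {"s": universe[1:6]}  # overlap 4, K=5
        res = ora_hypergeometric(selected, universe, sets)
        assert res.loc["s", "p"] == pytest.approx(
            hypergeom_tail_exact(4, 20, 5, 5), rel=1e-12
        )

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="x1"):
            ora_hypergeometric(["g1", "x1"], ["g1", "g2"], {"s": ["g1"]})


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_stay_equal(self):
        q = bh_adjust([0.2, 0.2, 0.2])
        np.testing.assert_allclose(q, 0.2)

    def test_matches_hand_stepup_and_dominates_p(self, rng):
        p = rng.uniform(0.001, 1.0, size=15)
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_stepup_by_hand(p), atol=1e-12)
        assert np.all(q >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        sets = {"a": ["g1", "g2"], "b": ["g3"]}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets
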