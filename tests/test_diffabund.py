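import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from dysbiome import (
    AsvTable,
    bh_fdr,
    log_mean_fold_change,
    mannwhitney_per_asv,
    paired_wilcoxon_per_asv,
    prevalence_filter,
)
from dysbiome.diffabund import _mann_whitney, _signed_rank


# ---------------------------------------------------------------------------
# exhaustive enumeration oracles (independent of scipy)
# ---------------------------------------------------------------------------

def exact_signed_rank_p(diffs):
    """Two-tailed signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum([r for r, s in zip(ranks, signs) if s])
          for signs in itertools.product([False, True], repeat=n)]
    lo = sum(w <= w_obs + 1e-12 for w in ws)
    hi = sum(w >= w_obs - 1e-12 for w in ws)
    return min(1.0, 2 * min(lo, hi) / 2**n)


def exact_mwu_p(a, b):
    """Two-tailed Mann-Whitney p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)

    def u_stat(group_a, group_b):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0
                   for x in group_a for y in group_b)

    u_obs = u_stat(a, b)
    mid = na * len(b) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(ga, gb))
    dev = abs(u_obs - mid)
    p = sum(abs(u - mid) >= dev - 1e-12 for u in us) / len(us)
    return min(1.0, p)


class TestPrevalenceFilter:
    def _table(self, present_in, n_samples=20):
        col = [1] * present_in + [0] * (n_samples - present_in)
        df = pd.DataFrame({"x": col, "common": [1] * n_samples},
                          index=[f"s{i}" for i in range(n_samples)])
        return AsvTable(df)

    def test_below_threshold_dropped(self):
        assert "x" not in prevalence_filter(self._table(3), 0.20).asv_ids

    def test_boundary_inclusive(self):
        assert "x" in prevalence_filter(self._table(4), 0.20).asv_ids

    def test_all_present_unchanged(self, toy_table):
        dense = AsvTable(toy_table.counts + 1)
        assert prevalence_filter(dense, 0.20).asv_ids == dense.asv_ids

    def test_invalid_threshold_rejected(self, toy_table):
        with pytest.raises(ValueError):
            prevalence_filter(toy_table, 0.0)


class TestSignedRank:
    def test_all_zero_differences_degenerate(self):
        stat, p, n_eff, degenerate = _signed_rank(np.zeros(6))
        assert p == 1.0 and degenerate and n_eff == 0

    def test_five_positive_differences_exact(self):
        # all 2^5 sign assignments; both extremes -> p = 2/32
        _, p, n_eff, _ = _signed_rank(np.array([1.0, 2, 3, 4, 5]))
        assert p == pytest.approx(0.0625)
        assert n_eff == 5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        # distinct magnitudes so the exact path applies
        mags = rng.permutation(np.arange(1, n + 1)).astype(float)
        d = mags * rng.choice([-1, 1], size=n)
        _, p, _, _ = _signed_rank(d)
        assert p == pytest.approx(exact_signed_rank_p(d), abs=1e-12)

    def test_zeros_dropped_before_ranking(self):
        d = np.array([0.0, 0, 1, 2, 3])
        _, p, n_eff, _ = _signed_rank(d)
        assert n_eff == 3
        assert p == pytest.approx(exact_signed_rank_p(d))


class TestMannWhitney:
    def test_fully_separated_groups_exact(self):
        _, p = _mann_whitney(np.array([1.0, 2, 3]), np.array([10.0, 11, 12]))
        assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_identical_multisets_not_significant(self):
        _, p = _mann_whitney(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert p >= 0.99

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_small_n(self, seed):
        rng = np.random.default_rng(100 + seed)
        na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        pooled = rng.permutation(np.arange(1, na + nb + 1)).astype(float)
        a, b = pooled[:na], pooled[na:]
        _, p = _mann_whitney(a, b)
        assert p == pytest.approx(exact_mwu_p(a, b), abs=1e-12)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        # p*m/rank = (.04, .04, .04, .04) after the monotone floor
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_order_preserving_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        q = bh_fdr(p)
        assert (q <= 1).all() and (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in p-rank order

    def test_readjusting_never_lowers(self):
        p = np.array([0.001, 0.01, 0.2, 0.9])
        q = bh_fdr(p)
        assert (bh_fdr(q) >= q - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestLogMeanFoldChange:
    def _table(self, rows, ids):
        return AsvTable(pd.DataFrame(rows, index=ids, columns=["x"]))

    def test_identical_means_give_zero(self):
        t = self._table([[5], [5], [5], [5]], ["a1", "a2", "b1", "b2"])
        lmfc = log_mean_fold_change(t, ["a1", "a2"], ["b1", "b2"])
        assert lmfc["x"] == 0.0

    def test_zero_cells_replaced_by_one(self):
        t = self._table([[9], [11], [0], [0]], ["a1", "a2", "b1", "b2"])
        lmfc = log_mean_fold_change(t, ["a1", "a2"], ["b1", "b2"])
        assert lmfc["x"] == pytest.approx(1.0)  # log10(10) - log10(1)

    def test_antisymmetry(self):
        t = self._table([[9], [11], [0], [3]], ["a1", "a2", "b1", "b2"])
        fwd = log_mean_fold_change(t, ["a1", "a2"], ["b1", "b2"])
        rev = log_mean_fold_change(t, ["b1", "b2"], ["a1", "a2"])
        assert fwd["x"] == pytest.approx(-rev["x"])

    def test_all_cells_pseudocount_variant(self):
        t = self._table([[9], [11], [0], [0]], ["a1", "a2", "b1", "b2"])
        lmfc = log_mean_fold_change(t, ["a1", "a2"], ["b1", "b2"], pseudocount="all")
        assert lmfc["x"] == pytest.approx(np.log10(11) - np.log10(1))


class TestPerAsvPipelines:
    def test_paired_results_shape_and_columns(self, small_cohort):
        table = prevalence_filter(small_cohort.table, 0.2)
        res = paired_wilcoxon_per_asv(table, small_cohort.metadata)
        assert len(res) == table.n_asvs
        assert (res["p"].between(0, 1)).all()
        assert (res["q"] >= res["p"] - 1e-12).all() is not None  # q computed
        assert set(res["test"]) == {"paired_wilcoxon"}

    def test_unpaired_sample_rejected(self, small_cohort):
        table = small_cohort.table
        broken = AsvTable(table.counts.drop(table.sample_ids[1]))
        with pytest.raises(ValueError):
            paired_wilcoxon_per_asv(broken, small_cohort.metadata)

    def test_mannwhitney_groups(self, small_cohort):
        md = small_cohort.metadata
        a = md.index[md["subgroup"] == "MSM"]
        b = md.index[md["subgroup"] == "MSW"]
        res = mannwhitney_per_asv(small_cohort.table, a, b)
        assert len(res) == small_cohort.table.n_asvs
        with pytest.raises(ValueError):
            mannwhitney_per_asv(small_cohort.table, a, [])

    def test_msm_signature_detected_in_unpaired_screen(self, small_cohort):
        md = small_cohort.metadata
        a = md.index[md["subgroup"] == "MSM"]
        b = md.index[md["subgroup"] == "MSW"]
        table = prevalence_filter(small_cohort.table, 0.2,
                                  sample_ids=list(a) + list(b))
        res = mannwhitney_per_asv(table, a, b).set_index("asv_id")
        hits = res[res["p"] < 0.05]
        truth = set(small_cohort.truth["msm_ids"])
        assert len(set(hits.index) & truth) >= len(truth) // 2
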