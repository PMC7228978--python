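import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from dysbiome import (
    canberra_matrix,
    compare_mean_distances,
    mean_distance_to_group,
    pcoa,
    permanova,
)
from dysbiome.community import permute_within_strata


def _brute_force_pseudo_f(D, labels):
    """Independent double-loop pseudo-F (Anderson's formulation)."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(D[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    a = len(groups)
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


@pytest.fixture()
def tiny_dm():
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(6, 3))
    pts[3:] += 1.5
    return DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(6)])


class TestPermanova:
    def test_exhaustive_p_equals_enumeration_oracle(self, tiny_dm):
        labels = ["x", "x", "x", "y", "y", "y"]
        strata = ["p1", "p2", "p3", "p1", "p2", "p3"]
        res = permanova(tiny_dm, labels, strata=strata, method="exhaustive")
        # oracle: enumerate every within-strata label arrangement from scratch
        D = np.asarray(tiny_dm.data)
        f_obs = _brute_force_pseudo_f(D, labels)
        hits = total = 0
        blocks = [[0, 3], [1, 4], [2, 5]]
        for choices in itertools.product([0, 1], repeat=3):
            perm = list(labels)
            for b, c in zip(blocks, choices):
                if c:
                    perm[b[0]], perm[b[1]] = perm[b[1]], perm[b[0]]
            total += 1
            if _brute_force_pseudo_f(D, perm) >= f_obs - 1e-12:
                hits += 1
        assert res.p == pytest.approx(hits / total)
        assert res.pseudo_F == pytest.approx(f_obs, rel=1e-12)

    def test_unstratified_f_matches_skbio(self, tiny_dm):
        labels = ["x", "x", "x", "y", "y", "y"]
        res = permanova(tiny_dm, labels, n_perm=9, seed=0)
        ref = skbio_permanova(tiny_dm, grouping=list(labels), permutations=9)
        assert res.pseudo_F == pytest.approx(float(ref["test statistic"]), rel=1e-8)

    def test_single_group_rejected(self, tiny_dm):
        with pytest.raises(ValueError):
            permanova(tiny_dm, ["x"] * 6)

    def test_tiny_group_rejected(self, tiny_dm):
        with pytest.raises(ValueError):
            permanova(tiny_dm, ["x", "y", "y", "y", "y", "y"])

    def test_tiny_stratum_rejected(self, tiny_dm):
        with pytest.raises(ValueError):
            permanova(tiny_dm, ["x", "x", "x", "y", "y", "y"],
                      strata=["a", "a", "a", "a", "a", "b"])

    def test_separated_clusters_hit_p_floor(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.01, (10, 2)), rng.normal(100, 0.01, (10, 2))])
        dm = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(20)])
        res = permanova(dm, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=3)
        assert res.p == pytest.approx(1 / 1000)

    def test_p_invariant_to_relabeling_and_scaling(self, tiny_dm):
        labels = ["x", "x", "x", "y", "y", "y"]
        base = permanova(tiny_dm, labels, n_perm=99, seed=5)
        renamed = permanova(tiny_dm, ["B" if l == "y" else "A" for l in labels],
                            n_perm=99, seed=5)
        scaled_dm = DistanceMatrix(np.asarray(tiny_dm.data) * 7.3, list(tiny_dm.ids))
        scaled = permanova(scaled_dm, labels, n_perm=99, seed=5)
        assert base.p == renamed.p == scaled.p

    def test_permuter_never_crosses_strata(self):
        rng = np.random.default_rng(0)
        codes = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        strata = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        for _ in range(200):
            perm = permute_within_strata(rng, codes, strata)
            for s in (0, 1):
                assert sorted(perm[strata == s]) == sorted(codes[strata == s])

    def test_p_bounds(self, tiny_dm):
        res = permanova(tiny_dm, ["x", "x", "x", "y", "y", "y"], n_perm=99, seed=1)
        assert 1 / 100 <= res.p <= 1.0


class TestPcoa:
    def test_two_samples_separated_by_their_distance(self):
        dm = DistanceMatrix([[0, 3.5], [3.5, 0]], ["a", "b"])
        res = pcoa(dm, k=1)
        coords = res.coordinates["PC1"]
        assert abs(coords["a"] - coords["b"]) == pytest.approx(3.5)

    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(12)])
        res = pcoa(dm, k=2)
        _, _, disparity = procrustes(pts, res.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_identical_samples_give_zero_coordinates(self, caplog):
        dm = DistanceMatrix(np.zeros((3, 3)), ["a", "b", "c"])
        with caplog.at_level("WARNING"):
            res = pcoa(dm, k=2)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)
        assert "truncating" in caplog.text

    def test_negative_eigenvalues_reported_but_excluded(self):
        # non-Euclidean Canberra distances typically yield negative eigenvalues
        rng = np.random.default_rng(5)
        X = rng.integers(0, 30, size=(10, 8))
        res = pcoa(canberra_matrix(X), k=3)
        assert (res.eigenvalues < 0).any()
        assert res.coordinates.shape[1] == 3

    def test_invalid_k_rejected(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ["a", "b"])
        with pytest.raises(ValueError):
            pcoa(dm, k=0)


class TestMeanDistanceToGroup:
    def test_arithmetic_mean(self):
        dm = DistanceMatrix([[0, 1, 3], [1, 0, 2], [3, 2, 0]], ["q", "r1", "r2"])
        out = mean_distance_to_group(dm, ["q"], ["r1", "r2"])
        assert out["q"] == pytest.approx(2.0)

    def test_constant_distances(self):
        n = 5
        D = np.full((n, n), 4.0)
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix(D, [f"s{i}" for i in range(n)])
        out = mean_distance_to_group(dm, ["s0", "s1"], ["s2", "s3", "s4"])
        assert np.allclose(out.to_numpy(), 4.0)

    def test_query_excluded_from_own_reference(self):
        dm = DistanceMatrix([[0, 1, 3], [1, 0, 2], [3, 2, 0]], ["a", "b", "c"])
        out = mean_distance_to_group(dm, ["a"], ["a", "b", "c"])
        assert out["a"] == pytest.approx(2.0)

    def test_empty_reference_rejected(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ["a", "b"])
        with pytest.raises(ValueError):
            mean_distance_to_group(dm, ["a"], [])


def test_rai_females_resemble_rai_msm():
    """An RAI effect shared across sexes pulls F/RAI+ communities toward the
    MSM/RAI+ reference group relative to F/RAI-."""
    from dysbiome import CohortConfig, generate_cohort

    config = CohortConfig(
        n_pairs={"F": 20, "MSM": 20}, n_asvs=200, sequencing_depth_mean=8000,
        rai_effect={i: 1.5 for i in range(100, 130)},
        rai_prob={"F": 0.4, "MSM": 0.8, "MSW": 0.0}, seed=5,
    )
    cohort = generate_cohort(config)
    md = cohort.metadata
    dm = canberra_matrix(cohort.table)
    msm_rai = md.index[(md.subgroup == "MSM") & (md.rai == "RAI+")]
    f_pos = md.index[(md.subgroup == "F") & (md.rai == "RAI+")]
    f_neg = md.index[(md.subgroup == "F") & (md.rai == "RAI-")]
    res = compare_mean_distances(dm, f_pos, f_neg, msm_rai)
    assert res["mean_a"] < res["mean_b"]
    assert res["p"] < 0.05
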