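import itertools
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conwas import (MDMR, correlation_distance, fdr_correct,
                    generate_cohort, gower_center, permutation_test,
                    pseudo_f_adjusted, pseudo_f_groups,
                    region_distance_matrix, run_mdmr)
from conwas.mdmr import _projectors

from tests.helpers import brute_force_ss, random_distance_matrix, two_group_spec

HAND_D = np.array([  # 2+2 subjects: within-pair distance 1, across 2
    [0, 1, 2, 2],
    [1, 0, 2, 2],
    [2, 2, 0, 1],
    [2, 2, 1, 0],
], dtype=float)
HAND_LABELS = np.array(["a", "a", "b", "b"])


class TestCorrelationDistance:
    def test_closed_forms(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlation_distance(v, v) == pytest.approx(0.0)          # r=1
        assert correlation_distance(v, -v) == pytest.approx(2.0)         # r=-1
        u = np.array([1.0, -1.0, 1.0, -1.0])
        w = np.array([1.0, -1.0, -1.0, 1.0])  # r=0 with u
        assert correlation_distance(u, w) == pytest.approx(np.sqrt(2))

    def test_r_half_gives_unit_distance(self):
        # construct vectors with Pearson correlation exactly 0.5
        u = np.array([1.0, -1.0, 1.0, -1.0])
        w = np.array([1.0, -1.0, -1.0, 1.0])
        v = u + np.sqrt(3) * w  # corr(u, v) = 1/2
        assert np.corrcoef(u, v)[0, 1] == pytest.approx(0.5)
        assert correlation_distance(u, v) == pytest.approx(1.0)

    def test_zero_variance_vector_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            d = correlation_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert d == pytest.approx(np.sqrt(2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            correlation_distance([1, 2, 3], [1, 2, 3, 4])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounds(self, seed):
        g = np.random.default_rng(seed)
        d = correlation_distance(g.standard_normal(6), g.standard_normal(6))
        assert 0.0 <= d <= 2.0


class TestRegionDistanceMatrix:
    def test_matches_pairwise_loop_oracle(self, rng):
        X = rng.standard_normal((7, 10))
        D = region_distance_matrix(X, 0).distances
        for u in range(7):
            for v in range(u + 1, 7):
                assert D[u, v] == pytest.approx(
                    correlation_distance(X[u], X[v]), abs=1e-12)
        np.testing.assert_array_equal(D, D.T)
        assert not np.diag(D).any()

    def test_identical_profiles_give_zero_matrix(self):
        X = np.tile(np.array([1.0, 5.0, 2.0, 4.0]), (4, 1))
        assert not region_distance_matrix(X, 0).distances.any()

    def test_cohort_interface(self, planted_cohort):
        rdm = region_distance_matrix(planted_cohort, 3)
        assert rdm.distances.shape == (planted_cohort.n_subjects,) * 2
        assert rdm.seed_region == 3


class TestPseudoF:
    def test_hand_example(self):
        res = pseudo_f_groups(HAND_D, HAND_LABELS)
        assert res.sst == pytest.approx(4.5)
        assert res.ssw == pytest.approx(1.0)
        assert res.ssa == pytest.approx(3.5)
        assert res.statistic == pytest.approx(10.5)

    @pytest.mark.parametrize("c", [0.3, 1.0, 1.7])
    def test_equal_distances_give_f_1_5(self, c):
        D = c * (np.ones((4, 4)) - np.eye(4))
        assert pseudo_f_groups(D, HAND_LABELS).statistic == pytest.approx(1.5)

    def test_sst_invariant_under_label_permutation(self, rng):
        D = random_distance_matrix(rng, 8)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        ssts = {pseudo_f_groups(D, labels[rng.permutation(8)]).sst
                for _ in range(5)}
        assert len({round(s, 12) for s in ssts}) == 1

    def test_matches_brute_force_oracle(self, rng):
        D = random_distance_matrix(rng, 9)
        labels = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = pseudo_f_groups(D, labels)
        sst, ssw, ssa = brute_force_ss(D, labels)
        assert res.sst == pytest.approx(sst, rel=1e-12)
        assert res.ssw == pytest.approx(ssw, rel=1e-12)
        assert res.ssa == pytest.approx(ssa, rel=1e-10)

    def test_zero_ssw_flagged_infinite(self):
        D = np.array([[0, 0, 2, 2], [0, 0, 2, 2],
                      [2, 2, 0, 0], [2, 2, 0, 0]], dtype=float)
        res = pseudo_f_groups(D, HAND_LABELS)
        assert np.isinf(res.statistic)
        assert "zero_ssw" in res.flags

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            pseudo_f_groups(HAND_D, np.array(["a", "a", "a", "b"]))


class TestGowerCentering:
    def test_zero_distances_give_zero_g(self):
        assert not gower_center(np.zeros((5, 5))).any()

    def test_rows_sum_to_zero(self, rng):
        G = gower_center(random_distance_matrix(rng, 10))
        np.testing.assert_allclose(G.sum(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(G.sum(axis=1), 0.0, atol=1e-10)

    def test_trace_identity_on_100_random_instances(self):
        # tr(Hd G) = SSA and tr((I - H_full) G) = SSW, classical
        # distance-ANOVA identity, checked numerically
        g = np.random.default_rng(2024)
        for _ in range(100):
            n = int(g.integers(6, 14))
            D = random_distance_matrix(g, n)
            k = int(g.integers(2, 4))
            labels = np.array([f"g{i % k}" for i in range(n)])
            G = gower_center(D)
            Hd, R_full, _ = _projectors(labels)
            res = pseudo_f_groups(D, labels)
            assert np.sum(Hd * G) == pytest.approx(res.ssa, abs=1e-8)
            assert np.sum(R_full * G) == pytest.approx(res.ssw, abs=1e-8)


class TestAdjustedPseudoF:
    def test_reduces_to_group_f_without_covariates(self, rng):
        D = random_distance_matrix(rng, 10)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        assert pseudo_f_adjusted(D, labels) == pytest.approx(
            pseudo_f_groups(D, labels).statistic, rel=1e-10)

    def test_constant_covariate_dropped(self, rng):
        D = random_distance_matrix(rng, 10)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.warns(UserWarning, match="constant covariate"):
            f = pseudo_f_adjusted(D, labels, np.ones(10))
        assert f == pytest.approx(pseudo_f_groups(D, labels).statistic)

    def test_rank_deficient_design_names_columns(self, rng):
        D = random_distance_matrix(rng, 10)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        Z = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            pseudo_f_adjusted(D, labels, Z, covariate_names=["z1", "z2"])

    def test_confounded_age_effect_removed_by_adjustment(self):
        # connectivity shift driven entirely by age, age confounded with
        # group: the unadjusted test sees a group effect, the adjusted
        # test does not
        spec = two_group_spec(3.0, n_per_group=30, seeds=(4,),
                              effect_driver="age", confounded=True,
                              confound_age_shift=10.0)
        cohort = generate_cohort(spec, seed=21).thresholded(0.25)
        D = region_distance_matrix(cohort, 4)
        labels = cohort.labels
        age = cohort.covariate_matrix(["age"])
        p_raw = permutation_test(D, labels, None, permutations=499, seed=1)
        p_adj = permutation_test(D, labels, age, permutations=499, seed=1)
        assert p_raw < 0.05
        assert p_adj > 0.05

    def test_same_permutation_ranks_as_unadjusted(self, rng):
        # empty covariate set: permutation p identical to the label test
        D = random_distance_matrix(rng, 8)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        perms = np.array(list(itertools.permutations(range(8))))[::100]
        p_adj = permutation_test(D, labels, None, permutations=perms)
        f_obs = pseudo_f_groups(D, labels).statistic
        count = sum(
            pseudo_f_groups(D, labels[list(p)]).statistic >= f_obs - 1e-12
            for p in perms)
        assert p_adj == pytest.approx((1 + count) / (len(perms) + 1))


class TestPermutationTest:
    def test_counting_convention_minimum_p(self, planted_cohort):
        D = region_distance_matrix(planted_cohort, 0)
        p = permutation_test(D, planted_cohort.labels, permutations=99,
                             seed=3)
        assert p == pytest.approx(1 / 100)

    def test_all_equal_distances_give_p_one(self):
        D = np.ones((8, 8)) - np.eye(8)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        assert permutation_test(D, labels, permutations=99, seed=0) == 1.0

    def test_exhaustive_equivalence_printed_vs_classical_f(self, rng):
        # printed F = (n-1) SSA/SSW and the dof-scaled classical F are
        # monotone transforms of each other: identical exact p-values
        for n, k in [(6, 2), (7, 2), (8, 2)]:
            D = random_distance_matrix(rng, n)
            labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
            perms = np.array(list(itertools.permutations(range(n))))
            stats_printed, stats_classical = [], []
            for p in perms:
                res = pseudo_f_groups(D, labels[list(p)])
                stats_printed.append(res.statistic)
                stats_classical.append(
                    (res.ssa / (k - 1)) / (res.ssw / (n - k)))
            obs_pr = pseudo_f_groups(D, labels)
            obs_cl = (obs_pr.ssa / (k - 1)) / (obs_pr.ssw / (n - k))
            c_pr = np.sum(np.asarray(stats_printed)
                          >= obs_pr.statistic - 1e-12)
            c_cl = np.sum(np.asarray(stats_classical) >= obs_cl - 1e-12)
            assert c_pr == c_cl
            p_fn = permutation_test(D, labels, permutations=perms)
            assert p_fn == pytest.approx((1 + c_pr) / (len(perms) + 1))

    def test_seed_reproducibility(self, planted_cohort):
        D = region_distance_matrix(planted_cohort, 7)
        args = (D, planted_cohort.labels)
        assert permutation_test(*args, permutations=199, seed=5) == \
            permutation_test(*args, permutations=199, seed=5)


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_correct([0.04])[0] == pytest.approx(0.04)

    def test_standard_bh_oracle(self):
        np.testing.assert_allclose(fdr_correct([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_correct([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(1e-4, 1, size=30)
        q = fdr_correct(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)


class TestScan:
    def test_planted_seeds_have_smallest_pvalues(self):
        from tests.helpers import RECOVERY_SEEDS, recovery_spec
        cohort = generate_cohort(recovery_spec(), seed=31).thresholded(0.05)
        res = run_mdmr(cohort, comparisons={"CNvsAD": ("CN", "AD")},
                       permutations=199, seed=9)["CNvsAD"]
        top3 = res.table.sort_values(
            ["p_perm", "pseudo_F"], ascending=[True, False],
            kind="mergesort").head(3)["region"].tolist()
        assert set(top3) == set(RECOVERY_SEEDS)

    def test_comparison_subset_controls_outputs(self, planted_cohort):
        res = run_mdmr(planted_cohort,
                       comparisons={"CNvsAD": ("CN", "AD")},
                       permutations=99, seed=1)
        assert set(res) == {"CNvsAD"}

    def test_missing_group_raises(self, planted_cohort):
        with pytest.raises(ValueError, match="absent"):
            run_mdmr(planted_cohort,
                     comparisons={"x": ("CN", "cMCI")}, permutations=99)

    def test_deterministic_given_seed(self, planted_cohort):
        a = run_mdmr(planted_cohort, comparisons={"c": ("CN", "AD")},
                     permutations=99, seed=42)["c"].table
        b = run_mdmr(planted_cohort, comparisons={"c": ("CN", "AD")},
                     permutations=99, seed=42)["c"].table
        assert a.equals(b)

    def test_model_results_summary(self, planted_cohort):
        D = region_distance_matrix(planted_cohort, 0)
        covs = planted_cohort.covariate_matrix(["age", "sex", "apoe4"])
        res = MDMR(D, planted_cohort.labels, covs).fit(permutations=99,
                                                       seed=0)
        assert res.ssa == pytest.approx(res.sst - res.ssw)
        assert 0 <= res.pseudo_r2 <= 1
        assert "pseudo-F" in str(res.summary())


def test_pseudo_f_matches_vegan_adonis2(rng, tmp_path):
    """Classical dof-scaled F from our decomposition equals vegan's
    PERMANOVA F on the same distance matrix (independent oracle)."""
    n, k = 12, 2
    D = random_distance_matrix(rng, n)
    labels = np.array(["a"] * 6 + ["b"] * 6)
    np.savetxt(tmp_path / "D.csv", D, delimiter=",")
    (tmp_path / "g.txt").write_text("\n".join(labels) + "\n")
    script = textwrap.dedent("""
        suppressMessages(library(vegan))
        D <- as.dist(as.matrix(read.csv('D.csv', header=FALSE)))
        g <- factor(readLines('g.txt'))
        res <- adonis2(D ~ g, permutations = 2)
        cat(sprintf('%.12f', res$F[1]))
    """)
    (tmp_path / "oracle.R").write_text(script)
    out = subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path,
                         capture_output=True, text=True, check=True)
    f_vegan = float(out.stdout.strip())
    res = pseudo_f_groups(D, labels)
    f_classical = (res.ssa / (k - 1)) / (res.ssw / (n - k))
    assert f_classical == pytest.approx(f_vegan, rel=1e-6)
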