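"""Group inference: t maps, permutation FWE, masks, clusters, eigenvariates."""

import numpy as np
import pytest

from rsgca.group import (
    GroupDesign,
    cluster_filter,
    eigenvariate,
    followup_tests,
    fwe_correct,
    mask_from_one_sample,
    one_sample_map,
    two_sample_map,
)


def vector_with_moments(n, mean, sd, rng=None):
    """Construct a vector with *exact* sample mean and (ddof=1) SD."""
    v = (rng or np.random.default_rng(0)).standard_normal(n)
    v = (v - v.mean()) / v.std(ddof=1)
    return mean + sd * v


def _design(n1, n2, rng=None, covariates=False):
    rng = rng or np.random.default_rng(0)
    g = np.r_[np.zeros(n1), np.ones(n2)]
    kw = {}
    if covariates:
        kw = {"age": rng.normal(34, 9, n1 + n2),
              "gender": rng.integers(0, 2, n1 + n2).astype(float)}
    return GroupDesign([f"s{i}" for i in range(n1 + n2)], g, **kw)


class TestOneSample:
    def test_reproduces_patient_followup_t(self):
        """n=38, mean 0.027, sd 0.08 -> t = 2.08 on 37 df (printed 2.06)."""
        v = vector_with_moments(38, 0.027, 0.08)
        m = one_sample_map(v[:, None])
        assert m.df == 37
        assert m.t[0] == pytest.approx(0.027 / (0.08 / np.sqrt(38)), abs=1e-10)
        assert m.t[0] == pytest.approx(2.06, rel=0.03)

    def test_reproduces_control_followup_t(self):
        """n=35, mean 0.103, sd 0.08 -> t = 7.62 on 34 df (printed 7.42)."""
        m = one_sample_map(vector_with_moments(35, 0.103, 0.08)[:, None])
        assert m.df == 34
        assert m.t[0] == pytest.approx(7.42, rel=0.03)

    def test_zero_variance_target_flagged(self):
        vals = np.column_stack([np.ones(10), np.random.default_rng(0).standard_normal(10)])
        m = one_sample_map(vals)
        assert m.flags[0] == "zero-variance" and np.isnan(m.t[0])
        assert m.flags[1] == ""

    def test_matches_scipy(self, rng):
        from scipy import stats
        vals = rng.standard_normal((20, 4)) + 0.3
        m = one_sample_map(vals)
        ref_t, ref_p = stats.ttest_1samp(vals, 0.0)
        assert np.allclose(m.t, ref_t, atol=1e-12)
        assert np.allclose(m.p_unc, ref_p, atol=1e-12)


class TestTwoSample:
    def test_reproduces_demographic_age_t(self, rng):
        """Group ages with printed means/SDs: t(71) = 0.469 (printed 0.46)."""
        a = vector_with_moments(38, 34.5, 9.1, rng)
        b = vector_with_moments(35, 33.5, 9.1, rng)
        vals = np.r_[a, b][:, None]
        m = two_sample_map(vals, _design(38, 35))
        assert m.df == 71
        assert abs(m.t[0]) == pytest.approx(0.46, rel=0.03)

    def test_no_covariates_equals_pooled_t(self, rng):
        v1, v2 = rng.standard_normal(12), rng.standard_normal(15) + 0.4
        m = two_sample_map(np.r_[v1, v2][:, None], _design(12, 15))
        sp = np.sqrt(((11 * v1.var(ddof=1) + 14 * v2.var(ddof=1)) / 25))
        t_pooled = (v2.mean() - v1.mean()) / (sp * np.sqrt(1 / 12 + 1 / 15))
        assert m.t[0] == pytest.approx(t_pooled, abs=1e-10)

    def test_identical_groups_give_zero_t(self):
        v = np.arange(10.0)
        vals = np.r_[v, v][:, None]
        m = two_sample_map(vals, _design(10, 10))
        assert m.t[0] == pytest.approx(0.0, abs=1e-12)

    def test_covariate_model_matches_normal_equations_oracle(self, rng):
        design = _design(20, 25, rng, covariates=True)
        vals = rng.standard_normal((45, 6))
        m = two_sample_map(vals, design)
        X = np.column_stack([np.ones(45), design.group, design.age,
                             design.gender])
        for j in range(6):
            beta = np.linalg.solve(X.T @ X, X.T @ vals[:, j])
            resid = vals[:, j] - X @ beta
            s2 = resid @ resid / (45 - 4)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            assert m.t[j] == pytest.approx(beta[1] / se, abs=1e-10)

    def test_collinear_design_rejected(self):
        d = _design(5, 5)
        d.age = np.ones((10, 1))  # collinear with the intercept
        with pytest.raises(ValueError, match="collinear"):
            two_sample_map(np.random.default_rng(0).standard_normal((10, 2)), d)


class TestFWE:
    def test_single_target_mask_equals_permutation_p(self, rng):
        vals = rng.standard_normal((15, 4)) + 0.6
        mask = np.array([False, True, False, False])
        p_masked = fwe_correct(vals, "one_sample", n_perm=400,
                               mask=mask, rng=np.random.default_rng(3))
        p_alone = fwe_correct(vals[:, [1]], "one_sample", n_perm=400,
                              rng=np.random.default_rng(3))
        assert p_masked[1] == pytest.approx(p_alone[0])
        assert np.isnan(p_masked[0])

    def test_mask_enlargement_never_decreases_p(self, rng):
        vals = rng.standard_normal((20, 6)) + 0.2
        small = np.zeros(6, bool)
        small[:2] = True
        big = np.ones(6, bool)
        p_small = fwe_correct(vals, "one_sample", n_perm=300, mask=small,
                              rng=np.random.default_rng(5))
        p_big = fwe_correct(vals, "one_sample", n_perm=300, mask=big,
                            rng=np.random.default_rng(5))
        assert np.all(p_big[:2] >= p_small[:2] - 1e-12)

    def test_corrected_p_invariant_to_subject_order(self, rng):
        """Relabelling subjects leaves corrected p values unchanged up to
        permutation Monte-Carlo error."""
        vals = rng.standard_normal((18, 5)) + 0.3
        design = _design(9, 9)
        p1 = fwe_correct(vals, "two_sample", design=design, n_perm=1500,
                         rng=np.random.default_rng(11))
        perm = np.random.default_rng(1).permutation(18)
        design2 = GroupDesign([design.subject_ids[i] for i in perm],
                              design.group[perm])
        p2 = fwe_correct(vals[perm], "two_sample", design=design2, n_perm=1500,
                         rng=np.random.default_rng(11))
        assert np.allclose(p1, p2, atol=0.05)

    def test_single_test_agrees_with_sign_flip_enumeration(self, rng):
        """With one target maxT equals the plain permutation p, and both
        agree with Bonferroni (which is the identity for one test)."""
        vals = (rng.standard_normal(12) + 1.2)[:, None]
        p = fwe_correct(vals, "one_sample", n_perm=2000,
                        rng=np.random.default_rng(2))[0]
        t_obs = abs(vals.mean() / (vals.std(ddof=1) / np.sqrt(12)))
        # oracle: direct sign-flip simulation
        r2 = np.random.default_rng(9)
        count = 0
        for _ in range(2000):
            v = vals[:, 0] * r2.choice([-1, 1], 12)
            tb = abs(v.mean() / (v.std(ddof=1) / np.sqrt(12)))
            count += tb >= t_obs
        p_oracle = (1 + count) / 2001
        assert p == pytest.approx(p_oracle, abs=0.02)
        assert min(1.0, 1 * p) == p  # Bonferroni m=1 identity

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="mask"):
            fwe_correct(rng.standard_normal((10, 3)), "one_sample",
                        n_perm=200, mask=np.zeros(3, bool))

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            fwe_correct(rng.standard_normal((10, 3)), "one_sample", n_perm=50)


class TestMask:
    def test_all_null_map_gives_empty_mask(self, rng):
        m = one_sample_map(rng.standard_normal((400, 5)) * 0.01)
        assert mask_from_one_sample(m, alpha=1e-6).sum() == 0

    def test_threshold_one_gives_full_mask(self, rng):
        m = one_sample_map(rng.standard_normal((10, 5)))
        assert mask_from_one_sample(m, alpha=1.0).all()

    def test_hand_checked_five_targets(self):
        m = one_sample_map(np.random.default_rng(0).standard_normal((30, 5)))
        m.p_fwe = np.array([0.01, 0.2, 0.04, np.nan, 0.8])
        m.t = np.array([3.0, 1.0, -2.5, np.nan, 0.1])
        got = mask_from_one_sample(m, alpha=0.05)
        assert got.tolist() == [True, False, True, False, False]


class TestClusterFilter:
    @staticmethod
    def _grid(shape):
        return np.array(np.meshgrid(*[np.arange(s) for s in shape],
                                    indexing="ij")).reshape(len(shape), -1).T

    def test_isolated_point_removed(self):
        coords = self._grid((10, 10, 10))
        t = np.zeros(len(coords))
        t[123] = 5.0
        assert len(cluster_filter(t, coords, 3.0, k=30)) == 0

    def test_contiguous_block_retained(self):
        coords = self._grid((10, 10, 10))
        t = np.zeros(len(coords))
        block = [i for i, c in enumerate(coords)
                 if c[0] < 4 and c[1] < 5 and c[2] < 2]
        t[block] = 4.0
        cs = cluster_filter(t, coords, 3.0, k=30)
        assert len(cs) == 1
        assert cs.clusters[0].size == 40
        assert cs.clusters[0].sign == 1

    def test_matches_flood_fill_oracle(self, rng):
        """Face-connectivity labelling against a brute-force BFS flood fill."""
        shape = (8, 8, 8)
        coords = self._grid(shape)
        t = rng.standard_normal(len(coords)) * 2.0
        cs = cluster_filter(t, coords, 2.0, k=1)

        def flood(mask):
            seen = np.zeros_like(mask, dtype=bool)
            comps = []
            for start in np.argwhere(mask & ~seen):
                start = tuple(start)
                if seen[start]:
                    continue
                comp, stack = [], [start]
                seen[start] = True
                while stack:
                    cur = stack.pop()
                    comp.append(cur)
                    for d in range(3):
                        for step in (-1, 1):
                            nxt = list(cur)
                            nxt[d] += step
                            nxt = tuple(nxt)
                            if (all(0 <= nxt[i] < shape[i] for i in range(3))
                                    and mask[nxt] and not seen[nxt]):
                                seen[nxt] = True
                                stack.append(nxt)
                comps.append(sorted(comp))
            return sorted(comps)

        grid_t = t.reshape(shape)
        oracle = flood(grid_t >= 2.0) + flood(-grid_t >= 2.0)
        got = sorted(
            sorted(tuple(coords[i]) for i in c.member_indices)
            for c in cs.clusters
        )
        assert got == sorted(oracle)

    def test_negative_clusters_found_separately(self):
        coords = self._grid((6, 6))
        t = np.zeros(len(coords))
        neg = [i for i, c in enumerate(coords) if c[0] < 2]
        t[neg] = -4.0
        cs = cluster_filter(t, coords, 3.0, k=5)
        assert len(cs) == 1 and cs.clusters[0].sign == -1


class TestFollowup:
    def test_bonferroni_arithmetic(self, rng):
        v = rng.standard_normal(20) + 0.55
        out = followup_tests({"g": v}, n_comparisons=8)["g"]
        assert out["p_bonferroni"] == pytest.approx(min(1.0, 8 * out["p_raw"]))

    def test_cap_at_one(self, rng):
        v = rng.standard_normal(20) * 5
        out = followup_tests({"g": v}, n_comparisons=8)["g"]
        if out["p_raw"] > 0.125:
            assert out["p_bonferroni"] == 1.0

    def test_enumeration_over_eight_tests(self, rng):
        from scipy import stats
        groups = {f"g{i}": rng.standard_normal(15) + 0.1 * i for i in range(8)}
        out = followup_tests(groups, n_comparisons=8)
        for name, vals in groups.items():
            _, p = stats.ttest_1samp(vals, 0.0)
            assert out[name]["p_raw"] == pytest.approx(p)
            assert out[name]["p_bonferroni"] == pytest.approx(min(1.0, 8 * p))


class TestEigenvariate:
    def test_single_target_is_standardized_column(self, rng):
        col = rng.standard_normal(25)
        scores = eigenvariate(col[:, None])
        ref = (col - col.mean()) / col.std(ddof=1)
        assert np.allclose(scores, ref, atol=1e-10)

    def test_rank_one_matrix_recovers_left_vector(self, rng):
        u = rng.standard_normal(30)
        v = rng.standard_normal(12)
        scores = eigenvariate(np.outer(u, v))
        uc = u - u.mean()
        r = abs(np.corrcoef(scores, uc)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((20, 50))
        scores = eigenvariate(X)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc @ Xc.T)
        ref = evecs[:, -1]
        r = abs(np.corrcoef(scores, ref)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-10)
        assert scores.std(ddof=1) == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            eigenvariate(np.ones((10, 4)))
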