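import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netgex import connectome as cn, groupdiff as gd, synthdata as sd
from netgex._types import EdgeStatMap, EffectSpec, SubjectRecord


def _subject(**kw):
    defaults = dict(
        subject_id="s0", site="a", age=30.0, sex="F", education=12.0,
        fd=0.1, hamd=15, hama=20, quality_score=4,
        timeseries=np.zeros((10, 3)),
    )
    defaults.update(kw)
    return SubjectRecord(**defaults)


class TestInclusion:
    def test_fd_boundary(self):
        inc, exc = gd.apply_inclusion_criteria([_subject(fd=0.21), _subject(fd=0.2)])
        assert len(inc) == 1 and inc[0].fd == 0.2
        assert "head motion" in exc[0][1][0]

    def test_hamd_boundary(self):
        inc, exc = gd.apply_inclusion_criteria([_subject(hamd=7), _subject(hamd=8)])
        assert len(inc) == 1 and inc[0].hamd == 8
        assert "remission" in exc[0][1][0]

    def test_all_boundaries_pass(self):
        inc, exc = gd.apply_inclusion_criteria(
            [_subject(fd=0.2, hamd=8, hama=10, quality_score=4)]
        )
        assert len(inc) == 1 and not exc

    def test_missing_scores_and_quality(self):
        inc, exc = gd.apply_inclusion_criteria(
            [_subject(hama=None), _subject(hamd=None), _subject(quality_score=3)]
        )
        assert not inc
        reasons = [r for _, rs in exc for r in rs]
        assert any("missing" in r for r in reasons)
        assert any("quality" in r for r in reasons)

    def test_multiple_reasons_recorded(self):
        _, exc = gd.apply_inclusion_criteria([_subject(fd=0.5, hamd=3)])
        assert len(exc[0][1]) == 2


class TestAssignGroups:
    @pytest.mark.parametrize("hama,label", [(19, "ANX+"), (18, "ANX-"), (0, "ANX-")])
    def test_boundaries(self, hama, label):
        assert gd.assign_groups([_subject(hama=hama)])[0] == label

    def test_missing_hama_raises(self):
        with pytest.raises(ValueError, match="HAMA"):
            gd.assign_groups([_subject(hama=None)])


class TestEdgeGLM:
    def test_matches_classical_two_sample_t(self, rng):
        stack = rng.standard_normal((6, 4, 4))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        group = np.array([0, 0, 0, 1, 1, 1])
        out = gd.edge_glm_ttest(stack, group)
        for i, j in [(0, 1), (0, 2), (2, 3)]:
            t_cl = stats.ttest_ind(stack[3:, i, j], stack[:3, i, j]).statistic
            assert out.t[i, j] == pytest.approx(t_cl, abs=1e-12)
            p_cl = stats.ttest_ind(stack[3:, i, j], stack[:3, i, j]).pvalue
            assert out.p[i, j] == pytest.approx(p_cl, abs=1e-12)

    def test_constant_group_raises(self, rng):
        stack = rng.standard_normal((6, 3, 3))
        with pytest.raises(ValueError, match="constant"):
            gd.edge_glm_ttest(stack, np.zeros(6))

    def test_collinear_covariate_named(self, rng):
        stack = rng.standard_normal((10, 3, 3))
        g = np.array([0, 1] * 5)
        cov = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(ValueError, match="'a'|'b'"):
            gd.edge_glm_ttest(stack, g, cov)

    def test_null_p_uniform(self, atlas30, null_effect):
        subs = sd.generate_cohort(atlas30, 25, 25, 150, ["s"], null_effect, seed=17)
        stack = np.stack([cn.compute_fc(s.timeseries) for s in subs])
        g = np.array([s.group for s in subs])
        cov = pd.DataFrame({"age": [s.age for s in subs], "fd": [s.fd for s in subs]})
        out = gd.edge_glm_ttest(stack, g, cov)
        iu = np.triu_indices(30, 1)
        assert stats.kstest(out.p[iu], "uniform").pvalue > 0.01

    def test_permutation_equivariance(self, rng):
        stack = rng.standard_normal((12, 5, 5))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        g = np.array([0, 1] * 6)
        t = gd.edge_glm_ttest(stack, g).t
        perm = rng.permutation(5)
        t_p = gd.edge_glm_ttest(stack[:, perm][:, :, perm], g).t
        np.testing.assert_allclose(t_p, t[np.ix_(perm, perm)], atol=1e-10)


class TestNBS:
    def test_no_suprathreshold_edges(self, rng):
        stack = 0.01 * rng.standard_normal((20, 6, 6))
        g = np.array([0, 1] * 10)
        res = gd.nbs_correct(stack, g, n_perm=120, seed=0)
        assert res.components == []

    def test_planted_component_recovered(self, atlas30):
        eff = EffectSpec(network_pairs=[("SC", "VN")], delta=0.35)
        subs = sd.generate_cohort(atlas30, 60, 60, 150, ["s"], eff, seed=5)
        stack = np.stack([cn.compute_fc(s.timeseries) for s in subs])
        g = np.array([s.group for s in subs])
        res = gd.nbs_correct(stack, g, n_perm=200, seed=1)
        assert res.significant
        nets = atlas30["network"].to_numpy()
        planted = {
            (i, j)
            for i in range(30) for j in range(i + 1, 30)
            if {nets[i], nets[j]} == {"SC", "VN"}
        }
        found = {e for c in res.significant for e in c.edges}
        assert len(planted & found) / len(planted) >= 0.9

    def test_p_monotone_in_size(self):
        null = np.array([0, 0, 1, 2, 3, 5, 8, 0, 1, 0])
        p = [
            (1 + np.sum(null >= s)) / (1 + len(null))
            for s in range(1, 10)
        ]
        assert all(a >= b for a, b in zip(p, p[1:]))

    def test_freedman_lane_no_covariates_is_label_permutation(self, rng):
        # with an intercept-only reduced model, permuting residuals and
        # refitting equals permuting the response outright
        Y = rng.standard_normal((12, 8))
        g = np.array([0, 1] * 6).astype(float)
        X = np.column_stack([np.ones(12), g])
        perm = rng.permutation(12)
        fitted = Y.mean(axis=0, keepdims=True) * np.ones((12, 1))
        resid = Y - fitted
        t_fl, _ = gd._glm_group_t(fitted + resid[perm], X)
        t_lp, _ = gd._glm_group_t(Y[perm], X)
        np.testing.assert_allclose(t_fl, t_lp, atol=1e-10)

    def test_low_nperm_warns(self, rng):
        stack = rng.standard_normal((10, 4, 4))
        g = np.array([0, 1] * 5)
        with pytest.warns(UserWarning, match="n_perm"):
            gd.nbs_correct(stack, g, n_perm=50, seed=0)

    def test_determinism(self, rng):
        stack = rng.standard_normal((16, 8, 8))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        g = np.array([0, 1] * 8)
        r1 = gd.nbs_correct(stack, g, edge_p=0.05, n_perm=150, seed=42)
        r2 = gd.nbs_correct(stack, g, edge_p=0.05, n_perm=150, seed=42)
        np.testing.assert_array_equal(r1.null_max_size, r2.null_max_size)


class TestNetworkTTest:
    def test_constant_matrices_zero_t(self):
        stack = np.full((12, 7, 7), 0.4)
        g = np.array([0, 1] * 6)
        t, p = gd.network_ttest(stack, g, n_perm=120, seed=0)
        np.testing.assert_allclose(t.to_numpy(), 0.0, atol=1e-8)

    def test_planted_network_cell_significant(self, atlas30):
        eff = EffectSpec(network_pairs=[("SC", "VN")], delta=0.3)
        subs = sd.generate_cohort(atlas30, 60, 60, 150, ["s"], eff, seed=6)
        stack = np.stack(
            [cn.network_average(cn.compute_fc(s.timeseries), atlas30).to_numpy() for s in subs]
        )
        g = np.array([s.group for s in subs])
        t, p = gd.network_ttest(stack, g, n_perm=200, seed=2)
        assert p.loc["SC", "VN"] < 0.05


class TestNetT:
    def test_hand_computed(self):
        t = np.array([[0.0, 2.0, -1.0], [2.0, 0.0, 0.5], [-1.0, 0.5, 0.0]])
        es = EdgeStatMap(t=t, p=np.ones((3, 3)), df=10)
        out = gd.net_t_value(es)
        np.testing.assert_allclose(out.to_numpy(), [1.0, 2.5, -0.5])

    def test_all_zero(self):
        es = EdgeStatMap(t=np.zeros((4, 4)), p=np.ones((4, 4)), df=5)
        assert (gd.net_t_value(es) == 0).all()

    def test_row_sum_identity(self, rng):
        t = rng.standard_normal((10, 10))
        t = (t + t.T) / 2
        es = EdgeStatMap(t=t, p=np.ones((10, 10)), df=5)
        tt = t.copy()
        np.fill_diagonal(tt, 0.0)
        pos_minus_neg = np.maximum(tt, 0).sum(axis=1) - np.abs(np.minimum(tt, 0)).sum(axis=1)
        np.testing.assert_array_equal(gd.net_t_value(es).to_numpy(), tt.sum(axis=1))
        np.testing.assert_allclose(gd.net_t_value(es).to_numpy(), pos_minus_neg, atol=1e-12)

    def test_region_subset(self, rng):
        t = rng.standard_normal((6, 6))
        t = (t + t.T) / 2
        es = EdgeStatMap(t=t, p=np.ones((6, 6)), df=5)
        sub = gd.net_t_value(es, [1, 3])
        assert list(sub.index) == [1, 3]
        full = gd.net_t_value(es)
        assert sub.loc[3] == full.loc[3]


class TestPropensityMatch:
    def _subjects(self, ages1, ages2):
        subs = [_subject(subject_id=f"t{i}", age=a, hama=25) for i, a in enumerate(ages1)]
        subs += [_subject(subject_id=f"c{i}", age=a, hama=10) for i, a in enumerate(ages2)]
        group = np.array(["T"] * len(ages1) + ["C"] * len(ages2))
        return subs, group

    def test_identical_distributions_all_matched(self, rng):
        ages = rng.uniform(20, 50, 20)
        subs, group = self._subjects(ages, ages)
        pairs = gd.propensity_match(subs, group, covariates=["age"], seed=0)
        assert len(pairs) == 20

    def test_disjoint_ranges_zero_matches(self):
        subs, group = self._subjects([20.0] * 10, [60.0] * 10)
        pairs = gd.propensity_match(subs, group, covariates=["age"], caliper_sd=0.2, seed=0)
        assert pairs == []

    def test_smd_reduced_on_shifted_ages(self, rng):
        a1 = rng.normal(40, 8, 150)
        a2 = rng.normal(36, 8, 150)
        subs, group = self._subjects(a1, a2)
        pairs = gd.propensity_match(subs, group, covariates=["age"], seed=1)
        assert len(pairs) > 50
        ti = np.array([p[0] for p in pairs])
        ci = np.array([p[1] for p in pairs])
        ages = np.array([s.age for s in subs])
        pooled = np.sqrt((a1.var() + a2.var()) / 2)
        smd = abs(ages[ti].mean() - ages[ci].mean()) / pooled
        assert smd < 0.1


class TestPairedTTest:
    def test_identical_pairs_zero_t(self, rng):
        stack = rng.standard_normal((10, 5, 5))
        stack = np.concatenate([stack, stack])
        pairs = [(i, i + 10) for i in range(10)]
        res = gd.paired_edge_ttest(stack, pairs, n_perm=120, seed=0)
        assert res.components == []

    def test_too_few_pairs(self, rng):
        stack = rng.standard_normal((4, 4, 4))
        with pytest.raises(ValueError, match="3"):
            gd.paired_edge_ttest(stack, [(0, 1), (2, 3)], n_perm=120, seed=0)

    def test_planted_paired_effect_recovered(self, rng):
        R, n = 8, 40
        base = rng.standard_normal((n, R, R)) * 0.1
        base = (base + base.transpose(0, 2, 1)) / 2
        treated = base.copy()
        treated[:, 0, 1] += 0.8
        treated[:, 1, 0] += 0.8
        treated[:, 1, 2] += 0.8
        treated[:, 2, 1] += 0.8
        stack = np.concatenate([treated, base])
        pairs = [(i, i + n) for i in range(n)]
        res = gd.paired_edge_ttest(stack, pairs, n_perm=200, seed=3)
        sig_edges = {e for c in res.significant for e in c.edges}
        assert {(0, 1), (1, 2)} <= sig_edges

    def test_null_fwer_light(self, rng):
        rej = 0
        n_rep = 30
        for rep in range(n_rep):
            local = np.random.default_rng(rep)
            stack = local.standard_normal((24, 6, 6))
            stack = (stack + stack.transpose(0, 2, 1)) / 2
            pairs = [(i, i + 12) for i in range(12)]
            fd = local.uniform(0.05, 0.15, 24)
            res = gd.paired_edge_ttest(stack, pairs, fd=fd, n_perm=100,
                                       edge_p=0.05, seed=rep)
            if res.significant:
                rej += 1
        assert rej / n_rep <= 0.2
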