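import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rehopipe import (
    BrainMask,
    GroupDesign,
    SummaryGroup,
    anova_from_summary,
    chisq_independence,
    critical_t,
    ttest_from_summary,
    voxelwise_ttest,
)


def two_point_sample(mean, sd, n, rng=None):
    """A dataset with exactly the requested mean and SD (reconstruction oracle).

    Takes a zero-mean pattern, standardizes it, then rescales.
    """
    base = np.linspace(-1, 1, n)
    base = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * base


def _maps_design(
    values_a, values_b, shape=(4, 4, 4), covariates=None, mode="none", names=None
):
    """Single-value maps (every voxel identical) for two groups."""
    maps, membership = {}, {}
    for i, v in enumerate(values_a):
        sid = f"a{i}"
        maps[sid] = np.full(shape, float(v))
        membership[sid] = "A"
    for i, v in enumerate(values_b):
        sid = f"b{i}"
        maps[sid] = np.full(shape, float(v))
        membership[sid] = "B"
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates, index=list(maps))
    kwargs = {}
    if names is not None:
        kwargs["covariate_names"] = names
    return GroupDesign(
        maps=maps,
        membership=membership,
        contrast=("A", "B"),
        covariates=cov,
        adjustment_mode=mode,
        **kwargs,
    )


@pytest.fixture
def mask_4(affine_3mm):
    return BrainMask(data=np.ones((4, 4, 4), bool), affine=affine_3mm)


class TestVoxelwiseTTest:
    def test_identical_groups_zero_t(self, mask_4):
        design = _maps_design([1.0, 1.1, 1.2], [1.0, 1.1, 1.2])
        out = voxelwise_ttest(design, mask_4)
        np.testing.assert_allclose(out.t, 0.0)
        assert out.df == 4

    def test_closed_form_pooled_t(self, mask_4):
        a, b = [1.1, 1.2, 1.3], [0.9, 1.0, 1.1]
        out = voxelwise_ttest(_maps_design(a, b), mask_4)
        # independent oracle: direct formula evaluation
        sa2, sb2 = np.var(a, ddof=1), np.var(b, ddof=1)
        sp2 = (2 * sa2 + 2 * sb2) / 4
        expect = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert out.t[0, 0, 0] == pytest.approx(expect, abs=1e-12)
        assert out.df == 4
        # scipy cross-check
        scipy_t = stats.ttest_ind(a, b, equal_var=True).statistic
        assert out.t[0, 0, 0] == pytest.approx(scipy_t, abs=1e-12)

    def test_sign_convention_first_group_higher(self, mask_4):
        out = voxelwise_ttest(_maps_design([2.0, 2.1, 2.2], [1.0, 1.1, 1.2]), mask_4)
        assert out.t[0, 0, 0] > 0

    @staticmethod
    def _orthogonal_setup(rng, n_per_group=4):
        """Maps and a covariate mutually orthogonalized by construction.

        The covariate is centered, identical across groups (so orthogonal to
        the group indicator), and the data are projected orthogonal to it,
        making the covariate fit exactly zero.
        """
        c = np.tile([-1.5, -0.5, 0.5, 1.5], 2)[: 2 * n_per_group]
        y = rng.normal([1.0] * n_per_group + [0.7] * n_per_group, 0.3)
        y = y - c * (c @ y) / (c @ c)
        return y[:n_per_group], y[n_per_group:], {"age": c}

    def test_orthogonal_covariate_matches_plain_t(self, mask_4):
        # covariate orthogonal to both the group indicator and the data:
        # residualizing only removes a global constant, leaving t unchanged
        a, b, cov = self._orthogonal_setup(np.random.default_rng(21))
        plain = voxelwise_ttest(_maps_design(a, b), mask_4)
        resid = voxelwise_ttest(
            _maps_design(a, b, covariates=cov, mode="residualize", names=["age"]),
            mask_4,
        )
        assert resid.t[0, 0, 0] == pytest.approx(plain.t[0, 0, 0], abs=1e-10)

    def test_ancova_coincides_with_residualize_when_orthogonal(self, mask_4):
        # same group-effect estimate; t values agree exactly after the
        # df-based rescaling of the residual variance
        a, b, cov = self._orthogonal_setup(np.random.default_rng(22))
        res = voxelwise_ttest(
            _maps_design(a, b, covariates=cov, mode="residualize", names=["age"]),
            mask_4,
        )
        anc = voxelwise_ttest(
            _maps_design(a, b, covariates=cov, mode="ancova", names=["age"]), mask_4
        )
        assert anc.df == res.df - 1
        expected = res.t[0, 0, 0] * np.sqrt(anc.df / res.df)
        assert anc.t[0, 0, 0] == pytest.approx(expected, abs=1e-10)

    def test_ancova_df_accounting(self, mask_4):
        rng = np.random.default_rng(23)
        cov = {
            "age": rng.normal(35, 8, 10),
            "gender": rng.integers(0, 2, 10).astype(float),
            "education": rng.normal(12, 2, 10),
            "hama": rng.normal(10, 4, 10),
        }
        out = voxelwise_ttest(
            _maps_design(rng.normal(size=5), rng.normal(size=5), covariates=cov, mode="ancova"),
            mask_4,
        )
        assert out.df == 10 - 2 - 4

    def test_zero_variance_voxel_flagged(self, mask_4):
        design = _maps_design([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        out = voxelwise_ttest(design, mask_4)
        np.testing.assert_array_equal(out.t, 0.0)
        assert out.n_degenerate == 64

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            _maps_design([1.0], [1.0, 2.0])

    def test_permutation_type_i_error(self, affine_3mm):
        # null maps, random relabelings: voxel-level rejection rate at the
        # two-tailed 0.05 threshold stays within binomial error of 0.05
        rng = np.random.default_rng(24)
        mask = BrainMask(data=np.ones((5, 5, 5), bool), affine=affine_3mm)
        n1 = n2 = 6
        maps = {f"s{i}": rng.standard_normal((5, 5, 5)) for i in range(n1 + n2)}
        ids = list(maps)
        crit = critical_t(0.05, n1 + n2 - 2)
        rates = []
        for _ in range(200):
            perm = rng.permutation(ids)
            membership = {s: ("A" if i < n1 else "B") for i, s in enumerate(perm)}
            design = GroupDesign(
                maps=maps, membership=membership, contrast=("A", "B"),
                adjustment_mode="none",
            )
            out = voxelwise_ttest(design, mask)
            rates.append((np.abs(out.t[mask.data]) > crit).mean())
        mean_rate = np.mean(rates)
        # 200 relabelings x 125 voxels; correlated across voxels, so allow
        # a generous but bounded band around the nominal level
        assert 0.03 < mean_rate < 0.07


class TestCriticalT:
    def test_paper_threshold_df30(self):
        assert critical_t(0.05, 30) == pytest.approx(2.042, abs=5e-4)

    def test_normal_limit(self):
        assert critical_t(0.05, 10**6) == pytest.approx(1.960, abs=5e-4)

    def test_quantile_oracle_df31(self):
        # independent inversion of the distribution function by bisection
        from scipy.optimize import brentq

        target = brentq(lambda c: 2 * stats.t.sf(c, 31) - 0.05, 0.1, 10.0)
        assert critical_t(0.05, 31) == pytest.approx(target, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            critical_t(0.0, 30)
        with pytest.raises(ValueError):
            critical_t(0.05, 0)


class TestSummaryStatistics:
    AGE = [SummaryGroup(36.06, 9.43, 16), SummaryGroup(34.47, 9.77, 17), SummaryGroup(35.13, 7.88, 16)]
    EDU = [SummaryGroup(12.75, 2.82, 16), SummaryGroup(12.06, 2.90, 17), SummaryGroup(12.75, 2.82, 16)]

    def test_age_anova_from_cohort_summaries(self):
        F, df_b, df_w, p = anova_from_summary(self.AGE)
        assert F == pytest.approx(0.128, abs=0.01)
        assert (df_b, df_w) == (2, 46)
        assert p == pytest.approx(0.881, abs=0.01)

    def test_education_anova_from_cohort_summaries(self):
        F, _, _, p = anova_from_summary(self.EDU)
        assert F == pytest.approx(0.327, abs=0.01)
        assert p == pytest.approx(0.723, abs=0.01)

    def test_equal_means_give_zero_f(self):
        groups = [SummaryGroup(5.0, 1.0, 10), SummaryGroup(5.0, 2.0, 12)]
        F, *_ = anova_from_summary(groups)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_reconstruction_oracle(self):
        # construct explicit datasets with exactly the summary moments and
        # compare against scipy's one-way ANOVA on the raw data
        samples = [two_point_sample(g.mean, g.sd, g.n) for g in self.AGE]
        F_raw = stats.f_oneway(*samples).statistic
        F_sum, *_ = anova_from_summary(self.AGE)
        assert F_sum == pytest.approx(F_raw, abs=1e-10)

    def test_ordering_and_scale_invariance(self):
        F1, *_ = anova_from_summary(self.AGE)
        F2, *_ = anova_from_summary(list(reversed(self.AGE)))
        assert F1 == pytest.approx(F2)
        scaled = [SummaryGroup(g.mean * 3, g.sd * 3, g.n) for g in self.AGE]
        F3, *_ = anova_from_summary(scaled)
        assert F3 == pytest.approx(F1)

    def test_ttest_from_summary_equal_groups(self):
        g = SummaryGroup(5.0, 1.0, 10)
        t, df, p = ttest_from_summary(g, g)
        assert t == 0.0 and df == 18 and p == pytest.approx(1.0)

    def test_ttest_from_summary_oracle(self):
        # severity-scale contrast: computed value cross-checked against a
        # reconstruction of raw data with exactly those moments
        ctrl = SummaryGroup(4.38, 1.63, 16)
        ud = SummaryGroup(26.19, 4.98, 16)
        t, df, p = ttest_from_summary(ctrl, ud)
        a = two_point_sample(ctrl.mean, ctrl.sd, ctrl.n)
        b = two_point_sample(ud.mean, ud.sd, ud.n)
        expect = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(expect.statistic, abs=1e-10)
        assert df == 30
        assert p == pytest.approx(expect.pvalue, abs=1e-12)
        assert t < 0  # severity much higher in the patient group

    def test_chi_square_uniform_table(self):
        chi2, df, p = chisq_independence(np.array([[10, 10], [10, 10]]))
        assert chi2 == pytest.approx(0.0)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_chi_square_gender_table_df(self):
        # 3 groups x 2 genders: df = (3-1)(2-1) = 2
        chi2, df, p = chisq_independence(np.array([[8, 8], [9, 8], [8, 8]]))
        assert df == 2
        assert chi2 < 0.2  # nearly balanced counts

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            chisq_independence(np.array([[0, 0], [5, 5]]))

    def test_summary_validation(self):
        with pytest.raises(ValueError):
            SummaryGroup(1.0, 1.0, 1)
        with pytest.raises(ValueError):
            SummaryGroup(1.0, -0.1, 5)
        with pytest.raises(ValueError):
            anova_from_summary([SummaryGroup(1, 1, 5)])
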