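"""MR estimators: Wald ratio, IVW, Cochran's Q, Egger, strength, overlap."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrsurv.core import (
    cochran_q,
    egger_regression,
    instrument_strength,
    ivw_pool,
    overlap_adjust,
    wald_ratio,
)
from mrsurv.summaries import OutcomeSummary, RatioEstimate, SnpSummary

from conftest import fit_cell


def snp(snp_id="rs1", beta=math.log(1.28), se=None, p=1e-9):
    return SnpSummary(
        snp_id=snp_id, chrom="1", pos=1, ref_allele="T", alt_allele="C",
        alt_freq=0.3, phenotype="FG", subgroup="overall",
        beta_exp=beta, se_exp=se, p_exp=p,
    )


def out(snp_id="rs1", hr=0.88, lo=0.78, hi=0.99):
    return OutcomeSummary(snp_id, math.log(hr), lo, hi, 0.5)


def est(r, se, snp_id="rs"):
    z = 1.96 * se
    return RatioEstimate(snp_id, r, se, math.exp(r - z), math.exp(r + z))


class TestWaldRatio:
    def test_strong_fg_instrument_matches_printed_estimate(self):
        # OR 1.28, HR 0.88 -> printed single-SNP MR estimate 0.59
        r = wald_ratio(out(), snp())
        assert math.exp(r.log_ratio) == pytest.approx(0.59, abs=0.01)

    def test_inactive_fi_instrument_matches_printed_estimate_and_ci(self):
        # OR 1.28, HR 0.59 (0.40-0.89) -> printed 0.12 (0.02-0.62)
        r = wald_ratio(out(hr=0.59, lo=0.40, hi=0.89), snp())
        assert math.exp(r.log_ratio) == pytest.approx(0.12, abs=0.01)
        assert r.ci_low == pytest.approx(0.02, abs=0.01)
        assert r.ci_high == pytest.approx(0.62, abs=0.01)

    def test_null_outcome_gives_unit_ratio(self):
        r = wald_ratio(out(hr=1.0, lo=0.8, hi=1.25), snp(beta=math.log(2.0)))
        assert math.exp(r.log_ratio) == 1.0

    def test_negative_exposure_flips_interval(self):
        r = wald_ratio(out(), snp(beta=-0.3))
        assert r.ci_low <= math.exp(r.log_ratio) <= r.ci_high

    def test_zero_exposure_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(out(), snp(beta=0.0))

    def test_delta_method_widens_with_exposure_noise(self):
        narrow = wald_ratio(out(), snp(se=1e-6), ci_method="delta")
        wide = wald_ratio(out(), snp(se=0.3), ci_method="delta")
        assert wide.se > narrow.se
        assert narrow.se == pytest.approx(wald_ratio(out(), snp()).se, rel=1e-3)


class TestIvwPool:
    def test_single_estimate_reduces_exactly(self):
        e = est(-0.3, 0.2)
        p = ivw_pool([e])
        assert p.log_pooled == e.log_ratio
        assert p.se_pooled == pytest.approx(e.se)
        assert (p.ci_low, p.ci_high) == pytest.approx((e.ci_low, e.ci_high))
        assert p.q_df == 0 and p.p_het is None

    def test_pool_is_weighted_mean(self):
        es = [est(-0.5, 0.1, "a"), est(0.1, 0.3, "b")]
        w = [0.1**-2, 0.3**-2]
        expected = (w[0] * -0.5 + w[1] * 0.1) / sum(w)
        p = ivw_pool(es)
        assert p.log_pooled == pytest.approx(expected)
        assert p.se_pooled == pytest.approx(sum(w) ** -0.5)

    def test_matches_grid_search_minimizer(self):
        """IVW equals the brute-force WLS minimizer of sum w(r - mu)^2."""
        rng = np.random.default_rng(7)
        es = [est(r, s, f"s{i}") for i, (r, s) in enumerate(
            zip(rng.normal(0, 0.5, 8), rng.uniform(0.05, 0.6, 8)))]
        grid = np.arange(-1.0, 1.0, 1e-5)
        w = np.array([e.weight for e in es])
        r = np.array([e.log_ratio for e in es])
        loss = ((r[None, :] - grid[:, None]) ** 2 * w).sum(axis=1)
        assert ivw_pool(es).log_pooled == pytest.approx(grid[loss.argmin()], abs=1e-5)

    def test_se_never_above_best_component(self):
        es = [est(0.0, 0.2, "a"), est(0.1, 0.5, "b"), est(-0.1, 0.3, "c")]
        assert ivw_pool(es).se_pooled <= min(e.se for e in es)

    def test_empty_and_zero_se_raise(self):
        with pytest.raises(ValueError):
            ivw_pool([])
        with pytest.raises(ValueError):
            ivw_pool([RatioEstimate("a", 0.0, 0.0, 1.0, 1.0)])

    def test_random_effects_widens_under_heterogeneity(self):
        es = [est(-1.0, 0.1, "a"), est(1.0, 0.1, "b"), est(0.0, 0.1, "c")]
        assert ivw_pool(es, method="random").se_pooled > ivw_pool(es).se_pooled

    def test_fg_pool_from_study_table(self, table1):
        assert fit_cell(table1, "FG").pooled.hr == pytest.approx(0.70, abs=0.01)

    def test_homa_low_fat_pool_from_study_table(self, table1):
        res = fit_cell(table1, "HOMA-IR", "low-fat")
        assert res.pooled.hr == pytest.approx(1.07, abs=0.01)


class TestCochranQ:
    def test_two_estimate_closed_form(self):
        r1, w1, r2, w2 = -0.4, 25.0, 0.3, 4.0
        es = [est(r1, w1**-0.5, "a"), est(r2, w2**-0.5, "b")]
        q, df, p = cochran_q(es)
        assert q == pytest.approx(w1 * w2 * (r1 - r2) ** 2 / (w1 + w2))
        assert df == 1

    def test_identical_estimates_are_homogeneous(self):
        es = [est(-0.2, 0.1, c) for c in "abc"]
        q, df, p = cochran_q(es)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_fg_group_heterogeneity(self, table1):
        res = fit_cell(table1, "FG")
        assert res.q_stat == pytest.approx(4.44, abs=0.05)
        assert res.pooled.q_df == 3
        assert res.p_het == pytest.approx(0.218, abs=0.005)

    def test_decomposition_identity(self):
        """sum w(r-mu)^2 == sum w r^2 - (sum w r)^2 / sum w."""
        rng = np.random.default_rng(3)
        es = [est(r, s, str(i)) for i, (r, s) in enumerate(
            zip(rng.normal(0, 1, 6), rng.uniform(0.1, 0.9, 6)))]
        w = np.array([e.weight for e in es])
        r = np.array([e.log_ratio for e in es])
        q, _, _ = cochran_q(es)
        assert q == pytest.approx(np.sum(w * r**2) - np.sum(w * r) ** 2 / np.sum(w))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cochran_q([])


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        pairs = [(x, -0.5 * x, 0.1) for x in bx]
        eg = egger_regression(pairs)
        assert eg.intercept == pytest.approx(0.0, abs=1e-12)
        assert eg.slope == pytest.approx(-0.5)
        assert eg.p_intercept == pytest.approx(1.0)

    def test_zero_intercept_constraint_equals_ivw(self):
        """Forcing the intercept to zero reproduces the IVW pool."""
        rng = np.random.default_rng(11)
        bx = rng.uniform(0.2, 1.0, 6)
        by = rng.normal(-0.3 * bx, 0.2)
        se = rng.uniform(0.1, 0.4, 6)
        # constrained WLS slope through the origin:
        w = se**-2.0
        slope0 = np.sum(w * bx * by) / np.sum(w * bx**2)
        ratios = [est(b / x, s / x, str(i)) for i, (x, b, s) in enumerate(zip(bx, by, se))]
        assert ivw_pool(ratios).log_pooled == pytest.approx(slope0)

    def test_recovers_injected_directional_pleiotropy(self):
        """Known per-SNP intercept delta is recovered, vs a grid WLS oracle."""
        rng = np.random.default_rng(5)
        delta, slope = 0.1, -0.2
        bx = rng.uniform(0.2, 1.2, 5)
        se = rng.uniform(0.05, 0.15, 5)
        by = delta + slope * bx + rng.normal(0, se)
        eg = egger_regression(list(zip(bx, by, se)))
        assert abs(eg.intercept - delta) < 2 * eg.se_intercept
        # oracle: brute-force weighted least squares on a 2-D grid
        a_grid = np.arange(-0.3, 0.5, 5e-4)
        b_grid = np.arange(-0.8, 0.4, 5e-4)
        w = se**-2.0
        loss = np.array([
            [(w * (by - a - b * bx) ** 2).sum() for b in b_grid] for a in a_grid
        ])
        ia, ib = np.unravel_index(loss.argmin(), loss.shape)
        assert eg.intercept == pytest.approx(a_grid[ia], abs=5e-4)
        assert eg.slope == pytest.approx(b_grid[ib], abs=5e-4)

    def test_matches_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        bx = rng.uniform(0.1, 1.0, 7)
        se = rng.uniform(0.1, 0.5, 7)
        by = 0.05 - 0.4 * bx + rng.normal(0, se)
        eg = egger_regression(list(zip(bx, by, se)))
        fit = sm.WLS(by, sm.add_constant(bx), weights=se**-2.0).fit()
        assert eg.intercept == pytest.approx(fit.params[0])
        assert eg.slope == pytest.approx(fit.params[1])

    def test_insufficient_instruments(self):
        with pytest.raises(ValueError):
            egger_regression([(0.2, 0.1, 0.1), (0.3, 0.2, 0.1)])

    def test_singular_design(self):
        with pytest.raises(np.linalg.LinAlgError):
            egger_regression([(0.5, 0.1, 0.1)] * 4)


class TestInstrumentStrength:
    def test_t2_from_p_value(self):
        rep = instrument_strength([snp(p=6.99e-9)])
        assert rep.total == pytest.approx(33.5, abs=0.2)

    def test_nominal_p_gives_definitional_t2(self):
        rep = instrument_strength([snp(p=0.05)])
        assert rep.total == pytest.approx(1.96**2, abs=1e-3)

    def test_se_route_preferred_when_available(self):
        rep = instrument_strength([snp(beta=0.5, se=0.1, p=0.5)])
        assert rep.total == pytest.approx(25.0)

    def test_fg_group_is_well_powered(self, table1):
        exposures, _ = table1
        rep = instrument_strength([e for e in exposures if e.phenotype == "FG"])
        assert rep.total > 10 and rep.passed
        assert rep.total == pytest.approx(sum(t for _, t in rep.per_snp_t2))


class TestOverlapAdjust:
    def test_rho_zero_is_identity(self):
        p = ivw_pool([est(-0.3, 0.2, "a"), est(0.0, 0.3, "b")])
        assert overlap_adjust(p, 0.0) == p

    def test_monotone_in_abs_rho(self):
        p = ivw_pool([est(-0.3, 0.2, "a"), est(0.0, 0.3, "b")])
        w1 = overlap_adjust(p, 0.1)
        w2 = overlap_adjust(p, 0.2)
        assert w2.ci_high - w2.ci_low > w1.ci_high - w1.ci_low > p.ci_high - p.ci_low

    @given(rho=st.floats(-0.99, 0.99))
    def test_point_estimate_invariant(self, rho):
        p = ivw_pool([est(-0.3, 0.2, "a"), est(0.0, 0.3, "b")])
        assert overlap_adjust(p, rho).log_pooled == p.log_pooled

    def test_out_of_range_rho(self):
        p = ivw_pool([est(0.0, 0.2, "a")])
        with pytest.raises(ValueError):
            overlap_adjust(p, 1.5)
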