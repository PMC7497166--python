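import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adipomr.errors import DegenerateInstrumentError, DomainError, EmptyInputError
from adipomr.harmonisation import HarmonisedSet
from adipomr.mr_estimators import (
    instrument_strength,
    ivw,
    ivw_correlated,
    leave_one_out,
    mr_egger,
    r2_from_sumstats,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from adipomr.sumstats_io import AssociationRecord, LDMatrix


def hset(bx, sx, by, sy, ld=None):
    bx = np.asarray(bx, dtype=float)
    ids = tuple(f"rs{i}" for i in range(len(bx)))
    return HarmonisedSet(
        snp_ids=ids,
        beta_exposure=bx,
        se_exposure=np.broadcast_to(np.asarray(sx, dtype=float), bx.shape).copy(),
        beta_outcome=np.asarray(by, dtype=float),
        se_outcome=np.broadcast_to(np.asarray(sy, dtype=float), bx.shape).copy(),
        eaf=np.full(bx.shape, 0.3),
        ld=LDMatrix(ids, ld) if ld is not None else None,
    )


class TestWaldRatio:
    def test_exact_ratio_when_exposure_se_is_zero(self):
        est = wald_ratio(hset([0.5], [0.0], [0.1], [0.05]))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)  # only the first delta term survives

    def test_zero_outcome_effect_gives_zero_estimate(self):
        est = wald_ratio(hset([0.5], [0.03], [0.0], [0.05]))
        assert est.beta == 0.0

    def test_zero_exposure_effect_is_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(hset([0.0], [0.03], [0.1], [0.05]))

    def test_delta_se_matches_monte_carlo_sd_of_the_ratio(self, rng):
        bx, sx, by, sy = 0.3, 0.03, 0.06, 0.02
        est = wald_ratio(hset([bx], [sx], [by], [sy]))
        draws = (by + sy * rng.standard_normal(1_000_000)) / (bx + sx * rng.standard_normal(1_000_000))
        assert est.se == pytest.approx(float(np.std(draws)), rel=0.03)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = hset([0.4], [0.02], [0.1], [0.05])
        a, b = ivw(h), wald_ratio(h)
        assert (a.beta, a.se, a.pvalue) == (b.beta, b.se, b.pvalue)

    def test_identical_ratios_floor_underdispersion_at_one(self):
        # three SNPs with the same ratio and equal weights: zero residuals
        h = hset([0.2, 0.4, 0.5], 0.0, [0.06, 0.12, 0.15], 0.05)
        est = ivw(h, effects="multiplicative_random")
        assert est.beta == pytest.approx(0.3)
        assert est.dispersion == 1.0
        assert est.cochran_q == pytest.approx(0.0, abs=1e-20)
        assert est.se == pytest.approx(ivw(h, effects="fixed").se)

    def test_matches_closed_form_and_gls_oracles(self, rng):
        for _ in range(5):
            k = int(rng.integers(3, 12))
            bx = np.abs(rng.normal(0.1, 0.05, k)) + 0.02
            sy = rng.uniform(0.01, 0.05, k)
            by = 0.3 * bx + rng.normal(0, 0.02, k)
            h = hset(bx, 0.01, by, sy)
            est = ivw(h, effects="fixed")
            # naive-loop closed form
            num = sum(1 / sy[i] ** 2 * bx[i] * by[i] for i in range(k))
            den = sum(1 / sy[i] ** 2 * bx[i] ** 2 for i in range(k))
            assert est.beta == pytest.approx(num / den, abs=1e-12)
            # independent GLS route: least squares on sqrt-weight-scaled data
            sol = np.linalg.lstsq((bx / sy)[:, None], by / sy, rcond=None)[0]
            assert est.beta == pytest.approx(float(sol[0]), abs=1e-10)
            assert est.se == pytest.approx(math.sqrt(1.0 / den), abs=1e-12)

    def test_random_effects_se_never_below_fixed(self, rng):
        for seed in range(4):
            r = np.random.default_rng(seed)
            k = 8
            bx = np.abs(r.normal(0.1, 0.05, k)) + 0.02
            by = 0.3 * bx + r.normal(0, 0.05, k)
            h = hset(bx, 0.01, by, 0.03)
            assert ivw(h).se >= ivw(h, effects="fixed").se


class TestIVWCorrelated:
    def test_identity_ld_equals_fixed_effect_ivw_exactly(self, hset_corr):
        h = hset(
            hset_corr.beta_exposure, hset_corr.se_exposure,
            hset_corr.beta_outcome, hset_corr.se_outcome, ld=np.eye(len(hset_corr)),
        )
        a = ivw_correlated(h, effects="fixed")
        b = ivw(h, effects="fixed")
        assert a.beta == pytest.approx(b.beta, abs=1e-14)
        assert a.se == pytest.approx(b.se, abs=1e-14)

    def test_duplicated_snp_approaches_single_snp_wald_as_ridge_vanishes(self):
        r = np.ones((2, 2))
        h = hset([0.4, 0.4], 0.0, [0.12, 0.12], 0.05, ld=r)
        wald = wald_ratio(hset([0.4], [0.0], [0.12], [0.05]))
        errs = [
            abs(ivw_correlated(h, effects="fixed", ridge=eps).beta - wald.beta)
            for eps in (1e-4, 1e-6, 1e-8)
        ]
        assert errs[0] < 1e-3 and errs == sorted(errs, reverse=True)
        assert abs(ivw_correlated(h, effects="fixed", ridge=1e-8).beta - wald.beta) < 1e-8

    def test_matches_direct_matrix_inverse_oracle(self, hset_corr):
        h = hset_corr
        est = ivw_correlated(h, effects="fixed")
        omega = np.outer(h.se_outcome, h.se_outcome) * h.ld.r
        oi = np.linalg.inv(omega)
        x, y = h.beta_exposure, h.beta_outcome
        beta = float(x @ oi @ y) / float(x @ oi @ x)
        se = math.sqrt(1.0 / float(x @ oi @ x))
        assert est.beta == pytest.approx(beta, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_underdispersion_floor_applies(self, hset_corr):
        re = ivw_correlated(hset_corr, effects="multiplicative_random")
        fe = ivw_correlated(hset_corr, effects="fixed")
        assert re.dispersion >= 1.0
        assert re.se >= fe.se


class TestMREgger:
    def test_orientation_invariance_under_snp_sign_flips(self, hset8):
        base = mr_egger(hset8)
        flipped = hset(
            hset8.beta_exposure * np.array([-1, 1, 1, -1, 1, 1, 1, -1]),
            hset8.se_exposure,
            hset8.beta_outcome * np.array([-1, 1, 1, -1, 1, 1, 1, -1]),
            hset8.se_outcome,
        )
        other = mr_egger(flipped)
        assert other.slope.beta == pytest.approx(base.slope.beta, abs=1e-12)
        assert other.intercept == pytest.approx(base.intercept, abs=1e-12)

    def test_intercept_constrained_fit_equals_fixed_effect_ivw(self, hset8):
        # augmented oracle: solving the weighted normal equations without the
        # intercept column reproduces the IVW fixed-effect estimate
        w = 1.0 / hset8.se_outcome**2
        sign = np.where(hset8.beta_exposure < 0, -1.0, 1.0)
        bx, by = hset8.beta_exposure * sign, hset8.beta_outcome * sign
        slope = float((w * bx * by).sum() / (w * bx * bx).sum())
        assert ivw(hset8, effects="fixed").beta == pytest.approx(slope, abs=1e-14)
        # and the free-intercept Egger fit matches its own normal equations
        X = np.column_stack([np.ones_like(bx), bx])
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * by))
        res = mr_egger(hset8)
        assert res.intercept == pytest.approx(float(coef[0]), abs=1e-12)
        assert res.slope.beta == pytest.approx(float(coef[1]), abs=1e-12)

    def test_constant_pleiotropy_recovered_in_large_sample(self, rng):
        # every SNP carries direct effect c: intercept -> c, slope -> truth
        k, c, truth = 200, 0.05, 0.3
        bx = rng.uniform(0.05, 0.25, k)
        sy = np.full(k, 0.01)
        by = truth * bx + c + rng.standard_normal(k) * sy
        res = mr_egger(hset(bx, 0.0, by, sy))
        assert res.intercept == pytest.approx(c, abs=0.01)
        assert res.slope.beta == pytest.approx(truth, abs=0.06)

    def test_requires_three_snps(self):
        with pytest.raises(EmptyInputError):
            mr_egger(hset([0.1, 0.2], 0.01, [0.03, 0.06], 0.02))


class TestWeightedMedian:
    def test_identical_ratios_return_that_ratio(self):
        est = weighted_median(hset([0.2, 0.4, 0.5], 0.01, [0.06, 0.12, 0.15], 0.05), n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.3, abs=1e-12)

    def test_equal_weight_three_snp_midpoint_rule(self):
        # ratios (0.1, 0.2, 0.9), equal weights: cumulative midpoints
        # (1/6, 1/2, 5/6) put the estimate exactly on the middle ratio
        est = weighted_median(hset([1.0, 1.0, 1.0], 0.0, [0.1, 0.2, 0.9], 0.05), n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_bootstrap_se_is_seed_reproducible(self, hset8):
        a = weighted_median(hset8, n_boot=200, seed=5)
        b = weighted_median(hset8, n_boot=200, seed=5)
        c = weighted_median(hset8, n_boot=200, seed=6)
        assert a.se == b.se
        assert a.se != c.se

    @given(st.integers(0, 2**31 - 1))
    def test_estimate_always_within_ratio_range(self, seed):
        r = np.random.default_rng(seed)
        k = int(r.integers(3, 10))
        bx = np.abs(r.normal(0.1, 0.05, k)) + 0.02
        by = r.normal(0.0, 0.1, k)
        h = hset(bx, 0.01, by, r.uniform(0.01, 0.1, k))
        est = weighted_median(h, n_boot=10, seed=0)
        ratios = by / bx
        assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12


class TestLeaveOneOut:
    def test_homogeneous_ratios_give_constant_estimates(self):
        h = hset([0.2, 0.4, 0.5, 0.3], 0.0, [0.06, 0.12, 0.15, 0.09], 0.05)
        full = ivw(h).beta
        results = leave_one_out(h)
        assert len(results) == 4
        assert [s for s, _ in results] == list(h.snp_ids)
        for _, est in results:
            assert est.beta == pytest.approx(full, abs=1e-12)

    def test_planted_outlier_is_most_influential(self):
        bx = np.array([0.2, 0.25, 0.3, 0.35, 0.4, 0.3, 0.2])
        by = 0.3 * bx
        by[3] += 0.5  # outlier SNP
        h = hset(bx, 0.0, by, 0.05)
        full = ivw(h).beta
        shifts = {s: abs(est.beta - full) for s, est in leave_one_out(h)}
        assert max(shifts, key=shifts.get) == h.snp_ids[3]


class TestInstrumentStrength:
    @pytest.mark.parametrize("r2,n,k,expected", [(0.012, 3301, 1, 40.1), (0.54, 3301, 1, 3872.7)])
    def test_reproduces_reported_single_snp_f_statistics(self, r2, n, k, expected):
        assert round(instrument_strength(r2, n, k).f_stat, 1) == expected

    def test_zero_r2_gives_zero_f(self):
        assert instrument_strength(0.0, 100, 1).f_stat == 0.0

    def test_strictly_increasing_in_r2(self):
        grid = np.linspace(0.0, 0.9, 30)
        f = [instrument_strength(r, 5000, 3).f_stat for r in grid]
        assert np.all(np.diff(f) > 0)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            instrument_strength(1.0, 100, 1)
        with pytest.raises(DomainError):
            instrument_strength(0.1, 2, 1)


class TestR2FromSumstats:
    @staticmethod
    def _rec(snp, eaf, beta):
        return AssociationRecord(snp, "1", 1000, "A", "G", beta, 0.01, 1e-9, 10_000, eaf)

    def test_single_snp_value_and_additivity(self):
        one = r2_from_sumstats([self._rec("a", 0.5, 0.2)])
        assert one == pytest.approx(0.02)
        two = r2_from_sumstats([self._rec("a", 0.5, 0.2), self._rec("b", 0.2, 0.1)])
        assert two == pytest.approx(one + 2 * 0.2 * 0.8 * 0.01)

    def test_missing_eaf_raises(self):
        with pytest.raises(DomainError):
            r2_from_sumstats([AssociationRecord("a", "1", 1, "A", "G", 0.1, 0.01, 1e-9, 100, None)])

    def test_matches_regression_variance_explained_on_simulated_genotypes(self, rng):
        # simulate additive genotypes and check the 2f(1-f)b^2 formula against
        # the empirically measured variance explained
        n = 20_000
        mafs, betas = np.array([0.3, 0.15]), np.array([0.25, 0.35])
        g = rng.binomial(2, mafs, size=(n, 2)).astype(float)
        lin = g @ betas
        y = lin + rng.standard_normal(n) * math.sqrt(max(1e-9, 1.0 - lin.var()))
        y = (y - y.mean()) / y.std()
        fitted = np.linalg.lstsq(np.column_stack([np.ones(n), g]), y, rcond=None)[0]
        yhat = np.column_stack([np.ones(n), g]) @ fitted
        emp = yhat.var() / y.var()
        formula = r2_from_sumstats(
            [self._rec("a", mafs[0], betas[0]), self._rec("b", mafs[1], betas[1])]
        )
        assert formula == pytest.approx(emp, abs=0.012)


class TestOddsRatio:
    def test_null_effect_gives_unit_or(self, hset8):
        est = ivw(hset8)
        orr, lo, hi = to_odds_ratio(est)
        assert orr == pytest.approx(math.exp(est.beta))
        null = wald_ratio(hset([0.5], [0.0], [0.0], [0.05]))
        assert to_odds_ratio(null)[0] == 1.0

    def test_reproduces_printed_interval_shape(self):
        # OR 1.17 with lower bound pinned at 1.01 gives an upper bound ~1.35
        z = 1.959963984540054
        beta = math.log(1.17)
        se = (beta - math.log(1.01)) / z
        est = wald_ratio(hset([1.0], [0.0], [beta], [se]))
        orr, lo, hi = to_odds_ratio(est)
        assert round(orr, 2) == 1.17
        assert round(lo, 2) == 1.01
        assert hi == pytest.approx(1.35, abs=0.01)

    def test_log_exp_round_trip(self, hset8):
        est = ivw(hset8)
        orr, lo, hi = to_odds_ratio(est)
        assert math.log(orr) == pytest.approx(est.beta, abs=1e-12)
        assert math.log(lo) == pytest.approx(est.ci_low, abs=1e-12)


class TestScaleEquivariance:
    @given(st.floats(0.1, 10.0))
    def test_rescaling_exposure_divides_every_estimate(self, c):
        h, _ = _fixture()
        scaled = hset(h.beta_exposure * c, h.se_exposure * c, h.beta_outcome, h.se_outcome)
        assert ivw(scaled).beta * c == pytest.approx(ivw(h).beta, rel=1e-10)
        assert mr_egger(scaled).slope.beta * c == pytest.approx(mr_egger(h).slope.beta, rel=1e-10)
        wm_a = weighted_median(scaled, n_boot=20, seed=3)
        wm_b = weighted_median(h, n_boot=20, seed=3)
        assert wm_a.beta * c == pytest.approx(wm_b.beta, rel=1e-10)
        assert wm_a.se * c == pytest.approx(wm_b.se, rel=1e-10)


def _fixture():
    r = np.random.default_rng(99)
    k = 10
    bx = np.abs(r.normal(0.12, 0.04, k)) + 0.02
    by = 0.25 * bx + r.normal(0, 0.02, k)
    return hset(bx, 0.01, by, 0.03), None
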