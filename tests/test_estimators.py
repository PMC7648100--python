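"""MR estimators against closed forms and independent brute-force oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from ibdmr import estimators as est
from ibdmr import summary_io as sio
from ibdmr.exceptions import DegenerateInstrumentError, InsufficientInstrumentsError

from conftest import random_instrument


def make_inst(x, sx, y, sy):
    x = np.asarray(x, float)
    return sio.HarmonizedInstrument(
        rsids=tuple(f"rs{i}" for i in range(len(x))), x=x, sx=sx, y=y, sy=sy
    )


class TestWaldRatios:
    def test_ratio_and_first_order_se(self):
        inst = make_inst([0.1], [0.01], [0.2], [0.02])
        (theta, se), = est.wald_ratios(inst)
        assert theta == pytest.approx(2.0)
        assert se == pytest.approx(0.2)

    def test_null_outcome_gives_zero(self):
        inst = make_inst([0.3], [0.01], [0.0], [0.02])
        assert est.wald_ratios(inst)[0][0] == 0.0

    def test_second_order_se_adds_exposure_term(self):
        inst = make_inst([0.1], [0.01], [0.2], [0.02])
        (_, se2), = est.wald_ratios(inst, second_order=True)
        expected = np.sqrt(0.02**2 / 0.1**2 + 0.2**2 * 0.01**2 / 0.1**4)
        assert se2 == pytest.approx(expected)
        assert se2 > 0.2

    def test_zero_exposure_beta_names_snp(self):
        inst = make_inst([0.1, 0.0], [0.01, 0.01], [0.2, 0.1], [0.02, 0.02])
        with pytest.raises(DegenerateInstrumentError, match="rs1"):
            est.wald_ratios(inst)


class TestMlEstimate:
    def test_single_snp_reduces_to_wald_ratio(self):
        inst = make_inst([0.1], [1e-6], [0.25], [0.02])
        fit = est.ml_estimate(inst)
        assert fit.theta == pytest.approx(2.5, abs=1e-6)

    def test_equals_ivw_when_exposure_ses_vanish(self, rng):
        for _ in range(5):
            inst = random_instrument(rng)
            shrunk = sio.HarmonizedInstrument(
                rsids=inst.rsids, x=inst.x, sx=np.full(inst.n_snp, 1e-8), y=inst.y, sy=inst.sy
            )
            ml = est.ml_estimate(shrunk)
            ivw = est.ivw_estimate(shrunk)
            assert ml.theta == pytest.approx(ivw.theta, abs=1e-6)

    def test_matches_profile_grid_search(self, small_instrument):
        # Independent oracle: dense 1-D scan of the profiled deviance.
        inst = small_instrument
        grid = np.linspace(-2, 2, 400_001)[:, None]
        obj = np.sum(
            (inst.y - grid * inst.x) ** 2 / (inst.sy**2 + grid**2 * inst.sx**2), axis=1
        )
        oracle = float(grid[np.argmin(obj), 0])
        assert est.ml_estimate(inst).theta == pytest.approx(oracle, abs=1e-5)

    def test_ci_and_or_scale_consistent(self, small_instrument):
        fit = est.ml_estimate(small_instrument)
        assert fit.ci_low < fit.theta < fit.ci_high
        assert fit.or_scale == pytest.approx(
            tuple(np.exp([fit.theta, fit.ci_low, fit.ci_high]))
        )


class TestIvwEstimate:
    def test_consensus_ratio_recovered(self):
        x = np.array([0.1, 0.2, 0.3])
        inst = make_inst(x, [0.01] * 3, 1.7 * x, [0.02] * 3)
        assert est.ivw_estimate(inst).theta == pytest.approx(1.7)

    def test_two_snp_closed_form(self):
        inst = make_inst([1.0, 1.0], [0.01, 0.01], [1.0, 3.0], [0.5, 0.5])
        assert est.ivw_estimate(inst).theta == pytest.approx(2.0)

    def test_matches_weighted_least_squares_oracle(self, rng):
        inst = random_instrument(rng, n_snp=12)
        fit = sm.WLS(inst.y, inst.x, weights=1.0 / inst.sy**2).fit()
        ours = est.ivw_estimate(inst)
        assert ours.theta == pytest.approx(fit.params[0], rel=1e-10)

    def test_requires_two_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            est.ivw_estimate(make_inst([0.1], [0.01], [0.2], [0.02]))


class TestEggerEstimate:
    def test_line_through_origin_has_zero_intercept(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        inst = make_inst(x, [0.01] * 4, 0.5 * x, [0.02] * 4)
        fit = est.egger_estimate(inst)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.slope.theta == pytest.approx(0.5)

    def test_exact_affine_fit_recovered(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        inst = make_inst(x, [0.01] * 4, 0.1 + 0.5 * x, [0.02] * 4)
        fit = est.egger_estimate(inst)
        assert fit.intercept == pytest.approx(0.1)
        assert fit.slope.theta == pytest.approx(0.5)

    def test_orientation_invariant_to_exposure_sign(self, rng):
        inst = random_instrument(rng, n_snp=10)
        flipped = sio.HarmonizedInstrument(
            rsids=inst.rsids, x=-inst.x, sx=inst.sx, y=-inst.y, sy=inst.sy
        )
        a, b = est.egger_estimate(inst), est.egger_estimate(flipped)
        assert a.slope.theta == pytest.approx(b.slope.theta)
        assert a.intercept == pytest.approx(b.intercept)

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            est.egger_estimate(make_inst([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.02] * 2))


class TestWeightedMedian:
    def test_equal_weight_median(self):
        # Ratios {1, 2, 9} with equal weights: median is the middle ratio.
        x = np.array([0.1, 0.1, 0.1])
        y = np.array([0.1, 0.2, 0.9])
        inst = make_inst(x, [0.01] * 3, y, [0.02] * 3)
        assert est.weighted_median_point(inst) == pytest.approx(2.0)

    def test_degenerate_common_ratio(self):
        # Bootstrap SE collapses as both sampling SEs shrink.
        x = np.array([0.1, 0.2, 0.3])
        inst = make_inst(x, [1e-8] * 3, 1.3 * x, [1e-4] * 3)
        fit = est.weighted_median_estimate(inst, n_boot=200, seed=1)
        assert fit.theta == pytest.approx(1.3)
        assert fit.se < 0.005

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_polyline_interpolation_oracle(self, seed):
        inst = random_instrument(np.random.default_rng(seed), n_snp=7)
        theta = inst.y / inst.x
        w = (inst.x / inst.sy) ** 2
        w = w / w.sum()
        order = np.argsort(theta)
        ts, ws = theta[order], w[order]
        cum = np.cumsum(ws) - ws / 2
        # Oracle: walk the polyline segment containing p = 0.5 explicitly.
        k = int(np.searchsorted(cum, 0.5))
        if k == 0:
            oracle = ts[0]
        elif k == len(ts):
            oracle = ts[-1]
        else:
            frac = (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1])
            oracle = ts[k - 1] + frac * (ts[k] - ts[k - 1])
        assert est.weighted_median_point(inst) == pytest.approx(oracle, rel=1e-12)

    def test_bootstrap_is_seed_reproducible(self, small_instrument):
        a = est.weighted_median_estimate(small_instrument, n_boot=100, seed=5)
        b = est.weighted_median_estimate(small_instrument, n_boot=100, seed=5)
        assert a == b


class TestModeEstimate:
    def test_point_mass_returns_common_ratio(self):
        x = np.array([0.1, 0.2, 0.4])
        inst = make_inst(x, [0.01] * 3, 0.7 * x, [0.02] * 3)
        fit = est.mode_estimate(inst, n_boot=10, seed=0)
        assert fit.theta == pytest.approx(0.7)
        assert fit.se == 0.0

    def test_majority_mode_dominates(self):
        x = np.array([0.1, 0.1, 0.1, 0.1])
        y = np.array([0.0, 0.0, 0.0, 0.5])
        inst = make_inst(x, [0.01] * 4, y, [0.02] * 4)
        assert est.mode_point(inst, phi=0.5) == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_matches_dense_grid_oracle(self, seed):
        inst = random_instrument(np.random.default_rng(seed), n_snp=9)
        theta = inst.y / inst.x
        w = (inst.x / inst.sy) ** 2
        w = w / w.sum()
        mean = np.sum(w * theta)
        sd = np.sqrt(np.sum(w * (theta - mean) ** 2))
        order = np.argsort(theta)
        cum = np.cumsum(w[order]) - w[order] / 2
        med = np.interp(0.5, cum, theta[order])
        dev = np.abs(theta - med)
        order_d = np.argsort(dev)
        cum_d = np.cumsum(w[order_d]) - w[order_d] / 2
        mad = np.interp(0.5, cum_d, dev[order_d]) / 0.6745
        h = 0.9 * min(sd, mad) * 9 ** (-0.2)
        grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 100_000)
        dens = sum(
            wj * np.exp(-0.5 * ((grid - tj) / h) ** 2) for wj, tj in zip(w, theta)
        )
        oracle = grid[np.argmax(dens)]
        # Agreement up to the implementation's own grid spacing.
        spacing = (theta.max() - theta.min() + 6 * h) / est.MODE_GRID_POINTS
        assert abs(est.mode_point(inst) - oracle) <= spacing


class TestCochranQ:
    def test_homogeneous_ratios_give_zero(self):
        x = np.array([0.1, 0.2, 0.3])
        inst = make_inst(x, [0.01] * 3, 0.4 * x, [0.02] * 3)
        q = est.cochran_q(inst)
        assert q.q == pytest.approx(0.0, abs=1e-20)
        assert q.pvalue == pytest.approx(1.0)

    def test_degrees_of_freedom(self):
        inst = make_inst([0.1, 0.2], [0.01] * 2, [0.05, 0.15], [0.02] * 2)
        assert est.cochran_q(inst).df == 1

    def test_matches_formula_oracle(self, rng):
        inst = random_instrument(rng, n_snp=10)
        ratios = inst.y / inst.x
        w = (inst.x / inst.sy) ** 2
        ivw = np.sum(w * ratios) / np.sum(w)
        q_oracle = float(np.sum(w * (ratios - ivw) ** 2))
        q = est.cochran_q(inst)
        assert q.q == pytest.approx(q_oracle, rel=1e-12)
        assert q.pvalue == pytest.approx(stats.chi2.sf(q_oracle, 9), rel=1e-12)


class TestEquivariance:
    """Shared invariances of all point estimators."""

    @pytest.mark.parametrize(
        # Bootstrap-based SEs are sign-symmetric only in distribution, hence
        # the looser SE tolerance for the median and mode estimators.
        ("fit", "se_rel"),
        [
            (est.ml_estimate, 1e-6),
            (est.ivw_estimate, 1e-6),
            (lambda i: est.egger_estimate(i).slope, 1e-6),
            (lambda i: est.weighted_median_estimate(i, n_boot=400, seed=3), 0.25),
            (lambda i: est.mode_estimate(i, n_boot=200, seed=3), 0.25),
        ],
        ids=["ml", "ivw", "egger", "weighted_median", "mode"],
    )
    def test_sign_equivariant_in_outcome(self, fit, se_rel, rng):
        inst = random_instrument(rng, n_snp=8)
        neg = sio.HarmonizedInstrument(
            rsids=inst.rsids, x=inst.x, sx=inst.sx, y=-inst.y, sy=inst.sy
        )
        a, b = fit(inst), fit(neg)
        assert b.theta == pytest.approx(-a.theta, rel=1e-6, abs=1e-9)
        assert b.se == pytest.approx(a.se, rel=se_rel, abs=1e-9)

    @pytest.mark.parametrize(
        "fit",
        [
            est.ml_estimate,
            est.ivw_estimate,
            lambda i: est.weighted_median_estimate(i, n_boot=100, seed=3),
            lambda i: est.mode_estimate(i, n_boot=50, seed=3),
        ],
        ids=["ml", "ivw", "weighted_median", "mode"],
    )
    def test_scale_equivariant_in_exposure(self, fit, rng):
        inst = random_instrument(rng, n_snp=8)
        c = 2.5
        scaled = sio.HarmonizedInstrument(
            rsids=inst.rsids, x=c * inst.x, sx=c * inst.sx, y=inst.y, sy=inst.sy
        )
        a, b = fit(inst), fit(scaled)
        assert b.theta == pytest.approx(a.theta / c, rel=1e-5, abs=1e-8)
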