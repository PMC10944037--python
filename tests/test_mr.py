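"""Two-sample MR estimators against closed-form and simulation oracles."""

import math

import numpy as np
import pytest

from proteomr.errors import NumericalError
from proteomr.instruments import InstrumentSet
from proteomr.mr import (
    ivw_correlated,
    mr_egger,
    run_all_methods,
    wald_ratio,
    weighted_median,
)
from proteomr.sumstats import LDMatrix


def _inst(bx, sx, by, sy, R=None, pid="P"):
    bx, sx, by, sy = map(lambda v: np.asarray(v, float), (bx, sx, by, sy))
    ids = [f"v{i}" for i in range(len(bx))]
    if R is None:
        R = np.eye(len(bx))
    return InstrumentSet(pid, ids, bx, sx, by, sy, LDMatrix(ids, R), ["cis"] * len(bx))


class TestWaldRatio:
    def test_arithmetic(self):
        theta, se = wald_ratio(0.4, 0.01, 0.2, 0.05)
        assert theta == pytest.approx(0.5)
        assert se == pytest.approx(0.125)

    def test_null_outcome(self):
        theta, se = wald_ratio(0.4, 0.01, 0.0, 0.05)
        assert theta == 0.0 and se == pytest.approx(0.125)

    def test_zero_exposure_raises(self):
        with pytest.raises(NumericalError):
            wald_ratio(0.0, 0.01, 0.2, 0.05)

    def test_second_order_close_when_instruments_strong(self, rng):
        # strong instruments (F > 10), causal effect of plausible size: the
        # first-order SE is adequate in the typical case and the discrepancy
        # shrinks with instrument strength
        close = 0
        for _ in range(100):
            sx = rng.uniform(0.01, 0.05)
            F = rng.uniform(15, 200)
            bx = sx * math.sqrt(F)
            sy = sx * rng.uniform(0.8, 1.5)  # outcome study on a similar scale
            by = 0.3 * bx + rng.normal(0, sy)
            _, se1 = wald_ratio(bx, sx, by, sy)
            _, se2 = wald_ratio(bx, sx, by, sy, second_order=True)
            assert se2 >= se1
            rel = (se2 - se1) / se2
            close += rel < 0.10
            if F > 100:
                assert rel < 0.10
        assert close >= 90


class TestIVW:
    def test_single_instrument_equals_wald(self):
        inst = _inst([0.23], [0.04], [0.11], [0.06])
        res = ivw_correlated(inst)
        theta, se = wald_ratio(0.23, 0.04, 0.11, 0.06)
        assert res.theta == pytest.approx(theta, abs=1e-12)
        assert res.se_theta == pytest.approx(se, abs=1e-12)

    def test_identity_ld_equals_textbook_ivw(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 8))
            bx = rng.normal(0.1, 0.05, m)
            by = rng.normal(0.05, 0.05, m)
            sy = rng.uniform(0.01, 0.1, m)
            res = ivw_correlated(_inst(bx, 0.01 * np.ones(m), by, sy))
            w = bx**2 / sy**2
            ratios = by / bx
            theta_fe = float((w * ratios).sum() / w.sum())
            se_fe = math.sqrt(1.0 / w.sum())
            assert res.theta == pytest.approx(theta_fe, abs=1e-10)
            assert res.se_theta == pytest.approx(se_fe, abs=1e-10)

    def test_three_instrument_fixture_matches_normal_equations_oracle(self):
        bx = np.array([0.1, 0.2, 0.15])
        by = np.array([0.05, 0.12, 0.09])
        sy = np.array([0.02, 0.03, 0.025])
        res = ivw_correlated(_inst(bx, 0.01 * np.ones(3), by, sy))
        # independent WLS oracle: solve (X' W X) theta = X' W y directly
        W = np.diag(1.0 / sy**2)
        theta = np.linalg.solve(bx[None] @ W @ bx[:, None], bx[None] @ W @ by[:, None]).item()
        assert res.theta == pytest.approx(theta, abs=1e-10)

    def test_duplicated_instrument_matches_deduplicated(self):
        bx, by, sy = [0.1, 0.2], [0.05, 0.12], [0.02, 0.03]
        dedup = ivw_correlated(_inst(bx, [0.01] * 2, by, sy))
        R = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
        dup = ivw_correlated(
            _inst([0.1, 0.2, 0.1], [0.01] * 3, [0.05, 0.12, 0.05], [0.02, 0.03, 0.02], R)
        )
        assert dup.theta == pytest.approx(dedup.theta, abs=1e-6)

    def test_cochran_q_zero_on_perfectly_proportional_effects(self):
        bx = np.array([0.1, 0.2, 0.3])
        res = ivw_correlated(_inst(bx, [0.01] * 3, 0.5 * bx, [0.02] * 3))
        assert res.cochran_q == pytest.approx(0.0, abs=1e-12)
        assert res.cochran_q_df == 2

    def test_allele_flip_equivariance(self, rng):
        m = 4
        bx = rng.normal(0.1, 0.05, m)
        by = rng.normal(0.05, 0.05, m)
        sy = rng.uniform(0.02, 0.06, m)
        A = rng.normal(size=(m, m + 3))
        R = np.corrcoef(A)
        base = ivw_correlated(_inst(bx, [0.01] * m, by, sy, R))
        flip = np.array([1, -1, 1, -1], dtype=float)
        res = ivw_correlated(
            _inst(bx * flip, [0.01] * m, by * flip, sy, R * np.outer(flip, flip))
        )
        assert res.theta == pytest.approx(base.theta, abs=1e-12)
        neg = ivw_correlated(_inst(bx, [0.01] * m, -by, sy, R))
        assert neg.theta == pytest.approx(-base.theta, abs=1e-12)

    def test_or_ci_construction_matches_invariant(self, rng):
        res = ivw_correlated(_inst([0.1, 0.2], [0.01] * 2, [0.07, 0.13], [0.02, 0.03]))
        assert res.or_ == pytest.approx(math.exp(res.theta), abs=1e-12)
        assert res.ci_low == pytest.approx(math.exp(res.theta - 1.96 * res.se_theta), rel=1e-9)
        assert res.ci_high == pytest.approx(math.exp(res.theta + 1.96 * res.se_theta), rel=1e-9)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.04 + 0.5 * bx  # intercept 0.04, slope 0.5
        res = mr_egger(_inst(bx, [0.01] * 3, by, [0.02, 0.03, 0.025]))
        assert res.theta == pytest.approx(0.5, abs=1e-12)
        assert res.egger_intercept == pytest.approx(0.04, abs=1e-12)

    def test_directional_pleiotropy_recovered(self, rng):
        # constant pleiotropy delta shifts the intercept, not the slope
        delta = 0.08
        intercepts, slopes = [], []
        for _ in range(60):
            m = 20
            bx = rng.uniform(0.05, 0.3, m)
            sy = rng.uniform(0.01, 0.03, m)
            by = 0.3 * bx + delta + rng.normal(0, sy)
            res = mr_egger(_inst(bx, [0.01] * m, by, sy))
            intercepts.append(res.egger_intercept)
            slopes.append(res.theta)
        assert abs(np.mean(intercepts) - delta) < 0.01
        assert abs(np.mean(slopes) - 0.3) < 0.05

    def test_fewer_than_three_not_applicable(self):
        assert mr_egger(_inst([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)) is None


class TestWeightedMedian:
    def test_equal_weight_median(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.5, 0.9])
        res = weighted_median(_inst(bx, [0.01] * 3, by, [0.05] * 3), n_boot=50, seed=0)
        assert res.theta == pytest.approx(0.5)

    def test_bootstrap_se_deterministic_given_seed(self):
        inst = _inst([0.1, 0.2, 0.15], [0.01] * 3, [0.05, 0.12, 0.09], [0.02, 0.03, 0.025])
        a = weighted_median(inst, n_boot=200, seed=7)
        b = weighted_median(inst, n_boot=200, seed=7)
        assert a.se_theta == b.se_theta

    def test_robust_to_one_wild_outlier(self, rng):
        m = 10
        bx = rng.uniform(0.1, 0.3, m)
        sy = np.full(m, 0.02)
        by = 0.3 * bx + rng.normal(0, sy)
        by[0] = 5.0  # wildly invalid instrument
        wm = weighted_median(_inst(bx, [0.01] * m, by, sy), n_boot=200, seed=1)
        ivw = ivw_correlated(_inst(bx, [0.01] * m, by, sy))
        assert abs(wm.theta - 0.3) < abs(ivw.theta - 0.3)
        assert abs(wm.theta - 0.3) < 2 * wm.se_theta


class TestRunAllMethods:
    def test_method_panel_by_instrument_count(self):
        single = run_all_methods(_inst([0.2], [0.01], [0.1], [0.02]))
        assert {r.method for r in single} == {"ivw", "wald"}
        triple = run_all_methods(
            _inst([0.1, 0.2, 0.15], [0.01] * 3, [0.05, 0.12, 0.09], [0.02, 0.03, 0.025])
        )
        assert {r.method for r in triple} == {"ivw", "egger", "weighted_median"}
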