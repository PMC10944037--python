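"""Cox screening, standardization and the effective-tests correction."""

import math

import numpy as np
import pandas as pd
import pytest

from proteomr.errors import ConfigurationError, UnidentifiableModelError
from proteomr.survival import (
    CohortTable,
    effective_tests,
    fit_cox,
    screen,
    standardize_proteins,
    volcano_table,
)


def breslow_neg_log_partial_likelihood(beta, time, event, x):
    """Independent oracle: Breslow partial likelihood, O(n^2), tie-free data."""
    nll = 0.0
    eta = beta * x
    for i in np.where(event == 1)[0]:
        at_risk = time >= time[i]
        nll -= eta[i] - math.log(np.exp(eta[at_risk]).sum())
    return nll


def grid_search_cox(time, event, x, lo=-3.0, hi=3.0):
    """1-D golden-ratio-free oracle: coarse grid then two refinements."""
    for _ in range(3):
        grid = np.linspace(lo, hi, 201)
        vals = [breslow_neg_log_partial_likelihood(b, time, event, x) for b in grid]
        k = int(np.argmin(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, 200)]
    return 0.5 * (lo + hi)


def simulate_survival(rng, n, log_hr, censor_quantile=0.5):
    x = rng.standard_normal(n)
    t = rng.exponential(np.exp(-log_hr * x))
    c = np.quantile(t, censor_quantile)
    time = np.minimum(t, c)
    # jitter removes ties from censoring so Efron == Breslow
    time = time + rng.uniform(0, 1e-9, n)
    event = (t <= c).astype(int)
    return time, event, x


class TestStandardize:
    def test_log_then_scale_known_values(self):
        raw = pd.DataFrame([[1.0, math.e, math.e**2]], index=["p"], columns=list("abc"))
        z, excluded = standardize_proteins(raw)
        np.testing.assert_allclose(z.loc["p"].to_numpy(), [-1.0, 0.0, 1.0], atol=1e-12)
        assert not excluded

    def test_constant_protein_excluded(self):
        raw = pd.DataFrame(
            [[2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0]], index=["flat", "ok"], columns=list("abcd")
        )
        z, excluded = standardize_proteins(raw)
        assert excluded == {"flat": "zero_variance"}
        assert list(z.index) == ["ok"]

    def test_lognormal_column_standardized(self, rng):
        raw = pd.DataFrame([np.exp(rng.normal(2, 0.7, 500))], index=["p"])
        z, _ = standardize_proteins(raw)
        assert abs(z.loc["p"].mean()) < 1e-10
        assert abs(z.loc["p"].std(ddof=1) - 1.0) < 1e-10

    def test_nonpositive_values_become_missing(self):
        raw = pd.DataFrame([[1.0, 0.0, math.e, -2.0, math.e**2]], index=["p"])
        z, _ = standardize_proteins(raw)
        assert z.loc["p"].isna().sum() == 2


class TestFitCox:
    def test_matches_grid_search_oracle_on_random_fixtures(self, rng):
        for _ in range(8):
            time, event, x = simulate_survival(rng, 50, rng.uniform(-1, 1))
            if event.sum() < 5:
                continue
            fit = fit_cox(time, event, x)
            oracle = grid_search_cox(time, event, x)
            assert abs(fit.beta - oracle) < 1e-4

    def test_no_events_unidentifiable(self, rng):
        with pytest.raises(UnidentifiableModelError):
            fit_cox(np.ones(20), np.zeros(20), rng.standard_normal(20))

    def test_hr_equivariance_under_negation(self, rng):
        time, event, x = simulate_survival(rng, 300, 0.4)
        a = fit_cox(time, event, x)
        b = fit_cox(time, event, -x)
        assert a.hr == pytest.approx(1.0 / b.hr, rel=1e-6)

    def test_null_covariate_rarely_significant(self, rng):
        hits = 0
        for _ in range(40):
            time, event, _ = simulate_survival(rng, 300, 0.0)
            x = rng.standard_normal(300)  # independent of hazard
            fit = fit_cox(time, event, x)
            hits += abs(fit.beta) > 3 * fit.se
        assert hits <= 4  # ~0.27% nominal; allow generous slack

    def test_ci_and_p_consistent(self, rng):
        time, event, x = simulate_survival(rng, 200, 0.5)
        fit = fit_cox(time, event, x)
        assert fit.ci_low == pytest.approx(math.exp(fit.beta - 1.96 * fit.se))
        assert fit.ci_high == pytest.approx(math.exp(fit.beta + 1.96 * fit.se))
        assert 0 < fit.pvalue <= 1


def _toy_cohort(rng, n=400, log_hrs=(0.4, 0.4, 0.0, 0.0, 0.0)):
    p = len(log_hrs)
    z = rng.standard_normal((p, n))
    eta = np.asarray(log_hrs) @ z
    t = rng.exponential(np.exp(-eta))
    c = np.quantile(t, 0.6)
    subjects = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "time_death": np.minimum(t, c) + 1e-9,
            "event_death": (t <= c).astype(int),
            "time_dhfa": np.minimum(t, c) + 1e-9,
            "event_dhfa": (t <= c).astype(int),
            "risk": rng.standard_normal(n),
        }
    )
    proteins = pd.DataFrame(
        np.exp(5 + 0.5 * z), index=[f"P{i}" for i in range(p)], columns=subjects["subject_id"]
    )
    return CohortTable(subjects=subjects, proteins=proteins, covariate_cols=["risk"])


class TestScreen:
    def test_hazardous_proteins_rank_first(self, rng):
        wins = 0
        for _ in range(5):
            cohort = _toy_cohort(rng)
            res = screen(cohort, "dhfa", "unadjusted")
            top2 = {r.protein_id for r in res[:2]}
            wins += top2 == {"P0", "P1"}
        assert wins >= 4

    def test_mediating_covariate_attenuates_hr(self, rng):
        n = 2000
        z = rng.standard_normal(n)
        mediator = 0.9 * z + 0.3 * rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.6 * mediator))
        c = np.quantile(t, 0.6)
        subjects = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "time_death": np.minimum(t, c) + 1e-9,
                "event_death": (t <= c).astype(int),
                "time_dhfa": np.minimum(t, c) + 1e-9,
                "event_dhfa": (t <= c).astype(int),
                "med": mediator,
            }
        )
        proteins = pd.DataFrame(np.exp(5 + 0.5 * z)[None, :], index=["P"], columns=subjects["subject_id"])
        cohort = CohortTable(subjects=subjects, proteins=proteins, covariate_cols=["med"])
        (unadj,) = screen(cohort, "dhfa", "unadjusted")
        (adj,) = screen(cohort, "dhfa", "adjusted")
        assert abs(adj.log_hr) < abs(unadj.log_hr)

    def test_empty_protein_matrix_gives_empty_result(self, rng):
        cohort = _toy_cohort(rng)
        res = screen(cohort, "dhfa", "unadjusted", z_proteins=pd.DataFrame())
        assert res == []

    def test_volcano_table_has_one_row_per_protein(self, rng):
        cohort = _toy_cohort(rng)
        res = screen(cohort, "dhfa", "unadjusted")
        df = volcano_table(res, alpha_corrected=0.01)
        assert len(df) == len(res)
        assert {"neg_log10_p", "sig_nominal", "sig_corrected"} <= set(df.columns)


class TestEffectiveTests:
    def test_identical_proteins_collapse_to_one(self, rng):
        base = rng.standard_normal(100)
        z = pd.DataFrame([base] * 6, index=[f"P{i}" for i in range(6)])
        corr = effective_tests(z, 0.95)
        assert corr.n_effective == 1
        assert corr.alpha_corrected == pytest.approx(0.05)

    def test_two_perfect_blocks_give_two(self, rng):
        a, b = rng.standard_normal(200), rng.standard_normal(200)
        z = pd.DataFrame([a, a, a, b, b, b], index=[f"P{i}" for i in range(6)])
        assert effective_tests(z, 0.95).n_effective == 2

    def test_independent_proteins_stay_near_full_count(self, rng):
        p, n = 20, 4000
        z = pd.DataFrame(rng.standard_normal((p, n)))
        corr = effective_tests(z, 0.95)
        assert 0.9 * p <= corr.n_effective <= p

    def test_monotone_in_threshold(self, rng):
        z = pd.DataFrame(rng.standard_normal((10, 150)))
        ks = [effective_tests(z, t).n_effective for t in (0.5, 0.7, 0.9, 0.99, 1.0)]
        assert ks == sorted(ks)

    def test_threshold_outside_unit_interval_rejected(self, rng):
        z = pd.DataFrame(rng.standard_normal((4, 30)))
        with pytest.raises(ConfigurationError):
            effective_tests(z, 1.5)
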