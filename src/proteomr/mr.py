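"""Two-sample Mendelian randomization estimators.

All estimates are on the log-odds scale per 1 SD of genetically predicted
protein level and reported as odds ratios with 95% CIs. The primary
estimator is fixed-effect inverse-variance weighting generalised to
correlated instruments: with Omega = diag(sy) R diag(sy),

    theta = (bx' Omega^-1 bx)^-1 bx' Omega^-1 by,
    se    = sqrt((bx' Omega^-1 bx)^-1),

which reduces to textbook fixed-effect IVW when R = I and to the Wald
ratio for a single instrument. Cochran's Q against the fitted slope is the
heterogeneity diagnostic. MR-Egger (weighted regression with intercept)
and the weighted median provide pleiotropy-robust sensitivity estimates
when at least three instruments are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import linalg, stats

from .errors import NumericalError
from .instruments import InstrumentSet
from .sumstats import ridge_repair

METHODS = ("wald", "ivw", "egger", "weighted_median")


@dataclass(slots=True)
class MRResult:
    protein_id: str
    outcome: str
    method: str
    theta: float
    se_theta: float
    or_: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_instruments: int
    egger_intercept: float = math.nan
    egger_intercept_p: float = math.nan
    cochran_q: float = math.nan
    cochran_q_df: int = 0
    source: str = ""


def _make_result(
    protein_id: str,
    outcome: str,
    method: str,
    theta: float,
    se: float,
    n: int,
    **extra,
) -> MRResult:
    z = theta / se
    return MRResult(
        protein_id=protein_id,
        outcome=outcome,
        method=method,
        theta=theta,
        se_theta=se,
        or_=math.exp(theta),
        ci_low=math.exp(theta - 1.96 * se),
        ci_high=math.exp(theta + 1.96 * se),
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        n_instruments=n,
        **extra,
    )


def wald_ratio(
    bx: float, sx: float, by: float, sy: float, second_order: bool = False
) -> tuple[float, float]:
    """Single-instrument ratio estimate with delta-method SE.

    First order: se = sy/|bx|. The optional second-order SE adds the
    exposure-uncertainty term sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4).
    """
    if bx == 0:
        raise NumericalError("Wald ratio undefined: exposure beta is zero")
    theta = by / bx
    if second_order:
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / abs(bx)
    return theta, se


def ivw_correlated(
    inst: InstrumentSet, outcome: str = "", source: str = ""
) -> MRResult:
    """Correlated-instrument fixed-effect IVW via generalised least squares."""
    bx, by, sy = inst.bx, inst.by, inst.sy
    n = inst.n_instruments
    R = ridge_repair(inst.R.R)
    omega = np.outer(sy, sy) * R
    try:
        c, low = linalg.cho_factor(omega)
    except linalg.LinAlgError:
        omega = omega + 1e-10 * np.mean(np.diag(omega)) * np.eye(n)
        try:
            c, low = linalg.cho_factor(omega)
        except linalg.LinAlgError as exc:
            raise NumericalError(
                f"singular instrument covariance (cond={np.linalg.cond(omega):.3g})"
            ) from exc
    oi_bx = linalg.cho_solve((c, low), bx)
    oi_by = linalg.cho_solve((c, low), by)
    denom = float(bx @ oi_bx)
    if denom <= 0:
        raise NumericalError("non-positive precision in IVW")
    theta = float(bx @ oi_by) / denom
    se = math.sqrt(1.0 / denom)
    resid = by - theta * bx
    q = float(resid @ linalg.cho_solve((c, low), resid))
    return _make_result(
        inst.protein_id, outcome, "ivw", theta, se, n,
        cochran_q=q, cochran_q_df=max(n - 1, 0), source=source,
    )


def mr_egger(inst: InstrumentSet, outcome: str = "", source: str = "") -> MRResult | None:
    """Weighted regression of by on bx with intercept (pleiotropy test).

    Instruments are oriented so all bx >= 0 (the estimate is invariant to
    allele coding only after this convention). Returns None for n < 3.
    """
    if inst.n_instruments < 3:
        return None
    sign = np.where(inst.bx < 0, -1.0, 1.0)
    bx = inst.bx * sign
    by = inst.by * sign
    w = 1.0 / inst.sy**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    se_int, se_slope = float(fit.bse[0]), float(fit.bse[1])
    p_int = float(2.0 * stats.norm.sf(abs(intercept / se_int)))
    return _make_result(
        inst.protein_id, outcome, "egger", slope, se_slope, inst.n_instruments,
        egger_intercept=intercept, egger_intercept_p=p_int, source=source,
    )


def _weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # mid-point cumulative weight
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(
    inst: InstrumentSet,
    outcome: str = "",
    source: str = "",
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult | None:
    """Weighted median of per-instrument ratios; bootstrap SE.

    Consistent when instruments carrying at least half the total weight are
    valid. SE from a parametric bootstrap resampling (bx, by) from their
    standard errors with a fixed seed. Returns None for n < 3.
    """
    n = inst.n_instruments
    if n < 3:
        return None
    if any(b == 0 for b in inst.bx):
        raise NumericalError("weighted median undefined with a zero exposure beta")
    ratios = inst.by / inst.bx
    se_r = inst.sy / np.abs(inst.bx)
    weights = 1.0 / se_r**2
    est = _weighted_median_estimate(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(inst.bx, inst.sx)
        by_b = rng.normal(inst.by, inst.sy)
        bx_b = np.where(bx_b == 0, 1e-12, bx_b)
        r_b = by_b / bx_b
        w_b = (bx_b / inst.sy) ** 2
        boots[b] = _weighted_median_estimate(r_b, w_b)
    se = float(boots.std(ddof=1))
    return _make_result(inst.protein_id, outcome, "weighted_median", est, se, n, source=source)


def run_all_methods(
    inst: InstrumentSet,
    outcome: str = "",
    source: str = "",
    n_boot: int = 1000,
    seed: int = 0,
) -> list[MRResult]:
    """IVW always; Wald for a single instrument; Egger and weighted median
    when n >= 3."""
    results = [ivw_correlated(inst, outcome, source)]
    if inst.n_instruments == 1:
        theta, se = wald_ratio(inst.bx[0], inst.sx[0], inst.by[0], inst.sy[0])
        results.append(_make_result(inst.protein_id, outcome, "wald", theta, se, 1, source=source))
    eg = mr_egger(inst, outcome, source)
    if eg is not None:
        results.append(eg)
    wm = weighted_median(inst, outcome, source, n_boot=n_boot, seed=seed)
    if wm is not None:
        results.append(wm)
    return results


def mr_table(results: list[MRResult]):
    import dataclasses

    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def forest_table(insts: dict[str, InstrumentSet], results: list[MRResult]):
    """Per-instrument ratios plus pooled estimates, forest-plot ready."""
    import pandas as pd

    rows = []
    for pid, inst in insts.items():
        for i, vid in enumerate(inst.variants):
            if inst.bx[i] == 0:
                continue
            theta, se = wald_ratio(inst.bx[i], inst.sx[i], inst.by[i], inst.sy[i])
            rows.append((pid, vid, "instrument", theta, se))
    for r in results:
        rows.append((r.protein_id, "pooled", r.method, r.theta, r.se_theta))
    return pd.DataFrame(rows, columns=["protein_id", "variant_id", "method", "theta", "se"])
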