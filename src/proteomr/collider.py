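"""Index-event (collider) bias correction for progression GWAS.

A GWAS of outcomes run only in people who already have the disease
conditions on disease liability. Variants that raise liability become
spuriously associated with outcome through the unmeasured factors they are
anti-correlated with in the selected sample; the induced outcome effect is
(approximately) linear in the incidence effect. The correction therefore:

1. fits a two-component mixture to (b_incidence, b_outcome) over
   LD-independent variants that pass an incidence p-value filter — one
   component concentrated on the line ``b_out = slope * b_inc``
   (incidence-only variants), one unconstrained (variants with genuine
   outcome effects);
2. subtracts ``slope * b_inc`` from every outcome association genome-wide.

The line component is structurally identified (it is constrained through
the origin), so no post-hoc cluster labelling is needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceFailure, InsufficientInstrumentsError
from .sumstats import AssociationRecord, harmonize, with_updated

logger = logging.getLogger(__name__)

DEFAULT_INCIDENCE_P = 1e-3
_VAR_FLOOR = 1e-12


@dataclass(slots=True)
class IncidenceOutcomePair:
    variant_id: str
    b_inc: float
    se_inc: float
    b_out: float
    se_out: float


@dataclass
class SlopeFit:
    """Fitted correction factor and mixture diagnostics."""

    slope_b: float
    se_slope: float
    mixing_proportion: float
    n_variants_used: int
    cluster_prob: np.ndarray = field(repr=False)
    variant_ids: list[str] = field(default_factory=list, repr=False)
    loglik: float = np.nan
    converged: bool = True


def pairs_from_records(
    incidence: list[AssociationRecord], outcome: list[AssociationRecord]
) -> list[IncidenceOutcomePair]:
    """Harmonize incidence onto outcome alleles and pair the effects."""
    inc_by_id = {r.variant_id: r for r in incidence}
    pairs = []
    for h in harmonize(outcome, incidence):
        if not h.kept:
            continue
        inc = inc_by_id[h.variant_id]
        pairs.append(
            IncidenceOutcomePair(
                variant_id=h.variant_id,
                b_inc=h.by,  # incidence beta aligned to the outcome allele
                se_inc=inc.se,
                b_out=h.bx,
                se_out=h.sx,
            )
        )
    return pairs


def _em_once(
    x: np.ndarray,
    y: np.ndarray,
    slope0: float,
    pi0: float,
    max_iter: int,
    tol: float,
    se2: np.ndarray,
) -> tuple[float, float, np.ndarray, float, bool, float]:
    """One EM run.

    Component 1 (incidence-only): x ~ N(0, tx2), y | x ~ N(slope*x,
    s1 + se_out^2). Component 2 (affects both): independent bivariate
    normal with free moments, y variance v2y + se_out^2. Anchoring the
    residual variances at the known per-variant sampling noise keeps the
    line component from tilting to absorb well-measured points. Returns
    (slope, pi, gamma, loglik, converged, s1).
    """
    n = x.size
    slope = slope0
    pi = pi0
    vx = max(x.var(), _VAR_FLOOR)
    tx2 = vx
    mean_se2 = float(se2.mean())
    s1 = max(np.var(y - slope * x) - mean_se2, 10.0 * _VAR_FLOOR)
    m2x, v2x = x.mean(), vx
    m2y, v2y = y.mean(), max(y.var() - mean_se2, 10.0 * _VAR_FLOOR)
    ll_prev = -np.inf
    gamma = np.full(n, pi)
    converged = False
    log2pi = math.log(2.0 * math.pi)
    for _ in range(max_iter):
        var1 = s1 + se2
        var2y = v2y + se2
        # inlined normal log-densities (hot loop)
        l1 = (
            -0.5 * (log2pi + math.log(tx2)) - 0.5 * x * x / tx2
            - 0.5 * (log2pi + np.log(var1)) - 0.5 * (y - slope * x) ** 2 / var1
            + math.log(pi)
        )
        l2 = (
            -0.5 * (log2pi + math.log(v2x)) - 0.5 * (x - m2x) ** 2 / v2x
            - 0.5 * (log2pi + np.log(var2y)) - 0.5 * (y - m2y) ** 2 / var2y
            + math.log(1.0 - pi)
        )
        m = np.maximum(l1, l2)
        denom = m + np.log(np.exp(l1 - m) + np.exp(l2 - m))
        ll = float(denom.sum())
        gamma = np.exp(l1 - denom)
        # M-step; slope by responsibility- and precision-weighted regression
        w1 = gamma.sum()
        w2 = n - w1
        pi = min(max(w1 / n, 1e-3), 1 - 1e-3)
        w = gamma / var1
        swxx = float((w * x * x).sum())
        if swxx > _VAR_FLOOR:
            slope = float((w * x * y).sum() / swxx)
        # moment update for the excess dispersion around the line
        s1 = max(
            float((gamma * ((y - slope * x) ** 2 - se2)).sum() / max(w1, 1e-9)),
            10.0 * _VAR_FLOOR,
        )
        tx2 = max(float((gamma * x * x).sum() / max(w1, 1e-9)), _VAR_FLOOR)
        if w2 > 1e-9:
            g2 = 1.0 - gamma
            m2x = float((g2 * x).sum() / w2)
            v2x = max(float((g2 * (x - m2x) ** 2).sum() / w2), _VAR_FLOOR)
            m2y = float((g2 * y).sum() / w2)
            v2y = max(
                float((g2 * ((y - m2y) ** 2 - se2)).sum() / w2), 10.0 * _VAR_FLOOR
            )
        if abs(ll - ll_prev) < tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return slope, pi, gamma, ll_prev, converged, s1


def _line_only_fit(
    x: np.ndarray, y: np.ndarray, se2: np.ndarray, max_iter: int = 200, tol: float = 1e-10
) -> tuple[float, float, float]:
    """Single-component fit: every variant on the line. Iterates GLS slope
    and excess-dispersion moment updates. Returns (slope, s1, loglik)."""
    mean_se2 = float(se2.mean())
    s1 = max(float(np.var(y)) - mean_se2, 10.0 * _VAR_FLOOR)
    slope = 0.0
    log2pi = math.log(2.0 * math.pi)
    tx2 = max(float(np.mean(x * x)), _VAR_FLOOR)
    ll = -np.inf
    for _ in range(max_iter):
        w = 1.0 / (s1 + se2)
        slope = float((w * x * y).sum() / (w * x * x).sum())
        s1_new = max(float(np.mean((y - slope * x) ** 2 - se2)), 10.0 * _VAR_FLOOR)
        var1 = s1_new + se2
        ll_new = float(
            (
                -0.5 * (log2pi + math.log(tx2)) - 0.5 * x * x / tx2
                - 0.5 * (log2pi + np.log(var1)) - 0.5 * (y - slope * x) ** 2 / var1
            ).sum()
        )
        if abs(ll_new - ll) < tol:
            ll = ll_new
            s1 = s1_new
            break
        ll, s1 = ll_new, s1_new
    return slope, s1, ll


def classify_and_fit(
    pairs: list[IncidenceOutcomePair],
    incidence_p_threshold: float = DEFAULT_INCIDENCE_P,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    min_variants: int = 30,
) -> SlopeFit:
    """Fit the correction slope by EM on incidence-filtered variant pairs.

    Variants must be LD-independent (clump upstream). Deterministic for a
    given seed: a fixed schedule of perturbed initialisations is run and
    the best-likelihood solution kept.
    """
    b_inc = np.array([p.b_inc for p in pairs])
    se_inc = np.array([p.se_inc for p in pairs])
    b_out = np.array([p.b_out for p in pairs])
    p_inc = 2.0 * stats.norm.sf(np.abs(b_inc / se_inc))
    mask = p_inc < incidence_p_threshold
    if int(mask.sum()) < min_variants:
        raise InsufficientInstrumentsError(
            f"only {int(mask.sum())} variants pass incidence p < {incidence_p_threshold}; "
            f"need >= {min_variants}"
        )
    x, y = b_inc[mask], b_out[mask]
    se2 = np.array([p.se_out for p in pairs])[mask] ** 2
    ids = [p.variant_id for p, m in zip(pairs, mask) if m]

    sxx = float((x * x).sum())
    ols = float((x * y).sum() / sxx) if sxx > 0 else 0.0
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_restarts):
        if k == 0:
            slope0, pi0 = ols, 0.7
        else:
            slope0 = ols * rng.uniform(0.3, 1.7) * rng.choice([-1.0, 1.0]) + rng.normal(0, 0.1)
            pi0 = rng.uniform(0.3, 0.9)
        fit = _em_once(x, y, slope0, pi0, max_iter, tol, se2)
        if best is None or fit[3] > best[3]:
            best = fit
    slope, pi, gamma, ll, converged, s1 = best
    if not converged and not np.isfinite(ll):
        raise ConvergenceFailure("collider EM did not converge in any restart")
    # model selection: a one-component (everything incidence-only) fit is
    # preferred by BIC when the data show no second cluster; the mixture is
    # unidentified there and can tilt on a small subset
    n_fit = x.size
    slope1, s1_one, ll_one = _line_only_fit(x, y, se2)
    bic_mix = -2.0 * ll + 8.0 * math.log(n_fit)
    bic_one = -2.0 * ll_one + 3.0 * math.log(n_fit)
    if bic_one <= bic_mix:
        slope, s1, ll = slope1, s1_one, ll_one
        pi = 1.0 - 1e-3
        gamma = np.ones(n_fit)
        converged = True
    # sandwich SE: robust to soft cluster assignment and residual-variance
    # misspecification in the weighted through-origin regression
    w_fin = gamma / (s1 + se2)
    wxx = float((w_fin * x * x).sum())
    resid = y - slope * x
    meat = float((w_fin**2 * x * x * resid**2).sum())
    se_slope = math.sqrt(meat) / wxx if wxx > 0 else math.nan
    return SlopeFit(
        slope_b=slope,
        se_slope=se_slope,
        mixing_proportion=pi,
        n_variants_used=int(mask.sum()),
        cluster_prob=gamma,
        variant_ids=ids,
        loglik=ll,
        converged=converged,
    )


def adjusted_outcome_covariance(
    b_inc: np.ndarray,
    se_out: np.ndarray,
    se_inc: np.ndarray,
    fit: SlopeFit,
) -> np.ndarray:
    """Covariance of adjusted outcome effects across a set of variants.

    The slope estimate is shared by every adjusted variant, so its error
    contributes a rank-one term ``se_slope^2 * b_inc b_inc'`` on top of the
    per-variant diagonal; ignoring it understates the variance of any
    statistic that combines several adjusted variants (e.g. IVW).
    """
    b_inc = np.asarray(b_inc, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    se_inc = np.asarray(se_inc, dtype=float)
    se_s = fit.se_slope if math.isfinite(fit.se_slope) else 0.0
    D = np.diag(se_out**2 + fit.slope_b**2 * se_inc**2)
    return D + se_s**2 * np.outer(b_inc, b_inc)


def adjust_outcome_stats(
    outcome: list[AssociationRecord],
    incidence: list[AssociationRecord],
    fit: SlopeFit,
) -> tuple[list[AssociationRecord], pd.DataFrame]:
    """Apply ``b_adj = b_out - slope * b_inc`` to every overlapping variant.

    SEs combine outcome noise, incidence noise scaled by the slope, and
    slope uncertainty: ``se_adj^2 = se_out^2 + slope^2 se_inc^2 +
    b_inc^2 se_slope^2``. P-values are recomputed under a normal
    approximation. Outcome variants without incidence data pass through
    unmodified and are flagged in the audit table.
    """
    inc_by_id = {r.variant_id: r for r in incidence}
    aligned: dict[str, tuple[float, float]] = {}
    try:
        for h in harmonize(outcome, incidence):
            if h.kept:
                aligned[h.variant_id] = (h.by, inc_by_id[h.variant_id].se)
    except Exception:  # no overlap at all -> everything passes through
        aligned = {}
    slope = fit.slope_b
    se_s = fit.se_slope if math.isfinite(fit.se_slope) else 0.0
    adjusted: list[AssociationRecord] = []
    rows = []
    for r in outcome:
        if r.variant_id in aligned:
            b_inc, se_inc = aligned[r.variant_id]
            b_adj = r.beta - slope * b_inc
            se_adj = math.sqrt(r.se**2 + slope**2 * se_inc**2 + b_inc**2 * se_s**2)
            p_adj = float(2.0 * stats.norm.sf(abs(b_adj / se_adj)))
            p_adj = max(p_adj, 5e-324)
            adjusted.append(
                with_updated(r, beta=b_adj, se=se_adj, pvalue=p_adj)
            )
            rows.append((r.variant_id, "adjusted", b_inc))
        else:
            adjusted.append(r)
            rows.append((r.variant_id, "passthrough_no_incidence", math.nan))
    audit = pd.DataFrame(rows, columns=["variant_id", "status", "b_inc_aligned"])
    return adjusted, audit
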