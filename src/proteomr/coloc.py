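"""Bayesian colocalization of a protein signal and an outcome signal.

Single-causal-variant model per trait per region. For each variant an
approximate Bayes factor against the null is computed from (beta, se) and
a prior effect SD W:

    V = se^2,  r = W^2 / (W^2 + V),  z = beta / se
    log ABF = 0.5 log(1 - r) + 0.5 r z^2

Hypotheses over the region: H0 no causal variant for either trait; H1/H2 a
causal variant for one trait only; H3 distinct causal variants; H4 a
shared causal variant. Their unnormalized weights are sums of per-variant
(pairs of) ABFs times the priors p1, p2 (per-SNP causal, one trait) and
p12 (per-SNP shared), accumulated in log space. Conditional colocalization
PP_H4 / (PP_H3 + PP_H4) quantifies sharing given that both traits have a
causal variant in the region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConfigurationError, DataError

#: per-SNP prior that a variant is causal for one trait
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
#: per-SNP prior that a variant is causal for both traits
DEFAULT_P12 = 1e-5
#: prior effect SDs: quantitative trait (SD units), case-control (log-odds)
DEFAULT_W_QUANT = 0.15
DEFAULT_W_CC = 0.2
#: posterior threshold for declaring a colocalization signal
COLOC_PP4_RULE = 0.8

HYPOTHESES = ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")


@dataclass
class ColocInput:
    """Harmonized region summary statistics for two traits."""

    variant_ids: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    trait1_type: str = "quantitative"
    trait2_type: str = "case_control"
    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12
    w1: float | None = None
    w2: float | None = None

    def __post_init__(self) -> None:
        n = len(self.variant_ids)
        for name in ("beta1", "se1", "beta2", "se2"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != (n,):
                raise DataError(f"{name} length mismatch with variant list")
        if n < 2:
            raise DataError("colocalization needs >= 2 variants")
        if (self.se1 <= 0).any() or (self.se2 <= 0).any():
            raise DataError("non-positive SE in coloc input")
        for p in (self.p1, self.p2, self.p12):
            if not (0.0 < p < 1.0):
                raise ConfigurationError("coloc priors must be in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise ConfigurationError("p12 must not exceed min(p1, p2)")
        if self.w1 is None:
            self.w1 = DEFAULT_W_QUANT if self.trait1_type == "quantitative" else DEFAULT_W_CC
        if self.w2 is None:
            self.w2 = DEFAULT_W_QUANT if self.trait2_type == "quantitative" else DEFAULT_W_CC


@dataclass
class ColocResult:
    pp: np.ndarray  # PP_H0..PP_H4
    n_snps: int
    conditional_pp: float  # nan when PP_H3 + PP_H4 == 0
    priors: tuple[float, float, float]
    colocalized: bool
    variant_pp: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])

    @property
    def pp_h3(self) -> float:
        return float(self.pp[3])


def log_abf(beta, se, prior_sd: float):
    """Log approximate Bayes factor for one association (vectorized)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DataError("se must be positive")
    if prior_sd <= 0:
        raise ConfigurationError("prior_sd must be positive")
    V = se**2
    r = prior_sd**2 / (prior_sd**2 + V)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * r * z**2


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when the difference underflows."""
    if b >= a:
        return -math.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_pp(inp: ColocInput) -> ColocResult:
    """Posterior probabilities for H0..H4 over a region.

    The H3 sum runs over ordered pairs of *distinct* variants; it is
    computed as the full cross-product sum minus the same-variant diagonal,
    all in log space.
    """
    l1 = log_abf(inp.beta1, inp.se1, inp.w1)
    l2 = log_abf(inp.beta2, inp.se2, inp.w2)
    n = len(l1)
    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))
    lp1, lp2, lp12 = math.log(inp.p1), math.log(inp.p2), math.log(inp.p12)
    lh0 = 0.0
    lh1 = lp1 + s1
    lh2 = lp2 + s2
    if n <= 2000:
        # exact pairwise sum over distinct variants (no cancellation)
        M = l1[:, None] + l2[None, :]
        np.fill_diagonal(M, -np.inf)
        lh3 = lp1 + lp2 + float(logsumexp(M))
    else:  # memory fallback: cross-product minus the diagonal
        lh3 = lp1 + lp2 + _log_diff_exp(s1 + s2, s12)
    lh4 = lp12 + s12
    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    denom = pp[3] + pp[4]
    cond = float(pp[4] / denom) if denom > 0 else math.nan
    per_snp = np.exp(l1 + l2 - s12)  # PP of each SNP being the shared one, given H4
    variant_pp = pd.DataFrame({"variant_id": inp.variant_ids, "pp_shared_given_h4": per_snp})
    return ColocResult(
        pp=pp,
        n_snps=len(inp.variant_ids),
        conditional_pp=cond,
        priors=(inp.p1, inp.p2, inp.p12),
        colocalized=bool(pp[4] > COLOC_PP4_RULE),
        variant_pp=variant_pp,
    )


def conditional_pp(result: ColocResult) -> float:
    """PP_H4 / (PP_H3 + PP_H4); nan when the denominator is zero."""
    denom = result.pp_h3 + result.pp_h4
    if denom <= 0:
        return math.nan
    return result.pp_h4 / denom


def prior_sensitivity(inp: ColocInput, p12_grid) -> pd.DataFrame:
    """Recompute posteriors over a grid of shared-causal priors.

    ABFs depend only on the data so they are reused; only the prior terms
    change. The result is flagged prior-sensitive when the colocalization
    call (PP_H4 > 0.8) differs across the grid.
    """
    rows = []
    for p12 in p12_grid:
        if not (0.0 < p12 <= min(inp.p1, inp.p2)):
            raise ConfigurationError("grid p12 outside (0, min(p1, p2)]")
        trial = ColocInput(
            variant_ids=inp.variant_ids,
            beta1=inp.beta1,
            se1=inp.se1,
            beta2=inp.beta2,
            se2=inp.se2,
            trait1_type=inp.trait1_type,
            trait2_type=inp.trait2_type,
            p1=inp.p1,
            p2=inp.p2,
            p12=float(p12),
            w1=inp.w1,
            w2=inp.w2,
        )
        res = coloc_pp(trial)
        rows.append((float(p12), res.pp_h4, res.conditional_pp, res.colocalized))
    df = pd.DataFrame(rows, columns=["p12", "pp_h4", "conditional_pp", "colocalized"])
    df["prior_sensitive"] = df["colocalized"].nunique() > 1
    return df


def coloc_report_row(protein_id: str, outcome: str, result: ColocResult) -> dict:
    return {
        "protein_id": protein_id,
        "outcome": outcome,
        "n_snps": result.n_snps,
        **{h: float(result.pp[i]) for i, h in enumerate(HYPOTHESES)},
        "conditional_pp": result.conditional_pp,
        "p1": result.priors[0],
        "p2": result.priors[1],
        "p12": result.priors[2],
        "colocalized": result.colocalized,
    }
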