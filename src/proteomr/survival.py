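"""Proteome-wide Cox proportional-hazards screening.

Protein abundances (relative fluorescence units) are natural-log
transformed and z-scored per protein, so every hazard ratio is "per 1 SD of
log abundance". Each protein is screened against all-cause death and
against the composite of death or HF hospitalization (DHFA), unadjusted or
adjusted for a clinical risk score plus log natriuretic peptide. The
multiple-comparison alpha is divided by the effective number of independent
tests: the number of principal components of the protein correlation
matrix needed to explain a set fraction of total variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from scipy import stats

from .errors import (
    ConfigurationError,
    ConvergenceFailure,
    DataError,
    UnidentifiableModelError,
)

logger = logging.getLogger(__name__)

OUTCOMES = ("death", "dhfa")
MODELS = ("unadjusted", "adjusted")


@dataclass
class CohortTable:
    """Survival cohort: one subjects table plus a proteins x subjects matrix.

    ``subjects`` must carry ``subject_id``, ``time_death``, ``event_death``,
    ``time_dhfa``, ``event_dhfa`` and any adjustment covariates;
    ``proteins`` is indexed by protein id with subject ids as columns.
    """

    subjects: pd.DataFrame
    proteins: pd.DataFrame
    covariate_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        need = {"subject_id", "time_death", "event_death", "time_dhfa", "event_dhfa"}
        missing = need - set(self.subjects.columns)
        if missing:
            raise ConfigurationError(f"cohort table missing columns {sorted(missing)}")
        s = self.subjects
        if (s["time_death"] <= 0).any() or (s["time_dhfa"] <= 0).any():
            raise DataError("non-positive follow-up times")
        for c in ("event_death", "event_dhfa"):
            if not s[c].isin((0, 1)).all():
                raise DataError(f"{c} is not binary")
        if (s["time_dhfa"] > s["time_death"] + 1e-9).any():
            raise DataError("DHFA time exceeds death time for some subjects")
        extra = set(self.proteins.columns) - set(s["subject_id"].astype(str))
        if extra and len(extra) == len(self.proteins.columns):
            raise ConfigurationError("protein matrix columns do not match subject ids")


@dataclass(slots=True)
class CoxFit:
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_used: int
    n_events: int


@dataclass(slots=True)
class ScreenResult:
    protein_id: str
    outcome: str
    model: str
    hr_per_sd: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_used: int
    n_events: int
    log_hr: float = np.nan
    se: float = np.nan


@dataclass(slots=True)
class AlphaCorrection:
    n_proteins: int
    n_effective: int
    variance_threshold: float
    alpha_corrected: float


def standardize_proteins(
    raw: pd.DataFrame, log_transform: bool = True
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Log-transform and z-score each protein row; exclude degenerate rows.

    Non-positive abundances become missing before the log. Returns the
    z-score matrix and a dict of excluded protein -> reason.
    """
    vals = raw.to_numpy(dtype=float)
    if log_transform:
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(vals > 0, np.log(vals), np.nan)
    excluded: dict[str, str] = {}
    out = np.full_like(vals, np.nan)
    keep_rows = []
    for i, pid in enumerate(raw.index):
        row = vals[i]
        ok = np.isfinite(row)
        if ok.sum() < 3:
            excluded[str(pid)] = "all_missing" if ok.sum() == 0 else "too_few_values"
            continue
        mu = row[ok].mean()
        sd = row[ok].std(ddof=1)
        if sd == 0:
            excluded[str(pid)] = "zero_variance"
            continue
        out[i, ok] = (row[ok] - mu) / sd
        keep_rows.append(i)
    z = pd.DataFrame(out[keep_rows], index=raw.index[keep_rows], columns=raw.columns)
    for pid, why in excluded.items():
        logger.info("protein %s excluded from screening: %s", pid, why)
    return z, excluded


def fit_cox(
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> CoxFit:
    """Cox PH fit for one protein (Efron ties, Newton-Raphson).

    Returns the protein coefficient only; covariates are nuisance columns.
    """
    df = pd.DataFrame({"time": np.asarray(time, float), "event": np.asarray(event, float), "x": np.asarray(x, float)})
    if covariates is not None:
        cov = pd.DataFrame(np.asarray(covariates, float))
        cov.columns = [f"c{j}" for j in range(cov.shape[1])]
        df = pd.concat([df.reset_index(drop=True), cov.reset_index(drop=True)], axis=1)
    df = df.dropna()
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise UnidentifiableModelError(f"only {n_events} events; Cox model unidentifiable")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (_LLConvergenceError, np.linalg.LinAlgError) as exc:
        raise ConvergenceFailure(f"Cox fit failed to converge: {exc}") from exc
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = beta / se
    return CoxFit(
        beta=beta,
        se=se,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        n_used=len(df),
        n_events=n_events,
    )


def screen(
    cohort: CohortTable,
    outcome: str = "dhfa",
    model: str = "adjusted",
    z_proteins: pd.DataFrame | None = None,
) -> list[ScreenResult]:
    """Screen every protein against one outcome; complete-case per protein.

    Per-protein fit failures are logged and skipped, never fatal. Results
    are sorted by ascending p-value.
    """
    if outcome not in OUTCOMES:
        raise ConfigurationError(f"outcome must be one of {OUTCOMES}")
    if model not in MODELS:
        raise ConfigurationError(f"model must be one of {MODELS}")
    if z_proteins is None:
        z_proteins, _ = standardize_proteins(cohort.proteins)
    if z_proteins.empty:
        logger.warning("empty protein matrix: nothing to screen")
        return []
    subj = cohort.subjects.set_index(cohort.subjects["subject_id"].astype(str))
    cols = [str(c) for c in z_proteins.columns]
    subj = subj.loc[[c for c in cols if c in subj.index]]
    time = subj[f"time_{outcome}"].to_numpy(float)
    event = subj[f"event_{outcome}"].to_numpy(float)
    cov = None
    if model == "adjusted" and cohort.covariate_cols:
        cov = subj[cohort.covariate_cols].to_numpy(float)
    results: list[ScreenResult] = []
    for pid in z_proteins.index:
        x = z_proteins.loc[pid, subj.index.to_list()].to_numpy(float)
        try:
            fit = fit_cox(time, event, x, cov)
        except (DataError, ConvergenceFailure) as exc:
            logger.warning("protein %s (%s/%s) failed: %s", pid, outcome, model, exc)
            continue
        results.append(
            ScreenResult(
                protein_id=str(pid),
                outcome=outcome,
                model=model,
                hr_per_sd=fit.hr,
                ci_low=fit.ci_low,
                ci_high=fit.ci_high,
                pvalue=fit.pvalue,
                n_used=fit.n_used,
                n_events=fit.n_events,
                log_hr=fit.beta,
                se=fit.se,
            )
        )
    results.sort(key=lambda r: (r.pvalue, r.protein_id))
    return results


def effective_tests(
    z_proteins: pd.DataFrame, variance_threshold: float = 0.95
) -> AlphaCorrection:
    """Effective number of independent tests from protein-matrix PCA.

    ``n_effective`` is the smallest k such that the top-k eigenvalues of the
    protein-protein correlation matrix explain >= ``variance_threshold`` of
    total variance; the corrected alpha is 0.05 / n_effective.
    """
    if not (0.0 < variance_threshold <= 1.0):
        raise ConfigurationError("variance_threshold must be in (0, 1]")
    p, n = z_proteins.shape
    if p < 2 or n < 3:
        raise ConfigurationError("need >= 2 proteins and >= 3 subjects")
    # correlation across proteins (rows); complete-case over subjects
    mat = z_proteins.dropna(axis=1).to_numpy(float)
    if mat.shape[1] < 3:
        mat = z_proteins.fillna(0.0).to_numpy(float)
    sd = mat.std(axis=1)
    if (sd == 0).any():
        raise ConfigurationError("zero-variance protein in effective-tests input")
    corr = np.corrcoef(mat)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)
    frac = np.cumsum(eig) / eig.sum()
    k = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    k = min(max(k, 1), p)
    return AlphaCorrection(
        n_proteins=p,
        n_effective=k,
        variance_threshold=variance_threshold,
        alpha_corrected=0.05 / k,
    )


def screen_table(results: list[ScreenResult]) -> pd.DataFrame:
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def volcano_table(results: list[ScreenResult], alpha_corrected: float) -> pd.DataFrame:
    """Plot-ready table: log-HR, -log10 p, nominal/corrected significance."""
    df = screen_table(results)
    if df.empty:
        return pd.DataFrame(
            columns=["protein_id", "log_hr", "neg_log10_p", "sig_nominal", "sig_corrected"]
        )
    df["neg_log10_p"] = -np.log10(df["pvalue"].clip(lower=1e-300))
    df["sig_nominal"] = df["pvalue"] < 0.05
    df["sig_corrected"] = df["pvalue"] < alpha_corrected
    return df[
        ["protein_id", "outcome", "model", "log_hr", "hr_per_sd", "neg_log10_p", "sig_nominal", "sig_corrected"]
    ]
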