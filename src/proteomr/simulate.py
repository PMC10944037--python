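"""Synthetic study generator.

Emulates every data role the pipeline consumes, with known truth:

* a variant panel split into per-protein cis regions plus a background
  block of liability variants, with AR(1) latent-Gaussian LD inside each
  region (corr(i, j) = ld_decay^|i-j| before dichotomisation to alleles);
* an external pQTL study: proteins built from cis effects at a target
  heritability, marginal per-variant regressions emitted as summary
  statistics (the deCODE/Fenland role);
* a reference genotype panel for LD estimation;
* a disease population under a liability-threshold model: liability =
  genetic score + protein effects + shared environmental frailty u; people
  above the threshold become the heart-failure cohort. Conditioning on
  liability makes genotypes anti-correlated with u inside the cohort, and
  u drives the adverse outcome — the collider bias the correction stage
  exists to remove (the case-only outcome GWAS role);
* an incidence GWAS computed in the full population (the HF-risk
  consortium role);
* a survival cohort whose death / death-or-HF-admission (DHFA) hazards
  depend on selected proteins and on u, with clinical covariates that
  proxy u (the observational cohort role).

Binary-trait GWAS effects are emitted on the log-odds scale via the
linear-probability-to-logit rescaling beta / (p*(1-p)).

Everything is driven by one ``numpy.random.default_rng`` seeded from
``SimConfig.seed`` (PCG64), so a config maps to one reproducible dataset.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .sumstats import AssociationRecord, LDMatrix, ld_from_genotypes, ridge_repair
from .sumstats import GeneLocus
from .survival import CohortTable

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "C"), ("T", "G"), ("G", "A"), ("C", "T")]


@dataclass
class VariantPanel:
    """Variant metadata: ids, coordinates, alleles, MAFs, region labels."""

    variant_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    maf: np.ndarray
    region: np.ndarray  # protein id for cis blocks, "bg" for background

    def __len__(self) -> int:
        return len(self.variant_id)

    def block(self, region: str) -> np.ndarray:
        return np.where(self.region == region)[0]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Default scales loosely mirror a single-centre HF cohort with an
    external pQTL resource: a ~2,000-subject proteomics cohort drawn from a
    larger liability-selected case set, ~50% composite event rate and ~25%
    death rate over follow-up, cis windows of a few tens of variants, and a
    well-powered external pQTL sample.
    """

    seed: int = 0
    # sample sizes
    n_ref: int = 2000
    n_pqtl: int = 15000
    n_population: int = 12000
    n_cohort: int = 2000
    # panel
    n_proteins: int = 20
    m_per_region: int = 30
    n_bg_variants: int = 80
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.8
    # protein architecture
    h2: float = 0.1
    n_causal_cis: int = 1
    # outcome model (per-protein, padded with zeros)
    causal_theta: dict[int, float] = field(default_factory=dict)  # log-odds / log-HR per SD
    protein_liability_effect: dict[int, float] = field(default_factory=dict)
    protein_u_loading: dict[int, float] = field(default_factory=dict)  # confounding
    # liability-threshold selection
    case_fraction: float = 0.25
    bg_liability_var: float = 0.3  # liability variance explained by bg variants
    env_liability_sd: float = 1.0  # SD of u's contribution to liability
    selection_on: bool = True
    # outcome event model among cases
    frailty_outcome_effect: float = 1.0  # effect of u on event log-odds / log-hazard
    target_dhfa_rate: float = 0.52
    target_death_rate: float = 0.26
    # horizontal pleiotropy of cis variants on the outcome
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigurationError("pleiotropy must be none, balanced or directional")
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ConfigurationError("maf_range must lie in (0, 0.5]")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ConfigurationError("ld_decay must be in [0, 1)")
        if not (0.0 <= self.h2 < 1.0):
            raise ConfigurationError("h2 must be in [0, 1)")
        if not (0.0 < self.case_fraction <= 1.0):
            raise ConfigurationError("case_fraction must be in (0, 1]")
        for name in ("causal_theta", "protein_liability_effect", "protein_u_loading"):
            d = getattr(self, name)
            if d and (min(d) < 0 or max(d) >= self.n_proteins):
                raise ConfigurationError(f"{name} indexes a protein outside 0..{self.n_proteins - 1}")

    def protein_ids(self) -> list[str]:
        return [f"P{k:02d}" for k in range(self.n_proteins)]


@dataclass
class SimTruth:
    """Ground truth shipped with every dataset for recovery tests."""

    causal_cis: dict[str, list[tuple[str, float]]]  # protein -> [(variant, per-allele beta)]
    causal_theta: dict[str, float]
    protein_liability_effect: dict[str, float]
    protein_u_loading: dict[str, float]
    bg_effects: dict[str, float]
    case_fraction: float
    frailty_outcome_effect: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


@dataclass
class SimBundle:
    """Everything the pipeline needs, in memory."""

    config: SimConfig
    panel: VariantPanel
    loci: list[GeneLocus]
    ld: LDMatrix
    cohort: CohortTable
    pqtl: dict[str, list[AssociationRecord]]  # protein -> exposure records
    outcome: dict[str, list[AssociationRecord]]  # "death"/"dhfa" -> case-only GWAS
    incidence: list[AssociationRecord]
    truth: SimTruth
    n_cases: int = 0


# ---------------------------------------------------------------- genotypes


def build_panel(config: SimConfig, rng: np.random.Generator) -> VariantPanel:
    """Cis region per protein on its own chromosome, plus a background
    block on a separate chromosome; 2 kb variant spacing."""
    ids, chroms, pos, eas, oas, mafs, regions = [], [], [], [], [], [], []
    lo, hi = config.maf_range
    counter = 0
    for k, pid in enumerate(config.protein_ids()):
        base = rng.uniform(max(lo, 0.15), hi)  # regional frequency anchor
        for j in range(config.m_per_region):
            ids.append(f"rs{counter}")
            chroms.append(str(k + 1))
            pos.append(1_000_000 + j * 2_000)
            ea, oa = _ALLELE_PAIRS[counter % len(_ALLELE_PAIRS)]
            eas.append(ea)
            oas.append(oa)
            mafs.append(float(np.clip(base + rng.uniform(-0.05, 0.05), lo, hi)))
            regions.append(pid)
            counter += 1
    for j in range(config.n_bg_variants):
        ids.append(f"rs{counter}")
        chroms.append(str(config.n_proteins + 1))
        pos.append(1_000_000 + j * 50_000)
        ea, oa = _ALLELE_PAIRS[counter % len(_ALLELE_PAIRS)]
        eas.append(ea)
        oas.append(oa)
        mafs.append(rng.uniform(lo, hi))
        regions.append("bg")
        counter += 1
    return VariantPanel(
        variant_id=np.array(ids),
        chrom=np.array(chroms),
        pos=np.array(pos, dtype=int),
        effect_allele=np.array(eas),
        other_allele=np.array(oas),
        maf=np.array(mafs),
        region=np.array(regions),
    )


def default_loci(config: SimConfig) -> list[GeneLocus]:
    """One gene per protein, centred in its cis region (gene body 20 kb)."""
    loci = []
    for k, pid in enumerate(config.protein_ids()):
        mid = 1_000_000 + config.m_per_region * 1_000
        loci.append(
            GeneLocus(gene=f"GENE{k:02d}", chrom=str(k + 1), start=mid, end=mid + 20_000, protein_id=pid)
        )
    return loci


def _ar1_block(n: int, m: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """n x m latent Gaussians with AR(1) column correlation rho^|i-j|."""
    z = rng.standard_normal((n, m), dtype=np.float32)
    if rho > 0:
        # arcsine-law compensation: latent correlation sin(pi*rho/2) yields
        # approximately rho between the dichotomised alleles
        lat = math.sin(math.pi * min(rho, 0.999) / 2.0)
        rho32 = np.float32(lat)
        scale = np.float32(math.sqrt(1.0 - lat * lat))
        for j in range(1, m):
            z[:, j] = rho32 * z[:, j - 1] + scale * z[:, j]
    return z


def simulate_genotypes(
    n: int,
    panel: VariantPanel,
    ld_decay: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dosage matrix (n x m) with AR(1) latent LD inside each region.

    Two latent haplotypes per subject are dichotomised at the MAF quantile,
    so allele frequencies match the panel and Pearson dosage LD is an
    attenuated (tetrachoric-to-Pearson) version of ld_decay^|i-j|.
    """
    G = np.empty((n, len(panel)), dtype=np.float32)
    thresholds = stats.norm.ppf(panel.maf).astype(np.float32)
    for region in np.unique(panel.region):
        idx = panel.block(region)
        m = len(idx)
        t = thresholds[idx]
        # background variants stand for genome-wide clumped hits: no LD
        rho = 0.0 if region == "bg" else ld_decay
        dos = np.zeros((n, m), dtype=np.float32)
        for _hap in range(2):
            z = _ar1_block(n, m, rho, rng)
            dos += z < t
        G[:, idx] = dos
    return G


def empirical_ld(G: np.ndarray, panel: VariantPanel) -> LDMatrix:
    """Block-diagonal LD: empirical within regions, zero across (regions sit
    on different chromosomes by construction)."""
    m = len(panel)
    R = np.zeros((m, m))
    flagged: list[str] = []
    for region in np.unique(panel.region):
        idx = panel.block(region)
        sub = ld_from_genotypes(G[:, idx], list(panel.variant_id[idx]))
        R[np.ix_(idx, idx)] = sub.R
        flagged.extend(sub.flagged)
    np.fill_diagonal(R, 1.0)
    return LDMatrix(list(panel.variant_id), ridge_repair(R), flagged)


# ------------------------------------------------------------- regressions


def marginal_linear(
    G: np.ndarray, y: np.ndarray, _sxx: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant simple linear regression, vectorized.

    Returns (beta, se, pvalue) per column of G. ``_sxx`` (centred sums of
    squares per column) may be precomputed when G is reused across traits.
    """
    n = len(y)
    yc = y - y.mean()
    if _sxx is None:
        _sxx = (G**2).sum(axis=0) - n * G.mean(axis=0) ** 2
    sxx = np.where(_sxx <= 0, np.nan, _sxx)
    # G.T @ yc equals centred cross-product because yc sums to zero
    beta = G.T @ yc / sxx
    syy = float((yc**2).sum())
    sse = np.clip(syy - beta**2 * sxx, 1e-12, None)
    se = np.sqrt(sse / (n - 2) / sxx)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 5e-324, 1.0)
    return beta, se, p


def linear_to_logodds(beta: np.ndarray, se: np.ndarray, prevalence: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear-probability effects rescaled to log-odds: divide by p(1-p)."""
    if not (0.0 < prevalence < 1.0):
        raise ConfigurationError("prevalence must be strictly inside (0, 1)")
    f = prevalence * (1.0 - prevalence)
    return beta / f, se / f


def _records(
    panel: VariantPanel,
    idx: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    p: np.ndarray,
    eaf: np.ndarray,
    n: int,
    trait_id: str,
) -> list[AssociationRecord]:
    return [
        AssociationRecord(
            variant_id=str(panel.variant_id[i]),
            chrom=str(panel.chrom[i]),
            pos=int(panel.pos[i]),
            effect_allele=str(panel.effect_allele[i]),
            other_allele=str(panel.other_allele[i]),
            eaf=float(eaf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pvalue=float(p[j]),
            n=n,
            trait_id=trait_id,
        )
        for j, i in enumerate(idx)
    ]


# ----------------------------------------------------------------- protein


def simulate_protein(
    G: np.ndarray,
    effects: list[tuple[int, float]],
    h2: float,
    rng: np.random.Generator,
    u: np.ndarray | None = None,
    u_loading: float = 0.0,
) -> np.ndarray:
    """Protein level: cis genetic score scaled to heritability h2, optional
    loading on a shared factor u, unit total variance (approximately).

    Raises when h2 and the effect list are inconsistent (h2 > 0 with no
    effects, or h2 = 0 with effects).
    """
    n = G.shape[0]
    if (h2 > 0) != bool(effects):
        raise ConfigurationError("h2 inconsistent with cis effect list")
    y = np.zeros(n)
    if effects:
        for j, eff in effects:
            y = y + eff * G[:, j]
        vg = y.var()
        if vg <= 0:
            raise ConfigurationError("degenerate cis genetic score")
        # rescale so the genetic component explains exactly h2 of variance 1
        y = y * math.sqrt(h2 / vg)
    resid_sd = math.sqrt(max(1.0 - h2 - u_loading**2, 1e-6))
    if u is not None and u_loading != 0.0:
        y = y + u_loading * u
    return y + resid_sd * rng.standard_normal(n)


def cis_architecture(config: SimConfig, panel: VariantPanel, rng: np.random.Generator) -> dict[str, list[tuple[int, float]]]:
    """Pick causal cis variants per protein; unit nominal per-allele effects
    (the realized scale is set by the h2 normalisation)."""
    arch: dict[str, list[tuple[int, float]]] = {}
    for pid in config.protein_ids():
        idx = panel.block(pid)
        chosen = rng.choice(idx, size=min(config.n_causal_cis, len(idx)), replace=False)
        arch[pid] = [(int(j), 1.0) for j in np.sort(chosen)]
    return arch


def simulate_pqtl_study(
    G: np.ndarray,
    panel: VariantPanel,
    arch: dict[str, list[tuple[int, float]]],
    h2: float,
    rng: np.random.Generator,
    trait_prefix: str = "pqtl",
) -> dict[str, list[AssociationRecord]]:
    """Marginal per-variant associations of each protein with every panel
    variant, in an independent pQTL sample."""
    n = G.shape[0]
    eaf = G.mean(axis=0) / 2.0
    sxx = (G**2).sum(axis=0) - n * G.mean(axis=0) ** 2
    out: dict[str, list[AssociationRecord]] = {}
    all_idx = np.arange(len(panel))
    for pid, effects in arch.items():
        y = simulate_protein(G, effects, h2, rng)
        y = (y - y.mean()) / y.std()
        beta, se, p = marginal_linear(G, y, _sxx=sxx)
        out[pid] = _records(panel, all_idx, beta, se, p, eaf, n, f"{trait_prefix}:{pid}")
    return out


# ------------------------------------------------------ cohort & outcomes


def _solve_base_rate(lin: np.ndarray, target: float) -> float:
    """Baseline cumulative hazard r0 with mean(1 - exp(-r0 e^lin)) = target."""
    e = np.exp(lin - lin.mean())
    lo, hi = 1e-10, 1e4
    for _ in range(100):
        mid = math.sqrt(lo * hi)
        rate = float(np.mean(1.0 - np.exp(-mid * e)))
        if rate < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi) / math.exp(lin.mean())


def simulate_hf_cohort_and_outcome_gwas(config: SimConfig) -> SimBundle:
    """Full synthetic study: population, selection, cohort, all GWAS."""
    rng = np.random.default_rng(config.seed)
    panel = build_panel(config, rng)
    loci = default_loci(config)
    pids = config.protein_ids()

    # LD reference panel
    G_ref = simulate_genotypes(config.n_ref, panel, config.ld_decay, rng)
    ld = empirical_ld(G_ref, panel)

    # cis architecture shared by every sample of the same config
    arch = cis_architecture(config, panel, rng)

    # external pQTL study
    G_pqtl = simulate_genotypes(config.n_pqtl, panel, config.ld_decay, rng)
    pqtl = simulate_pqtl_study(G_pqtl, panel, arch, config.h2, rng)

    # disease population
    n_pop = config.n_population
    G_pop = simulate_genotypes(n_pop, panel, config.ld_decay, rng)
    u = rng.standard_normal(n_pop)  # shared environmental frailty

    proteins = np.empty((config.n_proteins, n_pop))
    for k, pid in enumerate(pids):
        y = simulate_protein(
            G_pop, arch[pid], config.h2, rng, u=u, u_loading=config.protein_u_loading.get(k, 0.0)
        )
        proteins[k] = (y - y.mean()) / y.std()

    bg_idx = panel.block("bg")
    Gbg = G_pop[:, bg_idx]
    Gbg_std = (Gbg - Gbg.mean(0)) / Gbg.std(0)
    # background hits mimic published risk loci: magnitudes bounded away
    # from zero (they were themselves selected at genome-wide significance)
    a = rng.uniform(0.7, 1.3, size=len(bg_idx)) * rng.choice([-1.0, 1.0], size=len(bg_idx))
    a *= math.sqrt(config.bg_liability_var) / math.sqrt(float((a**2).sum()))
    gscore = Gbg_std @ a

    liability = gscore.copy()
    for k in range(config.n_proteins):
        gam = config.protein_liability_effect.get(k, 0.0)
        if gam:
            liability = liability + gam * proteins[k]
    liability = liability + config.env_liability_sd * u
    liability = liability + rng.standard_normal(n_pop) * 0.5  # idiosyncratic noise

    if config.selection_on and config.case_fraction < 1.0:
        thr = np.quantile(liability, 1.0 - config.case_fraction)
        cases = liability >= thr
    else:
        cases = np.ones(n_pop, dtype=bool)
    n_cases = int(cases.sum())
    if n_cases < 500:
        raise ConfigurationError(f"selection left only {n_cases} cases (< 500)")

    # linear predictors for the two outcomes among cases
    theta = np.zeros(config.n_proteins)
    for k, v in config.causal_theta.items():
        theta[k] = v
    lin = theta @ proteins + config.frailty_outcome_effect * u
    if config.pleiotropy != "none":
        delta = config.pleiotropy_delta
        for pid in pids:
            for j, _ in arch[pid]:
                d = delta if config.pleiotropy == "directional" else rng.choice([-delta, delta])
                lin = lin + d * (G_pop[:, j] - G_pop[:, j].mean())
    lin_c = lin[cases]

    # survival times: exponential hazards, one administrative censoring time
    r_death = _solve_base_rate(lin_c, config.target_death_rate)
    # competing processes: P(dhfa) = 1 - (1-p_death)(1-p_hf)
    extra = (config.target_dhfa_rate - config.target_death_rate) / max(
        1.0 - config.target_death_rate, 1e-6
    )
    r_dhfa_extra = _solve_base_rate(lin_c, max(extra, 0.05))
    e_lin = np.exp(lin_c)
    t_death = rng.exponential(1.0 / (r_death * e_lin))
    t_hf = rng.exponential(1.0 / (r_dhfa_extra * e_lin))
    censor = 1.0  # one follow-up window; times are in window units
    time_death = np.minimum(t_death, censor)
    event_death = (t_death <= censor).astype(int)
    t_first = np.minimum(t_death, t_hf)
    time_dhfa = np.minimum(t_first, censor)
    event_dhfa = (t_first <= censor).astype(int)

    # case-only outcome GWAS (log-odds of event within the window)
    G_cases = G_pop[cases]
    eaf_cases = G_cases.mean(axis=0) / 2.0
    outcome: dict[str, list[AssociationRecord]] = {}
    all_idx = np.arange(len(panel))
    for name, ev in (("death", event_death), ("dhfa", event_dhfa)):
        beta, se, p = marginal_linear(G_cases, ev.astype(float))
        prev = float(ev.mean())
        beta, se = linear_to_logodds(beta, se, prev)
        outcome[name] = _records(panel, all_idx, beta, se, p, eaf_cases, n_cases, f"outcome:{name}")

    # incidence GWAS in the full population
    beta, se, p = marginal_linear(G_pop, cases.astype(float))
    prev = float(cases.mean())
    beta, se = linear_to_logodds(beta, se, prev)
    eaf_pop = G_pop.mean(axis=0) / 2.0
    incidence = _records(panel, all_idx, beta, se, p, eaf_pop, n_pop, "incidence:hf")

    # proteomics cohort: first n_cohort cases, abundances on an RFU-like scale
    case_rows = np.where(cases)[0]
    cohort_rows = case_rows[: min(config.n_cohort, n_cases)]
    sel = np.searchsorted(case_rows, cohort_rows)  # positions within the case set
    subject_ids = [f"S{i:05d}" for i in range(len(cohort_rows))]
    u_coh = u[cohort_rows]
    # clinical covariates proxy the frailty that confounds protein-outcome links
    maggic = 0.7 * u_coh + 0.5 * rng.standard_normal(len(cohort_rows))
    log_nt = 0.6 * u_coh + 0.3 * theta @ proteins[:, cohort_rows] + 0.6 * rng.standard_normal(len(cohort_rows))
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "time_death": time_death[sel],
            "event_death": event_death[sel],
            "time_dhfa": time_dhfa[sel],
            "event_dhfa": event_dhfa[sel],
            "maggic": maggic,
            "log_ntprobnp": log_nt,
        }
    )
    rfu = np.exp(7.0 + 0.5 * proteins[:, cohort_rows])
    prot_df = pd.DataFrame(rfu, index=pids, columns=subject_ids)
    cohort = CohortTable(subjects=subjects, proteins=prot_df, covariate_cols=["maggic", "log_ntprobnp"])

    truth = SimTruth(
        causal_cis={
            pid: [(str(panel.variant_id[j]), float(e)) for j, e in effects]
            for pid, effects in arch.items()
        },
        causal_theta={pids[k]: float(v) for k, v in config.causal_theta.items()},
        protein_liability_effect={pids[k]: float(v) for k, v in config.protein_liability_effect.items()},
        protein_u_loading={pids[k]: float(v) for k, v in config.protein_u_loading.items()},
        bg_effects={str(panel.variant_id[i]): float(a[j]) for j, i in enumerate(bg_idx)},
        case_fraction=config.case_fraction,
        frailty_outcome_effect=config.frailty_outcome_effect,
    )
    return SimBundle(
        config=config,
        panel=panel,
        loci=loci,
        ld=ld,
        cohort=cohort,
        pqtl=pqtl,
        outcome=outcome,
        incidence=incidence,
        truth=truth,
        n_cases=n_cases,
    )


@dataclass
class ColliderReplicate:
    """One reduced collider-bias study: summary-level exposure, individual
    outcome, for calibration experiments."""

    pairs: list  # IncidenceOutcomePair over background variants
    bx: np.ndarray  # exposure effects at the protein's instruments
    sx: np.ndarray
    by_naive: np.ndarray  # unadjusted case-only outcome effects (log-odds)
    sy: np.ndarray
    b_inc: np.ndarray  # instrument incidence effects (log-odds)
    se_inc: np.ndarray
    outcome_records: list[AssociationRecord]
    incidence_records: list[AssociationRecord]
    instrument_ids: list[str]


def simulate_collider_replicate(
    rng: np.random.Generator,
    n_population: int = 8000,
    n_bg: int = 100,
    n_instruments: int = 5,
    h2_instrument: float = 0.03,
    gamma: float = 0.4,
    frailty_outcome_effect: float = 1.2,
    case_fraction: float = 0.25,
    causal_theta: float = 0.0,
    bg_liability_var: float = 0.3,
    exposure_n: int = 15000,
    n_incidence_study: int = 30000,
    selection_on: bool = True,
) -> ColliderReplicate:
    """Minimal liability-selection study for collider-bias calibration.

    Independent variants only: a background panel of ``n_bg`` liability
    variants standing for genome-wide clumped incidence hits, plus the
    protein's cis instruments (each explaining ``h2_instrument`` of protein
    variance); the exposure study is emulated at the summary level with
    per-allele effects drawn around their truth at the precision of a
    well-powered external pQTL sample of ``exposure_n``. Outcome and
    incidence GWAS are computed from individual-level data exactly as in
    the full generator.
    """
    from .collider import IncidenceOutcomePair

    m = n_bg + n_instruments
    maf = rng.uniform(0.1, 0.5, size=m)
    G = rng.binomial(2, maf, size=(n_population, m)).astype(np.float64)
    Gs = (G - G.mean(0)) / G.std(0)

    # protein with cis instruments (last n_instruments columns)
    inst_cols = np.arange(n_bg, m)
    b_std = math.sqrt(h2_instrument)  # per standardized-dosage effect
    protein = Gs[:, inst_cols] @ np.full(n_instruments, b_std)
    protein = protein + rng.standard_normal(n_population) * math.sqrt(
        max(1.0 - h2_instrument * n_instruments, 1e-6)
    )
    protein = (protein - protein.mean()) / protein.std()

    a = rng.uniform(0.7, 1.3, size=n_bg) * rng.choice([-1.0, 1.0], size=n_bg)
    a *= math.sqrt(bg_liability_var) / math.sqrt(float((a**2).sum()))
    u = rng.standard_normal(n_population)
    liability = Gs[:, :n_bg] @ a + gamma * protein + u + 0.5 * rng.standard_normal(n_population)
    if selection_on:
        thr = np.quantile(liability, 1.0 - case_fraction)
        cases = liability >= thr
    else:
        cases = rng.random(n_population) < case_fraction
    n_cases = int(cases.sum())

    logit = -0.2 + causal_theta * protein + frailty_outcome_effect * u
    event = (rng.random(n_population) < 1.0 / (1.0 + np.exp(-logit))).astype(float)
    ev_c = event[cases]

    beta_o, se_o, _ = marginal_linear(G[cases], ev_c)
    beta_o, se_o = linear_to_logodds(beta_o, se_o, float(ev_c.mean()))

    # independent large incidence study under the same liability model
    G2 = rng.binomial(2, maf, size=(n_incidence_study, m)).astype(np.float64)
    G2s = (G2 - G2.mean(0)) / G2.std(0)
    protein2 = G2s[:, inst_cols] @ np.full(n_instruments, b_std)
    protein2 = protein2 + rng.standard_normal(n_incidence_study) * math.sqrt(
        max(1.0 - h2_instrument * n_instruments, 1e-6)
    )
    protein2 = (protein2 - protein2.mean()) / protein2.std()
    u2 = rng.standard_normal(n_incidence_study)
    liab2 = G2s[:, :n_bg] @ a + gamma * protein2 + u2 + 0.5 * rng.standard_normal(n_incidence_study)
    cases2 = liab2 >= np.quantile(liab2, 1.0 - case_fraction)
    beta_i, se_i, _ = marginal_linear(G2, cases2.astype(float))
    beta_i, se_i = linear_to_logodds(beta_i, se_i, float(cases2.mean()))

    pairs = [
        IncidenceOutcomePair(
            variant_id=f"v{j}",
            b_inc=float(beta_i[j]),
            se_inc=float(se_i[j]),
            b_out=float(beta_o[j]),
            se_out=float(se_o[j]),
        )
        for j in range(n_bg)
    ]
    # summary-level exposure study: per-allele truth + sampling noise
    var_g = 2.0 * maf[inst_cols] * (1.0 - maf[inst_cols])
    bx_true = b_std / np.sqrt(var_g)
    sx = 1.0 / np.sqrt(exposure_n * var_g)
    bx = rng.normal(bx_true, sx)

    ids = [f"v{j}" for j in range(m)]

    def _recs(beta, se, n, trait):
        return [
            AssociationRecord(
                variant_id=ids[j],
                chrom="1" if j < n_bg else "2",
                pos=1_000_000 + j * 10_000,
                effect_allele="A",
                other_allele="G",
                eaf=float(maf[j]),
                beta=float(beta[j]),
                se=float(se[j]),
                pvalue=float(2.0 * stats.norm.sf(abs(beta[j] / se[j]))),
                n=n,
                trait_id=trait,
            )
            for j in range(m)
        ]

    return ColliderReplicate(
        pairs=pairs,
        bx=bx,
        sx=sx,
        by_naive=beta_o[inst_cols],
        sy=se_o[inst_cols],
        b_inc=beta_i[inst_cols],
        se_inc=se_i[inst_cols],
        outcome_records=_recs(beta_o, se_o, n_cases, "outcome"),
        incidence_records=_recs(beta_i, se_i, n_incidence_study, "incidence"),
        instrument_ids=[ids[j] for j in inst_cols],
    )


def demo_config(seed: int = 0, **overrides) -> SimConfig:
    """Reference 20-protein scenario: protein P00 causally worsens both
    outcomes (log-odds 0.7 per SD, i.e. OR ~ 2, the scale of the strongest
    replicated protein effects in HF outcome MR) and colocalizes at its
    strong cis locus (h2 = 0.2, typical of a top cis pQTL); P01..P06 are
    confounded with the frailty factor (observationally hazardous,
    causally null); the rest are null."""
    n_proteins = int(overrides.get("n_proteins", 20))
    base = dict(
        seed=seed,
        h2=0.2,
        causal_theta={0: 0.7},
        protein_liability_effect={0: 0.4},
        protein_u_loading={k: 0.4 for k in range(1, min(7, n_proteins))},
    )
    base.update(overrides)
    return SimConfig(**base)


# ----------------------------------------------------------------- export


def write_bundle(bundle: SimBundle, outdir) -> None:
    """Write the full input bundle as plain-text tables plus a truth file."""
    from pathlib import Path

    from .sumstats import write_ld_matrix, write_summary_stats

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.cohort.subjects.to_csv(out / "cohort_subjects.tsv", sep="\t", index=False)
    bundle.cohort.proteins.to_csv(out / "cohort_proteins.tsv", sep="\t", index_label="protein_id")
    allrecs = [r for recs in bundle.pqtl.values() for r in recs]
    write_summary_stats(allrecs, out / "pqtl.tsv")
    for name, recs in bundle.outcome.items():
        write_summary_stats(recs, out / f"outcome_{name}.tsv")
    write_summary_stats(bundle.incidence, out / "incidence.tsv")
    write_ld_matrix(bundle.ld, out / "ld.tsv")
    loci = pd.DataFrame(
        {
            "gene": [l.gene for l in bundle.loci],
            "chrom": [l.chrom for l in bundle.loci],
            "start": [l.start - 1 for l in bundle.loci],  # BED-like on disk
            "end": [l.end for l in bundle.loci],
            "protein_id": [l.protein_id for l in bundle.loci],
        }
    )
    loci.to_csv(out / "loci.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(bundle.truth.to_json())
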