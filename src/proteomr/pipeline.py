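"""End-to-end orchestration: screen -> collider adjustment -> cis-MR -> coloc.

Stage gating mirrors the analysis design: only proteins passing the
PC-corrected screening alpha advance to MR, and only MR-significant
proteins (IVW p below the nominal alpha in any exposure source) advance to
colocalization. Every stage emits a plot-ready table and the manifest
records parameters, seeds and in/out counts so the funnel can be read off
directly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .coloc import ColocInput, coloc_pp, coloc_report_row, prior_sensitivity
from .collider import SlopeFit, adjust_outcome_stats, classify_and_fit, pairs_from_records
from .errors import DataError, InsufficientInstrumentsError, NumericalError, ProteoMRError
from .instruments import build_instrument_set, clump, instrument_report, is_cis
from .mr import mr_table, run_all_methods
from .simulate import SimBundle
from .sumstats import (
    AssociationRecord,
    GeneLocus,
    LDMatrix,
    harmonize,
    read_gene_loci,
    read_ld_matrix,
    read_summary_stats,
)
from .survival import (
    CohortTable,
    effective_tests,
    screen,
    screen_table,
    standardize_proteins,
    volcano_table,
)

logger = logging.getLogger(__name__)

TIERS = ("none", "observational-only", "MR-supported", "MR+coloc-supported")


class PipelineConfig(BaseModel):
    """Schema-validated run configuration; all thresholds surfaced."""

    outcomes: list[str] = Field(default=["dhfa"])
    screen_model: str = "adjusted"
    variance_threshold: float = 0.95
    window_bp: int = 500_000
    p_threshold: float = 5e-8
    instrument_scope: str = "cis"
    r2_threshold: float = 0.1
    palindromic_band: float = 0.08
    apply_collider_adjustment: bool = True
    incidence_p_threshold: float = 1e-3
    mr_alpha: float = 0.05
    n_boot: int = 500
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_p12_grid: list[float] = Field(default=[1e-6, 1e-5, 1e-4])
    coloc_conditional_rule: float = 0.9
    seed: int = 0

    @field_validator("outcomes")
    @classmethod
    def _check_outcomes(cls, v):
        bad = set(v) - {"death", "dhfa"}
        if bad:
            raise ValueError(f"unknown outcomes {sorted(bad)}")
        return v

    @field_validator("variance_threshold")
    @classmethod
    def _check_vt(cls, v):
        if not (0 < v <= 1):
            raise ValueError("variance_threshold must be in (0, 1]")
        return v

    @field_validator("screen_model")
    @classmethod
    def _check_model(cls, v):
        if v not in ("unadjusted", "adjusted"):
            raise ValueError("screen_model must be unadjusted or adjusted")
        return v

    @field_validator("instrument_scope")
    @classmethod
    def _check_scope(cls, v):
        if v not in ("cis", "trans", "both"):
            raise ValueError("instrument_scope must be cis, trans or both")
        return v


@dataclass
class PipelineInputs:
    """All resolved inputs; pQTLs are nested source -> protein -> records."""

    cohort: CohortTable
    pqtl: dict[str, dict[str, list[AssociationRecord]]]
    outcome_gwas: dict[str, list[AssociationRecord]]
    incidence_gwas: list[AssociationRecord]
    ld: LDMatrix
    loci: dict[str, GeneLocus]

    @classmethod
    def from_bundle(cls, bundle: SimBundle, source: str = "synth") -> "PipelineInputs":
        return cls(
            cohort=bundle.cohort,
            pqtl={source: bundle.pqtl},
            outcome_gwas=bundle.outcome,
            incidence_gwas=bundle.incidence,
            ld=bundle.ld,
            loci={l.protein_id: l for l in bundle.loci},
        )

    @classmethod
    def from_dir(cls, path) -> "PipelineInputs":
        """Load a bundle directory written by ``simulate.write_bundle``."""
        p = Path(path)
        subjects = pd.read_csv(p / "cohort_subjects.tsv", sep="\t")
        proteins = pd.read_csv(p / "cohort_proteins.tsv", sep="\t", index_col="protein_id")
        covs = [c for c in ("maggic", "log_ntprobnp") if c in subjects.columns]
        cohort = CohortTable(subjects=subjects, proteins=proteins, covariate_cols=covs)
        pqtl_all = read_summary_stats(p / "pqtl.tsv")
        by_protein: dict[str, list[AssociationRecord]] = {}
        for r in pqtl_all:
            pid = r.trait_id.split(":", 1)[-1]
            by_protein.setdefault(pid, []).append(r)
        outcome = {}
        for name in ("death", "dhfa"):
            f = p / f"outcome_{name}.tsv"
            if f.exists():
                outcome[name] = read_summary_stats(f, trait_id=f"outcome:{name}")
        incidence = read_summary_stats(p / "incidence.tsv", trait_id="incidence:hf")
        ld = read_ld_matrix(p / "ld.tsv")
        loci = {l.protein_id: l for l in read_gene_loci(p / "loci.tsv")}
        return cls(cohort, {"pqtl": by_protein}, outcome, incidence, ld, loci)


@dataclass
class PipelineResult:
    config: PipelineConfig
    alpha: object
    screen_results: dict[str, list]  # outcome -> ScreenResult list
    slope_fits: dict[str, SlopeFit]
    adjusted_outcomes: dict[str, list[AssociationRecord]]
    instruments: pd.DataFrame
    mr_results: pd.DataFrame
    coloc_results: pd.DataFrame
    verdicts: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _clump_incidence(records, ld, r2):
    usable = [r for r in records if r.variant_id in set(ld.variant_ids)]
    return clump(usable, ld, r2)


def run_pipeline(inputs: PipelineInputs, config: PipelineConfig) -> PipelineResult:
    manifest: dict = {
        "package_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "counts": {},
    }
    counts = manifest["counts"]

    # ---- stage 1: proteome-wide survival screen
    z, excluded = standardize_proteins(inputs.cohort.proteins)
    alpha = effective_tests(z, config.variance_threshold)
    counts["proteins_in"] = int(inputs.cohort.proteins.shape[0])
    counts["proteins_excluded"] = len(excluded)
    counts["n_effective_tests"] = alpha.n_effective
    screen_results: dict[str, list] = {}
    significant: dict[str, list[str]] = {}
    for outcome in config.outcomes:
        res = screen(inputs.cohort, outcome, config.screen_model, z_proteins=z)
        screen_results[outcome] = res
        significant[outcome] = [r.protein_id for r in res if r.pvalue < alpha.alpha_corrected]
        counts[f"screen_significant_{outcome}"] = len(significant[outcome])

    # ---- stage 2: collider-bias adjustment of the outcome GWAS
    slope_fits: dict[str, SlopeFit] = {}
    adjusted: dict[str, list[AssociationRecord]] = {}
    for outcome in config.outcomes:
        out_recs = inputs.outcome_gwas[outcome]
        if not config.apply_collider_adjustment:
            adjusted[outcome] = out_recs
            continue
        inc_clumped = _clump_incidence(inputs.incidence_gwas, inputs.ld, config.r2_threshold)
        pairs = pairs_from_records(inc_clumped, out_recs)
        try:
            fit = classify_and_fit(
                pairs,
                incidence_p_threshold=config.incidence_p_threshold,
                seed=config.seed,
            )
        except InsufficientInstrumentsError as exc:
            logger.warning("%s: collider fit skipped (%s); outcome left unadjusted", outcome, exc)
            adjusted[outcome] = out_recs
            continue
        slope_fits[outcome] = fit
        adjusted[outcome], _ = adjust_outcome_stats(out_recs, inputs.incidence_gwas, fit)
        counts[f"collider_slope_{outcome}"] = fit.slope_b

    # ---- stage 3: instruments + MR for screen-significant proteins
    inst_rows = []
    mr_all = []
    inst_sets: dict[tuple[str, str, str], object] = {}
    for outcome in config.outcomes:
        for source, per_protein in inputs.pqtl.items():
            n_with_inst = 0
            for pid in significant[outcome]:
                if pid not in per_protein or pid not in inputs.loci:
                    continue
                try:
                    inst = build_instrument_set(
                        pid,
                        per_protein[pid],
                        adjusted[outcome],
                        inputs.ld,
                        inputs.loci[pid],
                        window_bp=config.window_bp,
                        p_threshold=config.p_threshold,
                        scope=config.instrument_scope,
                        r2_threshold=config.r2_threshold,
                        palindromic_eaf_band=config.palindromic_band,
                    )
                except (DataError, NumericalError) as exc:
                    logger.warning("protein %s (%s/%s) quarantined: %s", pid, outcome, source, exc)
                    continue
                if inst is None:
                    continue
                n_with_inst += 1
                inst_sets[(outcome, source, pid)] = inst
                rep = instrument_report(inst)
                rep.insert(0, "outcome", outcome)
                rep.insert(0, "source", source)
                inst_rows.append(rep)
                try:
                    mr_all.extend(
                        run_all_methods(inst, outcome, source, n_boot=config.n_boot, seed=config.seed)
                    )
                except (NumericalError, DataError) as exc:
                    logger.warning("MR failed for %s (%s/%s): %s", pid, outcome, source, exc)
            counts[f"instrumented_{outcome}_{source}"] = n_with_inst
    instruments_df = (
        pd.concat(inst_rows, ignore_index=True)
        if inst_rows
        else pd.DataFrame(columns=["source", "outcome", "protein_id", "variant_id", "cis_trans", "bx", "sx", "by", "sy", "F"])
    )
    mr_df = mr_table(mr_all)
    if mr_df.empty:
        mr_df = pd.DataFrame(
            columns=["protein_id", "outcome", "method", "theta", "se_theta", "or_", "ci_low",
                     "ci_high", "pvalue", "n_instruments", "egger_intercept",
                     "egger_intercept_p", "cochran_q", "cochran_q_df", "source"]
        )

    # ---- stage 4: colocalization for MR-significant proteins
    mr_sig: dict[str, set[str]] = {o: set() for o in config.outcomes}
    if not mr_df.empty:
        ivw = mr_df[(mr_df["method"] == "ivw") & (mr_df["pvalue"] < config.mr_alpha)]
        for _, row in ivw.iterrows():
            mr_sig[row["outcome"]].add(row["protein_id"])
    coloc_rows = []
    for outcome in config.outcomes:
        for source, per_protein in inputs.pqtl.items():
            for pid in sorted(mr_sig[outcome]):
                if pid not in per_protein or pid not in inputs.loci:
                    continue
                pack = _coloc_region(
                    per_protein[pid], adjusted[outcome], inputs.loci[pid], config
                )
                if pack is None:
                    continue
                res, inp = pack
                row = coloc_report_row(pid, outcome, res)
                row["source"] = source
                # sensitivity of the call to the least-constrained prior
                grid = sorted(p for p in config.coloc_p12_grid if p <= min(config.coloc_p1, config.coloc_p2))
                if grid:
                    sens = prior_sensitivity(inp, grid)
                    row["prior_sensitive"] = bool(sens["prior_sensitive"].iloc[0])
                else:
                    row["prior_sensitive"] = False
                coloc_rows.append(row)
        counts[f"mr_significant_{outcome}"] = len(mr_sig[outcome])
    coloc_df = pd.DataFrame(coloc_rows) if coloc_rows else pd.DataFrame(
        columns=["protein_id", "outcome", "n_snps", "pp_h0", "pp_h1", "pp_h2", "pp_h3",
                 "pp_h4", "conditional_pp", "p1", "p2", "p12", "colocalized", "source",
                 "prior_sensitive"]
    )

    verdicts = _verdicts(config, alpha, screen_results, significant, mr_df, mr_sig, coloc_df)
    for outcome in config.outcomes:
        counts[f"top_tier_{outcome}"] = int(
            (verdicts[(verdicts["outcome"] == outcome)]["tier"] == "MR+coloc-supported").sum()
        )
    return PipelineResult(
        config=config,
        alpha=alpha,
        screen_results=screen_results,
        slope_fits=slope_fits,
        adjusted_outcomes=adjusted,
        instruments=instruments_df,
        mr_results=mr_df,
        coloc_results=coloc_df,
        verdicts=verdicts,
        manifest=manifest,
    )


def _coloc_region(exposure, outcome_records, locus, config: PipelineConfig):
    """Coloc over all cis-window variants shared by both traits."""
    region = [r for r in exposure if is_cis(r, locus, config.window_bp)]
    if len(region) < 2:
        return None
    try:
        pairs = [p for p in harmonize(region, outcome_records, config.palindromic_band) if p.kept]
    except DataError:
        return None
    if len(pairs) < 2:
        return None
    inp = ColocInput(
        variant_ids=[p.variant_id for p in pairs],
        beta1=np.array([p.bx for p in pairs]),
        se1=np.array([p.sx for p in pairs]),
        beta2=np.array([p.by for p in pairs]),
        se2=np.array([p.sy for p in pairs]),
        p1=config.coloc_p1,
        p2=config.coloc_p2,
        p12=config.coloc_p12,
    )
    return coloc_pp(inp), inp


def _verdicts(config, alpha, screen_results, significant, mr_df, mr_sig, coloc_df) -> pd.DataFrame:
    rows = []
    for outcome, res in screen_results.items():
        coloc_by_pid: dict[str, float] = {}
        if not coloc_df.empty:
            sub = coloc_df[coloc_df["outcome"] == outcome]
            for pid, grp in sub.groupby("protein_id"):
                coloc_by_pid[pid] = float(grp["conditional_pp"].max())
        n_sources_sig: dict[str, int] = {}
        if not mr_df.empty:
            ivw = mr_df[(mr_df["outcome"] == outcome) & (mr_df["method"] == "ivw") & (mr_df["pvalue"] < config.mr_alpha)]
            n_sources_sig = ivw.groupby("protein_id")["source"].nunique().to_dict()
        for r in res:
            pid = r.protein_id
            screen_sig = pid in significant[outcome]
            mr_supported = screen_sig and pid in mr_sig[outcome]
            cpp = coloc_by_pid.get(pid, np.nan)
            coloc_supported = mr_supported and np.isfinite(cpp) and cpp > config.coloc_conditional_rule
            tier = (
                "MR+coloc-supported"
                if coloc_supported
                else "MR-supported"
                if mr_supported
                else "observational-only"
                if screen_sig
                else "none"
            )
            rows.append(
                {
                    "protein_id": pid,
                    "outcome": outcome,
                    "screen_significant": screen_sig,
                    "screen_p": r.pvalue,
                    "mr_significant": mr_supported,
                    "mr_replicated": n_sources_sig.get(pid, 0) >= 2,
                    "coloc_conditional_pp": cpp,
                    "tier": tier,
                }
            )
    return pd.DataFrame(rows)


def make_reports(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Volcano, forest and verdict tables (plot-ready, no rendering)."""
    volcano = pd.concat(
        [
            volcano_table(res, result.alpha.alpha_corrected)
            for res in result.screen_results.values()
        ],
        ignore_index=True,
    ) if result.screen_results else pd.DataFrame()
    forest = result.mr_results[
        ["protein_id", "outcome", "source", "method", "theta", "se_theta", "or_", "ci_low", "ci_high", "pvalue", "n_instruments"]
    ].copy() if not result.mr_results.empty else pd.DataFrame()
    return {"volcano": volcano, "forest": forest, "verdicts": result.verdicts.copy()}


def write_outputs(result: PipelineResult, outdir, force: bool = False) -> None:
    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ProteoMRError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    for outcome, res in result.screen_results.items():
        screen_table(res).to_csv(out / f"screen_{outcome}.tsv", sep="\t", index=False)
    result.instruments.to_csv(out / "instruments.tsv", sep="\t", index=False)
    result.mr_results.to_csv(out / "mr_results.tsv", sep="\t", index=False)
    result.coloc_results.to_csv(out / "coloc_results.tsv", sep="\t", index=False)
    result.verdicts.to_csv(out / "verdicts.tsv", sep="\t", index=False)
    slope = {
        o: {"slope_b": f.slope_b, "se_slope": f.se_slope, "mixing_proportion": f.mixing_proportion,
            "n_variants_used": f.n_variants_used}
        for o, f in result.slope_fits.items()
    }
    (out / "collider_fit.json").write_text(json.dumps(slope, indent=1, sort_keys=True))
    manifest = dict(result.manifest)
    manifest["alpha"] = dataclasses.asdict(result.alpha)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    for name, df in make_reports(result).items():
        df.to_csv(out / f"report_{name}.tsv", sep="\t", index=False)
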