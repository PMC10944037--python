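"""cis/trans pQTL instrument selection, LD clumping and strength checks.

A variant is *cis* for a protein when it lies on the gene's chromosome
within a window (default +/-500 kb) of the gene body, *trans* otherwise.
Candidates must pass genome-wide significance (default p < 5e-8, strict);
trans candidates inside the extended MHC (chr6:25-34 Mb) are excluded, as
its extreme LD and pleiotropy make trans signals there unreliable.
Clumping is a light greedy pre-filter (default r^2 < 0.1): correlated
instruments are retained deliberately and the residual correlation is
modelled downstream in the IVW generalised least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .sumstats import AssociationRecord, GeneLocus, HarmonizedPair, LDMatrix, harmonize

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 500_000
DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_THRESHOLD = 0.1
WEAK_F_THRESHOLD = 10.0

MHC_CHROM = "6"
MHC_START = 25_000_000
MHC_END = 34_000_000


def _norm_chrom(c: str) -> str:
    return str(c).removeprefix("chr")


@dataclass
class InstrumentSet:
    """Harmonized instruments for one protein with their LD structure."""

    protein_id: str
    variants: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    R: LDMatrix
    cis_flags: list[str]
    mean_F: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.variants)
        for name in ("bx", "sx", "by", "sy"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != (n,):
                raise ConfigurationError(f"{name} length mismatch in InstrumentSet")
        if n < 1:
            raise ConfigurationError("InstrumentSet needs >= 1 variant")
        if self.R.R.shape != (n, n):
            raise ConfigurationError("LD matrix shape mismatch in InstrumentSet")
        if len(self.cis_flags) != n:
            raise ConfigurationError("cis_flags length mismatch")
        self.mean_F = float(np.mean((self.bx / self.sx) ** 2))

    @property
    def n_instruments(self) -> int:
        return len(self.variants)

    @property
    def weak(self) -> bool:
        """Mean F at or below 10: conventionally inadequate instruments."""
        return self.mean_F <= WEAK_F_THRESHOLD


def is_cis(record: AssociationRecord, locus: GeneLocus, window_bp: int) -> bool:
    return (
        _norm_chrom(record.chrom) == _norm_chrom(locus.chrom)
        and locus.start - window_bp <= record.pos <= locus.end + window_bp
    )


def in_mhc(record: AssociationRecord) -> bool:
    return (
        _norm_chrom(record.chrom) == MHC_CHROM
        and MHC_START <= record.pos <= MHC_END
    )


def select_candidates(
    pqtls: list[AssociationRecord],
    locus: GeneLocus,
    window_bp: int = DEFAULT_WINDOW_BP,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    scope: str = "cis",
) -> list[AssociationRecord]:
    """Filter pQTLs to significant cis and/or trans candidates.

    Significance is strict (p < threshold); a variant at exactly the
    threshold is excluded. An empty result means "no instruments for this
    protein" and is not an error.
    """
    if scope not in ("cis", "trans", "both"):
        raise ConfigurationError("scope must be cis, trans or both")
    out = []
    for r in pqtls:
        if not (r.pvalue < p_threshold):
            continue
        cis = is_cis(r, locus, window_bp)
        if cis and scope in ("cis", "both"):
            out.append(r)
        elif not cis and scope in ("trans", "both"):
            if in_mhc(r):
                continue
            out.append(r)
    if not out:
        logger.info("protein %s: no instruments (scope=%s)", locus.protein_id, scope)
    return out


def clump(
    candidates: list[AssociationRecord],
    ld: LDMatrix,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> list[AssociationRecord]:
    """Greedy p-value clumping: keep a variant iff r^2 < threshold with all
    already-kept variants. Deterministic (p then variant_id tie-break) and
    invariant to input row order."""
    if not candidates:
        return []
    order = sorted(candidates, key=lambda r: (r.pvalue, r.variant_id))
    sub = ld.submatrix([r.variant_id for r in order])
    R = sub.R
    kept_idx: list[int] = []
    for i in range(len(order)):
        if all(R[i, j] ** 2 < r2_threshold for j in kept_idx):
            kept_idx.append(i)
    return [order[i] for i in kept_idx]


def build_instrument_set(
    protein_id: str,
    exposure: list[AssociationRecord],
    outcome: list[AssociationRecord],
    ld: LDMatrix,
    locus: GeneLocus,
    window_bp: int = DEFAULT_WINDOW_BP,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    scope: str = "cis",
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    palindromic_eaf_band: float = 0.08,
) -> InstrumentSet | None:
    """Select, clump and harmonize instruments for one protein.

    Returns ``None`` when no instrument survives (protein analysed only if
    pQTLs are available). The LD submatrix is taken over the surviving
    variants; exposure effect alleles are the reference orientation, so the
    sign convention of ``ld`` (built on exposure effect-allele dosages) is
    preserved under harmonization, which flips only outcome betas.
    """
    cand = select_candidates(exposure, locus, window_bp, p_threshold, scope)
    cand = [c for c in cand if c.variant_id in set(ld.variant_ids) and c.variant_id not in set(ld.flagged)]
    cand = clump(cand, ld, r2_threshold)
    if not cand:
        return None
    pairs = {p.variant_id: p for p in _safe_harmonize(cand, outcome, palindromic_eaf_band)}
    kept: list[tuple[AssociationRecord, HarmonizedPair]] = [
        (c, pairs[c.variant_id])
        for c in cand
        if c.variant_id in pairs and pairs[c.variant_id].kept
    ]
    if not kept:
        return None
    ids = [c.variant_id for c, _ in kept]
    inst = InstrumentSet(
        protein_id=protein_id,
        variants=ids,
        bx=np.array([p.bx for _, p in kept]),
        sx=np.array([p.sx for _, p in kept]),
        by=np.array([p.by for _, p in kept]),
        sy=np.array([p.sy for _, p in kept]),
        R=ld.submatrix(ids),
        cis_flags=["cis" if is_cis(c, locus, window_bp) else "trans" for c, _ in kept],
    )
    if inst.weak:
        logger.warning("protein %s: weak instruments (mean F = %.2f)", protein_id, inst.mean_F)
    return inst


def _safe_harmonize(exposure, outcome, band):
    try:
        return harmonize(exposure, outcome, band)
    except Exception:
        return []


def instrument_report(inst: InstrumentSet) -> pd.DataFrame:
    """Per-variant instrument table (TSV-ready)."""
    return pd.DataFrame(
        {
            "protein_id": inst.protein_id,
            "variant_id": inst.variants,
            "cis_trans": inst.cis_flags,
            "bx": inst.bx,
            "sx": inst.sx,
            "by": inst.by,
            "sy": inst.sy,
            "F": (inst.bx / inst.sx) ** 2,
        }
    )
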