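"""GWAS / pQTL summary-statistic I/O, harmonization and LD matrices.

Conventions used throughout the package:

* positions are 1-based inclusive (GWAS summary-statistic convention);
  BED-like locus tables are converted on read;
* every association record carries an explicit effect allele, and betas are
  interpreted per copy of that allele;
* LD correlations are signed with respect to each variant's effect allele,
  so flipping a variant's allele flips the corresponding row and column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EmptyInputError, EmptyOverlapError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default palindromic-EAF exclusion band: drop A/T and C/G variants whose
#: allele frequency falls in [0.5 - band, 0.5 + band], where strand cannot
#: be resolved from frequency.
DEFAULT_PALINDROMIC_BAND = 0.08

# canonical field -> canonical column name
_CANONICAL_COLUMNS = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}
_MANDATORY_FIELDS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "n",
)


@dataclass(slots=True)
class AssociationRecord:
    """One variant's summary statistics for one trait.

    ``beta`` is the per-effect-allele effect in trait units (quantitative
    traits) or log-odds (case-control traits); ``eaf`` is the effect-allele
    frequency, ``nan`` when unknown.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    trait_id: str = ""


@dataclass(slots=True)
class GeneLocus:
    """A protein-coding gene's genomic footprint (1-based inclusive)."""

    gene: str
    chrom: str
    start: int
    end: int
    protein_id: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ConfigurationError(f"locus {self.gene}: empty chromosome")
        if self.start > self.end:
            raise ConfigurationError(
                f"locus {self.gene}: start {self.start} > end {self.end}"
            )
        if not self.protein_id:
            self.protein_id = self.gene


@dataclass(slots=True)
class HarmonizedPair:
    """Exposure/outcome effects for one variant on a common effect allele."""

    variant_id: str
    bx: float
    sx: float
    by: float
    sy: float
    eaf_x: float
    eaf_y: float
    action: str  # kept | flipped | dropped_palindromic | dropped_mismatch
    reason: str = ""

    @property
    def kept(self) -> bool:
        return self.action in ("kept", "flipped")


@dataclass
class LDMatrix:
    """Signed pairwise LD correlations over an ordered variant list."""

    variant_ids: list[str]
    R: np.ndarray
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (len(self.variant_ids), len(self.variant_ids)):
            raise ConfigurationError("LD matrix shape does not match variant list")

    def validate(self, psd_tol: float = 1e-8) -> None:
        R = self.R
        if not np.allclose(R, R.T, atol=1e-9):
            raise ConfigurationError("LD matrix is not symmetric")
        if np.max(np.abs(np.diag(R) - 1.0)) >= 1e-9:
            raise ConfigurationError("LD matrix diagonal is not 1")
        if np.max(np.abs(R)) > 1.0 + 1e-9:
            raise ConfigurationError("LD matrix has |r| > 1")
        if np.linalg.eigvalsh(R).min() < -psd_tol:
            raise ConfigurationError("LD matrix is not PSD after repair")

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            return np.array([lookup[v] for v in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ConfigurationError(f"variant {exc} absent from LD matrix") from exc

    def submatrix(self, ids: Sequence[str]) -> "LDMatrix":
        idx = self.index_of(ids)
        return LDMatrix(list(ids), self.R[np.ix_(idx, idx)].copy())

    def flip_signs(self, flip: Sequence[bool]) -> "LDMatrix":
        """Return a copy with rows/columns of flipped variants sign-reversed."""
        s = np.where(np.asarray(flip, dtype=bool), -1.0, 1.0)
        return LDMatrix(list(self.variant_ids), self.R * np.outer(s, s), list(self.flagged))


def ridge_repair(R: np.ndarray) -> np.ndarray:
    """Project a correlation matrix to PSD while keeping a unit diagonal.

    When the smallest eigenvalue is negative, (R + eps*I)/(1 + eps) with
    eps = |lambda_min| + 1e-8 shrinks off-diagonals just enough; eigenvalues
    become (lambda + eps)/(1 + eps) >= 1e-8/(1 + eps) > 0.
    """
    R = np.asarray(R, dtype=float)
    lam_min = float(np.linalg.eigvalsh(R).min())
    if lam_min >= -1e-12:  # PSD already (exactly singular is fine)
        return R
    eps = abs(lam_min) + 1e-8
    out = (R + eps * np.eye(R.shape[0])) / (1.0 + eps)
    np.fill_diagonal(out, 1.0)
    return out


def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "",
    audit: list | None = None,
) -> list[AssociationRecord]:
    """Read and validate a delimited summary-statistic file.

    ``column_map`` maps canonical field names (``beta``, ``se``, ...) to the
    file's column names; unmapped fields use the canonical names. Invalid
    rows are dropped with a reason (appended to ``audit`` as
    ``(variant_id_or_row, reason)`` when given) and counted in the log.
    """
    colmap = dict(_CANONICAL_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(_CANONICAL_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown column-map fields: {sorted(unknown)}")
        colmap.update(column_map)

    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    missing = [colmap[f] for f in _MANDATORY_FIELDS if colmap[f] not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory columns {missing}")
    has_eaf = colmap["eaf"] in df.columns
    # a trait_id column in the file wins unless the caller overrides it
    trait_col = df["trait_id"].fillna("").astype(str) if "trait_id" in df.columns and not trait_id else None

    records: list[AssociationRecord] = []
    n_rejected = 0
    n_warned = 0
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))

        def _reject(reason: str, vid: str) -> None:
            nonlocal n_rejected
            n_rejected += 1
            if audit is not None:
                audit.append((vid or f"row{i}", reason))

        vid = str(row[colmap["variant_id"]])
        try:
            beta = float(row[colmap["beta"]])
        except (TypeError, ValueError):
            beta = math.nan
        if math.isnan(beta):
            _reject("missing_beta", vid)
            continue
        try:
            se = float(row[colmap["se"]])
        except (TypeError, ValueError):
            se = math.nan
        if not se > 0:
            _reject("nonpositive_se", vid)
            continue
        ea = str(row[colmap["effect_allele"]]).upper()
        oa = str(row[colmap["other_allele"]]).upper()
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            _reject("not_snp", vid)
            continue
        if ea == oa:
            _reject("identical_alleles", vid)
            continue
        try:
            pval = float(row[colmap["pvalue"]])
        except (TypeError, ValueError):
            pval = math.nan
        if not (0.0 < pval <= 1.0):
            _reject("bad_pvalue", vid)
            continue
        eaf = math.nan
        if has_eaf:
            try:
                eaf = float(row[colmap["eaf"]])
            except (TypeError, ValueError):
                eaf = math.nan
            if not (0.0 < eaf < 1.0):
                eaf = math.nan
        # normal-approximation consistency: warn only
        p_norm = 2.0 * stats.norm.sf(abs(beta / se))
        if p_norm > 0 and abs(math.log10(pval) - math.log10(p_norm)) > 2.0:
            n_warned += 1
        records.append(
            AssociationRecord(
                variant_id=vid,
                chrom=str(row[colmap["chrom"]]),
                pos=int(float(row[colmap["pos"]])),
                effect_allele=ea,
                other_allele=oa,
                eaf=eaf,
                beta=beta,
                se=se,
                pvalue=pval,
                n=int(float(row[colmap["n"]])),
                trait_id=str(trait_col.iloc[i]) if trait_col is not None else trait_id,
            )
        )
    if n_rejected:
        logger.info("%s: rejected %d invalid rows", path, n_rejected)
    if n_warned:
        logger.warning(
            "%s: %d rows with p-value inconsistent with beta/se by >2 orders of magnitude",
            path,
            n_warned,
        )
    if not records:
        raise EmptyInputError(f"{path}: zero valid rows")
    return records


def write_summary_stats(records: Iterable[AssociationRecord], path) -> None:
    """Write records tab-delimited; floats via repr so a re-read round-trips."""
    cols = list(_CANONICAL_COLUMNS) + ["trait_id"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.variant_id,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        repr(float(r.eaf)),
                        repr(float(r.beta)),
                        repr(float(r.se)),
                        repr(float(r.pvalue)),
                        str(r.n),
                        r.trait_id,
                    ]
                )
                + "\n"
            )


def read_gene_loci(path, one_based: bool = False) -> list[GeneLocus]:
    """Read a BED-like locus table (gene, chrom, start, end[, protein_id]).

    BED convention (0-based half-open) is assumed unless ``one_based``;
    coordinates are stored 1-based inclusive.
    """
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    need = {"gene", "chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise ConfigurationError(f"{path}: locus table needs columns {sorted(need)}")
    loci = []
    for row in df.itertuples(index=False):
        start = int(row.start) + (0 if one_based else 1)
        loci.append(
            GeneLocus(
                gene=str(row.gene),
                chrom=str(row.chrom),
                start=start,
                end=int(row.end),
                protein_id=str(getattr(row, "protein_id", "") or ""),
            )
        )
    if not loci:
        raise EmptyInputError(f"{path}: zero loci")
    return loci


def is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def _strand_flip(ea: str, oa: str) -> tuple[str, str]:
    return COMPLEMENT[ea], COMPLEMENT[oa]


def harmonize(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    palindromic_eaf_band: float = DEFAULT_PALINDROMIC_BAND,
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure's effect alleles.

    Rules, applied per shared variant:

    1. allele labels match -> kept; swapped -> outcome beta sign-flipped
       (and EAF complemented);
    2. otherwise a strand flip (A<->T, C<->G) of the outcome alleles is
       attempted before declaring a mismatch;
    3. palindromic variants (A/T, C/G) are retained only when both EAFs lie
       on the same side of 0.5 and outside ``0.5 +/- band`` — frequency is
       the only strand signal there;
    4. every drop carries a reason.

    Dropped variants are returned with their action set; use ``p.kept`` to
    filter. Raises :class:`EmptyOverlapError` when no variants are shared.
    """
    out_by_id = {r.variant_id: r for r in outcome}
    pairs: list[HarmonizedPair] = []
    overlap = 0
    for x in exposure:
        y = out_by_id.get(x.variant_id)
        if y is None:
            continue
        overlap += 1
        pairs.append(_harmonize_one(x, y, palindromic_eaf_band))
    if overlap == 0:
        raise EmptyOverlapError("no overlapping variants between exposure and outcome")
    return pairs


def _harmonize_one(
    x: AssociationRecord, y: AssociationRecord, band: float
) -> HarmonizedPair:
    def pair(by: float, eaf_y: float, action: str, reason: str = "") -> HarmonizedPair:
        return HarmonizedPair(
            variant_id=x.variant_id,
            bx=x.beta,
            sx=x.se,
            by=by,
            sy=y.se,
            eaf_x=x.eaf,
            eaf_y=eaf_y,
            action=action,
            reason=reason,
        )

    if is_palindromic(x.effect_allele, x.other_allele):
        # labels alone cannot resolve strand; orient by label then check EAF
        if {y.effect_allele, y.other_allele} != {x.effect_allele, x.other_allele}:
            return pair(math.nan, math.nan, "dropped_mismatch", "allele_set_mismatch")
        if y.effect_allele == x.effect_allele:
            by, eaf_y = y.beta, y.eaf
        else:
            by, eaf_y = -y.beta, 1.0 - y.eaf if not math.isnan(y.eaf) else math.nan
        if math.isnan(x.eaf) or math.isnan(eaf_y):
            return pair(math.nan, math.nan, "dropped_palindromic", "missing_eaf")
        lo, hi = 0.5 - band, 0.5 + band
        if lo <= x.eaf <= hi or lo <= eaf_y <= hi:
            return pair(math.nan, math.nan, "dropped_palindromic", "eaf_near_half")
        if (x.eaf < 0.5) != (eaf_y < 0.5):
            return pair(math.nan, math.nan, "dropped_palindromic", "eaf_side_mismatch")
        action = "kept" if y.effect_allele == x.effect_allele else "flipped"
        return pair(by, eaf_y, action)

    for flip_strand in (False, True):
        if flip_strand:
            ea, oa = _strand_flip(y.effect_allele, y.other_allele)
        else:
            ea, oa = y.effect_allele, y.other_allele
        if ea == x.effect_allele and oa == x.other_allele:
            return pair(y.beta, y.eaf, "kept")
        if ea == x.other_allele and oa == x.effect_allele:
            eaf_y = 1.0 - y.eaf if not math.isnan(y.eaf) else math.nan
            return pair(-y.beta, eaf_y, "flipped")
    return pair(math.nan, math.nan, "dropped_mismatch", "allele_mismatch")


def harmonization_audit(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """Audit table: variant, action, reason."""
    return pd.DataFrame(
        {
            "variant_id": [p.variant_id for p in pairs],
            "action": [p.action for p in pairs],
            "reason": [p.reason for p in pairs],
        }
    )


def ld_from_genotypes(G: np.ndarray, variant_ids: Sequence[str]) -> LDMatrix:
    """Pearson LD of dosage columns, ridge-repaired to PSD.

    Zero-variance columns get identity rows/cols and are listed in
    ``flagged`` for exclusion downstream.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] != len(variant_ids):
        raise ConfigurationError("dosage matrix shape does not match variant list")
    m = G.shape[1]
    if m == 1:
        flagged = [variant_ids[0]] if np.std(G[:, 0]) == 0 else []
        return LDMatrix(list(variant_ids), np.array([[1.0]]), flagged)
    sd = G.std(axis=0)
    zero = sd == 0
    flagged = [v for v, z in zip(variant_ids, zero) if z]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(G, rowvar=False)
    if zero.any():
        R[zero, :] = 0.0
        R[:, zero] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    R = ridge_repair(R)
    return LDMatrix(list(variant_ids), R, flagged)


def read_ld_matrix(path) -> LDMatrix:
    """Square matrix file: header row of variant ids, numeric body."""
    df = pd.read_csv(path, sep=_detect_sep(path))
    return LDMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.R, columns=ld.variant_ids).to_csv(path, sep="\t", index=False)


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Convenience view of a record list as a DataFrame (copies)."""
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pvalue": [r.pvalue for r in records],
            "n": [r.n for r in records],
            "trait_id": [r.trait_id for r in records],
        }
    )


def with_updated(record: AssociationRecord, **kwargs) -> AssociationRecord:
    return replace(record, **kwargs)
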