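"""Summary-statistic I/O, harmonization and LD-matrix behaviour."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from proteomr.errors import ConfigurationError, EmptyInputError, EmptyOverlapError
from proteomr.sumstats import (
    harmonize,
    harmonization_audit,
    ld_from_genotypes,
    read_gene_loci,
    read_summary_stats,
    write_summary_stats,
)

from conftest import make_record

HEADER = "variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"


def _write(tmp_path, body, header=HEADER, name="ss.tsv"):
    p = tmp_path / name
    p.write_text(header + body)
    return p


class TestRead:
    def test_well_formed_file_reads_all_rows(self, tmp_path):
        p = _write(
            tmp_path,
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-6\t5000\n"
            "rs2\t1\t200\tC\tT\t0.4\t-0.05\t0.03\t0.09\t5000\n"
            "rs3\t2\t300\tG\tA\t0.2\t0.2\t0.04\t1e-7\t5000\n",
        )
        audit = []
        recs = read_summary_stats(p, trait_id="x", audit=audit)
        assert len(recs) == 3 and not audit
        assert recs[0].variant_id == "rs1" and recs[0].pos == 100
        assert recs[1].beta == -0.05 and recs[2].trait_id == "x"

    @pytest.mark.parametrize(
        "row, reason",
        [
            ("rs9\t1\t10\tA\tG\t0.3\t0.1\t0\t0.5\t100", "nonpositive_se"),
            ("rs9\t1\t10\tA\tG\t0.3\t\t0.1\t0.5\t100", "missing_beta"),
            ("rs9\t1\t10\tAT\tG\t0.3\t0.1\t0.1\t0.5\t100", "not_snp"),
            ("rs9\t1\t10\tA\tA\t0.3\t0.1\t0.1\t0.5\t100", "identical_alleles"),
            ("rs9\t1\t10\tA\tG\t0.3\t0.1\t0.1\t0\t100", "bad_pvalue"),
        ],
    )
    def test_invalid_rows_rejected_with_reason(self, tmp_path, row, reason):
        p = _write(tmp_path, "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-6\t5000\n" + row + "\n")
        audit = []
        recs = read_summary_stats(p, audit=audit)
        assert len(recs) == 1
        assert audit == [("rs9", reason)]

    def test_column_map_matches_canonical_parse(self, tmp_path):
        canon = _write(
            tmp_path, "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-6\t5000\n", name="a.tsv"
        )
        mapped = _write(
            tmp_path,
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-6\t5000\n",
            header=HEADER.replace("beta", "Effect").replace("se\t", "StdErr\t"),
            name="b.tsv",
        )
        a = read_summary_stats(canon)
        b = read_summary_stats(mapped, column_map={"beta": "Effect", "se": "StdErr"})
        assert a == b

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        p = _write(tmp_path, "rs1\t1\t100\tA\tG\t0.3\t0.1\n", header="variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\n")
        with pytest.raises(ConfigurationError):
            read_summary_stats(p)

    def test_zero_valid_rows_is_empty_input_error(self, tmp_path):
        p = _write(tmp_path, "rs1\t1\t100\tA\tG\t0.3\t0.1\t0\t0.5\t100\n")
        with pytest.raises(EmptyInputError):
            read_summary_stats(p)

    @settings(
        max_examples=25,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        beta=st.floats(-5, 5, allow_nan=False),
        se=st.floats(1e-6, 10, allow_nan=False),
        eaf=st.floats(0.01, 0.99),
        pos=st.integers(1, 2**31),
        n=st.integers(1, 10**7),
    )
    def test_write_read_round_trip(self, tmp_path, beta, se, eaf, pos, n):
        rec = make_record(beta=beta, se=se, eaf=eaf, pos=pos, n=n, pvalue=0.5)
        path = tmp_path / "rt.tsv"
        write_summary_stats([rec], path)
        back = read_summary_stats(path, trait_id="t")[0]
        assert back.variant_id == rec.variant_id and back.pos == rec.pos and back.n == rec.n
        for f in ("beta", "se", "eaf", "pvalue"):
            assert abs(getattr(back, f) - getattr(rec, f)) <= 1e-12 * max(1, abs(getattr(rec, f)))


class TestLoci:
    def test_bed_like_start_converted_to_one_based(self, tmp_path):
        p = tmp_path / "loci.tsv"
        p.write_text("gene\tchrom\tstart\tend\tprotein_id\nG1\t3\t999\t2000\tP1\n")
        (locus,) = read_gene_loci(p)
        assert locus.start == 1000 and locus.end == 2000 and locus.protein_id == "P1"

    def test_invalid_interval_rejected(self, tmp_path):
        p = tmp_path / "loci.tsv"
        p.write_text("gene\tchrom\tstart\tend\nG1\t3\t5000\t2000\n")
        with pytest.raises(ConfigurationError):
            read_gene_loci(p)


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        x = make_record(ea="A", oa="G", beta=0.2)
        y = make_record(ea="G", oa="A", beta=0.3, eaf=0.7)
        (pair,) = harmonize([x], [y])
        assert pair.action == "flipped"
        assert pair.by == -0.3
        assert pair.eaf_y == pytest.approx(0.3)

    def test_strand_flip_resolves_before_mismatch(self):
        x = make_record(ea="A", oa="G", beta=0.2)
        y = make_record(ea="T", oa="C", beta=0.3)  # A/G on the other strand
        (pair,) = harmonize([x], [y])
        assert pair.action == "kept" and pair.by == 0.3

    def test_palindromic_at_half_frequency_dropped(self):
        x = make_record(ea="A", oa="T", eaf=0.50)
        y = make_record(ea="A", oa="T", eaf=0.50)
        (pair,) = harmonize([x], [y])
        assert pair.action == "dropped_palindromic"

    def test_no_overlap_raises(self):
        with pytest.raises(EmptyOverlapError):
            harmonize([make_record(variant_id="a")], [make_record(variant_id="b")])

    def test_ten_variant_fixture_matches_hand_table(self):
        # (exp EA/OA/eaf, out EA/OA/eaf) -> expected action, by multiplier
        table = [
            (("A", "G", 0.3), ("A", "G", 0.3), "kept", 1),
            (("A", "G", 0.3), ("G", "A", 0.7), "flipped", -1),
            (("C", "T", 0.2), ("G", "A", 0.2), "kept", 1),      # strand flip
            (("C", "T", 0.2), ("A", "G", 0.8), "flipped", -1),  # strand + swap
            (("A", "T", 0.2), ("A", "T", 0.25), "kept", 1),     # palindromic, clear EAF
            (("A", "T", 0.2), ("T", "A", 0.75), "flipped", -1),
            (("C", "G", 0.5), ("C", "G", 0.5), "dropped_palindromic", 0),
            (("A", "T", 0.2), ("A", "T", 0.8), "dropped_palindromic", 0),  # side mismatch
            (("A", "G", 0.3), ("A", "C", 0.3), "dropped_mismatch", 0),
            (("A", "G", 0.3), ("T", "G", 0.3), "dropped_mismatch", 0),
        ]
        exposure, outcome = [], []
        for i, ((ea, oa, fx), (eb, ob, fy), _, _) in enumerate(table):
            exposure.append(make_record(variant_id=f"v{i}", ea=ea, oa=oa, eaf=fx, beta=0.1))
            outcome.append(make_record(variant_id=f"v{i}", ea=eb, oa=ob, eaf=fy, beta=0.2))
        pairs = harmonize(exposure, outcome)
        for pair, (_, _, action, mult) in zip(pairs, table):
            assert pair.action == action, pair.variant_id
            if mult:
                assert pair.by == pytest.approx(0.2 * mult)
        audit = harmonization_audit(pairs)
        assert set(audit.columns) == {"variant_id", "action", "reason"}
        assert (audit["action"] == "dropped_palindromic").sum() == 2

    def test_harmonization_is_idempotent(self):
        exposure = [
            make_record(variant_id="v0", ea="A", oa="G", beta=0.2),
            make_record(variant_id="v1", ea="C", oa="T", beta=-0.1, eaf=0.2),
            make_record(variant_id="v2", ea="A", oa="T", beta=0.3, eaf=0.2),
        ]
        outcome = [
            make_record(variant_id="v0", ea="G", oa="A", beta=0.5),
            make_record(variant_id="v1", ea="A", oa="G", beta=0.4, eaf=0.8),
            make_record(variant_id="v2", ea="T", oa="A", beta=0.1, eaf=0.75),
        ]
        first = [p for p in harmonize(exposure, outcome) if p.kept]
        # rebuild outcome records already aligned to exposure alleles
        realigned = [
            make_record(
                variant_id=p.variant_id,
                ea=e.effect_allele,
                oa=e.other_allele,
                beta=p.by,
                eaf=p.eaf_y,
            )
            for p, e in zip(first, exposure)
        ]
        second = [q for q in harmonize(exposure, realigned) if q.kept]
        assert [q.action for q in second] == ["kept"] * len(first)
        assert [q.by for q in second] == [p.by for p in first]


class TestLDFromGenotypes:
    def test_duplicated_columns_give_unit_correlation(self, rng):
        g = rng.binomial(2, 0.3, size=(200, 1)).astype(float)
        ld = ld_from_genotypes(np.hstack([g, g]), ["a", "b"])
        assert ld.R[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_columns_near_zero(self, rng):
        G = rng.binomial(2, 0.3, size=(10000, 6)).astype(float)
        ld = ld_from_genotypes(G, [f"v{i}" for i in range(6)])
        off = ld.R[~np.eye(6, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_single_variant_identity(self, rng):
        ld = ld_from_genotypes(rng.binomial(2, 0.4, size=(50, 1)).astype(float), ["v"])
        assert ld.R.shape == (1, 1) and ld.R[0, 0] == 1.0

    def test_zero_variance_column_flagged(self, rng):
        G = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
        G[:, 1] = 2.0
        ld = ld_from_genotypes(G, ["a", "b"])
        assert ld.flagged == ["b"]
        ld.validate()

    def test_invariants_hold_on_random_fixtures(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 80))
            m = int(rng.integers(1, 8))
            G = rng.binomial(2, rng.uniform(0.05, 0.5, m), size=(n, m)).astype(float)
            ld = ld_from_genotypes(G, [f"v{i}" for i in range(m)])
            ld.validate()

    def test_flip_signs_flips_rows_and_columns(self, rng):
        G = rng.binomial(2, 0.3, size=(500, 3)).astype(float)
        ld = ld_from_genotypes(G, ["a", "b", "c"])
        flipped = ld.flip_signs([True, False, False])
        assert flipped.R[0, 1] == pytest.approx(-ld.R[0, 1])
        assert flipped.R[1, 2] == pytest.approx(ld.R[1, 2])
        assert flipped.R[0, 0] == 1.0
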