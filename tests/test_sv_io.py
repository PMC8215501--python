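"""VCF ingestion: filtering rules, normalization conventions, round-trips."""

import pytest

from svtrr.sv_io import (FilterPolicy, PERMISSIVE_POLICY, SVRecord,
                         apply_policy, read_sv_vcf, write_sv_vcf)
from _helpers import mk


class TestFiltering:
    def test_size_boundary_and_bnd_exclusion(self, write_vcf):
        """50 bp is the inclusive size floor; BND records are dropped."""
        path = write_vcf([
            ("1", 100, ".", "N", "<DEL>", ".", "PASS", "SVTYPE=DEL;END=149"),   # 49 bp
            ("1", 500, ".", "N", "<DEL>", ".", "PASS", "SVTYPE=DEL;END=550"),   # 50 bp
            ("1", 900, ".", "N", "N[2:333[", ".", "PASS", "SVTYPE=BND"),
        ])
        records, stats = read_sv_vcf(path, FilterPolicy(), return_stats=True)
        assert [(r.svtype, r.svlen) for r in records] == [("DEL", 50)]
        assert stats["size"] == 1 and stats["type"] == 1 and stats["kept"] == 1

    def test_non_canonical_chromosome_excluded(self, write_vcf):
        path = write_vcf(
            [("GL000207.1", 100, ".", "N", "<INS>", ".", "PASS", "SVTYPE=INS;SVLEN=80")],
            extra_header="##contig=<ID=GL000207.1,length=100000>\n")
        records, stats = read_sv_vcf(path, FilterPolicy(), return_stats=True)
        assert records == [] and stats["chrom"] == 1

    def test_require_pass_keeps_only_pass(self, write_vcf):
        path = write_vcf([
            ("1", 100, ".", "N", "<INS>", ".", "PASS", "SVTYPE=INS;SVLEN=80"),
            ("1", 900, ".", "N", "<INS>", ".", "LongReadHomRef", "SVTYPE=INS;SVLEN=80"),
        ])
        records = read_sv_vcf(path, FilterPolicy(require_pass=True))
        assert len(records) == 1 and records[0].filter_status == "PASS"

    @pytest.mark.parametrize("sz,cov,kept", [(3, 20, False), (5, 20, True), (4, 20, True)])
    def test_pbhoney_spots_ratio(self, write_vcf, sz, cov, kept):
        """szCount/coverage < 0.2 is filtered; the boundary ratio 0.2 is kept."""
        path = write_vcf([
            ("1", 100, ".", "N", "<DEL>", ".", "PASS",
             f"SVTYPE=DEL;END=400;szCount={sz};coverage={cov}"),
        ])
        records = read_sv_vcf(path, FilterPolicy(), dialect="pbhoney")
        assert bool(records) is kept
        # the same tags are ignored under the generic dialect
        assert len(read_sv_vcf(path, FilterPolicy(), dialect="generic")) == 1

    def test_pbhoney_tags_in_format_field(self, write_vcf):
        """szCount/coverage are accepted from per-sample FORMAT fields too."""
        path = write_vcf([
            ("1", 100, ".", "N", "<DEL>", ".", "PASS", "SVTYPE=DEL;END=400",
             "GT:szCount:coverage", "0/1:3:20"),
        ], with_sample=True)
        assert read_sv_vcf(path, FilterPolicy(), dialect="pbhoney") == []

    def test_filtering_is_idempotent_and_conserves_counts(self, write_vcf):
        path = write_vcf([
            ("1", 100, ".", "N", "<DEL>", ".", "PASS", "SVTYPE=DEL;END=149"),
            ("1", 500, ".", "N", "<DEL>", ".", "PASS", "SVTYPE=DEL;END=550"),
            ("2", 700, ".", "N", "<INS>", ".", "PASS", "SVTYPE=INS;SVLEN=120"),
            ("1", 900, ".", "N", "N[2:333[", ".", "PASS", "SVTYPE=BND"),
            ("1", 950, ".", "N", "<DUP>", ".", "PASS", "SVTYPE=DUP;END=2000"),
        ])
        policy = FilterPolicy()
        records, stats = read_sv_vcf(path, policy, return_stats=True)
        assert apply_policy(records, policy) == records
        assert sum(stats.values()) == 5  # records_in = kept + excluded


class TestNormalization:
    def test_del_negative_svlen_without_end(self, write_vcf):
        path = write_vcf([("1", 100, ".", "N", "<DEL>", ".", "PASS",
                           "SVTYPE=DEL;SVLEN=-300")])
        (rec,) = read_sv_vcf(path, FilterPolicy())
        assert (rec.pos, rec.end, rec.svlen) == (100, 400, 300)

    def test_ins_end_equals_pos(self, write_vcf):
        path = write_vcf([("1", 500, ".", "N", "<INS>", ".", "PASS",
                           "SVTYPE=INS;SVLEN=120;END=500")])
        (rec,) = read_sv_vcf(path, FilterPolicy())
        assert (rec.pos, rec.end, rec.svlen) == (500, 500, 120)

    def test_chr_prefix_stripped(self, write_vcf):
        path = write_vcf([("chr3", 100, ".", "N", "<INS>", ".", "PASS",
                           "SVTYPE=INS;SVLEN=99")])
        (rec,) = read_sv_vcf(path, FilterPolicy())
        assert rec.chrom == "3"

    def test_allele_span_wins_over_discrepant_svlen(self, write_vcf):
        """For sequence-resolved deletions the allele span is the coordinate
        ground truth; a discrepant SVLEN tag is warned about and ignored."""
        path = write_vcf([("1", 100, ".", "G" + "C" * 69, "G", ".", "PASS",
                           "SVTYPE=DEL;SVLEN=-500")])
        with pytest.warns(UserWarning, match="disagrees"):
            (rec,) = read_sv_vcf(path, FilterPolicy())
        assert rec.svlen == 69 and rec.end == 169

    def test_symbolic_del_conflicts_resolved_by_parser(self, write_vcf):
        """For symbolic <DEL> records the VCF layer already reconciles
        END/SVLEN (current VCF semantics let SVLEN define the span)."""
        path = write_vcf([("1", 100, ".", "N", "<DEL>", ".", "PASS",
                           "SVTYPE=DEL;END=400;SVLEN=-500")])
        (rec,) = read_sv_vcf(path, FilterPolicy())
        assert rec.end - rec.pos == rec.svlen == 500

    def test_sequence_resolved_alleles(self, write_vcf):
        path = write_vcf([
            ("1", 100, ".", "A", "A" + "T" * 60, ".", "PASS", "."),
            ("1", 900, ".", "G" + "C" * 70, "G", ".", "PASS", "."),
        ])
        ins, dele = read_sv_vcf(path, FilterPolicy())
        assert (ins.svtype, ins.svlen, ins.end) == ("INS", 60, 100)
        assert (dele.svtype, dele.svlen, dele.end) == ("DEL", 70, 970)

    def test_multiallelic_split_per_alt(self, write_vcf):
        path = write_vcf([
            ("1", 100, ".", "A", "A" + "T" * 60 + "," + "A" + "G" * 80,
             ".", "PASS", "."),
        ])
        records = read_sv_vcf(path, FilterPolicy())
        assert [r.svlen for r in records] == [60, 80]

    def test_unparseable_vcf_is_hard_error(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("this is not a vcf\n")
        with pytest.raises(ValueError, match="unparseable"):
            read_sv_vcf(bad, FilterPolicy())


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        records = [
            mk("INS", pos=1000, svlen=77, extras={"id": "a1"}),
            mk("DEL", chrom="2", pos=5000, end=5400, precise=False,
               extras={"id": "a2", "szCount": 8, "coverage": 20}),
            mk("INS", chrom="X", pos=9000, svlen=51,
               filter_status="LongReadHomRef"),
        ]
        path = tmp_path / "rt.vcf"
        write_sv_vcf(records, path)
        back = read_sv_vcf(path, PERMISSIVE_POLICY)
        assert [(r.chrom, r.pos, r.end, r.svtype, r.svlen, r.filter_status,
                 r.precise) for r in back] == \
               [(r.chrom, r.pos, r.end, r.svtype, r.svlen, r.filter_status,
                 r.precise) for r in records]
        assert back[1].extras["szCount"] == 8 and not back[1].precise

    def test_empty_list_gives_valid_header_only_vcf(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_sv_vcf([], path)
        assert read_sv_vcf(path, PERMISSIVE_POLICY) == []


def test_svrecord_invariants():
    with pytest.raises(ValueError):
        SVRecord("1", 100, 99, "DEL", 1)
    with pytest.raises(ValueError):
        SVRecord("1", 100, 200, "INS", 100)
    with pytest.raises(ValueError):
        SVRecord("1", 100, 100, "INS", 0)
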