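"""Region sets: rmsk/BED loading, breakpoint membership, partitioning."""

import numpy as np
import pytest

from svtrr.regions import (Region, RegionSet, breakpoints_in_regions, load_bed,
                           load_rmsk_trr, partition_by_trr, restrict_to_regions,
                           write_bed)
from _helpers import mk

RMSK_ROW = "{bin}\t500\t10\t10\t10\t{chrom}\t{start}\t{end}\t-100\t+\t(T)n\t{cls}\tfam\t1\t10\t0\t1"


def _rmsk_file(tmp_path, rows, name="rmsk.txt"):
    path = tmp_path / name
    path.write_text("".join(
        RMSK_ROW.format(bin=i, chrom=c, start=s, end=e, cls=cls) + "\n"
        for i, (c, s, e, cls) in enumerate(rows)))
    return path


class TestRmsk:
    def test_class_filter_keeps_tandem_repeats_only(self, tmp_path):
        path = _rmsk_file(tmp_path, [
            ("chr1", 100, 200, "Simple_repeat"),
            ("chr1", 300, 400, "Satellite"),
            ("chr1", 500, 600, "LINE"),
            ("chr1", 700, 800, "SINE"),
            ("chr1", 900, 1000, "LTR"),
        ])
        trr = load_rmsk_trr(path)
        assert len(trr) == 2
        assert {r.label for r in trr} == {"Simple_repeat", "Satellite"}

    def test_chr_prefix_stripped(self, tmp_path):
        path = _rmsk_file(tmp_path, [("chr7", 10, 50, "Satellite")])
        (region,) = load_rmsk_trr(path)
        assert region.chrom == "7"

    def test_overlapping_rows_retained_membership_matches_linear_scan(self, tmp_path):
        rows = [("chr1", 100, 300, "Simple_repeat"), ("chr1", 200, 400, "Simple_repeat")]
        trr = load_rmsk_trr(_rmsk_file(tmp_path, rows))
        assert len(trr) == 2
        for point in range(50, 450):
            linear = any(s <= point < e for _, s, e, _ in rows)
            assert trr.contains_point("1", point) is linear

    def test_zero_qualifying_rows_is_hard_error(self, tmp_path):
        path = _rmsk_file(tmp_path, [("chr1", 1, 2, "LINE")])
        with pytest.raises(ValueError, match="no rows"):
            load_rmsk_trr(path)

    def test_malformed_rows_skipped_with_warning(self, tmp_path):
        path = tmp_path / "rmsk.txt"
        good = RMSK_ROW.format(bin=0, chrom="chr1", start=10, end=90, cls="Satellite")
        bad = "0\t500\t10\t10\t10\tchr1\tnot_an_int\t90\t-1\t+\tx\tSatellite\tf\t1\t2\t0\t1"
        path.write_text(good + "\n" + bad + "\n")
        with pytest.warns(UserWarning, match="malformed"):
            trr = load_rmsk_trr(path)
        assert len(trr) == 1

    def test_gzip_transparent(self, tmp_path):
        import gzip
        path = tmp_path / "rmsk.txt.gz"
        row = RMSK_ROW.format(bin=0, chrom="chr2", start=5, end=50, cls="Simple_repeat")
        with gzip.open(path, "wt") as fh:
            fh.write(row + "\n")
        assert len(load_rmsk_trr(path)) == 1


class TestBed:
    def test_three_intervals(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("1\t10\t20\n1\t30\t40\nchr2\t0\t5\n")
        rs = load_bed(path)
        assert len(rs) == 3 and rs.contains_point("2", 3)

    def test_track_line_skipped(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("track name=x\n1\t10\t20\n")
        assert len(load_bed(path)) == 1

    def test_empty_file_is_error(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("")
        with pytest.raises(ValueError, match="no intervals"):
            load_bed(path)

    def test_non_integer_coordinates_are_error(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("1\tten\t20\n")
        with pytest.raises(ValueError, match="non-integer"):
            load_bed(path)

    def test_write_read_round_trip(self, tmp_path):
        rs = RegionSet("x", [Region("2", 5, 50), Region("1", 10, 20, "lbl")])
        path = tmp_path / "out.bed"
        write_bed(rs, path)
        back = load_bed(path)
        assert sorted((r.chrom, r.start, r.end) for r in back) == \
            [("1", 10, 20), ("2", 5, 50)]


class TestBreakpointMembership:
    REGIONS = RegionSet("r", [Region("1", 100, 200)])

    @pytest.mark.parametrize("pos,inside", [
        (150, True),
        (100, False),  # 1-based pos 100 -> 0-based point 99, left of [100,200)
        (101, True),   # 0-based 100, the first point inside
        (200, True),   # 0-based 199, the last point inside
        (201, False),  # 0-based 200, past the half-open end
    ])
    def test_ins_one_based_to_zero_based_boundary(self, pos, inside):
        assert breakpoints_in_regions(mk("INS", pos=pos), self.REGIONS) is inside

    def test_del_any_breakpoint_semantics(self):
        assert breakpoints_in_regions(mk("DEL", pos=90, end=150), self.REGIONS)
        assert not breakpoints_in_regions(mk("DEL", pos=10, end=95), self.REGIONS)
        assert not breakpoints_in_regions(
            mk("DEL", pos=90, end=150), self.REGIONS, mode="all")
        assert not breakpoints_in_regions(
            mk("DEL", pos=90, end=150), self.REGIONS, mode="start")
        assert breakpoints_in_regions(
            mk("DEL", pos=110, end=160), self.REGIONS, mode="all")

    def test_absent_chromosome_is_false(self):
        assert not breakpoints_in_regions(mk("INS", chrom="9", pos=150), self.REGIONS)

    def test_agrees_with_linear_scan_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        spans = [(int(s), int(s + rng.integers(1, 500)))
                 for s in rng.integers(0, 20_000, size=60)]
        rs = RegionSet("rand", [Region("1", s, e) for s, e in spans])
        for _ in range(300):
            pos = int(rng.integers(1, 21_000))
            rec = mk("INS", pos=pos)
            linear = any(s <= pos - 1 < e for s, e in spans)
            assert breakpoints_in_regions(rec, rs) is linear


class TestPartition:
    TRR = RegionSet("trr", [Region("1", 1000, 2000)])

    def test_partition_exhaustive_exclusive_order_preserved(self):
        records = [mk("INS", pos=1500), mk("INS", pos=5000),
                   mk("DEL", pos=1100, end=1200), mk("DEL", pos=8000, end=8100)]
        inside, outside = partition_by_trr(records, self.TRR)
        assert (len(inside), len(outside)) == (2, 2)
        assert inside + outside != records or inside == records[:2]
        assert sorted(map(id, inside + outside)) == sorted(map(id, records))

    def test_empty_and_whole_genome_trr(self):
        records = [mk("INS", pos=p) for p in (10, 5000)]
        assert partition_by_trr(records, RegionSet("none"))[0] == []
        whole = RegionSet("all", [Region("1", 0, 10_000_000)])
        assert partition_by_trr(records, whole)[1] == []

    def test_restriction_is_idempotent(self):
        records = [mk("INS", pos=p) for p in (1500, 5000, 1999)]
        once = restrict_to_regions(records, self.TRR)
        assert restrict_to_regions(once, self.TRR) == once
        assert len(once) == 2
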