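"""Genomic interval sets: tandem-repeat regions, benchmark regions, and
breakpoint-overlap queries.

Tandem-repeat regions (TRRs) are taken from a UCSC RepeatMasker table
(``rmsk.txt`` schema): rows whose ``repClass`` is ``Simple_repeat`` (short
pattern tandem repeats) or ``Satellite`` (medium-to-long pattern tandem
repeats). Benchmark regions arrive as BED3+.

Coordinate convention: regions are 0-based half-open ``[start, end)`` as in
their source files; a 1-based VCF breakpoint ``p`` is tested as the 0-based
point ``p - 1``. A record is "in" a region set when any of its breakpoints
falls inside some region (insertions have one breakpoint, deletions two);
``mode`` can tighten this to ``all`` or ``start``.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .sv_io import SVRecord, _strip_chr

__all__ = [
    "Region",
    "RegionSet",
    "load_rmsk_trr",
    "load_bed",
    "breakpoints_in_regions",
    "partition_by_trr",
    "restrict_to_regions",
]

#: repClass values that define tandem-repeat regions.
TRR_CLASSES = ("Simple_repeat", "Satellite")

# rmsk.txt columns (UCSC schema): genoName=5, genoStart=6, genoEnd=7, repClass=11
_RMSK_COLS = {5: "chrom", 6: "start", 7: "end", 11: "repClass"}


@dataclass(frozen=True)
class Region:
    """One genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


class RegionSet:
    """Named set of regions with O(log n + k) point and interval queries.

    Queries on a chromosome absent from the set return empty/False.
    Overlapping or adjacent regions are deliberately *not* merged, so region
    counts in reports reflect the source annotation.
    """

    def __init__(self, name: str, regions=()):
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        self._regions: list[Region] = []
        for region in regions:
            self.add(region)

    def add(self, region: Region) -> None:
        self._regions.append(region)
        self._trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, region.label
        )

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self):
        return iter(self._regions)

    @property
    def regions(self) -> list[Region]:
        return list(self._regions)

    def contains_point(self, chrom: str, point0: int) -> bool:
        """Membership of a 0-based point."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(point0))

    def overlapping(self, chrom: str, start0: int, end0: int) -> list[Region]:
        """Regions overlapping a 0-based half-open interval."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [Region(chrom, iv.begin, iv.end, iv.data) for iv in sorted(tree.overlap(start0, end0))]

    def total_bp(self) -> int:
        """Sum of region lengths (overlaps double-counted; see class note)."""
        return sum(len(r) for r in self._regions)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_rmsk_trr(path, classes=TRR_CLASSES, name: str = "TRR") -> RegionSet:
    """Load tandem-repeat regions from a UCSC rmsk.txt(.gz) table.

    Keeps rows whose repClass is in ``classes``; coordinates stay 0-based
    half-open as in the source. Malformed rows are skipped with a warning;
    zero qualifying rows raise (an empty TRR set almost certainly means a
    schema mismatch).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=list(_RMSK_COLS),
        names=[_RMSK_COLS[i] for i in sorted(_RMSK_COLS)],
        dtype=str,
        on_bad_lines="skip",
        compression="infer",
    )
    n_in = len(df)
    df["start"] = pd.to_numeric(df["start"], errors="coerce")
    df["end"] = pd.to_numeric(df["end"], errors="coerce")
    df = df.dropna(subset=["chrom", "start", "end", "repClass"])
    df = df[df["end"] > df["start"]]
    n_bad = n_in - len(df)
    if n_bad:
        warnings.warn(f"{path}: skipped {n_bad} malformed rmsk rows", stacklevel=2)
    df = df[df["repClass"].isin(classes)]
    if df.empty:
        raise ValueError(
            f"{path}: no rows with repClass in {classes}; wrong schema or file?"
        )
    regions = RegionSet(name)
    for chrom, start, end, rep in df[["chrom", "start", "end", "repClass"]].itertuples(index=False):
        regions.add(Region(_strip_chr(chrom), int(start), int(end), rep))
    return regions


def load_bed(path, name: str = "regions") -> RegionSet:
    """Load a BED3+ file into a :class:`RegionSet`.

    ``track``/``browser``/``#`` lines are skipped; non-integer coordinates
    are a hard error, as is a file with zero intervals.
    """
    regions = RegionSet(name)
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            label = fields[3] if len(fields) > 3 else ""
            regions.add(Region(_strip_chr(fields[0]), start, end, label))
    if len(regions) == 0:
        raise ValueError(f"{path}: no intervals")
    return regions


def write_bed(regions: RegionSet, path) -> None:
    """Write a RegionSet as BED3(+label), in genomic order."""
    def key(r: Region):
        return ((0, int(r.chrom)) if r.chrom.isdigit() else (1, r.chrom), r.start, r.end)

    with open(path, "w") as handle:
        for r in sorted(regions, key=key):
            suffix = f"\t{r.label}" if r.label else ""
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}{suffix}\n")


def breakpoints_in_regions(record: SVRecord, regions: RegionSet, mode: str = "any") -> bool:
    """Whether the record's breakpoints overlap the region set.

    A 1-based breakpoint ``p`` maps to the 0-based point ``p - 1``. ``mode``
    is the combinator over a deletion's two breakpoints: ``any`` (default,
    the literal reading of "breakpoints overlapped with these regions"),
    ``all``, or ``start``.
    """
    points = record.breakpoints
    if mode == "start":
        points = points[:1]
    hits = (regions.contains_point(record.chrom, p - 1) for p in points)
    if mode == "all":
        return all(hits)
    if mode in {"any", "start"}:
        return any(hits)
    raise ValueError(f"unknown mode {mode!r}")


def partition_by_trr(records, trr: RegionSet, mode: str = "any"):
    """Split records into (in_trr, outside_trr), preserving order.

    Every record appears in exactly one output list.
    """
    inside: list[SVRecord] = []
    outside: list[SVRecord] = []
    for rec in records:
        (inside if breakpoints_in_regions(rec, trr, mode) else outside).append(rec)
    return inside, outside


def restrict_to_regions(records, bench: RegionSet, mode: str = "any"):
    """Keep only records whose breakpoints overlap ``bench`` (order preserved)."""
    return [rec for rec in records if breakpoints_in_regions(rec, bench, mode)]
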