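"""Reading, filtering, normalizing and writing structural-variant callsets.

A structural variant (SV) here is an insertion or deletion of at least 50 bp.
Callsets arrive as VCF with ``SVTYPE``/``SVLEN``/``END`` INFO fields (or
sequence-resolved REF/ALT alleles); the PBHoney "Spots" dialect additionally
carries ``szCount`` and ``coverage`` tags whose ratio is used as a quality
filter. All records are normalized to a single in-memory representation,
:class:`SVRecord`, with a fixed coordinate convention:

* ``pos`` and ``end`` are 1-based breakpoints;
* insertions have ``end == pos`` (a single breakpoint);
* deletions span the half-open interval ``(pos, end]`` so that
  ``svlen == end - pos`` — when SVLEN and END disagree, END wins;
* chromosome names are stripped of any ``chr`` prefix so GRCh37 callsets and
  hg19 annotation tables interoperate.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pysam

__all__ = [
    "SVRecord",
    "FilterPolicy",
    "read_sv_vcf",
    "normalize_record",
    "write_sv_vcf",
    "CANONICAL_CHROMS",
]

#: Autosomes 1-22 plus the sex chromosomes, without "chr" prefix.
CANONICAL_CHROMS: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

#: Relative SVLEN / (END-POS) discrepancy above which a deletion is flagged.
_DEL_LEN_DISCREPANCY = 0.10


@dataclass
class SVRecord:
    """One normalized structural variant.

    Attributes
    ----------
    chrom : chromosome name, ``chr`` prefix stripped.
    pos : 1-based start breakpoint.
    end : 1-based end breakpoint; equals ``pos`` for insertions.
    svtype : ``"INS"`` or ``"DEL"`` (other types only transiently, pre-filter).
    svlen : positive SV size in bp; for deletions ``end - pos``.
    filter_status : raw VCF FILTER string (``"PASS"``, ``"."`` or joined names).
    precise : False iff the record carried the ``IMPRECISE`` INFO flag.
    source : callset identifier.
    extras : open key→value map for dialect tags (szCount, coverage, id, label).
    """

    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int
    filter_status: str = "PASS"
    precise: bool = True
    source: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.pos:
            raise ValueError(f"end < pos on {self.chrom}:{self.pos}-{self.end}")
        if self.svtype == "INS" and self.end != self.pos:
            raise ValueError("insertion must have end == pos")
        if self.svlen <= 0:
            raise ValueError("svlen must be positive")

    @property
    def breakpoints(self) -> tuple[int, ...]:
        """1-based breakpoints: (pos,) for INS, (pos, end) for DEL."""
        if self.svtype == "INS":
            return (self.pos,)
        return (self.pos, self.end)

    def span_length(self) -> int:
        """Interval length ``end - pos`` used for reciprocal overlap."""
        return self.end - self.pos


@dataclass(frozen=True)
class FilterPolicy:
    """Inclusion rules applied while reading a callset.

    ``spots_ratio_min`` implements the PBHoney Spots quality rule: records
    whose szCount/coverage ratio is below the threshold are filtered out
    (kept iff ratio >= threshold). It only applies to the ``pbhoney`` dialect.
    ``require_pass`` is meant for truth sets (e.g. a Tier 1 benchmark VCF
    where only FILTER=PASS records are usable).
    """

    min_size: int = 50
    excluded_types: frozenset = frozenset({"BND"})
    allowed_chroms: tuple = CANONICAL_CHROMS
    require_pass: bool = False
    spots_ratio_min: float = 0.2

    def __post_init__(self) -> None:
        if self.min_size <= 0:
            raise ValueError("min_size must be positive")
        if not 0.0 <= self.spots_ratio_min <= 1.0:
            raise ValueError("spots_ratio_min must be in [0, 1]")


#: Permissive policy for round-trip reading of already-filtered files.
PERMISSIVE_POLICY = FilterPolicy(min_size=1, allowed_chroms=(), require_pass=False)


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def _scalar(value):
    """INFO values may come back as 1-tuples depending on header Number."""
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def _infer_svtype(rec: pysam.VariantRecord, alt: str) -> tuple[str | None, int | None]:
    """SVTYPE and (if sequence-resolved) size from the alleles.

    Returns (svtype, svlen) where either may be None when not inferable.
    """
    if alt is None:
        return None, None
    if alt.startswith("<") and alt.endswith(">"):
        return alt.strip("<>").split(":")[0], None
    if alt in {".", "*"} or any(ch in alt for ch in "[]"):
        return "BND" if any(ch in alt for ch in "[]") else None, None
    ref = rec.ref or ""
    diff = len(alt) - len(ref)
    if diff >= 1:
        return "INS", diff
    if diff <= -1:
        return "DEL", -diff
    return None, None


def normalize_record(rec: pysam.VariantRecord, alt_index: int = 0, source: str = "") -> SVRecord:
    """Normalize one parsed VCF record (one ALT allele) into an :class:`SVRecord`.

    Conventions applied: negative SVLEN → absolute value; deletion END wins
    over SVLEN when both are present (a >10% relative discrepancy triggers a
    warning); a deletion missing END gets ``pos + |SVLEN|``; insertions get
    ``end = pos``; ``chr`` prefixes are stripped.

    Raises
    ------
    ValueError
        If the SV type or size cannot be resolved.
    """
    info = rec.info
    alts = rec.alts or (None,)
    alt = alts[alt_index] if alt_index < len(alts) else None

    svtype = _scalar(info.get("SVTYPE")) if "SVTYPE" in info else None
    seq_svtype, seq_svlen = _infer_svtype(rec, alt)
    if svtype is None:
        svtype = seq_svtype
    if svtype is None:
        raise ValueError(
            f"cannot resolve SVTYPE at {rec.chrom}:{rec.pos} (ALT={alt!r})"
        )

    svlen = None
    if "SVLEN" in info:
        raw = info.get("SVLEN")
        if isinstance(raw, (tuple, list)):
            raw = raw[alt_index] if alt_index < len(raw) else raw[0]
        if raw is not None:
            svlen = abs(int(raw))
    if svlen is None:
        svlen = abs(seq_svlen) if seq_svlen is not None else None

    pos = rec.pos  # pysam .pos is 1-based
    # pysam folds INFO/END into .stop (0-based exclusive == 1-based inclusive END)
    end = rec.stop

    if svtype == "INS":
        if svlen is None:
            raise ValueError(f"insertion without resolvable size at {rec.chrom}:{pos}")
        end = pos
    elif svtype == "DEL":
        if end > pos:
            span = end - pos
            if svlen is not None and svlen > 0:
                if abs(span - svlen) / max(span, svlen) > _DEL_LEN_DISCREPANCY:
                    warnings.warn(
                        f"DEL at {rec.chrom}:{pos}: SVLEN={svlen} disagrees with "
                        f"END-POS={span}; using END-POS",
                        stacklevel=2,
                    )
            svlen = span
        elif svlen is not None:
            end = pos + svlen
        else:
            raise ValueError(f"deletion without END or SVLEN at {rec.chrom}:{pos}")
    else:
        # BND and other types are representable only far enough to be filtered;
        # give them a 1 bp placeholder size.
        end = max(end, pos)
        svlen = svlen if svlen else 1
        if svtype == "INS":  # pragma: no cover - defensive
            end = pos

    filt = list(rec.filter.keys())
    filter_status = ";".join(filt) if filt else "."

    extras: dict = {}
    if rec.id not in (None, "."):
        extras["id"] = rec.id
    for key in ("szCount", "coverage", "PROV"):
        if key in info:
            extras[key] = _scalar(info.get(key))
        else:  # PBHoney variants put the tags in per-sample FORMAT fields
            for sample in rec.samples.values():
                if key in sample:
                    extras[key] = _scalar(sample[key])
                    break

    return SVRecord(
        chrom=_strip_chr(rec.chrom),
        pos=pos,
        end=end if svtype != "INS" else pos,
        svtype=svtype,
        svlen=int(svlen),
        filter_status=filter_status,
        precise="IMPRECISE" not in info,
        source=source,
        extras=extras,
    )


def read_sv_vcf(
    path,
    policy: FilterPolicy = FilterPolicy(),
    source: str = "",
    dialect: str = "generic",
    return_stats: bool = False,
):
    """Read a VCF and return the normalized records passing ``policy``.

    Parameters
    ----------
    path : VCF path (plain or bgzipped).
    policy : inclusion rules; see :class:`FilterPolicy`.
    source : callset identifier stamped on every record.
    dialect : ``"generic"`` or ``"pbhoney"``; the latter enables the
        szCount/coverage ratio filter.
    return_stats : also return a ``Counter`` of per-reason exclusion counts
        (keys: ``kept``, ``type``, ``size``, ``chrom``, ``filter``,
        ``spots_ratio``, ``unresolvable``). ``records_in`` equals ``kept``
        plus the sum of the exclusion reasons.

    Record order follows input order; multi-allelic records are split into
    one record per ALT allele.
    """
    if dialect not in {"generic", "pbhoney"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    stats: Counter = Counter()
    records: list[SVRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"unparseable VCF {path}: {exc}") from exc
    with vcf:
        for raw in vcf:
            n_alts = len(raw.alts or (None,))
            for ai in range(n_alts):
                try:
                    rec = normalize_record(raw, alt_index=ai, source=source)
                except ValueError:
                    stats["unresolvable"] += 1
                    warnings.warn(
                        f"skipping unresolvable record at {raw.chrom}:{raw.pos}",
                        stacklevel=2,
                    )
                    continue
                reason = _exclusion_reason(rec, policy, dialect)
                if reason is None:
                    stats["kept"] += 1
                    records.append(rec)
                else:
                    stats[reason] += 1
    if return_stats:
        return records, stats
    return records


def _exclusion_reason(rec: SVRecord, policy: FilterPolicy, dialect: str) -> str | None:
    if rec.svtype in policy.excluded_types:
        return "type"
    if rec.svtype not in {"INS", "DEL"}:
        return "type"
    if policy.allowed_chroms and rec.chrom not in policy.allowed_chroms:
        return "chrom"
    if rec.svlen < policy.min_size:
        return "size"
    if policy.require_pass and rec.filter_status != "PASS":
        return "filter"
    if dialect == "pbhoney":
        sz = rec.extras.get("szCount")
        cov = rec.extras.get("coverage")
        if sz is not None and cov is not None:
            if cov <= 0 or sz / cov < policy.spots_ratio_min:
                return "spots_ratio"
    return None


def apply_policy(records, policy: FilterPolicy, dialect: str = "generic"):
    """Filter an in-memory record list with the same rules as :func:`read_sv_vcf`."""
    return [r for r in records if _exclusion_reason(r, policy, dialect) is None]


def _build_header(records) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">')
    header.add_line('##INFO=<ID=szCount,Number=1,Type=Integer,Description="Supporting read count">')
    header.add_line('##INFO=<ID=coverage,Number=1,Type=Integer,Description="Local coverage">')
    header.add_line('##INFO=<ID=PROV,Number=1,Type=String,Description="Provenance label">')
    header.add_line('##ALT=<ID=INS,Description="Insertion">')
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    filters = set()
    lengths: dict[str, int] = {}
    for rec in records:
        lengths[rec.chrom] = max(lengths.get(rec.chrom, 0), rec.end + 1000)
        for name in rec.filter_status.split(";"):
            if name not in {"PASS", ".", ""}:
                filters.add(name)
    for name in sorted(filters):
        header.add_line(f'##FILTER=<ID={name},Description="{name}">')

    def chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    for chrom in sorted(lengths, key=chrom_key):
        header.add_line(f"##contig=<ID={chrom},length={lengths[chrom]}>")
    return header


def write_sv_vcf(records, path) -> None:
    """Write records as a minimal spec-compliant VCF.

    The output round-trips through :func:`read_sv_vcf` with a permissive
    policy to an identical record list (coordinates, type, size, FILTER,
    IMPRECISE flag and the szCount/coverage/id/PROV extras are preserved).
    """
    header = _build_header(records)
    try:
        out = pysam.VariantFile(str(path), "w", header=header)
    except OSError as exc:
        raise OSError(f"cannot write VCF {path}: {exc}") from exc
    with out:
        for rec in records:
            v = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                # END must be fixed at construction (htslib reconciles a
                # later SVLEN against it); for INS end == pos by convention
                stop=rec.end,
                alleles=("N", f"<{rec.svtype}>"),
                id=rec.extras.get("id"),
            )
            v.info["SVTYPE"] = rec.svtype
            v.info["SVLEN"] = -rec.svlen if rec.svtype == "DEL" else rec.svlen
            if not rec.precise:
                v.info["IMPRECISE"] = True
            for key in ("szCount", "coverage"):
                if key in rec.extras:
                    v.info[key] = int(rec.extras[key])
            if "PROV" in rec.extras or "label" in rec.extras:
                v.info["PROV"] = str(rec.extras.get("PROV", rec.extras.get("label")))
            if rec.filter_status not in {".", ""}:
                for name in rec.filter_status.split(";"):
                    v.filter.add(name)
            out.write(v)
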