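"""Precision / recall / F1 and their stratifications.

Definitions: precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2·P·R/(P+R). TP+FP equals the number of called SVs and TP+FN the
number of reference SVs. A metric whose denominator is zero is *undefined*
and reported as ``None`` (NA in tables), never silently 0 — this keeps F1
honest on empty strata.

Stratification follows the evaluation design: matching is performed once
globally (inside the benchmark regions) and the resulting TP/FP/FN records
are then distributed over strata — the cross of SV type × tandem-repeat
status × size bin. A matched pair is assigned to the stratum of its
*reference* record, so the benchmark composition defines the strata; FP
calls and FN references use their own stratum. Matching first and
stratifying second prevents a call inside a repeat from going unmatched
merely because its true partner's breakpoint falls 1 bp outside the repeat
(the alternative, stratify-then-match, is available for sensitivity
analysis via ``stratify_first=True``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .matching import MatchCriteria, MatchResult, compare_to_benchmark, match_callsets
from .regions import RegionSet, breakpoints_in_regions, restrict_to_regions
from .sv_io import SVRecord

__all__ = [
    "MetricsResult",
    "SizeBins",
    "compute_prf",
    "size_bin",
    "stratified_metrics",
    "flag_subset_precision",
]

IN_TRR = "in_trr"
OUTSIDE_TRR = "outside_trr"


@dataclass(frozen=True)
class SizeBins:
    """Half-open SV size bins over [min_size, inf).

    Default boundaries (50, 100, 300, 1000) produce the bins
    50-100, 100-300, 300-1000 and >1000 bp; the lower edge of each bin is
    inclusive, so a 1,000 bp SV falls in ">1000".
    """

    boundaries: tuple = (50, 100, 300, 1000)

    def __post_init__(self) -> None:
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def labels(self) -> tuple:
        bounds = self.boundaries
        inner = tuple(f"{a}-{b}" for a, b in zip(bounds, bounds[1:]))
        return inner + (f">{bounds[-1]}",)


def size_bin(record: SVRecord, bins: SizeBins = SizeBins()) -> str:
    """Bin label for a record's size; sizes below the first boundary are an error."""
    bounds = bins.boundaries
    if record.svlen < bounds[0]:
        raise ValueError(
            f"svlen {record.svlen} below {bounds[0]} bp; record should have been filtered"
        )
    for label, (lo, hi) in zip(bins.labels, zip(bounds, bounds[1:])):
        if lo <= record.svlen < hi:
            return label
    return bins.labels[-1]


@dataclass
class MetricsResult:
    """P/R/F1 with TP/FP/FN counts for one stratum; undefined metrics are None."""

    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None
    stratum: dict

    def as_dict(self) -> dict:
        return {**self.stratum, "tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall, "f1": self.f1}


def _prf(tp: int, fp: int, fn: int, stratum: dict | None = None) -> MetricsResult:
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsResult(tp, fp, fn, precision, recall, f1, stratum or {})


def compute_prf(match: MatchResult, stratum: dict | None = None) -> MetricsResult:
    """Precision/recall/F1 from a match result."""
    return _prf(match.tp, match.fp, match.fn, stratum)


def _stratum_of(rec: SVRecord, trr: RegionSet, bins: SizeBins, trr_mode: str) -> tuple:
    status = IN_TRR if breakpoints_in_regions(rec, trr, trr_mode) else OUTSIDE_TRR
    return rec.svtype, status, size_bin(rec, bins)


def stratified_metrics(
    calls,
    truth,
    trr: RegionSet,
    bench: RegionSet,
    criteria: MatchCriteria = MatchCriteria(),
    bins: SizeBins = SizeBins(),
    source: str = "",
    trr_mode: str = "any",
    stratify_first: bool = False,
) -> pd.DataFrame:
    """Metric table over {INS, DEL} × {in/outside TRR} × ({all} ∪ size bins).

    One row per stratum plus pooled rows: ``svtype="ALL"`` with
    ``aggregation="micro"`` (pooled TP/FP/FN) and ``aggregation="macro"``
    (unweighted mean of the defined INS/DEL metrics; counts pooled). Per-type
    rows carry ``aggregation="micro"``. Stratum sums are conserved: summing
    tp (fp, fn) over the per-type size="all" rows recovers the global counts.
    """
    counts: dict[tuple, list] = {}

    def bump(stratum: tuple, slot: int) -> None:
        counts.setdefault(stratum, [0, 0, 0])[slot] += 1

    if stratify_first:
        calls_r = restrict_to_regions(calls, bench)
        truth_r = restrict_to_regions(truth, bench)
        svtypes = {r.svtype for r in calls_r} | {r.svtype for r in truth_r}
        for svtype in svtypes:
            for status, side in ((IN_TRR, True), (OUTSIDE_TRR, False)):
                sub_c = [r for r in calls_r
                         if r.svtype == svtype and breakpoints_in_regions(r, trr, trr_mode) is side]
                sub_t = [r for r in truth_r
                         if r.svtype == svtype and breakpoints_in_regions(r, trr, trr_mode) is side]
                m = match_callsets(sub_c, sub_t, criteria)
                for _, ref, _ in m.pairs:
                    bump((svtype, status, size_bin(ref, bins)), 0)
                for rec in m.fp_calls:
                    bump((svtype, status, size_bin(rec, bins)), 1)
                for rec in m.fn_refs:
                    bump((svtype, status, size_bin(rec, bins)), 2)
    else:
        match = compare_to_benchmark(calls, truth, bench, criteria)
        for call, ref, _ in match.pairs:
            bump(_stratum_of(ref, trr, bins, trr_mode), 0)
        for rec in match.fp_calls:
            bump(_stratum_of(rec, trr, bins, trr_mode), 1)
        for rec in match.fn_refs:
            bump(_stratum_of(rec, trr, bins, trr_mode), 2)

    rows: list[dict] = []

    def add_row(svtype, status, binlabel, tp, fp, fn):
        res = _prf(tp, fp, fn)
        rows.append({
            "source": source, "svtype": svtype, "trr_status": status,
            "size_bin": binlabel, "aggregation": "micro",
            "tp": res.tp, "fp": res.fp, "fn": res.fn,
            "precision": res.precision, "recall": res.recall, "f1": res.f1,
        })

    bin_labels = ("all",) + bins.labels
    for svtype in ("INS", "DEL"):
        for status in (IN_TRR, OUTSIDE_TRR):
            per_bin = {b: counts.get((svtype, status, b), [0, 0, 0]) for b in bins.labels}
            total = [sum(v[k] for v in per_bin.values()) for k in range(3)]
            for binlabel in bin_labels:
                tp, fp, fn = total if binlabel == "all" else per_bin[binlabel]
                add_row(svtype, status, binlabel, tp, fp, fn)

    df = pd.DataFrame(rows)
    # pooled per-TRR-stratum rows, micro (pooled counts) and macro (mean of metrics)
    pooled = []
    for status in (IN_TRR, OUTSIDE_TRR):
        sub = df[(df.trr_status == status) & (df.size_bin == "all")]
        tp, fp, fn = int(sub.tp.sum()), int(sub.fp.sum()), int(sub.fn.sum())
        micro = _prf(tp, fp, fn)
        pooled.append({"source": source, "svtype": "ALL", "trr_status": status,
                       "size_bin": "all", "aggregation": "micro",
                       "tp": tp, "fp": fp, "fn": fn, "precision": micro.precision,
                       "recall": micro.recall, "f1": micro.f1})
        def _mean(col):
            vals = [v for v in sub[col] if v is not None]
            return sum(vals) / len(vals) if vals else None
        pooled.append({"source": source, "svtype": "ALL", "trr_status": status,
                       "size_bin": "all", "aggregation": "macro",
                       "tp": tp, "fp": fp, "fn": fn, "precision": _mean("precision"),
                       "recall": _mean("recall"), "f1": _mean("f1")})
    return pd.concat([df, pd.DataFrame(pooled)], ignore_index=True)


def flag_subset_precision(
    calls,
    truth,
    bench: RegionSet,
    criteria: MatchCriteria = MatchCriteria(),
    flag: str = "IMPRECISE",
) -> MetricsResult:
    """Precision over the subset of calls carrying an INFO flag.

    Matching is global (within the benchmark regions); precision is then
    computed over the flagged calls only. ``flag="IMPRECISE"`` selects
    records whose ``precise`` attribute is False; any other key is looked up
    in ``extras``. FN is not meaningful for a call subset and is reported
    as 0 with recall None.
    """
    match = compare_to_benchmark(calls, truth, bench, criteria)

    def has_flag(rec: SVRecord) -> bool:
        if flag == "IMPRECISE":
            return not rec.precise
        return flag in rec.extras

    tp_ids = {id(r) for r in match.tp_calls}
    flagged = [r for r in restrict_to_regions(calls, bench) if has_flag(r)]
    if not flagged:
        warnings.warn(f"no calls carry flag {flag!r}; precision undefined", stacklevel=2)
    tp = sum(1 for r in flagged if id(r) in tp_ids)
    fp = len(flagged) - tp
    res = _prf(tp, fp, 0, {"flag": flag})
    return MetricsResult(res.tp, res.fp, res.fn, res.precision, None, None,
                         {"flag": flag})
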