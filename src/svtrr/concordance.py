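"""Multi-callset concordance: pairwise/three-way Venn overlap, concurrent
detection against a truth set, and trio "de novo" rates.

When two callsets from the same sample are compared, the larger one plays
the reference role (ties: the first operand), so the overlap count is the
number of one-to-one matched pairs under the usual dual criteria. A
three-set Venn is assembled from the three pairwise comparisons: each
record's Venn region is given by the vector of "was matched in the pairwise
comparison with X". This is an approximation — a true simultaneous
three-way assignment is ill-defined under one-to-one pairwise criteria —
so the Venn counts are kept per set (each set's four regions sum exactly to
its record count) rather than forced into seven global numbers.

The "de novo" rate of a trio is the fraction of the son's calls that match
no call in either parent, under the same matching criteria used for
benchmarking; it is reported overall and stratified by tandem-repeat
status of the son's breakpoints. These rates conflate true de novo events
with the son's false positives and the parents' false negatives — they are
an upper bound, not a genotype-aware Mendelian analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matching import MatchCriteria, compare_to_benchmark, match_callsets
from .regions import RegionSet, breakpoints_in_regions, restrict_to_regions

__all__ = [
    "OverlapSummary",
    "TrioResult",
    "overlap_rate_percent",
    "pairwise_overlap",
    "three_way_overlap",
    "concurrent_detection",
    "denovo_rate",
]


@dataclass
class OverlapSummary:
    """Venn partition and overlap rates for 2 or 3 callsets.

    venn_counts[set_name][pattern] counts that set's records by the sorted
    concatenation of the sets they were matched in (including their own
    name); e.g. for sets A,B,C the patterns from A's perspective are
    "A", "AB", "AC", "ABC" and they sum to |A|. overlap_rate[set_name] is
    the fraction of the set's records matched in at least one other set.
    """

    set_names: tuple
    sizes: dict = field(default_factory=dict)
    venn_counts: dict = field(default_factory=dict)
    overlap_rate: dict = field(default_factory=dict)


@dataclass
class TrioResult:
    """De novo count and rate for one stratum of the son's callset."""

    n_son: int
    n_denovo: int
    denovo_rate: float | None
    stratum: str


def overlap_rate_percent(n_shared: int, n_total: int) -> float:
    """Overlap rate as a percentage rounded to the nearest percent.

    The convention used when quoting rates like "42% (5,643/13,419)".
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_shared / n_total)


def _matched_ids(x, y, criteria: MatchCriteria):
    """Ids of records of x and of y matched in a pairwise comparison.

    The larger set is the reference; ties make the first operand the
    reference. Because matching is one-to-one the matched counts agree on
    both sides.
    """
    if len(y) > len(x):
        calls, refs = x, y
        call_side_is_x = True
    else:
        calls, refs = y, x
        call_side_is_x = False
    m = match_callsets(calls, refs, criteria)
    call_ids = {id(c) for c, _, _ in m.pairs}
    ref_ids = {id(r) for _, r, _ in m.pairs}
    return (call_ids, ref_ids) if call_side_is_x else (ref_ids, call_ids)


def pairwise_overlap(a, b, criteria: MatchCriteria = MatchCriteria(),
                     names: tuple = ("A", "B")) -> OverlapSummary:
    """Two-set Venn: shared pairs plus each set's unique remainder."""
    a, b = list(a), list(b)
    ids_a, ids_b = _matched_ids(a, b, criteria)
    shared = len(ids_a)
    na, nb = names
    pattern = "".join(sorted(names))
    return OverlapSummary(
        set_names=tuple(names),
        sizes={na: len(a), nb: len(b)},
        venn_counts={
            na: {na: len(a) - shared, pattern: shared},
            nb: {nb: len(b) - shared, pattern: shared},
        },
        overlap_rate={
            na: shared / len(a) if a else None,
            nb: shared / len(b) if b else None,
        },
    )


def three_way_overlap(a, b, c, criteria: MatchCriteria = MatchCriteria(),
                      names: tuple = ("A", "B", "C")) -> OverlapSummary:
    """Three-set Venn from the three pairwise comparisons.

    Each record is labeled with the other sets it matched in; per-set region
    counts therefore reconstruct the set size exactly (see class note on the
    approximation involved).
    """
    sets = {names[0]: list(a), names[1]: list(b), names[2]: list(c)}
    matched: dict[str, dict[str, set]] = {n: {} for n in names}
    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            ids_i, ids_j = _matched_ids(sets[ni], sets[nj], criteria)
            matched[ni][nj] = ids_i
            matched[nj][ni] = ids_j

    venn_counts: dict[str, dict[str, int]] = {}
    overlap_rate: dict[str, float | None] = {}
    for name in names:
        counts: dict[str, int] = {}
        n_overlapping = 0
        for rec in sets[name]:
            partners = [other for other in names if other != name
                        and id(rec) in matched[name][other]]
            if partners:
                n_overlapping += 1
            pattern = "".join(sorted([name] + partners))
            counts[pattern] = counts.get(pattern, 0) + 1
        venn_counts[name] = counts
        overlap_rate[name] = n_overlapping / len(sets[name]) if sets[name] else None
    return OverlapSummary(
        set_names=tuple(names),
        sizes={n: len(sets[n]) for n in names},
        venn_counts=venn_counts,
        overlap_rate=overlap_rate,
    )


def concurrent_detection(truth, callsets: dict, bench: RegionSet,
                         criteria: MatchCriteria = MatchCriteria()) -> dict:
    """Histogram of truth records by how many callsets detected them.

    Each truth record inside the benchmark regions is labeled with the
    number of callsets in which it found a match (independent pairwise
    benchmark comparisons); returns ``{"counts": {k: n}, "proportions":
    {k: p}}`` over k = 0..len(callsets), proportions summing to 1.
    """
    truth_in = restrict_to_regions(truth, bench)
    detected = {id(r): 0 for r in truth_in}
    for calls in callsets.values():
        m = compare_to_benchmark(calls, truth_in, bench, criteria)
        for _, ref, _ in m.pairs:
            detected[id(ref)] += 1
    n = len(truth_in)
    ks = range(len(callsets) + 1)
    hist = {k: sum(1 for v in detected.values() if v == k) for k in ks}
    props = {k: (hist[k] / n if n else None) for k in ks}
    return {"n_truth": n, "counts": hist, "proportions": props}


def denovo_rate(son, father, mother, trr: RegionSet,
                criteria: MatchCriteria = MatchCriteria(),
                trr_mode: str = "any") -> dict[str, TrioResult]:
    """"De novo" rate of the son's callset, overall and by TRR status.

    A son record is de novo iff it matches no father record and no mother
    record (son as calls, each parent as reference; a son record counts as
    inherited if paired in either run). Rate = de novo / all son records.
    """
    son = list(son)
    inherited: set[int] = set()
    for parent in (father, mother):
        m = match_callsets(son, parent, criteria)
        inherited.update(id(c) for c in m.tp_calls)

    results: dict[str, TrioResult] = {}
    strata = {
        "all": son,
        "in_trr": [r for r in son if breakpoints_in_regions(r, trr, trr_mode)],
        "outside_trr": [r for r in son if not breakpoints_in_regions(r, trr, trr_mode)],
    }
    for label, records in strata.items():
        n = len(records)
        n_dn = sum(1 for r in records if id(r) not in inherited)
        results[label] = TrioResult(n, n_dn, (n_dn / n) if n else None, label)
    return results
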