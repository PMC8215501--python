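"""Shared test helpers: record factory, random fixtures, brute-force oracle."""

from __future__ import annotations

import numpy as np

from svtrr.matching import MatchCriteria, breakpoint_distance, reciprocal_overlap
from svtrr.sv_io import SVRecord


def mk(svtype="INS", chrom="1", pos=100, end=None, svlen=60, **kwargs):
    """Terse SVRecord factory; DEL svlen follows end - pos."""
    if svtype == "INS":
        end = pos
    elif end is None:
        end = pos + svlen
    if svtype == "DEL":
        svlen = end - pos
    return SVRecord(chrom, pos, end, svtype, svlen, **kwargs)


def quality(call, ref, criteria: MatchCriteria):
    """Candidate quality in [0, 1], or None when the pair is no match.

    Same scale the matcher optimizes: insertions prefer small breakpoint
    distance, deletions large reciprocal overlap.
    """
    if call.svtype != ref.svtype or call.chrom != ref.chrom:
        return None
    if call.svtype == "INS":
        dist = breakpoint_distance(call, ref)
        if dist <= criteria.ins_max_breakpoint_dist:
            return 1.0 - dist / (criteria.ins_max_breakpoint_dist + 1.0)
        return None
    ro = reciprocal_overlap(call, ref)
    return ro if ro >= criteria.del_min_reciprocal_overlap else None


def brute_force_best(calls, refs, criteria: MatchCriteria):
    """Exhaustive one-to-one assignment oracle.

    Enumerates every assignment and returns (max pair count, best total
    quality among maximum-cardinality assignments). Only feasible for a
    handful of records per side.
    """
    cands = {
        i: [(j, q) for j, ref in enumerate(refs)
            if (q := quality(call, ref, criteria)) is not None]
        for i, call in enumerate(calls)
    }

    def recurse(i: int, used: frozenset):
        if i == len(calls):
            return (0, 0.0)
        best = recurse(i + 1, used)
        for j, q in cands[i]:
            if j not in used:
                cnt, tot = recurse(i + 1, used | {j})
                best = max(best, (cnt + 1, tot + q))
        return best

    return recurse(0, frozenset())


def random_fixture(rng: np.random.Generator, max_side: int = 8):
    """Random call/ref sets dense enough to produce chained candidates."""
    def side(n):
        records = []
        for _ in range(n):
            if rng.random() < 0.5:
                records.append(mk("INS", pos=int(rng.integers(1, 1200))))
            else:
                pos = int(rng.integers(1, 800))
                records.append(mk("DEL", pos=pos,
                                  end=pos + int(rng.integers(50, 400))))
        return records

    return side(int(rng.integers(1, max_side + 1))), \
        side(int(rng.integers(1, max_side + 1)))
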