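#!/usr/bin/env python
"""Callset landscape: how many SVs each pipeline reports, split by type,
tandem-repeat status and size bin, plus the benchmark-region size
composition. Writes results/landscape.tsv and prints the in-TRR fractions.
"""

import argparse
from pathlib import Path

import pandas as pd

from svtrr.metrics import SizeBins, size_bin
from svtrr.regions import load_bed, partition_by_trr
from svtrr.report import summarize_regions
from svtrr.sv_io import FilterPolicy, read_sv_vcf

PIPELINES = ("pbsv_like", "sniffles_like", "pbhoney_like")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle", type=Path, default=Path("results/bundle"))
    parser.add_argument("--out", type=Path, default=Path("results/landscape.tsv"))
    args = parser.parse_args()

    trr = load_bed(args.bundle / "trr.bed", name="TRR")
    bins = SizeBins()
    rows = []
    for name in PIPELINES:
        records = read_sv_vcf(args.bundle / f"{name}.vcf", FilterPolicy(),
                              source=name)
        inside, outside = partition_by_trr(records, trr)
        frac = len(inside) / len(records) if records else float("nan")
        print(f"{name}: {len(records)} SVs, {100 * frac:.0f}% in TRRs")
        for status, recs in (("in_trr", inside), ("outside_trr", outside)):
            for svtype in ("INS", "DEL"):
                sub = [r for r in recs if r.svtype == svtype]
                counts = {b: 0 for b in bins.labels}
                for r in sub:
                    counts[size_bin(r, bins)] += 1
                rows.append({"source": name, "trr_status": status,
                             "svtype": svtype, "count": len(sub), **counts})

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, sep="\t", index=False)
    bench = load_bed(args.bundle / "bench.bed", name="benchmark")
    print("benchmark region size composition:")
    print(summarize_regions(bench).to_string(index=False))
    print(f"landscape table -> {args.out}")


if __name__ == "__main__":
    main()
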