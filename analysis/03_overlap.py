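#!/usr/bin/env python
"""Three-way concordance of the pipeline callsets: per-set Venn regions and
overlap rates (fraction of a callset matched by at least one other
pipeline), split by type and tandem-repeat status.
Writes results/overlap.json.
"""

import argparse
import json
from pathlib import Path

from svtrr.concordance import three_way_overlap
from svtrr.regions import load_bed, partition_by_trr
from svtrr.sv_io import FilterPolicy, read_sv_vcf

PIPELINES = ("pbsv_like", "sniffles_like", "pbhoney_like")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle", type=Path, default=Path("results/bundle"))
    parser.add_argument("--out", type=Path, default=Path("results/overlap.json"))
    args = parser.parse_args()

    trr = load_bed(args.bundle / "trr.bed", name="TRR")
    callsets = {name: read_sv_vcf(args.bundle / f"{name}.vcf", FilterPolicy(),
                                  source=name) for name in PIPELINES}

    payload = {}
    for svtype in ("INS", "DEL"):
        for status in ("in_trr", "outside_trr"):
            subsets = {}
            for name, records in callsets.items():
                typed = [r for r in records if r.svtype == svtype]
                inside, outside = partition_by_trr(typed, trr)
                subsets[name] = inside if status == "in_trr" else outside
            summary = three_way_overlap(*subsets.values(), names=PIPELINES)
            payload[f"{svtype}|{status}"] = {
                "sizes": summary.sizes,
                "venn_counts": summary.venn_counts,
                "overlap_rate": summary.overlap_rate,
            }
            rates = ", ".join(
                f"{n}={100 * r:.0f}%" if r is not None else f"{n}=NA"
                for n, r in summary.overlap_rate.items())
            print(f"{svtype} {status}: {rates}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(payload, indent=2))
    print(f"overlap summary -> {args.out}")


if __name__ == "__main__":
    main()
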