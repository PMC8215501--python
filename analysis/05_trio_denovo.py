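#!/usr/bin/env python
"""Trio analysis: the "de novo" rate — son calls matched in neither parent
under the benchmarking criteria — overall and by tandem-repeat status.
Writes results/denovo.json.
"""

import argparse
import json
from pathlib import Path

from svtrr.concordance import denovo_rate
from svtrr.regions import load_bed
from svtrr.sv_io import FilterPolicy, read_sv_vcf


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--bundle", type=Path, default=Path("results/bundle"))
    parser.add_argument("--out", type=Path, default=Path("results/denovo.json"))
    args = parser.parse_args()

    trr = load_bed(args.bundle / "trr.bed", name="TRR")
    son = read_sv_vcf(args.bundle / "son.vcf", FilterPolicy(), source="son")
    father = read_sv_vcf(args.bundle / "father.vcf", FilterPolicy(), source="father")
    mother = read_sv_vcf(args.bundle / "mother.vcf", FilterPolicy(), source="mother")

    results = denovo_rate(son, father, mother, trr)
    payload = {}
    for stratum, res in results.items():
        rate = "NA" if res.denovo_rate is None else f"{100 * res.denovo_rate:.1f}%"
        print(f"{stratum}: {res.n_denovo}/{res.n_son} de novo ({rate})")
        payload[stratum] = {"n_son": res.n_son, "n_denovo": res.n_denovo,
                            "denovo_rate": res.denovo_rate}

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(payload, indent=2))
    print(f"de novo rates -> {args.out}")


if __name__ == "__main__":
    main()
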