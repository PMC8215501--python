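"""Full-evaluation driver: ties ingestion, regions, matching, metrics and
concordance together and writes figure-level summary tables.

All numbers in the reports are produced by the module operations — the
reporting layer only arranges them. JSON is the machine surface (full
precision), TSV the human surface (percentages rounded to whole percent).
Outputs are fully determined by the run configuration and seed, and the
configuration is serialized alongside the outputs for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import concordance, metrics, regions, sv_io
from .matching import MatchCriteria

__all__ = ["RunConfig", "run_full_evaluation", "summarize_regions"]

log = logging.getLogger("svtrr")

#: Region size classes used in benchmark-region composition summaries.
_REGION_CLASSES = (("<1kb", 0, 1_000), ("1-10kb", 1_000, 10_000),
                   (">10kb", 10_000, None))


@dataclass
class RunConfig:
    """Inputs and knobs for one end-to-end evaluation run."""

    truth_vcf: str
    call_vcfs: dict  # name -> path
    trr_path: str  # BED or rmsk.txt(.gz)
    bench_bed: str
    out_dir: str
    son_vcf: str | None = None
    father_vcf: str | None = None
    mother_vcf: str | None = None
    policy: sv_io.FilterPolicy = field(default_factory=sv_io.FilterPolicy)
    truth_policy: sv_io.FilterPolicy = field(
        default_factory=lambda: sv_io.FilterPolicy(require_pass=True))
    criteria: MatchCriteria = field(default_factory=MatchCriteria)
    bins: metrics.SizeBins = field(default_factory=metrics.SizeBins)
    seed: int = 0

    def validate(self) -> None:
        paths = [self.truth_vcf, self.trr_path, self.bench_bed,
                 *self.call_vcfs.values()]
        paths += [p for p in (self.son_vcf, self.father_vcf, self.mother_vcf) if p]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")


def _load_trr(path) -> regions.RegionSet:
    if str(path).endswith((".bed", ".bed.gz")):
        return regions.load_bed(path, name="TRR")
    return regions.load_rmsk_trr(path)


def summarize_regions(region_set: regions.RegionSet) -> pd.DataFrame:
    """Counts and fractions of regions by size class (<1 kb, 1-10 kb, >10 kb)."""
    if len(region_set) == 0:
        raise ValueError("empty region set")
    rows = []
    n = len(region_set)
    for label, lo, hi in _REGION_CLASSES:
        count = sum(1 for r in region_set
                    if len(r) >= lo and (hi is None or len(r) < hi))
        rows.append({"size_class": label, "count": count, "fraction": count / n})
    return pd.DataFrame(rows)


def _callset_summary(name, records, trr, bins) -> list[dict]:
    inside, outside = regions.partition_by_trr(records, trr)
    rows = []
    for status, recs in (("in_trr", inside), ("outside_trr", outside)):
        for svtype in ("INS", "DEL"):
            sub = [r for r in recs if r.svtype == svtype]
            by_bin = {b: 0 for b in bins.labels}
            for r in sub:
                by_bin[metrics.size_bin(r, bins)] += 1
            rows.append({"source": name, "trr_status": status, "svtype": svtype,
                         "count": len(sub), **by_bin})
    return rows


def run_full_evaluation(config: RunConfig) -> dict:
    """Run every evaluation stage and write JSON + TSV reports to out_dir.

    Stages: callset landscape (counts by type/TRR/size), three-way overlap
    and overlap rates, concurrent detection against the truth, stratified
    precision/recall/F1, IMPRECISE-subset precision, and — when trio inputs
    are configured — de novo rates. Returns the report dict that was
    written to ``report.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)
        return name

    try:
        stage("ingest")
        truth, truth_stats = sv_io.read_sv_vcf(
            config.truth_vcf, config.truth_policy, source="truth", return_stats=True)
        callsets = {}
        attrition = {"truth": dict(truth_stats)}
        for name, path in config.call_vcfs.items():
            dialect = "pbhoney" if "honey" in name.lower() else "generic"
            recs, stats = sv_io.read_sv_vcf(path, config.policy, source=name,
                                            dialect=dialect, return_stats=True)
            callsets[name] = recs
            attrition[name] = dict(stats)
            log.info("%s: %s", name, dict(stats))
        stage("regions")
        trr = _load_trr(config.trr_path)
        bench = regions.load_bed(config.bench_bed, name="benchmark")
    except Exception as exc:
        raise RuntimeError(f"stage failed during input loading: {exc}") from exc

    report: dict = {"seed": config.seed, "attrition": attrition}

    stage("landscape")
    landscape = []
    for name, recs in callsets.items():
        landscape.extend(_callset_summary(name, recs, trr, config.bins))
    report["landscape"] = landscape
    report["benchmark_region_summary"] = summarize_regions(bench).to_dict("records")

    stage("overlap")
    names = list(callsets)
    if len(names) >= 3:
        ov = concordance.three_way_overlap(
            *(callsets[n] for n in names[:3]), config.criteria, tuple(names[:3]))
        report["overlap"] = {"sizes": ov.sizes, "venn_counts": ov.venn_counts,
                             "overlap_rate": ov.overlap_rate}
    elif len(names) == 2:
        ov = concordance.pairwise_overlap(
            callsets[names[0]], callsets[names[1]], config.criteria, tuple(names))
        report["overlap"] = {"sizes": ov.sizes, "venn_counts": ov.venn_counts,
                             "overlap_rate": ov.overlap_rate}

    stage("concurrent_detection")
    report["concurrent_detection"] = concordance.concurrent_detection(
        truth, callsets, bench, config.criteria)

    stage("stratified_metrics")
    tables = [metrics.stratified_metrics(recs, truth, trr, bench,
                                         config.criteria, config.bins, source=name)
              for name, recs in callsets.items()]
    metrics_table = pd.concat(tables, ignore_index=True)
    report["metrics"] = metrics_table.to_dict("records")

    stage("imprecise_precision")
    report["imprecise_precision"] = {
        name: metrics.flag_subset_precision(recs, truth, bench,
                                            config.criteria).as_dict()
        for name, recs in callsets.items()}

    if config.son_vcf and config.father_vcf and config.mother_vcf:
        stage("trio")
        son = sv_io.read_sv_vcf(config.son_vcf, config.policy, source="son")
        father = sv_io.read_sv_vcf(config.father_vcf, config.policy, source="father")
        mother = sv_io.read_sv_vcf(config.mother_vcf, config.policy, source="mother")
        trio = concordance.denovo_rate(son, father, mother, trr, config.criteria)
        report["denovo"] = {k: asdict(v) for k, v in trio.items()}

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    metrics_table.to_csv(out / "metrics.tsv", sep="\t", index=False,
                         float_format="%.4f")
    pd.DataFrame(landscape).to_csv(out / "landscape.tsv", sep="\t", index=False)
    _write_run_config(config, out)
    return report


def _write_run_config(config: RunConfig, out: Path) -> None:
    payload = {
        "truth_vcf": config.truth_vcf, "call_vcfs": config.call_vcfs,
        "trr_path": config.trr_path, "bench_bed": config.bench_bed,
        "son_vcf": config.son_vcf, "father_vcf": config.father_vcf,
        "mother_vcf": config.mother_vcf, "seed": config.seed,
        "policy": {**asdict(config.policy),
                   "excluded_types": sorted(config.policy.excluded_types)},
        "truth_policy": {**asdict(config.truth_policy),
                         "excluded_types": sorted(config.truth_policy.excluded_types)},
        "criteria": asdict(config.criteria),
        "bins": list(config.bins.boundaries),
    }
    (out / "run_config.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
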