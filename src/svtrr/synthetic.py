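"""Synthetic truth sets, tandem-repeat regions, derived callsets and trios
with fully known ground truth.

The generator emulates the statistical structure the evaluation assumes: a
truth set of insertions and deletions >= 50 bp spanning four size bins,
tandem-repeat regions (TRRs) covering a configurable genome fraction
(default 10%, the approximate TRR abundance in the human genome), SVs
enriched inside TRRs, per-pipeline callsets derived from the truth with
planted false negatives, false positives, breakpoint jitter and IMPRECISE
flags, and trios with planted inheritance and de novo structure.

Layout guarantees, which make parameter recovery an exact integer identity
rather than a statistical tolerance:

* the genome is divided into slots (default 10 kb) and every planted record
  gets its own slot, so distinct records are always farther apart than the
  200 bp insertion window and share zero deletion overlap;
* each slot's first ``trr_genome_fraction`` fraction is a TRR interval, so
  the TRR genome fraction is exact and in/out placement is controlled;
* breakpoint jitter is clamped to the recoverable range for the default
  matching criteria (|dpos| <= 200 for insertions; endpoint shifts <= L/8
  for a deletion of span L, keeping reciprocal overlap >= 0.75), so every
  emitted true call still matches its own truth record and nothing else;
* records planted as unrecoverable are relocated to a fresh slot, i.e. they
  are false positives by construction and their truth partner a false
  negative.

Everything is integer coordinate arithmetic driven by
``numpy.random.default_rng``, hence deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .regions import Region, RegionSet, write_bed
from .sv_io import SVRecord, write_sv_vcf

__all__ = [
    "CallsetProfile",
    "TrioConfig",
    "SyntheticConfig",
    "SyntheticTruthBundle",
    "generate_truth",
    "derive_callset",
    "generate_bundle",
    "generate_trio",
    "write_bundle",
    "tier1_like_records",
    "DEFAULT_PIPELINES",
]

#: Default size-bin sampling ranges (bp), matching the standard report bins.
_BIN_RANGES = ((50, 100), (100, 300), (300, 1000), (1000, 5001))

_INS_CLAMP = 200  # recoverable insertion jitter bound = default match window


@dataclass(frozen=True)
class CallsetProfile:
    """Error model for one derived callset.

    fn_rate_in_trr optionally overrides fn_rate inside TRRs (detection is
    typically worse there); unrecoverable_rate relocates that fraction of
    surviving calls beyond the match window (counted FP, partner FN).
    """

    name: str
    fn_rate: float = 0.0
    fp_rate: float = 0.0
    breakpoint_jitter_sd: float = 0.0
    size_jitter_fraction: float = 0.0
    imprecise_rate: float = 0.0
    unrecoverable_rate: float = 0.0
    fn_rate_in_trr: float | None = None


@dataclass(frozen=True)
class TrioConfig:
    """Trio structure: fraction of son's calls that are de novo, fraction of
    each parent's callset transmitted to the son, and son breakpoint jitter."""

    denovo_rate: float = 0.1
    parent_inheritance_rate: float = 0.5
    jitter_sd: float = 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic genome and callsets.

    Defaults: a 3 x 10 Mb genome on a 10 kb slot grid; 1,000 truth SVs with
    57% insertions (the truth-set insertion fraction of a typical human
    benchmark); sizes drawn mostly small and decreasing with size; TRRs
    covering 10% of the genome with an SV enrichment of 4.4, which places
    about one third of SVs inside TRRs as long-read callsets show.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 10_000_000
    slot_size: int = 10_000
    n_truth: int = 1000
    ins_fraction: float = 0.57
    size_mix: tuple = (0.50, 0.30, 0.15, 0.05)
    trr_genome_fraction: float = 0.10
    trr_sv_enrichment: float = 4.4
    callsets: tuple = ()
    trio: TrioConfig | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.size_mix) - 1.0) > 1e-9 or len(self.size_mix) != 4:
            raise ValueError("size_mix must be 4 probabilities summing to 1")
        for rate in (self.ins_fraction, self.trr_genome_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("fractions must be in [0, 1]")

    @property
    def p_in_trr(self) -> float:
        """Per-SV probability of TRR placement implied by the enrichment."""
        g, e = self.trr_genome_fraction, self.trr_sv_enrichment
        if g == 0.0:
            return 0.0
        return e * g / (e * g + (1.0 - g))


#: Error profiles loosely shaped like the three long-read pipelines the
#: evaluation design targets: two precise callers with moderate recall (one
#: flagging many calls IMPRECISE) and a noisier caller that misses half the
#: truth, degrades further inside TRRs, and adds many false positives.
DEFAULT_PIPELINES = (
    CallsetProfile("pbsv_like", fn_rate=0.28, fp_rate=0.08,
                   breakpoint_jitter_sd=20, imprecise_rate=0.03,
                   fn_rate_in_trr=0.52),
    CallsetProfile("sniffles_like", fn_rate=0.32, fp_rate=0.06,
                   breakpoint_jitter_sd=30, imprecise_rate=0.45,
                   fn_rate_in_trr=0.55),
    CallsetProfile("pbhoney_like", fn_rate=0.50, fp_rate=0.30,
                   breakpoint_jitter_sd=40, fn_rate_in_trr=0.80),
)


class _Geometry:
    """Slot bookkeeping: allocation and in/out-of-TRR placement."""

    def __init__(self, config: SyntheticConfig, rng: np.random.Generator):
        self.config = config
        s = config.slot_size
        self.trr_len = int(round(config.trr_genome_fraction * s))
        self.max_span = _BIN_RANGES[-1][1] - 1
        out_room = s - self.trr_len - 500 - self.max_span
        if out_room < 1:
            raise ValueError(
                f"slot_size {s} too small for SVs up to {self.max_span} bp "
                f"with a {self.trr_len} bp TRR sub-interval"
            )
        if self.trr_len and self.trr_len < 20:
            raise ValueError("trr_genome_fraction too small to host breakpoints")
        chroms = [str(i + 1) for i in range(config.n_chroms)]
        per_chrom = config.chrom_length // s
        self.slots = [(c, i * s) for c in chroms for i in range(per_chrom)]
        order = rng.permutation(len(self.slots))
        self._free = [self.slots[i] for i in order]
        self.chroms = chroms

    def n_free(self) -> int:
        return len(self._free)

    def take_slot(self) -> tuple:
        if not self._free:
            raise ValueError("genome exhausted: too many records for slot grid")
        return self._free.pop()

    def trr_regions(self) -> RegionSet:
        trr = RegionSet("TRR")
        if self.trr_len == 0:
            return trr
        for chrom, start in self.slots:
            trr.add(Region(chrom, start, start + self.trr_len, "Simple_repeat"))
        return trr

    def bench_regions(self) -> RegionSet:
        bench = RegionSet("benchmark")
        for chrom in self.chroms:
            bench.add(Region(chrom, 0, self.config.chrom_length, "bench"))
        return bench

    def place(self, rng, slot, svtype: str, svlen: int, in_trr: bool) -> int:
        """1-based breakpoint position inside the slot for the wanted status."""
        chrom, start = slot
        span = svlen if svtype == "DEL" else 0
        if in_trr:
            if self.trr_len == 0:
                raise ValueError("cannot place in TRR: trr_genome_fraction is 0")
            margin = min(250, max(1, self.trr_len // 4))
            lo = start + margin
            hi = start + self.trr_len - margin
        else:
            lo = start + self.trr_len + 250
            hi = start + self.config.slot_size - 250 - span
        if hi <= lo:
            raise ValueError("slot too crowded; reduce SV sizes or TRR fraction")
        pos0 = int(rng.integers(lo, hi))
        return pos0 + 1


@dataclass
class SyntheticTruthBundle:
    """Truth records, region sets, derived callsets and expected outcomes.

    ``expected`` is recomputable from the per-record provenance labels
    (``extras['label']``: ``TP:<truth id>``, ``UNREC:<truth id>``, ``FP``).
    """

    config: SyntheticConfig
    truth: list
    trr: RegionSet
    bench: RegionSet
    callsets: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)
    trio: dict | None = None
    _geometry: _Geometry | None = None


def _sample_svlen(rng, size_mix) -> int:
    bin_idx = int(rng.choice(len(_BIN_RANGES), p=np.asarray(size_mix)))
    lo, hi = _BIN_RANGES[bin_idx]
    return int(rng.integers(lo, hi))


def generate_truth(config: SyntheticConfig) -> SyntheticTruthBundle:
    """Generate the truth callset plus TRR and benchmark region sets.

    Deterministic under ``config.seed``; raises when the slot grid cannot
    host ``n_truth`` records.
    """
    rng = np.random.default_rng(config.seed)
    geom = _Geometry(config, rng)
    if config.n_truth > geom.n_free():
        raise ValueError(
            f"n_truth={config.n_truth} exceeds the {geom.n_free()} available "
            f"slots ({config.n_chroms} x {config.chrom_length} bp / "
            f"{config.slot_size} bp)"
        )
    truth: list[SVRecord] = []
    for i in range(config.n_truth):
        slot = geom.take_slot()
        svtype = "INS" if rng.random() < config.ins_fraction else "DEL"
        svlen = _sample_svlen(rng, config.size_mix)
        in_trr = bool(rng.random() < config.p_in_trr)
        pos = geom.place(rng, slot, svtype, svlen, in_trr)
        truth.append(SVRecord(
            chrom=slot[0], pos=pos,
            end=pos if svtype == "INS" else pos + svlen,
            svtype=svtype, svlen=svlen, filter_status="PASS",
            source="truth",
            extras={"id": f"T{i:05d}", "planted_in_trr": in_trr},
        ))
    return SyntheticTruthBundle(
        config=config, truth=truth,
        trr=geom.trr_regions(), bench=geom.bench_regions(),
        _geometry=geom,
    )


def _clamped_jitter(rng, sd: float, bound: int) -> int:
    if sd <= 0 or bound <= 0:
        return 0
    return int(np.clip(round(rng.normal(0.0, sd)), -bound, bound))


def _jitter_del(rng, sd: float, pos: int, end: int) -> tuple[int, int]:
    """Jitter deletion endpoints within the recoverable envelope.

    Shifts are clamped to L/8 (reciprocal overlap stays >= 0.75 under the
    default criteria) and coupled so the jittered span never drops below
    the 50 bp reporting floor.
    """
    svlen = end - pos
    bound = svlen // 8
    d1 = _clamped_jitter(rng, sd, bound)
    d2 = _clamped_jitter(rng, sd, bound)
    d2 = max(d2, d1 - (svlen - 50))  # keep end' - pos' >= 50
    return pos + d1, end + d2


def derive_callset(bundle: SyntheticTruthBundle, profile: CallsetProfile,
                   seed: int = 0) -> list:
    """Derive one labeled callset from the bundle's truth under ``profile``.

    Every emitted record carries a provenance label in ``extras['label']``.
    The callset is registered on the bundle and the expected-outcome table
    refreshed.
    """
    rng = np.random.default_rng(seed)
    geom = bundle._geometry
    cfg = bundle.config
    records: list[SVRecord] = []
    k = 0
    for truth_rec in bundle.truth:
        in_trr = truth_rec.extras["planted_in_trr"]
        fn = profile.fn_rate_in_trr if (in_trr and profile.fn_rate_in_trr is not None) \
            else profile.fn_rate
        if rng.random() < fn:
            continue
        tid = truth_rec.extras["id"]
        imprecise = rng.random() < profile.imprecise_rate
        if rng.random() < profile.unrecoverable_rate:
            rec = _fresh_record(rng, geom, cfg, truth_rec.svtype, truth_rec.svlen,
                                in_trr, profile.name, f"UNREC:{tid}", k, imprecise)
        elif truth_rec.svtype == "INS":
            dpos = _clamped_jitter(rng, profile.breakpoint_jitter_sd, _INS_CLAMP)
            svlen = truth_rec.svlen
            if profile.size_jitter_fraction > 0:
                svlen = max(50, int(round(
                    svlen * (1.0 + rng.normal(0.0, profile.size_jitter_fraction)))))
            pos = truth_rec.pos + dpos
            rec = SVRecord(truth_rec.chrom, pos, pos, "INS", svlen,
                           precise=not imprecise, source=profile.name,
                           extras={"id": f"{profile.name}_{k:05d}",
                                   "label": f"TP:{tid}"})
        else:
            pos, end = _jitter_del(rng, profile.breakpoint_jitter_sd,
                                   truth_rec.pos, truth_rec.end)
            rec = SVRecord(truth_rec.chrom, pos, end, "DEL", end - pos,
                           precise=not imprecise, source=profile.name,
                           extras={"id": f"{profile.name}_{k:05d}",
                                   "label": f"TP:{tid}"})
        records.append(rec)
        k += 1

    n_fp = int(round(profile.fp_rate * cfg.n_truth))
    for _ in range(n_fp):
        svtype = "INS" if rng.random() < cfg.ins_fraction else "DEL"
        svlen = _sample_svlen(rng, cfg.size_mix)
        in_trr = bool(rng.random() < cfg.p_in_trr)
        imprecise = rng.random() < profile.imprecise_rate
        records.append(_fresh_record(rng, geom, cfg, svtype, svlen, in_trr,
                                     profile.name, "FP", k, imprecise))
        k += 1

    bundle.callsets[profile.name] = records
    bundle.expected = compute_expected(bundle)
    return records


def _fresh_record(rng, geom, cfg, svtype, svlen, in_trr, source, label, k,
                  imprecise) -> SVRecord:
    if in_trr and geom.trr_len == 0:
        in_trr = False
    slot = geom.take_slot()
    pos = geom.place(rng, slot, svtype, svlen, in_trr)
    return SVRecord(slot[0], pos, pos if svtype == "INS" else pos + svlen,
                    svtype, svlen, precise=not imprecise, source=source,
                    extras={"id": f"{source}_{k:05d}", "label": label,
                            "planted_in_trr": in_trr})


def compute_expected(bundle: SyntheticTruthBundle) -> dict:
    """Expected benchmark outcome per callset, recomputed from labels.

    Per callset: global tp/fp/fn and precision/recall, plus per-stratum
    counts keyed ``"{svtype}|{trr_status}|{size_bin}"`` (true positives and
    false negatives follow the truth record's planted stratum; false
    positives their own).
    """
    from .metrics import SizeBins, size_bin  # local import to avoid cycle

    bins = SizeBins()
    n_truth = len(bundle.truth)
    expected: dict = {"n_truth": n_truth, "callsets": {}}
    for name, records in bundle.callsets.items():
        tp_of = {rec.extras["label"].split(":", 1)[1]
                 for rec in records if rec.extras.get("label", "").startswith("TP:")}
        tp = len(tp_of)
        fp = len(records) - tp
        fn = n_truth - tp
        strata: dict[str, dict] = {}

        def bump(key: str, slot: str) -> None:
            strata.setdefault(key, {"tp": 0, "fp": 0, "fn": 0})[slot] += 1

        for truth_rec in bundle.truth:
            status = "in_trr" if truth_rec.extras["planted_in_trr"] else "outside_trr"
            key = f"{truth_rec.svtype}|{status}|{size_bin(truth_rec, bins)}"
            bump(key, "tp" if truth_rec.extras["id"] in tp_of else "fn")
        for rec in records:
            if rec.extras.get("label", "").startswith("TP:"):
                continue
            status = "in_trr" if rec.extras.get("planted_in_trr") else "outside_trr"
            bump(f"{rec.svtype}|{status}|{size_bin(rec, bins)}", "fp")

        expected["callsets"][name] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": tp / (tp + fp) if tp + fp else None,
            "recall": tp / (tp + fn) if tp + fn else None,
            "strata": strata,
        }
    return expected


def generate_bundle(config: SyntheticConfig) -> SyntheticTruthBundle:
    """Truth plus one derived callset per ``config.callsets`` profile."""
    bundle = generate_truth(config)
    for i, profile in enumerate(config.callsets):
        derive_callset(bundle, profile, seed=config.seed * 100 + i + 1)
    if config.trio is not None:
        bundle.trio = generate_trio(config, seed=config.seed * 100 + 99)
    return bundle


def generate_trio(config: SyntheticConfig, seed: int | None = None) -> dict:
    """Son/father/mother callsets with planted inheritance and de novo calls.

    The son's ``config.n_truth`` records are composed of a de novo pool
    (fraction ``trio.denovo_rate``, placed on fresh slots absent from both
    parents) and inherited copies of parental records (with recoverable
    jitter ``trio.jitter_sd``). Each parent additionally carries
    non-transmitted records so that the transmitted fraction of its callset
    equals ``trio.parent_inheritance_rate``.
    """
    trio_cfg = config.trio or TrioConfig()
    if not 0.0 < trio_cfg.parent_inheritance_rate <= 1.0:
        raise ValueError("parent_inheritance_rate must be in (0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    geom = _Geometry(config, rng)

    n_son = config.n_truth
    n_dn = int(round(trio_cfg.denovo_rate * n_son))
    n_inherited = n_son - n_dn
    n_f = (n_inherited + 1) // 2
    n_m = n_inherited - n_f

    def make_pool(n: int, source: str, label: str) -> list:
        pool = []
        for i in range(n):
            slot = geom.take_slot()
            svtype = "INS" if rng.random() < config.ins_fraction else "DEL"
            svlen = _sample_svlen(rng, config.size_mix)
            in_trr = bool(rng.random() < config.p_in_trr)
            pos = geom.place(rng, slot, svtype, svlen, in_trr)
            pool.append(SVRecord(
                slot[0], pos, pos if svtype == "INS" else pos + svlen,
                svtype, svlen, source=source,
                extras={"id": f"{source}_{i:05d}", "label": label,
                        "planted_in_trr": in_trr}))
        return pool

    father_pool = make_pool(n_f, "father", "TRANSMITTED")
    mother_pool = make_pool(n_m, "mother", "TRANSMITTED")
    denovo_pool = make_pool(n_dn, "son", "DENOVO")

    def inherit(rec: SVRecord, idx: int) -> SVRecord:
        if rec.svtype == "INS":
            dpos = _clamped_jitter(rng, trio_cfg.jitter_sd, _INS_CLAMP)
            pos, end = rec.pos + dpos, rec.pos + dpos
        else:
            pos, end = _jitter_del(rng, trio_cfg.jitter_sd, rec.pos, rec.end)
        return replace(rec, pos=pos, end=end,
                       svlen=rec.svlen if rec.svtype == "INS" else end - pos,
                       source="son",
                       extras={**rec.extras, "id": f"son_inh_{idx:05d}",
                               "label": f"INHERITED:{rec.extras['id']}"})

    son = [inherit(r, i) for i, r in enumerate(father_pool + mother_pool)]
    son += denovo_pool

    r = trio_cfg.parent_inheritance_rate
    father = father_pool + make_pool(int(round(n_f * (1.0 - r) / r)),
                                     "father", "PARENT_ONLY")
    mother = mother_pool + make_pool(int(round(n_m * (1.0 - r) / r)),
                                     "mother", "PARENT_ONLY")
    return {
        "son": son, "father": father, "mother": mother,
        "trr": geom.trr_regions(), "bench": geom.bench_regions(),
        "expected": {"n_son": n_son, "n_denovo": n_dn,
                     "denovo_rate": n_dn / n_son if n_son else None},
    }


def tier1_like_records(n_pass_ins: int = 7281, n_pass_del: int = 5464,
                       n_nonpass: int = 500, seed: int = 0) -> list:
    """A truth-set-shaped callset with given PASS composition.

    Mimics the shape of a Tier 1 germline SV benchmark: isolated,
    sequence-resolved PASS insertions and deletions >= 50 bp plus non-PASS
    records, spread over the 24 canonical chromosomes. Intended for
    filter-accounting checks, not for matching.
    """
    rng = np.random.default_rng(seed)
    chroms = [str(i) for i in range(1, 23)] + ["X", "Y"]
    specs = ([("INS", "PASS")] * n_pass_ins + [("DEL", "PASS")] * n_pass_del
             + [("INS" if i % 2 else "DEL", "LongReadHomRef")
                for i in range(n_nonpass)])
    records = []
    cursors = {c: 1000 for c in chroms}
    for i, (svtype, filt) in enumerate(specs):
        chrom = chroms[i % len(chroms)]
        svlen = int(rng.integers(50, 2000))
        pos = cursors[chrom]
        cursors[chrom] = pos + svlen + 500
        records.append(SVRecord(
            chrom, pos, pos if svtype == "INS" else pos + svlen,
            svtype, svlen, filter_status=filt, source="tier1_like",
            extras={"id": f"B{i:05d}"}))
    return records


def write_bundle(bundle: SyntheticTruthBundle, directory) -> None:
    """Write truth.vcf, one VCF per callset, trr.bed, bench.bed, expected.json.

    Re-ingesting the files through the VCF/BED readers reproduces the
    in-memory records (coordinates, type, size, flags, ids and provenance
    labels, the latter via the PROV INFO tag).
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create {directory}: {exc}") from exc
    write_sv_vcf(bundle.truth, directory / "truth.vcf")
    for name, records in bundle.callsets.items():
        write_sv_vcf(records, directory / f"{name}.vcf")
    write_bed(bundle.trr, directory / "trr.bed")
    write_bed(bundle.bench, directory / "bench.bed")
    payload = {"config": asdict(bundle.config), "expected": bundle.expected}
    (directory / "expected.json").write_text(json.dumps(payload, indent=2))
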