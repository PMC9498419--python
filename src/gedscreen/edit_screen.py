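"""Three-stage filter for artificial gene-editing candidates.

Stage 1 selects INDEL calls whose zygosity is HomoALT or compound
heterozygous (ALT1/ALT2) — the classes a CRISPR/Cas9 knockout is expected
to produce, and the only ones distinguishable from natural variation here.
Stage 2 removes variants already catalogued in the population; stage 3
removes variants supported only by low sequence depth. What remains is
reported as candidate artificial edits with a full audit trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .formats_io import normalize_key, normalize_variant
from .genotyping import classify_zygosity
from .types import (
    DepthRecord,
    KnownVariantKey,
    TargetRegion,
    VariantRecord,
    Zygosity,
)

log = logging.getLogger(__name__)

STATUS_CANDIDATE = "candidate"
STATUS_KNOWN = "excluded_known"
STATUS_LOW_DEPTH = "excluded_low_depth"


@dataclass(frozen=True)
class ScreenConfig:
    min_candidate_depth: int = 50  # strict >, same convention as genotype calling
    coding_only: bool = False
    blind_spot_margin: int = 25  # bp from an amplicon end
    blind_spot_min_size: int = 50  # INDELs longer than this can be soft-clipped away


@dataclass
class CandidateVariant:
    """One (sample, site) artificial-edit candidate with its audit status."""

    sample: str
    chrom: str
    pos: int  # normalized, 1-based
    keys: tuple[KnownVariantKey, ...]  # one per called non-reference allele
    alleles: str  # display form REF>ALT[,ALT2]
    zygosity: Zygosity
    var_class: str  # {SNV, INDEL}
    depth: Optional[int]
    coding: bool
    status: str = STATUS_CANDIDATE
    notes: tuple[str, ...] = ()

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class ScreenReport:
    """Audit of the three filtering stages, per sample and per site."""

    samples: list[str]
    totals: dict[str, dict[str, int]]  # sample -> {variants, snvs, indels}
    stage1: list[CandidateVariant] = field(default_factory=list)
    excluded_known: list[CandidateVariant] = field(default_factory=list)
    excluded_low_depth: list[CandidateVariant] = field(default_factory=list)
    final: list[CandidateVariant] = field(default_factory=list)
    annotations: list[dict] = field(default_factory=list)

    def check_conservation(self) -> None:
        assert len(self.stage1) == (
            len(self.excluded_known) + len(self.excluded_low_depth) + len(self.final)
        ), "screen stages do not conserve candidates"

    def _sites(self, candidates: Iterable[CandidateVariant]) -> set[tuple[str, int]]:
        return {c.site for c in candidates}

    @property
    def stage1_loci(self) -> int:
        return len(self._sites(self.stage1))

    @property
    def final_loci(self) -> int:
        return len(self._sites(self.final))

    @property
    def final_sites(self) -> set[tuple[str, int]]:
        return self._sites(self.final)


def is_indel(record: VariantRecord, alt_index: int) -> bool:
    """True iff the ALT at 1-based allele index differs from REF in length."""
    return len(record.ref) != len(record.alts[alt_index - 1])


def _overlaps_any(regions: Sequence[TargetRegion], chrom: str, pos: int) -> bool:
    return any(r.chrom == chrom and r.contains(pos) for r in regions)


def _site_depth(
    record: VariantRecord, sample: str, depth_lookup: dict
) -> Optional[int]:
    depth = depth_lookup.get((record.chrom, record.pos, sample))
    if depth is not None:
        return depth
    call = record.calls.get(sample)
    return call.dp if call is not None else None


def _candidate_from_call(
    record: VariantRecord,
    sample: str,
    gt: tuple,
    exons: Sequence[TargetRegion],
    depth_lookup: dict,
) -> Optional[CandidateVariant]:
    zygosity = classify_zygosity(gt)
    if zygosity not in (Zygosity.HOMO_ALT, Zygosity.COMPOUND_HET):
        return None
    alt_indices = sorted({i for i in gt if i != 0})
    if not any(is_indel(record, i) for i in alt_indices):
        return None  # SNV-only genotype: never an edit candidate
    keys = tuple(normalize_key(record.chrom, record.pos, record.ref, record.alts[i - 1])
                 for i in alt_indices)
    alleles = f"{record.ref}>{','.join(record.alts[i - 1] for i in alt_indices)}"
    return CandidateVariant(
        sample=sample,
        chrom=record.chrom,
        pos=record.pos,
        keys=keys,
        alleles=alleles,
        zygosity=zygosity,
        var_class="INDEL",
        depth=_site_depth(record, sample, depth_lookup),
        coding=_overlaps_any(exons, record.chrom, record.pos),
    )


def _possible_compounds(
    records: Sequence[VariantRecord],
    sample: str,
    exons: Sequence[TargetRegion],
    depth_lookup: dict,
) -> list[CandidateVariant]:
    """Pairs of overlapping heterozygous INDEL records in one sample.

    Callers sometimes emit a compound heterozygote as two Het records at
    overlapping positions; these are included at stage 1 flagged
    "possible-compound" (conservative screening).
    """
    hets = []
    for rec in records:
        call = rec.calls.get(sample)
        if call is None or classify_zygosity(call.gt) is not Zygosity.HET:
            continue
        alt_idx = next(i for i in call.gt if i)
        if is_indel(rec, alt_idx):
            hets.append((rec, alt_idx))
    out = []
    for i in range(len(hets)):
        for j in range(i + 1, len(hets)):
            (a, ai), (b, bi) = hets[i], hets[j]
            if a.chrom != b.chrom:
                continue
            a_span = (a.pos, a.pos + len(a.ref) - 1)
            b_span = (b.pos, b.pos + len(b.ref) - 1)
            if a_span[0] <= b_span[1] and b_span[0] <= a_span[1]:
                keys = (
                    normalize_key(a.chrom, a.pos, a.ref, a.alts[ai - 1]),
                    normalize_key(b.chrom, b.pos, b.ref, b.alts[bi - 1]),
                )
                depths = [d for d in (_site_depth(a, sample, depth_lookup),
                                      _site_depth(b, sample, depth_lookup)) if d is not None]
                out.append(
                    CandidateVariant(
                        sample=sample,
                        chrom=a.chrom,
                        pos=min(a.pos, b.pos),
                        keys=keys,
                        alleles=f"{a.ref}>{a.alts[ai - 1]}|{b.ref}>{b.alts[bi - 1]}",
                        zygosity=Zygosity.COMPOUND_HET,
                        var_class="INDEL",
                        depth=min(depths) if depths else None,
                        coding=_overlaps_any(exons, a.chrom, a.pos),
                        notes=("possible-compound",),
                    )
                )
    return out


def select_candidates(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    exons: Sequence[TargetRegion],
    depths: Iterable[DepthRecord] = (),
    config: ScreenConfig = ScreenConfig(),
) -> list[CandidateVariant]:
    """Stage 1: HomoALT / compound-het INDEL calls across the given samples."""
    depth_lookup = {(d.chrom, d.pos, d.sample): d.depth for d in depths}
    normalized = [normalize_variant(r) for r in records]
    out = []
    for rec in normalized:
        for sample in samples:
            call = rec.calls.get(sample)
            if call is None or call.is_missing:
                continue
            cand = _candidate_from_call(rec, sample, call.gt, exons, depth_lookup)
            if cand is not None:
                out.append(cand)
    for sample in samples:
        out.extend(_possible_compounds(normalized, sample, exons, depth_lookup))
    if config.coding_only:
        out = [c for c in out if c.coding]
    return out


def filter_known(
    candidates: Sequence[CandidateVariant], known: set[KnownVariantKey]
) -> tuple[list[CandidateVariant], list[CandidateVariant]]:
    """Stage 2: partition into (retained, excluded-as-population-variant).

    A candidate is excluded when *every* called non-reference allele is in
    the catalogue — a compound heterozygote carrying one novel allele still
    contains something unseen in the population.
    """
    retained, excluded = [], []
    for cand in candidates:
        if all(k in known for k in cand.keys):
            excluded.append(replace(cand, status=STATUS_KNOWN))
        else:
            retained.append(cand)
    return retained, excluded


def filter_low_depth(
    candidates: Sequence[CandidateVariant], threshold: int
) -> tuple[list[CandidateVariant], list[CandidateVariant]]:
    """Stage 3: partition by site depth (strict >threshold retained)."""
    retained, excluded = [], []
    for cand in candidates:
        depth = cand.depth
        if depth is None:
            log.warning("candidate %s:%s has no depth record; treated as depth 0",
                        cand.chrom, cand.pos)
            cand = replace(cand, depth=0, notes=cand.notes + ("no-depth-record",))
            depth = 0
        if depth <= threshold:
            excluded.append(replace(cand, status=STATUS_LOW_DEPTH))
        else:
            retained.append(cand)
    return retained, excluded


def annotate_blind_spots(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    amplicons: Sequence[TargetRegion],
    config: ScreenConfig = ScreenConfig(),
) -> list[dict]:
    """Flag large INDELs whose ends fall near an amplicon boundary.

    Variant callers soft-clip read ends, so a long deletion hugging an
    amplicon end can be silently missed upstream; any such variant that
    *was* called is annotated as sitting in the blind-spot zone, and its
    non-candidate status (e.g. heterozygous) is stated. Informational only.
    """
    notes = []
    for rec in (normalize_variant(r) for r in records):
        for alt_i in range(1, len(rec.alts) + 1):
            size = abs(len(rec.ref) - len(rec.alts[alt_i - 1]))
            if size <= config.blind_spot_min_size:
                continue
            span = (rec.pos, rec.pos + len(rec.ref) - 1)
            for amp in amplicons:
                if amp.chrom != rec.chrom or amp.kind != "amplicon":
                    continue
                near = min(
                    abs(span[0] - (amp.start + 1)), abs(amp.end - span[0]),
                    abs(span[1] - (amp.start + 1)), abs(amp.end - span[1]),
                )
                if near <= config.blind_spot_margin:
                    for sample in samples:
                        call = rec.calls.get(sample)
                        if call is None or call.is_missing or alt_i not in call.gt:
                            continue
                        zyg = classify_zygosity(call.gt)
                        status = (
                            "non-candidate (Het)" if zyg is Zygosity.HET
                            else f"stage-1 class ({zyg.value})"
                        )
                        notes.append(
                            {
                                "chrom": rec.chrom,
                                "pos": rec.pos,
                                "sample": sample,
                                "size_bp": size,
                                "zygosity": zyg.value,
                                "status": status,
                                "note": "amplicon-end blind spot",
                                "amplicon": amp.name,
                            }
                        )
                    break
    return notes


def _totals(records: Sequence[VariantRecord], samples: Sequence[str]) -> dict[str, dict[str, int]]:
    totals = {}
    for sample in samples:
        n_var = n_snv = n_indel = 0
        for rec in records:
            call = rec.calls.get(sample)
            if call is None or call.is_missing:
                continue
            alt_indices = {i for i in call.gt if i}
            if not alt_indices:
                continue
            n_var += 1
            if any(is_indel(rec, i) for i in alt_indices):
                n_indel += 1
            else:
                n_snv += 1
        totals[sample] = {"variants": n_var, "snvs": n_snv, "indels": n_indel}
    return totals


def screen_samples(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    exons: Sequence[TargetRegion],
    amplicons: Sequence[TargetRegion],
    known: set[KnownVariantKey],
    depths: Iterable[DepthRecord] = (),
    config: ScreenConfig = ScreenConfig(),
) -> ScreenReport:
    """Run stages 1→2→3 over a sample set and assemble the audit report."""
    depths = list(depths)
    stage1 = select_candidates(records, samples, exons, depths, config)
    after_known, excluded_known = filter_known(stage1, known)
    final, excluded_low = filter_low_depth(after_known, config.min_candidate_depth)
    report = ScreenReport(
        samples=list(samples),
        totals=_totals([normalize_variant(r) for r in records], samples),
        stage1=stage1,
        excluded_known=excluded_known,
        excluded_low_depth=excluded_low,
        final=final,
        annotations=annotate_blind_spots(records, samples, amplicons, config),
    )
    report.check_conservation()
    return report


def screen_sample(
    records: Sequence[VariantRecord],
    sample: str,
    exons: Sequence[TargetRegion],
    amplicons: Sequence[TargetRegion],
    known: set[KnownVariantKey],
    depths: Iterable[DepthRecord] = (),
    config: ScreenConfig = ScreenConfig(),
) -> ScreenReport:
    return screen_samples(records, [sample], exons, amplicons, known, depths, config)


def report_frame(report: ScreenReport) -> pd.DataFrame:
    rows = [
        {
            "sample": c.sample,
            "chrom": c.chrom,
            "pos": c.pos,
            "alleles": c.alleles,
            "zygosity": c.zygosity.value,
            "class": c.var_class,
            "depth": "." if c.depth is None else c.depth,
            "coding": c.coding,
            "status": c.status,
            "notes": ";".join(c.notes),
        }
        for c in (*report.final, *report.excluded_known, *report.excluded_low_depth)
    ]
    return pd.DataFrame(rows)


def write_screen_report(report: ScreenReport, tsv_path: str | Path) -> Path:
    report_frame(report).to_csv(tsv_path, sep="\t", index=False)
    return Path(tsv_path)


def report_json(report: ScreenReport) -> dict:
    return {
        "samples": report.samples,
        "totals": report.totals,
        "stage1_candidates": len(report.stage1),
        "stage1_loci": report.stage1_loci,
        "excluded_known": len(report.excluded_known),
        "excluded_low_depth": len(report.excluded_low_depth),
        "final_candidates": len(report.final),
        "final_loci": report.final_loci,
        "final": [
            row
            for row in report_frame(report).to_dict(orient="records")
            if row["status"] == STATUS_CANDIDATE
        ]
        if report.final
        else [],
        "annotations": report.annotations,
    }
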