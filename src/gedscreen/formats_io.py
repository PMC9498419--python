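"""Readers/writers for every external format and variant-key normalization.

VCF parsing and writing go through :mod:`pysam`; a light pre-scan supplies
line-numbered diagnostics for the malformations htslib reports opaquely
(column counts, genotype separators, a FORMAT without GT). Tabular inputs
(panel, pedigree, depth, known variants) are read with pandas.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd
import pysam

from .types import (
    DepthRecord,
    FormatError,
    KnownVariantKey,
    PanelLocus,
    PedigreeEntry,
    SampleCall,
    TargetRegion,
    ValidationError,
    VariantRecord,
)

log = logging.getLogger(__name__)

_VCF_FIXED_COLS = 9  # CHROM..FORMAT before sample columns


# ---------------------------------------------------------------------------
# VCF


def _prescan_vcf(path: str | Path) -> None:
    """Raise FormatError with a line number for malformations pysam reports poorly."""
    n_columns = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1 and not line.startswith("##fileformat=VCF"):
                raise FormatError(f"{path}: line 1: missing ##fileformat=VCF header")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < _VCF_FIXED_COLS + 1:
                    raise FormatError(f"{path}: line {lineno}: header has no sample columns")
                n_columns = len(fields)
                continue
            if n_columns is None:
                raise FormatError(f"{path}: line {lineno}: data before #CHROM header")
            if len(fields) != n_columns:
                raise FormatError(
                    f"{path}: line {lineno}: expected {n_columns} columns, found {len(fields)}"
                )
            fmt_keys = fields[8].split(":")
            if "GT" not in fmt_keys:
                raise FormatError(f"{path}: line {lineno}: FORMAT lacks GT")
            gt_index = fmt_keys.index("GT")
            for sample_field in fields[_VCF_FIXED_COLS:]:
                gt = sample_field.split(":")[gt_index]
                if set(gt) - set("0123456789./|"):
                    raise FormatError(
                        f"{path}: line {lineno}: unsupported genotype separator in {gt!r}"
                    )


def read_vcf(path: str | Path) -> Tuple[list[VariantRecord], list[str]]:
    """Read a VCF (v4.x subset: GT required, AD/DP optional) into records.

    Multi-allelic sites are kept as single records with ordered ALTs.
    Missing AD/DP stay absent (None), never zero.
    """
    _prescan_vcf(path)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        records = []
        for rec in vcf:
            calls: dict[str, SampleCall] = {}
            for sample in samples:
                fmt = rec.samples[sample]
                gt = fmt.get("GT", (None, None))
                if gt is None or len(gt) != 2:
                    gt = (None, None)
                ad = fmt.get("AD")
                if ad is not None:
                    ad = None if all(a is None for a in ad) else tuple(int(a or 0) for a in ad)
                dp = fmt.get("DP")
                calls[sample] = SampleCall(
                    gt=tuple(gt), ad=ad, dp=None if dp is None else int(dp),
                    phased=bool(getattr(fmt, "phased", False)),
                )
            out = VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=tuple(rec.alts or ()),
                calls=calls,
                vid=rec.id or ".",
            )
            out.validate()
            records.append(out)
    return records, samples


def write_vcf(
    records: Sequence[VariantRecord], samples: Sequence[str], path: str | Path
) -> Path:
    """Write records (sorted by chrom, pos) so read_vcf round-trips exactly."""
    if not samples:
        raise ValidationError("write_vcf needs at least one sample")
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos))
    if [id(r) for r in ordered] != [id(r) for r in records]:
        log.info("write_vcf: records reordered into (chrom, pos) sort order")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    for chrom in dict.fromkeys(r.chrom for r in ordered):
        header.contigs.add(chrom)
    for sample in samples:
        header.add_sample(sample)
    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in ordered:
            rec.validate()
            out = vcf.new_record(
                contig=rec.chrom, start=rec.pos - 1, alleles=(rec.ref, *rec.alts), id=rec.vid
            )
            out.stop = rec.pos - 1 + len(rec.ref)
            for sample in samples:
                call = rec.calls.get(sample, SampleCall())
                out.samples[sample]["GT"] = call.gt
                out.samples[sample].phased = call.phased
                if call.ad is not None:
                    out.samples[sample]["AD"] = call.ad
                if call.dp is not None:
                    out.samples[sample]["DP"] = call.dp
            vcf.write(out)
    return path


# ---------------------------------------------------------------------------
# BED and tables


def read_bed(path: str | Path) -> list[TargetRegion]:
    """Read a 3+-column BED (0-based half-open).

    Column 4, when present, is the region name; an optional column 5 equal to
    ``exon`` or ``amplicon`` sets the region kind (default ``exon``).
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else "."
            kind = fields[4] if len(fields) > 4 and fields[4] in ("exon", "amplicon") else "exon"
            regions.append(TargetRegion(fields[0], start, end, name, kind))
    return regions


def read_panel_table(path: str | Path) -> list[PanelLocus]:
    """Read the parentage-SNV panel TSV (ID, chrom, pos, REF, ALT, REF frequency)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 6:
        raise FormatError(f"{path}: panel table needs >= 6 columns, found {df.shape[1]}")
    loci = []
    for row in df.itertuples(index=False):
        loci.append(
            PanelLocus(
                id=str(row[0]),
                chrom=str(row[1]),
                pos=int(row[2]),
                ref=str(row[3]),
                alt=str(row[4]),
                ref_freq=float(row[5]),
            )
        )
    return loci


def read_pedigree(path: str | Path) -> list[PedigreeEntry]:
    """Read a child/sire/dam TSV; '.' marks a missing parent."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    for row in df.itertuples(index=False):
        sire = None if row[1] in (".", "", None) else str(row[1])
        dam = None if row[2] in (".", "", None) else str(row[2])
        entries.append(PedigreeEntry(child=str(row[0]), sire=sire, dam=dam))
    return entries


def read_known_variants(path: str | Path) -> set[KnownVariantKey]:
    """Read the population-variant catalogue; keys are normalized on load."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        normalize_key(str(r[0]), int(r[1]), str(r[2]), str(r[3]))
        for r in df.itertuples(index=False)
    }


def read_depth_table(path: str | Path) -> list[DepthRecord]:
    """Read the per-base depth TSV (chrom, pos, sample, depth)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "sample": str, "depth": int})
    required = {"chrom", "pos", "sample", "depth"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: depth table needs columns {sorted(required)}")
    return [
        DepthRecord(row.chrom, int(row.pos), row.sample, int(row.depth))
        for row in df.itertuples(index=False)
    ]


def depth_frame(depths: Iterable[DepthRecord]) -> pd.DataFrame:
    """DepthRecords as a DataFrame (chrom, pos, sample, depth)."""
    return pd.DataFrame(
        [(d.chrom, d.pos, d.sample, d.depth) for d in depths],
        columns=["chrom", "pos", "sample", "depth"],
    )


def write_depth_table(depths: Iterable[DepthRecord], path: str | Path) -> Path:
    depth_frame(depths).to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Normalization


def _trim(pos: int, alleles: Tuple[str, ...]) -> Tuple[int, Tuple[str, ...]]:
    alleles = list(alleles)
    # shared suffix first, keeping at least one base per allele
    while all(len(a) > 1 for a in alleles) and len({a[-1] for a in alleles}) == 1:
        alleles = [a[:-1] for a in alleles]
    # then shared prefix, advancing pos
    while all(len(a) > 1 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        pos += 1
    return pos, tuple(alleles)


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> KnownVariantKey:
    """Normalize one (ref, alt) pair by suffix- then prefix-trimming.

    Context-free: no reference genome is consulted, so this is minimal-
    representation trimming, idempotent by construction.
    """
    pos, (ref, alt) = _trim(pos, (ref, alt))
    if ref == alt:
        raise ValidationError(f"{chrom}:{pos} {ref}>{alt} is not a variant after trimming")
    return KnownVariantKey(chrom, pos, ref, alt)


def normalize_variant(record: VariantRecord) -> VariantRecord:
    """Trim bases shared by REF and *all* ALTs so site keys are canonical.

    Joint trimming keeps multi-allelic sites intact (compound-heterozygote
    detection needs both ALTs at one record).
    """
    pos, alleles = _trim(record.pos, (record.ref, *record.alts))
    ref, alts = alleles[0], alleles[1:]
    if any(a == ref for a in alts):
        raise ValidationError(
            f"{record.chrom}:{record.pos}: an ALT equals REF after trimming"
        )
    return VariantRecord(
        chrom=record.chrom, pos=pos, ref=ref, alts=alts, calls=record.calls, vid=record.vid
    )


def variant_keys(record: VariantRecord) -> list[KnownVariantKey]:
    """Per-ALT normalized keys of a record (population-catalogue lookups)."""
    return [normalize_key(record.chrom, record.pos, record.ref, alt) for alt in record.alts]


def check_chrom_overlap(loci: Sequence[PanelLocus], records: Sequence[VariantRecord]) -> bool:
    """Warn when panel and VCF share no chromosome names (naming mismatch)."""
    if not loci or not records:
        return True
    shared = {l.chrom for l in loci} & {r.chrom for r in records}
    if not shared:
        log.warning("panel and VCF share zero chromosome names; check 'chr' prefixes")
    return bool(shared)


# ---------------------------------------------------------------------------
# Packaged reference tables


def packaged_path(name: str) -> Path:
    return Path(str(resources.files("gedscreen").joinpath("data", name)))


def load_packaged_panel() -> list[PanelLocus]:
    """The 120-SNV parentage panel with published REF-allele frequencies."""
    return read_panel_table(packaged_path("panel_table7.tsv"))


def load_packaged_panel_frame() -> pd.DataFrame:
    """Panel table including the published He/PE1/PE2 columns."""
    return pd.read_csv(packaged_path("panel_table7.tsv"), sep="\t")


def load_packaged_inheritance_counts() -> pd.DataFrame:
    """Published per-test consistent/inconsistent tallies (144- and 120-SNV panels)."""
    return pd.read_csv(packaged_path("table6_counts.tsv"), sep="\t")
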