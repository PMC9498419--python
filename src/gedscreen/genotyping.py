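"""Genotype calling on the parentage SNV panel.

The upstream caller only emits sites that differ from the reference, so a
panel locus with no VCF record is homozygous reference *provided the site
was actually sequenced*: REF/REF is called only when site depth strictly
exceeds the call-depth threshold (default 50), otherwise the locus is a
NoCall. Called genotypes are trusted as emitted; an allele-depth pattern
that contradicts the called class is flagged, never re-called.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import (
    DepthRecord,
    GedscreenError,
    GenotypeCall,
    GenotypeMatrix,
    GenotypePair,
    PanelLocus,
    VariantRecord,
    Zygosity,
)


class LocusMismatchError(GedscreenError):
    """VCF record alleles disagree with the panel definition of the locus."""


@dataclass(frozen=True)
class GenotypingThresholds:
    call_depth: int = 50  # strict >: depth 50 is a NoCall
    min_minor_allele_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.call_depth < 0:
            raise GedscreenError("call_depth must be >= 0")
        if not 0.0 <= self.min_minor_allele_fraction <= 0.5:
            raise GedscreenError("min_minor_allele_fraction must be in [0, 0.5]")


def classify_zygosity(gt: GenotypePair) -> Zygosity:
    """Map a pair of allele indices to its zygosity class (order-invariant)."""
    a, b = gt
    if a is None or b is None:
        return Zygosity.NO_CALL
    if a == b:
        return Zygosity.HOMO_REF if a == 0 else Zygosity.HOMO_ALT
    if 0 in (a, b):
        return Zygosity.HET
    return Zygosity.COMPOUND_HET


def _imbalance_flags(zygosity: Zygosity, ad: Optional[tuple], min_frac: float) -> tuple[str, ...]:
    """Flag calls whose allele-depth split contradicts the called class."""
    if ad is None or sum(ad) == 0:
        return ()
    minor = min(ad) / sum(ad) if len(ad) >= 2 else 0.0
    if zygosity is Zygosity.HET and minor < min_frac:
        return ("allele-imbalance",)
    if zygosity in (Zygosity.HOMO_REF, Zygosity.HOMO_ALT) and minor >= min_frac:
        return ("allele-imbalance",)
    return ()


def call_panel_genotype(
    locus: PanelLocus,
    record: Optional[VariantRecord],
    depth: Optional[DepthRecord],
    sample: str,
    thresholds: GenotypingThresholds = GenotypingThresholds(),
) -> GenotypeCall:
    """Call one sample at one panel locus from its VCF record and/or site depth.

    The depth table (BAM surrogate) takes precedence over the VCF DP field.
    """
    site_depth: Optional[int] = None
    if record is not None and sample in record.calls and record.calls[sample].dp is not None:
        site_depth = record.calls[sample].dp
    if depth is not None:
        site_depth = depth.depth

    if record is None:
        if site_depth is not None and site_depth > thresholds.call_depth:
            return GenotypeCall(
                sample, locus.id, Zygosity.HOMO_REF, (0, 0), depth=site_depth
            )
        return GenotypeCall(sample, locus.id, Zygosity.NO_CALL, depth=site_depth)

    if record.ref != locus.ref or (record.alts and locus.alt not in record.alts):
        raise LocusMismatchError(
            f"{locus.id}: panel defines {locus.ref}>{locus.alt} but VCF record has "
            f"{record.ref}>{','.join(record.alts)} at {record.chrom}:{record.pos}"
        )
    call = record.calls.get(sample)
    if call is None or call.is_missing:
        return GenotypeCall(sample, locus.id, Zygosity.NO_CALL, depth=site_depth)
    if site_depth is None or site_depth <= thresholds.call_depth:
        return GenotypeCall(sample, locus.id, Zygosity.NO_CALL, depth=site_depth)
    zygosity = classify_zygosity(call.gt)
    flags = _imbalance_flags(zygosity, call.ad, thresholds.min_minor_allele_fraction)
    return GenotypeCall(sample, locus.id, zygosity, call.gt, call.ad, site_depth, flags)


def build_genotype_matrix(
    panel: Sequence[PanelLocus],
    records: Iterable[VariantRecord],
    depths: Iterable[DepthRecord],
    samples: Sequence[str],
    thresholds: GenotypingThresholds = GenotypingThresholds(),
) -> GenotypeMatrix:
    """Assemble the samples x panel matrix from VCF records plus the depth table."""
    by_site = {(r.chrom, r.pos): r for r in records}
    by_depth = {(d.chrom, d.pos, d.sample): d for d in depths}
    matrix = GenotypeMatrix(samples, [l.id for l in panel])
    for locus in panel:
        record = by_site.get((locus.chrom, locus.pos))
        for sample in samples:
            depth = by_depth.get((locus.chrom, locus.pos, sample))
            rec = record if record is not None and sample in record.calls else None
            matrix.set(call_panel_genotype(locus, rec, depth, sample, thresholds))
    return matrix


def estimate_allele_freq(matrix: GenotypeMatrix, locus_id: str) -> float:
    """REF-allele frequency p = (2*HomoREF + Het) / (2*called); NoCalls excluded."""
    counts = {z: 0 for z in Zygosity}
    for call in matrix.column(locus_id):
        counts[call.zygosity] += 1
    called = sum(counts[z] for z in (Zygosity.HOMO_REF, Zygosity.HET, Zygosity.HOMO_ALT))
    if called == 0:
        raise GedscreenError(f"{locus_id}: allele frequency undefined (all NoCall)")
    return (2 * counts[Zygosity.HOMO_REF] + counts[Zygosity.HET]) / (2 * called)


def matrix_frame(matrix: GenotypeMatrix) -> pd.DataFrame:
    rows = [
        {
            "sample": c.sample,
            "locus": c.locus_id,
            "zygosity": c.zygosity.value,
            "alleles": "/".join("." if a is None else str(a) for a in c.alleles),
            "ad": "." if c.ad is None else ",".join(map(str, c.ad)),
            "depth": "." if c.depth is None else c.depth,
            "flags": ";".join(c.flags),
        }
        for c in matrix
    ]
    return pd.DataFrame(rows)


def write_genotype_matrix(matrix: GenotypeMatrix, path: str | Path) -> Path:
    matrix_frame(matrix).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a matrix TSV written by :func:`write_genotype_matrix`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    samples = list(dict.fromkeys(df["sample"]))
    loci = list(dict.fromkeys(df["locus"]))
    matrix = GenotypeMatrix(samples, loci)
    for row in df.itertuples(index=False):
        alleles = tuple(None if a == "." else int(a) for a in row.alleles.split("/"))
        matrix.set(
            GenotypeCall(
                sample=row.sample,
                locus_id=row.locus,
                zygosity=Zygosity(row.zygosity),
                alleles=alleles,
                ad=None if row.ad == "." else tuple(int(x) for x in row.ad.split(",")),
                depth=None if row.depth == "." else int(row.depth),
                flags=tuple(f for f in row.flags.split(";") if f),
            )
        )
    return matrix
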