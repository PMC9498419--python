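"""Core domain types shared across the screening and parentage pipeline.

All genomic positions are stored 1-based (VCF convention); BED input is
converted at the parsing boundary. Chromosome names are compared as exact
strings throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Sequence, Tuple

VALID_BASES = frozenset("ACGTN")


class GedscreenError(Exception):
    """Base class for all pipeline errors."""


class FormatError(GedscreenError):
    """Malformed input file."""


class ValidationError(GedscreenError):
    """Input is well-formed but violates a domain constraint."""


class Zygosity(enum.Enum):
    """Diploid genotype class at a single locus.

    CompoundHet denotes two *different* non-reference alleles (ALT1/ALT2),
    the second genotype class — besides HomoALT — treated as a plausible
    product of biallelic CRISPR/Cas9 editing.
    """

    HOMO_REF = "HomoREF"
    HET = "Het"
    HOMO_ALT = "HomoALT"
    COMPOUND_HET = "CompoundHet"
    NO_CALL = "NoCall"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


GenotypePair = Tuple[Optional[int], Optional[int]]


@dataclass
class SampleCall:
    """Per-sample FORMAT content of one VCF record.

    ``gt`` holds allele indices (0 = REF, 1.. = ALT, None = missing);
    ``ad``/``dp`` are absent (None) when the VCF did not provide them,
    never silently zero.
    """

    gt: GenotypePair = (None, None)
    ad: Optional[Tuple[int, ...]] = None
    dp: Optional[int] = None
    phased: bool = False

    @property
    def is_missing(self) -> bool:
        return self.gt[0] is None or self.gt[1] is None


@dataclass
class VariantRecord:
    """One variant site with ordered ALTs and per-sample calls."""

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alts: Tuple[str, ...]
    calls: dict[str, SampleCall] = field(default_factory=dict)
    vid: str = "."

    def validate(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, *self.alts):
            if not allele or set(allele) - VALID_BASES:
                raise ValidationError(f"bad allele {allele!r} at {self.chrom}:{self.pos}")
        n_alt = len(self.alts)
        for sample, call in self.calls.items():
            for idx in call.gt:
                if idx is not None and not 0 <= idx <= n_alt:
                    raise ValidationError(
                        f"{sample} genotype index {idx} out of range at {self.chrom}:{self.pos}"
                    )
            if call.ad is not None and call.dp is not None and sum(call.ad) > call.dp:
                raise ValidationError(
                    f"{sample} allele depths exceed total depth at {self.chrom}:{self.pos}"
                )

    def allele(self, index: int) -> str:
        return self.ref if index == 0 else self.alts[index - 1]


@dataclass(frozen=True)
class TargetRegion:
    """A targeted exon or PCR amplicon; half-open 0-based like BED."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    name: str = "."
    kind: str = "exon"  # {exon, amplicon}

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"degenerate region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def positions(self) -> Iterator[int]:
        """1-based positions covered by the region."""
        return iter(range(self.start + 1, self.end + 1))

    def contains(self, pos: int) -> bool:
        """1-based point-in-region test."""
        return self.start < pos <= self.end


@dataclass(frozen=True)
class PanelLocus:
    """One biallelic parentage SNV with its REF-allele frequency p."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_freq: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"{self.id}: REF and ALT alleles are identical")
        if not 0.0 <= self.ref_freq <= 1.0:
            raise ValidationError(f"{self.id}: REF frequency {self.ref_freq} outside [0, 1]")


@dataclass(frozen=True)
class PedigreeEntry:
    """Child with one or both alleged parents ('.' parents are missing)."""

    child: str
    sire: Optional[str]
    dam: Optional[str]

    def __post_init__(self) -> None:
        if self.sire is None and self.dam is None:
            raise ValidationError(f"{self.child}: pedigree entry needs at least one parent")

    @property
    def label(self) -> str:
        return "trio" if self.sire is not None and self.dam is not None else "duo"

    @property
    def parents(self) -> Tuple[str, ...]:
        return tuple(p for p in (self.sire, self.dam) if p is not None)


class KnownVariantKey(NamedTuple):
    """Normalized (chrom, pos, ref, alt) key for population-catalogue lookups."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class DepthRecord:
    """Per-base, per-sample sequencing depth (the BAM-derived surrogate)."""

    chrom: str
    pos: int  # 1-based
    sample: str
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValidationError(f"negative depth at {self.chrom}:{self.pos}")


@dataclass
class GenotypeCall:
    """A per-sample, per-locus genotype call with its supporting depths."""

    sample: str
    locus_id: str
    zygosity: Zygosity
    alleles: GenotypePair = (None, None)
    ad: Optional[Tuple[int, ...]] = None
    depth: Optional[int] = None
    flags: Tuple[str, ...] = ()

    @property
    def is_no_call(self) -> bool:
        return self.zygosity is Zygosity.NO_CALL


class GenotypeMatrix:
    """Rectangular samples x loci container of GenotypeCall objects."""

    def __init__(self, samples: Sequence[str], loci: Sequence[str]) -> None:
        self.samples = list(samples)
        self.loci = list(loci)
        no_call = {
            (s, l): GenotypeCall(s, l, Zygosity.NO_CALL) for s in self.samples for l in self.loci
        }
        self._calls: dict[Tuple[str, str], GenotypeCall] = no_call

    def set(self, call: GenotypeCall) -> None:
        key = (call.sample, call.locus_id)
        if key not in self._calls:
            raise KeyError(f"unknown sample/locus pair {key}")
        self._calls[key] = call

    def get(self, sample: str, locus_id: str) -> GenotypeCall:
        return self._calls[(sample, locus_id)]

    def column(self, locus_id: str) -> list[GenotypeCall]:
        return [self._calls[(s, locus_id)] for s in self.samples]

    def row(self, sample: str) -> list[GenotypeCall]:
        return [self._calls[(sample, l)] for l in self.loci]

    def copy(self) -> "GenotypeMatrix":
        out = GenotypeMatrix(self.samples, self.loci)
        out._calls = dict(self._calls)
        return out

    def __iter__(self) -> Iterator[GenotypeCall]:
        for s in self.samples:
            for l in self.loci:
                yield self._calls[(s, l)]
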