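"""Mendelian-consistency checks and exclusion-power statistics for the SNV panel.

For a biallelic locus with REF-allele frequency p (q = 1 - p):

    He  = 2pq                 expected heterozygosity
    PE1 = pq(1 - pq)          exclusion power when one parent is known (trio)
    PE2 = 2 p^2 q^2           exclusion power for a lone alleged parent (duo);
                              only opposite homozygotes exclude
    combined PE = 1 - prod(1 - PE_i)   across independent loci

Combined values are reported truncated toward zero — conservative for an
exclusion-power claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .coverage_qc import round_half_up
from .genotyping import estimate_allele_freq
from .types import (
    GedscreenError,
    GenotypeCall,
    GenotypeMatrix,
    PanelLocus,
    PedigreeEntry,
    Zygosity,
)

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
NO_CALL = "no_call"

# truth-status labels for simulated designs; the checker treats all identically
PEDIGREE_KINDS = ("trio", "pseudo_trio", "half_pseudo_trio", "duo", "pseudo_duo")


@dataclass(frozen=True)
class PedigreeTest:
    entry: PedigreeEntry
    kind: str = "trio"

    def __post_init__(self) -> None:
        expected = "trio" if self.entry.label == "trio" else "duo"
        if not self.kind.endswith(expected) and self.kind != expected:
            raise GedscreenError(
                f"{self.entry.child}: kind {self.kind!r} inconsistent with parents present"
            )


@dataclass
class ExclusionResult:
    test: PedigreeTest
    consistent: int
    inconsistent: int
    no_call: int
    inconsistent_loci: tuple[str, ...]

    def check_totals(self, panel_size: int) -> None:
        assert self.consistent + self.inconsistent + self.no_call == panel_size


def _alleles(call: GenotypeCall) -> Optional[tuple[int, int]]:
    if call.is_no_call or call.alleles[0] is None or call.alleles[1] is None:
        return None
    return call.alleles  # type: ignore[return-value]


def trio_consistent(child: GenotypeCall, sire: GenotypeCall, dam: GenotypeCall) -> str:
    """Mendelian verdict for a child against both alleged parents.

    Consistent iff the child's alleles can be split as one transmitted by
    the sire and one by the dam.
    """
    if child.locus_id != sire.locus_id or child.locus_id != dam.locus_id:
        raise GedscreenError("trio_consistent: calls are for different loci")
    c, s, d = _alleles(child), _alleles(sire), _alleles(dam)
    if c is None or s is None or d is None:
        return NO_CALL
    for a, b in (c, c[::-1]):
        if a in s and b in d:
            return CONSISTENT
    return INCONSISTENT


def duo_consistent(child: GenotypeCall, parent: GenotypeCall) -> str:
    """Single-parent verdict: consistent iff child and parent share an allele."""
    if child.locus_id != parent.locus_id:
        raise GedscreenError("duo_consistent: calls are for different loci")
    c, p = _alleles(child), _alleles(parent)
    if c is None or p is None:
        return NO_CALL
    return CONSISTENT if set(c) & set(p) else INCONSISTENT


def count_exclusions(
    matrix: GenotypeMatrix, test: PedigreeTest, panel: Sequence[PanelLocus]
) -> ExclusionResult:
    """Tally per-locus verdicts for one pedigree configuration."""
    entry = test.entry
    for sample in (entry.child, *entry.parents):
        if sample not in matrix.samples:
            raise GedscreenError(f"sample {sample!r} not in genotype matrix")
    tally = {CONSISTENT: 0, INCONSISTENT: 0, NO_CALL: 0}
    bad_loci = []
    for locus in panel:
        child = matrix.get(entry.child, locus.id)
        if entry.label == "trio":
            verdict = trio_consistent(
                child, matrix.get(entry.sire, locus.id), matrix.get(entry.dam, locus.id)
            )
        else:
            verdict = duo_consistent(child, matrix.get(entry.parents[0], locus.id))
        tally[verdict] += 1
        if verdict == INCONSISTENT:
            bad_loci.append(locus.id)
    result = ExclusionResult(
        test, tally[CONSISTENT], tally[INCONSISTENT], tally[NO_CALL], tuple(bad_loci)
    )
    result.check_totals(len(panel))
    return result


def drop_misinheriting_loci(
    panel: Sequence[PanelLocus], trio_results: Iterable[ExclusionResult]
) -> list[PanelLocus]:
    """Prune every locus inconsistent in ANY true trio (zero tolerance)."""
    bad = set()
    for result in trio_results:
        bad.update(result.inconsistent_loci)
    return [l for l in panel if l.id not in bad]


# ---------------------------------------------------------------------------
# Closed-form per-locus statistics


def _check_freq(p: float) -> float:
    if not 0.0 <= p <= 1.0:
        raise GedscreenError(f"allele frequency {p} outside [0, 1]")
    return p


def heterozygosity(p: float) -> float:
    """He = 2pq."""
    p = _check_freq(p)
    return 2.0 * p * (1.0 - p)


def pe1(p: float) -> float:
    """Trio (one parent known) exclusion probability: pq(1 - pq); max 0.1875."""
    p = _check_freq(p)
    pq = p * (1.0 - p)
    return pq * (1.0 - pq)


def pe2(p: float) -> float:
    """Duo exclusion probability: 2 p^2 q^2 (opposite homozygotes); max 0.125."""
    p = _check_freq(p)
    return 2.0 * (p * (1.0 - p)) ** 2


def truncate(x: float, digits: int) -> float:
    """Truncate toward zero at the given number of decimals."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_DOWN))


def combined_pe(per_locus_pe: Iterable[float], digits: Optional[int] = None) -> float:
    """1 - prod(1 - PE_i); optionally truncated toward zero at `digits`."""
    values = list(per_locus_pe)
    if any(not 0.0 <= v < 1.0 for v in values):
        raise GedscreenError("per-locus PE values must lie in [0, 1)")
    combined = 1.0 - math.prod(1.0 - v for v in values)
    return combined if digits is None else truncate(combined, digits)


@dataclass(frozen=True)
class PanelStats:
    locus: PanelLocus
    he: float
    pe1: float
    pe2: float


def panel_report(
    panel: Sequence[PanelLocus], matrix: Optional[GenotypeMatrix] = None
) -> tuple[list[PanelStats], float, float]:
    """Per-locus (He, PE1, PE2) plus combined PE1/PE2 for the panel.

    Frequencies come from the panel table unless a genotype matrix is given,
    in which case they are re-estimated from the called genotypes.
    """
    stats = []
    for locus in panel:
        p = estimate_allele_freq(matrix, locus.id) if matrix is not None else locus.ref_freq
        stats.append(PanelStats(locus, heterozygosity(p), pe1(p), pe2(p)))
    c1 = combined_pe([s.pe1 for s in stats], digits=10)
    c2 = combined_pe([s.pe2 for s in stats], digits=6)
    return stats, c1, c2


def panel_report_frame(stats: Sequence[PanelStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": s.locus.id,
                "chrom": s.locus.chrom,
                "pos": s.locus.pos,
                "ref": s.locus.ref,
                "alt": s.locus.alt,
                "ref_freq": s.locus.ref_freq,
                "He": round_half_up(s.he, 3),
                "PE1": round_half_up(s.pe1, 3),
                "PE2": round_half_up(s.pe2, 3),
            }
            for s in stats
        ]
    )


def mean_exclusions(results: Sequence[Union[ExclusionResult, int]]) -> float:
    """Arithmetic mean of inconsistent-locus counts (1-dp half-up in reports)."""
    if not results:
        raise GedscreenError("mean_exclusions: empty result list")
    counts = [r.inconsistent if isinstance(r, ExclusionResult) else int(r) for r in results]
    return sum(counts) / len(counts)


def exclusion_report_frame(results: Sequence[ExclusionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "child": r.test.entry.child,
                "sire": r.test.entry.sire or ".",
                "dam": r.test.entry.dam or ".",
                "kind": r.test.kind,
                "consistent": r.consistent,
                "inconsistent": r.inconsistent,
                "no_call": r.no_call,
                "inconsistent_loci": ";".join(r.inconsistent_loci),
            }
            for r in results
        ]
    )


def write_exclusion_report(results: Sequence[ExclusionResult], path: str | Path) -> Path:
    exclusion_report_frame(results).to_csv(path, sep="\t", index=False)
    return Path(path)
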