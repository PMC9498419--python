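"""Synthetic datasets emulating the study design: HWE genotypes at the
published panel frequencies, true and deliberately false pedigrees,
per-amplicon depth variation with planted low-coverage strata, injected
CRISPR-style edits, the amplicon-end blind spot for large deletions, and
genotyping faults (shallow coverage missing an allele; allele-depth bias).

Everything is deterministic under a seed. Planted screen variants carry
fixed genotypes so stage counts are reproducible under any seed; randomness
enters only through depths, Hardy-Weinberg draws and Mendelian transmission.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from . import formats_io
from .formats_io import load_packaged_panel, write_depth_table, write_vcf
from .parentage import PedigreeTest
from .types import (
    DepthRecord,
    GedscreenError,
    GenotypeCall,
    GenotypeMatrix,
    GenotypePair,
    KnownVariantKey,
    PanelLocus,
    PedigreeEntry,
    SampleCall,
    TargetRegion,
    VariantRecord,
    Zygosity,
)

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Configuration types


@dataclass(frozen=True)
class EditSpec:
    """A CRISPR-style edit to plant in one sample's variant calls."""

    chrom: str
    pos: int  # 1-based VCF position (anchor base for INDELs)
    ref: str
    alt: str
    zygosity: Zygosity
    label: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise GedscreenError(f"edit {self.label}: REF equals edited allele")


@dataclass(frozen=True)
class DepthModel:
    """Lognormal per-amplicon depth, constant across each amplicon's bases.

    The two strata are kept separated (high stratum floored, low stratum
    capped) so a planted low-coverage fraction is recovered exactly.
    """

    mean: float = 200.0
    sigma: float = 0.5  # log-scale sd between amplicons
    low_fraction: float = 0.0
    low_mean: float = 15.0
    low_sigma: float = 0.3
    high_floor: int = 60
    low_ceiling: int = 45

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_fraction <= 1.0:
            raise GedscreenError("low_fraction must be in [0, 1]")
        if min(self.mean, self.sigma, self.low_mean, self.low_sigma) < 0:
            raise GedscreenError("depth-model parameters must be non-negative")


@dataclass(frozen=True)
class PedigreeDesign:
    """Counts of each pedigree configuration to simulate."""

    trios: int = 29
    pseudo_trios: int = 5
    half_pseudo_trios: int = 5
    duos: int = 5
    pseudo_duos: int = 5


@dataclass
class PopulationVariant:
    """A planted variant site with fixed per-sample genotypes."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, GenotypePair]
    known: bool = False  # present in the population catalogue


@dataclass
class SimulationConfig:
    seed: int = 0
    samples: list[str] = field(default_factory=list)
    regions: list[TargetRegion] = field(default_factory=list)
    population: list[PopulationVariant] = field(default_factory=list)
    edits: dict[str, list[EditSpec]] = field(default_factory=dict)
    extra_known: list[KnownVariantKey] = field(default_factory=list)
    low_coverage_regions: list[str] = field(default_factory=list)
    depth_model: DepthModel = DepthModel()
    amplicon_end_dropout: bool = False
    panel: Optional[list[PanelLocus]] = None
    design: Optional[PedigreeDesign] = None
    fault_loci: dict[str, str] = field(default_factory=dict)
    name: str = "custom"


# ---------------------------------------------------------------------------
# Genotype simulation


def _call_from_pair(
    sample: str, locus_id: str, gt: GenotypePair, depth: int
) -> GenotypeCall:
    """Error-free call: allele depths split evenly across the two alleles."""
    if gt[0] is None or gt[1] is None:
        return GenotypeCall(sample, locus_id, Zygosity.NO_CALL, depth=depth)
    ref_n = (gt[0] == 0) + (gt[1] == 0)
    ad = {0: (0, depth), 1: (depth // 2, depth - depth // 2), 2: (depth, 0)}[ref_n]
    from .genotyping import classify_zygosity

    return GenotypeCall(sample, locus_id, classify_zygosity(gt), gt, ad, depth)


def matrix_from_pairs(
    pairs: dict[str, Sequence[GenotypePair]],
    panel: Sequence[PanelLocus],
    depth: int = 200,
) -> GenotypeMatrix:
    matrix = GenotypeMatrix(list(pairs), [l.id for l in panel])
    for sample, row in pairs.items():
        for locus, gt in zip(panel, row):
            matrix.set(_call_from_pair(sample, locus.id, gt, depth))
    return matrix


def _draw_individual(panel: Sequence[PanelLocus], rng: np.random.Generator) -> list[GenotypePair]:
    """One individual under HWE: genotype probs (p^2, 2pq, q^2) per locus."""
    out = []
    for locus in panel:
        p = locus.ref_freq
        u = rng.random()
        if u < p * p:
            out.append((0, 0))
        elif u < p * p + 2 * p * (1 - p):
            out.append((0, 1))
        else:
            out.append((1, 1))
    return out


def simulate_genotypes_hwe(
    panel: Sequence[PanelLocus],
    n_samples: int,
    seed: RngLike,
    prefix: str = "S",
    depth: int = 200,
) -> GenotypeMatrix:
    """n unrelated individuals drawn i.i.d. under Hardy-Weinberg equilibrium."""
    rng = _rng(seed)
    pairs = {f"{prefix}{i + 1:03d}": _draw_individual(panel, rng) for i in range(n_samples)}
    return matrix_from_pairs(pairs, panel, depth)


def simulate_offspring(
    sire: Sequence[GenotypePair], dam: Sequence[GenotypePair], seed: RngLike
) -> list[GenotypePair]:
    """Mendelian transmission: one uniform allele from each parent per locus."""
    rng = _rng(seed)
    child = []
    for s, d in zip(sire, dam):
        if s[0] is None or d[0] is None:
            child.append((None, None))
        else:
            child.append((s[rng.integers(2)], d[rng.integers(2)]))
    return child


@dataclass
class PedigreeSuite:
    matrix: GenotypeMatrix
    tests: list[PedigreeTest]
    pairs: dict[str, list[GenotypePair]]


def simulate_pedigree_suite(
    panel: Sequence[PanelLocus],
    design: PedigreeDesign,
    seed: RngLike,
    depth: int = 200,
) -> PedigreeSuite:
    """True families by Mendelian transmission; pseudo-relatives are fresh
    unrelated HWE draws. Test kinds record the simulation truth status; the
    consistency checker itself treats all kinds identically."""
    rng = _rng(seed)
    pairs: dict[str, list[GenotypePair]] = {}
    tests: list[PedigreeTest] = []

    def fresh(name: str) -> str:
        pairs[name] = _draw_individual(panel, rng)
        return name

    for i in range(1, design.trios + 1):
        sire, dam = fresh(f"sire{i:02d}"), fresh(f"dam{i:02d}")
        foal = f"foal{i:02d}"
        pairs[foal] = simulate_offspring(pairs[sire], pairs[dam], rng)
        tests.append(PedigreeTest(PedigreeEntry(foal, sire, dam), "trio"))

    def foal_of(k: int) -> str:
        if k > design.trios:
            raise GedscreenError("design needs at least as many trios as pseudo designs")
        return f"foal{k:02d}"

    for i in range(1, design.pseudo_trios + 1):
        ps, pd_ = fresh(f"psire{i:02d}"), fresh(f"pdam{i:02d}")
        tests.append(PedigreeTest(PedigreeEntry(foal_of(i), ps, pd_), "pseudo_trio"))
    for i in range(1, design.half_pseudo_trios + 1):
        foal = foal_of(i)
        if i % 2 == 1:  # true sire + pseudo-dam, alternating with the converse
            tests.append(
                PedigreeTest(
                    PedigreeEntry(foal, f"sire{i:02d}", fresh(f"hpdam{i:02d}")),
                    "half_pseudo_trio",
                )
            )
        else:
            tests.append(
                PedigreeTest(
                    PedigreeEntry(foal, fresh(f"hpsire{i:02d}"), f"dam{i:02d}"),
                    "half_pseudo_trio",
                )
            )
    for i in range(1, design.duos + 1):
        tests.append(PedigreeTest(PedigreeEntry(foal_of(i), None, f"dam{i:02d}"), "duo"))
    for i in range(1, design.pseudo_duos + 1):
        tests.append(
            PedigreeTest(PedigreeEntry(foal_of(i), None, fresh(f"pparent{i:02d}")), "pseudo_duo")
        )
    return PedigreeSuite(matrix_from_pairs(pairs, panel, depth), tests, pairs)


def extended_panel(
    panel: Sequence[PanelLocus], n_extra: int, seed: RngLike
) -> list[PanelLocus]:
    """Panel plus n synthetic pre-pruning loci (frequencies Uniform(0.2, 0.8))."""
    rng = _rng(seed)
    extra = [
        PanelLocus(
            id=f"XSNV{i + 1:03d}",
            chrom="1",
            pos=200_000_000 + i * 1000,
            ref="A",
            alt="G",
            ref_freq=float(np.round(rng.uniform(0.2, 0.8), 3)),
        )
        for i in range(n_extra)
    ]
    return list(panel) + extra


# ---------------------------------------------------------------------------
# Genotyping faults


def _flip_creates_inconsistency(
    pairs: dict[str, list[GenotypePair]],
    test: PedigreeTest,
    locus_index: int,
) -> Optional[tuple[str, GenotypePair]]:
    """Find one Het trio member whose flip to a homozygote breaks Mendelian
    consistency; returns (sample, new genotype) or None."""
    entry = test.entry
    child = pairs[entry.child][locus_index]
    sire = pairs[entry.sire][locus_index]
    dam = pairs[entry.dam][locus_index]
    # Het parent with a homozygous child: flip parent to the other homozygote
    for parent_name, parent in ((entry.sire, sire), (entry.dam, dam)):
        if parent[0] != parent[1] and child[0] == child[1] and child[0] is not None:
            other = 1 - child[0]
            return parent_name, (other, other)
    # Het child with a homozygous parent: flip child away from that parent
    if child[0] != child[1] and None not in child:
        for parent in (sire, dam):
            if parent[0] == parent[1] and parent[0] is not None:
                other = 1 - parent[0]
                return entry.child, (other, other)
    return None


def simulate_genotyping_faults(
    suite: PedigreeSuite,
    panel: Sequence[PanelLocus],
    fault_loci: dict[str, str],
    seed: RngLike,
    n_extra_low_depth: int = 3,
) -> GenotypeMatrix:
    """Corrupt the error-free matrix at the designated loci.

    Both fault flavors flip one Het call to a homozygote in a true trio
    (guaranteeing a mis-inheritance at that locus); they differ in the
    recorded evidence. ``low_depth`` mimics shallow coverage that sampled
    only one allele (depth barely above the call threshold, plus NoCalls
    at depth <= 50 for additional random samples); ``allele_bias`` mimics
    PCR amplification bias (normal depth, heavily skewed allele depths).
    """
    rng = _rng(seed)
    matrix = suite.matrix.copy()
    locus_index = {l.id: i for i, l in enumerate(panel)}
    trios = [t for t in suite.tests if t.kind == "trio"]
    for locus_id, kind in fault_loci.items():
        if locus_id not in locus_index:
            raise GedscreenError(f"fault locus {locus_id} not in panel")
        idx = locus_index[locus_id]
        order = list(rng.permutation(len(trios)))
        flip = flipped_trio = None
        for t in order:
            flip = _flip_creates_inconsistency(suite.pairs, trios[t], idx)
            if flip is not None:
                flipped_trio = trios[t]
                break
        if flip is None:
            raise GedscreenError(
                f"no single-call flip can break a trio at {locus_id}; "
                "panel frequency too extreme for this design"
            )
        sample, new_gt = flip
        if kind == "low_depth":
            depth = int(rng.integers(51, 61))
            ad = (0, depth) if new_gt[0] == 1 else (depth, 0)
            flags = ("low-depth-fault",)
        elif kind == "allele_bias":
            depth = 200
            minor = int(rng.integers(20, 51))
            ad = (minor, depth - minor) if new_gt[0] == 1 else (depth - minor, minor)
            flags = ("allele-imbalance",)
        else:
            raise GedscreenError(f"unknown fault kind {kind!r}")
        zyg = Zygosity.HOMO_ALT if new_gt[0] == 1 else Zygosity.HOMO_REF
        matrix.set(GenotypeCall(sample, locus_id, zyg, new_gt, ad, depth, flags))
        if kind == "low_depth":
            # keep the flipped trio fully called so its mis-inheritance stands
            shielded = {flipped_trio.entry.child, *flipped_trio.entry.parents}
            others = [s for s in matrix.samples if s != sample and s not in shielded]
            for j in rng.choice(len(others), size=min(n_extra_low_depth, len(others)),
                                replace=False):
                low = int(rng.integers(10, 51))
                matrix.set(
                    GenotypeCall(others[j], locus_id, Zygosity.NO_CALL, depth=low,
                                 flags=("low-depth-fault",))
                )
    return matrix


# ---------------------------------------------------------------------------
# Screen-side simulation: variants, edits, depths


def population_records(
    population: Sequence[PopulationVariant], samples: Sequence[str]
) -> list[VariantRecord]:
    """VariantRecords for planted sites; AD/DP are synthesized per genotype."""
    records = []
    for pv in population:
        calls = {}
        for sample in samples:
            gt = pv.genotypes.get(sample)
            if gt is None:
                continue
            calls[sample] = _sample_call_for_gt(gt, len(pv.alts), depth=200)
        if calls:
            rec = VariantRecord(pv.chrom, pv.pos, pv.ref, pv.alts, calls)
            rec.validate()
            records.append(rec)
    return records


def _sample_call_for_gt(gt: GenotypePair, n_alts: int, depth: int) -> SampleCall:
    ad = [0] * (n_alts + 1)
    for allele in gt:
        if allele is not None:
            ad[allele] += depth // 2
    return SampleCall(gt=gt, ad=tuple(ad), dp=depth)


def inject_edit(
    variants: list[VariantRecord],
    edit: EditSpec,
    sample: str,
    amplicons: Optional[Sequence[TargetRegion]] = None,
    depth: int = 200,
) -> list[VariantRecord]:
    """Add (or overwrite — idempotent) the edited variant for one sample."""
    if amplicons is not None and not any(
        a.chrom == edit.chrom and a.contains(edit.pos) for a in amplicons
    ):
        raise GedscreenError(
            f"edit {edit.label or edit.pos} lies outside every amplicon: undetectable by design"
        )
    gt: GenotypePair = {
        Zygosity.HOMO_ALT: (1, 1),
        Zygosity.HET: (0, 1),
        Zygosity.COMPOUND_HET: (1, 2),
    }[edit.zygosity]
    call = _sample_call_for_gt(gt, 1, depth)
    out = []
    replaced = False
    for rec in variants:
        if (rec.chrom, rec.pos, rec.ref, rec.alts) == (edit.chrom, edit.pos, edit.ref, (edit.alt,)):
            rec = replace(rec, calls={**rec.calls, sample: call})
            replaced = True
        out.append(rec)
    if not replaced:
        out.append(
            VariantRecord(edit.chrom, edit.pos, edit.ref, (edit.alt,), {sample: call})
        )
    return out


def apply_amplicon_end_dropout(
    variants: Sequence[VariantRecord],
    amplicons: Sequence[TargetRegion],
    margin: int = 25,
    min_size: int = 50,
) -> list[VariantRecord]:
    """Remove large INDELs hugging an amplicon boundary, emulating the
    upstream caller's soft-clip blind spot (margin 0 removes nothing)."""
    if margin <= 0:
        return list(variants)
    kept = []
    for rec in variants:
        norm = formats_io.normalize_variant(rec)
        span = (norm.pos, norm.pos + len(norm.ref) - 1)
        size = max(abs(len(norm.ref) - len(a)) for a in norm.alts)
        drop = False
        if size > min_size:
            for amp in amplicons:
                if amp.chrom != norm.chrom or amp.kind != "amplicon":
                    continue
                near = min(
                    abs(span[0] - (amp.start + 1)), abs(amp.end - span[0]),
                    abs(span[1] - (amp.start + 1)), abs(amp.end - span[1]),
                )
                if near <= margin:
                    drop = True
                    break
        if not drop:
            kept.append(rec)
    return kept


def simulate_depths(
    regions: Sequence[TargetRegion],
    model: DepthModel,
    samples: Sequence[str],
    seed: RngLike,
    low_regions: Optional[Iterable[str]] = None,
) -> list[DepthRecord]:
    """Per-region, per-sample depth: lognormal draws constant across bases.

    Low-coverage regions are either named explicitly or drawn as a fixed
    fraction of the region list (round(n * low_fraction), chosen at random).
    """
    rng = _rng(seed)
    if low_regions is None:
        n_low = int(round(len(regions) * model.low_fraction))
        low_idx = set(rng.choice(len(regions), size=n_low, replace=False)) if n_low else set()
        low_names = {regions[i].name for i in low_idx}
    else:
        low_names = set(low_regions)
    out = []
    for region in regions:
        low = region.name in low_names
        mean, sigma = (model.low_mean, model.low_sigma) if low else (model.mean, model.sigma)
        for sample in samples:
            if sigma == 0:
                depth = mean
            else:
                depth = rng.lognormal(np.log(mean), sigma)
            depth = min(depth, model.low_ceiling) if low else max(depth, model.high_floor)
            depth = max(1, int(round(depth)))
            out.extend(
                DepthRecord(region.chrom, pos, sample, depth) for pos in region.positions()
            )
    return out


# ---------------------------------------------------------------------------
# Dataset assembly


@dataclass
class Dataset:
    config: SimulationConfig
    samples: list[str]
    regions: list[TargetRegion]
    records: list[VariantRecord]
    depths: list[DepthRecord]
    known: set[KnownVariantKey]
    truth: dict
    suite: Optional[PedigreeSuite] = None
    matrix: Optional[GenotypeMatrix] = None

    @property
    def exons(self) -> list[TargetRegion]:
        return [r for r in self.regions if r.kind == "exon"]

    @property
    def amplicons(self) -> list[TargetRegion]:
        return [r for r in self.regions if r.kind == "amplicon"]


def build_dataset(config: SimulationConfig) -> Dataset:
    """Assemble the in-memory dataset a config describes (deterministic)."""
    rng = _rng(config.seed)
    amplicons = [r for r in config.regions if r.kind == "amplicon"]
    records = population_records(config.population, config.samples)
    for sample, edits in config.edits.items():
        for edit in edits:
            records = inject_edit(records, edit, sample, amplicons or None)
    if config.amplicon_end_dropout:
        records = apply_amplicon_end_dropout(records, amplicons)
    depths = simulate_depths(
        amplicons or config.regions,
        config.depth_model,
        config.samples,
        rng,
        low_regions=config.low_coverage_regions or None,
    )
    known = {
        k
        for pv in config.population
        if pv.known
        for k in formats_io.variant_keys(
            formats_io.normalize_variant(
                VariantRecord(pv.chrom, pv.pos, pv.ref, pv.alts)
            )
        )
    } | set(config.extra_known)
    truth = {
        "preset": config.name,
        "seed": config.seed,
        "edits": {
            sample: [
                {
                    "chrom": e.chrom, "pos": e.pos, "ref": e.ref, "alt": e.alt,
                    "zygosity": e.zygosity.value, "label": e.label,
                }
                for e in edits
            ]
            for sample, edits in config.edits.items()
        },
        "known_variants": len(known),
        "low_coverage_regions": list(config.low_coverage_regions),
        "fault_loci": dict(config.fault_loci),
    }
    suite = matrix = None
    if config.design is not None:
        panel = config.panel if config.panel is not None else load_packaged_panel()
        suite = simulate_pedigree_suite(panel, config.design, rng)
        matrix = (
            simulate_genotyping_faults(suite, panel, config.fault_loci, rng)
            if config.fault_loci
            else suite.matrix
        )
        truth["pedigree"] = {
            t.entry.child: {"kind": t.kind, "sire": t.entry.sire, "dam": t.entry.dam}
            for t in suite.tests
        }
    return Dataset(
        config=config,
        samples=list(config.samples),
        regions=list(config.regions),
        records=records,
        depths=depths,
        known=known,
        truth=truth,
        suite=suite,
        matrix=matrix,
    )


def emit_dataset(config: SimulationConfig, outdir: str | Path) -> Path:
    """Write the dataset as plain-text files parseable by formats_io."""
    from .genotyping import write_genotype_matrix

    data = build_dataset(config)
    data.records.sort(key=lambda r: (r.chrom, r.pos))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "targets.bed", "w") as fh:
        for r in data.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.kind}\n")
    write_vcf(data.records, data.samples, outdir / "variants.vcf")
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for sample in data.samples:
        mine = [
            replace(rec, calls={sample: rec.calls[sample]})
            for rec in data.records
            if sample in rec.calls
        ]
        write_vcf(mine, [sample], vcf_dir / f"{sample}.vcf")
    write_depth_table(data.depths, outdir / "depth.tsv")
    with open(outdir / "known_variants.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for k in sorted(data.known):
            fh.write(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\n")
    if data.suite is not None:
        panel = config.panel if config.panel is not None else load_packaged_panel()
        with open(outdir / "panel.tsv", "w") as fh:
            fh.write("SNV_ID\tChromosome\tLocation\tREF_allele\tALT_allele\tREF_frequency\n")
            for l in panel:
                fh.write(f"{l.id}\t{l.chrom}\t{l.pos}\t{l.ref}\t{l.alt}\t{l.ref_freq}\n")
        with open(outdir / "pedigree.tsv", "w") as fh:
            fh.write("child\tsire\tdam\n")
            for t in data.suite.tests:
                fh.write(
                    f"{t.entry.child}\t{t.entry.sire or '.'}\t{t.entry.dam or '.'}\n"
                )
        write_genotype_matrix(data.matrix, outdir / "genotype_matrix.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(data.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
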