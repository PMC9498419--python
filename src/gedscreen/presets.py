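"""Packaged simulation presets.

``validation-2022`` mirrors the validation design: thoroughbred samples plus
four gene-edited fibroblast lines carrying the documented myostatin edits
(three homozygous 1-bp insertions; one heterozygous 77-bp deletion lying
22 bp from its amplicon end), a population catalogue containing four
HomoALT and one compound-heterozygous INDEL, and three artifact loci in
designated low-coverage amplicons. ``casework-2022`` mirrors the casework
design: no edits; seven HomoALT/ALT1-ALT2 INDEL loci of which six are
catalogued and one has low coverage.

Non-myostatin coordinates and the deleted 77-bp sequence are synthetic
(chosen once, fixed); myostatin edit coordinates follow the published
EquCab3.0 positions. Variant-pool sizes are scaled down from the study's
sample-set totals; stage counts at each filter are preserved exactly.
"""

from __future__ import annotations

from .synthetic_data import (
    DepthModel,
    EditSpec,
    PopulationVariant,
    SimulationConfig,
)
from .types import TargetRegion, Zygosity

# synthetic 77-base deleted sequence (the published record gives coordinates only)
_DEL77 = "".join(
    [
        "TGGATCGTTT", "ACCTTGTACC", "GTCTTTCATG", "CAAATCTCTT",
        "CTGGATCGTT", "TACCTTGTAC", "CGTCTTTCAT", "GCAAATC",
    ]
)

MSTN_EDITS: dict[str, EditSpec] = {
    "EC1": EditSpec("chr18", 66605475, "A" + _DEL77, "A", Zygosity.HET, "MSTN 77-bp deletion"),
    "EC2": EditSpec("chr18", 66607750, "C", "CT", Zygosity.HOMO_ALT, "MSTN exon2 1-bp insertion"),
    "EC3": EditSpec("chr18", 66607753, "T", "TA", Zygosity.HOMO_ALT, "MSTN exon2 1-bp insertion"),
    "EC4": EditSpec("chr18", 66609936, "T", "TA", Zygosity.HOMO_ALT, "MSTN exon1 1-bp insertion"),
}


def _regions() -> list[TargetRegion]:
    spec = [
        # myostatin: real EquCab3.0 neighbourhoods of the edit sites
        ("chr18", 66605450, 66605600, "MSTN_ex3", "exon"),
        ("chr18", 66605454, 66605650, "amp_MSTN_ex3", "amplicon"),
        ("chr18", 66607700, 66607830, "MSTN_ex2", "exon"),
        ("chr18", 66607650, 66607860, "amp_MSTN_ex2", "amplicon"),
        ("chr18", 66609900, 66609990, "MSTN_ex1", "exon"),
        ("chr18", 66609850, 66610050, "amp_MSTN_ex1", "amplicon"),
        # other targeted genes (synthetic coordinates)
        ("chr13", 45000100, 45000250, "EPO_ex2", "exon"),
        ("chr13", 45000050, 45000300, "amp_EPO_2", "amplicon"),
        ("chr11", 23500100, 23500230, "GH1_ex3", "exon"),
        ("chr11", 23500050, 23500280, "amp_GH1_3", "amplicon"),
        ("chr28", 19800100, 19800240, "IGF1_ex2", "exon"),
        ("chr28", 19800060, 19800290, "amp_IGF1_2", "amplicon"),
        ("chr21", 30200100, 30200230, "FST_ex4", "exon"),
        ("chr21", 30200040, 30200270, "amp_FST_4", "amplicon"),
        ("chr10", 17600100, 17600220, "CKM_ex5", "exon"),
        ("chr10", 17600060, 17600260, "amp_CKM_5", "amplicon"),
        ("chr12", 52300100, 52300230, "ACTN3_ex7", "exon"),
        ("chr12", 52300050, 52300280, "amp_ACTN3_7", "amplicon"),
        # amplicons designated low-coverage (variable PCR efficiency)
        ("chr3", 44100100, 44100220, "PPARGC1A_ex1", "exon"),
        ("chr3", 44100050, 44100250, "amp_PPARGC1A_1", "amplicon"),
        ("chr20", 33400100, 33400220, "VEGFA_ex2", "exon"),
        ("chr20", 33400050, 33400250, "amp_VEGFA_2", "amplicon"),
        ("chr14", 10900100, 10900220, "ADRB2_ex1", "exon"),
        ("chr14", 10900050, 10900250, "amp_ADRB2_1", "amplicon"),
    ]
    return [TargetRegion(*row) for row in spec]


_LOW_AMPLICONS = ["amp_PPARGC1A_1", "amp_VEGFA_2", "amp_ADRB2_1"]


def _snv_background(samples: list[str]) -> list[PopulationVariant]:
    """A handful of catalogued SNVs with mixed genotypes (never candidates)."""
    s = samples
    return [
        PopulationVariant("chr13", 45000120, "A", ("G",),
                          {s[0]: (0, 1), s[1]: (1, 1), s[4]: (0, 1)}, known=True),
        PopulationVariant("chr11", 23500200, "C", ("T",),
                          {s[2]: (0, 1), s[6]: (1, 1)}, known=True),
        PopulationVariant("chr28", 19800200, "G", ("A",),
                          {s[3]: (0, 1), s[9]: (0, 1)}, known=True),
        PopulationVariant("chr21", 30200200, "T", ("C",),
                          {s[5]: (1, 1)}, known=True),
        PopulationVariant("chr10", 17600200, "G", ("T",),
                          {s[7]: (0, 1)}, known=False),
        PopulationVariant("chr12", 52300200, "C", ("A",),
                          {s[8]: (0, 1), s[10]: (1, 1)}, known=True),
        PopulationVariant("chr18", 66607820, "A", ("G",),
                          {s[11]: (0, 1)}, known=True),
        PopulationVariant("chr20", 33400200, "A", ("C",),
                          {s[12]: (0, 1)}, known=False),
    ]


def validation_2022(seed: int = 0) -> SimulationConfig:
    """The edited-cell validation design (three detectable 1-bp insertions)."""
    horses = [f"H{i:02d}" for i in range(1, 21)]
    cells = ["EC1", "EC2", "EC3", "EC4"]
    samples = horses + cells
    population = [
        # catalogued HomoALT INDELs (stage-2 exclusions)
        PopulationVariant("chr13", 45000150, "A", ("AG",),
                          {"H03": (1, 1), "H07": (0, 1)}, known=True),
        PopulationVariant("chr11", 23500150, "T", ("TC",), {"H05": (1, 1)}, known=True),
        PopulationVariant("chr28", 19800150, "G", ("GA",),
                          {"H11": (1, 1), "H12": (0, 1)}, known=True),
        PopulationVariant("chr21", 30200150, "C", ("CT",), {"H02": (1, 1)}, known=True),
        # catalogued compound heterozygote (stage-2 exclusion)
        PopulationVariant("chr10", 17600150, "A", ("AG", "AGG"), {"H09": (1, 2)}, known=True),
        # novel HomoALT INDELs in low-coverage amplicons (stage-3 exclusions)
        PopulationVariant("chr3", 44100150, "C", ("CA",), {"H04": (1, 1)}, known=False),
        PopulationVariant("chr20", 33400150, "T", ("TG",), {"H15": (1, 1)}, known=False),
        PopulationVariant("chr14", 10900150, "G", ("GT",), {"H08": (1, 1)}, known=False),
        # heterozygous INDEL background (never selected at stage 1)
        PopulationVariant("chr12", 52300140, "A", ("AT",),
                          {"H01": (0, 1), "H14": (0, 1)}, known=True),
        PopulationVariant("chr13", 45000230, "CT", ("C",), {"H06": (0, 1)}, known=False),
        PopulationVariant("chr18", 66607800, "G", ("GA",), {"H10": (0, 1)}, known=False),
    ] + _snv_background(horses)
    return SimulationConfig(
        seed=seed,
        samples=samples,
        regions=_regions(),
        population=population,
        edits={sample: [MSTN_EDITS[sample]] for sample in cells},
        low_coverage_regions=list(_LOW_AMPLICONS),
        depth_model=DepthModel(mean=200.0, sigma=0.4, low_mean=15.0),
        name="validation-2022",
    )


def casework_2022(seed: int = 0) -> SimulationConfig:
    """The casework design: no edits; every stage-1 locus is explained away."""
    samples = [f"C{i:02d}" for i in range(1, 21)]
    population = [
        # six catalogued stage-1 loci: five HomoALT INDELs + one compound het
        PopulationVariant("chr13", 45000150, "A", ("AG",), {"C02": (1, 1)}, known=True),
        PopulationVariant("chr11", 23500150, "T", ("TC",),
                          {"C04": (1, 1), "C05": (1, 1)}, known=True),
        PopulationVariant("chr28", 19800150, "G", ("GA",), {"C07": (1, 1)}, known=True),
        PopulationVariant("chr21", 30200150, "C", ("CT",), {"C09": (1, 1)}, known=True),
        PopulationVariant("chr12", 52300140, "A", ("AT",), {"C12": (1, 1)}, known=True),
        PopulationVariant("chr10", 17600150, "A", ("AG", "AGG"), {"C15": (1, 2)}, known=True),
        # one novel HomoALT INDEL covered only at low depth
        PopulationVariant("chr3", 44100150, "C", ("CA",), {"C11": (1, 1)}, known=False),
        # heterozygous INDEL + SNV background
        PopulationVariant("chr18", 66607800, "G", ("GA",), {"C01": (0, 1)}, known=False),
        PopulationVariant("chr13", 45000230, "CT", ("C",), {"C17": (0, 1)}, known=True),
    ] + _snv_background(samples)
    return SimulationConfig(
        seed=seed,
        samples=samples,
        regions=_regions(),
        population=population,
        edits={},
        low_coverage_regions=list(_LOW_AMPLICONS),
        depth_model=DepthModel(mean=200.0, sigma=0.4, low_mean=15.0),
        name="casework-2022",
    )


PRESETS = {
    "validation-2022": validation_2022,
    "casework-2022": casework_2022,
}


def get_preset(name: str, seed: int = 0) -> SimulationConfig:
    try:
        return PRESETS[name](seed)
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
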