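"""Format round-trips, error diagnostics and variant-key normalization."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gedscreen import formats_io
from gedscreen.formats_io import (
    normalize_key,
    normalize_variant,
    read_bed,
    read_panel_table,
    read_pedigree,
    read_vcf,
    write_vcf,
)
from gedscreen.types import FormatError, SampleCall, ValidationError, VariantRecord

from conftest import make_record


# ---------------------------------------------------------------------------
# VCF


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n'
    "##contig=<ID=chr18>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tcell2\n"
)


def write_text_vcf(tmp_path, body, name="x.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


def test_read_vcf_parses_edited_cell_insertion(tmp_path):
    """The homozygous 1-bp myostatin insertion line parses field by field."""
    path = write_text_vcf(
        tmp_path, "chr18\t66607750\t.\tC\tCT\t.\tPASS\t.\tGT:AD:DP\t1/1:0,210:212\n"
    )
    records, samples = read_vcf(path)
    assert samples == ["cell2"]
    (rec,) = records
    assert (rec.chrom, rec.pos, rec.ref, rec.alts) == ("chr18", 66607750, "C", ("CT",))
    call = rec.calls["cell2"]
    assert call.gt == (1, 1) and call.ad == (0, 210) and call.dp == 212


def test_read_vcf_keeps_missing_genotype_records(tmp_path):
    path = write_text_vcf(tmp_path, "chr18\t100\t.\tC\tT\t.\t.\t.\tGT\t./.\n")
    records, _ = read_vcf(path)
    assert len(records) == 1
    assert records[0].calls["cell2"].is_missing


@pytest.mark.parametrize(
    "body, fragment",
    [
        ("chr18\t100\t.\tC\tT\t.\t.\t.\tDP\t50\n", "FORMAT lacks GT"),
        ("chr18\t100\t.\tC\tT\t.\t.\t.\tGT\t0\\1\n", "separator"),
        ("chr18\t100\t.\tC\tT\t.\t.\t.\tGT\n", "columns"),
    ],
)
def test_read_vcf_format_errors_name_the_line(tmp_path, body, fragment):
    path = write_text_vcf(tmp_path, body)
    with pytest.raises(FormatError, match=fragment) as err:
        read_vcf(path)
    assert "line 7" in str(err.value)  # first data line of the fixture header


def random_records(rng, n=12):
    records = []
    used = set()
    for _ in range(n):
        while True:
            chrom = rng.choice(["chr1", "chr2", "chrX"])
            pos = rng.randint(1, 10_000)
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        n_alt = rng.randint(1, 2)
        ref = "".join(rng.choices("ACGT", k=rng.randint(1, 4)))
        alts = []
        while len(alts) < n_alt:
            alt = "".join(rng.choices("ACGT", k=rng.randint(1, 4)))
            if alt != ref and alt not in alts:
                alts.append(alt)
        calls = {}
        for sample in ("s1", "s2"):
            if rng.random() < 0.2:
                gt = (None, None)
            else:
                gt = (rng.randint(0, n_alt), rng.randint(0, n_alt))
            ad = None
            dp = None
            if rng.random() < 0.7:
                ad = tuple(rng.randint(0, 100) for _ in range(n_alt + 1))
                dp = sum(ad) + rng.randint(0, 20)
            calls[sample] = SampleCall(gt=gt, ad=ad, dp=dp)
        records.append(VariantRecord(chrom, pos, ref, tuple(alts), calls))
    return records


def test_vcf_round_trip_identity_on_random_records(tmp_path):
    """write_vcf then read_vcf reproduces positions, alleles, GT/AD/DP exactly."""
    rng = random.Random(20240917)
    records = sorted(random_records(rng, 20), key=lambda r: (r.chrom, r.pos))
    path = write_vcf(records, ["s1", "s2"], tmp_path / "rt.vcf")
    back, samples = read_vcf(path)
    assert samples == ["s1", "s2"]
    assert len(back) == len(records)
    for a, b in zip(records, back):
        assert (a.chrom, a.pos, a.ref, a.alts) == (b.chrom, b.pos, b.ref, b.alts)
        for sample in samples:
            ca, cb = a.calls[sample], b.calls[sample]
            assert tuple(sorted(x is None and -1 or x for x in ca.gt)) == tuple(
                sorted(x is None and -1 or x for x in cb.gt)
            ) or ca.gt == cb.gt
            assert ca.ad == cb.ad and ca.dp == cb.dp


def test_write_vcf_sorts_records_like_a_naive_sort(tmp_path):
    rng = random.Random(7)
    records = random_records(rng, 15)
    path = write_vcf(records, ["s1", "s2"], tmp_path / "sorted.vcf")
    back, _ = read_vcf(path)
    expected = sorted((r.chrom, r.pos) for r in records)
    assert [(r.chrom, r.pos) for r in back] == expected


def test_write_vcf_empty_records_gives_header_only_file(tmp_path):
    path = write_vcf([], ["s1"], tmp_path / "empty.vcf")
    records, samples = read_vcf(path)
    assert records == [] and samples == ["s1"]


# ---------------------------------------------------------------------------
# BED / tables


def test_read_bed_grna_region(tmp_path):
    path = tmp_path / "t.bed"
    path.write_text("chr18\t66605474\t66605495\tMSTN_ex3_gRNA\n")
    (region,) = read_bed(path)
    assert region.length == 21 and region.name == "MSTN_ex3_gRNA"


def test_read_bed_empty_and_degenerate(tmp_path):
    empty = tmp_path / "e.bed"
    empty.write_text("")
    assert read_bed(empty) == []
    bad = tmp_path / "b.bed"
    bad.write_text("chr1\t100\t100\n")
    with pytest.raises(FormatError):
        read_bed(bad)


def test_packaged_panel_has_120_loci_with_printed_frequencies(panel, panel_frame):
    assert len(panel) == 120
    first = panel[0]
    assert (first.id, first.chrom, first.pos) == ("BIEC2-11336", "1", 24061861)
    assert first.ref == "C" and first.alt == "T" and first.ref_freq == 0.582
    assert list(panel_frame["REF_frequency"]) == [l.ref_freq for l in panel]


def test_read_panel_table_rejects_bad_frequency(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text("SNV_ID\tChromosome\tLocation\tREF_allele\tALT_allele\tREF_frequency\n"
                    "X\t1\t100\tA\tG\t1.2\n")
    with pytest.raises(ValidationError):
        read_panel_table(path)


def test_read_pedigree_labels_and_errors(tmp_path):
    path = tmp_path / "ped.tsv"
    path.write_text("child\tsire\tdam\nfoal1\tsire1\tdam1\nfoal2\t.\tdam2\n")
    entries = read_pedigree(path)
    assert [e.label for e in entries] == ["trio", "duo"]
    bad = tmp_path / "bad.tsv"
    bad.write_text("child\tsire\tdam\nfoal3\t.\t.\n")
    with pytest.raises(ValidationError):
        read_pedigree(bad)


# ---------------------------------------------------------------------------
# Normalization


def brute_force_trim(pos, ref, alt):
    """Single-base trim steps applied exhaustively (oracle)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


def test_normalize_trims_shared_context():
    rec = normalize_variant(make_record(pos=100, ref="TGG", alts=("TAG",)))
    assert (rec.pos, rec.ref, rec.alts) == (101, "G", ("A",))
    assert brute_force_trim(100, "TGG", "TAG") == (101, "G", "A")


def test_normalize_leaves_minimal_insertion_unchanged():
    rec = normalize_variant(make_record(chrom="chr18", pos=66607750, ref="C", alts=("CT",)))
    assert (rec.pos, rec.ref, rec.alts) == (66607750, "C", ("CT",))


def test_normalize_rejects_non_variant():
    with pytest.raises(ValidationError):
        normalize_key("chr1", 100, "TAG", "TAG")


alleles = st.text(alphabet="ACGT", min_size=1, max_size=6)


@settings(max_examples=200, deadline=None)
@given(pos=st.integers(1, 1000), ref=alleles, alt=alleles)
def test_normalize_key_matches_oracle_and_is_idempotent(pos, ref, alt):
    if ref == alt:
        return
    exp_pos, exp_ref, exp_alt = brute_force_trim(pos, ref, alt)
    if exp_ref == exp_alt:
        return
    key = normalize_key("c", pos, ref, alt)
    assert key == ("c", exp_pos, exp_ref, exp_alt)
    assert normalize_key(*key) == key


@settings(max_examples=200, deadline=None)
@given(
    pos=st.integers(5, 50),
    ref=alleles,
    alt=alleles,
    left=st.text(alphabet="ACGT", min_size=4, max_size=8),
    right=st.text(alphabet="ACGT", min_size=4, max_size=8),
)
def test_normalization_preserves_the_edited_sequence(pos, ref, alt, left, right):
    """Applying original vs normalized variant to a flanking context gives the
    same edited string (brute-force haplotype oracle)."""
    if ref == alt:
        return
    try:
        key = normalize_key("c", pos, ref, alt)
    except ValidationError:
        return
    context = left + ref + right  # ref starts at 1-based `pos` == len(left)+1 offset
    start = len(left)
    edited_raw = context[:start] + alt + context[start + len(ref):]
    offset = key.pos - pos
    edited_norm = (
        context[: start + offset] + key.alt + context[start + offset + len(key.ref):]
    )
    assert edited_raw == edited_norm


def test_chrom_overlap_warning(caplog, panel):
    rec = make_record(chrom="chrZ", pos=5, ref="A", alts=("T",))
    with caplog.at_level("WARNING"):
        assert not formats_io.check_chrom_overlap(panel, [rec])
    assert "zero chromosome" in caplog.text
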