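"""Mendelian checkers vs exhaustive enumeration; He/PE statistics; Table-shape
reports."""

import itertools
import math

import numpy as np
import pytest

from gedscreen.coverage_qc import round_half_up
from gedscreen.parentage import (
    CONSISTENT,
    INCONSISTENT,
    NO_CALL,
    ExclusionResult,
    PedigreeTest,
    combined_pe,
    count_exclusions,
    drop_misinheriting_loci,
    duo_consistent,
    heterozygosity,
    mean_exclusions,
    panel_report,
    pe1,
    pe2,
    trio_consistent,
    truncate,
)
from gedscreen.synthetic_data import (
    PedigreeDesign,
    extended_panel,
    matrix_from_pairs,
    simulate_genotyping_faults,
    simulate_pedigree_suite,
)
from gedscreen.types import (
    GedscreenError,
    GenotypeCall,
    GenotypeMatrix,
    PanelLocus,
    PedigreeEntry,
    Zygosity,
)

GENOTYPES = [(0, 0), (0, 1), (1, 1)]  # AA, AB, BB


def call_for(sample, gt, locus="L"):
    if gt is None:
        return GenotypeCall(sample, locus, Zygosity.NO_CALL)
    zyg = {(0, 0): Zygosity.HOMO_REF, (0, 1): Zygosity.HET, (1, 1): Zygosity.HOMO_ALT}[gt]
    return GenotypeCall(sample, locus, zyg, gt, depth=200)


def mendelian_trio_oracle(child, sire, dam):
    """Exhaustive enumeration of transmissible allele pairs."""
    possible = {
        tuple(sorted((a, b))) for a in sire for b in dam
    }
    return tuple(sorted(child)) in possible


def mendelian_duo_oracle(child, parent):
    return bool(set(child) & set(parent))


def test_trio_checker_matches_exhaustive_enumeration():
    """All 27 biallelic genotype combinations agree with the brute-force oracle."""
    for child, sire, dam in itertools.product(GENOTYPES, repeat=3):
        verdict = trio_consistent(call_for("c", child), call_for("s", sire), call_for("d", dam))
        expected = CONSISTENT if mendelian_trio_oracle(child, sire, dam) else INCONSISTENT
        assert verdict == expected, (child, sire, dam)


def test_duo_checker_matches_exhaustive_enumeration():
    for child, parent in itertools.product(GENOTYPES, repeat=2):
        verdict = duo_consistent(call_for("c", child), call_for("p", parent))
        expected = CONSISTENT if mendelian_duo_oracle(child, parent) else INCONSISTENT
        assert verdict == expected
    # the single biallelic duo exclusion configuration: opposite homozygotes
    assert duo_consistent(call_for("c", (0, 0)), call_for("p", (1, 1))) == INCONSISTENT


def test_trio_consistency_implies_both_duo_consistencies():
    for child, sire, dam in itertools.product(GENOTYPES, repeat=3):
        if trio_consistent(call_for("c", child), call_for("s", sire), call_for("d", dam)) == CONSISTENT:
            assert duo_consistent(call_for("c", child), call_for("s", sire)) == CONSISTENT
            assert duo_consistent(call_for("c", child), call_for("d", dam)) == CONSISTENT


def test_no_call_propagates():
    assert trio_consistent(call_for("c", None), call_for("s", (0, 0)), call_for("d", (0, 0))) == NO_CALL
    assert duo_consistent(call_for("c", (0, 1)), call_for("p", None)) == NO_CALL


def test_locus_mismatch_raises():
    with pytest.raises(GedscreenError):
        trio_consistent(call_for("c", (0, 0), "A"), call_for("s", (0, 0), "B"),
                        call_for("d", (0, 0), "A"))


def small_panel(n=6):
    return [PanelLocus(f"L{i}", "1", 100 + i, "A", "G", 0.5) for i in range(n)]


def test_count_exclusions_error_free_trio_is_clean(panel):
    suite = simulate_pedigree_suite(panel, PedigreeDesign(trios=1, pseudo_trios=0,
                                                          half_pseudo_trios=0, duos=0,
                                                          pseudo_duos=0), seed=31)
    result = count_exclusions(suite.matrix, suite.tests[0], panel)
    assert result.inconsistent == 0 and result.no_call == 0
    assert result.consistent == 120


def test_count_exclusions_constructed_opposite_homozygotes():
    panel = small_panel(6)
    k = 4
    pairs = {
        "c": [(0, 0)] * 6,
        "s": [(1, 1)] * k + [(0, 0)] * 2,  # opposite homozygote at k loci
        "d": [(0, 0)] * 6,
    }
    matrix = matrix_from_pairs(pairs, panel)
    test = PedigreeTest(PedigreeEntry("c", "s", "d"), "trio")
    result = count_exclusions(matrix, test, panel)
    assert result.inconsistent == k
    assert set(result.inconsistent_loci) == {f"L{i}" for i in range(k)}


def test_count_exclusions_nocall_tally():
    panel = small_panel(3)
    pairs = {"c": [(0, 1)] * 3, "s": [(0, 1)] * 3, "d": [(0, 1)] * 3}
    matrix = matrix_from_pairs(pairs, panel)
    matrix.set(GenotypeCall("d", "L1", Zygosity.NO_CALL))
    result = count_exclusions(matrix, PedigreeTest(PedigreeEntry("c", "s", "d"), "trio"), panel)
    assert (result.consistent, result.inconsistent, result.no_call) == (2, 0, 1)
    with pytest.raises(GedscreenError, match="ghost"):
        count_exclusions(matrix, PedigreeTest(PedigreeEntry("c", "ghost", "d"), "trio"), panel)


def test_panel_pruning_retains_120_of_144(panel):
    """Faults planted at 24 synthetic loci are all flushed out by true trios."""
    panel144 = extended_panel(panel, 24, seed=99)
    suite = simulate_pedigree_suite(panel144, PedigreeDesign(), seed=199)
    faults = {l.id: ("low_depth" if i % 2 else "allele_bias")
              for i, l in enumerate(panel144[120:])}
    matrix = simulate_genotyping_faults(suite, panel144, faults, seed=299)
    trios = [t for t in suite.tests if t.kind == "trio"]
    results = [count_exclusions(matrix, t, panel144) for t in trios]
    kept = drop_misinheriting_loci(panel144, results)
    assert len(kept) == 120
    assert [l.id for l in kept] == [l.id for l in panel]  # order preserved
    # pruned panel is clean across all trios
    clean = [count_exclusions(matrix, t, kept) for t in trios]
    assert all(r.inconsistent == 0 for r in clean)


def test_pruning_is_set_like_and_stable():
    panel = small_panel(4)
    result = ExclusionResult(
        PedigreeTest(PedigreeEntry("c", "s", "d"), "trio"), 2, 2, 0, ("L1", "L3")
    )
    twice = [result, result, result]
    assert [l.id for l in drop_misinheriting_loci(panel, twice)] == ["L0", "L2"]
    assert drop_misinheriting_loci(panel, []) == list(panel)


# ---------------------------------------------------------------------------
# Closed forms


@pytest.mark.parametrize(
    "p, he, e1, e2",
    [
        (0.847, 0.259, 0.113, 0.034),
        (0.582, 0.487, 0.184, 0.118),
        (0.500, 0.500, 0.188, 0.125),
    ],
)
def test_published_spot_rows(p, he, e1, e2):
    assert round_half_up(heterozygosity(p), 3) == he
    assert round_half_up(pe1(p), 3) == e1
    assert round_half_up(pe2(p), 3) == e2


def test_closed_form_edges_and_domain():
    assert heterozygosity(1.0) == 0.0
    assert pe1(0.0) == 0.0 and pe2(1.0) == 0.0
    assert pe1(0.5) == 0.1875 and pe2(0.5) == 0.125
    for fn in (heterozygosity, pe1, pe2):
        with pytest.raises(GedscreenError):
            fn(1.2)


def test_symmetry_and_maxima():
    grid = np.linspace(0.0, 1.0, 101)
    for fn, peak in ((heterozygosity, 0.5), (pe1, 0.1875), (pe2, 0.125)):
        vals = [fn(p) for p in grid]
        assert np.allclose(vals, vals[::-1])
        assert max(vals) == pytest.approx(peak)
        assert np.argmax(vals) == 50


def test_combined_pe_basics():
    assert combined_pe([]) == 0.0
    assert combined_pe([0.5, 0.5]) == pytest.approx(0.75)
    with pytest.raises(GedscreenError):
        combined_pe([1.0])
    # monotone nondecreasing in panel size, order-invariant
    vals = [0.1, 0.05, 0.2, 0.15]
    seq = [combined_pe(vals[:i]) for i in range(len(vals) + 1)]
    assert seq == sorted(seq)
    assert combined_pe(vals) == pytest.approx(combined_pe(vals[::-1]))


def test_combined_pe_reproduces_published_figures(panel):
    """Across the 120-SNV panel the combined exclusion powers, truncated at
    printed precision, equal 0.9999999998 (trio) and 0.999997 (duo)."""
    c1 = combined_pe([pe1(l.ref_freq) for l in panel], digits=10)
    c2 = combined_pe([pe2(l.ref_freq) for l in panel], digits=6)
    assert c1 == 0.9999999998
    assert c2 == 0.999997


def test_panel_report_against_printed_columns(panel, panel_frame):
    """Recomputed He/PE1/PE2 track the printed columns to within 0.001 (the
    published columns were derived from unrounded frequencies, so exact 3-dp
    agreement is not attainable from the printed p); combined values match."""
    stats, c1, c2 = panel_report(panel)
    assert len(stats) == 120
    for s, (_, row) in zip(stats, panel_frame.iterrows()):
        assert abs(s.he - row["He"]) <= 0.001
        assert abs(s.pe1 - row["PE1"]) <= 0.001
        assert abs(s.pe2 - row["PE2"]) <= 0.001
    assert (c1, c2) == (0.9999999998, 0.999997)


def test_truncation_is_toward_zero():
    assert truncate(0.9999999998655, 10) == 0.9999999998
    assert truncate(0.9999978, 6) == 0.999997
    assert truncate(0.1239, 3) == 0.123


def test_mean_exclusions_matches_published_means(inheritance_counts):
    """Half-pseudo-trio and pseudo-parent-foal 120-SNV inconsistent counts
    average to 20.4 and 9.8."""
    df = inheritance_counts
    half = df[df["kind"] == "half_pseudo_trio"]["inconsistent_120"].tolist()
    pparent = df[df["kind"] == "pseudo_parent_foal"]["inconsistent_120"].tolist()
    assert half == [18, 25, 21, 23, 15]
    assert round_half_up(mean_exclusions(half), 1) == 20.4
    assert pparent == [11, 12, 10, 10, 6]
    assert round_half_up(mean_exclusions(pparent), 1) == 9.8
    assert mean_exclusions([7, 7, 7]) == 7.0
    with pytest.raises(GedscreenError):
        mean_exclusions([])


# ---------------------------------------------------------------------------
# Monte-Carlo validation of the closed forms


def test_pseudo_duo_exclusions_converge_to_sum_pe2(panel):
    """Unrelated child-adult duos under HWE exclude at Sum(2 p^2 q^2) loci on
    average (10,000 replicates, 3 se), validating PE2 against its definition."""
    rng = np.random.default_rng(13)
    p = np.array([l.ref_freq for l in panel])
    n = 10_000

    def draw(n):
        u = rng.random((n, p.size))
        return (u > p * p).astype(int) + (u > p * p + 2 * p * (1 - p)).astype(int)

    child, adult = draw(n), draw(n)
    exclusions = (np.abs(child - adult) == 2).sum(axis=1)
    expected = sum(pe2(l.ref_freq) for l in panel)
    var = sum(pe2(l.ref_freq) * (1 - pe2(l.ref_freq)) for l in panel)
    se = math.sqrt(var / n)
    assert abs(exclusions.mean() - expected) <= 3 * se


def test_random_male_per_locus_exclusion_rate_converges_to_pe1():
    """For true mother-child pairs tested against random males, the per-locus
    exclusion rate matches PE1(p) (trio-with-one-known-parent power)."""
    rng = np.random.default_rng(29)
    p = 0.3
    n = 10_000

    def genos(n):
        u = rng.random(n)
        return (u > p * p).astype(int) + (u > p * p + 2 * p * (1 - p)).astype(int)

    def draw_allele(code, rng):
        # code = number of ALT alleles; transmit one uniformly
        return np.where(code == 1, rng.integers(0, 2, code.size), (code == 2).astype(int))

    mother, father, male = genos(n), genos(n), genos(n)
    child = draw_allele(mother, rng) + draw_allele(father, rng)
    # verdict via the package checker on each replicate
    excluded = 0
    for c, m, x in zip(child, mother, male):
        gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        verdict = trio_consistent(call_for("c", gt[c]), call_for("s", gt[x]), call_for("d", gt[m]))
        excluded += verdict == INCONSISTENT
    expected = pe1(p)
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(excluded / n - expected) <= 3 * se
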