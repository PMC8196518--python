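"""PAV calling: window arithmetic, classification thresholds, merging,
clusters, PAV genes, length summary and hypergeometric enrichment."""

import numpy as np
import pytest

from paircomp.genome import Genome
from paircomp.pav import (PavParams, SpecificSegment, call_clusters,
                          call_pav_genes, classify_windows, enrich_pathways,
                          make_windows, merge_specific_windows,
                          summarize_lengths)

from .oracles import bitmap_cds_fraction, bitmap_union_segments, \
    hypergeom_upper_tail


def _genome(length, name="c1"):
    return Genome({name: "A" * length})


# -- windows ---------------------------------------------------------------

@pytest.mark.parametrize("length,expected_starts", [
    (1_000, [0, 100, 200, 300, 400, 500]),
    (500, [0]),
    (1_050, [0, 100, 200, 300, 400, 500, 550]),  # anchored tail window
])
def test_make_windows(length, expected_starts):
    wins = make_windows(_genome(length))
    assert [s for _, s, _ in wins] == expected_starts
    assert all(e - s == 500 for _, s, e in wins)


def test_short_chromosome_skipped():
    with pytest.warns(UserWarning, match="shorter than window"):
        assert make_windows(_genome(300)) == []


def test_classify_thresholds():
    flags = classify_windows([0.19, 0.20, None, 1.0, 0.0])
    assert list(flags) == [True, False, True, False, True]


def test_classify_rejects_bad_coverage():
    with pytest.raises(ValueError, match="coverage"):
        classify_windows([1.5])


# -- merging ---------------------------------------------------------------

def test_merge_union_kept():
    windows = [("c1", 0, 500), ("c1", 100, 600)]
    segs = merge_specific_windows(windows, [True, True])
    assert [(s.chrom, s.start, s.end) for s in segs] == [("c1", 0, 600)]
    assert segs[0].n_supporting_windows == 2


def test_single_window_segment_discarded():
    """A lone flagged window gives a 500-bp segment: not LARGER than
    500 bp, so it is dropped."""
    segs = merge_specific_windows([("c1", 0, 500)], [True])
    assert segs == []


@pytest.mark.parametrize("trial", range(4))
def test_merge_matches_bitmap_oracle(trial):
    local = np.random.default_rng(300 + trial)
    windows = make_windows(_genome(20_000))
    flags = local.random(len(windows)) < 0.3
    segs = merge_specific_windows(windows, flags)
    got = sorted((s.chrom, s.start, s.end) for s in segs)
    flagged = [w for w, f in zip(windows, flags) if f]
    assert got == bitmap_union_segments(flagged, 500)


def test_segments_do_not_overlap(small_result):
    for segs in (small_result.segments_a, small_result.segments_b):
        by_chrom: dict[str, list] = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for i in range(1, len(ivs)):
                assert ivs[i][0] >= ivs[i - 1][1]


# -- clusters --------------------------------------------------------------

def test_cluster_density_rule():
    # two 1-kb segments 49 kb apart: span 51 kb, density ~0.039 -> none
    segs = [SpecificSegment("A", "c1", 0, 1_000),
            SpecificSegment("A", "c1", 50_000, 51_000)]
    assert call_clusters(segs) == []
    # three 2-kb segments inside a 30-kb span: density 0.2 -> cluster
    segs = [SpecificSegment("A", "c1", 0, 2_000),
            SpecificSegment("A", "c1", 14_000, 16_000),
            SpecificSegment("A", "c1", 28_000, 30_000)]
    (cl,) = call_clusters(segs)
    assert (cl.start, cl.end) == (0, 30_000)
    assert cl.density == pytest.approx(0.2)


def test_clusters_empty_input():
    assert call_clusters([]) == []


# -- PAV genes -------------------------------------------------------------

def test_pav_gene_threshold():
    segs = [SpecificSegment("A", "c1", 0, 800)]
    ann = {"t1": [("c1", 0, 1_000)]}
    (hit,) = call_pav_genes(segs, ann)
    assert hit["gene_id"] == "t1" and hit["fraction"] == pytest.approx(0.8)
    segs = [SpecificSegment("A", "c1", 0, 700)]
    assert call_pav_genes(segs, ann) == []  # 0.70 <= 0.75


def test_pav_gene_no_cds_warns():
    with pytest.warns(UserWarning, match="no CDS"):
        assert call_pav_genes([], {"t1": []}) == []


@pytest.mark.parametrize("trial", range(3))
def test_multi_exon_fraction_matches_bitmap(trial):
    local = np.random.default_rng(400 + trial)
    segs = [SpecificSegment("A", "c1", int(s), int(s) + int(local.integers(200, 900)))
            for s in local.integers(0, 9_000, size=5)]
    cds = [("c1", int(s), int(s) + int(local.integers(100, 400)))
           for s in local.integers(0, 9_000, size=3)]
    hits = call_pav_genes(segs, {"tx": cds}, PavParams(gene_cds_fraction=0.0))
    exp = bitmap_cds_fraction(cds, [(s.chrom, s.start, s.end) for s in segs])
    if exp > 0.0:
        assert hits and hits[0]["fraction"] == pytest.approx(exp, abs=1e-4)


def test_gff3_parsing(tmp_path):
    gff = tmp_path / "ann.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "c1\tsrc\tgene\t1\t2000\t.\t+\t.\tID=g1\n"
        "c1\tsrc\tmRNA\t1\t2000\t.\t+\t.\tID=t1;Parent=g1\n"
        "c1\tsrc\tCDS\t1\t500\t.\t+\t0\tID=c1a;Parent=t1\n"
        "c1\tsrc\tCDS\t1001\t1500\t.\t+\t0\tID=c1b;Parent=t1\n")
    segs = [SpecificSegment("A", "c1", 0, 500),
            SpecificSegment("A", "c1", 1_000, 1_400)]
    (hit,) = call_pav_genes(segs, gff)
    assert hit["cds_len"] == 1_000 and hit["covered"] == 900


# -- length summary --------------------------------------------------------

def test_length_summary_printed_counts():
    """18,584 segments with 178 above 5 kb -> 99.04% below."""
    lengths = [1_000] * (18_584 - 178) + [6_000] * 178
    s = summarize_lengths(lengths, 5_000)
    assert s["n_total"] == 18_584 and s["n_above_cutoff"] == 178
    assert s["percent_below"] == 99.04


def test_length_summary_all_below_and_empty():
    assert summarize_lengths([100, 200], 5_000)["percent_below"] == 100.0
    assert summarize_lengths([], 5_000)["percent_below"] is None


def test_length_summary_recount(rng):
    lengths = list(rng.integers(501, 10_000, size=500))
    s = summarize_lengths(lengths, 5_000)
    n_above = sum(1 for x in lengths if x > 5_000)
    assert s["n_above_cutoff"] == n_above
    assert s["percent_below"] == round(100 * (500 - n_above) / 500, 2)


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.lists(st.integers(1, 20_000), max_size=80),
       st.integers(1_000, 10_000))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_length_summary_always_matches_recount(lengths, cutoff):
    s = summarize_lengths(lengths, cutoff)
    assert s["n_above_cutoff"] == sum(1 for x in lengths if x > cutoff)
    if lengths:
        assert s["percent_below"] == round(
            100 * (len(lengths) - s["n_above_cutoff"]) / len(lengths), 2)
    else:
        assert s["percent_below"] is None


# -- enrichment ------------------------------------------------------------

def test_hypergeom_exact_value():
    universe = {f"g{i}" for i in range(10)}
    pav = {f"g{i}" for i in range(5)}
    term_members = {"g0", "g1", "g2", "g7"}  # K=4, k=3 among draws g0..g4
    gene2term = {g: {"T"} for g in term_members}
    df = enrich_pathways(pav, gene2term, universe)
    assert df.loc[0, "p_raw"] == pytest.approx(66 / 252)
    assert df.loc[0, "p_raw"] == pytest.approx(hypergeom_upper_tail(3, 10, 4, 5))


def test_hypergeom_normalisation_and_tail():
    universe = {f"g{i}" for i in range(8)}
    gene2term = {"g7": {"T"}}  # K=1, k=0 among draws
    df = enrich_pathways({"g0", "g1"}, gene2term, universe)
    assert df.loc[0, "p_raw"] == pytest.approx(hypergeom_upper_tail(0, 8, 1, 2))
    assert hypergeom_upper_tail(0, 8, 1, 2) == 1.0
    # k = n = K: single-term tail equals the lone pmf value
    gene2term = {"g0": {"S"}, "g1": {"S"}}
    df = enrich_pathways({"g0", "g1"}, gene2term, universe)
    assert df.loc[0, "p_raw"] == pytest.approx(hypergeom_upper_tail(2, 8, 2, 2))


def test_enrich_requires_subset():
    with pytest.raises(ValueError, match="subset"):
        enrich_pathways({"x"}, {}, {"y"})


# -- recovery and symmetry on the simulated pair ---------------------------

def test_pav_recovery_and_symmetry(small_pair, small_result):
    """Planted insertions into B are reported B-specific, deletions from B
    (A material) A-specific, with breakpoints within one window step."""
    _, _, truth = small_pair
    for label, called in (("A", small_result.segments_a),
                          ("B", small_result.segments_b)):
        planted = [p for p in truth.pav_segments if p.genome == label]
        assert planted, "fixture must plant PAV on both sides"
        hits = 0
        for p in planted:
            if any(s.chrom == p.chrom and abs(s.start - p.start) <= 100
                   and abs(s.end - p.end) <= 100 for s in called):
                hits += 1
        assert hits / len(planted) >= 0.9
        matched_called = sum(
            1 for s in called
            if any(s.chrom == p.chrom and abs(s.start - p.start) <= 100
                   and abs(s.end - p.end) <= 100 for p in planted))
        assert matched_called / len(called) >= 0.9
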