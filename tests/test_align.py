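"""Aligner: MEM enumeration, chaining, polishing, block filters and
window mapping, each against an independent brute-force oracle."""

import numpy as np
import pytest

from paircomp.align import (AlignParams, AlignmentBlock, Anchor, align_genomes,
                            chain_anchors, filter_colinear, filter_one_to_one,
                            find_anchors, map_window, polish_block)
from paircomp.genome import Genome, revcomp

from .oracles import (best_chain_exhaustive, best_conflict_free_subset,
                      best_monotone_chain, mem_bruteforce, nw_edits,
                      smith_waterman_best_score)


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# -- find_anchors ----------------------------------------------------------

def test_identical_sequences_single_anchor():
    got = find_anchors("ACGTACGTAC", "ACGTACGTAC", 10)
    plus = [a for a in got if a.strand == "+"]
    assert plus == [Anchor(0, 0, 10, "+")]


def test_no_shared_kmer_empty():
    assert find_anchors("A" * 40, "C" * 40, 20) == []


def test_empty_sequence_empty_list():
    assert find_anchors("", "ACGT" * 10, 8) == []


@pytest.mark.parametrize("trial", range(6))
def test_find_anchors_matches_bruteforce(rng, trial):
    """MEM set on random 200-bp pairs equals the O(n^2) substring oracle,
    including reverse-complement matches and N exclusion."""
    local = np.random.default_rng(100 + trial)
    ref = _rand_seq(local, 200)
    query = (ref[50:120] + _rand_seq(local, 40) + revcomp(ref[140:180])
             + ("N" * 5 if trial % 2 else "") + ref[10:30])
    got = {(a.ref_pos, a.query_pos, a.length, a.strand)
           for a in find_anchors(ref, query, 8)}
    assert got == mem_bruteforce(ref, query, 8)


# -- chaining --------------------------------------------------------------

def test_single_anchor_single_chain():
    chains = chain_anchors([Anchor(0, 0, 30, "+")], AlignParams())
    assert chains == [[Anchor(0, 0, 30, "+")]]


def test_two_collinear_anchors_one_chain():
    a, b = Anchor(0, 0, 30, "+"), Anchor(130, 128, 40, "+")
    assert chain_anchors([a, b], AlignParams()) == [[a, b]]


@pytest.mark.parametrize("trial", range(4))
def test_best_chain_score_matches_exhaustive(trial):
    """Best extracted chain score equals exhaustive search over all
    collinear chains of 15 random anchors."""
    local = np.random.default_rng(7 + trial)
    anchors = [Anchor(int(local.integers(0, 3000)), int(local.integers(0, 3000)),
                      int(local.integers(15, 60)), "+") for _ in range(15)]
    params = AlignParams(max_anchor_gap=800)
    chains = chain_anchors(anchors, params)
    got = max(sum(a.length for a in c) for c in chains)
    exp = best_chain_exhaustive([(a.ref_pos, a.query_pos, a.length)
                                 for a in anchors], 800, params.min_mem_len - 1)
    assert got == exp


# -- polish ----------------------------------------------------------------

def test_polish_identity_trivials(rng):
    seq = _rand_seq(rng, 1000)
    chain = chain_anchors(find_anchors(seq, seq, 20), AlignParams())[0]
    (block,) = polish_block(chain, seq, seq, AlignParams())
    assert block.identity == 100.0

    mutated = list(seq)
    mutated[500] = {"A": "C"}.get(seq[500], "A")
    mutated = "".join(mutated)
    chain = chain_anchors(find_anchors(seq, mutated, 20), AlignParams(),
                          query_len=1000)[0]
    (block,) = polish_block(chain, seq, mutated, AlignParams())
    assert block.identity == pytest.approx(99.9)
    assert block.aligned_len == 1000 and block.n_matches == 999


def _unambiguous_indel_pos(seq, near):
    """A position whose base differs from both neighbours, so removing or
    flanking-inserting there has a unique optimal alignment."""
    for p in range(near, near + 50):
        if seq[p] != seq[p - 1] and seq[p] != seq[p + 1]:
            return p
    raise AssertionError("no suitable position")


def test_polish_edit_list_matches_nw_oracle(rng):
    """Five isolated planted edits in 500 bp: polished edit list equals
    the full quadratic DP oracle's (unique optimum by construction)."""
    local = np.random.default_rng(77)
    ref = _rand_seq(local, 500)
    q = list(ref)
    q[60] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[60]]
    q[160] = {"A": "G", "C": "T", "G": "A", "T": "C"}[q[160]]
    p_del = _unambiguous_indel_pos(ref, 260)
    del q[p_del]
    p_ins = _unambiguous_indel_pos(ref, 360)
    ins_base = next(b for b in "ACGT" if b not in (ref[p_ins - 1], ref[p_ins]))
    q.insert(p_ins - 1, ins_base)
    q[450] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[450]]
    query = "".join(q)
    chain = chain_anchors(find_anchors(ref, query, 12),
                          AlignParams(min_mem_len=12), query_len=len(query))[0]
    (block,) = polish_block(chain, ref, query, AlignParams(min_mem_len=12))
    # oracle over the same aligned span
    oref = ref[block.ref_start:block.ref_end]
    oq = query[block.query_start:block.query_end]
    assert block.edits == nw_edits(oref, oq)


def test_block_edit_length_invariant(small_result):
    for b in small_result.one_to_one:
        ref_consumed = sum(ln for op, ln in b.edits if op in "=XD")
        q_consumed = sum(ln for op, ln in b.edits if op in "=XI")
        assert ref_consumed == b.ref_end - b.ref_start
        assert q_consumed == b.query_end - b.query_start
        assert 0 <= b.identity <= 100


# -- filters ---------------------------------------------------------------

def _mk_block(rc, rs, re_, qc, qs, qe, score, strand="+", identity=99.0):
    return AlignmentBlock(rc, rs, re_, qc, qs, qe, strand, identity, score)


def test_one_to_one_dominance():
    b1 = _mk_block("r", 0, 900, "q", 0, 900, 900.0)
    b2 = _mk_block("r", 2000, 2500, "q", 100, 600, 500.0)  # query overlap
    kept = filter_one_to_one([b1, b2], AlignParams())
    assert kept == [b1]


def test_identity_threshold_is_90():
    low = _mk_block("r", 0, 500, "q", 0, 500, 450.0, identity=89.9)
    assert filter_one_to_one([low], AlignParams()) == []
    ok = _mk_block("r", 0, 500, "q", 0, 500, 450.0, identity=90.0)
    assert filter_one_to_one([ok], AlignParams()) == [ok]


@pytest.mark.parametrize("trial", range(4))
def test_one_to_one_matches_exhaustive_subset_search(trial):
    """Kept-set total score equals brute force over all conflict-free
    subsets of 12 random blocks."""
    local = np.random.default_rng(50 + trial)
    blocks = []
    for _ in range(12):
        rs = int(local.integers(0, 5_000))
        qs = int(local.integers(0, 5_000))
        ln = int(local.integers(200, 1_500))
        blocks.append(_mk_block(f"r{local.integers(2)}", rs, rs + ln,
                                f"q{local.integers(2)}", qs, qs + ln,
                                float(local.integers(100, 2_000))))
    kept = filter_one_to_one(blocks, AlignParams())
    got = sum(b.score for b in kept)
    exp = best_conflict_free_subset(
        [(b.ref_chrom, b.ref_start, b.ref_end, b.query_chrom,
          b.query_start, b.query_end, b.score) for b in blocks])
    assert got == pytest.approx(exp)


def test_colinear_passthrough_and_inversion_removal():
    blocks = [_mk_block("r", 0, 1000, "q", 0, 1000, 1000.0),
              _mk_block("r", 1000, 2000, "q", 1000, 2000, 1000.0, "-"),
              _mk_block("r", 2000, 3000, "q", 2000, 3000, 1000.0)]
    col = filter_colinear(blocks, AlignParams())
    assert [b.strand for b in col] == ["+", "+"]
    all_plus = [blocks[0], blocks[2]]
    assert filter_colinear(all_plus, AlignParams()) == all_plus


@pytest.mark.parametrize("trial", range(4))
def test_colinear_matches_lis_oracle(trial):
    local = np.random.default_rng(90 + trial)
    blocks = []
    pos = 0
    for _ in range(10):
        rs = pos
        ln = int(local.integers(200, 800))
        qs = int(local.integers(0, 6_000))
        blocks.append(_mk_block("r", rs, rs + ln, "q", qs, qs + ln,
                                float(ln), "+" if local.random() < 0.8 else "-"))
        pos = rs + ln + int(local.integers(0, 200))
    col = filter_colinear(blocks, AlignParams())
    got = sum(b.score for b in col)
    oto = filter_one_to_one(blocks, AlignParams())
    exp = best_monotone_chain(
        [(b.ref_chrom, b.ref_start, b.ref_end, b.query_chrom, b.query_start,
          b.query_end, b.score, b.strand) for b in oto])
    assert got == pytest.approx(exp)


def test_colinear_subset_of_one_to_one(small_result):
    oto_keys = {(b.ref_chrom, b.ref_start, b.ref_end, b.query_chrom,
                 b.query_start, b.query_end) for b in small_result.one_to_one}
    for b in small_result.colinear:
        assert (b.ref_chrom, b.ref_start, b.ref_end, b.query_chrom,
                b.query_start, b.query_end) in oto_keys


def test_one_to_one_no_overlap_sweep(small_result):
    for axis in ("ref", "query"):
        ivs: dict[str, list] = {}
        for b in small_result.one_to_one:
            ivs.setdefault(getattr(b, f"{axis}_chrom"), []).append(
                (getattr(b, f"{axis}_start"), getattr(b, f"{axis}_end")))
        for chrom, v in ivs.items():
            v.sort()
            for i in range(1, len(v)):
                assert v[i][0] >= v[i - 1][1], (axis, chrom, v[i - 1], v[i])


# -- whole-genome invariants ----------------------------------------------

def test_no_sv_pair_high_coverage_high_identity(nosv_pair):
    """With point mutations only (SNP rate 1e-3), one-to-one blocks must
    cover >= 99% of both genomes at >= 99% identity."""
    A, B, _ = nosv_pair
    oto = filter_one_to_one(align_genomes(A, B), AlignParams())
    cov_a = sum(b.ref_end - b.ref_start for b in oto) / A.total_length()
    cov_b = sum(b.query_end - b.query_start for b in oto) / B.total_length()
    assert cov_a >= 0.99 and cov_b >= 0.99
    assert all(b.identity >= 99.0 for b in oto)


# -- map_window ------------------------------------------------------------

def test_map_window_verbatim(rng):
    g = Genome({"c1": _rand_seq(rng, 20_000)})
    cov, hit = map_window(g["c1"][3_000:3_500], g)
    assert cov == 1.0 and hit["chrom"] == "c1" and hit["start"] == 3_000


def test_map_window_absent(rng):
    g = Genome({"c1": "AT" * 5_000})
    cov, hit = map_window("GC" * 250, g)
    assert cov == 0.0 and hit is None


def test_map_window_partial_matches_local_dp(rng):
    """Window with its first 400 of 500 bp foreign: coverage ~0.2,
    cross-checked against a Smith-Waterman oracle on the local region."""
    local = np.random.default_rng(11)
    target_seq = _rand_seq(local, 5_000)
    g = Genome({"c1": target_seq})
    window = _rand_seq(local, 400) + target_seq[2_000:2_100]
    cov, hit = map_window(window, g)
    score = smith_waterman_best_score(window, target_seq[1_900:2_200])
    assert cov == pytest.approx(score / len(window), abs=0.05)
    assert cov == pytest.approx(0.2, abs=0.05)
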