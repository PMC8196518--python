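"""Variant calling, indel merging, SNP density windows and enrichment."""

import numpy as np
import pandas as pd
import pytest

from paircomp.align import AlignParams, align_genomes, filter_one_to_one
from paircomp.errors import ContractViolation
from paircomp.genome import Genome
from paircomp.variants import (DensityParams, VariantRecord, call_variants,
                               density_summary, enrichment_regions,
                               merge_adjacent_indels, snp_density)

from .oracles import edits_to_variants, nw_edits


def _call(ref_seq, query_seq, min_mem=12):
    A, B = Genome({"c1": ref_seq}), Genome({"c1": query_seq})
    params = AlignParams(min_mem_len=min_mem)
    oto = filter_one_to_one(align_genomes(A, B, params), params)
    return call_variants(oto, A, B), oto


def test_identical_genomes_zero_variants(rng):
    seq = "".join(rng.choice(list("ACGT"), size=2_000))
    variants, _ = _call(seq, seq)
    assert variants == []


def test_single_substitution(rng):
    seq = "".join(rng.choice(list("ACGT"), size=2_000))
    q = list(seq)
    q[900] = {"A": "G", "C": "T", "G": "A", "T": "C"}[q[900]]
    variants, _ = _call(seq, "".join(q))
    assert len(variants) == 1
    v = variants[0]
    assert (v.kind, v.ref_pos, v.ref_allele, v.query_allele) == \
        ("SNP", 900, seq[900], q[900])


def test_call_variants_matches_dp_oracle():
    """Ten isolated planted edits in 1 kb: record list equals the
    column-by-column read-out of the quadratic DP oracle."""
    local = np.random.default_rng(55)
    ref = "".join(local.choice(list("ACGT"), size=1_000))
    q = list(ref)
    # 8 substitutions, spaced >= 60 bp
    for p in range(100, 900, 115):
        q[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[p]]
    # one unambiguous deletion and one unambiguous insertion
    def uniq(p0):
        for p in range(p0, p0 + 60):
            if ref[p] != ref[p - 1] and ref[p] != ref[p + 1]:
                return p
        raise AssertionError
    p_del = uniq(530)
    del q[p_del]
    p_ins = uniq(760)
    base = next(b for b in "ACGT" if b not in (ref[p_ins - 1], ref[p_ins]))
    q.insert(p_ins - 1, base)
    query = "".join(q)
    variants, oto = _call(ref, query)
    (block,) = oto
    exp_edits = nw_edits(ref[block.ref_start:block.ref_end],
                         query[block.query_start:block.query_end])
    exp = [(k, block.ref_start + p, r, a) for k, p, r, a in
           edits_to_variants(exp_edits, ref[block.ref_start:block.ref_end],
                             query[block.query_start:block.query_end])]
    got = [(v.kind, v.ref_pos, v.ref_allele, v.query_allele) for v in variants]
    assert got == exp


def test_block_without_edits_raises():
    from paircomp.align import AlignmentBlock
    blk = AlignmentBlock("c1", 0, 100, "c1", 0, 100, "+", 100.0, 100.0, None)
    with pytest.raises(ContractViolation, match="edit detail"):
        call_variants([blk], Genome({"c1": "A" * 100}), Genome({"c1": "A" * 100}))


# -- indel merging ---------------------------------------------------------

def _del1(pos, qpos, base="A"):
    return VariantRecord("deletion", "c1", pos, "c1", qpos, base, "-", 1)


def _ins1(pos, qpos, base="A"):
    return VariantRecord("insertion", "c1", pos, "c1", qpos, "-", base, 1)


def test_three_consecutive_deletions_merge():
    vs = [_del1(10, 5, "A"), _del1(11, 5, "C"), _del1(12, 5, "G")]
    (merged,) = merge_adjacent_indels(vs)
    assert merged.kind == "deletion" and merged.length == 3
    assert merged.ref_pos == 10 and merged.ref_allele == "ACG"


def test_separated_insertions_not_merged():
    vs = [_ins1(10, 5), _ins1(10, 7)]  # a matched query base in between
    assert len(merge_adjacent_indels(vs)) == 2


def test_snps_pass_through_unchanged():
    snp = VariantRecord("SNP", "c1", 3, "c1", 3, "A", "G", 1)
    vs = [snp, _del1(10, 8), _del1(11, 8)]
    out = merge_adjacent_indels(vs)
    assert snp in out and len(out) == 2


@pytest.mark.parametrize("trial", range(3))
def test_merge_matches_runlength_scan(trial):
    """Random single-base indel pattern: merged output equals a direct
    run-length scan over consecutive same-kind positions."""
    local = np.random.default_rng(600 + trial)
    pos = sorted(local.choice(2_000, size=60, replace=False))
    kinds = local.choice(["deletion", "insertion"], size=60)
    vs, qp = [], 0
    for p, k in zip(pos, kinds):
        qp = p + int(local.integers(0, 3))
        vs.append(_del1(p, qp) if k == "deletion" else _ins1(p, qp))
    merged = merge_adjacent_indels(vs)
    # oracle: scan runs of same kind at consecutive ref AND query spacing
    runs = []
    for v in vs:
        if runs:
            p = runs[-1][-1]
            if (p.kind == v.kind
                    and ((v.kind == "deletion" and v.ref_pos == p.ref_pos + 1
                          and v.query_pos == p.query_pos)
                         or (v.kind == "insertion" and v.ref_pos == p.ref_pos
                             and v.query_pos == p.query_pos + 1))):
                runs[-1].append(v)
                continue
        runs.append([v])
    assert len(merged) == len(runs)
    for m, r in zip(merged, runs):
        assert m.length == len(r) and m.kind == r[0].kind
        assert m.ref_pos == r[0].ref_pos


# -- density and enrichment ------------------------------------------------

def _snp(chrom, pos):
    return VariantRecord("SNP", chrom, pos, chrom, pos, "A", "G", 1)


def test_density_zero_and_full_window():
    g = Genome({"c1": "A" * 120_000})
    d = snp_density([], g)
    assert (d["count"] == 0).all()
    d = snp_density([_snp("c1", p) for p in range(10_000, 10_121)], g)
    assert d.loc[0, "count"] == 121
    assert list(d["end"] - d["start"]) == [50_000, 50_000, 20_000]


def test_density_conserves_total(rng):
    g = Genome({"c1": "A" * 500_000})
    snps = [_snp("c1", int(p)) for p in rng.integers(0, 500_000, size=777)]
    assert snp_density(snps, g)["count"].sum() == 777


def test_enrichment_threshold_is_fold_times_mean():
    g = Genome({"c1": "A" * 500_000})  # 10 full windows
    snps = []
    for w in range(10):
        n = 181 if w == 0 else 115  # mean 121.6, threshold 182.4
        snps += [_snp("c1", w * 50_000 + i) for i in range(n)]
    d = snp_density(snps, g)
    assert d["count"].mean() == pytest.approx(121.6)
    assert len(enrichment_regions(d)) == 0  # 181 < 1.5 * 121.6
    # the printed-threshold override flags that window
    out = enrichment_regions(d, DensityParams(threshold_override=180))
    assert len(out) == 1 and out.loc[0, "n_snps"] == 181


def test_enrichment_merge_rule():
    d = pd.DataFrame([
        ("c1", 0, 50_000, 200, True),
        ("c1", 50_000, 100_000, 200, True),
        ("c1", 180_000, 230_000, 200, True),
        ("c1", 400_000, 450_000, 0, True),
    ], columns=["chrom", "start", "end", "count", "full"])
    out = enrichment_regions(d, DensityParams(threshold_override=150))
    assert len(out) == 1
    assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 230_000)
    assert out.loc[0, "n_windows"] == 3 and out.loc[0, "n_snps"] == 600


def test_enrichment_none_above_threshold():
    d = pd.DataFrame([("c1", 0, 50_000, 5, True)],
                     columns=["chrom", "start", "end", "count", "full"])
    assert len(enrichment_regions(d, DensityParams(threshold_override=100))) == 0


def test_density_summary_examples():
    snps = [_snp("c1", p) for p in range(100)]
    s = density_summary(snps, [], 50_000)
    assert s["snps_per_kb"] == 2.00 and s["indels_per_kb"] == 0.0
    with pytest.raises(ValueError):
        density_summary([], [], 0)


def test_planted_rate_recovered(nosv_pair):
    """SNP rate 2e-3 planted over 1 Mb; called density over aligned bases
    recovers the configured rate within 5%."""
    A, B, truth = nosv_pair
    params = AlignParams()
    oto = filter_one_to_one(align_genomes(A, B, params), params)
    variants = call_variants(oto, A, B)
    aligned = sum(b.ref_end - b.ref_start for b in oto)
    snps = [v for v in variants if v.kind == "SNP"]
    rate = len(snps) / aligned
    assert rate == pytest.approx(len(truth.snps) / A.total_length(), rel=0.02)
    assert rate == pytest.approx(2e-3, rel=0.05)


def test_snp_indel_window_correlation_positive(small_result):
    """Indels co-cluster with SNPs in enriched blocks, so per-window SNP
    and indel counts correlate positively."""
    snps = [v for v in small_result.variants if v.kind == "SNP"]
    indels = [v for v in small_result.variants if v.kind != "SNP"]
    win = 25_000
    key = lambda v: (v.ref_chrom, v.ref_pos // win)
    from collections import Counter
    cs, ci = Counter(map(key, snps)), Counter(map(key, indels))
    keys = sorted(set(cs) | set(ci))
    xs = np.array([cs.get(k, 0) for k in keys], float)
    ys = np.array([ci.get(k, 0) for k in keys], float)
    r = np.corrcoef(xs, ys)[0, 1]
    assert r > 0
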