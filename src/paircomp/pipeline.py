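"""End-to-end orchestration: simulate a cultivar pair, run the full
comparison (alignment -> PAV both directions -> variants -> SV), write
per-stage artifacts plus a JSON summary, and score a run against a
simulation truth set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import pav as pav_mod
from . import sv as sv_mod
from . import variants as var_mod
from .align import (AlignParams, AlignmentBlock, GenomeIndex, align_genomes,
                    filter_colinear, filter_one_to_one, write_paf)
from .genome import Genome
from .pav import PavParams, SpecificSegment
from .simulate import (SimulationConfig, TruthSet, derive_cultivar,
                       simulate_ancestor, simulate_reads, write_reads_fasta,
                       write_truth)
from .variants import DensityParams, VariantRecord


@dataclass
class RunResult:
    """Everything a comparison run produced, plus the JSON-able summary."""

    blocks_raw: list[AlignmentBlock]
    one_to_one: list[AlignmentBlock]
    colinear: list[AlignmentBlock]
    variants: list[VariantRecord]
    segments_a: list[SpecificSegment]
    segments_b: list[SpecificSegment]
    clusters_a: list
    clusters_b: list
    sv_events: list
    density_ref: "pd.DataFrame"
    density_query: "pd.DataFrame"
    enrichment_ref: "pd.DataFrame"
    enrichment_query: "pd.DataFrame"
    summary: dict = field(default_factory=dict)


def run_simulate(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Simulation bundle: genomes, reads, truth files and config echo.
    The ancestor consumes config.seed, the derived genome config.seed + 1
    and the read simulator config.seed + 2 (kept below 2**31)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ancestor = simulate_ancestor(config)
    derived, truth = derive_cultivar(ancestor, config, (config.seed + 1) % 2**31)
    reads = simulate_reads(derived, config.read_coverage, config.read_length,
                           config.read_error_rate, (config.seed + 2) % 2**31)
    ancestor.to_fasta(out / "genome_a.fasta")
    derived.to_fasta(out / "genome_b.fasta")
    write_reads_fasta(reads, out / "reads.fasta")
    truth_files = write_truth(truth, out / "truth")
    (out / "config.json").write_text(config.to_json() + "\n")
    manifest = {"genome_a": "genome_a.fasta", "genome_b": "genome_b.fasta",
                "reads": "reads.fasta", "config": "config.json",
                "truth": [p.name for p in truth_files]}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return {"ancestor": ancestor, "derived": derived, "truth": truth,
            "reads": reads, "dir": out}


def run_compare(genome_a: Genome | str | Path, genome_b: Genome | str | Path,
                out_dir: str | Path | None = None,
                align_params: AlignParams | None = None,
                pav_params: PavParams | None = None,
                density_params: DensityParams | None = None) -> RunResult:
    """Full comparison of two genomes; genome A is the reference side.

    Stage order: alignment blocks -> one-to-one / colinear filters ->
    SNP+indel calling -> per-window density and enrichment (both
    genomes) -> PAV (both directions) -> SV classification -> summary.
    """
    align_params = align_params or AlignParams()
    pav_params = pav_params or PavParams()
    density_params = density_params or DensityParams()
    A = genome_a if isinstance(genome_a, Genome) else Genome.from_fasta(genome_a)
    B = genome_b if isinstance(genome_b, Genome) else Genome.from_fasta(genome_b)

    blocks = align_genomes(A, B, align_params)
    oto = filter_one_to_one(blocks, align_params)
    col = filter_colinear(oto, align_params)

    raw_variants = var_mod.call_variants(oto, A, B)
    variants = var_mod.merge_adjacent_indels(raw_variants)
    snps = [v for v in variants if v.kind == "SNP"]
    indels = [v for v in variants if v.kind != "SNP"]

    dens_ref = var_mod.snp_density(snps, A, density_params, side="ref")
    dens_query = var_mod.snp_density(snps, B, density_params, side="query")
    enr_ref = var_mod.enrichment_regions(dens_ref, density_params)
    enr_query = var_mod.enrichment_regions(dens_query, density_params)

    index_a = GenomeIndex(A, align_params.min_mem_len)
    index_b = GenomeIndex(B, align_params.min_mem_len)
    segments_a, _ = pav_mod.call_specific_segments(
        A, index_b, pav_params, align_params, genome_label="A")
    segments_b, _ = pav_mod.call_specific_segments(
        B, index_a, pav_params, align_params, genome_label="B")
    clusters_a = pav_mod.call_clusters(segments_a, pav_params)
    clusters_b = pav_mod.call_clusters(segments_b, pav_params)

    events = sv_mod.classify_rearrangements(oto, col, align_params.max_anchor_gap)

    aligned_ref = sum(b.ref_end - b.ref_start for b in oto)
    aligned_query = sum(b.query_end - b.query_start for b in oto)
    dens = var_mod.density_summary(snps, indels, aligned_ref) if aligned_ref \
        else {}
    summary = {
        "aligned_fraction_a": round(aligned_ref / A.total_length(), 4),
        "aligned_fraction_b": round(aligned_query / B.total_length(), 4),
        "n_one_to_one_blocks": len(oto),
        "n_colinear_blocks": len(col),
        "n_snps": len(snps),
        "n_indels": len(indels),
        "indel_bp": sum(v.length for v in indels),
        "density": dens,
        "pav_a": pav_mod.summarize_lengths(segments_a,
                                           pav_params.length_summary_cutoff),
        "pav_b": pav_mod.summarize_lengths(segments_b,
                                           pav_params.length_summary_cutoff),
        "n_pav_clusters_a": len(clusters_a),
        "n_pav_clusters_b": len(clusters_b),
        "n_enrichment_regions_a": int(len(enr_ref)),
        "n_enrichment_regions_b": int(len(enr_query)),
        "sv": sv_mod.sv_summary(events),
    }

    result = RunResult(blocks, oto, col, variants, segments_a, segments_b,
                       clusters_a, clusters_b, events, dens_ref, dens_query,
                       enr_ref, enr_query, summary)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_paf(blocks, out / "blocks_raw.paf.tsv")
        write_paf(oto, out / "blocks_one_to_one.paf.tsv")
        write_paf(col, out / "blocks_colinear.paf.tsv")
        var_mod.write_vcf(variants, out / "variants.vcf")
        pav_mod.write_segments_bed(segments_a, out / "pav_a.bed")
        pav_mod.write_segments_bed(segments_b, out / "pav_b.bed")
        dens_ref.to_csv(out / "snp_density_a.tsv", sep="\t", index=False)
        dens_query.to_csv(out / "snp_density_b.tsv", sep="\t", index=False)
        enr_ref.to_csv(out / "enrichment_a.tsv", sep="\t", index=False)
        enr_query.to_csv(out / "enrichment_b.tsv", sep="\t", index=False)
        sv_mod.write_events_tsv(events, out / "sv_events.tsv")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return result


# --------------------------------------------------------------------------
# truth-based scoring
# --------------------------------------------------------------------------

def _interval_overlap(a0, a1, b0, b1) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def evaluate_run(result: RunResult, truth: TruthSet,
                 breakpoint_tol: int = 100,
                 sv_reciprocal: float = 0.9,
                 enrichment_min_overlap: float = 0.8) -> dict:
    """Parameter-recovery metrics of a comparison run against the
    simulator's truth: PAV recall/precision at a breakpoint tolerance,
    SNP recall/precision within one-to-one reference intervals, SV
    classification per type, and planted-enrichment overlap."""
    metrics: dict = {}

    # PAV
    for label, called in (("A", result.segments_a), ("B", result.segments_b)):
        planted = [p for p in truth.pav_segments if p.genome == label]
        matched_truth = 0
        matched_called_idx = set()
        for p in planted:
            for i, s in enumerate(called):
                if (s.chrom == p.chrom
                        and abs(s.start - p.start) <= breakpoint_tol
                        and abs(s.end - p.end) <= breakpoint_tol):
                    matched_truth += 1
                    matched_called_idx.add(i)
                    break
        metrics[f"pav_{label}"] = {
            "n_planted": len(planted), "n_called": len(called),
            "recall": matched_truth / len(planted) if planted else None,
            "precision": (len(matched_called_idx) / len(called)
                          if called else None)}

    # SNPs inside one-to-one reference intervals
    ivs: dict[str, list[tuple[int, int]]] = {}
    for b in result.one_to_one:
        ivs.setdefault(b.ref_chrom, []).append((b.ref_start, b.ref_end))

    def inside(chrom, pos):
        return any(s <= pos < e for s, e in ivs.get(chrom, ()))

    truth_snps = {(s.chrom_a, s.pos_a, s.base_a, s.base_b) for s in truth.snps}
    truth_in = {t for t in truth_snps if inside(t[0], t[1])}
    called_snps = {(v.ref_chrom, v.ref_pos, v.ref_allele, v.query_allele)
                   for v in result.variants if v.kind == "SNP"}
    tp_in = len(called_snps & truth_in)
    tp_all = len(called_snps & truth_snps)
    metrics["snp"] = {
        "n_planted_in_blocks": len(truth_in), "n_called": len(called_snps),
        "recall": tp_in / len(truth_in) if truth_in else None,
        "precision": tp_all / len(called_snps) if called_snps else None}

    # SV classification
    sv_detail = []
    for tsv in truth.svs:
        hit = False
        for ev in result.sv_events:
            if ev.type != tsv.type or ev.ref_chrom != tsv.chrom_a:
                continue
            o = _interval_overlap(ev.ref_start, ev.ref_end, tsv.a_start, tsv.a_end)
            if (o >= sv_reciprocal * (tsv.a_end - tsv.a_start)
                    and o >= sv_reciprocal * (ev.ref_end - ev.ref_start)):
                hit = True
                break
        sv_detail.append({"type": tsv.type, "chrom": tsv.chrom_a,
                          "start": tsv.a_start, "end": tsv.a_end,
                          "recovered": hit})
    by_type: dict[str, dict] = {}
    for d in sv_detail:
        t = by_type.setdefault(d["type"], {"planted": 0, "recovered": 0})
        t["planted"] += 1
        t["recovered"] += int(d["recovered"])
    metrics["sv"] = {"per_type": by_type, "detail": sv_detail,
                     "all_recovered": all(d["recovered"] for d in sv_detail)}

    # planted enrichment overlap (planted regions live on genome B)
    overlaps = []
    enr = result.enrichment_query
    for chrom, s, e in truth.enriched_regions:
        sub = enr[enr["chrom"] == chrom]
        cov = sum(_interval_overlap(s, e, int(r["start"]), int(r["end"]))
                  for _, r in sub.iterrows())
        overlaps.append(cov / (e - s))
    metrics["enrichment"] = {
        "n_planted": len(overlaps),
        "overlaps": [round(o, 4) for o in overlaps],
        "min_overlap": min(overlaps) if overlaps else None,
        "all_above_threshold": all(o >= enrichment_min_overlap
                                   for o in overlaps) if overlaps else None}
    return metrics
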