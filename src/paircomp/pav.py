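"""Presence/absence variation (PAV) calling.

The genome being screened is cut into overlapping windows (500 bp, step
100 bp); each window is mapped against the other genome and flagged as
*specific* when it fails to map or maps with coverage below 20%.
Flagged windows are merged positionally into specific segments; segments
longer than 500 bp are kept.  Segments within 100 kb of each other chain
into candidate clusters, reported when PAV sequence covers more than 10%
of the chained span.  Genes with more than 75% of their CDS bases under
PAV segments are PAV genes; term enrichment of PAV gene sets uses the
upper-tail hypergeometric test with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .align import AlignParams, GenomeIndex, map_window
from .genome import Genome


@dataclass
class PavParams:
    window_size: int = 500
    step: int = 100
    min_coverage: float = 0.20      # strict: coverage < 20% flags a window
    min_segment: int = 500          # strict: segments must exceed this
    cluster_merge_dist: int = 100_000
    cluster_min_density: float = 0.10
    gene_cds_fraction: float = 0.75
    length_summary_cutoff: int = 5_000

    def __post_init__(self):
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")
        for name in ("min_coverage", "cluster_min_density", "gene_cds_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SpecificSegment:
    genome_label: str
    chrom: str
    start: int
    end: int
    n_supporting_windows: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PAVCluster:
    chrom: str
    start: int
    end: int
    covered_bp: int

    @property
    def density(self) -> float:
        return self.covered_bp / (self.end - self.start)


def make_windows(genome: Genome, params: PavParams | None = None
                 ) -> list[tuple[str, int, int]]:
    """Overlapping windows starting at 0, step, 2*step, ...; a tail window
    anchored at L - window_size is appended when the regular grid does not
    already end there, so every base is windowed.  Chromosomes shorter
    than the window are skipped with a warning."""
    params = params or PavParams()
    w, s = params.window_size, params.step
    out = []
    for chrom in genome.names:
        L = len(genome[chrom])
        if L < w:
            warnings.warn(f"chromosome {chrom} ({L} bp) shorter than window; skipped")
            continue
        last_regular = ((L - w) // s) * s
        for start in range(0, last_regular + 1, s):
            out.append((chrom, start, start + w))
        if last_regular != L - w:
            out.append((chrom, L - w, L))
    return out


def classify_windows(coverages: list[float | None],
                     params: PavParams | None = None) -> np.ndarray:
    """Specific-window flags: unmapped (None) or coverage strictly below
    the threshold."""
    params = params or PavParams()
    flags = np.zeros(len(coverages), dtype=bool)
    for i, c in enumerate(coverages):
        if c is None:
            flags[i] = True
            continue
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"coverage {c!r} outside [0, 1] at window {i}")
        flags[i] = c < params.min_coverage
    return flags


def merge_specific_windows(windows: list[tuple[str, int, int]],
                           flags, params: PavParams | None = None,
                           genome_label: str = "A") -> list[SpecificSegment]:
    """Union of overlapping/adjacent flagged windows per chromosome;
    segments not exceeding min_segment are discarded."""
    params = params or PavParams()
    segs: list[SpecificSegment] = []
    cur: SpecificSegment | None = None
    for (chrom, start, end), flag in zip(windows, flags):
        if not flag:
            continue
        if cur is not None and cur.chrom == chrom and start <= cur.end:
            cur.end = max(cur.end, end)
            cur.n_supporting_windows += 1
        else:
            if cur is not None and cur.length > params.min_segment:
                segs.append(cur)
            cur = SpecificSegment(genome_label, chrom, start, end, 1)
    if cur is not None and cur.length > params.min_segment:
        segs.append(cur)
    return segs


def call_specific_segments(genome: Genome, other: Genome | GenomeIndex,
                           pav_params: PavParams | None = None,
                           align_params: AlignParams | None = None,
                           genome_label: str = "A"
                           ) -> tuple[list[SpecificSegment], list[float | None]]:
    """Window-map one genome against the other and merge specific windows."""
    pav_params = pav_params or PavParams()
    align_params = align_params or AlignParams()
    index = other if isinstance(other, GenomeIndex) else \
        GenomeIndex(other, align_params.min_mem_len)
    windows = make_windows(genome, pav_params)
    coverages: list[float | None] = []
    for chrom, start, end in windows:
        cov, hit = map_window(genome[chrom][start:end], index, align_params)
        coverages.append(None if hit is None else cov)
    flags = classify_windows(coverages, pav_params)
    segments = merge_specific_windows(windows, flags, pav_params, genome_label)
    return segments, coverages


def call_clusters(segments: list[SpecificSegment],
                  params: PavParams | None = None) -> list[PAVCluster]:
    """Chain segments with inter-segment gaps <= cluster_merge_dist; keep
    a chain's span as a cluster iff covered/span exceeds the density
    threshold."""
    params = params or PavParams()
    out: list[PAVCluster] = []
    by_chrom: dict[str, list[SpecificSegment]] = {}
    for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        chain: list[SpecificSegment] = []
        for s in segs + [None]:
            if s is not None and (not chain or s.start - chain[-1].end
                                  <= params.cluster_merge_dist):
                chain.append(s)
                continue
            if chain:
                span_start, span_end = chain[0].start, chain[-1].end
                covered = sum(c.length for c in chain)
                cl = PAVCluster(chrom, span_start, span_end, covered)
                if cl.density > params.cluster_min_density:
                    out.append(cl)
            chain = [s] if s is not None else []
    return out


def _interval_union(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _overlap_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    j = 0
    for s, e in a:
        while j < len(b) and b[j][1] <= s:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            total += min(e, b[k][1]) - max(s, b[k][0])
            k += 1
    return total


def read_gff_cds(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Transcript id -> CDS intervals (chrom, start, end), 0-based half-open."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    cds: dict[str, list[tuple[str, int, int]]] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent", [feat.id or "unknown"])
        for parent in parents:
            cds.setdefault(parent, []).append(
                (feat.seqid, feat.start - 1, feat.end))
    return cds


def call_pav_genes(segments: list[SpecificSegment],
                   annotation: dict[str, list[tuple[str, int, int]]] | str | Path,
                   params: PavParams | None = None) -> list[dict]:
    """Transcripts whose CDS is covered by PAV segments beyond the
    threshold fraction.  `annotation` is a GFF3 path or a mapping of
    transcript id -> CDS intervals."""
    params = params or PavParams()
    if not isinstance(annotation, dict):
        annotation = read_gff_cds(annotation)
    seg_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        seg_by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    seg_by_chrom = {c: _interval_union(v) for c, v in seg_by_chrom.items()}
    out = []
    for tid, cds in annotation.items():
        if not cds:
            warnings.warn(f"transcript {tid} has no CDS features; skipped")
            continue
        total = covered = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in cds:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs = _interval_union(ivs)
            total += sum(e - s for s, e in ivs)
            covered += _overlap_bp(ivs, seg_by_chrom.get(chrom, []))
        fraction = covered / total if total else 0.0
        if fraction > params.gene_cds_fraction:
            out.append({"gene_id": tid, "cds_len": total,
                        "covered": covered, "fraction": round(fraction, 4)})
    return sorted(out, key=lambda d: d["gene_id"])


def summarize_lengths(segments, cutoff: int = 5_000) -> dict:
    """(n_total, n_above_cutoff, percent_below); percent to 2 decimals,
    None when there are no segments.  Accepts segments or plain lengths."""
    lengths = [s if isinstance(s, (int, np.integer)) else s.length
               for s in segments]
    n_total = len(lengths)
    n_above = sum(1 for x in lengths if x > cutoff)
    percent_below = (round(100.0 * (n_total - n_above) / n_total, 2)
                     if n_total else None)
    return {"n_total": n_total, "n_above_cutoff": n_above,
            "percent_below": percent_below,
            "total_bp": int(sum(lengths))}


def enrich_pathways(pav_genes: set[str], gene2term: dict[str, set[str]],
                    universe: set[str]) -> "pd.DataFrame":
    """Upper-tail hypergeometric enrichment P(X >= k) per term with
    population N = |universe|, successes K = term genes in universe,
    draws n = |pav_genes|; BH adjustment across tested terms."""
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    if not pav_genes <= universe:
        raise ValueError("pav_genes must be a subset of the universe")
    terms: dict[str, set[str]] = {}
    for gene, tset in gene2term.items():
        if gene not in universe:
            continue
        for t in tset:
            terms.setdefault(t, set()).add(gene)
    N, n = len(universe), len(pav_genes)
    rows = []
    for term, members in sorted(terms.items()):
        K = len(members)
        if K == 0:
            continue
        k = len(members & pav_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append((term, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_raw"])
    if len(df):
        df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    else:
        df["p_adj"] = []
    return df.sort_values("p_raw", kind="stable").reset_index(drop=True)


def write_segments_bed(segments: list[SpecificSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgenome\tlength\tstrand\n")
        for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.genome_label}\t"
                     f"{s.length}\t+\n")
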