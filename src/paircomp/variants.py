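"""SNP/indel calling from one-to-one alignment blocks, indel merging,
per-window SNP density and SNP-enrichment regions.

Variant positions are reported in both genomes.  Indels follow the short
variant definition (1-100 bp); longer gap runs inside a block are
structural/PAV-scale and are not emitted as indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .align import AlignmentBlock
from .errors import ContractViolation
from .genome import Genome

MAX_INDEL_LEN = 100


@dataclass
class VariantRecord:
    kind: str  # SNP | insertion | deletion
    ref_chrom: str
    ref_pos: int          # 0-based; SNP: the base; indel: anchor (see below)
    query_chrom: str
    query_pos: int        # 0-based, forward query strand
    ref_allele: str       # "-" for insertions
    query_allele: str     # "-" for deletions; forward query orientation
    length: int


@dataclass
class DensityParams:
    window: int = 50_000
    fold: float = 1.5
    merge_dist: int = 100_000
    report_min_span: int = 450_000
    threshold_override: float | None = None

    def __post_init__(self):
        if self.fold <= 1:
            raise ValueError("fold must exceed 1")
        if self.window <= 0:
            raise ValueError("window must be positive")


_COMP = str.maketrans("ACGTN", "TGCAN")


def call_variants(blocks: list[AlignmentBlock], ref: Genome,
                  query: Genome) -> list[VariantRecord]:
    """Read SNPs and indels off the base-level edits of one-to-one blocks.

    One SNP per mismatch column (columns containing N skipped); one indel
    per gap run of length <= 100.  Minus-strand blocks are walked in
    reference orientation and query alleles/coordinates are flipped back
    to the forward query strand.
    """
    out: list[VariantRecord] = []
    for b in blocks:
        if b.edits is None:
            raise ContractViolation(
                f"block {b.ref_chrom}:{b.ref_start}-{b.ref_end} has no edit detail")
        rseq = ref[b.ref_chrom]
        qfwd = query[b.query_chrom]
        minus = b.strand == "-"
        rp = b.ref_start
        # walk query in alignment orientation: for '-' this is the
        # reverse complement; track the forward coordinate directly.
        qp = b.query_end if minus else b.query_start  # '-' walks downward

        def q_base(fwd_pos: int) -> str:
            base = qfwd[fwd_pos]
            return base.translate(_COMP) if minus else base

        for op, ln in b.edits:
            if op == "=":
                rp += ln
                qp = qp - ln if minus else qp + ln
            elif op == "X":
                for i in range(ln):
                    r_i = rp + i
                    q_fwd = (qp - i - 1) if minus else (qp + i)
                    ra = rseq[r_i]
                    qa = qfwd[q_fwd]  # forward query orientation
                    if ra == "N" or qa == "N":
                        continue
                    out.append(VariantRecord(
                        "SNP", b.ref_chrom, r_i, b.query_chrom, q_fwd,
                        ra, qa, 1))
                rp += ln
                qp = qp - ln if minus else qp + ln
            elif op == "I":  # extra bases in query
                if ln <= MAX_INDEL_LEN:
                    q_lo = qp - ln if minus else qp
                    allele = qfwd[q_lo:q_lo + ln]  # forward orientation
                    if "N" not in allele:
                        out.append(VariantRecord(
                            "insertion", b.ref_chrom, rp, b.query_chrom, q_lo,
                            "-", allele, ln))
                qp = qp - ln if minus else qp + ln
            elif op == "D":  # extra bases in reference
                if ln <= MAX_INDEL_LEN:
                    alle = rseq[rp:rp + ln]
                    if "N" not in alle:
                        out.append(VariantRecord(
                            "deletion", b.ref_chrom, rp, b.query_chrom,
                            qp if not minus else qp, alle, "-", ln))
                rp += ln
            else:
                raise ContractViolation(f"unknown edit op {op!r}")
    out.sort(key=lambda v: (v.ref_chrom, v.ref_pos, v.kind))
    return out


def merge_adjacent_indels(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Collapse runs of single-base indels of the same kind at consecutive
    positions on both genomes into one indel of the run length.  SNPs and
    multi-base indels pass through untouched."""
    out: list[VariantRecord] = []
    run: list[VariantRecord] = []

    def flush():
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            first = run[0]
            alleles = "".join((v.ref_allele if first.kind == "deletion"
                               else v.query_allele) for v in run)
            out.append(VariantRecord(
                first.kind, first.ref_chrom, first.ref_pos,
                first.query_chrom, min(v.query_pos for v in run),
                alleles if first.kind == "deletion" else "-",
                "-" if first.kind == "deletion" else alleles,
                len(run)))
        run.clear()

    for v in sorted(variants, key=lambda v: (v.ref_chrom, v.ref_pos, v.query_pos)):
        if v.kind == "SNP" or v.length != 1:
            flush()
            out.append(v)
            continue
        if run:
            p = run[-1]
            same_kind = p.kind == v.kind and p.ref_chrom == v.ref_chrom \
                and p.query_chrom == v.query_chrom
            if same_kind and v.kind == "deletion":
                adjacent = (v.ref_pos == p.ref_pos + 1
                            and v.query_pos == p.query_pos)
            elif same_kind:
                adjacent = (v.ref_pos == p.ref_pos
                            and v.query_pos == p.query_pos + 1)
            else:
                adjacent = False
            if not adjacent:
                flush()
        run.append(v)
    flush()
    out.sort(key=lambda v: (v.ref_chrom, v.ref_pos, v.kind))
    return out


def snp_density(snps: list[VariantRecord], genome: Genome,
                params: DensityParams | None = None,
                side: str = "ref") -> "pd.DataFrame":
    """Per-window SNP counts: non-overlapping tiles of ``params.window``
    from each chromosome start; the last partial window keeps its true
    span.  ``side`` selects which genome's coordinates to bin on."""
    import pandas as pd

    params = params or DensityParams()
    rows = []
    pos_attr = "ref_pos" if side == "ref" else "query_pos"
    chrom_attr = "ref_chrom" if side == "ref" else "query_chrom"
    by_chrom: dict[str, list[int]] = {c: [] for c in genome.names}
    for v in snps:
        if v.kind == "SNP":
            by_chrom.setdefault(getattr(v, chrom_attr), []).append(
                getattr(v, pos_attr))
    for chrom in genome.names:
        L = len(genome[chrom])
        n_win = (L + params.window - 1) // params.window
        counts = np.zeros(n_win, dtype=int)
        pos = np.asarray(by_chrom.get(chrom, ()), dtype=int)
        if len(pos):
            np.add.at(counts, pos // params.window, 1)
        for i in range(n_win):
            start = i * params.window
            end = min(start + params.window, L)
            rows.append((chrom, start, end, int(counts[i]),
                         end - start == params.window))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count", "full"])


def enrichment_regions(window_counts: "pd.DataFrame",
                       params: DensityParams | None = None,
                       apply_report_filter: bool = False) -> "pd.DataFrame":
    """Flag windows with count >= fold x mean (mean over full windows;
    partial tails are tested against a pro-rated threshold), then merge
    flagged windows whose gaps are <= merge_dist.  The report layer may
    additionally keep only regions spanning > report_min_span."""
    import pandas as pd

    params = params or DensityParams()
    df = window_counts
    full = df[df["full"]]
    mean = full["count"].mean() if len(full) else 0.0
    threshold = (params.threshold_override if params.threshold_override is not None
                 else params.fold * mean)
    spans = (df["end"] - df["start"]).to_numpy()
    prorated = threshold * spans / params.window
    flagged = df[df["count"].to_numpy() >= prorated]
    regions = []
    for chrom, sub in flagged.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for _, row in sub.iterrows():
            if cur is not None and row["start"] - cur["end"] <= params.merge_dist:
                cur["end"] = row["end"]
                cur["n_windows"] += 1
                cur["n_snps"] += row["count"]
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {"chrom": chrom, "start": int(row["start"]),
                       "end": int(row["end"]), "n_windows": 1,
                       "n_snps": int(row["count"])}
        if cur is not None:
            regions.append(cur)
    out = pd.DataFrame(regions,
                       columns=["chrom", "start", "end", "n_windows", "n_snps"])
    if apply_report_filter and len(out):
        out = out[(out["end"] - out["start"]) > params.report_min_span]
    return out.reset_index(drop=True)


def density_summary(snps: list[VariantRecord], indels: list[VariantRecord],
                    denominator_bp: int) -> dict:
    """SNPs/kb, indels/kb and indel bp/kb over an explicit denominator,
    reported to two decimals (the denominator choice is the caller's)."""
    if denominator_bp <= 0:
        raise ValueError("denominator_bp must be positive")
    n_snp = sum(1 for v in snps if v.kind == "SNP")
    ind = [v for v in indels if v.kind in ("insertion", "deletion")]
    n_ind = len(ind)
    bp_ind = sum(v.length for v in ind)
    kb = denominator_bp / 1_000
    return {
        "snps_per_kb": round(n_snp / kb, 2),
        "indels_per_kb": round(n_ind / kb, 2),
        "indel_bp_per_kb": round(bp_ind / kb, 2),
        "n_snps": n_snp,
        "n_indels": n_ind,
        "indel_bp": bp_ind,
    }


def write_vcf(variants: list[VariantRecord], path: str | Path,
              source: str = "paircomp") -> None:
    """Minimal VCF 4.2.  Indels keep the gap-symbol convention of the
    internal records (REF or ALT '-'); TYPE, QCHROM and QPOS INFO tags
    carry the cross-genome context."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant kind">\n')
        fh.write('##INFO=<ID=QCHROM,Number=1,Type=String,Description="Query chromosome">\n')
        fh.write('##INFO=<ID=QPOS,Number=1,Type=Integer,Description="Query position (1-based)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.ref_chrom}\t{v.ref_pos + 1}\t.\t{v.ref_allele}\t"
                     f"{v.query_allele}\t.\tPASS\t"
                     f"TYPE={v.kind};QCHROM={v.query_chrom};QPOS={v.query_pos + 1}\n")
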