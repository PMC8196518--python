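"""Inversion and translocation classification.

Rearrangements are the one-to-one blocks that the colinear (no
rearrangement) filter rejects.  Each candidate is classified from its
strand and its position relative to the nearest flanking colinear
blocks on the reference:

* strand '-'                                      -> inversion
* strand '+', query chromosome != flank consensus -> inter-chromosomal
  translocation
* strand '+', same chromosome but breaking the flanks' query order
  -> intra-chromosomal translocation

Adjacent candidates of the same type (gap bounded on both genomes) merge
into one event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .align import AlignmentBlock


@dataclass
class SVEvent:
    type: str  # inversion | intra_translocation | inter_translocation
    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    source_blocks: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


def _block_key(b: AlignmentBlock):
    return (b.ref_chrom, b.ref_start, b.ref_end,
            b.query_chrom, b.query_start, b.query_end, b.strand)


def classify_rearrangements(one_to_one: list[AlignmentBlock],
                            colinear: list[AlignmentBlock],
                            max_gap: int = 1_000) -> list[SVEvent]:
    colinear_keys = {_block_key(b) for b in colinear}
    candidates = [(i, b) for i, b in enumerate(one_to_one)
                  if _block_key(b) not in colinear_keys]
    col_by_ref: dict[str, list[AlignmentBlock]] = {}
    for b in colinear:
        col_by_ref.setdefault(b.ref_chrom, []).append(b)
    for v in col_by_ref.values():
        v.sort(key=lambda b: b.ref_start)

    events: list[SVEvent] = []
    for idx, cand in candidates:
        flanks = col_by_ref.get(cand.ref_chrom, [])
        if not flanks:
            warnings.warn(
                f"no colinear blocks on {cand.ref_chrom}; classifying "
                f"{cand.ref_start}-{cand.ref_end} against global order")
            prev_b = next_b = None
            consensus = cand.query_chrom
        else:
            prev_b = max((b for b in flanks if b.ref_end <= cand.ref_start),
                         key=lambda b: b.ref_end, default=None)
            next_b = min((b for b in flanks if b.ref_start >= cand.ref_end),
                         key=lambda b: b.ref_start, default=None)
            neighbour_chroms = [b.query_chrom for b in (prev_b, next_b)
                                if b is not None]
            consensus = (neighbour_chroms[0] if neighbour_chroms
                         else flanks[0].query_chrom)
        if cand.strand == "-":
            sv_type = "inversion"
        elif cand.query_chrom != consensus:
            sv_type = "inter_translocation"
        else:
            fits = ((prev_b is None or prev_b.query_end <= cand.query_start)
                    and (next_b is None or cand.query_end <= next_b.query_start))
            if fits and flanks:
                # in order with its neighbours: a filter tie, not an SV
                continue
            sv_type = "intra_translocation"
        events.append(SVEvent(sv_type, cand.ref_chrom, cand.ref_start,
                              cand.ref_end, cand.query_chrom,
                              cand.query_start, cand.query_end, [idx]))

    # merge adjacent same-type events (gap bounded on both genomes)
    events.sort(key=lambda e: (e.type, e.ref_chrom, e.query_chrom, e.ref_start))
    merged: list[SVEvent] = []
    for ev in events:
        if merged:
            p = merged[-1]
            if (p.type == ev.type and p.ref_chrom == ev.ref_chrom
                    and p.query_chrom == ev.query_chrom
                    and 0 <= ev.ref_start - p.ref_end <= max_gap
                    and (min(abs(ev.query_start - p.query_end),
                             abs(p.query_start - ev.query_end)) <= max_gap)):
                p.ref_end = max(p.ref_end, ev.ref_end)
                p.query_start = min(p.query_start, ev.query_start)
                p.query_end = max(p.query_end, ev.query_end)
                p.source_blocks.extend(ev.source_blocks)
                continue
        merged.append(ev)
    merged.sort(key=lambda e: (e.ref_chrom, e.ref_start))
    return merged


def sv_summary(events: list[SVEvent]) -> dict:
    counts: dict[str, int] = {"inversion": 0, "intra_translocation": 0,
                              "inter_translocation": 0}
    bp: dict[str, int] = dict.fromkeys(counts, 0)
    for ev in events:
        counts[ev.type] += 1
        bp[ev.type] += ev.length
    return {"counts": counts, "bp": bp,
            "total_events": sum(counts.values()), "total_bp": sum(bp.values())}


def write_events_tsv(events: list[SVEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("TYPE\tREF_CHROM\tREF_START\tREF_END\t"
                 "QUERY_CHROM\tQUERY_START\tQUERY_END\tLENGTH\n")
        for ev in events:
            fh.write(f"{ev.type}\t{ev.ref_chrom}\t{ev.ref_start}\t{ev.ref_end}\t"
                     f"{ev.query_chrom}\t{ev.query_start}\t{ev.query_end}\t"
                     f"{ev.length}\n")
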