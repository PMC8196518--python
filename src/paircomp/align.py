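"""Self-contained whole-genome pairwise aligner.

Seeds with maximal exact matches (MEMs) found through a vectorised k-mer
code comparison, chains co-strand collinear anchors under a gap bound,
closes inter-anchor gaps with unit-cost global alignment (edlib), and
filters the resulting blocks two ways:

* :func:`filter_one_to_one` — best conflict-free subset with no overlap on
  either genome, rearrangements permitted (``delta-filter -1 -r -q``
  semantics);
* :func:`filter_colinear` — maximum-score chain monotone in both genomes
  on the plus strand, no rearrangements (``delta-filter -g`` semantics),
  computed over the one-to-one survivors so it is always a subset of them.

:func:`map_window` plays the role of mapping short windows against a
genome (``bwa mem -w 500 -M`` in spirit): best local placement with
internal gaps, reporting the aligned fraction of the window.

All coordinates 0-based half-open; minus-strand anchors/blocks store
forward-strand query coordinates, with ``ref[rs:re] ==
revcomp(query[qs:qe])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import edlib
import numpy as np

from .errors import ContractViolation
from .genome import Genome, revcomp

_ENCODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _ENCODE[b] = i
    _ENCODE[b + 32] = i


@dataclass
class AlignParams:
    min_mem_len: int = 20
    max_anchor_gap: int = 1_000
    band_width: int = 100
    min_identity: float = 90.0     # the "-i 90" threshold
    min_block_len: int = 200
    window_map_gap: int = 500      # internal gap allowance for map_window
    exact_filter_limit: int = 30   # component size cap for exact 1-to-1 search
    max_trim_overlap: int = 100    # small block overlaps trimmed, not dropped

    def __post_init__(self):
        if not (0.0 <= self.min_identity <= 100.0):
            raise ValueError("min_identity must be in [0, 100]")
        if self.min_mem_len < 4:
            raise ValueError("min_mem_len must be at least 4")


@dataclass(frozen=True)
class Anchor:
    """Maximal exact match.  For strand '-', ``ref[ref_pos:ref_pos+length]
    == revcomp(query[query_pos:query_pos+length])``."""

    ref_pos: int
    query_pos: int
    length: int
    strand: str = "+"


@dataclass
class AlignmentBlock:
    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    strand: str
    identity: float          # percent, matches / aligned columns * 100
    score: float             # aligned columns * identity / 100
    edits: list[tuple[str, int]] | None = None  # runs of '=', 'X', 'I', 'D'
    aligned_len: int = 0
    n_matches: int = 0


# --------------------------------------------------------------------------
# k-mer machinery
# --------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every k-mer start; windows containing N invalid."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    bad = (arr < 0).astype(np.int64)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    a = np.where(arr < 0, 0, arr).astype(np.int64)
    code = np.zeros(n, dtype=np.int64)
    for j in range(k):
        code = (code << 2) | a[j:j + n]
    return code, valid


class _SeqIndex:
    """Sorted k-mer codes over one sequence (the reference side)."""

    def __init__(self, seq: str, k: int):
        self.k = k
        self.length = len(seq)
        arr = _encode(seq)
        codes, valid = _kmer_codes(arr, k)
        pos = np.nonzero(valid)[0]
        codes = codes[valid]
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]


def _match_pairs(index: _SeqIndex, q_codes: np.ndarray,
                 q_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All (ref_pos, query_pos) k-mer identities."""
    lo = np.searchsorted(index.codes, q_codes, "left")
    hi = np.searchsorted(index.codes, q_codes, "right")
    cnt = hi - lo
    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    qp = np.repeat(q_pos, cnt)
    base = np.repeat(lo, cnt)
    offsets = np.arange(total) - np.repeat(np.concatenate(([0], np.cumsum(cnt)[:-1])), cnt)
    rp = index.pos[base + offsets]
    return rp.astype(np.int64), qp.astype(np.int64)


def _collapse_runs(rp: np.ndarray, qp: np.ndarray, k: int):
    """Collapse diagonal runs of k-mer matches into MEMs (>= k)."""
    if len(rp) == 0:
        return []
    diag = rp - qp
    order = np.lexsort((rp, diag))
    rp, qp, diag = rp[order], qp[order], diag[order]
    brk = np.empty(len(rp), bool)
    brk[0] = True
    brk[1:] = (np.diff(diag) != 0) | (np.diff(rp) != 1)
    starts = np.nonzero(brk)[0]
    ends = np.append(starts[1:], len(rp))
    return [(int(rp[s]), int(qp[s]), int(ends_i - s + k - 1))
            for s, ends_i in zip(starts, ends)]


def find_anchors(ref: str, query: str, min_mem_len: int) -> list[Anchor]:
    """Every maximal exact match of length >= min_mem_len, both strands.
    N never matches.  Empty sequences yield an empty list."""
    k = min_mem_len
    if len(ref) < k or len(query) < k:
        return []
    index = _SeqIndex(ref, k)
    out: list[Anchor] = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        codes, valid = _kmer_codes(_encode(qseq), k)
        qpos = np.nonzero(valid)[0]
        rp, qp = _match_pairs(index, codes[valid], qpos)
        for r, q, length in _collapse_runs(rp, qp, k):
            if strand == "+":
                out.append(Anchor(r, q, length, "+"))
            else:
                out.append(Anchor(r, len(query) - q - length, length, "-"))
    return out


# --------------------------------------------------------------------------
# chaining
# --------------------------------------------------------------------------

def _rc_coord_anchors(anchors: list[Anchor], query_len: int) -> list[Anchor]:
    """Express minus-strand anchors in reverse-complement query coordinates
    so chaining is monotone increasing in both axes."""
    return [replace(a, query_pos=query_len - a.query_pos - a.length)
            for a in anchors]


def _chain_dp(anchors: list[Anchor], max_gap: int, k_overlap: int):
    """Best chain over anchors monotone in (ref, query) with both gaps in
    [-k_overlap, max_gap].  Returns (score, list of indices)."""
    n = len(anchors)
    if n == 0:
        return 0, []
    order = sorted(range(n), key=lambda i: (anchors[i].ref_pos, anchors[i].query_pos))
    max_len = max(a.length for a in anchors)
    best = [anchors[order[i]].length for i in range(n)]
    prev = [-1] * n
    for i in range(n):
        ai = anchors[order[i]]
        j = i - 1
        while j >= 0:
            aj = anchors[order[j]]
            # sorted by ref_pos: once starts fall below the reachable window
            # (gap bound plus the longest anchor) no earlier anchor connects
            if aj.ref_pos < ai.ref_pos - max_gap - max_len:
                break
            rgap = ai.ref_pos - (aj.ref_pos + aj.length)
            qgap = ai.query_pos - (aj.query_pos + aj.length)
            if (-k_overlap <= rgap <= max_gap and -k_overlap <= qgap <= max_gap
                    and ai.ref_pos > aj.ref_pos and ai.query_pos > aj.query_pos):
                cand = best[j] + ai.length
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
            j -= 1
    i = int(np.argmax(best))
    chain = []
    while i != -1:
        chain.append(order[i])
        i = prev[i]
    chain.reverse()
    return max(best), chain


def chain_anchors(anchors: list[Anchor], params: AlignParams,
                  query_len: int | None = None) -> list[list[Anchor]]:
    """Partition co-strand anchors into collinear chains (monotone in both
    coordinates per strand, inter-anchor gaps <= max_anchor_gap), greedily
    extracting the best-scoring chain first.  Each anchor joins at most one
    chain.  Minus-strand chains require ``query_len``."""
    chains: list[list[Anchor]] = []
    k_ov = max(params.min_mem_len - 1, 0)
    for strand in ("+", "-"):
        sub = [a for a in anchors if a.strand == strand]
        if not sub:
            continue
        if strand == "-":
            if query_len is None:
                query_len = max(a.query_pos + a.length for a in sub)
            work = _rc_coord_anchors(sub, query_len)
        else:
            work = list(sub)
        remaining = list(range(len(work)))
        while remaining:
            pool = [work[i] for i in remaining]
            _, idx = _chain_dp(pool, params.max_anchor_gap, k_ov)
            chosen = [remaining[i] for i in idx]
            # report anchors in original (forward-query) orientation
            chains.append([sub[i] for i in chosen])
            chosen_set = set(chosen)
            remaining = [i for i in remaining if i not in chosen_set]
    return chains


# --------------------------------------------------------------------------
# polishing
# --------------------------------------------------------------------------

def _push(edits: list[list], op: str, length: int):
    if length <= 0:
        return
    if edits and edits[-1][0] == op:
        edits[-1][1] += length
    else:
        edits.append([op, length])


def _edlib_edits(query_seg: str, ref_seg: str) -> list[tuple[str, int]]:
    """Unit-cost global alignment path; 'I' = extra base in query,
    'D' = extra base in reference."""
    if not ref_seg and not query_seg:
        return []
    if not ref_seg:
        return [("I", len(query_seg))]
    if not query_seg:
        return [("D", len(ref_seg))]
    res = edlib.align(query_seg, ref_seg, mode="NW", task="path")
    out: list[tuple[str, int]] = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def polish_block(chain: list[Anchor], ref: str, query: str,
                 params: AlignParams) -> list[AlignmentBlock]:
    """Close inter-anchor gaps by global alignment and emit the block.

    Returns a list: normally one block; several when a gap is unbalanced
    beyond twice the band width (the block splits at that gap, mirroring a
    banded aligner giving up after doubling its band); empty when the
    result is shorter than ``min_block_len`` on the reference."""
    if not chain:
        return []
    strand = chain[0].strand
    qlen = len(query)
    qseq = query if strand == "+" else revcomp(query)
    work = sorted(chain if strand == "+" else _rc_coord_anchors(chain, qlen),
                  key=lambda a: a.ref_pos)

    # trim overlaps between consecutive anchors
    trimmed: list[Anchor] = []
    for a in work:
        if trimmed:
            p = trimmed[-1]
            ov = max(p.ref_pos + p.length - a.ref_pos,
                     p.query_pos + p.length - a.query_pos, 0)
            if ov:
                a = replace(a, ref_pos=a.ref_pos + ov,
                            query_pos=a.query_pos + ov, length=a.length - ov)
            if a.length <= 0:
                continue
        trimmed.append(a)

    pieces: list[list[Anchor]] = [[]]
    for a in trimmed:
        if pieces[-1]:
            p = pieces[-1][-1]
            rgap = a.ref_pos - (p.ref_pos + p.length)
            qgap = a.query_pos - (p.query_pos + p.length)
            if abs(rgap - qgap) > 2 * params.band_width:
                pieces.append([])
        pieces[-1].append(a)

    blocks: list[AlignmentBlock] = []
    for piece in pieces:
        if not piece:
            continue
        edits: list[list] = []
        for i, a in enumerate(piece):
            if i:
                p = piece[i - 1]
                ref_seg = ref[p.ref_pos + p.length:a.ref_pos]
                q_seg = qseq[p.query_pos + p.length:a.query_pos]
                for op, ln in _edlib_edits(q_seg, ref_seg):
                    _push(edits, op, ln)
            _push(edits, "=", a.length)
        rs, re = piece[0].ref_pos, piece[-1].ref_pos + piece[-1].length
        qs, qe = piece[0].query_pos, piece[-1].query_pos + piece[-1].length
        if re - rs < params.min_block_len:
            continue
        columns = sum(ln for _, ln in edits)
        matches = sum(ln for op, ln in edits if op == "=")
        identity = 100.0 * matches / columns if columns else 0.0
        if strand == "-":
            qs, qe = qlen - qe, qlen - qs
        blocks.append(AlignmentBlock(
            "", rs, re, "", qs, qe, strand,
            identity=identity, score=columns * identity / 100.0,
            edits=[tuple(e) for e in edits],
            aligned_len=columns, n_matches=matches))
    return blocks


# --------------------------------------------------------------------------
# block filters
# --------------------------------------------------------------------------

def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def _recalc(b: AlignmentBlock) -> None:
    b.aligned_len = sum(ln for _, ln in b.edits)
    b.n_matches = sum(ln for op, ln in b.edits if op == "=")
    b.identity = 100.0 * b.n_matches / b.aligned_len if b.aligned_len else 0.0
    b.score = b.aligned_len * b.identity / 100.0


def _trim_edits(edits: list[tuple[str, int]], from_front: bool,
                ref_amount: int = 0, query_amount: int = 0):
    """Remove columns from one end of an edit list until at least the
    requested reference/query consumption is reached, then strip any
    non-match runs left at the new edge so blocks stay anchored on
    matches.  Returns (ref_consumed, query_consumed, new_edits)."""
    work = list(edits if from_front else reversed(edits))
    rc = qc = 0
    i = 0
    consumed_any = False
    while i < len(work):
        op, ln = work[i]
        uses_ref = op in "=XD"
        uses_query = op in "=XI"
        need_more = rc < ref_amount or qc < query_amount
        if not need_more:
            if op == "=" or not consumed_any:
                break
            # strip a dangling mismatch/indel at the new edge
            rc += ln if uses_ref else 0
            qc += ln if uses_query else 0
            i += 1
            continue
        take = ln
        if op == "=":
            take = min(ln, max(ref_amount - rc, query_amount - qc))
        consumed_any = True
        if take == ln:
            rc += ln if uses_ref else 0
            qc += ln if uses_query else 0
            i += 1
        else:
            rc += take if uses_ref else 0
            qc += take if uses_query else 0
            work[i] = (op, ln - take)
            break
    new = work[i:]
    if not from_front:
        new = list(reversed(new))
    return rc, qc, new


def _trim_block(b: AlignmentBlock, axis: str, edge: str, amount: int) -> bool:
    """Shrink a block by ``amount`` bases of `axis` ('ref'/'query') at
    `edge` ('start'/'end', forward coordinates).  Returns False when the
    block collapses."""
    if b.edits is None:
        return False
    if axis == "ref":
        from_front = edge == "start"
    else:
        from_front = (edge == "start") == (b.strand == "+")
    rc, qc, new = _trim_edits(
        b.edits, from_front,
        ref_amount=amount if axis == "ref" else 0,
        query_amount=amount if axis == "query" else 0)
    b.edits = new
    if from_front:
        b.ref_start += rc
        if b.strand == "+":
            b.query_start += qc
        else:
            b.query_end -= qc
    else:
        b.ref_end -= rc
        if b.strand == "+":
            b.query_end -= qc
        else:
            b.query_start += qc
    if not new or b.ref_end - b.ref_start <= 0 or b.query_end - b.query_start <= 0:
        return False
    _recalc(b)
    return True


def _resolve_small_overlaps(blocks: list[AlignmentBlock],
                            params: AlignParams) -> list[AlignmentBlock]:
    """Trim overlaps up to max_trim_overlap off the lower-scoring block so
    that tiny boundary overlaps (shared seed k-mers at block junctions) do
    not knock out whole blocks in the conflict search."""
    blocks = [replace(b, edits=list(b.edits) if b.edits is not None else None)
              for b in blocks]
    alive = [True] * len(blocks)
    for _ in range(6):
        changed = False
        for axis in ("ref", "query"):
            idx = [i for i in range(len(blocks)) if alive[i]]
            idx.sort(key=lambda i: (getattr(blocks[i], f"{axis}_chrom"),
                                    getattr(blocks[i], f"{axis}_start")))
            active: list[int] = []
            for i in idx:
                bi = blocks[i]
                ci = getattr(bi, f"{axis}_chrom")
                si = getattr(bi, f"{axis}_start")
                ei = getattr(bi, f"{axis}_end")
                active = [j for j in active if alive[j]
                          and getattr(blocks[j], f"{axis}_chrom") == ci
                          and getattr(blocks[j], f"{axis}_end") > si]
                for j in active:
                    if not alive[i]:
                        break
                    bj = blocks[j]
                    o = min(ei, getattr(bj, f"{axis}_end")) - \
                        max(si, getattr(bj, f"{axis}_start"))
                    if not (0 < o <= params.max_trim_overlap):
                        continue
                    victim, other = (i, j) if bi.score <= bj.score else (j, i)
                    vb, ob = blocks[victim], blocks[other]
                    # trim the victim away from the shared edge
                    if getattr(vb, f"{axis}_start") < getattr(ob, f"{axis}_start"):
                        ok = _trim_block(vb, axis, "end", o)
                    else:
                        ok = _trim_block(vb, axis, "start", o)
                    if not ok or vb.ref_end - vb.ref_start < params.min_block_len:
                        alive[victim] = False
                    changed = True
                    if victim == i:
                        si = getattr(bi, f"{axis}_start")
                        ei = getattr(bi, f"{axis}_end")
                if alive[i]:
                    active.append(i)
        if not changed:
            break
    return [b for i, b in enumerate(blocks) if alive[i]]


def _conflicts(x: AlignmentBlock, y: AlignmentBlock) -> bool:
    if x.ref_chrom == y.ref_chrom and _overlaps(x.ref_start, x.ref_end,
                                                y.ref_start, y.ref_end):
        return True
    if x.query_chrom == y.query_chrom and _overlaps(x.query_start, x.query_end,
                                                    y.query_start, y.query_end):
        return True
    return False


def _mwis_exact(blocks: list[AlignmentBlock], adj: list[set[int]]) -> list[int]:
    """Exact max-weight independent set, branch and bound."""
    order = sorted(range(len(blocks)), key=lambda i: -blocks[i].score)
    best_set: list[int] = []
    best_score = -1.0
    suffix = [0.0] * (len(order) + 1)
    for i in range(len(order) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + blocks[order[i]].score

    def rec(i: int, chosen: list[int], score: float, banned: set[int]):
        nonlocal best_set, best_score
        if score + suffix[i] <= best_score:
            return
        if i == len(order):
            if score > best_score:
                best_score, best_set = score, list(chosen)
            return
        b = order[i]
        if b not in banned:
            chosen.append(b)
            rec(i + 1, chosen, score + blocks[b].score, banned | adj[b])
            chosen.pop()
        rec(i + 1, chosen, score, banned)

    rec(0, [], 0.0, set())
    return best_set


def filter_one_to_one(blocks: list[AlignmentBlock],
                      params: AlignParams) -> list[AlignmentBlock]:
    """Drop low-identity blocks, then keep the maximum-score subset with no
    overlap on either genome (rearrangements permitted)."""
    cand = [b for b in blocks if b.identity >= params.min_identity]
    if any(b.edits is not None for b in cand):
        cand = _resolve_small_overlaps(cand, params)
    n = len(cand)
    adj: list[set[int]] = [set() for _ in range(n)]
    for axis in ("ref", "query"):
        keyed = sorted(range(n), key=lambda i: (
            getattr(cand[i], f"{axis}_chrom"), getattr(cand[i], f"{axis}_start")))
        active: list[int] = []
        for i in keyed:
            ci, si, ei = (getattr(cand[i], f"{axis}_chrom"),
                          getattr(cand[i], f"{axis}_start"),
                          getattr(cand[i], f"{axis}_end"))
            active = [j for j in active
                      if getattr(cand[j], f"{axis}_chrom") == ci
                      and getattr(cand[j], f"{axis}_end") > si]
            for j in active:
                adj[i].add(j)
                adj[j].add(i)
            active.append(i)

    # connected components of the conflict graph
    seen = [False] * n
    kept: list[int] = []
    for start in range(n):
        if seen[start]:
            continue
        comp = []
        stack = [start]
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        if len(comp) == 1:
            kept.append(comp[0])
        elif len(comp) <= params.exact_filter_limit:
            sub = [cand[i] for i in comp]
            remap = {i: gi for i, gi in enumerate(comp)}
            sub_adj = [set() for _ in comp]
            for ii, gi in enumerate(comp):
                for gj in adj[gi]:
                    if gj in comp:
                        sub_adj[ii].add(comp.index(gj))
            kept.extend(remap[i] for i in _mwis_exact(sub, sub_adj))
        else:  # greedy fallback for very tangled components
            for i in sorted(comp, key=lambda i: -cand[i].score):
                if all(j not in adj[i] for j in kept if j in comp):
                    kept.append(i)
    kept_blocks = [cand[i] for i in sorted(kept)]
    return kept_blocks


def filter_colinear(blocks: list[AlignmentBlock],
                    params: AlignParams) -> list[AlignmentBlock]:
    """Per reference chromosome, the maximum-score chain strictly monotone
    in both genomes on the plus strand against the homologous (best
    total-score) query chromosome.  Runs on the one-to-one survivors, so
    its output is always a subset of :func:`filter_one_to_one`'s."""
    oto = filter_one_to_one(blocks, params)
    out: list[AlignmentBlock] = []
    by_ref: dict[str, list[AlignmentBlock]] = {}
    for b in oto:
        by_ref.setdefault(b.ref_chrom, []).append(b)
    for ref_chrom, blist in by_ref.items():
        totals: dict[str, float] = {}
        for b in blist:
            if b.strand == "+":
                totals[b.query_chrom] = totals.get(b.query_chrom, 0.0) + b.score
        if not totals:
            continue
        homolog = max(totals, key=lambda c: totals[c])
        sub = sorted((b for b in blist
                      if b.strand == "+" and b.query_chrom == homolog),
                     key=lambda b: b.ref_start)
        n = len(sub)
        best = [b.score for b in sub]
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                if (sub[j].ref_end <= sub[i].ref_start
                        and sub[j].query_end <= sub[i].query_start
                        and best[j] + sub[i].score > best[i]):
                    best[i] = best[j] + sub[i].score
                    prev[i] = j
        if n:
            i = int(np.argmax(best))
            chain = []
            while i != -1:
                chain.append(sub[i])
                i = prev[i]
            out.extend(reversed(chain))
    return sorted(out, key=lambda b: (b.ref_chrom, b.ref_start))


# --------------------------------------------------------------------------
# whole-genome driver and window mapping
# --------------------------------------------------------------------------

def align_genomes(ref: Genome, query: Genome,
                  params: AlignParams | None = None) -> list[AlignmentBlock]:
    """Raw alignment blocks over every chromosome pair and both strands."""
    params = params or AlignParams()
    blocks: list[AlignmentBlock] = []
    indexes = {c: _SeqIndex(ref[c], params.min_mem_len) for c in ref.names}
    for qc in query.names:
        qseq = query[qc]
        enc: dict[str, tuple] = {}
        for strand, s in (("+", qseq), ("-", revcomp(qseq))):
            codes, valid = _kmer_codes(_encode(s), params.min_mem_len)
            enc[strand] = (codes[valid], np.nonzero(valid)[0])
        for rc_name in ref.names:
            idx = indexes[rc_name]
            anchors: list[Anchor] = []
            for strand in ("+", "-"):
                codes, qpos = enc[strand]
                rp, qp = _match_pairs(idx, codes, qpos)
                for r, q, length in _collapse_runs(rp, qp, params.min_mem_len):
                    if strand == "+":
                        anchors.append(Anchor(r, q, length, "+"))
                    else:
                        anchors.append(Anchor(r, len(qseq) - q - length, length, "-"))
            for chain in chain_anchors(anchors, params, query_len=len(qseq)):
                for blk in polish_block(chain, ref[rc_name], qseq, params):
                    blk.ref_chrom = rc_name
                    blk.query_chrom = qc
                    blocks.append(blk)
    return blocks


class GenomeIndex:
    """Reusable k-mer index over a whole genome for window mapping."""

    def __init__(self, genome: Genome, k: int = 20):
        self.genome = genome
        self.k = k
        self.indexes = {c: _SeqIndex(genome[c], k) for c in genome.names}


def map_window(window: str, target: Genome | GenomeIndex,
               params: AlignParams | None = None) -> tuple[float, dict | None]:
    """Best placement of a window on the target genome.

    Returns ``(coverage, best_hit)`` where coverage is the fraction of
    window bases in aligned (match or mismatch) columns of the best chain,
    and best_hit a dict with chrom/start/end/strand/identity, or
    ``(0.0, None)`` when no anchor chain is found."""
    params = params or AlignParams()
    index = target if isinstance(target, GenomeIndex) else \
        GenomeIndex(target, params.min_mem_len)
    k = index.k
    wlen = len(window)
    if wlen < k:
        return 0.0, None
    cand_best = None  # (total_anchor_len, chrom, strand, anchors)
    for strand, wseq in (("+", window), ("-", revcomp(window))):
        codes, valid = _kmer_codes(_encode(wseq), k)
        qpos = np.nonzero(valid)[0]
        codes = codes[valid]
        for chrom, idx in index.indexes.items():
            rp, qp = _match_pairs(idx, codes, qpos)
            if len(rp) == 0:
                continue
            mems = _collapse_runs(rp, qp, k)
            anchors = [Anchor(r, q, ln, "+") for r, q, ln in mems]
            total = sum(a.length for a in anchors)
            if cand_best is None or total > cand_best[0]:
                cand_best = (total, chrom, strand, anchors, wseq)
    if cand_best is None:
        return 0.0, None
    _, chrom, strand, anchors, wseq = cand_best
    gap_params = replace(params, max_anchor_gap=params.window_map_gap,
                         min_block_len=1)
    _, idxs = _chain_dp(anchors, gap_params.max_anchor_gap, k - 1)
    chain = [anchors[i] for i in idxs]
    if not chain:
        return 0.0, None
    if len(chain) == 1 and chain[0].length == wlen:
        a = chain[0]
        hit = {"chrom": chrom, "start": a.ref_pos, "end": a.ref_pos + wlen,
               "strand": strand, "identity": 100.0}
        return 1.0, hit
    blocks = polish_block(chain, index.genome[chrom], wseq, gap_params)
    if not blocks:
        return 0.0, None
    best = max(blocks, key=lambda b: b.score)
    aligned_window_bases = sum(ln for op, ln in best.edits if op in "=X")
    coverage = min(aligned_window_bases / wlen, 1.0)
    qs, qe = best.query_start, best.query_end
    if strand == "-":
        qs, qe = wlen - qe, wlen - qs
    hit = {"chrom": chrom, "start": best.ref_start, "end": best.ref_end,
           "strand": strand, "identity": best.identity,
           "window_start": qs, "window_end": qe}
    return coverage, hit


# --------------------------------------------------------------------------
# PAF-like I/O (pluggable path for externally produced alignments)
# --------------------------------------------------------------------------

_PAF_HEADER = ("query\tq_start\tq_end\tstrand\ttarget\tt_start\tt_end\t"
               "matches\taligned_len\tidentity\tscore\n")


def write_paf(blocks: list[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_PAF_HEADER)
        for b in blocks:
            fh.write(f"{b.query_chrom}\t{b.query_start}\t{b.query_end}\t"
                     f"{b.strand}\t{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t"
                     f"{b.n_matches}\t{b.aligned_len}\t{b.identity:.4f}\t"
                     f"{b.score:.4f}\n")


def read_paf(path: str | Path) -> list[AlignmentBlock]:
    """Read PAF-like blocks (no base-level edit detail)."""
    blocks = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("query\t"):
            raise ContractViolation(f"{path} is not a block TSV")
        for line in fh:
            (qc, qs, qe, strand, tc, ts, te, matches, alen,
             ident, score) = line.rstrip("\n").split("\t")
            blocks.append(AlignmentBlock(
                tc, int(ts), int(te), qc, int(qs), int(qe), strand,
                float(ident), float(score), edits=None,
                aligned_len=int(alen), n_matches=int(matches)))
    return blocks
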