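"""Independent brute-force oracles used by the test suite.

Each function here recomputes, by direct enumeration or quadratic DP,
a quantity the package computes by a faster route.  They deliberately
share no code with the package internals.
"""

from __future__ import annotations

import math

from paircomp.genome import revcomp


def mem_bruteforce(ref: str, query: str, k: int) -> set[tuple[int, int, int, str]]:
    """All maximal exact matches >= k on both strands by O(n*m) DP."""
    out: set[tuple[int, int, int, str]] = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        n, m = len(ref), len(q)
        L = [[0] * (m + 1) for _ in range(n + 1)]
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                if ref[i - 1] == q[j - 1] and ref[i - 1] in "ACGT":
                    L[i][j] = L[i - 1][j - 1] + 1
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                length = L[i][j]
                if length < k:
                    continue
                right_extendable = (i < n and j < m and ref[i] == q[j]
                                    and ref[i] in "ACGT")
                if right_extendable:
                    continue
                qs = j - length
                if strand == "-":
                    qs = len(query) - (j - length) - length
                out.add((i - length, qs, length, strand))
    return out


def nw_edits(ref: str, query: str) -> list[tuple[str, int]]:
    """Full quadratic unit-cost global alignment with a fixed tie-break
    (diagonal > deletion > insertion); returns run-length edit ops
    ('=', 'X', 'I' extra-in-query, 'D' extra-in-ref)."""
    n, m = len(ref), len(query)
    INF = 10 ** 9
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        D[i][0] = i
    for j in range(m + 1):
        D[0][j] = j
    for i in range(1, n + 1):
        row, prev = D[i], D[i - 1]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (ref[i - 1] != query[j - 1])
            row[j] = min(sub, prev[j] + 1, row[j - 1] + 1)
    ops: list[tuple[str, int]] = []

    def push(op):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    i, j = n, m
    rev_ops: list[str] = []
    while i or j:
        if i and j and D[i][j] == D[i - 1][j - 1] + (ref[i - 1] != query[j - 1]):
            rev_ops.append("=" if ref[i - 1] == query[j - 1] else "X")
            i, j = i - 1, j - 1
        elif i and D[i][j] == D[i - 1][j] + 1:
            rev_ops.append("D")
            i -= 1
        else:
            rev_ops.append("I")
            j -= 1
    for op in reversed(rev_ops):
        push(op)
    return ops


def edits_to_variants(edits, ref: str, query: str):
    """Column read-out of an edit list into (kind, ref_pos, ref, alt)."""
    out = []
    rp = qp = 0
    for op, ln in edits:
        if op == "=":
            rp += ln
            qp += ln
        elif op == "X":
            for t in range(ln):
                out.append(("SNP", rp + t, ref[rp + t], query[qp + t]))
            rp += ln
            qp += ln
        elif op == "I":
            out.append(("insertion", rp, "-", query[qp:qp + ln]))
            qp += ln
        else:
            out.append(("deletion", rp, ref[rp:rp + ln], "-"))
            rp += ln
    return out


def smith_waterman_best_score(window: str, target: str) -> int:
    """Best local alignment score (match +1, mismatch/gap -1).  For a
    window whose alignable part matches the target exactly, the score is
    the number of aligned window bases (up to small spurious gains)."""
    n, m = len(target), len(window)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        row = [0] * (m + 1)
        for j in range(1, m + 1):
            d = prev[j - 1] + (1 if target[i - 1] == window[j - 1] else -1)
            v = max(0, d, prev[j] - 1, row[j - 1] - 1)
            row[j] = v
            if v > best:
                best = v
        prev = row
    return best


def best_chain_exhaustive(anchors, max_gap: int, k_overlap: int) -> int:
    """Maximum chain score by depth-first search over all chains.
    Anchors are (ref_pos, query_pos, length) on one strand."""
    n = len(anchors)
    order = sorted(range(n), key=lambda i: anchors[i][0])

    def compatible(a, b):
        rgap = b[0] - (a[0] + a[2])
        qgap = b[1] - (a[1] + a[2])
        return (-k_overlap <= rgap <= max_gap and -k_overlap <= qgap <= max_gap
                and b[0] > a[0] and b[1] > a[1])

    best = 0

    def rec(last, score, start):
        nonlocal best
        best = max(best, score)
        for t in range(start, n):
            a = anchors[order[t]]
            if last is None or compatible(last, a):
                rec(a, score + a[2], t + 1)

    rec(None, 0, 0)
    return best


def best_conflict_free_subset(blocks) -> float:
    """Exhaustive max total score over subsets with no overlap on either
    genome.  Blocks are (ref_chrom, rs, re, q_chrom, qs, qe, score)."""
    n = len(blocks)
    best = 0.0

    def conflict(x, y):
        if x[0] == y[0] and x[1] < y[2] and y[1] < x[2]:
            return True
        if x[3] == y[3] and x[4] < y[5] and y[4] < x[5]:
            return True
        return False

    for mask in range(1 << n):
        chosen = [blocks[i] for i in range(n) if mask >> i & 1]
        ok = all(not conflict(chosen[i], chosen[j])
                 for i in range(len(chosen)) for j in range(i + 1, len(chosen)))
        if ok:
            best = max(best, sum(b[6] for b in chosen))
    return best


def best_monotone_chain(blocks) -> float:
    """Exhaustive max total score over strictly increasing (both genomes)
    block subsets; blocks as in best_conflict_free_subset, plus strand at
    index 7 (only '+' may chain)."""
    n = len(blocks)
    best = 0.0
    order = sorted(range(n), key=lambda i: blocks[i][1])

    def rec(last, score, start):
        nonlocal best
        best = max(best, score)
        for t in range(start, n):
            b = blocks[order[t]]
            if b[7] != "+":
                continue
            if last is None or (b[1] >= last[2] and b[4] >= last[5]
                                and b[0] == last[0] and b[3] == last[3]):
                rec(b, score + b[6], t + 1)

    rec(None, 0.0, 0)
    return best


def bitmap_union_segments(flagged_windows, min_segment: int):
    """Per-base bitmap union of flagged windows -> kept segments."""
    by_chrom: dict[str, set[int]] = {}
    for chrom, s, e in flagged_windows:
        by_chrom.setdefault(chrom, set()).update(range(s, e))
    segs = []
    for chrom, bases in by_chrom.items():
        bases = sorted(bases)
        start = prev = None
        for b in bases + [None]:
            if prev is not None and (b is None or b != prev + 1):
                if prev + 1 - start > min_segment:
                    segs.append((chrom, start, prev + 1))
                start = b
            elif start is None:
                start = b
            prev = b
    return sorted(segs)


def bitmap_cds_fraction(cds_intervals, segments) -> float:
    """Per-base covered fraction of a CDS by PAV segments."""
    cds_bases = set()
    for chrom, s, e in cds_intervals:
        cds_bases.update((chrom, p) for p in range(s, e))
    seg_bases = set()
    for chrom, s, e in segments:
        seg_bases.update((chrom, p) for p in range(s, e))
    if not cds_bases:
        return 0.0
    return len(cds_bases & seg_bases) / len(cds_bases)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) by pmf enumeration with binomial coefficients."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


def nx_cumsum(lengths, X: float) -> tuple[int, int]:
    ls = sorted(lengths, reverse=True)
    target = X / 100 * sum(ls)
    acc = 0
    for r, x in enumerate(ls, 1):
        acc += x
        if acc >= target:
            return x, r
    raise AssertionError
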