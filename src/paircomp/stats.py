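"""K-mer genome-size estimation and assembly Nx statistics.

Genome size follows the classic k-mer spectrum argument: genomic k-mers
pile up at a modal depth (the peak), sequencing errors at depth ~1, so

    genome size = (number of k-mers above the error cutoff) / peak depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError
from .genome import revcomp


@dataclass
class KmerHistogram:
    k: int
    counts: dict[int, int] = field(default_factory=dict)  # depth -> distinct k-mers

    @property
    def total_kmers(self) -> int:
        return sum(d * c for d, c in self.counts.items())


def kmer_histogram(reads, k: int = 17) -> KmerHistogram:
    """Canonical k-mer occurrence histogram over a read set.

    `reads` is an iterable of sequences or (name, sequence) pairs.
    k must be odd and within 11..31 (odd k makes a k-mer never equal to
    its own reverse complement, so canonical counting is unambiguous).
    K-mers containing N are skipped; reads shorter than k contribute
    nothing.
    """
    if k % 2 == 0 or not (11 <= k <= 31):
        raise ValueError("k must be odd and within [11, 31]")
    counts: dict[str, int] = {}
    for read in reads:
        seq = read[1] if isinstance(read, tuple) else str(read)
        if len(seq) < k:
            continue
        rc = revcomp(seq)
        L = len(seq)
        for i in range(L - k + 1):
            fwd = seq[i:i + k]
            if "N" in fwd:
                continue
            rev = rc[L - k - i:L - i]
            kmer = fwd if fwd <= rev else rev
            counts[kmer] = counts.get(kmer, 0) + 1
    hist: dict[int, int] = {}
    for depth in counts.values():
        hist[depth] = hist.get(depth, 0) + 1
    return KmerHistogram(k, hist)


def first_local_minimum(hist: KmerHistogram) -> int:
    """Default error cutoff: the first depth where the spectrum stops
    falling (boundary between the error slope and the genomic peak)."""
    depths = sorted(hist.counts)
    for i in range(len(depths) - 1):
        d, nxt = depths[i], depths[i + 1]
        if hist.counts[d] <= hist.counts[nxt]:
            return d
    return depths[0] if depths else 1


def estimate_genome_size(hist: KmerHistogram,
                         error_depth_cutoff: int | None = None) -> int:
    """Genome size = k-mer count above the error cutoff / peak depth.

    Depths <= cutoff (default: first local minimum of the spectrum) are
    excluded from both the peak search and the numerator."""
    if not hist.counts:
        raise EstimationError("empty k-mer histogram")
    cutoff = (first_local_minimum(hist) if error_depth_cutoff is None
              else error_depth_cutoff)
    usable = {d: c for d, c in hist.counts.items() if d > cutoff}
    if not usable:
        raise EstimationError(
            f"no k-mer depth above the error cutoff {cutoff}; "
            "coverage too low or cutoff too high")
    peak_depth = max(usable, key=lambda d: (usable[d], -d))
    total = sum(d * c for d, c in usable.items())
    return int(round(total / peak_depth))


def nX_stats(lengths, X: float) -> tuple[int, int]:
    """(nX_size, nX_count): sort lengths descending; the first length at
    which the cumulative sum reaches X% of the total, and its 1-based rank."""
    lengths = sorted((int(x) for x in lengths), reverse=True)
    if not lengths:
        raise ValueError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    if not (0 < X < 100):
        raise ValueError("X must be in (0, 100)")
    target = X / 100.0 * sum(lengths)
    acc = 0
    for rank, x in enumerate(lengths, start=1):
        acc += x
        if acc >= target:
            return x, rank
    return lengths[-1], len(lengths)  # unreachable


def write_histogram_tsv(hist: KmerHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("depth\tcount\n")
        for d in sorted(hist.counts):
            fh.write(f"{d}\t{hist.counts[d]}\n")
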