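"""Cultivar-pair simulator with exact truth.

Generates a pair of closely related genomes the way two cultivars of a
selfing crop relate: mostly syntenic, with clustered SNPs (discrete
high-density blocks), short indels (1-100 bp), presence/absence segments
(> 500 bp, ~99% of mass below 5 kb), inversions and intra-/inter-
chromosomal translocations.  Every planted edit is logged in a
:class:`TruthSet` whose replay reproduces the derived genome byte for
byte, so downstream callers can be scored for parameter recovery.

Coordinate bookkeeping: structural events are drawn as mutually disjoint
intervals on the ancestor (genome A) with a safety buffer, the derived
genome (B) is assembled from a fragment map, and point mutations are then
applied within fragments, away from fragment boundaries.  Disjointness
makes the composite of edits order-independent and keeps truth
coordinates exact in both genomes.

A single `numpy` Generator per seed is consumed in a fixed, documented
order (ancestor bases; SV placement; enriched-tile choice; per-chromosome
point-mutation sampling; allele/length draws), so identical seed + config
give byte-identical outputs on any platform.
"""

from __future__ import annotations

import dataclasses
import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, SimulationError
from .genome import Genome, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# point mutations stay this far away from fragment boundaries so that
# truth SV/PAV breakpoints are never perturbed by indel offsets
EDGE_BUFFER = 200
# minimum spacing between accepted point edits (keeps calls unambiguous)
MIN_EDIT_SPACING = 10
# structural intervals are padded by this much when testing disjointness
SV_BUFFER = 2_000
END_MARGIN = 5_000


@dataclass
class SimulationConfig:
    """Study conditions for one cultivar pair.

    Defaults describe the desk-scale pair used throughout the test suite:
    two 1-Mb chromosomes, background SNP rate 2e-3/bp with 3x enriched
    blocks of 200 kb covering ~20% of the genome, indels at 4e-4/bp with
    geometric lengths in 1-100 bp, 30 PAV segments (0.6-8 kb, 99% of the
    length law's mass below 5 kb), three inversions of at least 5 kb and
    one translocation of each kind.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    gc_content: float = 0.46
    seed: int = 0

    snp_rate_background: float = 0.002
    enriched_fraction: float = 0.20
    enriched_fold: float = 3.0
    enriched_block_length: int = 200_000
    enriched_grid: int = 50_000  # placement lattice; matches the density window

    indel_rate: float = 0.0004
    indel_length_p: float = 0.5  # geometric parameter, lengths 1-100

    n_pav_insertions: int = 15
    n_pav_deletions: int = 15
    pav_min_length: int = 600
    pav_max_length: int = 8_000
    pav_fraction_below_5kb: float = 0.99

    n_inversions: int = 3
    inversion_length_range: tuple[int, int] = (5_000, 40_000)
    n_intra_translocations: int = 1
    n_inter_translocations: int = 1
    translocation_length_range: tuple[int, int] = (10_000, 30_000)

    read_coverage: float = 40.0
    read_length: int = 100
    read_error_rate: float = 0.002

    def validate(self) -> None:
        def _positive(name):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

        def _fraction(name):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")

        for name in ("n_chromosomes", "chrom_length", "enriched_block_length",
                     "pav_min_length", "pav_max_length", "read_length"):
            _positive(name)
        for name in ("gc_content", "snp_rate_background", "indel_rate",
                     "enriched_fraction", "pav_fraction_below_5kb",
                     "read_error_rate"):
            _fraction(name)
        if not (0.0 < self.indel_length_p <= 1.0):
            raise ConfigurationError("indel_length_p must be in (0, 1]")
        if self.enriched_fold <= 1.5:
            raise ConfigurationError("enriched_fold must exceed 1.5")
        if self.enriched_grid <= 0 or self.enriched_block_length % self.enriched_grid:
            raise ConfigurationError(
                "enriched_block_length must be a positive multiple of enriched_grid")
        if self.pav_min_length <= 500:
            raise ConfigurationError("pav_min_length must exceed 500 bp")
        if self.pav_max_length < self.pav_min_length:
            raise ConfigurationError("pav_max_length must be >= pav_min_length")
        for name in ("n_pav_insertions", "n_pav_deletions", "n_inversions",
                     "n_intra_translocations", "n_inter_translocations"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("inversion_length_range", "translocation_length_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must be an increasing positive range")
        if self.read_coverage <= 0:
            raise ConfigurationError("read_coverage must be positive")
        if self.n_inter_translocations > 0 and self.n_chromosomes < 2:
            raise ConfigurationError(
                "n_inter_translocations requires n_chromosomes >= 2")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["inversion_length_range"] = list(d["inversion_length_range"])
        d["translocation_length_range"] = list(d["translocation_length_range"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["inversion_length_range"] = tuple(d["inversion_length_range"])
        d["translocation_length_range"] = tuple(d["translocation_length_range"])
        return cls(**d)


@dataclass
class TruthSnp:
    chrom_a: str
    pos_a: int  # 0-based
    base_a: str
    chrom_b: str
    pos_b: int  # 0-based, final B coordinates
    base_b: str


@dataclass
class TruthIndel:
    kind: str  # "insertion" (extra bases in B) or "deletion" (bases missing from B)
    chrom_a: str
    pos_a: int  # insertion: B bases sit before A[pos_a]; deletion: start of the A interval
    chrom_b: str
    pos_b: int  # insertion: start of inserted bases in B; deletion: gap point in B
    length: int
    seq: str    # the inserted (B-orientation) or deleted (B1-orientation) bases


@dataclass
class TruthPav:
    genome: str  # "A": present in A, absent from B; "B": present in B only
    chrom: str
    start: int
    end: int


@dataclass
class TruthSV:
    type: str  # inversion | intra_translocation | inter_translocation
    chrom_a: str
    a_start: int
    a_end: int
    chrom_b: str
    b_start: int
    b_end: int
    strand: str


@dataclass
class Fragment:
    """One piece of a derived chromosome: a copy of an ancestor interval
    (possibly reverse-complemented) or novel sequence."""

    chrom_b: str
    b_start: int  # final B coordinates
    b_end: int
    kind: str     # "A" or "novel"
    chrom_a: str = ""
    a_start: int = -1
    a_end: int = -1
    strand: str = "+"
    novel_seq: str = ""


@dataclass
class TruthSet:
    """Ledger of planted edits, with liftover between the two genomes."""

    snps: list[TruthSnp] = field(default_factory=list)
    indels: list[TruthIndel] = field(default_factory=list)
    pav_segments: list[TruthPav] = field(default_factory=list)
    svs: list[TruthSV] = field(default_factory=list)
    fragments: list[Fragment] = field(default_factory=list)
    enriched_regions: list[tuple[str, int, int]] = field(default_factory=list)
    chrom_order: list[str] = field(default_factory=list)

    def apply_to(self, ancestor: Genome) -> Genome:
        """Replay all recorded edits on genome A; must reproduce B exactly."""
        frag_by_chrom: dict[str, list[Fragment]] = {c: [] for c in self.chrom_order}
        for fr in self.fragments:
            frag_by_chrom[fr.chrom_b].append(fr)
        edits_by_chrom: dict[str, list] = {c: [] for c in self.chrom_order}
        for s in self.snps:
            edits_by_chrom[s.chrom_b].append(("snp", s.pos_b, s))
        for ind in self.indels:
            edits_by_chrom[ind.chrom_b].append((ind.kind, ind.pos_b, ind))
        derived = {}
        for chrom in self.chrom_order:
            frags = sorted(frag_by_chrom[chrom], key=lambda f: f.b_start)
            pieces = []
            for fr in frags:
                if fr.kind == "novel":
                    pieces.append(fr.novel_seq)
                else:
                    seg = ancestor[fr.chrom_a][fr.a_start:fr.a_end]
                    pieces.append(revcomp(seg) if fr.strand == "-" else seg)
            b1 = "".join(pieces)
            out = []
            cur = 0      # position in b1
            offset = 0   # final = b1 + offset at the current point
            for kind, pos_b, ed in sorted(edits_by_chrom[chrom], key=lambda t: t[1]):
                q = pos_b - offset  # b1 coordinate of the edit
                out.append(b1[cur:q])
                if kind == "snp":
                    out.append(ed.base_b)
                    cur = q + 1
                elif kind == "insertion":
                    out.append(ed.seq)
                    offset += ed.length
                    cur = q
                else:  # deletion
                    offset -= ed.length
                    cur = q + ed.length
            out.append(b1[cur:])
            derived[chrom] = "".join(out)
        return Genome(derived)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def pav_length_law(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    """Sample PAV segment lengths: a mixture putting `pav_fraction_below_5kb`
    of its mass on a log-uniform [pav_min_length, 5000) component and the
    rest uniform on [5000, pav_max_length]."""
    if config.pav_max_length < 5_000:
        below = np.ones(n, dtype=bool)  # the whole range is below the knee
    else:
        below = rng.random(n) < config.pav_fraction_below_5kb
    lengths = np.empty(n, dtype=np.int64)
    n_below = int(below.sum())
    if n_below:
        lo = math.log(config.pav_min_length)
        hi = math.log(min(5_000, config.pav_max_length))
        lengths[below] = np.floor(np.exp(rng.uniform(lo, hi, n_below))).astype(np.int64)
    n_above = n - n_below
    if n_above:
        lengths[~below] = rng.integers(5_000, config.pav_max_length + 1, n_above)
    return np.clip(lengths, config.pav_min_length, config.pav_max_length)


def simulate_ancestor(config: SimulationConfig) -> Genome:
    """Random ancestor genome at the configured GC content (genome A)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = {}
    for i in range(config.n_chromosomes):
        chroms[f"chr{i + 1}"] = _random_seq(rng, config.chrom_length, config.gc_content)
    return Genome(chroms)


class _Placer:
    """Draws mutually disjoint intervals (with buffer) on the ancestor."""

    def __init__(self, rng, chrom_lengths: dict[str, int]):
        self.rng = rng
        self.lengths = chrom_lengths
        self.names = list(chrom_lengths)
        tot = sum(chrom_lengths.values())
        self.p = np.array([chrom_lengths[c] / tot for c in self.names])
        self.blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in self.names}

    def _free(self, chrom: str, start: int, end: int) -> bool:
        return all(end + SV_BUFFER <= s or start - SV_BUFFER >= e
                   for s, e in self.blocked[chrom])

    def place(self, length: int, chrom: str | None = None, what: str = "interval"):
        for _ in range(2_000):
            c = chrom if chrom is not None else self.names[self.rng.choice(len(self.names), p=self.p)]
            L = self.lengths[c]
            if L < length + 2 * END_MARGIN:
                if chrom is not None or all(
                        self.lengths[x] < length + 2 * END_MARGIN for x in self.names):
                    raise SimulationError(
                        f"requested {what} of {length} bp does not fit on any chromosome")
                continue
            s = int(self.rng.integers(END_MARGIN, L - END_MARGIN - length + 1))
            if self._free(c, s, s + length):
                self.blocked[c].append((s, s + length))
                return c, s
        raise SimulationError(f"could not place {what} of {length} bp after 2000 tries")


def derive_cultivar(ancestor: Genome, config: SimulationConfig,
                    seed: int) -> tuple[Genome, TruthSet]:
    """Apply SVs (inter-, then intra-translocations, inversions, PAV
    deletions/insertions) and then point mutations (indels, SNPs with
    enriched blocks drawn first) to the ancestor; log everything."""
    config.validate()
    if not len(ancestor) or ancestor.total_length() == 0:
        raise SimulationError("ancestor genome is empty")
    rng = np.random.default_rng(seed)
    truth = TruthSet(chrom_order=ancestor.names)
    placer = _Placer(rng, ancestor.lengths())

    # --- draw all structural events on A ------------------------------------
    # events per A chromosome: ("remove"|"invert", start, end, tag) and
    # ("insert", pos, payload)
    events: dict[str, list] = {c: [] for c in ancestor.names}

    for _ in range(config.n_inter_translocations):
        lo, hi = config.translocation_length_range
        length = int(rng.integers(lo, hi + 1))
        src_chrom, src_start = placer.place(length, what="inter-translocation source")
        others = [c for c in ancestor.names if c != src_chrom]
        dest_chrom = others[int(rng.integers(len(others)))]
        dest_chrom, dest_pos = placer.place(0, chrom=dest_chrom,
                                            what="inter-translocation destination")
        events[src_chrom].append(("remove", src_start, src_start + length, ("transloc",)))
        events[dest_chrom].append(
            ("insert", dest_pos,
             ("recv", "inter_translocation", src_chrom, src_start, src_start + length)))

    for _ in range(config.n_intra_translocations):
        lo, hi = config.translocation_length_range
        length = int(rng.integers(lo, hi + 1))
        src_chrom, src_start = placer.place(length, what="intra-translocation source")
        _, dest_pos = placer.place(0, chrom=src_chrom,
                                   what="intra-translocation destination")
        events[src_chrom].append(("remove", src_start, src_start + length, ("transloc",)))
        events[src_chrom].append(
            ("insert", dest_pos,
             ("recv", "intra_translocation", src_chrom, src_start, src_start + length)))

    for _ in range(config.n_inversions):
        lo, hi = config.inversion_length_range
        length = int(rng.integers(lo, hi + 1))
        chrom, start = placer.place(length, what="inversion")
        events[chrom].append(("invert", start, start + length, None))

    del_lengths = pav_length_law(rng, config, config.n_pav_deletions)
    for length in del_lengths:
        chrom, start = placer.place(int(length), what="PAV deletion")
        events[chrom].append(("remove", start, start + int(length), ("pav",)))

    ins_lengths = pav_length_law(rng, config, config.n_pav_insertions)
    for length in ins_lengths:
        chrom, pos = placer.place(0, what="PAV insertion anchor")
        seq = _random_seq(rng, int(length), config.gc_content)
        events[chrom].append(("insert", pos, ("novel", seq)))

    # --- assemble B1 fragment maps -----------------------------------------
    # B1 = derived genome before point mutations; fragments carry b1 coords.
    frag_lists: dict[str, list[Fragment]] = {}
    b1_seqs: dict[str, str] = {}
    for chrom in ancestor.names:
        evs = sorted(events[chrom], key=lambda e: (e[1], 0 if e[0] == "insert" else 1))
        frags: list[Fragment] = []
        pieces: list[str] = []
        pos_b1 = 0
        cur = 0

        def emit(fr: Fragment, seq: str):
            nonlocal pos_b1
            fr.b_start = pos_b1
            fr.b_end = pos_b1 + len(seq)
            pos_b1 += len(seq)
            frags.append(fr)
            pieces.append(seq)

        def emit_plain(a_from: int, a_to: int):
            if a_to > a_from:
                emit(Fragment(chrom, 0, 0, "A", chrom, a_from, a_to, "+"),
                     ancestor[chrom][a_from:a_to])

        for ev in evs:
            kind = ev[0]
            emit_plain(cur, ev[1])
            if kind == "remove":
                _, s, e, tag = ev
                if tag[0] == "pav":
                    truth.pav_segments.append(TruthPav("A", chrom, s, e))
                cur = e
            elif kind == "invert":
                _, s, e, _ = ev
                fr = Fragment(chrom, 0, 0, "A", chrom, s, e, "-")
                emit(fr, revcomp(ancestor[chrom][s:e]))
                truth.svs.append(TruthSV("inversion", chrom, s, e,
                                         chrom, fr.b_start, fr.b_end, "-"))
                cur = e
            else:  # insert (the plain piece up to p was emitted above)
                _, p, payload = ev
                cur = p
                if payload[0] == "novel":
                    fr = Fragment(chrom, 0, 0, "novel", novel_seq=payload[1])
                    emit(fr, payload[1])
                    truth.pav_segments.append(TruthPav("B", chrom, fr.b_start, fr.b_end))
                else:
                    _, sv_type, src_chrom, s, e = payload
                    fr = Fragment(chrom, 0, 0, "A", src_chrom, s, e, "+")
                    emit(fr, ancestor[src_chrom][s:e])
                    truth.svs.append(TruthSV(sv_type, src_chrom, s, e,
                                             chrom, fr.b_start, fr.b_end, "+"))
        emit_plain(cur, len(ancestor[chrom]))
        frag_lists[chrom] = frags
        b1_seqs[chrom] = "".join(pieces)

    # --- enriched SNP blocks on B1 ------------------------------------------
    # Blocks are runs of lattice cells (enriched_grid); a cell is eligible
    # when >= 80% of its bases derive from the ancestor, so the realized SNP
    # density inside a planted block stays close to fold x background.
    grid = config.enriched_grid
    k_cells = config.enriched_block_length // grid
    candidate_starts: list[tuple[str, int]] = []
    for chrom, frags in frag_lists.items():
        n_cells = len(b1_seqs[chrom]) // grid
        cov = np.zeros(n_cells)
        for fr in frags:
            if fr.kind != "A":
                continue
            lo_cell = fr.b_start // grid
            hi_cell = min((fr.b_end - 1) // grid, n_cells - 1)
            for ci in range(lo_cell, hi_cell + 1):
                c0, c1 = ci * grid, (ci + 1) * grid
                cov[ci] += max(0, min(fr.b_end, c1) - max(fr.b_start, c0))
        eligible_cell = cov / grid >= 0.8
        for start in range(0, n_cells - k_cells + 1):
            if eligible_cell[start:start + k_cells].all():
                candidate_starts.append((chrom, start))
    total_len = sum(len(s) for s in b1_seqs.values())
    n_blocks = round(config.enriched_fraction * total_len / config.enriched_block_length)
    enriched_b1: list[tuple[str, int, int]] = []
    if n_blocks and candidate_starts:
        order = rng.permutation(len(candidate_starts))
        taken: dict[str, list[tuple[int, int]]] = {c: [] for c in ancestor.names}
        for oi in order:
            chrom, start = candidate_starts[oi]
            s, e = start * grid, (start + k_cells) * grid
            if all(e <= ts or s >= te for ts, te in taken[chrom]):
                taken[chrom].append((s, e))
                enriched_b1.append((chrom, s, e))
                if len(enriched_b1) == n_blocks:
                    break
        enriched_b1.sort()

    # --- point mutations, per chromosome in order ---------------------------
    derived: dict[str, str] = {}
    for chrom in ancestor.names:
        b1 = b1_seqs[chrom]
        frags = frag_lists[chrom]
        n = len(b1)
        rate = np.zeros(n)
        for fr in frags:
            if fr.kind == "A" and fr.b_end - fr.b_start > 2 * EDGE_BUFFER:
                rate[fr.b_start + EDGE_BUFFER:fr.b_end - EDGE_BUFFER] = \
                    config.snp_rate_background
        for (c, t0, t1) in enriched_b1:
            if c == chrom:
                rate[t0:t1] *= config.enriched_fold
        snp_pos = np.nonzero(rng.random(n) < rate)[0]
        indel_pos = np.nonzero(
            rng.random(n) < rate * (config.indel_rate / config.snp_rate_background
                                    if config.snp_rate_background > 0 else 0.0))[0]

        cands = sorted([(int(p), "snp") for p in snp_pos] +
                       [(int(p), "indel") for p in indel_pos])
        frag_starts = [fr.b_start for fr in frags]

        def frag_at(q: int) -> Fragment:
            return frags[bisect_right(frag_starts, q) - 1]

        accepted: list[tuple[int, str, dict]] = []
        last_end = -MIN_EDIT_SPACING - 1
        for q, kind in cands:
            if q < last_end + MIN_EDIT_SPACING:
                continue
            fr = frag_at(q)
            if kind == "snp":
                old = b1[q]
                alts = [b for b in "ACGT" if b != old]
                new = alts[int(rng.integers(3))]
                accepted.append((q, "snp", {"new": new}))
                last_end = q + 1
            else:
                length = min(int(rng.geometric(config.indel_length_p)), 100)
                ins = bool(rng.integers(2))
                if ins:
                    seq = _random_seq(rng, length, config.gc_content)
                    accepted.append((q, "insertion", {"seq": seq, "len": length}))
                    last_end = q + 1
                else:
                    if q + length + EDGE_BUFFER > fr.b_end:
                        continue
                    accepted.append((q, "deletion", {"len": length}))
                    last_end = q + length

        out: list[str] = []
        cur = 0
        offset = 0
        shift_points: list[int] = []   # b1 position after which the shift applies
        shift_deltas: list[int] = []
        for q, kind, info in accepted:
            fr = frag_at(q)
            if fr.strand == "+":
                a_pos = fr.a_start + (q - fr.b_start)
            else:
                a_pos = fr.a_end - 1 - (q - fr.b_start)
            out.append(b1[cur:q])
            pos_b = q + offset
            if kind == "snp":
                base_a = ancestor[fr.chrom_a][a_pos]
                truth.snps.append(TruthSnp(fr.chrom_a, a_pos, base_a,
                                           chrom, pos_b, info["new"]))
                out.append(info["new"])
                cur = q + 1
            elif kind == "insertion":
                truth.indels.append(TruthIndel(
                    "insertion", fr.chrom_a,
                    a_pos if fr.strand == "+" else a_pos + 1,
                    chrom, pos_b, info["len"], info["seq"]))
                out.append(info["seq"])
                offset += info["len"]
                shift_points.append(q)
                shift_deltas.append(info["len"])
                cur = q
            else:
                L = info["len"]
                if fr.strand == "+":
                    a_start = a_pos
                else:
                    a_start = fr.a_end - 1 - (q + L - 1 - fr.b_start)
                truth.indels.append(TruthIndel(
                    "deletion", fr.chrom_a, a_start, chrom, pos_b, L, b1[q:q + L]))
                offset -= L
                shift_points.append(q + L)
                shift_deltas.append(-L)
                cur = q + L
        out.append(b1[cur:])
        derived[chrom] = "".join(out)

        # lift all recorded b1 intervals on this chromosome to final B coords
        cum = np.cumsum(shift_deltas) if shift_deltas else np.array([], dtype=int)

        def lift(b: int) -> int:
            i = bisect_right(shift_points, b)
            return b + (int(cum[i - 1]) if i else 0)

        for fr in frags:
            fr.b_start, fr.b_end = lift(fr.b_start), lift(fr.b_end)
        for pav in truth.pav_segments:
            if pav.genome == "B" and pav.chrom == chrom:
                pav.start, pav.end = lift(pav.start), lift(pav.end)
        for sv in truth.svs:
            if sv.chrom_b == chrom:
                sv.b_start, sv.b_end = lift(sv.b_start), lift(sv.b_end)
        truth.enriched_regions.extend(
            (c, lift(t0), lift(t1)) for c, t0, t1 in enriched_b1 if c == chrom)
        truth.fragments.extend(frags)

    return Genome(derived), truth


def simulate_reads(genome: Genome, coverage: float, read_length: int,
                   error_rate: float, seed: int) -> list[tuple[str, str]]:
    """Uniform error-bearing single-end reads (FASTA-style, no qualities)."""
    if coverage <= 0:
        raise ConfigurationError("read_coverage must be positive")
    for name, seq in genome.chroms.items():
        if read_length > len(seq):
            raise SimulationError(
                f"read_length {read_length} exceeds chromosome {name} length {len(seq)}")
    rng = np.random.default_rng(seed)
    total = genome.total_length()
    n_reads = int(round(coverage * total / read_length))
    names = genome.names
    weights = np.array([len(genome[c]) - read_length + 1 for c in names], dtype=float)
    weights /= weights.sum()
    chrom_idx = rng.choice(len(names), size=n_reads, p=weights)
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        c = names[chrom_idx[i]]
        start = int(rng.integers(0, len(genome[c]) - read_length + 1))
        seq = genome[c][start:start + read_length]
        if rng.integers(2):
            seq = revcomp(seq)
        n_err = rng.binomial(read_length, error_rate)
        if n_err:
            arr = list(seq)
            for p in rng.choice(read_length, size=n_err, replace=False):
                alts = [b for b in "ACGT" if b != arr[p]]
                arr[p] = alts[int(rng.integers(3))]
            seq = "".join(arr)
        reads.append((f"read_{i}:{c}:{start}", seq))
    return reads


def write_reads_fasta(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f">{name}\n{seq}\n")


# --------------------------------------------------------------------------
# truth I/O: BED for intervals plus VCF-like TSVs; write -> read -> write
# round-trips byte-identically
# --------------------------------------------------------------------------

def write_truth(truth: TruthSet, out_prefix: str | Path) -> list[Path]:
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []

    p = prefix.with_suffix(".snps.tsv")
    with open(p, "w") as fh:
        fh.write("CHROM_A\tPOS_A\tBASE_A\tCHROM_B\tPOS_B\tBASE_B\n")
        for s in truth.snps:
            fh.write(f"{s.chrom_a}\t{s.pos_a + 1}\t{s.base_a}\t"
                     f"{s.chrom_b}\t{s.pos_b + 1}\t{s.base_b}\n")
    paths.append(p)

    p = prefix.with_suffix(".indels.tsv")
    with open(p, "w") as fh:
        fh.write("KIND\tCHROM_A\tPOS_A\tCHROM_B\tPOS_B\tLENGTH\tSEQ\n")
        for d in truth.indels:
            fh.write(f"{d.kind}\t{d.chrom_a}\t{d.pos_a + 1}\t{d.chrom_b}\t"
                     f"{d.pos_b + 1}\t{d.length}\t{d.seq}\n")
    paths.append(p)

    p = prefix.with_suffix(".pav.bed")
    with open(p, "w") as fh:
        fh.write("#chrom\tstart\tend\tgenome\tlength\tstrand\n")
        for seg in truth.pav_segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.genome}\t"
                     f"{seg.end - seg.start}\t+\n")
    paths.append(p)

    p = prefix.with_suffix(".sv.tsv")
    with open(p, "w") as fh:
        fh.write("TYPE\tCHROM_A\tA_START\tA_END\tCHROM_B\tB_START\tB_END\tSTRAND\n")
        for sv in truth.svs:
            fh.write(f"{sv.type}\t{sv.chrom_a}\t{sv.a_start}\t{sv.a_end}\t"
                     f"{sv.chrom_b}\t{sv.b_start}\t{sv.b_end}\t{sv.strand}\n")
    paths.append(p)

    p = prefix.with_suffix(".enriched.bed")
    with open(p, "w") as fh:
        fh.write("#chrom\tstart\tend\n")
        for c, s, e in truth.enriched_regions:
            fh.write(f"{c}\t{s}\t{e}\n")
    paths.append(p)

    p = prefix.with_suffix(".fragments.tsv")
    with open(p, "w") as fh:
        fh.write("CHROM_B\tB_START\tB_END\tKIND\tCHROM_A\tA_START\tA_END\tSTRAND\tNOVEL_SEQ\n")
        fh.write(f"#chrom_order={','.join(truth.chrom_order)}\n")
        for fr in truth.fragments:
            fh.write(f"{fr.chrom_b}\t{fr.b_start}\t{fr.b_end}\t{fr.kind}\t"
                     f"{fr.chrom_a}\t{fr.a_start}\t{fr.a_end}\t{fr.strand}\t"
                     f"{fr.novel_seq}\n")
    paths.append(p)
    return paths


def read_truth(out_prefix: str | Path) -> TruthSet:
    prefix = Path(out_prefix)
    truth = TruthSet()

    with open(prefix.with_suffix(".snps.tsv")) as fh:
        next(fh)
        for line in fh:
            ca, pa, ba, cb, pb, bb = line.rstrip("\n").split("\t")
            truth.snps.append(TruthSnp(ca, int(pa) - 1, ba, cb, int(pb) - 1, bb))

    with open(prefix.with_suffix(".indels.tsv")) as fh:
        next(fh)
        for line in fh:
            kind, ca, pa, cb, pb, length, seq = line.rstrip("\n").split("\t")
            truth.indels.append(TruthIndel(kind, ca, int(pa) - 1, cb,
                                           int(pb) - 1, int(length), seq))

    with open(prefix.with_suffix(".pav.bed")) as fh:
        next(fh)
        for line in fh:
            chrom, start, end, genome, _len, _strand = line.rstrip("\n").split("\t")
            truth.pav_segments.append(TruthPav(genome, chrom, int(start), int(end)))

    with open(prefix.with_suffix(".sv.tsv")) as fh:
        next(fh)
        for line in fh:
            t, ca, a0, a1, cb, b0, b1_, strand = line.rstrip("\n").split("\t")
            truth.svs.append(TruthSV(t, ca, int(a0), int(a1), cb,
                                     int(b0), int(b1_), strand))

    with open(prefix.with_suffix(".enriched.bed")) as fh:
        next(fh)
        for line in fh:
            c, s, e = line.rstrip("\n").split("\t")
            truth.enriched_regions.append((c, int(s), int(e)))

    with open(prefix.with_suffix(".fragments.tsv")) as fh:
        next(fh)
        order_line = next(fh)
        truth.chrom_order = order_line.strip().split("=", 1)[1].split(",")
        for line in fh:
            cb, b0, b1_, kind, ca, a0, a1, strand, novel = line.rstrip("\n").split("\t")
            truth.fragments.append(Fragment(cb, int(b0), int(b1_), kind, ca,
                                            int(a0), int(a1), strand, novel))
    return truth
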