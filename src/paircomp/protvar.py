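"""Coding-sequence and protein-level allele comparison, plus in-silico PCR.

Built for the herbicide-resistance style analysis: a pair of CDS alleles
differing by a handful of nucleotide substitutions, of which typically
only one changes the protein (e.g. an AHAS S626N-type substitution),
and exact-match primer amplification to recover the amplicon a PCR assay
would produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
from Bio.Data.CodonTable import standard_dna_table

from .genome import Genome, revcomp

_CODON = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


@dataclass
class SubstitutionCall:
    position: int  # 1-based amino-acid index
    from_aa: str
    to_aa: str

    @property
    def label(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


def translate_cds(cds: str) -> str:
    """Standard-code translation of a CDS.

    Length must be divisible by 3; a non-ATG start only warns; a trailing
    stop codon is dropped; an internal stop raises naming the codon
    index; any codon with an ambiguous base becomes 'X' with a warning.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if not cds.startswith("ATG"):
        warnings.warn("CDS does not start with ATG")
    n_codons = len(cds) // 3
    aas = []
    for i in range(n_codons):
        codon = cds[3 * i:3 * i + 3]
        if codon in _STOPS:
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon at codon index {i + 1}")
        aa = _CODON.get(codon)
        if aa is None:
            warnings.warn(f"ambiguous codon {codon!r} at codon {i + 1}; using X")
            aa = "X"
        aas.append(aa)
    return "".join(aas)


def _align_pair(a: str, b: str) -> tuple[str, str]:
    """Global pairwise alignment (unit costs) producing gapped strings."""
    if len(a) == len(b):
        return a, b
    res = edlib.align(b, a, mode="NW", task="path")
    ga, gb = [], []
    ia = ib = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch in "=X":
            ga.append(a[ia:ia + ln]); gb.append(b[ib:ib + ln])
            ia += ln; ib += ln
        elif ch == "D":  # extra in a
            ga.append(a[ia:ia + ln]); gb.append("-" * ln)
            ia += ln
        else:  # 'I': extra in b
            ga.append("-" * ln); gb.append(b[ib:ib + ln])
            ib += ln
    return "".join(ga), "".join(gb)


def diff_cds(a: str, b: str) -> list[tuple[int, str, str]]:
    """Nucleotide substitutions between two CDS alleles as (1-based
    position in `a`, base_a, base_b); unequal lengths are aligned first
    and gap columns are not substitutions."""
    ga, gb = _align_pair(a.upper(), b.upper())
    out = []
    pos_a = 0
    for ca, cb in zip(ga, gb):
        if ca != "-":
            pos_a += 1
        if ca != "-" and cb != "-" and ca != cb:
            out.append((pos_a, ca, cb))
    return out


def diff_proteins(a: str, b: str) -> list[SubstitutionCall]:
    """One call per differing aligned column, labelled like "S626N"."""
    ga, gb = _align_pair(a, b)
    out = []
    pos = 0
    for ca, cb in zip(ga, gb):
        if ca != "-":
            pos += 1
        if ca != "-" and cb != "-" and ca != cb:
            out.append(SubstitutionCall(pos, ca, cb))
    return out


def in_silico_pcr(genome: Genome, fwd: str, rev: str,
                  max_product: int = 20_000) -> list[dict]:
    """Exact-match PCR product prediction.

    A product arises where the forward primer matches a strand exactly
    and the reverse primer's reverse complement matches downstream on the
    same strand; the amplicon runs from the forward primer start through
    the end of the reverse-primer binding site.  Both strands are
    searched; coordinates are always on the forward genome strand.
    """
    fwd, rev = fwd.upper(), rev.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 bp")

    def _find_all(hay: str, needle: str) -> list[int]:
        out, i = [], hay.find(needle)
        while i != -1:
            out.append(i)
            i = hay.find(needle, i + 1)
        return out

    products = []
    for chrom in genome.names:
        for strand in "+-":
            seq = genome[chrom] if strand == "+" else revcomp(genome[chrom])
            L = len(seq)
            f_sites = _find_all(seq, fwd)
            r_sites = _find_all(seq, revcomp(rev))
            for f in f_sites:
                for r in r_sites:
                    end = r + len(rev)
                    if end <= f or end - f > max_product:
                        continue
                    s, e = (f, end) if strand == "+" else (L - end, L - f)
                    products.append({"chrom": chrom, "start": s, "end": e,
                                     "length": end - f, "strand": strand})
    products.sort(key=lambda d: (d["chrom"], d["start"], d["strand"]))
    return products
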