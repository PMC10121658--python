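"""Candidate characterization: ORF finding, translation, in-silico PCR.

The screen's surviving candidates are mRNA isoforms, so ORF search runs on
the forward strand only, requires an ATG start and an in-frame stop inside
the sequence, and reports the longest hit (5'-most start on ties).
Coordinates are 0-based half-open on the given strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = ["OrfHit", "PrimerPair", "find_longest_orf", "translate",
           "reverse_complement", "insilico_pcr"]

_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class OrfHit:
    start: int  # 0-based, inclusive
    end: int  # exclusive; includes the stop codon
    frame: int  # 0, 1 or 2
    peptide: str  # excludes the stop

    @property
    def peptide_length(self) -> int:
        return len(self.peptide)


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str  # given 5'->3' on the opposite strand
    max_product: int = 3000

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if len(p) < 10:
                raise ValueError("primer length must be >= 10 nt")
            bad = set(p.upper()) - _IUPAC
            if bad:
                raise ValueError(f"non-IUPAC character(s) {sorted(bad)} in primer")


def _validate_dna(dna: str) -> str:
    dna = dna.upper()
    bad = set(dna) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC character(s): {sorted(bad)}")
    return dna


def translate(dna: str, frame: int = 0) -> str:
    """Standard-code translation of one frame; stop rendered as '*'.

    Codons containing ambiguity codes translate to 'X' unless every
    resolution agrees (Biopython semantics); trailing partial codons are
    dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    dna = _validate_dna(dna)
    sub = dna[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def reverse_complement(dna: str) -> str:
    return str(Seq(_validate_dna(dna)).reverse_complement())


def find_longest_orf(sequence: str) -> OrfHit | None:
    """Longest ATG-initiated, stop-terminated ORF on the forward strand.

    All three frames are scanned; ORFs without an in-frame stop inside the
    sequence are not reported.  Ties go to the 5'-most start.
    """
    dna = _validate_dna(sequence)
    best: OrfHit | None = None
    for frame in (0, 1, 2):
        aa = translate(dna, frame)
        i = 0
        while True:
            m_pos = aa.find("M", i)
            if m_pos == -1:
                break
            stop_pos = aa.find("*", m_pos)
            if stop_pos == -1:
                break
            start = frame + 3 * m_pos
            end = frame + 3 * (stop_pos + 1)
            hit = OrfHit(start, end, frame, aa[m_pos:stop_pos])
            if (
                best is None
                or hit.peptide_length > best.peptide_length
                or (hit.peptide_length == best.peptide_length and hit.start < best.start)
            ):
                best = hit
            i = stop_pos + 1
    return best


def insilico_pcr(
    template: str, primers: PrimerPair
) -> list[tuple[int, int, int]]:
    """Exact-match PCR product prediction.

    Finds every occurrence of the forward primer on the forward strand and
    of the reverse primer's reverse complement downstream of it; returns
    (start, end, product_length) triples with end exclusive, so
    product_length = end - start spans both primer footprints.  Products
    longer than ``max_product`` are dropped.
    """
    tpl = _validate_dna(template)
    fwd = primers.forward.upper()
    rev_site = reverse_complement(primers.reverse)

    fwd_starts = [m.start() for m in re.finditer(f"(?={re.escape(fwd)})", tpl)]
    rev_starts = [m.start() for m in re.finditer(f"(?={re.escape(rev_site)})", tpl)]

    products = []
    for fs in fwd_starts:
        for rs in rev_starts:
            if rs < fs + len(fwd):
                continue  # sites must not precede or overlap the forward primer
            end = rs + len(rev_site)
            length = end - fs
            if length <= primers.max_product:
                products.append((fs, end, length))
    products.sort()
    return products
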