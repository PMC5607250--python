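"""Shared nucleotide-sequence helpers.

All pipeline stages work on DNA-alphabet strings (U is normalised to T on
input, since mature miRNA references are usually given as RNA).
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

NUCLEOTIDES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize(seq: str) -> str:
    """Uppercase and convert U to T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_nucleotide(seq: str) -> bool:
    return bool(seq) and set(seq) <= NUCLEOTIDES


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


class SubstringIndex:
    """Approximate-substring lookup over a set of reference sequences.

    Supports queries "does this 18-26 nt tag occur in any reference with at
    most ``max_mismatch`` substitutions, on either strand?".  Exact seeds
    (query halves) are located with C-level ``str.find`` and verified at the
    implied offset, which is complete for ``max_mismatch <= 1`` by the
    pigeonhole principle; larger tolerances fall back to a full scan.
    """

    SEP = "\x01"

    def __init__(self, seqs: list[str]):
        self._text = self.SEP.join(normalize(s) for s in seqs)
        self._starts: list[int] = []
        pos = 0
        for s in seqs:
            self._starts.append(pos)
            pos += len(s) + 1

    def __bool__(self) -> bool:
        return bool(self._text)

    def _verify(self, query: str, start: int, max_mismatch: int) -> bool:
        end = start + len(query)
        if start < 0 or end > len(self._text):
            return False
        window = self._text[start:end]
        if self.SEP in window:
            return False
        return hamming(query, window) <= max_mismatch

    def _contains_oriented(self, query: str, max_mismatch: int) -> bool:
        text = self._text
        if max_mismatch == 0:
            return query in text
        if max_mismatch > 1:
            span = len(query)
            for start in range(len(text) - span + 1):
                if self._verify(query, start, max_mismatch):
                    return True
            return False
        half = len(query) // 2
        for seed, offset in ((query[:half], 0), (query[half:], half)):
            pos = text.find(seed)
            while pos != -1:
                if self._verify(query, pos - offset, max_mismatch):
                    return True
                pos = text.find(seed, pos + 1)
        return False

    def contains(self, query: str, max_mismatch: int = 0, both_strands: bool = True) -> bool:
        query = normalize(query)
        if not query or not self._text:
            return False
        if self._contains_oriented(query, max_mismatch):
            return True
        if both_strands:
            return self._contains_oriented(revcomp(query), max_mismatch)
        return False


class GenomeIndex:
    """Exact-match locator for short tags against a contig set.

    Returns loci as (contig, start, end, strand) with 0-based half-open
    coordinates on the + strand; a - strand hit reports the + strand
    interval covered by the match.
    """

    def __init__(self, contigs: dict[str, str]):
        self.contigs = {name: normalize(seq) for name, seq in contigs.items()}

    def find_loci(self, query: str, max_loci: int | None = None) -> list[tuple[str, int, int, str]]:
        query = normalize(query)
        loci: list[tuple[str, int, int, str]] = []
        limit = max_loci + 1 if max_loci is not None else None
        for strand, q in (("+", query), ("-", revcomp(query))):
            for name, seq in self.contigs.items():
                pos = seq.find(q)
                while pos != -1:
                    loci.append((name, pos, pos + len(q), strand))
                    if limit is not None and len(loci) >= limit:
                        return loci
                    pos = seq.find(q, pos + 1)
        return loci

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.contigs[contig][max(0, start):end]
        return revcomp(seq) if strand == "-" else seq
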