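"""Raw-read cleaning: junk removal, 3' adapter trimming, length filter,
and collapse of identical inserts into unique tags with counts.

The ledger partitions every input read into exactly one disposition
(junk, missing-adapter/length, valid), tracked both as total reads and as
distinct sequences, mirroring the per-library accounting table of a
small-RNA vendor pipeline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from ._seq import NUCLEOTIDES, hamming, normalize

DISPOSITIONS = ("junk", "no_3adt", "length", "valid")


@dataclass
class ReadRecord:
    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length differs from sequence length")


@dataclass
class JunkParams:
    """Low-complexity heuristics: a read is junk when any single base makes
    up >= ``max_base_frac`` of it, it contains a homopolymer run of
    ``max_homopolymer`` or more, it contains N or any non-nucleotide
    character, or a 2-periodic (dinucleotide) repeat covers >=
    ``max_dinuc_frac`` of it."""

    max_base_frac: float = 0.8
    max_homopolymer: int = 10
    max_dinuc_frac: float = 0.9


DEFAULT_JUNK = JunkParams()


def is_junk(seq: str, params: JunkParams = DEFAULT_JUNK) -> bool:
    seq = normalize(seq)
    n = len(seq)
    if n == 0 or set(seq) - NUCLEOTIDES:
        return True
    counts = Counter(seq)
    if max(counts.values()) >= params.max_base_frac * n:
        return True
    run = best_run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best_run = max(best_run, run)
    if best_run >= params.max_homopolymer:
        return True
    if n >= 4:
        run2 = best2 = 2
        for i in range(2, n):
            run2 = run2 + 1 if seq[i] == seq[i - 2] else 2
            best2 = max(best2, run2)
        # require a genuine dinucleotide (not homopolymer, handled above)
        if best2 >= params.max_dinuc_frac * n and best2 >= 6:
            return True
    return False


def trim_adapter3(
    read: "ReadRecord | str",
    adapter: str,
    min_overlap: int = 6,
    max_mismatch: int = 1,
) -> Optional[str]:
    """Return the insert 5' of the best 3' adapter match, or None (3ADT).

    The match is the leftmost position where a prefix of the adapter of
    length >= ``min_overlap`` aligns with at most ``max_mismatch``
    substitutions; ties at a position take the fewest mismatches (the
    longest available prefix is always compared).  For ``max_mismatch <= 1``
    an exact-seed search keeps this linear in practice.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    seq = normalize(seq)
    adapter = normalize(adapter)
    if min_overlap < 4 or len(adapter) < min_overlap:
        raise ValueError("adapter length must be >= min_overlap >= 4")
    n, m = len(seq), len(adapter)

    def mismatches_at(p: int) -> Optional[int]:
        span = min(m, n - p)
        if span < min_overlap:
            return None
        mm = hamming(seq[p:p + span], adapter[:span])
        return mm if mm <= max_mismatch else None

    full_limit = n - m  # positions where the whole adapter fits
    if max_mismatch <= 1 and m >= 2 * min_overlap:
        half = m // 2
        a1, a2 = adapter[:half], adapter[half:]
        candidates = set()
        pos = seq.find(a1)
        while pos != -1:
            candidates.add(pos)
            pos = seq.find(a1, pos + 1)
        pos = seq.find(a2)
        while pos != -1:
            if pos - half >= 0:
                candidates.add(pos - half)
            pos = seq.find(a2, pos + 1)
        best = None
        for p in sorted(candidates):
            if p > full_limit:
                continue
            mm = mismatches_at(p)
            if mm is not None:
                best = p
                break
        # tail region: truncated adapter prefixes (seed pair may not fit)
        tail_start = max(0, full_limit + 1)
        if best is None:
            for p in range(tail_start, n - min_overlap + 1):
                mm = mismatches_at(p)
                if mm is not None:
                    best = p
                    break
        if best is None:
            return None
        return seq[:best]

    for p in range(0, n - min_overlap + 1):
        if mismatches_at(p) is not None:
            return seq[:p]
    return None


@dataclass
class FilterLedger:
    """Exact partition of input reads by disposition, per library."""

    library_id: str
    reads: Counter = field(default_factory=Counter)
    unique: Counter = field(default_factory=Counter)

    @property
    def raw(self) -> int:
        return sum(self.reads.values())

    @property
    def adt_or_length(self) -> int:
        return self.reads["no_3adt"] + self.reads["length"]

    def check_partition(self) -> bool:
        return self.raw == sum(self.reads[d] for d in DISPOSITIONS)

    def as_dict(self) -> dict:
        return {
            "library": self.library_id,
            "raw": self.raw,
            "junk": self.reads["junk"],
            "3adt_or_length": self.adt_or_length,
            "valid": self.reads["valid"],
            **{f"unique_{d}": self.unique[d] for d in DISPOSITIONS},
        }


def filter_and_collapse(
    inserts: Iterable[Optional[str]],
    library_id: str,
    min_len: int = 18,
    max_len: int = 26,
    junk_params: JunkParams = DEFAULT_JUNK,
) -> tuple[dict[str, int], FilterLedger]:
    """Collapse adapter-trimmed inserts into unique tags with counts.

    ``None`` entries are reads whose 3' adapter was not found (3ADT).
    Filters apply in order junk -> 3ADT -> length; a read failing several is
    ledgered under the first.  Survivors are collapsed case-insensitively
    with U normalised to T.
    """
    ledger = FilterLedger(library_id)
    tags: Counter = Counter()
    seen: dict[str, set] = {d: set() for d in DISPOSITIONS}

    for ins in inserts:
        if ins is None:
            ledger.reads["no_3adt"] += 1
            continue
        seq = normalize(ins)
        if is_junk(seq, junk_params):
            disp = "junk"
        elif not (min_len <= len(seq) <= max_len):
            disp = "length"
        else:
            disp = "valid"
            tags[seq] += 1
        ledger.reads[disp] += 1
        seen[disp].add(seq)
    for d in DISPOSITIONS:
        ledger.unique[d] = len(seen[d])
    ledger.unique["no_3adt"] = 0  # untrimmed sequences are not tag-comparable
    return dict(tags), ledger


def preprocess_library(
    reads: Iterable[ReadRecord],
    library_id: str,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch: int = 1,
    min_len: int = 18,
    max_len: int = 26,
    junk_params: JunkParams = DEFAULT_JUNK,
) -> tuple[dict[str, int], FilterLedger]:
    """Full per-library preprocessing: trim, filter, collapse."""

    def trimmed() -> Iterator[Optional[str]]:
        for r in reads:
            yield trim_adapter3(r, adapter, min_overlap, max_mismatch)

    return filter_and_collapse(trimmed(), library_id, min_len, max_len, junk_params)


def merge_libraries(per_library: dict[str, dict[str, int]]):
    """Combine per-library tag counts into one tag table.

    Returns a DataFrame indexed by tag sequence with one count column per
    library plus ``total``.
    """
    import pandas as pd

    df = pd.DataFrame(per_library).fillna(0).astype(int)
    df.index.name = "sequence"
    df.columns = [f"count_{c}" for c in df.columns]
    df["total"] = df.sum(axis=1)
    return df.sort_index()


def length_distribution(tag_df) -> "object":
    """Count-weighted and unique-tag length histograms per library.

    Returns a DataFrame indexed by insert length with, per library, total
    read counts, unique tag counts, and the corresponding fractions
    (each fraction column sums to 1).
    """
    import pandas as pd

    lengths = tag_df.index.str.len()
    count_cols = [c for c in tag_df.columns if c.startswith("count_")]
    out = {}
    for col in count_cols:
        lib = col.removeprefix("count_")
        grp = tag_df.groupby(lengths)[col]
        total = grp.sum()
        uniq = tag_df[tag_df[col] > 0].groupby(
            tag_df.index[tag_df[col] > 0].str.len())[col].count()
        out[f"reads_{lib}"] = total
        out[f"unique_{lib}"] = uniq
    df = pd.DataFrame(out).fillna(0).astype(int)
    df.index.name = "length"
    for col in list(df.columns):
        s = df[col].sum()
        df[f"frac_{col}"] = df[col] / s if s else 0.0
    return df


def read_fastx(path) -> Iterator[ReadRecord]:
    """Read FASTA or FASTQ (optionally gzipped) into ReadRecords."""
    import gzip

    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        head = fh.read(1)
        fh.seek(0)
        fmt = "fastq" if head == "@" else "fasta"
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if "phred_quality" in rec.letter_annotations:
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield ReadRecord(rec.id, str(rec.seq), qual)


def write_tags_tsv(tag_df, path) -> None:
    tag_df.to_csv(path, sep="\t")


def write_tags_fasta(tag_df, path) -> None:
    """Collapsed-FASTA export with ``>tagN_xCOUNT`` headers."""
    with open(path, "w") as fh:
        for n, (seq, row) in enumerate(tag_df.iterrows(), start=1):
            fh.write(f">tag{n}_x{int(row['total'])}\n{seq}\n")
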