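"""Six-group classification of valid tags against miRNA references and the
genome, plus family and cross-species conservation summaries.

Groups (decided by a cascade, each tag gets exactly one):

* 1a - tag matches a focal-species mature miRNA whose precursor maps to the
  genome/EST;
* 1b - as 1a but the mature belongs to another mammal;
* 2a - mature match, precursor does not map, the tag itself maps to the
  genome and its flanking context folds into a passing hairpin;
* 2b - as 2a but no hairpin;
* 3  - mature match, neither precursor nor tag maps to the genome;
* 4  - no mature match; genome-mapped hairpin-forming tags, assigned by
  :mod:`caprimir.hairpin` (novel candidates);
* unassigned - everything else.

Matches on the opposite precursor arm (tag contained in a precursor but not
matching any mature) are recorded as arm-derived known miRNAs and follow
the same cascade.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

from ._seq import GenomeIndex, hamming, normalize, revcomp
from .contaminants import RefRecord, ReferenceBundle
from .hairpin import arm_of, fold_hairpin, hairpin_forms

SEED_K = 7  # seed-index k-mer for candidate lookup


@dataclass(frozen=True)
class MapTolerance:
    """Alignment slack for matching a tag to a reference mature miRNA:
    at most ``max_substitutions`` internal substitutions and at most
    ``max_end_shift`` nt of 5'/3' truncation or extension."""

    max_substitutions: int = 2
    max_end_shift: int = 2


DEFAULT_TOLERANCE = MapTolerance()


@dataclass
class GroupAssignment:
    tag: str
    group: str  # 1a, 1b, 2a, 2b, 3, 4, unassigned
    matched_mirna_id: Optional[str] = None
    matched_species: Optional[str] = None
    precursor_id: Optional[str] = None
    arm: str = "unknown"
    contig: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None
    mismatches: Optional[int] = None
    arm_derived: bool = False


def align_tag(tag: str, ref: str, tol: MapTolerance = DEFAULT_TOLERANCE) -> Optional[int]:
    """Mismatch count of the best tolerated ungapped alignment, else None.

    The tag start may shift by up to ``max_end_shift`` nt relative to the
    reference start, and the 3' ends may likewise differ by up to
    ``max_end_shift`` nt; substitutions are counted over the overlap.
    """
    best = None
    for shift in range(-tol.max_end_shift, tol.max_end_shift + 1):
        end_diff = abs(len(ref) - (shift + len(tag)))
        if end_diff > tol.max_end_shift:
            continue
        lo = max(0, shift)
        hi = min(shift + len(tag), len(ref))
        if hi - lo < max(len(tag), len(ref)) - 2 * tol.max_end_shift:
            continue
        mm = hamming(tag[lo - shift:hi - shift], ref[lo:hi])
        if mm <= tol.max_substitutions and (best is None or mm < best):
            best = mm
    return best


class MatureMatcher:
    """Seed-indexed approximate matcher of tags against mature references."""

    def __init__(self, records: list[RefRecord], tol: MapTolerance = DEFAULT_TOLERANCE):
        self.records = [RefRecord(r.id, normalize(r.seq), r.species) for r in records]
        self.tol = tol
        self._index: dict[str, set[int]] = defaultdict(set)
        for n, rec in enumerate(self.records):
            for i in range(len(rec.seq) - SEED_K + 1):
                self._index[rec.seq[i:i + SEED_K]].add(n)

    def match(self, tag: str) -> list[tuple[RefRecord, int]]:
        """All (record, mismatches) hits within tolerance."""
        tag = normalize(tag)
        cand: set[int] = set()
        for i in range(len(tag) - SEED_K + 1):
            cand |= self._index.get(tag[i:i + SEED_K], set())
        hits = []
        for n in cand:
            rec = self.records[n]
            mm = align_tag(tag, rec.seq, self.tol)
            if mm is not None:
                hits.append((rec, mm))
        return hits


class PrecursorMatcher:
    """Find tags contained inside precursor sequences (arm-derived hits)."""

    def __init__(self, records: list[RefRecord], max_mismatch: int = 2):
        self.records = [RefRecord(r.id, normalize(r.seq), r.species) for r in records]
        self.max_mismatch = max_mismatch
        self._index: dict[str, set[int]] = defaultdict(set)
        for n, rec in enumerate(self.records):
            for i in range(len(rec.seq) - SEED_K + 1):
                self._index[rec.seq[i:i + SEED_K]].add(n)

    def match(self, tag: str) -> list[tuple[RefRecord, int, int]]:
        """All (record, offset, mismatches) containments within tolerance."""
        tag = normalize(tag)
        cand: set[int] = set()
        for i in range(len(tag) - SEED_K + 1):
            cand |= self._index.get(tag[i:i + SEED_K], set())
        hits = []
        for n in cand:
            seq = self.records[n].seq
            best = None
            for off in range(len(seq) - len(tag) + 1):
                mm = hamming(tag, seq[off:off + len(tag)])
                if mm <= self.max_mismatch and (best is None or mm < best[1]):
                    best = (off, mm)
            if best is not None:
                hits.append((self.records[n], best[0], best[1]))
        return hits


class Classifier:
    """Stateful cascade over one reference bundle (indices built once)."""

    def __init__(
        self,
        bundle: ReferenceBundle,
        tolerance: MapTolerance = DEFAULT_TOLERANCE,
        flank: int = 80,
    ):
        self.bundle = bundle
        self.tolerance = tolerance
        self.flank = flank
        self.genome = GenomeIndex(bundle.genome) if bundle.genome else None
        self.matures = MatureMatcher(bundle.mature, tolerance)
        self.precursors = PrecursorMatcher(
            bundle.premirna, tolerance.max_substitutions)
        self._pre_seq = {r.id: normalize(r.seq) for r in bundle.premirna}
        self._pre_maps: dict[str, bool] = {}
        self._pre_fold = {}

    def _precursor_maps(self, pre_id: str) -> bool:
        if pre_id not in self._pre_maps:
            seq = self._pre_seq.get(pre_id)
            mapped = False
            if seq and self.genome:
                mapped = bool(self.genome.find_loci(seq, max_loci=1))
            self._pre_maps[pre_id] = mapped
        return self._pre_maps[pre_id]

    def _fold_precursor(self, pre_id: str):
        if pre_id not in self._pre_fold:
            seq = self._pre_seq[pre_id]
            try:
                self._pre_fold[pre_id] = fold_hairpin(seq)
            except ValueError:
                self._pre_fold[pre_id] = None
        return self._pre_fold[pre_id]

    def _arm_in_precursor(self, tag: str, pre_id: str, offset: int) -> str:
        h = self._fold_precursor(pre_id)
        if h is None or not h.is_hairpin:
            return "unknown"
        return arm_of((offset, offset + len(tag)), h)

    def _pick_best(self, hits):
        focal = self.bundle.focal_species

        def key(item):
            rec, mm = item[0], item[-1]
            return (rec.species != focal, mm, rec.id)

        return sorted(hits, key=key)[0]

    def map_known(self, tag: str) -> GroupAssignment:
        """Run the cascade for one tag (everything except group 4)."""
        tag = normalize(tag)
        hits = self.matures.match(tag)
        if hits:
            rec, mm = self._pick_best(hits)
            pre_id = self.bundle.mature_to_pre.get(rec.id)
            arm = "unknown"
            m = re.search(r"-(5p|3p)$", rec.id)
            if m:
                arm = m.group(1)
            elif pre_id and pre_id in self._pre_seq:
                off = self._pre_seq[pre_id].find(normalize(rec.seq))
                if off >= 0:
                    arm = self._arm_in_precursor(rec.seq, pre_id, off)
            return self._grouped(tag, rec, mm, pre_id, arm, arm_derived=False)
        pre_hits = self.precursors.match(tag)
        if pre_hits:
            rec, off, mm = self._pick_best(pre_hits)
            arm = self._arm_in_precursor(tag, rec.id, off)
            star = RefRecord(f"{rec.id}-{arm}*", rec.seq, rec.species)
            return self._grouped(tag, star, mm, rec.id, arm, arm_derived=True)
        return GroupAssignment(tag=tag, group="unassigned")

    def _grouped(self, tag, rec, mm, pre_id, arm, arm_derived) -> GroupAssignment:
        a = GroupAssignment(
            tag=tag, group="3", matched_mirna_id=rec.id,
            matched_species=rec.species, precursor_id=pre_id, arm=arm,
            mismatches=mm, arm_derived=arm_derived,
        )
        focal = rec.species == self.bundle.focal_species
        if pre_id and self._precursor_maps(pre_id):
            a.group = "1a" if focal else "1b"
            return a
        loci = self.genome.find_loci(tag, max_loci=5) if self.genome else []
        if loci:
            contig, s, e, strand = loci[0]
            a.contig, a.start, a.end, a.strand = contig, s, e, strand
            forms = any(hairpin_forms(self.genome, loc, self.flank) for loc in loci)
            a.group = "2a" if forms else "2b"
            return a
        a.group = "3"
        return a


def classify_tags(
    tag_df,
    bundle: ReferenceBundle,
    tolerance: MapTolerance = DEFAULT_TOLERANCE,
    min_reads: int = 3,
    flank: int = 80,
):
    """Classify every sufficiently evidenced tag in a tag table.

    Tags whose total count does not exceed ``min_reads`` (the "more than 3
    reads" evidence rule) are left out.  Returns a DataFrame of
    assignments; group-4 calling is a separate step on the ``unassigned``
    rows (see :func:`caprimir.hairpin.call_novel`).
    """
    import pandas as pd

    if not bundle.genome:
        import warnings

        warnings.warn("bundle has no genome: groups 1a/1b/2a/2b/4 unreachable")
    clf = Classifier(bundle, tolerance, flank)
    rows = []
    kept = tag_df[tag_df["total"] > min_reads]
    for tag in kept.index:
        a = clf.map_known(tag)
        rows.append({
            "sequence": tag,
            **{c: kept.at[tag, c] for c in kept.columns},
            "group": a.group, "mirna_id": a.matched_mirna_id,
            "species": a.matched_species, "precursor_id": a.precursor_id,
            "arm": a.arm, "contig": a.contig, "start": a.start,
            "end": a.end, "strand": a.strand, "mismatches": a.mismatches,
            "arm_derived": a.arm_derived,
        })
    cols = ["sequence", *kept.columns, "group", "mirna_id", "species",
            "precursor_id", "arm", "contig", "start", "end", "strand",
            "mismatches", "arm_derived"]
    return pd.DataFrame(rows, columns=cols).set_index("sequence")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

_FAMILY_RE = re.compile(
    r"^(?:[a-z]{2,4}-)?(mir|let|lin)-?(\d+)", re.IGNORECASE)

_CANONICAL = {"mir": "miR", "let": "let", "lin": "lin"}


def family_of(mirna_id: str) -> Optional[str]:
    """Name-stem family rule: species prefix, paralog letters and the
    -5p/-3p arm suffix are dropped; ``chi-miR-30a-5p`` -> ``miR-30``."""
    m = _FAMILY_RE.match(mirna_id.strip())
    if not m:
        return None
    return f"{_CANONICAL[m.group(1).lower()]}-{m.group(2)}"


def seed_of(mature_seq: str) -> str:
    """Seed region (nt 2-8, 1-based) used as a tie-check on the name rule."""
    return normalize(mature_seq)[1:8]


def family_summary(assignments) -> "object":
    """Group identified miRNAs into families by the name-stem rule.

    Returns a DataFrame indexed by family with member ids, member count and
    per-family species-occurrence count.
    """
    import pandas as pd

    named = assignments.dropna(subset=["mirna_id"])
    fams: dict[str, dict] = {}
    for row in named.itertuples():
        fam = family_of(row.mirna_id)
        if fam is None:
            continue
        d = fams.setdefault(fam, {"members": set(), "species": set()})
        d["members"].add(row.mirna_id)
        if row.species:
            d["species"].add(row.species)
    rows = [
        {"family": fam, "n_members": len(d["members"]),
         "n_species": len(d["species"]),
         "members": ",".join(sorted(d["members"]))}
        for fam, d in sorted(fams.items())
    ]
    return pd.DataFrame(rows, columns=["family", "n_members", "n_species", "members"]
                        ).set_index("family")


def conservation_profile(assignments, bundle: ReferenceBundle,
                         tolerance: MapTolerance = DEFAULT_TOLERANCE):
    """Per-species counts of distinct identified miRNAs, plus the
    distribution of "conserved among >= n species".

    Each identified miRNA (distinct matched id) is re-matched against every
    species' mature set; it counts once for each species with a hit.
    """
    import pandas as pd

    matcher = MatureMatcher(bundle.mature, tolerance)
    named = assignments.dropna(subset=["mirna_id"])
    species_sets: dict[str, set] = {}
    for row in named.itertuples():
        if row.mirna_id in species_sets:
            continue
        hits = matcher.match(row.Index)
        species_sets[row.mirna_id] = {r.species for r, _ in hits if r.species}
    per_species = {sp: 0 for sp in bundle.species}
    for sps in species_sets.values():
        for sp in sps:
            per_species[sp] = per_species.get(sp, 0) + 1
    conserved_in = pd.Series(
        [len(s) for s in species_sets.values()], dtype=int
    ).value_counts().sort_index()
    profile = pd.Series(per_species, name="n_mirnas").sort_values(ascending=False)
    return profile, conserved_in
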