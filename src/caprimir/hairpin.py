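"""Hairpin folding, secondary-structure criteria, and novel miRNA calling.

A candidate precursor is accepted as a novel miRNA only if its predicted
hairpin satisfies eleven structural criteria (stem length, loop size, bulge
sizes, free energy, and placement of the mature sequence in the stem).
Folding uses a maximum-weight non-crossing pairing (Nussinov-style dynamic
programme with a stacking bonus) over Watson-Crick and GU wobble pairs;
an externally computed dot-bracket structure and energy (e.g. from a
thermodynamic folder) may be supplied instead and take precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import GenomeIndex, normalize, revcomp

# Pair weights for the folding DP: GC > AU > GU wobble (DNA alphabet, so U=T)
PAIR_SCORES = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}
STACK_BONUS = 1.0
# Cost charged to every non-stacked closing pair (one per hairpin loop,
# bulge, interior loop or multiloop).  This is the discrete analogue of
# thermodynamic loop penalties: without it, maximum-pairing folding chains
# isolated long-range pairs across unstructured flanks.
LOOP_PENALTY = 3.0
MIN_LOOP = 3
# Crude energy calibration: each stacked pair contributes -1.6 kcal/mol,
# halved when either pair of the stack is a GU wobble.
ENERGY_PER_STACK = -1.6
GU_STACK_WEIGHT = 0.5

WOBBLE = {("G", "T"), ("T", "G")}


def pair_score(a: str, b: str) -> float:
    return PAIR_SCORES.get((a, b), 0.0)


# ---------------------------------------------------------------------------
# Folding
# ---------------------------------------------------------------------------

def _fill_dp(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Fill M (best score of s[i..j]) and P (best score with i,j paired)."""
    n = len(seq)
    M = np.zeros((n, n))
    P = np.full((n, n), -np.inf)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            s = pair_score(seq[i], seq[j])
            if s > 0:
                best_in = (M[i + 1, j - 1] if j - 1 >= i + 1 else 0.0) - LOOP_PENALTY
                if P[i + 1, j - 1] > -np.inf:
                    best_in = max(best_in, P[i + 1, j - 1] + STACK_BONUS)
                P[i, j] = s + best_in
            best = M[i, j - 1]
            if P[i, j] > best:
                best = P[i, j]
            if j - i >= 2:
                # bifurcation: split before k, pair (k, j)
                ks = P[i + 1:j, j] + M[i, i:j - 1]
                if len(ks):
                    kmax = ks.max()
                    if kmax > best:
                        best = kmax
            M[i, j] = best
    return M, P


def _traceback(seq: str, M: np.ndarray, P: np.ndarray) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    stack = [("M", 0, len(seq) - 1)]
    eps = 1e-9
    while stack:
        kind, i, j = stack.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if kind == "P":
            pairs.append((i, j))
            s = pair_score(seq[i], seq[j])
            if P[i + 1, j - 1] > -np.inf and abs(
                P[i, j] - (s + P[i + 1, j - 1] + STACK_BONUS)
            ) < eps:
                stack.append(("P", i + 1, j - 1))
            else:  # closes a loop (charged LOOP_PENALTY)
                stack.append(("M", i + 1, j - 1))
            continue
        if abs(M[i, j] - M[i, j - 1]) < eps:
            stack.append(("M", i, j - 1))
            continue
        if abs(M[i, j] - P[i, j]) < eps:
            stack.append(("P", i, j))
            continue
        for k in range(i + 1, j):
            if P[k, j] > -np.inf and abs(M[i, j] - (M[i, k - 1] + P[k, j])) < eps:
                stack.append(("M", i, k - 1))
                stack.append(("P", k, j))
                break
        else:  # pragma: no cover - defensive
            raise RuntimeError("traceback failed")
    return sorted(pairs)


def fold_score(seq: str) -> float:
    """Optimal pairing score of the folding DP (used by the oracle test)."""
    seq = normalize(seq)
    if len(seq) < 2:
        return 0.0
    M, _ = _fill_dp(seq)
    return float(M[0, len(seq) - 1])


def pairing_score(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Score an explicit non-crossing pairing with the DP's objective."""
    score = 0.0
    pairset = set(pairs)
    for i, j in pairs:
        score += pair_score(seq[i], seq[j])
        if (i + 1, j - 1) in pairset:
            score += STACK_BONUS
        else:
            score -= LOOP_PENALTY
    return score


def enumerate_pairings(seq: str) -> list[list[tuple[int, int]]]:
    """All non-crossing pairings of ``seq`` (exponential; oracle use only)."""
    seq = normalize(seq)
    n = len(seq)
    if n > 16:
        raise ValueError("exhaustive enumeration limited to length <= 16")
    memo: dict[tuple[int, int], list[list[tuple[int, int]]]] = {}

    def rec(i: int, j: int) -> list[list[tuple[int, int]]]:
        if j - i < 1:
            return [[]]
        if (i, j) in memo:
            return memo[(i, j)]
        out = [p for p in rec(i + 1, j)]  # i unpaired
        for k in range(i + MIN_LOOP + 1, j + 1):
            if pair_score(seq[i], seq[k]) > 0:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append([(i, k)] + left + right)
        memo[(i, j)] = out
        return out

    return rec(0, n - 1)


def estimate_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Stack-count energy estimate in kcal/mol (<= 0)."""
    pairset = set(pairs)
    total = 0.0
    for i, j in pairs:
        if (i + 1, j - 1) in pairset:
            w = 1.0
            if (seq[i], seq[j]) in WOBBLE or (seq[i + 1], seq[j - 1]) in WOBBLE:
                w = GU_STACK_WEIGHT
            total += w
    return ENERGY_PER_STACK * total


def parse_dot_bracket(db: str) -> list[tuple[int, int]]:
    pairs = []
    stack = []
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def to_dot_bracket(n: int, pairs: list[tuple[int, int]]) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


@dataclass
class HairpinStructure:
    """A folded precursor with the mature miRNA span annotated.

    ``loop_span`` and ``stem`` describe the single hairpin selected from the
    structure: the terminal loop whose enclosing stem carries the most base
    pairs, and all pairs nested around it.
    """

    seq: str
    dot_bracket: str
    energy_kcal_mol: float
    mature_span: tuple[int, int]
    pairs: list[tuple[int, int]] = field(default_factory=list)
    loop_span: tuple[int, int] = (0, 0)
    stem: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.dot_bracket) != len(self.seq):
            raise ValueError("structure and sequence lengths differ")
        if not self.pairs:
            self.pairs = parse_dot_bracket(self.dot_bracket)
        self.loop_span, self.stem = _select_hairpin(self.pairs, self.mature_span)

    @property
    def is_hairpin(self) -> bool:
        return bool(self.stem)

    @property
    def partner(self) -> dict[int, int]:
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


def _select_hairpin(
    pairs: list[tuple[int, int]],
    mature_span: tuple[int, int],
) -> tuple[tuple[int, int], list[tuple[int, int]]]:
    """Pick the terminal loop of the mature sequence's own hairpin.

    Among the structure's terminal loops, choose the one whose enclosing
    stem carries the most base pairs involving the mature region (ties go
    to the deeper stem); the criteria are then measured on that stem.
    """
    if not pairs:
        return (0, 0), []
    ms, me = mature_span
    paired_pos = {p for ij in pairs for p in ij}
    inner = [
        (i, j) for i, j in pairs
        if not any(i < a and b < j for a, b in pairs if (a, b) != (i, j))
    ]
    best = None
    for i0, j0 in inner:
        # walk outward; stop where the gap to the next enclosing pair holds
        # other helices (a multiloop branch ends the hairpin stem)
        enclosing = sorted(
            [(i, j) for i, j in pairs if i <= i0 and j >= j0], reverse=True)
        stem = [enclosing[0]]
        for i, j in enclosing[1:]:
            ci, cj = stem[-1]
            gap = set(range(i + 1, ci)) | set(range(cj + 1, j))
            if gap & paired_pos:
                break
            stem.append((i, j))
        stem = sorted(stem)
        n_mature = sum(1 for i, j in stem if ms <= i < me or ms <= j < me)
        key = (n_mature, len(stem))
        if best is None or key > best[0]:
            best = (key, (i0 + 1, j0), stem)
    return best[1], best[2]


def fold_hairpin(
    seq: str,
    mature_span: tuple[int, int] | None = None,
    structure: str | None = None,
    energy: float | None = None,
) -> HairpinStructure:
    """Fold a candidate precursor, or adopt a supplied structure verbatim.

    ``seq`` must be 50-300 nt over ACGT/U.  When ``structure`` is given the
    internal folder is bypassed; ``energy`` defaults to the stack-count
    estimate when not supplied.
    """
    seq = normalize(seq)
    if not (50 <= len(seq) <= 300):
        raise ValueError(f"precursor length {len(seq)} outside [50, 300]")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence contains non-ACGU(T) characters")
    if mature_span is None:
        mature_span = (0, min(22, len(seq)))
    if structure is not None:
        pairs = parse_dot_bracket(structure)
    else:
        M, P = _fill_dp(seq)
        pairs = _traceback(seq, M, P)
        structure = to_dot_bracket(len(seq), pairs)
    if energy is None:
        energy = estimate_energy(seq, pairs)
    return HairpinStructure(seq, structure, energy, mature_span, pairs=pairs)


# ---------------------------------------------------------------------------
# Structural features and the 11 criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CriteriaThresholds:
    """Acceptance thresholds for hairpin-based miRNA precursor calling.

    Comparisons are inclusive exactly as listed: a value equal to the
    threshold passes.
    """

    max_stem_bulge: int = 12          # c1: nt in one bulge of the stem <=
    min_stem_pairs: int = 16          # c2: base pairs in the stem >=
    max_energy: float = -15.0         # c3: free energy (kcal/mol) <=
    min_hairpin_length: int = 50      # c4: up stem + down stem + loop >=
    max_loop_length: int = 20         # c5: terminal loop length <=
    max_mature_bulge: int = 4         # c6: nt in one bulge in mature region <=
    max_mature_biased_errors: int = 2  # c7: biased errors in one mature bulge <=
    max_mature_biased_bulges: int = 2  # c8: biased bulges in mature region <=
    max_mature_errors: int = 4        # c9: unpaired nt in mature region <=
    min_mature_pairs: int = 12        # c10: base pairs in mature region >=
    min_mature_in_stem_pct: float = 80.0  # c11: % of mature nt in the stem >=


DEFAULT_THRESHOLDS = CriteriaThresholds()

CRITERION_KEYS = (
    ("c1", "largest_stem_bulge"),
    ("c2", "stem_pairs"),
    ("c3", "energy"),
    ("c4", "hairpin_length"),
    ("c5", "loop_length"),
    ("c6", "largest_mature_bulge"),
    ("c7", "mature_biased_errors"),
    ("c8", "mature_biased_bulges"),
    ("c9", "mature_errors"),
    ("c10", "mature_pairs"),
    ("c11", "mature_in_stem_pct"),
)


def structure_features(h: HairpinStructure) -> dict[str, float]:
    """Measure the quantities the eleven criteria are applied to.

    A "bulge" is a maximal unpaired run on one or both strands strictly
    inside the stem (the gap between consecutive stem pairs); its size is
    the longer of the two strand runs and its bias the difference between
    them.  An "error" in the mature region is an unpaired mature nucleotide.
    """
    if not h.is_hairpin:
        return {
            "largest_stem_bulge": float("inf"), "stem_pairs": 0,
            "energy": 0.0, "hairpin_length": 0, "loop_length": 0,
            "largest_mature_bulge": float("inf"), "mature_biased_errors": float("inf"),
            "mature_biased_bulges": float("inf"), "mature_errors": len(h.seq),
            "mature_pairs": 0, "mature_in_stem_pct": 0.0,
        }
    stem = h.stem
    (i_out, j_out), (i_in, j_in) = stem[0], stem[-1]
    ms, me = h.mature_span
    mature_positions = set(range(ms, me))

    bulges = []  # (size, bias, positions)
    for (i1, j1), (i2, j2) in zip(stem, stem[1:]):
        left = i2 - i1 - 1
        right = j1 - j2 - 1
        if left or right:
            positions = set(range(i1 + 1, i2)) | set(range(j2 + 1, j1))
            bulges.append((max(left, right), abs(left - right), positions))

    partner = h.partner
    mature_errors = sum(1 for p in mature_positions if p not in partner)
    # base pairs of the predicted hairpin involving the mature region
    mature_pairs = sum(1 for i, j in stem
                       if i in mature_positions or j in mature_positions)
    mature_bulges = [b for b in bulges if b[2] & mature_positions]

    up_arm = set(range(i_out, i_in + 1))
    down_arm = set(range(j_in, j_out + 1))
    in_stem = sum(1 for p in mature_positions if p in up_arm or p in down_arm)
    width = max(1, me - ms)

    return {
        "largest_stem_bulge": max((b[0] for b in bulges), default=0),
        "stem_pairs": len(stem),
        "energy": h.energy_kcal_mol,
        "hairpin_length": j_out - i_out + 1,
        "loop_length": h.loop_span[1] - h.loop_span[0],
        "largest_mature_bulge": max((b[0] for b in mature_bulges), default=0),
        "mature_biased_errors": max((b[1] for b in mature_bulges), default=0),
        "mature_biased_bulges": sum(1 for b in mature_bulges if b[1] > 0),
        "mature_errors": mature_errors,
        "mature_pairs": mature_pairs,
        "mature_in_stem_pct": 100.0 * in_stem / width,
    }


@dataclass
class CriteriaReport:
    values: dict[str, float]
    flags: dict[str, bool]

    @property
    def overall(self) -> bool:
        return all(self.flags.values())


def evaluate_criteria(
    features: dict[str, float],
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
) -> CriteriaReport:
    t = thresholds
    f = features
    flags = {
        "c1": f["largest_stem_bulge"] <= t.max_stem_bulge,
        "c2": f["stem_pairs"] >= t.min_stem_pairs,
        "c3": f["energy"] <= t.max_energy,
        "c4": f["hairpin_length"] >= t.min_hairpin_length,
        "c5": f["loop_length"] <= t.max_loop_length,
        "c6": f["largest_mature_bulge"] <= t.max_mature_bulge,
        "c7": f["mature_biased_errors"] <= t.max_mature_biased_errors,
        "c8": f["mature_biased_bulges"] <= t.max_mature_biased_bulges,
        "c9": f["mature_errors"] <= t.max_mature_errors,
        "c10": f["mature_pairs"] >= t.min_mature_pairs,
        "c11": f["mature_in_stem_pct"] >= t.min_mature_in_stem_pct,
    }
    values = {c: float(f[name]) for c, name in CRITERION_KEYS}
    return CriteriaReport(values=values, flags=flags)


def evaluate_hairpin(
    h: HairpinStructure, thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS
) -> CriteriaReport:
    return evaluate_criteria(structure_features(h), thresholds)


# ---------------------------------------------------------------------------
# Novel candidate calling (classification "Group 4")
# ---------------------------------------------------------------------------

@dataclass
class NovelCandidate:
    tag: str
    counts: dict[str, int]
    contig: str
    start: int            # precursor window, 0-based half-open, + strand coords
    end: int
    strand: str
    precursor_seq: str
    structure: HairpinStructure
    report: CriteriaReport
    arm: str

    @property
    def precursor_id(self) -> str:
        return f"novel-{self.contig}-{self.start}-{self.strand}"


def arm_of(mature_span: tuple[int, int], precursor: HairpinStructure) -> str:
    """5p when the mature midpoint lies 5' of the loop midpoint (tie -> 5p)."""
    m_mid = (mature_span[0] + mature_span[1] - 1) / 2
    l_mid = (precursor.loop_span[0] + precursor.loop_span[1] - 1) / 2
    return "5p" if m_mid <= l_mid else "3p"


def candidate_windows(
    genome: GenomeIndex,
    locus: tuple[str, int, int, str],
    flank: int = 80,
) -> list[tuple[int, int, tuple[int, int]]]:
    """Precursor windows around a mapped tag: tag at 5' arm, centred, 3' arm.

    Returns (start, end, mature_span_within_window) in + strand coordinates;
    for - strand loci the mature span is given in the reverse-complemented
    window's coordinates.
    """
    contig, s, e, strand = locus
    n = len(genome.contigs[contig])
    length = e - s
    slack = flank // 8  # room for stem pairs just outside the mature arm
    raw = [
        (max(0, s - slack), min(n, e + flank)),      # tag on the 5' arm
        (max(0, s - flank // 2), min(n, e + flank // 2)),  # centred
        (max(0, s - flank), min(n, e + slack)),      # tag on the 3' arm
    ]
    out = []
    for ws, we in raw:
        if strand == "+":
            span = (s - ws, s - ws + length)
        else:
            span = (we - e, we - e + length)
        out.append((ws, we, span))
    return out


def call_novel(
    unmatched: dict[str, dict[str, int]],
    genome: GenomeIndex,
    min_reads: int = 3,
    flank: int = 80,
    max_loci: int = 5,
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
    external_structures: dict[str, tuple[str, float]] | None = None,
) -> list[NovelCandidate]:
    """Call novel miRNA candidates from genome-mapped, reference-unmatched tags.

    ``unmatched`` maps tag sequence -> per-library counts.  Tags whose total
    count does not exceed ``min_reads`` are skipped, as are tags mapping to
    more than ``max_loci`` genomic sites.  Each locus is evaluated in three
    80-nt-flank windows; the first window whose folded structure passes all
    criteria yields the candidate.  At most one candidate is reported per
    locus (the highest-count tag wins).
    """
    external_structures = external_structures or {}
    candidates: list[NovelCandidate] = []
    claimed: list[tuple[str, int, int]] = []  # precursor windows already called

    def is_claimed(contig: str, s: int, e: int) -> bool:
        # strand-agnostic: a hairpin called on either strand owns its locus
        return any(c == contig and s < ce and cs < e for c, cs, ce in claimed)

    order = sorted(unmatched, key=lambda t: (-sum(unmatched[t].values()), t))
    for tag in order:
        counts = unmatched[tag]
        if sum(counts.values()) <= min_reads:
            continue
        loci = genome.find_loci(tag, max_loci=max_loci)
        if not loci or len(loci) > max_loci:
            continue
        done = False
        for locus in loci:
            contig, s, e, strand = locus
            if is_claimed(contig, s, e):
                continue
            for ws, we, span in candidate_windows(genome, locus, flank):
                if not (50 <= we - ws <= 300):
                    continue
                window_seq = genome.fetch(contig, ws, we, strand)
                ext = external_structures.get(window_seq)
                try:
                    h = fold_hairpin(
                        window_seq, mature_span=span,
                        structure=ext[0] if ext else None,
                        energy=ext[1] if ext else None,
                    )
                except ValueError:
                    continue
                report = evaluate_hairpin(h, thresholds)
                if report.overall:
                    claimed.append((contig, ws, we))
                    candidates.append(NovelCandidate(
                        tag=tag, counts=dict(counts), contig=contig,
                        start=ws, end=we, strand=strand,
                        precursor_seq=window_seq, structure=h,
                        report=report, arm=arm_of(span, h),
                    ))
                    done = True
                    break
            if done:
                break
    return candidates


def hairpin_forms(genome: GenomeIndex, locus, flank: int = 80,
                  thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Does any flanking window of this locus fold into a passing hairpin?

    Used by the known-miRNA cascade to separate genome-mapped tags whose
    context forms a hairpin (group 2a) from those whose context does not
    (group 2b).
    """
    contig, s, e, strand = locus
    for ws, we, span in candidate_windows(genome, locus, flank):
        if not (50 <= we - ws <= 300):
            continue
        try:
            h = fold_hairpin(genome.fetch(contig, ws, we, strand), mature_span=span)
        except ValueError:
            continue
        if evaluate_hairpin(h, thresholds).overall:
            return True
    return False
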