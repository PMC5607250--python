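# Methods

`caprimir` re-implements, as a tested pipeline, the analysis chain used in
two-library small RNA-seq studies of the kind run on dairy-goat mammary
glands at early versus late lactation: one pooled sequencing library per
condition, cleaned and collapsed to unique 18–26 nt tags, filtered against
contaminant databases, classified against miRBase-style mature/precursor
references and a genome, searched for novel hairpin-derived miRNAs, and
tested for differential expression with a count-based exact test.  Because
studies of this design typically deposit no raw reads, the package ships a
ground-truth simulator and scores every stage against planted truth.

## Preprocessing

Reads are cleaned in the order junk → 3′ adapter → length, and a ledger
partitions every input read into exactly one disposition (total reads and
distinct sequences tracked separately per library).

* **Junk / low complexity.**  The source pipelines say only "junk and low
  complexity"; the rule here is: any single base ≥ 80 % of the read, a
  homopolymer run ≥ 10, any `N` or non-nucleotide character, or a
  dinucleotide repeat covering ≥ 90 %.  All four thresholds are
  parameters of `JunkParams`.  The rule is applied to the trimmed insert
  (the adapter would otherwise mask low-complexity inserts); reads failing
  it are ledgered under "junk", which precedes the adapter filter in the
  accounting.
* **Adapter trimming** (`trim_adapter3`).  The insert is everything 5′ of
  the leftmost position where a prefix of the adapter of length ≥
  `min_overlap` (default 6) matches with ≤ `max_mismatch` (default 1)
  substitutions.  Reads with no such match are "3ADT" (null 3′ adapter)
  and removed.  For the default tolerance the search uses exact seed
  halves located with C-level string search and is complete by the
  pigeonhole principle; higher tolerances fall back to a full scan.
* **Length filter and collapse.**  Surviving inserts outside 18–26 nt are
  removed; the rest are collapsed case-insensitively with U→T
  normalisation into unique tags with per-library counts.

## Contaminant filtering

Tags are matched by substring containment with ≤ 1 substitution (both
strands) against categorised reference sets.  When a tag hits several
databases, the first category in the priority order
repeat → rRNA → tRNA → snoRNA → snRNA → other ncRNA → mRNA wins; the
order mirrors the accounting-table row order of the vendor pipelines
(repeats before Rfam before mRNA) and is configurable.  Whether mRNA
filtering precedes or follows Rfam is not fixed by the sources; here it
comes last, which only matters for multi-hit tags and is logged as a
config choice.  Percentages in the accounting table are computed against
each library's **raw** read total and rounded half-up to two decimals,
matching the arithmetic of the published table this package mirrors
(e.g. 85,700 / 18,908,954 → 0.45 %); the stored published counts
(`caprimir.datasets`) serve as a fixture proving the formatter reproduces
the published percentages (91.52 % / 79.31 % valid reads, Rfam 1.66 %,
repeats 0.21 %).

## Classification (groups 1a/1b/2a/2b/3/4)

A tag is matched to a reference mature miRNA allowing ≤ 2 internal
substitutions and ≤ 2 nt of 5′/3′ truncation or extension; the tolerance
is a parameter (`MapTolerance`) and was chosen to cover the three
known-miRNA subclasses reported in this literature (exact matches,
replacement/missing-base variants, and opposite-arm sequences) while
bounding false matches for 18–26-mers.  Multi-hit ties break to the focal
species, then fewest mismatches, then lexicographic id.  The cascade:
mature match whose precursor maps to the genome → 1a (focal species) or
1b (other mammal); precursor unmapped but the tag maps and its flanking
context folds into a criteria-passing hairpin → 2a, without a hairpin →
2b; nothing maps → 3; no mature match at all → candidate for group 4
(novel discovery).  Tags contained inside a precursor but matching no
mature are recorded as arm-derived known miRNAs and follow the same
cascade; the arm is determined by folding the precursor.  Tags with ≤ 3
total reads are never classified — the sources' "more than 3 reads" is
read literally as count > 3, with the threshold configurable for the
≥ 3 reading.

Families use a name-stem rule (drop the species prefix, paralog letters
and -5p/-3p; keep the `miR-`/`let-`/`lin-` token and first number); the
seed region (nt 2–8) is exposed as a tie-check.  Conservation counts, per
species, the distinct identified miRNAs matching that species' mature
set, plus the distribution of "conserved among ≥ n species".

## Hairpin discovery and the 11 criteria

Candidate precursors are folded with a maximum-weight non-crossing
pairing dynamic programme (Watson–Crick plus GU wobble; minimum loop 3)
with two additions to the classical maximum-pairing recursion:

* a **stacking bonus** (+1 per stacked pair; pair weights GC = 3, AU = 2,
  GU = 1), and
* a **loop-closure penalty** (−3 for every closing pair whose interior is
  not a stacked continuation — i.e. one charge per hairpin loop, bulge,
  interior loop or multiloop).  This is the discrete analogue of
  thermodynamic loop penalties; without it, maximum-pairing folding
  chains isolated long-range pairs across unstructured flanks and
  manufactures giant "bulges".

The DP optimum provably equals exhaustive enumeration over all
non-crossing pairings under the same objective (tested to length 12).
Energies are a calibrated estimate, −1.6 kcal/mol per stacked pair with
GU-containing stacks at half weight, which places well-formed precursors
in the −20…−60 kcal/mol range typical of reported novel candidates; an
externally computed dot-bracket structure and energy (e.g. from a
thermodynamic folder such as RNAfold) can be supplied per window and then
takes precedence, so the free-energy criterion is meaningful with either
the documented estimate or supplied energies.  One test cross-checks the
planted precursors against RNAfold's MFE structures.

From the folded window the **hairpin** is selected as the terminal loop
whose enclosing stem carries the most mature-region base pairs; the stem
is walked outward from that loop and terminates where the gap to the next
enclosing pair contains other paired bases (a multiloop branch is not a
bulge).  Definitions the sources leave open: a *bulge* is a maximal
unpaired run on one or both strands strictly inside the stem (size = the
longer strand run, bias = the difference between the runs); an *error* in
the mature region is an unpaired mature nucleotide; *mature base pairs*
are stem pairs with an endpoint in the mature span; the *percentage of
the mature region in the stem* counts mature positions lying within the
stem's two arm spans.  All eleven criteria use inclusive comparisons
exactly as printed (bulge ≤ 12; stem pairs ≥ 16; energy ≤ −15 kcal/mol;
hairpin length ≥ 50; loop ≤ 20; mature bulge ≤ 4; biased errors per
mature bulge ≤ 2; biased mature bulges ≤ 2; mature errors ≤ 4; mature
pairs ≥ 12; mature-in-stem ≥ 80 %).

Novel calling evaluates, for each genomic locus of an unmatched tag
(≤ 5 loci, else discarded as repetitive), three windows — tag on the 5′
arm, centred, tag on the 3′ arm — distributing 80 nt of flanking context
per window (plus 10 nt of slack on the arm side for stem pairs just
outside the mature duplex).  The first window passing all criteria yields
the candidate; loci are claimed strand-agnostically so the same physical
hairpin is not re-called from its opposite arm on the minus strand.
Minus-strand windows are reverse-complemented before folding.
Coordinates are 0-based half-open throughout.

## Differential expression

Expression is normalised to reads per million of each library's
valid-read total ("clean reads" = reads surviving all filters, not raw
reads).  The exact test is the Audic–Claverie conditional form

    p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

computed in log space via log-gamma with deterministic ascending
summation; lower tail C = Σ_{k≤y} p(k|x), upper tail D = 1 − C_{y−1}
clamped to [0, 1], two-sided p = min(1, 2·min(C, D)).  The formula as
printed in this literature drops the factorial and the power of y from
the numerator (a typesetting loss); the standard form above is the only
one under which the printed tail definitions are sums over a proper
distribution (the masses sum to 1, which is tested).  The point-mass
"symmetry" between swapped libraries holds exactly at equal totals and as
an exact N2/N1-scaled identity otherwise; both forms are tested.
Fisher's exact test and a continuity-corrected chi-square on
[[x, N1−x], [y, N2−y]] are computed alongside (via scipy), and a
Benjamini–Hochberg column is emitted for reference but never gates flags,
matching the single-pool, no-correction design of the source analyses.

Record handling order: TPM; drop records < 1 TPM in both libraries;
substitute 0.01 for zero TPM before the fold change log2(L/E); tests on
raw counts.  A miRNA is flagged differentially expressed when pooled raw
reads > 10, exact-test p < 0.05 and |log2FC| ≥ 1.5.  The source
literature states both |log2| ≥ 1 (results) and > 1.5 (methods); the
methods value is the default and both are configurable
(`DEThresholds`).  Library-specific flags require a zero count on one
side and > 10 reads on the other.  The 2^−ΔΔCt helper implements the
standard qPCR relative-expression arithmetic against a reference gene
and calibrator condition.

**Calibration.**  Under its own sampling model — Poisson counts around a
fixed per-gene abundance in both libraries — the two-sided exact test
holds its nominal level (measured ≈ 0.047–0.053 at α = 0.05 over 2,000
genes).  Under negative-binomial overdispersion (dispersion 0.1) it is
strongly anticonservative (≈ 0.5), as expected for a test that models
only sampling noise in pooled libraries.  The type-I-error check is
therefore run on a Poisson null simulation; the power/sensitivity
simulations keep overdispersion, which the planted |log2FC| ≥ 3 effects
dominate easily.

## Synthetic data

The generator emulates the two-library design: a single 100-kb contig
with hairpin precursors planted ≥ 500 nt apart on the + strand (minus
strand handling elsewhere is still exercised by opposite-arm matches);
100 known miRNAs split across a focal species and one other mammal, half
of the focal miRNAs carrying identical orthologue records in the other
species (so conservation and focal-removal behaviour are testable); 10
novel hairpins absent from the mature set; seven contaminant reference
classes totalling 10 % of reads; 5 % of reads without adapter; mature
lengths 20–24 dominated by 22-mers; per-miRNA counts negative-binomial
(Poisson at dispersion 0) around lognormal baselines (median 200 reads,
σ = 0.8); 20 % of miRNAs differential with |log2FC| drawn from [3, 5]
(sign random); isomiRs as ±1–2 nt 3′ offsets taken from precursor
context with probability 0.2; substitution errors at 0.001/nt; constant
FASTQ quality.  Planted precursors are perfect stems (mature + 3 extra
pairs, 8-nt A/C loop), which by construction satisfy all eleven criteria
after re-folding — so the pipeline's recall ceiling on clean data is
100 % and any missed hairpin is a pipeline defect, not a truth defect.

What the simulator deliberately does **not** emulate: position-dependent
sequencing error profiles, 5′ isomiRs, RNA editing, imperfect or
multi-branch precursor stems, repetitive genomes (multi-mapping), or
more than two libraries.  Passing tests therefore demonstrate the
pipeline's correctness and internal consistency on idealised data, not
its discovery performance on real tissue libraries, where imperfect
hairpins and repeat-derived reads dominate the error budget.

## Problem sizes

The reference simulation used by the integration tests and the
acceptance script is 2 × 200k reads with 100 known + 10 novel miRNAs — a
deliberate desk-scale stand-in for the published library-scale runs
(~19 M and ~10 M reads), chosen so the whole chain (including ~10² DP
folds of ~110–180 nt windows) completes in well under a minute.  The
published dataset-level outcomes (total miRNA counts, 45 novel
candidates, 378 differential miRNAs, network sizes) depend on the
unreleased raw libraries and external databases and are not reproduction
targets; the accounting percentages, exact-test values, criteria
behaviour and truth-recovery rates are.
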