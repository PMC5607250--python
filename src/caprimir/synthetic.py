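"""Ground-truth simulator: reference bundles and two small-RNA libraries.

The generator emulates a two-condition (early/late lactation style) small
RNA sequencing experiment: a toy genome with planted miRNA hairpin
precursors, mature/precursor reference sets spanning a focal species plus
other mammals, contaminant reference sets (mRNA, Rfam classes, repeats),
and two adapter-ligated read libraries with negative-binomial counts and
known per-miRNA log2 fold changes.  Every read records its source category,
so each downstream stage can be scored against truth.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import GenomeIndex, revcomp
from .contaminants import CONTAMINANT_CATEGORIES, RefRecord, ReferenceBundle
from .preprocess import ReadRecord

# Library labels for the two conditions (early / late).
LIBRARIES = ("E", "L")

# Illumina TruSeq small RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

# Mature miRNA length distribution, dominated by 22-mers.
MATURE_LENGTHS = (20, 21, 22, 23, 24)
MATURE_LENGTH_P = (0.10, 0.20, 0.50, 0.15, 0.05)

# Typical reference lengths per contaminant category (n_seqs, length).
CONTAMINANT_SHAPES = {
    "mRNA": (30, 500),
    "rRNA": (4, 1500),
    "tRNA": (20, 75),
    "snRNA": (10, 120),
    "snoRNA": (15, 100),
    "other_ncRNA": (10, 200),
    "repeat": (10, 400),
}

DEFAULT_CONTAMINANT_FRACTIONS = {
    "mRNA": 0.020,
    "rRNA": 0.025,
    "tRNA": 0.015,
    "snRNA": 0.005,
    "snoRNA": 0.010,
    "other_ncRNA": 0.010,
    "repeat": 0.015,
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the simulated two-library experiment.

    ``contaminant_fractions`` must sum to <= 1; the remainder of each
    library is miRNA-derived reads.  ``dispersion`` is the negative-binomial
    overdispersion (variance = mu + dispersion * mu^2); 0 gives Poisson
    counts.  ``log2fc_range`` is the magnitude interval that planted
    differential miRNAs draw their |log2 fold change| from (sign random).
    """

    seed: int = 1
    n_reads_per_library: tuple[int, int] = (200_000, 200_000)
    n_mirnas: int = 100
    n_novel_hairpins: int = 10
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINANT_FRACTIONS))
    de_fraction: float = 0.2
    log2fc_range: tuple[float, float] = (3.0, 5.0)
    dispersion: float = 0.1
    adapter: str = DEFAULT_ADAPTER
    read_error_rate: float = 0.001
    no_adapter_fraction: float = 0.05
    isomir_prob: float = 0.2
    read_length: int = 50
    genome_length: int = 100_000
    focal_species: str = "chi"
    other_species: tuple[str, ...] = ("bta",)
    n_families: int | None = None  # default: ~60% of n_mirnas
    conserved_fraction: float = 0.5  # focal miRNAs also recorded in other species

    def __post_init__(self):
        bad = set(self.contaminant_fractions) - set(CONTAMINANT_CATEGORIES)
        if bad:
            raise ConfigurationError(f"unknown contaminant categories: {sorted(bad)}")
        if any(f < 0 or f > 1 for f in self.contaminant_fractions.values()):
            raise ConfigurationError("contaminant fractions must lie in [0, 1]")
        if sum(self.contaminant_fractions.values()) > 1:
            raise ConfigurationError("contaminant fractions sum to more than 1")
        if min(self.n_reads_per_library) <= 0:
            raise ConfigurationError("n_reads_per_library must be positive")
        if len(self.adapter) < 6:
            raise ConfigurationError("adapter must be at least 6 nt")
        if self.n_mirnas < 1:
            raise ConfigurationError("n_mirnas must be >= 1")


@dataclass
class TruthTable:
    """Per-miRNA ground truth plus per-read source-category tallies."""

    mirnas: "object"  # pandas DataFrame, one row per planted mature miRNA
    read_categories: dict[str, Counter] = field(default_factory=dict)
    no_adapter_counts: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        cols = ["id", "category", "contig", "start", "end", "strand",
                "count_E", "count_L", "log2fc_true", "is_de", "is_novel"]
        self.mirnas[cols].to_csv(path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _make_precursor(rng: np.random.Generator, mature: str, arm: str) -> tuple[str, tuple[int, int]]:
    """Build a clean hairpin precursor around a mature arm.

    Structure: 3 extra stem pairs outside the mature duplex and an 8-nt
    A/C-only loop, giving a perfect stem of >= 23 bp, total length >= 54,
    and a stack-count energy far below -15 kcal/mol, so planted precursors
    always satisfy the 11 structural criteria.
    """
    ext = _random_seq(rng, 3)
    loop = "".join(np.array(list("AC"))[rng.integers(0, 2, 8)])
    if arm == "5p":
        pre = ext + mature + loop + revcomp(mature) + revcomp(ext)
        span = (3, 3 + len(mature))
    else:
        pre = ext + revcomp(mature) + loop + mature + revcomp(ext)
        span = (3 + len(mature) + 8, 3 + 2 * len(mature) + 8)
    return pre, span


def gen_references(config: SimulationConfig):
    """Generate the reference bundle and truth table for a simulation.

    Returns ``(bundle, truth)``.  All planted precursors (known and novel)
    are embedded in the toy genome >= 500 nt apart on the + strand; novel
    matures are deliberately absent from the mature reference set.
    """
    import pandas as pd

    rng = np.random.default_rng([config.seed, 7])
    n_total = config.n_mirnas + config.n_novel_hairpins
    genome = list(_random_seq(rng, config.genome_length))

    spacing = config.genome_length // (n_total + 1)
    if spacing < 560:
        raise ConfigurationError(
            "genome too short to plant hairpins >= 500 nt apart")

    species_cycle = [config.focal_species] + list(config.other_species)
    n_fam = config.n_families or max(1, int(math.ceil(config.n_mirnas * 0.6)))
    fam_of = [i % n_fam for i in range(config.n_mirnas)]
    fam_member = Counter()

    mature_recs, pre_recs, mature_to_pre = [], [], {}
    rows = []
    for i in range(n_total):
        is_novel = i >= config.n_mirnas
        length = int(rng.choice(MATURE_LENGTHS, p=MATURE_LENGTH_P))
        mature = _random_seq(rng, length)
        arm = "5p" if rng.random() < 0.6 else "3p"
        pre, span = _make_precursor(rng, mature, arm)
        start = spacing * (i + 1)
        genome[start:start + len(pre)] = list(pre)

        n_species = 1
        if is_novel:
            name = f"novel-cand-{i - config.n_mirnas + 1}"
            species = config.focal_species
            family = ""
        else:
            species = species_cycle[i % len(species_cycle)]
            fam = fam_of[i]
            letter = "abcdefghijklmnopqrstuvwxyz"[fam_member[fam] % 26]
            fam_member[fam] += 1
            family = f"miR-{100 + fam}"
            name = f"{species}-{family}{letter}-{arm}"
            pre_id = f"{species}-mir-{100 + fam}{letter}"
            mature_recs.append(RefRecord(name, mature, species))
            pre_recs.append(RefRecord(pre_id, pre, species))
            mature_to_pre[name] = pre_id
            # conserved focal miRNAs carry identical orthologue records
            if (species == config.focal_species
                    and rng.random() < config.conserved_fraction):
                for sp in config.other_species:
                    o_name = f"{sp}-{family}{letter}-{arm}"
                    o_pre = f"{sp}-mir-{100 + fam}{letter}"
                    mature_recs.append(RefRecord(o_name, mature, sp))
                    pre_recs.append(RefRecord(o_pre, pre, sp))
                    mature_to_pre[o_name] = o_pre
                n_species = 1 + len(config.other_species)
        rows.append({
            "id": name, "category": "novel_mirna" if is_novel else "known_mirna",
            "species": species, "family": family, "arm": arm,
            "contig": "chr1", "start": start, "end": start + len(pre),
            "strand": "+",
            "mature_start": start + span[0], "mature_end": start + span[1],
            "mature_seq": mature, "precursor_seq": pre,
            "mature_offset": span[0],
            "is_novel": is_novel, "n_species": n_species,
        })

    categories = {}
    for cat, (n_seqs, length) in CONTAMINANT_SHAPES.items():
        categories[cat] = [
            RefRecord(f"{cat}_{k + 1}", _random_seq(rng, length))
            for k in range(n_seqs)
        ]

    bundle = ReferenceBundle(
        genome={"chr1": "".join(genome)},
        mature=mature_recs, premirna=pre_recs, mature_to_pre=mature_to_pre,
        categories=categories,
        focal_species=config.focal_species,
        species=list(dict.fromkeys(species_cycle)),
    )

    df = pd.DataFrame(rows)
    # expression truth: lognormal baseline, DE flags on a random subset
    n = len(df)
    base = rng.lognormal(mean=np.log(200.0), sigma=0.8, size=n)
    is_de = rng.random(n) < config.de_fraction
    lo, hi = config.log2fc_range
    mag = rng.uniform(lo, hi, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    lfc = np.where(is_de, mag * sign, 0.0)
    df["base_mean"] = base
    df["is_de"] = is_de
    df["log2fc_true"] = lfc
    mass_e = base * np.power(2.0, -lfc / 2)
    mass_l = base * np.power(2.0, lfc / 2)
    frac_mirna = 1.0 - sum(config.contaminant_fractions.values())
    n_e, n_l = config.n_reads_per_library
    df["expected_E"] = n_e * frac_mirna * mass_e / mass_e.sum()
    df["expected_L"] = n_l * frac_mirna * mass_l / mass_l.sum()
    df["count_E"] = 0
    df["count_L"] = 0
    truth = TruthTable(mirnas=df)
    return bundle, truth


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for p in pos:
        s[p] = "ACGT"[(("ACGT".index(s[p]) + int(rng.integers(1, 4))) % 4)]
    return "".join(s)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.clip(mu, 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    return rng.poisson(lam)


def simulate_library(
    bundle: ReferenceBundle,
    truth: TruthTable,
    config: SimulationConfig,
    library_id: str,
) -> list[ReadRecord]:
    """Draw one adapter-ligated read library and update the truth table.

    miRNA reads are the mature sequence, optionally with a +-2 nt 3'
    isomiR offset taken from precursor context, plus the 3' adapter,
    truncated to the read length; a configured fraction of reads carries no
    adapter at all.  Contaminant reads are random 18-26-mers from the
    category references.  Per-miRNA counts are negative-binomial around the
    planted expected counts.
    """
    if library_id not in LIBRARIES:
        raise ConfigurationError(f"library_id must be one of {LIBRARIES}")
    lib_index = LIBRARIES.index(library_id)
    rng = np.random.default_rng([config.seed, 11, lib_index])
    n_reads = config.n_reads_per_library[lib_index]

    for cat, frac in config.contaminant_fractions.items():
        if frac > 0 and not bundle.categories.get(cat):
            raise ConfigurationError(f"category {cat} has positive fraction but no references")

    df = truth.mirnas
    cat_counter: Counter = Counter()
    reads: list[ReadRecord] = []
    no_adapter_total = 0
    serial = 0

    def emit(insert: str, category: str):
        nonlocal serial, no_adapter_total
        serial += 1
        insert = _mutate(rng, insert, config.read_error_rate)
        if rng.random() < config.no_adapter_fraction:
            seq = insert
            no_adapter_total += 1
        else:
            seq = (insert + config.adapter)[:config.read_length]
        reads.append(ReadRecord(f"{library_id}_{serial}", seq, "I" * len(seq)))
        cat_counter[category] += 1

    # contaminant reads: deterministic category totals, random windows
    lengths = np.array(MATURE_LENGTHS)
    for cat, frac in config.contaminant_fractions.items():
        n_cat = int(round(n_reads * frac))
        refs = bundle.categories.get(cat, [])
        if n_cat == 0 or not refs:
            continue
        ref_idx = rng.integers(0, len(refs), n_cat)
        win_len = rng.choice(lengths, p=MATURE_LENGTH_P, size=n_cat)
        for ri, wl in zip(ref_idx, win_len):
            seq = refs[ri].seq
            wl = int(min(wl, len(seq)))
            start = int(rng.integers(0, len(seq) - wl + 1))
            emit(seq[start:start + wl], cat)

    # miRNA reads: means are the planted expected counts
    expected = df[f"expected_{library_id}"].to_numpy(float)
    counts = _nb_counts(rng, expected, config.dispersion)
    for row, c in zip(df.itertuples(), counts):
        if c == 0:
            continue
        offsets = np.where(
            rng.random(c) < config.isomir_prob,
            rng.choice([-2, -1, 1, 2], size=c),
            0,
        )
        pre = row.precursor_seq
        m0 = row.mature_offset
        m1 = m0 + len(row.mature_seq)
        for off in offsets:
            end = m1 + int(off)
            if end - m0 < 18 or end > len(pre):
                end = m1
            emit(pre[m0:end], "novel_mirna" if row.is_novel else "known_mirna")
        df.loc[row.Index, f"count_{library_id}"] = int(c)

    truth.read_categories[library_id] = cat_counter
    truth.no_adapter_counts[library_id] = no_adapter_total
    return reads


def gen_target_tables(truth: TruthTable, config: SimulationConfig,
                      n_genes: int = 50, n_pathways: int = 10):
    """Synthetic miRNA->gene and gene->pathway edge tables tied to truth.

    Every differentially expressed miRNA targets 1-6 genes; each targeted
    gene participates in 1-3 pathways.  Returns two DataFrames shaped like
    the external target-prediction / annotation inputs the network stage
    consumes.
    """
    import pandas as pd

    rng = np.random.default_rng([config.seed, 23])
    genes = [f"GENE{i + 1}" for i in range(n_genes)]
    pathways = [f"path{i + 1}" for i in range(n_pathways)]
    mg = []
    for row in truth.mirnas.itertuples():
        if not row.is_de:
            continue
        k = 1 + int(rng.integers(0, 6))
        for g in rng.choice(n_genes, size=min(k, n_genes), replace=False):
            mg.append({"mirna_id": row.id, "gene_id": genes[g]})
    mg = pd.DataFrame(mg, columns=["mirna_id", "gene_id"])
    gp = []
    for g in sorted(set(mg["gene_id"])):
        for p in rng.choice(n_pathways, size=1 + int(rng.integers(0, 3)), replace=False):
            gp.append({"gene_id": g, "pathway_id": pathways[p]})
    gp = pd.DataFrame(gp, columns=["gene_id", "pathway_id"])
    return mg, gp


def write_fastq(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality or 'I' * len(r.sequence)}\n")


def write_fasta(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")
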