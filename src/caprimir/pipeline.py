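"""End-to-end orchestration of the two-library miRNA pipeline on
simulated data, with truth-based scoring.

Stages: simulate -> preprocess -> contaminant filter -> classify ->
novel-hairpin discovery -> per-miRNA differential expression.  Every stage
is the corresponding library module; this file only wires them together
and measures recall/sensitivity against the generator's truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import GenomeIndex
from .classify import DEFAULT_TOLERANCE, MapTolerance, classify_tags
from .contaminants import partition_valid
from .diffexp import DEFAULT_DE, DEThresholds, ac_pvalue, de_table
from .hairpin import call_novel
from .preprocess import merge_libraries, preprocess_library
from .synthetic import (LIBRARIES, SimulationConfig, gen_references,
                        simulate_library)


@dataclass
class PipelineResult:
    config: SimulationConfig
    bundle: object
    truth: object
    ledgers: dict
    tag_df: object
    valid: object
    stats: object
    assignments: object
    novel_candidates: list
    mirna_counts: object
    de: object
    metrics: dict = field(default_factory=dict)


def aggregate_mirna_counts(assignments, novel_candidates):
    """Per-miRNA raw counts: assigned known tags summed per matched id,
    novel candidates keyed by precursor locus id."""
    import pandas as pd

    known = assignments[assignments["group"].isin(["1a", "1b", "2a", "2b", "3"])]
    rows = known.groupby("mirna_id")[["count_E", "count_L"]].sum()
    novel_rows = pd.DataFrame(
        [{"mirna_id": c.precursor_id,
          "count_E": c.counts.get("E", 0), "count_L": c.counts.get("L", 0)}
         for c in novel_candidates]
    )
    if len(novel_rows):
        novel_rows = novel_rows.groupby("mirna_id").sum()
        rows = pd.concat([rows, novel_rows])
    rows.index.name = "mirna_id"
    return rows.astype(int)


def _novel_recall(truth, candidates) -> float:
    planted = truth.mirnas[truth.mirnas["is_novel"]]
    if not len(planted):
        return float("nan")
    hit = 0
    for row in planted.itertuples():
        for c in candidates:
            if (c.contig == row.contig and c.strand == row.strand
                    and c.start < row.end and row.start < c.end):
                hit += 1
                break
    return hit / len(planted)


def run_pipeline(
    config: SimulationConfig,
    tolerance: MapTolerance = DEFAULT_TOLERANCE,
    de_thresholds: DEThresholds = DEFAULT_DE,
    min_reads: int = 3,
) -> PipelineResult:
    bundle, truth = gen_references(config)
    genome = GenomeIndex(bundle.genome)

    per_lib = {}
    ledgers = {}
    for lib in LIBRARIES:
        reads = simulate_library(bundle, truth, config, lib)
        tags, ledger = preprocess_library(reads, lib, config.adapter)
        per_lib[lib] = tags
        ledgers[lib] = ledger
    tag_df = merge_libraries(per_lib)

    raw_totals = {lib: ledgers[lib].raw for lib in LIBRARIES}
    valid, stats = partition_valid(tag_df, bundle, raw_totals)

    assignments = classify_tags(valid, bundle, tolerance, min_reads=min_reads)
    unmatched = assignments[assignments["group"] == "unassigned"]
    unmatched_counts = {
        t: {lib: int(unmatched.at[t, f"count_{lib}"]) for lib in LIBRARIES}
        for t in unmatched.index
    }
    candidates = call_novel(unmatched_counts, genome, min_reads=min_reads)
    for c in candidates:
        if c.tag in assignments.index:
            assignments.loc[c.tag, "group"] = "4"
            assignments.loc[c.tag, "arm"] = c.arm

    mirna_counts = aggregate_mirna_counts(assignments, candidates)
    valid_totals = tuple(
        int(stats.query("library == @lib and category == 'valid'")["reads"].iloc[0])
        for lib in LIBRARIES
    )
    de = de_table(mirna_counts, valid_totals, de_thresholds)

    metrics = score_against_truth(truth, assignments, candidates, de)
    return PipelineResult(
        config=config, bundle=bundle, truth=truth, ledgers=ledgers,
        tag_df=tag_df, valid=valid, stats=stats, assignments=assignments,
        novel_candidates=candidates, mirna_counts=mirna_counts, de=de,
        metrics=metrics,
    )


def score_against_truth(truth, assignments, candidates, de) -> dict:
    """Recall / sensitivity of the pipeline against the planted truth."""
    known = truth.mirnas[~truth.mirnas["is_novel"]]
    detected = set(
        assignments.loc[assignments["group"].isin(["1a", "1b"]), "mirna_id"])
    known_recall = (
        sum(1 for i in known["id"] if i in detected) / len(known)
        if len(known) else float("nan")
    )
    novel_recall = _novel_recall(truth, candidates)

    de_ids = set(de.index[de["de"]])
    truly_de = truth.mirnas[truth.mirnas["is_de"] & ~truth.mirnas["is_novel"]]
    flagged = sum(1 for i in truly_de["id"] if i in de_ids)
    de_sensitivity = flagged / len(truly_de) if len(truly_de) else float("nan")

    group_counts = assignments["group"].value_counts().to_dict()
    return {
        "known_recall": known_recall,
        "novel_recall": novel_recall,
        "de_sensitivity": de_sensitivity,
        "group_counts": group_counts,
        "n_novel_candidates": len(candidates),
    }


def null_type1_rate(
    n_genes: int = 100,
    mean_count: float = 100.0,
    totals: tuple[int, int] = (1_000_000, 1_000_000),
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the exact test under its own null.

    Each gene has one true abundance; both libraries' counts are Poisson
    around it (scaled by library size), which is the sampling model the
    exact test assumes.  Returns the fraction of two-sided p-values below
    ``alpha``.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = totals
    lam = rng.lognormal(np.log(mean_count), 0.5, size=n_genes)
    x = rng.poisson(lam)
    y = rng.poisson(lam * n2 / n1)
    rej = sum(
        1 for xi, yi in zip(x, y)
        if ac_pvalue(int(xi), int(yi), n1, n2).two_sided < alpha
    )
    return rej / n_genes
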