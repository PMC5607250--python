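"""Per-miRNA differential expression between the two libraries: aggregate
assigned tag counts per miRNA, normalise to reads per million of valid
reads, and apply the exact test with Fisher/chi-square companions and the
published flagging thresholds; scored against the planted fold changes.

Reads results/sim + results/filter + results/classify + results/novel;
writes results/diffexp/: mirna_counts.tsv, de_table.tsv.
"""

from pathlib import Path

import pandas as pd

from caprimir.diffexp import de_table

ROOT = Path(__file__).resolve().parents[1]


def main(simdir=ROOT / "results" / "sim",
         filterdir=ROOT / "results" / "filter",
         classdir=ROOT / "results" / "classify",
         noveldir=ROOT / "results" / "novel",
         outdir=ROOT / "results" / "diffexp"):
    outdir.mkdir(parents=True, exist_ok=True)
    assignments = pd.read_csv(classdir / "assignments.tsv", sep="\t")
    cands = pd.read_csv(noveldir / "candidates.tsv", sep="\t")
    truth = pd.read_csv(simdir / "truth.tsv", sep="\t")
    stats = pd.read_csv(filterdir / "stats.tsv", sep="\t")

    known = assignments[assignments["group"].isin(["1a", "1b", "2a", "2b", "3"])]
    counts = known.groupby("mirna_id")[["count_E", "count_L"]].sum()
    novel_counts = cands.set_index("candidate")[["count_E", "count_L"]]
    counts = pd.concat([counts, novel_counts]).astype(int)
    counts.index.name = "mirna_id"
    counts.to_csv(outdir / "mirna_counts.tsv", sep="\t")

    totals = tuple(
        int(stats.query("library == @lib and category == 'valid'")["reads"].iloc[0])
        for lib in ("E", "L"))
    de = de_table(counts, totals)
    de.to_csv(outdir / "de_table.tsv", sep="\t")

    n_de = int(de["de"].sum())
    spec_e, spec_l = int(de["specific_E"].sum()), int(de["specific_L"].sum())
    print(f"{len(de)} miRNAs tested (valid-read totals {totals[0]:,} / "
          f"{totals[1]:,}); {n_de} differentially expressed, "
          f"{spec_e} specific to E, {spec_l} specific to L")

    truly_de = truth[truth["is_de"] & ~truth["is_novel"]]
    flagged = de.index[de["de"]]
    sens = sum(i in set(flagged) for i in truly_de["id"]) / max(len(truly_de), 1)
    print(f"sensitivity on planted |log2fc| >= 3 miRNAs: {sens:.1%}")
    top = de.loc[de["p_ac"].notna()].sort_values("p_ac").head(3)
    print("strongest signals:")
    for mid, row in top.iterrows():
        print(f"  {mid}: {int(row['count_E'])} vs {int(row['count_L'])} reads, "
              f"log2fc {row['log2fc']:+.2f}, p_ac {row['p_ac']:.2e}")
    print(f"wrote {outdir}")


if __name__ == "__main__":
    main()
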