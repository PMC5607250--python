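"""Partition unique tags into contaminant classes (repeats, the five Rfam
classes, mRNA) versus valid tags, and emit the accounting table with
percentages of each library's raw total.  Also reproduces the published
two-library accounting percentages from the stored counts as a formatter
check.

Reads results/sim + results/preprocess; writes results/filter/:
valid_tags.tsv, stats.tsv, published_accounting.tsv.
"""

from pathlib import Path

import pandas as pd

from caprimir.contaminants import ReferenceBundle, partition_valid
from caprimir.datasets import published_stats

ROOT = Path(__file__).resolve().parents[1]


def main(simdir=ROOT / "results" / "sim",
         predir=ROOT / "results" / "preprocess",
         outdir=ROOT / "results" / "filter"):
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReferenceBundle.load(simdir / "bundle")
    tag_df = pd.read_csv(predir / "tags.tsv", sep="\t", index_col="sequence")
    ledger = pd.read_csv(predir / "ledger.tsv", sep="\t")
    raw_totals = dict(zip(ledger["library"], ledger["raw"]))

    valid, stats = partition_valid(tag_df, bundle, raw_totals)
    valid.to_csv(outdir / "valid_tags.tsv", sep="\t")
    stats.to_csv(outdir / "stats.tsv", sep="\t", index=False)
    for lib in ("E", "L"):
        s = stats.query("library == @lib").set_index("category")
        print(f"library {lib}: Rfam {s.loc['Rfam', 'percent']}%, "
              f"mRNA {s.loc['mRNA', 'percent']}%, "
              f"repeat {s.loc['repeat', 'percent']}%, "
              f"valid {s.loc['valid', 'reads']:,} reads "
              f"({s.loc['valid', 'percent']}% of raw)")

    pub = pd.concat([published_stats(lib).assign(library=lib)
                     for lib in ("E", "L")])
    pub.to_csv(outdir / "published_accounting.tsv", sep="\t", index=False)
    e = pub.query("library == 'E'").set_index("category")["percent"]
    print(f"published accounting check: valid E {e['valid']}% "
          f"(expected 91.52), Rfam E {e['Rfam']}% (expected 1.66)")
    print(f"wrote {outdir}")


if __name__ == "__main__":
    main()
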