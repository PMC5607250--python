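"""Clean the raw libraries: 3' adapter trimming, junk and length filters,
collapse to unique 18-26 nt tags, and the per-library accounting ledger
plus length distributions.

Reads results/sim/, writes results/preprocess/: tags.tsv, ledger.tsv,
length_distribution.tsv, tags.fa.
"""

from pathlib import Path

import pandas as pd
import yaml

from caprimir.preprocess import (length_distribution, merge_libraries,
                                 preprocess_library, read_fastx,
                                 write_tags_fasta)

ROOT = Path(__file__).resolve().parents[1]


def main(simdir=ROOT / "results" / "sim", outdir=ROOT / "results" / "preprocess"):
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = yaml.safe_load((simdir / "config.yaml").read_text())

    per_lib, ledgers = {}, []
    for lib in ("E", "L"):
        tags, ledger = preprocess_library(
            read_fastx(simdir / f"library_{lib}.fastq"), lib, cfg["adapter"])
        per_lib[lib] = tags
        d = ledger.as_dict()
        ledgers.append(d)
        print(f"library {lib}: raw {d['raw']:,} -> junk {d['junk']:,}, "
              f"3ADT/length {d['3adt_or_length']:,}, kept {d['valid']:,} "
              f"({d['unique_valid']:,} unique tags)")

    tag_df = merge_libraries(per_lib)
    tag_df.to_csv(outdir / "tags.tsv", sep="\t")
    write_tags_fasta(tag_df, outdir / "tags.fa")
    pd.DataFrame(ledgers).to_csv(outdir / "ledger.tsv", sep="\t", index=False)

    dist = length_distribution(tag_df)
    dist.to_csv(outdir / "length_distribution.tsv", sep="\t")
    mode = dist["reads_E"].idxmax()
    share = dist.loc[mode, "frac_reads_E"]
    print(f"most abundant insert length: {mode} nt "
          f"({share:.1%} of kept reads in E)")
    print(f"wrote {outdir}")


if __name__ == "__main__":
    main()
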