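"""Call novel miRNA candidates (group 4) from genome-mapped tags that
matched no mature or precursor reference: fold the flanking genomic
windows and keep loci passing all eleven structural criteria.

Reads results/sim + results/classify; writes results/novel/:
candidates.tsv, precursors.fa, structures.txt (Vienna-style).
"""

from pathlib import Path

import pandas as pd

from caprimir._seq import GenomeIndex
from caprimir.contaminants import ReferenceBundle
from caprimir.hairpin import call_novel

ROOT = Path(__file__).resolve().parents[1]


def main(simdir=ROOT / "results" / "sim",
         classdir=ROOT / "results" / "classify",
         outdir=ROOT / "results" / "novel"):
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReferenceBundle.load(simdir / "bundle")
    truth = pd.read_csv(simdir / "truth.tsv", sep="\t")
    assignments = pd.read_csv(classdir / "assignments.tsv", sep="\t",
                              index_col="sequence")

    unmatched = assignments.query("group == 'unassigned'")
    counts = {t: {"E": int(r["count_E"]), "L": int(r["count_L"])}
              for t, r in unmatched.iterrows()}
    cands = call_novel(counts, GenomeIndex(bundle.genome))
    print(f"{len(unmatched)} unmatched tags -> {len(cands)} novel candidates")

    rows = []
    with open(outdir / "precursors.fa", "w") as fa, \
            open(outdir / "structures.txt", "w") as st:
        for c in cands:
            fa.write(f">{c.precursor_id}\n{c.precursor_seq}\n")
            st.write(f">{c.precursor_id}\n{c.precursor_seq}\n"
                     f"{c.structure.dot_bracket} "
                     f"({c.structure.energy_kcal_mol:.1f})\n")
            rows.append({
                "candidate": c.precursor_id, "tag": c.tag, "arm": c.arm,
                "contig": c.contig, "start": c.start, "end": c.end,
                "strand": c.strand, "count_E": c.counts.get("E", 0),
                "count_L": c.counts.get("L", 0),
                "energy": c.structure.energy_kcal_mol,
                **{k: v for k, v in c.report.values.items()},
            })
    pd.DataFrame(rows).to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    planted = truth[truth["is_novel"]]
    hit = sum(
        any(c.contig == r.contig and c.start < r.end and r.start < c.end
            for c in cands)
        for r in planted.itertuples())
    arms = pd.Series([c.arm for c in cands]).value_counts().to_dict()
    energies = [c.structure.energy_kcal_mol for c in cands]
    print(f"recall of planted novel hairpins: {hit}/{len(planted)}")
    if cands:
        print(f"arm split: {arms}; energy range "
              f"{min(energies):.1f} to {max(energies):.1f} kcal/mol")
    print(f"wrote {outdir}")


if __name__ == "__main__":
    main()
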