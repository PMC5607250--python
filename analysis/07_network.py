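"""Build the miRNA-gene and miRNA-gene-pathway regulation networks from
the (synthetic, truth-linked) target and pathway edge tables, restricted
to differentially expressed miRNAs, and export them for Cytoscape-style
viewers.

Reads results/sim + results/diffexp; writes results/network/:
mirna_gene.graphml/.sif, mirna_gene_pathway.graphml, stats.txt.
"""

from pathlib import Path

import pandas as pd
import yaml

from caprimir.network import build_network, export_graph, network_stats
from caprimir.synthetic import SimulationConfig, TruthTable, gen_target_tables

ROOT = Path(__file__).resolve().parents[1]


def main(simdir=ROOT / "results" / "sim",
         dedir=ROOT / "results" / "diffexp",
         outdir=ROOT / "results" / "network"):
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in yaml.safe_load((simdir / "config.yaml").read_text()).items()
    })
    truth = TruthTable(mirnas=pd.read_csv(simdir / "truth.tsv", sep="\t"))
    de = pd.read_csv(dedir / "de_table.tsv", sep="\t", index_col="mirna_id")
    de_set = set(de.index[de["de"]])

    mirna_gene, gene_pathway = gen_target_tables(truth, cfg)

    bipartite = build_network(mirna_gene, de_set=de_set)
    export_graph(bipartite, outdir / "mirna_gene.graphml", "graphml")
    export_graph(bipartite, outdir / "mirna_gene.sif", "sif")
    tripartite = build_network(mirna_gene, gene_pathway, de_set=de_set)
    export_graph(tripartite, outdir / "mirna_gene_pathway.graphml", "graphml")

    lines = []
    for name, g in (("miRNA-gene", bipartite),
                    ("miRNA-gene-pathway", tripartite)):
        s = network_stats(g, hub_k=4)
        lines.append(
            f"{name}: {s['n_nodes']} nodes, {s['n_edges']} edges "
            f"({s['n_mirnas']} miRNAs, {s['n_genes']} genes, "
            f"{s['n_pathways']} pathways); "
            f"hub miRNAs (>=4 targets): {', '.join(s['hub_mirnas']) or 'none'}")
    (outdir / "stats.txt").write_text("\n".join(lines) + "\n")
    print("\n".join(lines))
    print(f"wrote {outdir}")


if __name__ == "__main__":
    main()
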