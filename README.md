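# caprimir

A small RNA-seq miRNA pipeline for two-library designs — the analysis
chain used to profile miRNAs in dairy-goat mammary glands at early (E)
versus late (L) lactation, rebuilt as a tested, reusable Python package:

1. **preprocess** — 3′ adapter trimming, junk/length filters, collapse of
   reads into unique 18–26 nt tags, with an exact accounting ledger;
2. **contaminant filter** — partition of tags into repeat, Rfam
   (rRNA/tRNA/snRNA/snoRNA/other) and mRNA classes versus valid tags,
   with percentages of raw totals;
3. **classification** — the six-group scheme (1a/1b/2a/2b/3/4) against
   mature/pre-miRNA references and a genome, plus family and
   cross-species conservation summaries;
4. **hairpin discovery** — novel miRNA calling from genomic context under
   eleven structural criteria (stem ≥ 16 bp, bulges ≤ 12 nt, ΔG ≤ −15
   kcal/mol, hairpin ≥ 50 nt, loop ≤ 20 nt, mature-region rules), using a
   bundled Nussinov-style folder with stacking bonus and loop penalties,
   or externally supplied structures;
5. **differential expression** — TPM normalisation
   (10⁶ · count / valid reads), the Audic–Claverie exact test
   p(y|x) = (N₂/N₁)^y (x+y)! / (x!·y!·(1+N₂/N₁)^(x+y+1)) with
   two-sided p = min(1, 2·min(C, D)), Fisher/χ² companions, and the
   published flagging rule (reads > 10, p < 0.05, |log₂FC| ≥ 1.5), plus a
   2^−ΔΔCt qPCR helper;
6. **network export** — miRNA–gene(–pathway) regulation networks from
   edge tables, with hub statistics and GraphML/SIF/TSV round trips.

Because experiments of this design typically deposit no raw data, the
package includes a first-class **synthetic-data module**: a toy genome
with planted hairpin precursors, two-species miRNA references,
contaminant sets, and two adapter-ligated libraries with known
composition and known log₂ fold changes — so every stage is scored
against ground truth.

It is intended for bioinformaticians who want a transparent, scriptable
re-implementation of this vendor-style pipeline (the original studies
used closed tooling), or a truth-backed benchmark harness for small-RNA
method development.

## Worked example

```python
from caprimir import SimulationConfig, run_pipeline

res = run_pipeline(SimulationConfig(seed=1))
print(res.metrics)
```

prints

```
{'known_recall': 1.0, 'novel_recall': 1.0, 'de_sensitivity': 1.0,
 'group_counts': {'1a': 429, '1b': 371, 'unassigned': 86, '4': 10},
 'n_novel_candidates': 10}
```

i.e. on the reference simulation (2 × 200k reads, 100 known miRNAs in
two species, 10 planted novel hairpins, 10 % contaminants, 20 % of
miRNAs differential at |log₂FC| ≥ 3) the pipeline recovers every planted
known miRNA into groups 1a/1b (429 + 371 unique tags including isomiR
and sequencing-error variants), calls exactly the 10 planted novel
hairpins as group 4, and flags 100 % of the truly differential miRNAs.

The same run as a step-by-step narrative, writing tables under
`results/`:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py          # ledger, length distribution
python analysis/03_filter_contaminants.py # Table-style accounting
python analysis/04_classify.py            # groups, families, conservation
python analysis/05_discover_novel.py      # group-4 candidates + structures
python analysis/06_diffexp.py             # exact-test DE table
python analysis/07_network.py             # GraphML/SIF networks
```

A `caprimir` console command exposes the same stages for external data
(`caprimir simulate|preprocess|filter|classify|discover|diffexp|network`).

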