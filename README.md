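# phagescape

Analysis of **landscape (p8-type) phage display libraries evolved in vivo**,
from targeted gp8 amplicon sequencing reads to tissue-selective peptide motifs
and their interaction networks.

Landscape phage libraries display a random 9-mer peptide on every one of the
~4,000 copies of the filamentous-phage major coat protein p8. After a library
is injected into an animal and allowed to circulate, the phage population
recovered from each organ is a tissue-filtered sub-library: short linear
fragments of the displayed peptides — 3-mer *elementary binding units* (EBUs)
— become enriched in tissues where they mediate binding or navigation.
`phagescape` implements the complete computational side of such a study, for
researchers running in vivo phage-display selections:

- **`phagescape.synthetic`** — a simulator of the gp8-targeted single-end
  sequencing run (150 bp reads, 27-nt degenerate insert between fixed gp8
  flanks, sense/anti-sense strand mixture, Phred qualities, substitution
  errors) with planted, ground-truth tissue-selective motifs.
- **`phagescape.processing`** — read orientation and linked-flank trimming on
  both strands, exact 27-nt size filter, quality filter (default Q ≥ 34 over
  the insert), collapsing of identical nucleotide inserts, translation, and
  collapsing of synonymous encodings into peptide records.
- **`phagescape.enrichment`** — overlapping 3-mer counting (once per distinct
  peptide by default), percentage frequency profiles, Ward-clustered heatmap
  matrices (motifs below 0.0125 % in all samples removed), and
  tissue-selectivity testing: for each motif a 2×2 table
  `[[a, T_t − a], [c, T_n − c]]` of motif vs all-other-motif counts in the
  tissue and a normalizing sample (unselected library, pooled other tissues,
  or serum), a one-sided Fisher's exact test `P(X ≥ a)`, Benjamini–Hochberg
  correction per tissue, and the selectivity call *adjusted p < 0.05 and
  fold change > 2*.
- **`phagescape.network`** — undirected EBU co-occurrence networks: nodes are
  tissue-selective motifs, edge weights count distinct peptides containing
  both motifs; edges below weight 20 are filtered for display; components are
  classified *isolated* / *simple* (chain extension via overlapping motifs) /
  *complex* (motifs combined at variable spacing); GraphML/GEXF export.
- **`phagescape.biodistribution`** — titering arithmetic (TU/g, infectivity
  correction to virions), qPCR standard curves (slope, R², efficiency
  `100·(10^(−1/slope) − 1)`), concentration inversion, mammalian-gDNA
  normalization to vir/g, and percent injected dose per gram (%ID/g).
- **`phagescape.pipeline` / `phagescape` CLI** — one-command orchestration
  with a checksummed run manifest.

Real runs of this kind are deposited, e.g., as NCBI SRA BioProject
PRJNA576688; the package consumes any demultiplexed Phred+33 single-end FASTQ
per tissue.

## Worked example

```python
import phagescape as ps
from phagescape.enrichment import count_motifs, fisher_enrichment, adjust_and_flag
from phagescape.network import build_network, classify_components

# simulate an 8-tissue run with one 5-fold planted motif per tissue
cfg = ps.SimulationConfig(n_tissues=8, n_background_peptides=20_000, seed=11)
planted = [ps.PlantedEnrichment("WKH", "tissue_1", fold=5.0)]
truth = ps.generate_peptide_pool(cfg, planted)

lib = count_motifs(truth.library_pool, tissue_id="library")
tis = count_motifs(truth.tissue_pools["tissue_1"], tissue_id="tissue_1")
res = adjust_and_flag(fisher_enrichment(tis, lib))
print(res[res.selective][["motif", "fold_change", "p_adjusted"]])
#      motif  fold_change    p_adjusted
# 7366   WKH     4.335532  1.685754e-07
```

The planted motif — and nothing else — is called tissue-selective: its
frequency among the tissue's unique peptides is ~4.3× its frequency in the
unselected library sample, with a BH-adjusted one-sided Fisher p of ~2e-7.

On the bundled example peptide families (`phagescape.examples`), the network
module reproduces the canonical component types:

```python
from phagescape.examples import all_example_peptides
g = build_network(all_example_peptides(), {"MYW", "LMH", "MHP", "HPG", "VGS", "AVS", "SEG"})
print(g["VGS"]["AVS"]["weight"], g["VGS"]["SEG"]["weight"])   # 3 8
print(classify_components(g)["MYW"], classify_components(g)["LMH"])  # isolated simple
```

A full pipeline run from a shell:

```bash
phagescape all --config run.json      # simulate -> process -> enrich -> network
phagescape quantify --cq cq.csv --samples samples.csv --outdir quant/
```

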