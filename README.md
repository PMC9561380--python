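# mpraloc

Analysis toolkit for massively parallel reporter assays (MPRAs) of **RNA
localization to neurites**. Neuronal cells grown on microporous membranes can
be separated into a soma and a neurite fraction; a pooled library of barcoded
reporters, each carrying a 150-nt fragment of a native 3′UTR, then yields a
per-fragment readout of how strongly that sequence drives the reporter RNA
into neurites. `mpraloc` covers the full computational arc of such a study:

- **Library design** — tile 3′UTRs (150 nt windows, 50 nt step, polyadenylation
  signals excluded), draw 12-nt barcodes with pairwise Hamming distance ≥ 3,
  mutate or insert RBP motifs (optionally inside a 9-bp hairpin), and assemble
  constant-length 198-nt oligos (18-nt primer + 12-nt barcode + 150-nt
  variable region + 18-nt primer).
- **Simulation** — ground-truthed synthetic studies: gene classes with planted
  localization effects, negative-binomial UMI counts over 3 replicates per
  compartment, a 0/4/24 h transcription-shutoff decay series, and optional
  paired FASTQ reads.
- **Quantification** — assign read 2 barcodes to library variants (≤ 1
  mismatch under the distance-3 code), deduplicate with the 15-nt UMI in read
  1, and count distinct UMIs per variant and sample.
- **Enrichment statistics** — an in-house negative-binomial GLM per variant
  with median-of-ratios size factors, moderated method-of-moments dispersion
  and a likelihood-ratio test, giving logFC(neurite/soma) and the analogous
  relative-stability contrasts logFC(4 h/0 h) and logFC(24 h/0 h).
- **Localization landscapes** — per-gene positional logFC profiles, peak
  calling (fold change > 1.5 and mean *P* < 0.05 over a run of consecutive
  tiles), cross-condition peak overlap, and classification of genes as
  *focused*, *broadly encoded* or *not enriched*.
- **Motif analysis** — MEME-format PWMs, top-*n* k-mers, cumulative binding
  scores, Fisher motif enrichment, score–logFC correlations (BH, FDR 0.1),
  paired insertion/deletion effects (Wilcoxon signed-rank, exact for small
  *n*) and copy-number dose–response.
- **Prediction** — dual gradient-boosted classifiers (neurite-positive and
  soma-positive, fourmer or cumulative-RBP-score features) whose combined
  output P(neurite) − P(soma) scores unseen sequences; native 3′UTRs are
  scored as median tile neurite probability minus maximum tile soma
  probability.

## The statistical core

For variant *i* in sample *j* with size factor *s<sub>j</sub>* (median of
ratios, geometric mean 1) the UMI count is modelled as

> y<sub>ij</sub> ~ NB(μ<sub>ij</sub>, φ<sub>i</sub>),  log μ<sub>ij</sub> = β<sub>0i</sub> + β<sub>1i</sub>·x<sub>j</sub> + log s<sub>j</sub>,  Var = μ + φμ²

where x<sub>j</sub> indicates the compartment (or shutoff timepoint).
φ<sub>i</sub> is a method-of-moments estimate shrunk toward a lowess
mean–dispersion trend with weight n<sub>rep</sub>/(n<sub>rep</sub>+10). The
reported logFC is β<sub>1i</sub>/ln 2 and the p-value comes from a
likelihood-ratio test (χ², 1 df) of the condition term. Because size factors
absorb any global change, decay logFCs are *relative to the library
population*: positive = more stable than average.

## Worked example

```python
import mpraloc as m

cfg = m.SimConfig(seed=7)                       # 10-gene pilot study
sim = m.simulate_study(cfg, with_decay=True)
print(f"library: {len(sim.variants)} variants, {len(sim.genes)} genes")

enr = m.glm_lrt(sim.localization, "neurite_vs_soma")
print(f"significant variants (p<0.05): {(enr.pvalue < 0.05).sum()}")

design_df = m.design.design_to_frame(sim.variants, sim.design_config)
profiles = m.build_profiles(enr, design_df)
lengths = {g.gene_id: len(g.sequence) for g in sim.genes}
summary = m.classify_genes(profiles, utr_lengths=lengths)
print(summary.gene_class.value_counts().to_string())

for prof in profiles:
    for p in m.detect_peaks(prof):
        print(f"peak {p.gene_id} [{p.start},{p.end}) "
              f"mean logFC={p.mean_logfc:.2f} mean p={p.mean_pvalue:.2e}")
```

prints

```
library: 1119 variants, 10 genes
significant variants (p<0.05): 168
gene_class
not_enriched    5
broad           3
focused         2
peak gene003_focused [800,1250) mean logFC=2.02 mean p=1.81e-14
peak gene004_focused [250,700) mean logFC=2.03 mean p=1.37e-07
```

The two focused genes each yield one peak whose interval overlaps the
planted 200-nt localization window (the detected interval is wider because
every 150-nt tile touching the window inherits its effect); broadly encoded
genes show net neurite enrichment without a peak; soma-restricted and null
genes fall in `not_enriched`.

The same steps are available from the shell:

```bash
mpraloc simulate --outdir sim/ --seed 7
mpraloc enrich --counts sim/counts_localization.tsv \
               --samples sim/samples_localization.tsv --out enr.tsv
mpraloc peaks --enrichment enr.tsv --design sim/design.tsv --out peaks.tsv
mpraloc classify --enrichment enr.tsv --design sim/design.tsv \
                 --utrs sim/utrs.fa --out classes.tsv
```

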