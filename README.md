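# mhcatlas

Organism-wide analysis of MHC class I immunopeptidomes across primary
tissues.

Mass-spectrometry atlases of MHC-I (HLA-I in human) ligands now cover most
organs of the mouse and the human body. `mhcatlas` turns the questions such
atlases raise into a tested, reusable pipeline for immunologists and
computational biologists:

- **Which allotypes dominate where?** Per-subject allele × tissue peptide
  shares and fold-enrichments, averaged across subjects and flagged at
  ≥1.5-fold over-representation.
- **How tissue-specific is the peptidome?** Binder filtering (8–12mers,
  percentile rank ≤ 2.0), tissue connectivity matrices (shared peptides
  off-diagonal, tissue-unique counts on the diagonal), tissue-specific /
  shared partitions, tissue PCA, and breadth-vs-abundance/affinity trends.
- **What drives presentation?** Source-gene expression linkage (gene
  classes, source-tissue expression z-scores), housekeeping/universal
  peptide selection, and promoter/exon conservation scoring against
  per-base PhastCons-style tracks with a 12-bp sliding window.
- **Which proteins track presentation capacity?** A proteome-wide screen
  regressing each protein's log10 abundance across tissues against total
  MHC-I peptide counts, with dual thresholds (R² > 0.4 plus a p-value
  cutoff, replicated across subjects in the human design) and permutation
  false-positive calibration.

Because the public atlases are large downloads, the package ships a
first-class synthetic-cohort generator (`mhcatlas.simulate`) that emulates
their statistical structure — expression-coupled peptide detection, planted
allele enrichments, conservation-classed genes, abundance-correlated
proteins — and emits machine-readable ground truth, so every stage is
testable end to end offline.

## The statistics at the core

*Allele enrichment* for allele $a$ in tissue $k$ of one subject:

$$E_{a,k} = \frac{s_{a,k}}{\tfrac{1}{n-1}\sum_{j \ne k} s_{a,j}}$$

where $s_{a,k}$ is the fraction of tissue $k$'s assigned peptides carried
by $a$. The default divides by the mean share of the *other* tissues
(exclusive mode, matching the worked 55%-vs-22% → 2.5-fold arithmetic); the
all-tissues denominator is available as inclusive mode, in which the
per-allele mean enrichment over tissues is exactly 1.

*Conservation score* of a region: the maximum over all stride-1 12-bp
windows of the mean per-base conservation probability; promoters are
2000 bp upstream to 200 bp downstream of the TSS, strand-aware; exons are
scored individually. Universal versus tissue-specific source-gene score
distributions are compared with the two-sided Wilcoxon rank-sum test.

*Screen null*: for independent data with $n$ tissue pairs, the per-protein
$R^2$ follows $\mathrm{Beta}(\tfrac12, \tfrac{n-2}{2})$; at $n = 10$ the
tail above 0.4 is 4.97%, which is why the R² > 0.4 cutoff keeps false
positives near or below 5%.

## Worked example

Simulate a default cohort (19 tissues, 3 subjects, planted structures) and
run the full pipeline:

```bash
mhcatlas simulate --outdir demo/cohort --seed 7
mhcatlas run --outdir demo/run --seed 7
```

`demo/run/run_report.json` from this exact invocation contains (excerpt):

```
tissue_specific_percent: 19.0
rho_breadth_intensity:   0.292
enrichment:   {n_flagged_pairs: 4, n_alleles: 2, n_tissues: 3}
universal:    {n_universal: 104, universal_percent: 29.0, n_source_genes: 73}
conservation: promoter p = 4.5e-16, exon p = 5.7e-40
screen:       {n_hits: 20, n_positive: 10, n_negative: 10}
```

Reading: 19% of the 353 filtered peptides were seen in exactly one tissue;
peptide breadth correlates positively with abundance (Spearman ρ = 0.29);
the two planted 3-fold allele–tissue enrichments are among the flagged
pairs; the universal selection (union of the three human criteria) covers
the 30 planted universal peptides; universal source genes are far more
conserved than tissue-specific ones at both promoters and exons; and the
screen recovers all 20 planted abundance-correlated proteins, half
positive, half negative.

Individual stages are also exposed (`mhcatlas filter | connectivity | pca |
breadth | enrich | link-expression | universal | conserve | screen`), each
reading and writing plain TSV/BED/bedGraph.

## Layout

```
src/mhcatlas/
  types.py         domain types (catalog, matrices, gene models, track)
  io.py            TSV / BED / bedGraph readers and writers, YAML config
  simulate.py      synthetic cohorts + null screens with planted truth
  landscape.py     filtering, counts, connectivity, specificity, PCA, trends
  enrichment.py    allele shares, fold-enrichment, cross-subject flagging
  linkage.py       gene classes, expression z-scores, molecular weights
  conservation.py  universal selection, window scoring, CDF comparison
  screen.py        per-protein regression screen + FP calibration
  pipeline.py      one-config orchestration with a JSON run report
  cli.py           `mhcatlas` command-line interface
```

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
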