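# Methods

This note documents the models, conventions and parameter choices behind
`mhcatlas`, what the synthetic cohorts do and do not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Data model and conventions

A *peptide catalog* holds at most one aggregated observation per
(sequence, tissue, subject). Replicate pulldowns are collapsed by keeping
the highest-intensity row: immunopeptidomic intensities are not normalized
across heterogeneous pulldowns, so a rank-preserving, non-additive rule is
the defensible aggregate; summing would conflate sampling depth with
abundance. Aggregation is idempotent, and all analyses behave identically
on catalogs read from disk or generated in memory.

Coordinates are 0-based half-open everywhere; BED and bedGraph files are
taken in their native convention. Missing-value tokens on input are
`{"", "NA", "NaN", "nan"}` (configurable). Tissue names pass through an
editable synonym map; the shipped default identifies Myelon with Spinal
cord, the same organ named differently in human and mouse vocabularies.
Writers emit deterministic row order (sorted identifiers) and
full-precision floats, so write→read round-trips are exact.

## Binder filtering and allele assignment

MHC-I ligands are defined as 8–12-mers with binding percentile rank
≤ 2.0, both bounds inclusive. Rank scores are consumed as input (binding
prediction itself is out of scope). Each peptide is assigned the allele
with the lowest (best) rank among the subject's genotyped alleles; ties
break lexicographically and are logged; peptides without any scored allele
are excluded from allele-resolved analyses but retained elsewhere.

## Allele enrichment

Within a subject, the share of tissue *k*'s assigned peptides carried by
allele *a* is compared with that allele's average share elsewhere. Two
denominators are defensible and appear interchangeably in practice: the
mean share over *all* tissues, or the mean over the *other* tissues; they
disagree by a factor (n−1+r)/n. We ship both: *exclusive* (other-tissues
mean) is the default because it matches the intuitive worked arithmetic
(0.55 focal vs 0.22 elsewhere → 2.5-fold); *inclusive* is selectable and
satisfies the algebraic identity mean_k(E_{a,k}) = 1, which the test suite
checks to 1e-9. The two agree as the tissue count grows, and every output
records the mode used.

Fold values are averaged across the subjects carrying the allele and
flagged at ≥ 1.5. An allele absent from all non-focal tissues yields an
infinite fold; such sentinels are flagged separately and excluded from
cross-subject means. Shares computed from fewer than 50 assigned peptides
trigger a warning (the floor itself defaults to 1 so that nothing is
silently dropped).

## Tissue landscape

The connectivity matrix counts peptides with a reported intensity in both
tissues off-diagonal and tissue-unique peptides on the diagonal; it equals
brute-force set intersection by construction and by test. Tissue-specific
peptides are those detected in exactly one tissue; shared-core peptides
are detected in every named core organ. Percentages are reported half-up
to integer percent, one decimal below 2% (matching the mixed 42% / 0.5%
reporting style of atlas papers).

PCA follows the variable-space convention common in tissue-profile
analyses (tissues as variables over peptides as observations, the
FactoMineR default): tissue columns of the peptide × tissue
log10-intensity matrix (undetected = 0) are centered and unit-scaled, and
tissue coordinates are the eigenvectors of the tissue correlation matrix
scaled by the square roots of their eigenvalues. Unit scaling is exposed
as a flag and recorded in output metadata. Signs are fixed by making each
component's largest-magnitude coordinate positive. An observation-space
PCA (e.g. scikit-learn's) is *not* the same object, which is why the
eigendecomposition is done directly.

Breadth trends use Spearman rather than Pearson correlation because
breadth is an integer scale with heavy ties. Cross-species count
comparison reports the OLS R² on name-matched tissue counts.

## Expression linkage

Peptides credit *all* their source genes (dropping multi-mappers discards
signal; a strict flag is provided). Gene classes: `presents_peptides` (any
detected peptide), `presents_tissue_specific` (≥ 1 single-tissue peptide, a
subset of the former), `none`; for plotting each gene gets one primary
label with tissue-specific taking precedence. Expression distributions are
compared on log10(TPM+1) — the pseudocount avoids log 0 — with two-sided
rank-sum tests.

The z-score matrix averages, for each source tissue, the expression of
genes whose tissue-specific peptides arose there, then standardizes each
row across tissues with the sample (n−1) standard deviation; a zero-sd row
is set to zero and flagged rather than dropped.

## Universal peptides and conservation

Mouse mode selects peptides present in every catalog tissue and insists
that all subjects share one allele set (a strain). Human mode first
restricts to donors with ≥ 14 sampled tissues (avoiding bias toward
shallowly sampled donors), then takes the union of three criteria:
present in all tissues of ≥ 2 donors; present in all samples whose subject
carries the peptide's assigned allele (requiring ≥ 2 such samples, so a
single-sample allele cannot qualify vacuously); or among the top 100
peptides by sample frequency, with ties at rank 100 all included and the
tie count logged.

Promoters span [TSS−2000, TSS+200) on the plus strand and the mirrored
[TSS−200, TSS+2000) on the minus strand, clipped at the chromosome start.
Region score = max over stride-1 12-bp windows of the window-mean
conservation probability. "Maximum conservation value" is ambiguous
between a raw base maximum and a window aggregate; the window mean
preserves the stated purpose of windowing and is the default (the raw
maximum is the same computation with window 1). Windows containing missing
bases are skipped; regions shorter than one window take the mean of
available bases; fully missing regions are flagged. Exons are scored
individually so windows never straddle introns, and each region
contributes one score to the pooled group distribution (a per-gene-max
option exists for analyses that prefer one score per gene).
Group comparisons use the two-sided Wilcoxon rank-sum test (exact for
small groups: the fully separated 3-vs-3 case gives p = 2/20 = 0.1).

## Proteome screen

Per protein: OLS of per-tissue peptide counts on log10 abundance, pairwise
dropping missing and non-positive abundances, requiring more than nine
pairs (ten points being the commonly cited floor for a meaningful simple
regression). The p-value is the two-sided t-test on the slope, equivalent
to the F-test in simple regression. Hits require R² > 0.4 and p < 0.01
(single-subject / mouse design) or p < 0.05 replicated in ≥ 2 subjects
(human design, per-subject peptide counts; no direction-consistency
requirement by default, with a strict flag available). No multiple-testing
correction is applied — matching the raw-threshold design — but BH
q-values are emitted alongside. Jejunum and duodenum abundance columns are
averaged into small intestine via a configurable merge map before pairing.

Calibration: permuting the tissue labels of the count vector and refitting
estimates the false-positive fraction of the R² cutoff. Under
independence, R² ~ Beta(1/2, (n−2)/2); at n = 10 tissues
P(R² > 0.4) = 0.0497, the analytic cross-check for the ≈ ≤ 5% false-positive
behaviour of the cutoff, and the quantity `scripts/acceptance.py`
re-estimates empirically (2000 pseudo-proteins, 10 tissues).

## Synthetic cohorts

The generator emulates the *statistical* structure of a tissue atlas, not
its biology. Defaults are desk-scale study conditions chosen once: 19
tissues (the mouse atlas organ count, drawn from a 29-organ vocabulary),
3 deeply sampled donors carrying 6 of 8 pooled HLA allotypes
(allotype-resolved atlas analyses rest on a handful of deeply sampled
donors), ~270 genes in
three conservation classes (30 universal-source, 40 tissue-restricted, 200
background), ~3 peptides per gene, two planted 3-fold allele–tissue
enrichments, and 20 abundance-correlated proteins among 500 nulls.

Mechanics:

- Detection is Bernoulli with logit p = −2.2 + 1.0·log10(TPM+1) − 0.8·rank
  + a per-tissue N(0, 0.5) sampling-depth offset. The offset creates the
  realistic variation in per-tissue totals that the screen needs; raising
  the expression slope never decreases counts under a shared seed (tested
  by seed coupling).
- Universal-class genes are highly expressed everywhere and their
  designated peptide is presented in every tissue of every carrier
  subject; tissue-restricted genes are expressed in one home tissue
  (expression z > 2 there) and their designated peptide appears only
  there. Designated peptides draw rank scores in (0, 2) — broadly
  presented peptides are empirically strong binders — so planted truth
  survives the binder filter; undesignated peptides draw uniform (0, 5],
  exercising the filter. Designated universal peptides take alleles
  carried by ≥ 2 subjects so the human all-tissues criterion is reachable.
- A planted (allele, tissue) enrichment multiplies detection probability
  by the fold (saturating at 1) for every carrier subject, so the
  cross-subject mean that the flagging stage computes reflects the planted
  fold rather than being diluted by unaffected subjects.
- log10 intensity ~ N(4 + 1.0·log10(TPM+1), 0.5), coupling abundance to
  expression and hence to breadth.
- Genes are laid end-to-end on one pseudo-chromosome (3 × 300 bp exons,
  500 bp introns, 5.5 kb spacing); per-base conservation is drawn from
  class Beta distributions — Beta(8,2) universal, Beta(2,8)
  tissue-restricted, Beta(2,5) background, Beta(1,4) intergenic — with
  promoter bases drawn from a separately tunable Beta (the 200 bp of
  promoter–exon overlap at the TSS takes the promoter distribution).
- Planted correlated proteins have abundance = 200 + 20·(per-tissue
  filtered peptide count) + N(0, 30), with half the proteins reversed in
  direction; null proteins are independent lognormals. The null-screen
  generator draws abundances and counts independently for calibration.

Everything funnels through one seeded generator: a fixed seed gives
byte-identical cohorts.

What the simulator does **not** emulate — and what passing tests therefore
do not establish about real data: peptide sequence biology (cleavage
motifs, binding motifs, hotspots), MS acquisition bias and missingness
structure, shared peptides between alleles, inter-donor batch effects,
isoform structure, or realistic genome organisation. Recovery results
(universal recall ≥ 0.9, planted-pair flagging, conservation-gap
detection, screen recall ≥ 0.8 at ≤ 5% false hits) certify the inference
machinery under the generator's assumptions, not atlas-scale biology.

## Problem sizes and determinism

Default test and pipeline cohorts are a few hundred genes / a few thousand
observations, generating in under a second; the calibration uses 2000
pseudo-proteins at 10 tissues. These sizes give comfortable statistical
resolution for every planted effect while keeping the full suite fast.
All randomness in library, tests and scripts flows through explicit seeds;
hypothesis runs derandomized.

## Known limitations

- The enrichment denominator (inclusive vs exclusive) is a genuine
  convention choice; both modes are shipped and the choice is recorded in
  every output.
- Identifier mapping (UniProt/ENSEMBL) is assumed done upstream; tables
  arrive with consistent gene identifiers.
- The human screen defaults to subject-restricted peptide counts; pooled
  per-tissue counts are an equally plausible design and can be supplied
  instead.
- Atlas-scale headline numbers (e.g. hit counts of specific screens)
  depend on the full public datasets and are outside what synthetic
  cohorts can or should reproduce.
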