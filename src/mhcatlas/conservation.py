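"""Housekeeping/universal peptide selection and conservation scoring.

Universal peptides are those presented across (effectively) all sampled
tissues: in the single-strain mouse setting that means every catalog tissue;
in the multi-donor human setting a three-criterion union is used. Their
source genes' promoters and exons are scored against a per-base conservation
track with a 12-bp sliding window, and score distributions are compared
between universal and tissue-specific source genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import round_percent
from .types import (
    ConservationTrack,
    GeneModel,
    PeptideCatalog,
    UNASSIGNED,
    ValidationError,
)

logger = logging.getLogger("mhcatlas")


@dataclass
class UniversalSelection:
    peptides: set[str]
    criteria: pd.DataFrame  # one row per selected peptide, boolean criterion columns
    source_genes: set[str]
    n_total: int
    species_mode: str
    n_c3_ties: int = 0

    @property
    def fraction(self) -> float:
        return len(self.peptides) / self.n_total if self.n_total else 0.0

    @property
    def percent(self) -> float:
        return round_percent(len(self.peptides), self.n_total)


def _source_genes_of(catalog: PeptideCatalog, peptides: set[str]) -> set[str]:
    df = catalog.df
    genes: set[str] = set()
    for gs in df.loc[df["sequence"].isin(peptides), "source_genes"]:
        genes.update(gs)
    return genes


def select_universal(
    catalog: PeptideCatalog,
    species_mode: str,
    min_tissues_per_donor: int = 14,
    top_k: int = 100,
    min_allele_samples: int = 2,
) -> UniversalSelection:
    """Select housekeeping/universal peptides.

    mouse mode: peptides present in every tissue of the catalog. All
    subjects must share one allele set (a strain), otherwise the catalog is
    not a mouse-style atlas and an error is raised.

    human mode: donors with fewer than ``min_tissues_per_donor`` sampled
    tissues are excluded (avoiding a bias toward shallowly sampled donors),
    then a peptide qualifies by the union of
      c1: present in every tissue sampled of at least two retained donors;
      c2: present in every sample (subject, tissue) whose subject carries
          the peptide's assigned allele, that allele occurring in at least
          ``min_allele_samples`` samples;
      c3: among the ``top_k`` peptides most frequently identified across all
          samples, ties at the k-th rank included (tie count logged).
    """
    n_total = len(catalog.peptides)
    if species_mode == "mouse":
        allele_sets = set(catalog.subject_alleles.values())
        if len(allele_sets) > 1:
            raise ValidationError(
                "mouse mode requires a single shared allele set across subjects"
            )
        presence = catalog.presence()
        selected = set(presence.index[presence.all(axis=1)]) if len(presence) else set()
        criteria = pd.DataFrame(
            {"all_tissues": True}, index=pd.Index(sorted(selected), name="peptide")
        )
        return UniversalSelection(
            selected, criteria, _source_genes_of(catalog, selected), n_total, "mouse"
        )
    if species_mode != "human":
        raise ValidationError(f"unknown species mode {species_mode!r}")

    df = catalog.df
    donor_tissues = df.groupby("subject")["tissue"].nunique()
    donors = set(donor_tissues.index[donor_tissues >= min_tissues_per_donor])
    sub = df[df["subject"].isin(donors)]
    logger.info(
        "human universal selection over %d/%d donors with >= %d tissues",
        len(donors),
        len(catalog.subjects),
        min_tissues_per_donor,
    )

    # c1: all tissues of >= 2 retained donors
    c1: dict[str, int] = {}
    for donor, g in sub.groupby("subject"):
        n_tis = g["tissue"].nunique()
        per_pep = g.groupby("sequence")["tissue"].nunique()
        for pep in per_pep.index[per_pep == n_tis]:
            c1[pep] = c1.get(pep, 0) + 1
    c1_set = {p for p, n in c1.items() if n >= 2}

    # c2: all samples carrying the peptide's assigned allele
    samples = sub[["subject", "tissue"]].drop_duplicates()
    best = sub.sort_values(["rank_score", "allele"], kind="mergesort")
    assigned = best[best["allele"] != UNASSIGNED].drop_duplicates("sequence")
    pep_allele = dict(zip(assigned["sequence"], assigned["allele"]))
    samples_by_allele: dict[str, set[tuple[str, str]]] = {}
    for subj, tissue in samples.itertuples(index=False):
        for allele in catalog.subject_alleles.get(subj, ()):
            samples_by_allele.setdefault(allele, set()).add((subj, tissue))
    pep_samples = (
        sub.groupby("sequence")[["subject", "tissue"]]
        .apply(lambda g: set(map(tuple, g.values)))
        .to_dict()
    )
    c2_set = set()
    for pep, allele in pep_allele.items():
        allele_samples = samples_by_allele.get(allele, set())
        if len(allele_samples) >= min_allele_samples and allele_samples <= pep_samples.get(
            pep, set()
        ):
            c2_set.add(pep)

    # c3: top-k by sample frequency, ties at rank k included
    freq = (
        sub[["sequence", "subject", "tissue"]]
        .drop_duplicates()
        .groupby("sequence")
        .size()
        .sort_values(ascending=False)
    )
    c3_set: set[str] = set()
    n_ties = 0
    if len(freq):
        k = min(top_k, len(freq))
        cutoff = freq.iloc[k - 1]
        c3_set = set(freq.index[freq >= cutoff])
        n_ties = len(c3_set) - k
        if n_ties > 0:
            logger.info("c3 tie at rank %d: %d peptides selected", top_k, len(c3_set))

    selected = c1_set | c2_set | c3_set
    criteria = pd.DataFrame(
        {
            "c1_all_tissues_two_donors": [p in c1_set for p in sorted(selected)],
            "c2_all_allele_samples": [p in c2_set for p in sorted(selected)],
            "c3_top_frequency": [p in c3_set for p in sorted(selected)],
        },
        index=pd.Index(sorted(selected), name="peptide"),
    )
    return UniversalSelection(
        selected,
        criteria,
        _source_genes_of(catalog, selected),
        n_total,
        "human",
        n_c3_ties=max(n_ties, 0),
    )


def promoter_region(
    gene: GeneModel, upstream: int = 2000, downstream: int = 200
) -> tuple[int, int]:
    """Strand-aware promoter interval: 2000 bases upstream of the TSS through
    200 bases downstream, half-open, clipped at the chromosome start."""
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    return max(start, 0), end


@dataclass
class RegionScore:
    gene_id: str
    feature: str  # promoter | exon
    score: float  # max over 12-bp window means; NaN when fully missing

    missing: bool = field(init=False)

    def __post_init__(self):
        self.missing = not np.isfinite(self.score)
        if not self.missing and not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"{self.gene_id}: score {self.score} outside [0, 1]")


def region_conservation(
    track: ConservationTrack,
    chrom: str,
    interval: tuple[int, int],
    gene_id: str = "",
    feature: str = "region",
    window: int = 12,
) -> RegionScore:
    """Score one region: the maximum, over all step-1 windows of ``window``
    bases, of the window mean conservation probability.

    Windows containing a missing base are skipped; a region shorter than the
    window is scored as the mean of its available bases; a fully missing
    region scores NaN (flagged via ``RegionScore.missing``).
    """
    start, end = interval
    if start >= end:
        raise ValidationError(f"empty interval [{start}, {end})")
    values = track.region(chrom, start, end)
    finite = np.isfinite(values)
    if not finite.any():
        return RegionScore(gene_id, feature, float("nan"))
    if len(values) < window:
        return RegionScore(gene_id, feature, float(values[finite].mean()))
    windows = np.lib.stride_tricks.sliding_window_view(values, window)
    means = windows.mean(axis=1)
    valid = np.isfinite(means)
    if not valid.any():
        # every window straddles a gap; fall back to available bases
        return RegionScore(gene_id, feature, float(values[finite].mean()))
    return RegionScore(gene_id, feature, float(means[valid].max()))


def score_genes(
    track: ConservationTrack,
    genes: list[GeneModel],
    window: int = 12,
    upstream: int = 2000,
    downstream: int = 200,
    per_gene_max: bool = False,
) -> pd.DataFrame:
    """Promoter and exon conservation scores for a gene set.

    Exons are scored individually (windows must not straddle introns); with
    ``per_gene_max`` the exon scores of a gene are collapsed to their
    maximum, otherwise each exon contributes one score to the pooled
    distribution.
    """
    rows = []
    for gene in genes:
        prom = promoter_region(gene, upstream=upstream, downstream=downstream)
        rs = region_conservation(track, gene.chrom, prom, gene.gene_id, "promoter", window)
        rows.append((gene.gene_id, "promoter", rs.score))
        exon_scores = [
            region_conservation(track, gene.chrom, ex, gene.gene_id, "exon", window).score
            for ex in gene.exons
        ]
        if per_gene_max:
            finite = [s for s in exon_scores if np.isfinite(s)]
            rows.append((gene.gene_id, "exon", max(finite) if finite else float("nan")))
        else:
            rows.extend((gene.gene_id, "exon", s) for s in exon_scores)
    return pd.DataFrame(rows, columns=["gene", "feature", "score"])


def compare_conservation(
    scores_universal: pd.DataFrame, scores_tissue_specific: pd.DataFrame
) -> dict:
    """Per-feature comparison of conservation score distributions.

    Returns, for promoter and exon separately, the empirical CDF grids of
    both groups on [0, 1], the two-sided Wilcoxon rank-sum p value and the
    median difference (universal minus tissue-specific).
    """
    out = {}
    for feature in ("promoter", "exon"):
        a = scores_universal.loc[
            scores_universal["feature"] == feature, "score"
        ].dropna()
        b = scores_tissue_specific.loc[
            scores_tissue_specific["feature"] == feature, "score"
        ].dropna()
        if len(a) < 3 or len(b) < 3:
            raise ValidationError(f"{feature}: need >= 3 scores per group")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        grid = np.linspace(0, 1, 101)
        out[feature] = {
            "cdf_grid": grid,
            "cdf_universal": np.searchsorted(np.sort(a), grid, side="right") / len(a),
            "cdf_tissue_specific": np.searchsorted(np.sort(b), grid, side="right")
            / len(b),
            "p_value": float(res.pvalue),
            "median_difference": float(a.median() - b.median()),
            "n_universal": int(len(a)),
            "n_tissue_specific": int(len(b)),
        }
    return out
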