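"""Linking peptides to source-gene mRNA expression.

Classifies genes by whether they yield detectable peptides (and whether any
of those peptides are tissue-specific), compares expression between the
classes, builds the source-tissue x tissue expression z-score matrix, and
compares molecular weights of universal versus other source genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, PeptideCatalog, ValidationError

logger = logging.getLogger("mhcatlas")


def _peptide_gene_map(catalog: PeptideCatalog, multimappers: bool = True) -> pd.DataFrame:
    """Long (sequence, gene) pairs. Peptides mapping to several genes credit
    all of them unless ``multimappers`` is False, which drops such peptides."""
    df = catalog.df[["sequence", "source_genes"]].drop_duplicates("sequence")
    rows = []
    for seq, genes in zip(df["sequence"], df["source_genes"]):
        if not multimappers and len(genes) > 1:
            continue
        for g in genes:
            rows.append((seq, g))
    return pd.DataFrame(rows, columns=["sequence", "gene"]).drop_duplicates()


def classify_genes(
    catalog: PeptideCatalog,
    expression: ExpressionMatrix,
    multimappers: bool = True,
) -> dict:
    """Label every expression-matrix gene by its peptide output.

    ``presents_peptides`` marks genes with any detected peptide;
    ``presents_tissue_specific`` marks genes with at least one peptide seen
    in exactly one tissue (a subset of the former). ``primary_label`` gives
    each gene exactly one plotting class with tissue-specific taking
    precedence. Returns the table, per-class log10(TPM+1) distributions and
    pairwise rank-sum comparisons.
    """
    pg = _peptide_gene_map(catalog, multimappers=multimappers)
    breadth = catalog.presence().sum(axis=1)
    specific_peptides = set(breadth.index[breadth == 1])
    genes_any = set(pg["gene"])
    genes_specific = set(pg.loc[pg["sequence"].isin(specific_peptides), "gene"])
    universe = list(expression.gene_ids)
    mapped = genes_any & set(universe)
    if not mapped:
        raise ValidationError("no peptide source gene maps into the expression matrix")
    unmapped_fraction = 1 - len(mapped) / len(genes_any) if genes_any else 0.0
    logger.info(
        "%.1f%% of source genes matched to expression entries",
        100 * (1 - unmapped_fraction),
    )
    table = pd.DataFrame(index=pd.Index(universe, name="gene"))
    table["presents_peptides"] = table.index.isin(genes_any)
    table["presents_tissue_specific"] = table.index.isin(genes_specific)
    table["primary_label"] = np.where(
        table["presents_tissue_specific"],
        "tissue_specific",
        np.where(table["presents_peptides"], "any_peptide", "none"),
    )
    log_expr = np.log10(expression.values.mean(axis=1) + 1.0)
    dists = {
        label: log_expr[table.index[table["primary_label"] == label]].dropna()
        for label in ["any_peptide", "tissue_specific", "none"]
    }
    comparisons = {}
    labels = [l for l, d in dists.items() if len(d) >= 3]
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            res = stats.mannwhitneyu(dists[a], dists[b], alternative="two-sided")
            comparisons[(a, b)] = float(res.pvalue)
    return {
        "table": table,
        "distributions": dists,
        "comparisons": comparisons,
        "unmapped_fraction": unmapped_fraction,
    }


def zscore_matrix(
    catalog: PeptideCatalog,
    expression: ExpressionMatrix,
    multimappers: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Source-tissue x tissue z-scores of mean source-gene expression.

    For each source tissue s, the genes whose tissue-specific peptides were
    detected in s are collected; their expression is averaged per tissue and
    standardized across tissues with the sample (n-1) standard deviation:
    z_t = (x_t - mean(x)) / sd(x). A zero-sd row is set to all zeros and its
    tissue returned in the flags list; source tissues with no mapped
    tissue-specific gene are omitted with a warning.
    """
    if len(expression.tissue_ids) < 2:
        raise ValidationError("z-scores need expression in at least 2 tissues")
    presence = catalog.presence()
    breadth = presence.sum(axis=1)
    specific = presence.loc[breadth == 1]
    pg = _peptide_gene_map(catalog, multimappers=multimappers)
    rows, flags = {}, []
    for tissue in catalog.tissues:
        if tissue not in specific.columns:
            continue
        peps = set(specific.index[specific[tissue]])
        genes = sorted(
            set(pg.loc[pg["sequence"].isin(peps), "gene"]) & set(expression.gene_ids)
        )
        if not genes:
            logger.warning("source tissue %s has no mapped tissue-specific genes", tissue)
            continue
        x = expression.values.loc[genes].mean(axis=0)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            rows[tissue] = x * 0.0
            flags.append(tissue)
        else:
            rows[tissue] = (x - x.mean()) / sd
    if not rows:
        raise ValidationError("no source tissue with tissue-specific genes")
    z = pd.DataFrame(rows).T
    z.index.name = "source_tissue"
    return z, flags


def mw_comparison(
    universal_genes: set[str],
    other_source_genes: set[str],
    molecular_weights: pd.Series,
) -> dict:
    """Compare molecular weights of universal-peptide source genes against
    other source genes (two-sided Wilcoxon rank-sum, exact where feasible)."""
    mw = molecular_weights.dropna()
    a = mw[mw.index.isin(universal_genes)]
    b = mw[mw.index.isin(other_source_genes - set(universal_genes))]
    dropped = (len(universal_genes) - len(a)) + (
        len(other_source_genes - set(universal_genes)) - len(b)
    )
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("need molecular weights for >= 3 genes per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "median_universal": float(a.median()),
        "median_other": float(b.median()),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_dropped_missing_mw": int(dropped),
    }
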