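"""Subject-level allotype representation across tissues.

For each subject, the share of a tissue's assigned peptides carried by each
allotype is compared with that allele's average share in other tissues,
giving a dimensionless fold-enrichment; folds are averaged across subjects
and flagged at the 1.5-fold over-representation threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ConfigurationError, PeptideCatalog, UNASSIGNED, ValidationError

logger = logging.getLogger("mhcatlas")


def allele_shares(
    catalog: PeptideCatalog, subject: str, min_peptides: int = 1
) -> pd.DataFrame:
    """Per-tissue allotype shares for one subject.

    share(allele, tissue) = assigned peptides of that allele / all assigned
    peptides in the tissue. Unassigned peptides are excluded from the
    denominator; tissues with fewer than ``min_peptides`` assigned peptides
    are omitted (a warning is logged below 50, where shares get noisy).

    Returns a long DataFrame (subject, allele, tissue, share, n_assigned).
    """
    if subject not in catalog.subjects:
        raise ValidationError(f"unknown subject {subject!r}")
    df = catalog.df
    df = df[(df["subject"] == subject) & (df["allele"] != UNASSIGNED)]
    rows = []
    for tissue, g in df.groupby("tissue"):
        n = g["sequence"].nunique()
        if n < min_peptides:
            continue
        if n < 50:
            logger.warning(
                "%s/%s: only %d assigned peptides; shares are noisy", subject, tissue, n
            )
        counts = g.groupby("allele")["sequence"].nunique()
        for allele in catalog.subject_alleles.get(subject, counts.index):
            rows.append(
                {
                    "subject": subject,
                    "allele": allele,
                    "tissue": tissue,
                    "share": counts.get(allele, 0) / n,
                    "n_assigned": n,
                }
            )
    return pd.DataFrame(rows, columns=["subject", "allele", "tissue", "share", "n_assigned"])


def enrichment(shares: pd.DataFrame, mode: str = "exclusive") -> pd.DataFrame:
    """Fold-enrichment of each allele in each tissue for one subject.

    exclusive (default): divide the focal tissue's share by the mean share
    over the OTHER tissues (55% focal vs 22% elsewhere -> 2.5-fold).
    inclusive: divide by the mean over ALL tissues including the focal one
    (the formula as printed). The mode is recorded in the output.

    An allele absent from every other tissue has denominator 0; its
    enrichment is reported as +inf with ``undefined_denominator`` set.
    """
    if mode not in {"exclusive", "inclusive"}:
        raise ConfigurationError(f"unknown enrichment mode {mode!r}")
    if shares["tissue"].nunique() < 2:
        raise ValidationError("enrichment needs shares from at least 2 tissues")
    out = []
    for (subject, allele), g in shares.groupby(["subject", "allele"]):
        vals = g.set_index("tissue")["share"]
        n = len(vals)
        total = vals.sum()
        for tissue, share in vals.items():
            if mode == "inclusive":
                denom = total / n
            else:
                denom = (total - share) / (n - 1) if n > 1 else np.nan
            if denom == 0:
                fold = np.inf if share > 0 else 1.0
            else:
                fold = share / denom
            out.append(
                {
                    "subject": subject,
                    "allele": allele,
                    "tissue": tissue,
                    "share": share,
                    "enrichment": fold,
                    "n_tissues": n,
                    "mode": mode,
                    "undefined_denominator": denom == 0 and share > 0,
                }
            )
    return pd.DataFrame(out)


def average_and_flag(
    tables: list[pd.DataFrame], threshold: float = 1.5
) -> pd.DataFrame:
    """Average fold-enrichments across subjects and flag over-representation.

    The mean is taken over the subjects carrying the allele (i.e. over the
    tables contributing a finite value for that allele/tissue); pairs whose
    mean meets ``threshold`` are flagged. Infinite sentinel values are
    excluded from the mean and surfaced via ``n_undefined``.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    if not tables:
        raise ValidationError("no enrichment tables supplied")
    long = pd.concat(tables, ignore_index=True)
    finite = long[np.isfinite(long["enrichment"])]
    agg = (
        finite.groupby(["allele", "tissue"])
        .agg(
            mean_enrichment=("enrichment", "mean"),
            n_subjects=("subject", "nunique"),
        )
        .reset_index()
    )
    undef = (
        long[~np.isfinite(long["enrichment"])]
        .groupby(["allele", "tissue"])
        .size()
        .rename("n_undefined")
    )
    agg = agg.merge(undef, on=["allele", "tissue"], how="left")
    agg["n_undefined"] = agg["n_undefined"].fillna(0).astype(int)
    agg["flagged"] = agg["mean_enrichment"] >= threshold
    n_flag = int(agg["flagged"].sum())
    logger.info(
        "%d flagged (allele, tissue) pairs over %d alleles and %d tissues",
        n_flag,
        agg.loc[agg["flagged"], "allele"].nunique(),
        agg.loc[agg["flagged"], "tissue"].nunique(),
    )
    return agg


def summarize_flags(agg: pd.DataFrame) -> dict:
    """Counts reported alongside a flagged table: flagged pairs, distinct
    alleles and distinct tissues involved."""
    flagged = agg[agg["flagged"]]
    return {
        "n_flagged_pairs": int(len(flagged)),
        "n_alleles": int(flagged["allele"].nunique()),
        "n_tissues": int(flagged["tissue"].nunique()),
    }
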