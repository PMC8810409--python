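"""Tissue-level landscape of the immunopeptidome.

Binder filtering, per-tissue peptide counting, tissue connectivity matrices,
the tissue-specific / shared partition, variable-space PCA of tissue
intensity profiles, breadth-versus-property trends and the cross-species
count comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .types import PeptideCatalog, UNASSIGNED, ValidationError

logger = logging.getLogger("mhcatlas")


def round_percent(count: int, total: int) -> float:
    """Report count/total as a percentage, half-up to an integer percent, or
    to one decimal below 2% where an integer would obliterate the value."""
    if total <= 0:
        raise ValidationError("total must be positive")
    pct = Decimal(count) * 100 / Decimal(total)
    if pct < 2:
        return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return float(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def filter_binders(
    catalog: PeptideCatalog,
    min_len: int = 8,
    max_len: int = 12,
    rank_max: float = 2.0,
) -> PeptideCatalog:
    """Retain 8-12mer observations with binding percentile rank <= 2.0.

    Bounds are inclusive; observations without a rank score are dropped.
    """
    df = catalog.df
    lengths = df["sequence"].str.len()
    mask = (
        (lengths >= min_len)
        & (lengths <= max_len)
        & (df["rank_score"] <= rank_max)
    )
    kept = catalog.subset(mask)
    logger.info("binder filter kept %d / %d observations", len(kept), len(df))
    return kept


def assign_best_allele(rank_by_allele: dict[str, float]) -> str:
    """Best-rank allele assignment: the allele with the lowest percentile
    rank wins; ties break lexicographically (logged); no scored allele at
    all yields the unassigned sentinel."""
    scored = {a: r for a, r in rank_by_allele.items() if np.isfinite(r)}
    if not scored:
        return UNASSIGNED
    best = min(scored.values())
    winners = sorted(a for a, r in scored.items() if r == best)
    if len(winners) > 1:
        logger.info("rank tie among %s resolved to %s", winners, winners[0])
    return winners[0]


def count_per_tissue(catalog: PeptideCatalog, subject: str | None = None) -> pd.Series:
    """Distinct peptide count per tissue (pooled over subjects by default)."""
    presence = catalog.presence(subject=subject)
    counts = presence.sum(axis=0) if len(presence) else pd.Series(0, index=catalog.tissues)
    return counts.reindex(catalog.tissues, fill_value=0).astype(int)


def connectivity(catalog: PeptideCatalog, subject: str | None = None) -> pd.DataFrame:
    """Tissue x tissue connectivity matrix.

    Off-diagonal (i, j) counts peptides detected in both tissues (an
    intensity reported in each); the diagonal counts peptides detected ONLY
    in that tissue.
    """
    presence = catalog.presence(subject=subject)
    if presence.empty:
        return pd.DataFrame(
            np.zeros((len(catalog.tissues),) * 2, dtype=int),
            index=catalog.tissues,
            columns=catalog.tissues,
        )
    m = presence.to_numpy(dtype=int)
    shared = m.T @ m
    unique = (m[m.sum(axis=1) == 1]).sum(axis=0)
    np.fill_diagonal(shared, unique)
    return pd.DataFrame(shared, index=presence.columns, columns=presence.columns)


@dataclass
class SpecificityPartition:
    tissue_specific: set[str]
    shared_core: set[str]
    total: int
    core_tissues: tuple[str, ...]

    @property
    def tissue_specific_fraction(self) -> float:
        return len(self.tissue_specific) / self.total if self.total else 0.0

    @property
    def shared_core_fraction(self) -> float:
        return len(self.shared_core) / self.total if self.total else 0.0

    @property
    def tissue_specific_percent(self) -> float:
        return round_percent(len(self.tissue_specific), self.total)

    @property
    def shared_core_percent(self) -> float:
        return round_percent(len(self.shared_core), self.total)


def partition_specificity(
    catalog: PeptideCatalog, core_tissues: list[str] | None = None
) -> SpecificityPartition:
    """Split distinct peptides into tissue-specific (detected in exactly one
    tissue) and shared-across-core (detected in every named core organ)."""
    if core_tissues:
        unknown = set(core_tissues) - set(catalog.tissues)
        if unknown:
            raise ValidationError(f"unknown core tissues: {sorted(unknown)}")
    presence = catalog.presence()
    breadth = presence.sum(axis=1)
    specific = set(breadth.index[breadth == 1])
    if core_tissues:
        shared = set(presence.index[presence[list(core_tissues)].all(axis=1)])
    else:
        shared = set(presence.index[presence.all(axis=1)])
    return SpecificityPartition(
        tissue_specific=specific,
        shared_core=shared,
        total=int(len(presence)),
        core_tissues=tuple(core_tissues or catalog.tissues),
    )


def pca_tissues(
    catalog: PeptideCatalog, scale: bool = True, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Variable-space PCA of per-tissue log10 intensity profiles.

    Each tissue is a variable observed over all distinct peptides; undetected
    peptides contribute 0 after the log transform of detected intensities.
    With ``scale`` (default, mirroring the reference implementation's
    correlation PCA) tissue vectors are centered and unit-scaled, and tissue
    coordinates are loadings scaled by the singular values. Component signs
    are fixed so each component's largest-magnitude coordinate is positive.

    Returns (coordinates DataFrame indexed by tissue, explained-variance
    shares for all components, non-increasing).
    """
    if len(catalog.tissues) < 3:
        raise ValidationError("PCA requires at least 3 tissues")
    df = catalog.df.copy()
    df["log_int"] = np.log10(df["intensity"])
    mat = (
        df.pivot_table(index="sequence", columns="tissue", values="log_int", aggfunc="max")
        .reindex(columns=catalog.tissues)
        .fillna(0.0)
    )
    if mat.shape[0] < 2:
        raise ValidationError("PCA requires at least 2 peptides")
    x = mat.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = x / sd
    cov = (x.T @ x) / len(x)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    coords = eigvec * np.sqrt(eigval)
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    shares = eigval / eigval.sum() if eigval.sum() > 0 else eigval
    out = pd.DataFrame(
        coords[:, :n_components],
        index=mat.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return out, shares


def breadth_table(catalog: PeptideCatalog) -> pd.DataFrame:
    """Per-peptide breadth (tissues detected), mean log10 intensity and best
    (minimum) binding rank."""
    df = catalog.df.copy()
    df["log_int"] = np.log10(df["intensity"])
    g = df.groupby("sequence")
    out = pd.DataFrame(
        {
            "breadth": g["tissue"].nunique(),
            "mean_log10_intensity": g["log_int"].mean(),
            "best_rank": g["rank_score"].min(),
        }
    )
    return out.reset_index(names="peptide")


def breadth_vs_property(catalog: PeptideCatalog) -> dict:
    """Spearman rank correlation of breadth against mean log10 intensity and
    against best rank (two-sided p, no multiplicity correction: two tests)."""
    table = breadth_table(catalog)
    result = {"table": table}
    if table["breadth"].nunique() < 2:
        result["flag"] = "constant breadth; correlations undefined"
        result["rho_intensity"] = result["rho_rank"] = float("nan")
        return result
    rho_i, p_i = stats.spearmanr(table["breadth"], table["mean_log10_intensity"])
    result["rho_intensity"], result["p_intensity"] = float(rho_i), float(p_i)
    if table["best_rank"].notna().all() and table["best_rank"].nunique() > 1:
        rho_r, p_r = stats.spearmanr(table["breadth"], table["best_rank"])
        result["rho_rank"], result["p_rank"] = float(rho_r), float(p_r)
    else:
        result["rho_rank"] = float("nan")
    return result


def cross_species_counts(
    counts_a: pd.Series, counts_b: pd.Series, tissue_name_map: dict[str, str]
) -> float:
    """OLS R-squared of per-tissue peptide counts matched across species via
    the tissue name map (keys index counts_a, values counts_b)."""
    pairs = [
        (counts_a[a], counts_b[b])
        for a, b in tissue_name_map.items()
        if a in counts_a.index and b in counts_b.index
    ]
    if len(pairs) < 3:
        raise ValidationError("need at least 3 matched tissue pairs")
    x, y = np.array(pairs, dtype=float).T
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
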