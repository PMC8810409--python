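"""Proteome-wide correlation screen for antigen-processing components.

Each protein's log10 abundance profile across tissues is regressed against
the per-tissue total MHC-I peptide count; proteins clearing the R-squared
and p-value thresholds (replicated across subjects in the human design) are
screen hits, and the false-positive behaviour of the R-squared cutoff is
calibrated by permuting tissue labels. Under independence with n tissue
pairs, R-squared follows Beta(1/2, (n-2)/2), which serves as the analytic
cross-check for the permutation estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ConfigurationError, ProteinAbundanceMatrix, ValidationError

logger = logging.getLogger("mhcatlas")


@dataclass
class RegressionRecord:
    protein_id: str
    subject_id: str
    n_pairs: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float

    @property
    def direction(self) -> str:
        return "positive" if self.slope >= 0 else "negative"


@dataclass
class ScreenConfig:
    r2_min: float = 0.4
    p_max: float = 0.01  # mouse default; human analyses use 0.05
    min_pairs: int = 10
    min_subjects: int = 2  # human replication requirement
    tissue_merge_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"Small intestine": ("Jejunum", "Duodenum")}
    )

    def __post_init__(self):
        if not 0 < self.p_max < 1:
            raise ConfigurationError("p_max must lie in (0, 1)")
        if not 0 < self.r2_min < 1:
            raise ConfigurationError("r2_min must lie in (0, 1)")


def fit_protein(
    abundance_by_tissue: pd.Series,
    counts_by_tissue: pd.Series,
    protein_id: str = "",
    subject_id: str = "",
    min_pairs: int = 10,
) -> RegressionRecord | None:
    """OLS of peptide counts on log10 protein abundance across tissues.

    Missing and non-positive abundances are dropped pairwise before the log
    transform. Returns None when fewer than ``min_pairs`` valid pairs remain
    (more than 9 measurement pairs are required at the default) or when the
    regressor has zero variance (degenerate, excluded from the screen).
    """
    common = abundance_by_tissue.index.intersection(counts_by_tissue.index)
    a = abundance_by_tissue[common].astype(float)
    c = counts_by_tissue[common].astype(float)
    mask = np.isfinite(a) & (a > 0) & np.isfinite(c)
    a, c = a[mask], c[mask]
    if len(a) < min_pairs:
        return None
    x = np.log10(a.to_numpy())
    y = c.to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.debug("%s/%s: zero-variance axis, fit degenerate", protein_id, subject_id)
        return None
    fit = stats.linregress(x, y)
    return RegressionRecord(
        protein_id=protein_id,
        subject_id=subject_id,
        n_pairs=int(len(a)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def apply_tissue_merge(
    matrix: ProteinAbundanceMatrix, merge_map: dict[str, tuple[str, ...]]
) -> pd.DataFrame:
    """Average the abundance columns named in the merge map into their target
    tissue (e.g. jejunum + duodenum -> small intestine)."""
    values = matrix.values.copy()
    for target, sources in merge_map.items():
        present = [s for s in sources if s in values.columns]
        if present:
            values[target] = values[present].mean(axis=1)
            values = values.drop(columns=[s for s in present if s != target])
    return values


def fit_all(
    values: pd.DataFrame,
    counts: pd.Series,
    subject_id: str = "",
    min_pairs: int = 10,
) -> pd.DataFrame:
    records = []
    for protein in values.index:
        rec = fit_protein(
            values.loc[protein], counts, protein, subject_id, min_pairs=min_pairs
        )
        if rec is not None:
            records.append(rec)
    df = pd.DataFrame(
        [
            {
                "protein": r.protein_id,
                "subject": r.subject_id,
                "n_pairs": r.n_pairs,
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "p_value": r.p_value,
                "direction": r.direction,
            }
            for r in records
        ]
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def run_screen(
    matrix: ProteinAbundanceMatrix,
    counts_by_subject: dict[str, pd.Series],
    config: ScreenConfig | None = None,
    mode: str = "mouse",
) -> dict:
    """Proteome-wide screen over one (mouse) or several (human) subjects.

    mouse: a protein is a hit when p < p_max and R-squared > r2_min.
    human: the same per-subject significance must replicate in at least
    ``min_subjects`` subjects (no direction-consistency requirement by
    default). BH q-values are emitted alongside for transparency; the hit
    calls themselves use the raw thresholds.
    """
    config = config or ScreenConfig()
    values = apply_tissue_merge(matrix, config.tissue_merge_map)
    fits = []
    for subject, counts in counts_by_subject.items():
        overlap = values.columns.intersection(counts.index)
        if overlap.empty:
            raise ValidationError(f"no tissue overlap for subject {subject}")
        fits.append(fit_all(values, counts, subject, min_pairs=config.min_pairs))
    fits = pd.concat(fits, ignore_index=True) if fits else pd.DataFrame()
    if not len(fits):
        raise ValidationError("no protein produced enough measurement pairs")
    fits["significant"] = (fits["p_value"] < config.p_max) & (
        fits["r_squared"] > config.r2_min
    )
    if mode == "mouse":
        hits = fits[fits["significant"]].copy()
    elif mode == "human":
        per = fits[fits["significant"]].groupby("protein")["subject"].nunique()
        hit_proteins = set(per.index[per >= config.min_subjects])
        hits = fits[fits["significant"] & fits["protein"].isin(hit_proteins)].copy()
    else:
        raise ConfigurationError(f"unknown screen mode {mode!r}")
    hit_proteins = sorted(hits["protein"].unique())
    sign = hits.groupby("protein")["slope"].mean()
    n_pos = int((sign > 0).sum())
    n_neg = int((sign <= 0).sum())
    n_hits = len(hit_proteins)
    return {
        "fits": fits,
        "hits": hits,
        "hit_proteins": hit_proteins,
        "n_hits": n_hits,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "positive_fraction": n_pos / n_hits if n_hits else float("nan"),
    }


def null_r2_tail(n_pairs: int, r2_min: float = 0.4) -> float:
    """P(R-squared > r2_min) for independent data with n pairs:
    R-squared ~ Beta(1/2, (n-2)/2)."""
    return float(stats.beta.sf(r2_min, 0.5, (n_pairs - 2) / 2))


def calibrate_fp(
    matrix: ProteinAbundanceMatrix,
    counts: pd.Series,
    n_permutations: int = 100,
    seed: int = 0,
    config: ScreenConfig | None = None,
) -> dict:
    """Empirical false-positive fraction of the R-squared cutoff.

    For each permutation the tissue labels of the count vector are shuffled
    and every protein refit; the fraction of fits exceeding ``r2_min`` (and,
    separately, also passing ``p_max``) estimates the false-positive rate,
    with a binomial Monte-Carlo standard error attached.
    """
    config = config or ScreenConfig()
    if n_permutations < 100:
        raise ConfigurationError("need at least 100 permutations")
    values = apply_tissue_merge(matrix, config.tissue_merge_map)
    common = values.columns.intersection(counts.index)
    if len(common) < config.min_pairs:
        raise ValidationError(
            f"only {len(common)} shared tissues; need >= {config.min_pairs}"
        )
    rng = np.random.default_rng(seed)
    base = counts[common].to_numpy()
    n_fits = 0
    n_r2 = 0
    n_joint = 0
    for _ in range(n_permutations):
        perm = pd.Series(rng.permutation(base), index=common)
        fits = fit_all(values[common], perm, min_pairs=config.min_pairs)
        n_fits += len(fits)
        n_r2 += int((fits["r_squared"] > config.r2_min).sum())
        n_joint += int(
            ((fits["r_squared"] > config.r2_min) & (fits["p_value"] < config.p_max)).sum()
        )
    frac = n_r2 / n_fits if n_fits else float("nan")
    se = float(np.sqrt(frac * (1 - frac) / n_fits)) if n_fits else float("nan")
    return {
        "fp_fraction_r2": frac,
        "fp_fraction_joint": n_joint / n_fits if n_fits else float("nan"),
        "mc_standard_error": se,
        "n_fits": n_fits,
        "analytic_null": null_r2_tail(len(common), config.r2_min),
    }
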