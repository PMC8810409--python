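"""Core domain types shared by every analysis stage.

The catalog and matrix types are thin, validated wrappers around pandas
DataFrames; downstream modules consume only these types so that a catalog
read from disk and a catalog produced by the cohort simulator behave
identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mhcatlas")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Sentinel allele name for peptides without a binding-rank assignment.
UNASSIGNED = "unassigned"

#: Canonical catalog column order.
CATALOG_COLUMNS = [
    "sequence",
    "subject",
    "tissue",
    "allele",
    "rank_score",
    "intensity",
    "source_genes",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Well-formed input violates a domain invariant."""


class ConfigurationError(ValueError):
    """An analysis or simulation configuration is infeasible."""


def _check_sequences(seqs: pd.Series) -> None:
    bad = [s for s in seqs.unique() if not set(s) <= AMINO_ACIDS or s != s.upper()]
    if bad:
        raise ValidationError(
            f"peptide sequences outside the 20-letter amino-acid alphabet: {bad[:5]}"
        )


@dataclass(frozen=True)
class PeptideObservation:
    """One aggregated detection of a peptide in one tissue of one subject."""

    sequence: str
    subject: str
    tissue: str
    allele: str
    rank_score: float
    intensity: float
    source_genes: frozenset = frozenset()


class PeptideCatalog:
    """Multi-subject, multi-tissue table of MHC-I peptide observations.

    At most one aggregated observation exists per (sequence, tissue, subject);
    duplicates are collapsed by keeping the highest-intensity row (MS pulldowns
    are not normalized across replicates, so a rank-preserving, non-additive
    rule is used). ``source_genes`` holds a sorted tuple of gene identifiers.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        tissues: list[str] | None = None,
        subject_alleles: dict[str, tuple[str, ...]] | None = None,
        aggregate: bool = True,
    ):
        df = df.copy()
        missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"catalog missing mandatory columns: {missing}")
        df = df[CATALOG_COLUMNS]
        if len(df):
            _check_sequences(df["sequence"])
            nonpos = df["intensity"] <= 0
            if nonpos.any():
                raise ValidationError(
                    f"{int(nonpos.sum())} observation(s) with non-positive intensity "
                    f"(first at row {int(np.flatnonzero(nonpos)[0])})"
                )
            df["source_genes"] = df["source_genes"].map(
                lambda g: tuple(sorted(g)) if not isinstance(g, str) else tuple(sorted(g.split(";"))) if g else ()
            )
            if aggregate:
                df = self._aggregate(df)
        self._df = df.reset_index(drop=True)
        obs_tissues = list(dict.fromkeys(self._df["tissue"]))
        if tissues is None:
            tissues = sorted(obs_tissues)
        else:
            unknown = set(obs_tissues) - set(tissues)
            if unknown:
                raise ValidationError(f"tissues outside the vocabulary: {sorted(unknown)}")
        self.tissues: list[str] = list(tissues)
        self.subjects: list[str] = sorted(self._df["subject"].unique())
        if subject_alleles is None:
            subject_alleles = {
                s: tuple(
                    sorted(a for a in g["allele"].unique() if a != UNASSIGNED)
                )
                for s, g in self._df.groupby("subject")
            }
        self.subject_alleles: dict[str, tuple[str, ...]] = dict(subject_alleles)
        for s in self.subjects:
            if not self.subject_alleles.get(s):
                self.subject_alleles[s] = ()

    @staticmethod
    def _aggregate(df: pd.DataFrame) -> pd.DataFrame:
        keys = ["sequence", "tissue", "subject"]
        if df.duplicated(keys).any():
            n_before = len(df)
            idx = df.groupby(keys, sort=False)["intensity"].idxmax()
            df = df.loc[idx]
            logger.info(
                "aggregated %d duplicate observations (max-intensity rule)",
                n_before - len(df),
            )
        return df

    # -- accessors -------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        """The underlying observation table (read-only by convention)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def peptides(self) -> set[str]:
        return set(self._df["sequence"].unique())

    def presence(self, subject: str | None = None) -> pd.DataFrame:
        """Boolean peptide x tissue detection matrix (pooled over subjects
        unless one subject is named). Columns follow the tissue vocabulary."""
        df = self._df if subject is None else self._df[self._df["subject"] == subject]
        if not len(df):
            return pd.DataFrame(columns=self.tissues, dtype=bool)
        m = pd.crosstab(df["sequence"], df["tissue"]) > 0
        return m.reindex(columns=self.tissues, fill_value=False)

    def subset(self, mask: pd.Series) -> "PeptideCatalog":
        return PeptideCatalog(
            self._df[mask],
            tissues=self.tissues,
            subject_alleles=self.subject_alleles,
            aggregate=False,
        )

    def observations(self):
        for row in self._df.itertuples(index=False):
            yield PeptideObservation(
                row.sequence,
                row.subject,
                row.tissue,
                row.allele,
                row.rank_score,
                row.intensity,
                frozenset(row.source_genes),
            )


class _TissueMatrix:
    """Shared validation for identifier x tissue abundance matrices."""

    kind = "matrix"
    allow_missing = True
    require_positive = False

    def __init__(self, values: pd.DataFrame):
        values = values.copy()
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        dup_rows = values.index[values.index.duplicated()].unique().tolist()
        if dup_rows:
            raise ValidationError(f"duplicate {self.kind} identifiers: {dup_rows}")
        dup_cols = values.columns[values.columns.duplicated()].unique().tolist()
        if dup_cols:
            raise ValidationError(f"duplicate tissue identifiers: {dup_cols}")
        arr = values.to_numpy(dtype=float)
        finite = np.isfinite(arr)
        if not self.allow_missing and not finite.all():
            raise ValidationError(f"{self.kind} matrix contains missing values")
        if self.require_positive:
            if (arr[finite] <= 0).any():
                raise ValidationError(f"non-positive value in {self.kind} matrix")
        elif (arr[finite] < 0).any():
            raise ValidationError(f"negative value in {self.kind} matrix")
        self.values = values

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)


class ExpressionMatrix(_TissueMatrix):
    """Gene x tissue mRNA abundance in TPM; all values >= 0."""

    kind = "gene"

    @property
    def gene_ids(self) -> list[str]:
        return self.ids


class ProteinAbundanceMatrix(_TissueMatrix):
    """Protein x tissue label-free MS intensity; missing allowed, values > 0.

    ``molecular_weight`` optionally maps protein id -> mass in Da.
    """

    kind = "protein"
    require_positive = True

    def __init__(self, values: pd.DataFrame, molecular_weight: pd.Series | None = None):
        super().__init__(values)
        if molecular_weight is not None:
            molecular_weight = molecular_weight.astype(float)
            molecular_weight.index = molecular_weight.index.astype(str)
        self.molecular_weight = molecular_weight

    @property
    def protein_ids(self) -> list[str]:
        return self.ids


@dataclass
class GeneModel:
    """Strand-aware gene coordinates, 0-based half-open throughout."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        for start, end in self.exons:
            if start >= end:
                raise FormatError(
                    f"{self.gene_id}: exon interval [{start}, {end}) has start >= end"
                )
        merged = merge_intervals(self.exons)
        if len(merged) != len(self.exons):
            logger.warning("%s: overlapping exons merged into their union", self.gene_id)
        self.exons = merged


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted; touching intervals are merged."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


class ConservationTrack:
    """Per-base conservation probabilities per chromosome.

    Bases never covered by the source track are NaN (the explicit missing
    marker); all covered values lie in [0, 1].
    """

    def __init__(self, arrays: dict[str, np.ndarray]):
        for chrom, arr in arrays.items():
            vals = arr[np.isfinite(arr)]
            if len(vals) and ((vals < 0).any() or (vals > 1).any()):
                raise ValidationError(f"{chrom}: conservation score outside [0, 1]")
        self.arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.arrays[chrom]

    def region(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores over [start, end); raises if outside the track."""
        if chrom not in self.arrays:
            raise ValidationError(f"chromosome {chrom!r} not in track")
        arr = self.arrays[chrom]
        if start < 0 or end > len(arr) or start >= end:
            raise ValidationError(
                f"interval [{start}, {end}) outside track {chrom} of length {len(arr)}"
            )
        return arr[start:end]
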