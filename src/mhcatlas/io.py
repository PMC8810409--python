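"""Readers and writers for the plain-text formats the pipeline consumes.

Catalogs and matrices are tab-delimited UTF-8 with a header row; gene models
are BED-like (6 or 12 columns, 0-based half-open); conservation tracks are
bedGraph. Column names, missing-value tokens and the tissue synonym map are
configurable through :class:`IOConfig` (YAML-loadable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    UNASSIGNED,
    ConservationTrack,
    ExpressionMatrix,
    FormatError,
    GeneModel,
    PeptideCatalog,
    ProteinAbundanceMatrix,
    ValidationError,
)

logger = logging.getLogger("mhcatlas")

#: Spinal cord (mouse) and Myelon (human) denote the same organ; shipped as
#: the default synonym map and fully overridable from YAML.
DEFAULT_TISSUE_SYNONYMS = {"Myelon": "Spinal cord"}

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan")


@dataclass
class IOConfig:
    columns: dict[str, str] = field(
        default_factory=lambda: {
            "sequence": "sequence",
            "subject": "subject",
            "tissue": "tissue",
            "allele": "allele",
            "rank_score": "rank_score",
            "intensity": "intensity",
            "source_genes": "source_genes",
        }
    )
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS
    tissue_synonyms: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_SYNONYMS)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IOConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        cfg.columns.update(raw.get("columns", {}))
        if "missing_tokens" in raw:
            cfg.missing_tokens = tuple(raw["missing_tokens"])
        cfg.tissue_synonyms.update(raw.get("tissue_synonyms", {}))
        return cfg


def read_peptide_table(
    path: str | Path, species_mode: str = "human", config: IOConfig | None = None
) -> PeptideCatalog:
    """Load a peptide observation TSV into an aggregated catalog.

    ``species_mode`` is recorded for provenance only ("mouse" catalogs use a
    single pseudo-subject by convention); it does not change parsing.
    """
    config = config or IOConfig()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rename = {v: k for k, v in config.columns.items()}
    df = df.rename(columns=rename)
    mandatory = ["sequence", "subject", "tissue", "intensity"]
    for col in mandatory:
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing mandatory column {config.columns.get(col, col)!r}"
            )
    if "allele" not in df.columns:
        df["allele"] = UNASSIGNED
    if "rank_score" not in df.columns:
        df["rank_score"] = "nan"
    if "source_genes" not in df.columns:
        df["source_genes"] = ""
    df["allele"] = df["allele"].replace(list(config.missing_tokens), UNASSIGNED)
    df["tissue"] = df["tissue"].map(lambda t: config.tissue_synonyms.get(t, t))
    df["rank_score"] = pd.to_numeric(
        df["rank_score"].replace(list(config.missing_tokens), "nan")
    )
    try:
        df["intensity"] = pd.to_numeric(df["intensity"])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric intensity ({exc})") from exc
    df["source_genes"] = df["source_genes"].map(
        lambda s: tuple(sorted(g for g in s.split(";") if g)) if s else ()
    )
    logger.info("read %d peptide rows from %s (%s mode)", len(df), path, species_mode)
    return PeptideCatalog(df)


def write_peptide_table(
    catalog: PeptideCatalog, path: str | Path, config: IOConfig | None = None
) -> None:
    config = config or IOConfig()
    df = catalog.df.copy()
    df["source_genes"] = df["source_genes"].map(";".join)
    df = df.sort_values(["sequence", "subject", "tissue"], kind="mergesort")
    df = df.rename(columns=config.columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_matrix(
    path: str | Path, kind: str, config: IOConfig | None = None
) -> ExpressionMatrix | ProteinAbundanceMatrix:
    """Load an identifier x tissue TSV.

    ``kind`` is "expression" (TPM, no missing values allowed to be negative)
    or "protein" (label-free intensity, missing allowed, positive). A
    trailing ``molecular_weight`` column of a protein matrix, if present, is
    split off into the matrix's MW annotation.
    """
    config = config or IOConfig()
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(config.missing_tokens), keep_default_na=False)
    if kind == "expression":
        return ExpressionMatrix(df)
    if kind == "protein":
        mw = None
        if "molecular_weight" in df.columns:
            mw = df.pop("molecular_weight")
        return ProteinAbundanceMatrix(df, molecular_weight=mw)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(matrix, path: str | Path) -> None:
    df = matrix.values.sort_index()
    if getattr(matrix, "molecular_weight", None) is not None:
        df = df.copy()
        df["molecular_weight"] = matrix.molecular_weight
    df.to_csv(path, sep="\t", float_format="%.17g", na_rep="NA")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a BED6/BED12 gene file into strand-aware models.

    With 12 columns the block fields define the exons; with 6 the whole span
    is a single exon. The TSS is the strand-dependent 5' end of the record.
    """
    models = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected >= 6 BED columns")
        chrom, start, end, name, _score, strand = fields[:6]
        start, end = int(start), int(end)
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end")
        if len(fields) >= 12:
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
        else:
            exons = [(start, end)]
        tss = start if strand == "+" else end - 1
        models.append(GeneModel(name, chrom, strand, tss, exons))
    return models


def write_gene_models(models: list[GeneModel], path: str | Path) -> None:
    lines = []
    for m in sorted(models, key=lambda g: (g.chrom, g.exons[0][0], g.gene_id)):
        start = m.exons[0][0]
        end = m.exons[-1][1]
        sizes = ",".join(str(e - s) for s, e in m.exons)
        starts = ",".join(str(s - start) for s, e in m.exons)
        lines.append(
            "\t".join(
                [
                    m.chrom,
                    str(start),
                    str(end),
                    m.gene_id,
                    "0",
                    m.strand,
                    str(start),
                    str(end),
                    "0",
                    str(len(m.exons)),
                    sizes,
                    starts,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_conservation(path: str | Path) -> ConservationTrack:
    """Parse a bedGraph of per-base conservation probabilities.

    Uncovered bases are NaN; each chromosome array spans [0, max end seen).
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end")
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"{path}:{lineno}: score {value} outside [0, 1]")
        spans.setdefault(chrom, []).append((start, end, value))
    arrays = {}
    for chrom, items in spans.items():
        arr = np.full(max(e for _, e, _ in items), np.nan)
        for start, end, value in items:
            arr[start:end] = value
        arrays[chrom] = arr
    return ConservationTrack(arrays)


def write_conservation(track: ConservationTrack, path: str | Path) -> None:
    """Emit a run-length-merged bedGraph (NaN runs are simply not covered)."""
    lines = []
    for chrom in sorted(track.arrays):
        arr = track.arrays[chrom]
        start = None
        for i in range(len(arr) + 1):
            v = arr[i] if i < len(arr) else np.nan
            if start is not None and (i == len(arr) or v != arr[start]):
                if np.isfinite(arr[start]):
                    lines.append(f"{chrom}\t{start}\t{i}\t{arr[start]:.6g}")
                start = i if i < len(arr) else None
            elif start is None and i < len(arr):
                start = i
    Path(path).write_text("\n".join(lines) + "\n")
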