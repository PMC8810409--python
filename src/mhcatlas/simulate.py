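"""Synthetic multi-omics cohorts with planted, machine-readable ground truth.

The generator emulates the statistical structure of a tissue-based MHC-I
atlas: peptide detection probability rises with source-gene expression and
falls with binding rank; universal-class genes are highly expressed
everywhere and their designated peptides are presented in every tissue;
tissue-restricted genes are expressed (and present peptides) in one home
tissue; chosen (allele, tissue) cells get multiplied detection odds; and a
subset of proteins has abundance linearly tied to per-tissue peptide counts.
Every planted structure is reported in a :class:`SyntheticTruth` so recovery
can be measured without external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .landscape import filter_binders, count_per_tissue
from .types import (
    ConfigurationError,
    ConservationTrack,
    ExpressionMatrix,
    GeneModel,
    PeptideCatalog,
    ProteinAbundanceMatrix,
)

logger = logging.getLogger("mhcatlas")

#: Organ vocabulary the simulator draws from; the first six are the classic
#: high-yield core organs used for shared-peptide reporting.
TISSUE_NAMES = [
    "Spleen", "Bone Marrow", "Kidney", "Lung", "Liver", "Colon",
    "Thymus", "Lymph node", "Brain", "Heart", "Stomach", "Small intestine",
    "Pancreas", "Skin", "Muscle", "Testis", "Thyroid", "Spinal cord",
    "Adrenal gland", "Bladder", "Esophagus", "Prostate", "Uterus", "Tongue",
    "Trachea", "Gallbladder", "Cerebellum", "Mammary gland", "Ovary",
]

HLA_POOL = [
    "A*01:01", "A*02:01", "B*07:02", "B*08:01",
    "B*40:02", "C*03:04", "C*04:01", "C*07:02",
]

MOUSE_ALLELES = ("H2-Db", "H2-Kb")

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults are a desk-scale atlas: 19 tissues (the mouse atlas tissue
    count), three deeply sampled donors carrying 6 of 8 pooled class-I
    allotypes, and three conservation classes of genes whose per-base scores
    come from class-specific Beta distributions.
    """

    n_tissues: int = 19
    n_subjects: int = 3
    alleles_per_subject: int = 6
    allele_pool: tuple[str, ...] = tuple(HLA_POOL)

    n_universal_genes: int = 30
    n_tissue_restricted_genes: int = 40
    n_background_genes: int = 200
    peptides_per_gene_mean: float = 3.0

    # logistic detection model: logit p = intercept + expr_slope*log10(TPM+1)
    #                                   + rank_slope*rank + tissue effect
    detect_intercept: float = -2.2
    detect_expr_slope: float = 1.0
    detect_rank_slope: float = -0.8
    tissue_effect_sd: float = 0.5  # per-tissue sampling-depth offset (logit scale)
    background_expr_sd: float = 0.8  # log10 TPM spread of background genes

    # log10 intensity ~ Normal(mu + coef*log10(TPM+1), sigma)
    intensity_log_mu: float = 4.0
    intensity_expr_coef: float = 1.0
    intensity_log_sigma: float = 0.5

    # per-base conservation Beta parameters by gene class and feature
    universal_exon_beta: tuple[float, float] = (8.0, 2.0)
    universal_promoter_beta: tuple[float, float] = (8.0, 2.0)
    tissue_exon_beta: tuple[float, float] = (2.0, 8.0)
    tissue_promoter_beta: tuple[float, float] = (2.0, 8.0)
    background_exon_beta: tuple[float, float] = (2.0, 5.0)
    background_promoter_beta: tuple[float, float] = (2.0, 5.0)
    intergenic_beta: tuple[float, float] = (1.0, 4.0)

    n_planted_enriched: int = 2
    enriched_fold: float = 3.0

    n_planted_correlated: int = 20
    n_null_proteins: int = 500
    correlated_intercept: float = 200.0
    correlated_slope: float = 20.0
    correlated_noise_sd: float = 30.0

    # gene geometry on the single pseudo-chromosome
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 500
    gene_spacing: int = 5500
    chrom: str = "chrS"

    species_mode: str = "human"
    seed: int = 0

    @classmethod
    def mouse(cls, **overrides) -> "CohortConfig":
        """Single-strain configuration: one pooled subject, two alleles."""
        base = dict(
            n_subjects=1,
            alleles_per_subject=2,
            allele_pool=MOUSE_ALLELES,
            species_mode="mouse",
        )
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.n_tissues < 1 or self.n_tissues > len(TISSUE_NAMES):
            raise ConfigurationError(
                f"n_tissues must be in [1, {len(TISSUE_NAMES)}]"
            )
        if self.alleles_per_subject > len(self.allele_pool):
            raise ConfigurationError("alleles_per_subject exceeds the allele pool")
        if self.n_planted_enriched > len(self.allele_pool) * self.n_tissues:
            raise ConfigurationError(
                "more planted enriched pairs than allele x tissue cells"
            )
        for name in (
            "n_tissues", "n_subjects", "n_universal_genes",
            "n_tissue_restricted_genes", "n_background_genes",
            "n_planted_enriched", "n_planted_correlated", "n_null_proteins",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted labels for every recoverable structure in a cohort."""

    universal_peptides: set[str] = field(default_factory=set)
    tissue_specific_peptides: dict[str, str] = field(default_factory=dict)
    enriched_pairs: set[tuple[str, str, str, float]] = field(default_factory=set)
    correlated_proteins: dict[str, tuple[int, float]] = field(default_factory=dict)
    gene_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        overlap = self.universal_peptides & set(self.tissue_specific_peptides)
        if overlap:
            raise ConfigurationError(
                f"peptides both universal and tissue-specific: {sorted(overlap)[:3]}"
            )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _random_sequences(rng: np.random.Generator, n: int) -> list[str]:
    lengths = rng.choice([8, 9, 10, 11, 12], size=n, p=[0.10, 0.40, 0.25, 0.15, 0.10])
    seen: set[str] = set()
    out = []
    for length in lengths:
        while True:
            seq = "".join(rng.choice(_AA, size=int(length)))
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
                break
    return out


def generate_cohort(config: CohortConfig):
    """Generate one cohort.

    Returns (catalog, expression, proteins, gene_models, track, truth).
    Identical configs (same seed) yield byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tissues = TISSUE_NAMES[: config.n_tissues]

    if config.species_mode == "mouse":
        subjects = ["mouse"]
        subject_alleles = {"mouse": tuple(sorted(config.allele_pool[: config.alleles_per_subject]))}
    else:
        subjects = [f"AUT-DN{i + 11:02d}" for i in range(config.n_subjects)]
        subject_alleles = {
            s: tuple(
                sorted(rng.choice(config.allele_pool, size=config.alleles_per_subject, replace=False))
            )
            for s in subjects
        }
    carriers: dict[str, list[str]] = {}
    for s, alleles in subject_alleles.items():
        for a in alleles:
            carriers.setdefault(a, []).append(s)
    shared_alleles = sorted(a for a, subs in carriers.items() if len(subs) >= 2) or sorted(carriers)

    # ---- genes and expression -------------------------------------------
    gene_class: dict[str, str] = {}
    genes: list[str] = []
    for i in range(config.n_universal_genes):
        g = f"GU{i + 1:04d}"
        genes.append(g)
        gene_class[g] = "universal-source"
    home_tissue: dict[str, str] = {}
    for i in range(config.n_tissue_restricted_genes):
        g = f"GT{i + 1:04d}"
        genes.append(g)
        gene_class[g] = "tissue-restricted"
        home_tissue[g] = tissues[i % len(tissues)]
    for i in range(config.n_background_genes):
        g = f"GB{i + 1:04d}"
        genes.append(g)
        gene_class[g] = "background"

    expr = np.empty((len(genes), len(tissues)))
    for gi, g in enumerate(genes):
        cls = gene_class[g]
        if cls == "universal-source":
            expr[gi] = 10 ** (2.5 + 0.3 * rng.standard_normal(len(tissues)))
        elif cls == "tissue-restricted":
            low = 10 ** (0.2 + 0.3 * rng.standard_normal(len(tissues)))
            low[tissues.index(home_tissue[g])] = 10 ** (2.5 + 0.3 * rng.standard_normal())
            expr[gi] = low
        else:
            # one expression level per gene plus mild tissue scatter, so that
            # detection breadth genuinely tracks expression level
            level = 1.0 + config.background_expr_sd * rng.standard_normal()
            expr[gi] = 10 ** (level + 0.2 * rng.standard_normal(len(tissues)))
    expression = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=tissues))

    # ---- peptides --------------------------------------------------------
    pep_rows = []  # (sequence, gene, allele, rank, kind)
    for g in genes:
        n_pep = 1 + rng.poisson(max(config.peptides_per_gene_mean - 1, 0))
        seqs = _random_sequences(rng, n_pep)
        for j, seq in enumerate(seqs):
            cls = gene_class[g]
            if cls == "universal-source" and j == 0:
                kind = "universal"
                allele = shared_alleles[int(rng.integers(len(shared_alleles)))]
                rank = rng.uniform(0.05, 1.95)
            elif cls == "tissue-restricted" and j == 0:
                kind = "tissue_specific"
                allele = sorted(carriers)[int(rng.integers(len(carriers)))]
                rank = rng.uniform(0.05, 1.95)
            else:
                kind = "background"
                allele = sorted(carriers)[int(rng.integers(len(carriers)))]
                rank = rng.uniform(0.0, 5.0) + 1e-9
            pep_rows.append((seq, g, allele, rank, kind))
    # distinct sequences across genes
    all_seqs = [r[0] for r in pep_rows]
    if len(set(all_seqs)) != len(all_seqs):
        seen: set[str] = set()
        fixed = []
        for seq, g, allele, rank, kind in pep_rows:
            while seq in seen:
                seq = _random_sequences(rng, 1)[0]
            seen.add(seq)
            fixed.append((seq, g, allele, rank, kind))
        pep_rows = fixed

    # ---- planted allele enrichments -------------------------------------
    truth_pairs: set[tuple[str, str, str, float]] = set()
    planted_cells: set[tuple[str, str]] = set()
    pool = [(a, t) for a in shared_alleles for t in tissues]
    if config.n_planted_enriched > len(pool):
        raise ConfigurationError("more planted pairs than plantable allele x tissue cells")
    if config.n_planted_enriched:
        idx = rng.choice(len(pool), size=config.n_planted_enriched, replace=False)
        for k in idx:
            a, t = pool[int(k)]
            planted_cells.add((a, t))
            for s in carriers[a]:
                truth_pairs.add((s, a, t, config.enriched_fold))

    # ---- detection and intensities --------------------------------------
    tissue_eff = config.tissue_effect_sd * rng.standard_normal(len(tissues))
    log_expr = np.log10(expr + 1.0)
    gene_index = {g: i for i, g in enumerate(genes)}
    obs = []
    truth = SyntheticTruth(gene_class=gene_class, enriched_pairs=truth_pairs)
    for seq, g, allele, rank, kind in pep_rows:
        gi = gene_index[g]
        for s in carriers[allele]:
            logit = (
                config.detect_intercept
                + config.detect_expr_slope * log_expr[gi]
                + config.detect_rank_slope * rank
                + tissue_eff
            )
            p = _sigmoid(logit)
            # planted fold multiplies the detection probability (saturating
            # at 1) so the allele's expected count scales by ~fold
            boost = np.array(
                [config.enriched_fold if (allele, t) in planted_cells else 1.0 for t in tissues]
            )
            u = rng.random(len(tissues))
            detected = u < np.minimum(p * boost, 1.0)
            if kind == "universal":
                detected[:] = True
            elif kind == "tissue_specific":
                detected[:] = False
                detected[tissues.index(home_tissue[g])] = True
            log_int = (
                config.intensity_log_mu
                + config.intensity_expr_coef * log_expr[gi]
                + config.intensity_log_sigma * rng.standard_normal(len(tissues))
            )
            for ti, t in enumerate(tissues):
                if detected[ti]:
                    obs.append(
                        {
                            "sequence": seq,
                            "subject": s,
                            "tissue": t,
                            "allele": allele,
                            "rank_score": rank,
                            "intensity": 10 ** log_int[ti],
                            "source_genes": (g,),
                        }
                    )
        if kind == "universal":
            truth.universal_peptides.add(seq)
        elif kind == "tissue_specific":
            truth.tissue_specific_peptides[seq] = home_tissue[g]
    catalog = PeptideCatalog(
        pd.DataFrame(obs), tissues=tissues, subject_alleles=subject_alleles
    )

    # ---- gene models and conservation track ------------------------------
    models = []
    offset = 3000
    gene_len = config.exons_per_gene * config.exon_length + (
        config.exons_per_gene - 1
    ) * config.intron_length
    for i, g in enumerate(genes):
        strand = "+" if i % 2 == 0 else "-"
        exons = [
            (
                offset + k * (config.exon_length + config.intron_length),
                offset + k * (config.exon_length + config.intron_length) + config.exon_length,
            )
            for k in range(config.exons_per_gene)
        ]
        tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
        models.append(GeneModel(g, config.chrom, strand, tss, exons))
        offset += config.gene_spacing
    genome_len = offset + 3000
    arr = rng.beta(*config.intergenic_beta, size=genome_len)
    beta_by_class = {
        "universal-source": (config.universal_exon_beta, config.universal_promoter_beta),
        "tissue-restricted": (config.tissue_exon_beta, config.tissue_promoter_beta),
        "background": (config.background_exon_beta, config.background_promoter_beta),
    }
    from .conservation import promoter_region

    for m in models:
        exon_beta, prom_beta = beta_by_class[gene_class[m.gene_id]]
        for s0, e0 in m.exons:
            arr[s0:e0] = rng.beta(*exon_beta, size=e0 - s0)
        p0, p1 = promoter_region(m)
        p1 = min(p1, genome_len)
        arr[p0:p1] = rng.beta(*prom_beta, size=p1 - p0)
    track = ConservationTrack({config.chrom: arr})

    # ---- protein abundances ---------------------------------------------
    counts = count_per_tissue(filter_binders(catalog)).astype(float)
    prot_rows = {}
    for i in range(config.n_planted_correlated):
        pid = f"PC{i + 1:04d}"
        sign = 1 if i % 2 == 0 else -1
        c = counts.to_numpy()
        base = c if sign > 0 else (c.max() + c.min() - c)
        vals = (
            config.correlated_intercept
            + config.correlated_slope * base
            + config.correlated_noise_sd * rng.standard_normal(len(c))
        )
        prot_rows[pid] = np.clip(vals, 1.0, None)
        truth.correlated_proteins[pid] = (sign, config.correlated_slope)
    for i in range(config.n_null_proteins):
        pid = f"PN{i + 1:04d}"
        prot_rows[pid] = 10 ** (2.0 + 0.5 * rng.standard_normal(len(tissues)))
    prot_df = pd.DataFrame(prot_rows, index=tissues).T
    mw = pd.Series(
        10 ** (4.7 + 0.2 * rng.standard_normal(len(prot_df))), index=prot_df.index
    )
    proteins = ProteinAbundanceMatrix(prot_df, molecular_weight=mw)

    return catalog, expression, proteins, models, track, truth


def generate_null_screen(
    n_proteins: int, n_tissues: int, seed: int = 0
) -> tuple[ProteinAbundanceMatrix, pd.Series]:
    """Independent pseudo-proteins for false-positive calibration.

    Abundances (lognormal) and per-tissue peptide counts (uniform integers)
    are statistically independent, mimicking a randomized dataset of the
    same shape as the real screen input.
    """
    if n_tissues < 3:
        raise ConfigurationError("need at least 3 tissues")
    rng = np.random.default_rng(seed)
    tissues = [f"T{i + 1:02d}" for i in range(n_tissues)]
    counts = pd.Series(rng.integers(100, 1000, size=n_tissues), index=tissues, dtype=float)
    if n_proteins == 0:
        return (
            ProteinAbundanceMatrix(pd.DataFrame(index=[], columns=tissues, dtype=float)),
            counts,
        )
    vals = 10 ** (2.0 + 0.5 * rng.standard_normal((n_proteins, n_tissues)))
    matrix = ProteinAbundanceMatrix(
        pd.DataFrame(vals, index=[f"N{i + 1:05d}" for i in range(n_proteins)], columns=tissues)
    )
    return matrix, counts


# ---- persistence ---------------------------------------------------------


def write_cohort(outdir: str | Path, catalog, expression, proteins, models, track, truth, config=None) -> dict:
    """Serialize a cohort to the same plain-text formats core IO reads.

    Returns the path map. Truth tables are TSV; the config, when given, is
    recorded as YAML for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": outdir / "peptides.tsv",
        "expression": outdir / "expression.tsv",
        "proteins": outdir / "proteins.tsv",
        "genes": outdir / "genes.bed",
        "conservation": outdir / "conservation.bedGraph",
        "truth_peptides": outdir / "truth_peptides.tsv",
        "truth_pairs": outdir / "truth_enriched_pairs.tsv",
        "truth_proteins": outdir / "truth_correlated_proteins.tsv",
        "truth_genes": outdir / "truth_gene_classes.tsv",
    }
    mio.write_peptide_table(catalog, paths["peptides"])
    mio.write_matrix(expression, paths["expression"])
    mio.write_matrix(proteins, paths["proteins"])
    mio.write_gene_models(models, paths["genes"])
    mio.write_conservation(track, paths["conservation"])
    rows = [{"peptide": p, "label": "universal", "tissue": ""} for p in sorted(truth.universal_peptides)]
    rows += [
        {"peptide": p, "label": "tissue_specific", "tissue": t}
        for p, t in sorted(truth.tissue_specific_peptides.items())
    ]
    pd.DataFrame(rows, columns=["peptide", "label", "tissue"]).to_csv(
        paths["truth_peptides"], sep="\t", index=False
    )
    pd.DataFrame(
        sorted(truth.enriched_pairs), columns=["subject", "allele", "tissue", "fold"]
    ).to_csv(paths["truth_pairs"], sep="\t", index=False)
    pd.DataFrame(
        [(p, s, b) for p, (s, b) in sorted(truth.correlated_proteins.items())],
        columns=["protein", "sign", "slope"],
    ).to_csv(paths["truth_proteins"], sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.gene_class.items()), columns=["gene", "class"]
    ).to_csv(paths["truth_genes"], sep="\t", index=False)
    if config is not None:
        cfg = asdict(config)
        cfg["allele_pool"] = list(cfg["allele_pool"])
        (outdir / "cohort_config.yaml").write_text(yaml.safe_dump(cfg))
        paths["config"] = outdir / "cohort_config.yaml"
    return {k: str(v) for k, v in paths.items()}
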