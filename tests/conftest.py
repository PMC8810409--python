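import pandas as pd
import pytest
from hypothesis import settings

from mhcatlas.landscape import filter_binders
from mhcatlas.simulate import CohortConfig, generate_cohort
from mhcatlas.types import PeptideCatalog

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_catalog(rows, tissues=None, subject_alleles=None):
    """Build a small catalog from (sequence, subject, tissue, allele, rank,
    intensity, genes) tuples; trailing fields may be omitted."""
    records = []
    for r in rows:
        r = list(r) + [None] * (7 - len(r))
        records.append(
            {
                "sequence": r[0],
                "subject": r[1] or "S1",
                "tissue": r[2],
                "allele": r[3] or "A*01:01",
                "rank_score": r[4] if r[4] is not None else 0.5,
                "intensity": r[5] if r[5] is not None else 100.0,
                "source_genes": tuple(r[6]) if r[6] else (),
            }
        )
    return PeptideCatalog(
        pd.DataFrame(records), tissues=tissues, subject_alleles=subject_alleles
    )


@pytest.fixture(scope="session")
def cohort():
    """Default human-style cohort with planted structures (seed 1)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def filtered(cohort):
    catalog = cohort[0]
    return filter_binders(catalog)


@pytest.fixture(scope="session")
def mouse_cohort():
    return generate_cohort(CohortConfig.mouse(seed=3))
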