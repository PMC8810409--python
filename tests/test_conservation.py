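"""Universal peptide selection and sliding-window conservation scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mhcatlas import conservation as cons
from mhcatlas.types import ConservationTrack, GeneModel, ValidationError
from tests.conftest import make_catalog

_AA = "ACDEFGHIKLMNPQRSTVWY"
PEP = [_AA[i // 20] + _AA[i % 20] + "CDEFGHI" for i in range(150)]  # unique 9-mers


class TestSelectUniversalMouse:
    def test_all_tissues_required(self):
        tissues = [f"T{i:02d}" for i in range(19)]
        rows = [(PEP[0], "mouse", t) for t in tissues]
        rows += [(PEP[1], "mouse", t) for t in tissues[:18]]
        cat = make_catalog(
            rows,
            tissues=tissues,
            subject_alleles={"mouse": ("H2-Db", "H2-Kb")},
        )
        sel = cons.select_universal(cat, "mouse")
        assert sel.peptides == {PEP[0]}

    def test_subject_specific_alleles_rejected(self):
        rows = [(PEP[0], "D1", "T1"), (PEP[1], "D2", "T1")]
        cat = make_catalog(
            rows, subject_alleles={"D1": ("A*01:01",), "D2": ("B*07:02",)}
        )
        with pytest.raises(ValidationError, match="allele set"):
            cons.select_universal(cat, "mouse")

    def test_planted_fraction_exact(self, mouse_cohort):
        from mhcatlas.landscape import filter_binders

        catalog, *_, truth = mouse_cohort
        f = filter_binders(catalog)
        sel = cons.select_universal(f, "mouse")
        assert sel.peptides == truth.universal_peptides
        assert sel.fraction == len(truth.universal_peptides) / len(f.peptides)


class TestSelectUniversalHuman:
    def _catalog(self, rows):
        return make_catalog(
            rows,
            subject_alleles={
                "D1": ("A*01:01", "B*07:02"),
                "D2": ("A*01:01", "C*03:04"),
                "D3": ("B*07:02",),
            },
        )

    def test_c1_all_tissues_of_two_deep_donors(self):
        tissues = [f"T{i:02d}" for i in range(14)]
        rows = []
        for donor in ("D1", "D2"):
            rows += [(PEP[0], donor, t, "A*01:01") for t in tissues]
            rows += [(PEP[1], donor, t, "A*01:01") for t in tissues[:5]]
        sel = cons.select_universal(self._catalog(rows), "human", top_k=1)
        crit = sel.criteria
        assert crit.loc[PEP[0], "c1_all_tissues_two_donors"]
        assert PEP[1] not in crit.index or not crit.loc[PEP[1], "c1_all_tissues_two_donors"]

    def test_shallow_donors_excluded(self):
        # only 5 tissues sampled: no donor passes the depth floor
        rows = [(PEP[0], "D1", f"T{i}", "A*01:01") for i in range(5)]
        sel = cons.select_universal(self._catalog(rows), "human")
        assert sel.peptides == set()

    def test_c2_all_samples_of_assigned_allele(self):
        tissues = [f"T{i:02d}" for i in range(14)]
        rows = [(PEP[0], "D1", t, "B*07:02") for t in tissues]
        rows += [(PEP[0], "D3", t, "B*07:02") for t in tissues]
        # D3 samples the same tissues; B*07:02 occurs in every (D1, D3) sample
        rows += [(PEP[1], "D1", tissues[0], "B*07:02")]
        sel = cons.select_universal(self._catalog(rows), "human", top_k=1)
        assert sel.criteria.loc[PEP[0], "c2_all_allele_samples"]

    def test_c3_rank_ties_all_included(self):
        tissues = [f"T{i:02d}" for i in range(14)]
        rows = []
        # two clear leaders, then three peptides tied at the k-th rank
        for p in PEP[:2]:
            rows += [(p, "D1", t, "A*01:01") for t in tissues]
        for p in PEP[2:5]:
            rows += [(p, "D1", t, "A*01:01") for t in tissues[:6]]
        rows += [(PEP[5], "D1", tissues[0], "A*01:01")]
        sel = cons.select_universal(self._catalog(rows), "human", top_k=3)
        c3 = set(sel.criteria.index[sel.criteria["c3_top_frequency"]])
        assert set(PEP[:5]) <= c3  # 2 leaders + 3 tied at rank 3 -> 5 selected
        assert sel.n_c3_ties == 2

    def test_top100_tie_expands_selection(self):
        tissues = [f"T{i:02d}" for i in range(14)]
        rows = []
        for i, p in enumerate(PEP[:99]):  # frequencies 99 descending
            rows += [(p, "D1", t, "A*01:01") for t in tissues[: min(14, 99 - i)]]
        for p in PEP[99:102]:  # three peptides tied at rank 100
            rows += [(p, "D1", t, "A*01:01") for t in tissues[:1]]
        sel = cons.select_universal(self._catalog(rows), "human", top_k=100)
        c3 = set(sel.criteria.index[sel.criteria["c3_top_frequency"]])
        assert len(c3) == 102

    def test_universal_recall_on_cohort(self, filtered, cohort):
        truth = cohort[5]
        sel = cons.select_universal(filtered, "human")
        recall = len(sel.peptides & truth.universal_peptides) / len(truth.universal_peptides)
        assert recall >= 0.9


class TestPromoterRegion:
    @pytest.mark.parametrize(
        "strand, tss, expected",
        [("+", 10_000, (8000, 10_200)), ("-", 10_000, (9800, 12_000)), ("+", 500, (0, 700))],
    )
    def test_strand_aware_with_clipping(self, strand, tss, expected):
        gene = GeneModel("G", "chr1", strand, tss, exons=[(tss, tss + 10)])
        assert cons.promoter_region(gene) == expected


class TestRegionConservation:
    def test_constant_track(self):
        track = ConservationTrack({"c": np.full(50, 0.3)})
        assert cons.region_conservation(track, "c", (0, 50)).score == pytest.approx(0.3)

    def test_fourteen_bp_brute_force(self):
        values = np.array([0.0, 0.0] + [1.0] * 12)
        track = ConservationTrack({"c": values})
        rs = cons.region_conservation(track, "c", (0, 14))
        assert rs.score == pytest.approx(1.0)  # window means 10/12, 11/12, 1.0

    def test_short_region_mean_rule(self):
        track = ConservationTrack({"c": np.full(8, 0.5)})
        assert cons.region_conservation(track, "c", (0, 8)).score == pytest.approx(0.5)

    def test_fully_missing_region_flagged(self):
        track = ConservationTrack({"c": np.full(30, np.nan)})
        rs = cons.region_conservation(track, "c", (0, 30))
        assert rs.missing and np.isnan(rs.score)

    def test_windows_with_gaps_skipped(self):
        values = np.concatenate([np.full(12, 0.9), [np.nan], np.full(12, 0.1)])
        track = ConservationTrack({"c": values})
        # only the two gap-free windows are eligible; the high one wins
        assert cons.region_conservation(track, "c", (0, 25)).score == pytest.approx(0.9)

    def test_outside_track_rejected(self):
        track = ConservationTrack({"c": np.full(10, 0.5)})
        with pytest.raises(ValidationError):
            cons.region_conservation(track, "c", (5, 20))

    @given(
        hnp.arrays(
            float,
            st.integers(12, 60),
            elements=st.floats(0, 1, allow_nan=False),
        )
    )
    def test_exhaustive_window_oracle(self, values):
        track = ConservationTrack({"c": values})
        rs = cons.region_conservation(track, "c", (0, len(values)))
        best = max(
            float(np.mean(values[i : i + 12])) for i in range(len(values) - 11)
        )
        assert rs.score == pytest.approx(best, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.random(200)
        shifted = np.concatenate([np.full(37, np.nan), values])
        a = cons.region_conservation(ConservationTrack({"c": values}), "c", (0, 200))
        b = cons.region_conservation(ConservationTrack({"c": shifted}), "c", (37, 237))
        assert a.score == pytest.approx(b.score, abs=1e-12)


class TestCompareConservation:
    def _scores(self, promoter, exon):
        return pd.DataFrame(
            [("g", "promoter", s) for s in promoter] + [("g", "exon", s) for s in exon],
            columns=["gene", "feature", "score"],
        )

    def test_identical_multisets_coincide(self):
        s = self._scores([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        res = cons.compare_conservation(s, s)
        for feat in ("promoter", "exon"):
            assert res[feat]["p_value"] == pytest.approx(1.0)
            np.testing.assert_array_equal(
                res[feat]["cdf_universal"], res[feat]["cdf_tissue_specific"]
            )

    def test_exact_enumeration_p(self):
        hi = self._scores([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        lo = self._scores([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        res = cons.compare_conservation(hi, lo)
        assert res["promoter"]["p_value"] == pytest.approx(0.1)
        assert res["promoter"]["median_difference"] == pytest.approx(0.6)

    def test_empty_group_rejected(self):
        s = self._scores([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        empty = self._scores([], [])
        with pytest.raises(ValidationError):
            cons.compare_conservation(s, empty)

    def test_planted_conservation_gap(self, cohort):
        _, _, _, models, track, truth = cohort
        by_id = {m.gene_id: m for m in models}
        uni = [by_id[g] for g, c in truth.gene_class.items() if c == "universal-source"]
        ts = [by_id[g] for g, c in truth.gene_class.items() if c == "tissue-restricted"]
        res = cons.compare_conservation(
            cons.score_genes(track, uni), cons.score_genes(track, ts)
        )
        for feat in ("promoter", "exon"):
            assert res[feat]["p_value"] < 1e-10
            # universal CDF lies to the right (stochastic dominance)
            assert np.all(
                res[feat]["cdf_universal"] <= res[feat]["cdf_tissue_specific"] + 1e-12
            )


def test_universal_and_tissue_specific_disjoint(filtered):
    from mhcatlas.landscape import partition_specificity

    sel = cons.select_universal(filtered, "human")
    part = partition_specificity(filtered)
    universal_by_breadth = {
        p for p in sel.peptides if p in part.tissue_specific
    }
    # a peptide detected everywhere cannot be detected in exactly one tissue
    presence = filtered.presence()
    all_tissue_peps = set(presence.index[presence.all(axis=1)])
    assert not (all_tissue_peps & part.tissue_specific)
    assert universal_by_breadth <= sel.peptides  # c2/c3 may admit narrow peptides
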