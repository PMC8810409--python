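"""Binder filtering, counting, connectivity, specificity, PCA, trends."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mhcatlas import landscape as land
from mhcatlas.types import UNASSIGNED, ValidationError
from tests.conftest import make_catalog


class TestFilterBinders:
    def test_rank_bound_inclusive(self):
        cat = make_catalog([("AAAAKLAVA", "S1", "T1", None, 2.0, 10)])
        assert len(land.filter_binders(cat)) == 1

    def test_short_peptide_removed(self):
        cat = make_catalog([("AAAAKLA", "S1", "T1", None, 0.1, 10)])
        assert len(land.filter_binders(cat)) == 0

    def test_mixed_table_brute_force(self):
        rows = [
            ("AAAAKLAVA", "S1", "T1", None, 0.5, 10),   # keep
            ("AAAAKL", "S1", "T1", None, 0.5, 10),      # too short
            ("A" * 13, "S1", "T1", None, 0.5, 10),      # too long
            ("AAAAKLAVAL", "S1", "T1", None, 2.5, 10),  # rank too high
            ("AAAAKLAVALL", "S1", "T1", None, 1.9, 10),  # keep
            ("AAAAKLAVALLK", "S1", "T1", None, 2.0, 10),  # keep, both bounds
        ]
        kept = land.filter_binders(make_catalog(rows))
        assert len(kept) == 3

    def test_idempotent(self, filtered):
        twice = land.filter_binders(filtered)
        pd.testing.assert_frame_equal(twice.df, filtered.df)


class TestAssignBestAllele:
    @pytest.mark.parametrize(
        "ranks, expected",
        [
            ({"A*02:01": 0.3, "B*07:02": 1.8}, "A*02:01"),
            ({"X": 0.5, "Y": 0.5}, "X"),
            ({"B*08:01": 4.2}, "B*08:01"),
            ({}, UNASSIGNED),
            ({"A": float("nan")}, UNASSIGNED),
        ],
    )
    def test_argmin_with_lexicographic_ties(self, ranks, expected):
        assert land.assign_best_allele(ranks) == expected


class TestCountsAndConnectivity:
    def test_count_per_tissue_toy(self):
        cat = make_catalog(
            [("AAAAKLAVA", "S1", "T1"), ("AAAAKLAVA", "S1", "T2")],
            tissues=["T1", "T2", "T3"],
        )
        counts = land.count_per_tissue(cat)
        assert counts.to_dict() == {"T1": 1, "T2": 1, "T3": 0}

    def test_counts_hand_enumeration(self):
        rows = [
            ("AAAAKLAVA", "S1", "T1"), ("CCCCKLAVA", "S1", "T1"),
            ("CCCCKLAVA", "S1", "T2"), ("DDDDKLAVA", "S1", "T3"),
            ("EEEEKLAVA", "S1", "T3"), ("FFFFKLAVA", "S1", "T3"),
        ]
        counts = land.count_per_tissue(make_catalog(rows))
        assert counts.to_dict() == {"T1": 2, "T2": 1, "T3": 3}

    def test_connectivity_toy(self):
        rows = [
            ("AAAAKLAVA", "S1", "T1"),
            ("CCCCKLAVA", "S1", "T1"), ("CCCCKLAVA", "S1", "T2"),
            ("DDDDKLAVA", "S1", "T2"), ("DDDDKLAVA", "S1", "T3"),
        ]
        conn = land.connectivity(make_catalog(rows, tissues=["T1", "T2", "T3"]))
        assert conn.loc["T1", "T2"] == 1
        assert conn.loc["T2", "T3"] == 1
        assert conn.loc["T1", "T3"] == 0
        assert [conn.loc[t, t] for t in ["T1", "T2", "T3"]] == [1, 0, 0]

    def test_single_tissue_diagonal_is_total(self):
        rows = [("AAAAKLAVA", "S1", "T1"), ("CCCCKLAVA", "S1", "T1")]
        conn = land.connectivity(make_catalog(rows))
        assert conn.loc["T1", "T1"] == 2

    def test_all_shared_zero_diagonal(self):
        rows = [(s, "S1", t) for s in ("AAAAKLAVA", "CCCCKLAVA") for t in ("T1", "T2")]
        conn = land.connectivity(make_catalog(rows))
        assert (np.diag(conn) == 0).all()
        assert conn.loc["T1", "T2"] == 2

    def test_connectivity_equals_brute_force(self, filtered):
        conn = land.connectivity(filtered)
        presence = filtered.presence()
        by_tissue = {
            t: set(presence.index[presence[t]]) for t in filtered.tissues
        }
        for a, b in itertools.combinations(filtered.tissues, 2):
            assert conn.loc[a, b] == len(by_tissue[a] & by_tissue[b])
            assert conn.loc[a, b] == conn.loc[b, a]
        for t in filtered.tissues:
            others = set().union(*(by_tissue[o] for o in filtered.tissues if o != t))
            assert conn.loc[t, t] == len(by_tissue[t] - others)

    def test_sum_rule(self, filtered):
        conn = land.connectivity(filtered)
        presence = filtered.presence()
        breadth = presence.sum(axis=1)
        for t in filtered.tissues:
            total = int(presence[t].sum())
            seen_elsewhere = int((presence[t] & (breadth > 1)).sum())
            assert conn.loc[t, t] + seen_elsewhere == total


class TestSpecificityPartition:
    def test_fractions_on_toy(self):
        rows = [("AAAAKLAVA", "S1", "T1")] + [
            ("CCCCKLAVA", "S1", t) for t in ("T1", "T2", "T3")
        ]
        part = land.partition_specificity(make_catalog(rows))
        assert part.tissue_specific == {"AAAAKLAVA"}
        assert part.shared_core == {"CCCCKLAVA"}
        assert part.total == 2

    def test_no_specific_when_everything_shared(self):
        rows = [(s, "S1", t) for s in ("AAAAKLAVA", "CCCCKLAVA") for t in ("T1", "T2")]
        part = land.partition_specificity(make_catalog(rows))
        assert part.tissue_specific_fraction == 0.0

    def test_unknown_core_tissue_rejected(self, filtered):
        with pytest.raises(ValidationError):
            land.partition_specificity(filtered, core_tissues=["Atlantis"])

    @pytest.mark.parametrize(
        "count, total, expected",
        [
            (3212, 7665, 42.0),
            (961, 7665, 13.0),
            (5, 1000, 0.5),
            (19, 1000, 1.9),
            (25, 1000, 3.0),  # 2.5 rounds half-up
        ],
    )
    def test_percent_rounding(self, count, total, expected):
        assert land.round_percent(count, total) == expected


class TestPCA:
    def test_identical_tissues_identical_coordinates(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(6):
            seq = "ADE" + "".join(rng.choice(list("ACDEFGHIKL"), 6))
            inten = float(10 ** rng.uniform(2, 5))
            for t in ("T1", "T2", "T3"):
                rows.append((seq, "S1", t, None, 0.5, inten if t != "T3" else inten * 2))
        coords, shares = land.pca_tissues(make_catalog(rows))
        # PC2 is numerically degenerate here; identical tissues must agree to
        # eigensolver precision
        np.testing.assert_allclose(coords.loc["T1"], coords.loc["T2"], atol=1e-6)
        assert np.all(np.diff(shares) <= 1e-12)

    def test_explained_variance_matches_svd_oracle(self, filtered):
        coords, shares = land.pca_tissues(filtered)
        # independent oracle: SVD of the standardized peptide x tissue matrix
        df = filtered.df.copy()
        df["log_int"] = np.log10(df["intensity"])
        mat = (
            df.pivot_table(index="sequence", columns="tissue", values="log_int", aggfunc="max")
            .reindex(columns=filtered.tissues)
            .fillna(0.0)
            .to_numpy()
        )
        x = mat - mat.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1
        x /= sd
        sv = np.linalg.svd(x, compute_uv=False)
        var = sv**2 / len(x)
        np.testing.assert_allclose(shares[:2], (var / var.sum())[:2], atol=1e-9)

    def test_row_order_invariance(self, filtered):
        from mhcatlas.types import PeptideCatalog

        coords_a, _ = land.pca_tissues(filtered)
        shuffled = PeptideCatalog(
            filtered.df.sample(frac=1, random_state=0),
            tissues=filtered.tissues,
            subject_alleles=filtered.subject_alleles,
            aggregate=False,
        )
        coords_b, _ = land.pca_tissues(shuffled)
        np.testing.assert_allclose(np.abs(coords_a), np.abs(coords_b), atol=1e-9)

    def test_too_few_tissues_rejected(self):
        cat = make_catalog([("AAAAKLAVA", "S1", "T1"), ("CCCCKLAVA", "S1", "T2")])
        with pytest.raises(ValidationError):
            land.pca_tissues(cat)


class TestBreadthTrends:
    def test_monotone_toy_rho_one(self):
        rows = []
        for i, seq in enumerate(["AAAAKLAVA", "CCCCKLAVA", "DDDDKLAVA"]):
            for t in [f"T{j+1}" for j in range(i + 1)]:
                rows.append((seq, "S1", t, None, 0.5, 10.0 ** (i + 1)))
        res = land.breadth_vs_property(make_catalog(rows))
        assert res["rho_intensity"] == pytest.approx(1.0)

    def test_hand_computed_rank_correlation(self):
        # 6 peptides, breadths (1,1,2,2,3,3), intensities give log ranks
        breadths = [1, 1, 2, 2, 3, 3]
        intensities = [10, 40, 20, 80, 30, 160]
        rows = []
        for i, (b, inten) in enumerate(zip(breadths, intensities)):
            seq = "ACDEFGHIK"[:8] + "LMNPQRST"[i]
            for t in [f"T{j+1}" for j in range(b)]:
                rows.append((seq, "S1", t, None, 0.5, float(inten)))
        res = land.breadth_vs_property(make_catalog(rows))
        from scipy import stats

        expected = stats.spearmanr(breadths, np.log10(intensities)).statistic
        assert res["rho_intensity"] == pytest.approx(expected)

    def test_constant_breadth_flagged(self):
        rows = [("AAAAKLAVA", "S1", "T1"), ("CCCCKLAVA", "S1", "T1")]
        res = land.breadth_vs_property(make_catalog(rows))
        assert "flag" in res and np.isnan(res["rho_intensity"])

    def test_cohort_abundance_trend_positive(self, filtered):
        res = land.breadth_vs_property(filtered)
        assert res["rho_intensity"] > 0
        assert res["p_intensity"] < 0.01
        assert res["rho_rank"] < 0  # broader peptides are stronger binders


class TestCrossSpecies:
    def test_identical_counts_r2_one(self):
        a = pd.Series([1, 2, 3], index=["x", "y", "z"], dtype=float)
        assert land.cross_species_counts(a, a, {t: t for t in a.index}) == pytest.approx(1.0)

    def test_proportional_counts_r2_one(self):
        a = pd.Series([1, 2, 3], index=["x", "y", "z"], dtype=float)
        b = 2 * a
        assert land.cross_species_counts(a, b, {t: t for t in a.index}) == pytest.approx(1.0)

    def test_closed_form_pearson(self):
        a = pd.Series([1, 2, 3, 4], index=list("wxyz"), dtype=float)
        b = pd.Series([1, 3, 2, 4], index=list("wxyz"), dtype=float)
        r2 = land.cross_species_counts(a, b, {t: t for t in a.index})
        assert r2 == pytest.approx(0.64)

    def test_too_few_matches_rejected(self):
        a = pd.Series([1, 2], index=["x", "y"], dtype=float)
        with pytest.raises(ValidationError):
            land.cross_species_counts(a, a, {"x": "x", "y": "y"})


@given(
    st.lists(
        st.tuples(st.integers(0, 4), st.integers(0, 3)),
        min_size=1,
        max_size=30,
    )
)
def test_connectivity_matches_sets_property(assignments):
    """Random peptide-tissue incidence agrees with brute-force intersection."""
    peptides = [f"{'ACDEFGHIK'[:8]}{'LMNPQRSTV'[i]}" for i in range(5)]
    tissues = [f"T{j}" for j in range(4)]
    rows = sorted({(peptides[p], "S1", tissues[t]) for p, t in assignments})
    cat = make_catalog(rows, tissues=tissues)
    conn = land.connectivity(cat)
    membership = {}
    for p, _, t in rows:
        membership.setdefault(p, set()).add(t)
    for a, b in itertools.combinations(tissues, 2):
        expected = sum(1 for s in membership.values() if {a, b} <= s)
        assert conn.loc[a, b] == expected
    for t in tissues:
        expected = sum(1 for s in membership.values() if s == {t})
        assert conn.loc[t, t] == expected
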