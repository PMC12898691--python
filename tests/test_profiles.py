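"""Profile matrix construction, normalization, filtering and clade logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladecoev import (
    BitscoreTable,
    CladeMap,
    ConservationCriterion,
    ProfileError,
    ProfileMatrix,
    build_lnpp,
    conserved_genes,
    filter_all_zero_genes,
    normalize_npp,
    read_clade_map,
    read_profile_csv,
    restrict_to_clade,
)


class TestReadProfileCsv:
    def test_round_trip_identity(self, toy_matrix, tmp_path):
        path = tmp_path / "m.csv"
        toy_matrix.write_csv(path)
        back = read_profile_csv(path)
        assert back.genes == toy_matrix.genes
        assert back.species == toy_matrix.species
        np.testing.assert_allclose(back.values, toy_matrix.values)

    def test_lowercase_symbols_are_uppercased(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("gene,s1,s2,s3\nalad,1,0.5,0.2\nfech,0.9,0.4,0\nhmbs,1,1,1\n")
        m = read_profile_csv(path)
        assert m.genes == ["ALAD", "FECH", "HMBS"]

    def test_duplicate_gene_symbol_is_reported(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("gene,s1,s2\nFECH,1,0.5\nFECH,0.9,0.4\n")
        with pytest.raises(ProfileError, match="FECH"):
            read_profile_csv(path)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("gene,s1,s2\nALAD,1,oops\nFECH,0.9,0.4\n")
        with pytest.raises(ProfileError, match="oops.*ALAD.*s2"):
            read_profile_csv(path)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("")
        with pytest.raises(ProfileError, match="empty"):
            read_profile_csv(path)


class TestBuildLnpp:
    def _table(self):
        records = pd.DataFrame(
            [
                ("ALAD", "sp1", 200.0),
                ("ALAD", "sp2", 100.0),
                ("FECH", "sp1", 150.0),
            ],
            columns=["gene", "species", "bitscore"],
        )
        return BitscoreTable(records, {"ALAD": 200.0, "FECH": 300.0})

    def test_ratio_definition(self):
        m = build_lnpp(self._table(), ["ALAD", "FECH"], ["sp1", "sp2"])
        assert m.gene_row("ALAD")[1] == pytest.approx(0.5)
        assert m.gene_row("FECH")[0] == pytest.approx(0.5)

    def test_absent_record_yields_zero(self):
        m = build_lnpp(self._table(), ["ALAD", "FECH"], ["sp1", "sp2"])
        assert m.gene_row("FECH")[1] == 0.0

    def test_self_hit_ratio_is_one(self):
        m = build_lnpp(self._table(), ["ALAD"], ["sp1"])
        assert m.gene_row("ALAD")[0] == pytest.approx(1.0)

    def test_missing_self_hit_errors(self):
        with pytest.raises(ProfileError, match="UROD"):
            build_lnpp(self._table(), ["UROD"], ["sp1"])

    def test_negative_bitscore_errors(self):
        records = pd.DataFrame(
            [("ALAD", "sp1", -5.0)], columns=["gene", "species", "bitscore"]
        )
        with pytest.raises(ProfileError, match="negative"):
            BitscoreTable(records, {"ALAD": 100.0})

    def test_duplicate_hits_resolved_by_maximum(self):
        records = pd.DataFrame(
            [("ALAD", "sp1", 50.0), ("ALAD", "sp1", 80.0)],
            columns=["gene", "species", "bitscore"],
        )
        m = build_lnpp(BitscoreTable(records, {"ALAD": 100.0}), ["ALAD"], ["sp1"])
        assert m.gene_row("ALAD")[0] == pytest.approx(0.8)

    def test_ratio_invariant_to_uniform_bitscore_rescaling(self):
        t1 = self._table()
        records2 = t1.records.copy()
        records2.loc[records2["gene"] == "ALAD", "bitscore"] *= 7.0
        t2 = BitscoreTable(records2, {"ALAD": 7.0 * 200.0, "FECH": 300.0})
        m1 = build_lnpp(t1, ["ALAD", "FECH"], ["sp1", "sp2"])
        m2 = build_lnpp(t2, ["ALAD", "FECH"], ["sp1", "sp2"])
        np.testing.assert_allclose(m1.values, m2.values)

    def test_ceiling_clips_ratios(self):
        records = pd.DataFrame(
            [("ALAD", "sp1", 250.0)], columns=["gene", "species", "bitscore"]
        )
        m = build_lnpp(BitscoreTable(records, {"ALAD": 200.0}), ["ALAD"], ["sp1"])
        assert m.gene_row("ALAD")[0] == 1.0


class TestFilterAllZero:
    def test_single_exclusion(self):
        m = ProfileMatrix(
            ["A1", "B1", "C1"],
            ["s1", "s2"],
            np.array([[1.0, 0.5], [0.0, 0.0], [0.2, 0.0]]),
        )
        out, removed = filter_all_zero_genes(m)
        assert out.genes == ["A1", "C1"]
        assert removed == ["B1"]

    def test_noop_when_no_zero_genes(self, toy_matrix):
        out, removed = filter_all_zero_genes(toy_matrix)
        assert removed == []
        assert out.genes == toy_matrix.genes

    def test_idempotent_on_second_application(self, toy_matrix):
        once, _ = filter_all_zero_genes(toy_matrix)
        twice, removed = filter_all_zero_genes(once)
        assert removed == []
        np.testing.assert_array_equal(once.values, twice.values)

    def test_removed_matches_brute_force_scan(self, rng):
        values = rng.random((50, 20))
        values[values < 0.6] = 0.0
        zero_rows = rng.choice(50, size=7, replace=False)
        values[zero_rows] = 0.0
        genes = [f"G{i}" for i in range(50)]
        m = ProfileMatrix(genes, [f"s{j}" for j in range(20)], values)
        _, removed = filter_all_zero_genes(m)
        expected = [g for g, row in zip(genes, values) if all(v == 0 for v in row)]
        assert removed == expected

    def test_all_zero_matrix_errors(self):
        m = ProfileMatrix(["A1"], ["s1"], np.zeros((1, 1)))
        with pytest.raises(ProfileError, match="nothing left"):
            filter_all_zero_genes(m)


class TestNormalizeNpp:
    def test_constant_column_maps_to_zero(self, caplog):
        values = np.column_stack([np.full(5, 0.4), np.linspace(0.1, 0.9, 5)])
        m = ProfileMatrix([f"G{i}" for i in range(5)], ["s1", "s2"], values)
        out = normalize_npp(m)
        np.testing.assert_array_equal(out.values[:, 0], 0.0)
        assert out.variant == "NPP"

    def test_columns_are_standardized(self, rng):
        values = rng.random((20, 6))
        m = ProfileMatrix([f"G{i}" for i in range(20)], [f"s{j}" for j in range(6)], values)
        out = normalize_npp(m)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_hand_computed_log2_zscore_column(self):
        # frozen oracle: log2(v + 0.01) of {0, .2, .4, .6, .8}, then z-score
        values = np.column_stack(
            [np.array([0, 0.2, 0.4, 0.6, 0.8]), np.linspace(0.05, 0.95, 5)]
        )
        m = ProfileMatrix([f"G{i}" for i in range(5)], ["s1", "s2"], values)
        out = normalize_npp(m, floor_epsilon=0.01)
        expected = [-1.7148406307, -0.0045844678, 0.3712532127, 0.5944369342, 0.7537349516]
        np.testing.assert_allclose(out.values[:, 0], expected, atol=1e-9)

    def test_too_few_genes_errors(self):
        m = ProfileMatrix(["A1", "B1"], ["s1"], np.array([[0.1], [0.2]]))
        with pytest.raises(ProfileError, match="3 genes"):
            normalize_npp(m)


class TestRestrictToClade:
    def test_universal_clade_is_identity(self, toy_matrix, toy_clades):
        out = restrict_to_clade(toy_matrix, toy_clades, "Eukaryota")
        assert out.species == toy_matrix.species
        np.testing.assert_array_equal(out.values, toy_matrix.values)

    def test_subset_preserves_column_order(self, toy_matrix, toy_clades):
        out = restrict_to_clade(toy_matrix, toy_clades, "Fungi")
        assert out.species == ["sp3", "sp4"]

    def test_unknown_clade_lists_available(self, toy_matrix, toy_clades):
        with pytest.raises(ProfileError, match="Fungi"):
            restrict_to_clade(toy_matrix, toy_clades, "Plants")

    def test_no_overlap_errors(self, toy_matrix):
        clades = CladeMap({"other": {"Fungi"}})
        with pytest.raises(ProfileError, match="no species"):
            restrict_to_clade(toy_matrix, clades, "Fungi")

    def test_column_count_matches_set_intersection(self, rng):
        species = [f"s{j}" for j in range(30)]
        m = ProfileMatrix(["A1", "B1", "C1"], species, rng.random((3, 30)))
        members = set(rng.choice(species, size=11, replace=False)) | {"ghost"}
        clades = CladeMap({sp: {"X"} for sp in members})
        out = restrict_to_clade(m, clades, "X")
        assert out.n_species == len(members & set(species))

    def test_commutes_with_gene_subsetting(self, toy_matrix, toy_clades):
        a = restrict_to_clade(toy_matrix, toy_clades, "Fungi").subset_genes(["FECH"])
        b = restrict_to_clade(toy_matrix.subset_genes(["FECH"]), toy_clades, "Fungi")
        np.testing.assert_array_equal(a.values, b.values)


class TestConservedGenes:
    def test_all_zero_gene_excluded(self):
        m = ProfileMatrix(
            ["A1", "B1"], ["s1", "s2"], np.array([[0.0, 0.0], [0.5, 0.5]])
        )
        assert conserved_genes(m, ConservationCriterion(0.01, 0.1)) == ["B1"]

    def test_fully_conserved_gene_included(self):
        m = ProfileMatrix(["A1"], ["s1", "s2"], np.ones((1, 2)))
        assert conserved_genes(m, ConservationCriterion(0.9, 1.0)) == ["A1"]

    def test_counting_matches_brute_force(self, rng):
        values = rng.random((4, 10))
        genes = ["A1", "B1", "C1", "D1"]
        m = ProfileMatrix(genes, [f"s{j}" for j in range(10)], values)
        crit = ConservationCriterion(0.05, 0.2)
        expected = []
        for g, row in zip(genes, values):
            count = sum(1 for v in row if v > 0.05)
            if count / 10 >= 0.2:
                expected.append(g)
        assert conserved_genes(m, crit) == expected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        floor1=st.floats(0.0, 0.5),
        floor2=st.floats(0.0, 0.5),
        frac1=st.floats(0.0, 1.0),
        frac2=st.floats(0.0, 1.0),
        seed=st.integers(0, 1000),
    )
    def test_monotone_in_criterion(self, floor1, floor2, frac1, frac2, seed):
        """Raising value_floor or min_fraction never adds a gene."""
        values = np.random.default_rng(seed).random((8, 12))
        m = ProfileMatrix(
            [f"G{i}" for i in range(8)], [f"s{j}" for j in range(12)], values
        )
        lo = ConservationCriterion(min(floor1, floor2), min(frac1, frac2))
        hi = ConservationCriterion(max(floor1, floor2), max(frac1, frac2))
        assert set(conserved_genes(m, hi)) <= set(conserved_genes(m, lo))


class TestCladeMap:
    def test_universal_covers_all_species(self, toy_clades):
        assert toy_clades.members("Eukaryota") == {"sp1", "sp2", "sp3", "sp4"}

    def test_csv_round_trip(self, toy_clades, tmp_path):
        path = tmp_path / "clades.csv"
        toy_clades.write_csv(path)
        back = read_clade_map(path)
        assert back.clade_names == toy_clades.clade_names
        for clade in toy_clades.clade_names:
            assert back.members(clade) == toy_clades.members(clade)
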