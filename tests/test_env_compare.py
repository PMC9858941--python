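"""Top-k quadrants, gene annotation, DBVs and reranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import thigblup as tg
from conftest import ENV1, ENV2, make_genotypes


def effect_table(pct1, pct2, chroms=None, positions=None):
    m = len(pct1)
    df = pd.DataFrame(
        {
            "marker_id": [f"M{i+1}" for i in range(m)],
            "chromosome": chroms or ["1"] * m,
            "position": positions or [(i + 1) * 1000 for i in range(m)],
            f"u_{ENV1}": 1.0,
            f"u_{ENV2}": 1.0,
            f"var_{ENV1}": pct1,
            f"var_{ENV2}": pct2,
            f"pct_{ENV1}": pct1,
            f"pct_{ENV2}": pct2,
        }
    )
    return tg.SNPEffectTable(data=df)


class TestTopK:
    def test_identical_columns_full_overlap(self):
        pct = [5.0, 4.0, 3.0, 2.0, 1.0]
        cmp_ = tg.top_k(effect_table(pct, pct), k=2)
        assert cmp_.n_common == 2
        assert cmp_.n_different == 0
        assert set(cmp_.quadrant[cmp_.quadrant == "both"].index) == {"M1", "M2"}

    def test_opposing_rankings_hand_enumeration(self):
        cmp_ = tg.top_k(
            effect_table([5, 4, 3, 2, 1], [1, 2, 3, 4, 5]), k=2
        )
        assert cmp_.T_env1 == 4.0 and cmp_.T_env2 == 4.0
        assert cmp_.n_common == 0
        assert (cmp_.quadrant == "only_env1").sum() == 2
        assert (cmp_.quadrant == "only_env2").sum() == 2
        assert (cmp_.quadrant == "neither").sum() == 1

    def test_k_equals_table_size(self):
        pct = [5.0, 4.0, 3.0]
        cmp_ = tg.top_k(effect_table(pct, pct[::-1]), k=3)
        assert (cmp_.quadrant == "both").all()
        assert cmp_.T_env1 == min(pct)

    def test_set_counting_invariant(self, pipeline):
        cmp_ = tg.top_k(pipeline["effects"], k=50)
        only1 = (cmp_.quadrant == "only_env1").sum()
        only2 = (cmp_.quadrant == "only_env2").sum()
        assert cmp_.n_common + only1 == 50
        assert cmp_.n_common + only2 == 50
        assert only1 == only2

    def test_tie_at_kth_value_warns_and_is_deterministic(self):
        pct = [5.0, 3.0, 3.0, 3.0, 1.0]
        tab = effect_table(pct, pct, chroms=["2", "1", "1", "3", "1"],
                           positions=[100, 900, 200, 50, 10])
        with pytest.warns(UserWarning, match="tie"):
            cmp_ = tg.top_k(tab, k=2)
        # among the tied 3.0s, chromosome 1 position 200 (M3) wins
        assert set(cmp_.quadrant[cmp_.quadrant == "both"].index) == {"M1", "M3"}

    def test_per_chromosome_summary(self):
        tab = effect_table(
            [5, 4, 3, 2, 1], [5, 4, 3, 2, 1], chroms=["1", "1", "2", "2", "2"]
        )
        cmp_ = tg.top_k(tab, k=3)
        sub = cmp_.per_chromosome
        row = sub[(sub["env"] == ENV1) & (sub["chromosome"] == "1")].iloc[0]
        assert row["n_top_snps"] == 2 and row["summed_pct"] == 9.0
        row2 = sub[(sub["env"] == ENV1) & (sub["chromosome"] == "2")].iloc[0]
        assert row2["n_top_snps"] == 1 and row2["summed_pct"] == 3.0

    def test_too_few_markers_raise(self):
        with pytest.raises(ValueError, match="need at least"):
            tg.top_k(effect_table([1.0], [1.0]), k=2)


class TestAnnotateMarkers:
    @pytest.fixture
    def genes(self):
        return tg.GeneIntervalSet(
            data=pd.DataFrame(
                {
                    "gene": ["GENE1", "GENE2"],
                    "chromosome": ["1", "2"],
                    "start": [500_000, 1_000_000],
                    "end": [600_000, 1_200_000],
                }
            )
        )

    def marker(self, chrom, pos):
        return pd.DataFrame(
            {"marker_id": ["Mx"], "chromosome": [chrom], "position": [pos]}
        )

    def test_marker_inside_gene(self, genes):
        out = tg.annotate_markers(self.marker("1", 550_000), genes)
        row = out.iloc[0]
        assert row["gene"] == "GENE1"
        assert row["distance_bp"] == 0 and row["relation"] == "within"

    def test_marker_upstream_within_window(self, genes):
        out = tg.annotate_markers(self.marker("1", 400_000), genes, window=600_000)
        row = out.iloc[0]
        assert row["gene"] == "GENE1"
        assert row["distance_bp"] == 100_000
        assert row["annotation"] == "100 kb upstream"

    def test_marker_downstream(self, genes):
        out = tg.annotate_markers(self.marker("2", 1_395_000), genes)
        row = out.iloc[0]
        assert row["gene"] == "GENE2"
        assert row["distance_bp"] == 195_000
        assert row["annotation"] == "195 kb downstream"

    def test_no_gene_in_window_unannotated(self, genes):
        out = tg.annotate_markers(self.marker("1", 5_000_000), genes)
        assert pd.isna(out.iloc[0]["gene"])

    def test_chromosome_mismatch_unannotated(self, genes):
        out = tg.annotate_markers(self.marker("9", 550_000), genes)
        assert pd.isna(out.iloc[0]["gene"])


class TestComputeDbv:
    def test_hand_matrix_product(self):
        # centered dosages Z = [[1, -1], [0, 2]] via p = 0.5 per marker
        g = make_genotypes([[2, 0], [1, 3]])
        freq = tg.AlleleFrequencies(np.array([0.5, 0.5]), g.marker_ids)
        df = g.marker_map.copy()
        df[f"u_{ENV1}"] = [0.5, 0.25]
        df[f"u_{ENV2}"] = [0.5, 0.25]
        dbv = tg.compute_dbv(g, tg.SNPEffectTable(data=df), freq)
        np.testing.assert_allclose(dbv.data[f"dbv_{ENV1}"], [0.25, 0.5])

    def test_zero_effects_zero_dbv(self):
        g = make_genotypes([[0, 1], [2, 1]])
        freq = tg.allele_frequencies(g)
        df = g.marker_map.copy()
        df[f"u_{ENV1}"] = 0.0
        df[f"u_{ENV2}"] = 0.0
        dbv = tg.compute_dbv(g, tg.SNPEffectTable(data=df), freq)
        assert np.abs(dbv.data[[f"dbv_{ENV1}", f"dbv_{ENV2}"]].to_numpy()).max() == 0

    def test_marker_set_mismatch_lists_difference(self):
        g = make_genotypes([[0, 1], [2, 1]])
        freq = tg.allele_frequencies(g)
        df = g.marker_map.iloc[:1].copy()
        df[f"u_{ENV1}"] = 1.0
        df[f"u_{ENV2}"] = 1.0
        with pytest.raises(ValueError, match="M2"):
            tg.compute_dbv(g, tg.SNPEffectTable(data=df), freq)

    def test_round_trip_matches_gebv(self, pipeline):
        # blended full pipeline: DBV approximates GEBV up to the blend ridge
        g, eff, freq, gebv = (
            pipeline["g"], pipeline["effects"], pipeline["freq"], pipeline["gebv"],
        )
        dbv = tg.compute_dbv(g, eff, freq)
        a = np.column_stack([gebv.vector(e, g.animal_ids) for e in (ENV1, ENV2)])
        d = dbv.data[[f"dbv_{ENV1}", f"dbv_{ENV2}"]].to_numpy()
        assert np.corrcoef(a.ravel(), d.ravel())[0, 1] > 0.999


def dbv_table(v1, v2):
    n = len(v1)
    return tg.DBVTable(
        data=pd.DataFrame(
            {
                "animal_id": [f"A{i+1:03d}" for i in range(n)],
                f"dbv_{ENV1}": v1,
                f"dbv_{ENV2}": v2,
            }
        ),
        env_labels=(ENV1, ENV2),
    )


class TestRankCorrelations:
    def test_identical_dbvs_give_unit_rho_everywhere(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(40)
        rep = tg.rank_correlations(dbv_table(v, v.copy()))
        assert np.allclose(rep.data["spearman_rho"], 1.0)
        assert (rep.data["n_not_retained"] == 0).all()

    def test_reversed_dbvs_give_minus_one_on_all_animals(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(30)
        rep = tg.rank_correlations(dbv_table(v, -v))
        assert rep.data.loc[rep.data["fraction"] == 1.0, "spearman_rho"].iloc[0] == -1.0

    def test_matches_brute_force_spearman_formula(self):
        rng = np.random.default_rng(3)
        v1 = rng.standard_normal(10)
        v2 = rng.standard_normal(10)
        rep = tg.rank_correlations(dbv_table(v1, v2), fractions=(1.0,))
        r1 = sps.rankdata(v1)
        r2 = sps.rankdata(v2)
        d2 = np.sum((r1 - r2) ** 2)
        rho = 1 - 6 * d2 / (10 * (100 - 1))
        assert rep.data["spearman_rho"].iloc[0] == pytest.approx(rho, abs=1e-12)

    def test_selection_counts(self):
        # env1 top-2 = {A5, A4}; env2 top-2 = {A1, A2} -> none retained
        rep = tg.rank_correlations(
            dbv_table(
                [1, 2, 3, 4, 5, -1, -2, -3, -4, -5],
                [5, 4, 3, 2, 1, -1, -2, -3, -4, -5],
            ),
            fractions=(0.2, 1.0),
        )
        row = rep.data.iloc[0]
        assert row["n_selected"] == 2
        assert row["n_not_retained"] == 2

    def test_constant_dbvs_flagged_not_raised(self):
        rep = tg.rank_correlations(dbv_table([1.0] * 12, list(range(12))))
        assert rep.data["flagged"].any()
        assert rep.data.loc[rep.data["flagged"], "spearman_rho"].isna().all()

    def test_too_few_animals_raise(self):
        with pytest.raises(ValueError, match="at least 10"):
            tg.rank_correlations(dbv_table([1, 2, 3], [1, 2, 3]))


class TestPlotTables:
    def test_single_chromosome_cumulative_equals_position(self):
        tab = effect_table([3.0, 2.0, 1.0], [1.0, 2.0, 3.0])
        man = tg.manhattan_table(tab)
        np.testing.assert_array_equal(
            man["cumulative_position"], man["position"]
        )
        assert set(man["env"]) == {ENV1, ENV2}

    def test_cumulative_positions_offset_by_chromosome(self):
        tab = effect_table(
            [1, 1, 1, 1], [1, 1, 1, 1], chroms=["1", "1", "2", "2"],
            positions=[100, 200, 50, 80],
        )
        man = tg.manhattan_table(tab)
        chr2 = man[(man["chromosome"] == "2") & (man["env"] == ENV1)]
        np.testing.assert_array_equal(chr2["cumulative_position"], [250, 280])

    def test_quadrant_table_consistency(self, pipeline):
        eff = pipeline["effects"]
        cmp_ = tg.top_k(eff, k=50)
        qt = tg.quadrant_table(cmp_, eff)
        assert len(qt) == len(eff.data)
        assert (qt["quadrant"] == "both").sum() == cmp_.n_common
        back = qt.set_index("marker_id")["quadrant"]
        pd.testing.assert_series_equal(
            back.sort_index(), cmp_.quadrant.sort_index(), check_names=False
        )
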