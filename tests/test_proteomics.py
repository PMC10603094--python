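"""Differential-abundance pipeline: parsing, filtering, SAM statistic,
permutation FDR, classification, annotation, screens and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from scarmech.proteomics import (AbundanceMatrix, BUCKET_A_UP, BUCKET_B_UP,
                                 BUCKET_CONCORDANT, BUCKET_OTHER,
                                 annotate_matrisome, classify_regulation,
                                 cross_species_screen, filter_and_impute,
                                 load_protein_groups, ora_enrichment,
                                 permutation_fdr, sam_statistic,
                                 write_protein_groups, zscore_rows,
                                 _label_splits)


def _toy_tsv(path, rows):
    cols = ["Protein IDs", "Gene names",
            "LFQ intensity c1", "LFQ intensity c2", "LFQ intensity c3",
            "LFQ intensity l1", "LFQ intensity l2", "LFQ intensity l3",
            "Reverse", "Potential contaminant", "Only identified by site"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path


CONDS = {f"c{i}": "control" for i in (1, 2, 3)} | \
        {f"l{i}": "lesioned" for i in (1, 2, 3)}


class TestLoadProteinGroups:
    def test_toy_table_parses(self, tmp_path):
        p = _toy_tsv(tmp_path / "pg.tsv", [
            ["P1", "ga", 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, "", "", ""],
            ["P2", "gb", 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, "+", "", ""],
            ["P3", "gc", 0.0, 2.0, 2.0, 2.0, 2.0, 2.0, "", "", ""],
        ])
        m = load_protein_groups(p, CONDS)
        assert len(m.intensities) == 3
        assert m.intensities.loc["P1", "c2"] == pytest.approx(2.0)  # log2(4)
        assert m.flags.loc["P2", "reverse"]

    def test_zero_intensity_becomes_missing(self, tmp_path):
        p = _toy_tsv(tmp_path / "pg.tsv",
                     [["P1", "g", 0.0, 2.0, 2.0, 2.0, 2.0, 2.0, "", "", ""]])
        m = load_protein_groups(p, CONDS)
        assert np.isnan(m.intensities.loc["P1", "c1"])

    def test_round_trip_write_read_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        ids = [f"P{i}" for i in range(20)]
        intens = pd.DataFrame(rng.normal(25, 2, (20, 6)), index=ids,
                              columns=list(CONDS))
        intens.iloc[0, 0] = np.nan
        flags = pd.DataFrame(False, index=ids,
                             columns=["reverse", "contaminant", "identified_by_site"])
        flags.iloc[3, 1] = True
        m = AbundanceMatrix(intensities=intens, conditions=pd.Series(CONDS),
                            flags=flags)
        path = tmp_path / "out.tsv"
        write_protein_groups(m, path)
        m2 = load_protein_groups(path, CONDS)
        pd.testing.assert_frame_equal(m.intensities, m2.intensities,
                                      check_names=False, atol=1e-12)
        pd.testing.assert_frame_equal(m.flags, m2.flags, check_names=False)

    def test_unassigned_sample_rejected(self, tmp_path):
        p = _toy_tsv(tmp_path / "pg.tsv",
                     [["P1", "g", 1, 1, 1, 1, 1, 1, "", "", ""]])
        with pytest.raises(ValueError, match="condition"):
            load_protein_groups(p, {"c1": "control"})

    def test_duplicate_ids_rejected(self, tmp_path):
        p = _toy_tsv(tmp_path / "pg.tsv", [
            ["P1", "g", 1, 1, 1, 1, 1, 1, "", "", ""],
            ["P1", "g", 2, 2, 2, 2, 2, 2, "", "", ""],
        ])
        with pytest.raises(ValueError, match="duplicate"):
            load_protein_groups(p, CONDS)


def _matrix(values: dict, flags: dict | None = None) -> AbundanceMatrix:
    intens = pd.DataFrame(values, index=list(CONDS)).T
    fl = pd.DataFrame(False, index=intens.index,
                      columns=["reverse", "contaminant", "identified_by_site"])
    for pid, col in (flags or {}).items():
        fl.loc[pid, col] = True
    return AbundanceMatrix(intensities=intens, conditions=pd.Series(CONDS),
                           flags=fl)


class TestFilterAndImpute:
    def test_flagged_row_removed(self):
        m = _matrix({"P1": [25, 25, 25, 26, 26, 26],
                     "P2": [25, 25, 25, 26, 26, 26]},
                    flags={"P2": "contaminant"})
        out = filter_and_impute(m)
        assert list(out.intensities.index) == ["P1"]

    def test_presence_absence_row_retained_and_imputed(self):
        m = _matrix({"P1": [25, 25, 25, np.nan, np.nan, np.nan],
                     "P2": [25, 25, 25, 26, 26, 26]})
        out = filter_and_impute(m, seed=0)
        assert "P1" in out.intensities.index
        assert out.presence_absence["P1"] and not out.presence_absence["P2"]
        assert out.intensities.notna().all().all()
        # imputed values are down-shifted below the observed sample mean (26)
        assert out.intensities.loc["P1", ["l1", "l2", "l3"]].mean() < 26 - 0.5

    def test_partially_missing_row_removed_in_both_modes(self):
        m = _matrix({"P1": [25, 25, np.nan, 26, 26, 26],
                     "P2": [25, 25, 25, 26, 26, 26]})
        for mode in ("presence_absence", "strict"):
            out = filter_and_impute(m, mode)
            assert list(out.intensities.index) == ["P2"]

    def test_strict_mode_drops_presence_absence_rows(self):
        m = _matrix({"P1": [25, 25, 25, np.nan, np.nan, np.nan],
                     "P2": [25, 25, 25, 26, 26, 26]})
        out = filter_and_impute(m, "strict")
        assert list(out.intensities.index) == ["P2"]

    def test_unknown_rule_rejected(self):
        m = _matrix({"P1": [25, 25, 25, 26, 26, 26]})
        with pytest.raises(ValueError, match="unknown rule"):
            filter_and_impute(m, "bogus")


class TestSamStatistic:
    def test_identical_groups_score_zero(self):
        assert sam_statistic([1, 2, 3], [1, 2, 3], s0=0.1) == 0.0

    def test_hand_computed_example(self):
        # |t| = 3 / (sqrt(2/3) + 0.1)
        t = sam_statistic([10, 11, 12], [13, 14, 15], s0=0.1)
        assert t == pytest.approx(3 / (math.sqrt(2 / 3) + 0.1), abs=1e-12)
        assert t == pytest.approx(3.2733, abs=1e-4)

    def test_s0_zero_reduces_to_classical_t(self, rng):
        for _ in range(200):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            t0 = sam_statistic(a, b, s0=0.0)
            t_ref = sps.ttest_ind(b, a).statistic
            assert t0 == pytest.approx(t_ref, abs=1e-12)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            sam_statistic([1.0], [2.0, 3.0], 0.1)


class TestPermutationFdr:
    def test_three_vs_three_has_twenty_label_splits(self):
        rng = np.random.default_rng(0)
        splits = _label_splits(6, 3, n_perm=250, rng=rng)
        assert len(splits) == math.comb(6, 3) == 20

    def test_invariant_to_sample_order_within_condition(self):
        rng = np.random.default_rng(1)
        x = rng.normal(25, 1, size=(50, 6))
        m1 = _matrix({f"P{i}": x[i] for i in range(50)})
        # swap replicate columns within each condition
        perm_cols = ["c3", "c1", "c2", "l2", "l3", "l1"]
        m2 = AbundanceMatrix(intensities=m1.intensities[perm_cols],
                             conditions=m1.conditions,
                             flags=m1.flags)
        r1 = permutation_fdr(m1, n_perm=20, seed=0)
        r2 = permutation_fdr(m2, n_perm=20, seed=0)
        np.testing.assert_allclose(r1["q"], r2["q"])

    def test_spiked_protein_called_significant(self):
        rng = np.random.default_rng(3)
        vals = {f"P{i}": rng.normal(25, 0.3, 6) for i in range(300)}
        vals["SPIKE"] = np.array([25, 25.1, 24.9, 30, 30.1, 29.9])
        m = _matrix(vals)
        res = permutation_fdr(m, n_perm=20, seed=3)
        assert res.loc["SPIKE", "significant"]
        assert res.loc["SPIKE", "log2fc"] == pytest.approx(5.0, abs=0.2)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        m = _matrix({f"P{i}": rng.normal(25, 1, 6) for i in range(30)})
        r1 = permutation_fdr(m, n_perm=10, seed=9)
        r2 = permutation_fdr(m, n_perm=10, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_bad_nperm_rejected(self):
        m = _matrix({"P1": [25, 25, 25, 26, 26, 26]})
        with pytest.raises(ValueError):
            permutation_fdr(m, n_perm=0)


class TestClassifyRegulation:
    @pytest.mark.parametrize("log2fc,sig,expected", [
        (1.0, True, "up"),
        (0.2, True, "ns"),          # 0.2 < log2(1.3) ~ 0.378
        (-1.0, False, "ns"),
        (-0.5, True, "down"),
        (np.log2(1.3), True, "up"),  # boundary inclusive
    ])
    def test_examples(self, log2fc, sig, expected):
        assert classify_regulation(log2fc, sig) == expected

    @given(st.floats(-5, 5), st.floats(0, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_fold_change(self, log2fc, bump):
        """Increasing log2fc never demotes a significant protein from up."""
        rank = {"down": -1, "ns": 0, "up": 1}
        lo = classify_regulation(log2fc, True)
        hi = classify_regulation(log2fc + bump, True)
        assert rank[hi] >= rank[lo]

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_regulation(1.0, True, fc_threshold=1.0)


class TestZscoreRows:
    def test_hand_example(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"], columns=list("abc"))
        out = zscore_rows(df)
        np.testing.assert_allclose(out.loc["p"], [-1, 0, 1])

    def test_standardized_row_is_fixed_point(self):
        df = pd.DataFrame([[-1.0, 0.0, 1.0]], index=["p"], columns=list("abc"))
        np.testing.assert_allclose(zscore_rows(df), df, atol=1e-15)

    def test_moments_on_random_rows(self, rng):
        df = pd.DataFrame(rng.normal(10, 3, size=(40, 6)))
        z = zscore_rows(df)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_constant_row_rejected(self):
        df = pd.DataFrame([[2.0, 2.0, 2.0]])
        with pytest.raises(ValueError, match="constant"):
            zscore_rows(df)


ANNOTATION = pd.DataFrame({
    "gene": ["col1a1a", "fn1a", "lum"],
    "division": ["core matrisome", "core matrisome", "core matrisome"],
    "category": ["collagen", "glycoprotein", "proteoglycan"],
    "mammalian_ortholog": ["COL1A1", "FN1", "LUM"],
})


class TestAnnotateMatrisome:
    def test_known_id_gets_division(self):
        out = annotate_matrisome(["lum"], ANNOTATION)
        assert out.loc["lum", "division"] == "core matrisome"
        assert out.loc["lum", "category"] == "proteoglycan"

    def test_unknown_id_flagged_non_matrisome(self):
        out = annotate_matrisome(["gapdh"], ANNOTATION)
        assert out.loc["gapdh", "division"] == "non-matrisome"
        assert not out.loc["gapdh", "is_matrisome"]

    @pytest.mark.parametrize("query,matches", [
        ("LUM", True), ("Lum", True), ("lum", True), ("lumb", False)])
    def test_casefold_normalizer(self, query, matches):
        out = annotate_matrisome([query], ANNOTATION, normalizer=str.casefold)
        assert out.loc[query, "is_matrisome"] == matches

    def test_duplicate_annotation_keys_rejected(self):
        dup = pd.concat([ANNOTATION, ANNOTATION.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            annotate_matrisome(["lum"], dup)


def _diff_table(classes: dict) -> pd.DataFrame:
    return pd.DataFrame({"class": list(classes.values()),
                         "t": np.linspace(1, 2, len(classes))},
                        index=list(classes))


class TestCrossSpeciesScreen:
    def test_bucket_assignment(self):
        res_a = _diff_table({"a1": "up", "a2": "up", "a3": "down", "a4": "ns"})
        res_b = _diff_table({"b1": "ns", "b2": "up", "b3": "up", "b4": "down"})
        omap = pd.DataFrame({"gene_a": ["a1", "a2", "a3", "a4"],
                             "gene_b": ["b1", "b2", "b3", "b4"]})
        out = cross_species_screen(res_a, res_b, omap)
        got = dict(zip(out.table["gene_a"], out.table["bucket"]))
        assert got == {"a1": BUCKET_A_UP, "a2": BUCKET_CONCORDANT,
                       "a3": BUCKET_B_UP, "a4": BUCKET_OTHER}

    def test_counts_match_construction(self):
        rng = np.random.default_rng(4)
        classes = ["up", "down", "ns"]
        res_a = _diff_table({f"a{i}": classes[rng.integers(3)] for i in range(10)})
        res_b = _diff_table({f"b{i}": classes[rng.integers(3)] for i in range(10)})
        omap = pd.DataFrame({"gene_a": [f"a{i}" for i in range(10)],
                             "gene_b": [f"b{i}" for i in range(10)]})
        out = cross_species_screen(res_a, res_b, omap)
        assert sum(out.counts.values()) == 10
        expected_a_up = sum(
            1 for i in range(10)
            if res_a.loc[f"a{i}", "class"] == "up"
            and res_b.loc[f"b{i}", "class"] != "up")
        assert out.counts[BUCKET_A_UP] == expected_a_up

    def test_many_to_many_resolved_to_strongest(self):
        res_a = _diff_table({"a1": "up"})
        res_b = pd.DataFrame({"class": ["ns", "up"], "t": [0.5, 3.0]},
                             index=["b1", "b2"])
        omap = pd.DataFrame({"gene_a": ["a1", "a1"], "gene_b": ["b1", "b2"]})
        out = cross_species_screen(res_a, res_b, omap)
        assert len(out.table) == 1
        assert out.table.iloc[0]["gene_b"] == "b2"   # |t|=3 wins
        assert len(out.dropped_ambiguous) == 1


class TestOraEnrichment:
    def test_set_equal_to_background_is_unenriched(self):
        bg = {f"g{i}" for i in range(50)}
        fg = {f"g{i}" for i in range(10)}
        out = ora_enrichment(fg, bg, {"all": bg})
        assert out.loc["all", "p"] == pytest.approx(1.0)

    def test_zero_overlap_is_unenriched(self):
        bg = {f"g{i}" for i in range(50)}
        out = ora_enrichment({"g0"}, bg, {"disjoint": {"g40", "g41"}})
        assert out.loc["disjoint", "p"] == pytest.approx(1.0)

    def test_matches_brute_force_hypergeometric_tail(self):
        # N=100, K=10, n=10, k=5: sum_{j>=5} C(10,j) C(90,10-j) / C(100,10)
        expected = sum(math.comb(10, j) * math.comb(90, 10 - j)
                       for j in range(5, 11)) / math.comb(100, 10)
        bg = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        fg = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        out = ora_enrichment(fg, bg, {"s": gene_set})
        assert out.loc["s", "p"] == pytest.approx(expected, rel=1e-12)

    def test_foreground_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ora_enrichment({"x"}, {"a", "b"}, {})

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            ora_enrichment(set(), set(), {})
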