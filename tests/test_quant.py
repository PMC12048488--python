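"""Bait normalization, contrast ratios and priority-set assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from epiquant.quant import (
    age_polyq_gain,
    assemble_priority_set,
    contrast_ratio,
    epitope_preference_summary,
    normalize_to_bait,
    run_priority_pipeline,
    scale_to_proteome,
    set_overlap,
    tissue_enrichment,
)


def design_from_runs(runs):
    """runs: list of (run_id, bait, epitope, tissue, genotype, age)."""
    rows = []
    for i, (run_id, bait, pool, tissue, genotype, age) in enumerate(runs):
        rows.append(
            {"run_id": run_id, "bait": bait, "epitope_class": pool,
             "tissue": tissue, "genotype": genotype, "age": age,
             "replicate": i + 1, "role": "IP"}
        )
    return pd.DataFrame(rows)


class TestNormalizeToBait:
    def design(self):
        return design_from_runs([
            ("r1", "HTT", "N-term", "striatum", "Q20", "8wk"),
            ("r2", "HTT", "N-term", "striatum", "Q20", "8wk"),
            ("g1", "IgG", "IgG", "striatum", "Q20", "8wk"),
        ])

    def test_division_and_na_propagation(self):
        intens = pd.DataFrame(
            {"r1": [5e5, 1e6, np.nan], "r2": [2e5, 4e5, 8e5], "g1": [1, 1, 1]},
            index=pd.Index(["HTT", "P1", "P2"], name="Protein"),
        )
        norm = normalize_to_bait(intens, self.design(), bait="HTT")
        assert list(norm.columns) == ["r1", "r2"]  # IgG excluded
        assert norm.loc["P1", "r1"] == pytest.approx(2.0)
        assert np.isnan(norm.loc["P2", "r1"])
        assert norm.loc["P2", "r2"] == pytest.approx(4.0)

    def test_homogeneity_run_scaling_cancels(self):
        intens = pd.DataFrame(
            {"r1": [5e5, 1e6], "r2": [2e5, 4e5], "g1": [1.0, 1.0]},
            index=pd.Index(["HTT", "P1"], name="Protein"),
        )
        scaled = intens.copy()
        scaled["r1"] *= 7.3
        a = normalize_to_bait(intens, self.design(), bait="HTT")
        b = normalize_to_bait(scaled, self.design(), bait="HTT")
        pd.testing.assert_frame_equal(a, b)

    def test_run_without_bait_dropped_with_warning(self):
        intens = pd.DataFrame(
            {"r1": [np.nan, 1e6], "r2": [2e5, 4e5], "g1": [1.0, 1.0]},
            index=pd.Index(["HTT", "P1"], name="Protein"),
        )
        with pytest.warns(UserWarning, match="r1"):
            norm = normalize_to_bait(intens, self.design(), bait="HTT")
        assert list(norm.columns) == ["r2"]


class TestScaleToProteome:
    def test_ratio_guards(self):
        ip = pd.Series([10.0, 4.0, 6.0], index=["a", "b", "c"])
        proteome = pd.Series([5.0, 0.0], index=["a", "b"])
        out = scale_to_proteome(ip, proteome)
        assert out["a"] == pytest.approx(2.0)
        assert np.isnan(out["b"])  # zero proteome -> NA, never infinity
        assert np.isnan(out["c"])  # unmatched condition

    def test_equal_vectors_give_ones(self):
        ip = pd.Series([3.0, 4.0], index=["a", "b"])
        assert scale_to_proteome(ip, ip).tolist() == [1.0, 1.0]


class TestContrastRatio:
    def design(self):
        return design_from_runs(
            [(f"a{i}", "HTT", "N-term", "striatum", "Q20", "8wk") for i in range(3)]
            + [(f"b{i}", "HTT", "Central", "striatum", "Q20", "8wk") for i in range(3)]
        )

    def test_log2_ratio_of_group_means(self):
        norm = pd.DataFrame(
            [[40, 40, 40, 5, 5, 5]],
            index=pd.Index(["P1"], name="Protein"),
            columns=["a0", "a1", "a2", "b0", "b1", "b2"],
        )
        rec = contrast_ratio(norm, self.design(), "epitope_class",
                             "N-term", "Central")
        assert rec.log2_ratio.iloc[0] == pytest.approx(3.0)

    def test_identical_groups_null_case(self):
        norm = pd.DataFrame(
            [[7, 7, 7, 7, 7, 7]],
            index=pd.Index(["P1"], name="Protein"),
            columns=["a0", "a1", "a2", "b0", "b1", "b2"],
        )
        rec = contrast_ratio(norm, self.design(), "epitope_class",
                             "N-term", "Central")
        assert rec.log2_ratio.iloc[0] == pytest.approx(0.0)
        assert rec.p_value.iloc[0] == pytest.approx(1.0)
        assert bool(rec.degenerate_variance.iloc[0])

    def test_t_statistic_matches_textbook_computation(self):
        # groups (10, 12, 11) vs (5, 6, 5) on log2 values, pooled-variance t
        a, b = [10.0, 12.0, 11.0], [5.0, 6.0, 5.0]
        la, lb = np.log2(a), np.log2(b)
        m1, m2 = la.mean(), lb.mean()
        sp2 = (la.var(ddof=1) * 2 + lb.var(ddof=1) * 2) / 4
        t = (m1 - m2) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        from scipy.stats import t as tdist
        p_expected = 2 * tdist.sf(abs(t), 4)

        norm = pd.DataFrame(
            [a + b], index=pd.Index(["P1"], name="Protein"),
            columns=["a0", "a1", "a2", "b0", "b1", "b2"],
        )
        rec = contrast_ratio(norm, self.design(), "epitope_class",
                             "N-term", "Central")
        assert rec.p_value.iloc[0] == pytest.approx(p_expected, rel=1e-9)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(0)
        norm = pd.DataFrame(
            rng.lognormal(0, 1, size=(20, 6)),
            index=pd.Index([f"P{i}" for i in range(20)], name="Protein"),
            columns=["a0", "a1", "a2", "b0", "b1", "b2"],
        )
        fwd = contrast_ratio(norm, self.design(), "epitope_class",
                             "N-term", "Central")
        rev = contrast_ratio(norm, self.design(), "epitope_class",
                             "Central", "N-term")
        np.testing.assert_allclose(fwd.log2_ratio, -rev.log2_ratio)
        np.testing.assert_allclose(fwd.p_value, rev.p_value)

    def test_min_obs_gives_na(self):
        norm = pd.DataFrame(
            [[4, np.nan, np.nan, 2, 2, 2]],
            index=pd.Index(["P1"], name="Protein"),
            columns=["a0", "a1", "a2", "b0", "b1", "b2"],
        )
        rec = contrast_ratio(norm, self.design(), "epitope_class",
                             "N-term", "Central", min_obs=2)
        assert np.isnan(rec.log2_ratio.iloc[0])


class TestEpitopePreference:
    def records(self, ratios):
        return pd.DataFrame(
            [{"prey": "P1", "tissue": "striatum", "stratum": f"s{i}",
              "log2_ratio": r} for i, r in enumerate(ratios)]
        )

    @pytest.mark.parametrize(
        "ratios, expected_value, expected_label",
        [
            ((1.0, 2.8), 2.8, "N-term"),
            ((2.0, -2.6), -2.6, "Central"),
            ((2.5,), 2.5, "shared"),           # strict inequality at the bound
            ((np.nan, np.nan), np.nan, "unclassified"),
        ],
    )
    def test_max_abs_rule_and_threshold(self, ratios, expected_value,
                                        expected_label):
        out = epitope_preference_summary(self.records(ratios), threshold=2.5)
        assert out.preference.iloc[0] == expected_label
        if np.isnan(expected_value):
            assert np.isnan(out.log2_ratio.iloc[0])
        else:
            assert out.log2_ratio.iloc[0] == pytest.approx(expected_value)


def factorial_norm(values_by_cell, tissues=("striatum", "cortex", "cerebellum")):
    """Build (norm, design) with one value per tissue/genotype/age/replicate.

    values_by_cell: {prey: {(tissue, genotype, age): level}}; two replicates
    with identical values are emitted per cell.
    """
    runs, columns = [], []
    for tissue in tissues:
        for genotype in ("Q20", "Q140"):
            for age in ("8wk", "40wk"):
                for rep in (1, 2):
                    run_id = f"{tissue[:3]}_{genotype}_{age}_r{rep}"
                    runs.append((run_id, "HTT", "N-term", tissue, genotype, age))
                    columns.append((run_id, tissue, genotype, age))
    design = design_from_runs(runs)
    data = {}
    for prey, cells in values_by_cell.items():
        data[prey] = [cells.get((t, g, a), np.nan) for _, t, g, a in columns]
    norm = pd.DataFrame.from_dict(
        data, orient="index", columns=[c[0] for c in columns]
    ).rename_axis("Protein")
    return norm, design


class TestAgePolyqGain:
    def cells(self, striatum_gain, cortex_gain=1.0, cerebellum_gain=1.0):
        base = {}
        for tissue, gain in [("striatum", striatum_gain),
                             ("cortex", cortex_gain),
                             ("cerebellum", cerebellum_gain)]:
            base[(tissue, "Q20", "8wk")] = 10.0
            base[(tissue, "Q20", "40wk")] = 12.0   # Q20 age ratio 1.2
            base[(tissue, "Q140", "8wk")] = 10.0
            base[(tissue, "Q140", "40wk")] = 10.0 * 1.2 * gain
        return base

    def test_gain_above_fold_passes_target_only(self):
        norm, design = factorial_norm({"P1": self.cells(striatum_gain=8.0 / 1.2)})
        # Q140 age ratio 8.0, Q20 age ratio 1.2 -> gain 6.67 > 5
        out = age_polyq_gain(norm, design, fold_min=5.0)
        assert out.loc["P1", "gain_striatum"] == pytest.approx(8.0 / 1.2, rel=1e-9)
        assert bool(out.loc["P1", "passes"])

    def test_identical_genotypes_gain_one_fails(self):
        norm, design = factorial_norm({"P1": self.cells(striatum_gain=1.0)})
        out = age_polyq_gain(norm, design, fold_min=5.0)
        assert out.loc["P1", "gain_striatum"] == pytest.approx(1.0)
        assert not bool(out.loc["P1", "passes"])

    def test_gain_in_two_tissues_fails_exclusivity(self):
        norm, design = factorial_norm(
            {"P1": self.cells(striatum_gain=6.0, cortex_gain=6.0)}
        )
        out = age_polyq_gain(norm, design, fold_min=5.0)
        assert out.loc["P1", "gain_striatum"] > 5.0
        assert out.loc["P1", "gain_cortex"] > 5.0
        assert not bool(out.loc["P1", "passes"])


class TestTissueEnrichment:
    def test_fourfold_over_both_other_tissues(self):
        norm, design = factorial_norm({"P1": {
            (t, g, a): v
            for t, v in [("striatum", 80.0), ("cortex", 5.0), ("cerebellum", 4.0)]
            for g in ("Q20", "Q140") for a in ("8wk", "40wk")
        }})
        out = tissue_enrichment(norm, design, fold_min=4.0)
        row = out[(out.prey == "P1") & (out.tissue == "striatum")].iloc[0]
        assert row.min_log2_enrichment == pytest.approx(np.log2(80 / 5))
        assert bool(row.enriched)

    def test_equal_tissues_not_enriched(self):
        norm, design = factorial_norm({"P1": {
            (t, g, a): 10.0 for t in ("striatum", "cortex", "cerebellum")
            for g in ("Q20", "Q140") for a in ("8wk", "40wk")
        }})
        out = tissue_enrichment(norm, design, fold_min=4.0)
        row = out[(out.prey == "P1") & (out.tissue == "striatum")].iloc[0]
        assert row.min_log2_enrichment == pytest.approx(0.0)
        assert not bool(row.enriched)

    def test_missing_tissue_flagged_partial(self):
        cells = {
            (t, g, a): v
            for t, v in [("striatum", 80.0), ("cortex", 5.0)]
            for g in ("Q20", "Q140") for a in ("8wk", "40wk")
        }
        norm, design = factorial_norm({"P1": cells})
        out = tissue_enrichment(norm, design, fold_min=4.0)
        row = out[(out.prey == "P1") & (out.tissue == "striatum")].iloc[0]
        assert bool(row.enriched) and bool(row.partial)


class TestSets:
    def test_priority_union_and_provenance(self):
        ps = assemble_priority_set({"P1", "P2"}, {"P2", "P3"})
        assert ps.union == {"P1", "P2", "P3"}
        prov = ps.provenance().set_index("prey").provenance
        assert prov["P2"] == "both"
        assert prov["P1"] == "enriched-only"
        assert prov["P3"] == "gain-only"

    def test_disjoint_and_empty_cases(self):
        assert assemble_priority_set({"a"}, {"b"}).union == {"a", "b"}
        assert assemble_priority_set({"a", "b"}, set()).union == {"a", "b"}

    def test_set_overlap_partitions_union(self):
        shared, uq, ur = set_overlap({"a", "b", "c"}, {"b", "c", "d"})
        assert shared == {"b", "c"} and uq == {"a"} and ur == {"d"}
        assert set_overlap({"a"}, {"a"}) == ({"a"}, set(), set())
        assert set_overlap({"a"}, {"b"}) == (set(), {"a"}, {"b"})


class TestPipeline:
    def test_recovers_planted_priority_set(self, ipms_small):
        counts, intens, design, truth = ipms_small
        result = run_priority_pipeline(counts, intens, design, bait="HTT")
        predicted = result["priority"].union
        planted = set(truth.index[(truth.tissue_enriched != "")
                                  | truth.polyq_gain])
        jaccard = len(predicted & planted) / len(predicted | planted)
        assert jaccard >= 0.8
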