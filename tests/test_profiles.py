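"""Trait-methylation trends, DMR windows, SD, correlation, export."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from conftest import two_pass_pearson
from ewasviz import (
    BetaMatrix,
    TraitTable,
    correlation_profile,
    dmr_window,
    export_merged,
    probe_sd,
    trait_color_scale,
    trait_methylation,
    violin_summary,
)


def linear_cohort(n=20, slope=0.01, intercept=0.5, sexes=None):
    individuals = [f"I{i:02d}" for i in range(n)]
    trait = np.linspace(1.0, 10.0, n)
    meth = intercept + slope * trait
    betas = BetaMatrix(values=pd.DataFrame([meth], index=["cgL"],
                                           columns=individuals))
    sexes = sexes or ["female", "male"] * (n // 2)
    traits = TraitTable(data=pd.DataFrame(
        {"sex": sexes, "conc": trait},
        index=pd.Index(individuals, name="ID")))
    return betas, traits


class TestTraitMethylation:
    def test_exact_line_recovered(self):
        """Noiseless linear relation: slope/intercept to machine precision."""
        betas, traits = linear_cohort(slope=0.01, intercept=0.5)
        records, fits = trait_methylation("cgL", "conc", betas, traits)
        for stratum in ("all", "female", "male"):
            assert fits[stratum].slope == pytest.approx(0.01, abs=1e-9)
            assert fits[stratum].intercept == pytest.approx(0.5, abs=1e-9)

    def test_single_sex_cohort_drops_other_fit(self):
        betas, traits = linear_cohort(sexes=["female"] * 20)
        _, fits = trait_methylation("cgL", "conc", betas, traits)
        assert "male" not in fits
        assert fits["all"].slope == pytest.approx(fits["female"].slope)

    def test_strata_partition_records(self, dataset):
        probe = dataset["truth"][0][1]
        records, _ = trait_methylation(probe, "trait_1", dataset["betas"],
                                       dataset["traits"])
        by_sex = records.groupby("sex").size()
        assert by_sex.sum() == len(records)
        assert set(records["sex"]).issubset({"female", "male", "unknown"})

    def test_records_require_both_values(self, dataset):
        probe = dataset["truth"][0][1]
        records, _ = trait_methylation(probe, "trait_1", dataset["betas"],
                                       dataset["traits"])
        assert records["methylation"].notna().all()
        assert records["trait_value"].notna().all()

    def test_ci_covers_true_slope_in_simulation(self):
        """95% CI on the slope covers truth in >=90 of 100 noisy replicates."""
        true_slope, true_intercept, sigma, n = 0.02, 0.4, 0.05, 100
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            individuals = [f"I{i:03d}" for i in range(n)]
            x = rng.uniform(0.0, 10.0, n)
            y = true_intercept + true_slope * x + rng.normal(0, sigma, n)
            betas = BetaMatrix(values=pd.DataFrame([y], index=["cgN"],
                                                   columns=individuals))
            traits = TraitTable(data=pd.DataFrame(
                {"sex": ["female"] * n, "conc": x},
                index=pd.Index(individuals, name="ID")))
            _, fits = trait_methylation("cgN", "conc", betas, traits)
            lo, hi = fits["all"].slope_ci
            covered += lo <= true_slope <= hi
        assert covered >= 90

    def test_no_shared_individuals_is_error(self):
        betas = BetaMatrix(values=pd.DataFrame([[0.5]], index=["cgL"],
                                               columns=["I_a"]))
        traits = TraitTable(data=pd.DataFrame(
            {"sex": ["female"], "conc": [1.0]},
            index=pd.Index(["I_b"], name="ID")))
        with pytest.raises(ValueError):
            trait_methylation("cgL", "conc", betas, traits)


class TestViolinSummary:
    def test_quantiles_per_stratum(self):
        betas, traits = linear_cohort()
        records, _ = trait_methylation("cgL", "conc", betas, traits)
        table = violin_summary(records)
        all_row = table[table["stratum"] == "all"].iloc[0]
        assert all_row["min"] == pytest.approx(1.0)
        assert all_row["max"] == pytest.approx(10.0)
        assert all_row["q25"] <= all_row["median"] <= all_row["q75"]
        assert set(table["stratum"]) == {"all", "female", "male"}


class TestDmrWindow:
    def test_interior_window_is_2k_plus_1(self, dataset):
        ann = dataset["annotation"]
        chrom1 = ann[ann["chromosome"] == "1"].reset_index(drop=True)
        center = chrom1.iloc[len(chrom1) // 2]["probe_id"]
        window = dmr_window(center, 3, ann, dataset["betas"],
                            dataset["traits"], "trait_1")
        assert len(window.probes) == 7
        assert not window.truncated_left and not window.truncated_right
        assert center in set(window.probes["probe_id"])

    def test_chromosome_start_truncates_left(self, dataset):
        ann = dataset["annotation"]
        first = ann[ann["chromosome"] == "2"].iloc[0]["probe_id"]
        window = dmr_window(first, 3, ann, dataset["betas"],
                            dataset["traits"], "trait_1")
        assert window.truncated_left and not window.truncated_right
        assert len(window.probes) == 4

    def test_k_zero_is_center_only(self, dataset):
        center = dataset["truth"][0][1]
        window = dmr_window(center, 0, dataset["annotation"],
                            dataset["betas"], dataset["traits"], "trait_1")
        assert list(window.probes["probe_id"]) == [center]

    def test_never_crosses_chromosomes_anywhere(self, dataset):
        """Every probe of the 3-chromosome fixture obeys the window contract."""
        ann = dataset["annotation"]
        betas, traits = dataset["betas"], dataset["traits"]
        k = 4
        for _, row in ann.iterrows():
            window = dmr_window(row["probe_id"], k, ann, betas, traits,
                                "trait_1")
            assert (window.probes["chromosome"] == row["chromosome"]).all()
            assert len(window.probes) <= 2 * k + 1
            if not (window.truncated_left or window.truncated_right
                    or window.skipped_probes):
                assert len(window.probes) == 2 * k + 1
            ranks = window.probes["global_array_position"].to_numpy()
            assert (np.diff(ranks) > 0).all()

    def test_unannotated_center_is_error(self, dataset):
        with pytest.raises(KeyError):
            dmr_window("cg_not_annotated", 2, dataset["annotation"],
                       dataset["betas"], dataset["traits"], "trait_1")


class TestColorScale:
    def test_endpoints_and_midpoint(self):
        vals = pd.Series([0.0, 5.0, 10.0], index=["lo", "mid", "hi"])
        colors = trait_color_scale(vals)
        assert colors["lo"] == "#ff0000"   # red = low
        assert colors["hi"] == "#0000ff"   # blue = high
        assert colors["mid"] == "#800080"  # linear midpoint

    def test_constant_trait_single_midpoint_color(self):
        vals = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        colors = trait_color_scale(vals)
        assert len(set(colors.values())) == 1

    def test_missing_values_left_out(self):
        vals = pd.Series([1.0, np.nan, 3.0], index=list("abc"))
        assert set(trait_color_scale(vals)) == {"a", "c"}


class TestProbeSd:
    def test_closed_form(self, ):
        betas = BetaMatrix(values=pd.DataFrame([[0.1, 0.2, 0.3]],
                                               index=["cgS"],
                                               columns=["a", "b", "c"]))
        assert probe_sd("cgS", betas) == pytest.approx(0.1)

    def test_constant_probe_has_zero_sd(self):
        betas = BetaMatrix(values=pd.DataFrame([[0.4] * 5], index=["cgS"],
                                               columns=list("abcde")))
        assert probe_sd("cgS", betas) == 0.0

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 1, 50)
        betas = BetaMatrix(values=pd.DataFrame(
            [vals], index=["cgS"], columns=[f"I{i}" for i in range(50)]))
        mean = vals.sum() / 50
        oracle = math.sqrt(((vals - mean) ** 2).sum() / 49)
        assert probe_sd("cgS", betas) == pytest.approx(oracle, abs=1e-12)

    def test_fewer_than_two_values_missing(self):
        betas = BetaMatrix(values=pd.DataFrame([[0.5, np.nan]], index=["cgS"],
                                               columns=["a", "b"]))
        assert math.isnan(probe_sd("cgS", betas))


class TestCorrelationProfile:
    def test_duplicate_probe_ranks_first_with_r_one(self, tiny_betas):
        values = tiny_betas.values.copy()
        values.loc["cg_dup"] = values.loc["cg000"]
        betas = BetaMatrix(values=values)
        hits = correlation_profile("cg000", betas, top_n=3, min_overlap=3)
        assert hits.iloc[0]["probe_id"] == "cg_dup"
        assert hits.iloc[0]["corr_coeff"] == pytest.approx(1.0)

    def test_complement_probe_is_anticorrelated(self, tiny_betas):
        values = tiny_betas.values.copy()
        values.loc["cg_inv"] = 1.0 - values.loc["cg000"]
        betas = BetaMatrix(values=values)
        hits = correlation_profile("cg000", betas, top_n=3, min_overlap=3)
        inv = hits[hits["probe_id"] == "cg_inv"].iloc[0]
        assert inv["corr_coeff"] == pytest.approx(-1.0)

    def test_matches_exhaustive_oracle_rank_for_rank(self):
        """Seeded 200x50 fixture against brute-force two-pass Pearson."""
        rng = np.random.default_rng(21)
        probes = [f"cg{i:05d}" for i in range(200)]
        values = pd.DataFrame(rng.uniform(0, 1, (200, 50)), index=probes,
                              columns=[f"I{i:02d}" for i in range(50)])
        values[values < 0.03] = np.nan  # some missingness
        betas = BetaMatrix(values=values)
        query = "cg00000"
        hits = correlation_profile(query, betas, top_n=199, min_overlap=10)

        oracle = []
        q = values.loc[query].to_numpy()
        for probe in probes[1:]:
            r = two_pass_pearson(q, values.loc[probe].to_numpy())
            n_pairs = int((~np.isnan(q)
                           & ~np.isnan(values.loc[probe].to_numpy())).sum())
            if n_pairs >= 10 and not math.isnan(r):
                oracle.append((probe, r))
        oracle.sort(key=lambda t: (-abs(t[1]), t[0]))

        assert list(hits["probe_id"]) == [p for p, _ in oracle]
        np.testing.assert_allclose(hits["corr_coeff"].to_numpy(),
                                   [r for _, r in oracle], atol=1e-9)

    def test_self_excluded_and_min_overlap_enforced(self, tiny_betas):
        hits = correlation_profile("cg000", tiny_betas, top_n=10,
                                   min_overlap=3)
        assert "cg000" not in set(hits["probe_id"])
        assert (hits["n_pairs"] >= 3).all()

    def test_unknown_probe_is_error(self, tiny_betas):
        with pytest.raises(KeyError):
            correlation_profile("cg_missing", tiny_betas)


class TestExportMerged:
    def test_shape_and_round_trip(self, dataset, tmp_path):
        center = dataset["truth"][0][1]
        window = dmr_window(center, 5, dataset["annotation"],
                            dataset["betas"], dataset["traits"], "trait_1")
        out = tmp_path / "export.csv"
        main = export_merged(window, dataset["traits"], out,
                             trait_name="trait_1",
                             results=dataset["results"]["trait_1"])
        n_probes = len(window.probes)
        assert main.shape == (len(window.methylation.columns), 3 + n_probes)
        reread = pd.read_csv(out)
        for probe in window.probes["probe_id"]:
            np.testing.assert_allclose(
                reread[probe].to_numpy(),
                window.methylation.loc[probe].to_numpy(), atol=1e-9)
        probe_sheet = pd.read_csv(tmp_path / "export_probes.csv")
        assert {"probe_id", "gene_symbol", "p_value",
                "delta_meth"} <= set(probe_sheet.columns)

    def test_missing_trait_value_keeps_row(self, dataset, tmp_path):
        traits = dataset["traits"]
        patched = TraitTable(data=traits.data.copy())
        victim = patched.data.index[0]
        patched.data.loc[victim, "trait_1"] = np.nan
        center = dataset["truth"][0][1]
        window = dmr_window(center, 2, dataset["annotation"],
                            dataset["betas"], patched, "trait_1")
        out = tmp_path / "export.csv"
        main = export_merged(window, patched, out, trait_name="trait_1")
        row = main[main["individual_id"] == victim]
        assert len(row) == 1
        assert row["trait_1"].isna().all()
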