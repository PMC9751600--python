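import numpy as np
import pandas as pd
import pytest

from pollenheat.descriptives import (
    DEFAULT_BINS,
    EraRule,
    descriptive_stats,
    era_from_year,
    era_trend,
    hsi_correlations,
    viability_bins,
)
from pollenheat.hsi import screen_panel
from pollenheat.simulate import SimConfig, fixture_from_table2, simulate_panel
from pollenheat.trial_data import genotype_means, make_panel
from conftest import build_records


def means_frame(values, condition="normal", season="S1"):
    return pd.DataFrame(
        {
            "genotype": [f"g{i}" for i in range(len(values))],
            "season": season,
            "treatment": condition,
            "mean_viability": values,
            "n": 1,
        }
    )


class TestViabilityBins:
    def test_three_value_example(self):
        out = viability_bins(means_frame([100.0, 95.0, 85.0]), "normal")
        assert out["count"].tolist() == [1, 1, 1, 0, 0, 0]

    def test_all_in_one_bin(self):
        out = viability_bins(means_frame([90.0] * 7), "normal")
        assert out.set_index("label").loc["90-99", "count"] == 7

    def test_rounding_to_integer_percent_default(self):
        # 89.6 rounds to 90 -> decade bin 90-99
        out = viability_bins(means_frame([89.6]), "normal")
        assert out.set_index("label").loc["90-99", "count"] == 1
        raw = viability_bins(means_frame([89.6]), "normal", round_to_int=False)
        assert raw.set_index("label").loc["80-89", "count"] == 1

    def test_counts_match_brute_force_histogram(self):
        panel, _ = simulate_panel(SimConfig(n_genotypes=100, seed=15))
        means = genotype_means(panel)
        out = viability_bins(means, "stress", season="S1")
        per_geno = (
            means[(means["treatment"] == "stress") & (means["season"] == "S1")]
            .groupby("genotype")["mean_viability"]
            .mean()
            .round()
        )
        for _, row in out.iterrows():
            expected = ((per_geno >= row["bin_low"]) & (per_geno <= row["bin_high"])).sum()
            assert row["count"] == expected
        assert out["count"].sum() == 100

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            viability_bins(means_frame([90.0]), "normal", bins=((0, 50, "a"), (40, 100, "b")))


class TestCorrelations:
    def test_perfect_negative_correlation_with_fixed_normal_mean(self):
        # constant x_normal makes the index affine decreasing in stress viability
        rows = []
        for i, xs in enumerate([70.0, 75.0, 80.0, 85.0, 90.0]):
            rows.append((f"g{i}", "S1", "normal", 1, 95.0))
            rows.append((f"g{i}", "S1", "stress", 1, xs))
        results, _, _ = screen_panel(make_panel(build_records(rows)))
        out = hsi_correlations(results, pairs=("stress",)).set_index("pair")
        assert out.loc["hsi_vs_stress_viability", "r"] == pytest.approx(-1.0)

    def test_matches_textbook_covariance_formula(self):
        panel, _ = simulate_panel(SimConfig(n_genotypes=60, seed=19))
        results, _, _ = screen_panel(panel)
        out = hsi_correlations(results).set_index("pair")
        for col, pair in (("x_normal", "hsi_vs_normal_viability"), ("x_stress", "hsi_vs_stress_viability")):
            x = results[col].to_numpy()
            y = results["hsi"].to_numpy()
            r_oracle = (
                np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
            )
            assert out.loc[pair, "r"] == pytest.approx(r_oracle, abs=1e-12)
            assert -1 <= out.loc[pair, "r"] <= 1

    def test_zero_variance_rejected(self):
        results = pd.DataFrame(
            {"x_normal": [90.0] * 5, "x_stress": [80.0] * 5, "hsi": [1.0] * 5}
        )
        with pytest.raises(ValueError, match="zero variance"):
            hsi_correlations(results)

    def test_too_few_pairs_rejected(self):
        results = pd.DataFrame({"x_normal": [90.0], "x_stress": [80.0], "hsi": [1.0]})
        with pytest.raises(ValueError, match=">= 3"):
            hsi_correlations(results)


class TestEra:
    @pytest.mark.parametrize(
        "year, era",
        [
            (1940, "pre_green_revolution"),
            (1964, "pre_green_revolution"),
            (1965, "post_green_revolution"),
            (2000, "post_green_revolution"),
            (2001, "modern"),
            (2021, "modern"),
            (None, None),
        ],
    )
    def test_default_cut_years(self, year, era):
        assert era_from_year(year) == era

    def test_published_tolerant_panel_assignment(self):
        panel = fixture_from_table2()
        results, _, _ = screen_panel(panel)
        reg = panel.registry.assign(era=pd.NA)  # force derivation from years
        summary, values, unassigned = era_trend(results, reg)
        by_geno = values.set_index("genotype")["era"]
        assert by_geno["Frontana"] == "pre_green_revolution"
        for g in ("Chenab-70", "Pari-73", "Pak-81", "Punjab-76", "Amin-2000"):
            assert by_geno[g] == "post_green_revolution"
        for g in ("MH-21", "NIFA-Aman", "Swabi-1", "Nisnan-21", "Pirsabak-2004"):
            assert by_geno[g] == "modern"
        assert "NUWYT-63" in unassigned  # advanced line, no release year

    def test_singleton_groups_return_their_inputs(self):
        results = pd.DataFrame(
            {
                "genotype": ["A", "B", "C"],
                "season": ["S1"] * 3,
                "hsi": [0.2, 0.8, 1.4],
            }
        )
        registry = pd.DataFrame(
            {
                "genotype": ["A", "B", "C"],
                "release_year": [1950, 1980, 2010],
                "era": [pd.NA] * 3,
                "pedigree": [pd.NA] * 3,
            }
        )
        summary, values, _ = era_trend(results, registry)
        s = summary.set_index("era")
        assert s.loc["pre_green_revolution", "mean_hsi"] == pytest.approx(0.2)
        assert s.loc["post_green_revolution", "mean_hsi"] == pytest.approx(0.8)
        assert s.loc["modern", "mean_hsi"] == pytest.approx(1.4)
        assert (s["n"] == 1).all()

    def test_monotone_era_trend_recovered_from_synthetic_truth(self):
        # tie genotype stress response to era: older eras more susceptible
        rng = np.random.default_rng(4)
        rows, reg_rows = [], []
        eras = [("pre", 1950, 1.6), ("post", 1985, 1.0), ("mod", 2010, 0.4)]
        for tag, year, hsi_level in eras:
            for i in range(15):
                name = f"{tag}{i}"
                xn = 95.0
                d_bar_target = 0.10
                xs = xn * (1 - hsi_level * d_bar_target + rng.normal(0, 0.005))
                for season in ("S1", "S2"):
                    rows.append((name, season, "normal", 1, xn))
                    rows.append((name, season, "stress", 1, xs))
                reg_rows.append((name, year, pd.NA, pd.NA))
        panel = make_panel(
            build_records(rows),
        )
        registry = pd.DataFrame(
            reg_rows, columns=["genotype", "release_year", "era", "pedigree"]
        )
        results, _, _ = screen_panel(panel)
        summary, _, _ = era_trend(results, registry)
        s = summary.set_index("era")["mean_hsi"]
        assert (
            s["pre_green_revolution"] > s["post_green_revolution"] > s["modern"]
        )

    def test_empty_era_reported_with_zero_n(self):
        results = pd.DataFrame({"genotype": ["A"], "season": ["S1"], "hsi": [0.5]})
        registry = pd.DataFrame(
            {"genotype": ["A"], "release_year": [2010], "era": [pd.NA], "pedigree": [pd.NA]}
        )
        summary, _, _ = era_trend(results, registry)
        assert summary.set_index("era").loc["pre_green_revolution", "n"] == 0

    def test_bad_cut_order_rejected(self):
        with pytest.raises(ValueError):
            EraRule(post_start=2010, modern_start=1965)


class TestDescriptiveStats:
    def test_small_example(self):
        rows = [("A", "S1", "normal", r, v) for r, v in enumerate([1.0, 2.0, 3.0], 1)]
        out = descriptive_stats(make_panel(build_records(rows)))
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["min"] == 1.0 and row["max"] == 3.0 and row["n"] == 3

    def test_singleton_group_has_absent_sd(self):
        rows = [("A", "S1", "normal", 1, 90.0)]
        out = descriptive_stats(make_panel(build_records(rows)))
        assert np.isnan(out.iloc[0]["sd"])

    def test_matches_independent_summation_oracle(self, random_panel_factory):
        panel = random_panel_factory(G=5, S=2, r=3, seed=30)
        out = descriptive_stats(panel, grouping=["treatment"])
        for _, row in out.iterrows():
            vals = [
                r.viability
                for r in panel.records.itertuples()
                if r.treatment == row["treatment"]
            ]
            m = sum(vals) / len(vals)
            sd = (sum((v - m) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            assert row["mean"] == pytest.approx(m, abs=1e-12)
            assert row["sd"] == pytest.approx(sd, abs=1e-12)
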