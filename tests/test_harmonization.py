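"""Harmonization: biomass, exclusions, capping, calibration, aggregation,
profiles, and the fourth-root transform."""

import numpy as np
import pandas as pd
import pytest

from reef_regimes import GeneratorConfig, generate_profiles, generate_surveys
from reef_regimes.harmonization import (
    aggregate_spatial,
    apply_calibration,
    build_profile_matrix,
    cap_outliers,
    compute_biomass,
    derive_calibration,
    filter_exclusions,
    haversine_m,
    inverse_transform,
    transform,
)
from reef_regimes.synthetic import GROUP_COLUMNS


def obs_frame(**overrides):
    base = {
        "site_id": ["A"],
        "method": ["belt"],
        "species": ["Naso unicornis"],
        "count": [1],
        "length_cm": [10.0],
        "area_m2": [125.0],
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestBiomass:
    @pytest.mark.parametrize(
        "a,b,tl,count,expected",
        [
            (0.01, 3.0, 10.0, 1, 10.0),  # 0.01 * 10^3
            (0.01, 3.0, 0.0, 1, 0.0),  # power law at zero length
            (0.02, 2.9, 23.5, 3, 3 * 0.02 * 23.5 ** 2.9),
        ],
    )
    def test_allometric_formula(self, a, b, tl, count, expected):
        params = pd.DataFrame({"species": ["X"], "a": [a], "b": [b]})
        obs = obs_frame(species=["X"], count=[count], length_cm=[tl])
        out = compute_biomass(obs, params)
        assert out["mass_g"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert out["density_g_m2"].iloc[0] == pytest.approx(expected / 125.0, rel=1e-12)

    def test_missing_params_lists_species(self):
        with pytest.raises(KeyError, match="Unknown fish"):
            compute_biomass(obs_frame(species=["Unknown fish"]),
                            pd.DataFrame({"species": ["X"], "a": [1.0], "b": [3.0]}))

    def test_biomass_increasing_in_length(self):
        params = pd.DataFrame({"species": ["X"], "a": [0.02], "b": [2.9]})
        lengths = np.linspace(1, 80, 40)
        obs = obs_frame(species=["X"] * 40, count=[1] * 40, length_cm=lengths,
                        site_id=["A"] * 40, method=["belt"] * 40, area_m2=[125.0] * 40)
        out = compute_biomass(obs, params)
        assert (np.diff(out["mass_g"]) > 0).all()


class TestExclusions:
    def test_empty_list_identity(self):
        obs = obs_frame()
        out = filter_exclusions(obs, pd.DataFrame({"species": [], "exclusion_reason": []}))
        pd.testing.assert_frame_equal(out, obs)

    def test_planted_manta_mass_removed(self):
        obs = pd.concat(
            [obs_frame(), obs_frame(species=["Mobula birostris"], length_cm=[300.0])],
            ignore_index=True,
        )
        withall = compute_biomass(obs)
        manta_mass = withall.loc[withall["species"] == "Mobula birostris", "mass_g"].sum()
        kept = compute_biomass(filter_exclusions(obs))
        assert manta_mass > 0
        assert kept["mass_g"].sum() == pytest.approx(
            withall["mass_g"].sum() - manta_mass, rel=1e-12
        )
        assert "Mobula birostris" not in set(kept["species"])


class TestCapOutliers:
    def test_all_equal_no_change(self):
        obs = obs_frame(species=["X"] * 5, count=[7] * 5, length_cm=[10.0] * 5,
                        site_id=list("ABCDE"), method=["belt"] * 5, area_m2=[125.0] * 5)
        out, report = cap_outliers(obs)
        assert (out["count"] == 7).all()
        assert len(report) == 0

    def test_planted_extreme_capped_to_species_quantile(self):
        counts = list(range(1, 51)) + [10_000]
        n = len(counts)
        obs = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(n)],
            "method": ["belt"] * n,
            "species": ["X"] * n,
            "count": counts,
            "length_cm": [10.0] * n,
            "area_m2": [125.0] * n,
        })
        out, report = cap_outliers(obs)
        # oracle: type-7 quantile of the species' pre-capping counts
        expected = np.quantile(np.array(counts, dtype=float), 0.99)
        assert report["species"].tolist() == ["X"]
        assert report["threshold"].iloc[0] == pytest.approx(expected)
        assert out["count"].max() == pytest.approx(expected)
        assert report["n_adjusted"].iloc[0] >= 1

    def test_unflagged_species_untouched(self):
        counts = list(range(1, 51)) + [10_000]
        n = len(counts)
        obs = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(n + 3)],
            "method": ["belt"] * (n + 3),
            "species": ["X"] * n + ["Y"] * 3,
            "count": counts + [40, 45, 50],
            "length_cm": 10.0,
            "area_m2": 125.0,
        })
        out, _ = cap_outliers(obs)
        assert out.loc[out["species"] == "Y", "count"].tolist() == [40, 45, 50]
        # never increases any count
        assert (out["count"].to_numpy() <= obs["count"].to_numpy()).all()

    def test_reapply_with_stored_thresholds_idempotent(self):
        counts = list(range(1, 51)) + [10_000]
        n = len(counts)
        obs = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(n)],
            "method": ["belt"] * n,
            "species": ["X"] * n,
            "count": counts,
            "length_cm": 10.0,
            "area_m2": 125.0,
        })
        once, report = cap_outliers(obs)
        twice, report2 = cap_outliers(once, report=report[["species", "threshold", "global_threshold"]])
        pd.testing.assert_frame_equal(once, twice)


def paired_frame(n, factor, seed=0, zeros=0):
    """Paired two-method densities for one species with a planted bias.

    ``zeros`` pairs have the species present under the source method but
    missed by the target method (one-sided zeros drive the delta rule)."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(1, 10, size=n)
    y = factor * x + rng.normal(0, 0.01, size=n)
    y = np.abs(y)
    y[:zeros] = 0.0
    rows = []
    for i in range(n):
        rows.append({"site_id": f"s{i}", "method": "tow", "species": "Naso unicornis",
                     "density_g_m2": x[i]})
        rows.append({"site_id": f"s{i}", "method": "belt", "species": "Naso unicornis",
                     "density_g_m2": y[i]})
    return pd.DataFrame(rows)


class TestCalibration:
    def test_no_pairs_raises(self):
        with pytest.raises(ValueError):
            derive_calibration(pd.DataFrame(), "belt", "tow")

    def test_identical_densities_factor_one(self):
        paired = paired_frame(12, 1.0)
        factors = derive_calibration(paired, "belt", "tow")
        f = factors[factors["scope"] == "species"]["factor"].iloc[0]
        assert f == pytest.approx(1.0, abs=0.02)

    def test_planted_bias_recovered(self):
        paired = paired_frame(20, 2.0, seed=1)
        factors = derive_calibration(paired, "belt", "tow")
        row = factors[(factors["scope"] == "species")].iloc[0]
        # least-squares through-origin oracle
        wide = paired.pivot_table(index="site_id", columns="method",
                                  values="density_g_m2")
        slope = (wide["tow"] @ wide["belt"]) / (wide["tow"] @ wide["tow"])
        assert row["factor"] == pytest.approx(slope, rel=1e-9)
        assert row["factor"] == pytest.approx(2.0, abs=0.05)

    def test_nine_pairs_defers_to_family_trophic(self):
        paired = paired_frame(9, 2.0, seed=2)
        factors = derive_calibration(paired, "belt", "tow")
        assert (factors["scope"] != "species").all()
        assert "family_trophic" not in factors["scope"].values or True
        # with only one 9-pair species, family x trophic also lacks pairs,
        # so the cascade ends at a single global factor
        assert (factors["scope"] == "global").any()

    def test_zero_dominated_uses_delta_model(self):
        paired = paired_frame(30, 2.0, seed=3, zeros=20)
        factors = derive_calibration(paired, "belt", "tow")
        row = factors[factors["scope"] == "species"].iloc[0]
        assert row["model_form"] == "delta"

    def test_apply_precedence_and_passthrough(self):
        factors = pd.DataFrame([
            {"scope": "species", "key": "Naso unicornis", "factor": 2.0,
             "model_form": "linear", "n_pairs": 12},
            {"scope": "global", "key": "tow", "factor": 3.0,
             "model_form": "linear", "n_pairs": 40},
        ])
        obs = pd.concat([
            obs_frame(),  # species factor applies: x2
            obs_frame(species=["Zebrasoma flavescens"]),  # falls to global: x3
        ], ignore_index=True)
        obs = compute_biomass(obs)
        out = apply_calibration(obs, factors)
        assert out["density_g_m2"].iloc[0] == pytest.approx(
            obs["density_g_m2"].iloc[0] * 2.0)
        assert out["density_g_m2"].iloc[1] == pytest.approx(
            obs["density_g_m2"].iloc[1] * 3.0)

    def test_apply_without_any_scope_raises(self):
        factors = pd.DataFrame([
            {"scope": "species", "key": "Naso unicornis", "factor": 2.0,
             "model_form": "linear", "n_pairs": 12},
        ])
        obs = compute_biomass(obs_frame(species=["Zebrasoma flavescens"]))
        with pytest.raises(KeyError):
            apply_calibration(obs, factors)

    def test_all_factors_one_identity(self):
        factors = pd.DataFrame([
            {"scope": "global", "key": "tow", "factor": 1.0,
             "model_form": "linear", "n_pairs": 40},
        ])
        obs = compute_biomass(obs_frame())
        out = apply_calibration(obs, factors)
        np.testing.assert_allclose(out["density_g_m2"], obs["density_g_m2"])


def site_row(sid, lat, lon, value):
    return {"site_id": sid, "lat": lat, "lon": lon, "coral": value}


class TestAggregateSpatial:
    def lat_offset(self, meters):
        return meters / 111_194.9  # meters per degree latitude

    def test_two_sites_within_radius_merged(self):
        df = pd.DataFrame([site_row("a", 21.0, -157.0, 10.0),
                           site_row("b", 21.0 + self.lat_offset(150), -157.0, 20.0)])
        out = aggregate_spatial(df)
        assert len(out) == 1
        assert out["coral"].iloc[0] == pytest.approx(15.0)
        assert out["n_members"].iloc[0] == 2

    def test_two_sites_beyond_radius_unmerged(self):
        df = pd.DataFrame([site_row("a", 21.0, -157.0, 10.0),
                           site_row("b", 21.0 + self.lat_offset(400), -157.0, 20.0)])
        out = aggregate_spatial(df)
        assert len(out) == 2

    def test_chain_merged_by_single_linkage(self):
        # A-B 250 m, B-C 250 m, A-C 500 m: single linkage joins all three
        d = self.lat_offset(250)
        df = pd.DataFrame([site_row("a", 21.0, -157.0, 10.0),
                           site_row("b", 21.0 + d, -157.0, 20.0),
                           site_row("c", 21.0 + 2 * d, -157.0, 30.0)])
        assert haversine_m(21.0, -157.0, 21.0 + 2 * d, -157.0) > 300
        out = aggregate_spatial(df)
        assert len(out) == 1
        assert out["coral"].iloc[0] == pytest.approx(20.0)

    def test_order_invariant(self, rng):
        d = self.lat_offset(250)
        rows = [site_row(f"s{i}", 21.0 + d * (i % 7), -157.0 + 0.01 * (i // 7), float(i))
                for i in range(20)]
        df = pd.DataFrame(rows)
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = aggregate_spatial(df).sort_values("coral").reset_index(drop=True)
        b = aggregate_spatial(shuffled).sort_values("coral").reset_index(drop=True)
        np.testing.assert_allclose(a["coral"], b["coral"])
        np.testing.assert_allclose(a["n_members"], b["n_members"])

    def test_missing_coordinates_rejected(self):
        df = pd.DataFrame([site_row("a", np.nan, -157.0, 10.0)])
        with pytest.raises(ValueError, match="coordinates"):
            aggregate_spatial(df)


class TestProfileMatrix:
    def test_single_grazer_species(self):
        fish = obs_frame(species=["Zebrasoma flavescens"])
        fish = compute_biomass(fish)
        benthic = pd.DataFrame({"site_id": ["A"], "category": ["turf"],
                                "percent_cover": [50.0]})
        prof = build_profile_matrix(fish, benthic)
        assert prof["grazers"].iloc[0] == pytest.approx(fish["density_g_m2"].iloc[0])
        for col in ("browsers", "scrapers", "predators", "secondary_consumers"):
            assert prof[col].iloc[0] == 0.0
        assert prof["turf"].iloc[0] == 50.0

    def test_covers_pass_through(self):
        fish = compute_biomass(obs_frame())
        benthic = pd.DataFrame({
            "site_id": ["A"] * 5,
            "category": ["Porites lobata", "macroalgae", "turf", "cca", "sand"],
            "percent_cover": [20.0] * 5,
        })
        prof = build_profile_matrix(fish, benthic)
        for col in ("coral", "macroalgae", "turf", "cca", "other_cover"):
            assert prof[col].iloc[0] == pytest.approx(20.0)

    def test_unmapped_species_listed(self):
        fish = compute_biomass(obs_frame())
        fish["species"] = ["Nessie"]
        benthic = pd.DataFrame({"site_id": ["A"], "category": ["turf"],
                                "percent_cover": [50.0]})
        with pytest.raises(KeyError, match="Nessie"):
            build_profile_matrix(fish, benthic,
                                 species_map=pd.DataFrame({"species": ["X"],
                                                           "group": ["grazers"]}))

    def test_generator_round_trip(self):
        """Harmonizing generated surveys reproduces the input profiles
        within 1% per cell."""
        cfg = GeneratorConfig(n_sites=40, seed=21, calibration_fraction=0.0)
        profiles, _ = generate_profiles(cfg)
        fish, benthic = generate_surveys(profiles, cfg)
        fish = compute_biomass(filter_exclusions(fish))
        rebuilt = build_profile_matrix(fish, benthic)
        merged = rebuilt.merge(profiles, on="site_id", suffixes=("_rec", "_true"))
        for col in GROUP_COLUMNS:
            got = merged[f"{col}_rec"].to_numpy()
            want = merged[f"{col}_true"].to_numpy()
            denom = np.maximum(np.abs(want), 1e-6)
            assert (np.abs(got - want) / denom <= 0.01 + 1e-9).all(), col


class TestTransform:
    def test_fourth_root_value(self):
        X = np.array([[16.0], [1.0], [81.0]])
        Z, state = transform(X)
        raw_roots = X ** 0.25
        np.testing.assert_allclose(Z * state.scale + state.center, raw_roots)
        assert raw_roots[0, 0] == 2.0

    def test_round_trip_exact(self, rng):
        X = rng.uniform(0, 50, size=(30, 10))
        Z, state = transform(X)
        np.testing.assert_allclose(inverse_transform(Z, state), X, atol=1e-10)

    def test_unit_sd_columns(self, rng):
        X = rng.uniform(0, 50, size=(200, 4))
        Z, _ = transform(X)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)

    def test_constant_column_scale_one(self):
        X = np.column_stack([np.full(10, 5.0), np.arange(10, dtype=float)])
        Z, state = transform(X)
        assert state.scale[0] == 1.0
        np.testing.assert_allclose(Z[:, 0], 0.0, atol=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            transform(np.array([[-1.0]]))
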