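"""Feature assembly and the boosted-regression protocol."""

import numpy as np
import pandas as pd
import pytest

from troposse.states import ValidationError
from troposse.boostrates import (BoostSpec, assemble_features, bootstrap_models,
                                 bootstrap_importance, fit_and_validate,
                                 great_circle_km, predict_profiles,
                                 size_class_effects, tune_two_step)
from troposse.treesim import TraitGenSpec, constant_rate, simulate_trait_table


def _traits(index, **over):
    base = {"trophic": "GC", "size": 10.0, "activity": "diurnal",
            "position": "benthic", "basin": "both", "sst": 27.0, "prprod": 300.0}
    base.update(over)
    return pd.DataFrame({k: [v] * len(index) for k, v in base.items()},
                        index=index)


class TestAssembleFeatures:
    def test_cell_at_reference_point(self):
        occ = pd.DataFrame({"lat": [0.0], "lon": [121.0]}, index=["sp"])
        out = assemble_features(occ, _traits(["sp"]))
        assert out.loc["sp", "range"] == 1
        assert out.loc["sp", "abs_lat"] == 0.0
        assert out.loc["sp", "dist_iaa"] == pytest.approx(0.0, abs=1e-9)

    def test_one_degree_of_equatorial_arc(self):
        # pi/180 * 6371 km
        occ = pd.DataFrame({"lat": [0.0], "lon": [122.0]}, index=["sp"])
        out = assemble_features(occ, _traits(["sp"]))
        assert out.loc["sp", "dist_iaa"] == pytest.approx(
            np.pi / 180 * 6371.0, rel=1e-6)

    def test_symmetric_cells_cancel_latitude(self):
        occ = pd.DataFrame({"lat": [10.0, -10.0], "lon": [121.0, 121.0]},
                           index=["sp", "sp"])
        out = assemble_features(occ, _traits(["sp"]))
        assert out.loc["sp", "range"] == 2
        assert out.loc["sp", "abs_lat"] == 0.0

    def test_species_without_cells_dropped(self):
        occ = pd.DataFrame({"lat": [0.0], "lon": [121.0]}, index=["a"])
        out = assemble_features(occ, _traits(["a", "b"]))
        assert list(out.index) == ["a"]

    def test_bad_coordinates_rejected(self):
        occ = pd.DataFrame({"lat": [99.0], "lon": [0.0]}, index=["a"])
        with pytest.raises(ValidationError):
            assemble_features(occ, _traits(["a"]))

    def test_great_circle_symmetry(self):
        d1 = great_circle_km(-20.0, 100.0, 0.0, 121.0)
        d2 = great_circle_km(20.0, 100.0, 0.0, 121.0)
        assert d1 == pytest.approx(d2)


@pytest.fixture(scope="module")
def signal_data():
    gen = TraitGenSpec(n_species=700, noise_shape=30.0,
                       rate_fn=lambda g, s: 0.05 * (s / 25.0) ** 0.6, seed=3)
    return simulate_trait_table(gen)


HP = {"learning_rate": 0.1, "max_depth": 4, "gamma": 0.5, "subsample": 0.8,
      "num_boost_round": 60}


class TestTuning:
    def test_single_combo_passthrough(self, signal_data):
        table, rates = signal_data
        spec = BoostSpec(grid={"learning_rate": [0.1], "max_depth": [4],
                               "gamma": [0.5], "subsample": [0.8]},
                         stage2_draws=1, stage2_frac=0.0, num_boost_round=30,
                         seed=0)
        hp = tune_two_step(table, rates, spec)
        assert hp["stage1"] == {"learning_rate": 0.1, "max_depth": 4,
                                "gamma": 0.5, "subsample": 0.8}
        # with a zero-width band stage 2 re-draws the same combination
        assert hp["learning_rate"] == pytest.approx(0.1)
        assert hp["max_depth"] == 4

    def test_stage2_within_ten_percent(self, signal_data, monkeypatch):
        """Every stage-2 draw lies within +/-10% of the stage-1 best."""
        table, rates = signal_data
        import troposse.boostrates as br
        seen = []
        real = br._cv_rmse

        def spy(table_, y, hp, spec, seed):
            seen.append(dict(hp))
            return real(table_, y, hp, spec, seed)

        monkeypatch.setattr(br, "_cv_rmse", spy)
        spec = BoostSpec(grid={"learning_rate": [0.1], "max_depth": [4],
                               "gamma": [0.5], "subsample": [0.8]},
                         stage2_draws=25, num_boost_round=10, seed=1)
        tune_two_step(table, rates, spec)
        stage2 = seen[1:]
        assert len(stage2) == 25
        for hp in stage2:
            assert 0.09 <= hp["learning_rate"] <= 0.11
            assert 0.45 <= hp["gamma"] <= 0.55
            assert 0.72 <= hp["subsample"] <= 0.88
            assert hp["max_depth"] == 4          # integer rounding of +/-10%

    def test_nonpositive_response_rejected(self, signal_data):
        table, rates = signal_data
        bad = rates.copy()
        bad.iloc[0] = 0.0
        with pytest.raises(ValidationError):
            tune_two_step(table, bad, BoostSpec(seed=0))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            BoostSpec(grid={"learning_rate": []})


class TestValidation:
    def test_recoverable_signal(self, signal_data):
        table, rates = signal_data
        spec = BoostSpec(cv_reps=15, seed=4)
        out = fit_and_validate(table, rates, HP, spec)
        assert out["precision_r2"] > 0.5
        assert abs(out["accuracy_bias_pct"]) < 5.0
        assert out["n_reps"] == 15

    def test_overfit_interpolates_training_rows(self, signal_data):
        """A deep, unregularized fit approaches the observed values."""
        import xgboost as xgb
        from troposse.boostrates import _dmatrix, _train
        table, rates = signal_data
        hp = {"learning_rate": 0.5, "max_depth": 10, "gamma": 0.0,
              "subsample": 1.0, "num_boost_round": 300}
        model = _train(table, rates, hp, seed=0)
        pred = model.predict(_dmatrix(table))
        r = np.corrcoef(pred, rates)[0, 1]
        assert r ** 2 > 0.98


class TestImportanceAndProfiles:
    def test_importances_normalized(self, signal_data):
        table, rates = signal_data
        models = bootstrap_models(table, rates, HP, 10, seed=5)
        imp = bootstrap_importance(models)
        raw = imp.attrs["raw"].to_numpy()
        assert np.allclose(raw.sum(axis=1), 100.0, atol=1e-6)
        assert imp["chance"].iloc[0] == pytest.approx(10.0)
        assert (imp["q25"] <= imp["q75"]).all()

    def test_permuting_a_predictor_kills_its_importance(self, signal_data):
        table, rates = signal_data
        rng = np.random.default_rng(0)
        shuffled = table.copy()
        shuffled["size"] = rng.permutation(shuffled["size"].to_numpy())
        m_orig = bootstrap_models(table, rates, HP, 10, seed=6)
        m_perm = bootstrap_models(shuffled, rates, HP, 10, seed=6)
        i_orig = bootstrap_importance(m_orig).loc["size", "mean"]
        i_perm = bootstrap_importance(m_perm).loc["size", "mean"]
        assert i_perm < i_orig
        assert i_perm < 15.0                 # near or below the 10% chance line

    def test_profile_quantile_ordering(self, signal_data):
        table, rates = signal_data
        models = bootstrap_models(table, rates, HP, 10, seed=7)
        prof = predict_profiles(models, table, size_grid=20)
        s = prof.summary()
        assert (s["q25"] <= s["median"]).all() and (s["median"] <= s["q75"]).all()
        assert len(s) == 6 * 20

    def test_constant_response_constant_profiles(self):
        gen = TraitGenSpec(n_species=400, rate_fn=constant_rate(0.1),
                           noise_shape=1e6, seed=8)
        table, rates = simulate_trait_table(gen)
        models = bootstrap_models(table, rates, HP, 5, seed=9)
        prof = predict_profiles(models, table, size_grid=8)
        assert np.allclose(prof.summary()["median"], 0.1, rtol=0.02)

    def test_effects_of_identical_guilds_are_zero(self):
        gen = TraitGenSpec(n_species=400, rate_fn=constant_rate(0.1),
                           noise_shape=1e6, seed=10)
        table, rates = simulate_trait_table(gen)
        models = bootstrap_models(table, rates, HP, 5, seed=11)
        prof = predict_profiles(models, table, size_grid=30)
        eff = size_class_effects(prof)
        assert np.abs(eff["median_effect"]).max() < 0.002

    def test_planted_guild_contrast_in_profiles(self):
        base = {g: 0.05 for g in ("GC", "MI", "OM", "PK", "SI")}
        base["HD"] = 0.10
        from troposse.treesim import guild_size_rate
        gen = TraitGenSpec(n_species=1200, rate_fn=guild_size_rate(base),
                           noise_shape=20.0, seed=12)
        table, rates = simulate_trait_table(gen)
        models = bootstrap_models(table, rates, HP, 20, seed=13)
        prof = predict_profiles(models, table, size_grid=10)
        s = prof.summary()
        hd = s[s["trophic"] == "HD"].set_index("size")["median"]
        gc = s[s["trophic"] == "GC"].set_index("size")["median"]
        assert (hd.to_numpy() > gc.to_numpy()).mean() >= 0.9
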