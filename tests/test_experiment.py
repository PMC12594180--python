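"""Scenario training: regimes, balancing, mean predictor, leakage."""

import dataclasses
import logging

import numpy as np
import pytest

import tmelt
from tmelt.data import EmbeddedProtein, MeltomeDataset
from tmelt.experiment import (
    ScenarioSpec,
    balanced_batch_weights,
    mean_predictor,
    train_scenario,
)

FAST = dict(max_epochs=12, patience=5)


def _mini_ds(rng, species_sizes, dim=6, length=8, no_val_species=(), mu=None):
    proteins = []
    for s, n in enumerate(species_sizes):
        name = f"sp{s}"
        center = (mu or {}).get(name, 50.0 + 10 * s)
        for i in range(n):
            if name in no_val_species:
                split = "train" if i < n - 1 else "test"
            else:
                split = "train" if i < int(0.7 * n) else ("val" if i < int(0.85 * n) else "test")
            proteins.append(
                EmbeddedProtein(
                    f"{name}_{i:04d}",
                    name,
                    rng.standard_normal((length, dim)).astype(np.float32),
                    center + rng.normal(0, 3),
                    split,
                )
            )
    return MeltomeDataset(proteins)


class TestBalancedWeights:
    def test_equal_sizes_give_uniform_weights(self, rng):
        ds = _mini_ds(rng, [20, 20, 20])
        w = balanced_batch_weights(ds)
        np.testing.assert_allclose(w, w[0])

    def test_inverse_frequency_ratio(self, rng):
        ds = _mini_ds(rng, [100, 300])
        w = balanced_batch_weights(ds)
        train = ds.split_proteins("train")
        w_by_species = {}
        for wi, p in zip(w, train):
            w_by_species.setdefault(p.species, wi)
        assert w_by_species["sp0"] / w_by_species["sp1"] == pytest.approx(3.0)

    def test_resampling_balances_species_frequencies(self, rng):
        ds = _mini_ds(rng, [40, 120])
        w = balanced_batch_weights(ds)
        train = ds.split_proteins("train")
        draws = np.random.default_rng(0).choice(len(train), size=10_000, p=w)
        frac_sp0 = np.mean([train[i].species == "sp0" for i in draws])
        se = np.sqrt(0.25 / 10_000)
        assert abs(frac_sp0 - 0.5) < 3 * se


class TestMeanPredictor:
    def test_predicts_train_mean(self):
        proteins = [
            EmbeddedProtein("a_1", "a", np.zeros((3, 2), np.float32), 50.0, "train"),
            EmbeddedProtein("a_2", "a", np.zeros((3, 2), np.float32), 60.0, "train"),
            EmbeddedProtein("a_3", "a", np.zeros((3, 2), np.float32), 70.0, "test"),
        ]
        ds = MeltomeDataset(proteins)
        for scope in ("global", "per_species"):
            recs = mean_predictor(ds, scope)
            assert len(recs) == 1 and recs[0].y_pred == 55.0

    def test_species_without_training_data_errors(self, rng):
        proteins = [
            EmbeddedProtein("a_1", "a", np.zeros((3, 2), np.float32), 50.0, "train"),
            EmbeddedProtein("b_1", "b", np.zeros((3, 2), np.float32), 70.0, "test"),
        ]
        ds = MeltomeDataset(proteins)
        with pytest.raises(ValueError, match="'b'"):
            mean_predictor(ds, "per_species")
        assert mean_predictor(ds, "global")[0].y_pred == 50.0

    def test_matches_synthetic_oracles(self, tiny_config, tiny_dataset):
        g = tmelt.rmse(mean_predictor(tiny_dataset, "global"))
        s = tmelt.rmse(mean_predictor(tiny_dataset, "per_species"))
        # small test sets: generous Monte Carlo tolerance, but the ordering
        # and rough magnitudes must match the closed forms
        assert s < g
        assert g == pytest.approx(tmelt.mean_predictor_rmse_oracle(tiny_config, "global"), rel=0.35)
        assert s == pytest.approx(tmelt.mean_predictor_rmse_oracle(tiny_config, "per_species"), rel=0.35)


class TestScenarioSpec:
    def test_learning_rate_defaults_follow_regime(self):
        assert ScenarioSpec(regime="G").resolved_lr() == 1e-4
        assert ScenarioSpec(regime="GB").resolved_lr() == 1e-4
        assert ScenarioSpec(regime="S").resolved_lr() == 1e-3
        assert ScenarioSpec(approach="rnc", regime="G").resolved_lr_predictor() == 1e-4
        assert ScenarioSpec(approach="rnc", regime="S").resolved_lr_predictor() == 1e-3
        assert ScenarioSpec().lr_encoder == 1e-5

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(approach="lora")
        with pytest.raises(ValueError):
            ScenarioSpec(regime="X")
        with pytest.raises(ValueError):
            ScenarioSpec(lr=-1.0)


class TestTrainScenario:
    def test_fixed_seed_reproducibility(self, rng):
        ds = _mini_ds(rng, [30, 30])
        r1 = train_scenario(ds, ScenarioSpec(seed=7, **FAST))
        r2 = train_scenario(ds, ScenarioSpec(seed=7, **FAST))
        assert r1 == r2

    def test_single_species_s_regime_degenerates_to_global(self, rng):
        ds = _mini_ds(rng, [40])
        sg = ScenarioSpec(regime="G", lr=1e-3, seed=3, **FAST)
        ss = ScenarioSpec(regime="S", lr=1e-3, seed=3, **FAST)
        rg = train_scenario(ds, sg)
        rs = train_scenario(ds, ss)
        assert [r.protein_id for r in rg] == [r.protein_id for r in rs]
        np.testing.assert_allclose([r.y_pred for r in rg], [r.y_pred for r in rs])

    def test_species_without_validation_is_skipped_with_warning(self, rng, caplog):
        ds = _mini_ds(rng, [30, 12], no_val_species=("sp1",))
        with caplog.at_level(logging.WARNING, logger="tmelt.experiment"):
            recs = train_scenario(ds, ScenarioSpec(regime="S", seed=0, **FAST))
        assert all(r.species == "sp0" for r in recs)
        assert any("sp1" in m and "skipped" in m for m in caplog.messages)

    def test_tiny_validation_falls_back_to_train_monitoring(self, rng, caplog):
        proteins = [
            EmbeddedProtein(f"a_{i}", "a", rng.standard_normal((6, 4)).astype(np.float32),
                            50.0 + i, "train" if i < 10 else ("val" if i == 10 else "test"))
            for i in range(13)
        ]
        ds = MeltomeDataset(proteins)
        with caplog.at_level(logging.WARNING, logger="tmelt.experiment"):
            recs = train_scenario(ds, ScenarioSpec(regime="G", seed=0, **FAST))
        assert len(recs) == 2
        assert any("falls back to training RMSE" in m for m in caplog.messages)

    def test_concat_requires_structure_view(self, rng):
        ds = _mini_ds(rng, [20])
        with pytest.raises(ValueError, match="structure"):
            train_scenario(ds, ScenarioSpec(approach="concat", **FAST))

    def test_test_labels_never_influence_predictions(self, rng):
        """Poisoning the test labels must leave every prediction unchanged."""
        ds = _mini_ds(rng, [25, 25])
        poisoned = MeltomeDataset(
            [
                dataclasses.replace(p, tm=p.tm + 1000.0) if p.split == "test" else p
                for p in ds.proteins
            ]
        )
        for approach in ("baseline", "dual"):
            spec = ScenarioSpec(approach=approach, regime="G", seed=2, **FAST)
            clean = train_scenario(ds, spec)
            dirty = train_scenario(poisoned, spec)
            np.testing.assert_array_equal(
                [r.y_pred for r in clean], [r.y_pred for r in dirty]
            )

    def test_record_bookkeeping(self, rng):
        ds = _mini_ds(rng, [30, 30])
        recs = train_scenario(ds, ScenarioSpec(seed=0, **FAST))
        test = ds.split_proteins("test")
        assert {r.protein_id for r in recs} == {p.protein_id for p in test}
        assert all(r.split == "test" and r.approach == "baseline" and r.regime == "G" for r in recs)


def test_species_specific_training_wins_when_signal_is_local():
    """Directional check: with learnable within-species signal, per-species
    models beat the pooled model on mean per-species RMSE."""
    cfg = tmelt.SyntheticConfig(
        n_species=4, proteins_per_species=100, embedding_dim=10,
        length_range=(20, 30), kappa=0.4, seed=17,
    )
    ds = tmelt.generate_dataset(cfg)
    rg = train_scenario(ds, ScenarioSpec(regime="G", max_epochs=60, patience=10, seed=1))
    rs = train_scenario(ds, ScenarioSpec(regime="S", max_epochs=60, patience=10, seed=1))
    rep = tmelt.build_report(rg + rs, n_boot=50)
    assert rep.scenario("baseline", "S").mean_species_rmse < rep.scenario("baseline", "G").mean_species_rmse
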