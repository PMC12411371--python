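"""Synthetic replicate-study generator: calibration and signal placement."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from reprofeat.concordance import ccc, ccc_per_feature
from reprofeat.synthetic import GeneratorConfig, generate, preset, theoretical_ccc


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"reliability": (0.5, 1.2), "n_features": 2},
        {"reliability": (-0.1, 0.5), "n_features": 2},
        {"reliability": (0.5,), "n_features": 2},
        {"scenario": "bogus"},
        {"scenario": "distributed", "n_carriers": 0},
        {"scenario": "distributed", "n_carriers": 200, "n_features": 100},
        {"effect_size": -1.0},
        {"class_balance": 0.0},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorConfig(**kw)

    def test_default_reliability_spans_range(self):
        rel = GeneratorConfig().resolved_reliability()
        assert rel.min() == pytest.approx(0.05) and rel.max() == pytest.approx(0.95)

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(n_train=50, n_test=20, n_features=4,
                              reliability=(0.1, 0.4, 0.6, 0.9),
                              scenario="distributed", n_carriers=2, seed=5)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert GeneratorConfig.from_yaml(tmp_path / "cfg.yaml") == cfg


class TestTheoreticalCCC:
    def test_pass_through_for_null(self):
        cfg = GeneratorConfig(n_features=2, reliability=(0.3, 0.9))
        assert theoretical_ccc(cfg).tolist() == [0.3, 0.9]
        cfg0 = GeneratorConfig(n_features=3, reliability=(0.0, 0.0, 0.0))
        assert theoretical_ccc(cfg0).tolist() == [0.0, 0.0, 0.0]

    def test_rejects_non_null_scenario(self):
        cfg = GeneratorConfig(scenario="distributed")
        with pytest.raises(ValueError):
            theoretical_ccc(cfg)


class TestGenerate:
    def test_structure_and_determinism(self, small_study):
        cfg, study = small_study
        again = generate(cfg)
        assert study.train_rep1.equals(again.train_rep1)
        assert study.test_features.equals(again.test_features)
        assert study.train_labels.equals(again.train_labels)
        assert study.feature_names == list(study.test_features.columns)
        assert not study.train_rep1.isna().any().any()
        # class counts follow class_balance up to rounding
        assert study.train_labels.sum() == round(cfg.class_balance * cfg.n_train)
        assert study.test_labels.sum() == round(cfg.class_balance * cfg.n_test)

    def test_noiseless_limit_gives_ccc_one(self):
        cfg = GeneratorConfig(n_train=200, n_test=10, n_features=5,
                              reliability=(1.0,) * 5, seed=3)
        study = generate(cfg)
        out = ccc_per_feature(study.train_rep1, study.train_rep2)
        assert np.all(np.abs(out.to_numpy() - 1.0) < 0.01)

    def test_null_scenario_ccc_matches_reliability_targets(self):
        cfg = GeneratorConfig(n_train=5000, n_test=10, n_features=10,
                              reliability=(0.5,) * 10, seed=4)
        out = ccc_per_feature(generate(cfg).train_rep1, generate(cfg).train_rep2)
        assert np.all(np.abs(out.to_numpy() - 0.5) < 0.05)

    def test_replicate_shift_breaks_concordance_not_correlation(self):
        base = GeneratorConfig(n_train=2000, n_test=10, n_features=3,
                               reliability=(0.9,) * 3, seed=6)
        shifted = dataclasses.replace(base, replicate_shift=3.0)
        s0, s1 = generate(base), generate(shifted)
        c0 = ccc_per_feature(s0.train_rep1, s0.train_rep2).mean()
        c1 = ccc_per_feature(s1.train_rep1, s1.train_rep2).mean()
        assert c1 < c0 - 0.4

    def test_distributed_carriers_nonconcordant_but_sum_informative(self):
        cfg = GeneratorConfig(n_train=5000, n_test=10, n_features=10,
                              scenario="distributed", n_carriers=3,
                              effect_size=2.0, seed=8)
        study = generate(cfg)
        vals = ccc_per_feature(study.train_rep1, study.train_rep2)
        carriers = [study.feature_names[j] for j in cfg.carriers()]
        carrier_ccc = vals[carriers].to_numpy()
        assert np.all(carrier_ccc < 0.6)
        sum_ccc = ccc(study.train_rep1[carriers].sum(axis=1),
                      study.train_rep2[carriers].sum(axis=1))
        assert sum_ccc > carrier_ccc.max()

    def test_concentrated_carriers_are_most_reliable_and_class_shifted(self):
        cfg = preset("concentrated", seed=9, n_train=500)
        study = generate(cfg)
        rel = cfg.resolved_reliability()
        assert np.all(rel[cfg.carriers()] >= 0.9)
        carriers = [study.feature_names[j] for j in cfg.carriers()]
        y = study.train_labels
        gap = study.train_rep1.loc[y == 1, carriers].mean() - \
            study.train_rep1.loc[y == 0, carriers].mean()
        assert (gap > 1.0).all()

    def test_null_scenario_features_uncorrelated_with_labels(self):
        cfg = preset("null", seed=10, n_train=2000)
        study = generate(cfg)
        y = study.train_labels.to_numpy()
        corr = study.train_rep1.apply(lambda c: np.corrcoef(c, y)[0, 1])
        assert np.abs(corr).max() < 0.1
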