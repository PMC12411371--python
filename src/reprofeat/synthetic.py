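"""Synthetic generator for radiomics-style replicate feature tables.

Emulates a test-retest feature study: many correlated continuous features
measured twice on every training subject (think features from image slices
just above vs just below a tumor's central slice), once on every test
subject, plus a binary outcome label.

Generative law, per subject i and feature f with reliability target r_f:

    x_{i,f}^{(rep)} = s_{i,f} + e_{i,f}^{(rep)},   e ~ N(0, 1 - r_f) iid per replicate
    s_{i,f} = sqrt(r_f) * t_{i,f},                 Var(t) = 1

so Var(s) / (Var(s) + Var(e)) = r_f and, with equal replicate means, the
theoretical CCC of feature f equals r_f exactly. The stable component t
carries background correlation through a small number of shared latent
factors, mimicking the strong inter-feature correlation of real radiomic
panels.

Class signal placement (the point of the generator) is controlled by
``scenario``:

``concentrated``
    A class-shifted latent z is added to the *stable* part of the
    ``n_carriers`` most reliable features: the signal lives in features
    that are individually highly concordant between replicates.
``distributed``
    The same latent z is added to exactly ONE of the ``n_carriers`` least
    reliable features per subject *per replicate*, the carrier chosen
    uniformly at random -- the elephant mechanism. Each carrier alone is
    non-concordant (the signal keeps "moving rooms" between replicates),
    yet the carrier aggregate retains the full signal.
``null``
    No signal; labels are independent of all features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed

SCENARIOS = ("concentrated", "distributed", "null")


@dataclass(frozen=True)
class GeneratorConfig:
    n_train: int = 300
    n_test: int = 150
    n_features: int = 100
    #: Target CCC per feature, in [0, 1]. None -> evenly spaced over
    #: [0.05, 0.95], spanning the reliability range seen in real panels.
    reliability: tuple[float, ...] | None = None
    scenario: str = "null"
    #: Number of features sharing the latent class signal.
    n_carriers: int = 3
    #: Standardized class separation of the latent signal z (in SD of z).
    effect_size: float = 2.0
    #: Amplitude of z injected into carrier features, in units of the
    #: features' unit marginal SD. Chosen so the carrier aggregate is
    #: strongly predictive even under one-hot (distributed) allocation.
    signal_scale: float = 3.0
    class_balance: float = 0.5
    #: Shared latent factors inducing background feature correlation.
    n_factors: int = 5
    #: Fraction of stable-component variance from the shared factors.
    factor_strength: float = 0.3
    #: Systematic mean shift of replicate 2 (0 = exchangeable replicates).
    replicate_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 2 or self.n_test < 1:
            raise ValueError("need n_train >= 2 and n_test >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        rel = self.resolved_reliability()
        if len(rel) != self.n_features:
            raise ValueError(
                f"reliability has length {len(rel)}, expected n_features={self.n_features}")
        if np.any(rel < 0.0) or np.any(rel > 1.0):
            raise ValueError("reliability values must lie in [0, 1]")
        if self.scenario != "null":
            if self.n_carriers < 1:
                raise ValueError("n_carriers must be >= 1 for a non-null scenario")
            if self.n_carriers > self.n_features:
                raise ValueError("n_carriers cannot exceed n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if not 0.0 <= self.factor_strength <= 1.0:
            raise ValueError("factor_strength must be in [0, 1]")
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")

    def resolved_reliability(self) -> np.ndarray:
        if self.reliability is None:
            return np.linspace(0.05, 0.95, self.n_features)
        return np.asarray(self.reliability, dtype=float)

    def carriers(self) -> np.ndarray:
        """Indices of the signal-carrying features for this scenario."""
        rel = self.resolved_reliability()
        order = np.argsort(rel, kind="stable")
        if self.scenario == "concentrated":
            return np.sort(order[-self.n_carriers:])
        if self.scenario == "distributed":
            return np.sort(order[:self.n_carriers])
        return np.array([], dtype=int)

    # --- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        if d["reliability"] is not None:
            d["reliability"] = [float(v) for v in d["reliability"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("reliability") is not None:
            d["reliability"] = tuple(d["reliability"])
        return cls(**d)


@dataclass(frozen=True)
class ReplicateStudy:
    """Two replicate training tables + labels, and a single-measurement test set."""

    train_rep1: pd.DataFrame
    train_rep2: pd.DataFrame
    train_labels: pd.Series
    test_features: pd.DataFrame
    test_labels: pd.Series

    def __post_init__(self) -> None:
        if list(self.train_rep1.columns) != list(self.train_rep2.columns) or \
                list(self.train_rep1.columns) != list(self.test_features.columns):
            raise ValueError("feature names differ across study tables")
        if not self.train_rep1.index.equals(self.train_rep2.index):
            raise ValueError("sample IDs differ between the two training replicates")
        if not self.train_rep1.index.equals(self.train_labels.index):
            raise ValueError("training labels misaligned with training tables")
        if not self.test_features.index.equals(self.test_labels.index):
            raise ValueError("test labels misaligned with test table")

    @property
    def feature_names(self) -> list[str]:
        return list(self.train_rep1.columns)


def _labels(rng: np.random.Generator, n: int, balance: float) -> np.ndarray:
    y = np.zeros(n, dtype=np.int64)
    y[rng.choice(n, size=int(round(balance * n)), replace=False)] = 1
    return y


def _stable_component(rng: np.random.Generator, n: int, cfg: GeneratorConfig,
                      rel: np.ndarray) -> np.ndarray:
    """Unit-variance correlated latent t, scaled to sqrt(r_f)."""
    assign = np.arange(cfg.n_features) % cfg.n_factors
    g = rng.standard_normal((n, cfg.n_factors))
    u = rng.standard_normal((n, cfg.n_features))
    c = cfg.factor_strength
    t = np.sqrt(c) * g[:, assign] + np.sqrt(1.0 - c) * u
    return np.sqrt(rel) * t


def _signal_latent(rng: np.random.Generator, y: np.ndarray,
                   effect_size: float) -> np.ndarray:
    return rng.standard_normal(y.size) + effect_size * y


def generate(config: GeneratorConfig) -> ReplicateStudy:
    """Draw a full replicate study under the generative law above.

    The test set is drawn from the replicate-1 law (single measurement);
    in the distributed scenario its one-hot carrier allocation is drawn
    once, as a single measurement implies.
    """
    rel = config.resolved_reliability()
    noise_sd = np.sqrt(1.0 - rel)
    carriers = config.carriers()
    names = [f"feat_{j:04d}" for j in range(config.n_features)]

    def build(rng: np.random.Generator, n: int, n_reps: int, prefix: str):
        y = _labels(rng, n, config.class_balance)
        s = _stable_component(rng, n, config, rel)
        z = _signal_latent(rng, y, config.effect_size)
        if config.scenario == "concentrated":
            s = s.copy()
            s[:, carriers] += config.signal_scale * z[:, None]
        reps = []
        for _ in range(n_reps):
            x = s + noise_sd * rng.standard_normal((n, config.n_features))
            if config.scenario == "distributed":
                alloc = carriers[rng.integers(0, carriers.size, size=n)]
                x[np.arange(n), alloc] += config.signal_scale * z
            reps.append(x)
        idx = pd.Index([f"{prefix}_{i:04d}" for i in range(n)], name="sample_id")
        tables = [pd.DataFrame(x, index=idx, columns=names) for x in reps]
        labels = pd.Series(y, index=idx, name="label")
        return tables, labels

    rng_train = np.random.default_rng(derive_seed(config.seed, "train"))
    (rep1, rep2), y_train = build(rng_train, config.n_train, 2, "train")
    rep2 = rep2 + config.replicate_shift
    rng_test = np.random.default_rng(derive_seed(config.seed, "test"))
    (test,), y_test = build(rng_test, config.n_test, 1, "test")
    return ReplicateStudy(train_rep1=rep1, train_rep2=rep2, train_labels=y_train,
                          test_features=test, test_labels=y_test)


def theoretical_ccc(config: GeneratorConfig) -> np.ndarray:
    """Expected per-feature CCC under the null generative law.

    Equals the reliability vector: with equal replicate means the CCC of
    s + e1 vs s + e2 is Var(s) / (Var(s) + Var(e)). Only guaranteed
    without signal injection, hence restricted to scenario='null'.
    """
    if config.scenario != "null":
        raise ValueError("theoretical CCC is only available for the null scenario")
    return config.resolved_reliability().copy()


def preset(scenario: str, seed: int = 0, n_features: int = 50,
           n_train: int = 300, n_test: int = 150) -> GeneratorConfig:
    """Desk-scale study configurations for the three signal regimes."""
    return GeneratorConfig(n_train=n_train, n_test=n_test, n_features=n_features,
                           scenario=scenario, seed=seed)
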