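"""The "elephants in the house" test-retest simulator.

Each house is a subject; each room is a binary feature. A house either
contains one elephant or none (the binary label). At each of two timepoints
the elephant occupies one room, drawn independently and uniformly, so the
room indicators vary strongly between timepoints while the OR over rooms
is a perfect indicator of the label at both timepoints.

This toy makes per-feature test-retest concordance and predictive value
come apart: at prevalence p with R rooms, the per-room CCC tends to
(1 - p) / (R - p) as the number of houses grows (0.2 for R=3, p=0.5),
far below the conventional 0.70 reproducibility cutoff, while the OR rule
scores a perfect AUC of 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .concordance import ccc, mean_ci

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElephantConfig:
    """Configuration of one simulated test-retest cohort of houses."""

    n_houses: int
    n_rooms: int = 3
    prevalence: float = 0.5
    seed: int = 0
    #: If True, an elephant must change rooms between timepoints (requires
    #: n_rooms >= 2). Default False: independent uniform re-draw, the
    #: elephant may stay put, which admits the closed form above.
    forced_move: bool = False

    def __post_init__(self) -> None:
        if self.n_houses < 1:
            raise ValueError(f"n_houses must be >= 1, got {self.n_houses}")
        if self.n_rooms < 1:
            raise ValueError(f"n_rooms must be >= 1, got {self.n_rooms}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.forced_move and self.n_rooms < 2:
            raise ValueError("forced_move requires at least 2 rooms")


@dataclass(frozen=True)
class ElephantDataset:
    """Binary room-occupancy matrices at two timepoints plus labels.

    Invariant: every row of X1 and X2 sums to the house's label (0 or 1) --
    one elephant per occupied house, none in empty houses.
    """

    X1: np.ndarray
    X2: np.ndarray
    labels: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format export with a `timepoint` column."""
        n, r = self.X1.shape
        names = [f"room_{j + 1}" for j in range(r)]
        frames = []
        for tp, x in ((1, self.X1), (2, self.X2)):
            df = pd.DataFrame(x, columns=names,
                              index=pd.Index([f"house_{i + 1}" for i in range(n)],
                                             name="sample_id"))
            df.insert(0, "timepoint", tp)
            df["label"] = self.labels
            frames.append(df)
        return pd.concat(frames)


def simulate_houses(config: ElephantConfig) -> ElephantDataset:
    """Simulate room occupancy at two timepoints.

    Exactly round(prevalence * n_houses) houses receive an elephant
    (deterministic count, random placement), so both classes are present
    whenever 0 < prevalence < 1 and n_houses >= 2. For each elephant house
    the occupied room at each timepoint is uniform over rooms, independent
    between timepoints (unless ``forced_move``).
    """
    rng = np.random.default_rng(config.seed)
    n, r = config.n_houses, config.n_rooms
    n_pos = int(round(config.prevalence * n))
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1

    X1 = np.zeros((n, r), dtype=np.int64)
    X2 = np.zeros((n, r), dtype=np.int64)
    pos = np.flatnonzero(labels)
    rooms1 = rng.integers(0, r, size=pos.size)
    if config.forced_move:
        # draw uniformly over the r-1 other rooms
        shift = rng.integers(1, r, size=pos.size)
        rooms2 = (rooms1 + shift) % r
    else:
        rooms2 = rng.integers(0, r, size=pos.size)
    X1[pos, rooms1] = 1
    X2[pos, rooms2] = 1
    return ElephantDataset(X1=X1, X2=X2, labels=labels)


def or_rule_scores(X: np.ndarray) -> np.ndarray:
    """OR over room indicators: 1 if any room is occupied, else 0."""
    X = np.asarray(X)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("or_rule_scores requires a binary (0/1) matrix")
    return (X.max(axis=1) > 0).astype(np.int64)


def per_feature_ccc(dataset: ElephantDataset) -> np.ndarray:
    """CCC of each room indicator between the two timepoints (NaN if undefined)."""
    return np.array([ccc(dataset.X1[:, j], dataset.X2[:, j])
                     for j in range(dataset.X1.shape[1])])


def theoretical_ccc(n_rooms: int, prevalence: float) -> float:
    """Large-cohort per-room CCC under the uniform re-draw law.

    Cov(X1_j, X2_j) = p(1-p)/R^2 and Var(X_j) = (p/R)(1 - p/R) give
    rho_c = (1 - p) / (R - p).
    """
    return (1.0 - prevalence) / (n_rooms - prevalence)


def sample_size_sweep(sizes, repeats: int, base: ElephantConfig,
                      level: float = 0.95) -> pd.DataFrame:
    """Mean per-repeat CCC (averaged over rooms) vs cohort size, with CIs.

    For each size, ``repeats`` independent cohorts are simulated under seeds
    derived from ``base.seed``; the statistic per repeat is the mean of the
    per-room CCCs (undefined rooms dropped and counted). Returns a table
    sorted by size with columns size, mean_ccc, ci_lo, ci_hi, n_dropped.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes must be non-empty")
    if any(s < 2 for s in sizes):
        raise ValueError(f"every size must be >= 2, got {sizes}")
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")

    rows = []
    for size in sorted(sizes):
        per_repeat = []
        n_dropped = 0
        for rep in range(repeats):
            cfg = ElephantConfig(
                n_houses=int(size), n_rooms=base.n_rooms,
                prevalence=base.prevalence,
                seed=derive_seed(base.seed, "samplesize", size, rep),
                forced_move=base.forced_move,
            )
            vals = per_feature_ccc(simulate_houses(cfg))
            defined = vals[~np.isnan(vals)]
            n_dropped += int(np.isnan(vals).sum())
            if defined.size:
                per_repeat.append(float(defined.mean()))
        if n_dropped:
            logger.info("sample_size_sweep: size=%d dropped %d undefined CCCs",
                        size, n_dropped)
        ci = mean_ci(per_repeat, level=level)
        rows.append({"size": int(size), "mean_ccc": ci.mean,
                     "ci_lo": ci.lo, "ci_hi": ci.hi, "n_dropped": n_dropped})
    return pd.DataFrame(rows)
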