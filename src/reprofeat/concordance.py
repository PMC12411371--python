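"""Lin's concordance correlation coefficient (CCC) and aggregation helpers.

The CCC measures agreement between two measurements of the same quantity,

    rho_c = 2 * s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2),

combining Pearson correlation with a penalty for mean and scale
disagreement. Moments are population moments (divide by n), following Lin's
original estimator; sample-moment variants change values at small n.

A feature whose denominator vanishes (both measurement vectors constant and
equal) has no defined CCC; such features carry NaN as an undefined sentinel
and are excluded downstream rather than raising, so a degenerate feature
cannot abort a long repeated experiment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Sentinel for an undefined CCC (zero denominator).
UNDEFINED = float("nan")


@dataclass(frozen=True)
class MeanCI:
    """Mean with a normal-approximation confidence interval over k repeats."""

    mean: float
    lo: float
    hi: float
    k: int

    @property
    def width(self) -> float:
        return self.hi - self.lo


def _validate_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"paired vectors differ in length: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError(f"need at least 2 pairs for a defined CCC, got {x.size}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed in paired vectors")
    return x, y


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient of two paired vectors.

    Returns a value in [-1, 1], or NaN (the undefined sentinel) when both
    vectors are constant and equal so the denominator is exactly zero.
    Symmetric in (x, y) and invariant under a common additive shift.
    """
    x, y = _validate_pair(x, y)
    mx, my = x.mean(), y.mean()
    vx = np.mean((x - mx) ** 2)
    vy = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        return UNDEFINED
    return float(2.0 * sxy / denom)


def ccc_per_feature(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.Series:
    """Per-feature CCC between two aligned replicate feature tables.

    Both tables must share the same feature columns and the same sample IDs
    in the same order (no silent realignment). Features with an undefined
    CCC carry NaN; a summary of such features is logged.
    """
    cols_a, cols_b = list(table_a.columns), list(table_b.columns)
    if cols_a != cols_b:
        only_a = sorted(set(cols_a) - set(cols_b))
        only_b = sorted(set(cols_b) - set(cols_a))
        raise ValueError(
            "feature columns differ between replicate tables: "
            f"only in first={only_a}, only in second={only_b}, "
            f"or column order differs"
        )
    if not table_a.index.equals(table_b.index):
        raise ValueError(
            "sample IDs (index) differ between replicate tables; "
            f"first starts {list(table_a.index[:5])}, second starts {list(table_b.index[:5])}"
        )
    values = {name: ccc(table_a[name].to_numpy(), table_b[name].to_numpy())
              for name in cols_a}
    out = pd.Series(values, name="ccc")
    n_undef = int(out.isna().sum())
    if n_undef:
        logger.info(
            "ccc_per_feature: %d/%d features undefined (constant and equal in both "
            "replicates): %s", n_undef, len(out), sorted(out.index[out.isna()])[:10],
        )
    return out


def mean_ci(values, level: float = 0.95) -> MeanCI:
    """Mean of repeat-level values with a normal-approximation CI.

    CI is mean +/- z(level) * sd / sqrt(k) with the sample sd (divide by
    k - 1). With a single value, or zero variance, the interval collapses
    to the mean. NaNs must be removed by the caller before the call.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("mean_ci requires a non-empty vector of values")
    if np.isnan(v).any():
        raise ValueError("mean_ci received NaN; drop undefined values first")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    k = int(v.size)
    m = float(v.mean())
    if k == 1:
        return MeanCI(mean=m, lo=m, hi=m, k=1)
    sd = float(v.std(ddof=1))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    half = z * sd / math.sqrt(k)
    return MeanCI(mean=m, lo=m - half, hi=m + half, k=k)
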