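"""Three serial data-reduction filters pruning the GCOD pool before model search.

The raw occupancy pool is far larger than the training set, so descriptors are
eliminated in three serial levels: (1) columns whose Pearson correlation with
the training activities has absolute value below a floor, (2) columns whose
self-variance over the training compounds is below a preset fraction, and
(3) columns occupied by too few compounds (too many exact-zero entries).
The filters are per-column predicates, so the surviving set is independent of
stage order; the order only determines which stage an audit log charges a
column to.

Presets ship for the six alignment x cell-size combinations of the original
analysis; all share the 0.1 correlation floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .align_grid import OccupancyMatrix

__all__ = ["ReductionConfig", "PRESETS", "GcodReducer", "reduce_descriptors"]


@dataclass(frozen=True)
class ReductionConfig:
    min_abs_activity_corr: float = 0.1
    min_self_variance: float = 0.004
    max_empty_cells: int = 37

    def __post_init__(self):
        if self.min_abs_activity_corr < 0 or self.min_self_variance < 0:
            raise ValueError("thresholds must be non-negative")
        if self.max_empty_cells < 0:
            raise ValueError("max_empty_cells must be non-negative")


#: named presets, keyed ``a<alignment>_c<cell size x10>``
PRESETS: dict[str, ReductionConfig] = {
    "a1_c20": ReductionConfig(0.1, 0.00800, 37),
    "a1_c10": ReductionConfig(0.1, 0.00400, 37),
    "a2_c20": ReductionConfig(0.1, 0.00500, 37),
    "a2_c10": ReductionConfig(0.1, 0.00015, 36),
    "a3_c20": ReductionConfig(0.1, 0.00500, 38),
    "a3_c10": ReductionConfig(0.1, 0.00018, 36),
}


class GcodReducer(SelectorMixin, BaseEstimator):
    """Serial activity-correlation / self-variance / empty-cell column filter.

    A scikit-learn selector: ``fit(X, y)`` computes the survivor mask over the
    training compounds, ``transform`` drops the pruned columns.  ``audit_``
    records, per column, its correlation, variance, zero count, and the first
    stage (if any) that eliminated it.

    Parameters follow the three serial levels: ``min_abs_activity_corr``
    (stage 1, |Pearson R| floor), ``min_self_variance`` (stage 2, n-1
    denominator), ``max_empty_cells`` (stage 3, maximum number of training
    compounds with exactly zero occupancy).
    """

    def __init__(
        self,
        min_abs_activity_corr: float = 0.1,
        min_self_variance: float = 0.004,
        max_empty_cells: int = 37,
    ):
        self.min_abs_activity_corr = min_abs_activity_corr
        self.min_self_variance = min_self_variance
        self.max_empty_cells = max_empty_cells

    @classmethod
    def from_config(cls, config: ReductionConfig | str) -> "GcodReducer":
        if isinstance(config, str):
            config = PRESETS[config]
        return cls(
            config.min_abs_activity_corr,
            config.min_self_variance,
            config.max_empty_cells,
        )

    def fit(self, X, y):
        X = pd.DataFrame(X)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training compounds")
        y = np.asarray(y, dtype=float)
        if y.shape[0] != X.shape[0]:
            raise ValueError("activity vector length must match rows of X")
        if np.var(y) == 0:
            raise ValueError(
                "activity vector has zero variance; correlations are undefined"
            )

        vals = X.to_numpy(dtype=float)
        n = vals.shape[0]
        var = vals.var(axis=0, ddof=1)
        yc = y - y.mean()
        xc = vals - vals.mean(axis=0)
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (xc * yc[:, None]).sum(axis=0) / denom
        zeros = (vals == 0.0).sum(axis=0)

        stage = np.zeros(vals.shape[1], dtype=int)  # 0 = kept
        # stage 1: zero-variance columns have undefined R and pass to stage 2
        drop1 = np.isfinite(corr) & (np.abs(corr) < self.min_abs_activity_corr)
        stage[drop1] = 1
        drop2 = (stage == 0) & (var < self.min_self_variance)
        stage[drop2] = 2
        drop3 = (stage == 0) & (zeros > self.max_empty_cells)
        stage[drop3] = 3

        self.n_features_in_ = vals.shape[1]
        if all(isinstance(c, str) for c in X.columns):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.support_ = stage == 0
        self.feature_keys_ = list(X.columns)
        self.audit_ = pd.DataFrame(
            {
                "key": [str(k) for k in X.columns],
                "activity_corr": corr,
                "self_variance": var,
                "n_empty": zeros,
                "dropped_at_stage": stage,
                "kept": stage == 0,
            }
        )
        return self

    def _get_support_mask(self):
        return self.support_

    def _more_tags(self):
        return {"requires_y": True}


def reduce_descriptors(
    occupancy: OccupancyMatrix | pd.DataFrame,
    activities,
    config: ReductionConfig | str = "a1_c10",
) -> tuple[OccupancyMatrix | pd.DataFrame, pd.DataFrame]:
    """Apply the three serial filters; returns (filtered matrix, audit log).

    ``occupancy`` must already be restricted to the training compounds;
    ``activities`` may be a Series indexed like the matrix or a plain array in
    row order.
    """
    is_om = isinstance(occupancy, OccupancyMatrix)
    frame = occupancy.values if is_om else occupancy
    if isinstance(activities, pd.Series):
        y = activities.loc[frame.index].to_numpy(dtype=float)
    else:
        y = np.asarray(activities, dtype=float)

    reducer = GcodReducer.from_config(config) if isinstance(config, (str, ReductionConfig)) else config
    reducer.fit(frame, y)
    kept = frame.loc[:, reducer.support_]
    if is_om:
        return OccupancyMatrix(kept, dict(occupancy.cep_sizes), occupancy.grid), reducer.audit_
    return kept, reducer.audit_
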