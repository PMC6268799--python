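"""End-to-end orchestration: occupancy -> reduction -> GA search -> validation.

A run takes an activity table plus per-compound ensembles, computes the
occupancy pool for one alignment / cell-size choice, prunes it with a named
reduction preset, sweeps model sizes (seven, eight, nine terms by default),
validates each winner by LOO cross-validation, and predicts the external test
set.  Models whose adjusted Q² falls below 0.5 are flagged as weak in the
report - flagged, never silently dropped.  Every artifact records the config
and seed, and a fixed seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align_grid import AlignmentSpec, GridSpec, OccupancyMatrix, compute_gcods
from .compounds import ActivityTable
from .ensembles import ConformerEnsemble
from .gfa_pls import GfaConfig, ModelCandidate, size_sweep
from .reduction import PRESETS, ReductionConfig, reduce_descriptors
from .validation import ValidationReport, validate_model

__all__ = ["RunConfig", "RunReport", "StageError", "run", "WEAK_Q2_ADJ"]

#: adjusted-Q² floor below which a model is flagged as weak
WEAK_Q2_ADJ = 0.5


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    alignment: AlignmentSpec | None = None  # None: ensembles already in frame
    cell_size: float = 1.0
    reduction: str | ReductionConfig = "a1_c10"
    gfa: GfaConfig = field(default_factory=GfaConfig)
    sizes: tuple[int, ...] = (7, 8, 9)
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.reduction, str) and self.reduction not in PRESETS:
            raise ValueError(
                f"unknown reduction preset {self.reduction!r}; choose from {sorted(PRESETS)}"
            )


@dataclass
class RunReport:
    config: RunConfig
    occupancy: OccupancyMatrix
    reduced: OccupancyMatrix
    audit: pd.DataFrame
    best_by_size: dict[int, ModelCandidate]
    validation: dict[int, ValidationReport]
    weak_sizes: list[int]
    test_predictions: pd.DataFrame | None
    summary: pd.DataFrame

    def to_summary_row(self) -> dict:
        row = {
            "cell_size": self.config.cell_size,
            "reduction": str(self.config.reduction),
            "seed": self.config.seed,
            "n_pool": len(self.occupancy.keys),
            "n_reduced": len(self.reduced.keys),
        }
        for size, cand in self.best_by_size.items():
            row[f"q2_adj_{size}"] = cand.q2_adj
        return row


def run(
    config: RunConfig,
    activity_table: ActivityTable,
    ensembles: Mapping | Sequence[ConformerEnsemble],
    reference: np.ndarray | None = None,
    occupancy: OccupancyMatrix | None = None,
) -> RunReport:
    """Execute one full pipeline run; see module docstring.

    ``occupancy`` may be supplied directly (e.g. from a previous stage) to
    skip recomputation.  A stage failure raises :class:`StageError` naming the
    stage; artifacts produced before the failure are left on disk.
    """
    ens_list = list(ensembles.values()) if isinstance(ensembles, Mapping) else list(ensembles)
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        (out / "models").mkdir(parents=True, exist_ok=True)
        (out / "reports").mkdir(parents=True, exist_ok=True)

    gfa = dataclasses.replace(config.gfa, seed=config.seed)

    if occupancy is None:
        try:
            occupancy = compute_gcods(
                ens_list,
                reference=reference,
                alignment=config.alignment,
                grid=GridSpec(cell_size=config.cell_size),
            )
        except Exception as err:
            raise StageError("occupancy", err) from err
    if out:
        occupancy.to_sparse_csv(out / "occupancy.csv")

    train = activity_table.subset("train")
    y_train = train.activities()
    train_occ = occupancy.restrict(train.ids)

    try:
        reduced, audit = reduce_descriptors(train_occ, y_train, config.reduction)
    except Exception as err:
        raise StageError("reduction", err) from err
    if out:
        audit.to_csv(out / "reduction_audit.csv", index=False)

    try:
        best = size_sweep(reduced, y_train, gfa, sizes=config.sizes)
    except Exception as err:
        raise StageError("search", err) from err

    validation: dict[int, ValidationReport] = {}
    weak: list[int] = []
    X = reduced.values.to_numpy(dtype=float)
    y = y_train.loc[reduced.values.index].to_numpy(dtype=float)
    try:
        for size, cand in best.items():
            cols = list(cand.descriptor_idx)
            validation[size] = validate_model(
                X[:, cols], y, predictions=cand.predict(X), ids=reduced.compound_ids
            )
            if cand.q2_adj is not None and cand.q2_adj < WEAK_Q2_ADJ:
                weak.append(size)
    except Exception as err:
        raise StageError("validation", err) from err

    test = activity_table.subset("test")
    test_pred = None
    if len(test):
        test_occ = occupancy.restrict(test.ids).values.reindex(
            columns=list(reduced.values.columns), fill_value=0.0
        )
        rows = {}
        for size, cand in best.items():
            rows[f"pred_{size}"] = cand.predict(test_occ.to_numpy(dtype=float))
        test_pred = pd.DataFrame(rows, index=test.ids)
        test_pred.insert(0, "pic50_exp", test.activities().loc[test.ids].to_numpy())

    summary = pd.DataFrame(
        [
            {
                "n_terms": size,
                "lof": cand.lof,
                "lse": cand.lse,
                "q2": cand.q2,
                "q2_adj": cand.q2_adj,
                "r2": validation[size].r2,
                "sd_res": validation[size].sd_res,
                "weak": size in weak,
                "seed": config.seed,
            }
            for size, cand in best.items()
        ]
    )

    report = RunReport(
        config=config,
        occupancy=occupancy,
        reduced=reduced,
        audit=audit,
        best_by_size=best,
        validation=validation,
        weak_sizes=weak,
        test_predictions=test_pred,
        summary=summary,
    )

    if out:
        for size, cand in best.items():
            payload = {
                "seed": config.seed,
                "n_terms": size,
                "equation": cand.equation(),
                "intercept": cand.intercept,
                "terms": [
                    {"key": list(k) if isinstance(k, tuple) else k, "coef": c}
                    for k, c in zip(cand.descriptor_keys, cand.coefficients)
                ],
                "lof": cand.lof,
                "q2": cand.q2,
                "q2_adj": cand.q2_adj,
                "weak": size in weak,
            }
            (out / "models" / f"terms{size}.json").write_text(
                json.dumps(payload, indent=1, sort_keys=True)
            )
            (out / "reports" / f"terms{size}.json").write_text(
                json.dumps(validation[size].to_dict(), indent=1, sort_keys=True)
            )
        summary.to_csv(out / "summary.csv", index=False)
        if test_pred is not None:
            test_pred.to_csv(out / "test_predictions.csv")
    return report
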