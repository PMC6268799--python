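"""The five published GCOD equations and the bioactive-conformer rule.

Models 1B7/1B9 (alignment 1) and 2B7/2B8/2B9 (alignment 2), all on the 1.0 A
lattice, are shipped as JSON exactly as printed.  They predict pIC50 as
intercept plus coefficient-weighted occupancies keyed by the *published* cell
indices - a namespace registered to the original program's lattice, which is
not recoverable.  Predicting for newly sampled ensembles against these models
therefore requires an explicit registration offset between the de-novo grid
and the published indices; the default is the identity, with this caveat.

The bioactive-conformer rule picks, among conformers within 10 kcal/mol of
the ensemble minimum, the one the model scores most potent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PublishedModel",
    "MODEL_NAMES",
    "load_model",
    "load_all_models",
    "predict",
    "residual",
    "select_bioactive",
    "equation",
]

MODEL_NAMES = ("1B7", "1B9", "2B7", "2B8", "2B9")
_EXPECTED_TERMS = {"1B7": 7, "1B9": 9, "2B7": 7, "2B8": 8, "2B9": 9}

#: energy window (kcal/mol above the ensemble minimum) for bioactive selection
BIOACTIVE_WINDOW_KCAL = 10.0


@dataclass(frozen=True)
class PublishedModel:
    name: str
    alignment: int
    grid_size: float
    intercept: float
    terms: tuple[tuple[tuple[int, int, int], str, float], ...]  # (cell, ipe, coef)

    def __post_init__(self):
        want = _EXPECTED_TERMS.get(self.name)
        if want is not None and len(self.terms) != want:
            raise ValueError(
                f"model {self.name} must have {want} terms, got {len(self.terms)}"
            )

    @property
    def keys(self) -> list[tuple[int, int, int, str]]:
        return [(c[0], c[1], c[2], ipe) for c, ipe, _ in self.terms]


def load_model(name: str) -> PublishedModel:
    name = name.upper()
    if name not in MODEL_NAMES:
        raise KeyError(f"unknown published model {name!r}; choose from {MODEL_NAMES}")
    path = resources.files("qsar4d.data.models").joinpath(f"{name.lower()}.json")
    raw = json.loads(path.read_text())
    return PublishedModel(
        name=raw["name"],
        alignment=int(raw["alignment"]),
        grid_size=float(raw["grid_size"]),
        intercept=float(raw["intercept"]),
        terms=tuple(
            (tuple(t["cell"]), t["ipe"], float(t["coef"])) for t in raw["terms"]
        ),
    )


def load_all_models() -> dict[str, PublishedModel]:
    return {n: load_model(n) for n in MODEL_NAMES}


def predict(model: PublishedModel, occupancy: Mapping) -> float:
    """pIC50 = intercept + sum of coefficient x occupancy over the model's terms.

    ``occupancy`` maps ``(x, y, z, ipe)`` keys to non-negative values; missing
    keys count as zero occupancy.
    """
    total = model.intercept
    for cell, ipe, coef in model.terms:
        key = (*cell, ipe)
        v = float(occupancy.get(key, 0.0))
        if v < 0:
            raise ValueError(f"negative occupancy {v} for {key}")
        total += coef * v
    return total


def residual(calc: float, exp: float) -> float:
    """Residual convention: calculated minus experimental potency."""
    return calc - exp


def select_bioactive(
    energies: Sequence[float],
    occupancies: Sequence[Mapping],
    model: PublishedModel,
    window: float = BIOACTIVE_WINDOW_KCAL,
) -> int:
    """Index of the bioactive conformer.

    Among conformers within ``window`` kcal/mol of the minimum energy, return
    the one with the highest model-predicted potency; ties break toward lower
    energy, then lower index.  ``occupancies`` are per-conformer occupancy
    mappings (ensemble size 1, i.e. indicator occupancies).
    """
    e = np.asarray(energies, dtype=float)
    if len(e) != len(occupancies):
        raise ValueError("energies and occupancies must have equal length")
    in_window = np.flatnonzero(e <= e.min() + window)
    best = None
    for i in in_window:
        score = predict(model, occupancies[i])
        rank = (-score, e[i], i)
        if best is None or rank < best[0]:
            best = (rank, int(i))
    return best[1]


def equation(model: PublishedModel) -> str:
    """Pretty-print the model in the published equation style."""
    parts = [f"pIC50 = {model.intercept:.2f}"]
    for (x, y, z), ipe, coef in model.terms:
        sign = "-" if coef < 0 else "+"
        parts.append(f"{sign} {abs(coef):.2f} ({x},{y},{z})({ipe})")
    return " ".join(parts)
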