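"""Compound and activity data for the 2-arylbenzothiophene (raloxifene analog) series.

The series shares a 3-aroyl-2-arylbenzothiophene scaffold carrying a basic
piperidinyl-ethoxy side chain; the piperidine nitrogen is modelled protonated.
Analogs differ in the substituents on the benzothiophene ring (positions 4-7,
"R") and on the 2-aryl ring (positions 2'-5', "R'").  Potencies are pIC50 in
molar -log10 units, derived from IC50 (nM) against estrogen-stimulated MCF-7
proliferation.  The packaged table covers 54 analogs split into 41 training
and 13 external test compounds.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "Compound",
    "ActivityTable",
    "ResidualRecord",
    "pic50_from_ic50",
    "build_smiles",
    "load_fixture",
    "load_residual_fixture",
    "TRAIN_IDS",
    "TEST_IDS",
]

#: training / external-test membership of the 54-compound series
TRAIN_IDS = frozenset(
    [1, 2, 3, 4, 5, 6, 7, 9, 10, 11, 12, 13, 15, 16, 19, 21, 22, 23, 24, 25,
     27, 28, 29, 30, 32, 34, 35, 36, 37, 38, 39, 42, 43, 44, 45, 47, 49, 50,
     52, 53, 54]
)
TEST_IDS = frozenset([8, 14, 17, 18, 20, 26, 31, 33, 40, 41, 46, 48, 51])


def pic50_from_ic50(ic50_nm: float) -> float:
    """Convert an IC50 in nanomolar to pIC50 = -log10 of the molar IC50.

    Raises ValueError for non-positive concentrations.
    """
    if ic50_nm <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nm!r}")
    return -math.log10(ic50_nm * 1e-9)


@dataclass(frozen=True)
class Compound:
    id: int
    scaffold_substituents: Mapping[str, str]
    smiles: str
    role: str  # "train" or "test"
    pic50_exp: float

    def __post_init__(self):
        if self.role not in ("train", "test"):
            raise ValueError(f"role must be 'train' or 'test', got {self.role!r}")


@dataclass
class ActivityTable:
    compounds: list[Compound]
    provenance: str = ""

    def __post_init__(self):
        ids = [c.id for c in self.compounds]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate compound ids in activity table")

    def __len__(self):
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    def by_id(self, cid: int) -> Compound:
        for c in self.compounds:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def subset(self, role: str) -> "ActivityTable":
        return ActivityTable(
            [c for c in self.compounds if c.role == role],
            provenance=f"{self.provenance} ({role} subset)",
        )

    @property
    def ids(self) -> list[int]:
        return [c.id for c in self.compounds]

    def activities(self) -> pd.Series:
        return pd.Series({c.id: c.pic50_exp for c in self.compounds}, name="pic50_exp")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.compounds],
                "role": [c.role for c in self.compounds],
                "pic50_exp": [c.pic50_exp for c in self.compounds],
                "smiles": [c.smiles for c in self.compounds],
            }
        ).set_index("id")


@dataclass(frozen=True)
class ResidualRecord:
    compound_id: int
    model_name: str
    pic50_exp: float
    pic50_calc: float
    residual: float  # pic50_calc - pic50_exp, to table rounding


# --------------------------------------------------------------------------
# Scaffold SMILES construction
#
# The common core is written once; substituents from the activity table are
# spliced onto the benzothiophene (4..7) and 2-aryl (2'..5') positions.  The
# two ring-fused substituent patterns in the series (4,5-benzo on the
# benzothiophene, 3',4'-methylenedioxy on the aryl ring) are handled as
# dedicated templates.

_FRAGMENTS = {
    "OH": "O",
    "OMe": "OC",
    "Me": "C",
    "F": "F",
    "Cl": "Cl",
    "C#CH": "C#C",
    "CO2Me": "C(=O)OC",
    "CO2Et": "C(=O)OCC",
    "CO2H": "C(=O)O",
    "COMe": "C(C)=O",
    "CONH2": "C(N)=O",
    "CONHMe": "C(NC)=O",
    "CONMe2": "C(N(C)C)=O",
    "Et": "CC",
    "nBu": "CCCC",
    "iPr": "C(C)C",
    "CH=CH2": "C=C",
    "CH2SEt": "CSCC",
    "CH2OH": "CO",
    "Ph": "c8ccccc8",
    "NO2": "[N+](=O)[O-]",
    "CF3": "C(F)(F)F",
}

#: 4-[2-(piperidin-1-ium-1-yl)ethoxy]benzoyl group on C3 of the benzothiophene
_AROYL = "O=C(c1ccc(OCC[NH+]2CCCCC2)cc1)"


def parse_substituents(spec: str, primed: bool) -> dict[str, str]:
    """Parse a substituent string like ``"4,7-di(Me), 6-OH"`` into {position: group}.

    ``primed`` selects the 2-aryl ring (positions carry a prime).  The fused
    patterns ``4,5-benzo`` and ``3',4'-OCH2O-`` map to the pseudo-group names
    ``benzo`` and ``OCH2O``.
    """
    out: dict[str, str] = {}
    spec = spec.strip()
    if spec in ("H", ""):
        return out
    # fused-ring patterns: annotate and strip them before positional parsing
    if "benzo" in spec:
        out["fused"] = "benzo"
        spec = re.sub(r"[\d',]+-benzo,?\s*", "", spec).strip().strip(",").strip()
    if "OCH2O" in spec:
        out["fused"] = "OCH2O"
        spec = re.sub(r"[\d',]+-OCH2O-?,?\s*", "", spec).strip().strip(",").strip()
    if not spec:
        return out
    for token in re.split(r",\s+(?=\d)", spec):
        token = token.strip()
        if token == "H":
            continue
        m = re.match(r"^([\d',]+)-(?:di|tri)\((.+)\)$", token)
        if m:
            positions, group = m.group(1).split(","), m.group(2)
        else:
            m = re.match(r"^(\d'?)-(.+)$", token)
            if not m:
                raise ValueError(f"cannot parse substituent token {token!r}")
            positions, group = [m.group(1)], m.group(2)
        for pos in positions:
            pos = pos.strip()
            if primed and not pos.endswith("'"):
                raise ValueError(f"unprimed position {pos!r} on the 2-aryl ring")
            out[pos] = group
    return out


def _site(groups: dict[str, str], pos: str) -> str:
    g = groups.get(pos)
    if g is None:
        return "c"
    if g not in _FRAGMENTS:
        raise ValueError(f"unknown substituent group {g!r} at position {pos}")
    return f"c({_FRAGMENTS[g]})"


def build_smiles(r: str, rprime: str) -> str:
    """SMILES for one analog from its R (benzothiophene) and R' (2-aryl) strings."""
    rg = parse_substituents(r, primed=False)
    pg = parse_substituents(rprime, primed=True)

    if pg.get("fused") == "OCH2O":
        aryl = "-c5cc6OCOc6cc5"  # 3',4'-methylenedioxyphenyl
    else:
        aryl = "-c5" + "".join(_site(pg, p) for p in ("2'", "3'", "4'", "5'")) + "c5"

    if rg.get("fused") == "benzo":
        # benzo ring fused across C4-C5; remaining R groups sit on C6/C7
        benzo = "sc4" + _site(rg, "7") + _site(rg, "6") + "c6ccccc6c34"
    else:
        benzo = (
            "sc4"
            + "".join(_site(rg, p) for p in ("7", "6", "5", "4"))
            + "c34"
        )
    return f"{_AROYL}c3c({aryl}){benzo}"


# --------------------------------------------------------------------------
# Packaged fixtures


def _data_path(name: str):
    return resources.files("qsar4d.data").joinpath(name)


def load_fixture() -> ActivityTable:
    """The packaged 54-compound activity table (41 train / 13 test)."""
    with resources.as_file(_data_path("compounds.csv")) as p:
        df = pd.read_csv(p)
    compounds = []
    for row in df.itertuples(index=False):
        subs = parse_substituents(row.R, primed=False)
        subs.update(parse_substituents(row.Rprime, primed=True))
        compounds.append(
            Compound(
                id=int(row.id),
                scaffold_substituents=subs,
                smiles=build_smiles(row.R, row.Rprime),
                role=row.role,
                pic50_exp=float(row.pic50_exp),
            )
        )
    return ActivityTable(compounds, provenance="packaged 54-analog series")


def load_residual_fixture(model_name: str) -> list[ResidualRecord]:
    """Packaged experimental/calculated potencies and residuals for one model.

    ``model_name`` is ``"1B9"`` or ``"2B9"`` (the two representative nine-term
    models, one per alignment).
    """
    if model_name not in ("1B9", "2B9"):
        raise KeyError(f"no residual fixture for model {model_name!r}")
    with resources.as_file(_data_path("table3_residuals.csv")) as p:
        df = pd.read_csv(p)
    return [
        ResidualRecord(
            compound_id=int(row.id),
            model_name=model_name,
            pic50_exp=float(row.pic50_exp),
            pic50_calc=float(getattr(row, f"calc_{model_name}")),
            residual=float(getattr(row, f"res_{model_name}")),
        )
        for row in df.itertuples(index=False)
    ]
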