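"""Alignment, pharmacophore atom typing, and grid cell occupancy descriptors.

Every conformation of every compound is rigidly superposed onto a reference
structure using three anchor atoms, overlaid on a cubic lattice, and each atom
is binned into the cell containing it.  Counting how often atoms of a given
interaction pharmacophore element (IPE) class visit a cell across the whole
ensemble, divided by the ensemble size, gives the grid cell occupancy
descriptor (GCOD) - the normalized absolute occupancy that serves as the
QSAR variable pool.

Cell registration here is ``cell(p) = floor((p - origin) / cell_size)`` per
axis with half-open cells ``[k, k+1)`` and the origin defaulting to the
reference frame's origin.  The absolute indices attached to previously
published models came from a different (unstated) registration, so published
cell indices and de-novo indices are distinct keyed namespaces; see
:mod:`qsar4d.published_models`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ensembles import ConformerEnsemble

__all__ = [
    "IPE_CLASSES",
    "AlignmentSpec",
    "GridSpec",
    "DegenerateAlignmentError",
    "superpose_three_point",
    "canonicalize_reference",
    "assign_ipe",
    "compute_gcods",
    "cell_center_distance",
    "OccupancyMatrix",
]

#: the seven interaction pharmacophore element classes
IPE_CLASSES = ("any", "np", "p+", "p-", "hba", "hbd", "ar")


class DegenerateAlignmentError(ValueError):
    """Raised when the three alignment atoms are collinear or duplicated."""


@dataclass(frozen=True)
class AlignmentSpec:
    """Ordered triple of atom indices anchoring the rigid superposition."""

    name: str
    atom_indices: tuple[int, int, int]

    def __post_init__(self):
        if len(set(self.atom_indices)) != 3:
            raise DegenerateAlignmentError(
                f"alignment {self.name!r} needs three distinct atoms, "
                f"got {self.atom_indices}"
            )


@dataclass(frozen=True)
class GridSpec:
    cell_size: float = 1.0  # Angstrom; 1.0 and 2.0 are the standard choices
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def cell_of(self, points: np.ndarray) -> np.ndarray:
        """Integer cell index triples for an (n, 3) array of positions.

        Scaled coordinates are rounded to 9 decimals before flooring: aligned
        anchor atoms land exactly on cell boundaries (the superposition puts
        the anchor plane at z = 0), where raw floating-point noise of either
        sign would otherwise assign them to cells nondeterministically.
        Coordinates within 5e-10 of a boundary therefore snap to the upper
        cell.
        """
        scaled = (
            np.asarray(points, dtype=float) - np.asarray(self.origin)
        ) / self.cell_size
        return np.floor(np.round(scaled, 9)).astype(int)


def cell_center_distance(a: Sequence[int], b: Sequence[int], cell_size: float = 1.0) -> float:
    """Euclidean distance between two cell centers: cell_size * |a - b|."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(cell_size * np.linalg.norm(d))


# --------------------------------------------------------------------------
# Three-point rigid superposition


def _check_noncollinear(triple: np.ndarray, name: str = "") -> None:
    v1 = triple[1] - triple[0]
    v2 = triple[2] - triple[0]
    if np.linalg.norm(np.cross(v1, v2)) < 1e-8 * max(
        1.0, np.linalg.norm(v1) * np.linalg.norm(v2)
    ):
        raise DegenerateAlignmentError(
            f"alignment atoms {name} are collinear or coincident"
        )


def superpose_three_point(
    coords: np.ndarray,
    reference: np.ndarray,
    alignment: AlignmentSpec,
    ref_alignment: AlignmentSpec | None = None,
) -> np.ndarray:
    """Rigidly fit ``coords`` so its alignment triple matches the reference's.

    Least-squares over the three anchor atoms with a proper rotation
    (determinant +1; the reflection that three points would otherwise admit is
    forbidden).  All atoms are transformed and returned.
    """
    from scipy.spatial.transform import Rotation

    idx = list(alignment.atom_indices)
    ridx = list((ref_alignment or alignment).atom_indices)
    mob = np.asarray(coords, dtype=float)[idx]
    ref = np.asarray(reference, dtype=float)[ridx]
    _check_noncollinear(ref, "of reference")
    _check_noncollinear(mob, f"of {alignment.name}")

    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mob - mc)
    return rot.apply(np.asarray(coords, dtype=float) - mc) + rc


def canonicalize_reference(reference: np.ndarray, alignment: AlignmentSpec) -> np.ndarray:
    """Express the reference in the canonical frame of its alignment triple.

    The frame puts the triple's centroid at the origin, the first->second atom
    direction along +x, and the triple plane in z = 0 (right-handed).  Because
    the frame is built from the triple's internal geometry only, any global
    rigid motion applied to the reference (and the ensembles superposed onto
    it) cancels out - which is what makes the occupancy matrix invariant to
    how the input structures happen to sit in space.
    """
    ref = np.asarray(reference, dtype=float)
    t = ref[list(alignment.atom_indices)]
    _check_noncollinear(t, "of reference")
    centroid = t.mean(axis=0)
    e1 = t[1] - t[0]
    e1 /= np.linalg.norm(e1)
    u = (t[2] - t[0]) - np.dot(t[2] - t[0], e1) * e1
    e2 = u / np.linalg.norm(u)
    e3 = np.cross(e1, e2)
    basis = np.vstack([e1, e2, e3])
    return (ref - centroid) @ basis.T


# --------------------------------------------------------------------------
# IPE typing
#
# The published method names the seven classes but not the assignment rules;
# the table below follows common pharmacophore conventions and is
# parameter-overridable.  Partial charges are used when present; otherwise a
# simple per-element fallback stands in so the polar classes remain usable
# without quantum charges.

_FALLBACK_CHARGES = {
    "O": -0.40,
    "N": -0.35,
    "S": -0.10,
    "F": -0.20,
    "Cl": -0.10,
    "C": 0.0,
    "H": 0.05,
}


def _perceive_aromatic(elements: list[str], g: nx.Graph) -> np.ndarray:
    """Fallback aromaticity: 5/6-rings of C/N/O/S whose members all have degree <= 3.

    With hydrogens explicit in the bond graph this separates benzene-like rings
    (ring-CH degree 3) from saturated rings (ring-CH2 degree 4).
    """
    flags = np.zeros(len(elements), dtype=bool)
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        if not all(elements[i] in ("C", "N", "O", "S") for i in cycle):
            continue
        if all(g.degree(i) <= 3 for i in cycle):
            flags[list(cycle)] = True
    return flags


def assign_ipe(
    ensemble: ConformerEnsemble,
    charge_threshold: float = 0.25,
) -> list[frozenset[str]]:
    """Per-atom IPE class memberships, identical across an ensemble's conformations.

    Rules: every atom is ``any``; ``np`` = carbon and H-on-carbon; ``p+`` =
    positive formal charge, partial charge >= +threshold, or H on such an
    atom; ``p-`` = negative formal charge or partial charge <= -threshold;
    ``hba`` = N/O/S with an available lone pair (no positive formal charge,
    N limited to degree <= 3); ``hbd`` = H bonded to N/O/S together with that
    heteroatom; ``ar`` = atoms of perceived aromatic rings.
    """
    elements = ensemble.atom_elements
    unknown = sorted({e for e in elements if e not in _FALLBACK_CHARGES})
    if unknown and ensemble.atom_charges is None:
        raise ValueError(f"unknown element(s) without supplied charges: {unknown}")

    g = nx.Graph()
    g.add_nodes_from(range(len(elements)))
    g.add_edges_from(ensemble.bonds)

    formal = (
        np.asarray(ensemble.formal_charges, dtype=float)
        if ensemble.formal_charges is not None
        else np.zeros(len(elements))
    )
    if ensemble.atom_charges is not None:
        partial = np.asarray(ensemble.atom_charges, dtype=float)
    else:
        partial = np.array([_FALLBACK_CHARGES.get(e, 0.0) for e in elements])
        # formal charge dominates the element rule; hydrogens on heteroatoms
        # polarize strongly
        partial[formal > 0] = 0.40
        partial[formal < 0] = -0.40
        for i, e in enumerate(elements):
            if e != "H":
                continue
            heavy = next(iter(g.neighbors(i)), None)
            if heavy is not None and elements[heavy] in ("N", "O", "S"):
                partial[i] = 0.35 if formal[heavy] > 0 else 0.30

    if ensemble.aromatic_flags is not None:
        aromatic = np.asarray(ensemble.aromatic_flags, dtype=bool)
    else:
        aromatic = _perceive_aromatic(elements, g)

    out = []
    for i, e in enumerate(elements):
        classes = {"any"}
        neighbors = list(g.neighbors(i))
        heavy = elements[neighbors[0]] if e == "H" and neighbors else None
        if e == "C" or (e == "H" and heavy == "C"):
            classes.add("np")
        if formal[i] > 0 or partial[i] >= charge_threshold:
            classes.add("p+")
        if e == "H" and heavy is not None and formal[neighbors[0]] > 0:
            classes.add("p+")
        if formal[i] < 0 or (formal[i] <= 0 and partial[i] <= -charge_threshold):
            classes.add("p-")
        if e in ("N", "O", "S") and formal[i] <= 0 and not (e == "N" and g.degree(i) > 3):
            classes.add("hba")
        if e == "H" and heavy in ("N", "O", "S"):
            classes.add("hbd")
        if e in ("N", "O", "S") and any(elements[j] == "H" for j in neighbors):
            classes.add("hbd")
        if aromatic[i]:
            classes.add("ar")
        out.append(frozenset(classes))
    return out


# --------------------------------------------------------------------------
# Occupancy matrix


@dataclass
class OccupancyMatrix:
    """Compounds x (cell, IPE class) table of normalized occupancies.

    ``values`` is a DataFrame whose index holds compound ids and whose columns
    are 4-tuples ``(x, y, z, ipe)``; entries are raw visit counts divided by
    the per-compound ensemble size (so multiple same-class atoms in one cell
    in one snapshot can push a value above 1 - occupancy is uncapped).
    """

    values: pd.DataFrame
    cep_sizes: dict = field(default_factory=dict)
    grid: GridSpec | None = None

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ValueError("occupancies must be non-negative")

    @property
    def compound_ids(self):
        return list(self.values.index)

    @property
    def keys(self) -> list[tuple]:
        return list(self.values.columns)

    def restrict(self, ids: Iterable) -> "OccupancyMatrix":
        ids = list(ids)
        return OccupancyMatrix(self.values.loc[ids], dict(self.cep_sizes), self.grid)

    def vector(self, compound_id) -> dict:
        """One compound's occupancy as a {(x, y, z, ipe): value} mapping."""
        row = self.values.loc[compound_id]
        return {k: float(v) for k, v in row.items() if v != 0.0}

    def to_sparse_frame(self) -> pd.DataFrame:
        rows = []
        for cid in self.values.index:
            for (x, y, z, ipe), v in self.values.loc[cid].items():
                if v != 0.0:
                    rows.append((cid, x, y, z, ipe, v))
        return pd.DataFrame(
            rows, columns=["compound_id", "x", "y", "z", "ipe", "occupancy"]
        )

    def to_sparse_csv(self, path) -> None:
        self.to_sparse_frame().to_csv(path, index=False)

    @classmethod
    def from_sparse_frame(cls, df: pd.DataFrame) -> "OccupancyMatrix":
        pivot = df.pivot_table(
            index="compound_id",
            columns=["x", "y", "z", "ipe"],
            values="occupancy",
            fill_value=0.0,
        )
        pivot.columns = pd.Index(
            [(int(x), int(y), int(z), str(ipe)) for x, y, z, ipe in pivot.columns],
            tupleize_cols=False,
        )
        return cls(pivot)

    @classmethod
    def from_sparse_csv(cls, path) -> "OccupancyMatrix":
        return cls.from_sparse_frame(pd.read_csv(path))


def compute_gcods(
    ensembles: Sequence[ConformerEnsemble],
    reference: np.ndarray | None = None,
    alignment: AlignmentSpec | Mapping[object, AlignmentSpec] | None = None,
    grid: GridSpec = GridSpec(),
    classes: Sequence[str] = IPE_CLASSES,
    typing: Mapping[object, list[frozenset[str]]] | None = None,
) -> OccupancyMatrix:
    """Grid cell occupancy descriptors for a set of conformer ensembles.

    For every compound, every snapshot is (optionally) superposed onto
    ``reference`` via its three-point ``alignment``; each atom's cell is then
    counted once per snapshot for each IPE class it belongs to, and counts are
    divided by the ensemble size.  ``alignment`` may be a single spec (same
    atom indices for every compound) or a mapping from compound id to spec;
    ``typing`` optionally supplies precomputed per-atom class sets.
    """
    if not ensembles:
        raise ValueError("no ensembles given")
    bad = [c for c in classes if c not in IPE_CLASSES]
    if bad:
        raise ValueError(f"unknown IPE class(es): {bad}")

    rows = {}
    cep_sizes = {}
    for ens in ensembles:
        cid = ens.compound_id
        if typing is not None and cid in typing:
            atom_classes = typing[cid]
        elif len(set(classes)) == 1 and "any" in classes:
            atom_classes = [frozenset({"any"})] * ens.n_atoms
        else:
            atom_classes = assign_ipe(ens)
        spec = alignment.get(cid) if isinstance(alignment, Mapping) else alignment
        if spec is not None:
            if reference is None:
                raise ValueError("alignment given without a reference structure")
            # anchor the lattice to the reference triple's internal frame so
            # occupancies are invariant to global rigid motion of the inputs
            ref_canonical = canonicalize_reference(reference, spec)
        counts: dict[tuple, float] = {}
        for conf in ens.conformations:
            coords = conf.coords
            if spec is not None:
                coords = superpose_three_point(coords, ref_canonical, spec)
            cells = grid.cell_of(coords)
            for atom, (cx, cy, cz) in enumerate(cells):
                for cls in atom_classes[atom]:
                    if cls in classes:
                        key = (int(cx), int(cy), int(cz), cls)
                        counts[key] = counts.get(key, 0.0) + 1.0
        n = len(ens)
        rows[cid] = {k: v / n for k, v in counts.items()}
        cep_sizes[cid] = n

    all_keys = sorted({k for r in rows.values() for k in r})
    data = np.zeros((len(rows), len(all_keys)))
    pos = {k: j for j, k in enumerate(all_keys)}
    for i, r in enumerate(rows.values()):
        for k, v in r.items():
            data[i, pos[k]] = v
    # flat object Index of 4-tuples (a MultiIndex would coerce key dtypes)
    frame = pd.DataFrame(
        data,
        index=list(rows),
        columns=pd.Index(all_keys, tupleize_cols=False),
    )
    frame.index.name = "compound_id"
    return OccupancyMatrix(frame, cep_sizes, grid)
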