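"""Conformational ensembles: data model, stochastic sampler, and multi-conformer I/O.

A compound's "fourth dimension" is its conformational ensemble profile (CEP):
an ordered set of 3D snapshots with per-snapshot energies, all sharing one atom
ordering.  Ensembles can be imported from multi-record SDF or multi-frame XYZ
files, or generated here by a Metropolis torsional sampler: torsion-angle
perturbations plus a small Cartesian jitter, accepted at the schedule
temperature against a periodic-torsion-plus-soft-sphere energy.  Any sampler
with roughly Boltzmann visitation exercises the downstream occupancy
descriptors identically, and externally produced ensembles can always be read
in for higher fidelity.

Energies are reported relative to the ensemble minimum (kcal/mol), which is
the scale the 10 kcal/mol bioactive-conformer window operates on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "BOLTZMANN_KCAL",
    "SamplingSchedule",
    "DEFAULT_SCHEDULE",
    "Conformation",
    "ConformerEnsemble",
    "Molecule3D",
    "snapshot_count",
    "metropolis_chain",
    "rotatable_bonds",
    "rotate_torsion",
    "torsional_energy",
    "sample_ensemble",
    "read_ensemble",
    "write_ensemble",
]

#: Boltzmann constant in kcal/(mol K)
BOLTZMANN_KCAL = 0.0019872041


@dataclass(frozen=True)
class SamplingSchedule:
    """Snapshot-recording schedule for ensemble generation.

    Defaults reproduce the study conditions: 310 K, 100 ps of sampling at a
    0.001 ps step, one snapshot every 50 steps -> 2,000 conformations.
    """

    temperature: float = 310.0  # K
    duration_ps: float = 100.0
    step_ps: float = 0.001
    record_every: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0 or self.duration_ps <= 0:
            raise ValueError("temperature and duration must be positive")
        if self.step_ps <= 0 or self.record_every <= 0:
            raise ValueError("step_ps and record_every must be positive")


DEFAULT_SCHEDULE = SamplingSchedule()


def snapshot_count(schedule: SamplingSchedule) -> int:
    """Number of recorded snapshots: floor(duration / step / record_every)."""
    return int(schedule.duration_ps / schedule.step_ps / schedule.record_every)


@dataclass(frozen=True)
class Conformation:
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    energy: float  # kcal/mol, relative scale

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", c)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError(f"coords must be (n_atoms, 3), got {c.shape}")
        if not math.isfinite(self.energy):
            raise ValueError("conformer energy must be finite")


@dataclass
class Molecule3D:
    """A light 3D structure: elements, one coordinate set, and a bond list.

    ``bonds`` are index pairs including bonds to hydrogens; ``charges`` are
    optional partial charges and ``formal_charges`` integer formal charges.
    ``aromatic_flags`` may carry externally perceived aromaticity (e.g. from
    RDKit); otherwise ring perception falls back on the bond graph.
    """

    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int]]
    charges: np.ndarray | None = None
    formal_charges: np.ndarray | None = None
    aromatic_flags: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coords shape must match element count")

    @classmethod
    def from_rdkit(cls, mol, conf_id: int = -1) -> "Molecule3D":
        """Build from an RDKit Mol with at least one 3D conformer."""
        conf = mol.GetConformer(conf_id)
        coords = np.array(
            [[*conf.GetAtomPosition(i)] for i in range(mol.GetNumAtoms())]
        )
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
        formal = np.array([a.GetFormalCharge() for a in mol.GetAtoms()], dtype=float)
        aromatic = np.array([a.GetIsAromatic() for a in mol.GetAtoms()], dtype=bool)
        return cls(elements, coords, bonds, formal_charges=formal,
                   aromatic_flags=aromatic)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.elements)))
        g.add_edges_from(self.bonds)
        return g


@dataclass
class ConformerEnsemble:
    """One compound's conformational ensemble profile."""

    compound_id: int | str
    conformations: list[Conformation]
    atom_elements: list[str]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    atom_charges: np.ndarray | None = None
    formal_charges: np.ndarray | None = None
    aromatic_flags: np.ndarray | None = None
    schedule: SamplingSchedule | None = None

    def __post_init__(self):
        if not self.conformations:
            raise ValueError("ensemble must contain at least one conformation")
        n = len(self.atom_elements)
        for k, c in enumerate(self.conformations):
            if c.coords.shape[0] != n:
                raise ValueError(
                    f"conformation {k} has {c.coords.shape[0]} atoms, expected {n}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_elements)

    def __len__(self):
        return len(self.conformations)

    def coords_array(self) -> np.ndarray:
        """(n_conformations, n_atoms, 3) stack."""
        return np.stack([c.coords for c in self.conformations])

    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformations])


# --------------------------------------------------------------------------
# Torsion machinery


def rotatable_bonds(molecule: Molecule3D) -> list[tuple[int, int]]:
    """Acyclic single bonds between two non-terminal atoms (heavy or not)."""
    g = molecule.graph()
    ring_edges = set()
    for cycle in nx.cycle_basis(g):
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            ring_edges.add(frozenset((a, b)))
    out = []
    for a, b in molecule.bonds:
        if frozenset((a, b)) in ring_edges:
            continue
        if g.degree(a) < 2 or g.degree(b) < 2:
            continue
        out.append((a, b))
    return out


def _moving_side(g: nx.Graph, bond: tuple[int, int]) -> np.ndarray:
    """Atom indices on the smaller side of the (removed) bond."""
    a, b = bond
    h = g.copy()
    h.remove_edge(a, b)
    side_b = nx.node_connected_component(h, b)
    side_a = nx.node_connected_component(h, a)
    moving = side_b if len(side_b) <= len(side_a) else side_a
    return np.fromiter(moving, dtype=int)


def rotate_torsion(
    coords: np.ndarray,
    molecule: Molecule3D,
    bond: tuple[int, int],
    angle_rad: float,
) -> np.ndarray:
    """Rotate the smaller fragment about the bond axis by ``angle_rad``."""
    from scipy.spatial.transform import Rotation

    a, b = bond
    axis = coords[b] - coords[a]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("degenerate bond axis")
    rot = Rotation.from_rotvec(axis / norm * angle_rad)
    moving = _moving_side(molecule.graph(), bond)
    out = coords.copy()
    out[moving] = rot.apply(coords[moving] - coords[a]) + coords[a]
    return out


_VDW = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "F": 1.47,
        "Cl": 1.75, "Br": 1.85, "I": 1.98}


def _clash_pairs(molecule: Molecule3D) -> np.ndarray:
    """Atom pairs separated by more than three bonds (the non-bonded set)."""
    g = molecule.graph()
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
    n = len(molecule.elements)
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if j not in dist.get(i, {})
    ]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def torsional_energy(
    coords: np.ndarray,
    molecule: Molecule3D,
    torsions: Sequence[tuple[int, int]],
    clash_pairs: np.ndarray | None = None,
    barrier: float = 1.4,
    clash_k: float = 10.0,
    vdw_scale: float = 0.8,
) -> float:
    """Periodic 3-fold torsion terms plus a soft-sphere clash penalty (kcal/mol).

    Each rotatable bond contributes 0.5*V*(1 + cos 3*phi) through one
    representative dihedral; non-bonded pairs closer than the scaled sum of
    van der Waals radii pay a harmonic penalty.
    """
    g = molecule.graph()
    e = 0.0
    for a, b in torsions:
        na = [x for x in g.neighbors(a) if x != b]
        nb = [x for x in g.neighbors(b) if x != a]
        if not na or not nb:
            continue
        phi = _dihedral(coords[na[0]], coords[a], coords[b], coords[nb[0]])
        e += 0.5 * barrier * (1.0 + math.cos(3.0 * phi))
    if clash_pairs is None:
        clash_pairs = _clash_pairs(molecule)
    if len(clash_pairs):
        d = np.linalg.norm(coords[clash_pairs[:, 0]] - coords[clash_pairs[:, 1]], axis=1)
        r0 = vdw_scale * np.array(
            [
                _VDW.get(molecule.elements[i], 1.7) + _VDW.get(molecule.elements[j], 1.7)
                for i, j in clash_pairs
            ]
        )
        overlap = np.clip(r0 - d, 0.0, None)
        e += clash_k * float(np.sum(overlap**2))
    return e


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.atan2(y, x)


# --------------------------------------------------------------------------
# Metropolis kernel


def metropolis_chain(
    energy_fn: Callable[[np.ndarray], float],
    state0: np.ndarray,
    propose_fn: Callable[[np.ndarray, np.random.Generator], np.ndarray],
    n_steps: int,
    kT: float,
    rng: np.random.Generator,
    record_every: int = 1,
) -> tuple[list[np.ndarray], list[float]]:
    """Generic Metropolis sampler; returns states/energies every ``record_every`` steps."""
    state = np.asarray(state0, dtype=float)
    energy = energy_fn(state)
    states, energies = [], []
    for step in range(1, n_steps + 1):
        proposal = propose_fn(state, rng)
        e_new = energy_fn(proposal)
        if e_new <= energy or rng.random() < math.exp(-(e_new - energy) / kT):
            state, energy = proposal, e_new
        if step % record_every == 0:
            states.append(state.copy())
            energies.append(energy)
    return states, energies


# --------------------------------------------------------------------------
# Ensemble sampler


def sample_ensemble(
    molecule: Molecule3D,
    schedule: SamplingSchedule = DEFAULT_SCHEDULE,
    compound_id: int | str = 0,
    torsion_sigma_deg: float = 30.0,
    jitter_sigma: float = 0.02,
) -> ConformerEnsemble:
    """Generate a conformer ensemble from a seed structure.

    Runs a Metropolis chain in torsion space at the schedule temperature; each
    chain step perturbs one randomly chosen rotatable torsion (Gaussian, sigma
    ``torsion_sigma_deg``).  Snapshots are recorded every
    ``schedule.record_every`` proposals so imported and generated ensembles
    share the same CEP-size normalization, and a small Cartesian jitter
    (sigma ``jitter_sigma`` per coordinate) is added to each recorded snapshot
    - at recording rather than in the chain state, which keeps heavy-atom
    connectivity intact across the ensemble.

    Molecules with no rotatable bonds yield an ensemble of independently
    jittered copies of the seed (Gaussian, sigma ``jitter_sigma`` per
    coordinate) rather than an error.
    """
    n_snap = snapshot_count(schedule)
    if n_snap < 1:
        raise ValueError("schedule records no snapshots")
    rng = np.random.default_rng(schedule.seed)
    kT = BOLTZMANN_KCAL * schedule.temperature
    torsions = rotatable_bonds(molecule)

    if not torsions:
        coords = [
            molecule.coords + rng.normal(0.0, jitter_sigma, molecule.coords.shape)
            for _ in range(n_snap)
        ]
        energies = [0.0] * n_snap
    else:
        pairs = _clash_pairs(molecule)
        sigma = math.radians(torsion_sigma_deg)

        def energy_fn(c):
            return torsional_energy(c, molecule, torsions, clash_pairs=pairs)

        def propose(c, r):
            bond = torsions[r.integers(len(torsions))]
            return rotate_torsion(c, molecule, bond, r.normal(0.0, sigma))

        n_steps = n_snap * schedule.record_every
        coords, energies = metropolis_chain(
            energy_fn,
            molecule.coords,
            propose,
            n_steps,
            kT,
            rng,
            record_every=schedule.record_every,
        )
        # the chain walks the torsion manifold (bond lengths and angles are
        # exactly preserved); the Cartesian jitter is added per recorded
        # snapshot so it cannot accumulate into geometry drift
        coords = [c + rng.normal(0.0, jitter_sigma, c.shape) for c in coords]

    e = np.asarray(energies, dtype=float)
    e -= e.min()  # report relative to the ensemble minimum
    confs = [Conformation(c, float(ei)) for c, ei in zip(coords, e)]
    return ConformerEnsemble(
        compound_id=compound_id,
        conformations=confs,
        atom_elements=list(molecule.elements),
        bonds=list(molecule.bonds),
        atom_charges=molecule.charges,
        formal_charges=molecule.formal_charges,
        aromatic_flags=molecule.aromatic_flags,
        schedule=schedule,
    )


# --------------------------------------------------------------------------
# I/O: multi-record SDF and multi-frame XYZ

ENERGY_TAG = "ENERGY_KCAL"


def write_ensemble(ensemble: ConformerEnsemble, path, fmt: str = "sdf") -> None:
    path = Path(path)
    if fmt == "sdf":
        _write_sdf(ensemble, path)
    elif fmt == "xyz":
        _write_xyz(ensemble, path)
    else:
        raise ValueError(f"unknown ensemble format {fmt!r}")


def read_ensemble(path, fmt: str = "sdf", compound_id: int | str = 0) -> ConformerEnsemble:
    path = Path(path)
    if fmt == "sdf":
        return _read_sdf(path, compound_id)
    if fmt == "xyz":
        return _read_xyz(path, compound_id)
    raise ValueError(f"unknown ensemble format {fmt!r}")


def _rdkit_mol(ensemble: ConformerEnsemble):
    from rdkit import Chem

    em = Chem.RWMol()
    for k, el in enumerate(ensemble.atom_elements):
        atom = Chem.Atom(el)
        if ensemble.formal_charges is not None:
            atom.SetFormalCharge(int(ensemble.formal_charges[k]))
        atom.SetNoImplicit(True)
        em.AddAtom(atom)
    for a, b in ensemble.bonds:
        em.AddBond(int(a), int(b), Chem.BondType.SINGLE)
    mol = em.GetMol()
    return mol


def _write_sdf(ensemble: ConformerEnsemble, path: Path) -> None:
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = _rdkit_mol(ensemble)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for conf in ensemble.conformations:
        c = Chem.Conformer(mol.GetNumAtoms())
        for i, (x, y, z) in enumerate(conf.coords):
            c.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
        m = Chem.Mol(mol)
        m.RemoveAllConformers()
        m.AddConformer(c)
        m.SetProp("_Name", str(ensemble.compound_id))
        m.SetProp(ENERGY_TAG, f"{conf.energy:.8f}")
        writer.write(m)
    writer.close()


def _read_sdf(path: Path, compound_id) -> ConformerEnsemble:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    confs, elements, bonds = [], None, []
    for k, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparseable SDF record at index {k} in {path}")
        els = [a.GetSymbol() for a in mol.GetAtoms()]
        if elements is None:
            elements = els
            bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
        elif els != elements:
            raise ValueError(
                f"SDF record {k} has {len(els)} atoms / different ordering; "
                f"expected {len(elements)} atoms as in record 0"
            )
        conf = mol.GetConformer()
        coords = np.array([[*conf.GetAtomPosition(i)] for i in range(mol.GetNumAtoms())])
        energy = float(mol.GetProp(ENERGY_TAG)) if mol.HasProp(ENERGY_TAG) else 0.0
        confs.append(Conformation(coords, energy))
    if not confs:
        raise ValueError(f"no SDF records found in {path}")
    return ConformerEnsemble(compound_id, confs, elements, bonds)


def _write_xyz(ensemble: ConformerEnsemble, path: Path) -> None:
    with open(path, "w") as fh:
        for conf in ensemble.conformations:
            fh.write(f"{ensemble.n_atoms}\n{ENERGY_TAG}={conf.energy:.8f}\n")
            for el, (x, y, z) in zip(ensemble.atom_elements, conf.coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_xyz(path: Path, compound_id) -> ConformerEnsemble:
    lines = Path(path).read_text().splitlines()
    confs, elements = [], None
    pos, k = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as err:
            raise ValueError(f"bad atom-count line in XYZ record {k} of {path}") from err
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        energy = 0.0
        if ENERGY_TAG + "=" in comment:
            energy = float(comment.split(ENERGY_TAG + "=")[1].split()[0])
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise ValueError(f"truncated XYZ record {k} in {path}")
        els, coords = [], []
        for line in body:
            parts = line.split()
            els.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if elements is None:
            elements = els
        elif els != elements:
            raise ValueError(f"XYZ record {k} atom list differs from record 0")
        confs.append(Conformation(np.array(coords), energy))
        pos += 2 + n
        k += 1
    if not confs:
        raise ValueError(f"no XYZ records found in {path}")
    return ConformerEnsemble(compound_id, confs, elements)
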