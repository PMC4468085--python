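"""Core data model and I/O: structures, ensembles, correlation matrices.

Residues are identified everywhere by their *author* key ``"<chain>:<seq_id><icode>"``
exactly as numbered in the source PDB (e.g. ``"A:315"`` for the ABL
gate-keeper T315); no internal renumbering is ever exposed.  This key is the
universal join index across all analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Bondi-style van der Waals radii (Å), keyed by element symbol.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "B": 1.92,
}

# Backbone atom names; everything else on a standard amino acid is side chain.
BACKBONE_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "HN", "H1", "H2", "H3", "HA", "HA2", "HA3"}
)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "TIP", "TIP3", "SOL"})
ION_NAMES = frozenset(
    {"NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "CU", "CO", "NI", "CD", "IOD", "BR"}
)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "SE": 78.971, "B": 10.81,
}


def vdw_radius(element: str) -> float:
    """van der Waals radius for an element symbol; unknown element is an error."""
    key = element.strip().upper()
    if key not in VDW_RADII:
        raise KeyError(f"no van der Waals radius for element {element!r}")
    return VDW_RADII[key]


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int
    coords: np.ndarray
    is_sidechain: bool
    radius: float
    partial_charge: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")
        if self.radius <= 0:
            raise ValueError(f"atom {self.name}: radius must be positive")

    @property
    def is_heavy(self) -> bool:
        return self.element.strip().upper() not in ("H", "D")


@dataclass
class Residue:
    chain: str
    seq_id: int
    res_type: str
    atoms: list[Atom]
    is_ligand: bool = False
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.res_type} {self.seq_id}: no atoms")

    @property
    def key(self) -> str:
        return f"{self.chain}:{self.seq_id}{self.icode}"

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.res_type, "X")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.key}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def sidechain_heavy_atoms(self) -> list[Atom]:
        """Side-chain heavy atoms; glycine contributes CA (it has no side chain)."""
        atoms = [a for a in self.atoms if a.is_sidechain and a.is_heavy]
        if not atoms and not self.is_ligand:
            atoms = [a for a in self.atoms if a.name == "CA"]
        return atoms

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class Structure:
    residues: list[Residue]
    title: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate residue keys: {sorted(dupes)}")
        for idx, res in enumerate(self.residues):
            for atom in res.atoms:
                atom.residue_index = idx

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        """All atom coordinates, (n_atoms, 3), in residue/atom order."""
        return np.array([a.coords for a in self.atoms()])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords of shape ({self.n_atoms}, 3)")
        for atom, xyz in zip(self.atoms(), coords):
            atom.coords = xyz.copy()

    def residue(self, key: str) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(f"no residue with key {key!r}")

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_ligand]

    def ligand_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_ligand]

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.protein_residues())

    def copy(self) -> "Structure":
        residues = []
        for r in self.residues:
            atoms = [
                Atom(a.serial, a.name, a.element, a.residue_index, a.coords.copy(),
                     a.is_sidechain, a.radius, a.partial_charge)
                for a in r.atoms
            ]
            residues.append(Residue(r.chain, r.seq_id, r.res_type, atoms,
                                    r.is_ligand, r.icode))
        return Structure(residues, self.title)


@dataclass
class ConformationalEnsemble:
    """Ordered frames over a shared topology (one 3-vector per atom, Å)."""

    topology: Structure
    frames: np.ndarray
    frame_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frames must have shape (n_frames, {self.topology.n_atoms}, 3), "
                f"got {self.frames.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        s = self.topology.copy()
        s.set_coords(self.frames[i])
        return s


@dataclass
class CorrelationMatrix:
    """Per-residue cross-correlations C_ij in [-1, 1] from an ensemble."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric within 1e-12")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal must be exactly 1")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")

    def get(self, label_i: str, label_j: str) -> float:
        i = self.labels.index(label_i)
        j = self.labels.index(label_j)
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# PDB I/O


def _atom_from_biopdb(bio_atom, residue_index: int, is_ligand: bool) -> Atom:
    name = bio_atom.get_name().strip()
    element = (bio_atom.element or name[0]).strip().upper()
    is_sidechain = bool(is_ligand or name not in BACKBONE_NAMES)
    return Atom(
        serial=int(bio_atom.get_serial_number() or 0),
        name=name,
        element=element,
        residue_index=residue_index,
        coords=np.asarray(bio_atom.get_coord(), dtype=float),
        is_sidechain=is_sidechain,
        radius=vdw_radius(element),
    )


def _pick_altloc(bio_atom):
    """Highest occupancy wins; ties go to the first altloc encountered."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = bio_atom.disordered_get_list()
    best = children[0]
    for child in children[1:]:
        if (child.get_occupancy() or 0.0) > (best.get_occupancy() or 0.0):
            best = child
    return best


def _structure_from_model(model, title: str, keep_waters: bool) -> Structure:
    residues: list[Residue] = []
    for chain in model:
        for bio_res in chain:
            hetflag, seq_id, icode = bio_res.get_id()
            resname = bio_res.get_resname().strip()
            is_het = hetflag.strip() != ""
            if not keep_waters and (
                resname in WATER_NAMES or (is_het and resname in ION_NAMES)
            ):
                continue
            is_ligand = is_het and resname not in AA3_TO_1
            seen: dict[str, Atom] = {}
            for bio_atom in bio_res:
                picked = _pick_altloc(bio_atom)
                seen[picked.get_name().strip()] = _atom_from_biopdb(
                    picked, len(residues), is_ligand
                )
            atoms = list(seen.values())
            if not atoms:
                continue
            residues.append(
                Residue(chain.id, int(seq_id), resname, atoms, is_ligand,
                        icode.strip())
            )
    return Structure(residues, title=title)


def read_pdb(path, model="all", keep_waters: bool = False):
    """Read a PDB file into a :class:`Structure` or :class:`ConformationalEnsemble`.

    Parameters
    ----------
    path
        PDB file with ATOM/HETATM (and optionally MODEL/ENDMDL) records.
    model
        ``"all"`` returns a Structure for single-model files and an ensemble
        for multi-model files; an integer selects that model (1-based, as in
        the PDB format) as a Structure.
    keep_waters
        Retain crystallographic waters and monoatomic ions (dropped by default).
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        bio_structure = parser.get_structure("pdb", str(path))
    except PDBConstructionException as exc:
        raise ValueError(f"malformed PDB record in {path}: {exc}") from exc

    models = list(bio_structure)
    if not models:
        raise ValueError(f"{path}: no models found")

    if model != "all":
        wanted = [m for m in models if m.serial_num == model or m.id == model - 1]
        if not wanted:
            raise ValueError(f"{path}: model {model} not present")
        return _structure_from_model(wanted[0], title=str(path), keep_waters=keep_waters)

    structures = [
        _structure_from_model(m, title=str(path), keep_waters=keep_waters)
        for m in models
    ]
    if len(structures) == 1:
        return structures[0]

    topo = structures[0]
    ident = [(r.key, r.res_type, tuple(a.name for a in r.atoms)) for r in topo.residues]
    for k, s in enumerate(structures[1:], start=2):
        ident_k = [(r.key, r.res_type, tuple(a.name for a in r.atoms)) for r in s.residues]
        if ident_k != ident:
            raise ValueError(
                f"{path}: MODEL {k} differs from MODEL 1 in atom/residue content"
            )
    frames = np.stack([s.coords() for s in structures])
    return ConformationalEnsemble(topology=topo, frames=frames)


def _format_atom_line(atom: Atom, res: Residue, serial: int) -> str:
    record = "HETATM" if res.is_ligand else "ATOM"
    name = atom.name
    # standard PDB convention: 1-char element names start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    x, y, z = atom.coords
    return (
        f"{record:<6}{serial:>5} {name:<4}{'':1}{res.res_type:>3} {res.chain:1}"
        f"{res.seq_id:>4}{res.icode or '':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element.upper():>2}"
    )


def _write_structure_records(structure: Structure, lines: list[str]) -> None:
    serial = 0
    prev_chain = None
    for res in structure.residues:
        if prev_chain is not None and res.chain != prev_chain:
            lines.append("TER")
        prev_chain = res.chain
        for atom in res.atoms:
            serial += 1
            lines.append(_format_atom_line(atom, res, serial))
    lines.append("TER")


def write_pdb(obj, path) -> None:
    """Write a Structure or ConformationalEnsemble to fixed-width PDB."""
    lines: list[str] = []
    if isinstance(obj, ConformationalEnsemble):
        for i in range(obj.n_frames):
            lines.append(f"MODEL     {i + 1:>4}")
            _write_structure_records(obj.frame_structure(i), lines)
            lines.append("ENDMDL")
    elif isinstance(obj, Structure):
        _write_structure_records(obj, lines)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    lines.append("END")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Matrix TSV I/O


def write_matrix(matrix: CorrelationMatrix | pd.DataFrame, path) -> None:
    """Write a labelled square matrix as TSV (header row and index column)."""
    if isinstance(matrix, CorrelationMatrix):
        df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    else:
        df = matrix
        if df.shape[0] != df.shape[1]:
            raise ValueError(f"matrix must be square, got shape {df.shape}")
    df.to_csv(path, sep="\t", float_format="%.17g", lineterminator="\n")


def read_matrix(path, as_correlation: bool = True):
    """Read a labelled square TSV matrix; returns CorrelationMatrix by default."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square, shape {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row and column labels differ")
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or missing entries")
    labels = [str(x) for x in df.index]
    if as_correlation:
        return CorrelationMatrix(labels=labels, values=df.to_numpy())
    return pd.DataFrame(df.to_numpy(), index=labels, columns=labels)
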