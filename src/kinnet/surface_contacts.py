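"""Intermolecular contacts, atom classification, SASA and RSA.

Contacts are counted between heavy atoms at a 4.5 Å cutoff (inclusive at
the cutoff).  Each contacting atom pair is classified by an LPC-style
8-class atom typing (hydrophilic, hydrophobic, aromatic, acceptor, donor,
neutral, neutral-donor, neutral-acceptor) shipped as an editable TSV
resource; the table is a reconstruction of the published LPC scheme.
Solvent-accessible surface areas use the Shrake–Rupley algorithm on a
deterministic golden-spiral sphere quadrature, and relative solvent
accessibility divides the observed residue area by a theoretical
unfolded-state (Gly-X-Gly tripeptide) reference area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from kinnet.structio import Atom, ConformationalEnsemble, Residue, Structure

CONTACT_CUTOFF = 4.5
PROBE_RADIUS = 1.4

ATOM_CLASSES = (
    "hydrophilic",
    "hydrophobic",
    "aromatic",
    "acceptor",
    "donor",
    "neutral",
    "neutral-donor",
    "neutral-acceptor",
)

# priority used to assign a single interaction class to an atom pair;
# a complementary donor/acceptor pair is a hydrogen-bond-like (hydrophilic)
# interaction
_CLASS_PRIORITY = (
    "hydrophilic",
    "donor",
    "acceptor",
    "neutral-donor",
    "neutral-acceptor",
    "aromatic",
    "hydrophobic",
    "neutral",
)

# theoretical maximum (unfolded-state) residue SASA, Å² (Gly-X-Gly based)
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@lru_cache(maxsize=1)
def _atom_class_table() -> dict[tuple[str, str], str]:
    table: dict[tuple[str, str], str] = {}
    text = resources.files("kinnet.data").joinpath("atom_classes.tsv").read_text()
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        res_type, atom, cls = line.rstrip("\n").split("\t")
        if res_type == "res_type":
            continue
        if cls not in ATOM_CLASSES:
            raise ValueError(f"unknown atom class {cls!r} in shipped table")
        table[(res_type, atom)] = cls
    return table


def classify_atom(atom: Atom, residue: Residue) -> str:
    """8-class LPC-style atom type; unknown atoms fall back to neutral."""
    table = _atom_class_table()
    cls = table.get((residue.res_type, atom.name))
    if cls is None:
        cls = table.get(("*", atom.element.upper()))
    if cls is None:
        warnings.warn(
            f"no classification for {residue.res_type}:{atom.name}; using neutral"
        )
        cls = "neutral"
    return cls


def pair_class(class_i: str, class_j: str) -> str:
    """Interaction class of an atom pair from its two atom classes."""
    if class_i == class_j:
        return class_i
    if {class_i, class_j} <= {"donor", "acceptor", "hydrophilic"}:
        return "hydrophilic"
    for cls in _CLASS_PRIORITY:
        if cls in (class_i, class_j):
            return cls
    raise ValueError(f"unknown classes {class_i!r}, {class_j!r}")


@dataclass
class ContactRecord:
    residue: str
    partner: str
    n_atom_pairs: int
    class_tally: dict[str, int]


def _contact_atoms(res: Residue, atoms: str):
    if atoms == "sidechain":
        return res.sidechain_heavy_atoms()
    if atoms == "heavy":
        return res.heavy_atoms()
    raise ValueError(f"unknown atom selection {atoms!r}")


def count_contacts(
    res_i: Residue,
    res_j: Residue,
    cutoff: float = CONTACT_CUTOFF,
    atoms: str = "sidechain",
) -> int:
    """Number of heavy-atom pairs between two residues within the cutoff.

    The default selection is side-chain heavy atoms; glycine contributes its
    CA (it has no side chain).  A pair exactly at the cutoff counts.
    """
    a_i = _contact_atoms(res_i, atoms)
    a_j = _contact_atoms(res_j, atoms)
    if not a_i or not a_j:
        return 0
    d = cdist([a.coords for a in a_i], [a.coords for a in a_j])
    return int((d <= cutoff).sum())


def contact_record(
    res_i: Residue,
    res_j: Residue,
    cutoff: float = CONTACT_CUTOFF,
    atoms: str = "sidechain",
) -> ContactRecord:
    """Contact count plus the per-class tally; the tally partitions the count."""
    a_i = _contact_atoms(res_i, atoms)
    a_j = _contact_atoms(res_j, atoms)
    tally = {cls: 0 for cls in ATOM_CLASSES}
    n = 0
    if a_i and a_j:
        d = cdist([a.coords for a in a_i], [a.coords for a in a_j])
        cls_i = [classify_atom(a, res_i) for a in a_i]
        cls_j = [classify_atom(a, res_j) for a in a_j]
        for ii, jj in zip(*np.nonzero(d <= cutoff)):
            tally[pair_class(cls_i[ii], cls_j[jj])] += 1
            n += 1
    return ContactRecord(res_i.key, res_j.key, n, tally)


def ensemble_ligand_contacts(
    ensemble: ConformationalEnsemble,
    ligand_key: str | None = None,
    cutoff: float = CONTACT_CUTOFF,
) -> pd.DataFrame:
    """Per-residue mean ligand contact counts and class tallies over frames.

    Contacts are counted per frame between ligand heavy atoms and all
    protein heavy atoms; the returned table is indexed by residue key with a
    ``n_contacts`` column plus one mean-count column per interaction class.
    """
    topo = ensemble.topology
    ligands = topo.ligand_residues()
    if ligand_key is not None:
        ligands = [r for r in ligands if r.key == ligand_key]
    if not ligands:
        raise ValueError("no ligand residue in the ensemble topology")
    ligand = ligands[0]

    flat_index: dict[int, list[int]] = {}
    flat = 0
    for idx, res in enumerate(topo.residues):
        rows = [flat + k for k, a in enumerate(res.atoms) if a.is_heavy]
        flat += len(res.atoms)
        flat_index[idx] = rows
    lig_idx = topo.residues.index(ligand)
    lig_rows = flat_index[lig_idx]
    lig_classes = [classify_atom(a, ligand) for a in ligand.heavy_atoms()]

    protein = [(i, r) for i, r in enumerate(topo.residues) if not r.is_ligand]
    keys = [r.key for _, r in protein]
    counts = np.zeros((len(protein), 1 + len(ATOM_CLASSES)))
    cls_col = {cls: 1 + k for k, cls in enumerate(ATOM_CLASSES)}

    for frame in ensemble.frames:
        lig_xyz = frame[lig_rows]
        for row, (idx, res) in enumerate(protein):
            rows = flat_index[idx]
            if not rows:
                continue
            d = cdist(frame[rows], lig_xyz)
            hits = np.nonzero(d <= cutoff)
            if len(hits[0]) == 0:
                continue
            res_classes = [classify_atom(a, res) for a in res.heavy_atoms()]
            counts[row, 0] += len(hits[0])
            for ii, jj in zip(*hits):
                counts[row, cls_col[pair_class(res_classes[ii], lig_classes[jj])]] += 1

    counts /= ensemble.n_frames
    return pd.DataFrame(
        counts, index=keys, columns=["n_contacts", *ATOM_CLASSES]
    )


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


@dataclass
class SASAProfile:
    per_atom: pd.Series  # indexed by (residue key, atom name)
    per_residue: pd.Series  # indexed by residue key, Å²
    res_types: dict[str, str]

    def __post_init__(self) -> None:
        if (self.per_atom < -1e-9).any() or (self.per_residue < -1e-9).any():
            raise ValueError("areas must be non-negative")


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa(
    structure: Structure,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
    heavy_only: bool = True,
) -> SASAProfile:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's area is the exposed fraction of its quadrature sphere times
    4π(r + probe)².  Atoms at identical coordinates are an error (the
    quadrature is undefined for coincident spheres).
    """
    entries = []
    for res in structure.residues:
        for atom in res.atoms:
            if heavy_only and not atom.is_heavy:
                continue
            entries.append((res.key, atom.name, atom.coords, atom.radius))
    if not entries:
        raise ValueError("no atoms selected for SASA")
    coords = np.array([e[2] for e in entries])
    radii = np.array([e[3] for e in entries]) + probe

    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    if (d < 1e-6).any():
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValueError(
            f"atoms at identical coordinates: "
            f"{entries[i][0]}:{entries[i][1]} and {entries[j][0]}:{entries[j][1]}"
        )

    unit = _sphere_points(n_points)
    areas = np.empty(len(entries))
    for i in range(len(entries)):
        neighbors = np.nonzero(d[i] < radii[i] + radii)[0]
        pts = coords[i] + radii[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            exposed &= ((pts - coords[j]) ** 2).sum(axis=1) > radii[j] ** 2
        areas[i] = exposed.mean() * 4.0 * np.pi * radii[i] ** 2

    index = pd.MultiIndex.from_tuples(
        [(e[0], e[1]) for e in entries], names=["residue", "atom"]
    )
    per_atom = pd.Series(areas, index=index, name="sasa")
    per_residue = per_atom.groupby(level=0, sort=False).sum()
    res_types = {r.key: r.res_type for r in structure.residues}
    return SASAProfile(per_atom, per_residue, res_types)


def rsa(
    profile: SASAProfile, reference: dict[str, float] | None = None
) -> pd.Series:
    """Relative solvent accessibility: observed area / unfolded reference.

    Values may slightly exceed 1 for highly exposed residues.  A residue
    type missing from the reference table is an error.
    """
    ref = dict(MAX_SASA)
    if reference:
        ref.update(reference)
    values = {}
    for key, area in profile.per_residue.items():
        res_type = profile.res_types[key]
        if res_type not in ref:
            raise KeyError(f"no reference SASA for residue type {res_type!r}")
        values[key] = area / ref[res_type]
    return pd.Series(values, name="rsa")
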