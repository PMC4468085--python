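"""Deterministic generators of toy structures, ensembles, MSAs and complexes.

Every generator is a pure function of its arguments plus an explicit integer
seed (``numpy.random.default_rng``; no global random state).  The generated
objects are small but exercise every downstream analysis stage:

* ``gen_toy_structure`` — ideal-geometry peptide backbones (helix, hairpin,
  globule) with a single pseudo side-chain atom (``CB2``) per non-glycine
  residue, so contact counts stay small hand-checkable integers.
* ``gen_ensemble`` — Gaussian sampling along chosen elastic-network modes,
  standing in for molecular-dynamics trajectories.
* ``gen_msa`` — alignments with planted conserved columns and planted
  coevolving column pairs over a stated background.  Coevolving pairs use a
  two-state paired alphabet, which gives a closed-form target mutual
  information (ln 2 nats at coupling 1).
* ``gen_complex`` — apo/holo pairs in which the ligand bridges two weakly
  connected lobes of the protein contact network, the qualitative mechanism
  probed by the centrality analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kinnet import dynamics
from kinnet.structio import AA3_TO_1, Atom, ConformationalEnsemble, Residue, Structure, vdw_radius

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# internal-coordinate ideals for peptide backbone construction (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 117.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.5

DEFAULT_SEQUENCE_CYCLE = "LAKVDEFGIRSTNQHYW"

FOLD_TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 130.0),
}


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom D given A-B-C, the C-D bond, B-C-D angle and A-B-C-D torsion."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _fold_torsions(fold: str, n_residues: int, rng: np.random.Generator):
    """Per-residue (phi, psi) for the requested fold."""
    if fold == "helix":
        return [FOLD_TORSIONS["helix"]] * n_residues
    if fold == "hairpin":
        turn_start = n_residues // 2 - 1
        torsions = []
        for i in range(n_residues):
            if i == turn_start:
                torsions.append((-60.0, -30.0))
            elif i == turn_start + 1:
                torsions.append((-90.0, 0.0))
            else:
                torsions.append(FOLD_TORSIONS["strand"])
        return torsions
    if fold == "globule":
        basins = [(-57.0, -47.0), (-120.0, 130.0), (-75.0, -40.0), (60.0, 45.0)]
        picks = rng.integers(0, len(basins), size=n_residues)
        jitter = rng.normal(0.0, 8.0, size=(n_residues, 2))
        return [
            (basins[p][0] + j[0], basins[p][1] + j[1]) for p, j in zip(picks, jitter)
        ]
    raise ValueError(f"unknown fold {fold!r}; expected helix, hairpin or globule")


def gen_toy_structure(
    n_residues: int,
    fold: str = "helix",
    seed: int = 0,
    sequence: str | None = None,
) -> Structure:
    """Ideal-geometry toy peptide with one pseudo side-chain atom per residue.

    The backbone is grown residue by residue from ideal bond lengths and
    angles with fold-specific (phi, psi) torsions; glycines carry no side
    chain, every other residue carries a single ``CB2`` carbon at the ideal
    beta-carbon position.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    torsions = _fold_torsions(fold, n_residues, rng)
    if sequence is None:
        sequence = "".join(
            DEFAULT_SEQUENCE_CYCLE[i % len(DEFAULT_SEQUENCE_CYCLE)]
            for i in range(n_residues)
        )
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")

    # seed the first residue in the xy-plane
    n_pos = [np.array([0.0, 0.0, 0.0])]
    ca_pos = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.deg2rad(ANGLE_N_CA_C)
    c_pos = [
        ca_pos[0]
        + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    ]
    for i in range(1, n_residues):
        psi_prev = torsions[i - 1][1]
        n_i = _nerf(n_pos[-1], ca_pos[-1], c_pos[-1], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = _nerf(ca_pos[-1], c_pos[-1], n_i, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        phi_i = torsions[i][0]
        c_i = _nerf(c_pos[-1], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        n_pos.append(n_i)
        ca_pos.append(ca_i)
        c_pos.append(c_i)

    residues = []
    serial = 0
    for i in range(n_residues):
        one = sequence[i].upper()
        res_type = AA1_TO_3.get(one)
        if res_type is None:
            raise ValueError(f"unknown amino acid code {one!r}")
        psi = torsions[i][1]
        o_i = _nerf(n_pos[i], ca_pos[i], c_pos[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        atoms = []
        for name, element, xyz, sidechain in (
            ("N", "N", n_pos[i], False),
            ("CA", "C", ca_pos[i], False),
            ("C", "C", c_pos[i], False),
            ("O", "O", o_i, False),
        ):
            serial += 1
            atoms.append(
                Atom(serial, name, element, i, xyz, sidechain, vdw_radius(element))
            )
        if res_type != "GLY":
            cb = _nerf(c_pos[i], n_pos[i], ca_pos[i], BOND_CA_CB, ANGLE_N_CA_CB, 122.6)
            serial += 1
            atoms.append(Atom(serial, "CB2", "C", i, cb, True, vdw_radius("C")))
        residues.append(Residue("A", i + 1, res_type, atoms))
    return Structure(residues, title=f"toy-{fold}-{n_residues}")


def gen_ensemble(
    structure: Structure,
    n_frames: int,
    mode_spectrum: list[tuple[int, float]] | None = None,
    temperature_scale: float = 1.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
    anm_cutoff: float = 15.0,
) -> ConformationalEnsemble:
    """Sample frames along elastic-network modes around a reference structure.

    Each requested mode (index into the ANM eigenvalue-ordered mode list;
    indices 0-5 are the rigid-body modes and are rejected) receives i.i.d.
    Gaussian coefficients with standard deviation ``amplitude *
    temperature_scale``, so the sample variance of the CA displacement
    projected on a mode converges to the squared amplitude.  Per-residue
    displacements move all atoms of the residue rigidly.  ``noise_sigma``
    adds independent isotropic per-atom Gaussian noise on top.
    """
    if len(structure.protein_residues()) < 4:
        raise ValueError("need at least 4 residues")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    mode_spectrum = mode_spectrum or []
    rng = np.random.default_rng(seed)

    ref = structure.coords()
    n_atoms = ref.shape[0]
    frames = np.tile(ref, (n_frames, 1, 1))

    if mode_spectrum:
        anm = dynamics.anm_modes(structure, cutoff=anm_cutoff)
        n_res = len(anm.labels)
        # map residue -> atom rows so CA-space modes displace whole residues
        res_atoms = []
        flat = 0
        for res in structure.residues:
            rows = list(range(flat, flat + len(res.atoms)))
            flat += len(res.atoms)
            if not res.is_ligand:
                res_atoms.append(rows)
        for mode_index, amplitude in mode_spectrum:
            if mode_index < 6:
                raise ValueError(
                    f"mode {mode_index} is a rigid-body (zero-frequency) mode"
                )
            vec = anm.modes[:, mode_index].reshape(n_res, 3)
            coeff = rng.normal(0.0, amplitude * temperature_scale, size=n_frames)
            for r, rows in enumerate(res_atoms):
                frames[:, rows, :] += coeff[:, None, None] * vec[r]

    if noise_sigma > 0:
        frames += rng.normal(0.0, noise_sigma, size=(n_frames, n_atoms, 3))
    return ConformationalEnsemble(topology=structure, frames=frames)


# ---------------------------------------------------------------------------
# Planted-signal MSAs

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# two-state paired alphabet for coevolving columns: state 0 -> (A, R),
# state 1 -> (C, D); equiprobable states give MI = ln 2 at coupling 1
PAIRED_STATES = (("A", "R"), ("C", "D"))


@dataclass
class MSASpec:
    """Specification of a synthetic alignment with planted signal."""

    n_sequences: int
    n_columns: int
    background: np.ndarray | None = None  # 20-vector over AMINO_ACIDS order
    conserved_columns: list[tuple[int, str, float]] = field(default_factory=list)
    coevolving_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background is None:
            self.background = np.full(20, 1.0 / 20.0)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,) or abs(self.background.sum() - 1) > 1e-9:
            raise ValueError("background must be a 20-vector summing to 1")
        cols = [c for c, _, _ in self.conserved_columns]
        for a, b, c in self.coevolving_pairs:
            cols.extend([a, b])
            if not 0.0 <= c <= 1.0:
                raise ValueError("coupling must lie in [0, 1]")
        if any(c < 0 or c >= self.n_columns for c in cols):
            raise ValueError("planted column index out of range")
        if len(cols) != len(set(cols)):
            raise ValueError("planted columns overlap")


def gen_msa(spec: MSASpec):
    """Generate an alignment with planted conservation and coevolution.

    Unplanted columns are i.i.d. from the background.  A coevolving pair
    with coupling ``c`` draws, per sequence, with probability ``c`` a shared
    equiprobable two-state symbol pair, and otherwise both columns
    independently from the background.  A conserved column emits its residue
    with the stated probability and a background draw otherwise.
    """
    from kinnet.coevo import MSA

    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_sequences, spec.n_columns
    aa = np.array(list(AMINO_ACIDS))
    cols = rng.choice(aa, size=(n, m), p=spec.background)

    for col, residue, p in spec.conserved_columns:
        keep = rng.random(n) < p
        cols[keep, col] = residue

    for col_a, col_b, coupling in spec.coevolving_pairs:
        coupled = rng.random(n) < coupling
        states = rng.integers(0, len(PAIRED_STATES), size=n)
        for s, (sym_a, sym_b) in enumerate(PAIRED_STATES):
            mask = coupled & (states == s)
            cols[mask, col_a] = sym_a
            cols[mask, col_b] = sym_b

    sequences = ["".join(row) for row in cols]
    ids = [f"seq{i + 1:05d}" for i in range(n)]
    return MSA(sequences=sequences, ids=ids, reference_id=ids[0])


# ---------------------------------------------------------------------------
# Ligand-bridged apo/holo complexes


@dataclass
class ComplexSpec:
    """Specification of a two-lobe toy complex with a bridging ligand."""

    n_residues: int = 12
    pocket_residues: tuple[int, ...] | None = None  # 0-based indices; default lobe tips
    ligand_atoms: int = 8
    bridge_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 6:
            raise ValueError("need at least 6 residues")
        if self.n_residues % 2:
            raise ValueError(
                "n_residues must be even (the two arms of the layout are "
                "interleaved over even/odd sequence indices)"
            )
        if self.ligand_atoms < 1:
            raise ValueError("need at least 1 ligand atom")
        if self.pocket_residues is None:
            self.pocket_residues = (0, self.n_residues - 1)
        self.pocket_residues = tuple(self.pocket_residues)
        if any(p < 0 or p >= self.n_residues for p in self.pocket_residues):
            raise ValueError("pocket residue index out of range")


# geometry constants of the two-arm ("theta") layout, Å
_ARM_SPACING = 4.3  # vertical CA spacing within an arm
_TOP_HALF_WIDTH = 6.0
_BOTTOM_HALF_WIDTH = 3.25
# ligand anchor distance beyond the CB2 tip: the carbon-carbon LJ minimum
# of the toy force field, so pocket contacts are attractive hot spots
_LIGAND_REACH = 4.0
_CONTACT_CUTOFF = 4.5

# residue template offsets in the (x, y) plane around CA; CB2 direction is
# supplied per placement
_TEMPLATE = {
    "N": np.array([-1.203, -0.824, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.258, -0.862, 0.0]),
}


def _complex_layout(n_residues: int):
    """CA positions, CB2 directions and mirror flags of the two-arm layout.

    Sequence indices are interleaved over the arms (evens down arm A, odds
    up arm B) so that spatial neighbours are never sequence-adjacent and the
    bottom cross-link joins the two lobes into one weakly connected network.
    """
    m_a = (n_residues + 1) // 2
    m_b = n_residues // 2
    # small alternating out-of-plane stagger keeps the CA elastic network
    # three-dimensional (a strictly planar bead network has spurious
    # out-of-plane zero modes)
    stagger = 0.25
    placements: dict[int, tuple[np.ndarray, np.ndarray, bool]] = {}
    for t in range(m_a):
        frac = t / max(m_a - 1, 1)
        x = -(_TOP_HALF_WIDTH - (_TOP_HALF_WIDTH - _BOTTOM_HALF_WIDTH) * frac)
        ca = np.array([x, stagger * (-1.0) ** t, -_ARM_SPACING * t])
        # the bottom residue's side chain tilts inward and upward so that it
        # stays in contact with its in-arm neighbour and the opposite arm
        u = np.array([0.8, 0.0, 0.6]) if t == m_a - 1 else np.array([0.0, 1.0, 0.0])
        placements[2 * t] = (ca, u, False)
    for t in range(m_b):
        frac = t / max(m_b - 1, 1)
        x = _TOP_HALF_WIDTH - (_TOP_HALF_WIDTH - _BOTTOM_HALF_WIDTH) * frac
        ca = np.array([x, -stagger * (-1.0) ** t, -_ARM_SPACING * t])
        u = np.array([-0.8, 0.0, 0.6]) if t == m_b - 1 else np.array([0.0, 1.0, 0.0])
        placements[2 * (m_b - 1 - t) + 1] = (ca, u, True)
    return placements


def gen_complex(spec: ComplexSpec):
    """Generate an (apo, holo) pair where the ligand bridges the pocket.

    The protein is laid out as two arms joined by a single bottom
    cross-link (a theta-like two-lobe contact network); pocket residues
    receive ligand heavy atoms within 4.5 Å of their side-chain tip while
    every non-pocket residue stays beyond the cutoff.  ``bridge_strength``
    sets how many ligand atoms anchor each pocket residue; 0 parks the whole
    ligand more than 20 Å away (non-interacting control).  Apo and holo
    protein coordinates are identical.
    """
    rng = np.random.default_rng(spec.seed)
    placements = _complex_layout(spec.n_residues)

    residues = []
    serial = 0
    for i in range(spec.n_residues):
        ca, u, mirrored = placements[i]
        atoms = []
        for name in ("N", "CA", "C"):
            off = _TEMPLATE[name].copy()
            if mirrored:
                off[0] = -off[0]
            serial += 1
            element = name[0]
            atoms.append(
                Atom(serial, name, element, i, ca + off, False, vdw_radius(element))
            )
        serial += 1
        atoms.append(
            Atom(serial, "CB2", "C", i, ca + BOND_CA_CB * u, True, vdw_radius("C"))
        )
        residues.append(Residue("A", i + 1, "LEU", atoms))
    apo = Structure(residues, title="synthetic-apo")

    # ligand placement
    per_pocket = max(1, int(round(spec.bridge_strength))) if spec.bridge_strength > 0 else 0
    needed = per_pocket * len(spec.pocket_residues)
    if spec.bridge_strength > 0 and spec.ligand_atoms < needed:
        raise ValueError(
            f"ligand_atoms={spec.ligand_atoms} cannot anchor "
            f"{len(spec.pocket_residues)} pocket residues at bridge_strength "
            f"{spec.bridge_strength} (need {needed})"
        )
    lig_coords = []
    if spec.bridge_strength <= 0:
        # non-interacting control: park the ligand far above the protein
        for k in range(spec.ligand_atoms):
            lig_coords.append(np.array([1.5 * k, 40.0, 0.0]))
    else:
        anchors = []
        for p in spec.pocket_residues:
            ca, u, _ = placements[p]
            anchors.append(ca + (BOND_CA_CB + _LIGAND_REACH) * u)
        for p, anchor in zip(spec.pocket_residues, anchors):
            for _ in range(per_pocket):
                jitter = rng.normal(0.0, 0.1, size=3)
                lig_coords.append(anchor + jitter)
        # spare atoms span the top gap in the safe zone between the pockets
        n_spare = spec.ligand_atoms - len(lig_coords)
        safe = _TOP_HALF_WIDTH - 3.5
        for k in range(n_spare):
            x = -safe + 2 * safe * (k + 1) / (n_spare + 1)
            lig_coords.append(np.array([x, BOND_CA_CB + _LIGAND_REACH, 0.0]))

    lig_atoms = [
        Atom(serial + 1 + k, f"L{k + 1}", "C", spec.n_residues, xyz, True, vdw_radius("C"))
        for k, xyz in enumerate(lig_coords)
    ]
    holo_residues = [r for r in apo.copy().residues]
    holo_residues.append(Residue("L", 1, "LIG", lig_atoms, is_ligand=True))
    holo = Structure(holo_residues, title="synthetic-holo")

    _check_pocket_geometry(holo, spec)
    return apo, holo


def _check_pocket_geometry(holo: Structure, spec: ComplexSpec) -> None:
    """Verify the placement contract; raise if the pocket is not realizable."""
    if spec.bridge_strength <= 0:
        return
    ligand = holo.ligand_residues()[0]
    lig_xyz = np.array([a.coords for a in ligand.heavy_atoms()])
    pocket = {spec.pocket_residues[i] for i in range(len(spec.pocket_residues))}
    for i, res in enumerate(holo.protein_residues()):
        res_xyz = np.array([a.coords for a in res.heavy_atoms()])
        dmin = np.sqrt(
            ((res_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(axis=2)
        ).min()
        if i in pocket and dmin > _CONTACT_CUTOFF:
            raise ValueError(
                f"pocket residue {res.key} has no ligand atom within "
                f"{_CONTACT_CUTOFF} Å (min {dmin:.2f})"
            )
        if i not in pocket and dmin <= _CONTACT_CUTOFF:
            raise ValueError(
                f"pocket residues not mutually placeable: non-pocket residue "
                f"{res.key} is {dmin:.2f} Å from the ligand"
            )
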