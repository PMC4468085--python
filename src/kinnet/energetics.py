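"""MM-GBSA binding free energies and computational alanine scanning.

The binding free energy of a protein-ligand complex is assembled per frame
from the single-trajectory decomposition

    dG_bind = <dG_MM> + <dG_solv> - T<dS>

where dG_MM collects the intermolecular van der Waals and electrostatic
terms (the internal-energy difference of the isolated molecules upon
complexation is neglected, as in the single-trajectory protocol),
dG_solv = dG_np + dG_GB combines a surface-area nonpolar term
(sigma_np * SASA, sigma_np = 0.0072 kcal/(mol A^2)) with a pairwise
generalized-Born electrostatic term (HCT-style descreening Born radii),
and the entropy is a rigid-rotor/harmonic-oscillator estimate on minimized
structures.

Alanine scanning truncates the side chain of a residue beyond C-beta
(C-gamma replaced by a hydrogen at ideal bond length), relaxes only the new
hydrogen with steepest descent (1000 steps or gradient tolerance) against
the fixed remainder, and recomputes the per-frame decomposition on the
wild-type trajectory:

    ddG_bind = <dE_vdw> + <dE_elec> + <ddG_np> + <ddG_GB>

with the entropy term omitted.  The molecular-mechanics parameter set is a
documented minimal one (element-based Lennard-Jones, per-atom charges,
bonds-only topology): the combination bookkeeping is the object of
interest, not force-field fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kinnet.structio import ATOMIC_MASSES, Atom, ConformationalEnsemble, Structure
from kinnet.surface_contacts import _sphere_points

COULOMB_K = 332.06  # kcal Å / (mol e²)
KB_KCAL = 1.987204259e-3  # kcal/(mol K)
DEFAULT_TEMPERATURE = 300.0
BOND_FORCE_CONSTANT = 300.0  # kcal/(mol Å²)

# ideal bond lengths (Å) by sorted atom-name pair; fallback: observed length
IDEAL_BONDS = {
    ("CA", "N"): 1.458,
    ("C", "CA"): 1.525,
    ("C", "N"): 1.329,
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.530,
    ("CA", "CB2"): 1.530,
    ("CA", "HB"): 1.090,
    ("CB", "HB"): 1.090,
}

_BOND_NAME_PAIRS = frozenset(IDEAL_BONDS) | {("CB", "CG"), ("CB2", "HB")}


@dataclass
class EnergyModelParams:
    """Minimal toy molecular-mechanics parameter set.

    Lennard-Jones well depths (kcal/mol) and rmin/2 radii (Å) are keyed by
    element; partial charges (e) by (residue type, atom name), defaulting
    to 0.  ``sigma_np`` is the surface-tension coefficient of the nonpolar
    solvation term.
    """

    lj_eps: dict[str, float] = field(
        default_factory=lambda: {"C": 0.10, "N": 0.17, "O": 0.21, "S": 0.25, "H": 0.03}
    )
    lj_rmin_half: dict[str, float] = field(
        default_factory=lambda: {"C": 2.00, "N": 1.85, "O": 1.70, "S": 2.00, "H": 0.80}
    )
    charges: dict[tuple[str, str], float] = field(default_factory=dict)
    eps_in: float = 1.0
    eps_solvent: float = 80.0
    sigma_np: float = 0.0072  # kcal/(mol Å²)
    gb_scale: float = 0.8
    gb_offset: float = 0.09
    probe: float = 1.4
    sasa_points: int = 240
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.sigma_np <= 0:
            raise ValueError("sigma_np must be positive")
        if self.eps_in < 1 or self.eps_solvent < 1:
            raise ValueError("dielectric constants must be >= 1")

    def atom_params(self, atom: Atom, res_type: str):
        elem = atom.element.upper()
        if elem not in self.lj_eps or elem not in self.lj_rmin_half:
            raise KeyError(
                f"unparameterized atom {res_type}:{atom.name} (element {elem})"
            )
        charge = atom.partial_charge
        if charge is None:
            charge = self.charges.get((res_type, atom.name), 0.0)
        return self.lj_eps[elem], self.lj_rmin_half[elem], charge


@dataclass
class EnergyDecomposition:
    """Per-term energies (kcal/mol) of one molecule/selection."""

    e_bond: float
    e_vdw: float
    e_elec: float
    g_solv_np: float
    g_solv_elec: float

    @property
    def total(self) -> float:
        return self.e_bond + self.e_vdw + self.e_elec + self.g_solv_np + self.g_solv_elec

    def __post_init__(self) -> None:
        for name in ("e_bond", "e_vdw", "e_elec", "g_solv_np", "g_solv_elec"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")


@dataclass
class EntropyResult:
    s_trans: float  # kcal/(mol K)
    s_rot: float
    s_vib: float

    @property
    def total(self) -> float:
        return self.s_trans + self.s_rot + self.s_vib


@dataclass
class BindingFreeEnergy:
    dg_bind: float
    dg_mm: float
    dg_solv: float
    t_ds: float
    entropy: dict | None
    per_frame: pd.DataFrame
    n_frames: int

    def __post_init__(self) -> None:
        if abs(self.dg_bind - (self.dg_mm + self.dg_solv - self.t_ds)) > 1e-9:
            raise ValueError("dG_bind != dG_MM + dG_solv - TdS")


@dataclass
class AlanineScanResult:
    table: pd.DataFrame  # ddG + term-wise breakdown per scanned residue
    skipped: dict[str, str]


# ---------------------------------------------------------------------------
# internal system representation


class _System:
    """Flat arrays + bond topology for one selection of a structure."""

    def __init__(self, structure: Structure, params: EnergyModelParams, which: str):
        if which == "complex":
            residues = structure.residues
        elif which == "protein":
            residues = structure.protein_residues()
        elif which == "ligand":
            residues = structure.ligand_residues()
            if not residues:
                raise ValueError("structure has no ligand residue")
        else:
            raise ValueError(f"unknown selection {which!r}")
        self.atoms: list[Atom] = []
        self.labels: list[tuple[str, str]] = []
        res_of: list[int] = []
        for r_idx, res in enumerate(residues):
            for atom in res.atoms:
                self.atoms.append(atom)
                self.labels.append((res.key, atom.name))
                res_of.append(r_idx)
        n = len(self.atoms)
        self.coords = np.array([a.coords for a in self.atoms])
        eps = np.empty(n)
        rmin = np.empty(n)
        charge = np.empty(n)
        for k, (atom, r_idx) in enumerate(zip(self.atoms, res_of)):
            eps[k], rmin[k], charge[k] = params.atom_params(atom, residues[r_idx].res_type)
        self.eps, self.rmin_half, self.charge = eps, rmin, charge
        self.radius = np.array([a.radius for a in self.atoms])
        self.mass = np.array(
            [ATOMIC_MASSES.get(a.element.upper(), 12.011) for a in self.atoms]
        )
        self.heavy = np.array([a.is_heavy for a in self.atoms])

        # bonds: named backbone/side-chain pairs within a residue, the
        # peptide C-N link between consecutive residues, and a generic
        # distance criterion (< 1.9 Å between heavy atoms) for HET groups
        bonds: list[tuple[int, int, float]] = []
        index_of = {}
        for k, (r_idx, atom) in enumerate(zip(res_of, self.atoms)):
            index_of[(r_idx, atom.name)] = k
        for k in range(n):
            for m in range(k + 1, n):
                same_res = res_of[k] == res_of[m]
                pair = tuple(sorted((self.atoms[k].name, self.atoms[m].name)))
                d = float(np.linalg.norm(self.coords[k] - self.coords[m]))
                bonded = False
                if same_res and pair in _BOND_NAME_PAIRS and d < 2.2:
                    bonded = True
                elif (
                    abs(res_of[k] - res_of[m]) == 1
                    and pair == ("C", "N")
                    and d < 1.8
                ):
                    bonded = True
                elif same_res and self.heavy[k] and self.heavy[m] and d < 1.9:
                    bonded = True
                if bonded:
                    bonds.append((k, m, IDEAL_BONDS.get(pair, d)))
        self.bonds = bonds

        # nonbonded exclusions: 1-2 and 1-3 neighbours on the bond graph
        adj: dict[int, set[int]] = {k: set() for k in range(n)}
        for i, j, _ in bonds:
            adj[i].add(j)
            adj[j].add(i)
        excl = np.zeros((n, n), dtype=bool)
        for i, j, _ in bonds:
            excl[i, j] = excl[j, i] = True
        for i in range(n):
            for j in adj[i]:
                for k in adj[j]:
                    if k != i:
                        excl[i, k] = excl[k, i] = True
        self.excluded = excl

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def _pair_distances(coords: np.ndarray):
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return diff, dist


def _mm_terms(system: _System, coords: np.ndarray, params: EnergyModelParams):
    """(E_bond, E_vdw, E_elec) of the system at the given coordinates."""
    n = system.n_atoms
    e_bond = 0.0
    for i, j, r0 in system.bonds:
        r = float(np.linalg.norm(coords[i] - coords[j]))
        e_bond += BOND_FORCE_CONSTANT * (r - r0) ** 2
    if n < 2:
        return e_bond, 0.0, 0.0
    _, dist = _pair_distances(coords)
    mask = np.triu(np.ones((n, n), dtype=bool), k=1) & ~system.excluded
    r = dist[mask]
    eps_ij = np.sqrt(np.outer(system.eps, system.eps))[mask]
    rmin_ij = (system.rmin_half[:, None] + system.rmin_half[None, :])[mask]
    q_ij = np.outer(system.charge, system.charge)[mask]
    sr6 = (rmin_ij / r) ** 6
    e_vdw = float((eps_ij * (sr6**2 - 2.0 * sr6)).sum())
    e_elec = float((COULOMB_K * q_ij / (params.eps_in * r)).sum())
    return e_bond, e_vdw, e_elec


def _born_radii(system: _System, coords: np.ndarray, params: EnergyModelParams):
    """HCT pairwise-descreening effective Born radii."""
    rho = np.maximum(system.radius - params.gb_offset, 0.5)
    n = system.n_atoms
    _, dist = _pair_distances(coords)
    inv_alpha = 1.0 / rho
    s = params.gb_scale * rho
    for i in range(n):
        integral = 0.0
        for j in range(n):
            if j == i:
                continue
            r = dist[i, j]
            sj = s[j]
            if rho[i] >= r + sj:
                continue  # descreening sphere buried inside atom i
            upper = r + sj
            lower = max(abs(r - sj), rho[i])
            term = (
                0.5 * (1.0 / lower - 1.0 / upper)
                + 0.125 * r * (1.0 / upper**2 - 1.0 / lower**2)
                + 0.25 / r * np.log(lower / upper)
                + 0.125 * sj**2 / r * (1.0 / lower**2 - 1.0 / upper**2)
            )
            integral += term
        inv_alpha[i] = 1.0 / rho[i] - integral
    alpha = np.where(inv_alpha > 1e-3, 1.0 / np.maximum(inv_alpha, 1e-3), 1000.0)
    return np.clip(alpha, rho, 1000.0)


def _gb_energy(system: _System, coords: np.ndarray, params: EnergyModelParams):
    """Pairwise generalized-Born electrostatic solvation energy."""
    q = system.charge
    if not np.any(q):
        return 0.0
    tau = 1.0 / params.eps_in - 1.0 / params.eps_solvent
    alpha = _born_radii(system, coords, params)
    _, dist = _pair_distances(coords)
    aa = np.outer(alpha, alpha)
    f_gb = np.sqrt(dist**2 + aa * np.exp(-(dist**2) / (4.0 * aa)))
    qq = np.outer(q, q)
    upper = np.triu(np.ones_like(f_gb, dtype=bool), k=1)
    e = (qq[upper] / f_gb[upper]).sum() + 0.5 * (q**2 / alpha).sum()
    return float(-COULOMB_K * tau * e)


def _sasa_area(system: _System, coords: np.ndarray, params: EnergyModelParams):
    """Total heavy-atom SASA (Å²) by Shrake-Rupley quadrature."""
    sel = np.nonzero(system.heavy)[0]
    xyz = coords[sel]
    radii = system.radius[sel] + params.probe
    unit = _sphere_points(params.sasa_points)
    _, dist = _pair_distances(xyz)
    np.fill_diagonal(dist, np.inf)
    total = 0.0
    for i in range(len(sel)):
        neighbors = np.nonzero(dist[i] < radii[i] + radii)[0]
        pts = xyz[i] + radii[i] * unit
        exposed = np.ones(len(unit), dtype=bool)
        for j in neighbors:
            exposed &= ((pts - xyz[j]) ** 2).sum(axis=1) > radii[j] ** 2
        total += exposed.mean() * 4.0 * np.pi * radii[i] ** 2
    return float(total)


def _decomposition(system: _System, coords: np.ndarray, params: EnergyModelParams):
    e_bond, e_vdw, e_elec = _mm_terms(system, coords, params)
    g_np = params.sigma_np * _sasa_area(system, coords, params)
    g_gb = _gb_energy(system, coords, params)
    return EnergyDecomposition(e_bond, e_vdw, e_elec, g_np, g_gb)


def energy_terms(
    structure: Structure,
    params: EnergyModelParams | None = None,
    selection: str = "complex",
) -> EnergyDecomposition:
    """Per-term MM + GB/SA energies of a structure selection.

    ``selection`` is ``complex`` (all residues), ``protein`` or ``ligand``.
    Every atom must be parameterizable (element known to the LJ tables);
    an unparameterized atom raises, naming it.
    """
    params = params or EnergyModelParams()
    system = _System(structure, params, selection)
    return _decomposition(system, system.coords, params)


# ---------------------------------------------------------------------------
# gradients and minimization (gas-phase MM terms)


def _mm_gradient(system: _System, coords: np.ndarray, params: EnergyModelParams):
    """Analytic gradient of E_bond + E_vdw + E_elec."""
    n = system.n_atoms
    grad = np.zeros_like(coords)
    diff, dist = _pair_distances(coords)
    np.fill_diagonal(dist, np.inf)
    mask = ~system.excluded & ~np.eye(n, dtype=bool)
    eps_ij = np.sqrt(np.outer(system.eps, system.eps))
    rmin_ij = system.rmin_half[:, None] + system.rmin_half[None, :]
    qq = np.outer(system.charge, system.charge)
    sr6 = np.where(mask, (rmin_ij / dist) ** 6, 0.0)
    # dE/dr for LJ and Coulomb; force on i along diff[i, j] = r_i - r_j
    dE_dr = np.where(
        mask,
        eps_ij * 12.0 * (-(sr6**2) + sr6) / dist
        - COULOMB_K * qq / (params.eps_in * dist**2),
        0.0,
    )
    grad = ((dE_dr / dist)[:, :, None] * diff).sum(axis=1)
    for i, j, r0 in system.bonds:
        d = coords[i] - coords[j]
        r = float(np.linalg.norm(d))
        f = 2.0 * BOND_FORCE_CONSTANT * (r - r0) / r
        grad[i] += f * d
        grad[j] -= f * d
    return grad


def steepest_descent(
    system: _System,
    coords: np.ndarray,
    params: EnergyModelParams,
    move_mask: np.ndarray,
    max_steps: int = 1000,
    gtol: float = 0.01,
    step0: float = 1e-3,
):
    """Adaptive-step steepest descent on the gas-phase MM energy.

    Only atoms in ``move_mask`` move; stops at ``max_steps`` or when the
    largest gradient component on the moving atoms drops below ``gtol``
    kcal/(mol Å).
    """
    coords = coords.copy()
    step = step0

    def energy(c):
        e_bond, e_vdw, e_elec = _mm_terms(system, c, params)
        return e_bond + e_vdw + e_elec

    e = energy(coords)
    for _ in range(max_steps):
        grad = _mm_gradient(system, coords, params)
        grad[~move_mask] = 0.0
        gmax = np.abs(grad).max()
        if gmax < gtol:
            break
        trial = coords - step * grad
        e_trial = energy(trial)
        if e_trial < e:
            coords, e = trial, e_trial
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return coords


def minimize_structure(
    structure: Structure, params: EnergyModelParams | None = None, gtol: float = 1e-6
) -> Structure:
    """Full minimization of the gas-phase MM energy (for normal-mode prep)."""
    from scipy.optimize import minimize

    params = params or EnergyModelParams()
    system = _System(structure, params, "complex")

    def fun(x):
        c = x.reshape(-1, 3)
        e_bond, e_vdw, e_elec = _mm_terms(system, c, params)
        return e_bond + e_vdw + e_elec

    def jac(x):
        return _mm_gradient(system, x.reshape(-1, 3), params).ravel()

    res = minimize(fun, system.coords.ravel(), jac=jac, method="L-BFGS-B",
                   options={"maxiter": 2000, "gtol": gtol})
    out = structure.copy()
    out.set_coords(res.x.reshape(-1, 3))
    return out


# ---------------------------------------------------------------------------
# normal modes and entropy


def _radial_hessian_block(d: np.ndarray, r: float, d1: float, d2: float):
    """Hessian block of a radial pair potential: d1 = phi'(r), d2 = phi''(r)."""
    u = d / r
    uu = np.outer(u, u)
    return d2 * uu + d1 / r * (np.eye(3) - uu)


def mm_hessian(system: _System, coords: np.ndarray, params: EnergyModelParams):
    """Analytic Hessian of E_bond + E_vdw + E_elec (3N x 3N)."""
    n = system.n_atoms
    h = np.zeros((3 * n, 3 * n))

    def add_pair(i, j, d1, d2):
        d = coords[i] - coords[j]
        r = float(np.linalg.norm(d))
        block = _radial_hessian_block(d, r, d1, d2)
        h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= block
        h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= block
        h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += block
        h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += block

    for i in range(n):
        for j in range(i + 1, n):
            if system.excluded[i, j]:
                continue
            d = coords[i] - coords[j]
            r = float(np.linalg.norm(d))
            eps = np.sqrt(system.eps[i] * system.eps[j])
            rmin = system.rmin_half[i] + system.rmin_half[j]
            sr6 = (rmin / r) ** 6
            d1 = eps * 12.0 * (-(sr6**2) + sr6) / r
            d2 = eps * 12.0 * (13.0 * sr6**2 - 7.0 * sr6) / r**2
            qq = system.charge[i] * system.charge[j]
            d1 += -COULOMB_K * qq / (params.eps_in * r**2)
            d2 += 2.0 * COULOMB_K * qq / (params.eps_in * r**3)
            add_pair(i, j, d1, d2)
    for i, j, r0 in system.bonds:
        d = coords[i] - coords[j]
        r = float(np.linalg.norm(d))
        d1 = 2.0 * BOND_FORCE_CONSTANT * (r - r0)
        d2 = 2.0 * BOND_FORCE_CONSTANT
        add_pair(i, j, d1, d2)
    return h


# unit conversion: (kcal/mol/Å²/amu) -> s^-2
_FREQ_SQ_SI = 4184.0 / (6.02214076e23 * 1e-20 * 1.66053907e-27)
_HBAR = 1.054571817e-34  # J s
_KB_J = 1.380649e-23  # J/K
_H_PLANCK = 6.62607015e-34
_ATM_PA = 101325.0
_AMU_KG = 1.66053907e-27


def entropy_terms(
    structure: Structure,
    params: EnergyModelParams | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> EntropyResult:
    """Rigid-rotor / harmonic-oscillator entropy of a minimized molecule.

    Translational and rotational entropies use the ideal-gas (1 atm) and
    classical rigid-rotor closed forms; the vibrational entropy sums
    quantum harmonic-oscillator contributions over the positive-frequency
    normal modes of the analytic mass-weighted MM Hessian.  More than 6
    near-zero Hessian eigenvalues indicate an unminimized structure and
    raise an error.  All entropies are in kcal/(mol K).
    """
    params = params or EnergyModelParams()
    system = _System(structure, params, "complex")
    n = system.n_atoms
    t = temperature

    # translational (Sackur-Tetrode at 1 atm)
    m_total = system.mass.sum() * _AMU_KG
    q_trans = (2.0 * np.pi * m_total * _KB_J * t / _H_PLANCK**2) ** 1.5 * (
        _KB_J * t / _ATM_PA
    )
    s_trans = KB_KCAL * (np.log(q_trans) + 2.5)

    # rotational (rigid rotor, sigma = 1)
    if n == 1:
        s_rot = 0.0
        s_vib = 0.0
        return EntropyResult(float(s_trans), s_rot, s_vib)
    com = (system.mass[:, None] * system.coords).sum(axis=0) / system.mass.sum()
    rel = system.coords - com
    inertia = np.zeros((3, 3))
    for k in range(n):
        r2 = rel[k] @ rel[k]
        inertia += system.mass[k] * (r2 * np.eye(3) - np.outer(rel[k], rel[k]))
    inertia *= _AMU_KG * 1e-20  # kg m²
    moments = np.sort(np.linalg.eigvalsh(inertia))
    linear = moments[0] < 1e-6 * moments[-1]
    rot_const = 8.0 * np.pi**2 * _KB_J * t / _H_PLANCK**2
    if linear:
        s_rot = KB_KCAL * (np.log(rot_const * moments[-1]) + 1.0)
        n_rigid = 5
    else:
        q_rot = np.sqrt(np.pi) * np.sqrt(rot_const**3 * np.prod(moments))
        s_rot = KB_KCAL * (np.log(q_rot) + 1.5)
        n_rigid = 6

    # vibrational
    h = mm_hessian(system, system.coords, params)
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(system.mass, 3))
    h_mw = h * np.outer(inv_sqrt_m, inv_sqrt_m)
    evals = np.linalg.eigvalsh(h_mw)
    scale = max(np.abs(evals).max(), 1.0)
    near_zero = int((np.abs(evals) < 1e-8 * scale).sum())
    negative = int((evals < -1e-8 * scale).sum())
    if near_zero + negative > 6:
        raise ValueError(
            f"{near_zero + negative} near-zero/negative Hessian eigenvalues "
            f"(expected <= {n_rigid}): structure is not minimized"
        )
    s_vib = 0.0
    for lam in evals:
        if lam <= 1e-8 * scale:
            continue
        omega = np.sqrt(lam * _FREQ_SQ_SI)  # s^-1 (angular)
        x = _HBAR * omega / (_KB_J * t)
        s_vib += KB_KCAL * (x / np.expm1(x) - np.log(-np.expm1(-x)))
    return EntropyResult(float(s_trans), float(s_rot), float(s_vib))


# ---------------------------------------------------------------------------
# MM-GBSA and alanine scanning


def _frame_deltas(
    complex_sys: _System,
    protein_sys: _System,
    ligand_sys: _System,
    coords: np.ndarray,
    protein_rows: np.ndarray,
    ligand_rows: np.ndarray,
    params: EnergyModelParams,
):
    """Per-frame (complex - protein - ligand) term differences."""
    dec_c = _decomposition(complex_sys, coords, params)
    dec_p = _decomposition(protein_sys, coords[protein_rows], params)
    dec_l = _decomposition(ligand_sys, coords[ligand_rows], params)
    return {
        "dE_vdw": dec_c.e_vdw - dec_p.e_vdw - dec_l.e_vdw,
        "dE_elec": dec_c.e_elec - dec_p.e_elec - dec_l.e_elec,
        "dG_np": dec_c.g_solv_np - dec_p.g_solv_np - dec_l.g_solv_np,
        "dG_gb": dec_c.g_solv_elec - dec_p.g_solv_elec - dec_l.g_solv_elec,
    }


def _selection_rows(structure: Structure):
    protein_rows, ligand_rows = [], []
    flat = 0
    for res in structure.residues:
        rows = range(flat, flat + len(res.atoms))
        (ligand_rows if res.is_ligand else protein_rows).extend(rows)
        flat += len(res.atoms)
    return np.array(protein_rows, dtype=int), np.array(ligand_rows, dtype=int)


def mmgbsa(
    ensemble: ConformationalEnsemble,
    params: EnergyModelParams | None = None,
    entropy: str = "none",
    entropy_subsample: int = 50,
) -> BindingFreeEnergy:
    """Single-trajectory MM-GBSA binding free energy over a holo ensemble.

    Per frame the intermolecular van der Waals/electrostatic and the
    GB/SA solvation differences of (complex - protein - ligand) are
    computed on identical coordinates; internal-energy differences of the
    isolated species are neglected (single-trajectory protocol).  With
    ``entropy="rigid+harmonic"`` the -TdS term comes from
    :func:`entropy_terms` on the minimized ensemble-average structures.
    """
    params = params or EnergyModelParams()
    topo = ensemble.topology
    if not topo.ligand_residues():
        raise ValueError("ensemble topology has no ligand residue")
    complex_sys = _System(topo, params, "complex")
    protein_sys = _System(topo, params, "protein")
    ligand_sys = _System(topo, params, "ligand")
    protein_rows, ligand_rows = _selection_rows(topo)

    records = []
    for f in range(ensemble.n_frames):
        records.append(
            _frame_deltas(
                complex_sys, protein_sys, ligand_sys, ensemble.frames[f],
                protein_rows, ligand_rows, params,
            )
        )
    per_frame = pd.DataFrame(records)
    per_frame["dG_frame"] = per_frame.sum(axis=1)

    dg_mm = float(per_frame["dE_vdw"].mean() + per_frame["dE_elec"].mean())
    dg_solv = float(per_frame["dG_np"].mean() + per_frame["dG_gb"].mean())

    t_ds = 0.0
    entropy_detail = None
    if entropy == "rigid+harmonic":
        n_sub = min(entropy_subsample, ensemble.n_frames)
        sub = np.linspace(0, ensemble.n_frames - 1, n_sub).astype(int)
        avg = topo.copy()
        avg.set_coords(ensemble.frames[sub].mean(axis=0))
        minimized = minimize_structure(avg, params)
        protein = Structure([r for r in minimized.copy().residues if not r.is_ligand])
        ligand = Structure([r for r in minimized.copy().residues if r.is_ligand])
        s_c = entropy_terms(minimized, params, params.temperature)
        s_p = entropy_terms(minimize_structure(protein, params), params, params.temperature)
        s_l = entropy_terms(minimize_structure(ligand, params), params, params.temperature)
        ds = s_c.total - s_p.total - s_l.total
        t_ds = params.temperature * ds
        entropy_detail = {
            "dS_trans": s_c.s_trans - s_p.s_trans - s_l.s_trans,
            "dS_rot": s_c.s_rot - s_p.s_rot - s_l.s_rot,
            "dS_vib": s_c.s_vib - s_p.s_vib - s_l.s_vib,
            "n_frames_entropy": int(n_sub),
        }
    elif entropy != "none":
        raise ValueError(f"unknown entropy mode {entropy!r}")

    dg_bind = dg_mm + dg_solv - t_ds
    return BindingFreeEnergy(
        dg_bind=dg_bind,
        dg_mm=dg_mm,
        dg_solv=dg_solv,
        t_ds=t_ds,
        entropy=entropy_detail,
        per_frame=per_frame,
        n_frames=ensemble.n_frames,
    )


def _truncate_to_alanine(structure: Structure, key: str) -> Structure:
    """Side-chain truncation beyond C-beta; the next atom becomes hydrogen.

    For multi-atom side chains the C-gamma atom is replaced by a hydrogen at
    1.09 Å along the C-beta -> C-gamma vector and atoms beyond are removed;
    for single-pseudo-atom side chains (toy CB2) the pseudo atom itself
    becomes the hydrogen at 1.09 Å from CA.
    """
    mut = structure.copy()
    res = mut.residue(key)
    backbone = [a for a in res.atoms if not a.is_sidechain]
    side = [a for a in res.atoms if a.is_sidechain]
    if not side:
        return mut
    ca = res.atom("CA")
    if res.has_atom("CB") and res.has_atom("CG"):
        cb = res.atom("CB")
        cg = res.atom("CG")
        u = cg.coords - cb.coords
        u = u / np.linalg.norm(u)
        hb = Atom(cg.serial, "HB", "H", cg.residue_index, cb.coords + 1.09 * u,
                  True, 1.20)
        keep = [a for a in side if a.name in ("CB", "HB1", "HB2", "HB3")]
        res.atoms = backbone + keep + [hb]
    else:
        anchor = side[0]
        u = anchor.coords - ca.coords
        u = u / np.linalg.norm(u)
        hb = Atom(anchor.serial, "HB", "H", anchor.residue_index,
                  ca.coords + 1.09 * u, True, 1.20)
        res.atoms = backbone + [hb]
    return Structure(mut.residues, mut.title)


def alanine_scan(
    ensemble: ConformationalEnsemble,
    residues: list[str],
    params: EnergyModelParams | None = None,
    max_steps: int = 1000,
    gtol: float = 0.01,
) -> AlanineScanResult:
    """Computational alanine scanning over a wild-type holo ensemble.

    For every frame the targeted side chain is truncated beyond C-beta, the
    introduced hydrogen is relaxed by steepest descent against the fixed
    remainder, and the per-frame binding decomposition is recomputed; the
    entropy term is omitted.  Glycine and proline are skipped (no side
    chain / backbone-coupled ring), alanine reports ddG = 0 exactly.
    """
    params = params or EnergyModelParams()
    topo = ensemble.topology
    if not topo.ligand_residues():
        raise ValueError("ensemble topology has no ligand residue")

    wt_complex = _System(topo, params, "complex")
    wt_protein = _System(topo, params, "protein")
    ligand_sys = _System(topo, params, "ligand")
    protein_rows, ligand_rows = _selection_rows(topo)

    wt_frames = [
        _frame_deltas(wt_complex, wt_protein, ligand_sys, ensemble.frames[f],
                      protein_rows, ligand_rows, params)
        for f in range(ensemble.n_frames)
    ]
    wt_mean = pd.DataFrame(wt_frames).mean()

    rows = []
    skipped: dict[str, str] = {}
    for key in residues:
        res = topo.residue(key)
        if res.is_ligand:
            skipped[key] = "ligand residue"
            continue
        if res.res_type == "GLY":
            skipped[key] = "glycine has no side chain to truncate"
            continue
        if res.res_type == "PRO":
            skipped[key] = "proline side chain is backbone-coupled"
            continue
        if res.res_type == "ALA":
            rows.append({"residue": key, "ddG": 0.0, "ddE_vdw": 0.0,
                         "ddE_elec": 0.0, "ddG_np": 0.0, "ddG_gb": 0.0})
            continue

        mut_topo = _truncate_to_alanine(topo, key)
        mut_complex = _System(mut_topo, params, "complex")
        mut_protein = _System(mut_topo, params, "protein")
        mut_p_rows, mut_l_rows = _selection_rows(mut_topo)
        move = np.array(
            [lbl == (key, "HB") for lbl in mut_complex.labels], dtype=bool
        )
        # map wild-type frame coordinates onto the mutated topology
        wt_labels = {lbl: k for k, lbl in enumerate(wt_complex.labels)}
        src = []
        for lbl in mut_complex.labels:
            src.append(wt_labels.get(lbl, -1))
        src = np.array(src)
        hb_row = int(np.nonzero(move)[0][0])

        mut_frames = []
        for f in range(ensemble.n_frames):
            frame = ensemble.frames[f]
            coords = np.empty((mut_complex.n_atoms, 3))
            coords[src >= 0] = frame[src[src >= 0]]
            # seed the hydrogen from the truncation geometry for this frame
            ca_row = wt_labels[(key, "CA")]
            if (key, "CB") in wt_labels and (key, "CG") in wt_labels:
                base = frame[wt_labels[(key, "CB")]]
                u = frame[wt_labels[(key, "CG")]] - base
            else:
                base = frame[ca_row]
                anchor = next(
                    k for k, lbl in enumerate(wt_complex.labels)
                    if lbl[0] == key and wt_complex.atoms[k].is_sidechain
                )
                u = frame[anchor] - base
            u = u / np.linalg.norm(u)
            coords[hb_row] = base + 1.09 * u
            coords = steepest_descent(
                mut_complex, coords, params, move, max_steps=max_steps, gtol=gtol
            )
            mut_frames.append(
                _frame_deltas(mut_complex, mut_protein, ligand_sys, coords,
                              mut_p_rows, mut_l_rows, params)
            )
        mut_mean = pd.DataFrame(mut_frames).mean()
        delta = mut_mean - wt_mean
        rows.append(
            {
                "residue": key,
                "ddG": float(delta.sum()),
                "ddE_vdw": float(delta["dE_vdw"]),
                "ddE_elec": float(delta["dE_elec"]),
                "ddG_np": float(delta["dG_np"]),
                "ddG_gb": float(delta["dG_gb"]),
            }
        )
    table = pd.DataFrame(rows).set_index("residue") if rows else pd.DataFrame(
        columns=["ddG", "ddE_vdw", "ddE_elec", "ddG_np", "ddG_gb"]
    )
    return AlanineScanResult(table=table, skipped=skipped)
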