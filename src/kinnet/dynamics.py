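"""Ensemble dynamics statistics.

Implements the trajectory-derived observables used to characterise
kinase-inhibitor complexes: rigid-body superposition, per-residue
crystallographic-style B-factors, essential-dynamics PCA with a mobility
profile over the three largest-variance ("lowest frequency") modes, the
residue cross-correlation matrix that weights the interaction network, and
anisotropic-network-model (ANM) normal modes used both as a comparison and
as the displacement basis for synthetic ensembles.

B-factors follow the standard conversion from mean-square fluctuations,

    B_i = (8 pi^2 / 3) * <|r_i - <r_i>|^2>,

and cross-correlations are

    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>),  C_ij in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from kinnet.structio import ConformationalEnsemble, CorrelationMatrix, Structure

BACKBONE_SELECTION = ("N", "CA", "C", "O")
PCA_BACKBONE_SELECTION = ("N", "CA", "CB", "C", "O")

BFACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


@dataclass
class DynamicsResult:
    """Modes, eigenvalues and per-residue profiles from PCA or ANM."""

    labels: list[str]
    modes: np.ndarray  # (n_dof, n_modes), orthonormal columns
    eigenvalues: np.ndarray  # variance (PCA, descending) or stiffness (ANM, ascending)
    mobility_profile: pd.Series | None = None
    per_residue_bfactor: pd.Series | None = None
    kind: str = "pca"


def _selection_indices(structure: Structure, selection: str):
    """Flat atom indices and their residue keys for a named atom selection."""
    if selection == "CA":
        wanted = ("CA",)
    elif selection == "backbone":
        wanted = BACKBONE_SELECTION
    elif selection == "backbone_heavy":
        wanted = PCA_BACKBONE_SELECTION
    elif selection == "all":
        wanted = None
    else:
        raise ValueError(f"unknown selection {selection!r}")
    indices: list[int] = []
    keys: list[str] = []
    flat = 0
    for res in structure.residues:
        for atom in res.atoms:
            if not res.is_ligand and (wanted is None or atom.name in wanted):
                indices.append(flat)
                keys.append(res.key)
            flat += 1
    return np.array(indices, dtype=int), keys


def superpose(
    ensemble: ConformationalEnsemble,
    reference: int | str = 0,
    selection: str = "CA",
) -> ConformationalEnsemble:
    """Least-squares rigid-body fit of every frame onto a reference.

    Each frame is translated and rotated (proper rotation, det = +1) to
    minimise the RMSD over the selected atoms.  ``reference`` is a frame
    index, or ``"mean"`` for a two-pass fit to the ensemble-average
    structure.
    """
    if ensemble.n_frames < 2:
        raise ValueError("superposition requires at least 2 frames")
    idx, _ = _selection_indices(ensemble.topology, selection)
    if len(idx) < 3:
        raise ValueError(f"selection {selection!r} yields fewer than 3 atoms")

    def _fit_all(frames: np.ndarray, ref_sel: np.ndarray) -> np.ndarray:
        ref_centered = ref_sel - ref_sel.mean(axis=0)
        out = np.empty_like(frames)
        for f in range(frames.shape[0]):
            sel = frames[f, idx]
            centroid = sel.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_centered, sel - centroid)
            out[f] = rot.apply(frames[f] - centroid) + ref_sel.mean(axis=0)
        return out

    frames = ensemble.frames
    if reference == "mean":
        aligned = _fit_all(frames, frames[0, idx])
        mean_sel = aligned[:, idx].mean(axis=0)
        aligned = _fit_all(aligned, mean_sel)
    else:
        aligned = _fit_all(frames, frames[int(reference), idx])
    return ConformationalEnsemble(
        topology=ensemble.topology, frames=aligned, frame_spacing=ensemble.frame_spacing
    )


def compute_bfactors(
    ensemble: ConformationalEnsemble, selection: str = "backbone"
) -> pd.Series:
    """Per-residue computed B-factor (Å²) from an aligned ensemble.

    The mean-square fluctuation is averaged over the selected atoms of each
    residue and converted with the 8π²/3 prefactor.
    """
    if ensemble.n_frames < 2:
        raise ValueError("B-factors require at least 2 frames")
    idx, keys = _selection_indices(ensemble.topology, selection)
    coords = ensemble.frames[:, idx, :]
    msf = ((coords - coords.mean(axis=0)) ** 2).sum(axis=2).mean(axis=0)
    msf[msf < 1e-15] = 0.0  # rounding residue of the mean on static atoms
    series = pd.Series(BFACTOR_PREFACTOR * msf, index=keys, name="bfactor")
    return series.groupby(level=0, sort=False).mean()


def cross_correlation(
    ensemble: ConformationalEnsemble, selection: str = "CA"
) -> CorrelationMatrix:
    """Normalized cross-correlation matrix of residue fluctuations.

    Residues with zero positional variance cannot be normalized; their
    off-diagonal entries are defined as 0 and a warning is emitted.
    """
    if ensemble.n_frames < 2:
        raise ValueError("cross-correlation requires at least 2 frames")
    idx, keys = _selection_indices(ensemble.topology, selection)
    if len(set(keys)) != len(keys):
        raise ValueError(f"selection {selection!r} is not one atom per residue")
    disp = ensemble.frames[:, idx, :]
    disp = disp - disp.mean(axis=0)
    # covariance of the 3-vector fluctuations: <dr_i . dr_j>
    cov = np.einsum("fix,fjx->ij", disp, disp) / ensemble.n_frames
    var = np.diag(cov).copy()
    # a residue is effectively static when its variance is at floating-point
    # noise level, absolutely or relative to the most mobile residue
    zero = (var <= 1e-18) | (var <= 1e-10 * var.max())
    if zero.any():
        warnings.warn(
            f"zero-variance residues set to C_ij = 0: "
            f"{[k for k, z in zip(keys, zero) if z]}"
        )
        var[zero] = 1.0
    corr = cov / np.sqrt(np.outer(var, var))
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    return CorrelationMatrix(labels=list(keys), values=corr)


def pca(
    ensemble: ConformationalEnsemble,
    selection: str = "CA",
    n_modes: int | None = None,
) -> DynamicsResult:
    """Essential-dynamics PCA of an aligned ensemble.

    Eigen-decomposition of the Cartesian coordinate covariance over the
    selected atoms.  Eigenvalues are returned in decreasing order of
    variance; the largest-variance principal components are the slow
    collective ("lowest frequency") motions.  The mobility profile is the
    RMS displacement magnitude of each residue's selected atoms over the
    three largest-variance modes.
    """
    idx, keys = _selection_indices(ensemble.topology, selection)
    n_dof = 3 * len(idx)
    if n_modes is None:
        n_modes = min(n_dof, ensemble.n_frames - 1)
    if ensemble.n_frames <= n_modes:
        raise ValueError("PCA requires more frames than requested modes")
    x = ensemble.frames[:, idx, :].reshape(ensemble.n_frames, n_dof)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / ensemble.n_frames
    if np.allclose(cov, 0.0):
        raise ValueError("degenerate ensemble: zero total variance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    n_top = min(3, n_modes)
    per_atom = np.zeros(len(idx))
    for m in range(n_top):
        comp = evecs[:, m].reshape(len(idx), 3)
        per_atom += evals[m] * (comp**2).sum(axis=1)
    profile = pd.Series(per_atom, index=keys, name="mobility")
    profile = np.sqrt(profile.groupby(level=0, sort=False).mean())

    unique_keys = list(dict.fromkeys(keys))
    return DynamicsResult(
        labels=unique_keys,
        modes=evecs[:, :n_modes],
        eigenvalues=evals[:n_modes],
        mobility_profile=profile,
        kind="pca",
    )


def anm_modes(
    structure: Structure, cutoff: float = 15.0, gamma: float = 1.0
) -> DynamicsResult:
    """Anisotropic network model normal modes from CA contact topology.

    Builds the standard 3N×3N ANM Hessian with a uniform spring constant
    ``gamma`` between CA atoms within ``cutoff`` Å and diagonalizes it.  A
    connected structure has exactly 6 zero-frequency (rigid-body) modes;
    eigenvalues are returned in ascending order of stiffness.
    """
    coords = []
    labels = []
    for res in structure.protein_residues():
        coords.append(res.atom("CA").coords)
        labels.append(res.key)
    coords = np.asarray(coords)
    n = len(coords)
    if n < 2:
        raise ValueError("ANM requires at least 2 CA atoms")

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)

    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from(zip(*np.nonzero(np.triu(contact))))
    if not nx.is_connected(graph):
        comps = [sorted(labels[i] for i in c) for c in nx.connected_components(graph)]
        raise ValueError(
            f"CA network disconnected at cutoff {cutoff} Å: "
            f"{len(comps)} components {comps}"
        )

    hessian = np.zeros((3 * n, 3 * n))
    for i, j in zip(*np.nonzero(np.triu(contact))):
        d = diff[i, j]
        block = -gamma * np.outer(d, d) / (d @ d)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block

    evals, evecs = np.linalg.eigh(hessian)
    near_zero = int(np.sum(np.abs(evals) < 1e-8 * max(np.abs(evals).max(), 1.0)))
    if near_zero != 6:
        warnings.warn(
            f"expected 6 rigid-body modes, found {near_zero} near-zero eigenvalues"
        )

    # mobility from the 3 softest internal modes, amplitude ~ 1/eigenvalue
    soft = range(near_zero, min(near_zero + 3, 3 * n))
    per_res = np.zeros(n)
    for m in soft:
        comp = evecs[:, m].reshape(n, 3)
        per_res += (comp**2).sum(axis=1) / evals[m]
    profile = pd.Series(np.sqrt(per_res), index=labels, name="mobility")

    return DynamicsResult(
        labels=labels,
        modes=evecs,
        eigenvalues=evals,
        mobility_profile=profile,
        kind="anm",
    )


def anm_hessian(structure: Structure, cutoff: float = 15.0, gamma: float = 1.0):
    """The raw ANM Hessian (for oracle tests and inspection)."""
    result = anm_modes(structure, cutoff=cutoff, gamma=gamma)
    return result.modes @ np.diag(result.eigenvalues) @ result.modes.T
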