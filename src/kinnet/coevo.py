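"""Mutual-information coevolution analysis of multiple sequence alignments.

Scores per column pair and per column:

* ``mi_matrix`` — plug-in mutual information between columns, in nats,
  MI(i,j) = sum_ab P(a_i, b_j) ln[P(a_i, b_j) / (P(a_i) P(b_j))], with
  optional sequence weights; pairs with a gap in either column are dropped
  from the joint counts (gap-as-symbol available as a flag).
* ``mi_zscore`` — permutation z-scores: the null shuffles each column's
  residues within its non-gap positions, preserving composition and gap
  mask; the 6.5 significance threshold is applied on this z scale, since
  raw plug-in MI over a 20-letter alphabet is bounded by ln 20 ≈ 3.0.
* ``kl_conservation`` — per-column Kullback-Leibler conservation,
  KL_i = sum_a P(a_i) ln[P(a_i)/Q(a)] against background frequencies Q
  (a literal unweighted form, sum_a ln[P(a_i)/Q(a)], is available).
* ``cmi`` — per-column sum of supra-threshold MI values.
* ``pmi`` — structure-mapped average of cMI over residues within 5 Å
  (minimal heavy-atom distance).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from kinnet.structio import Structure

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
N_AA = 20

# database-wide amino-acid background frequencies (UniProtKB-style averages)
DEFAULT_BACKGROUND = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

MI_Z_THRESHOLD = 6.5
PMI_DISTANCE = 5.0
IDENTITY_CLUSTER = 0.62

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class BackgroundFrequencies:
    """Strictly positive amino-acid background distribution Q."""

    values: np.ndarray  # ordered as AMINO_ACIDS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_AA,):
            raise ValueError("background must be a 20-vector")
        if np.any(self.values <= 0) or abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("background must be strictly positive and normalized")

    @classmethod
    def uniform(cls) -> "BackgroundFrequencies":
        return cls(np.full(N_AA, 1.0 / N_AA))

    @classmethod
    def database(cls) -> "BackgroundFrequencies":
        v = np.array([DEFAULT_BACKGROUND[a] for a in AMINO_ACIDS])
        return cls(v / v.sum())


@dataclass
class MSA:
    """Uniform-length alignment over the 20 amino acids plus gap."""

    sequences: list[str]
    ids: list[str]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.ids):
            raise ValueError("sequences and ids differ in length")
        if not self.sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            ragged = [
                self.ids[k]
                for k, s in enumerate(self.sequences)
                if len(s) != len(self.sequences[0])
            ]
            raise ValueError(f"ragged alignment; offending records: {ragged}")
        self.sequences = [
            s.upper().replace(".", GAP).replace("*", GAP) for s in self.sequences
        ]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def reference_sequence(self) -> str:
        if self.reference_id is None:
            raise ValueError("no reference sequence set")
        return self.sequences[self.ids.index(self.reference_id)]

    def encoded(self) -> np.ndarray:
        """Integer matrix: 0..19 amino acids in AMINO_ACIDS order, 20 = gap."""
        out = np.full((self.n_sequences, self.n_columns), N_AA, dtype=np.int64)
        for r, seq in enumerate(self.sequences):
            for c, ch in enumerate(seq):
                out[r, c] = _AA_INDEX.get(ch, N_AA)
        return out


def read_msa(path, fmt: str | None = None) -> MSA:
    """Read a FASTA or Stockholm alignment (format inferred from extension)."""
    from Bio import AlignIO

    if fmt is None:
        fmt = "stockholm" if str(path).endswith((".sto", ".stk", ".stockholm")) else "fasta"
    try:
        alignment = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    sequences = [str(rec.seq) for rec in alignment]
    ids = [rec.id for rec in alignment]
    return MSA(sequences=sequences, ids=ids, reference_id=ids[0] if ids else None)


def write_msa(msa: MSA, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for seq_id, seq in zip(msa.ids, msa.sequences):
            fh.write(f">{seq_id}\n{seq}\n")


def sequence_weights(msa: MSA, identity: float = IDENTITY_CLUSTER) -> np.ndarray:
    """Redundancy weights: 1 / cluster size under single-linkage clustering.

    Sequences at or above the pairwise identity threshold (fraction of
    matching positions over columns where neither is a gap) are linked into
    one cluster; each member receives 1/|cluster|, so weights sum to the
    number of clusters.
    """
    if msa.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    enc = msa.encoded()
    n = msa.n_sequences
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] != N_AA) & (enc[j] != N_AA)
            denom = both.sum()
            ident = ((enc[i] == enc[j]) & both).sum() / denom if denom else 0.0
            if ident >= identity:
                parent[find(i)] = find(j)

    roots = [find(i) for i in range(n)]
    sizes: dict[int, int] = {}
    for r in roots:
        sizes[r] = sizes.get(r, 0) + 1
    return np.array([1.0 / sizes[r] for r in roots])


def _pair_mi(enc: np.ndarray, weights: np.ndarray, i: int, j: int, gap_as_symbol: bool):
    """Weighted plug-in MI of one column pair (marginals on the same subset)."""
    a, b = enc[:, i], enc[:, j]
    if gap_as_symbol:
        mask = np.ones(len(a), dtype=bool)
        n_sym = N_AA + 1
    else:
        mask = (a != N_AA) & (b != N_AA)
        n_sym = N_AA
    if not mask.any():
        return 0.0
    w = weights[mask]
    joint = np.bincount(
        a[mask] * (N_AA + 1) + b[mask], weights=w, minlength=(N_AA + 1) ** 2
    ).reshape(N_AA + 1, N_AA + 1)[:n_sym, :n_sym]
    total = joint.sum()
    if total <= 0:
        return 0.0
    p = joint / total
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / np.outer(pa, pb)[nz])).sum())


def mi_matrix(
    msa: MSA,
    weights: np.ndarray | None = None,
    gap_as_symbol: bool = False,
) -> pd.DataFrame:
    """Symmetric plug-in mutual information matrix (nats) over columns.

    The diagonal is 0 by convention (MI(i,i) is not defined here).  A
    column consisting entirely of gaps is an error.
    """
    if msa.n_columns < 2:
        raise ValueError("need at least 2 columns")
    enc = msa.encoded()
    if weights is None:
        weights = np.ones(msa.n_sequences)
    weights = np.asarray(weights, dtype=float)
    all_gap = [c for c in range(msa.n_columns) if (enc[:, c] == N_AA).all()]
    if all_gap:
        raise ValueError(f"columns entirely gaps: {all_gap}")
    m = msa.n_columns
    mi = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            mi[i, j] = mi[j, i] = _pair_mi(enc, weights, i, j, gap_as_symbol)
    cols = list(range(m))
    return pd.DataFrame(np.maximum(mi, 0.0), index=cols, columns=cols)


def column_entropy(msa: MSA, weights: np.ndarray | None = None) -> pd.Series:
    """Shannon entropy (nats) per column over non-gap residues."""
    enc = msa.encoded()
    if weights is None:
        weights = np.ones(msa.n_sequences)
    out = np.zeros(msa.n_columns)
    for c in range(msa.n_columns):
        mask = enc[:, c] != N_AA
        counts = np.bincount(enc[mask, c], weights=weights[mask], minlength=N_AA)
        p = counts / counts.sum()
        nz = p > 0
        out[c] = float(-(p[nz] * np.log(p[nz])).sum())
    return pd.Series(out, index=range(msa.n_columns), name="entropy")


def mi_zscore(
    mi: pd.DataFrame,
    msa: MSA,
    n_permutations: int = 200,
    seed: int = 0,
    weights: np.ndarray | None = None,
    gap_as_symbol: bool = False,
    pooled: bool = True,
) -> pd.DataFrame:
    """Permutation z-scores of the MI matrix.

    The null model independently shuffles each column's residues among its
    non-gap positions (composition and gap mask preserved).  By default the
    null mean and standard deviation are pooled over all pairs and
    permutations, which stabilizes the variance estimate at moderate
    permutation counts; ``pooled=False`` uses per-pair null statistics.
    """
    if n_permutations < 20:
        raise ValueError("need at least 20 permutations")
    rng = np.random.default_rng(seed)
    enc = msa.encoded()
    if weights is None:
        weights = np.ones(msa.n_sequences)
    m = msa.n_columns
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    null = np.empty((n_permutations, len(pairs)))
    shuffled = enc.copy()
    for p in range(n_permutations):
        for c in range(m):
            rows = np.nonzero(enc[:, c] != N_AA)[0]
            shuffled[rows, c] = enc[rng.permutation(rows), c]
        for k, (i, j) in enumerate(pairs):
            null[p, k] = _pair_mi(shuffled, weights, i, j, gap_as_symbol)

    z = np.zeros((m, m))
    if pooled:
        mean, sd = null.mean(), null.std(ddof=1)
        if sd == 0:
            raise ValueError("zero null variance; z-scores undefined")
        for k, (i, j) in enumerate(pairs):
            z[i, j] = z[j, i] = (mi.values[i, j] - mean) / sd
    else:
        for k, (i, j) in enumerate(pairs):
            sd = null[:, k].std(ddof=1)
            if sd == 0:
                warnings.warn(f"zero null variance for pair ({i}, {j}); z set to nan")
                z[i, j] = z[j, i] = np.nan
                continue
            z[i, j] = z[j, i] = (mi.values[i, j] - null[:, k].mean()) / sd
    return pd.DataFrame(z, index=mi.index, columns=mi.columns)


def kl_conservation(
    msa: MSA,
    weights: np.ndarray | None = None,
    background: BackgroundFrequencies | None = None,
    literal: bool = False,
) -> pd.Series:
    """Per-column KL conservation score (nats) against the background.

    Default is the standard probability-weighted divergence
    sum_a P(a) ln[P(a)/Q(a)] over the observed (non-gap, renormalized)
    column distribution; ``literal=True`` computes the unweighted sum
    sum_a ln[P(a)/Q(a)] over observed residues instead.
    """
    if background is None:
        background = BackgroundFrequencies.database()
    enc = msa.encoded()
    if weights is None:
        weights = np.ones(msa.n_sequences)
    out = np.zeros(msa.n_columns)
    for c in range(msa.n_columns):
        mask = enc[:, c] != N_AA
        if not mask.any():
            raise ValueError(f"column {c} is entirely gaps")
        counts = np.bincount(enc[mask, c], weights=weights[mask], minlength=N_AA)
        p = counts / counts.sum()
        nz = p > 0
        ratio = np.log(p[nz] / background.values[nz])
        out[c] = float((p[nz] * ratio).sum() if not literal else ratio.sum())
    return pd.Series(np.where(np.abs(out) < 1e-15, 0.0, out), name="kl")


def cmi(
    score_matrix: pd.DataFrame,
    t: float = MI_Z_THRESHOLD,
    mi: pd.DataFrame | None = None,
) -> pd.Series:
    """Cumulative MI per column: sum of MI over pairs scoring above t.

    ``score_matrix`` supplies the thresholded score (typically the z-score
    matrix); ``mi`` supplies the MI values that are summed (defaults to the
    score matrix itself, for raw-scale thresholding).
    """
    values = mi if mi is not None else score_matrix
    mask = (score_matrix.values > t) & ~np.eye(len(score_matrix), dtype=bool)
    out = np.where(mask, values.values, 0.0).sum(axis=1)
    return pd.Series(out, index=score_matrix.index, name="cmi")


def map_msa_to_structure(
    msa: MSA,
    structure: Structure,
    reference_id: str | None = None,
    min_identity: float = 0.9,
):
    """Map non-gap reference columns onto structure residues, in order.

    Returns ``(mapping, mismatches)`` where mapping is {column -> residue
    key}.  The reference row's ungapped length must equal the number of
    protein residues, and at least ``min_identity`` of the mapped positions
    must agree between the reference row and the structure sequence;
    disagreeing positions are reported.
    """
    ref_id = reference_id or msa.reference_id
    if ref_id is None:
        raise ValueError("no reference sequence id")
    ref_row = msa.sequences[msa.ids.index(ref_id)]
    residues = structure.protein_residues()
    columns = [c for c, ch in enumerate(ref_row) if ch != GAP]
    if len(columns) != len(residues):
        raise ValueError(
            f"reference row has {len(columns)} non-gap columns but the "
            f"structure has {len(residues)} residues"
        )
    mismatches = []
    mapping = {}
    for col, res in zip(columns, residues):
        mapping[col] = res.key
        if ref_row[col] != res.one_letter:
            mismatches.append((col, ref_row[col], res.key, res.one_letter))
    identity = 1.0 - len(mismatches) / max(len(columns), 1)
    if identity < min_identity:
        raise ValueError(
            f"reference/structure identity {identity:.2%} below "
            f"{min_identity:.0%}; mismatches: {mismatches}"
        )
    return mapping, mismatches


def residue_min_distances(structure: Structure) -> pd.DataFrame:
    """Minimal heavy-atom distance between every protein residue pair."""
    residues = structure.protein_residues()
    keys = [r.key for r in residues]
    coords = [np.array([a.coords for a in r.heavy_atoms()]) for r in residues]
    n = len(residues)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = cdist(coords[i], coords[j]).min()
    return pd.DataFrame(out, index=keys, columns=keys)


def pmi(
    cmi_scores: pd.Series,
    structure: Structure,
    mapping: dict[int, str],
    distance: float = PMI_DISTANCE,
) -> pd.Series:
    """Proximity MI: mean cMI of the residues within ``distance`` Å.

    Structural proximity is the minimal heavy-atom distance between two
    residues.  Residues with no neighbor inside the threshold get NaN and
    are reported in a warning.
    """
    dmat = residue_min_distances(structure)
    key_to_col = {key: col for col, key in mapping.items()}
    keys = [k for k in dmat.index if k in key_to_col]
    out = {}
    isolated = []
    for key in keys:
        neighbors = [
            other
            for other in keys
            if other != key and dmat.loc[key, other] <= distance
        ]
        if not neighbors:
            isolated.append(key)
            out[key] = np.nan
            continue
        out[key] = float(
            np.mean([cmi_scores[key_to_col[other]] for other in neighbors])
        )
    if isolated:
        warnings.warn(f"residues with no structural neighbors within {distance} Å: {isolated}")
    return pd.Series(out, name="pmi")


@dataclass
class CoevolutionScores:
    """Bundle of per-pair and per-column coevolution scores."""

    mi: pd.DataFrame
    mi_z: pd.DataFrame | None = None
    kl: pd.Series | None = None
    cmi: pd.Series | None = None
    pmi: pd.Series | None = None
    threshold: float = MI_Z_THRESHOLD
    extras: dict = field(default_factory=dict)


def export_circular(
    scores: CoevolutionScores,
    mapping: dict[int, str],
    msa: MSA,
    t: float | None = None,
    tsv_path=None,
    json_path=None,
):
    """Per-position ring records plus the supra-threshold edge list.

    This is the data behind a sequential circular MSA representation: one
    record per mapped column (position, reference residue, KL, cMI, pMI)
    and a symmetric-deduplicated list of column pairs whose score exceeds
    the threshold.
    """
    t = scores.threshold if t is None else t
    ref = msa.reference_sequence()
    ring = []
    for col in sorted(mapping):
        key = mapping[col]
        ring.append(
            {
                "position": col,
                "residue_key": key,
                "ref_residue": ref[col],
                "kl": float(scores.kl[col]) if scores.kl is not None else np.nan,
                "cmi": float(scores.cmi[col]) if scores.cmi is not None else np.nan,
                "pmi": float(scores.pmi.get(key, np.nan))
                if scores.pmi is not None
                else np.nan,
            }
        )
    score_matrix = scores.mi_z if scores.mi_z is not None else scores.mi
    edges = []
    cols = list(score_matrix.index)
    for a_idx, i in enumerate(cols):
        for j in cols[a_idx + 1 :]:
            if score_matrix.loc[i, j] > t:
                edges.append(
                    {"i": int(i), "j": int(j), "score": float(score_matrix.loc[i, j]),
                     "mi": float(scores.mi.loc[i, j])}
                )
    ring_df = pd.DataFrame(ring)
    if tsv_path is not None:
        ring_df.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g",
                       lineterminator="\n")
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump({"threshold": t, "edges": edges}, fh, indent=1)
    return ring_df, edges
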