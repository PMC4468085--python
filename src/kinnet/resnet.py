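"""Residue interaction networks and betweenness centrality.

The network nodes are residues (plus an optional ligand node).  Two
residues are connected when their interaction strength

    I_ij = n_ij / sqrt(N_i * N_j) * 100   [%]

exceeds a threshold I_min (default 3.0 %), where n_ij is the number of
side-chain heavy-atom pairs within 4.5 Å and N_i, N_j are residue-type
normalization factors (the largest total heavy-atom contact count observed
for that residue type).  Edges are weighted by the residue
cross-correlation matrix, w_ij = -log|C_ij|, so strongly coupled residues
are close in path length.  Betweenness centrality is computed from
all-pairs shortest paths (Floyd–Warshall) with path-multiplicity counting
and normalized per connected component by (N-1)(N-2)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from kinnet.structio import CorrelationMatrix, Structure
from kinnet.surface_contacts import CONTACT_CUTOFF, count_contacts

DEFAULT_I_MIN = 3.0
CORRELATION_CLAMP = 1e-6
TIE_TOLERANCE = 1e-9
LIGAND_NODE_PREFIX = "LIG"


@dataclass
class NormalizationTable:
    """Per-residue-type normalization factors N_i (strictly positive)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for res_type, value in self.values.items():
            if value <= 0:
                raise ValueError(f"N_{res_type} must be strictly positive")

    def get(self, res_type: str) -> float:
        if res_type not in self.values:
            raise KeyError(f"no normalization factor for residue type {res_type!r}")
        return self.values[res_type]


@dataclass
class CentralityProfile:
    """Normalized betweenness C_b in [0, 1] and component id per node."""

    centrality: pd.Series
    component: pd.Series

    def __post_init__(self) -> None:
        if ((self.centrality < -1e-12) | (self.centrality > 1 + 1e-12)).any():
            raise ValueError("betweenness must lie in [0, 1]")


def normalization_factors(
    structures,
    mode: str = "dataset",
    table: dict[str, float] | None = None,
    cutoff: float = CONTACT_CUTOFF,
) -> NormalizationTable:
    """Residue-type normalization factors N_i for the interaction strength.

    In ``dataset`` mode N_i is the maximum, over all residues of type i in
    the given structures, of the residue's total heavy-atom pair count
    (main chain and side chain) to all surrounding residues at the contact
    cutoff.  An explicit ``table`` entry always overrides the dataset value.
    """
    values: dict[str, float] = {}
    if mode == "dataset":
        if not structures:
            raise ValueError("dataset mode requires at least one structure")
        for structure in structures:
            residues = structure.protein_residues()
            coords = [np.array([a.coords for a in r.heavy_atoms()]) for r in residues]
            for i, res in enumerate(residues):
                total = 0
                for j, other in enumerate(residues):
                    if i == j:
                        continue
                    d = np.sqrt(
                        ((coords[i][:, None, :] - coords[j][None, :, :]) ** 2).sum(
                            axis=2
                        )
                    )
                    total += int((d <= cutoff).sum())
                values[res.res_type] = max(values.get(res.res_type, 0), total)
        values = {k: v for k, v in values.items() if v > 0}
    elif mode != "table":
        raise ValueError(f"unknown mode {mode!r}")
    if table:
        values.update(table)
    if not values:
        raise ValueError("no normalization factors available")
    return NormalizationTable(values)


def interaction_strength(
    n_ij: float, n_i: float, n_j: float, geometric: bool = True
) -> float:
    """Interaction strength I_ij in percent.

    The default normalizes the pair count by the geometric mean of the
    residue-type factors, I_ij = n_ij / sqrt(N_i N_j) * 100; setting
    ``geometric=False`` divides by the plain product instead (sensitivity
    variant).
    """
    if n_i <= 0 or n_j <= 0:
        raise ValueError("normalization factors must be positive")
    if n_ij < 0:
        raise ValueError("contact count must be non-negative")
    denom = np.sqrt(n_i * n_j) if geometric else n_i * n_j
    return float(n_ij / denom * 100.0)


def _edge_weight(c_ij: float, eps: float = CORRELATION_CLAMP) -> float:
    """w_ij = -log|C_ij| with |C| clamped into [eps, 1 - eps]."""
    return float(-np.log(np.clip(abs(c_ij), eps, 1.0 - eps)))


def build_graph(
    structure: Structure,
    correlation: CorrelationMatrix | None = None,
    norm: NormalizationTable | None = None,
    i_min: float = DEFAULT_I_MIN,
    include_ligand: str = "single-node",
    ligand_contacts: pd.Series | None = None,
    include_adjacent: bool = False,
    cutoff: float = CONTACT_CUTOFF,
    geometric: bool = True,
) -> nx.Graph:
    """Build the residue interaction network of a structure.

    Edges connect residue pairs with I_ij > i_min; sequence-adjacent pairs
    (|Δseq_id| <= 1 on the same chain) are excluded by default since their
    contact is covalent rather than an interaction.  Under correlation
    weighting w_ij = -log|C_ij| (clamped); without a correlation matrix all
    weights are 1.  With ``include_ligand="single-node"`` each ligand
    residue becomes one node with edges to every protein residue having at
    least one heavy-atom contact (count from ``ligand_contacts`` means if
    given, else from this structure), weighted by the median protein edge
    weight.  ``include_ligand="off"`` drops ligands.
    """
    if i_min < 0:
        raise ValueError("I_min must be non-negative")
    if norm is None:
        norm = normalization_factors([structure])
    residues = structure.protein_residues()
    graph = nx.Graph(i_min=i_min, weighting="correlation" if correlation else "uniform")

    corr_index = {}
    if correlation is not None:
        corr_index = {label: k for k, label in enumerate(correlation.labels)}
        missing = [r.key for r in residues if r.key not in corr_index]
        if missing:
            raise ValueError(f"correlation matrix lacks entries for {missing}")

    for res in residues:
        graph.add_node(res.key, res_type=res.res_type, ligand=False)

    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            res_a, res_b = residues[a], residues[b]
            if (
                not include_adjacent
                and res_a.chain == res_b.chain
                and abs(res_a.seq_id - res_b.seq_id) <= 1
            ):
                continue
            n_ab = count_contacts(res_a, res_b, cutoff=cutoff)
            if n_ab == 0:
                continue
            strength = interaction_strength(
                n_ab, norm.get(res_a.res_type), norm.get(res_b.res_type), geometric
            )
            if strength > i_min:
                if correlation is not None:
                    c = correlation.values[corr_index[res_a.key], corr_index[res_b.key]]
                    weight = _edge_weight(c)
                else:
                    weight = 1.0
                graph.add_edge(
                    res_a.key, res_b.key, strength=strength, weight=weight, n_ij=n_ab
                )

    if include_ligand != "off":
        protein_weights = [d["weight"] for _, _, d in graph.edges(data=True)]
        lig_weight = float(np.median(protein_weights)) if protein_weights else 1.0
        for ligand in structure.ligand_residues():
            node = f"{LIGAND_NODE_PREFIX}:{ligand.key}"
            graph.add_node(node, res_type=ligand.res_type, ligand=True)
            for res in residues:
                if ligand_contacts is not None:
                    mean_n = float(ligand_contacts.get(res.key, 0.0))
                else:
                    mean_n = count_contacts(res, ligand, cutoff=cutoff, atoms="heavy")
                if mean_n >= 1.0:
                    graph.add_edge(
                        res.key, node, strength=np.nan, weight=lig_weight, n_ij=mean_n
                    )
    return graph


# ---------------------------------------------------------------------------
# All-pairs shortest paths with multiplicity counting


def _tight(a: float, b: float, tol: float = TIE_TOLERANCE) -> bool:
    return a <= b + tol * max(1.0, abs(b))


def shortest_paths(graph: nx.Graph, tol: float = TIE_TOLERANCE):
    """All-pairs shortest-path distances and path multiplicities.

    Distances come from the Floyd–Warshall recursion; the number of
    co-optimal paths g_jk is counted over "tight" edges, where paths within
    a relative tolerance of the minimum count as shortest (floating-point
    weights).  Returns (nodes, distance matrix, path-count matrix);
    unreachable pairs have infinite distance and zero paths.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError(f"negative edge weight on ({u}, {v})")
        i, j = index[u], index[v]
        dist[i, j] = min(dist[i, j], w)
        dist[j, i] = dist[i, j]

    adj = dist.copy()  # direct edge weights before relaxation
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])

    # count shortest paths from every source over the tight-edge DAG
    sigma = np.zeros((n, n))
    edge_list = [(index[u], index[v]) for u, v in graph.edges]
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(dist[s])
        for v in order:
            if v == s or not np.isfinite(dist[s, v]):
                continue
            total = 0.0
            for u, w_ in edge_list:
                for a, b in ((u, w_), (w_, u)):
                    if b == v and np.isfinite(dist[s, a]):
                        if _tight(dist[s, a] + adj[a, b], dist[s, v], tol):
                            total += sigma[s, a]
            sigma[s, v] = total
    return nodes, dist, sigma


def betweenness(graph: nx.Graph, tol: float = TIE_TOLERANCE) -> CentralityProfile:
    """Normalized betweenness centrality per node.

    C_b(i) sums g_jk(i)/g_jk over unordered pairs j < k (j, k != i) in i's
    connected component and divides by (N-1)(N-2)/2 with N the component
    size.  Components of fewer than 3 nodes have C_b = 0.
    """
    nodes, dist, sigma = shortest_paths(graph, tol)
    index = {v: i for i, v in enumerate(nodes)}
    centrality = pd.Series(0.0, index=nodes, name="betweenness")
    component = pd.Series(-1, index=nodes, name="component", dtype=int)

    for comp_id, comp in enumerate(nx.connected_components(graph)):
        members = sorted(comp, key=index.get)
        idx = np.array([index[v] for v in members])
        component.loc[members] = comp_id
        n_comp = len(members)
        if n_comp < 3:
            continue
        norm = (n_comp - 1) * (n_comp - 2) / 2.0
        d = dist[np.ix_(idx, idx)]
        s = sigma[np.ix_(idx, idx)]
        for a, node in enumerate(members):
            through = d[:, a, None] + d[None, a, :]
            tight = through <= d * 1.0 + tol * np.maximum(1.0, np.abs(d))
            contrib = np.where(
                tight & (s > 0), s[:, a, None] * s[a, None, :] / np.where(s > 0, s, 1.0), 0.0
            )
            mask = np.triu(np.ones((n_comp, n_comp), dtype=bool), k=1)
            mask[a, :] = False
            mask[:, a] = False
            centrality[node] = float(contrib[mask].sum()) / norm
    centrality = centrality.clip(lower=0.0, upper=1.0)
    return CentralityProfile(centrality=centrality, component=component)


def delta_centrality(
    apo: CentralityProfile, holo: CentralityProfile
) -> pd.Series:
    """Ligand-induced change in centrality, ΔC_b = C_b(holo) - C_b(apo).

    Computed on the shared residue keys; ligand nodes are excluded from the
    report.
    """
    shared = [
        k
        for k in apo.centrality.index
        if k in holo.centrality.index and not str(k).startswith(LIGAND_NODE_PREFIX + ":")
    ]
    if not shared:
        raise ValueError("apo and holo profiles share no residue keys")
    delta = holo.centrality[shared] - apo.centrality[shared]
    delta.name = "delta_betweenness"
    return delta


def joint_profiles(
    centrality: CentralityProfile | pd.Series,
    bfactors: pd.Series,
    rsa: pd.Series,
) -> pd.DataFrame:
    """Per-residue table of centrality, B-factor and RSA for joint analysis.

    One row per residue key present in all three inputs; keys missing from
    any input are dropped with a warning.  No binning is applied.
    """
    cent = centrality.centrality if isinstance(centrality, CentralityProfile) else centrality
    cent = cent[[not str(k).startswith(LIGAND_NODE_PREFIX + ":") for k in cent.index]]
    shared = [k for k in cent.index if k in bfactors.index and k in rsa.index]
    dropped = [k for k in cent.index if k not in shared]
    if dropped:
        warnings.warn(f"residues missing from B-factor/RSA profiles: {dropped}")
    return pd.DataFrame(
        {
            "betweenness": cent[shared],
            "bfactor": bfactors[shared],
            "rsa": rsa[shared],
        }
    )


def export_graph(graph: nx.Graph, path, fmt: str = "tsv") -> None:
    """Write the network as GraphML or an edge-list TSV (i, j, I_ij, w_ij)."""
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return
    rows = [
        (u, v, d.get("strength", np.nan), d.get("weight", np.nan))
        for u, v, d in graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["i", "j", "I_ij", "w_ij"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
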