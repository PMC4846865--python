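"""Motional correlation matrices and dynamic community networks.

* DCCM — normalised covariance of Cα displacement vectors, entries in [−1, 1].
* LMI — linear (Gaussian-model) mutual information between the 3-D
  displacements of residue pairs, in nats:
  ``I_ij = ½(ln det Σ_i + ln det Σ_j − ln det Σ_ij)``.
* Community networks — edges kept where LMI ≥ a threshold and the mean
  inter-residue distance is below a cutoff scanned over a range, the cutoff
  chosen to minimise the number of communities (ties → larger cutoff),
  followed by Girvan–Newman clustering (iterative removal of the highest
  edge-betweenness edge, keeping the maximum-modularity partition).

Edges are unweighted for betweenness and modularity: the correlation values
gate which edges exist but do not weight them (a weighted mode is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from networkx.algorithms.community import modularity as nx_modularity

from .ensembles import Ensemble, EnsembleError, LoopDefinition, SelectionMask

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "CommunityPartition",
    "dccm",
    "lmi",
    "loop_pair_average",
    "build_network",
    "girvan_newman",
]


@dataclass
class CorrelationMatrix:
    """Symmetric residue-by-residue correlation matrix.

    ``kind`` is ``"dccm"`` (entries in [−1, 1], unit diagonal) or ``"lmi"``
    (entries ≥ 0 in nats, diagonal +inf and excluded from any filtering).
    Undefined entries (zero-variance residues) are NaN.  For LMI a companion
    matrix of ensemble-average inter-residue distances (Å) is carried for
    distance-gated network construction.
    """

    residues: list[tuple[str, int]]
    matrix: np.ndarray
    kind: str
    distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = self.matrix
        finite = np.isfinite(m)
        with np.errstate(invalid="ignore"):
            sym = np.where(finite & finite.T, np.abs(m - m.T), 0.0)
        if np.nanmax(sym) > 1e-9:
            raise EnsembleError("correlation matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{c}{r}" for c, r in self.residues]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


@dataclass
class CommunityPartition:
    """Residue-to-community assignment plus inter-community connectivity."""

    assignment: dict[tuple[str, int], int]
    sizes: list[int]
    edge_weights: dict[tuple[int, int], float]
    selected_cutoff: float | None = None

    @property
    def n_communities(self) -> int:
        return len(self.sizes)


def _displacements(ensemble: Ensemble, mask: SelectionMask) -> np.ndarray:
    sub = ensemble.coords[:, mask.indices, :]
    return sub - sub.mean(axis=0, keepdims=True)


def _mask_residues(mask: SelectionMask) -> list[tuple[str, int]]:
    return [(c, r) for c, r, _ in mask.references]


def dccm(ensemble: Ensemble, mask: SelectionMask) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)."""
    dev = _displacements(ensemble, mask)
    f, n, _ = dev.shape
    num = np.einsum("fia,fja->ij", dev, dev) / f
    var = np.diag(num).copy()
    zero = var <= 0
    if zero.any():
        logger.warning("%d zero-variance residues: DCCM entries set to NaN",
                       int(zero.sum()))
    denom = np.sqrt(np.where(zero, np.nan, var))
    mat = np.clip(num / np.outer(denom, denom), -1.0, 1.0)
    return CorrelationMatrix(_mask_residues(mask), mat, "dccm")


def lmi(ensemble: Ensemble, mask: SelectionMask) -> CorrelationMatrix:
    """Linear mutual information (nats) with companion mean-distance matrix.

    A singular marginal covariance makes the entry NaN (missing, logged); a
    singular joint covariance with regular marginals means perfect linear
    coupling and is reported as +inf.
    """
    dev = _displacements(ensemble, mask)
    f, n, _ = dev.shape
    flat = dev.reshape(f, 3 * n)
    cov = flat.T @ flat / f  # (3n, 3n)
    mat = np.full((n, n), np.inf)
    logdet = np.empty(n)
    singular_marginal = np.zeros(n, dtype=bool)
    for i in range(n):
        sign, ld = np.linalg.slogdet(cov[3 * i:3 * i + 3, 3 * i:3 * i + 3])
        singular_marginal[i] = sign <= 0
        logdet[i] = ld
    if singular_marginal.any():
        logger.warning("%d residues with singular displacement covariance: "
                       "LMI entries set to NaN", int(singular_marginal.sum()))
    for i in range(n):
        for j in range(i + 1, n):
            if singular_marginal[i] or singular_marginal[j]:
                mat[i, j] = mat[j, i] = np.nan
                continue
            rows = np.r_[3 * i:3 * i + 3, 3 * j:3 * j + 3]
            sign, ld = np.linalg.slogdet(cov[np.ix_(rows, rows)])
            if sign <= 0:
                value = np.inf  # perfectly coupled pair, flagged as +inf
            else:
                value = max(0.0, 0.5 * (logdet[i] + logdet[j] - ld))
            mat[i, j] = mat[j, i] = value
    # companion mean distances over frames
    sub = ensemble.coords[:, mask.indices, :]
    dist = np.zeros((n, n))
    batch = max(1, int(2e7 // max(1, n * n)))
    for s in range(0, f, batch):
        diff = sub[s:s + batch, :, None, :] - sub[s:s + batch, None, :, :]
        dist += np.linalg.norm(diff, axis=3).sum(axis=0)
    dist /= f
    return CorrelationMatrix(_mask_residues(mask), mat, "lmi", dist)


def loop_pair_average(matrix: CorrelationMatrix,
                      loops: list[LoopDefinition]) -> pd.DataFrame:
    """Unweighted mean correlation over all residue pairs of each loop pair.

    For a loop against itself only off-diagonal pairs enter the mean.
    """
    index = {res: k for k, res in enumerate(matrix.residues)}
    loop_idx = {}
    for loop in loops:
        try:
            loop_idx[loop.name] = np.array(
                [index[(loop.chain_id, int(r))] for r in loop.res_ids]
            )
        except KeyError as exc:
            raise EnsembleError(
                f"loop {loop.name}: residue {exc} not present in the matrix"
            ) from exc
    names = [l.name for l in loops]
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for a in loops:
        for b in loops:
            block = matrix.matrix[np.ix_(loop_idx[a.name], loop_idx[b.name])]
            if a.name == b.name:
                vals = block[~np.eye(len(block), dtype=bool)]
            else:
                vals = block.ravel()
            out.loc[a.name, b.name] = float(np.nanmean(vals))
    return out


# -- community networks --------------------------------------------------------

def _deterministic_most_valuable_edge(graph: nx.Graph) -> tuple:
    bet = nx.edge_betweenness_centrality(graph)
    return min(bet, key=lambda e: (-bet[e], tuple(sorted(e))))


def _components_partition(graph: nx.Graph) -> list[set]:
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: min(c))


def girvan_newman(graph: nx.Graph) -> CommunityPartition:
    """Girvan–Newman clustering, keeping the maximum-modularity partition.

    Edges are removed one at a time (highest edge betweenness; ties broken by
    lexicographic node-pair order), and every intermediate
    connected-component partition — including the initial one — is scored by
    Newman–Girvan modularity on the original graph.  Ties in modularity keep
    the earliest (coarsest) partition.  An edgeless graph yields singleton
    communities with a warning.
    """
    if graph.number_of_nodes() == 0:
        raise EnsembleError("cannot cluster an empty graph")
    if graph.number_of_edges() == 0:
        logger.warning("graph has no edges: every node is its own community")
        best = [{n} for n in sorted(graph.nodes)]
    else:
        work = graph.copy()
        best, best_q = None, -np.inf
        while True:
            part = _components_partition(work)
            q = nx_modularity(graph, part)
            if q > best_q + 1e-12:
                best, best_q = part, q
            if work.number_of_edges() == 0:
                break
            work.remove_edge(*_deterministic_most_valuable_edge(work))
    communities = sorted(best, key=lambda c: min(c))
    assignment = {node: k for k, comm in enumerate(communities) for node in comm}
    weights: dict[tuple[int, int], float] = {}
    for u, v, data in graph.edges(data=True):
        cu, cv = assignment[u], assignment[v]
        if cu != cv:
            key = (min(cu, cv), max(cu, cv))
            weights[key] = weights.get(key, 0.0) + data.get("weight", 1.0)
    return CommunityPartition(
        assignment, [len(c) for c in communities], weights
    )


def build_network(lmi_matrix: CorrelationMatrix,
                  lmi_min: float = 0.4,
                  distance_range: tuple[float, float] = (8.0, 10.0),
                  step: float = 0.5,
                  weighted: bool = False) -> tuple[nx.Graph, CommunityPartition]:
    """Distance-gated LMI network with automatic cutoff selection.

    For every candidate cutoff in ``distance_range`` (inclusive, fixed
    ``step``) a graph is built keeping residue pairs with LMI ≥ ``lmi_min``
    and mean distance ≤ cutoff; Girvan–Newman community detection is run and
    the cutoff minimising the community count is selected, ties resolved in
    favour of the larger cutoff.  With ``weighted=True`` edges carry the LMI
    value as weight for the inter-community connectivity report.
    """
    if lmi_matrix.kind != "lmi" or lmi_matrix.distances is None:
        raise EnsembleError("build_network needs an LMI matrix with distances")
    lo, hi = distance_range
    cutoffs = np.arange(lo, hi + step / 2, step)
    residues = lmi_matrix.residues
    n = len(residues)
    mat, dist = lmi_matrix.matrix, lmi_matrix.distances
    best = None  # (count, cutoff, graph, partition)
    for cutoff in cutoffs:
        g = nx.Graph()
        g.add_nodes_from(residues)
        for i in range(n):
            for j in range(i + 1, n):
                v = mat[i, j]
                if np.isnan(v) or v < lmi_min or dist[i, j] > cutoff:
                    continue
                g.add_edge(residues[i], residues[j],
                           weight=float(v) if weighted and np.isfinite(v) else 1.0)
        if g.number_of_edges() == 0:
            continue
        part = girvan_newman(g)
        if (best is None or part.n_communities < best[0]
                or (part.n_communities == best[0] and cutoff > best[1])):
            best = (part.n_communities, float(cutoff), g, part)
    if best is None:
        raise EnsembleError(
            f"no edges survive LMI ≥ {lmi_min} at any distance cutoff in "
            f"[{lo}, {hi}] Å"
        )
    _, cutoff, graph, part = best
    part.selected_cutoff = cutoff
    return graph, part
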