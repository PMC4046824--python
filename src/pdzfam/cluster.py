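"""Identity-graph construction and Markov clustering into specificity families.

Domains are nodes of a weighted graph whose edges are pairwise identities at
or above a cutoff (default 50%, the identity level above which PDZ domains
are expected to share binding specificity). The graph is partitioned with a
from-scratch Markov cluster (MCL) implementation: iterate expansion (matrix
squaring) and inflation (elementwise power, default 1.4, then column
renormalisation) of the column-stochastic transition matrix until it is
idempotent, then read clusters off the attractor rows. Families must have
at least two members; singletons and isolated nodes are left unclassified.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Family",
    "ClusteringResult",
    "MCLDiagnostics",
    "build_identity_graph",
    "mcl",
    "assign_families",
    "write_abc_graph",
    "read_abc_graph",
    "write_family_table",
]


@dataclass
class Family:
    """A cluster of domain ids (>= 2 members) with optional structure/MSA handles."""

    family_id: str
    members: frozenset[str]
    reference_structure: Optional[str] = None
    reference_alignment: Optional[str] = None

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if len(self.members) < 2:
            raise ValueError("a family needs at least 2 members")


@dataclass
class MCLDiagnostics:
    """Per-iteration bookkeeping from an MCL run.

    ``max_column_sum_error`` is the largest deviation of any column sum from
    1 observed immediately after an inflation step (stochasticity check);
    ``converged`` is False if the iteration hit ``max_iter`` first.
    """

    iterations: int = 0
    converged: bool = False
    max_column_sum_error: float = 0.0


@dataclass
class ClusteringResult:
    """Families plus the unclassified remainder; together a partition."""

    families: list[Family]
    unclassified: frozenset[str]
    diagnostics: Optional[MCLDiagnostics] = None

    def membership(self) -> dict[str, Optional[str]]:
        """domain id -> family id (None when unclassified)."""
        out: dict[str, Optional[str]] = {d: None for d in self.unclassified}
        for fam in self.families:
            for d in fam.members:
                out[d] = fam.family_id
        return out


def build_identity_graph(identity: pd.DataFrame, cutoff: float = 50.0) -> nx.Graph:
    """Threshold an identity matrix into an undirected weighted graph.

    An edge (a, b) is present iff identity(a, b) >= cutoff; pairs strictly
    below the cutoff are discarded. Edge weight is the identity percentage.
    No self-edges are stored.
    """
    if not 0.0 < cutoff <= 100.0:
        raise ValueError(f"cutoff must be in (0, 100], got {cutoff}")
    ids = list(identity.index)
    if list(identity.columns) != ids:
        raise ValueError("identity table rows and columns must agree")
    values = identity.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("identity table must be symmetric")
    if not np.allclose(np.diag(values), 100.0, atol=1e-8):
        raise ValueError("identity table diagonal must be 100")
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if values[i, j] >= cutoff:
                g.add_edge(ids[i], ids[j], weight=float(values[i, j]))
    return g


def _interpret_clusters(
    matrix: np.ndarray, nodes: Sequence[str], attractor_tol: float
) -> list[set[int]]:
    """Read clusters off the (near-)idempotent MCL matrix.

    Attractors are nodes with positive mass on their own diagonal. Each
    attractor row defines a cluster of the nodes it attracts; attractor
    systems sharing an attractor are merged. A non-attractor node attracted
    to several distinct clusters goes to the one holding the larger
    attraction mass (tie: the cluster with the lexicographically smallest
    member).
    """
    n = matrix.shape[0]
    attractors = [i for i in range(n) if matrix[i, i] > attractor_tol]
    # Merge attractor systems that overlap (share any attracted attractor).
    systems: list[set[int]] = []  # sets of attractor indices
    for a in attractors:
        linked = {a} | {
            b for b in attractors if matrix[a, b] > attractor_tol or matrix[b, a] > attractor_tol
        }
        merged = [s for s in systems if s & linked]
        for s in merged:
            systems.remove(s)
            linked |= s
        systems.append(linked)
    clusters: list[set[int]] = [set(s) for s in systems]
    # Attach non-attractor nodes by attraction mass toward each system.
    for j in range(n):
        if any(j in c for c in clusters):
            continue
        masses = []
        for ci, system in enumerate(systems):
            mass = float(sum(matrix[a, j] for a in system))
            masses.append((mass, ci))
        if not masses:
            continue
        best_mass = max(m for m, _ in masses)
        if best_mass <= attractor_tol:
            continue  # attracted nowhere: stays a singleton
        tied = [ci for m, ci in masses if m >= best_mass - 1e-12]
        if len(tied) > 1:
            tied.sort(key=lambda ci: min(nodes[i] for i in clusters[ci]))
        clusters[tied[0]].add(j)
    return clusters


def mcl(
    graph: nx.Graph,
    inflation: float = 1.4,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
    diagnostics: Optional[MCLDiagnostics] = None,
) -> ClusteringResult:
    """Partition an identity graph into families with Markov clustering.

    Canonical MCL: add self-loops (weight = the node's maximum incident edge
    weight, or 1 for isolated nodes), column-normalise to a stochastic
    matrix, then iterate expansion (matrix power ``expansion``) and
    inflation (elementwise power ``inflation`` followed by column
    renormalisation), pruning entries below ``prune_threshold``, until the
    matrix change falls below ``tol`` or ``max_iter`` is reached (the latter
    emits a warning and interprets the current matrix). Clusters of size 1
    and isolated nodes are reported as unclassified.
    """
    if inflation <= 1.0:
        raise ValueError(f"inflation must be > 1, got {inflation}")
    nodes: list[str] = sorted(graph.nodes())
    diag = diagnostics if diagnostics is not None else MCLDiagnostics()
    if not nodes:
        return ClusteringResult([], frozenset(), diag)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w
    # Self-loops stabilise the iteration; weight = max incident edge weight.
    for i in range(n):
        incident = m[i].max()
        m[i, i] = incident if incident > 0 else 1.0
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for iteration in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m /= m.sum(axis=0, keepdims=True)
        diag.max_column_sum_error = max(
            diag.max_column_sum_error, float(np.abs(m.sum(axis=0) - 1.0).max())
        )
        m[m < prune_threshold] = 0.0
        col = m.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0  # fully pruned column cannot occur, but guard
        m /= col
        diag.iterations = iteration
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    diag.converged = converged
    if not converged:
        warnings.warn(
            f"MCL did not converge in {max_iter} iterations; "
            "interpreting the current matrix",
            RuntimeWarning,
            stacklevel=2,
        )

    clusters = _interpret_clusters(m, nodes, attractor_tol=prune_threshold)
    families: list[Family] = []
    unclassified: set[str] = set(nodes)
    raw = sorted(
        ({nodes[i] for i in c} for c in clusters if len(c) >= 2),
        key=lambda members: (-len(members), min(members)),
    )
    for k, members in enumerate(raw, start=1):
        families.append(Family(family_id=f"F{k:03d}", members=frozenset(members)))
        unclassified -= members
    return ClusteringResult(families, frozenset(unclassified), diag)


def assign_families(
    result: ClusteringResult, domains: Optional[Iterable] = None
) -> pd.DataFrame:
    """Deterministic family table: one row per family.

    Families are ordered (and re-identified F001, F002, ...) by size
    descending then lexicographically smallest member; a final row per
    unclassified domain carries family_id "unclassified". Every input domain
    appears exactly once.
    """
    ordered = sorted(
        result.families, key=lambda f: (-len(f.members), min(f.members))
    )
    rows = []
    for k, fam in enumerate(ordered, start=1):
        rows.append(
            {
                "family_id": f"F{k:03d}",
                "size": len(fam.members),
                "members": ",".join(sorted(fam.members)),
            }
        )
    for d in sorted(result.unclassified):
        rows.append({"family_id": "unclassified", "size": 1, "members": d})
    return pd.DataFrame(rows, columns=["family_id", "size", "members"])


def write_abc_graph(graph: nx.Graph, path) -> None:
    """Write the graph in ABC edge-list format (node\\tnode\\tweight)."""
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):g}\n")


def read_abc_graph(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            a, b, w = line.split("\t")
            g.add_edge(a, b, weight=float(w))
    return g


def write_family_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
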