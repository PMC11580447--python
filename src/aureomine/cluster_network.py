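"""All-vs-all identity matrix, sequence-similarity network, and greedy
identity clustering for tree-representative selection.

The SSN keeps an edge between two peptides when their global-alignment
percent identity is *strictly greater* than the edge threshold (default
64.29), so a singleton is exactly a peptide with <= 64.29% identity to
every other peptide.  Connected components define peptide groups;
components are labeled in a stable order (size descending, then the
smallest member id).

Greedy clustering mirrors the CD-HIT procedure at desk scale without
its word-filter heuristics: sequences sorted by length descending (ties
by id), the longest unassigned sequence founds a cluster, and each
subsequent sequence joins the first representative it matches at or
above the identity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .align import DEFAULT_SCHEME, ScoringScheme, global_align, percent_identity
from .seqio import SeqRecord


class NetworkError(ValueError):
    pass


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix with an exact-100 diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise NetworkError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise NetworkError("identity matrix must be symmetric")
        if not (np.diag(self.values) == 100.0).all():
            raise NetworkError("identity matrix diagonal must be exactly 100")
        if (self.values < 0).any() or (self.values > 100).any():
            raise NetworkError("identities must lie in [0, 100]")

    def pid(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def identity_matrix(
    records: Sequence[SeqRecord], scheme: ScoringScheme = DEFAULT_SCHEME
) -> IdentityMatrix:
    """Percent identity for every unordered pair via global alignment."""
    if len(records) < 1:
        raise NetworkError("identity_matrix needs at least 1 record")
    n = len(records)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(global_align(records[i], records[j], scheme))
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(ids=[r.id for r in records], values=values)


@dataclass
class SSN:
    """Sequence-similarity network over peptide ids."""

    graph: nx.Graph
    edge_threshold_pct: float
    components: list[list[str]]
    singletons: list[str]

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_components_excluding_singletons(self) -> int:
        return sum(1 for c in self.components if len(c) > 1)


def build_ssn(
    matrix: IdentityMatrix,
    edge_threshold_pct: float = 64.29,
    phylum_by_id: Mapping[str, str] | None = None,
) -> SSN:
    """Threshold the identity matrix into a network.

    An edge is kept when pid > ``edge_threshold_pct`` (strictly), so
    nodes below the threshold to everything else have degree 0 and are
    singletons.  Components are sorted by size descending, then by the
    smallest member id; members within a component are sorted by id.
    """
    g = nx.Graph()
    for node_id in matrix.ids:
        attrs = {}
        if phylum_by_id is not None:
            attrs["phylum"] = phylum_by_id.get(node_id, "")
        g.add_node(node_id, **attrs)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            pid = float(matrix.values[i, j])
            if pid > edge_threshold_pct:
                g.add_edge(matrix.ids[i], matrix.ids[j], pid=pid)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    singletons = sorted(node for node in g.nodes if g.degree(node) == 0)
    return SSN(
        graph=g,
        edge_threshold_pct=edge_threshold_pct,
        components=comps,
        singletons=singletons,
    )


@dataclass(frozen=True)
class Cluster:
    representative: str
    members: tuple[str, ...]  # includes the representative


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float

    def representative_ids(self) -> list[str]:
        return [c.representative for c in self.clusters]

    def member_count(self) -> int:
        return sum(len(c.members) for c in self.clusters)


def greedy_cluster(
    records: Sequence[SeqRecord],
    threshold_fraction: float = 0.90,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> ClusterSet:
    """CD-HIT-style greedy incremental clustering on exact identities.

    Sequences are processed longest first (ties broken by id); each
    sequence joins the first existing representative it matches with
    pid/100 >= ``threshold_fraction``, else founds a new cluster.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise NetworkError("threshold_fraction must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[SeqRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        for k, rep in enumerate(reps):
            pid = percent_identity(global_align(rep, rec, scheme))
            if pid / 100.0 >= threshold_fraction:
                members[k].append(rec.id)
                break
        else:
            reps.append(rec)
            members.append([rec.id])
    clusters = [
        Cluster(representative=rep.id, members=tuple(m))
        for rep, m in zip(reps, members)
    ]
    return ClusterSet(clusters=clusters, threshold=threshold_fraction)


# ---------------------------------------------------------------------------
# Exports


def write_edge_list(ssn: SSN, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tpid\n")
        for a, b, data in sorted(ssn.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['pid']:.2f}\n")


def write_node_attributes(ssn: SSN, path: str | Path) -> None:
    component_of = {
        node: idx for idx, comp in enumerate(ssn.components) for node in comp
    }
    with open(path, "w") as fh:
        fh.write("id\tphylum\tcomponent\tsingleton\n")
        for node in sorted(ssn.graph.nodes):
            phylum = ssn.graph.nodes[node].get("phylum", "")
            single = "yes" if node in set(ssn.singletons) else "no"
            fh.write(f"{node}\t{phylum}\t{component_of[node]}\t{single}\n")


def write_clusters(clusters: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("representative\tmember\n")
        for cluster in clusters.clusters:
            for member in cluster.members:
                fh.write(f"{cluster.representative}\t{member}\n")
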