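"""Sequence similarity networks (SSNs) for paralog separation.

An SSN is a graph whose nodes are sequences — or meta-nodes collapsing
near-identical sequences (>= 70% identity by convention) — and whose
edges mark pairwise similarity above an alignment-score (AS) cutoff, AS
being on the -log10(E-value) scale. Non-isofunctional paralogous
subgroups inside a superfamily merge into one component at a permissive
cutoff; gradually raising the cutoff in small increments (typically 5 AS
units) strips the weaker between-subgroup edges until clusters become
annotation-homogeneous, separating the paralogs. Gene-neighborhood
signatures per cluster (e.g. a subgroup consistently colocalized with a
partner gene family) provide the orthogonal functional evidence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimilarityEdge",
    "SSN",
    "ClusterReport",
    "read_blast_tab",
    "write_blast_tab",
    "edges_from_sequences",
    "collapse_nodes",
    "build_network",
    "connected_components",
    "cluster_purity",
    "sweep_threshold",
    "neighborhood_signature",
    "read_neighborhood_table",
]

#: cap for AS derived from an E-value of exactly 0
AS_CAP = 200.0

BLAST_TAB_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected similarity between two sequences.

    ``pct_identity`` is a fraction in [0, 1]; ``as_score`` is on the
    -log10(E-value) scale, capped at :data:`AS_CAP`. Endpoints are stored
    sorted so (a, b) and (b, a) compare equal.
    """

    id_a: str
    id_b: str
    pct_identity: float
    as_score: float

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError(f"self-edge on {self.id_a!r}")
        if self.id_a > self.id_b:
            a, b = self.id_b, self.id_a
            object.__setattr__(self, "id_a", a)
            object.__setattr__(self, "id_b", b)
        if not 0.0 <= self.pct_identity <= 1.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 1]")
        if self.as_score < 0:
            raise ValueError(f"as_score {self.as_score} must be non-negative")


def read_blast_tab(path) -> list[SimilarityEdge]:
    """Read all-vs-all pairwise scores from BLAST tabular (outfmt 6) output.

    pident on the 0-100 scale is converted to a fraction; AS is
    min(-log10(evalue), 200) with evalue 0 mapped to 200. Reciprocal
    hits and self-hits collapse to one undirected edge keeping the best
    (maximum) AS and identity.
    """
    df = pd.read_csv(path, sep="\t", names=BLAST_TAB_COLUMNS, comment="#")
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for q, s, pident, evalue in zip(df.qseqid, df.sseqid, df.pident, df.evalue):
        q, s = str(q), str(s)
        if q == s:
            continue
        key = (q, s) if q < s else (s, q)
        as_score = AS_CAP if evalue <= 0 else min(-np.log10(evalue), AS_CAP)
        ident = pident / 100.0
        if key not in best:
            best[key] = (ident, as_score)
        else:
            pi, pa = best[key]
            best[key] = (max(pi, ident), max(pa, as_score))
    return [SimilarityEdge(a, b, pi, sc) for (a, b), (pi, sc) in sorted(best.items())]


def write_blast_tab(edges: Sequence[SimilarityEdge], path, length: int = 0) -> None:
    """Write edges as minimal BLAST tabular rows (round-trips through
    :func:`read_blast_tab`; E-value encodes the AS as 10**-AS)."""
    rows = []
    for e in sorted(edges, key=lambda e: (e.id_a, e.id_b)):
        rows.append(
            [
                e.id_a, e.id_b, f"{e.pct_identity * 100:.4f}", length, 0, 0,
                1, max(length, 1), 1, max(length, 1),
                f"{10.0 ** (-e.as_score):.6g}", f"{2 * e.as_score:.1f}",
            ]
        )
    pd.DataFrame(rows, columns=BLAST_TAB_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


def edges_from_sequences(sequences: Mapping[str, str]) -> list[SimilarityEdge]:
    """All-vs-all edges for equal-length, ungapped synthetic sequences.

    Identity is the fraction of matching columns; the AS surrogate is
    identity x length / 2, a monotone stand-in for -log10(E-value) on
    alignments of equal length. Real data should supply BLAST tabular
    scores instead.
    """
    ids = sorted(sequences)
    if not ids:
        return []
    lengths = {len(sequences[i]) for i in ids}
    if len(lengths) != 1:
        raise ValueError("edges_from_sequences requires equal-length sequences")
    (L,) = lengths
    arr = np.frombuffer("".join(sequences[i] for i in ids).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(ids), L)
    edges = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        ident = float(np.mean(arr[i] == arr[j]))
        edges.append(SimilarityEdge(ids[i], ids[j], ident, ident * L / 2.0))
    return edges


def collapse_nodes(
    edges: Sequence[SimilarityEdge], all_ids: Iterable[str], identity_cutoff: float = 0.7
) -> dict[str, frozenset[str]]:
    """Single-linkage collapse of near-identical sequences into meta-nodes.

    Sequences joined by any chain of pairwise identities >= cutoff share
    a meta-node; everything else is a singleton. Returns meta-node id
    (the lexicographically smallest member) -> member set.
    """
    if not 0.0 < identity_cutoff <= 1.0:
        raise ValueError("identity_cutoff must lie in (0, 1]")
    all_ids = set(all_ids)
    g = nx.Graph()
    g.add_nodes_from(all_ids)
    for e in edges:
        if e.id_a not in all_ids or e.id_b not in all_ids:
            raise ValueError(f"edge ({e.id_a}, {e.id_b}) references an unknown sequence id")
        if e.pct_identity >= identity_cutoff:
            g.add_edge(e.id_a, e.id_b)
    return {min(comp): frozenset(comp) for comp in nx.connected_components(g)}


@dataclass
class SSN:
    """Similarity network over meta-nodes at a given AS threshold."""

    meta_nodes: dict[str, frozenset[str]]
    graph: nx.Graph
    as_threshold: float

    @property
    def n_sequences(self) -> int:
        return sum(len(m) for m in self.meta_nodes.values())

    def members(self, meta_ids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for m in meta_ids:
            out |= self.meta_nodes[m]
        return out


def build_network(
    partition: Mapping[str, frozenset[str]],
    edges: Sequence[SimilarityEdge],
    as_threshold: float,
    aggregate: str = "max",
) -> SSN:
    """Build the meta-node SSN at one AS threshold.

    Cross-meta-node AS is aggregated over all member pairs (``max`` by
    default, ``mean`` optionally); an inter-node edge survives iff the
    aggregate is strictly greater than the threshold. Intra-meta-node
    edges are dropped.
    """
    if as_threshold < 0:
        raise ValueError("as_threshold must be >= 0")
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    member_of = {sid: mid for mid, members in partition.items() for sid in members}
    scores: dict[tuple[str, str], list[float]] = {}
    idents: dict[tuple[str, str], list[float]] = {}
    for e in edges:
        ma, mb = member_of[e.id_a], member_of[e.id_b]
        if ma == mb:
            continue
        key = (ma, mb) if ma < mb else (mb, ma)
        scores.setdefault(key, []).append(e.as_score)
        idents.setdefault(key, []).append(e.pct_identity)
    agg = max if aggregate == "max" else (lambda xs: sum(xs) / len(xs))
    g = nx.Graph()
    g.add_nodes_from(partition)
    for (ma, mb), vals in scores.items():
        a = agg(vals)
        if a > as_threshold:  # strict: "AS higher than" the cutoff
            g.add_edge(ma, mb, as_score=a, pct_identity=max(idents[(ma, mb)]))
    return SSN(meta_nodes=dict(partition), graph=g, as_threshold=as_threshold)


def connected_components(ssn: SSN) -> list[frozenset[str]]:
    """Clusters (sets of meta-node ids), largest first, ties by min member id."""
    comps = [frozenset(c) for c in nx.connected_components(ssn.graph)]
    return sorted(comps, key=lambda c: (-sum(len(ssn.meta_nodes[m]) for m in c), min(c)))


def cluster_purity(ssn: SSN, cluster: frozenset[str], labels: Mapping[str, str]) -> float:
    """Max label fraction over a cluster's member sequences."""
    members = ssn.members(cluster)
    missing = [m for m in members if m not in labels]
    if missing:
        raise ValueError(f"labels missing for sequences: {sorted(missing)[:5]}")
    counts: dict[str, int] = {}
    for m in members:
        counts[labels[m]] = counts.get(labels[m], 0) + 1
    return max(counts.values()) / len(members)


@dataclass
class ClusterReport:
    """Result of an AS threshold sweep."""

    chosen_threshold: float
    converged: bool
    clusters: list[frozenset[str]]
    purities: list[float]
    sizes: list[int]
    ssn: SSN
    history: list[dict] = field(default_factory=list)

    def cluster_labels(self, labels: Mapping[str, str]) -> list[set[str]]:
        return [
            {labels[m] for m in self.ssn.members(cluster)} for cluster in self.clusters
        ]


def sweep_threshold(
    partition: Mapping[str, frozenset[str]],
    edges: Sequence[SimilarityEdge],
    labels: Mapping[str, str],
    as_start: float = 0.0,
    step: float = 5.0,
    purity_target: float = 0.9,
    frac_clusters: float = 0.9,
    min_cluster_size: int = 5,
    aggregate: str = "max",
    max_steps: int = 1000,
) -> ClusterReport:
    """Raise the AS cutoff stepwise until clusters are annotation-homogeneous.

    Starting from ``as_start`` and increasing by ``step``, stop at the
    first threshold where at least ``frac_clusters`` of the clusters
    holding >= ``min_cluster_size`` sequences reach label purity >=
    ``purity_target`` (no such clusters counts as vacuously
    homogeneous). If the network runs out of edges first, the report
    carries the last threshold that still had edges and
    ``converged=False``.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if as_start < 0:
        raise ValueError("as_start must be >= 0")
    history: list[dict] = []
    last_with_edges: Optional[ClusterReport] = None
    for i in range(max_steps):
        t = as_start + i * step
        ssn = build_network(partition, edges, t, aggregate=aggregate)
        comps = connected_components(ssn)
        purities = [cluster_purity(ssn, c, labels) for c in comps]
        sizes = [sum(len(ssn.meta_nodes[m]) for m in c) for c in comps]
        big = [p for p, s in zip(purities, sizes) if s >= min_cluster_size]
        frac_pure = (sum(p >= purity_target for p in big) / len(big)) if big else 1.0
        history.append(
            {
                "threshold": t,
                "n_edges": ssn.graph.number_of_edges(),
                "n_clusters": len(comps),
                "frac_pure": frac_pure,
            }
        )
        report = ClusterReport(
            chosen_threshold=t,
            converged=True,
            clusters=comps,
            purities=purities,
            sizes=sizes,
            ssn=ssn,
            history=history,
        )
        if frac_pure >= frac_clusters:
            return report
        if ssn.graph.number_of_edges() > 0:
            report.converged = False
            last_with_edges = report
        else:
            break
    if last_with_edges is None:
        # no threshold had edges and none converged: report the start threshold
        ssn = build_network(partition, edges, as_start, aggregate=aggregate)
        comps = connected_components(ssn)
        return ClusterReport(
            chosen_threshold=as_start,
            converged=False,
            clusters=comps,
            purities=[cluster_purity(ssn, c, labels) for c in comps],
            sizes=[sum(len(ssn.meta_nodes[m]) for m in c) for c in comps],
            ssn=ssn,
            history=history,
        )
    return last_with_edges


def read_neighborhood_table(path) -> pd.DataFrame:
    """Read a gene-neighborhood TSV.

    Long format, one row per (sequence, neighbor slot): seq_id,
    genome_id, neighbor_family, offset. Offsets are signed 1-based gene
    ranks; negative = upstream.
    """
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "genome_id": str, "neighbor_family": str})
    required = {"seq_id", "genome_id", "neighbor_family", "offset"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"neighborhood table missing columns: {sorted(missing)}")
    return df


def neighborhood_signature(
    report: ClusterReport,
    context: pd.DataFrame,
    window: int = 5,
    dominant_fraction: float = 0.5,
) -> dict[int, dict]:
    """Per-cluster gene-neighborhood signatures.

    For each cluster, the fraction of member sequences (among those with
    any context) whose +/-window neighborhood contains each neighboring
    gene family. Families at fraction >= ``dominant_fraction`` form the
    dominant signature. Members without context rows are tallied in a
    no-context count. Keyed by cluster index in ``report.clusters``.
    """
    ctx = context[context.offset.abs() <= window]
    fams_by_seq: dict[str, set[str]] = (
        ctx.groupby("seq_id")["neighbor_family"].agg(set).to_dict()
    )
    out: dict[int, dict] = {}
    for ci, cluster in enumerate(report.clusters):
        members = sorted(report.ssn.members(cluster))
        with_ctx = [m for m in members if m in fams_by_seq]
        fam_counts: dict[str, int] = {}
        for m in with_ctx:
            for fam in fams_by_seq[m]:
                fam_counts[fam] = fam_counts.get(fam, 0) + 1
        n = len(with_ctx)
        fractions = {f: c / n for f, c in sorted(fam_counts.items())} if n else {}
        out[ci] = {
            "n_members": len(members),
            "n_no_context": len(members) - n,
            "fractions": fractions,
            "dominant": {f for f, v in fractions.items() if v >= dominant_fraction},
        }
    return out


def export_edge_list(ssn: SSN, path, cluster_ids: Optional[Mapping[str, int]] = None) -> None:
    """Write the surviving meta-node edges as a TSV."""
    rows = [
        {
            "id_a": a,
            "id_b": b,
            "as_score": round(d["as_score"], 6),
            "pct_identity": round(d["pct_identity"], 6),
        }
        for a, b, d in sorted(ssn.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["id_a", "id_b", "as_score", "pct_identity"]).to_csv(
        path, sep="\t", index=False
    )


def export_graphml(
    ssn: SSN,
    path,
    labels: Optional[Mapping[str, str]] = None,
    cluster_ids: Optional[Mapping[str, int]] = None,
) -> None:
    """Write the SSN as GraphML with membership / label / cluster attributes."""
    g = ssn.graph.copy()
    for mid, members in ssn.meta_nodes.items():
        g.nodes[mid]["members"] = ";".join(sorted(members))
        g.nodes[mid]["n_members"] = len(members)
        if labels is not None:
            labs = sorted({labels[m] for m in members if m in labels})
            g.nodes[mid]["labels"] = ";".join(labs)
        if cluster_ids is not None and mid in cluster_ids:
            g.nodes[mid]["cluster"] = cluster_ids[mid]
    nx.write_graphml(g, path)
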