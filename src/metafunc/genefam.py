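"""Gene families by Markov clustering of a transcript similarity graph.

Transcripts are clustered without reference genomes: an all-vs-all
similarity search yields a weighted undirected graph (edges where some hit
in either direction passes the E-value cutoff, weighted by the best bit
score), which Markov clustering (MCL) partitions into gene families.

MCL simulates flow on the graph: starting from a column-stochastic matrix
of edge weights (with self-loops for regularization), it alternates
*expansion* (matrix power, spreading flow along paths) and *inflation*
(elementwise power followed by column renormalization, strengthening
strong currents and pruning weak ones) until the matrix stops changing.
At convergence the matrix is a union of star-like "attractor" systems;
each attractor's row spans one cluster. The inflation exponent controls
granularity — higher inflation, finer families. The default here is 2.6.

The MCL iteration is implemented from scratch on dense numpy arrays; it is
the core primitive of this module, not a wrapper.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .classify import HitRecord

logger = logging.getLogger(__name__)

DEFAULT_MAX_EVALUE = 1e-5


@dataclass(frozen=True)
class MCLParams:
    inflation: float = 2.6
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 200
    convergence_tol: float = 1e-6
    self_loop: str = "max_column_weight"  # or "one"

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.self_loop not in ("max_column_weight", "one"):
            raise ValueError(f"unknown self_loop mode {self.self_loop!r}")


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def build_similarity_graph(
    hits: Iterable[HitRecord],
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> nx.Graph:
    """Undirected similarity graph from all-vs-all hits.

    An edge (a, b) exists iff some hit a->b or b->a has E-value strictly
    below ``max_evalue``; its weight is the maximum bit score over
    qualifying hits in either direction. Self-hits are dropped. Nodes are
    added for every query and subject seen, so transcripts with no
    qualifying partner remain as isolated nodes.
    """
    g = nx.Graph()
    for hit in hits:
        a, b = hit.query_id, hit.subject_id
        g.add_node(a)
        g.add_node(b)
        if a == b or hit.evalue >= max_evalue:
            continue
        w = hit.bitscore
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], w)
        else:
            g.add_edge(a, b, weight=w)
    return g


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0.0] = 1.0
    return m / sums


def _mcl_matrix(adj: np.ndarray, params: MCLParams) -> tuple[np.ndarray, bool]:
    """Run the expansion/inflation loop; returns (converged matrix, did_converge)."""
    m = adj.astype(float).copy()
    np.fill_diagonal(m, 0.0)
    if params.self_loop == "max_column_weight":
        loops = m.max(axis=0)
        loops[loops == 0.0] = 1.0
    else:
        loops = np.ones(m.shape[0])
    np.fill_diagonal(m, loops)
    m = _normalize_columns(m)
    for _ in range(params.max_iter):
        expanded = np.linalg.matrix_power(m, params.expansion)
        inflated = expanded**params.inflation
        # absolute pruning of vanishing flow; a column's maximum survives
        keep = inflated >= params.prune_threshold
        keep[np.argmax(inflated, axis=0), np.arange(inflated.shape[1])] = True
        inflated[~keep] = 0.0
        inflated = _normalize_columns(inflated)
        if np.abs(inflated - m).max() < params.convergence_tol:
            return inflated, True
        m = inflated
    return m, False


def _clusters_from_matrix(m: np.ndarray, nodes: Sequence[str]) -> list[frozenset[str]]:
    """Interpret a converged MCL matrix as a node partition.

    Attractors are nodes with positive diagonal flow; each attractor row
    spans a candidate cluster. A node claimed by several candidates is
    assigned to the one whose lexicographically smallest member is
    smallest (deterministic overlap resolution). Nodes claimed by no
    attractor (possible only without full convergence) follow their
    strongest outgoing flow.
    """
    eps = 1e-12
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > eps]
    candidates: list[set[int]] = []
    for i in attractors:
        members = set(np.nonzero(m[i, :] > eps)[0])
        members.add(i)
        merged = False
        for cand in candidates:
            if cand & members:
                # attractor systems sharing members belong to one cluster
                cand |= members
                merged = True
                break
        if not merged:
            candidates.append(members)
    # repeated merging until stable (sharing is transitive)
    changed = True
    while changed:
        changed = False
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                if candidates[i] & candidates[j]:
                    candidates[i] |= candidates[j]
                    del candidates[j]
                    changed = True
                    break
            if changed:
                break
    assigned: dict[int, int] = {}
    keyed = sorted(
        range(len(candidates)),
        key=lambda k: min(nodes[i] for i in candidates[k]),
    )
    for rank_key in keyed:
        for i in candidates[rank_key]:
            assigned.setdefault(i, rank_key)
    for i in range(n):
        if i not in assigned:
            j = int(np.argmax(m[:, i]))
            assigned[i] = assigned.get(j, len(candidates))
            if assigned[i] == len(candidates):
                candidates.append({i})
                assigned[i] = len(candidates) - 1
    out: dict[int, set[str]] = {}
    for i, k in assigned.items():
        out.setdefault(k, set()).add(nodes[i])
    return [frozenset(s) for s in out.values()]


def name_families(clusters: Iterable[frozenset[str]]) -> list[GeneFamily]:
    """Assign GF1..GFn ids by descending member count, ties lexicographic."""
    ordered = sorted(clusters, key=lambda c: (-len(c), min(c)))
    return [GeneFamily(f"GF{i + 1}", members) for i, members in enumerate(ordered)]


def mcl(graph: nx.Graph, params: MCLParams = MCLParams()) -> list[GeneFamily]:
    """Partition a similarity graph into gene families with Markov clustering.

    Clustering runs independently on each connected component (flow cannot
    cross components, and per-component matrices keep the dense iteration
    small). Families are named GF1.. by descending size.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    clusters: list[frozenset[str]] = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            clusters.append(frozenset(nodes))
            continue
        adj = nx.to_numpy_array(graph.subgraph(nodes), nodelist=nodes, weight="weight")
        m, converged = _mcl_matrix(adj, params)
        if not converged:
            logger.warning(
                "MCL did not converge within %d iterations on a %d-node component",
                params.max_iter,
                len(nodes),
            )
        clusters.extend(_clusters_from_matrix(m, nodes))
    return name_families(clusters)


def families_to_frame(families: Sequence[GeneFamily]) -> pd.DataFrame:
    rows = [(f.family_id, t) for f in families for t in sorted(f.members)]
    return pd.DataFrame(rows, columns=["family_id", "transcript_id"])


def family_table(
    families: Sequence[GeneFamily],
    rpkm_per_sample: Mapping[str, Mapping[str, float]],
    annotations: Mapping[str, str] | None = None,
    taxa: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Ranked family summary: size, majority annotation, predominant taxon,
    and the family's abundance rank in every sample.

    ``rpkm_per_sample`` maps sample id -> {transcript_id: rpkm}. Families
    with no annotated member are described as "Hypothetical"; the
    predominant taxon is the mode over members (ties lexicographic).
    """
    from .abundance import rank_classes

    annotations = annotations or {}
    taxa = taxa or {}
    member_map = {t: f.family_id for f in families for t in f.members}

    per_sample_ranks: dict[str, dict[str, int]] = {}
    for sample, values in rpkm_per_sample.items():
        fam_rpkm: dict[str, float] = {f.family_id: 0.0 for f in families}
        for tid, v in values.items():
            fam = member_map.get(tid)
            if fam is not None:
                fam_rpkm[fam] += v
        per_sample_ranks[sample] = rank_classes(fam_rpkm)

    rows = []
    for fam in families:
        ann = Counter(
            annotations[t] for t in fam.members if annotations.get(t)
        )
        description = min(
            (a for a, c in ann.items() if c == max(ann.values())), default="Hypothetical"
        ) if ann else "Hypothetical"
        tax = Counter(taxa[t] for t in fam.members if taxa.get(t))
        predominant = min(
            (t for t, c in tax.items() if c == max(tax.values())), default=""
        ) if tax else ""
        row = {
            "family_id": fam.family_id,
            "n_members": len(fam),
            "description": description,
            "predominant_taxon": predominant,
        }
        for sample in rpkm_per_sample:
            row[f"rank_{sample}"] = per_sample_ranks[sample][fam.family_id]
        rows.append(row)
    return pd.DataFrame(rows).set_index("family_id")
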