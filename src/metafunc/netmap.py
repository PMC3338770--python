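"""Network-level mapping of expression data.

Two scaffolds organize class-level abundances:

* A **metabolic network** whose nodes are EC numbers and whose edges join
  enzymes sharing a substrate or product compound. Ubiquitous currency
  metabolites (water, ATP, NAD(P)(H), ...) connect nearly everything and
  are blacklisted by default, otherwise the network is close to complete
  and shortest paths are meaningless. Expression (aggregated EC RPKM) is
  a node attribute only — it never alters topology. Betweenness
  centrality over unweighted shortest paths identifies enzymes that
  mediate flux between pathway neighbourhoods.

* A **protein-protein interaction network** for a model organism
  (E. coli), on which each gene carries two attributes: conservation (the
  number of bacterial genomes with a putative ortholog) and expression
  (summed RPKM of transcripts mapping to the gene). Comparing the two
  flags genes whose expression is out of line with their conservation.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

# common currency metabolites; connecting through these is not informative
DEFAULT_COMPOUND_BLACKLIST = frozenset(
    {
        "H2O",
        "H+",
        "ATP",
        "ADP",
        "AMP",
        "NAD+",
        "NADH",
        "NADP+",
        "NADPH",
        "CO2",
        "Orthophosphate",
        "Diphosphate",
        "Phosphate",
        "CoA",
    }
)

DEFAULT_TOTAL_GENOMES = 1078


def build_metabolic_network(
    reactions: pd.DataFrame,
    blacklist: Iterable[str] | None = DEFAULT_COMPOUND_BLACKLIST,
) -> nx.Graph:
    """Enzyme-substrate network from a reaction table.

    ``reactions`` has columns ``ec``, ``role`` (substrate|product) and
    ``compound``. Two enzymes are joined iff they share at least one
    non-blacklisted compound, regardless of direction; edge attribute
    ``compounds`` is the set of shared compounds. No self-edges.
    """
    from .funcprofile import normalize_ec

    banned = frozenset(blacklist) if blacklist else frozenset()
    g = nx.Graph()
    by_compound: dict[str, set[str]] = {}
    for row in reactions.itertuples(index=False):
        ec = normalize_ec(str(row.ec))
        g.add_node(ec)
        compound = str(row.compound)
        if compound in banned:
            continue
        by_compound.setdefault(compound, set()).add(ec)
    for compound, enzymes in by_compound.items():
        members = sorted(enzymes)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if g.has_edge(a, b):
                    g[a][b]["compounds"].add(compound)
                else:
                    g.add_edge(a, b, compounds={compound})
    return g


def overlay_expression(net: nx.Graph, ec_rpkm: Mapping[str, float]) -> nx.Graph:
    """Attach aggregated RPKM to each node (0 when absent). Idempotent;
    removes nothing."""
    for node in net.nodes:
        net.nodes[node]["expression"] = float(ec_rpkm.get(node, 0.0))
    return net


def top_n_subnetwork(net: nx.Graph, n: int = 100) -> nx.Graph:
    """Induced subgraph on the n highest-expression nodes (ties by node id).

    Nodes isolated within the subgraph are retained. Requires a prior
    :func:`overlay_expression` (missing attributes count as 0).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(net.nodes, key=lambda v: (-net.nodes[v].get("expression", 0.0), v))
    return net.subgraph(ranked[:n]).copy()


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Betweenness centrality on unweighted shortest paths, normalized per
    connected component.

    Each component of size n is normalized by (n-1)(n-2)/2 (endpoints
    excluded), so the centre of a path or star scores exactly 1 regardless
    of what else the graph contains. Components with fewer than 3 nodes
    score 0.
    """
    result: dict[str, float] = {}
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        if len(comp) < 3:
            result.update(dict.fromkeys(comp, 0.0))
        else:
            result.update(nx.betweenness_centrality(sub, normalized=True, endpoints=False))
    return result


def conservation_vs_expression(
    ppi: nx.Graph,
    ortholog_counts: Mapping[str, int],
    gene_rpkm: Mapping[str, float],
    total_genomes: int = DEFAULT_TOTAL_GENOMES,
    quantile: float = 0.25,
) -> pd.DataFrame:
    """Per-gene table comparing conservation against expression on a PPI.

    Returns one row per network node with columns ``module`` (node
    attribute, if any), ``conservation`` (ortholog genome count, 0 when
    absent), ``expression`` (RPKM, 0 when absent), ``expression_rank``
    (1 = highest), and two discordance flags at the configurable quantile
    (default quartiles):

    - ``conserved_silent``: top-quartile conservation, bottom-quartile
      expression (e.g. well-conserved cell-wall genes that are barely
      transcribed in the sample);
    - ``rare_expressed``: bottom-quartile conservation, top-quartile
      expression.

    A degenerate axis (all values equal, e.g. an empty ortholog table)
    yields no flags on that axis.
    """
    if not 0 < quantile < 0.5:
        raise ValueError("quantile must be in (0, 0.5)")
    rows = []
    for node in sorted(ppi.nodes):
        cons = int(ortholog_counts.get(node, 0))
        if cons > total_genomes:
            raise ValueError(f"{node}: conservation {cons} exceeds genome total {total_genomes}")
        rows.append(
            {
                "gene": node,
                "module": ppi.nodes[node].get("module", ""),
                "conservation": cons,
                "expression": float(gene_rpkm.get(node, 0.0)),
            }
        )
    df = pd.DataFrame(rows).set_index("gene")
    df["expression_rank"] = (
        df["expression"].rank(ascending=False, method="first").astype(int)
    )

    def _bands(series: pd.Series) -> tuple[pd.Series, pd.Series]:
        if series.nunique() <= 1:
            false = pd.Series(False, index=series.index)
            return false, false
        lo, hi = series.quantile(quantile), series.quantile(1 - quantile)
        return series <= lo, series >= hi

    cons_lo, cons_hi = _bands(df["conservation"])
    expr_lo, expr_hi = _bands(df["expression"])
    df["conserved_silent"] = cons_hi & expr_lo
    df["rare_expressed"] = cons_lo & expr_hi
    return df


def annotate_network(
    net: nx.Graph,
    betweenness_values: Mapping[str, float] | None = None,
    conservation: Mapping[str, int] | None = None,
) -> nx.Graph:
    """Attach computed metrics as node attributes (for GraphML export)."""
    for node in net.nodes:
        if betweenness_values is not None:
            net.nodes[node]["betweenness"] = float(betweenness_values.get(node, 0.0))
        if conservation is not None:
            net.nodes[node]["conservation"] = int(conservation.get(node, 0))
    return net


def write_graphml(net: nx.Graph, path: str) -> None:
    """GraphML export; set-valued edge labels are serialized as sorted strings."""
    export = net.copy()
    for a, b, data in export.edges(data=True):
        if isinstance(data.get("compounds"), set):
            data["compounds"] = ",".join(sorted(data["compounds"]))
    nx.write_graphml(export, path)
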