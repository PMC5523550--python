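"""Gene-group construction and hypergeometric over-representation tests.

Gene groups come from three sources, mirroring how functional enrichment is
done for *Aspergillus* genomes:

* **GO-propagated** — a gene annotated to a term belongs to that term and to
  every ancestor reachable over ``is_a``/``part_of`` edges;
* **FunCat-direct** — flat category membership, no propagation;
* **curated** — explicit gene-ID lists supplied in configuration (e.g. an
  antioxidant-enzyme panel or the nitrate-utilization cluster).

Enrichment of a selected gene list against the chip background is the
one-sided over-representation hypergeometric (Fisher exact upper tail):

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n)

with N the background size, K the group size on the background, n the
selected-list size and k the overlap.  Raw p and Benjamini-Hochberg-adjusted
p are both reported; the significance flag defaults to raw p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import OntologyError

logger = logging.getLogger(__name__)

PROPAGATION_RELATIONS = ("is_a", "part_of")
DEFAULT_ALPHA = 0.05


@dataclass
class GeneSet:
    id: str
    label: str
    source: str  # "GO-propagated" | "FunCat-direct" | "curated"
    members: set[str]
    untestable: bool = False


@dataclass
class EnrichmentResult:
    gene_set_id: str
    k: int  # selected ∩ set
    n: int  # selected
    K: int  # set ∩ background
    N: int  # background
    p_value: float
    significant: bool


def load_ontology(path) -> nx.MultiDiGraph:
    """Read an OBO file into a child→parent multigraph (obonet convention)."""
    return obonet.read_obo(path)


def _propagation_subgraph(ontology: nx.MultiDiGraph,
                          relations=PROPAGATION_RELATIONS) -> nx.DiGraph:
    sub = nx.DiGraph()
    sub.add_nodes_from(ontology.nodes)
    for child, parent, key in ontology.edges(keys=True):
        if key in relations:
            sub.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(sub):
        cycle = nx.find_cycle(sub)
        raise OntologyError(f"ontology contains a cycle over {relations}: {cycle}")
    return sub


def propagate_ontology(ontology: nx.MultiDiGraph, annotations: pd.DataFrame,
                       relations=PROPAGATION_RELATIONS) -> dict[str, set[str]]:
    """Term → member-gene map with transitive annotation propagation.

    ``annotations`` has columns (gene_id, term_id).  A gene annotated to a
    term is a member of that term and of all its ancestors over the chosen
    relationship types; membership is a set, so diamond paths do not double
    count.  Annotations to unknown terms are skipped with a warning.
    """
    sub = _propagation_subgraph(ontology, relations)
    ancestors: dict[str, set[str]] = {}
    members: dict[str, set[str]] = {}
    for gene, term in annotations[["gene_id", "term_id"]].itertuples(index=False):
        if term not in sub:
            logger.warning("annotation to unknown term %s skipped (gene %s)", term, gene)
            continue
        if term not in ancestors:
            # Edges run child→parent, so ancestors are graph descendants.
            ancestors[term] = {term} | nx.descendants(sub, term)
        for t in ancestors[term]:
            members.setdefault(t, set()).add(gene)
    return members


def go_gene_sets(ontology: nx.MultiDiGraph, annotations: pd.DataFrame,
                 background: set[str]) -> list[GeneSet]:
    """Propagated GO gene sets intersected with the chip background."""
    sets = []
    for term, genes in propagate_ontology(ontology, annotations).items():
        name = ontology.nodes[term].get("name", term)
        members = genes & background
        sets.append(GeneSet(term, name, "GO-propagated", members, untestable=not members))
    return sets


def funcat_gene_sets(annotations: pd.DataFrame, background: set[str]) -> list[GeneSet]:
    """Flat FunCat category sets (direct membership, no propagation)."""
    sets = []
    for term, group in annotations.groupby("term_id"):
        members = set(group["gene_id"]) & background
        sets.append(GeneSet(str(term), str(term), "FunCat-direct", members,
                            untestable=not members))
    return sets


def build_curated_group(name: str, gene_ids, background: set[str]) -> GeneSet:
    """Curated gene group restricted to the background; off-background IDs logged."""
    requested = set(gene_ids)
    members = requested & background
    dropped = requested - members
    if dropped:
        logger.warning("curated group %r: %d IDs off background dropped: %s",
                       name, len(dropped), sorted(dropped))
    if not members:
        logger.warning("curated group %r has no on-background members; flagged untestable",
                       name)
    return GeneSet(name, name, "curated", members, untestable=not members)


def hypergeometric_enrichment(selected: set[str], gene_set: GeneSet, background: set[str],
                              alpha: float = DEFAULT_ALPHA) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation test of one list vs one set."""
    offenders = selected - background
    if offenders:
        raise ValueError(
            f"selected genes not on the background: {sorted(offenders)[:10]}")
    members = gene_set.members & background
    N, K, n = len(background), len(members), len(selected)
    k = len(selected & members)
    # P(X >= k) including k itself; sf(k-1) is the exact upper tail.
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(gene_set.id, k, n, K, N, p, significant=p < alpha)


def enrich_all(selected_lists: dict[str, set[str]], gene_sets: list[GeneSet],
               background: set[str], alpha: float = DEFAULT_ALPHA,
               significance_on: str = "raw") -> pd.DataFrame:
    """Cartesian product of selected lists x gene sets, sorted by raw p.

    Columns: list_id, set_id, source, k, n, K, N, p, p_adj, significant.
    BH adjustment is per selected list; the significance flag uses raw p by
    default (``significance_on="adjusted"`` switches to BH-adjusted p).
    """
    if significance_on not in ("raw", "adjusted"):
        raise ValueError("significance_on must be 'raw' or 'adjusted'")
    rows = []
    for list_id, selected in selected_lists.items():
        testable = [gs for gs in gene_sets if not gs.untestable]
        results = [hypergeometric_enrichment(selected, gs, background, alpha)
                   for gs in testable]
        if results:
            p_adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        else:
            p_adj = []
        for gs, res, adj in zip(testable, results, p_adj):
            flag = res.p_value < alpha if significance_on == "raw" else adj < alpha
            rows.append((list_id, gs.id, gs.source, res.k, res.n, res.K, res.N,
                         res.p_value, float(adj), flag))
    out = pd.DataFrame(rows, columns=["list_id", "set_id", "source", "k", "n", "K", "N",
                                      "p", "p_adj", "significant"])
    return out.sort_values(["list_id", "p"], kind="mergesort").reset_index(drop=True)
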