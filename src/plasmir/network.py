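"""miRNA-target network construction with tissue filtering, PPI expansion
and pathway enrichment.

The workflow mirrors a placenta-focused perturbed-network analysis: take the
targets of differentially abundant miRNAs, keep genes enriched in the tissue
of interest, expand that core by one hop in a protein-protein interaction
(PPI) graph, test pathway over-representation with a hypergeometric tail
test, and emit the bipartite miRNA-gene network restricted to selected
pathways.  Enrichment is an offline over-representation test (hypergeometric
upper tail with Benjamini-Hochberg correction) so no web service is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def load_interactions(path_or_df) -> pd.DataFrame:
    """miRNA-gene interaction table with columns mirna, gene, validated."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    required = {"mirna", "gene"}
    if not required <= set(df.columns):
        raise ValueError(f"interaction table needs columns {sorted(required)}")
    if "validated" not in df.columns:
        df["validated"] = 0
    df["validated"] = df["validated"].astype(int)
    if (df["mirna"].astype(str).str.len() == 0).any() or \
       (df["gene"].astype(str).str.len() == 0).any():
        raise ValueError("empty ids in interaction table")
    if df.duplicated(subset=["mirna", "gene"]).any():
        raise ValueError("duplicate (mirna, gene) pairs in interaction table")
    return df


def load_tissue_genes(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def load_ppi(path_or_df) -> nx.Graph:
    """Undirected PPI graph from a two-column edge TSV; self-loops dropped."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    g = nx.Graph()
    cols = list(df.columns[:2])
    for a, b in df[cols].itertuples(index=False):
        if a != b:
            g.add_edge(str(a), str(b))
    return g


def load_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """GMT pathway file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    pathways = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        pathways[parts[0]] = (parts[1], set(parts[2:]))
    return pathways


def select_targets(de_mirnas: list[str] | set[str], interactions: pd.DataFrame,
                   validated_only: bool = False) -> pd.DataFrame:
    """Edges of the interaction table whose miRNA is differentially abundant."""
    de_mirnas = set(de_mirnas)
    if not de_mirnas:
        raise ValueError("empty differential miRNA list")
    missing = de_mirnas - set(interactions["mirna"])
    if missing:
        logger.info("miRNAs without interactions: %s", sorted(missing))
    edges = interactions[interactions["mirna"].isin(de_mirnas)]
    if validated_only:
        edges = edges[edges["validated"] == 1]
    return edges.reset_index(drop=True)


def filter_tissue_enriched(edges: pd.DataFrame, tissue_genes: set[str]) -> pd.DataFrame:
    """Keep edges into tissue-enriched genes; miRNAs left without edges drop out."""
    if not tissue_genes:
        raise ValueError("empty tissue gene set")
    return edges[edges["gene"].isin(tissue_genes)].reset_index(drop=True)


def expand_first_neighbors(core_genes: set[str], ppi: nx.Graph) -> set[str]:
    """core plus all PPI genes adjacent to it -- exactly one hop."""
    expanded = set(core_genes)
    for g in core_genes:
        if g in ppi:
            expanded.update(ppi.neighbors(g))
    return expanded


def pathway_enrichment(gene_set: set[str], pathways: dict[str, tuple[str, set[str]]],
                       universe: set[str] | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of `gene_set` in each pathway.

    p = P(X >= k) with X ~ Hypergeometric(N = |universe|, K = pathway size,
    n = selection size); by default the universe is the union of all pathway
    genes, and both selection and pathways are restricted to it.
    """
    if universe is None:
        universe = set().union(*(genes for _, genes in pathways.values())) \
            if pathways else set()
    if not universe:
        raise ValueError("empty gene universe")
    selection = set(gene_set) & universe
    n = len(selection)
    N = len(universe)
    rows = []
    for name, (description, genes) in pathways.items():
        pk = genes & universe
        K = len(pk)
        k = len(selection & pk)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"pathway": name, "description": description,
                     "n_overlap": k, "pathway_size": K,
                     "selection_size": n, "universe_size": N, "p_value": p})
    out = pd.DataFrame(rows).set_index("pathway").sort_values("p_value")
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1] if len(out) else []
    return out


@dataclass
class NetworkSummary:
    n_mirnas: int
    n_genes: int
    n_interactions: int
    per_pathway: dict[str, int] = field(default_factory=dict)


@dataclass
class InteractionNetwork:
    """Bipartite miRNA-gene network plus gene-gene (PPI) context edges."""

    graph: nx.Graph
    edges: pd.DataFrame
    summary: NetworkSummary


def build_pathway_network(edges: pd.DataFrame, expanded_genes: set[str],
                          selected_pathways: list[str],
                          pathways: dict[str, tuple[str, set[str]]],
                          tissue_genes: set[str] | None = None,
                          ppi: nx.Graph | None = None) -> InteractionNetwork:
    """Restrict miRNA-gene edges to expanded genes in the selected pathways.

    Nodes carry tissue-enrichment flags and pathway memberships; edges carry
    the validated flag.  An empty surviving edge set yields an empty network
    with a zeroed summary (not an error).
    """
    unknown = [p for p in selected_pathways if p not in pathways]
    if unknown:
        raise ValueError(f"selected pathways not in collection: {unknown}")
    pathway_genes: dict[str, set[str]] = {p: pathways[p][1] for p in selected_pathways}
    allowed = set().union(*pathway_genes.values()) if pathway_genes else set()
    keep = edges[edges["gene"].isin(allowed & set(expanded_genes))].reset_index(drop=True)

    g = nx.Graph()
    tissue_genes = tissue_genes or set()
    for row in keep.itertuples(index=False):
        g.add_node(row.mirna, kind="mirna")
        memberships = sorted(p for p, genes in pathway_genes.items() if row.gene in genes)
        g.add_node(row.gene, kind="gene", tissue_enriched=row.gene in tissue_genes,
                   pathways=",".join(memberships))
        g.add_edge(row.mirna, row.gene, validated=bool(row.validated), kind="mirna-gene")
    if ppi is not None:
        genes = {n for n, d in g.nodes(data=True) if d.get("kind") == "gene"}
        for a, b in ppi.edges():
            if a in genes and b in genes:
                g.add_edge(a, b, kind="ppi")

    per_pathway = {p: len({row.gene for row in keep.itertuples(index=False)
                           if row.gene in genes_p})
                   for p, genes_p in pathway_genes.items()}
    summary = NetworkSummary(
        n_mirnas=keep["mirna"].nunique(),
        n_genes=keep["gene"].nunique(),
        n_interactions=len(keep),
        per_pathway=per_pathway,
    )
    return InteractionNetwork(graph=g, edges=keep, summary=summary)


def toy_network_data(seed: int = 0) -> dict:
    """Small self-contained interaction/PPI/pathway dataset for tests and
    examples (synthetic: ids are generated, not curated resources)."""
    rng = np.random.default_rng(seed)
    mirnas = [f"toy-miR-{i + 1:02d}" for i in range(20)]
    genes = [f"GENE{i + 1:03d}" for i in range(60)]
    rows = []
    for m in mirnas:
        targets = rng.choice(genes, size=rng.integers(3, 9), replace=False)
        for t in targets:
            rows.append({"mirna": m, "gene": t,
                         "validated": int(rng.random() < 0.3)})
    interactions = pd.DataFrame(rows).drop_duplicates(subset=["mirna", "gene"])
    tissue = set(rng.choice(genes, size=30, replace=False))
    ppi = nx.Graph()
    for _ in range(120):
        a, b = rng.choice(genes, size=2, replace=False)
        ppi.add_edge(a, b)
    pathways = {}
    for p in range(5):
        members = set(rng.choice(genes, size=rng.integers(8, 16), replace=False))
        pathways[f"toy{p + 1:04d}"] = (f"toy pathway {p + 1}", members)
    de_mirnas = list(rng.choice(mirnas, size=8, replace=False))
    return {"interactions": load_interactions(interactions), "tissue": tissue,
            "ppi": ppi, "pathways": pathways, "de_mirnas": de_mirnas}
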