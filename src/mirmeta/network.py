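"""Set integration, pathway enrichment, hub connectivity, network assembly.

The integration step intersects named gene collections (e.g. the
literature-derived disease gene list with the consensus microRNA targets).
Pathway enrichment scores each gene set by the hypergeometric upper-tail
probability of its overlap with the query — the same tail statistic as the
literature co-citation score, parameterized by (background size, pathway
size, query size, overlap).

Hub connectivity follows the degree z-test convention: within a candidate
hub population, each gene's degree is standardized by the population's
sample mean and n−1 SD, and the one-sided upper-tail normal probability is
reported.  Networks are undirected and unweighted; every edge carries one
or more source tags (pathway_relation | ppi | literature) and can round-trip
through SIF or GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DegenerateInputError
from .litmine import hypergeom_upper_tail

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "Network",
    "intersect_sets",
    "pathway_enrichment",
    "connectivity_ztest",
    "assemble_network",
    "export_network",
    "import_network",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_edge_tsv",
]

EDGE_SOURCES = ("pathway_relation", "ppi", "literature")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(str(g).strip().upper() for g in genes))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    count: int
    p: float
    genes: tuple[str, ...]


def intersect_sets(a: GeneSet, b: GeneSet) -> GeneSet:
    """Overlap of two gene sets; the name records provenance."""
    return GeneSet(name=f"{a.name}&{b.name}", members=a.members & b.members)


def pathway_enrichment(
    query: GeneSet,
    pathways: Sequence[GeneSet],
    background: int | GeneSet | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each pathway.

    With an explicit background set, every pathway must be contained in it;
    by default the background is the union of all pathway members.  An
    integer background is taken as a genome size.  Rows are sorted by p
    ascending, then pathway label.
    """
    if len(query) == 0:
        raise ValueError("query gene set is empty")
    if background is None:
        universe = frozenset().union(*(p.members for p in pathways)) if pathways else frozenset()
        bg_size = len(universe)
        restrict = universe
    elif isinstance(background, GeneSet):
        for p in pathways:
            stray = p.members - background.members
            if stray:
                raise ValueError(
                    f"pathway {p.name!r} has members outside the background: {sorted(stray)[:5]}"
                )
        bg_size = len(background)
        restrict = background.members
    else:
        bg_size = int(background)
        restrict = None

    q_members = query.members & restrict if restrict is not None else query.members
    draws = len(q_members)
    rows = []
    for p_set in pathways:
        overlap = tuple(sorted(p_set.members & q_members))
        p_val = hypergeom_upper_tail(bg_size, len(p_set.members), draws, len(overlap))
        rows.append(
            {
                "pathway": p_set.name,
                "count": len(overlap),
                "p": p_val,
                "genes": ",".join(overlap),
            }
        )
    return (
        pd.DataFrame(rows, columns=["pathway", "count", "p", "genes"])
        .sort_values(["p", "pathway"], kind="mergesort")
        .reset_index(drop=True)
    )


class Network:
    """Undirected gene network with per-edge source tags (networkx-backed)."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def edge_sources(self, u: str, v: str) -> set[str]:
        return set(self.graph.edges[u, v]["sources"])

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene] if gene in self.graph else 0

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def assemble_network(
    edge_sources: Sequence[tuple[pd.DataFrame, str]],
) -> Network:
    """Merge tagged edge tables into one undirected network.

    Each table needs two symbol columns (first two columns are used).
    Symbols are upper-cased; self-loops are dropped (counted in
    ``net.graph.graph['self_loops_dropped']``); an edge present in several
    sources carries the union of tags.  Malformed rows (missing symbols)
    are skipped and counted.
    """
    g = nx.Graph()
    dropped_loops = 0
    skipped = 0
    for table, tag in edge_sources:
        if table.shape[1] < 2:
            raise ValueError("edge table needs at least two symbol columns")
        a_col, b_col = table.columns[0], table.columns[-1]
        for row in table.itertuples(index=False):
            a, b = getattr(row, a_col, None), getattr(row, b_col, None)
            if not isinstance(a, str) or not isinstance(b, str) or not a.strip() or not b.strip():
                skipped += 1
                continue
            a, b = a.strip().upper(), b.strip().upper()
            if a == b:
                dropped_loops += 1
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["sources"].add(tag)
            else:
                g.add_edge(a, b, sources={tag})
    g.graph["self_loops_dropped"] = dropped_loops
    g.graph["rows_skipped"] = skipped
    return Network(g)


def connectivity_ztest(
    net: Network, hub_genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Degree z-test over a candidate hub population.

    For each gene in ``hub_genes`` (default: all network nodes) the degree
    within the network is standardized by the population's sample mean and
    n−1 SD; p is the one-sided upper-tail standard-normal probability.
    Rows are sorted by degree descending, then symbol.
    """
    if len(net) == 0:
        raise ValueError("network is empty")
    population = [str(x).strip().upper() for x in hub_genes] if hub_genes else net.nodes
    if len(population) != len(set(population)):
        raise ValueError("duplicate genes in hub population")
    degrees = np.array([net.degree(gene) for gene in population], dtype=float)
    if len(population) < 2 or degrees.std(ddof=1) == 0:
        raise DegenerateInputError("degree population has zero variance")
    mean, sd = degrees.mean(), degrees.std(ddof=1)
    z = (degrees - mean) / sd
    return (
        pd.DataFrame(
            {
                "gene": population,
                "degree": degrees.astype(int),
                "z": z,
                "p": stats.norm.sf(z),
            }
        )
        .sort_values(["degree", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# formats

def export_network(net: Network, path, format: str = "sif") -> None:
    """Write the network as SIF or GraphML; tags survive a round trip."""
    path = Path(path)
    if format == "sif":
        lines = []
        for u, v in sorted((sorted(e) for e in net.edges)):
            tag = "|".join(sorted(net.edge_sources(u, v)))
            lines.append(f"{u}\t{tag}\t{v}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.graph.nodes)
        for u, v, data in net.graph.edges(data=True):
            g.add_edge(u, v, sources="|".join(sorted(data["sources"])))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_network(path, format: str = "sif") -> Network:
    path = Path(path)
    if format == "sif":
        g = nx.Graph()
        for line_no, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{line_no}: SIF line needs 3 tab-separated fields")
            a, tag, b = parts
            sources = set(tag.split("|"))
            if g.has_edge(a, b):
                g.edges[a, b]["sources"] |= sources
            else:
                g.add_edge(a, b, sources=sources)
        return Network(g)
    if format == "graphml":
        raw = nx.read_graphml(path)
        g = nx.Graph()
        g.add_nodes_from(raw.nodes)
        for u, v, data in raw.edges(data=True):
            g.add_edge(u, v, sources=set(str(data.get("sources", "")).split("|")))
        return Network(g)
    raise ValueError(f"unknown import format {format!r}")


def read_edge_tsv(path) -> pd.DataFrame:
    """Read a 2-column or SIF-style 3-column edge table (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] == 3:
        df.columns = ["source_symbol", "interaction", "target_symbol"]
    elif df.shape[1] == 2:
        df.columns = ["source_symbol", "target_symbol"]
    else:
        raise ValueError("edge table must have 2 or 3 tab-separated columns")
    return df


def read_gmt(path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError("GMT line needs name, description, and >= 1 gene")
        sets.append(GeneSet.from_iterable(parts[0], parts[2:]))
    return sets


def write_gmt(sets: Sequence[GeneSet], path, description: str = "na") -> None:
    lines = [
        "\t".join([s.name, description, *sorted(s.members)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gene_list(path) -> list[str]:
    """Plain text gene list, one symbol per line, upper-cased."""
    return [
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
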