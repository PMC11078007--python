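"""Pan-genome data model: gene records, pan-gene families, and the adjacency graph.

A pan-genome graph has one node per gene family and an edge between two
families whenever they are adjacent in the gene order of at least one
genome.  Edge *support* records which genomes exhibit the adjacency.
Families are partitioned into core / shell / cloud divisions by how many
genomes carry them ("representation"): core families are near-universal
(default 44 of 47 genomes, ~94%), cloud families occur in exactly one
genome, and everything in between is shell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import pandas as pd

__all__ = [
    "GeneRecord",
    "PanFamily",
    "PanGraph",
    "default_core_threshold",
    "cluster_families",
    "build_graph",
    "classify_families",
    "read_panaroo_presence_absence",
    "read_panaroo_gml",
    "write_family_table",
    "write_gml",
]

CORE = "core"
SHELL = "shell"
CLOUD = "cloud"


@dataclass
class GeneRecord:
    """One gene occurrence in one genome.

    ``index`` is the 0-based position in gene order within the contig;
    (genome_id, contig_id, index) identifies the occurrence uniquely.
    """

    genome_id: str
    contig_id: str
    index: int
    strand: str = "+"
    family_id: str | None = None
    nt_seq: str | None = None
    aa_seq: str | None = None
    annotation: str = ""

    def key(self) -> tuple[str, str, int]:
        return (self.genome_id, self.contig_id, self.index)


@dataclass
class PanFamily:
    family_id: str
    name: str = ""
    members: list[GeneRecord] = field(default_factory=list)
    representation: int = 0
    division: str = SHELL

    def genomes(self) -> set[str]:
        return {g.genome_id for g in self.members}


# Genomes are handled as ``{genome_id: {contig_id: [GeneRecord, ...]}}``
# with each contig list ordered by gene index.
GenomeDict = dict[str, dict[str, list[GeneRecord]]]


class PanGraph:
    """Gene families plus their genome-supported adjacencies.

    Wraps a :class:`networkx.Graph` whose nodes are family ids and whose
    edges carry a ``support`` set of genome ids.  No edge ever crosses a
    contig boundary.
    """

    def __init__(self, n_genomes: int, core_threshold: int | None = None):
        self.graph = nx.Graph()
        self.families: dict[str, PanFamily] = {}
        self.n_genomes = n_genomes
        self.core_threshold = (
            core_threshold
            if core_threshold is not None
            else default_core_threshold(n_genomes)
        )

    def division(self, family_id: str) -> str:
        return self.families[family_id].division

    def is_core(self, family_id: str) -> bool:
        return self.families[family_id].division == CORE

    def edge_support(self, fam_a: str, fam_b: str) -> set[str]:
        return self.graph.edges[fam_a, fam_b]["support"]

    def division_counts(self) -> dict[str, int]:
        counts = {CORE: 0, SHELL: 0, CLOUD: 0}
        for fam in self.families.values():
            counts[fam.division] += 1
        return counts


def default_core_threshold(n_genomes: int) -> int:
    """Core-representation cutoff: ceil(0.94 n), pinned to 44 when n = 47."""
    if n_genomes == 47:
        return 44
    return math.ceil(0.94 * n_genomes)


# ---------------------------------------------------------------------------
# Family clustering (simplified stand-in for a full Panaroo-style pipeline)
# ---------------------------------------------------------------------------


def _global_nt_identity(a: str, b: str) -> float:
    """Global (NW) nucleotide identity, edit-distance based."""
    res = edlib.align(a, b, mode="NW", task="distance")
    aln_len = max(len(a), len(b))
    if aln_len == 0:
        return 1.0
    return 1.0 - res["editDistance"] / aln_len


def cluster_families(
    genes: Sequence[GeneRecord], identity_threshold: float = 0.98
) -> dict[tuple[str, str, int], str]:
    """Greedy single-linkage clustering of genes by global nucleotide identity.

    Returns a mapping from gene key to family id.  Any pair joined into the
    same cluster is connected by a chain of pairs at identity >= threshold.
    Deterministic: genes are processed in lexicographic key order and family
    ids are assigned in first-seen order (``fam00001`` ...).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    for g in genes:
        if g.nt_seq is None:
            raise ValueError(f"gene {g.key()} has no nucleotide sequence")
    ordered = sorted(genes, key=lambda g: g.key())
    n = len(ordered)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = ordered[i].nt_seq, ordered[j].nt_seq
            # identity >= t forces a length ratio >= t; skip hopeless pairs
            if min(len(a), len(b)) < identity_threshold * max(len(a), len(b)):
                continue
            if find(i) == find(j):
                continue
            if _global_nt_identity(a, b) >= identity_threshold:
                union(i, j)

    root_to_fam: dict[int, str] = {}
    assignment: dict[tuple[str, str, int], str] = {}
    for i, gene in enumerate(ordered):
        root = find(i)
        if root not in root_to_fam:
            root_to_fam[root] = f"fam{len(root_to_fam) + 1:05d}"
        assignment[gene.key()] = root_to_fam[root]
    return assignment


# ---------------------------------------------------------------------------
# Graph construction and division classification
# ---------------------------------------------------------------------------


def build_graph(
    genomes: GenomeDict,
    core_threshold: int | None = None,
) -> PanGraph:
    """Build the pan-genome graph from per-genome ordered gene calls.

    Consecutive genes on the same contig contribute their unordered family
    pair to the edge set, with the genome added to that edge's support.  A
    genome supports an edge at most once regardless of copy number.
    """
    pg = PanGraph(n_genomes=len(genomes), core_threshold=core_threshold)
    for genome_id in sorted(genomes):
        for contig_id in sorted(genomes[genome_id]):
            contig = genomes[genome_id][contig_id]
            for gene in contig:
                if gene.family_id is None:
                    raise ValueError(f"gene {gene.key()} has no family_id")
                fam = pg.families.get(gene.family_id)
                if fam is None:
                    fam = PanFamily(gene.family_id, name=gene.annotation)
                    pg.families[gene.family_id] = fam
                    pg.graph.add_node(gene.family_id)
                fam.members.append(gene)
                if not fam.name and gene.annotation:
                    fam.name = gene.annotation
            for left, right in zip(contig, contig[1:]):
                u, v = left.family_id, right.family_id
                if pg.graph.has_edge(u, v):
                    pg.graph.edges[u, v]["support"].add(genome_id)
                else:
                    pg.graph.add_edge(u, v, support={genome_id})
    for fam in pg.families.values():
        fam.representation = len(fam.genomes())
    classify_families(pg)
    return pg


def classify_families(pg: PanGraph) -> dict[str, str]:
    """Assign core/shell/cloud divisions from representation counts.

    Core: representation >= core_threshold. Cloud: found in exactly one
    genome. Shell: everything else (>= 2 genomes, below the core cutoff).
    """
    for fam in pg.families.values():
        if fam.representation >= pg.core_threshold:
            fam.division = CORE
        elif fam.representation == 1:
            fam.division = CLOUD
        else:
            fam.division = SHELL
        pg.graph.nodes[fam.family_id]["representation"] = fam.representation
        pg.graph.nodes[fam.family_id]["division"] = fam.division
    return {f.family_id: f.division for f in pg.families.values()}


# ---------------------------------------------------------------------------
# Panaroo-style input and table/graph output
# ---------------------------------------------------------------------------


def read_panaroo_presence_absence(path: str) -> pd.DataFrame:
    """Read a gene_presence_absence table (CSV dialect or Rtab).

    Returns a boolean DataFrame families x genomes.
    """
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header and "," not in header:
        df = pd.read_csv(path, sep="\t", index_col=0)
        return df.astype(bool)
    df = pd.read_csv(path, index_col=0, dtype=str)
    meta_cols = [c for c in ("Non-unique Gene name", "Annotation") if c in df.columns]
    df = df.drop(columns=meta_cols)
    return df.notna() & (df != "")


def read_panaroo_gml(path: str, n_genomes: int, core_threshold: int | None = None) -> PanGraph:
    """Import a Panaroo-dialect GML graph.

    Node and edge counts match the file exactly; per-edge genome support is
    taken from the ``members`` attribute when present, else left empty-set
    equivalent (support unknown).
    """
    g = nx.read_gml(path, label="id")
    pg = PanGraph(n_genomes=n_genomes, core_threshold=core_threshold)
    for node, data in g.nodes(data=True):
        fid = str(data.get("name", node))
        fam = PanFamily(fid, name=str(data.get("annotation", "")))
        members = data.get("genomeIDs", data.get("members", ""))
        if isinstance(members, str) and members:
            genome_ids = set(members.split(";"))
        elif isinstance(members, (list, tuple)):
            genome_ids = {str(m) for m in members}
        else:
            genome_ids = set()
        fam.representation = len(genome_ids) or int(data.get("size", 0))
        pg.families[fid] = fam
        pg.graph.add_node(fid, gml_id=node)
    id_to_fid = {data["gml_id"]: fid for fid, data in pg.graph.nodes(data=True)}
    for u, v, data in g.edges(data=True):
        members = data.get("genomeIDs", data.get("members", ""))
        if isinstance(members, str) and members:
            support = set(members.split(";"))
        elif isinstance(members, (list, tuple)):
            support = {str(m) for m in members}
        else:
            support = set()
        pg.graph.add_edge(id_to_fid[u], id_to_fid[v], support=support)
    classify_families(pg)
    return pg


def write_family_table(pg: PanGraph, path: str) -> None:
    rows = [
        {
            "family_id": f.family_id,
            "name": f.name,
            "representation": f.representation,
            "division": f.division,
        }
        for f in sorted(pg.families.values(), key=lambda f: f.family_id)
    ]
    pd.DataFrame(rows, columns=["family_id", "name", "representation", "division"]).to_csv(
        path, sep="\t", index=False
    )


def write_gml(pg: PanGraph, path: str) -> None:
    out = nx.Graph()
    for fid in sorted(pg.graph.nodes):
        fam = pg.families[fid]
        out.add_node(fid, representation=fam.representation, division=fam.division)
    for u, v, data in pg.graph.edges(data=True):
        out.add_edge(u, v, support=";".join(sorted(data.get("support", set()))))
    nx.write_gml(out, path)


def genome_family_orders(genomes: GenomeDict) -> dict[str, dict[str, list[str]]]:
    """Family-id sequences per genome contig, in gene order."""
    return {
        gid: {cid: [g.family_id for g in contig] for cid, contig in contigs.items()}
        for gid, contigs in genomes.items()
    }
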