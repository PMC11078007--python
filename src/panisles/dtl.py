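"""Duplication-transfer-loss reconciliation of gene trees with a species tree.

Gene "proto-phylogenies" are neighbor-joining trees on Jukes-Cantor
distances.  An unrooted gene tree is rooted at the edge minimizing the DTL
reconciliation cost.  Reconciliation uses the undated parsimony model: a
dynamic program over (gene node, species node) mappings with speciation,
duplication, and transfer cases (transfers may land on any species edge
incomparable to the donor) and per-edge loss accounting.  The minimum cost
is exact; event counts are averaged over uniform samples of optimal
reconciliations, drawn by DP solution counting.  Event counts are
normalized by (number of internal gene-tree nodes) x (total branch length),
and island trees are compared with core-gene trees by Welch's two-sided
t-test per event class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import TreeNode
from skbio.tree import nj as _skbio_nj

__all__ = [
    "Clade",
    "DtlCosts",
    "DtlResult",
    "infer_gene_tree",
    "optimal_root",
    "dtl_reconcile",
    "reconcile_cost",
    "normalize_events",
    "compare_island_vs_core",
    "jc_distance_matrix",
    "clade_from_newick",
    "clade_from_skbio",
]

INF = float("inf")


@dataclass
class DtlCosts:
    d: float = 2.0
    t: float = 3.0
    l: float = 1.0

    def __post_init__(self) -> None:
        if min(self.d, self.t, self.l) <= 0:
            raise ValueError("DTL costs must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.d, self.t, self.l)


@dataclass
class Clade:
    """Minimal rooted tree node (binary internals for reconciliation)."""

    name: str | None = None
    length: float = 0.0
    children: list["Clade"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> list["Clade"]:
        out: list[Clade] = []

        def rec(node: Clade) -> None:
            for ch in node.children:
                rec(ch)
            out.append(node)

        rec(self)
        return out

    def leaves(self) -> list["Clade"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def n_internal(self) -> int:
        return sum(1 for n in self.postorder() if not n.is_leaf())

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self)


def clade_from_skbio(node: TreeNode) -> Clade:
    return Clade(
        name=node.name,
        length=node.length or 0.0,
        children=[clade_from_skbio(c) for c in node.children],
    )


def clade_from_newick(newick: str) -> Clade:
    return clade_from_skbio(TreeNode.read([newick]))


# ---------------------------------------------------------------------------
# Gene-tree inference
# ---------------------------------------------------------------------------


def jc_distance_matrix(alignment: dict[str, str], max_distance: float = 5.0) -> DistanceMatrix:
    """Jukes-Cantor corrected pairwise distances (gap/N sites dropped per
    pair); saturated pairs (p >= 3/4) are capped."""
    labels = sorted(alignment)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = alignment[labels[i]].upper(), alignment[labels[j]].upper()
        pairs = [
            (x, y)
            for x, y in zip(a, b)
            if x in "ACGT" and y in "ACGT"
        ]
        if not pairs:
            dist = max_distance
        else:
            p = sum(1 for x, y in pairs if x != y) / len(pairs)
            if p >= 0.75:
                dist = max_distance
            else:
                dist = -0.75 * math.log(1 - 4.0 * p / 3.0)
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, labels)


def infer_gene_tree(alignment: dict[str, str]) -> TreeNode:
    """Unrooted NJ proto-phylogeny on JC distances.

    Requires at least three taxa and non-identical sequences (the same rule
    the DTL survey applies before attempting tree building); negative NJ
    branch lengths are clamped to zero.
    """
    if len(alignment) < 3:
        raise ValueError("tree building needs at least three taxa")
    seqs = set(alignment.values())
    if len(seqs) == 1:
        raise ValueError("tree building needs non-identical sequences")
    dm = jc_distance_matrix(alignment)
    tree = _skbio_nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# Species-tree preprocessing
# ---------------------------------------------------------------------------


class _Species:
    def __init__(self, root: Clade):
        self.nodes = root.postorder()
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.children: list[tuple[int, ...]] = []
        self.leaf_name: dict[str, int] = {}
        for i, node in enumerate(self.nodes):
            self.children.append(tuple(self.index[id(c)] for c in node.children))
            if node.is_leaf():
                if node.name in self.leaf_name:
                    raise ValueError(f"duplicate species leaf {node.name!r}")
                self.leaf_name[node.name] = i
            elif len(node.children) != 2:
                raise ValueError("species tree must be binary")
        # descendant-or-self relation
        self.desc = np.zeros((self.n, self.n), dtype=bool)
        for i in range(self.n):
            self.desc[i, i] = True
            for c in self.children[i]:
                self.desc[i] |= self.desc[c]
        comparable = self.desc | self.desc.T
        self.incomparable = [np.flatnonzero(~comparable[i]) for i in range(self.n)]


# ---------------------------------------------------------------------------
# The DTL dynamic program with solution counting
# ---------------------------------------------------------------------------


class _DTLTables:
    """Per-(gene node, species node) minimum costs plus solution counts for
    uniform sampling of optimal reconciliations."""

    def __init__(self, gene: Clade, sp: _Species, costs: DtlCosts,
                 leaf_map: dict[str, str]):
        self.gene = gene
        self.sp = sp
        self.costs = costs
        self.gnodes = gene.postorder()
        self.gindex = {id(n): i for i, n in enumerate(self.gnodes)}
        ng, ns = len(self.gnodes), sp.n
        self.C = np.full((ng, ns), INF)
        self.NC = np.zeros((ng, ns), dtype=object)
        self.IN = np.full((ng, ns), INF)
        self.NIN = np.zeros((ng, ns), dtype=object)
        self.OUT = np.full((ng, ns), INF)
        self.NOUT = np.zeros((ng, ns), dtype=object)
        self._fill(leaf_map)

    def _fill(self, leaf_map: dict[str, str]) -> None:
        d, t, l = self.costs.as_tuple()
        sp = self.sp
        for gi, g in enumerate(self.gnodes):
            if g.is_leaf():
                species = leaf_map.get(g.name, g.name)
                if species not in sp.leaf_name:
                    raise ValueError(f"gene leaf {g.name!r} maps to unknown species")
                si = sp.leaf_name[species]
                self.C[gi, si] = 0.0
                self.NC[gi, si] = 1
            else:
                ca, cb = (self.gindex[id(c)] for c in g.children)
                if len(g.children) != 2:
                    raise ValueError("gene tree must be binary after rooting")
                for si in range(sp.n):
                    best = INF
                    options: list[tuple[float, object]] = []
                    kids = sp.children[si]
                    if kids:
                        sl, sr = kids
                        options.append(
                            (self.IN[ca, sl] + self.IN[cb, sr],
                             self.NIN[ca, sl] * self.NIN[cb, sr])
                        )
                        options.append(
                            (self.IN[ca, sr] + self.IN[cb, sl],
                             self.NIN[ca, sr] * self.NIN[cb, sl])
                        )
                    options.append(
                        (d + self.IN[ca, si] + self.IN[cb, si],
                         self.NIN[ca, si] * self.NIN[cb, si])
                    )
                    options.append(
                        (t + self.IN[ca, si] + self.OUT[cb, si],
                         self.NIN[ca, si] * self.NOUT[cb, si])
                    )
                    options.append(
                        (t + self.IN[cb, si] + self.OUT[ca, si],
                         self.NIN[cb, si] * self.NOUT[ca, si])
                    )
                    best = min(c for c, _ in options)
                    self.C[gi, si] = best
                    if best < INF:
                        self.NC[gi, si] = sum(
                            cnt for c, cnt in options if c == best
                        )
            # IN: allow descending into the subtree, paying a loss per edge
            for si in range(sp.n):  # postorder: children before parents
                val = self.C[gi, si]
                for ch in sp.children[si]:
                    val = min(val, self.IN[gi, ch] + l)
                self.IN[gi, si] = val
                if val < INF:
                    cnt = self.NC[gi, si] if self.C[gi, si] == val else 0
                    for ch in sp.children[si]:
                        if self.IN[gi, ch] + l == val:
                            cnt += self.NIN[gi, ch]
                    self.NIN[gi, si] = cnt
            # OUT: best landing site incomparable to si (no loss charged)
            for si in range(sp.n):
                inc = sp.incomparable[si]
                if len(inc) == 0:
                    continue
                vals = self.C[gi, inc]
                best = vals.min() if len(vals) else INF
                self.OUT[gi, si] = best
                if best < INF:
                    self.NOUT[gi, si] = sum(
                        self.NC[gi, sj] for sj in inc if self.C[gi, sj] == best
                    )

    def min_cost(self) -> float:
        root = len(self.gnodes) - 1
        return float(self.C[root].min())

    # -- uniform sampling of optimal reconciliations -----------------------

    def sample_events(self, rng: np.random.Generator) -> tuple[int, int, int]:
        """One uniform draw from the optimal reconciliations; returns
        (duplications, transfers, losses)."""
        root = len(self.gnodes) - 1
        best = self.C[root].min()
        sites = [si for si in range(self.sp.n) if self.C[root, si] == best]
        weights = [self.NC[root, si] for si in sites]
        events = [0, 0, 0]
        si = sites[self._choice(rng, weights)]
        self._sample_cell(root, si, events, rng)
        return tuple(events)  # type: ignore[return-value]

    @staticmethod
    def _choice(rng: np.random.Generator, weights: list) -> int:
        total = sum(weights)
        u = rng.random() * total
        acc = 0.0
        for i, w in enumerate(weights):
            acc += w
            if u < acc:
                return i
        return len(weights) - 1

    def _sample_cell(self, gi: int, si: int, events: list[int],
                     rng: np.random.Generator) -> None:
        g = self.gnodes[gi]
        if g.is_leaf():
            return
        d, t, l = self.costs.as_tuple()
        ca, cb = (self.gindex[id(c)] for c in g.children)
        best = self.C[gi, si]
        opts = []  # (weight, kind, payload)
        kids = self.sp.children[si]
        if kids:
            sl, sr = kids
            if self.IN[ca, sl] + self.IN[cb, sr] == best:
                opts.append((self.NIN[ca, sl] * self.NIN[cb, sr], "spec", (ca, sl, cb, sr)))
            if self.IN[ca, sr] + self.IN[cb, sl] == best:
                opts.append((self.NIN[ca, sr] * self.NIN[cb, sl], "spec", (ca, sr, cb, sl)))
        if d + self.IN[ca, si] + self.IN[cb, si] == best:
            opts.append((self.NIN[ca, si] * self.NIN[cb, si], "dup", (ca, cb)))
        if t + self.IN[ca, si] + self.OUT[cb, si] == best:
            opts.append((self.NIN[ca, si] * self.NOUT[cb, si], "trans", (ca, cb)))
        if t + self.IN[cb, si] + self.OUT[ca, si] == best:
            opts.append((self.NIN[cb, si] * self.NOUT[ca, si], "trans", (cb, ca)))
        weights = [w for w, _, _ in opts]
        _, kind, payload = opts[self._choice(rng, weights)]
        if kind == "spec":
            ca_, sl, cb_, sr = payload
            self._sample_in(ca_, sl, events, rng)
            self._sample_in(cb_, sr, events, rng)
        elif kind == "dup":
            events[0] += 1
            for ci in payload:
                self._sample_in(ci, si, events, rng)
        else:
            events[1] += 1
            stay, move = payload
            self._sample_in(stay, si, events, rng)
            self._sample_out(move, si, events, rng)

    def _sample_in(self, gi: int, si: int, events: list[int],
                   rng: np.random.Generator) -> None:
        l = self.costs.l
        val = self.IN[gi, si]
        opts = []
        if self.C[gi, si] == val:
            opts.append((self.NC[gi, si], None))
        for ch in self.sp.children[si]:
            if self.IN[gi, ch] + l == val:
                opts.append((self.NIN[gi, ch], ch))
        weights = [w for w, _ in opts]
        _, target = opts[self._choice(rng, weights)]
        if target is None:
            self._sample_cell(gi, si, events, rng)
        else:
            events[2] += 1  # loss on the skipped copy along this edge
            self._sample_in(gi, target, events, rng)

    def _sample_out(self, gi: int, si: int, events: list[int],
                    rng: np.random.Generator) -> None:
        best = self.OUT[gi, si]
        inc = self.sp.incomparable[si]
        sites = [sj for sj in inc if self.C[gi, sj] == best]
        weights = [self.NC[gi, sj] for sj in sites]
        sj = sites[self._choice(rng, weights)]
        self._sample_cell(gi, sj, events, rng)


@dataclass
class DtlResult:
    costs: DtlCosts
    min_cost: float
    mean_d: float
    mean_t: float
    mean_l: float
    n_samples: int
    rates: dict[str, float] | None = None


def reconcile_cost(
    gene: Clade, species: Clade, costs: DtlCosts,
    leaf_map: dict[str, str] | None = None,
) -> float:
    """Exact minimum DTL reconciliation cost for a rooted gene tree."""
    tables = _DTLTables(gene, _Species(species), costs, leaf_map or _default_leaf_map(gene))
    return tables.min_cost()


def _default_leaf_map(gene: Clade) -> dict[str, str]:
    """Gene leaves map to species by name; multi-copy leaves use the
    'species|copy' convention."""
    return {leaf.name: leaf.name.split("|")[0] for leaf in gene.leaves()}


def dtl_reconcile(
    gene: Clade,
    species: Clade,
    costs: DtlCosts,
    n_samples: int = 300,
    seed: int = 0,
    leaf_map: dict[str, str] | None = None,
) -> DtlResult:
    """Minimum-cost reconciliation with event counts averaged over
    ``n_samples`` uniform samples of optimal reconciliations."""
    tables = _DTLTables(
        gene, _Species(species), costs, leaf_map or _default_leaf_map(gene)
    )
    best = tables.min_cost()
    if best == INF:
        raise ValueError("no feasible reconciliation (check leaf mapping)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD71]))
    totals = np.zeros(3)
    for _ in range(n_samples):
        ev = tables.sample_events(rng)
        totals += ev
    mean_d, mean_t, mean_l = totals / n_samples
    return DtlResult(
        costs=costs, min_cost=best,
        mean_d=float(mean_d), mean_t=float(mean_t), mean_l=float(mean_l),
        n_samples=n_samples,
    )


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------


def _unrooted_adjacency(tree: TreeNode):
    """Adjacency view of an skbio tree treated as unrooted."""
    nodes = list(tree.traverse(include_self=True))
    idx = {id(n): i for i, n in enumerate(nodes)}
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(nodes))}
    edges: list[tuple[int, int, float]] = []
    for n in tree.traverse(include_self=False):
        u, v = idx[id(n.parent)], idx[id(n)]
        ln = n.length or 0.0
        adj[u].append((v, ln))
        adj[v].append((u, ln))
        edges.append((u, v, ln))
    names = {i: n.name for i, n in enumerate(nodes)}
    is_leaf = {i: n.is_tip() for i, n in enumerate(nodes)}
    return adj, edges, names, is_leaf


def _root_at_edge(adj, names, is_leaf, u: int, v: int, ln: float) -> Clade:
    def build(node: int, parent: int, length: float) -> Clade:
        children = [
            build(nbr, node, w) for nbr, w in adj[node] if nbr != parent
        ]
        return Clade(name=names[node] if is_leaf[node] else None,
                     length=length, children=children)

    left = build(u, v, ln / 2)
    right = build(v, u, ln / 2)
    root = Clade(children=[left, right])
    # suppress any unifurcations introduced by the old root position
    def suppress(node: Clade) -> Clade:
        node.children = [suppress(c) for c in node.children]
        if len(node.children) == 1:
            child = node.children[0]
            child.length += node.length
            return child
        return node

    root.children = [suppress(c) for c in root.children]
    return root


def optimal_root(
    gene_tree: TreeNode,
    species: Clade,
    costs: DtlCosts,
    leaf_map: dict[str, str] | None = None,
) -> tuple[Clade, float]:
    """Root the unrooted gene tree at the edge minimizing DTL cost.

    Every edge is evaluated; ties are broken by the smallest edge index in
    the deterministic traversal order, so repeated runs agree.
    """
    adj, edges, names, is_leaf = _unrooted_adjacency(gene_tree)
    sp = _Species(species)
    best: tuple[float, int] | None = None
    best_tree: Clade | None = None
    for k, (u, v, ln) in enumerate(edges):
        rooted = _root_at_edge(adj, names, is_leaf, u, v, ln)
        lm = leaf_map or _default_leaf_map(rooted)
        cost = _DTLTables(rooted, sp, costs, lm).min_cost()
        if best is None or cost < best[0]:
            best = (cost, k)
            best_tree = rooted
    assert best_tree is not None
    return best_tree, best[0]


# ---------------------------------------------------------------------------
# Normalization and the island-vs-core comparison
# ---------------------------------------------------------------------------


def normalize_events(result: DtlResult, gene: Clade) -> dict[str, float]:
    """Per-class rate = mean count / (internal nodes x total branch length)."""
    n_int = gene.n_internal()
    total_bl = gene.total_branch_length()
    if n_int < 1:
        raise ValueError("gene tree has no internal nodes")
    if total_bl <= 0:
        raise ValueError("zero total branch length: gene excluded from rates")
    denom = n_int * total_bl
    result.rates = {
        "duplication": result.mean_d / denom,
        "transfer": result.mean_t / denom,
        "loss": result.mean_l / denom,
    }
    return result.rates


def compare_island_vs_core(
    island_rates: dict[str, list[float]],
    core_rates: dict[str, list[float]],
) -> dict[str, float]:
    """Welch two-sided t-test p-value per event class."""
    out = {}
    for cls in ("duplication", "transfer", "loss"):
        a = np.asarray(island_rates.get(cls, []), dtype=float)
        b = np.asarray(core_rates.get(cls, []), dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >=2 rates per group for class {cls!r}")
        if np.var(a) == 0 and np.var(b) == 0:
            out[cls] = 1.0
            continue
        out[cls] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return out


def write_dtl_table(rows: list[dict], path: str) -> None:
    cols = ["gene", "scheme", "min_cost", "D", "T", "L",
            "rate_duplication", "rate_transfer", "rate_loss"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
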