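"""DTL reconciliation: DP vs exhaustive oracle, rooting, rates, t-tests."""

import itertools
import math

import numpy as np
import pytest

from panisles.dtl import (
    Clade,
    DtlCosts,
    _DTLTables,
    _Species,
    clade_from_newick,
    compare_island_vs_core,
    dtl_reconcile,
    infer_gene_tree,
    normalize_events,
    optimal_root,
    reconcile_cost,
)

INF = float("inf")
SCHEMES = [(2, 3, 1), (3, 3, 1), (2, 4, 1)]


# ---------------------------------------------------------------------------
# Exhaustive oracle: enumerate every mapping of gene nodes to species nodes
# and take the cheapest valid event assignment per node.
# ---------------------------------------------------------------------------


def _prep_species(root: Clade):
    nodes = root.postorder()
    idx = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    desc = [[False] * n for _ in range(n)]
    children = []
    depth = {}

    def set_depth(node, d):
        depth[id(node)] = d
        for c in node.children:
            set_depth(c, d + 1)

    set_depth(root, 0)
    for i, node in enumerate(nodes):
        desc[i][i] = True
        children.append([idx[id(c)] for c in node.children])
        for c in node.children:
            ci = idx[id(c)]
            for j in range(n):
                desc[i][j] = desc[i][j] or desc[ci][j]
    dist = [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if desc[i][j]:
                dist[i][j] = depth[id(nodes[j])] - depth[id(nodes[i])]
    leaf = {node.name: i for i, node in enumerate(nodes) if node.is_leaf()}
    return nodes, children, desc, dist, leaf


def oracle_min_cost(gene: Clade, species: Clade, costs, leaf_map=None) -> float:
    d, t, l = costs
    snodes, children, desc, dist, leaf = _prep_species(species)
    gnodes = gene.postorder()
    internals = [g for g in gnodes if not g.is_leaf()]
    fixed = {}
    for g in gnodes:
        if g.is_leaf():
            name = (leaf_map or {}).get(g.name, g.name.split("|")[0])
            fixed[id(g)] = leaf[name]
    ns = len(snodes)

    def comparable(i, j):
        return desc[i][j] or desc[j][i]

    best_total = INF
    for combo in itertools.product(range(ns), repeat=len(internals)):
        mapping = dict(fixed)
        for g, s in zip(internals, combo):
            mapping[id(g)] = s
        total = 0.0
        for g in internals:
            ms = mapping[id(g)]
            ma = mapping[id(g.children[0])]
            mb = mapping[id(g.children[1])]
            node_best = INF
            if children[ms]:
                sl, sr = children[ms]
                for x, y in ((ma, mb), (mb, ma)):
                    if desc[sl][x] and desc[sr][y]:
                        node_best = min(
                            node_best, l * (dist[sl][x] + dist[sr][y])
                        )
            if desc[ms][ma] and desc[ms][mb]:
                node_best = min(node_best, d + l * (dist[ms][ma] + dist[ms][mb]))
            if desc[ms][ma] and not comparable(ms, mb):
                node_best = min(node_best, t + l * dist[ms][ma])
            if desc[ms][mb] and not comparable(ms, ma):
                node_best = min(node_best, t + l * dist[ms][mb])
            if node_best == INF:
                total = INF
                break
            total += node_best
        best_total = min(best_total, total)
    return best_total


def _random_rooted_topology(labels, rng) -> Clade:
    nodes = [Clade(name=lab, length=0.1) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Clade(children=[a, b], length=0.1))
    return nodes[0]


class TestReconcileCost:
    def test_congruent_trees_cost_zero(self):
        for newick in ["((A,B),C);", "(((A,B),(C,D)),E);"]:
            sp = clade_from_newick(newick)
            gene = clade_from_newick(newick)
            for scheme in SCHEMES:
                assert reconcile_cost(gene, sp, DtlCosts(*scheme)) == 0.0

    def test_three_leaf_transfer_case(self):
        # gene ((A,C),B) vs species ((A,B),C): one transfer at cost (2,3,1)
        gene = clade_from_newick("((A,C),B);")
        sp = clade_from_newick("((A,B),C);")
        res = dtl_reconcile(gene, sp, DtlCosts(2, 3, 1), n_samples=50, seed=0)
        assert res.min_cost == 3.0
        assert (res.mean_d, res.mean_t, res.mean_l) == (0.0, 1.0, 0.0)

    def test_two_copy_duplication_case(self):
        gene = clade_from_newick("((A|1,A|2),B);")
        sp = clade_from_newick("(A,B);")
        res = dtl_reconcile(gene, sp, DtlCosts(2, 3, 1), n_samples=50, seed=0)
        assert res.min_cost == 2.0
        assert (res.mean_d, res.mean_t, res.mean_l) == (1.0, 0.0, 0.0)

    def test_unknown_leaf_rejected(self):
        gene = clade_from_newick("((A,Z),B);")
        sp = clade_from_newick("((A,B),C);")
        with pytest.raises(ValueError, match="unknown species"):
            reconcile_cost(gene, sp, DtlCosts())

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_dp_equals_exhaustive_enumeration(self, scheme):
        """DP minimum equals brute-force over all mappings, for random
        gene/species topology pairs of 3-6 leaves."""
        rng = np.random.default_rng(17)
        cases = []
        for n_leaves in (3, 4, 5, 6):
            n_cases = {3: 6, 4: 5, 5: 3, 6: 2}[n_leaves]
            labels = [chr(ord("A") + i) for i in range(n_leaves)]
            for _ in range(n_cases):
                sp = _random_rooted_topology(labels, rng)
                gene = _random_rooted_topology(labels, rng)
                cases.append((gene, sp))
        for gene, sp in cases:
            dp = reconcile_cost(gene, sp, DtlCosts(*scheme))
            brute = oracle_min_cost(gene, sp, scheme)
            assert dp == brute

    def test_every_sample_is_optimal(self):
        """Event counts of each sampled reconciliation satisfy
        d*D + t*T + l*L == min_cost."""
        rng = np.random.default_rng(23)
        labels = list("ABCDE")
        for _ in range(5):
            sp = _random_rooted_topology(labels, rng)
            gene = _random_rooted_topology(labels, rng)
            costs = DtlCosts(2, 3, 1)
            tables = _DTLTables(
                gene, _Species(sp), costs,
                {leaf.name: leaf.name for leaf in gene.leaves()},
            )
            best = tables.min_cost()
            sampler = np.random.default_rng(1)
            for _ in range(30):
                D, T, L = tables.sample_events(sampler)
                assert 2 * D + 3 * T + 1 * L == best

    def test_transfer_priced_out_reduces_to_duplication_loss(self):
        """With t -> infinity the DP agrees with the classic LCA-mapping
        duplication-loss reconciliation."""

        def lca_dl_oracle(gene, species, d, l):
            snodes, children, desc, dist, leaf = _prep_species(species)

            def lca(i, j):
                for k in range(len(snodes)):
                    if desc[k][i] and desc[k][j]:
                        if all(
                            not (desc[c][i] and desc[c][j])
                            for c in children[k]
                        ):
                            return k
                raise AssertionError

            cost = 0.0
            mapping = {}
            for g in gene.postorder():
                if g.is_leaf():
                    mapping[id(g)] = leaf[g.name]
                    continue
                ma = mapping[id(g.children[0])]
                mb = mapping[id(g.children[1])]
                m = lca(ma, mb)
                mapping[id(g)] = m
                if m == ma or m == mb:  # duplication
                    cost += d + l * (dist[m][ma] + dist[m][mb])
                else:
                    cost += l * (dist[m][ma] - 1 + dist[m][mb] - 1)
            return cost

        rng = np.random.default_rng(31)
        labels = list("ABCDE")
        for _ in range(8):
            sp = _random_rooted_topology(labels, rng)
            gene = _random_rooted_topology(labels, rng)
            dp = reconcile_cost(gene, sp, DtlCosts(2, 10**6, 1))
            assert dp < 10**6  # no transfer used
            assert dp == lca_dl_oracle(gene, sp, 2, 1)


class TestOptimalRoot:
    def _skbio_tree(self, newick):
        from skbio.tree import TreeNode

        return TreeNode.read([newick])

    def test_congruent_tree_roots_at_species_root(self):
        sp = clade_from_newick("((A,B),(C,D));")
        unrooted = self._skbio_tree("(A,B,(C,D));")
        rooted, cost = optimal_root(unrooted, sp, DtlCosts(2, 3, 1))
        assert cost == 0.0
        sides = [sorted(l.name for l in c.leaves()) for c in rooted.children]
        assert sorted(map(tuple, sides)) == [("A", "B"), ("C", "D")]

    def test_three_leaf_rooting_cost(self):
        sp = clade_from_newick("((A,B),C);")
        unrooted = self._skbio_tree("(A,C,B);")
        _, cost = optimal_root(unrooted, sp, DtlCosts(2, 3, 1))
        assert cost == 0.0  # some rooting is congruent

    def test_deterministic_tie_breaking(self):
        sp = clade_from_newick("((A,B),(C,D));")
        unrooted = self._skbio_tree("((A,C),(B,D));")
        results = [
            optimal_root(unrooted, sp, DtlCosts(2, 3, 1)) for _ in range(3)
        ]
        costs = {c for _, c in results}
        assert len(costs) == 1
        newicks = set()
        for tree, _ in results:
            newicks.add(_canonical(tree))
        assert len(newicks) == 1


def _canonical(clade: Clade) -> str:
    if clade.is_leaf():
        return clade.name
    parts = sorted(_canonical(c) for c in clade.children)
    return "(" + ",".join(parts) + ")"


class TestInferGeneTree:
    def _alignment_from_tree(self, rng, length=600):
        # two clearly separated pairs: (A,B) vs (C,D) at ~5% divergence
        base = rng.choice(list("ACGT"), size=length)
        other = base.copy()
        idx = rng.choice(length, size=int(0.05 * length), replace=False)
        for i in idx:
            other[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[str(other[i])]

        def jitter(arr, k=3):
            out = arr.copy()
            for i in rng.choice(length, size=k, replace=False):
                out[i] = {"A": "G", "C": "A", "G": "C", "T": "G"}[str(out[i])]
            return out

        return {
            "A": "".join(jitter(base)),
            "B": "".join(jitter(base)),
            "C": "".join(jitter(other)),
            "D": "".join(jitter(other)),
        }

    def test_planted_topology_recovered(self):
        rng = np.random.default_rng(41)
        aln = self._alignment_from_tree(rng)
        tree = infer_gene_tree(aln)
        from panisles.tani import tree_bipartitions

        assert frozenset(["A", "B"]) in tree_bipartitions(tree)

    def test_identical_sequences_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            infer_gene_tree({"A": "ACGT", "B": "ACGT", "C": "ACGT"})

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="three taxa"):
            infer_gene_tree({"A": "ACGT", "B": "ACGA"})


class TestRatesAndComparison:
    def test_normalization_arithmetic(self):
        from panisles.dtl import DtlResult

        gene = clade_from_newick("((A:0.5,B:0.5):0.25,C:0.25);")
        assert gene.n_internal() == 2
        assert gene.total_branch_length() == pytest.approx(1.5)
        res = DtlResult(DtlCosts(), min_cost=9, mean_d=0, mean_t=3, mean_l=0,
                        n_samples=1)
        rates = normalize_events(res, gene)
        assert rates["transfer"] == pytest.approx(1.0)
        assert rates["duplication"] == 0.0

    def test_zero_branch_length_excluded(self):
        from panisles.dtl import DtlResult

        gene = clade_from_newick("((A:0,B:0):0,C:0);")
        res = DtlResult(DtlCosts(), 0, 0, 0, 0, 1)
        with pytest.raises(ValueError, match="branch length"):
            normalize_events(res, gene)

    def test_identical_samples_p_one(self):
        rates = {"duplication": [0.1, 0.2, 0.3], "transfer": [0.1, 0.2, 0.3],
                 "loss": [0.1, 0.2, 0.3]}
        p = compare_island_vs_core(rates, {k: list(v) for k, v in rates.items()})
        assert all(v == pytest.approx(1.0) for v in p.values())

    def test_welch_matches_closed_form(self):
        a = [1.0, 2.0, 3.0]
        b = [2.0, 4.0, 6.0]
        rates_a = {"duplication": a, "transfer": a, "loss": a}
        rates_b = {"duplication": b, "transfer": b, "loss": b}
        p = compare_island_vs_core(rates_a, rates_b)
        # textbook Welch: t = (ma-mb)/sqrt(va/na+vb/nb), df via Satterthwaite
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        tstat = (ma - mb) / math.sqrt(va / 3 + vb / 3)
        df = (va / 3 + vb / 3) ** 2 / (
            (va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2
        )
        from scipy.stats import t as tdist

        expected = 2 * tdist.sf(abs(tstat), df)
        assert p["transfer"] == pytest.approx(expected, rel=1e-10)

    def test_separated_rate_distributions_significant(self):
        rng = np.random.default_rng(51)
        isl = list(rng.normal(0.23, 0.05, size=50))
        core = list(rng.normal(0.15, 0.05, size=200))
        p = compare_island_vs_core(
            {"duplication": isl, "transfer": isl, "loss": isl},
            {"duplication": core, "transfer": core, "loss": core},
        )
        assert p["transfer"] < 0.01
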