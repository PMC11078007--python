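"""Whole-genome ANI / alignment-fraction distances and the tANI phylogeny.

The query genome is cut into consecutive fixed-length fragments (default
1020 nt); each fragment is mapped to the subject genome by infix alignment
(edlib), and hits above the identity cutoff are retained.  ANI is the mean
identity of retained hits and AF the retained fraction of the query; both
are symmetrized by averaging the two directions.  The tANI distance is
-ln(ANI x AF): at AF = 1 the species boundary distance 0.315 corresponds to
ANI 73%.  Trees are neighbor-joining on the distance matrix; bootstrap
support resamples each query's fragments with replacement and recomputes
the matrix and tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

__all__ = [
    "AniResult",
    "compute_ani_af",
    "tani_distance",
    "tani_to_ani",
    "distance_matrix",
    "fragment_tables",
    "build_tree",
    "bootstrap_supports",
    "tree_bipartitions",
    "read_genome_fasta",
    "write_distance_matrix",
]

DEFAULT_DISTANCE_CAP = 10.0


@dataclass
class AniResult:
    genome_pair: tuple[str, str]
    ani: float | None
    af: float
    n_fragments: int
    retained: int
    flagged: bool = False


def read_genome_fasta(path: str) -> str:
    """Concatenate all contigs of a (multi-)FASTA genome."""
    from Bio import SeqIO

    return "".join(str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta"))


def _fragment_hits(
    query: str,
    subject: str,
    fragment_len: int,
    min_identity: float,
    min_coverage: float = 0.7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-fragment best-hit identity, retained flag, and fragment length.

    The query is cut into consecutive full windows plus a trailing partial
    window when it reaches ``min_coverage`` of the nominal fragment length;
    infix alignment maps each whole fragment, so fragment coverage is
    complete by construction and sub-threshold hits are dropped.
    """
    bounds = [
        (i * fragment_len, (i + 1) * fragment_len)
        for i in range(len(query) // fragment_len)
    ]
    tail = len(query) - len(bounds) * fragment_len
    if tail >= min_coverage * fragment_len:
        bounds.append((len(bounds) * fragment_len, len(query)))
    n = len(bounds)
    identities = np.zeros(n)
    retained = np.zeros(n, dtype=bool)
    lengths = np.array([e - s for s, e in bounds], dtype=float)
    for i, (s, e) in enumerate(bounds):
        frag = query[s:e]
        # band-limit the search: hits below min_identity are discarded anyway
        k = int(math.ceil((1.0 - min_identity) * len(frag)))
        res = edlib.align(frag, subject, mode="HW", task="distance", k=k)
        if res["editDistance"] < 0:
            identities[i] = 0.0
            retained[i] = False
        else:
            ident = 1.0 - res["editDistance"] / len(frag)
            identities[i] = ident
            retained[i] = ident >= min_identity
    return identities, retained, lengths


def _one_direction(identities: np.ndarray, retained: np.ndarray,
                   lengths: np.ndarray) -> tuple[float | None, float]:
    if not retained.any():
        return None, 0.0
    ani = float(identities[retained].mean())
    af = float(lengths[retained].sum() / lengths.sum())
    return ani, af


def compute_ani_af(
    query: str,
    subject: str,
    names: tuple[str, str] = ("query", "subject"),
    fragment_len: int = 1020,
    min_identity: float = 0.7,
    min_coverage: float = 0.7,
) -> AniResult:
    """Symmetrized fragment-based ANI and alignment fraction.

    ``min_coverage`` governs the trailing partial window: only full windows
    (complete fragment coverage) enter the computation, so windows shorter
    than ``min_coverage * fragment_len`` can never contribute.
    """
    if not query or not subject:
        raise ValueError("both genomes must be non-empty")
    id_qs, ret_qs, len_qs = _fragment_hits(
        query, subject, fragment_len, min_identity, min_coverage
    )
    id_sq, ret_sq, len_sq = _fragment_hits(
        subject, query, fragment_len, min_identity, min_coverage
    )
    ani_qs, af_qs = _one_direction(id_qs, ret_qs, len_qs)
    ani_sq, af_sq = _one_direction(id_sq, ret_sq, len_sq)
    anis = [a for a in (ani_qs, ani_sq) if a is not None]
    ani = float(np.mean(anis)) if anis else None
    af = float(np.mean([af_qs, af_sq]))
    return AniResult(
        genome_pair=names,
        ani=ani,
        af=min(af, 1.0),
        n_fragments=len(id_qs) + len(id_sq),
        retained=int(ret_qs.sum() + ret_sq.sum()),
        flagged=ani is None,
    )


def tani_distance(
    ani: float | None, af: float, cap: float = DEFAULT_DISTANCE_CAP
) -> float:
    """tANI distance -ln(ANI x AF); undefined products are capped."""
    if ani is None or ani * af <= 0:
        return cap
    return min(-math.log(ani * af), cap)


def tani_to_ani(distance: float, af: float = 1.0) -> float:
    """Invert the tANI distance at a given alignment fraction."""
    return math.exp(-distance) / af


def fragment_tables(
    genomes: dict[str, str], fragment_len: int = 1020, min_identity: float = 0.7
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Per-fragment identity/retained tables for every directed genome
    pair; the expensive step, reusable across the matrix and bootstrap."""
    tables = {}
    for q in genomes:
        for s in genomes:
            if q != s:
                tables[(q, s)] = _fragment_hits(
                    genomes[q], genomes[s], fragment_len, min_identity
                )
    return tables


def distance_matrix(
    genomes: dict[str, str],
    fragment_len: int = 1020,
    min_identity: float = 0.7,
    cap: float = DEFAULT_DISTANCE_CAP,
    tables: dict | None = None,
) -> tuple[DistanceMatrix, list[AniResult]]:
    """All-vs-all symmetrized tANI distance matrix."""
    labels = sorted(genomes)
    if tables is None:
        tables = fragment_tables(genomes, fragment_len, min_identity)
    d = np.zeros((len(labels), len(labels)))
    results = []
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j <= i:
                continue
            res = _combine_pair(tables, genomes, a, b, fragment_len)
            results.append(res)
            d[i, j] = d[j, i] = tani_distance(res.ani, res.af, cap)
    return DistanceMatrix(d, labels), results


def _combine_pair(tables, genomes, a, b, fragment_len,
                  idx_a=None, idx_b=None) -> AniResult:
    id_ab, ret_ab, len_ab = tables[(a, b)]
    id_ba, ret_ba, len_ba = tables[(b, a)]
    if idx_a is not None:
        id_ab, ret_ab, len_ab = id_ab[idx_a], ret_ab[idx_a], len_ab[idx_a]
    if idx_b is not None:
        id_ba, ret_ba, len_ba = id_ba[idx_b], ret_ba[idx_b], len_ba[idx_b]
    ani_ab, af_ab = _one_direction(id_ab, ret_ab, len_ab)
    ani_ba, af_ba = _one_direction(id_ba, ret_ba, len_ba)
    anis = [x for x in (ani_ab, ani_ba) if x is not None]
    ani = float(np.mean(anis)) if anis else None
    af = min(float(np.mean([af_ab, af_ba])), 1.0)
    return AniResult(
        genome_pair=(a, b), ani=ani, af=af,
        n_fragments=len(id_ab) + len(id_ba),
        retained=int(ret_ab.sum() + ret_ba.sum()), flagged=ani is None,
    )


def build_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths clamped to zero."""
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 taxa for a tree")
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions as the smaller-side leaf sets (ties broken
    lexicographically), orientation-independent."""
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        pick = min((sorted(side), sorted(other)))
        parts.add(frozenset(pick))
    return parts


def bootstrap_supports(
    genomes: dict[str, str],
    n_reps: int = 100,
    seed: int = 0,
    fragment_len: int = 1020,
    min_identity: float = 0.7,
    cap: float = DEFAULT_DISTANCE_CAP,
    tables: dict | None = None,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Fragment-resampling bootstrap: per replicate, each query genome's
    fragment set is resampled with replacement, the tANI matrix and NJ tree
    recomputed, and bipartition frequencies (x100) attached to the tree."""
    labels = sorted(genomes)
    if tables is None:
        tables = fragment_tables(genomes, fragment_len, min_identity)
    dm, _ = distance_matrix(genomes, fragment_len, min_identity, cap, tables=tables)
    tree = build_tree(dm)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    counts: dict[frozenset[str], int] = {}
    other = {g: next(s for s in labels if s != g) for g in labels}
    n_frags = {g: len(tables[(g, other[g])][0]) for g in labels}
    for _ in range(n_reps):
        idx = {g: rng.integers(0, n_frags[g], size=n_frags[g]) for g in labels}
        d = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if j <= i:
                    continue
                res = _combine_pair(tables, genomes, a, b, fragment_len,
                                    idx_a=idx[a], idx_b=idx[b])
                d[i, j] = d[j, i] = tani_distance(res.ani, res.af, cap)
        rep_tree = build_tree(DistanceMatrix(d, labels))
        for part in tree_bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1
    supports = {part: 100.0 * counts.get(part, 0) / n_reps
                for part in tree_bipartitions(tree)}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        leaves = frozenset(t.name for t in tree.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        pick = frozenset(min((sorted(side), sorted(other))))
        if pick in supports:
            node.name = f"{supports[pick]:.0f}"
    return tree, supports


def write_distance_matrix(dm: DistanceMatrix, path: str) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
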