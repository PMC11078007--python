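"""Neutral-core population structure: Tajima's D filter, SNP matrix, and
nested population assignment.

Core-gene alignments are screened with Tajima's D; families with |D| < 0.2
are treated as effectively neutral (not shaped by purifying selection).
Neutral alignments are concatenated into a SNP matrix of polymorphic sites,
from which genomes are hierarchically clustered into nested populations.
The clustering is a silhouette-guided agglomerative stand-in for a Bayesian
nested-population model: level 1 cuts the N-aware SNP Hamming distance
dendrogram at the best mean-silhouette k, and each level-1 cluster is
re-clustered the same way for level 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "TajimaResult",
    "tajimas_d",
    "build_snp_matrix",
    "snp_distance_matrix",
    "cluster_populations",
    "write_tajima_table",
    "write_population_table",
]

NEUTRALITY_THRESHOLD = 0.2
_MISSING = set("N-.?X")


@dataclass
class TajimaResult:
    family_id: str
    n: int
    S: int
    pi: float
    D: float | None
    neutral: bool


def _clean_columns(seqs: list[str]) -> list[str]:
    """Drop alignment columns containing gaps or ambiguous bases."""
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    keep = [
        i for i in range(length)
        if all(s[i].upper() not in _MISSING for s in seqs)
    ]
    return ["".join(s[i] for i in keep) for s in seqs]


def tajimas_d(alignment: dict[str, str | None], family_id: str = "") -> TajimaResult:
    """Tajima's (1989) D for one core-gene alignment.

    ``pi`` is the mean number of pairwise differences per alignment (not per
    site); the neutral flag applies the strict |D| < 0.2 filter.  With no
    segregating sites D is undefined and the family is non-neutral.
    """
    seqs = [s.upper() for s in alignment.values() if s]
    n = len(seqs)
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 sequences")
    seqs = _clean_columns(seqs)
    length = len(seqs[0])
    S = sum(1 for i in range(length) if len({s[i] for s in seqs}) > 1)
    total_diff = 0
    for a, b in combinations(seqs, 2):
        total_diff += sum(1 for x, y in zip(a, b) if x != y)
    n_pairs = n * (n - 1) // 2
    pi = total_diff / n_pairs
    if S == 0:
        return TajimaResult(family_id, n, 0, pi, None, False)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    D = (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
    return TajimaResult(family_id, n, S, pi, float(D), abs(D) < NEUTRALITY_THRESHOLD)


def build_snp_matrix(
    alignments: dict[str, dict[str, str | None]],
    genomes: list[str] | None = None,
) -> pd.DataFrame:
    """Concatenate neutral core alignments and keep polymorphic columns.

    Genomes missing a family contribute N for its columns; a column is kept
    iff it has >= 2 distinct non-N states.  Returns genomes x sites with
    single-character entries; an empty frame signals no polymorphic sites.
    """
    if not alignments:
        raise ValueError("no neutral alignments supplied")
    if genomes is None:
        genomes = sorted({g for aln in alignments.values() for g in aln})
    columns: list[list[str]] = []
    names: list[str] = []
    for fam in sorted(alignments):
        aln = alignments[fam]
        present = [g for g in genomes if aln.get(g)]
        if not present:
            continue
        length = len(aln[present[0]])
        rows = {g: (aln.get(g) or "N" * length).upper() for g in genomes}
        for i in range(length):
            col = [rows[g][i] if rows[g][i] not in _MISSING else "N" for g in genomes]
            states = {c for c in col if c != "N"}
            if len(states) >= 2:
                columns.append(col)
                names.append(f"{fam}:{i}")
    if not columns:
        return pd.DataFrame(index=genomes)
    data = np.array(columns).T
    df = pd.DataFrame(data, index=genomes, columns=names)
    df.index.name = "genome"
    return df


def snp_distance_matrix(snp: pd.DataFrame) -> np.ndarray:
    """Pairwise N-aware Hamming distance: fraction of sites differing among
    sites where both genomes are called (N excluded from the denominator)."""
    mat = snp.to_numpy(dtype="<U1")
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            called = (mat[i] != "N") & (mat[j] != "N")
            denom = called.sum()
            if denom == 0:
                d[i, j] = d[j, i] = 0.0
            else:
                d[i, j] = d[j, i] = (mat[i][called] != mat[j][called]).sum() / denom
    return d


def _cluster_once(d: np.ndarray, labels: list[str], k_max: int = 10) -> dict[str, int]:
    """Average-linkage cut at the k in [2, k_max] maximizing mean
    silhouette; deterministic (silhouette is distance-based, no sampling)."""
    n = len(labels)
    if n < 3 or np.allclose(d, 0):
        return {lab: 1 for lab in labels}
    z = linkage(squareform(d, checks=False), method="average")
    best_k, best_score = None, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        assign = fcluster(z, t=k, criterion="maxclust")
        if len(set(assign)) < 2:
            continue
        score = silhouette_score(d, assign, metric="precomputed")
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    if best_k is None:
        return {lab: 1 for lab in labels}
    assign = fcluster(z, t=best_k, criterion="maxclust")
    # renumber clusters by first appearance for determinism
    seen: dict[int, int] = {}
    out = {}
    for lab, a in zip(labels, assign):
        if a not in seen:
            seen[a] = len(seen) + 1
        out[lab] = seen[a]
    return out


def cluster_populations(
    snp: pd.DataFrame,
    max_levels: int = 2,
    seed: int = 0,
    k_max: int = 10,
) -> dict[str, tuple[str, ...]]:
    """Nested population assignment: genome -> one label per level, each
    level refining the previous.  ``seed`` is accepted for interface
    stability; the procedure is deterministic."""
    genomes = list(snp.index)
    if len(genomes) < 3 or snp.shape[1] == 0:
        return {g: tuple("1" for _ in range(max_levels)) for g in genomes}
    d = snp_distance_matrix(snp)
    level1 = _cluster_once(d, genomes, k_max)
    assignments = {g: [str(level1[g])] for g in genomes}
    current = level1
    for _ in range(1, max_levels):
        nxt: dict[str, str] = {}
        for cl in sorted(set(current.values())):
            members = [g for g in genomes if current[g] == cl]
            idx = [genomes.index(g) for g in members]
            sub = _cluster_once(d[np.ix_(idx, idx)], members, k_max)
            for g in members:
                nxt[g] = f"{assignments[g][-1]}.{sub[g]}"
        for g in genomes:
            assignments[g].append(nxt[g])
        current = {g: nxt[g] for g in genomes}
    return {g: tuple(v) for g, v in assignments.items()}


def write_tajima_table(results: list[TajimaResult], path: str) -> None:
    rows = [
        {
            "family_id": r.family_id,
            "n": r.n,
            "S": r.S,
            "pi": f"{r.pi:.6f}",
            "D": "" if r.D is None else f"{r.D:.6f}",
            "neutral": r.neutral,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=["family_id", "n", "S", "pi", "D", "neutral"]).to_csv(
        path, sep="\t", index=False
    )


def write_population_table(assignment: dict[str, tuple[str, ...]], path: str) -> None:
    levels = max((len(v) for v in assignment.values()), default=0)
    rows = [
        {"genome": g, **{f"level{i+1}": assignment[g][i] for i in range(levels)}}
        for g in sorted(assignment)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
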