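"""Conflicting island pairs, homeoallele mapping, and homeocassette calls.

Two islands inserted between the same pair of core genes in different
genomes form a *conflicting pair*; genomes carrying both are reported as
mutual-exclusivity violations.  Every cross-island gene pair is scored by
local amino-acid alignment (BLOSUM62, affine gaps), with significance from
a shuffle-permutation test (the PRSS idea): the observed score is compared
with scores against shuffled partners, and the empirical p-value uses the
standard pseudocount estimator (1 + #null >= obs) / (1 + n_shuffles).
Significant pairs are resolved greedily by descending score into one-to-one
*homeoalleles*; leftover significant one-to-many matches are *unbalanced
duplications*; genes without any significant partner are *iORFans*.  A pair
is a *homeocassette* when at least half of each island's gene content
participates in homeoallele/duplication matches.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .islands import GenomicIsland

__all__ = [
    "HomologyHit",
    "IslandPair",
    "find_conflicting_pairs",
    "homology_search",
    "classify_pair",
    "write_pair_report",
    "write_homeoallele_map",
]


@dataclass
class HomologyHit:
    gene_a: str
    gene_b: str
    aln_score: float
    perm_p: float
    coverage: float
    aa_identity: float | None = None
    nt_identity: float | None = None
    significant: bool = False


@dataclass
class IslandPair:
    island_a: GenomicIsland
    island_b: GenomicIsland
    exclusivity_violations: set[str] = field(default_factory=set)
    hits: list[HomologyHit] = field(default_factory=list)
    homeoalleles: list[tuple[str, str]] = field(default_factory=list)
    duplications: list[tuple[str, str]] = field(default_factory=list)
    iorfans_a: list[str] = field(default_factory=list)
    iorfans_b: list[str] = field(default_factory=list)
    classification: str | None = None

    @property
    def pair_id(self) -> str:
        return f"{self.island_a.island_id}+{self.island_b.island_id}"


def find_conflicting_pairs(islands: list[GenomicIsland]) -> list[IslandPair]:
    """Pair up islands sharing the same unordered flank pair.

    Carrier-set intersections are recorded as exclusivity violations
    (reported, not fatal).
    """
    by_locus: dict[tuple[str, str], list[GenomicIsland]] = {}
    for isl in islands:
        by_locus.setdefault(isl.locus, []).append(isl)
    pairs = []
    for locus in sorted(by_locus):
        group = sorted(by_locus[locus], key=lambda i: i.island_id)
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                pairs.append(
                    IslandPair(
                        island_a=a,
                        island_b=b,
                        exclusivity_violations=a.carriers & b.carriers,
                    )
                )
    return pairs


def _aa_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "local"
    return al


def _nt_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.match_score = 2.0
    al.mismatch_score = -3.0
    al.open_gap_score = -5.0
    al.extend_gap_score = -2.0
    al.mode = "local"
    return al


def _alignment_stats(aligner: PairwiseAligner, a: str, b: str) -> tuple[float, float, float]:
    """(score, identity over aligned columns, coverage of shorter seq)."""
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    aligned_cols = 0
    covered = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        covered += ea - sa
        for x, y in zip(a[sa:ea], b[sb:eb]):
            aligned_cols += 1
            if x == y:
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    coverage = covered / min(len(a), len(b)) if min(len(a), len(b)) else 0.0
    return float(aln.score), identity, coverage


def _pair_rng(seed: int, ga: str, gb: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [seed, zlib.crc32(ga.encode()), zlib.crc32(gb.encode())]
        )
    )


def homology_search(
    pair: IslandPair,
    sequences: Mapping[str, tuple[str | None, str | None]],
    alpha: float = 0.01,
    n_shuffles: int = 200,
    seed: int = 0,
) -> list[HomologyHit]:
    """Score all cross-island gene pairs and partition members.

    A cross pair is homologous iff perm_p <= alpha and the alignment covers
    at least half of the shorter protein.  The shuffle target and the
    per-pair RNG stream depend only on the (unordered) gene-family names, so
    the result is symmetric in the two islands and deterministic given the
    seed.
    """
    aa_al = _aa_aligner()
    nt_al = _nt_aligner()
    hits: list[HomologyHit] = []
    for ga in pair.island_a.members:
        for gb in pair.island_b.members:
            nt_a, aa_a = sequences.get(ga, (None, None))
            nt_b, aa_b = sequences.get(gb, (None, None))
            if not aa_a or not aa_b:
                hits.append(HomologyHit(ga, gb, 0.0, 1.0, 0.0))
                continue
            # canonical orientation: shuffle the lexicographically larger name
            if ga <= gb:
                fixed, shuffled = aa_a, aa_b
            else:
                fixed, shuffled = aa_b, aa_a
            score, identity, coverage = _alignment_stats(aa_al, aa_a, aa_b)
            rng = _pair_rng(seed, *sorted((ga, gb)))
            arr = np.array(list(shuffled))
            worse = 0
            for _ in range(n_shuffles):
                rng.shuffle(arr)
                if aa_al.score(fixed, "".join(arr)) >= score:
                    worse += 1
            perm_p = (1 + worse) / (1 + n_shuffles)
            nt_identity = None
            if nt_a and nt_b:
                _, nt_identity, _ = _alignment_stats(nt_al, nt_a, nt_b)
            hit = HomologyHit(
                ga, gb, score, perm_p, coverage,
                aa_identity=identity, nt_identity=nt_identity,
                significant=(perm_p <= alpha and coverage >= 0.5),
            )
            hits.append(hit)
    pair.hits = hits
    _partition(pair)
    return hits


def _partition(pair: IslandPair) -> None:
    """Greedy score-descending one-to-one matching; leftovers with a
    significant partner become duplications, the rest iORFans."""
    sig = [h for h in pair.hits if h.significant]
    sig.sort(key=lambda h: (-h.aln_score, h.gene_a, h.gene_b))
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    pair.homeoalleles = []
    for h in sig:
        if h.gene_a not in matched_a and h.gene_b not in matched_b:
            pair.homeoalleles.append((h.gene_a, h.gene_b))
            matched_a.add(h.gene_a)
            matched_b.add(h.gene_b)
    pair.duplications = []
    dup_a: set[str] = set()
    dup_b: set[str] = set()
    for h in sig:
        if h.gene_a not in matched_a and h.gene_a not in dup_a and h.gene_b in matched_b:
            pair.duplications.append((h.gene_a, h.gene_b))
            dup_a.add(h.gene_a)
        elif h.gene_b not in matched_b and h.gene_b not in dup_b and h.gene_a in matched_a:
            pair.duplications.append((h.gene_a, h.gene_b))
            dup_b.add(h.gene_b)
    pair.iorfans_a = [
        g for g in pair.island_a.members if g not in matched_a and g not in dup_a
    ]
    pair.iorfans_b = [
        g for g in pair.island_b.members if g not in matched_b and g not in dup_b
    ]


def classify_pair(pair: IslandPair, threshold: float = 0.5) -> str:
    """Homeocassette iff, on BOTH islands, at least ``threshold`` of the
    members participate in homeoallele or duplication matches (inclusive)."""
    in_a = {a for a, _ in pair.homeoalleles} | {
        a for a, _ in pair.duplications if a in pair.island_a.members
    }
    in_b = {b for _, b in pair.homeoalleles} | {
        b for _, b in pair.duplications if b in pair.island_b.members
    }
    frac_a = len(in_a & set(pair.island_a.members)) / len(pair.island_a.members)
    frac_b = len(in_b & set(pair.island_b.members)) / len(pair.island_b.members)
    pair.classification = (
        "homeocassette" if frac_a >= threshold and frac_b >= threshold
        else "conflicting_only"
    )
    return pair.classification


def write_pair_report(pairs: list[IslandPair], path: str) -> None:
    rows = []
    for p in pairs:
        for h in p.hits:
            rows.append(
                {
                    "pair_id": p.pair_id,
                    "flank_left": p.island_a.flank_left,
                    "flank_right": p.island_a.flank_right,
                    "classification": p.classification or "",
                    "gene_a": h.gene_a,
                    "gene_b": h.gene_b,
                    "aln_score": h.aln_score,
                    "aa_identity": "" if h.aa_identity is None else f"{h.aa_identity:.3f}",
                    "nt_identity": "" if h.nt_identity is None else f"{h.nt_identity:.3f}",
                    "coverage": f"{h.coverage:.3f}",
                    "perm_p": f"{h.perm_p:.5f}",
                    "significant": h.significant,
                    "exclusivity_violations": ",".join(sorted(p.exclusivity_violations)),
                }
            )
    cols = [
        "pair_id", "flank_left", "flank_right", "classification", "gene_a",
        "gene_b", "aln_score", "aa_identity", "nt_identity", "coverage",
        "perm_p", "significant", "exclusivity_violations",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_homeoallele_map(pairs: list[IslandPair], path: str) -> None:
    rows = []
    for p in pairs:
        for a, b in p.homeoalleles:
            rows.append({"pair_id": p.pair_id, "kind": "homeoallele", "gene_a": a, "gene_b": b})
        for a, b in p.duplications:
            rows.append({"pair_id": p.pair_id, "kind": "duplication", "gene_a": a, "gene_b": b})
        for g in p.iorfans_a:
            rows.append({"pair_id": p.pair_id, "kind": "iorfan_a", "gene_a": g, "gene_b": ""})
        for g in p.iorfans_b:
            rows.append({"pair_id": p.pair_id, "kind": "iorfan_b", "gene_a": "", "gene_b": g})
    pd.DataFrame(rows, columns=["pair_id", "kind", "gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )
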