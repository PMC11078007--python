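"""Genomic-island discovery on the pan-genome graph.

A genomic island is a maximal run of non-core gene families bounded on both
sides by core families ("core gene - rare gene(s) - core gene").  The
graph-neighborhood traversal is realized as an equivalent per-genome linear
scan with locus-level merging: per contig, every bounded non-core run is an
island occurrence; occurrences sharing the same unordered flank pair are
grouped into islands (identical, reverse-ordered, or subset member sets
merge; sufficiently overlapping sets merge; disjoint sets found a new
island).  Loci that fragment into too many island variants are discarded as
unresolvable multifurcations.

Islands of a single gene are kept only when another island invades the same
core-gene pair.  Post-processing annotates the +-5-gene mobilome
neighborhood (transposase / integrase / tRNA), island G+C, and whether the
island sequence is identical across its carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .pangraph import GeneRecord, GenomeDict, PanGraph

__all__ = [
    "Occurrence",
    "GenomicIsland",
    "DiscoveryReport",
    "find_islands",
    "neighborhood_scan",
    "gc_content",
    "find_identical_islands",
    "island_sequences",
    "write_island_table",
    "write_presence_absence",
]


@dataclass
class Occurrence:
    genome_id: str
    contig_id: str
    start: int  # gene-order index of first member (half-open interval)
    end: int  # index one past the last member; flanks sit at start-1 / end
    members: tuple[str, ...]
    reversed_orientation: bool = False


@dataclass
class GenomicIsland:
    island_id: str
    flank_left: str
    flank_right: str
    members: tuple[str, ...]
    carriers: set[str] = field(default_factory=set)
    occurrences: dict[str, Occurrence] = field(default_factory=dict)
    partial_carriers: set[str] = field(default_factory=set)
    per_carrier_seq: dict[str, str] = field(default_factory=dict)
    gc: float | None = None
    identical_flag: bool | None = None
    neighborhood: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)

    @property
    def locus(self) -> tuple[str, str]:
        return tuple(sorted((self.flank_left, self.flank_right)))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DiscoveryReport:
    contig_end_runs: int = 0
    overlong_runs: int = 0
    singleton_rejected: int = 0
    short_rejected: int = 0
    discarded_loci: list[tuple[tuple[str, str], int]] = field(default_factory=list)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def find_islands(
    graph: PanGraph,
    genomes: GenomeDict,
    min_len: int = 2,
    max_len: int = 40,
    max_variants_per_locus: int = 3,
) -> tuple[list[GenomicIsland], DiscoveryReport]:
    """Find genomic islands as core-flanked non-core runs, merged per locus.

    Returns the island list (deterministically ordered and numbered) and a
    report of skipped runs and discarded loci.
    """
    report = DiscoveryReport()
    occurrences: dict[tuple[str, str], list[Occurrence]] = {}

    for genome_id in sorted(genomes):
        for contig_id in sorted(genomes[genome_id]):
            contig = genomes[genome_id][contig_id]
            run_start: int | None = None
            last_core: int | None = None
            for idx, rec in enumerate(contig):
                if graph.is_core(rec.family_id):
                    if run_start is not None:
                        if last_core is None:
                            report.contig_end_runs += 1
                        elif idx - run_start > max_len:
                            report.overlong_runs += 1
                        else:
                            fl = contig[last_core].family_id
                            fr = rec.family_id
                            members = tuple(
                                g.family_id for g in contig[run_start:idx]
                            )
                            locus = tuple(sorted((fl, fr)))
                            if (fl, fr) != locus:
                                members = members[::-1]
                            occurrences.setdefault(locus, []).append(
                                Occurrence(genome_id, contig_id, run_start, idx, members)
                            )
                        run_start = None
                    last_core = idx
                else:
                    if run_start is None:
                        run_start = idx
            if run_start is not None:
                report.contig_end_runs += 1

    islands: list[GenomicIsland] = []
    for locus in sorted(occurrences):
        occs = sorted(
            occurrences[locus],
            key=lambda o: (-len(o.members), o.members, o.genome_id, o.contig_id, o.start),
        )
        locus_islands: list[GenomicIsland] = []
        for occ in occs:
            placed = False
            oset = set(occ.members)
            for isl in locus_islands:
                iset = set(isl.members)
                if occ.members == isl.members:
                    pass
                elif occ.members[::-1] == isl.members:
                    occ.reversed_orientation = True
                elif oset < iset:
                    isl.partial_carriers.add(occ.genome_id)
                else:
                    continue
                isl.carriers.add(occ.genome_id)
                isl.occurrences.setdefault(occ.genome_id, occ)
                placed = True
                break
            if not placed:
                best, best_j = None, 0.0
                for isl in locus_islands:
                    j = _jaccard(oset, set(isl.members))
                    if j > best_j:
                        best, best_j = isl, j
                if best is not None and best_j >= 0.5:
                    best.carriers.add(occ.genome_id)
                    best.occurrences.setdefault(occ.genome_id, occ)
                else:
                    fl, fr = locus
                    # orient flanks to the founding occurrence's scan direction
                    locus_islands.append(
                        GenomicIsland(
                            island_id="",
                            flank_left=fl,
                            flank_right=fr,
                            members=occ.members,
                            carriers={occ.genome_id},
                            occurrences={occ.genome_id: occ},
                        )
                    )
        if len(locus_islands) > max_variants_per_locus:
            report.discarded_loci.append((locus, len(locus_islands)))
            continue
        kept = []
        multi = len(locus_islands) >= 2
        for isl in locus_islands:
            if len(isl.members) >= min_len or multi:
                kept.append(isl)
            elif len(isl.members) == 1:
                report.singleton_rejected += 1
            else:
                report.short_rejected += 1
        islands.extend(kept)

    for k, isl in enumerate(islands, start=1):
        isl.island_id = f"island{k:03d}"
    return islands, report


def neighborhood_scan(
    island: GenomicIsland,
    genomes: GenomeDict,
    radius: int = 5,
) -> dict[str, list[tuple[str, int, str]]]:
    """Flag mobilome elements within ``radius`` genes beyond each flank.

    Offsets are negative upstream of the left flank and positive downstream
    of the right flank (offset k = k genes beyond the flank gene).  A tRNA
    whose family is itself an island member is not counted as neighborhood
    ("while not being found on the island itself" rule).
    """
    member_set = set(island.members)
    flags: dict[str, list[tuple[str, int, str]]] = {}
    for carrier in sorted(island.carriers):
        occ = island.occurrences.get(carrier)
        if occ is None:
            flags[carrier] = []
            continue
        contig = genomes[carrier][occ.contig_id]
        found: list[tuple[str, int, str]] = []
        for k in range(1, radius + 1):
            for idx, offset in (((occ.start - 1) - k, -k), (occ.end + k, +k)):
                if not 0 <= idx < len(contig):
                    continue
                rec = contig[idx]
                label = _element_label(rec.annotation)
                if label is None:
                    continue
                if label == "tRNA" and rec.family_id in member_set:
                    continue
                found.append((label, offset, rec.family_id))
        flags[carrier] = sorted(found, key=lambda t: (t[1], t[0]))
    island.neighborhood = flags
    return flags


def _element_label(annotation: str) -> str | None:
    a = annotation.lower()
    if "transposase" in a or "is element" in a:
        return "transposase"
    if "integrase" in a or "recombinase" in a:
        return "integrase"
    if a.startswith("trna") or "trna" in a:
        return "tRNA"
    return None


def gc_content(seq: str) -> float:
    """Fraction (G+C)/(A+C+G+T); N bases are excluded from both sides."""
    counts = {b: seq.upper().count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty or all-N sequence: G+C undefined")
    return (counts["G"] + counts["C"]) / total


def island_sequences(islands: list[GenomicIsland], genomes: GenomeDict) -> None:
    """Fill per-carrier concatenated member sequences (orientation
    normalized to the canonical island direction) and pooled island G+C."""
    for isl in islands:
        for carrier, occ in isl.occurrences.items():
            contig = genomes[carrier][occ.contig_id]
            parts = [r.nt_seq or "" for r in contig[occ.start : occ.end]]
            seq = "".join(parts)
            if occ.reversed_orientation:
                seq = str(Seq(seq).reverse_complement())
            if seq:
                isl.per_carrier_seq[carrier] = seq
        pooled = "".join(isl.per_carrier_seq.values())
        if pooled:
            isl.gc = gc_content(pooled)


def find_identical_islands(islands: list[GenomicIsland]) -> dict[str, bool | None]:
    """identical_flag: all carriers' island sequences byte-identical after
    orientation normalization; None (not applicable) below 2 carriers."""
    out: dict[str, bool | None] = {}
    for isl in islands:
        seqs = [isl.per_carrier_seq[c] for c in sorted(isl.per_carrier_seq)]
        if len(seqs) < 2:
            isl.identical_flag = None
        else:
            isl.identical_flag = all(s == seqs[0] for s in seqs[1:])
        out[isl.island_id] = isl.identical_flag
    return out


def write_island_table(islands: list[GenomicIsland], path: str) -> None:
    rows = []
    for isl in islands:
        nb = sorted({lbl for flags in isl.neighborhood.values() for lbl, _, _ in flags})
        rows.append(
            {
                "island_id": isl.island_id,
                "flank_left": isl.flank_left,
                "flank_right": isl.flank_right,
                "members": ",".join(isl.members),
                "length": len(isl.members),
                "carriers": ",".join(sorted(isl.carriers)),
                "n_carriers": len(isl.carriers),
                "partial_carriers": ",".join(sorted(isl.partial_carriers)),
                "gc": "" if isl.gc is None else f"{isl.gc:.4f}",
                "identical_flag": "" if isl.identical_flag is None else isl.identical_flag,
                "neighborhood": ",".join(nb),
            }
        )
    cols = [
        "island_id", "flank_left", "flank_right", "members", "length",
        "carriers", "n_carriers", "partial_carriers", "gc", "identical_flag",
        "neighborhood",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_presence_absence(
    islands: list[GenomicIsland], genomes: GenomeDict, path: str
) -> pd.DataFrame:
    """Genome x island presence matrix with coded entries:
    1 = carrier, 2 = partial carrier, 0 = absent."""
    gids = sorted(genomes)
    data = {}
    for isl in islands:
        col = []
        for g in gids:
            if g in isl.partial_carriers:
                col.append(2)
            elif g in isl.carriers:
                col.append(1)
            else:
                col.append(0)
        data[isl.island_id] = col
    df = pd.DataFrame(data, index=gids)
    df.index.name = "genome"
    df.to_csv(path, sep="\t")
    return df
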