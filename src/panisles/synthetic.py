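"""Synthetic pan-genome generator with known ground truth.

Emulates the structure of a single-species collection of closely related
prokaryotic draft genomes (default: 47 genomes at >= 98.5% ANI): a conserved
core backbone in fixed gene order, scattered shell/cloud singleton genes,
genomic islands of 2-22 genes inserted between specific core-gene pairs with
distinct G+C content, mutually exclusive island pairs sharing divergent
homologs (homeoalleles), transposase/integrase/tRNA elements flanking
islands, and SNPs on core genes structured into nested clades.

Every downstream stage (graph construction, island discovery, homeocassette
classification, tANI phylogeny, population structure, DTL rates) can thus be
tested against planted truth without any external data.
"""

from __future__ import annotations

import dataclasses
import os
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .pangraph import GeneRecord, GenomeDict

__all__ = [
    "IslandSpec",
    "SynthConfig",
    "SynthTruth",
    "PlantedIsland",
    "PlantedPair",
    "generate",
    "mutate_to_identity",
    "default_island_specs",
    "family_sequences",
    "write_genomes",
    "read_genomes",
    "write_truth",
    "write_config",
]

_NT = np.array(list("ACGT"))
_AA = list("ACDEFGHIKLMNPQRSTVWY")
_STOPS = {"TAA", "TAG", "TGA"}

# codon table for back-translation (standard code, stops excluded)
_CODONS_BY_AA: dict[str, list[str]] = {}
for _c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3)):
    if _c in _STOPS:
        continue
    _CODONS_BY_AA.setdefault(str(Seq(_c).translate()), []).append(_c)


@dataclass
class IslandSpec:
    """One planted genomic island.

    ``locus`` is the index i of the core-gene pair invaded: the island sits
    between core gene i and core gene i+1.  ``partner_of`` references an
    earlier spec (by position in ``island_specs``) to form a conflicting
    pair at the same locus; ``homeoallele_fraction`` of this island's genes
    are then generated as divergent homologs (at ``target_identity`` amino
    acid identity) of the partner's genes.
    """

    locus: int
    n_genes: int
    carriers: tuple[str, ...]
    gc_target: float = 0.45
    partner_of: int | None = None
    homeoallele_fraction: float = 0.0
    target_identity: float = 0.5
    flank_elements: dict[str, int] = field(default_factory=dict)
    identical_across_carriers: bool = True
    reversed_in: tuple[str, ...] = ()
    annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("island must have at least one gene")
        if not 0 <= self.homeoallele_fraction <= 1:
            raise ValueError("homeoallele_fraction must be in [0, 1]")
        if not 0 <= self.target_identity <= 1:
            raise ValueError("target_identity must be in [0, 1]")


@dataclass
class SynthConfig:
    """Study-scale defaults: 47 genomes, 2,000 core families, 10 islands."""

    n_genomes: int = 47
    n_core: int = 2000
    n_shell: int = 400
    n_cloud: int = 300
    gene_len_range: tuple[int, int] = (300, 900)
    core_gc: float = 0.68
    core_snp_rate: float = 0.01
    island_specs: list[IslandSpec] | None = None
    seed: int = 0
    with_sequences: bool = True
    fragmentation: int = 0
    n_clades: int = 2
    nested_subclades: bool = True

    def __post_init__(self) -> None:
        if self.n_genomes < 4:
            raise ValueError("need at least 4 genomes")
        if min(self.n_core, self.n_shell, self.n_cloud) < 0:
            raise ValueError("counts must be non-negative")
        if not (0 <= self.core_gc <= 1 and 0 <= self.core_snp_rate <= 1):
            raise ValueError("rates/fractions must be in [0, 1]")

    def genome_ids(self) -> list[str]:
        return [f"G{i:02d}" for i in range(self.n_genomes)]


@dataclass
class PlantedIsland:
    index: int
    locus: int
    flank_left: str
    flank_right: str
    members: tuple[str, ...]
    carriers: tuple[str, ...]
    gc_target: float
    flank_elements: dict[str, int]
    reversed_in: tuple[str, ...]


@dataclass
class PlantedPair:
    a_index: int
    b_index: int
    homeoallele_map: dict[str, str]  # member of b -> member of a
    expected_class: str


@dataclass
class SynthTruth:
    islands: list[PlantedIsland]
    pairs: list[PlantedPair]
    populations: dict[str, tuple[str, str]]  # genome -> (clade, subclade)


def default_island_specs(n_genomes: int = 47, n_core: int = 2000) -> list[IslandSpec]:
    """Ten islands with lengths spanning 2-22, incl. one homeocassette pair.

    Loci are spaced widely along the core backbone; carrier sets are small
    deterministic subsets; a few islands carry mobilome flanking elements.
    """
    gids = [f"G{i:02d}" for i in range(n_genomes)]
    step = max(2, (n_core - 100) // 12)
    lengths = [2, 3, 4, 5, 6, 8, 12, 22]
    sizes = [5, 3, 8, 2, 6, 4, 10, 7]
    elems: list[dict[str, int]] = [
        {"transposase": -2},
        {"tRNA": 1},
        {},
        {"integrase": 3},
        {},
        {"transposase": 2, "tRNA": -1},
        {},
        {},
    ]
    specs = []
    for i, (ln, sz) in enumerate(zip(lengths, sizes)):
        carriers = tuple(gids[(i * 5 + j) % n_genomes] for j in range(sz))
        specs.append(
            IslandSpec(
                locus=50 + step * i,
                n_genes=ln,
                carriers=tuple(sorted(set(carriers))),
                gc_target=0.45,
                flank_elements=elems[i],
            )
        )
    # one conflicting pair at a shared locus (homeocassette at fraction 0.6)
    locus = 50 + step * 9
    a_car = tuple(gids[1:6])
    b_car = tuple(gids[n_genomes // 2 : n_genomes // 2 + 5])
    specs.append(IslandSpec(locus=locus, n_genes=6, carriers=a_car, gc_target=0.50))
    specs.append(
        IslandSpec(
            locus=locus,
            n_genes=6,
            carriers=b_car,
            gc_target=0.50,
            partner_of=len(specs) - 1,
            homeoallele_fraction=0.6,
            target_identity=0.5,
        )
    )
    return specs


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _random_orf(rng: np.random.Generator, length_nt: int, gc: float) -> str:
    """Random ORF: per-position i.i.d. nucleotides at the target G+C,
    start/stop codons added, internal stops resampled."""
    n_codons = max(1, length_nt // 3 - 2)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    body = rng.choice(_NT, size=3 * n_codons, p=p)
    codons = ["".join(body[3 * i : 3 * i + 3]) for i in range(n_codons)]
    for i, c in enumerate(codons):
        while codons[i] in _STOPS:
            codons[i] = "".join(rng.choice(_NT, size=3, p=p))
    return "ATG" + "".join(codons) + "TAA"


def _translate(nt: str) -> str:
    aa = str(Seq(nt).translate())
    return aa.rstrip("*").replace("*", "X")


def _back_translate(aa: str, gc: float, rng: np.random.Generator) -> str:
    """Reverse-translate, choosing codons with probability weighted toward
    the target G+C."""
    out = []
    for res in aa:
        codons = _CODONS_BY_AA.get(res, _CODONS_BY_AA["A"])
        w = np.array(
            [
                np.prod([(gc / 2) if b in "GC" else ((1 - gc) / 2) for b in c])
                for c in codons
            ]
        )
        out.append(codons[rng.choice(len(codons), p=w / w.sum())])
    return "ATG" + "".join(out) + "TAA"


def mutate_to_identity(
    seq: str, target_identity: float, alphabet: str = "aa", seed: int = 0
) -> str:
    """Substitute positions of ``seq`` so pairwise identity to the input is
    ``target_identity`` (no indels; length preserved).

    With substitutions only, global-alignment identity equals the fraction
    of unchanged positions, so the realized identity is round-exact.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    if target_identity == 1.0:
        return seq
    letters = list("ACGT") if alphabet == "nt" else _AA
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(seq.encode())]))
    n_mut = round((1 - target_identity) * len(seq))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [c for c in letters if c != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _validate(config: SynthConfig, specs: list[IslandSpec]) -> None:
    gids = set(config.genome_ids())
    used_loci: dict[int, list[int]] = {}
    for i, spec in enumerate(specs):
        unknown = set(spec.carriers) - gids
        if unknown:
            raise ValueError(f"island {i}: unknown carrier genomes {sorted(unknown)}")
        if not 0 <= spec.locus <= config.n_core - 2:
            raise ValueError(f"island {i}: locus {spec.locus} out of range")
        used_loci.setdefault(spec.locus, []).append(i)
        if spec.partner_of is not None:
            if not 0 <= spec.partner_of < i:
                raise ValueError(f"island {i}: partner_of must reference an earlier spec")
            partner = specs[spec.partner_of]
            if partner.locus != spec.locus:
                raise ValueError(f"island {i}: partner must share the locus")


def _core_snp_sites(
    rng: np.random.Generator,
    length: int,
    rate: float,
    gids: list[str],
    populations: dict[str, tuple[str, str]],
) -> list[tuple[int, set[str]]]:
    """Choose polymorphic sites and the genome subset carrying the derived
    allele.  Sites are a mix of clade-informative (balanced), subclade-
    informative, and neutral-SFS random subsets, so both Tajima's D and the
    nested population clustering have recoverable signal."""
    n_sites = rng.binomial(length, rate)
    clades: dict[str, list[str]] = {}
    subclades: dict[str, list[str]] = {}
    for g in gids:
        cl, sub = populations[g]
        clades.setdefault(cl, []).append(g)
        subclades.setdefault(sub, []).append(g)
    sites = []
    positions = rng.choice(length, size=min(n_sites, length), replace=False)
    for pos in positions:
        u = rng.random()
        if u < 0.4 and len(clades) > 1:
            key = sorted(clades)[rng.integers(len(clades))]
            carriers = set(clades[key])
        elif u < 0.6 and len(subclades) > 1:
            key = sorted(subclades)[rng.integers(len(subclades))]
            carriers = set(subclades[key])
        else:
            n = len(gids)
            weights = 1.0 / np.arange(1, n)
            k = int(rng.choice(np.arange(1, n), p=weights / weights.sum()))
            carriers = set(rng.choice(gids, size=k, replace=False))
        sites.append((int(pos), carriers))
    return sites


def generate(config: SynthConfig) -> tuple[GenomeDict, SynthTruth]:
    """Generate the pan-genomes and the planted-truth tables.

    Output is fully determined by (config, seed): all randomness flows from
    one :class:`numpy.random.SeedSequence`.
    """
    specs = (
        config.island_specs
        if config.island_specs is not None
        else default_island_specs(config.n_genomes, config.n_core)
    )
    _validate(config, specs)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    gids = config.genome_ids()
    n = config.n_genomes

    # nested population truth: clades split the genome list evenly, each
    # clade split again into two subclades
    populations: dict[str, tuple[str, str]] = {}
    n_clades = max(1, config.n_clades)
    for i, g in enumerate(gids):
        cl = chr(ord("A") + min(i * n_clades // n, n_clades - 1))
        members_start = [j for j, gg in enumerate(gids)
                         if chr(ord("A") + min(j * n_clades // n, n_clades - 1)) == cl]
        half = members_start[len(members_start) // 2] if members_start else 0
        sub = f"{cl}.1" if (config.nested_subclades and i < half) else (
            f"{cl}.2" if config.nested_subclades else f"{cl}.1")
        populations[g] = (cl, sub)

    lo, hi = config.gene_len_range

    def gene_len() -> int:
        return 3 * (int(rng.integers(lo, hi + 1)) // 3)

    # --- core backbone ----------------------------------------------------
    core_ids = [f"core{i:04d}" for i in range(config.n_core)]
    core_seqs: dict[str, dict[str, str]] = {}  # family -> genome -> seq
    if config.with_sequences:
        for fid in core_ids:
            base = _random_orf(rng, gene_len(), config.core_gc)
            variants: dict[str, str] = {}
            edits: dict[str, dict[int, str]] = {g: {} for g in gids}
            for pos, carriers in _core_snp_sites(
                rng, len(base), config.core_snp_rate, gids, populations
            ):
                alt = [c for c in "ACGT" if c != base[pos]][int(rng.integers(3))]
                for g in carriers:
                    edits[g][pos] = alt
            for g in gids:
                if edits[g]:
                    s = list(base)
                    for pos, alt in edits[g].items():
                        s[pos] = alt
                    variants[g] = "".join(s)
                else:
                    variants[g] = base
            core_seqs[fid] = variants

    # --- islands ----------------------------------------------------------
    planted: list[PlantedIsland] = []
    pairs: list[PlantedPair] = []
    island_fams: list[dict] = []  # per spec: {"members": [...], "seqs": {fid: (nt, aa)}}
    used_slots: set[int] = set()
    for i, spec in enumerate(specs):
        used_slots.add(spec.locus)
        members = [f"isl{i:02d}_g{j:02d}" for j in range(spec.n_genes)]
        seqs: dict[str, tuple[str, str]] = {}
        hmap: dict[str, str] = {}
        if config.with_sequences:
            if spec.partner_of is not None:
                partner = island_fams[spec.partner_of]
                n_home = round(spec.homeoallele_fraction * spec.n_genes)
                for j, fid in enumerate(members):
                    if j < n_home and j < len(partner["members"]):
                        src = partner["members"][j]
                        src_aa = partner["seqs"][src][1]
                        aa = mutate_to_identity(
                            src_aa, spec.target_identity, "aa",
                            seed=config.seed * 1000 + i * 64 + j,
                        )
                        nt = _back_translate(aa, spec.gc_target,
                                             np.random.default_rng(
                                                 np.random.SeedSequence(
                                                     [config.seed, 7, i, j])))
                        seqs[fid] = (nt, aa)
                        hmap[fid] = src
                    else:
                        nt = _random_orf(rng, gene_len(), spec.gc_target)
                        seqs[fid] = (nt, _translate(nt))
            else:
                for fid in members:
                    nt = _random_orf(rng, gene_len(), spec.gc_target)
                    seqs[fid] = (nt, _translate(nt))
        elif spec.partner_of is not None:
            partner = island_fams[spec.partner_of]
            n_home = round(spec.homeoallele_fraction * spec.n_genes)
            for j, fid in enumerate(members):
                if j < n_home and j < len(partner["members"]):
                    hmap[fid] = partner["members"][j]
        island_fams.append({"members": members, "seqs": seqs})
        planted.append(
            PlantedIsland(
                index=i,
                locus=spec.locus,
                flank_left=core_ids[spec.locus],
                flank_right=core_ids[spec.locus + 1],
                members=tuple(members),
                carriers=tuple(sorted(spec.carriers)),
                gc_target=spec.gc_target,
                flank_elements=dict(spec.flank_elements),
                reversed_in=tuple(spec.reversed_in),
            )
        )
        if spec.partner_of is not None:
            pairs.append(
                PlantedPair(
                    a_index=spec.partner_of,
                    b_index=i,
                    homeoallele_map=hmap,
                    expected_class=(
                        "homeocassette"
                        if spec.homeoallele_fraction >= 0.5
                        else "conflicting_only"
                    ),
                )
            )

    # --- flanking mobilome elements ---------------------------------------
    # an element at offset -k / +k sits k genes beyond the left/right flank
    elements: dict[int, list[tuple[str, str, tuple[str, ...]]]] = {}  # slot -> [(fid, label, carriers)]
    for i, spec in enumerate(specs):
        for label, offset in sorted(spec.flank_elements.items()):
            if offset == 0:
                raise ValueError("flank element offset must be non-zero")
            slot = spec.locus + offset if offset > 0 else spec.locus + offset
            if not 0 <= slot <= config.n_core - 2:
                raise ValueError(f"island {i}: element offset {offset} out of range")
            fid = f"elem{i:02d}_{label}"
            ann = {"transposase": "transposase", "integrase": "integrase",
                   "tRNA": "tRNA-Ala"}[label]
            elements.setdefault(slot, []).append((fid, ann, tuple(sorted(spec.carriers))))
            used_slots.add(slot)

    # --- shell / cloud singleton genes ------------------------------------
    free_slots = [s for s in range(config.n_core - 1) if s not in used_slots]
    rng.shuffle(free_slots)
    needed = config.n_shell + config.n_cloud
    if needed > len(free_slots):
        raise ValueError("not enough inter-core slots for shell+cloud genes")
    singles: dict[int, tuple[str, str, tuple[str, ...]]] = {}  # slot -> (fid, ann, carriers)
    from .pangraph import default_core_threshold

    core_thr = default_core_threshold(n)
    for k in range(config.n_shell):
        slot = free_slots[k]
        rep = int(rng.integers(2, max(3, core_thr)))
        carriers = tuple(sorted(rng.choice(gids, size=min(rep, n - 1), replace=False)))
        singles[slot] = (f"shell{k:04d}", "hypothetical protein", carriers)
    for k in range(config.n_cloud):
        slot = free_slots[config.n_shell + k]
        carriers = (gids[int(rng.integers(n))],)
        singles[slot] = (f"cloud{k:04d}", "hypothetical protein", carriers)

    single_seqs: dict[str, str] = {}
    if config.with_sequences:
        for slot in sorted(singles):
            fid = singles[slot][0]
            single_seqs[fid] = _random_orf(rng, gene_len(), config.core_gc)
        for slot in sorted(elements):
            for fid, ann, _ in elements[slot]:
                if fid not in single_seqs:
                    single_seqs[fid] = _random_orf(rng, gene_len(), 0.5)

    # --- assemble per-genome ordered gene lists ---------------------------
    spec_by_locus: dict[int, list[int]] = {}
    for i, spec in enumerate(specs):
        spec_by_locus.setdefault(spec.locus, []).append(i)

    genomes: GenomeDict = {}
    for g in gids:
        records: list[GeneRecord] = []

        def add(fid: str, ann: str = "", nt: str | None = None,
                aa: str | None = None, strand: str = "+") -> None:
            records.append(
                GeneRecord(
                    genome_id=g, contig_id="c0", index=len(records), strand=strand,
                    family_id=fid, nt_seq=nt, aa_seq=aa, annotation=ann,
                )
            )

        for ci, core_fid in enumerate(core_ids):
            nt = core_seqs[core_fid][g] if config.with_sequences else None
            add(core_fid, "hypothetical protein", nt)
            slot = ci
            if slot > config.n_core - 2:
                continue
            for i in spec_by_locus.get(slot, []):
                spec = specs[i]
                if g not in spec.carriers:
                    continue
                members = island_fams[i]["members"]
                seqs = island_fams[i]["seqs"]
                order = list(range(len(members)))
                strand = "+"
                if g in spec.reversed_in:
                    order = order[::-1]
                    strand = "-"
                for j in order:
                    fid = members[j]
                    nt, aa = seqs.get(fid, (None, None))
                    if nt is not None and not spec.identical_across_carriers:
                        # per-carrier divergence so island trees are buildable
                        nt = mutate_to_identity(
                            nt, 0.99, "nt",
                            seed=config.seed * 4096 + zlib.crc32(f"{g}:{fid}".encode()) % 4096,
                        )
                    if nt is not None and strand == "-":
                        nt = str(Seq(nt).reverse_complement())
                    ann = (
                        spec.annotations[j]
                        if j < len(spec.annotations)
                        else "hypothetical protein"
                    )
                    add(fid, ann, nt, aa, strand)
            for fid, ann, carriers in elements.get(slot, []):
                if g in carriers:
                    add(fid, ann, single_seqs.get(fid))
            if slot in singles:
                fid, ann, carriers = singles[slot]
                if g in carriers:
                    add(fid, ann, single_seqs.get(fid))
        contigs = {"c0": records}
        if config.fragmentation > 0:
            contigs = _fragment(records, config.fragmentation, rng, specs, core_ids)
        genomes[g] = contigs

    truth = SynthTruth(islands=planted, pairs=pairs, populations=populations)
    return genomes, truth


def _fragment(
    records: list[GeneRecord],
    n_breaks: int,
    rng: np.random.Generator,
    specs: list[IslandSpec],
    core_ids: list[str],
) -> dict[str, list[GeneRecord]]:
    """Split the single contig at core-core junctions away from islands."""
    core_set = set(core_ids)
    flank_cores = set()
    for spec in specs:
        for off in range(-1, 3):
            idx = spec.locus + off
            if 0 <= idx < len(core_ids):
                flank_cores.add(core_ids[idx])
    candidates = [
        k
        for k in range(1, len(records))
        if records[k - 1].family_id in core_set
        and records[k].family_id in core_set
        and records[k - 1].family_id not in flank_cores
        and records[k].family_id not in flank_cores
    ]
    if not candidates:
        return {"c0": records}
    breaks = sorted(
        rng.choice(candidates, size=min(n_breaks, len(candidates)), replace=False)
    )
    contigs: dict[str, list[GeneRecord]] = {}
    start = 0
    for ci, brk in enumerate(list(breaks) + [len(records)]):
        part = records[start:brk]
        cid = f"c{ci}"
        for k, rec in enumerate(part):
            rec.contig_id = cid
            rec.index = k
        contigs[cid] = part
        start = brk
    return contigs


# ---------------------------------------------------------------------------
# sequence lookup and file I/O
# ---------------------------------------------------------------------------


def family_sequences(genomes: GenomeDict) -> dict[str, tuple[str | None, str | None]]:
    """Representative (nt, aa) per family: first occurrence in sorted genome
    order, forward-strand normalized."""
    out: dict[str, tuple[str | None, str | None]] = {}
    for g in sorted(genomes):
        for cid in sorted(genomes[g]):
            for rec in genomes[g][cid]:
                if rec.family_id in out:
                    continue
                nt = rec.nt_seq
                if nt is not None and rec.strand == "-":
                    nt = str(Seq(nt).reverse_complement())
                out[rec.family_id] = (nt, rec.aa_seq)
    return out


def genome_sequence(contig: list[GeneRecord]) -> str:
    return "".join(r.nt_seq or "" for r in contig)


def write_genomes(genomes: GenomeDict, outdir: str) -> None:
    """One FASTA + one GFF3 per genome; genes abut on the contig sequence."""
    os.makedirs(outdir, exist_ok=True)
    for g in sorted(genomes):
        with open(os.path.join(outdir, f"{g}.fasta"), "w") as fa, open(
            os.path.join(outdir, f"{g}.gff3"), "w"
        ) as gff:
            gff.write("##gff-version 3\n")
            for cid in sorted(genomes[g]):
                contig = genomes[g][cid]
                seq = genome_sequence(contig)
                fa.write(f">{cid}\n")
                for k in range(0, len(seq), 80):
                    fa.write(seq[k : k + 80] + "\n")
                pos = 1
                for rec in contig:
                    ln = len(rec.nt_seq or "")
                    ftype = "tRNA" if rec.annotation.startswith("tRNA") else "CDS"
                    attrs = (
                        f"ID={g}_{cid}_{rec.index:05d};"
                        f"locus_tag={g}_{rec.index:05d};"
                        f"product={rec.annotation};family={rec.family_id}"
                    )
                    gff.write(
                        f"{cid}\tpanisles\t{ftype}\t{pos}\t{pos + ln - 1}\t.\t"
                        f"{rec.strand}\t0\t{attrs}\n"
                    )
                    pos += ln


def read_genomes(indir: str) -> GenomeDict:
    """Re-read genomes written by :func:`write_genomes` (FASTA + GFF3 with a
    ``family`` attribute)."""
    from Bio import SeqIO

    genomes: GenomeDict = {}
    for fname in sorted(os.listdir(indir)):
        if not fname.endswith(".fasta"):
            continue
        g = fname[: -len(".fasta")]
        contigs_seq = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(os.path.join(indir, fname), "fasta")
        }
        contigs: dict[str, list[GeneRecord]] = {}
        with open(os.path.join(indir, f"{g}.gff3")) as gff:
            for line in gff:
                if line.startswith("#") or not line.strip():
                    continue
                cid, _src, _type, start, end, _score, strand, _frame, attrs = (
                    line.rstrip("\n").split("\t")
                )
                fields = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                nt = contigs_seq[cid][int(start) - 1 : int(end)]
                contig = contigs.setdefault(cid, [])
                contig.append(
                    GeneRecord(
                        genome_id=g,
                        contig_id=cid,
                        index=len(contig),
                        strand=strand,
                        family_id=fields.get("family"),
                        nt_seq=nt,
                        annotation=fields.get("product", ""),
                    )
                )
        genomes[g] = contigs
    return genomes


def write_truth(truth: SynthTruth, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "truth_islands.tsv"), "w") as fh:
        fh.write("index\tlocus\tflank_left\tflank_right\tmembers\tcarriers\tgc_target\n")
        for isl in truth.islands:
            fh.write(
                f"{isl.index}\t{isl.locus}\t{isl.flank_left}\t{isl.flank_right}\t"
                f"{','.join(isl.members)}\t{','.join(isl.carriers)}\t{isl.gc_target}\n"
            )
    with open(os.path.join(outdir, "truth_pairs.tsv"), "w") as fh:
        fh.write("a_index\tb_index\thomeoallele_map\texpected_class\n")
        for pr in truth.pairs:
            hm = ",".join(f"{k}:{v}" for k, v in sorted(pr.homeoallele_map.items()))
            fh.write(f"{pr.a_index}\t{pr.b_index}\t{hm}\t{pr.expected_class}\n")
    with open(os.path.join(outdir, "truth_populations.tsv"), "w") as fh:
        fh.write("genome\tclade\tsubclade\n")
        for g in sorted(truth.populations):
            cl, sub = truth.populations[g]
            fh.write(f"{g}\t{cl}\t{sub}\n")


def write_config(config: SynthConfig, path: str) -> None:
    """Flat key = value dump of the generator configuration."""
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            if f.name == "island_specs":
                continue
            fh.write(f"{f.name} = {getattr(config, f.name)!r}\n")
        specs = config.island_specs or []
        fh.write(f"n_island_specs = {len(specs)}\n")
        for i, spec in enumerate(specs):
            fh.write(f"island_{i} = {dataclasses.asdict(spec)!r}\n")
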