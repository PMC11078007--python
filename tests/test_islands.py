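"""Island discovery: scan correctness, neighborhood, G+C, identity flags."""

import numpy as np
import pytest
from Bio.Seq import Seq

from panisles.islands import (
    find_identical_islands,
    find_islands,
    gc_content,
    island_sequences,
    neighborhood_scan,
)
from panisles.pangraph import build_graph
from conftest import genomes_from_orders


def _backbone(n_genomes, core, extra=None):
    """Genome orders: every genome carries the core list; ``extra`` maps
    genome -> {position_after_core_index: [families]}."""
    extra = extra or {}
    orders = {}
    for i in range(n_genomes):
        gid = f"g{i:02d}"
        fams = []
        for ci, c in enumerate(core):
            fams.append(c)
            for fam in extra.get(gid, {}).get(ci, []):
                fams.append(fam)
        orders[gid] = fams
    return orders


class TestFindIslands:
    def test_simple_shared_island(self):
        core = ["A", "B", "C"]
        extra = {"g00": {0: ["x", "y"]}, "g01": {0: ["x", "y"]}}
        genomes = genomes_from_orders(_backbone(5, core, extra))
        pg = build_graph(genomes, core_threshold=5)
        islands, _ = find_islands(pg, genomes)
        assert len(islands) == 1
        isl = islands[0]
        assert isl.members == ("x", "y")
        assert {isl.flank_left, isl.flank_right} == {"A", "B"}
        assert isl.carriers == {"g00", "g01"}

    def test_length_one_rejected_at_lone_locus(self):
        core = ["A", "B", "C"]
        extra = {"g00": {0: ["x"]}, "g01": {0: ["x"]}}
        genomes = genomes_from_orders(_backbone(5, core, extra))
        pg = build_graph(genomes, core_threshold=5)
        islands, report = find_islands(pg, genomes)
        assert islands == []
        assert report.singleton_rejected == 1

    def test_length_one_kept_when_locus_shared(self):
        core = ["A", "B", "C"]
        extra = {
            "g00": {0: ["x"]},
            "g01": {0: ["p", "q"]},
            "g02": {0: ["p", "q"]},
        }
        genomes = genomes_from_orders(_backbone(6, core, extra))
        pg = build_graph(genomes, core_threshold=6)
        islands, _ = find_islands(pg, genomes)
        assert len(islands) == 2
        lengths = sorted(len(i.members) for i in islands)
        assert lengths == [1, 2]

    def test_contig_end_run_skipped(self):
        genomes = genomes_from_orders(
            {
                "g00": {"c0": ["x", "y", "B", "C", "D"]},
                "g01": {"c0": ["B", "C", "D"]},
                "g02": {"c0": ["B", "C", "D"]},
            }
        )
        pg = build_graph(genomes, core_threshold=3)
        islands, report = find_islands(pg, genomes)
        assert islands == []
        assert report.contig_end_runs == 1

    def test_conflicting_pair_at_one_locus(self):
        core = ["A", "B", "C"]
        extra = {
            "g00": {0: ["x", "y"]},
            "g01": {0: ["x", "y"]},
            "g02": {0: ["p", "q"]},
            "g03": {0: ["p", "q"]},
        }
        genomes = genomes_from_orders(_backbone(8, core, extra))
        pg = build_graph(genomes, core_threshold=8)
        islands, _ = find_islands(pg, genomes)
        assert len(islands) == 2
        assert {i.members for i in islands} == {("x", "y"), ("p", "q")}

    def test_subset_occurrence_becomes_partial_carrier(self):
        core = ["A", "B", "C"]
        extra = {
            "g00": {0: ["x", "y", "z"]},
            "g01": {0: ["x", "y", "z"]},
            "g02": {0: ["x", "y"]},
        }
        genomes = genomes_from_orders(_backbone(6, core, extra))
        pg = build_graph(genomes, core_threshold=6)
        islands, _ = find_islands(pg, genomes)
        assert len(islands) == 1
        isl = islands[0]
        assert isl.members == ("x", "y", "z")
        assert "g02" in isl.carriers and isl.partial_carriers == {"g02"}

    def test_reverse_ordered_occurrence_merges(self):
        core = ["A", "B", "C"]
        extra = {"g00": {0: ["x", "y", "z"]}, "g01": {0: ["z", "y", "x"]}}
        genomes = genomes_from_orders(_backbone(5, core, extra))
        pg = build_graph(genomes, core_threshold=5)
        islands, _ = find_islands(pg, genomes)
        assert len(islands) == 1
        assert islands[0].carriers == {"g00", "g01"}

    def test_overcrowded_locus_discarded(self):
        core = ["A", "B", "C"]
        extra = {
            f"g{k:02d}": {0: [f"u{k}", f"v{k}"]} for k in range(4)
        }
        genomes = genomes_from_orders(_backbone(8, core, extra))
        pg = build_graph(genomes, core_threshold=8)
        islands, report = find_islands(pg, genomes, max_variants_per_locus=3)
        assert islands == []
        assert len(report.discarded_loci) == 1
        assert report.discarded_loci[0][1] == 4

    def test_flanks_are_core_members_are_not(self, small_pangenome):
        _, genomes, _ = small_pangenome
        pg = build_graph(genomes)
        islands, _ = find_islands(pg, genomes)
        assert islands
        for isl in islands:
            assert pg.is_core(isl.flank_left) and pg.is_core(isl.flank_right)
            assert all(not pg.is_core(m) for m in isl.members)


def _oracle_runs(orders: dict[str, list[str]], core: set[str], max_len: int = 40):
    """Brute-force scan oracle: maximal core-bounded non-core runs."""
    found = set()
    for gid, fams in orders.items():
        for i, fam in enumerate(fams):
            if fam in core:
                continue
            # extend the run containing position i
            s = i
            while s > 0 and fams[s - 1] not in core:
                s -= 1
            e = i
            while e < len(fams) - 1 and fams[e + 1] not in core:
                e += 1
            if s == 0 or e == len(fams) - 1:
                continue
            run = tuple(fams[s : e + 1])
            if len(run) <= max_len:
                flanks = tuple(sorted((fams[s - 1], fams[e + 1])))
                found.add((gid, flanks, frozenset(run)))
    return found


def test_scan_equivalence_against_bruteforce_oracle():
    """On random pan-genomes with single-variant loci, discovered islands
    equal the oracle's maximal non-core runs (length >= 2)."""
    rng = np.random.default_rng(2024)
    for _ in range(15):
        n_core = int(rng.integers(5, 12))
        core = [f"C{i}" for i in range(n_core)]
        n_genomes = int(rng.integers(4, 8))
        # per locus, one fixed accessory cassette carried by a random subset
        extra = {}
        cassettes = {}
        for ci in range(n_core - 1):
            if rng.random() < 0.4:
                size = int(rng.integers(2, 5))
                cassettes[ci] = [f"L{ci}_{j}" for j in range(size)]
        for g in range(n_genomes):
            gid = f"g{g:02d}"
            extra[gid] = {}
            for ci, cas in cassettes.items():
                if rng.random() < 0.5:
                    extra[gid][ci] = cas
        orders = _backbone(n_genomes, core, extra)
        genomes = genomes_from_orders(orders)
        pg = build_graph(genomes, core_threshold=n_genomes)
        islands, _ = find_islands(pg, genomes)
        got = {
            (g, tuple(sorted((i.flank_left, i.flank_right))), frozenset(i.members))
            for i in islands
            for g in i.carriers
        }
        # independent core call: a family is core iff every genome has it
        representation: dict[str, set] = {}
        for g, fams in orders.items():
            for fam in fams:
                representation.setdefault(fam, set()).add(g)
        oracle_core = {f for f, gs in representation.items() if len(gs) == n_genomes}
        expected = _oracle_runs(orders, oracle_core)
        expected = {t for t in expected if len(t[2]) >= 2}
        assert got == expected


class TestNeighborhoodScan:
    def _setup(self, ann_offset, radius=5):
        core = [f"C{i}" for i in range(8)]
        extra = {"g00": {3: ["x", "y"]}, "g01": {3: ["x", "y"]}}
        orders = _backbone(4, core, extra)
        genomes = genomes_from_orders(orders)
        pg = build_graph(genomes, core_threshold=4)
        islands, _ = find_islands(pg, genomes)
        (isl,) = islands
        occ = isl.occurrences["g00"]
        contig = genomes["g00"]["c0"]
        if ann_offset < 0:
            contig[(occ.start - 1) + ann_offset].annotation = "IS66 transposase"
            contig[(occ.start - 1) + ann_offset - 2].annotation = ""  # noop guard
        else:
            contig[occ.end + ann_offset].annotation = "IS66 transposase"
        return isl, genomes, radius

    def test_upstream_transposase_flagged_with_offset(self):
        isl, genomes, radius = self._setup(-3)
        flags = neighborhood_scan(isl, genomes, radius=radius)
        assert ("transposase", -3) in [(l, o) for l, o, _ in flags["g00"]]

    def test_element_beyond_radius_not_flagged(self):
        isl, genomes, _ = self._setup(-3)
        flags = neighborhood_scan(isl, genomes, radius=2)
        assert flags["g00"] == []

    def test_island_internal_trna_family_excluded(self):
        core = [f"C{i}" for i in range(8)]
        extra = {
            "g00": {3: ["x", "trnX"], 4: ["trnX"]},
            "g01": {3: ["x", "trnX"], 4: ["trnX"]},
        }
        orders = _backbone(4, core, extra)
        ann = {"trnX": "tRNA-Ala"}
        genomes = genomes_from_orders(orders, annotations=ann)
        pg = build_graph(genomes, core_threshold=4)
        islands, _ = find_islands(pg, genomes)
        isl = next(i for i in islands if "x" in i.members)
        flags = neighborhood_scan(isl, genomes, radius=5)
        # the trnX copy one slot downstream shares the island's family: excluded
        assert all(lbl != "tRNA" for lbl, _, _ in flags["g00"])


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("AATT", 0.0), ("GCATN", 0.5), ("GCGCATAT", 0.5)],
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_and_all_n_signalled(self):
        with pytest.raises(ValueError):
            gc_content("")
        with pytest.raises(ValueError):
            gc_content("NNNN")

    def test_planted_island_gc_recovered(self, small_pangenome):
        cfg, genomes, truth = small_pangenome
        pg = build_graph(genomes)
        islands, _ = find_islands(pg, genomes)
        island_sequences(islands, genomes)
        for t in truth.islands:
            match = [i for i in islands if set(i.members) == set(t.members)]
            assert len(match) == 1
            seq_len = sum(len(s) for s in match[0].per_carrier_seq.values())
            if seq_len >= 2000:
                assert match[0].gc == pytest.approx(t.gc_target, abs=0.03)


class TestIdenticalIslands:
    def test_identical_and_mutated_flags(self, small_pangenome):
        _, genomes, _ = small_pangenome
        pg = build_graph(genomes)
        islands, _ = find_islands(pg, genomes)
        island_sequences(islands, genomes)
        flags = find_identical_islands(islands)
        # generator default: identical across carriers
        assert all(v is True for v in flags.values())

    def test_single_substitution_breaks_flag(self, small_pangenome):
        _, genomes, _ = small_pangenome
        pg = build_graph(genomes)
        islands, _ = find_islands(pg, genomes)
        island_sequences(islands, genomes)
        isl = islands[0]
        carrier = sorted(isl.per_carrier_seq)[0]
        s = isl.per_carrier_seq[carrier]
        isl.per_carrier_seq[carrier] = ("A" if s[0] != "A" else "C") + s[1:]
        find_identical_islands(islands)
        assert isl.identical_flag is False

    def test_reverse_complement_occurrence_normalized(self):
        from panisles import synthetic as sy

        gids = [f"G{i:02d}" for i in range(6)]
        spec = sy.IslandSpec(
            locus=3, n_genes=3, carriers=tuple(gids[0:3]), reversed_in=(gids[2],)
        )
        cfg = sy.SynthConfig(
            n_genomes=6, n_core=10, n_shell=0, n_cloud=0,
            island_specs=[spec], seed=5, gene_len_range=(300, 450),
        )
        genomes, _ = sy.generate(cfg)
        pg = build_graph(genomes)
        islands, _ = find_islands(pg, genomes)
        (isl,) = islands
        island_sequences(islands, genomes)
        # oracle: the reversed carrier's raw contig sequence is the exact
        # reverse complement of a forward carrier's
        occ_f = isl.occurrences[gids[0]]
        occ_r = isl.occurrences[gids[2]]
        raw_f = "".join(
            r.nt_seq for r in genomes[gids[0]]["c0"][occ_f.start : occ_f.end]
        )
        raw_r = "".join(
            r.nt_seq for r in genomes[gids[2]]["c0"][occ_r.start : occ_r.end]
        )
        assert raw_r == str(Seq(raw_f).reverse_complement())
        flags = find_identical_islands(islands)
        assert flags[isl.island_id] is True
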