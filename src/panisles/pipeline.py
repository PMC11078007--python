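"""End-to-end orchestration: inputs -> graph -> islands -> pairs, plus the
tANI, population-structure, and DTL side analyses, with a reproducible run
manifest.

All stage randomness derives from the single top-level seed; re-running
with an identical config and inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import sys
import time
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import dtl as dtl_mod
from . import homeocassette as hc
from . import islands as isl_mod
from . import pangraph as pg_mod
from . import popgen as popgen_mod
from . import synthetic as synth_mod
from . import tani as tani_mod

__all__ = ["PipelineConfig", "run_pipeline", "write_reports", "StageFailure"]


class StageFailure(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | fasta+gff | panaroo
    outdir: str = "panisles_out"
    seed: int = 0
    # inputs for non-synthetic modes
    input_dir: str | None = None
    panaroo_csv: str | None = None
    panaroo_gml: str | None = None
    # synthetic-mode generator configuration (desk-scale demo default)
    synth: synth_mod.SynthConfig | None = None
    # stage toggles
    run_graph: bool = True
    run_islands: bool = True
    run_pairs: bool = True
    run_tani: bool = True
    run_popgen: bool = True
    run_dtl: bool = True
    # stage parameters
    core_threshold: int | None = None
    identity_threshold: float = 0.98
    min_len: int = 2
    max_len: int = 40
    max_variants_per_locus: int = 3
    radius: int = 5
    alpha: float = 0.01
    n_shuffles: int = 200
    fragment_len: int = 1020
    n_boot: int = 100
    dtl_costs: tuple[tuple[float, float, float], ...] = ((2, 3, 1), (3, 3, 1), (2, 4, 1))
    dtl_samples: int = 300
    n_core_trees: int = 30
    levels: int = 2

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
            .generate_state(1)[0]
            % 2**31
        )


def _demo_synth_config(seed: int) -> synth_mod.SynthConfig:
    """Desk-scale demo pan-genome: 12 genomes, 150 core families, the
    default island structure scaled down."""
    gids = [f"G{i:02d}" for i in range(12)]
    specs = [
        synth_mod.IslandSpec(locus=20, n_genes=3, carriers=tuple(gids[1:5]),
                             flank_elements={"transposase": -2},
                             identical_across_carriers=False),
        synth_mod.IslandSpec(locus=50, n_genes=5, carriers=tuple(gids[5:9]),
                             flank_elements={"tRNA": 1},
                             identical_across_carriers=False),
        synth_mod.IslandSpec(locus=80, n_genes=4, carriers=tuple(gids[0:3]),
                             gc_target=0.50),
        synth_mod.IslandSpec(locus=80, n_genes=4, carriers=tuple(gids[6:10]),
                             gc_target=0.50, partner_of=2,
                             homeoallele_fraction=0.75, target_identity=0.5),
    ]
    return synth_mod.SynthConfig(
        n_genomes=12, n_core=150, n_shell=40, n_cloud=20,
        gene_len_range=(300, 600), island_specs=specs, seed=seed,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(logfile, message: str) -> None:
    logfile.write(message + "\n")
    print(message, file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages in dependency order and write the run manifest.

    Stage wall times go to stderr only, so the written outputs (manifest
    included) are byte-reproducible for a fixed config and seed.
    """
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {"mode": config.mode, "seed": config.seed, "stages": {}}
    failed = False

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    with open(out("run.log"), "w") as logfile:
        t_start = time.monotonic()

        # ------------------------------------------------------ input stage
        genomes = None
        truth = None
        graph = None
        try:
            if config.mode == "synthetic":
                synth = config.synth or _demo_synth_config(config.seed)
                synth = dataclasses.replace(synth, seed=config.stage_seed("synthetic"))
                genomes, truth = synth_mod.generate(synth)
                gdir = out("genomes")
                synth_mod.write_genomes(genomes, gdir)
                synth_mod.write_truth(truth, config.outdir)
                synth_mod.write_config(synth, out("synth_config.txt"))
                manifest["stages"]["input"] = {
                    "status": "ok",
                    "n_genomes": len(genomes),
                    "n_planted_islands": len(truth.islands),
                    "n_planted_pairs": len(truth.pairs),
                }
                _log(logfile, f"input: generated {len(genomes)} synthetic genomes")
            elif config.mode == "fasta+gff":
                if not config.input_dir or not os.path.isdir(config.input_dir):
                    raise StageFailure(
                        f"input directory not found: {config.input_dir!r}"
                    )
                genomes = synth_mod.read_genomes(config.input_dir)
                hashes = {
                    f: _sha256(os.path.join(config.input_dir, f))
                    for f in sorted(os.listdir(config.input_dir))
                }
                manifest["stages"]["input"] = {
                    "status": "ok", "n_genomes": len(genomes), "input_hashes": hashes,
                }
                _log(logfile, f"input: read {len(genomes)} genomes")
            elif config.mode == "panaroo":
                if not config.panaroo_gml or not os.path.exists(config.panaroo_gml):
                    raise StageFailure(
                        f"Panaroo graph file not found: {config.panaroo_gml!r}"
                    )
                pa = pg_mod.read_panaroo_presence_absence(config.panaroo_csv) \
                    if config.panaroo_csv and os.path.exists(config.panaroo_csv) else None
                n_genomes = pa.shape[1] if pa is not None else 0
                graph = pg_mod.read_panaroo_gml(
                    config.panaroo_gml, n_genomes=n_genomes,
                    core_threshold=config.core_threshold,
                )
                manifest["stages"]["input"] = {
                    "status": "ok",
                    "n_families": len(graph.families),
                    "input_hashes": {config.panaroo_gml: _sha256(config.panaroo_gml)},
                }
                _log(logfile, f"input: imported Panaroo graph "
                              f"({len(graph.families)} families)")
            else:
                raise StageFailure(f"unknown mode {config.mode!r}")
        except (StageFailure, ValueError) as exc:
            manifest["stages"]["input"] = {"status": "failed", "error": str(exc)}
            failed = True

        # ------------------------------------------------------ graph stage
        if not failed and config.run_graph and genomes is not None:
            needs_clustering = any(
                rec.family_id is None
                for contigs in genomes.values()
                for contig in contigs.values()
                for rec in contig
            )
            if needs_clustering:
                all_genes = [
                    rec
                    for contigs in genomes.values()
                    for contig in contigs.values()
                    for rec in contig
                ]
                assignment = pg_mod.cluster_families(all_genes, config.identity_threshold)
                for rec in all_genes:
                    rec.family_id = assignment[rec.key()]
            graph = pg_mod.build_graph(genomes, core_threshold=config.core_threshold)
            pg_mod.write_family_table(graph, out("families.tsv"))
            pg_mod.write_gml(graph, out("pangraph.gml"))
            manifest["stages"]["graph"] = {
                "status": "ok",
                "n_families": len(graph.families),
                "n_edges": graph.graph.number_of_edges(),
                "divisions": graph.division_counts(),
            }
            _log(logfile, f"graph: {len(graph.families)} families, "
                          f"{graph.graph.number_of_edges()} edges")

        # ---------------------------------------------------- islands stage
        islands = None
        if (
            not failed and config.run_islands and graph is not None
            and genomes is not None
        ):
            islands, report = isl_mod.find_islands(
                graph, genomes,
                min_len=config.min_len, max_len=config.max_len,
                max_variants_per_locus=config.max_variants_per_locus,
            )
            isl_mod.island_sequences(islands, genomes)
            for island in islands:
                isl_mod.neighborhood_scan(island, genomes, radius=config.radius)
            isl_mod.find_identical_islands(islands)
            isl_mod.write_island_table(islands, out("islands.tsv"))
            isl_mod.write_presence_absence(islands, genomes, out("island_presence.tsv"))
            with open(out("discarded_loci.tsv"), "w") as fh:
                fh.write("flank_left\tflank_right\tn_variants\n")
                for (fl, fr), n in report.discarded_loci:
                    fh.write(f"{fl}\t{fr}\t{n}\n")
            manifest["stages"]["islands"] = {
                "status": "ok",
                "n_islands": len(islands),
                "contig_end_runs": report.contig_end_runs,
                "singleton_rejected": report.singleton_rejected,
                "discarded_loci": len(report.discarded_loci),
            }
            if truth is not None:
                planted = {
                    (isl.flank_left, isl.flank_right, isl.members)
                    for isl in truth.islands
                }
                recovered = sum(
                    1 for t in truth.islands
                    if any(
                        set(t.members) == set(i.members)
                        and {i.flank_left, i.flank_right} == {t.flank_left, t.flank_right}
                        and set(t.carriers) <= i.carriers
                        for i in islands
                    )
                )
                manifest["stages"]["islands"]["planted_recovered"] = (
                    f"{recovered}/{len(truth.islands)}"
                )
            _log(logfile, f"islands: {len(islands)} islands")

        # ------------------------------------------------------ pairs stage
        pairs = None
        if not failed and config.run_pairs and islands is not None:
            sequences = synth_mod.family_sequences(genomes)
            sequences = {
                fid: (nt, aa if aa else (_translate_safe(nt) if nt else None))
                for fid, (nt, aa) in sequences.items()
            }
            pairs = hc.find_conflicting_pairs(islands)
            for pair in pairs:
                hc.homology_search(
                    pair, sequences, alpha=config.alpha,
                    n_shuffles=config.n_shuffles,
                    seed=config.stage_seed("pairs"),
                )
                hc.classify_pair(pair)
            hc.write_pair_report(pairs, out("pair_report.tsv"))
            hc.write_homeoallele_map(pairs, out("homeoalleles.tsv"))
            write_reports(islands, pairs, config.outdir)
            manifest["stages"]["pairs"] = {
                "status": "ok",
                "n_pairs": len(pairs),
                "n_homeocassettes": sum(
                    1 for p in pairs if p.classification == "homeocassette"
                ),
            }
            _log(logfile, f"pairs: {len(pairs)} conflicting pairs")

        # ------------------------------------------------------- tANI stage
        tree = None
        if not failed and config.run_tani and genomes is not None:
            seqs = {
                g: "".join(
                    synth_mod.genome_sequence(genomes[g][c]) for c in sorted(genomes[g])
                )
                for g in sorted(genomes)
            }
            seqs = {g: s for g, s in seqs.items() if s}
            if len(seqs) >= 3:
                tables = tani_mod.fragment_tables(
                    seqs, fragment_len=config.fragment_len
                )
                dm, _results = tani_mod.distance_matrix(
                    seqs, fragment_len=config.fragment_len, tables=tables
                )
                tani_mod.write_distance_matrix(dm, out("tani_matrix.tsv"))
                tree, supports = tani_mod.bootstrap_supports(
                    seqs, n_reps=config.n_boot,
                    seed=config.stage_seed("tani"),
                    fragment_len=config.fragment_len,
                    tables=tables,
                )
                tree.write(out("tani_tree.nwk"))
                manifest["stages"]["tani"] = {
                    "status": "ok", "n_genomes": len(seqs),
                    "n_bipartitions": len(supports),
                }
                _log(logfile, f"tani: matrix + tree for {len(seqs)} genomes")
            else:
                manifest["stages"]["tani"] = {
                    "status": "skipped", "reason": "need >=3 genomes with sequence",
                }

        # ----------------------------------------------------- popgen stage
        if not failed and config.run_popgen and graph is not None and genomes is not None:
            alignments = _core_alignments(graph, genomes)
            results = []
            neutral = {}
            for fam in sorted(alignments):
                try:
                    res = popgen_mod.tajimas_d(alignments[fam], family_id=fam)
                except ValueError:
                    continue
                results.append(res)
                if res.neutral:
                    neutral[fam] = alignments[fam]
            popgen_mod.write_tajima_table(results, out("tajima.tsv"))
            if neutral:
                snp = popgen_mod.build_snp_matrix(neutral, genomes=sorted(genomes))
                snp.to_csv(out("snp_matrix.tsv"), sep="\t")
                assignment = popgen_mod.cluster_populations(
                    snp, max_levels=config.levels,
                    seed=config.stage_seed("popgen"),
                )
                popgen_mod.write_population_table(assignment, out("populations.tsv"))
                manifest["stages"]["popgen"] = {
                    "status": "ok",
                    "n_core_tested": len(results),
                    "n_neutral": len(neutral),
                    "n_snp_sites": int(snp.shape[1]),
                }
            else:
                manifest["stages"]["popgen"] = {
                    "status": "ok", "n_core_tested": len(results),
                    "n_neutral": 0, "n_snp_sites": 0,
                }
            _log(logfile, f"popgen: {len(neutral)} neutral core families")

        # -------------------------------------------------------- DTL stage
        if not failed and config.run_dtl and graph is not None and tree is not None:
            dtl_rows, island_rates, core_rates = _dtl_stage(
                config, graph, genomes, islands or [], tree
            )
            dtl_mod.write_dtl_table(dtl_rows, out("dtl_events.tsv"))
            comparison: dict = {}
            try:
                comparison = dtl_mod.compare_island_vs_core(island_rates, core_rates)
            except ValueError as exc:
                comparison = {"error": str(exc)}
            with open(out("dtl_comparison.tsv"), "w") as fh:
                fh.write("event_class\tp_value\n")
                for cls in sorted(comparison):
                    fh.write(f"{cls}\t{comparison[cls]}\n")
            manifest["stages"]["dtl"] = {
                "status": "ok",
                "n_gene_trees": len({r["gene"] for r in dtl_rows}),
                "n_island_trees": len(island_rates["transfer"]),
                "n_core_trees": len(core_rates["transfer"]),
            }
            _log(logfile, f"dtl: {len(dtl_rows)} reconciliations")

        _log(logfile, f"done (failed={failed})")
        print(f"total wall time: {time.monotonic() - t_start:.1f}s", file=sys.stderr)

    manifest["failed"] = failed
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _translate_safe(nt: str) -> str | None:
    try:
        return synth_mod._translate(nt)
    except Exception:
        return None


def _core_alignments(graph, genomes) -> dict[str, dict[str, str]]:
    """Per-core-family per-genome sequences; only families whose copies are
    equal length (pre-aligned or indel-free) are usable as alignments."""
    out: dict[str, dict[str, str]] = {}
    for fid, fam in graph.families.items():
        if fam.division != pg_mod.CORE:
            continue
        per_genome: dict[str, str] = {}
        for rec in fam.members:
            if rec.nt_seq and rec.genome_id not in per_genome:
                per_genome[rec.genome_id] = rec.nt_seq
        if len(per_genome) < 4:
            continue
        lengths = {len(s) for s in per_genome.values()}
        if len(lengths) != 1:
            continue
        out[fid] = per_genome
    return out


def _dtl_stage(config, graph, genomes, islands, species_tree):
    """Reconcile core-gene and island trees against the species tree."""
    sp_rooted = species_tree.copy()
    sp_rooted = sp_rooted.root_at_midpoint()
    species = dtl_mod.clade_from_skbio(sp_rooted)
    _binarize(species)
    alignments = _core_alignments(graph, genomes)
    core_fams = sorted(alignments)[: config.n_core_trees]
    rows = []
    island_rates: dict[str, list[float]] = {"duplication": [], "transfer": [], "loss": []}
    core_rates: dict[str, list[float]] = {"duplication": [], "transfer": [], "loss": []}
    headline = config.dtl_costs[0]
    jobs = [("core:" + f, alignments[f], core_rates) for f in core_fams]
    for isl in islands:
        aln = _island_alignment(isl)
        if aln is not None:
            jobs.append((f"island:{isl.island_id}", aln, island_rates))
    seed = config.stage_seed("dtl")
    for name, aln, bucket in jobs:
        try:
            gtree = dtl_mod.infer_gene_tree(aln)
        except ValueError:
            continue
        for scheme in config.dtl_costs:
            costs = dtl_mod.DtlCosts(*scheme)
            rooted, _cost = dtl_mod.optimal_root(gtree, species, costs)
            result = dtl_mod.dtl_reconcile(
                rooted, species, costs,
                n_samples=config.dtl_samples, seed=seed,
            )
            try:
                rates = dtl_mod.normalize_events(result, rooted)
            except ValueError:
                continue
            rows.append(
                {
                    "gene": name,
                    "scheme": f"({scheme[0]:g},{scheme[1]:g},{scheme[2]:g})",
                    "min_cost": result.min_cost,
                    "D": result.mean_d,
                    "T": result.mean_t,
                    "L": result.mean_l,
                    "rate_duplication": rates["duplication"],
                    "rate_transfer": rates["transfer"],
                    "rate_loss": rates["loss"],
                }
            )
            if scheme == headline:
                for cls in bucket:
                    bucket[cls].append(rates[cls])
    return rows, island_rates, core_rates


def _island_alignment(isl) -> dict[str, str] | None:
    """Concatenated island sequence per full carrier (the 'island tree'
    alignment); usable when >=3 carriers share the full equal-length set."""
    seqs = {
        c: s for c, s in isl.per_carrier_seq.items()
        if c not in isl.partial_carriers
    }
    lengths = {len(s) for s in seqs.values()}
    if len(seqs) < 3 or len(lengths) != 1:
        return None
    if len(set(seqs.values())) == 1:
        return None
    return seqs


def _binarize(clade: dtl_mod.Clade) -> None:
    """Resolve any polytomy deterministically (left-ladderized)."""
    for node in clade.postorder():
        while len(node.children) > 2:
            a = node.children.pop()
            b = node.children.pop()
            node.children.append(dtl_mod.Clade(children=[b, a], length=0.0))


def write_reports(islands, pairs, outdir: str) -> None:
    """Island-pair summary mirroring the published table layout: invaded
    core genes, 'n vs m' ORF counts, homeoallele count, average G+C."""
    path = os.path.join(outdir, "pair_summary.tsv")
    with open(path, "w") as fh:
        fh.write(
            "pair_id\tinvaded_core_genes\torfs_encoded\tn_homeoalleles\t"
            "avg_gc\tclassification\texclusivity_violations\n"
        )
        for p in pairs:
            gcs = [g for g in (p.island_a.gc, p.island_b.gc) if g is not None]
            avg_gc = f"{sum(gcs) / len(gcs):.3f}" if gcs else ""
            fh.write(
                f"{p.pair_id}\t"
                f"{p.island_a.flank_left},{p.island_a.flank_right}\t"
                f"{len(p.island_a.members)} vs {len(p.island_b.members)}\t"
                f"{len(p.homeoalleles)}\t{avg_gc}\t{p.classification or ''}\t"
                f"{','.join(sorted(p.exclusivity_violations))}\n"
            )
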