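import pytest

from panisles.pangraph import GeneRecord


def genomes_from_orders(orders: dict[str, list[str]], annotations: dict[str, str] | None = None):
    """Build the genomes dict from per-genome family-id order lists.

    ``orders`` may also map to a dict of contigs.  Annotations (by family)
    are optional; sequences are left unset.
    """
    annotations = annotations or {}
    genomes = {}
    for gid, val in orders.items():
        contigs = val if isinstance(val, dict) else {"c0": val}
        genomes[gid] = {
            cid: [
                GeneRecord(
                    genome_id=gid,
                    contig_id=cid,
                    index=i,
                    family_id=fam,
                    annotation=annotations.get(fam, ""),
                )
                for i, fam in enumerate(fams)
            ]
            for cid, fams in contigs.items()
        }
    return genomes


@pytest.fixture(scope="session")
def small_pangenome():
    """Compact synthetic pan-genome with sequences: 10 genomes, 40 core
    families, one plain island and one conflicting pair (fraction 0.6)."""
    from panisles import synthetic as sy

    gids = [f"G{i:02d}" for i in range(10)]
    specs = [
        sy.IslandSpec(
            locus=5, n_genes=3, carriers=tuple(gids[0:3]),
            flank_elements={"transposase": -2, "tRNA": 1},
        ),
        sy.IslandSpec(locus=20, n_genes=5, carriers=tuple(gids[0:3]), gc_target=0.5),
        sy.IslandSpec(
            locus=20, n_genes=5, carriers=tuple(gids[5:8]), gc_target=0.5,
            partner_of=1, homeoallele_fraction=0.6, target_identity=0.5,
        ),
    ]
    cfg = sy.SynthConfig(
        n_genomes=10, n_core=40, n_shell=6, n_cloud=4,
        gene_len_range=(300, 600), island_specs=specs, seed=11,
    )
    genomes, truth = sy.generate(cfg)
    return cfg, genomes, truth
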