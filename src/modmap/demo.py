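"""Self-contained demo inputs for the full pipeline.

Writes a small but complete input bundle — strain genotypes with an embedded
two-locus complementation trait, dose-response counts, a backcross cohort,
a functional network with a planted module containing the enhancer gene,
trait-term gene sets, gene coordinates and a TOML config — so the pipeline
can run end-to-end from one seed.  The planted enhancer gene is both the top
association signal and a member of the functional module, so it should rank
first by the combined gene score.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .datatypes import FunctionalNetwork, GeneSetCollection
from .simulate import (
    BackcrossSimConfig,
    NetworkSimConfig,
    PanelSimConfig,
    TwoLocusTraitModel,
    assign_trait_alleles,
    simulate_backcross,
    simulate_dose_response,
    simulate_network,
    simulate_strain_panel,
)

LOCUS = ("6", 50_000_000, 60_000_000)
ENHANCER_POS = 52_000_000
PRIMARY_POS = 55_100_000


def build_demo_inputs(
    outdir,
    seed: int = 0,
    n_groups: int = 5,
    strains_per_group: int = 6,
    n_snps: int = 400,
    penetrance: float = 0.9,
) -> Path:
    """Write all pipeline inputs plus ``config.toml`` into ``outdir``;
    returns the config path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    model = TwoLocusTraitModel(
        primary_locus_pos=PRIMARY_POS, enhancer_locus_pos=ENHANCER_POS, penetrance=penetrance
    )
    panel = simulate_strain_panel(
        PanelSimConfig(
            n_groups=n_groups,
            strains_per_group=strains_per_group,
            n_snps=n_snps,
            missing_rate_range=(0.0, 0.15),
            seed=int(rng.integers(2**31 - 1)),
        )
    )
    # all strains carry the resistant primary allele; the enhancer segregates
    # by group, so the enhancer locus is the sole association signal
    plan = {f"G{g}": ("r", "E" if g <= n_groups // 2 else "e") for g in range(1, n_groups + 1)}
    annotated = assign_trait_alleles(panel, model, plan)
    io.write_genotype_tsv(annotated.genotypes, out / "genotypes.tsv", seed=seed)

    doses = simulate_dose_response(
        annotated, [100.0, 50.0, 25.0], animals_per_dose=6, seed=int(rng.integers(2**31 - 1))
    )
    io.write_dose_response_tsv(doses, out / "phenotypes.tsv", seed=seed)

    bc = simulate_backcross(
        BackcrossSimConfig(seed=int(rng.integers(2**31 - 1))), model
    )
    io.write_backcross(bc, out / "backcross.tsv", out / "backcross_map.tsv", seed=seed)

    # gene models tiling the locus; one gene covers the enhancer position
    genes = []
    for i, start in enumerate(range(50_000_000, 60_000_000, 500_000)):
        gid = f"L{i + 1:02d}"
        if start <= ENHANCER_POS - 1 < start + 100_000:
            gid = "Enh1"
        genes.append((LOCUS[0], start, start + 100_000, gid))
    # make sure the enhancer gene exists even if tiling missed the position
    if not any(g[3] == "Enh1" for g in genes):
        genes.append((LOCUS[0], ENHANCER_POS - 50_000, ENHANCER_POS + 50_000, "Enh1"))
    with open(out / "genes.bed", "w") as fh:
        for chrom, start, end, gid in sorted(genes, key=lambda g: g[1]):
            fh.write(f"{chrom}\t{start}\t{end}\t{gid}\n")
    locus_gene_ids = [g[3] for g in genes]

    # functional network: planted module carries the enhancer gene plus
    # background genes; the remaining locus genes sit outside the module
    net_cfg = NetworkSimConfig(
        n_genes=220, module_sizes=(30,), within_weight_mean=0.8,
        between_weight_mean=0.1, seed=int(rng.integers(2**31 - 1)),
    )
    raw_net, raw_modules = simulate_network(net_cfg)
    new_ids = list(raw_net.gene_ids)
    new_ids[0] = "Enh1"  # first planted-module gene becomes the enhancer gene
    # remaining locus genes become background (non-module) genes
    others = [g for g in locus_gene_ids if g != "Enh1"]
    for j, gid in enumerate(others):
        new_ids[30 + j] = gid
    net = FunctionalNetwork(new_ids, raw_net.weights)
    io.write_network_tsv(net, out / "network.tsv", seed=seed)

    module_genes = ["Enh1"] + [new_ids[i] for i in range(1, 30)]
    sets = GeneSetCollection({"Cardiac": module_genes})
    with open(out / "sets.gmt", "w") as fh:
        fh.write("Cardiac\tdemo trait term\t" + "\t".join(sets["Cardiac"]) + "\n")

    config = out / "config.toml"
    config.write_text(
        "\n".join(
            [
                "[paths]",
                'genotypes = "genotypes.tsv"',
                'phenotypes = "phenotypes.tsv"',
                'backcross = "backcross.tsv"',
                'backcross_map = "backcross_map.tsv"',
                'network = "network.tsv"',
                'gene_sets = "sets.gmt"',
                'genes_bed = "genes.bed"',
                'outdir = "out"',
                "",
                "[params]",
                'reference_strain = "G%dS1"' % n_groups,
                'locus = "%s:%d-%d"' % LOCUS,
                "",
                "[seeds]",
                f"prioritize = {seed + 1}",
                "",
            ]
        )
    )
    return config
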