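"""End-to-end pipeline orchestration with a single TOML config.

Stage order: pheno-test -> linkage-scan (if a backcross is given) ->
impute -> assoc -> prioritize -> rank.  Each stage writes a TSV into the
output directory and records itself in a run manifest (config hash, stage
seeds, input digests); a stage whose output already exists is skipped, so
deleting one output and rerunning regenerates only it and its dependents
(every downstream stage re-reads its inputs from disk).
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .datatypes import GeneModel
from .impute import HmmParams, impute_panel
from .linkage import scan_markers
from .mixedmodel import AssociationResult, MixedModelAssociation
from .phenotype import susceptibility_screen
from .prioritize import FunctionalPrioritizer
from .ranking import assign_snps_to_genes, combined_score, gene_assoc_score

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]

REQUIRED_SEEDS = ("prioritize",)


@dataclass
class PipelineConfig:
    genotypes: Path
    phenotypes: Path
    network: Path
    gene_sets: Path
    genes_bed: Path
    outdir: Path
    reference_strain: str
    locus_chrom: str
    locus_start: int
    locus_end: int
    seeds: dict[str, int]
    backcross: Path | None = None
    backcross_map: Path | None = None
    hmm: HmmParams = HmmParams()
    susceptible_alpha: float = 0.05

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        try:
            paths = raw["paths"]
            params = raw["params"]
            seeds = {k: int(v) for k, v in raw["seeds"].items()}
        except KeyError as e:
            raise ValueError(f"config missing section {e}") from None
        for stage in REQUIRED_SEEDS:
            if stage not in seeds:
                raise ValueError(f"config missing seed for stage {stage!r}")
        chrom, span = params["locus"].split(":")
        start, end = (int(x) for x in span.split("-"))
        if not start < end:
            raise ValueError(f"malformed locus interval {params['locus']!r}")
        base = path.parent

        def p(key, optional=False):
            if optional and key not in paths:
                return None
            q = Path(paths[key])
            return q if q.is_absolute() else base / q

        hmm_raw = raw.get("hmm", {})
        return cls(
            genotypes=p("genotypes"),
            phenotypes=p("phenotypes"),
            network=p("network"),
            gene_sets=p("gene_sets"),
            genes_bed=p("genes_bed"),
            outdir=p("outdir"),
            backcross=p("backcross", optional=True),
            backcross_map=p("backcross_map", optional=True),
            reference_strain=params["reference_strain"],
            locus_chrom=chrom,
            locus_start=start,
            locus_end=end,
            seeds=seeds,
            hmm=HmmParams(
                epsilon=float(hmm_raw.get("epsilon", 0.01)),
                tau=float(hmm_raw.get("tau", 0.002)),
                k=int(hmm_raw.get("k", 8)),
            ),
            susceptible_alpha=float(params.get("susceptible_alpha", 0.05)),
        )

    def digest(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def run_all(config: PipelineConfig, resume: bool = True) -> dict[str, Path]:
    """Execute all stages; returns stage -> output path.  With ``resume``,
    stages whose outputs exist are skipped."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "modmap": __version__,
        "config_hash": config.digest(),
        "seeds": config.seeds,
        "stages": {},
    }
    artifacts: dict[str, Path] = {}

    def stage(name: str, output: Path, fn) -> Path:
        if resume and output.exists():
            logger.info("stage %s: output exists, skipping", name)
        else:
            try:
                fn(output)
            except Exception as e:
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
            manifest["stages"][name] = {"output": output.name, "digest": _file_digest(output)}
        artifacts[name] = output
        return output

    # 1. phenotype screen -----------------------------------------------------
    def pheno(dest: Path):
        table = io.read_dose_response_tsv(config.phenotypes)
        results = susceptibility_screen(table, config.reference_strain)
        df = pd.DataFrame(
            [
                {
                    "strain": r.strain,
                    "affected": r.affected,
                    "tested": r.tested,
                    "pct": r.percent_affected,
                    "p_raw": r.p_value,
                    "p_display": r.p_display,
                    "susceptible": int(r.p_value < config.susceptible_alpha),
                }
                for r in results
            ]
        )
        io.write_table(df, dest)

    pheno_out = stage("pheno-test", out / "phenotype_screen.tsv", pheno)

    # 2. optional backcross linkage scan --------------------------------------
    if config.backcross is not None:
        def link(dest: Path):
            cohort = io.read_backcross(config.backcross, config.backcross_map)
            rows = [
                {
                    "marker_id": r.marker_id,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "chi2": r.chi2,
                    "p": r.p_value,
                    "a_ho": r.a_ho,
                    "a_he": r.a_he,
                    "u_ho": r.u_ho,
                    "u_he": r.u_he,
                    "total": r.n_used,
                }
                for r in scan_markers(cohort)
            ]
            io.write_table(pd.DataFrame(rows), dest)

        stage("linkage-scan", out / "linkage_scan.tsv", link)

    # 3. imputation ------------------------------------------------------------
    def imp(dest: Path):
        gm = io.read_genotype_tsv(config.genotypes)
        imputed, summary = impute_panel(gm, config.hmm)
        io.write_genotype_tsv(imputed, dest)
        summary_path = dest.with_suffix(".summary.json")
        summary_path.write_text(
            json.dumps(
                {
                    "per_strain": summary.to_dict(orient="records"),
                    "median_post_missing": summary.attrs["median_post_missing"],
                    "max_post_missing": summary.attrs["max_post_missing"],
                },
                indent=1,
            )
        )

    impute_out = stage("impute", out / "genotypes_imputed.tsv", imp)

    # 4. mixed-model association -----------------------------------------------
    def assoc(dest: Path):
        gm = io.read_genotype_tsv(impute_out)
        screen = io.read_table(pheno_out).set_index("strain")
        phen = []
        for s in gm.strains:
            if s == config.reference_strain:
                phen.append(0.0)
            elif s in screen.index:
                phen.append(float(screen.at[s, "susceptible"]))
            else:
                raise ValueError(f"strain {s!r} has genotypes but no phenotype")
        est = MixedModelAssociation().fit(gm, np.array(phen))
        df = est.results_frame()
        io.write_table(
            df,
            dest,
            extra_header=[
                f"stringent_threshold={est.stringent_threshold_:.6g}",
                f"moderate_threshold={est.moderate_threshold_:.6g}",
            ],
        )

    assoc_out = stage("assoc", out / "association.tsv", assoc)

    # 5. functional prioritization ----------------------------------------------
    genes = io.read_bed(config.genes_bed)
    locus_genes = [
        g.gene_id
        for g in genes
        if g.chrom == config.locus_chrom and g.start < config.locus_end and g.end > config.locus_start
    ]

    def prio(dest: Path):
        network = io.read_network_tsv(config.network)
        sets = io.read_gmt(config.gene_sets)
        fp = FunctionalPrioritizer(seed=config.seeds["prioritize"]).fit(sets, network)
        scores = fp.score_candidates(locus_genes)
        df = pd.DataFrame(
            [
                {
                    "gene_id": s.gene_id,
                    "best_module": s.best_module,
                    "score": s.score,
                    "fpr": s.fpr,
                    "neglog10_fpr": s.neglog10_fpr,
                }
                for s in scores
            ]
        )
        io.write_table(df, dest, seed=config.seeds["prioritize"])

    prio_out = stage("prioritize", out / "functional_scores.tsv", prio)

    # 6. combined gene ranking ---------------------------------------------------
    def rank(dest: Path):
        adf = io.read_table(assoc_out)
        results = [
            AssociationResult(r.snp_id, str(r.chrom), int(r.pos), r.lrt, r.p, int(r.n))
            for r in adf.itertuples()
        ]
        locus_models = [g for g in genes if g.gene_id in set(locus_genes)]
        assignment = assign_snps_to_genes(results, locus_models)
        assoc_scores = gene_assoc_score(assignment)
        fdf = io.read_table(prio_out)
        func_scores = dict(zip(fdf["gene_id"], fdf["neglog10_fpr"]))
        table = combined_score(assoc_scores, func_scores)
        io.write_score_table(table, dest)

    stage("rank", out / "gene_ranking.tsv", rank)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return artifacts
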