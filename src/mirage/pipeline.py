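"""End-to-end pipeline driver: simulate -> preprocess -> annotate -> stats.

Stages run in dependency order; each stage writes its outputs (TSV/FASTQ/
FASTA/JSON) into the run directory and logs its record counts to stderr.
Every JSON result carries a provenance block with the package version, a
hash of the full configuration and the RNG seed, so equal configurations
produce verifiably identical runs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .annotate import MatureReference, PreprocessParams, annotate, preprocess
from .errors import ConfigError, InputError
from .signature import classify_types, concordance, intersect_degs
from .simulate import (
    ExpressionMatrix,
    SimulationConfig,
    simulate_deg_tables,
    simulate_expression,
    simulate_smallrna_reads,
)
from .stats import AnticorrConfig, anticorrelation_test, enrich_mirnas

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "preprocess", "annotate", "anticorr", "enrich", "intersect")

#: Example mature miRNAs (miRBase sequences) used by self-contained
#: simulated runs: the two miR-29 family members plus unrelated controls.
EXAMPLE_MATURE_MIRNAS = {
    "dre-miR-29a": "UAGCACCAUCUGAAAUCGGUUA",
    "dre-miR-29b": "UAGCACCAUUUGAAAUCAGUGUU",
    "dre-let-7a": "UGAGGUAGUAGGUUGUAUAGUU",
    "dre-miR-124": "UAAGGCACGCGGUGAAUGCC",
    "dre-miR-9": "UCUUUGGUUAUCUAGCUGUAUGA",
}


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    prep: PreprocessParams = field(default_factory=PreprocessParams)
    anticorr: AnticorrConfig = field(default_factory=AnticorrConfig)
    deg_type_counts: tuple[int, int, int, int] = (225, 34, 231, 34)
    alpha: float = 0.05
    fdr: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        # one seed drives every stage's generator
        self.sim.rng_seed = self.rng_seed
        self.anticorr.rng_seed = self.rng_seed


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute the requested stages; returns the paths written.

    Later stages read the files earlier stages wrote, so a partial stage
    list requires its inputs to be present in ``out_dir`` already.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, path: Path) -> Path:
        paths[name] = path
        return path

    if "simulate" in config.stages:
        expr, mirna, truth = simulate_expression(config.sim)
        io.write_tsv_matrix(expr.values, emit("expression", out / "expression.tsv"))
        expr.samples.to_csv(emit("samples", out / "samples.tsv"), sep="\t")
        mirna.rename("expression").to_csv(emit("mirna", out / "mirna.tsv"), sep="\t")
        (out / "targets.txt").write_text(
            "".join(f"{g}\n" for g in sorted(truth.target_gene_ids))
        )
        emit("targets", out / "targets.txt")

        ref = MatureReference(EXAMPLE_MATURE_MIRNAS.items())
        io.write_fasta(ref.entries, emit("mature", out / "mature.fasta"))
        reads, read_truth = simulate_smallrna_reads(ref, config.sim)
        io.write_fastq(reads, emit("reads", out / "reads.fastq"))

        aging, sponge, _ = simulate_deg_tables(
            config.deg_type_counts, config=config.sim
        )
        io.write_deg_table(aging, emit("deg_aging", out / "deg_aging.tsv"))
        io.write_deg_table(sponge, emit("deg_sponge", out / "deg_sponge.tsv"))
        io.write_results(
            {
                "target_gene_ids": truth.target_gene_ids,
                "read_sources": read_truth.read_sources,
            },
            emit("ground_truth", out / "ground_truth.json"),
            config=asdict(config.sim) | {"isomir_len_shift": dict(config.sim.isomir_len_shift)},
            seed=config.rng_seed,
        )
        logger.info(
            "simulate: %d genes x %d samples, %d reads",
            *expr.values.shape, len(reads),
        )

    if "preprocess" in config.stages:
        reads = io.read_fastq(io.check_exists(out / "reads.fastq"))
        clean, stats = preprocess(reads, config.prep)
        io.write_fastq(clean, emit("clean_reads", out / "reads.clean.fastq"))
        io.write_results(
            stats, emit("preprocess_stats", out / "preprocess_stats.json"),
            config=asdict(config.prep), seed=config.rng_seed,
        )
        logger.info("preprocess: %s", stats)

    if "annotate" in config.stages:
        clean = io.read_fastq(io.check_exists(out / "reads.clean.fastq"))
        ref = io.read_mature_reference(io.check_exists(out / "mature.fasta"))
        assignments, table = annotate(clean, ref)
        pd.DataFrame(
            [(a.read_id, a.mirna_id, a.phase, a.mismatches, a.offset) for a in assignments],
            columns=["read_id", "miRNA_id", "phase", "mismatches", "offset"],
        ).to_csv(emit("assignments", out / "assignments.tsv"), sep="\t", index=False)
        counts = pd.DataFrame(
            sorted(table.counts.items()), columns=["miRNA_id", "count"]
        )
        counts.loc[len(counts)] = ["*unassigned*", table.unassigned]
        counts.to_csv(emit("counts", out / "counts.tsv"), sep="\t", index=False)
        logger.info(
            "annotate: %d assigned, %d unassigned", len(assignments), table.unassigned
        )

    if "anticorr" in config.stages or "enrich" in config.stages:
        values = io.read_tsv_matrix(io.check_exists(out / "expression.tsv"))
        samples = pd.read_csv(io.check_exists(out / "samples.tsv"), sep="\t", index_col=0)
        expr = ExpressionMatrix(values, samples)
        mirna = pd.read_csv(io.check_exists(out / "mirna.tsv"), sep="\t", index_col=0)["expression"]
        targets = io.read_gene_set(io.check_exists(out / "targets.txt"))

    if "anticorr" in config.stages:
        result = anticorrelation_test(expr, mirna, targets, config.anticorr)
        io.write_results(
            {
                "n_targets": len(result.target_r),
                "n_null": len(result.null_r),
                "n_null_effective": result.n_null_effective,
                "mean_target_r": float(result.target_r.mean()),
                "mean_null_r": float(np.mean(result.null_r)),
                "D": result.D,
                "p": result.p,
            },
            emit("anticorr", out / "anticorr.json"),
            config=asdict(config.anticorr), seed=config.rng_seed,
        )
        logger.info("anticorr: D=%.4f p=%.3g", result.D, result.p)

    if "enrich" in config.stages:
        # cluster: most negatively miRNA-correlated quartile (the analogue of
        # an age-dependent-decay expression cluster); decoy target sets are
        # size-matched random gene draws.
        cfg = config.anticorr
        from .stats import target_correlations

        all_r = target_correlations(expr, mirna, list(values.index), cfg)
        cluster = set(all_r.nsmallest(max(1, len(all_r) // 4)).index)
        rng = np.random.default_rng(config.rng_seed)
        universe = list(values.index)
        target_sets = {"miRNA-sim": set(targets)}
        for i in range(4):
            target_sets[f"decoy-{i + 1}"] = set(
                rng.choice(universe, size=len(targets), replace=False)
            )
        records = enrich_mirnas(target_sets, cluster, universe, alpha=config.alpha)
        io.write_results(
            {"records": [asdict(r) for r in records]},
            emit("enrichment", out / "enrichment.json"),
            config=asdict(config.anticorr), seed=config.rng_seed,
        )
        logger.info(
            "enrich: %d/%d consensus", sum(r.consensus for r in records), len(records)
        )

    if "intersect" in config.stages:
        aging = io.read_deg_table(io.check_exists(out / "deg_aging.tsv"))
        sponge = io.read_deg_table(io.check_exists(out / "deg_sponge.tsv"))
        genes = intersect_degs(aging, sponge, fdr=config.fdr)
        typed = classify_types(
            aging[aging["gene_id"].isin(genes)], sponge[sponge["gene_id"].isin(genes)]
        )
        typed.to_csv(emit("typed", out / "typed_genes.tsv"), sep="\t", index=False)
        summary = concordance(typed)
        io.write_results(
            {
                "intersection_size": len(genes),
                "type_counts": summary.counts,
                "concordant_percent": summary.concordant_percent,
                "discordant_percent": summary.discordant_percent,
                "chi2": summary.chi2,
                "chi2_p": summary.chi2_p,
            },
            emit("concordance", out / "concordance.json"),
            config={"fdr": config.fdr}, seed=config.rng_seed,
        )
        logger.info(
            "intersect: %d genes, %d%% concordant",
            len(genes), summary.concordant_percent,
        )

    return paths
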