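"""End-to-end pipeline: simulate -> mutation rate -> recurrence -> association -> phenomics.

`run_pipeline` wires the library modules together for a fully synthetic run:
it writes the simulated founder/pool VCFs and embryo tables, then reads them
back through the standard-format readers before analysis, so a pipeline run
also exercises the interchange formats.  Every output table starts with
comment lines naming the package version, the seed and the resolved
thresholds; reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assoc as assoc_mod
from . import mutrate as mutrate_mod
from . import pheno as pheno_mod
from . import recurrence as recurrence_mod
from . import simgen, vcfio
from .containers import embryos_to_frame

logger = logging.getLogger("evoreseq")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Thresholds default to the analysis' standard values: depth band 4-50 and
    missingness 2 for the mutation-rate filter, r^2 0.6 within 1 kb for
    pruning, >=3 supporting reads for private calls, minimum depth 10 /
    minimum alt depth 2 / alpha 0.05 for the recurrence Fisher tests, sign
    cutoff |S| > 5, pool-genotype het band (0.1, 0.9) and minimum mean depth
    10 for association.
    """

    out_dir: str = "evoreseq_out"
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig field overrides
    generations: tuple = (3, 7)              # sequenced generations
    pheno_pairing: dict = field(default_factory=lambda: {3: 4, 7: 8})
    n_embryos: int = 40
    # mutrate thresholds
    depth_min: int = 4
    depth_max: int = 50
    max_missing: int = 2
    r2_threshold: float = 0.6
    window_bp: int = 1000
    min_support: int = 3
    individual_mean_depth: float = 30.0
    # recurrence thresholds
    alpha: float = 0.05
    min_alt: int = 2
    min_depth: int = 10
    fdr_scope: str = "population"
    cutoff: int = 5
    # association thresholds
    min_mean_depth: float = 10.0
    het_band: tuple = (0.1, 0.9)
    coding: str = "both"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = vcfio.load_yaml_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if "pheno_pairing" in data:
            cfg.pheno_pairing = {int(k): int(v) for k, v in data["pheno_pairing"].items()}
        if "generations" in data:
            cfg.generations = tuple(int(g) for g in data["generations"])
        if "het_band" in data:
            cfg.het_band = tuple(float(x) for x in data["het_band"])
        return cfg

    def sim_config(self) -> simgen.SimConfig:
        return simgen.SimConfig(**{"seed": self.seed, **self.sim})

    def resolved(self) -> dict:
        data = dataclasses.asdict(self)
        data["sim_resolved"] = dataclasses.asdict(self.sim_config())
        data["version"] = __version__
        return data


def _header(config: RunConfig, stage: str) -> list[str]:
    items = (
        f"alpha={config.alpha}", f"min_alt={config.min_alt}",
        f"min_depth={config.min_depth}", f"cutoff={config.cutoff}",
        f"depth_band=[{config.depth_min},{config.depth_max}]",
        f"max_missing={config.max_missing}", f"r2={config.r2_threshold}",
        f"window_bp={config.window_bp}", f"min_support={config.min_support}",
        f"min_mean_depth={config.min_mean_depth}",
    )
    return [
        f"evoreseq {__version__} stage={stage} seed={config.seed}",
        "thresholds: " + " ".join(items),
    ]


def run_pipeline(config: RunConfig, stages=("simulate", "mutrate", "recurrence", "assoc", "pheno")) -> dict:
    """Run the requested stages; returns a dict of output paths and results."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcfio.dump_yaml_config(config.resolved(), out_dir / "resolved_config.yaml")
    logger.info("resolved config written to %s", out_dir / "resolved_config.yaml")

    outputs: dict = {"out_dir": str(out_dir)}
    sim_cfg = config.sim_config()
    try:
        founders = simgen.simulate_founders(sim_cfg)
        traj = simgen.evolve_all(founders, sim_cfg)
    except Exception as exc:  # config problems surface before any stage
        raise PipelineError(f"stage simulate failed: {exc}") from exc

    if "simulate" in stages:
        try:
            matrix = simgen.founders_to_genotype_matrix(
                founders, mean_depth=config.individual_mean_depth
            )
            vcfio.write_individual_vcf(matrix, out_dir / "founders.vcf")
            ind_sheet = matrix.individuals.copy()
            vcfio.write_table_with_header(
                ind_sheet, out_dir / "individuals.tsv", _header(config, "simulate")
            )
            pools = simgen.sample_pool_generations(
                traj, sim_cfg, config.generations
            )
            vcfio.write_pool_vcf(pools, out_dir / "pools.vcf")
            sheet = pools.samples.copy()
            sheet["role"] = "pool"
            sheet["mutagenized"] = True
            vcfio.write_sample_sheet(sheet, out_dir / "sample_sheet.tsv")
            embryo_gens = sorted(set(config.pheno_pairing.values()))
            embryos = []
            for g in embryo_gens:
                embryos.extend(
                    simgen.simulate_phenotypes(traj, sim_cfg, g, config.n_embryos)
                )
            vcfio.write_embryo_table(
                embryos, out_dir / "embryos.tsv", _header(config, "simulate")
            )
            outputs["founders_vcf"] = str(out_dir / "founders.vcf")
            outputs["pools_vcf"] = str(out_dir / "pools.vcf")
            outputs["embryos_tsv"] = str(out_dir / "embryos.tsv")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage simulate failed: {exc}") from exc

    if "mutrate" in stages:
        try:
            path = out_dir / "founders.vcf"
            if not path.exists():
                raise FileNotFoundError(f"missing input path {path}")
            ind = pd.read_csv(out_dir / "individuals.tsv", sep="\t", comment="#")
            matrix = vcfio.read_individual_vcf(path, ind)
            filtered = mutrate_mod.filter_individual_variants(
                matrix, config.max_missing, config.depth_min, config.depth_max
            )
            pruned = mutrate_mod.prune_linked_sites(
                filtered, config.r2_threshold, config.window_bp
            )
            counts = mutrate_mod.identify_private_mutations(
                pruned, config.min_support
            )
            est = mutrate_mod.estimate_rate(
                counts,
                pruned.individuals["covered_bases"].to_numpy() / 1e6,
                pruned.individuals["mutagenized"].to_numpy(),
                pruned.individuals["name"].tolist(),
            )
            total = mutrate_mod.extrapolate_total(
                est.mean_rate_per_mb,
                sim_cfg.genome_size_mb,
                sim_cfg.n_founders,
            )
            vcfio.write_table_with_header(
                est.per_individual,
                out_dir / "mutrate_report.tsv",
                _header(config, "mutrate")
                + [
                    f"mean_rate_per_mb={est.mean_rate_per_mb:.4f}",
                    f"mean_count={est.mean_count_display}",
                    f"extrapolated_total={total}",
                ],
            )
            outputs["mutrate"] = est
            outputs["mutrate_total"] = total
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage mutrate failed: {exc}") from exc

    if "recurrence" in stages or "assoc" in stages:
        try:
            path = out_dir / "pools.vcf"
            if not path.exists():
                raise FileNotFoundError(f"missing input path {path}")
            sheet = vcfio.read_sample_sheet(out_dir / "sample_sheet.tsv")
            pools = vcfio.read_pool_vcf(path, sheet)
        except Exception as exc:
            raise PipelineError(f"stage recurrence failed: {exc}") from exc

    if "recurrence" in stages:
        try:
            gen_a, gen_b = config.generations[0], config.generations[-1]
            results, scores, report = recurrence_mod.recurrence_scan(
                pools, gen_a, gen_b,
                alpha=config.alpha, min_alt=config.min_alt,
                min_depth=config.min_depth, fdr_scope=config.fdr_scope,
                cutoff=config.cutoff,
            )
            vcfio.write_table_with_header(
                results, out_dir / "recurrence_sites.tsv", _header(config, "recurrence")
            )
            vcfio.write_table_with_header(
                scores, out_dir / "sign_scores.tsv", _header(config, "recurrence")
            )
            summary = pd.DataFrame(
                [
                    {
                        "n_tested": report.n_tested,
                        "n_significant": report.n_significant,
                        "n_recurrent": report.n_recurrent,
                        "n_flagged": report.n_flagged,
                        "pct_significant": report.pct_significant,
                        "pct_recurrent": report.pct_recurrent,
                        "pct_flagged_of_recurrent": report.pct_flagged_of_recurrent,
                        "mean_s_recurrent": report.mean_s_recurrent,
                    }
                ]
            )
            vcfio.write_table_with_header(
                summary, out_dir / "recurrence_report.tsv", _header(config, "recurrence")
            )
            outputs["recurrence_report"] = report
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage recurrence failed: {exc}") from exc

    if "assoc" in stages or "pheno" in stages:
        try:
            path = out_dir / "embryos.tsv"
            if not path.exists():
                raise FileNotFoundError(f"missing input path {path}")
            embryos = vcfio.read_embryo_table(path)
        except Exception as exc:
            raise PipelineError(f"stage assoc failed: {exc}") from exc

    if "assoc" in stages:
        try:
            frame = embryos_to_frame(embryos)
            pheno_means = (
                frame.groupby(["population", "generation"])["length_um"]
                .mean()
                .reset_index()
                .rename(columns={"length_um": "mean_length_um"})
            )
            gtable = assoc_mod.build_genotype_table(
                pools, config.min_mean_depth, config.het_band
            )
            results = assoc_mod.associate_table(
                gtable, pheno_means, config.pheno_pairing, coding=config.coding
            )
            vcfio.write_table_with_header(
                results, out_dir / "assoc_results.tsv", _header(config, "assoc")
            )
            outputs["assoc_results"] = results
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage assoc failed: {exc}") from exc

    if "pheno" in stages:
        try:
            gens = sorted({r.generation for r in embryos})
            medians, tests = pheno_mod.length_summary(
                embryos, group_keys=("population", "generation")
            )
            vcfio.write_table_with_header(
                medians, out_dir / "length_medians.tsv", _header(config, "pheno")
            )
            vcfio.write_table_with_header(
                tests, out_dir / "length_tests.tsv", _header(config, "pheno")
            )
            if len(gens) >= 2:
                first = [r for r in embryos if r.generation == gens[0]]
                last = [r for r in embryos if r.generation == gens[-1]]
                a = np.vstack([pheno_mod.scale_positions(r) for r in first])
                b = np.vstack([pheno_mod.scale_positions(r) for r in last])
                shifts = pheno_mod.stripe_shift_test(a, b, alpha=config.alpha)
                vcfio.write_table_with_header(
                    shifts, out_dir / "stripe_shifts.tsv", _header(config, "pheno")
                )
                outputs["stripe_shifts"] = shifts
            outputs["length_medians"] = medians
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage pheno failed: {exc}") from exc

    logger.info("pipeline finished: %s", sorted(outputs))
    return outputs
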