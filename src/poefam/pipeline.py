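"""End-to-end orchestration: simulate → QC → origins → association → report.

``run_pipeline`` is deterministic given the config seed: all randomness
(cohort simulation and the discovery/replication family split) flows from
it, and every stage writes a TSV so each number in the final report can be
traced to its upstream stage.  The final report uses the canonical result
column layout (Trait/SNP, Cohort, CHR, GENE, Location, E/O, N, B_MAT,
P_MAT, B_PAT, P_PAT, P_POE).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .association import AnalysisPlan, apply_replication_rule, run_analysis
from .origin import infer_cohort_origins
from .pedigree import snp_qc, write_pedigree
from .simulate import SimulationConfig, simulate_families, table1_defaults

__all__ = ["RunConfig", "run_pipeline", "REPORT_COLUMNS"]

REPORT_COLUMNS = [
    "Trait/SNP", "Cohort", "CHR", "GENE", "Location", "E/O", "N",
    "B_MAT", "P_MAT", "B_PAT", "P_PAT", "P_POE",
]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    cohort: str = "botnia"  # simulation preset
    n_families: int | None = None
    beta_mat: dict[str, float] = field(default_factory=dict)
    beta_pat: dict[str, float] = field(default_factory=dict)
    traits: list[str] | None = None
    strata: tuple[str, ...] = ("all",)
    contrast_mode: str = "subset"
    working_correlation: str = "independence"
    alpha: float = 0.05
    bonferroni_m: int | None = None
    log_level: str = "INFO"


def _config_hash(cfg: RunConfig) -> str:
    # hash the scientific configuration only: where outputs land (and how
    # verbosely) must not change what is computed
    payload = {k: v for k, v in asdict(cfg).items() if k not in ("out_dir", "log_level")}
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sim_config(cfg: RunConfig) -> SimulationConfig:
    sim = table1_defaults(cfg.cohort, seed=cfg.seed)
    if cfg.n_families is not None:
        sim.n_families = cfg.n_families
    sim.beta_mat = dict(cfg.beta_mat)
    sim.beta_pat = dict(cfg.beta_pat)
    return sim


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for ln in header_lines:
            fh.write(f"# {ln}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the full family POE analysis on a simulated cohort.

    Returns a mapping of stage name to output path.  Raises with the stage
    name on failure; outputs already written are left in place.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    header = [f"poefam {__version__}", f"seed {cfg.seed}", f"config {chash}"]
    paths: dict[str, Path] = {}
    stage = "simulate"
    try:
        sim = _sim_config(cfg)
        cohort = simulate_families(sim)
        write_pedigree(cohort.pedigree, out / "pedigree.ped")
        cohort.genotypes.to_csv(out / "genotypes.tsv", sep="\t", na_rep="NA",
                                float_format="%.0f")
        cohort.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", na_rep="NA",
                                 float_format="%.6g")
        truth = dict(cohort.truth)
        (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
        paths["pedigree"] = out / "pedigree.ped"
        paths["genotypes"] = out / "genotypes.tsv"
        paths["phenotypes"] = out / "phenotypes.tsv"

        stage = "qc"
        qc = snp_qc(cohort.pedigree, cohort.genotypes, sim.snps)
        _write_tsv(qc, out / "qc.tsv", header)
        paths["qc"] = out / "qc.tsv"

        stage = "infer-origin"
        calls, summary = infer_cohort_origins(cohort.pedigree, cohort.genotypes)
        _write_tsv(calls, out / "origin_calls.tsv", header)
        _write_tsv(summary, out / "origin_summary.tsv", header)
        paths["origins"] = out / "origin_calls.tsv"

        stage = "assoc"
        traits = cfg.traits or [t for t in sim.traits]
        plan = AnalysisPlan(
            traits=traits,
            trait_family={
                t: ("obesity" if t in ("BMI", "WHR", "WHtR", "WHRadjBMI") else "lipid")
                for t in traits
            },
            strata=cfg.strata,
            working_correlation=cfg.working_correlation,
            contrast_mode=cfg.contrast_mode,
            alpha=cfg.alpha,
            bonferroni_m=cfg.bonferroni_m,
            bmi_adjusted=("WHRadjBMI",),
            source_trait={"WHRadjBMI": "WHR"},
        )
        results = run_analysis(
            plan, cohort.pedigree, cohort.genotypes, cohort.phenotypes,
            calls, sim.snps, cohort=sim.cohort_label, split_seed=cfg.seed,
        )
        _write_tsv(results, out / "association.tsv", header)
        paths["association"] = out / "association.tsv"

        replication = apply_replication_rule(results, alpha=cfg.alpha)
        _write_tsv(replication, out / "replication.tsv", header)
        paths["replication"] = out / "replication.tsv"

        stage = "report"
        report = pd.DataFrame(
            {
                "Trait/SNP": results["trait"] + "/" + results["snp_id"],
                "Cohort": results["cohort"] + ":" + results["split"],
                "CHR": results["chromosome"],
                "GENE": results["gene_label"],
                "Location": results["location"],
                "E/O": results["alleles"],
                "N": results["N_het"],
                "B_MAT": results["B_MAT"],
                "P_MAT": results["P_MAT"],
                "B_PAT": results["B_PAT"],
                "P_PAT": results["P_PAT"],
                "P_POE": results["P_POE"],
            }
        )
        _write_tsv(report, out / "report.tsv", header)
        paths["report"] = out / "report.tsv"

        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": chash,
            "config": asdict(cfg),
            "stages": {k: str(v.name) for k, v in paths.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = out / "manifest.json"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return paths
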