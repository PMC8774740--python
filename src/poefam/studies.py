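"""Simulation studies validating the POE pipeline end to end.

Each study regenerates synthetic cohorts from scratch, runs the relevant
pipeline stages, and summarizes calibration, recovery, or power.  They are
used by the package's validation suite and by the reproduction script;
problem sizes are parameters so callers can trade runtime for precision.
"""

from __future__ import annotations

import numpy as np

from .association import AnalysisPlan, run_analysis
from .origin import ASSIGNED, infer_cohort_origins
from .pedigree import SnpInfo
from .simulate import SimulationConfig, simulate_families, simulate_unrelateds
from .varpoe import het_variance_test

__all__ = [
    "assignable_fraction_study",
    "null_poe_calibration",
    "effect_recovery_study",
    "het_variance_study",
]

_PLAN = AnalysisPlan(
    traits=["trait"], trait_family={"trait": "lipid"}, splits=("combined",)
)


def _single_snp_config(seed, n_families, maf, beta_mat=0.0, beta_pat=0.0, **kw):
    return SimulationConfig(
        seed=seed,
        n_families=n_families,
        snps=[SnpInfo("snp1", "1", "GENE1", "A", "G", maf)],
        beta_mat={"snp1": beta_mat},
        beta_pat={"snp1": beta_pat},
        **kw,
    )


def assignable_fraction_study(
    n_trios: int = 10_000, maf: float = 0.5, seed: int = 0
) -> dict:
    """Fraction of heterozygous offspring with assignable origin in full trios.

    Under HWE and random mating the only unassignable full trio has both
    parents heterozygous, so the expected fraction is
    1 − P(both parents het | offspring het) = 1 − pq.
    """
    cfg = _single_snp_config(
        seed, n_trios, maf,
        offspring_lambda=0.0, geno_missing_rate=0.0, parent_missing_rate=0.0,
    )
    sim = simulate_families(cfg)
    calls, _ = infer_cohort_origins(sim.pedigree, sim.genotypes)
    off = sim.genotypes.loc[sim.pedigree.offspring_ids, "snp1"]
    het_ids = set(off.index[off == 1])
    het_calls = calls[calls["individual_id"].isin(het_ids)]
    frac = float((het_calls["status"] == ASSIGNED).mean())
    expected = 1 - maf * (1 - maf)
    return {
        "fraction": frac,
        "expected": expected,
        "n_het": int(len(het_calls)),
        "se": float(np.sqrt(expected * (1 - expected) / len(het_calls))),
    }


def _poe_row(seed: int, n_families: int, maf: float, beta_mat=0.0, beta_pat=0.0):
    cfg = _single_snp_config(seed, n_families, maf, beta_mat, beta_pat)
    sim = simulate_families(cfg)
    calls, _ = infer_cohort_origins(sim.pedigree, sim.genotypes)
    res = run_analysis(
        _PLAN, sim.pedigree, sim.genotypes, sim.phenotypes, calls, cfg.snps,
        split_seed=seed,
    )
    return res.iloc[0]


def null_poe_calibration(
    n_reps: int = 1000, n_families: int = 300, maf: float = 0.3,
    alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Type-I error of the POE contrast on null cohorts."""
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    hits = 0
    used = 0
    for s in sub_seeds:
        row = _poe_row(int(s), n_families, maf)
        if np.isfinite(row["P_POE"]):
            used += 1
            hits += row["P_POE"] < alpha
    return {"rejection_rate": hits / used, "n_reps": used, "alpha": alpha}


def effect_recovery_study(
    n_reps: int = 200, n_families: int = 300, maf: float = 0.3,
    beta_mat: float = 0.0, beta_pat: float = 0.3, seed: int = 0,
) -> dict:
    """Coverage of the simulated parental effects by the GEE estimates.

    Counts replicates where each estimated coefficient falls within 3
    robust SEs of its generative truth, and where B_POE is within 3
    combined SEs of B_PAT − B_MAT on the same cohort.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    cover_pat = cover_mat = cover_diff = used = 0
    for s in sub_seeds:
        row = _poe_row(int(s), n_families, maf, beta_mat, beta_pat)
        if not np.isfinite(row["B_PAT"]) or not np.isfinite(row["B_POE"]):
            continue
        used += 1
        cover_pat += abs(row["B_PAT"] - beta_pat) < 3 * row["SE_PAT"]
        cover_mat += abs(row["B_MAT"] - beta_mat) < 3 * row["SE_MAT"]
        tol = 3 * np.sqrt(row["SE_POE"] ** 2 + row["SE_MAT"] ** 2 + row["SE_PAT"] ** 2)
        cover_diff += abs(row["B_POE"] - (row["B_PAT"] - row["B_MAT"])) < tol
    return {
        "coverage_pat": cover_pat / used,
        "coverage_mat": cover_mat / used,
        "poe_equals_difference_rate": cover_diff / used,
        "n_reps": used,
    }


def het_variance_study(
    n_reps: int = 200, n: int = 3000, maf: float = 0.5,
    beta_mat: float = 0.3, beta_pat: float = -0.3,
    alpha: float = 0.05, seed: int = 0, with_null: bool = True,
) -> dict:
    """Heterozygote/homozygote residual-variance ratio and test power.

    With opposite parental effects ±δ hidden in unrelateds, heterozygote
    variance is inflated by δ² (ratio 1 + δ² in trait-SD units).
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    ratios = []
    hits_alt = hits_null = 0
    for s in sub_seeds:
        cfg = _single_snp_config(
            int(s), 1, maf, beta_mat, beta_pat,
            geno_missing_rate=0.0, pheno_missing_rate=0.0,
        )
        cohort = simulate_unrelateds(cfg, n)
        res = het_variance_test(
            cohort.phenotypes["trait"].to_numpy(),
            cohort.genotypes["snp1"].to_numpy(),
        )
        hom_var = (res.n0 * res.var0 + res.n2 * res.var2) / (res.n0 + res.n2)
        ratios.append(res.var1 / hom_var)
        hits_alt += res.p_value < alpha
        if with_null:
            cfg0 = _single_snp_config(
                int(s) + 1, 1, maf, 0.0, 0.0,
                geno_missing_rate=0.0, pheno_missing_rate=0.0,
            )
            null = simulate_unrelateds(cfg0, n)
            res0 = het_variance_test(
                null.phenotypes["trait"].to_numpy(),
                null.genotypes["snp1"].to_numpy(),
            )
            hits_null += res0.p_value < alpha
    delta = 0.5 * abs(beta_pat - beta_mat)
    return {
        "mean_ratio": float(np.mean(ratios)),
        "expected_ratio": 1 + delta**2,
        "sem_ratio": float(np.std(ratios) / np.sqrt(len(ratios))),
        "power": hits_alt / n_reps,
        "null_rate": (hits_null / n_reps) if with_null else np.nan,
        "n_reps": n_reps,
    }
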