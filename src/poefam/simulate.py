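"""Synthetic nuclear-family and unrelated cohorts with known POE architecture.

Families consist of two parents drawn under Hardy–Weinberg equilibrium at
each SNP's minor-allele frequency and 1 + Poisson offspring receiving one
allele from each parent by Mendelian transmission, with the true parental
origin of every transmitted minor allele recorded.  Phenotypes are
generated on the analysis (transformed) scale,

    z = Σ_snp sexscale · (β_mat·m + β_pat·p) + covariate terms
        + family intercept + residual,          value = mean + sd·z,

so β_mat/β_pat are directly comparable to association betas in trait-SD
units.  Genotype, whole-parent, and phenotype missingness are applied
last.  ``table1_defaults`` pre-loads cohort shapes and trait means/SDs
matching the two family studies the package emulates (a Finnish/Swedish
cohort with a full lipid panel and a Hungarian cohort with obesity traits
only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pedigree import IndividualRecord, Pedigree, SnpInfo

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_families",
    "simulate_unrelateds",
    "table1_defaults",
    "default_snp_panel",
]


def default_snp_panel() -> list[SnpInfo]:
    """Candidate lipid-loci panel (rsIDs/genes/chromosomes as studied).

    Minor-allele frequencies are plausible values chosen for the
    simulator; the effect allele is the minor allele throughout.
    """
    rows = [
        ("rs12027135", "1", "TMEM57", "A", "T", 0.35, "intron"),
        ("rs2479409", "1", "PCSK9", "G", "A", 0.30, "nearGene-5"),
        ("rs4660293", "1", "PABPC4", "G", "A", 0.23, "intron"),
        ("rs2131925", "1", "ANGPTL3/DOCK7", "G", "T", 0.30, "intron"),
        ("rs673548", "2", "APOB", "A", "G", 0.22, "intron"),
        ("rs4731702", "7", "KLF14", "T", "C", 0.45, "intergenic"),
        ("rs10503669", "8", "LPL", "A", "C", 0.10, "intergenic"),
        ("rs12272004", "11", "APOA", "A", "C", 0.06, "intergenic"),
    ]
    return [SnpInfo(*r) for r in rows]


@dataclass
class SimulationConfig:
    """Complete generative truth for a synthetic cohort.

    Effects are in trait-SD units.  ``residual_sd=None`` auto-completes the
    non-genetic variance so that family + residual variance equals 1 on the
    latent scale.
    """

    seed: int = 0
    n_families: int = 300
    offspring_lambda: float = 0.5  # offspring count = 1 + Poisson, truncated
    max_offspring: int = 5
    snps: list[SnpInfo] = field(default_factory=lambda: [SnpInfo("snp1", "1", "GENE1", "A", "G", 0.3)])
    beta_mat: dict[str, float] = field(default_factory=dict)
    beta_pat: dict[str, float] = field(default_factory=dict)
    affected_traits: list[str] | None = None  # None = all traits
    daughter_scale: float = 1.0
    son_scale: float = 1.0
    covariate_betas: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.1, "age": 0.1, "age2": 0.0, "diabetes": 0.1, "bmi": 0.1}
    )
    family_sd: float = 0.3
    residual_sd: float | None = None
    traits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"trait": (0.0, 1.0)}
    )
    diabetes_prev_offspring: float = 0.27
    diabetes_prev_parent: float = 0.41
    parent_age: tuple[float, float] = (59.9, 12.5)
    offspring_age: tuple[float, float] = (44.4, 16.1)
    geno_missing_rate: float = 0.05
    parent_missing_rate: float = 0.10  # whole parent ungenotyped
    pheno_missing_rate: float = 0.05
    cohort_label: str = "simulated"

    def __post_init__(self) -> None:
        for snp in self.snps:
            if not (0 < snp.maf <= 0.5):
                raise ValueError(f"{snp.snp_id}: maf outside (0, 0.5]")
        for rate in (self.geno_missing_rate, self.parent_missing_rate, self.pheno_missing_rate):
            if not (0 <= rate < 1):
                raise ValueError("missingness rates must lie in [0, 1)")
        if self.family_sd < 0 or (self.residual_sd is not None and self.residual_sd < 0):
            raise ValueError("standard deviations must be >= 0")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        unknown = (set(self.beta_mat) | set(self.beta_pat)) - {s.snp_id for s in self.snps}
        if unknown:
            raise ValueError(f"effects reference unknown SNPs: {sorted(unknown)}")

    @property
    def effective_residual_sd(self) -> float:
        if self.residual_sd is not None:
            return self.residual_sd
        return float(np.sqrt(max(0.0, 1.0 - self.family_sd**2)))


@dataclass
class SimulatedCohort:
    pedigree: Pedigree
    genotypes: pd.DataFrame
    true_origins: pd.DataFrame  # offspring × SNP long table, pre-missingness
    phenotypes: pd.DataFrame
    truth: dict


def _sample_offspring_counts(cfg: SimulationConfig, rng) -> np.ndarray:
    k = 1 + rng.poisson(cfg.offspring_lambda, size=cfg.n_families)
    return np.minimum(k, cfg.max_offspring)


def simulate_families(config: SimulationConfig) -> SimulatedCohort:
    """Generate a nuclear-family cohort with tracked allele origins."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_off_per_fam = _sample_offspring_counts(cfg, rng)
    n_fam = cfg.n_families
    n_off = int(n_off_per_fam.sum())

    fam_ids = [f"F{i + 1}" for i in range(n_fam)]
    father_ids = [f"{f}_P1" for f in fam_ids]
    mother_ids = [f"{f}_P2" for f in fam_ids]
    off_fam_idx = np.repeat(np.arange(n_fam), n_off_per_fam)
    off_ids = []
    for i, k in enumerate(n_off_per_fam):
        off_ids += [f"{fam_ids[i]}_C{j + 1}" for j in range(k)]

    records = []
    for i, f in enumerate(fam_ids):
        records.append(IndividualRecord(f, father_ids[i], None, None, "male", "parent"))
        records.append(IndividualRecord(f, mother_ids[i], None, None, "female", "parent"))
    off_sex = rng.random(n_off) < 0.5  # True = female
    for j, iid in enumerate(off_ids):
        i = off_fam_idx[j]
        records.append(
            IndividualRecord(
                fam_ids[i], iid, father_ids[i], mother_ids[i],
                "female" if off_sex[j] else "male", "offspring",
            )
        )
    pedigree = Pedigree(records)

    snp_ids = [s.snp_id for s in cfg.snps]
    mafs = np.array([s.maf for s in cfg.snps])
    # parental haplotypes under HWE: two independent Bernoulli(maf) alleles
    dad_alleles = rng.random((n_fam, len(snp_ids), 2)) < mafs[None, :, None]
    mom_alleles = rng.random((n_fam, len(snp_ids), 2)) < mafs[None, :, None]
    dad_gt = dad_alleles.sum(axis=2).astype(float)
    mom_gt = mom_alleles.sum(axis=2).astype(float)
    # Mendelian transmission with recorded origin
    pick_m = rng.integers(0, 2, size=(n_off, len(snp_ids)))
    pick_d = rng.integers(0, 2, size=(n_off, len(snp_ids)))
    mat_minor = np.take_along_axis(
        mom_alleles[off_fam_idx], pick_m[:, :, None], axis=2
    )[:, :, 0].astype(int)
    pat_minor = np.take_along_axis(
        dad_alleles[off_fam_idx], pick_d[:, :, None], axis=2
    )[:, :, 0].astype(int)
    off_gt = (mat_minor + pat_minor).astype(float)

    # phenotypes (analysis scale)
    phenos = _build_phenotypes(
        cfg, rng,
        fam_idx=np.concatenate([np.arange(n_fam), np.arange(n_fam), off_fam_idx]),
        ids=father_ids + mother_ids + off_ids,
        is_offspring=np.r_[np.zeros(2 * n_fam, bool), np.ones(n_off, bool)],
        is_female=np.r_[np.zeros(n_fam, bool), np.ones(n_fam, bool), off_sex],
        mat_minor=mat_minor, pat_minor=pat_minor,
        parent_gt=np.concatenate([dad_gt, mom_gt], axis=0),
    )

    # genotype table with missingness
    geno = np.concatenate([dad_gt, mom_gt, off_gt], axis=0)
    all_ids = father_ids + mother_ids + off_ids
    if cfg.parent_missing_rate > 0:
        drop = rng.random(2 * n_fam) < cfg.parent_missing_rate
        geno[: 2 * n_fam][drop] = np.nan
    if cfg.geno_missing_rate > 0:
        geno[rng.random(geno.shape) < cfg.geno_missing_rate] = np.nan
    genotypes = pd.DataFrame(geno, index=pd.Index(all_ids, name="individual_id"),
                             columns=snp_ids)

    origins = pd.DataFrame(
        {
            "individual_id": np.repeat(np.asarray(off_ids, dtype=object), len(snp_ids)),
            "snp_id": np.tile(np.asarray(snp_ids, dtype=object), n_off),
            "maternal_minor": mat_minor.ravel(),
            "paternal_minor": pat_minor.ravel(),
        }
    )

    truth = asdict(cfg)
    truth["snps"] = [asdict(s) for s in cfg.snps]
    truth["n_offspring"] = n_off
    return SimulatedCohort(pedigree, genotypes, origins, phenos, truth)


def _build_phenotypes(
    cfg: SimulationConfig, rng, fam_idx, ids, is_offspring, is_female,
    mat_minor, pat_minor, parent_gt,
) -> pd.DataFrame:
    n = len(ids)
    n_parent = int((~is_offspring).sum())
    age = np.where(
        is_offspring,
        rng.normal(cfg.offspring_age[0], cfg.offspring_age[1], n),
        rng.normal(cfg.parent_age[0], cfg.parent_age[1], n),
    )
    age = np.clip(age, 18.0, 95.0)
    prev = np.where(is_offspring, cfg.diabetes_prev_offspring, cfg.diabetes_prev_parent)
    diabetes = (rng.random(n) < prev).astype(float)
    u_fam = rng.normal(0.0, cfg.family_sd, fam_idx.max() + 1)

    # per-individual genetic value per SNP, sex-scaled for offspring
    sexscale = np.where(is_female, cfg.daughter_scale, cfg.son_scale)
    gvalues = np.zeros(n)
    for j, snp in enumerate(cfg.snps):
        bm = cfg.beta_mat.get(snp.snp_id, 0.0)
        bp = cfg.beta_pat.get(snp.snp_id, 0.0)
        if bm == 0 and bp == 0:
            continue
        g = np.zeros(n)
        g[is_offspring] = (
            bm * mat_minor[:, j] + bp * pat_minor[:, j]
        ) * sexscale[is_offspring]
        g[~is_offspring] = 0.5 * (bm + bp) * parent_gt[:n_parent, j]
        gvalues = gvalues + g

    cb = cfg.covariate_betas
    age_std = (age - 50.7) / 16.6
    cov_term = (
        cb.get("sex", 0.0) * (is_female.astype(float) - 0.5)
        + cb.get("age", 0.0) * age_std
        + cb.get("age2", 0.0) * (age_std**2 - 1.0)
        + cb.get("diabetes", 0.0) * (diabetes - prev)
    )
    resid_sd = cfg.effective_residual_sd
    affected = set(cfg.affected_traits or cfg.traits)

    data = {
        "sex": np.where(is_female, "female", "male"),
        "age": age,
        "diabetes": diabetes,
    }
    bmi_z = None
    trait_order = sorted(cfg.traits, key=lambda t: (t != "BMI", t))  # BMI first
    for trait in trait_order:
        mean, sd = cfg.traits[trait]
        z = cov_term + u_fam[fam_idx] + rng.normal(0.0, resid_sd, n)
        if trait != "BMI" and bmi_z is not None:
            z = z + cb.get("bmi", 0.0) * bmi_z
        if trait in affected:
            z = z + gvalues
        if trait == "BMI":
            bmi_z = z.copy()
        data[trait] = mean + sd * z
    phenos = pd.DataFrame(data, index=pd.Index(list(ids), name="individual_id"))
    if "BMI" not in phenos.columns:
        # covariate column for association even when BMI is not a study trait
        phenos["BMI"] = 26.7 + 4.6 * (cov_term + u_fam[fam_idx] + rng.normal(0.0, resid_sd, n))
    if cfg.pheno_missing_rate > 0:
        for trait in cfg.traits:
            mask = rng.random(n) < cfg.pheno_missing_rate
            col = phenos[trait].to_numpy(dtype=float)
            col[mask] = np.nan
            phenos[trait] = col
    return phenos


def simulate_unrelateds(config: SimulationConfig, n: int) -> SimulatedCohort:
    """Unrelated individuals as offspring of unobserved random parents.

    Phenotypes use the hidden true origins (so opposite parental effects
    inflate heterozygote variance); only the offspring genotypes are
    exposed in the genotype table.  The hidden origins are returned in
    ``true_origins`` for validation.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ids = [f"U{i + 1}" for i in range(n)]
    snp_ids = [s.snp_id for s in cfg.snps]
    mafs = np.array([s.maf for s in cfg.snps])
    mat_minor = (rng.random((n, len(snp_ids))) < mafs).astype(int)
    pat_minor = (rng.random((n, len(snp_ids))) < mafs).astype(int)
    gt = (mat_minor + pat_minor).astype(float)

    records = [
        IndividualRecord(f"UF{i + 1}", iid, None, None,
                         "female" if f else "male", "offspring")
        for i, (iid, f) in enumerate(zip(ids, rng.random(n) < 0.5))
    ]
    is_female = np.array([r.sex == "female" for r in records])
    phenos = _build_phenotypes(
        cfg, rng,
        fam_idx=np.arange(n), ids=ids,
        is_offspring=np.ones(n, bool), is_female=is_female,
        mat_minor=mat_minor, pat_minor=pat_minor,
        parent_gt=np.zeros((0, len(snp_ids))),
    )
    if cfg.geno_missing_rate > 0:
        gt[rng.random(gt.shape) < cfg.geno_missing_rate] = np.nan
    genotypes = pd.DataFrame(gt, index=pd.Index(ids, name="individual_id"),
                             columns=snp_ids)
    origins = pd.DataFrame(
        {
            "individual_id": np.repeat(np.asarray(ids, dtype=object), len(snp_ids)),
            "snp_id": np.tile(np.asarray(snp_ids, dtype=object), n),
            "maternal_minor": mat_minor.ravel(),
            "paternal_minor": pat_minor.ravel(),
        }
    )
    truth = asdict(cfg)
    truth["snps"] = [asdict(s) for s in cfg.snps]
    truth["n"] = n
    # family random effect is meaningless for unrelateds
    pedigree = Pedigree(records)
    return SimulatedCohort(pedigree, genotypes, origins, phenos, truth)


_BOTNIA_TRAITS = {
    "BMI": (26.69, 4.61),
    "WHR": (0.90, 0.10),
    "WHtR": (0.54, 0.08),
    "TC": (5.44, 1.11),
    "TG": (1.47, 0.94),
    "LDL": (3.47, 0.99),
    "HDL": (1.31, 0.35),
    "ApoA1": (135.88, 22.98),
    "ApoA2": (36.06, 12.63),
    "ApoB": (93.39, 23.84),
    "ApoB_ApoA1": (0.71, 0.22),
}

_HTB_TRAITS = {
    "BMI": (27.89, 5.45),
    "WHR": (0.86, 0.13),
    "WHtR": (0.52, 0.09),
}


def table1_defaults(cohort: str = "botnia", seed: int = 0) -> SimulationConfig:
    """Cohort-shaped defaults: sizes, trait means/SDs, diabetes prevalence.

    ``botnia`` — 2257 families, ~3552 offspring, full lipid + obesity
    panel; ``htb`` — 2264 families, ~3366 offspring, obesity traits only.
    The Poisson offspring rate is set so the expected offspring count
    matches the cohort's offspring/family ratio.
    """
    if cohort == "botnia":
        return SimulationConfig(
            seed=seed, n_families=2257, offspring_lambda=0.574,
            snps=default_snp_panel(), traits=dict(_BOTNIA_TRAITS),
            diabetes_prev_offspring=0.27, diabetes_prev_parent=0.41,
            parent_age=(59.93, 12.52), offspring_age=(44.43, 16.09),
            cohort_label="botnia_like",
        )
    if cohort == "htb":
        return SimulationConfig(
            seed=seed, n_families=2264, offspring_lambda=0.487,
            snps=default_snp_panel(), traits=dict(_HTB_TRAITS),
            diabetes_prev_offspring=0.065, diabetes_prev_parent=0.32,
            parent_age=(60.08, 11.79), offspring_age=(35.61, 11.29),
            cohort_label="htb_like",
        )
    raise ValueError(f"unknown cohort {cohort!r} (expected 'botnia' or 'htb')")
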