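"""Maternal, paternal, and parent-of-origin association contrasts via GEE.

For each SNP × trait × stratum the module fits three linear
(identity-link, Gaussian) generalized estimating equations, clustered by
nuclear family with a robust sandwich covariance:

* maternal contrast — origin-assigned heterozygotes carrying a maternally
  inherited minor allele vs major-allele homozygotes (B_MAT);
* paternal contrast — the symmetric paternal comparison (B_PAT);
* POE contrast — paternal- vs maternal-origin heterozygotes only (B_POE,
  P_POE); its N is the number of origin-assigned heterozygous offspring.

Minor-allele homozygotes, ambiguous, Mendelian-error and untestable calls
are excluded from the subset contrasts.  An alternative joint-dosage mode
regresses the trait on maternal and paternal minor-allele counts jointly
over all origin-assigned offspring.  A discovery/replication family split,
the same-direction replication rule, and Bonferroni flags round out the
sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .origin import ASSIGNED
from .pedigree import Pedigree, SnpInfo

__all__ = [
    "AnalysisPlan",
    "GEEFitError",
    "split_families",
    "build_contrast_sample",
    "gee_fit",
    "run_analysis",
    "apply_replication_rule",
    "LIPID_COVARIATES",
    "OBESITY_COVARIATES",
]

LIPID_COVARIATES = ("BMI", "sex", "age", "age2", "diabetes")
OBESITY_COVARIATES = ("sex", "age", "age2", "diabetes")

RESULT_COLUMNS = [
    "snp_id", "chromosome", "gene_label", "location", "alleles", "trait",
    "stratum", "cohort", "split", "N_het",
    "B_MAT", "SE_MAT", "P_MAT",
    "B_PAT", "SE_PAT", "P_PAT",
    "B_POE", "SE_POE", "P_POE",
    "bonferroni_flag", "note",
]


class GEEFitError(RuntimeError):
    """Design problems (rank deficiency, too few clusters) in a GEE fit."""


@dataclass
class AnalysisPlan:
    """What to fit: traits, covariates, split scheme, thresholds.

    ``trait_family`` maps each trait to ``lipid`` or ``obesity`` to select
    its covariate set; traits listed in ``bmi_adjusted`` (e.g. WHRadjBMI
    realized as the WHR analysis) get BMI appended.  ``bonferroni_m``
    defaults to the number of SNP × trait tests actually executed.
    """

    traits: list[str]
    trait_family: dict[str, str]
    splits: tuple[str, ...] = ("discovery", "replication", "combined")
    strata: tuple[str, ...] = ("all",)
    working_correlation: str = "independence"
    contrast_mode: str = "subset"  # or "joint"
    alpha: float = 0.05
    bonferroni_m: int | None = None
    bmi_adjusted: tuple[str, ...] = ()
    source_trait: dict[str, str] = field(default_factory=dict)

    def covariates_for(self, trait: str, stratum: str) -> list[str]:
        fam = self.trait_family.get(trait, "lipid")
        cols = list(LIPID_COVARIATES if fam == "lipid" else OBESITY_COVARIATES)
        if trait in self.bmi_adjusted and "BMI" not in cols:
            cols.append("BMI")
        if stratum != "all" and "sex" in cols:
            cols.remove("sex")
        # the BMI analysis cannot adjust for itself
        src = self.source_trait.get(trait, trait)
        if src == "BMI" and "BMI" in cols:
            cols.remove("BMI")
        return cols


def split_families(pedigree: Pedigree, seed: int) -> dict[str, str]:
    """Randomly assign whole families to discovery/replication halves."""
    family_ids = sorted({r.family_id for r in pedigree.records})
    if len(family_ids) < 2:
        raise ValueError("split_families requires >= 2 families")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(family_ids))
    half = (len(family_ids) + 1) // 2
    labels = {}
    for rank, idx in enumerate(order):
        labels[family_ids[idx]] = "discovery" if rank < half else "replication"
    return labels


def build_contrast_sample(
    origin_calls: pd.DataFrame,
    genotypes: pd.Series,
    contrast: str,
) -> pd.DataFrame:
    """Exposure coding for one SNP and one contrast.

    ``origin_calls`` holds this SNP's calls (columns individual_id, status,
    maternal_minor, paternal_minor); ``genotypes`` is the per-individual
    minor-allele count for the same SNP.

    Returns a DataFrame (individual_id, exposure).  For ``maternal``:
    major homozygotes (0) vs assigned maternal-origin heterozygotes (1);
    ``paternal`` symmetric; ``poe``: assigned heterozygotes only, exposure
    1 = paternal origin.
    """
    if contrast not in ("maternal", "paternal", "poe"):
        raise ValueError(f"unknown contrast {contrast!r}")
    calls = origin_calls.set_index("individual_id")
    het = calls[(calls["status"] == ASSIGNED)]
    het = het[
        (het["maternal_minor"].fillna(0) + het["paternal_minor"].fillna(0)) == 1
    ]
    pat_het = het[het["paternal_minor"] == 1].index
    mat_het = het[het["maternal_minor"] == 1].index
    if contrast == "poe":
        ids = list(mat_het) + list(pat_het)
        exposure = [0] * len(mat_het) + [1] * len(pat_het)
    else:
        gt = genotypes.dropna()
        hom_major = gt.index[gt == 0]
        carriers = mat_het if contrast == "maternal" else pat_het
        ids = list(hom_major) + list(carriers)
        exposure = [0] * len(hom_major) + [1] * len(carriers)
    out = pd.DataFrame({"individual_id": ids, "exposure": exposure})
    if out["exposure"].sum() == 0:
        warnings.warn(f"{contrast} contrast has zero exposed rows", stacklevel=2)
    return out


_COV_STRUCTS = {
    "independence": sm.cov_struct.Independence,
    "exchangeable": sm.cov_struct.Exchangeable,
}


def _design(exposure: np.ndarray, covariates) -> tuple[np.ndarray, list[str]]:
    X = [np.ones_like(exposure, dtype=float), np.asarray(exposure, dtype=float)]
    names = ["intercept", "exposure"]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        for j in range(C.shape[1]):
            X.append(C[:, j])
        if isinstance(covariates, pd.DataFrame):
            names += list(map(str, covariates.columns))
        else:
            names += [f"c{j}" for j in range(C.shape[1])]
    return np.column_stack(X), names


def gee_fit(
    y,
    exposure,
    covariates,
    clusters,
    working_correlation: str = "independence",
    reference: str = "normal",
) -> tuple[float, float, float]:
    """Gaussian GEE for the exposure coefficient with cluster-robust SE.

    Returns (beta, robust SE, two-sided p).  ``reference="t"`` swaps the
    normal reference for a t with (clusters − 2) df.
    """
    y = np.asarray(y, dtype=float)
    X, names = _design(np.asarray(exposure, dtype=float), covariates)
    clusters = np.asarray(clusters)
    mask = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    y, X, clusters = y[mask], X[mask], clusters[mask]
    n_clusters = len(np.unique(clusters))
    if n_clusters < 2:
        raise GEEFitError("gee_fit requires >= 2 family clusters")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise GEEFitError(f"design matrix rank deficient; aliased columns: {aliased}")
    try:
        cov_struct = _COV_STRUCTS[working_correlation]()
    except KeyError:
        raise ValueError(f"unknown working correlation {working_correlation!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(y, X, groups=clusters, family=sm.families.Gaussian(),
                       cov_struct=cov_struct)
        fit = model.fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    z = beta / se
    if reference == "t":
        p = float(2 * stats.t.sf(abs(z), max(1, n_clusters - 2)))
    else:
        p = float(2 * stats.norm.sf(abs(z)))
    return beta, se, p


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    keep: list[int] = []
    aliased = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            aliased.append(names[j])
    return aliased


def _joint_fit(
    y, mat_count, pat_count, covariates, clusters, working_correlation
) -> dict[str, float]:
    """Joint-dosage model: trait ~ maternal count + paternal count (+ covs)."""
    y = np.asarray(y, dtype=float)
    base = np.column_stack(
        [np.ones(len(y)), np.asarray(mat_count, float), np.asarray(pat_count, float)]
    )
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        base = np.column_stack([base, C])
    clusters = np.asarray(clusters)
    mask = ~np.isnan(y) & ~np.isnan(base).any(axis=1)
    y, base, clusters = y[mask], base[mask], clusters[mask]
    if len(np.unique(clusters)) < 2:
        raise GEEFitError("joint fit requires >= 2 family clusters")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GEE(
            y, base, groups=clusters, family=sm.families.Gaussian(),
            cov_struct=_COV_STRUCTS[working_correlation](),
        ).fit()
    V = np.asarray(fit.cov_params())
    b_mat, b_pat = float(fit.params[1]), float(fit.params[2])
    se_mat, se_pat = float(fit.bse[1]), float(fit.bse[2])
    d = b_pat - b_mat
    se_d = float(np.sqrt(V[1, 1] + V[2, 2] - 2 * V[1, 2]))
    return {
        "B_MAT": b_mat, "SE_MAT": se_mat,
        "P_MAT": float(2 * stats.norm.sf(abs(b_mat / se_mat))),
        "B_PAT": b_pat, "SE_PAT": se_pat,
        "P_PAT": float(2 * stats.norm.sf(abs(b_pat / se_pat))),
        "B_POE": d, "SE_POE": se_d,
        "P_POE": float(2 * stats.norm.sf(abs(d / se_d))),
    }


def _covariate_frame(phenotypes: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Numeric covariate matrix; sex 0/1, age² derived, diabetes indicators."""
    out = {}
    for c in cols:
        if c == "age2":
            out["age2"] = phenotypes["age"].astype(float) ** 2
        elif c == "sex":
            s = phenotypes["sex"]
            out["sex"] = (
                s.map({"male": 0.0, "female": 1.0}).astype(float)
                if s.dtype == object
                else s.astype(float)
            )
        elif c == "diabetes":
            d = phenotypes["diabetes"]
            if d.dtype == object:
                levels = sorted(x for x in d.dropna().unique())
                for lev in levels[1:]:
                    out[f"diabetes_{lev}"] = (d == lev).astype(float).where(d.notna())
            else:
                out["diabetes"] = d.astype(float)
        else:
            out[c] = phenotypes[c].astype(float)
    return pd.DataFrame(out, index=phenotypes.index)


def run_analysis(
    plan: AnalysisPlan,
    pedigree: Pedigree,
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    origin_calls: pd.DataFrame,
    snps: list[SnpInfo],
    cohort: str = "cohort",
    split_seed: int = 0,
) -> pd.DataFrame:
    """Full SNP × trait × stratum × split association sweep.

    ``phenotypes`` is indexed by individual_id and holds analysis-scale
    traits plus sex/age/diabetes (and BMI) covariate columns.  Fit failures
    are recorded as flagged rows; the sweep never aborts.
    """
    split_labels = split_families(pedigree, split_seed)
    fam_of = {r.individual_id: r.family_id for r in pedigree.records}
    sex_of = {r.individual_id: r.sex for r in pedigree.records}
    rows = []
    for snp in snps:
        snp_calls = origin_calls[origin_calls["snp_id"] == snp.snp_id]
        for trait in plan.traits:
            src = plan.source_trait.get(trait, trait)
            if src not in phenotypes.columns:
                continue
            for stratum in plan.strata:
                cov_cols = plan.covariates_for(trait, stratum)
                for split in plan.splits:
                    rows.append(
                        _one_cell(
                            plan, snp, trait, src, stratum, split, cohort,
                            snp_calls, genotypes, phenotypes,
                            split_labels, fam_of, sex_of,
                            cov_cols,
                        )
                    )
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    m = plan.bonferroni_m or max(
        1, results[["snp_id", "trait"]].drop_duplicates().shape[0]
    )
    results["bonferroni_flag"] = results["P_POE"] < plan.alpha / m
    return results


def _one_cell(
    plan, snp, trait, src, stratum, split, cohort,
    snp_calls, genotypes, phenotypes, split_labels, fam_of, sex_of, cov_cols,
) -> dict:
    base = {
        "snp_id": snp.snp_id, "chromosome": snp.chromosome,
        "gene_label": snp.gene_label, "location": snp.location,
        "alleles": f"{snp.effect_allele}/{snp.other_allele}",
        "trait": trait, "stratum": stratum, "cohort": cohort, "split": split,
        "N_het": 0, "bonferroni_flag": False, "note": "",
        **{k: np.nan for k in (
            "B_MAT", "SE_MAT", "P_MAT", "B_PAT", "SE_PAT", "P_PAT",
            "B_POE", "SE_POE", "P_POE",
        )},
    }

    def keep(iid: str) -> bool:
        if iid not in phenotypes.index:
            return False
        if split != "combined" and split_labels.get(fam_of.get(iid)) != split:
            return False
        if stratum == "sons" and sex_of.get(iid) != "male":
            return False
        if stratum == "daughters" and sex_of.get(iid) != "female":
            return False
        return True

    calls = snp_calls[snp_calls["individual_id"].map(keep)]
    gt = genotypes[snp.snp_id]
    gt = gt[gt.index.map(keep)]
    cov_all = _covariate_frame(phenotypes, cov_cols) if cov_cols else None

    try:
        if plan.contrast_mode == "joint":
            assigned = calls[calls["status"] == ASSIGNED]
            ids = assigned["individual_id"].tolist()
            if len(ids) < 3:
                base["note"] = "too few assigned offspring"
                return base
            res = _joint_fit(
                phenotypes.loc[ids, src].to_numpy(),
                assigned["maternal_minor"].to_numpy(),
                assigned["paternal_minor"].to_numpy(),
                cov_all.loc[ids] if cov_all is not None else None,
                [fam_of[i] for i in ids],
                plan.working_correlation,
            )
            base.update(res)
            het = assigned[
                assigned["maternal_minor"] + assigned["paternal_minor"] == 1
            ]
            base["N_het"] = int(len(het))
            return base

        poe_sample = build_contrast_sample(calls, gt, "poe")
        base["N_het"] = int(len(poe_sample))
        for contrast, (bk, sk, pk) in (
            ("maternal", ("B_MAT", "SE_MAT", "P_MAT")),
            ("paternal", ("B_PAT", "SE_PAT", "P_PAT")),
            ("poe", ("B_POE", "SE_POE", "P_POE")),
        ):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sample = build_contrast_sample(calls, gt, contrast)
            if sample["exposure"].sum() == 0 or len(sample) < 3:
                base["note"] += f"{contrast}:skipped;"
                continue
            ids = sample["individual_id"].tolist()
            beta, se, p = gee_fit(
                phenotypes.loc[ids, src].to_numpy(),
                sample["exposure"].to_numpy(),
                cov_all.loc[ids] if cov_all is not None else None,
                [fam_of[i] for i in ids],
                plan.working_correlation,
            )
            base[bk], base[sk], base[pk] = beta, se, p
    except GEEFitError as exc:
        base["note"] = f"fit_error: {exc}"
    return base


def apply_replication_rule(
    results: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Mark discovery hits replicated when the replication half agrees.

    A discovery-split POE hit (P_POE < alpha) is ``replicated`` when the
    replication split has P_POE < 0.05 with the same sign of B_POE.
    Returns the discovery rows with a ``replicated`` column.
    """
    keys = ["snp_id", "trait", "stratum", "cohort"]
    disc = results[results["split"] == "discovery"].copy()
    repl = results[results["split"] == "replication"].set_index(keys)
    flags = []
    for _, row in disc.iterrows():
        key = tuple(row[k] for k in keys)
        ok = False
        if row["P_POE"] < alpha and key in repl.index:
            r = repl.loc[key]
            ok = bool(
                r["P_POE"] < 0.05
                and np.sign(r["B_POE"]) == np.sign(row["B_POE"])
            )
        flags.append(ok)
    disc["replicated"] = flags
    return disc
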