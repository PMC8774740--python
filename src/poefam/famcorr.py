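"""Father–offspring vs mother–offspring trait resemblance.

Three nested analyses:

* model 1 — Spearman rank (or partial rank) correlation using only the
  oldest child per family, father–offspring and mother–offspring pairs
  compared with Fisher's r-to-z;
* model 2 — all offspring, random-intercept-by-family linear mixed model of
  offspring trait on parent trait;
* model 3 — model 2 plus offspring sex, age, age² and BMI as covariates;
  parental slopes compared with a Wald test.

The Fisher comparison treats the two correlations as independent even
though they share offspring (the conventional approach); a dependent-
correlation variant (Steiger) is available via ``dependent=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pedigree import Pedigree

__all__ = [
    "CorrelationComparison",
    "MixedSlopeResult",
    "parent_offspring_pairs",
    "spearman_partial",
    "mixed_slope",
    "fisher_r_to_z_compare",
    "wald_slope_compare",
    "compare_parental_correlations",
]


@dataclass
class CorrelationComparison:
    trait: str
    stratum: str
    r_father: float
    n_father: int
    r_mother: float
    n_mother: int
    z_diff: float
    p_diff: float


@dataclass
class MixedSlopeResult:
    trait: str
    parent_sex: str
    slope: float
    se: float
    p: float
    model: str
    converged: bool = True


def parent_offspring_pairs(
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    trait: str,
    parent_sex: str,
    oldest_only: bool = False,
    offspring_sex: str | None = None,
) -> pd.DataFrame:
    """Collect (parent value, offspring value) pairs for one trait.

    Parameters
    ----------
    parent_sex
        ``"male"`` for father–offspring pairs, ``"female"`` for mother–offspring.
    oldest_only
        Keep only the oldest child per family (requires an ``age`` column);
        families with no offspring age are skipped with a warning.
    offspring_sex
        Optional filter, ``"male"`` (sons) or ``"female"`` (daughters).

    Returns a DataFrame with columns family_id, parent_id, offspring_id,
    parent_value, offspring_value (rows with either value missing dropped).
    """
    rows = []
    skipped = 0
    for fam in pedigree.families:
        parent_id = fam.father_id if parent_sex == "male" else fam.mother_id
        if parent_id is None or parent_id not in phenotypes.index:
            continue
        kids = [k for k in fam.offspring if k in phenotypes.index]
        if offspring_sex is not None:
            kids = [k for k in kids if pedigree[k].sex == offspring_sex]
        if not kids:
            continue
        if oldest_only:
            if "age" not in phenotypes.columns:
                raise ValueError("oldest_only requires an 'age' phenotype column")
            ages = phenotypes.loc[kids, "age"]
            if ages.isna().all():
                skipped += 1
                continue
            kids = [ages.idxmax()]
        pv = phenotypes.at[parent_id, trait]
        for kid in kids:
            ov = phenotypes.at[kid, trait]
            if pd.isna(pv) or pd.isna(ov):
                continue
            rows.append(
                {
                    "family_id": fam.family_id,
                    "parent_id": parent_id,
                    "offspring_id": kid,
                    "parent_value": float(pv),
                    "offspring_value": float(ov),
                }
            )
    if skipped:
        warnings.warn(
            f"{skipped} family(ies) skipped: no offspring age for oldest_only",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows,
        columns=["family_id", "parent_id", "offspring_id", "parent_value", "offspring_value"],
    )


def spearman_partial(
    x, y, covariates: pd.DataFrame | np.ndarray | None = None
) -> tuple[float, int, float]:
    """Spearman correlation, optionally partialling covariates on the rank scale.

    With covariates, both variables are rank-transformed, residualized on
    the (rank-transformed numeric) covariates by least squares, and the
    Pearson correlation of the residuals is returned with its usual
    t-reference p-value.

    Returns (r, n, p); requires n >= 4 complete cases.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(x) & ~np.isnan(y)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        mask &= ~np.isnan(C).any(axis=1)
    n = int(mask.sum())
    if n < 4:
        raise ValueError(f"spearman_partial requires >= 4 complete pairs, got {n}")
    xr = stats.rankdata(x[mask])
    yr = stats.rankdata(y[mask])
    if C is None:
        r, p = stats.spearmanr(x[mask], y[mask])
        return float(r), n, float(p)
    Cr = np.column_stack(
        [np.ones(n)] + [stats.rankdata(C[mask, j]) for j in range(C.shape[1])]
    )
    rx = xr - Cr @ np.linalg.lstsq(Cr, xr, rcond=None)[0]
    ry = yr - Cr @ np.linalg.lstsq(Cr, yr, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - (Cr.shape[1] - 1)
    t = r * np.sqrt(df / max(1e-300, 1 - r * r))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, n, p


def mixed_slope(
    offspring_values,
    parent_values,
    family_ids,
    covariates: pd.DataFrame | np.ndarray | None = None,
    trait: str = "",
    parent_sex: str = "",
    model: str = "model2",
) -> MixedSlopeResult:
    """Random-intercept-by-family regression of offspring trait on parent trait.

    Fitted by REML via statsmodels MixedLM.  ``covariates`` (numeric
    columns) are added as fixed effects.  Non-convergence is flagged on the
    result rather than raised.
    """
    y = np.asarray(offspring_values, dtype=float)
    x = np.asarray(parent_values, dtype=float)
    groups = np.asarray(family_ids)
    mask = ~np.isnan(y) & ~np.isnan(x)
    X = x[:, None]
    names = ["parent"]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        mask &= ~np.isnan(C).any(axis=1)
        X = np.column_stack([X, C])
        if isinstance(covariates, pd.DataFrame):
            names += list(covariates.columns)
        else:
            names += [f"c{j}" for j in range(C.shape[1])]
    if len(np.unique(groups[mask])) < 2:
        raise ValueError("mixed_slope requires >= 2 families")
    exog = sm.add_constant(X[mask])
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.MixedLM(y[mask], exog, groups=groups[mask]).fit(reml=True)
            converged = bool(getattr(fit, "converged", True))
        except Exception:
            # fall back to OLS (family variance ~ 0 or tiny data)
            fit = sm.OLS(y[mask], exog).fit()
            converged = False
    return MixedSlopeResult(
        trait=trait,
        parent_sex=parent_sex,
        slope=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        model=model,
        converged=converged,
    )


def fisher_r_to_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations.

    z = (atanh(r1) − atanh(r2)) / sqrt(1/(n1−3) + 1/(n2−3)), two-sided
    normal p.
    """
    if min(n1, n2) < 4:
        raise ValueError("fisher_r_to_z_compare requires n >= 4 in each sample")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def wald_slope_compare(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Wald test of equality of two independent slopes."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.sqrt(se1**2 + se2**2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def compare_parental_correlations(
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    trait: str,
    stratum: str = "all",
    covariates: list[str] | None = None,
    oldest_only: bool = True,
    dependent: bool = False,
) -> CorrelationComparison:
    """Model-1 comparison of father– vs mother–offspring rank correlations.

    ``stratum`` is one of all / sons / daughters.  ``covariates`` names
    phenotype columns to partial out.  ``dependent=True`` applies Steiger's
    correction for the shared offspring member of the two correlations.
    """
    offspring_sex = {"all": None, "sons": "male", "daughters": "female"}[stratum]
    out = {}
    shared: dict[str, pd.Series] = {}
    for label, sex in (("father", "male"), ("mother", "female")):
        pairs = parent_offspring_pairs(
            pedigree, phenotypes, trait, sex,
            oldest_only=oldest_only, offspring_sex=offspring_sex,
        )
        cov = (
            phenotypes.loc[pairs["offspring_id"], covariates].to_numpy()
            if covariates
            else None
        )
        r, n, _ = spearman_partial(pairs["parent_value"], pairs["offspring_value"], cov)
        out[label] = (r, n)
        shared[label] = pairs.set_index("offspring_id")["offspring_value"]
    (rf, nf), (rm, nm) = out["father"], out["mother"]
    if dependent:
        common = shared["father"].index.intersection(shared["mother"].index)
        # correlation between the two parents' trait values over shared kids
        fp = phenotypes
        z, p = _steiger_compare(pedigree, fp, trait, rf, rm, nf, nm, common)
    else:
        z, p = fisher_r_to_z_compare(rf, nf, rm, nm)
    return CorrelationComparison(
        trait=trait, stratum=stratum,
        r_father=rf, n_father=nf, r_mother=rm, n_mother=nm,
        z_diff=z, p_diff=p,
    )


def _steiger_compare(pedigree, phenotypes, trait, rf, rm, nf, nm, common) -> tuple[float, float]:
    """Steiger's z for dependent correlations sharing the offspring variable."""
    fv, mv = [], []
    for kid in common:
        rec = pedigree[kid]
        if (
            rec.father_id in phenotypes.index
            and rec.mother_id in phenotypes.index
        ):
            a = phenotypes.at[rec.father_id, trait]
            b = phenotypes.at[rec.mother_id, trait]
            if not (pd.isna(a) or pd.isna(b)):
                fv.append(float(a))
                mv.append(float(b))
    n = min(nf, nm)
    if len(fv) < 4 or n < 4:
        return fisher_r_to_z_compare(rf, nf, rm, nm)
    r_fm = float(stats.spearmanr(fv, mv)[0])
    # Steiger's Z1*: difference of Fisher z's over the dependent-case SE
    z = (np.arctanh(rf) - np.arctanh(rm)) * np.sqrt(
        (n - 3) / (2 * (1 - r_fm) * _h(rf, rm, r_fm))
    )
    return float(z), float(2 * stats.norm.sf(abs(z)))


def _h(rf, rm, r_fm) -> float:
    rbar = (rf + rm) / 2
    f = min(1.0, (1 - r_fm) / (2 * (1 - rbar**2))) if rbar**2 < 1 else 1.0
    return (1 - f * rbar**2) / (1 - rbar**2)
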