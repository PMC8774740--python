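"""Parent-of-origin screening in unrelateds via heterozygote variance.

When the maternally and paternally inherited copies of an allele push a
trait in different directions, heterozygotes — whose parental origin is
hidden in a cohort of unrelateds — are a 50/50 mixture of two shifted
distributions, so their phenotypic variance exceeds the homozygotes' by
δ² where ±δ are the origin-specific means.  Two tests of that inflation
are provided:

* ``levene_het`` (default) — a one-sided Brown–Forsythe/Levene-type
  comparison of median-centered absolute deviations, heterozygotes vs
  pooled homozygotes;
* ``mixture_lrt`` — a likelihood-ratio test of the heterozygote residuals
  as an equal-weight two-component normal mixture with means μ ± δ against
  δ = 0, referred to a half–chi-square(1) boundary distribution.

Covariates are removed once by least-squares residualization before
grouping.  Fractional (imputed) dosages are supported through per-group
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceTestResult",
    "het_variance_test",
    "mean_genotype_support",
    "variance_poe_sweep",
]


@dataclass
class VarianceTestResult:
    snp_id: str
    trait: str
    n0: int
    n1: int
    n2: int
    var0: float
    var1: float
    var2: float
    statistic: float
    p_value: float
    method: str
    tested: bool = True
    note: str = ""


def _residualize(y: np.ndarray, covariates) -> np.ndarray:
    if covariates is None:
        return y - np.nanmean(y)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(len(y)), C])
    mask = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    beta = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
    out = np.full_like(y, np.nan)
    out[mask] = y[mask] - X[mask] @ beta
    return out


def mean_genotype_support(dosages) -> np.ndarray:
    """Per-group weights for (possibly fractional) mean genotypes.

    Maps each dosage d ∈ [0, 2] to weights over hard-call groups (0, 1, 2)
    by linear interpolation between the neighbouring integers; integer
    dosages reduce to exact one-hot grouping.  Returns an (n, 3) array.
    """
    d = np.asarray(dosages, dtype=float)
    if np.nanmin(d) < 0 or np.nanmax(d) > 2:
        raise ValueError("dosages must lie in [0, 2]")
    w = np.zeros((len(d), 3))
    lo = np.clip(np.floor(d), 0, 1).astype(int)
    frac = d - lo
    rows = np.arange(len(d))
    w[rows, lo] = 1 - frac
    w[rows, lo + 1] = frac
    w[np.isnan(d)] = np.nan
    return w


def _weighted_var(y: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    if sw <= 1:
        return np.nan
    mu = (w * y).sum() / sw
    return float((w * (y - mu) ** 2).sum() / (sw - 1))


def het_variance_test(
    trait_values,
    genotypes,
    covariates=None,
    method: str = "levene_het",
    snp_id: str = "",
    trait: str = "",
    min_group: int = 10,
) -> VarianceTestResult:
    """Test for excess residual variance among heterozygotes.

    ``genotypes`` may be integer hard calls or fractional dosages in
    [0, 2].  One-sided in the inflation direction for ``levene_het``;
    half-chi-square(1) reference for ``mixture_lrt``.
    """
    y = np.asarray(trait_values, dtype=float)
    d = np.asarray(genotypes, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(d)
    y, d = y[mask], d[mask]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C = C[mask]
    else:
        C = None
    resid = _residualize(y, C)
    ok = ~np.isnan(resid)
    resid, d = resid[ok], d[ok]
    w = mean_genotype_support(d)
    n_grp = np.round(w.sum(axis=0)).astype(int)
    var_grp = [_weighted_var(resid, w[:, g]) for g in range(3)]

    base = VarianceTestResult(
        snp_id=snp_id, trait=trait,
        n0=int(n_grp[0]), n1=int(n_grp[1]), n2=int(n_grp[2]),
        var0=var_grp[0], var1=var_grp[1], var2=var_grp[2],
        statistic=np.nan, p_value=np.nan, method=method,
    )
    hard_het = d == 1
    hard_hom = (d == 0) | (d == 2)
    # fractional dosages contribute via weights; hard calls drive group sizes
    if min(n_grp[1], n_grp[0] + n_grp[2]) < min_group:
        base.tested = False
        base.note = "group too small"
        return base

    if method == "levene_het":
        w_het = w[:, 1]
        w_hom = w[:, 0] + w[:, 2]
        med_het = _weighted_median(resid, w_het)
        med_hom = _weighted_median(resid, w_hom)
        a_het = np.abs(resid - med_het)
        a_hom = np.abs(resid - med_hom)
        n1 = w_het.sum()
        n0 = w_hom.sum()
        m1 = (w_het * a_het).sum() / n1
        m0 = (w_hom * a_hom).sum() / n0
        v1 = (w_het * (a_het - m1) ** 2).sum() / (n1 - 1)
        v0 = (w_hom * (a_hom - m0) ** 2).sum() / (n0 - 1)
        pooled = v1 / n1 + v0 / n0
        if pooled <= 0:  # degenerate: no dispersion in either group
            base.statistic, base.p_value = 0.0, 1.0
            return base
        t = (m1 - m0) / np.sqrt(pooled)
        df = pooled**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        )
        base.statistic = float(t)
        base.p_value = float(stats.t.sf(t, df))  # one-sided: inflation only
    elif method == "mixture_lrt":
        r_het = resid[hard_het]
        ll1, _ = _fit_symmetric_mixture(r_het)
        ll0 = _normal_loglik(r_het)
        lrt = max(0.0, 2 * (ll1 - ll0))
        base.statistic = float(lrt)
        base.p_value = float(0.5 * stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0
        del hard_hom
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.allclose(resid, resid[0] if len(resid) else 0.0):
        base.statistic = 0.0
        base.p_value = 1.0
    return base


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    if cw[-1] <= 0:
        return np.nan
    return float(x[order][np.searchsorted(cw, 0.5 * cw[-1])])


def _normal_loglik(x: np.ndarray) -> float:
    mu, sd = x.mean(), x.std()
    sd = max(sd, 1e-12)
    return float(stats.norm.logpdf(x, mu, sd).sum())


def _fit_symmetric_mixture(x: np.ndarray) -> tuple[float, float]:
    """MLE of the equal-weight N(μ−δ,σ²)/N(μ+δ,σ²) mixture; returns (ll, δ̂)."""

    def nll(params):
        mu, log_sd, delta = params
        sd = np.exp(log_sd)
        ll = np.logaddexp(
            stats.norm.logpdf(x, mu - delta, sd),
            stats.norm.logpdf(x, mu + delta, sd),
        ) - np.log(2.0)
        return -ll.sum()

    sd0 = max(x.std(), 1e-6)
    best = None
    for delta0 in (0.0, 0.5 * sd0, sd0):
        res = optimize.minimize(
            nll, x0=[x.mean(), np.log(sd0), delta0], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return -float(best.fun), float(abs(best.x[2]))


def variance_poe_sweep(
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    traits: list[str],
    covariate_cols: list[str] | None = None,
    method: str = "levene_het",
) -> pd.DataFrame:
    """Run het_variance_test for every SNP × trait in an unrelated cohort."""
    rows = []
    ids = genotypes.index.intersection(phenotypes.index)
    cov = (
        phenotypes.loc[ids, covariate_cols].to_numpy(dtype=float)
        if covariate_cols
        else None
    )
    for snp_id in genotypes.columns:
        for trait in traits:
            res = het_variance_test(
                phenotypes.loc[ids, trait].to_numpy(dtype=float),
                genotypes.loc[ids, snp_id].to_numpy(dtype=float),
                covariates=cov,
                method=method,
                snp_id=snp_id,
                trait=trait,
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
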