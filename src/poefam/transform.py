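"""Trait derivations and normalizations for lipid and obesity phenotypes.

Derived traits: Friedewald LDL-C, ApoB/ApoA1 ratio, BMI, waist–hip ratio
(WHR), and waist–height ratio (WHtR).  Normalizations: rank-based inverse
normal (Blom) transform for TG, ApoB, LDL-C and all obesity measures;
natural log for the remaining lipid measures; a single-pass 5-SD outlier
filter on the transformed scale.  Every transformed column carries a
provenance tag (raw / ln / blom) so downstream results can report the scale
their betas live on.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "friedewald_ldl",
    "blom_transform",
    "ln_transform",
    "sd_outlier_filter",
    "derive_traits",
    "BLOM_TRAITS",
    "LN_TRAITS",
    "OBESITY_TRAITS",
    "LIPID_TRAITS",
]

# transformation scheme: rank-normal for skewed lipids and all obesity
# measures, natural log for the rest of the lipid panel
OBESITY_TRAITS = ("BMI", "WHR", "WHtR")
BLOM_TRAITS = ("TG", "ApoB", "LDL") + OBESITY_TRAITS
LN_TRAITS = ("TC", "HDL", "ApoA1", "ApoA2", "ApoB_ApoA1")
LIPID_TRAITS = ("TC", "TG", "HDL", "LDL", "ApoA1", "ApoA2", "ApoB", "ApoB_ApoA1")

# Friedewald validity threshold: TG < 400 mg/dL; the mmol/L form divides
# TG by 2.2 and applies the equivalent threshold
_TG_LIMIT_MGDL = 400.0
_TG_LIMIT_MMOL = 4.52
_TG_DIVISOR = {"mg/dL": 5.0, "mmol/L": 2.2}


def friedewald_ldl(tc, hdl, tg, unit: str = "mg/dL"):
    """Estimate LDL-C as TC − HDL-C − TG/5 (mg/dL), valid when TG < 400 mg/dL.

    In mmol/L mode the triglyceride divisor is 2.2 and the validity
    threshold 4.52 mmol/L.  Above-threshold TG yields a missing value.
    Accepts scalars or array-likes; NaN inputs propagate as missing.
    """
    if unit not in _TG_DIVISOR:
        raise ValueError(f"unit must be 'mg/dL' or 'mmol/L', got {unit!r}")
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(tc < 0) or np.any(hdl < 0) or np.any(tg < 0):
            raise ValueError("lipid concentrations must be non-negative")
    limit = _TG_LIMIT_MGDL if unit == "mg/dL" else _TG_LIMIT_MMOL
    ldl = tc - hdl - tg / _TG_DIVISOR[unit]
    with np.errstate(invalid="ignore"):
        ldl = np.where(tg < limit, ldl, np.nan)
    return float(ldl) if ldl.ndim == 0 else ldl


def blom_transform(values) -> np.ndarray:
    """Blom rank-based inverse normal transform.

    Non-missing entries are replaced by Φ⁻¹((rᵢ − 3/8)/(n + 1/4)) where rᵢ
    is the average rank among the n non-missing values; missing entries are
    preserved.
    """
    v = np.asarray(values, dtype=float)
    mask = ~np.isnan(v)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("blom_transform requires at least 2 non-missing values")
    obs = v[mask]
    if np.all(obs == obs[0]):
        raise ValueError("blom_transform undefined for constant input")
    ranks = stats.rankdata(obs, method="average")
    out = np.full_like(v, np.nan)
    out[mask] = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return out


def ln_transform(values) -> np.ndarray:
    """Elementwise natural log; non-positive values become missing with a warning."""
    v = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (v <= 0) & ~np.isnan(v)
    if bad.any():
        warnings.warn(
            f"ln_transform: {int(bad.sum())} non-positive value(s) set to missing",
            stacklevel=2,
        )
    out = np.full_like(v, np.nan)
    ok = ~np.isnan(v) & ~bad
    out[ok] = np.log(v[ok])
    return out


def sd_outlier_filter(values, k: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass k-SD outlier removal.

    Mean and SD are computed once on the non-missing values; entries with
    \\|v − mean\\| > k·SD are set to missing.  Returns the filtered vector and
    the integer positions removed.
    """
    v = np.asarray(values, dtype=float).copy()
    mask = ~np.isnan(v)
    if mask.sum() < 3:
        raise ValueError("sd_outlier_filter requires at least 3 non-missing values")
    mu = v[mask].mean()
    sd = v[mask].std(ddof=1)
    if sd == 0:
        return v, np.array([], dtype=int)
    removed = np.nonzero(mask & (np.abs(v - mu) > k * sd))[0]
    v[removed] = np.nan
    return v, removed


def _require(df: pd.DataFrame, cols: list[str]) -> bool:
    return all(c in df.columns for c in cols)


def derive_traits(
    raw: pd.DataFrame,
    units: dict[str, str],
    outlier_k: float = 5.0,
    filter_on_transformed: bool = True,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Fill derived traits and apply the per-trait normalization scheme.

    Parameters
    ----------
    raw
        Phenotype table with any of: TC, TG, HDL, ApoA1, ApoA2, ApoB
        (lipids), height (m), weight (kg), waist (cm), hip (cm), plus
        sex/age/diabetes covariates, indexed by individual.
    units
        Unit declarations; must at least declare ``lipids`` as ``mg/dL`` or
        ``mmol/L`` when lipid columns are present.
    filter_on_transformed
        Run the k-SD filter on the transformed scale (default); the raw
        scale mode exists for sensitivity analyses.

    Returns
    -------
    (table, tags)
        The transformed table and a per-trait transformation tag
        (raw / ln / blom).
    """
    df = raw.copy()
    has_lipids = any(c in df.columns for c in ("TC", "TG", "HDL"))
    if has_lipids and "lipids" not in units:
        raise ValueError("units must declare the lipid unit ('mg/dL' or 'mmol/L')")
    lipid_unit = units.get("lipids", "mg/dL")

    # derived columns
    if _require(df, ["weight", "height"]):
        df["BMI"] = df["weight"] / df["height"] ** 2
    if _require(df, ["waist", "hip"]):
        df["WHR"] = df["waist"] / df["hip"]
    if _require(df, ["waist", "height"]):
        # waist in cm, height in m
        df["WHtR"] = df["waist"] / (df["height"] * 100.0)
    if _require(df, ["ApoB", "ApoA1"]):
        df["ApoB_ApoA1"] = df["ApoB"] / df["ApoA1"]
    if _require(df, ["TC", "HDL", "TG"]) and "LDL" not in df.columns:
        df["LDL"] = friedewald_ldl(df["TC"], df["HDL"], df["TG"], unit=lipid_unit)

    tags: dict[str, str] = {}
    for trait in df.columns:
        if trait in BLOM_TRAITS:
            scheme = "blom"
        elif trait in LN_TRAITS:
            scheme = "ln"
        else:
            tags[trait] = "raw"
            continue
        col = df[trait].to_numpy(dtype=float)
        if not filter_on_transformed:
            col, _ = sd_outlier_filter(col, k=outlier_k)
        if scheme == "ln":
            col = ln_transform(col)
        else:
            col = blom_transform(col)
        if filter_on_transformed:
            col, _ = sd_outlier_filter(col, k=outlier_k)
        df[trait] = col
        tags[trait] = scheme
    return df, tags
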