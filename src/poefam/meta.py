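"""Fixed-effects meta-analysis of per-cohort POE estimates.

Two standard schemes: inverse-variance weighting of betas/SEs (default —
the strata tables report betas) and sample-size-weighted z-scores for
SE-less inputs.  A direction-consistency flag records whether all cohorts
agree in sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaResult",
    "inverse_variance_meta",
    "sample_size_meta",
    "direction_consistency",
    "meta_analyze_results",
]


@dataclass
class MetaResult:
    snp_id: str = ""
    trait: str = ""
    stratum: str = ""
    method: str = "inverse_variance"
    cohort_betas: list = field(default_factory=list)
    cohort_ses: list = field(default_factory=list)
    beta: float = np.nan
    se: float = np.nan
    z: float = np.nan
    p: float = np.nan
    direction: str = ""


def inverse_variance_meta(
    estimates: list[tuple[float, float]], **meta_fields
) -> MetaResult:
    """Combine (beta, se) pairs with weights 1/se²."""
    if len(estimates) < 1:
        raise ValueError("need at least one estimate")
    if any(se <= 0 for _, se in estimates):
        raise ValueError("all standard errors must be positive")
    if len(estimates) == 1:
        warnings.warn("single estimate: meta-analysis is a passthrough", stacklevel=2)
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    return MetaResult(
        method="inverse_variance",
        cohort_betas=list(betas), cohort_ses=list(ses),
        beta=beta, se=se, z=float(z),
        p=float(2 * stats.norm.sf(abs(z))),
        direction="".join("+" if b > 0 else "-" if b < 0 else "0" for b in betas),
        **meta_fields,
    )


def sample_size_meta(
    estimates: list[tuple[float, float]], **meta_fields
) -> MetaResult:
    """Combine (z, n) pairs: meta z = Σ zᵢ√nᵢ / √Σnᵢ (signs carried by zᵢ)."""
    if len(estimates) < 1:
        raise ValueError("need at least one estimate")
    if any(n <= 0 for _, n in estimates):
        raise ValueError("all sample sizes must be positive")
    if len(estimates) == 1:
        warnings.warn("single estimate: meta-analysis is a passthrough", stacklevel=2)
    zs = np.array([z for z, _ in estimates], dtype=float)
    ns = np.array([n for _, n in estimates], dtype=float)
    z = float((zs * np.sqrt(ns)).sum() / np.sqrt(ns.sum()))
    return MetaResult(
        method="sample_size_z",
        cohort_betas=list(zs), cohort_ses=list(np.sqrt(ns)),
        z=z, p=float(2 * stats.norm.sf(abs(z))),
        direction="".join("+" if v > 0 else "-" if v < 0 else "0" for v in zs),
        **meta_fields,
    )


def direction_consistency(estimates) -> bool:
    """True iff all non-null effect estimates share a sign."""
    vals = [b for b in np.asarray(estimates, dtype=float).ravel() if b == b and b != 0]
    if len(vals) < 2:
        warnings.warn("fewer than two non-null estimates", stacklevel=2)
        return True
    signs = {np.sign(v) for v in vals}
    return len(signs) == 1


def meta_analyze_results(
    per_cohort: list[pd.DataFrame],
    method: str = "inverse_variance",
    beta_col: str = "B_POE",
    se_col: str = "SE_POE",
) -> pd.DataFrame:
    """Meta-analyze the POE contrast across cohort result tables.

    Each input is a run_analysis result table; rows are matched on
    (snp_id, trait, stratum).  Returns one row per matched key with the
    combined estimate and a direction string.
    """
    keys = ["snp_id", "trait", "stratum"]
    indexed = [df.set_index(keys) for df in per_cohort]
    common = indexed[0].index
    for df in indexed[1:]:
        common = common.intersection(df.index)
    rows = []
    for key in common.unique():
        ests = []
        for df in indexed:
            sub = df.loc[[key]]
            b, s = float(sub[beta_col].iloc[0]), float(sub[se_col].iloc[0])
            if np.isnan(b) or np.isnan(s) or s <= 0:
                break
            ests.append((b, s))
        if len(ests) != len(indexed):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if method == "inverse_variance":
                res = inverse_variance_meta(ests)
            else:
                zs = [(b / s, 1.0 / s**2) for b, s in ests]
                res = sample_size_meta(zs)
        rows.append(
            {
                "snp_id": key[0], "trait": key[1], "stratum": key[2],
                "method": res.method, "beta": res.beta, "se": res.se,
                "z": res.z, "p": res.p, "direction": res.direction,
                "consistent": direction_consistency([b for b, _ in ests]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "trait", "stratum", "method", "beta", "se", "z", "p",
                 "direction", "consistent"],
    )
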