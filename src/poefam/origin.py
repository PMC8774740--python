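"""Parental-origin inference for offspring alleles from trio/duo genotypes.

For each offspring and SNP, decide how many copies of the minor allele were
inherited from the mother and from the father by intersecting the observed
offspring genotype with the transmission configurations the parental
genotypes allow.  A call is ``assigned`` only when exactly one ordered
(maternal allele, paternal allele) configuration is compatible: a trio in
which both parents are heterozygous and so is the child stays ``ambiguous``
— no sibling-aided phasing, no population phasing.  Offspring whose
genotype is impossible given the parents' are ``mendelian_error``;
offspring with neither parent genotyped are ``untestable``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = ["OriginCall", "infer_trio_origin", "infer_cohort_origins"]

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
MENDELIAN_ERROR = "mendelian_error"
UNTESTABLE = "untestable"


@dataclass(frozen=True)
class OriginCall:
    individual_id: str
    snp_id: str
    status: str
    maternal_minor: int | None = None
    paternal_minor: int | None = None


def _is_missing(gt) -> bool:
    return gt is None or (isinstance(gt, float) and math.isnan(gt))


def _check_gt(gt, who: str, allow_missing: bool):
    if _is_missing(gt):
        if allow_missing:
            return None
        raise ValueError(f"{who} genotype is missing")
    g = float(gt)
    if g not in (0.0, 1.0, 2.0):
        raise ValueError(f"invalid {who} genotype {gt!r}: expected 0, 1 or 2")
    return int(g)


def infer_trio_origin(
    offspring_gt,
    mother_gt=None,
    father_gt=None,
    individual_id: str = "",
    snp_id: str = "",
) -> OriginCall:
    """Infer maternal/paternal minor-allele counts for one offspring.

    Parameters
    ----------
    offspring_gt
        Offspring minor-allele count in {0, 1, 2} (must be non-missing).
    mother_gt, father_gt
        Parental counts; ``None``/NaN marks an ungenotyped parent.

    Returns
    -------
    OriginCall
        ``assigned`` with the unique (maternal, paternal) split, or
        ``ambiguous``/``mendelian_error``/``untestable``.
    """
    off = _check_gt(offspring_gt, "offspring", allow_missing=False)
    mom = _check_gt(mother_gt, "mother", allow_missing=True)
    dad = _check_gt(father_gt, "father", allow_missing=True)

    if mom is None and dad is None:
        return OriginCall(individual_id, snp_id, UNTESTABLE)

    trans = {None: (0, 1), 0: (0,), 1: (0, 1), 2: (1,)}
    configs = {
        (a, b) for a in trans[mom] for b in trans[dad] if a + b == off
    }
    if not configs:
        return OriginCall(individual_id, snp_id, MENDELIAN_ERROR)
    if len(configs) > 1:
        return OriginCall(individual_id, snp_id, AMBIGUOUS)
    a, b = configs.pop()
    return OriginCall(individual_id, snp_id, ASSIGNED, maternal_minor=a, paternal_minor=b)


def _call_lookup() -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Tabulate infer_trio_origin over all (offspring, mother, father) codes.

    Parent code 3 encodes a missing genotype.  Returns integer status codes
    plus maternal/paternal counts (-1 where unassigned).
    """
    statuses = [ASSIGNED, AMBIGUOUS, MENDELIAN_ERROR, UNTESTABLE]
    status_idx = {s: i for i, s in enumerate(statuses)}
    stat = np.zeros((3, 4, 4), dtype=np.int8)
    mat = np.full((3, 4, 4), -1, dtype=np.int8)
    pat = np.full((3, 4, 4), -1, dtype=np.int8)
    for off in range(3):
        for m in range(4):
            for d in range(4):
                call = infer_trio_origin(
                    off,
                    np.nan if m == 3 else m,
                    np.nan if d == 3 else d,
                )
                stat[off, m, d] = status_idx[call.status]
                if call.status == ASSIGNED:
                    mat[off, m, d] = call.maternal_minor
                    pat[off, m, d] = call.paternal_minor
    return stat, mat, pat, statuses


_STAT_TABLE, _MAT_TABLE, _PAT_TABLE, _STATUSES = _call_lookup()


def infer_cohort_origins(
    pedigree: Pedigree, genotypes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run origin inference for every offspring × SNP.

    Returns
    -------
    calls : DataFrame
        Columns individual_id, snp_id, status, maternal_minor,
        paternal_minor — one row per offspring × SNP with a non-missing
        offspring genotype.
    summary : DataFrame
        Per-SNP counts of assigned / ambiguous / mendelian_error /
        untestable calls.
    """
    off_ids: list[str] = []
    mom_ids: list[str] = []
    dad_ids: list[str] = []
    for fam in pedigree.families:
        for child in fam.offspring:
            if child in genotypes.index:
                off_ids.append(child)
                mom_ids.append(fam.mother_id if fam.mother_id in genotypes.index else "\0")
                dad_ids.append(fam.father_id if fam.father_id in genotypes.index else "\0")

    snp_ids = list(genotypes.columns)
    if off_ids and snp_ids:
        O = genotypes.reindex(off_ids).to_numpy(dtype=float)
        M = genotypes.reindex(mom_ids).to_numpy(dtype=float)
        D = genotypes.reindex(dad_ids).to_numpy(dtype=float)
        valid = ~np.isnan(O)
        oc = np.where(valid, O, 0).astype(int)
        mc = np.where(np.isnan(M), 3, M).astype(int)
        dc = np.where(np.isnan(D), 3, D).astype(int)
        stat = _STAT_TABLE[oc, mc, dc]
        mat = _MAT_TABLE[oc, mc, dc].astype(float)
        pat = _PAT_TABLE[oc, mc, dc].astype(float)
        mat[mat < 0] = np.nan
        pat[pat < 0] = np.nan
        rows, cols = np.nonzero(valid)
        calls = pd.DataFrame(
            {
                "individual_id": np.asarray(off_ids, dtype=object)[rows],
                "snp_id": np.asarray(snp_ids, dtype=object)[cols],
                "status": np.asarray(_STATUSES, dtype=object)[stat[rows, cols]],
                "maternal_minor": mat[rows, cols],
                "paternal_minor": pat[rows, cols],
            }
        )
    else:
        calls = pd.DataFrame(
            columns=["individual_id", "snp_id", "status", "maternal_minor", "paternal_minor"]
        )
    if len(calls):
        summary = (
            calls.groupby(["snp_id", "status"]).size().unstack(fill_value=0)
        )
        for col in (ASSIGNED, AMBIGUOUS, MENDELIAN_ERROR, UNTESTABLE):
            if col not in summary.columns:
                summary[col] = 0
        summary = summary[[ASSIGNED, AMBIGUOUS, MENDELIAN_ERROR, UNTESTABLE]].reset_index()
    else:
        summary = pd.DataFrame(
            columns=["snp_id", ASSIGNED, AMBIGUOUS, MENDELIAN_ERROR, UNTESTABLE]
        )
    return calls, summary
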