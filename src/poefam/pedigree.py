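"""Nuclear-family pedigrees, genotype tables, and per-SNP quality control.

Pedigrees are nuclear families: two parents (either of whom may be
ungenotyped or absent from the file) and their common offspring.  Genotypes
are stored as minor-allele counts in {0, 1, 2}, keyed by individual and SNP.
QC covers per-SNP call rate, an exact Hardy–Weinberg equilibrium test
(founders only by default, since offspring genotypes are correlated with
their parents'), and Mendelian-consistency checks within each family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "IndividualRecord",
    "SnpInfo",
    "NuclearFamily",
    "Pedigree",
    "PedigreeError",
    "GenotypeParseError",
    "read_pedigree",
    "read_snp_panel",
    "write_pedigree",
    "hwe_exact_test",
    "mendelian_check",
    "snp_qc",
]


class PedigreeError(ValueError):
    """Invalid pedigree structure (duplicate ids, inconsistent parent sex...)."""


class GenotypeParseError(ValueError):
    """Malformed genotype file (non-{0,1,2,NA} cell, unknown individual...)."""


@dataclass(frozen=True)
class IndividualRecord:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"
    role: str  # "parent" | "offspring"


@dataclass(frozen=True)
class SnpInfo:
    """Panel annotation for one biallelic SNP.

    ``effect_allele`` is the minor allele: genotype counts and association
    betas are per copy of this allele.
    """

    snp_id: str
    chromosome: str
    gene_label: str
    effect_allele: str
    other_allele: str
    maf: float
    location: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf {self.maf} outside (0, 0.5]")


@dataclass
class NuclearFamily:
    family_id: str
    father_id: str | None
    mother_id: str | None
    offspring: list[str] = field(default_factory=list)


class Pedigree:
    """A validated set of nuclear families.

    Parameters
    ----------
    records
        One :class:`IndividualRecord` per pedigree member.
    """

    def __init__(self, records: list[IndividualRecord]):
        self.records = list(records)
        self._by_id: dict[str, IndividualRecord] = {}
        self._validate()
        self.families = self._index_families()

    def _validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.family_id, rec.individual_id)
            if key in seen:
                raise PedigreeError(
                    f"duplicated individual_id {rec.individual_id!r} "
                    f"in family {rec.family_id!r}"
                )
            seen.add(key)
            if rec.individual_id in self._by_id:
                raise PedigreeError(
                    f"individual_id {rec.individual_id!r} appears in more than "
                    "one family; ids must be unique to key genotype rows"
                )
            self._by_id[rec.individual_id] = rec

        offenders = []
        for rec in self.records:
            for pid, want_sex, label in (
                (rec.father_id, "male", "father"),
                (rec.mother_id, "female", "mother"),
            ):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    warnings.warn(
                        f"{rec.family_id}/{rec.individual_id}: {label}_id {pid!r} "
                        "not present in pedigree",
                        stacklevel=3,
                    )
                    continue
                if parent.family_id != rec.family_id:
                    raise PedigreeError(
                        f"{rec.family_id}/{rec.individual_id}: {label} {pid!r} "
                        f"belongs to family {parent.family_id!r}"
                    )
                if parent.sex != want_sex:
                    offenders.append(f"{rec.family_id}/{rec.individual_id}")
        if offenders:
            raise PedigreeError(
                "sex-inconsistent parent link(s) for: " + ", ".join(offenders)
            )

    def _index_families(self) -> list[NuclearFamily]:
        fams: dict[tuple[str, str | None, str | None], NuclearFamily] = {}
        for rec in self.records:
            if rec.role != "offspring":
                continue
            key = (rec.family_id, rec.father_id, rec.mother_id)
            fam = fams.get(key)
            if fam is None:
                fam = NuclearFamily(rec.family_id, rec.father_id, rec.mother_id)
                fams[key] = fam
            fam.offspring.append(rec.individual_id)
        return list(fams.values())

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, individual_id: str) -> IndividualRecord:
        return self._by_id[individual_id]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    @property
    def founder_ids(self) -> list[str]:
        return [r.individual_id for r in self.records if r.role == "parent"]

    @property
    def offspring_ids(self) -> list[str]:
        return [r.individual_id for r in self.records if r.role == "offspring"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family_id": [r.family_id for r in self.records],
                "individual_id": [r.individual_id for r in self.records],
                "father_id": [r.father_id or "0" for r in self.records],
                "mother_id": [r.mother_id or "0" for r in self.records],
                "sex": [r.sex for r in self.records],
                "role": [r.role for r in self.records],
            }
        )


_SEX_FROM_PED = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}


def _records_from_rows(rows: list[tuple[str, str, str, str, str]]) -> list[IndividualRecord]:
    # role is derived: anyone named as a father/mother is a parent
    parent_ids = set()
    for _fam, _iid, fid, mid, _sex in rows:
        if fid != "0":
            parent_ids.add(fid)
        if mid != "0":
            parent_ids.add(mid)
    records = []
    for fam, iid, fid, mid, sex in rows:
        role = "parent" if iid in parent_ids else "offspring"
        records.append(
            IndividualRecord(
                family_id=fam,
                individual_id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=sex,
                role=role,
            )
        )
    return records


def read_pedigree(pedigree_path, genotype_path=None) -> tuple[Pedigree, pd.DataFrame | None]:
    """Read a pedigree (PLINK PED/FAM dialect or headered TSV) and genotypes.

    The dialect is auto-detected: a first line containing a ``family``
    column header selects the TSV dialect, otherwise 6-column PED/FAM
    conventions apply (0 = missing parent, sex 1=male/2=female/0=unknown).

    Returns the validated :class:`Pedigree` and, when ``genotype_path`` is
    given, a genotype table (rows = individuals, columns = SNP ids, values
    float minor-allele counts with NaN for missing).
    """
    with open(pedigree_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise PedigreeError(f"{pedigree_path}: empty pedigree file")

    header_tokens = lines[0].lower().split()
    rows: list[tuple[str, str, str, str, str]] = []
    if "family" in header_tokens or "family_id" in header_tokens:
        cols = lines[0].split("\t")
        colmap = {c.lower().replace("_id", ""): i for i, c in enumerate(cols)}
        needed = ["family", "individual", "father", "mother", "sex"]
        missing = [c for c in needed if c not in colmap]
        if missing:
            raise PedigreeError(f"{pedigree_path}: missing columns {missing}")
        for ln in lines[1:]:
            parts = ln.split("\t")
            fam, iid, fid, mid, sex = (parts[colmap[c]].strip() for c in needed)
            sex = sex.lower()
            if sex in _SEX_FROM_PED:
                sex = _SEX_FROM_PED[sex]
            if sex not in ("male", "female", "unknown"):
                raise PedigreeError(f"{pedigree_path}: bad sex code {sex!r}")
            rows.append((fam, iid, fid or "0", mid or "0", sex))
    else:
        for lineno, ln in enumerate(lines, start=1):
            parts = ln.split()
            if len(parts) < 5:
                raise PedigreeError(
                    f"{pedigree_path}:{lineno}: expected >=5 whitespace-separated "
                    f"columns, got {len(parts)}"
                )
            fam, iid, fid, mid, sex = parts[:5]
            if sex not in _SEX_FROM_PED:
                raise PedigreeError(f"{pedigree_path}:{lineno}: bad sex code {sex!r}")
            rows.append((fam, iid, fid, mid, _SEX_FROM_PED[sex]))

    pedigree = Pedigree(_records_from_rows(rows))
    genotypes = None
    if genotype_path is not None:
        genotypes = read_genotypes(genotype_path)
        unknown = set(genotypes.index) - {r.individual_id for r in pedigree.records}
        if unknown:
            warnings.warn(
                f"{genotype_path}: {len(unknown)} genotyped individual(s) absent "
                "from the pedigree",
                stacklevel=2,
            )
    return pedigree, genotypes


def read_genotypes(genotype_path) -> pd.DataFrame:
    """Read a genotype TSV (first column individual_id, cells in {0,1,2,NA})."""
    df = pd.read_csv(genotype_path, sep="\t", dtype=str)
    df = df.set_index(df.columns[0])
    out = pd.DataFrame(index=df.index.astype(str), dtype=float)
    for col in df.columns:
        vals = np.full(len(df), np.nan)
        for i, raw in enumerate(df[col].to_numpy()):
            s = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
            if s in ("", "NA", "nan", "."):
                continue
            if s not in ("0", "1", "2"):
                raise GenotypeParseError(
                    f"{genotype_path}: line {i + 2}, column {col!r}: "
                    f"invalid genotype {raw!r} (expected 0/1/2/NA)"
                )
            vals[i] = float(s)
        out[col] = vals
    out.index.name = "individual_id"
    return out


def write_pedigree(pedigree: Pedigree, path, dialect: str = "ped") -> None:
    """Write a pedigree back out; ``ped`` emits 6-column PED/FAM lines."""
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("family\tindividual\tfather\tmother\tsex\n")
            for r in pedigree.records:
                fh.write(
                    f"{r.family_id}\t{r.individual_id}\t{r.father_id or '0'}\t"
                    f"{r.mother_id or '0'}\t{r.sex}\n"
                )
        else:
            for r in pedigree.records:
                fh.write(
                    f"{r.family_id} {r.individual_id} {r.father_id or '0'} "
                    f"{r.mother_id or '0'} {_SEX_TO_PED[r.sex]} -9\n"
                )


def read_snp_panel(path) -> list[SnpInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    panel = []
    for _, row in df.iterrows():
        panel.append(
            SnpInfo(
                snp_id=row["snp_id"],
                chromosome=str(row["chr"]),
                gene_label=row.get("gene", ""),
                effect_allele=row["effect_allele"],
                other_allele=row["other_allele"],
                maf=float(row.get("maf", 0.25)),
                location=str(row.get("location", "")),
            )
        )
    return panel


def hwe_exact_test(genotypes: pd.Series | np.ndarray) -> float:
    """Two-sided exact Hardy–Weinberg equilibrium p-value.

    Enumerates the full conditional distribution of the heterozygote count
    given the observed allele counts and sums the probabilities of all
    outcomes no more likely than the observed one (the standard exact HWE
    test).  Monomorphic SNPs return p = 1 with a warning.
    """
    g = np.asarray(pd.Series(genotypes).dropna(), dtype=float)
    if g.size == 0:
        raise ValueError("hwe_exact_test requires at least one non-missing genotype")
    if not np.isin(g, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotypes must be minor-allele counts in {0,1,2}")
    n_het = int((g == 1).sum())
    n_hom_minor = int((g == 2).sum())
    n = g.size
    n_minor = 2 * n_hom_minor + n_het  # minor-allele count
    if n_minor == 0 or n_minor == 2 * n:
        warnings.warn("monomorphic SNP: HWE p-value set to 1", stacklevel=2)
        return 1.0
    rare = min(n_minor, 2 * n - n_minor)
    # conditional distribution of het count h given (n, rare):
    # P(h) ∝ 2^h * n! / (h! * ((rare-h)/2)! * ((2n-rare-h)/2)!)
    hs = np.arange(rare % 2, rare + 1, 2)
    logp = (
        hs * np.log(2.0)
        - gammaln(hs + 1)
        - gammaln((rare - hs) / 2 + 1)
        - gammaln((2 * n - rare - hs) / 2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _transmissible(parent_gt: float | None) -> set[int]:
    """Alleles a parent with the given minor-allele count can transmit."""
    if parent_gt is None or (isinstance(parent_gt, float) and np.isnan(parent_gt)):
        return {0, 1}
    return {0: {0}, 1: {0, 1}, 2: {1}}[int(parent_gt)]


def mendelian_check(
    family: NuclearFamily, snp_id: str, genotypes: pd.DataFrame
) -> list[str]:
    """Offspring ids whose genotype is impossible given parental genotypes."""

    def _gt(iid: str | None) -> float | None:
        if iid is None or iid not in genotypes.index:
            return None
        v = genotypes.at[iid, snp_id]
        return None if pd.isna(v) else float(v)

    mother = _gt(family.mother_id)
    father = _gt(family.father_id)
    flags = []
    for child in family.offspring:
        gt = _gt(child)
        if gt is None:
            continue
        ok = any(
            a + b == int(gt)
            for a in _transmissible(mother)
            for b in _transmissible(father)
        )
        if not ok:
            flags.append(child)
    return flags


def snp_qc(
    pedigree: Pedigree,
    genotypes: pd.DataFrame,
    snps: list[SnpInfo] | None = None,
    founders_only: bool = True,
) -> pd.DataFrame:
    """Per-SNP QC table: call rate, empirical MAF, HWE p, Mendelian errors."""
    snp_ids = [s.snp_id for s in snps] if snps else list(genotypes.columns)
    hwe_ids = pedigree.founder_ids if founders_only else [
        r.individual_id for r in pedigree.records
    ]
    hwe_ids = [i for i in hwe_ids if i in genotypes.index]
    rows = []
    for snp_id in snp_ids:
        col = genotypes[snp_id]
        n_called = int(col.notna().sum())
        call_rate = n_called / len(col) if len(col) else np.nan
        sub = col.loc[hwe_ids].dropna()
        maf = float(sub.mean() / 2) if len(sub) else np.nan
        if maf == maf and maf > 0.5:
            maf = 1 - maf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hwe_p = hwe_exact_test(sub) if len(sub) else np.nan
        n_mendel = sum(
            len(mendelian_check(fam, snp_id, genotypes)) for fam in pedigree.families
        )
        rows.append(
            {
                "snp_id": snp_id,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "n_mendel_errors": n_mendel,
            }
        )
    return pd.DataFrame(rows)
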