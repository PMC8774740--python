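"""Pedigree parsing, HWE exact test, and Mendelian-consistency checks."""

import math
from fractions import Fraction

import numpy as np
import pytest

from poefam.pedigree import (
    GenotypeParseError,
    IndividualRecord,
    NuclearFamily,
    Pedigree,
    PedigreeError,
    hwe_exact_test,
    mendelian_check,
    read_pedigree,
    snp_qc,
    write_pedigree,
)
from poefam.simulate import SimulationConfig, simulate_families

import pandas as pd


def _trio_records():
    return [
        IndividualRecord("F1", "P1", None, None, "male", "parent"),
        IndividualRecord("F1", "P2", None, None, "female", "parent"),
        IndividualRecord("F1", "C1", "P1", "P2", "unknown", "offspring"),
    ]


class TestPedigreeStructure:
    def test_minimal_trio(self):
        ped = Pedigree(_trio_records())
        assert len(ped) == 3
        assert ped["C1"].role == "offspring"
        assert len(ped.families) == 1
        assert ped.families[0].offspring == ["C1"]

    def test_duplicate_individual_id_rejected(self):
        recs = _trio_records() + [
            IndividualRecord("F1", "C1", "P1", "P2", "male", "offspring")
        ]
        with pytest.raises(PedigreeError, match="duplicated"):
            Pedigree(recs)

    def test_sex_inconsistent_father_link_names_offenders(self):
        recs = [
            IndividualRecord("F1", "P1", None, None, "female", "parent"),
            IndividualRecord("F1", "P2", None, None, "female", "parent"),
            IndividualRecord("F1", "C1", "P1", "P2", "male", "offspring"),
        ]
        with pytest.raises(PedigreeError, match="F1/C1"):
            Pedigree(recs)


class TestPedigreeIO:
    def test_ped_round_trip_byte_identical(self, tmp_path):
        ped = Pedigree(_trio_records())
        p1 = tmp_path / "a.ped"
        write_pedigree(ped, p1)
        again, _ = read_pedigree(p1)
        p2 = tmp_path / "b.ped"
        write_pedigree(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_tsv_dialect_autodetected(self, tmp_path):
        path = tmp_path / "ped.tsv"
        path.write_text(
            "family\tindividual\tfather\tmother\tsex\n"
            "F1\tP1\t0\t0\tmale\n"
            "F1\tP2\t0\t0\tfemale\n"
            "F1\tC1\tP1\tP2\t2\n"
        )
        ped, _ = read_pedigree(path)
        assert ped["C1"].sex == "female"
        assert ped["C1"].father_id == "P1"

    def test_invalid_genotype_value_reports_line(self, tmp_path):
        ped_path = tmp_path / "p.ped"
        write_pedigree(Pedigree(_trio_records()), ped_path)
        geno = tmp_path / "g.tsv"
        geno.write_text("individual_id\tsnp1\nP1\t0\nP2\t3\nC1\t1\n")
        with pytest.raises(GenotypeParseError, match="line 3"):
            read_pedigree(ped_path, geno)

    def test_missing_genotypes_read_as_nan(self, tmp_path):
        ped_path = tmp_path / "p.ped"
        write_pedigree(Pedigree(_trio_records()), ped_path)
        geno = tmp_path / "g.tsv"
        geno.write_text("individual_id\tsnp1\nP1\t2\nP2\tNA\nC1\t1\n")
        _, gt = read_pedigree(ped_path, geno)
        assert gt.at["P1", "snp1"] == 2
        assert np.isnan(gt.at["P2", "snp1"])


def _hwe_oracle(n_hom_major, n_het, n_hom_minor):
    """Exact-rational enumeration of the conditional het-count distribution."""
    n = n_hom_major + n_het + n_hom_minor
    rare = min(2 * n_hom_minor + n_het, 2 * n_hom_major + n_het)

    def weight(h):
        return (
            Fraction(2**h)
            * Fraction(math.factorial(n))
            / math.factorial(h)
            / math.factorial((rare - h) // 2)
            / math.factorial((2 * n - rare - h) // 2)
        )

    hs = list(range(rare % 2, rare + 1, 2))
    ws = {h: weight(h) for h in hs}
    total = sum(ws.values())
    p_obs = ws[n_het] / total
    return float(sum(w for w in ws.values() if w / total <= p_obs) / total)


class TestHweExactTest:
    def test_perfect_hwe_proportions_give_p_one(self):
        g = [0] * 25 + [1] * 50 + [2] * 25
        assert hwe_exact_test(g) == pytest.approx(1.0)

    def test_total_het_deficit_is_extreme(self):
        g = [0] * 100 + [2] * 100
        assert hwe_exact_test(g) < 1e-6

    def test_monomorphic_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            assert hwe_exact_test([0] * 10) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(10, 5, 2), (3, 20, 3), (0, 7, 13), (18, 2, 30), (25, 25, 0), (1, 1, 1)],
    )
    def test_agrees_with_rational_enumeration(self, counts):
        a, h, b = counts
        g = [0] * a + [1] * h + [2] * b
        assert hwe_exact_test(g) == pytest.approx(_hwe_oracle(a, h, b), abs=1e-10)

    def test_enumeration_sweep_small_n(self):
        # every genotype configuration with n <= 12 individuals
        for n in (2, 5, 12):
            for het in range(n + 1):
                for hom2 in range(n - het + 1):
                    hom0 = n - het - hom2
                    minor = 2 * hom2 + het
                    if minor == 0 or minor == 2 * n:
                        continue
                    g = [0] * hom0 + [1] * het + [2] * hom2
                    assert hwe_exact_test(g) == pytest.approx(
                        _hwe_oracle(hom0, het, hom2), abs=1e-10
                    )


class TestMendelianCheck:
    @pytest.mark.parametrize(
        "mother, father, child, flagged",
        [
            (0, 0, 1, True),
            (2, 2, 1, True),
            (1, np.nan, 2, False),
            (0, 2, 1, False),
            (0, 2, 0, True),
            (np.nan, np.nan, 2, False),
        ],
    )
    def test_trio_consistency(self, mother, father, child, flagged):
        fam = NuclearFamily("F1", "P1", "P2", ["C1"])
        gt = pd.DataFrame(
            {"snp1": [father, mother, child]}, index=["P1", "P2", "C1"]
        )
        flags = mendelian_check(fam, "snp1", gt)
        assert (flags == ["C1"]) == flagged

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_simulated_cohorts_have_no_mendelian_errors(self, seed):
        cfg = SimulationConfig(seed=seed, n_families=80)
        sim = simulate_families(cfg)
        qc = snp_qc(sim.pedigree, sim.genotypes)
        assert (qc["n_mendel_errors"] == 0).all()


def test_snp_qc_reports_call_rate_and_maf(small_cohort):
    qc = snp_qc(small_cohort.pedigree, small_cohort.genotypes)
    row = qc.iloc[0]
    assert row["call_rate"] == 1.0
    assert 0 < row["maf"] <= 0.5
    assert 0 <= row["hwe_p"] <= 1
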