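"""Parent–offspring resemblance: correlations, mixed slopes, comparisons."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from poefam.famcorr import (
    compare_parental_correlations,
    fisher_r_to_z_compare,
    mixed_slope,
    parent_offspring_pairs,
    spearman_partial,
    wald_slope_compare,
)
from poefam.pedigree import IndividualRecord, Pedigree


def _family(fam, n_children, child_sexes=None):
    recs = [
        IndividualRecord(fam, f"{fam}_P1", None, None, "male", "parent"),
        IndividualRecord(fam, f"{fam}_P2", None, None, "female", "parent"),
    ]
    for j in range(n_children):
        sex = child_sexes[j] if child_sexes else "male"
        recs.append(
            IndividualRecord(fam, f"{fam}_C{j}", f"{fam}_P1", f"{fam}_P2", sex, "offspring")
        )
    return recs


class TestPairs:
    def test_oldest_only_keeps_one_child(self):
        ped = Pedigree(_family("F1", 3))
        pheno = pd.DataFrame(
            {"y": [1.0, 2.0, 3.0, 4.0, 5.0], "age": [60, 58, 30, 25, 20]},
            index=["F1_P1", "F1_P2", "F1_C0", "F1_C1", "F1_C2"],
        )
        pairs = parent_offspring_pairs(ped, pheno, "y", "male", oldest_only=True)
        assert len(pairs) == 1
        assert pairs["offspring_id"].iloc[0] == "F1_C0"

    def test_sex_filter_excludes_all_sons(self):
        ped = Pedigree(_family("F1", 2, ["male", "male"]))
        pheno = pd.DataFrame(
            {"y": [1.0, 2.0, 3.0, 4.0]},
            index=["F1_P1", "F1_P2", "F1_C0", "F1_C1"],
        )
        pairs = parent_offspring_pairs(ped, pheno, "y", "male", offspring_sex="female")
        assert len(pairs) == 0

    def test_two_parents_one_child_gives_pair_per_parent(self):
        ped = Pedigree(_family("F1", 1))
        pheno = pd.DataFrame({"y": [1.0, 2.0, 3.0]}, index=["F1_P1", "F1_P2", "F1_C0"])
        pf = parent_offspring_pairs(ped, pheno, "y", "male")
        pm = parent_offspring_pairs(ped, pheno, "y", "female")
        assert len(pf) == 1 and len(pm) == 1


class TestSpearmanPartial:
    def test_monotone_pairs_give_r_one(self):
        x = np.arange(10.0)
        r, n, p = spearman_partial(x, np.exp(x))
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_independent_pairs_near_zero(self, rng):
        x, y = rng.standard_normal((2, 1000))
        r, n, _ = spearman_partial(x, y)
        assert abs(r) < 0.08  # null sampling SD ~ 1/sqrt(n)

    def test_partialling_shared_driver_kills_correlation(self, rng):
        c = rng.standard_normal(2000)
        x = c + 0.05 * rng.standard_normal(2000)
        y = c + 0.05 * rng.standard_normal(2000)
        r_raw, _, _ = spearman_partial(x, y)
        r_adj, _, _ = spearman_partial(x, y, covariates=c)
        assert r_raw > 0.9
        assert abs(r_adj) < 0.1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            spearman_partial([1, 2, 3], [1, 2, 3])


class TestMixedSlope:
    def test_no_family_variance_equals_ols(self, rng):
        n = 400
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        fams = np.array([f"F{i}" for i in range(n)])  # singleton families
        res = mixed_slope(y, x, fams)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.slope == pytest.approx(ols.params[1], abs=1e-6)

    def test_near_identity_relation_gives_unit_slope(self, rng):
        x = np.linspace(-2, 2, 100)
        y = x + 0.001 * rng.standard_normal(100)
        fams = np.repeat([f"F{i}" for i in range(50)], 2)
        res = mixed_slope(y, x, fams)
        assert res.slope == pytest.approx(1.0, abs=1e-3)
        assert res.p < 1e-10

    def test_recovers_simulated_slope_within_3se(self, rng):
        n_fam, kids = 500, 2
        u = rng.normal(0, 0.5, n_fam)
        parent = rng.standard_normal(n_fam)
        rows = []
        for i in range(n_fam):
            for _ in range(kids):
                rows.append((parent[i], 0.4 * parent[i] + u[i] + rng.normal(), f"F{i}"))
        p, y, f = zip(*rows)
        res = mixed_slope(np.array(y), np.array(p), np.array(f))
        assert abs(res.slope - 0.4) < 3 * res.se


class TestClosedFormComparisons:
    def test_fisher_equal_correlations(self):
        z, p = fisher_r_to_z_compare(0.3, 50, 0.3, 80)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fisher_worked_example(self):
        z, p = fisher_r_to_z_compare(0.5, 103, 0.0, 103)
        assert z == pytest.approx(np.arctanh(0.5) / np.sqrt(2 / 100), abs=1e-10)
        assert z == pytest.approx(3.884, abs=2e-3)

    def test_fisher_antisymmetry(self):
        z1, p1 = fisher_r_to_z_compare(0.5, 40, 0.2, 60)
        z2, p2 = fisher_r_to_z_compare(0.2, 60, 0.5, 40)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_fisher_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_r_to_z_compare(1.0, 50, 0.0, 50)

    def test_wald_examples(self):
        assert wald_slope_compare(0.4, 0.1, 0.4, 0.2) == pytest.approx((0.0, 1.0))
        z, _ = wald_slope_compare(1.0, 0.1, 0.0, 0.1)
        assert z == pytest.approx(7.0710678, abs=1e-6)
        z_swap, p_swap = wald_slope_compare(0.0, 0.1, 1.0, 0.1)
        assert z_swap == pytest.approx(-z)

    def test_wald_requires_positive_se(self):
        with pytest.raises(ValueError):
            wald_slope_compare(1.0, 0.0, 0.0, 0.1)


def test_fisher_comparison_null_calibration(rng):
    """With no parental or family effect the comparison p-value is uniform."""
    n = 100
    hits = 0
    reps = 2000
    for _ in range(reps):
        off = rng.standard_normal(n)
        father = rng.standard_normal(n)
        mother = rng.standard_normal(n)
        rf = np.corrcoef(np.argsort(np.argsort(father)), np.argsort(np.argsort(off)))[0, 1]
        rm = np.corrcoef(np.argsort(np.argsort(mother)), np.argsort(np.argsort(off)))[0, 1]
        _, p = fisher_r_to_z_compare(rf, n, rm, n)
        hits += p < 0.05
    assert 0.03 <= hits / reps <= 0.07


def test_model1_comparison_on_simulated_cohort(small_cohort):
    res = compare_parental_correlations(
        small_cohort.pedigree, small_cohort.phenotypes, "trait", oldest_only=True
    )
    assert -1 <= res.r_father <= 1 and -1 <= res.r_mother <= 1
    assert res.n_father >= 4 and res.n_mother >= 4
    assert 0 <= res.p_diff <= 1
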