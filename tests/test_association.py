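"""GEE association contrasts: coding, fitting, sweep behaviour."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from poefam.association import (
    AnalysisPlan,
    GEEFitError,
    apply_replication_rule,
    build_contrast_sample,
    gee_fit,
    run_analysis,
    split_families,
)
from poefam.origin import infer_cohort_origins
from poefam.pedigree import SnpInfo
from poefam.simulate import SimulationConfig, simulate_families


def _calls(rows):
    """rows: list of (iid, status, maternal_minor, paternal_minor)."""
    return pd.DataFrame(
        rows, columns=["individual_id", "status", "maternal_minor", "paternal_minor"]
    ).assign(snp_id="s")


class TestContrastCoding:
    def _example(self):
        rows = []
        gts = {}
        for i in range(10):
            rows.append((f"hom{i}", "assigned", 0, 0))
            gts[f"hom{i}"] = 0
        for i in range(4):
            rows.append((f"matHet{i}", "assigned", 1, 0))
            gts[f"matHet{i}"] = 1
        for i in range(3):
            rows.append((f"patHet{i}", "assigned", 0, 1))
            gts[f"patHet{i}"] = 1
        for i in range(2):
            rows.append((f"amb{i}", "ambiguous", np.nan, np.nan))
            gts[f"amb{i}"] = 1
        rows.append(("minorHom", "assigned", 1, 1))
        gts["minorHom"] = 2
        return _calls(rows), pd.Series(gts)

    def test_row_counts_per_contrast(self):
        calls, gt = self._example()
        mat = build_contrast_sample(calls, gt, "maternal")
        pat = build_contrast_sample(calls, gt, "paternal")
        poe = build_contrast_sample(calls, gt, "poe")
        assert len(mat) == 14  # 10 hom-major + 4 maternal hets
        assert len(pat) == 13
        assert len(poe) == 7  # N_het: origin-assigned heterozygotes
        assert poe["exposure"].sum() == 3  # paternal-origin coded 1

    def test_ambiguous_and_minor_homozygotes_excluded(self):
        calls, gt = self._example()
        for contrast in ("maternal", "paternal", "poe"):
            sample = build_contrast_sample(calls, gt, contrast)
            ids = set(sample["individual_id"])
            assert not any(i.startswith("amb") for i in ids)
            assert "minorHom" not in ids

    def test_all_hets_ambiguous_warns_zero_exposed(self):
        rows = [(f"hom{i}", "assigned", 0, 0) for i in range(5)]
        rows += [(f"amb{i}", "ambiguous", np.nan, np.nan) for i in range(3)]
        calls = _calls(rows)
        gt = pd.Series({**{f"hom{i}": 0 for i in range(5)}, **{f"amb{i}": 1 for i in range(3)}})
        with pytest.warns(UserWarning, match="zero exposed"):
            poe = build_contrast_sample(calls, gt, "poe")
        assert len(poe) == 0


class TestGeeFit:
    def test_singleton_clusters_match_ols_to_1e8(self, rng):
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        c = rng.standard_normal(n)
        y = 0.4 * x + 0.2 * c + rng.standard_normal(n)
        beta, se, p = gee_fit(y, x, c[:, None], np.arange(n))
        ols = sm.OLS(y, sm.add_constant(np.column_stack([x, c]))).fit()
        assert beta == pytest.approx(ols.params[1], abs=1e-8)

    def test_rank_deficiency_names_aliased_column(self, rng):
        n = 100
        x = rng.integers(0, 2, n).astype(float)
        C = pd.DataFrame({"dup": x})  # perfectly collinear with exposure
        y = rng.standard_normal(n)
        with pytest.raises(GEEFitError, match="dup"):
            gee_fit(y, x, C, np.repeat(np.arange(50), 2))

    def test_single_cluster_rejected(self, rng):
        y = rng.standard_normal(20)
        x = rng.integers(0, 2, 20).astype(float)
        with pytest.raises(GEEFitError, match="clusters"):
            gee_fit(y, x, None, np.zeros(20))

    def test_null_exposure_p_roughly_uniform(self, rng):
        hits = 0
        reps = 300
        for _ in range(reps):
            groups = np.repeat(np.arange(250), 2)
            y = rng.standard_normal(500)
            x = rng.integers(0, 2, 500).astype(float)
            _, _, p = gee_fit(y, x, None, groups)
            hits += p < 0.05
        assert 0.02 < hits / reps < 0.09

    def test_exchangeable_structure_supported(self, rng):
        groups = np.repeat(np.arange(100), 3)
        y = rng.standard_normal(300)
        x = rng.integers(0, 2, 300).astype(float)
        beta, se, p = gee_fit(y, x, None, groups, working_correlation="exchangeable")
        assert np.isfinite(beta) and se > 0


class TestSplitFamilies:
    def test_near_equal_halves_and_determinism(self, small_cohort):
        labels = split_families(small_cohort.pedigree, seed=3)
        counts = pd.Series(labels).value_counts()
        assert abs(counts["discovery"] - counts["replication"]) <= 1
        assert labels == split_families(small_cohort.pedigree, seed=3)

    def test_2257_families_split_1129_1128(self):
        cfg = SimulationConfig(seed=0, n_families=2257)
        sim = simulate_families(cfg)
        labels = split_families(sim.pedigree, seed=1)
        counts = pd.Series(labels).value_counts()
        assert counts["discovery"] == 1129
        assert counts["replication"] == 1128

    def test_different_seeds_differ(self, small_cohort):
        assert split_families(small_cohort.pedigree, 1) != split_families(
            small_cohort.pedigree, 2
        )


def _run(cfg, plan, split_seed=0, swap=False):
    sim = simulate_families(cfg)
    calls, _ = infer_cohort_origins(sim.pedigree, sim.genotypes)
    if swap:
        calls = calls.rename(
            columns={"maternal_minor": "paternal_minor", "paternal_minor": "maternal_minor"}
        )
    return run_analysis(
        plan, sim.pedigree, sim.genotypes, sim.phenotypes, calls, cfg.snps,
        split_seed=split_seed,
    )


class TestRunAnalysis:
    plan = AnalysisPlan(
        traits=["trait"], trait_family={"trait": "lipid"}, splits=("combined",)
    )

    def test_result_schema_and_nhet(self, small_cohort):
        calls, _ = infer_cohort_origins(small_cohort.pedigree, small_cohort.genotypes)
        res = run_analysis(
            self.plan, small_cohort.pedigree, small_cohort.genotypes,
            small_cohort.phenotypes, calls, [SnpInfo("snp1", "1", "GENE1", "A", "G", 0.3)],
        )
        row = res.iloc[0]
        # N equals the POE-contrast row count: origin-assigned heterozygotes
        assigned_het = calls[
            (calls["status"] == "assigned")
            & (calls["maternal_minor"] + calls["paternal_minor"] == 1)
        ]
        assert row["N_het"] == len(assigned_het)
        for col in ("B_MAT", "P_MAT", "B_PAT", "P_PAT", "B_POE", "P_POE"):
            assert np.isfinite(row[col])
        assert 0 <= row["P_POE"] <= 1

    def test_origin_label_swap_flips_poe_sign(self):
        cfg = SimulationConfig(seed=5, n_families=250, beta_pat={"snp1": 0.5})
        res = _run(cfg, self.plan)
        res_sw = _run(cfg, self.plan, swap=True)
        assert res_sw["B_POE"].iloc[0] == pytest.approx(-res["B_POE"].iloc[0], abs=1e-10)
        assert res_sw["P_POE"].iloc[0] == pytest.approx(res["P_POE"].iloc[0], abs=1e-10)
        # marginal contrasts swap roles
        assert res_sw["B_MAT"].iloc[0] == pytest.approx(res["B_PAT"].iloc[0], abs=1e-10)

    def test_poe_beta_close_to_marginal_difference(self):
        cfg = SimulationConfig(
            seed=9, n_families=400, beta_pat={"snp1": 0.4}, beta_mat={"snp1": -0.1}
        )
        res = _run(cfg, self.plan)
        row = res.iloc[0]
        diff = row["B_PAT"] - row["B_MAT"]
        tol = 3 * np.sqrt(row["SE_POE"] ** 2 + row["SE_MAT"] ** 2 + row["SE_PAT"] ** 2)
        assert abs(row["B_POE"] - diff) < tol

    def test_joint_dosage_mode_recovers_effects(self):
        cfg = SimulationConfig(
            seed=2, n_families=500, beta_pat={"snp1": 0.3}, beta_mat={"snp1": 0.0}
        )
        plan = AnalysisPlan(
            traits=["trait"], trait_family={"trait": "lipid"},
            splits=("combined",), contrast_mode="joint",
        )
        res = _run(cfg, plan)
        row = res.iloc[0]
        assert abs(row["B_PAT"] - 0.3) < 3 * row["SE_PAT"]
        assert abs(row["B_MAT"]) < 3 * row["SE_MAT"]

    def test_sex_stratified_runs_drop_sex_and_filter(self):
        cfg = SimulationConfig(seed=4, n_families=300, beta_pat={"snp1": 0.6},
                               daughter_scale=1.0, son_scale=0.0)
        plan = AnalysisPlan(
            traits=["trait"], trait_family={"trait": "lipid"},
            splits=("combined",), strata=("sons", "daughters"),
        )
        res = _run(cfg, plan)
        res = res.set_index("stratum")
        # effect simulated in daughters only
        assert res.loc["daughters", "P_PAT"] < res.loc["sons", "P_PAT"]
        assert res.loc["daughters", "N_het"] + res.loc["sons", "N_het"] > 0

    def test_covariate_sets_per_trait_family(self):
        plan = AnalysisPlan(
            traits=["TG", "WHR", "WHRadjBMI", "BMI"],
            trait_family={"TG": "lipid", "WHR": "obesity", "WHRadjBMI": "obesity",
                          "BMI": "obesity"},
            bmi_adjusted=("WHRadjBMI",), source_trait={"WHRadjBMI": "WHR"},
        )
        assert "BMI" in plan.covariates_for("TG", "all")
        assert "BMI" not in plan.covariates_for("WHR", "all")
        assert "BMI" in plan.covariates_for("WHRadjBMI", "all")
        assert "BMI" not in plan.covariates_for("BMI", "all")
        assert "sex" not in plan.covariates_for("TG", "daughters")


class TestReplicationRule:
    def _frame(self, rows):
        cols = ["snp_id", "trait", "stratum", "cohort", "split", "B_POE", "P_POE"]
        return pd.DataFrame(rows, columns=cols)

    def test_same_direction_replicates(self):
        res = self._frame(
            [
                ("s", "t", "all", "c", "discovery", 0.5, 0.01),
                ("s", "t", "all", "c", "replication", 0.3, 0.02),
            ]
        )
        out = apply_replication_rule(res)
        assert out["replicated"].iloc[0]

    def test_opposite_sign_does_not_replicate(self):
        res = self._frame(
            [
                ("s", "t", "all", "c", "discovery", 0.5, 0.01),
                ("s", "t", "all", "c", "replication", -0.3, 0.02),
            ]
        )
        out = apply_replication_rule(res)
        assert not out["replicated"].iloc[0]

    def test_nonsignificant_replication_fails(self):
        res = self._frame(
            [
                ("s", "t", "all", "c", "discovery", 0.5, 0.01),
                ("s", "t", "all", "c", "replication", 0.3, 0.40),
            ]
        )
        assert not apply_replication_rule(res)["replicated"].iloc[0]
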