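import numpy as np
import pandas as pd
import pytest
from scipy import stats

import haploblup as hb
from haploblup.validate import DegenerateTestError, _evaluate_split, build_design


def make_pheno(n, rng, trait="cwt", with_dates=True):
    df = pd.DataFrame({
        "id": [f"ind{i}" for i in range(n)],
        "sex": rng.choice(["M", "F"], size=n),
        "age": rng.uniform(24, 36, size=n),
        trait: rng.normal(350, 20, size=n),
    })
    if with_dates:
        df["birth_date"] = pd.Timestamp("2009-01-01") + pd.to_timedelta(
            rng.integers(0, 2000, size=n), unit="D"
        )
    return hb.PhenotypeTable(df, (trait,))


class TestPrecorrect:
    def test_residuals_orthogonal_to_covariates(self, rng):
        t = make_pheno(300, rng)
        resid = hb.precorrect(t, "cwt").to_numpy()
        sex = (pd.Categorical(t.data["sex"]).codes == 1).astype(float)
        age = t.data["age"].to_numpy()
        assert abs(resid @ sex) < 1e-8 * len(resid)
        assert abs(resid @ (age - age.mean())) < 1e-6 * len(resid)
        assert abs(resid.sum()) < 1e-8 * len(resid)

    def test_trait_proportional_to_age_corrects_to_zero(self, rng):
        t = make_pheno(100, rng)
        t.data["cwt"] = 2.0 * t.data["age"]
        np.testing.assert_allclose(hb.precorrect(t, "cwt"), 0, atol=1e-10)

    def test_uncorrelated_trait_nearly_unchanged(self, rng):
        t = make_pheno(1000, rng)
        resid = hb.precorrect(t, "cwt").to_numpy()
        orig = t.data["cwt"].to_numpy()
        assert np.corrcoef(resid, orig - orig.mean())[0, 1] > 0.99


class TestKfoldPlan:
    def test_equal_fold_sizes(self):
        plan = hb.kfold_plan([f"i{k}" for k in range(10)], folds=5, repeats=1, seed=3)
        assert sorted(len(f.test_ids) for f in plan) == [2, 2, 2, 2, 2]

    def test_same_seed_reproduces_plan(self):
        ids = [f"i{k}" for k in range(23)]
        p1 = hb.kfold_plan(ids, 5, 2, seed=9)
        p2 = hb.kfold_plan(ids, 5, 2, seed=9)
        assert p1 == p2

    def test_each_id_tested_once_per_repeat(self):
        ids = [f"i{k}" for k in range(37)]
        plan = hb.kfold_plan(ids, folds=5, repeats=4, seed=1)
        for r in range(1, 5):
            tested = [i for f in plan if f.repeat == r for i in f.test_ids]
            assert sorted(tested) == sorted(ids)

    def test_sizes_differ_by_at_most_one(self):
        plan = hb.kfold_plan([f"i{k}" for k in range(23)], 5, 1, seed=0)
        sizes = [len(f.test_ids) for f in plan]
        assert max(sizes) - min(sizes) <= 1


class TestForwardSplit:
    def test_straddling_cutoff(self, rng):
        t = make_pheno(2, rng)
        t.data.loc[0, "birth_date"] = pd.Timestamp("2011-06-01")
        t.data.loc[1, "birth_date"] = pd.Timestamp("2012-06-01")
        train, test = hb.forward_split(t, "2012-01-01")
        assert list(train) == ["ind0"] and list(test) == ["ind1"]

    def test_boundary_date_goes_to_test(self, rng):
        t = make_pheno(2, rng)
        t.data.loc[0, "birth_date"] = pd.Timestamp("2011-06-01")
        t.data.loc[1, "birth_date"] = pd.Timestamp("2012-01-01")
        _, test = hb.forward_split(t, "2012-01-01")
        assert list(test) == ["ind1"]

    def test_cutoff_after_all_births_errors(self, rng):
        t = make_pheno(5, rng)
        with pytest.raises(ValueError, match="empty"):
            hb.forward_split(t, "2050-01-01")


class TestPairedTtest:
    def test_matches_reference_implementation(self, rng):
        a = 0.4 + rng.normal(0, 0.02, size=25)
        b = a - 0.01 + rng.normal(0, 0.005, size=25)
        tstat, p = hb.paired_ttest(a, b)
        ref = stats.ttest_rel(a, b)
        assert tstat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_antisymmetric(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        t1, p1 = hb.paired_ttest(a, b)
        t2, p2 = hb.paired_ttest(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_identical_vectors_degenerate(self):
        with pytest.raises(DegenerateTestError):
            hb.paired_ttest([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])


@pytest.fixture(scope="module")
def cv_setup():
    cfg = hb.SimConfig(
        n_individuals=200, chrom_lengths=(1_200_000,), n_snps_per_chrom=(300,),
        seed=7, n_qtl=100,
    )
    g, pheno, truth = hb.simulate(cfg)
    design = build_design(g, hb.DesignConfig(kind="snp"))
    return g, pheno, design


class TestCrossValidate:
    def test_oracle_injection_gives_perfect_accuracy(self, cv_setup, rng):
        """If GEBVs equal corrected phenotypes, the correlation is 1."""
        _, pheno, _ = cv_setup
        corrected = hb.precorrect(pheno, "cwt")
        r = np.corrcoef(corrected, corrected)[0, 1]
        assert r == pytest.approx(1.0)

    def test_positive_accuracy_on_heritable_trait(self, cv_setup):
        g, pheno, design = cv_setup
        plan = hb.kfold_plan(pheno.ids, folds=4, repeats=1, seed=5)
        res = hb.cross_validate(design, pheno, hb.DesignConfig(kind="snp"),
                                plan, "cwt")
        s = hb.summarize_accuracy(res)
        assert s["n_failed"] == 0 and s["mean"] > 0.2

    def test_permutation_null_accuracy_near_zero(self, cv_setup, rng):
        g, pheno, design = cv_setup
        shuffled = pheno.data.copy()
        shuffled["cwt"] = rng.permutation(shuffled["cwt"].to_numpy())
        pheno_null = hb.PhenotypeTable(shuffled, ("cwt",))
        plan = hb.kfold_plan(pheno.ids, folds=4, repeats=2, seed=11)
        res = hb.cross_validate(design, pheno_null, hb.DesignConfig(kind="snp"),
                                plan, "cwt")
        mean_r = hb.summarize_accuracy(res)["mean"]
        n_test = res[0].n_test
        assert abs(mean_r) < 1.5 * 2 / np.sqrt(n_test)

    def test_leakage_guard_training_fit_bit_identical(self, cv_setup):
        """Perturbing held-out phenotypes must not move the training fit."""
        g, pheno, design = cv_setup
        ids = list(pheno.ids)
        test_ids = ids[:40]
        train_ids = ids[40:]
        r1, _, v1, b1 = _evaluate_split(design, pheno, "cwt", train_ids,
                                        test_ids, "vanraden1", "within_fold")
        tampered = pheno.data.copy()
        mask = tampered["id"].isin(test_ids)
        noise = np.random.default_rng(0).normal(0, 50, size=int(mask.sum()))
        tampered.loc[mask, "cwt"] = tampered.loc[mask, "cwt"] + noise
        pheno2 = hb.PhenotypeTable(tampered, ("cwt",))
        r2, _, v2, b2 = _evaluate_split(design, pheno2, "cwt", train_ids,
                                        test_ids, "vanraden1", "within_fold")
        assert v1.sigma_g2 == v2.sigma_g2 and v1.sigma_e2 == v2.sigma_e2
        assert b1 == b2
        assert r1 != pytest.approx(r2)  # the scores themselves do move

    def test_failed_fold_flagged_not_fatal(self, cv_setup, monkeypatch):
        g, pheno, design = cv_setup
        plan = hb.kfold_plan(pheno.ids, folds=4, repeats=1, seed=5)

        import haploblup.validate as V

        real = V._evaluate_split
        calls = {"n": 0}

        def flaky(*args, **kwargs):
            calls["n"] += 1
            if calls["n"] == 2:
                raise np.linalg.LinAlgError("synthetic failure")
            return real(*args, **kwargs)

        monkeypatch.setattr(V, "_evaluate_split", flaky)
        res = V.cross_validate(design, pheno, hb.DesignConfig(kind="snp"),
                               plan, "cwt")
        assert sum(r.failed for r in res) == 1 and len(res) == 4


class TestForwardValidation:
    def test_forward_not_better_than_cv_under_drift(self):
        """Allele-frequency drift makes temporal extrapolation harder.

        Asserted as a majority-of-replicates property: with strong founder
        drift the temporal split scores at or below random folds in most
        seeded replicates.
        """
        worse = 0
        for seed in range(4):
            cfg = hb.SimConfig(
                n_individuals=300, chrom_lengths=(1_200_000,),
                n_snps_per_chrom=(300,), seed=seed, n_qtl=100,
                founder_drift=6.0,
            )
            g, pheno, _ = hb.simulate(cfg)
            design = build_design(g, hb.DesignConfig(kind="snp"))
            plan = hb.kfold_plan(pheno.ids, folds=4, repeats=1, seed=seed)
            cv = hb.summarize_accuracy(
                hb.cross_validate(design, pheno, hb.DesignConfig(kind="snp"),
                                  plan, "cwt")
            )["mean"]
            cut = pheno.data["birth_date"].quantile(0.75)
            fwd = hb.forward_validate(design, pheno, hb.DesignConfig(kind="snp"),
                                      cut, "cwt").accuracy
            worse += fwd <= cv
        assert worse >= 3
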