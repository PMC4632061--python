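"""MANOVA with Wilk's Lambda, univariate follow-ups, pooling, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gsflux.generate import generate_design
from gsflux.stats import (FULL_MODEL_TERMS, AnovaResult, ManovaTermResult,
                          anova_table, build_design_matrix,
                          genotype_change_table, herbivory_anova,
                          manova_by_line, manova_fit, manova_table,
                          pooling_policy, proportional_change,
                          treatment_change_table, univariate_followups)


def toy_two_group() -> pd.DataFrame:
    """Two groups of three bivariate observations with known Wilk's Lambda.

    Hand computation: H = [[6,6],[6,6]], E = [[4/3,-2/3],[-2/3,4/3]],
    so Lambda = det(E)/det(H+E) = (4/3)/(76/3) = 1/19.
    """
    return pd.DataFrame({
        "group": ["A"] * 3 + ["B"] * 3,
        "y1": [1, 0, 1, 3, 2, 3],
        "y2": [0, 1, 1, 2, 3, 3],
    })


def random_instance(rng, n=40, p=3):
    data = pd.DataFrame({
        "g1": rng.choice(["a", "b"], n),
        "g2": rng.choice(["x", "y"], n),
    })
    for j in range(p):
        data[f"y{j}"] = rng.normal(size=n)
    return data


class TestWilksLambda:
    def test_hand_computed_toy_instance(self):
        res = manova_fit(toy_two_group(), responses=("y1", "y2"),
                         terms=(("group",),), log_transform=False)
        assert len(res) == 1
        assert res[0].wilks_lambda == pytest.approx(1.0 / 19.0, abs=1e-12)
        # q=1, p=2: Rao's F is exact with df (2, 3)
        assert res[0].df1 == 2
        assert res[0].df2 == pytest.approx(3.0)
        assert res[0].f_stat == pytest.approx(18.0 * 3.0 / 2.0)

    def test_determinant_identity_on_random_instances(self):
        # Lambda from the fitting routine equals det(E)/det(H+E) computed
        # directly from group cross-products on small instances
        rng = np.random.default_rng(42)
        for _ in range(5):
            n = 30
            data = pd.DataFrame({"g": rng.choice(["a", "b", "c"], n)})
            Y = rng.normal(size=(n, 3))
            for j in range(3):
                data[f"y{j}"] = Y[:, j]
            res = manova_fit(data, responses=("y0", "y1", "y2"),
                             terms=(("g",),), log_transform=False)[0]
            # direct one-way MANOVA cross-products
            grand = Y.mean(axis=0)
            H = np.zeros((3, 3))
            E = np.zeros((3, 3))
            for lev in ("a", "b", "c"):
                sub = Y[(data["g"] == lev).to_numpy()]
                d = sub.mean(axis=0) - grand
                H += len(sub) * np.outer(d, d)
                E += (sub - sub.mean(axis=0)).T @ (sub - sub.mean(axis=0))
            want = np.linalg.det(E) / np.linalg.det(H + E)
            assert res.wilks_lambda == pytest.approx(want, abs=1e-10)

    def test_cross_check_against_statsmodels(self):
        # independent implementation: statsmodels MANOVA on the same data
        from statsmodels.multivariate.manova import MANOVA

        data = toy_two_group()
        sm_res = MANOVA.from_formula("y1 + y2 ~ C(group, Sum)",
                                     data=data).mv_test()
        stat = sm_res.results["C(group, Sum)"]["stat"]
        lam_sm = float(stat.loc["Wilks' lambda", "Value"])
        f_sm = float(stat.loc["Wilks' lambda", "F Value"])
        res = manova_fit(data, responses=("y1", "y2"), terms=(("group",),),
                         log_transform=False)[0]
        assert res.wilks_lambda == pytest.approx(lam_sm, abs=1e-10)
        assert res.f_stat == pytest.approx(f_sm, rel=1e-8)

    def test_single_response_reduces_to_univariate_anova_f(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame({"g": rng.choice(["a", "b"], 24),
                             "y0": rng.normal(size=24)})
        res = manova_fit(data, responses=("y0",), terms=(("g",),),
                         log_transform=False)[0]
        a = data.loc[data["g"] == "a", "y0"]
        b = data.loc[data["g"] == "b", "y0"]
        f, p = sps.f_oneway(a, b)
        assert res.f_stat == pytest.approx(f, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_invariance_under_nonsingular_response_transform(self):
        rng = np.random.default_rng(11)
        data = random_instance(rng, n=36, p=3)
        resp = ["y0", "y1", "y2"]
        base = manova_fit(data, responses=resp, terms=(("g1",), ("g2",)),
                          log_transform=False)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        Yt = data[resp].to_numpy() @ A.T
        data2 = data.copy()
        for j in range(3):
            data2[resp[j]] = Yt[:, j]
        trans = manova_fit(data2, responses=resp, terms=(("g1",), ("g2",)),
                           log_transform=False)
        for r0, r1 in zip(base, trans):
            assert r0.wilks_lambda == pytest.approx(r1.wilks_lambda,
                                                    abs=1e-10)

    def test_null_p_values_uniform(self):
        # pure-noise responses in a balanced factorial: term p-values are
        # U(0,1); KS on 200 seeded simulations must not reject at 0.01
        rng = np.random.default_rng(2024)
        design = generate_design(lines=("Cyp79f1",), n_wt_per_condition=2,
                                 n_het_per_condition=2)
        pvals = []
        for _ in range(200):
            data = design.copy()
            for c in ("c1", "c2", "c3"):
                data[c] = rng.normal(size=len(data))
            res = manova_fit(data, responses=("c1", "c2", "c3"),
                             log_transform=False)
            pvals.append([r.p_value for r in res])
        pvals = np.asarray(pvals)
        for j, term in enumerate(FULL_MODEL_TERMS[:5]):
            _, p = sps.kstest(pvals[:, j], "uniform")
            assert p > 0.01, f"term {term} null p-values non-uniform"

    def test_rank_deficiency_reported(self):
        data = toy_two_group()
        data["dup"] = data["group"]
        with pytest.raises(ValueError, match="rank"):
            manova_fit(data, responses=("y1", "y2"),
                       terms=(("group",), ("dup",)), log_transform=False)

    def test_too_few_observations_rejected(self):
        data = toy_two_group()
        with pytest.raises(ValueError, match="responses|observations"):
            manova_fit(data, responses=("y1", "y2", "y1", "y2", "y1"),
                       terms=(("group",),), log_transform=False)


class TestFullModelOnSimulatedStudy:
    def test_fifteen_terms_per_line(self, plants):
        results = manova_by_line(plants)
        assert set(results) == {"Cyp79f1", "Cyp83a1", "Sur1"}
        for res in results.values():
            assert [r.term for r in res] == [" × ".join(t)
                                             for t in FULL_MODEL_TERMS]
            for r in res:
                assert 0 < r.wilks_lambda <= 1
                assert 0 <= r.p_value <= 1

    def test_genotype_and_treatments_detected(self, plants):
        res = manova_by_line(plants)["Cyp79f1"]
        by_term = {r.term: r for r in res}
        for term in ("genotype", "W", "C", "S", "J"):
            assert by_term[term].p_value < 0.05

    def test_manova_table_formatting(self, plants):
        res = manova_by_line(plants)["Cyp79f1"]
        tab = manova_table(res)
        assert set(tab.columns) >= {"term", "wilks_lambda", "F", "p_value",
                                    "sig"}
        assert tab.loc[tab["term"] == "genotype", "sig"].iloc[0] == "***"


class TestUnivariateFollowups:
    def test_identical_arms_give_zero_change(self):
        design = generate_design(lines=("Cyp79f1",), n_wt_per_condition=2,
                                 n_het_per_condition=2)
        data = design.copy()
        from gsflux.pathway import COMPOUND_NAMES
        for j, c in enumerate(COMPOUND_NAMES):
            # values depend on W only, never on genotype: in the balanced
            # design both genotype arms share the same distribution
            data[c] = np.where(data["W"] == 1, 2.0 + j, 1.0 + j)
        out = univariate_followups(data, "genotype")
        for c in out:
            assert c.prop_change == pytest.approx(0.0, abs=1e-12)
            assert c.p_value > 0.9 or np.isnan(c.p_value)

    @pytest.mark.parametrize("t_c,u_c,expected", [
        (2.0, 1.0, 1.0), (1.5, 2.0, -0.25), (3.0, 3.0, 0.0)])
    def test_proportional_change_definition(self, t_c, u_c, expected):
        assert proportional_change(t_c, u_c) == pytest.approx(expected)

    def test_prop_change_validates_denominator(self):
        with pytest.raises(ValueError):
            proportional_change(1.0, 0.0)

    def test_genotype_followup_recovers_knockdown_signs(self, plants):
        sub = plants[(plants["line"] == "Cyp79f1")]
        out = {c.compound: c for c in univariate_followups(sub, "genotype")}
        assert out["3MSOP"].prop_change < 0
        assert out["3MSOP"].significant
        assert out["4MSOB"].prop_change < 0
        assert out["6MSOH"].prop_change > 0

    def test_treatment_tables_cover_all_cells(self, plants):
        geno = genotype_change_table(plants)
        assert len(geno) == 3 * 7
        trt = treatment_change_table(plants)
        assert len(trt) == 4 * 7
        j = trt[(trt["treatment"] == "J")].set_index("compound")
        assert j.loc["4OHI3M", "prop_change"] < 0
        assert j.loc["I3M", "prop_change"] > 0
        assert j.loc["1MOI3M", "prop_change"] > 0


class TestPoolingPolicy:
    def _mk(self, term, p):
        return ManovaTermResult(term=term, wilks_lambda=0.9, f_stat=1.0,
                                df1=7, df2=100, p_value=p)

    def test_all_interactions_null_enables_pooling(self):
        res = [self._mk(f"genotype × {e}", 0.5) for e in "WCSJ"]
        out = pooling_policy(res)
        assert out == {"pool_genotypes_for_env_effects": True,
                       "pool_environments_for_genotype_effects": True}

    def test_one_significant_interaction_disables_pooling(self):
        res = [self._mk("genotype × W", 0.01)] + \
            [self._mk(f"genotype × {e}", 0.5) for e in "CSJ"]
        out = pooling_policy(res)
        assert not out["pool_genotypes_for_env_effects"]
        assert not out["pool_environments_for_genotype_effects"]

    def test_missing_interactions_is_an_error(self):
        with pytest.raises(ValueError):
            pooling_policy([self._mk("genotype", 0.001)])


class TestHerbivoryAnova:
    def _records(self, rng, n_per_cell=10, geno_effect=0.0, flat_effect=0.0,
                 noise=1.0):
        rows = []
        for genotype in ("WT", "HET"):
            for i, flat in enumerate(("flat1", "flat2", "flat3")):
                mu = 10 + (geno_effect if genotype == "HET" else 0) \
                    + flat_effect * i
                rows += [{"genotype": genotype, "flat": flat,
                          "LR": mu + rng.normal(0, noise)}
                         for _ in range(n_per_cell)]
        return pd.DataFrame(rows)

    def test_constant_response_has_zero_effect_ss(self):
        rng = np.random.default_rng(0)
        rec = self._records(rng, noise=0.0)
        rec["LR"] = 5.0
        out = {r.term: r for r in herbivory_anova(rec)}
        for term in ("genotype", "flat", "genotype × flat"):
            assert out[term].ss == pytest.approx(0.0, abs=1e-18)

    def test_genotype_effect_detected(self):
        rng = np.random.default_rng(1)
        rec = self._records(rng, geno_effect=3.0)
        out = {r.term: r for r in herbivory_anova(rec)}
        assert out["genotype"].p_value < 1e-4

    def test_flat_p_uniform_under_null(self):
        rng = np.random.default_rng(5)
        pvals = [
            {r.term: r for r in herbivory_anova(
                self._records(rng, n_per_cell=6))}["flat"].p_value
            for _ in range(120)]
        _, p = sps.kstest(pvals, "uniform")
        assert p > 0.01

    def test_simulated_herbivory_genotype_power(self, cyp79f1_plants):
        # under default deterrence settings the genotype term is detected
        # in the large majority of replicates
        from gsflux.generate import simulate_herbivory
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            sub = cyp79f1_plants.sample(n=80, random_state=s)
            herb = simulate_herbivory(sub, seed=s)
            out = {r.term: r for r in herbivory_anova(herb)}
            hits += out["genotype"].p_value < 0.05
        assert hits >= int(0.8 * n_rep)

    def test_empty_cell_rejected(self):
        rng = np.random.default_rng(2)
        rec = self._records(rng)
        rec = rec[~((rec["genotype"] == "WT") & (rec["flat"] == "flat2"))]
        with pytest.raises(ValueError, match="cell"):
            herbivory_anova(rec)

    def test_anova_table_shape(self):
        rng = np.random.default_rng(3)
        tab = anova_table(herbivory_anova(self._records(rng)))
        assert list(tab["term"]) == ["genotype", "flat", "genotype × flat",
                                     "residual"]


class TestDesignMatrix:
    def test_balanced_design_orthogonal_terms(self):
        design = generate_design(lines=("Cyp79f1",), n_wt_per_condition=1,
                                 n_het_per_condition=1)
        X, spans = build_design_matrix(design)
        G = X.T @ X
        off = G - np.diag(np.diag(G))
        assert np.allclose(off, 0.0, atol=1e-9)
        assert len(spans) == 15
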