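"""The evaluation model: MME correctness, REML behaviour, derived statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from treegs.ablup import (
    ModelSpec,
    fit_ablup,
    heritability,
    theoretical_accuracy,
)
from treegs.pedigree import Pedigree, build_A
from treegs.reml import MixedModel, RandomTerm

from conftest import random_pedigree


def toy_phenotypes(rng, rm, n_obs=50, sites=("S1", "S2"), h2=0.4, seed_bv=None):
    ids = rng.choice(rm.ids, size=n_obs, replace=False)
    fam = rng.integers(0, 5, n_obs)
    bv = rng.multivariate_normal(np.zeros(len(rm.ids)), rm.A * h2)
    idx = rm.index_of(ids)
    y = 3.0 + bv[idx] + rng.normal(0, np.sqrt(1 - h2), n_obs)
    return pd.DataFrame({
        "id": ids, "site": rng.choice(sites, n_obs),
        "block": rng.integers(1, 4, n_obs), "family": fam,
        "age": 10.0, "trait": y,
    })


class TestStatistics:
    def test_heritability_ratio(self):
        vc = {"additive": 1.0, "residual": 1.0}
        assert heritability(vc) == pytest.approx(0.5)

    def test_heritability_excludes_block_term(self):
        vc = {"additive": 0.14, "site_additive": 0.2, "site_family": 0.3,
              "family": 0.06, "residual": 0.3, "block": 123.0}
        assert heritability(vc) == pytest.approx(0.14)

    def test_zero_additive_gives_zero(self):
        assert heritability({"additive": 0.0, "residual": 2.0}) == 0.0

    def test_all_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            heritability({"additive": 0.0, "residual": 0.0})

    @pytest.mark.parametrize("frac, expected", [
        (0.0, 1.0), (1.0, 0.0), (0.75, 0.5),
    ])
    def test_theoretical_accuracy_closed_form(self, frac, expected):
        f = np.array([0.25])
        s2a = 2.0
        se = np.sqrt(frac * (1 + f) * s2a)
        assert theoretical_accuracy(se, f, s2a)[0] == pytest.approx(expected)

    def test_accuracy_clamps_negative_radicand(self):
        out = theoretical_accuracy(np.array([10.0]), np.array([0.0]), 1.0)
        assert out[0] == 0.0

    def test_accuracy_requires_positive_variance(self):
        with pytest.raises(ValueError):
            theoretical_accuracy(np.array([1.0]), np.array([0.0]), 0.0)


class TestMMEAgainstGLS:
    def test_solution_equals_generalised_least_squares(self, rng):
        """At fixed variance components the MME solution matches the direct
        GLS/BLUP closed form on a 50-observation toy, to 1e-8."""
        ped = random_pedigree(rng, n=60, n_founders=10)
        rm = build_A(ped)
        phen = toy_phenotypes(rng, rm)
        vc = {"additive": 0.5, "site_additive": 0.2, "block": 0.1,
              "site_family": 0.15, "family": 0.1, "residual": 0.7}
        res = fit_ablup(phen, rm, ModelSpec(), varcomps=vc)

        from treegs.ablup import build_design
        y, X, terms = build_design(phen, rm, ModelSpec())
        model = MixedModel(y, X, terms)
        Xk = model.X
        V = np.eye(len(y)) * vc["residual"]
        for t in terms:
            A = np.eye(t.nlevels) if t.Ainv is None else np.linalg.inv(t.Ainv)
            V += t.Z.toarray() @ (A * vc[t.name]) @ t.Z.toarray().T
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(Xk.T @ Vi @ Xk, Xk.T @ Vi @ y)
        resid = y - Xk @ beta
        A_full = rm.A * vc["additive"]
        Z1 = terms[0].Z.toarray()
        u_gls = A_full @ Z1.T @ Vi @ resid
        assert np.abs(res.table["ebv"].to_numpy() - u_gls).max() < 1e-8

    def test_cloned_records_match_halved_residual(self, rng):
        ped = random_pedigree(rng, n=30, n_founders=8)
        rm = build_A(ped)
        phen = toy_phenotypes(rng, rm, n_obs=25)
        vc = {"additive": 0.5, "site_additive": 0.2, "block": 0.1,
              "site_family": 0.1, "family": 0.05, "residual": 0.8}
        halved = fit_ablup(phen, rm, ModelSpec(), varcomps=dict(vc, residual=0.4))
        doubled = pd.concat([phen, phen], ignore_index=True)
        twice = fit_ablup(doubled, rm, ModelSpec(), varcomps=vc)
        single = halved
        assert np.allclose(single.table["ebv"], twice.table["ebv"], atol=1e-8)

    def test_pure_fixed_effect_data_gives_zero_ebvs(self, rng):
        ped = random_pedigree(rng, n=30, n_founders=8)
        rm = build_A(ped)
        phen = toy_phenotypes(rng, rm, n_obs=25)
        site_means = {"S1": 4.0, "S2": 9.0}
        phen["trait"] = phen["site"].map(site_means)
        vc = {"additive": 0.5, "block": 0.1, "residual": 0.8,
              "site_additive": 0.0, "site_family": 0.0, "family": 0.0}
        res = fit_ablup(phen, rm, ModelSpec(), varcomps=vc)
        assert np.abs(res.table["ebv"]).max() < 1e-8

    def test_unphenotyped_tip_gets_parent_average(self, rng):
        """An individual with no records and no recorded descendants is
        predicted at the mean of its parents' EBVs."""
        ped = random_pedigree(rng, n=40, n_founders=10)
        rm = build_A(ped)
        phen = toy_phenotypes(rng, rm, n_obs=30)
        recorded = set(phen["id"])
        pm = ped.parent_map()
        kids = {i for i, (s, d) in pm.items() if s is not None}
        parents_used = {p for s, d in pm.values() for p in (s, d) if p is not None}
        tips = [i for i in kids if i not in recorded and i not in parents_used]
        assert tips, "fixture should contain unrecorded tip individuals"
        vc = {"additive": 0.5, "site_additive": 0.1, "block": 0.1,
              "site_family": 0.1, "family": 0.1, "residual": 0.8}
        res = fit_ablup(phen, rm, ModelSpec(), varcomps=vc)
        ebv = res.table.set_index("id")["ebv"]
        for tip in tips:
            s, d = pm[tip]
            assert ebv[tip] == pytest.approx(0.5 * (ebv[s] + ebv[d]), abs=1e-8)


class TestREML:
    def test_em_loglik_monotone(self, rng):
        ped = random_pedigree(rng, n=80, n_founders=12)
        rm = build_A(ped)
        phen = toy_phenotypes(rng, rm, n_obs=70)
        from treegs.ablup import build_design
        y, X, terms = build_design(phen, rm, ModelSpec())
        model = MixedModel(y, X, terms)
        res = model.reml(method="em", max_iter=60, on_nonconvergence="warn")
        diffs = np.diff(res.loglik_trace[:-1])
        assert (diffs > -1e-7).all()

    def test_ai_and_em_agree_on_well_posed_problem(self, rng):
        n, q = 300, 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = sp.csr_matrix((np.ones(n), (np.arange(n), rng.integers(0, q, n))),
                          shape=(n, q))
        u = rng.normal(0, np.sqrt(2.0), q)
        y = X @ [1.0, 0.5] + Z @ u + rng.normal(0, 1.0, n)
        m = MixedModel(y, X, [RandomTerm("grp", Z)])
        ai = m.reml(method="ai", on_nonconvergence="warn")
        em = m.reml(method="em", max_iter=1000, tol_loglik=1e-9,
                    on_nonconvergence="warn")
        assert ai.varcomps["grp"] == pytest.approx(em.varcomps["grp"], rel=1e-2)
        assert ai.varcomps["residual"] == pytest.approx(em.varcomps["residual"],
                                                        rel=1e-2)

    def test_nonconvergence_raises_with_trace(self, rng):
        from treegs.reml import ConvergenceError
        ped = random_pedigree(rng, n=40, n_founders=8)
        rm = build_A(ped)
        phen = toy_phenotypes(rng, rm, n_obs=35)
        spec = ModelSpec(max_iter=2)
        with pytest.raises(ConvergenceError) as err:
            fit_ablup(phen, rm, spec)
        assert len(err.value.loglik_trace) >= 2

    def test_aliased_age_covariate_absorbed(self, rng):
        """Age constant within site is collinear with site effects; the fit
        proceeds by reducing the fixed design to full rank."""
        ped = random_pedigree(rng, n=40, n_founders=8)
        rm = build_A(ped)
        phen = toy_phenotypes(rng, rm, n_obs=35)
        phen["age"] = phen["site"].map({"S1": 10.0, "S2": 12.0})
        vc = {"additive": 0.5, "site_additive": 0.1, "block": 0.1,
              "site_family": 0.1, "family": 0.1, "residual": 0.8}
        res = fit_ablup(phen, rm, ModelSpec(), varcomps=vc)
        assert np.isfinite(res.table["ebv"]).all()

    def test_phenotyped_id_missing_from_pedigree_rejected(self, rng):
        ped = random_pedigree(rng, n=10, n_founders=4)
        rm = build_A(ped)
        phen = pd.DataFrame({"id": ["ghost"], "site": "S1", "block": 1,
                             "family": 0, "age": 10.0, "trait": 1.0})
        with pytest.raises(ValueError, match="absent"):
            fit_ablup(phen, rm, ModelSpec())
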