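"""Mixed-model equations, REML and contrasts against dense oracles."""

import numpy as np
import pandas as pd
import pytest

from lactbias.io_formats import PedigreeEntry
from lactbias.mixed_models import (
    ModelSpec,
    assemble_mme,
    contrast,
    estimate_variance_components,
    fit_model,
    restricted_m2ll,
)
from lactbias.pedigree import build_A_inverse, relationship_matrix

from conftest import random_pedigree


def toy_dataset(seed, n=10, n_ped=8, herds=2):
    """Random records over a random pedigree, plus the dense pieces the GLS
    oracle needs."""
    rng = np.random.default_rng(seed)
    entries = random_pedigree(rng, n_ped)
    order, A = relationship_matrix(entries)
    animals = rng.choice(order, n)
    herd = rng.choice([f"h{i}" for i in range(herds)], n)
    y = rng.normal(100, 10, n)
    df = pd.DataFrame({"animal_id": animals, "herd_year": herd, "milk_yield": y})
    return entries, order, A, df, y


def dense_blup(order, A, df, y, s2a, s2e):
    idx = {a: i for i, a in enumerate(order)}
    n = len(df)
    Z = np.zeros((n, len(order)))
    for r, a in enumerate(df.animal_id):
        Z[r, idx[a]] = 1
    hlev = sorted(df.herd_year.unique())
    X = np.zeros((n, len(hlev)))
    for r, h in enumerate(df.herd_year):
        X[r, hlev.index(h)] = 1
    V = Z @ A @ Z.T * s2a + np.eye(n) * s2e
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = s2a * A @ Z.T @ Vi @ (y - X @ beta)
    return beta, u, hlev


SPEC = ModelSpec(
    response="milk_yield",
    fixed_factors=["herd_year"],
    random_terms=["animal"],
    variance_components={"animal": 40.0, "residual": 90.0},
)


class TestSolutions:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_gls_blup(self, seed):
        entries, order, A, df, y = toy_dataset(seed)
        rel = build_A_inverse(entries)
        fit = fit_model(df, SPEC, rel)
        beta, u, hlev = dense_blup(order, A, df, y, 40.0, 90.0)
        got_beta = fit.fixed_solutions.set_index("level").loc[hlev, "estimate"]
        assert np.abs(got_beta.to_numpy() - beta).max() < 1e-8
        assert np.abs(fit.ebv().loc[order].to_numpy() - u).max() < 1e-8

    def test_no_random_terms_is_ols(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"herd_year": rng.choice(["a", "b", "c"], 30),
             "milk_yield": rng.normal(50, 5, 30)}
        )
        spec = ModelSpec(response="milk_yield", fixed_factors=["herd_year"])
        fit = fit_model(df, spec)
        means = df.groupby("herd_year")["milk_yield"].mean()
        got = fit.fixed_solutions.set_index("level")["estimate"]
        assert got.loc[means.index].to_numpy() == pytest.approx(means.to_numpy())

    def test_extreme_shrinkage_sends_ebvs_to_zero(self):
        entries, order, A, df, y = toy_dataset(3)
        rel = build_A_inverse(entries)
        spec = ModelSpec(
            response="milk_yield", fixed_factors=["herd_year"],
            random_terms=["animal"],
            variance_components={"animal": 1e-10, "residual": 90.0},
        )
        fit = fit_model(df, spec, rel)
        assert np.abs(fit.ebv()).max() < 1e-6

    def test_record_order_irrelevant(self):
        entries, order, A, df, y = toy_dataset(4)
        rel = build_A_inverse(entries)
        fit1 = fit_model(df, SPEC, rel)
        fit2 = fit_model(df.sample(frac=1.0, random_state=1), SPEC, rel)
        assert fit1.fixed_solutions["estimate"].to_numpy() == pytest.approx(
            fit2.fixed_solutions["estimate"].to_numpy(), abs=1e-10
        )
        assert (fit1.ebv() - fit2.ebv()).abs().max() < 1e-10

    def test_translation_invariance(self):
        entries, order, A, df, y = toy_dataset(5)
        rel = build_A_inverse(entries)
        fit1 = fit_model(df, SPEC, rel)
        df2 = df.assign(milk_yield=df.milk_yield + 1000.0)
        fit2 = fit_model(df2, SPEC, rel)
        hlev = sorted(df.herd_year.unique())
        w = {("herd_year", hlev[0]): 1.0, ("herd_year", hlev[-1]): -1.0}
        c1, c2 = contrast(fit1, w), contrast(fit2, w)
        assert c1.estimate == pytest.approx(c2.estimate, abs=1e-8)
        assert (fit1.ebv() - fit2.ebv()).abs().max() < 1e-8

    def test_reference_level_choice_does_not_move_contrasts(self):
        entries, order, A, df, y = toy_dataset(6, herds=3)
        rel = build_A_inverse(entries)
        spec2 = ModelSpec(
            response="milk_yield", fixed_factors=["group", "herd_year"],
            random_terms=["animal"],
            variance_components={"animal": 40.0, "residual": 90.0},
        )
        rng = np.random.default_rng(1)
        df = df.assign(group=rng.choice(["g1", "g2"], len(df)))
        fit_a = fit_model(df, spec2, rel)
        # relabel herd levels so a different one sorts first (new reference)
        relab = {h: f"z{h}" if h == sorted(df.herd_year.unique())[0] else h
                 for h in df.herd_year.unique()}
        fit_b = fit_model(df.assign(herd_year=df.herd_year.map(relab)), spec2, rel)
        w = {("group", "g1"): 1.0, ("group", "g2"): -1.0}
        assert contrast(fit_a, w).estimate == pytest.approx(
            contrast(fit_b, w).estimate, abs=1e-8
        )


class TestRestrictedLikelihood:
    def test_mme_form_equals_dense_form(self):
        entries, order, A, df, y = toy_dataset(7)
        rel = build_A_inverse(entries)
        system = assemble_mme(df, SPEC, rel)
        m2_mme = restricted_m2ll(system, {"animal": 40.0, "residual": 90.0})
        beta, u, hlev = dense_blup(order, A, df, y, 40.0, 90.0)
        idx = {a: i for i, a in enumerate(order)}
        n = len(df)
        Z = np.zeros((n, len(order)))
        for r, a in enumerate(df.animal_id):
            Z[r, idx[a]] = 1
        X = np.zeros((n, len(hlev)))
        for r, h in enumerate(df.herd_year):
            X[r, hlev.index(h)] = 1
        V = Z @ A @ Z.T * 40.0 + np.eye(n) * 90.0
        Vi = np.linalg.inv(V)
        resid = y - X @ beta
        m2_dense = (
            np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(X.T @ Vi @ X)[1]
            + float(resid @ Vi @ resid)
        )
        assert m2_mme == pytest.approx(m2_dense, abs=1e-8)


def half_sib_dataset(seed=42, n_sires=30, n_daughters=15, s2s=25.0, s2w=75.0):
    rng = np.random.default_rng(seed)
    entries = [PedigreeEntry(f"S{i}") for i in range(n_sires)]
    rows = []
    for i in range(n_sires):
        se = rng.normal(0, np.sqrt(s2s))
        for j in range(n_daughters):
            d = f"S{i}D{j}"
            entries.append(PedigreeEntry(d, sire_id=f"S{i}"))
            rows.append({"animal_id": d, "mu": "1", "sire": f"S{i}",
                         "y": 50 + se + rng.normal(0, np.sqrt(s2w))})
    return entries, pd.DataFrame(rows)


class TestREML:
    def anova_components(self, df, n_sires, n_daughters):
        """Closed-form ANOVA for the balanced paternal half-sib design,
        mapped to animal-model components (s2a = 4 * sire variance)."""
        gm = df.groupby("sire")["y"]
        msb = n_daughters * gm.mean().var(ddof=1)
        within = df["y"] - gm.transform("mean")
        msw = (within**2).sum() / (n_sires * (n_daughters - 1))
        sig_s = (msb - msw) / n_daughters
        return 4 * sig_s, msw - 3 * sig_s

    def test_direct_reml_matches_anova_closed_form(self):
        entries, df = half_sib_dataset()
        rel = build_A_inverse(entries)
        spec = ModelSpec(response="y", fixed_factors=["mu"], random_terms=["animal"])
        vc, _, ok = estimate_variance_components(df, spec, rel, method="direct")
        s2a, s2e = self.anova_components(df, 30, 15)
        assert ok
        assert vc["animal"] == pytest.approx(s2a, rel=1e-3)
        assert vc["residual"] == pytest.approx(s2e, rel=1e-3)

    def test_em_reml_monotone_and_agrees_with_direct(self):
        entries, df = half_sib_dataset(n_sires=15, n_daughters=10)
        rel = build_A_inverse(entries)
        spec = ModelSpec(response="y", fixed_factors=["mu"], random_terms=["animal"])
        em, trace, _ = estimate_variance_components(
            df, spec, rel, method="em", max_iter=200
        )
        m2 = [t["m2ll"] for t in trace]
        assert all(b <= a + 1e-7 for a, b in zip(m2, m2[1:]))
        direct, _, _ = estimate_variance_components(df, spec, rel, method="direct")
        assert em["animal"] == pytest.approx(direct["animal"], rel=0.05)
        assert em["residual"] == pytest.approx(direct["residual"], rel=0.02)

    def test_zero_genetic_variance_hits_boundary(self):
        rng = np.random.default_rng(11)
        entries, df = half_sib_dataset(s2s=0.0, s2w=50.0, n_sires=20, n_daughters=10)
        rel = build_A_inverse(entries)
        spec = ModelSpec(response="y", fixed_factors=["mu"], random_terms=["animal"])
        vc, _, _ = estimate_variance_components(df, spec, rel, method="direct")
        assert vc["animal"] / vc["residual"] < 0.02

    def test_pe_variance_zero_equals_animal_only_fit(self):
        # repeated records, PE component pinned at (numerically) zero
        rng = np.random.default_rng(2)
        entries = [PedigreeEntry(f"A{i}") for i in range(12)]
        rows = []
        for e in entries:
            for rep in range(3):
                rows.append({"animal_id": e.animal_id, "mu": "1",
                             "y": rng.normal(20, 4)})
        df = pd.DataFrame(rows)
        rel = build_A_inverse(entries)
        with_pe = ModelSpec(
            response="y", fixed_factors=["mu"],
            random_terms=["animal", "permanent_environment"],
            variance_components={"animal": 5.0,
                                 "permanent_environment": 1e-10,
                                 "residual": 16.0},
        )
        without = ModelSpec(
            response="y", fixed_factors=["mu"], random_terms=["animal"],
            variance_components={"animal": 5.0, "residual": 16.0},
        )
        f1 = fit_model(df, with_pe, rel)
        f2 = fit_model(df, without, rel)
        assert (f1.ebv() - f2.ebv()).abs().max() < 1e-6
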