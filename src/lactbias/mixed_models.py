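"""Henderson's mixed-model equations for the animal models of the pipeline.

Supports the model family used throughout: a response with categorical fixed
factors (calf-gender sequence, herd-year contemporary group), optional
covariates with factor-specific slopes (days in milk by calf gender), a
pedigree-structured random animal effect (EBVs) and an identity-structured
permanent-environment effect for repeated records.

Variance components are estimated by REML on the restricted likelihood
evaluated through the mixed-model equations:

``-2 l_R = (n-p) ln s2e - sum_u q_u ln(lambda_u) + ln|A| + ln|C| + y'Py``

where ``C = W'W + sum_u lambda_u K_u`` is the lambda-scaled coefficient
matrix, ``lambda_u = s2e / s2u`` and ``K_u`` the structure matrix (A-inverse
or identity).  Two maximisers are provided: classic EM iteration (requires
the dense inverse of C each round, so it is reserved for small systems, but
its restricted likelihood is provably non-decreasing) and direct
maximisation of the variance-ratio-profiled likelihood through sparse LU
factorisations, which scales to herd-sized problems.  Both agree on toy
problems to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import optimize, stats

from .pedigree import RelationshipStructure

__all__ = [
    "Covariate",
    "ModelSpec",
    "MMESystem",
    "MMEFit",
    "ContrastResult",
    "assemble_mme",
    "solve_mme",
    "estimate_variance_components",
    "fit_model",
    "contrast",
]

ANIMAL = "animal"
PE = "permanent_environment"


@dataclass(frozen=True)
class Covariate:
    """A regression covariate, optionally with a separate slope per level
    of an interacting factor (``by``)."""

    name: str
    by: str | None = None


@dataclass
class ModelSpec:
    """Declarative model description.

    ``variance_components`` maps term name (``"animal"``,
    ``"permanent_environment"``, ``"residual"``) to a value in squared
    response units, or is ``None`` to request REML estimation.
    """

    response: str
    fixed_factors: list[str] = field(default_factory=list)
    covariates: list[Covariate] = field(default_factory=list)
    random_terms: list[str] = field(default_factory=list)
    variance_components: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for t in self.random_terms:
            if t not in (ANIMAL, PE):
                raise ValueError(f"unknown random term {t!r}")
        if self.random_terms.count(ANIMAL) > 1:
            raise ValueError("at most one pedigree-structured term")


@dataclass
class MMESystem:
    """Assembled (lambda-form) mixed-model equations."""

    WtW: sp.csc_matrix          # W'W, W = [X Z...]
    Wty: np.ndarray
    yty: float
    n: int
    p: int                      # fixed-effect columns (X assumed full rank)
    col_labels: list[tuple[str, str]]   # (term, level) per column
    blocks: dict[str, slice]    # term -> column slice (fixed terms + random)
    structures: dict[str, sp.csc_matrix]  # random term -> K (A-inverse or I)
    log_det_K: dict[str, float]           # log|A| (0 for identity)
    animal_order: list[str]     # equation order of the animal block
    pe_order: list[str]
    response: str
    data_animals: list[str] = field(default_factory=list)  # animals with records

    def coefficient_matrix(self, lambdas: dict[str, float]) -> sp.csc_matrix:
        C = self.WtW.tocsc(copy=True)
        for term, lam in lambdas.items():
            K = self.structures[term]
            blk = self.blocks[term]
            pad = sp.csc_matrix((self.WtW.shape[0],) * 2)
            # embed K at the block position
            idx = np.arange(blk.start, blk.stop)
            K = K.tocoo()
            pad = sp.csc_matrix(
                (lam * K.data, (idx[K.row], idx[K.col])), shape=C.shape
            )
            C = C + pad
        return C.tocsc()


@dataclass
class ContrastResult:
    estimate: float
    se: float
    t: float
    p: float
    df: float


@dataclass
class MMEFit:
    """Solved mixed-model equations with variance components."""

    spec: ModelSpec
    system: MMESystem
    solutions: np.ndarray
    fixed_solutions: pd.DataFrame          # term, level, estimate, se
    random_solutions: dict[str, pd.Series]  # term -> per-animal estimates
    variance_components: dict[str, float]
    log_likelihood: float                   # restricted log-likelihood (-0.5*-2lR)
    converged: bool
    reml_trace: list[dict] = field(default_factory=list)
    _factor: object | None = None

    @property
    def residual_df(self) -> int:
        return self.system.n - self.system.p

    def ebv(self) -> pd.Series:
        """Estimated breeding values (animal-block solutions)."""
        return self.random_solutions[ANIMAL]

    def column_index(self, term: str, level: str) -> int:
        try:
            return self.system.col_labels.index((term, str(level)))
        except ValueError:
            raise KeyError(f"no column for ({term}, {level})") from None


# ---------------------------------------------------------------------------
# assembly


def _factor_columns(values: pd.Series, drop_first: bool) -> tuple[sp.csc_matrix, list[str]]:
    cat = pd.Categorical(values.astype(str))
    levels = list(cat.categories)
    codes = cat.codes.copy()
    if drop_first:
        keep = levels[1:]
        mask = codes > 0
        rows = np.nonzero(mask)[0]
        cols = codes[mask] - 1
        X = sp.csc_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(len(values), len(keep))
        )
        return X, keep
    rows = np.arange(len(values))
    X = sp.csc_matrix(
        (np.ones(len(values)), (rows, codes)), shape=(len(values), len(levels))
    )
    return X, levels


def assemble_mme(
    data: pd.DataFrame,
    spec: ModelSpec,
    relationships: RelationshipStructure | None = None,
) -> MMESystem:
    """Build the lambda-form normal equations for ``spec`` on ``data``.

    ``data`` needs one row per record with the response, every fixed factor
    and covariate, and an ``animal_id`` column when random terms are present.
    The fixed part uses a reference-level constraint: the first factor keeps
    all its levels, later factors drop their first level, so X is full rank
    and all between-level contrasts within a factor are estimable.
    """
    n = len(data)
    if n == 0:
        raise ValueError("empty data")
    y = data[spec.response].to_numpy(dtype=float)

    mats: list[sp.csc_matrix] = []
    labels: list[tuple[str, str]] = []
    blocks: dict[str, slice] = {}
    col = 0
    for i, f in enumerate(spec.fixed_factors):
        X, levels = _factor_columns(data[f], drop_first=(i > 0))
        mats.append(X)
        labels += [(f, lv) for lv in levels]
        blocks[f] = slice(col, col + len(levels))
        col += len(levels)
    for cov in spec.covariates:
        v = data[cov.name].to_numpy(dtype=float)
        if cov.by is None:
            mats.append(sp.csc_matrix(v.reshape(-1, 1)))
            labels.append((cov.name, ""))
            blocks[cov.name] = slice(col, col + 1)
            col += 1
        else:
            cat = pd.Categorical(data[cov.by].astype(str))
            term = f"{cov.name}:{cov.by}"
            start = col
            cols = []
            for lv in cat.categories:
                cols.append(sp.csc_matrix((v * (cat == lv)).reshape(-1, 1)))
                labels.append((term, str(lv)))
                col += 1
            mats.append(sp.hstack(cols, format="csc"))
            blocks[term] = slice(start, col)
    p = col

    structures: dict[str, sp.csc_matrix] = {}
    log_det_K: dict[str, float] = {}
    animal_order: list[str] = []
    pe_order: list[str] = []
    data_animals: list[str] = []
    if spec.random_terms:
        if "animal_id" not in data.columns:
            raise ValueError("random terms require an animal_id column")
        ids = data["animal_id"].astype(str)
        data_animals = list(dict.fromkeys(ids))
    for term in spec.random_terms:
        if term == ANIMAL:
            if relationships is None:
                raise ValueError("animal term requires a RelationshipStructure")
            animal_order = relationships.order
            idx = ids.map(relationships.index)
            if idx.isna().any():
                missing = ids[idx.isna()].unique()[:5]
                raise ValueError(f"animals missing from pedigree: {list(missing)}")
            q = relationships.n
            Z = sp.csc_matrix(
                (np.ones(n), (np.arange(n), idx.to_numpy(dtype=int))), shape=(n, q)
            )
            structures[ANIMAL] = relationships.A_inverse.tocsc()
            log_det_K[ANIMAL] = relationships.log_det_A
        else:
            cat = pd.Categorical(ids)
            pe_order = list(cat.categories)
            q = len(pe_order)
            Z = sp.csc_matrix(
                (np.ones(n), (np.arange(n), cat.codes)), shape=(n, q)
            )
            structures[PE] = sp.identity(q, format="csc")
            log_det_K[PE] = 0.0
        mats.append(Z)
        blocks[term] = slice(col, col + q)
        order = animal_order if term == ANIMAL else pe_order
        labels += [(term, a) for a in order]
        col += q

    W = sp.hstack(mats, format="csc")
    return MMESystem(
        WtW=(W.T @ W).tocsc(),
        Wty=np.asarray(W.T @ y).ravel(),
        yty=float(y @ y),
        n=n,
        p=p,
        col_labels=labels,
        blocks=blocks,
        structures=structures,
        log_det_K=log_det_K,
        animal_order=animal_order,
        pe_order=pe_order,
        response=spec.response,
        data_animals=data_animals,
    )


# ---------------------------------------------------------------------------
# restricted likelihood


def _lambdas(spec: ModelSpec, comps: dict[str, float]) -> dict[str, float]:
    s2e = comps["residual"]
    return {t: s2e / comps[t] for t in spec.random_terms}


def restricted_m2ll(
    system: MMESystem, comps: dict[str, float], factor=None, theta=None
) -> float:
    """-2 * restricted log-likelihood (without the (n-p) ln 2pi constant)."""
    lambdas = {t: comps["residual"] / comps[t] for t in system.structures}
    if factor is None:
        C = system.coefficient_matrix(lambdas)
        factor = spla.splu(C, permc_spec="MMD_AT_PLUS_A")
        theta = factor.solve(system.Wty)
    s = system.yty - float(theta @ system.Wty)
    s2e = comps["residual"]
    val = (system.n - system.p) * np.log(s2e) + s / s2e
    val += float(np.sum(np.log(np.abs(factor.U.diagonal()))))
    for t in system.structures:
        q = system.blocks[t].stop - system.blocks[t].start
        val += -q * np.log(lambdas[t]) + system.log_det_K[t]
    return float(val)


def _solve_system(system: MMESystem, lambdas: dict[str, float]):
    C = system.coefficient_matrix(lambdas)
    factor = spla.splu(C, permc_spec="MMD_AT_PLUS_A")
    theta = factor.solve(system.Wty)
    return factor, theta


# ---------------------------------------------------------------------------
# REML


def _em_reml(
    system: MMESystem,
    spec: ModelSpec,
    start: dict[str, float],
    tol: float,
    max_iter: int,
) -> tuple[dict[str, float], list[dict], bool]:
    """Classic EM-REML via dense inverse of the coefficient matrix.

    Each iteration: solve the MME at the current ratios, then
    ``s2u <- (u'K u + s2e tr(K Cuu)) / q`` for every random term and
    ``s2e <- (y'y - theta'W'y) / (n - p)``.  The restricted likelihood is
    non-decreasing along the sequence (asserted in tests).
    """
    comps = dict(start)
    trace: list[dict] = []
    converged = False
    dim = system.WtW.shape[0]
    if dim > 4000:
        raise ValueError(
            f"EM-REML needs the dense inverse of a {dim}x{dim} system; "
            "use method='direct' for systems this large"
        )
    for it in range(max_iter):
        lambdas = _lambdas(spec, comps)
        C = system.coefficient_matrix(lambdas).toarray()
        Cinv = np.linalg.inv(C)
        theta = Cinv @ system.Wty
        s2e = comps["residual"]
        new = dict(comps)
        for t in spec.random_terms:
            blk = system.blocks[t]
            u = theta[blk]
            K = system.structures[t]
            q = blk.stop - blk.start
            quad = float(u @ (K @ u))
            tr = float(np.sum(K.multiply(Cinv[blk, blk].T).data))
            new[t] = (quad + s2e * tr) / q
        s = system.yty - float(theta @ system.Wty)
        new["residual"] = s / (system.n - system.p)
        m2ll = restricted_m2ll(system, new)
        trace.append({"iter": it, **new, "m2ll": m2ll})
        rel = max(
            abs(new[k] - comps[k]) / max(abs(comps[k]), 1e-12) for k in new
        )
        comps = new
        if rel < tol:
            converged = True
            break
    return comps, trace, converged


def _direct_reml(
    system: MMESystem,
    spec: ModelSpec,
    start: dict[str, float],
    tol: float,
    max_iter: int,
) -> tuple[dict[str, float], list[dict], bool]:
    """Maximise the ratio-profiled restricted likelihood by sparse solves.

    The residual variance is profiled out analytically
    (``s2e = (y'y - theta'W'y)/(n-p)``), leaving an optimisation over
    ``log gamma_u`` with ``gamma_u = s2u / s2e``; each evaluation is one
    sparse LU factorisation.
    """
    terms = spec.random_terms
    n_p = system.n - system.p
    trace: list[dict] = []

    def neg_profile(x: np.ndarray) -> float:
        gam = np.exp(x)
        lambdas = {t: 1.0 / g for t, g in zip(terms, gam)}
        try:
            factor, theta = _solve_system(system, lambdas)
        except RuntimeError:
            return 1e30
        s = system.yty - float(theta @ system.Wty)
        if s <= 0:
            return 1e30
        val = n_p * (np.log(s / n_p) + 1.0)
        val += float(np.sum(np.log(np.abs(factor.U.diagonal()))))
        for t, g in zip(terms, gam):
            q = system.blocks[t].stop - system.blocks[t].start
            val += q * np.log(g) + system.log_det_K[t]
        trace.append({"x": x.tolist(), "m2ll_profiled": val})
        return val

    x0 = np.log([start[t] / start["residual"] for t in terms])
    if len(terms) == 1:
        res = optimize.minimize_scalar(
            lambda v: neg_profile(np.array([v])),
            bounds=(-12.0, 12.0),
            method="bounded",
            options={"xatol": tol},
        )
        x = np.array([res.x])
        ok = res.success
    else:
        res = optimize.minimize(
            neg_profile,
            x0,
            method="Nelder-Mead",
            options={"xatol": tol, "fatol": 1e-8, "maxiter": max_iter},
        )
        x = res.x
        ok = res.success
    gam = np.exp(x)
    lambdas = {t: 1.0 / g for t, g in zip(terms, gam)}
    _, theta = _solve_system(system, lambdas)
    s = system.yty - float(theta @ system.Wty)
    s2e = s / n_p
    comps = {"residual": s2e}
    for t, g in zip(terms, gam):
        comps[t] = g * s2e
    return comps, trace, bool(ok)


def estimate_variance_components(
    data: pd.DataFrame,
    spec: ModelSpec,
    relationships: RelationshipStructure | None = None,
    method: str = "auto",
    tol: float = 1e-6,
    max_iter: int = 500,
    start: dict[str, float] | None = None,
) -> tuple[dict[str, float], list[dict], bool]:
    """REML variance components for ``spec``.

    ``method``: ``"em"`` (dense, monotone likelihood), ``"direct"``
    (sparse profiled maximisation) or ``"auto"`` (EM below 1500 equations,
    direct above).
    """
    system = assemble_mme(data, spec, relationships)
    return _estimate_on_system(system, spec, method, tol, max_iter, start)


def _estimate_on_system(system, spec, method, tol, max_iter, start=None):
    if not spec.random_terms:
        # OLS residual variance
        factor, theta = _solve_system(system, {})
        s = system.yty - float(theta @ system.Wty)
        return {"residual": s / (system.n - system.p)}, [], True
    if start is None:
        # split the OLS residual variance half to residual, half across terms
        p = system.p
        beta = np.linalg.lstsq(
            system.WtW[:p, :p].toarray(), system.Wty[:p], rcond=None
        )[0]
        s_ols = max(system.yty - float(beta @ system.Wty[:p]), 1e-8)
        vy = s_ols / max(system.n - p, 1)
        k = len(spec.random_terms)
        start = {t: vy / (2 * k) for t in spec.random_terms}
        start["residual"] = vy / 2
    if method == "auto":
        method = "em" if system.WtW.shape[0] <= 1500 else "direct"
    if method == "em":
        return _em_reml(system, spec, start, tol, max_iter)
    if method == "direct":
        return _direct_reml(system, spec, start, tol, max_iter)
    raise ValueError(f"unknown REML method {method!r}")


# ---------------------------------------------------------------------------
# solving and fitting


def solve_mme(
    system: MMESystem, comps: dict[str, float]
) -> tuple[np.ndarray, object]:
    """Solve the assembled equations at given components; returns
    (solutions, LU factor)."""
    lambdas = {t: comps["residual"] / comps[t] for t in system.structures}
    factor, theta = _solve_system(system, lambdas)
    return theta, factor


def _fixed_table(system: MMESystem, theta, factor, s2e) -> pd.DataFrame:
    rows = []
    for j in range(system.p):
        term, level = system.col_labels[j]
        e = np.zeros(system.WtW.shape[0])
        e[j] = 1.0
        var = s2e * float(factor.solve(e)[j])
        rows.append(
            {
                "term": term,
                "level": level,
                "estimate": theta[j],
                "se": np.sqrt(max(var, 0.0)),
            }
        )
    return pd.DataFrame(rows)


def fit_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    relationships: RelationshipStructure | None = None,
    reml_method: str = "auto",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MMEFit:
    """Estimate components (unless given), assemble and solve the MME."""
    system = assemble_mme(data, spec, relationships)
    if spec.variance_components is not None:
        comps = dict(spec.variance_components)
        trace, conv = [], True
    else:
        comps, trace, conv = _estimate_on_system(
            system, spec, reml_method, tol, max_iter
        )
    if spec.random_terms:
        theta, factor = solve_mme(system, comps)
    else:
        factor, theta = _solve_system(system, {})
    s2e = comps["residual"]
    fixed = _fixed_table(system, theta, factor, s2e)
    random_solutions: dict[str, pd.Series] = {}
    for t in spec.random_terms:
        blk = system.blocks[t]
        order = system.animal_order if t == ANIMAL else system.pe_order
        random_solutions[t] = pd.Series(theta[blk], index=order, name=t)
    m2ll = restricted_m2ll(system, comps, factor, theta) if spec.random_terms else np.nan
    return MMEFit(
        spec=spec,
        system=system,
        solutions=theta,
        fixed_solutions=fixed,
        random_solutions=random_solutions,
        variance_components=comps,
        log_likelihood=-0.5 * m2ll if np.isfinite(m2ll) else np.nan,
        converged=conv,
        reml_trace=trace,
        _factor=factor,
    )


def contrast(fit: MMEFit, weights: dict[tuple[str, str], float]) -> ContrastResult:
    """Estimate, SE and t-test of a linear contrast of solutions.

    ``weights`` maps (term, level) to its coefficient.  The SE comes from the
    quadratic form ``s2e * L' C^-1 L`` via one sparse solve; degrees of
    freedom are the residual df (n - rank(X)).
    """
    dim = fit.system.WtW.shape[0]
    L = np.zeros(dim)
    for (term, level), w in weights.items():
        L[fit.column_index(term, level)] = w
    est = float(L @ fit.solutions)
    s2e = fit.variance_components["residual"]
    var = s2e * float(L @ fit._factor.solve(L))
    se = float(np.sqrt(max(var, 0.0)))
    df = fit.residual_df
    if se > 0:
        tval = est / se
        pval = 2.0 * stats.t.sf(abs(tval), df)
    else:
        tval = 0.0 if est == 0 else np.copysign(np.inf, est)
        pval = 1.0 if est == 0 else 0.0
    return ContrastResult(estimate=est, se=se, t=float(tval), p=float(pval), df=df)
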