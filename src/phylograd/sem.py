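"""Piecewise structural equation modeling with mixed-model components.

A piecewise SEM expresses a causal hypothesis as a DAG and fits one local
regression per endogenous node; the global fit is judged by testing the
independence claims implied by the *missing* edges (the d-separation basis
set) and combining their p-values into Fisher's C, which is chi-squared with
2k degrees of freedom under the model (k = number of claims).

Component models here are random-intercept GLMMs: Gaussian responses are fit
by profiled REML (a closed-form profile over the variance ratio, implemented
here and cross-checked against statsmodels MixedLM); Poisson responses (plot
species richness) use a Laplace-approximate maximum-likelihood fit
implemented in this module, since the random intercept integral has no
closed form. Predictors are z-scored beforehand so fitted
coefficients are standardized path coefficients, and total effects decompose
exactly into the direct edge plus products of coefficients along directed
paths.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PathModel", "DSepClaim", "ComponentFit", "SEMFit",
    "scale_variables", "fit_component", "basis_set", "dsep_test",
    "fishers_c", "total_effects", "r_squared", "run_psem",
    "a_priori_model",
]

logger = logging.getLogger(__name__)


def scale_variables(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Z-score the given columns (mean 0, sd 1 with the n-1 denominator).

    Count responses destined for Poisson fits must not be passed here. A
    constant column raises rather than silently producing NaN.
    """
    out = table.copy()
    for col in columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot scale constant column {col!r}")
        out[col] = (x - x.mean()) / sd
    return out


@dataclass(frozen=True)
class PathModel:
    """A priori causal DAG plus per-response family and grouping.

    ``edges`` are directed (cause, effect) pairs over named variables.
    ``families`` maps each endogenous variable to ``"gaussian"`` or
    ``"poisson"``; endogenous variables absent from the map default to
    Gaussian. ``derived`` maps derived covariates to the structural node they
    are a function of (e.g. a quadratic term to its base variable); derived
    covariates enter regressions as predictors but have no structural
    equation and generate no independence claims.
    """

    edges: tuple
    families: dict = field(default_factory=dict)
    group: str = "site"
    derived: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "edges", tuple((u, v) for u, v in self.edges))
        g = self.structural_graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model must be acyclic")
        for node in self.endogenous():
            if self.families.get(node, "gaussian") not in ("gaussian", "poisson"):
                raise ValueError(f"unknown family for {node!r}")

    def nodes(self) -> list:
        seen = dict.fromkeys(u for e in self.edges for u in e)
        return list(seen)

    def structural_nodes(self) -> list:
        return [n for n in self.nodes() if n not in self.derived]

    def _base(self, node: str) -> str:
        return self.derived.get(node, node)

    def structural_graph(self) -> nx.DiGraph:
        """DAG over structural nodes, derived covariates folded into their base."""
        g = nx.DiGraph()
        g.add_nodes_from(self.structural_nodes())
        for u, v in self.edges:
            bu, bv = self._base(u), self._base(v)
            if bu != bv:
                g.add_edge(bu, bv)
        return g

    def endogenous(self) -> list:
        g = self.structural_graph()
        return [n for n in g.nodes if g.in_degree(n) > 0]

    def exogenous(self) -> list:
        g = self.structural_graph()
        return [n for n in g.nodes if g.in_degree(n) == 0]

    def predictors_of(self, node: str) -> list:
        """Regression predictors of a node: structural parents plus any
        derived covariates whose edges point at it."""
        preds = []
        for u, v in self.edges:
            if v == node and u not in preds:
                preds.append(u)
        return preds

    def family_of(self, node: str) -> str:
        return self.families.get(node, "gaussian")


def a_priori_model(response: str = "richness",
                   family: str = "poisson") -> PathModel:
    """The study's a priori path model for one diversity response.

    Temperature, precipitation and forest-use intensity are exogenous; PET is
    endogenous on temperature and precipitation (water-energy dynamics); the
    response depends on all five predictor terms, with the quadratic PET term
    as a derived covariate of PET.
    """
    return PathModel(
        edges=(
            ("Temp", "PET"), ("Precip", "PET"),
            ("Temp", response), ("Precip", response),
            ("PET", response), ("PET2", response), ("FUI", response),
        ),
        families={"PET": "gaussian", response: family},
        group="site",
        derived={"PET2": "PET"},
    )


# ---------------------------------------------------------------------------
# component GLMM fits


@dataclass
class ComponentFit:
    """One fitted structural equation (fixed effects + site random intercept)."""

    response: str
    predictors: list
    family: str
    params: pd.Series          # includes "Intercept"
    bse: pd.Series
    pvalues: pd.Series
    re_var: float              # random-intercept variance
    resid_var: float           # residual variance (Gaussian; NaN for Poisson)
    n: int
    converged: bool = True
    singular: bool = False
    fallback: bool = False     # Poisson mixed fit replaced by fixed-effects GLM
    design: pd.DataFrame | None = None
    y: np.ndarray | None = None

    def coef(self, predictor: str) -> float:
        return float(self.params[predictor])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "p": self.pvalues})


def _design(data: pd.DataFrame, response: str, predictors) -> tuple:
    cols = [response, *predictors]
    sub = data.dropna(subset=cols)
    dropped = len(data) - len(sub)
    if dropped:
        logger.info("dropped %d incomplete rows for %s model", dropped, response)
    y = sub[response].to_numpy(dtype=float)
    X = pd.DataFrame({"Intercept": np.ones(len(sub))})
    for p in predictors:
        X[p] = sub[p].to_numpy(dtype=float)
    return y, X, sub


class PoissonRandomInterceptGLMM:
    """Poisson GLMM with one random intercept, fit by Laplace-approximate ML.

    The marginal log-likelihood integrates the group intercepts out of
    ``y_ij ~ Poisson(exp(x_ij'b + u_j))``, ``u_j ~ N(0, s^2)``. Each group's
    integral is approximated by Laplace expansion around the conditional mode
    of ``u_j`` (found by a damped scalar Newton iteration, which is globally
    convergent here because the integrand is log-concave). The outer
    optimization over ``(b, log s)`` uses L-BFGS-B; standard errors come from
    the numerically differentiated Hessian of the Laplace log-likelihood.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("Poisson response must be non-negative integers")
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        codes, self.group_levels = pd.factorize(groups)
        self.group_idx = [np.flatnonzero(codes == j)
                          for j in range(len(self.group_levels))]

    def _group_loglik(self, eta: np.ndarray, y: np.ndarray,
                      sigma2: float) -> float:
        """Laplace-approximate log integral for one group."""
        u = 0.0
        sy = y.sum()
        for _ in range(100):
            lam = np.exp(eta + u)
            g1 = sy - lam.sum() - u / sigma2
            g2 = -lam.sum() - 1.0 / sigma2
            step = g1 / g2
            # damp steps to keep exp() in range; g is concave so this converges
            step = np.clip(step, -5.0, 5.0)
            u -= step
            if abs(step) < 1e-10:
                break
        lam = np.exp(eta + u)
        g = (y @ (eta + u) - lam.sum() - u * u / (2 * sigma2)
             - 0.5 * math.log(2 * math.pi * sigma2))
        g2 = -lam.sum() - 1.0 / sigma2
        return g + 0.5 * math.log(2 * math.pi) - 0.5 * math.log(-g2)

    def nloglik(self, theta: np.ndarray) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma2 = math.exp(2.0 * log_sigma)
        eta_all = self.X @ beta
        if not np.all(np.isfinite(eta_all)) or eta_all.max() > 50:
            return 1e10
        total = 0.0
        for idx in self.group_idx:
            total += self._group_loglik(eta_all[idx], self.y[idx], sigma2)
        return -total

    def fit(self) -> dict:
        import statsmodels.api as sm
        glm = sm.GLM(self.y, self.X, family=sm.families.Poisson()).fit()
        x0 = np.append(glm.params, math.log(0.3))
        res = optimize.minimize(self.nloglik, x0, method="L-BFGS-B",
                                bounds=[(None, None)] * (len(x0) - 1)
                                + [(-8.0, 3.0)],
                                options={"maxiter": 500})
        theta = res.x
        from statsmodels.tools.numdiff import approx_hess1
        H = approx_hess1(theta, self.nloglik)
        k = len(theta) - 1
        try:
            diag = np.diag(np.linalg.inv(H))[:k]
        except np.linalg.LinAlgError:
            diag = np.diag(np.linalg.pinv(H))[:k]
        if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
            # Hessian not positive definite (variance at its boundary);
            # fall back to the pseudo-inverse magnitude
            diag = np.abs(np.diag(np.linalg.pinv(H))[:k])
        bse = np.sqrt(diag)
        return {
            "params": theta[:k],
            "bse": bse,
            "sigma2": math.exp(2.0 * theta[-1]),
            "converged": bool(res.success),
            "loglik": -res.fun,
        }


def _gaussian_reml(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> dict:
    """Profiled REML for a single-random-intercept Gaussian mixed model.

    Profiles the fixed effects and residual variance out analytically
    (Woodbury identity per group), leaving a bounded one-dimensional search
    over the variance ratio — a search that cannot mis-converge the way a
    general multivariate optimizer can on this likelihood. Pseudo-inverses
    keep it stable when predictors are nearly collinear within groups, which
    happens routinely here because the quadratic PET term varies only
    through plot-level jitter inside a site.
    """
    codes, levels = pd.factorize(groups)
    idx = [np.flatnonzero(codes == j) for j in range(len(levels))]
    n, p = X.shape

    def profile(log_theta: float):
        theta = math.exp(log_theta)  # var ratio sigma_u^2 / sigma_e^2
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        ytWy = 0.0
        logdet = 0.0
        for rows in idx:
            Xj, yj = X[rows], y[rows]
            nj = len(rows)
            shrink = theta / (1.0 + theta * nj)
            sx, sy = Xj.sum(axis=0), yj.sum()
            XtWX += Xj.T @ Xj - shrink * np.outer(sx, sx)
            XtWy += Xj.T @ yj - shrink * sx * sy
            ytWy += yj @ yj - shrink * sy * sy
            logdet += math.log1p(theta * nj)
        beta = np.linalg.pinv(XtWX) @ XtWy
        rss = max(ytWy - beta @ XtWy, 1e-300)
        sign, logdet_x = np.linalg.slogdet(XtWX)
        crit = (n - p) * math.log(rss) + logdet + logdet_x
        return crit, beta, rss, XtWX

    res = optimize.minimize_scalar(lambda lt: profile(lt)[0],
                                   bounds=(-15.0, 15.0), method="bounded")
    _, beta, rss, XtWX = profile(res.x)
    sigma2_e = rss / (n - p)
    cov = sigma2_e * np.linalg.pinv(XtWX)
    return {"params": beta, "bse": np.sqrt(np.abs(np.diag(cov))),
            "re_var": math.exp(res.x) * sigma2_e, "resid_var": sigma2_e,
            "converged": True}


def fit_component(data: pd.DataFrame, response: str, predictors,
                  family: str, group: str = "site") -> ComponentFit:
    """Fit one structural equation as a random-intercept GLMM.

    Gaussian: profiled REML (plain OLS when only one group is present, the
    degenerate zero-variance case). Poisson: Laplace ML via
    :class:`PoissonRandomInterceptGLMM`; if that fit fails to converge the
    component falls back to a fixed-effects GLM with the group as a covariate
    and is flagged. A near-zero random-intercept variance is reported as a
    singular fit with a warning, and the fit is retained.
    """
    import statsmodels.api as sm

    y, X, sub = _design(data, response, predictors)
    groups = sub[group].to_numpy()
    names = list(X.columns)
    n_groups = len(pd.unique(groups))

    if family == "gaussian":
        if n_groups < 2:
            ols = sm.OLS(y, X.to_numpy()).fit()
            params, bse, pvals = ols.params, ols.bse, ols.pvalues
            re_var, resid_var, converged = 0.0, float(ols.scale), True
        else:
            res = _gaussian_reml(y, X.to_numpy(), groups)
            params, bse = res["params"], res["bse"]
            re_var, resid_var = res["re_var"], res["resid_var"]
            converged = res["converged"]
            z = params / bse
            pvals = 2 * stats.norm.sf(np.abs(z))
        singular = re_var < 1e-8
        if singular:
            logger.warning("singular fit (zero random-effect variance) for %s",
                           response)
        return ComponentFit(
            response=response, predictors=list(predictors), family=family,
            params=pd.Series(np.asarray(params), index=names),
            bse=pd.Series(np.asarray(bse), index=names),
            pvalues=pd.Series(np.asarray(pvals), index=names),
            re_var=re_var, resid_var=resid_var, n=len(y),
            converged=converged, singular=singular, design=X, y=y)

    if family == "poisson":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError(
                f"Poisson response {response!r} must be non-negative integers")
        fallback = False
        try:
            model = PoissonRandomInterceptGLMM(y, X.to_numpy(), groups)
            res = model.fit()
            converged = res["converged"]
            if not converged:
                raise RuntimeError("Laplace optimization did not converge")
            params = pd.Series(res["params"], index=names)
            bse = pd.Series(res["bse"], index=names)
            re_var = res["sigma2"]
        except Exception as exc:
            logger.warning("Poisson mixed fit failed for %s (%s); falling back"
                           " to fixed-effects GLM with group covariate",
                           response, exc)
            fallback = True
            Xf = pd.concat([X, pd.get_dummies(pd.Series(groups), prefix=group,
                                              drop_first=True, dtype=float)
                            .set_index(X.index)], axis=1)
            glm = sm.GLM(y, Xf.to_numpy(), family=sm.families.Poisson()).fit()
            params = pd.Series(glm.params[:len(names)], index=names)
            bse = pd.Series(glm.bse[:len(names)], index=names)
            re_var, converged = 0.0, True
        z = params / bse
        pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
        singular = (not fallback) and re_var < 1e-8
        if singular:
            logger.warning("singular fit (zero random-effect variance) for %s",
                           response)
        return ComponentFit(
            response=response, predictors=list(predictors), family=family,
            params=params, bse=bse, pvalues=pvals,
            re_var=re_var, resid_var=float("nan"), n=len(y),
            converged=converged, singular=singular, fallback=fallback,
            design=X, y=y)

    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# d-separation machinery


@dataclass
class DSepClaim:
    """One implied conditional independence: u _||_ v | conditioning set.

    ``downstream`` is the node whose component model is refit with the
    claimed-independent variable added; its Wald p-value is the claim's test.
    """

    u: str
    v: str
    conditioning: tuple
    downstream: str
    added: str
    pvalue: float = float("nan")


def basis_set(model: PathModel) -> list:
    """Enumerate the d-separation basis set of the model's DAG.

    One claim per unordered pair of non-adjacent structural nodes, excluding
    pairs in which both nodes are exogenous (their association is outside the
    model) and excluding derived covariates. The conditioning set is the
    union of the two nodes' parents; the claim is tested in the component
    model of whichever node is downstream in the causal ordering.
    """
    g = model.structural_graph()
    order = {n: i for i, n in enumerate(nx.topological_sort(g))}
    exo = set(model.exogenous())
    nodes = sorted(g.nodes, key=order.get)
    claims = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if g.has_edge(u, v) or g.has_edge(v, u):
                continue
            if u in exo and v in exo:
                continue
            parents = set(g.predecessors(u)) | set(g.predecessors(v))
            parents -= {u, v}
            down, other = (u, v) if order[u] > order[v] else (v, u)
            if down in exo:  # only possible if both exo; guarded above
                continue
            claims.append(DSepClaim(u=other, v=down,
                                    conditioning=tuple(sorted(parents)),
                                    downstream=down, added=other))
    return claims


def dsep_test(claim: DSepClaim, model: PathModel,
              data: pd.DataFrame) -> float:
    """Two-sided Wald p-value for one independence claim.

    Refits the downstream node's component model with the claimed-independent
    variable appended to its predictors and returns the added term's p-value.
    """
    preds = model.predictors_of(claim.downstream)
    if claim.added in preds:
        raise ValueError("claimed-independent variable already a predictor")
    fit = fit_component(data, claim.downstream, [*preds, claim.added],
                        model.family_of(claim.downstream), group=model.group)
    return float(fit.pvalues[claim.added])


def fishers_c(pvalues) -> tuple:
    """Fisher's C over basis-set p-values: C = -2 sum(ln p), df = 2k.

    Returns ``(C, df, P)`` with P the upper chi-squared tail. An empty list
    (saturated model) gives ``(0.0, 0, 1.0)``; any p = 0 is an error because
    C would be infinite.
    """
    ps = list(pvalues)
    if any(p == 0 for p in ps):
        raise ValueError("p-value of 0 makes Fisher's C infinite")
    if any(not (0 < p <= 1) for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    C = -2.0 * sum(math.log(p) for p in ps) if ps else 0.0
    df = 2 * len(ps)
    P = float(stats.chi2.sf(C, df)) if df else 1.0
    return C, df, P


# ---------------------------------------------------------------------------
# effects, variance explained, and the full piecewise fit


def _coef_graph(components: dict, model: PathModel) -> nx.DiGraph:
    g = nx.DiGraph()
    for u, v in model.edges:
        coef = components[v].coef(u) if v in components else float("nan")
        g.add_edge(u, v, coef=coef)
    return g


def total_effects(components: dict, model: PathModel,
                  response: str) -> pd.DataFrame:
    """Direct, indirect and total standardized effects on one response.

    The indirect effect of a source is the sum over all directed paths of
    length >= 2 of the product of standardized edge coefficients; the total
    is direct + indirect, an exact decomposition. Derived covariates (the
    quadratic PET term) carry only their direct edge.
    """
    g = _coef_graph(components, model)
    rows = []
    for source in [n for n in model.nodes() if n != response]:
        direct = g[source][response]["coef"] if g.has_edge(source, response) \
            else 0.0
        indirect = 0.0
        if nx.has_path(g, source, response):
            for path in nx.all_simple_paths(g, source, response):
                if len(path) <= 2:
                    continue
                prod = 1.0
                for a, b in zip(path, path[1:]):
                    prod *= g[a][b]["coef"]
                indirect += prod
        rows.append({"source": source, "direct": direct,
                     "indirect": indirect, "total": direct + indirect})
    return pd.DataFrame(rows).set_index("source")


def r_squared(fit: ComponentFit) -> tuple:
    """Marginal and conditional variance explained for one component.

    Marginal uses the fixed effects only, conditional adds the random
    intercept; both follow the variance-partitioning scheme for mixed models,
    with the Poisson case handled on the latent (log) scale via the lognormal
    approximation to the observation-level variance, ln(1 + 1/mean(y)).
    """
    X = fit.design[fit.predictors].to_numpy(dtype=float) if fit.predictors \
        else np.zeros((fit.n, 0))
    beta = fit.params[fit.predictors].to_numpy(dtype=float) if fit.predictors \
        else np.zeros(0)
    var_f = float(np.var(X @ beta)) if X.size else 0.0
    if fit.family == "gaussian":
        var_e = fit.resid_var
    else:
        lam_bar = float(np.mean(fit.y))
        var_e = math.log1p(1.0 / lam_bar) if lam_bar > 0 else float("nan")
    denom = var_f + fit.re_var + var_e
    if denom <= 0 or not np.isfinite(denom):
        return float("nan"), float("nan")
    marginal = var_f / denom
    conditional = (var_f + fit.re_var) / denom
    return float(marginal), float(conditional)


@dataclass
class SEMFit:
    """Assembled piecewise SEM result for one response model."""

    model: PathModel
    response: str
    components: dict               # node -> ComponentFit
    claims: list                   # DSepClaim with p-values filled in
    fisher_c: float
    df: int
    pvalue: float
    r2: dict                       # node -> (marginal, conditional)
    effects: pd.DataFrame          # source x (direct, indirect, total)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "fisher_c": self.fisher_c,
            "df": self.df,
            "pvalue": self.pvalue,
            "claims": [{"u": c.u, "v": c.v,
                        "conditioning": list(c.conditioning),
                        "downstream": c.downstream, "p": c.pvalue}
                       for c in self.claims],
            "r2": {k: {"marginal": v[0], "conditional": v[1]}
                   for k, v in self.r2.items()},
            "coefficients": {
                node: {
                    "params": {k: float(v) for k, v in fit.params.items()},
                    "se": {k: float(v) for k, v in fit.bse.items()},
                    "p": {k: float(v) for k, v in fit.pvalues.items()},
                    "re_var": float(fit.re_var),
                    "family": fit.family,
                    "n": int(fit.n),
                    "singular": bool(fit.singular),
                    "fallback": bool(fit.fallback),
                } for node, fit in self.components.items()},
            "total_effects": {
                src: {k: float(row[k]) for k in ("direct", "indirect", "total")}
                for src, row in self.effects.iterrows()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def run_psem(model: PathModel, data: pd.DataFrame,
             scale_columns=None) -> SEMFit:
    """Fit the full piecewise SEM for one response variable.

    Scales the predictor columns (and Gaussian responses) unless
    ``scale_columns`` is an empty list, fits every endogenous component,
    evaluates the d-separation basis set, and assembles Fisher's C,
    standardized coefficients, total effects and variance explained.
    """
    endo = model.endogenous()
    response = [n for n in endo if model.structural_graph().out_degree(n) == 0]
    if len(response) != 1:
        raise ValueError("model must have exactly one terminal response node")
    response = response[0]

    if scale_columns is None:
        scale_columns = [n for n in model.nodes()
                         if not (n == response and
                                 model.family_of(response) == "poisson")]
    used = [*model.nodes(), model.group]
    missing_cols = [c for c in used if c not in data.columns]
    if missing_cols:
        raise KeyError(f"data is missing columns {missing_cols}")
    complete = data.dropna(subset=[c for c in used])
    if len(complete) < len(data):
        logger.info("excluded %d incomplete plots from SEM",
                    len(data) - len(complete))
    scaled = scale_variables(complete, scale_columns) if scale_columns \
        else complete

    components = {}
    for node in endo:
        components[node] = fit_component(
            scaled, node, model.predictors_of(node), model.family_of(node),
            group=model.group)

    claims = basis_set(model)
    for claim in claims:
        claim.pvalue = dsep_test(claim, model, scaled)
    C, df, P = fishers_c([c.pvalue for c in claims])

    r2 = {node: r_squared(fit) for node, fit in components.items()}
    effects = total_effects(components, model, response)
    return SEMFit(model=model, response=response, components=components,
                  claims=claims, fisher_c=C, df=df, pvalue=P, r2=r2,
                  effects=effects)
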