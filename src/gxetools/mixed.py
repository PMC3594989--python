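"""REML mixed models for the genotype-by-environment table.

Genotypes are treated as a random sample, so the J observations of a
genotype (one per environment) form a multivariate normal vector with a
structured covariance matrix.  Four structures of increasing flexibility
are supported:

``cs``
    compound symmetry: one genetic variance plus one residual variance;
    constant correlation between environments.
``cs_het``
    compound symmetry with environment-specific residual variances;
    constant covariance, heterogeneous correlations.
``grouped``
    environments clustered into groups with an unstructured group-level
    genetic covariance matrix plus environment-specific residuals.
``unstructured``
    a free J x J covariance matrix (closed-form REML estimate).

For a balanced table with environment means as the only fixed effects,
the restricted deviance (up to a data-independent constant) is::

    dev(Sigma) = (I - 1) * log det Sigma + tr(Sigma^{-1} W)

with ``W`` the matrix of cross-products of genotype deviations from the
environment means.  This profile is minimized numerically over an
unconstrained parameterization (log variances; a row-normalized Cholesky
factor for the grouped structure).  Standard errors come from the
observed information (central-difference Hessian of the deviance on the
variance scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import GxETable, ValidationError

__all__ = [
    "VarianceStructureSpec",
    "REMLFit",
    "fit_mixed",
    "env_correlation",
    "total_variance",
    "wald_test",
    "deviance_test",
    "aic",
]

_KINDS = ("cs", "cs_het", "grouped", "unstructured")
_NESTING = {k: i for i, k in enumerate(_KINDS)}
_VAR_FLOOR = 1e-10


@dataclass
class VarianceStructureSpec:
    """Choice of variance-covariance structure for the mixed model.

    Parameters
    ----------
    kind
        One of ``cs``, ``cs_het``, ``grouped``, ``unstructured``.
    groups
        For ``grouped``: a partition of the environment labels, e.g.
        ``[["E1", "E2"], ["E3"], ["E4", "E5"]]``.
    fixed
        Parameters pinned to a constant instead of estimated.  Singleton
        groups have their group variance pinned automatically (default
        1.0) because it is confounded with the environment residual.
    """

    kind: str
    groups: list | None = None
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown variance structure {self.kind!r}")
        if self.kind == "grouped":
            if not self.groups:
                raise ValidationError("grouped structure needs a group partition")
            flat = [e for g in self.groups for e in g]
            if len(flat) != len(set(flat)):
                raise ValidationError("groups overlap")
        elif self.groups is not None:
            raise ValidationError(f"{self.kind} takes no groups")

    def validate_environments(self, env_ids: list) -> None:
        if self.kind == "grouped":
            flat = {e for g in self.groups for e in g}
            if flat != set(env_ids):
                raise ValidationError(
                    "groups must partition the environment set exactly"
                )

    def pinned_groups(self) -> dict:
        """Group index -> pinned variance for singleton groups."""
        if self.kind != "grouped":
            return {}
        out = {}
        for g, members in enumerate(self.groups):
            key = f"sigma2_c{g + 1}"
            if len(members) == 1:
                out[g] = float(self.fixed.get(key, 1.0))
            elif key in self.fixed:
                out[g] = float(self.fixed[key])
        return out

    def n_parameters(self, n_env: int) -> int:
        if self.kind == "cs":
            return 2
        if self.kind == "cs_het":
            return 1 + n_env
        if self.kind == "unstructured":
            return n_env * (n_env + 1) // 2
        ng = len(self.groups)
        return ng * (ng + 1) // 2 - len(self.pinned_groups()) + n_env


@dataclass
class REMLFit:
    """Result of a REML fit (or of injecting known variance components).

    ``covariance`` is the implied J x J genetic(+residual) covariance of
    a genotype's environment vector; all derived quantities (genetic
    correlations, total variances, Wald tests) are read off it.
    """

    spec: VarianceStructureSpec
    env_ids: list
    estimates: dict  # parameter name -> value
    std_errors: dict  # parameter name -> SE (may be NaN)
    covariance: pd.DataFrame  # J x J implied covariance
    env_means: pd.Series | None = None
    deviance: float | None = None
    n_params: int = 0
    n_genotypes: int | None = None
    converged: bool = True
    boundary: list = field(default_factory=list)
    message: str = ""

    @classmethod
    def from_components(
        cls, spec: VarianceStructureSpec, components: dict, env_ids: list
    ) -> "REMLFit":
        """Build a fit object directly from known variance components.

        Useful for evaluating implied correlations and variances at
        published parameter values without refitting.
        """
        spec.validate_environments(list(env_ids))
        cov = _implied_covariance(spec, components, list(env_ids))
        return cls(
            spec=spec,
            env_ids=list(env_ids),
            estimates=dict(components),
            std_errors={},
            covariance=cov,
            n_params=spec.n_parameters(len(env_ids)),
        )

    def summary(self) -> pd.DataFrame:
        rows = [
            (name, val, self.std_errors.get(name, np.nan))
            for name, val in self.estimates.items()
        ]
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se"])


# ---------------------------------------------------------------------------
# Implied covariance builders
# ---------------------------------------------------------------------------

def _group_of(spec: VarianceStructureSpec, env_ids: list) -> np.ndarray:
    lookup = {}
    for g, members in enumerate(spec.groups):
        for e in members:
            lookup[e] = g
    return np.array([lookup[e] for e in env_ids])


def _implied_covariance(
    spec: VarianceStructureSpec, params: dict, env_ids: list
) -> pd.DataFrame:
    j = len(env_ids)
    if spec.kind == "cs":
        v = params["sigma2_G"] * np.ones((j, j)) + params["sigma2_eps"] * np.eye(j)
    elif spec.kind == "cs_het":
        eps = np.array([params[f"sigma2_eps{k + 1}"] for k in range(j)])
        v = params["sigma2_G"] * np.ones((j, j)) + np.diag(eps)
    elif spec.kind == "grouped":
        ng = len(spec.groups)
        sig_c = np.zeros((ng, ng))
        for g in range(ng):
            sig_c[g, g] = params[f"sigma2_c{g + 1}"]
            for h in range(g + 1, ng):
                c = params.get(
                    f"sigma_c{g + 1}c{h + 1}", params.get(f"sigma_c{h + 1}c{g + 1}", 0.0)
                )
                sig_c[g, h] = sig_c[h, g] = c
        gi = _group_of(spec, env_ids)
        eps = np.array([params[f"sigma2_eps{k + 1}"] for k in range(j)])
        v = sig_c[np.ix_(gi, gi)] + np.diag(eps)
    else:  # unstructured
        v = np.zeros((j, j))
        for a in range(j):
            v[a, a] = params[f"sigma2_{a + 1}"]
            for b in range(a + 1, j):
                v[a, b] = v[b, a] = params[f"sigma_{a + 1}_{b + 1}"]
    return pd.DataFrame(v, index=env_ids, columns=env_ids)


def _params_from_cov(spec: VarianceStructureSpec, cov: np.ndarray, extras: dict):
    """Named parameter dict from a covariance matrix (unstructured only)."""
    j = cov.shape[0]
    out = {}
    for a in range(j):
        out[f"sigma2_{a + 1}"] = float(cov[a, a])
        for b in range(a + 1, j):
            out[f"sigma_{a + 1}_{b + 1}"] = float(cov[a, b])
    out.update(extras)
    return out


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------

def _cross_products(table: GxETable):
    table.require_complete("REML fitting")
    y = table.values()
    ybar = y.mean(axis=0)
    dev = y - ybar
    return y.shape[0], ybar, dev.T @ dev


def _deviance_of_cov(v: np.ndarray, w: np.ndarray, n_geno: int) -> float:
    sign, logdet = np.linalg.slogdet(v)
    if sign <= 0:
        return np.inf
    try:
        solve = np.linalg.solve(v, w)
    except np.linalg.LinAlgError:
        return np.inf
    return (n_geno - 1) * logdet + float(np.trace(solve))


class _Structure:
    """Maps between the unconstrained optimizer vector, the natural
    (variance-scale) vector, and the implied covariance matrix."""

    def __init__(self, spec: VarianceStructureSpec, env_ids: list):
        self.spec = spec
        self.env_ids = env_ids
        self.j = len(env_ids)
        if spec.kind == "grouped":
            self.gi = _group_of(spec, env_ids)
            self.ng = len(spec.groups)
            self.pinned = spec.pinned_groups()
        self.names = self._names()

    # natural parameters ------------------------------------------------
    def _names(self) -> list:
        j, spec = self.j, self.spec
        if spec.kind == "cs":
            return ["sigma2_G", "sigma2_eps"]
        if spec.kind == "cs_het":
            return ["sigma2_G"] + [f"sigma2_eps{k + 1}" for k in range(j)]
        if spec.kind == "grouped":
            names = []
            for g in range(self.ng):
                if g not in self.pinned:
                    names.append(f"sigma2_c{g + 1}")
            for g in range(self.ng):
                for h in range(g + 1, self.ng):
                    names.append(f"sigma_c{g + 1}c{h + 1}")
            names += [f"sigma2_eps{k + 1}" for k in range(j)]
            return names
        raise AssertionError

    def natural_to_cov(self, vec: np.ndarray) -> np.ndarray:
        params = dict(zip(self.names, vec))
        if self.spec.kind == "grouped":
            for g, pin in self.pinned.items():
                params[f"sigma2_c{g + 1}"] = pin
        return _implied_covariance(self.spec, params, self.env_ids).to_numpy()

    # unconstrained optimizer parameters --------------------------------
    def start(self, s: np.ndarray) -> np.ndarray:
        """Moment-based starting values on the unconstrained scale."""
        j = self.j
        off = s[~np.eye(j, dtype=bool)]
        s2g = max(float(off.mean()), 1e-4)
        if self.spec.kind == "cs":
            s2e = max(float(np.mean(np.diag(s))) - s2g, 1e-4)
            return np.log([s2g, s2e])
        if self.spec.kind == "cs_het":
            eps = np.maximum(np.diag(s) - s2g, 1e-4)
            return np.log(np.concatenate([[s2g], eps]))
        # grouped: start Sigma_c from between-group means of S, residuals
        # from the diagonal remainder; Cholesky of a jittered Sigma_c.
        ng, gi = self.ng, self.gi
        sig_c = np.zeros((ng, ng))
        for g in range(ng):
            for h in range(ng):
                block = s[np.ix_(gi == g, gi == h)]
                if g == h:
                    mask = ~np.eye(block.shape[0], dtype=bool)
                    sig_c[g, g] = block[mask].mean() if mask.any() else s2g
                else:
                    sig_c[g, h] = block.mean()
        for g, pin in self.pinned.items():
            sig_c[g, g] = pin
        sig_c = _nearest_pd(sig_c)
        for g, pin in self.pinned.items():  # re-impose pin after repair
            scale = np.sqrt(pin / max(sig_c[g, g], 1e-8))
            sig_c[g, :] *= scale
            sig_c[:, g] *= scale
        chol = np.linalg.cholesky(sig_c)
        eps = np.maximum(np.diag(s) - sig_c[gi, gi], 1e-4)
        vec = []
        for g in range(ng):
            for h in range(g + 1):
                vec.append(np.log(max(chol[g, h], 1e-4)) if g == h else chol[g, h])
        return np.concatenate([vec, np.log(eps)])

    def unconstrained_to_natural(self, x: np.ndarray) -> np.ndarray:
        if self.spec.kind in ("cs", "cs_het"):
            return np.exp(x)
        ng, j = self.ng, self.j
        ntri = ng * (ng + 1) // 2
        chol = np.zeros((ng, ng))
        pos = 0
        for g in range(ng):
            for h in range(g + 1):
                chol[g, h] = np.exp(x[pos]) if g == h else x[pos]
                pos += 1
        # pinned groups: rescale the row so the diagonal hits the pin
        for g, pin in self.pinned.items():
            norm = np.linalg.norm(chol[g, : g + 1])
            chol[g, : g + 1] *= np.sqrt(pin) / max(norm, 1e-12)
        sig_c = chol @ chol.T
        eps = np.exp(x[ntri:])
        vec = []
        for g in range(ng):
            if g not in self.pinned:
                vec.append(sig_c[g, g])
        for g in range(ng):
            for h in range(g + 1, ng):
                vec.append(sig_c[g, h])
        return np.concatenate([vec, eps])


def _nearest_pd(a: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh((a + a.T) / 2)
    return (vecs * np.maximum(vals, floor)) @ vecs.T


def _hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    hess = np.zeros((n, n))
    f0 = fun(x)

    def at(delta):
        return fun(x + delta)

    for a in range(n):
        ea = np.zeros(n)
        ea[a] = h[a]
        fpp = at(ea) + at(-ea)
        hess[a, a] = (fpp - 2 * f0) / h[a] ** 2
        for b in range(a + 1, n):
            eb = np.zeros(n)
            eb[b] = h[b]
            fab = at(ea + eb) - at(ea - eb) - at(-ea + eb) + at(-ea - eb)
            hess[a, b] = hess[b, a] = fab / (4 * h[a] * h[b])
    return hess


def fit_mixed(
    table: GxETable,
    spec: VarianceStructureSpec,
    max_iter: int = 200,
    gtol: float = 1e-8,
) -> REMLFit:
    """REML fit of the genotype-random mixed model on a balanced table.

    Environment means are the fixed effects (profiled out); the restricted
    deviance is minimized over the variance parameters of the requested
    structure.  The unstructured model has the closed-form solution
    ``W / (I - 1)`` and skips the optimizer.
    """
    env_ids = table.environments
    spec.validate_environments(env_ids)
    n_geno, ybar, w = _cross_products(table)
    j = len(env_ids)
    if n_geno <= j and spec.kind == "unstructured":
        raise ValidationError(
            "unstructured REML needs more genotypes than environments"
        )
    env_means = pd.Series(ybar, index=env_ids, name="env_mean")
    n_par = spec.n_parameters(j)

    if spec.kind == "unstructured":
        cov = w / (n_geno - 1)
        dev = _deviance_of_cov(cov, w, n_geno)
        est = _params_from_cov(spec, cov, {})
        ses = _unstructured_ses(cov, n_geno)
        return REMLFit(
            spec=spec, env_ids=env_ids, estimates=est, std_errors=ses,
            covariance=pd.DataFrame(cov, index=env_ids, columns=env_ids),
            env_means=env_means, deviance=float(dev), n_params=n_par,
            n_genotypes=n_geno, converged=True,
        )

    struct = _Structure(spec, env_ids)

    def objective(x):
        nat = struct.unconstrained_to_natural(x)
        return _deviance_of_cov(struct.natural_to_cov(nat), w, n_geno)

    x0 = struct.start(w / (n_geno - 1))
    res = optimize.minimize(
        objective, x0, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(
            f"REML did not converge for {spec.kind}: {res.message}; "
            f"trace: nit={res.nit}, fun={res.fun}"
        )
    nat = struct.unconstrained_to_natural(res.x)
    nat_clipped = nat.copy()
    boundary = []
    for name, val in zip(struct.names, nat):
        if name.startswith("sigma2") and val < 1e-8:
            boundary.append(name)
    nat_clipped[np.array([n.startswith("sigma2") for n in struct.names])] = np.maximum(
        nat_clipped[np.array([n.startswith("sigma2") for n in struct.names])],
        _VAR_FLOOR,
    )
    cov = struct.natural_to_cov(nat_clipped)
    dev = _deviance_of_cov(cov, w, n_geno)

    # observed information on the natural scale
    ses = dict.fromkeys(struct.names, np.nan)
    try:
        hess = _hessian(
            lambda v: _deviance_of_cov(struct.natural_to_cov(v), w, n_geno),
            nat_clipped,
        )
        pcov = 2.0 * np.linalg.pinv(hess)
        diag = np.diag(pcov)
        for name, d in zip(struct.names, diag):
            ses[name] = float(np.sqrt(d)) if d > 0 else np.nan
    except Exception as exc:  # pragma: no cover
        warnings.warn(f"standard errors unavailable: {exc}")

    estimates = dict(zip(struct.names, map(float, nat_clipped)))
    if spec.kind == "grouped":
        for g, pin in struct.pinned.items():
            estimates[f"sigma2_c{g + 1}"] = pin
            ses[f"sigma2_c{g + 1}"] = np.nan
    return REMLFit(
        spec=spec, env_ids=env_ids, estimates=estimates, std_errors=ses,
        covariance=pd.DataFrame(cov, index=env_ids, columns=env_ids),
        env_means=env_means, deviance=float(dev), n_params=n_par,
        n_genotypes=n_geno, converged=bool(res.success or np.isfinite(res.fun)),
        boundary=boundary, message=str(res.message),
    )


def _unstructured_ses(cov: np.ndarray, n_geno: int) -> dict:
    """Asymptotic SEs of Wishart-based covariance estimates:
    var(s_ab) = (s_aa s_bb + s_ab^2) / (I - 1)."""
    j = cov.shape[0]
    out = {}
    dof = n_geno - 1
    for a in range(j):
        out[f"sigma2_{a + 1}"] = float(np.sqrt(2 * cov[a, a] ** 2 / dof))
        for b in range(a + 1, j):
            va = (cov[a, a] * cov[b, b] + cov[a, b] ** 2) / dof
            out[f"sigma_{a + 1}_{b + 1}"] = float(np.sqrt(va))
    return out


# ---------------------------------------------------------------------------
# Derived quantities and tests
# ---------------------------------------------------------------------------

def env_correlation(fit: REMLFit, j, jstar) -> float:
    """Implied genetic correlation between two environments."""
    cov = fit.covariance
    for e in (j, jstar):
        if e not in cov.index:
            raise ValidationError(f"unknown environment {e!r}")
    va, vb = float(cov.loc[j, j]), float(cov.loc[jstar, jstar])
    if va <= 0 or vb <= 0:
        raise ValidationError("zero variance: correlation undefined")
    return float(cov.loc[j, jstar] / np.sqrt(va * vb))


def total_variance(fit: REMLFit, j) -> float:
    """Implied total variance in one environment (diagonal of the
    covariance: group/common genetic variance plus residual)."""
    if j not in fit.covariance.index:
        raise ValidationError(f"unknown environment {j!r}")
    return float(fit.covariance.loc[j, j])


def wald_test(fit: REMLFit, term: str = "E", mode: str = "sequential"):
    """Wald chi-square test of a fixed term (environment main effects).

    The statistic is the quadratic form of the J-1 independent
    environment contrasts against their estimated covariance; it is
    approximately chi-square with J-1 degrees of freedom.
    """
    if mode not in ("sequential", "conditional"):
        raise ValueError(f"unknown mode {mode!r}")
    if term not in ("E", "environment"):
        raise ValidationError(f"term {term!r} not in the fixed model")
    if fit.env_means is None or fit.n_genotypes is None:
        raise ValidationError("Wald test needs a data-based fit")
    j = len(fit.env_ids)
    m = fit.env_means.to_numpy()
    c = np.hstack([np.eye(j - 1), -np.ones((j - 1, 1))])  # contrasts vs last
    cm = c @ m
    vc = c @ (fit.covariance.to_numpy() / fit.n_genotypes) @ c.T
    rank = np.linalg.matrix_rank(vc)
    if rank < j - 1:
        warnings.warn("singular contrast covariance: DF reduced to rank")
    stat = float(cm @ np.linalg.pinv(vc) @ cm)
    df = int(rank)
    p = 1.0 if stat <= 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


def deviance_test(nested: REMLFit, full: REMLFit, tol: float = 1e-6):
    """Likelihood-ratio (deviance) test of two nested variance structures.

    Returns (delta deviance, delta DF, P).  The fixed model must be the
    same; structures must nest (cs within cs_het within grouped within
    unstructured).  When the null is on a variance boundary the
    chi-square reference is conservative.
    """
    for f in (nested, full):
        if f.deviance is None:
            raise ValidationError("deviance test needs data-based fits")
    if nested.env_ids != full.env_ids:
        raise ValidationError("fits are not on the same environments")
    if _NESTING[nested.spec.kind] > _NESTING[full.spec.kind]:
        raise ValidationError(
            f"{nested.spec.kind} is not nested in {full.spec.kind}"
        )
    ddev = nested.deviance - full.deviance
    if ddev < -tol * max(1.0, abs(full.deviance)) - 1e-3:
        raise ValidationError(
            "nested model has smaller deviance: check convergence"
        )
    ddev = max(ddev, 0.0)
    ddf = full.n_params - nested.n_params
    if ddf <= 0:
        p = 1.0 if ddev <= tol else 0.0
    else:
        p = float(stats.chi2.sf(ddev, ddf))
    if nested.boundary:
        warnings.warn(
            "null fit is on a variance boundary: chi-square P is conservative"
        )
    return float(ddev), int(ddf), p


def aic(fit: REMLFit) -> float:
    """Akaike information criterion: deviance + 2 x number of variance
    parameters.  Comparable only across fits with the same fixed model on
    the same data."""
    if fit.deviance is None:
        raise ValidationError("AIC needs a data-based fit")
    return float(fit.deviance + 2 * fit.n_params)


def summary_csv(fit: REMLFit, path) -> None:
    """Export a three-section summary (fixed Wald / variance estimates /
    deviance) as CSV."""
    rows = []
    if fit.env_means is not None:
        stat, df, p = wald_test(fit)
        rows.append(("fixed", "E", stat, df, p))
    for name, val in fit.estimates.items():
        rows.append(("random", name, val, np.nan, fit.std_errors.get(name, np.nan)))
    rows.append(("deviance", "", fit.deviance, fit.n_params, np.nan))
    pd.DataFrame(
        rows, columns=["section", "term", "value", "df_or_npar", "p_or_se"]
    ).to_csv(path, index=False)
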