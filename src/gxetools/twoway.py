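"""Fixed-effects models for the genotype-by-environment mean table.

Implements the classical sequence of two-way models used to describe
genotype-by-environment interaction (GEI):

* the additive (main effects) ANOVA benchmark,
* Finlay-Wilkinson joint regression (regression on the environment mean),
* AMMI (additive main effects and multiplicative interaction),
* GGE (genotype main effects + GEI, environment-centered SVD),
* factorial regression on explicit environmental covariates,

together with biplot geometry for the bilinear models.

Effects use the sum-to-zero parameterization throughout, so genotypic and
environmental main effects are interpretable as deviations from the grand
mean.  All F tests in an ANOVA table are against that table's own
residual mean square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import EnvCovariates, GxETable, ValidationError, environment_index, two_way_center

__all__ = [
    "AnovaTable",
    "FWFit",
    "BilinearFit",
    "FactorialFit",
    "additive_effects",
    "fit_additive",
    "fit_finlay_wilkinson",
    "fit_ammi",
    "fit_gge",
    "biplot_coords",
    "fit_factorial_regression",
]


@dataclass
class AnovaTable:
    """Sequential ANOVA table: one row per model term plus residual/total."""

    rows: pd.DataFrame  # columns: term, df, ss, ms, F, p

    def __post_init__(self) -> None:
        self.rows = self.rows.reset_index(drop=True)

    def __getitem__(self, term: str) -> pd.Series:
        match = self.rows[self.rows["term"] == term]
        if match.empty:
            raise KeyError(term)
        return match.iloc[0]

    @property
    def terms(self) -> list:
        return list(self.rows["term"])

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _anova(rows: list, resid: tuple, total_ss: float, total_df: int) -> AnovaTable:
    """Assemble an ANOVA table, testing every term against the residual MS."""
    r_ss, r_df = resid
    r_ms = r_ss / r_df if r_df > 0 else np.nan
    out = []
    for term, df, ss in rows:
        ms = ss / df if df > 0 else np.nan
        if r_df > 0 and r_ms > 0:
            f = ms / r_ms
            p = float(stats.f.sf(f, df, r_df))
        else:
            f, p = np.nan, np.nan
        out.append((term, df, ss, ms, f, p))
    out.append(("residual", r_df, r_ss, r_ms, np.nan, np.nan))
    out.append(("total", total_df, total_ss, total_ss / total_df, np.nan, np.nan))
    return AnovaTable(
        pd.DataFrame(out, columns=["term", "df", "ss", "ms", "F", "p"])
    )


def _main_effect_ss(table: GxETable):
    y = table.values()
    i, j = y.shape
    grand = y.mean()
    gi = y.mean(axis=1) - grand
    ej = y.mean(axis=0) - grand
    ss_e = i * float(np.sum(ej**2))
    ss_g = j * float(np.sum(gi**2))
    ss_tot = float(np.sum((y - grand) ** 2))
    ss_int = float(np.sum(two_way_center(table).to_numpy() ** 2))
    return grand, gi, ej, ss_e, ss_g, ss_int, ss_tot


def additive_effects(table: GxETable):
    """Sum-to-zero effect estimates (grand mean, genotype, environment)."""
    table.require_complete("the additive model")
    grand, gi, ej, *_ = _main_effect_ss(table)
    return (
        float(grand),
        pd.Series(gi, index=table.means.index, name="G"),
        pd.Series(ej, index=table.means.columns, name="E"),
    )


def fit_additive(table: GxETable) -> AnovaTable:
    """ANOVA of the additive two-way model ``mu + G_i + E_j``.

    The residual holds everything not captured by the main effects,
    i.e. GEI confounded with error when working on a table of means.
    """
    table.require_complete("the additive model")
    i, j = table.means.shape
    _, _, _, ss_e, ss_g, ss_int, ss_tot = _main_effect_ss(table)
    rows = [("E", j - 1, ss_e), ("G", i - 1, ss_g)]
    return _anova(rows, (ss_int, (i - 1) * (j - 1)), ss_tot, i * j - 1)


@dataclass
class FWFit:
    """Finlay-Wilkinson joint regression fit.

    ``slopes_prime`` are the reaction-norm slopes b'_i (mean 1 on
    balanced data); ``slopes`` are the centered b_i = b'_i - 1.
    """

    intercepts: pd.Series  # G'_i, trait units
    slopes_prime: pd.Series  # b'_i
    slopes: pd.Series  # b_i = b'_i - 1
    env_index: pd.Series  # E-hat_j
    anova: AnovaTable


def fit_finlay_wilkinson(table: GxETable) -> FWFit:
    """Regression-on-the-mean model: ``mu + G_i + b'_i * E_j``.

    The environmental quality index is the environment mean deviation;
    each genotype gets a regression slope on it.  The interaction sum of
    squares of the additive model splits into a heterogeneity-of-slopes
    part (DF I-1) and a residual (DF (I-1)(J-2)).
    """
    table.require_complete("Finlay-Wilkinson regression")
    i, j = table.means.shape
    if j < 3:
        raise ValidationError("Finlay-Wilkinson needs at least 3 environments")
    y = table.values()
    e_hat = environment_index(table)
    e = e_hat.to_numpy()
    s_e2 = float(np.sum(e**2))
    if s_e2 < 1e-12 * max(1.0, np.abs(y).max() ** 2):
        raise ValidationError(
            "all environment indices equal: slopes are undefined"
        )
    row_mean = y.mean(axis=1)
    b_prime = (y - row_mean[:, None]) @ e / s_e2
    _, _, _, ss_e, ss_g, ss_int, ss_tot = _main_effect_ss(table)
    ss_het = float(np.sum((b_prime - 1.0) ** 2) * s_e2)
    ss_res = ss_int - ss_het
    rows = [
        ("E", j - 1, ss_e),
        ("G", i - 1, ss_g),
        ("heterogeneity", i - 1, ss_het),
    ]
    anova = _anova(rows, (ss_res, (i - 1) * (j - 2)), ss_tot, i * j - 1)
    idx = table.means.index
    return FWFit(
        intercepts=pd.Series(row_mean, index=idx, name="intercept"),
        slopes_prime=pd.Series(b_prime, index=idx, name="slope"),
        slopes=pd.Series(b_prime - 1.0, index=idx, name="centered_slope"),
        env_index=e_hat,
        anova=anova,
    )


@dataclass
class BilinearFit:
    """SVD-based bilinear decomposition (AMMI or GGE).

    Scores are the unit-norm singular vectors; per-axis sums of squares
    equal the squared singular values.  Axis degrees of freedom follow
    Gollob: I + J - 1 - 2k for axis k.
    """

    kind: str  # "AMMI" | "GGE"
    k: int
    gen_scores: pd.DataFrame  # I x K
    env_scores: pd.DataFrame  # J x K
    singular_values: np.ndarray
    axis_ss: np.ndarray
    axis_df: np.ndarray
    residual_ss: float
    residual_df: int
    centering: str
    anova: AnovaTable

    def reconstruct(self, k: int | None = None) -> pd.DataFrame:
        """Rank-k reconstruction of the centered matrix."""
        k = self.k if k is None else k
        g = self.gen_scores.to_numpy()[:, :k] * self.singular_values[:k]
        z = self.env_scores.to_numpy()[:, :k]
        return pd.DataFrame(
            g @ z.T, index=self.gen_scores.index, columns=self.env_scores.index
        )


def _fix_signs(u: np.ndarray, vt: np.ndarray):
    """Resolve SVD sign ambiguity: the largest-|loading| environmental
    score on each axis is made positive."""
    for k in range(vt.shape[0]):
        jmax = int(np.argmax(np.abs(vt[k])))
        if vt[k, jmax] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    return u, vt


def _bilinear(table: GxETable, k: int, kind: str) -> BilinearFit:
    table.require_complete(f"the {kind} model")
    i, j = table.means.shape
    # the double-centered matrix has rank <= min(I-1, J-1); removing only
    # the environment means leaves rank up to min(I-1, J)
    kmax = min(i - 1, j - 1) if kind == "AMMI" else min(i - 1, j)
    if not (1 <= k <= kmax):
        raise ValidationError(f"K must be between 1 and {kmax} for {kind}")
    y = table.values()
    if kind == "AMMI":
        centered = two_way_center(table).to_numpy()
        centering = "double (G and E main effects removed)"
    else:
        centered = y - y.mean(axis=0, keepdims=True)
        centering = "environment (E main effect removed)"
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u, vt = _fix_signs(u, vt)
    ss_axes = s[:k] ** 2
    df_axes = np.array([i + j - 1 - 2 * (a + 1) for a in range(k)])
    ss_centered = float(np.sum(centered**2))
    ss_res = ss_centered - float(np.sum(ss_axes))

    _, _, _, ss_e, ss_g, ss_int, ss_tot = _main_effect_ss(table)
    if kind == "AMMI":
        res_df = (i - 1) * (j - 1) - int(np.sum(df_axes))
        rows = [("E", j - 1, ss_e), ("G", i - 1, ss_g)]
    else:
        # GGE absorbs G into the multiplicative part
        res_df = (i - 1) * j - int(np.sum(df_axes))
        rows = [("E", j - 1, ss_e)]
    rows += [
        (f"PCA{a + 1}", int(df_axes[a]), float(ss_axes[a])) for a in range(k)
    ]
    anova = _anova(rows, (ss_res, res_df), ss_tot, i * j - 1)
    return BilinearFit(
        kind=kind,
        k=k,
        gen_scores=pd.DataFrame(
            u[:, :k], index=table.means.index,
            columns=[f"PCA{a + 1}" for a in range(k)],
        ),
        env_scores=pd.DataFrame(
            vt[:k].T, index=table.means.columns,
            columns=[f"PCA{a + 1}" for a in range(k)],
        ),
        singular_values=s[:k].copy(),
        axis_ss=ss_axes,
        axis_df=df_axes,
        residual_ss=ss_res,
        residual_df=res_df,
        centering=centering,
        anova=anova,
    )


def fit_ammi(table: GxETable, k: int) -> BilinearFit:
    """AMMI model: SVD of the double-centered interaction matrix.

    GEI is described by K multiplicative axes, each the product of a
    genotypic score and an environmental score.
    """
    return _bilinear(table, k, "AMMI")


def fit_gge(table: GxETable, k: int) -> BilinearFit:
    """GGE model: SVD of the environment-centered table.

    The multiplicative axes jointly represent genotype main effects and
    GEI, so genotype projections approximate overall performance.
    """
    return _bilinear(table, k, "GGE")


_GAMMA = {"symmetric": 0.5, "genotype": 1.0, "environment": 0.0}


def biplot_coords(fit: BilinearFit, scaling: str = "symmetric"):
    """2-D biplot coordinates from the first two bilinear axes.

    Singular values are split between genotype and environment scores
    with exponent gamma (symmetric: 1/2).  The inner product of a
    genotype and an environment point equals the rank-2 reconstruction of
    the centered table value.
    """
    if fit.k < 2:
        raise ValidationError("biplot coordinates need at least 2 axes")
    if scaling not in _GAMMA:
        raise ValueError(f"unknown scaling {scaling!r}")
    gamma = _GAMMA[scaling]
    lam = fit.singular_values[:2]
    g = fit.gen_scores.to_numpy()[:, :2] * lam**gamma
    e = fit.env_scores.to_numpy()[:, :2] * lam ** (1.0 - gamma)
    gcoord = pd.DataFrame(g, index=fit.gen_scores.index, columns=["x", "y"])
    ecoord = pd.DataFrame(e, index=fit.env_scores.index, columns=["x", "y"])
    # unit direction of each environment axis (for projections)
    norms = np.linalg.norm(e, axis=1, keepdims=True)
    dirs = np.divide(e, norms, out=np.zeros_like(e), where=norms > 0)
    edirs = pd.DataFrame(dirs, index=fit.env_scores.index, columns=["x", "y"])
    return gcoord, ecoord, edirs


@dataclass
class FactorialFit:
    """Factorial regression fit: genotype sensitivities to covariates."""

    sensitivities: pd.DataFrame  # I x K, trait units per covariate unit
    anova: AnovaTable


def fit_factorial_regression(
    table: GxETable, covs: EnvCovariates, order: list | None = None
) -> FactorialFit:
    """GEI explained by genotype-specific regressions on explicit
    environmental covariates.

    Covariates enter sequentially in the given order; each term carries
    I-1 degrees of freedom and its sum of squares is the sequential
    reduction of the interaction residual.  F tests are against this
    table's residual MS.
    """
    table.require_complete("factorial regression")
    i, j = table.means.shape
    order = list(order) if order is not None else list(covs.names)
    if not order:
        raise ValidationError("no covariates given")
    if len(order) > j - 2:
        raise ValidationError(
            f"at most J-2 = {j - 2} covariates can be fitted with a residual"
        )
    z_all = covs.aligned_to(table)[order]
    for name in order:
        if not covs.centered.get(name, False) and abs(z_all[name].sum()) > 1e-9:
            raise ValidationError(
                f"covariate {name!r} is not centered; call EnvCovariates.center"
            )
    r = two_way_center(table).to_numpy()  # I x J interaction residuals
    _, _, _, ss_e, ss_g, ss_int, ss_tot = _main_effect_ss(table)
    rows = [("E", j - 1, ss_e), ("G", i - 1, ss_g)]
    rss_prev = ss_int
    sens = np.zeros((i, len(order)))
    for k, name in enumerate(order):
        z = z_all[order[: k + 1]].to_numpy()  # J x (k+1)
        if np.linalg.matrix_rank(z) <= k:
            raise ValidationError(
                f"covariate {name!r} is collinear with earlier covariates"
            )
        beta, *_ = np.linalg.lstsq(z, r.T, rcond=None)  # (k+1) x I
        rss = float(np.sum((r.T - z @ beta) ** 2))
        rows.append((f"G.{name}", i - 1, rss_prev - rss))
        rss_prev = rss
        sens = beta.T  # sensitivities from the fit with terms 1..k+1
    res_df = (i - 1) * (j - 1 - len(order))
    anova = _anova(rows, (rss_prev, res_df), ss_tot, i * j - 1)
    return FactorialFit(
        sensitivities=pd.DataFrame(sens, index=table.means.index, columns=order),
        anova=anova,
    )
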