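"""Mixed-model QTL detection across environments.

The scan follows the standard multi-environment mapping strategy:

1. select a variance-covariance structure for the phenotypic data (see
   :mod:`gxetools.mixed`);
2. genome-wide simple interval mapping (SIM): at every grid position the
   fixed model gains environment-specific additive (optionally
   dominance) QTL effects, tested with a Wald chi-square;
3. composite interval mapping (CIM) with cofactors chosen from the SIM
   peaks, by default excluding all cofactors on the chromosome being
   tested (restricted CIM);
4. a final multi-QTL model with backward elimination, partition of each
   QTL's effect into a main effect and QTL-by-environment interaction
   (QEI), and optional regression of a QTL's effect on an environmental
   covariate.

The variance structure and its parameters are fixed at the step-1 REML
fit during scanning.  With the covariance known, all Wald statistics are
computed as differences of generalized-least-squares objective minima
between nested fixed models, which makes sequential tests exactly
additive and non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import EnvCovariates, GxETable, ValidationError
from .mixed import REMLFit, VarianceStructureSpec, fit_mixed
from .predictors import PredictorSet

__all__ = [
    "ScanResult",
    "MultiQTLFit",
    "QEIPartition",
    "CovariateQTLFit",
    "sim_scan",
    "cim_scan",
    "significance_threshold",
    "select_cofactors",
    "fit_multi_qtl",
    "partition_qei",
    "qtl_covariate_model",
]

_MONO_TOL = 1e-9


# ---------------------------------------------------------------------------
# GLS with a known residual covariance
# ---------------------------------------------------------------------------

def _gls(y: np.ndarray, z_env: np.ndarray, siginv: np.ndarray,
         z_main: np.ndarray | None = None):
    """GLS fit of y_i = sum_c z_env[i,c] * beta_c (one coefficient per
    environment) + sum_m z_main[i,m] * gamma_m * 1_J, with per-genotype
    covariance Sigma.

    Returns (beta, Ainv, Q) where Q is the minimized GLS objective
    sum_i (y_i - fit)' Sigma^-1 (y_i - fit).  Parameter order: for each
    env-specific column its J coefficients, then the main columns.
    """
    i, j = y.shape
    q = z_env.shape[1]
    m = 0 if z_main is None else z_main.shape[1]
    ztz = z_env.T @ z_env
    ysig = y @ siginv
    a = np.zeros((q * j + m, q * j + m))
    b = np.zeros(q * j + m)
    a[: q * j, : q * j] = np.kron(ztz, siginv)
    b[: q * j] = (z_env.T @ ysig).reshape(-1)
    if m:
        s1 = siginv @ np.ones(j)
        a_em = np.einsum("cm,j->cjm", z_env.T @ z_main, s1).reshape(q * j, m)
        a[: q * j, q * j:] = a_em
        a[q * j:, : q * j] = a_em.T
        a[q * j:, q * j:] = (z_main.T @ z_main) * float(np.ones(j) @ s1)
        b[q * j:] = z_main.T @ ysig.sum(axis=1)
    try:
        ainv = np.linalg.inv(a)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular scan design (collinear columns)") from exc
    beta = ainv @ b
    yquad = float(np.einsum("ij,ij->", ysig, y))
    return beta, ainv, yquad - float(b @ beta)


def _chi2_record(q_without: float, q_with: float, df: int):
    stat = max(q_without - q_with, 0.0)
    p = 1.0 if stat <= 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


def _align(table: GxETable, preds: PredictorSet) -> np.ndarray:
    if set(table.genotypes) != set(preds.individuals):
        raise ValidationError(
            "genotypes in the phenotype table and predictor set differ"
        )
    return preds.x_add.reindex(table.genotypes).to_numpy(), preds.x_dom.reindex(
        table.genotypes
    ).to_numpy()


# ---------------------------------------------------------------------------
# Scan results
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-position Wald profile plus environment-specific effects."""

    profile: pd.DataFrame  # chromosome, position_cM, wald, df, p, neglog10p
    effects: pd.DataFrame  # tested positions x environments, alpha_j
    std_errors: pd.DataFrame
    dom_profile: pd.DataFrame | None
    dom_effects: pd.DataFrame | None
    cofactors: list
    restriction: object
    skipped: list  # [(chromosome, position, reason), ...]
    x_add_tested: pd.DataFrame  # predictor columns at tested positions
    sigma: pd.DataFrame
    spec: VarianceStructureSpec
    threshold: dict = field(default_factory=dict)

    @property
    def positions(self) -> list:
        return list(
            zip(self.profile["chromosome"], self.profile["position_cM"])
        )

    def peak(self) -> tuple:
        row = self.profile.loc[self.profile["neglog10p"].idxmax()]
        return (row["chromosome"], float(row["position_cM"]))

    def to_csv(self, path) -> None:
        out = self.profile.copy()
        eff = self.effects.copy()
        eff.columns = [f"alpha_{e}" for e in eff.columns]
        out = pd.concat([out.reset_index(drop=True), eff.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)


def sim_scan(
    table: GxETable,
    preds: PredictorSet,
    spec: VarianceStructureSpec,
    fit_dominance: bool = False,
    sigma: pd.DataFrame | None = None,
) -> ScanResult:
    """Genome-wide single-QTL scan (simple interval mapping).

    At every predictor position the fixed model is extended with
    environment-specific additive effects (and, if requested, dominance
    effects tested sequentially after the additive term).  The genotypic
    covariance is the step-1 REML fit of ``spec`` on the table.
    """
    return cim_scan(table, preds, [], spec, fit_dominance=fit_dominance, sigma=sigma)


def cim_scan(
    table: GxETable,
    preds: PredictorSet,
    cofactors: list,
    spec: VarianceStructureSpec,
    restriction: object = "same-chromosome",
    fit_dominance: bool = False,
    sigma: pd.DataFrame | None = None,
) -> ScanResult:
    """Composite interval mapping: a scan that corrects for background
    QTLs via environment-specific cofactor effects.

    ``restriction`` controls which cofactors are dropped near the tested
    position: ``"same-chromosome"`` (restricted CIM, the default)
    excludes every cofactor on the tested chromosome; ``("window", w)``
    excludes cofactors within ``w`` cM.  With an empty cofactor list the
    scan is identical to SIM.
    """
    if sigma is None:
        sigma = fit_mixed(table, spec).covariance
    env_ids = table.environments
    j = len(env_ids)
    siginv = np.linalg.inv(sigma.to_numpy())
    y = table.values()
    x_add, x_dom = _align(table, preds)
    n_ind = y.shape[0]
    ones = np.ones((n_ind, 1))

    cof = [(c, float(p)) for c, p in cofactors]
    pos_index = {pos: k for k, pos in enumerate(preds.positions)}
    for c in cof:
        if c not in pos_index:
            raise ValidationError(f"cofactor {c} is not on the predictor grid")

    def excluded(chrom, pos):
        if restriction == "same-chromosome":
            return {c for c in cof if c[0] == chrom}
        if isinstance(restriction, tuple) and restriction[0] == "window":
            w = float(restriction[1])
            return {c for c in cof if c[0] == chrom and abs(c[1] - pos) <= w}
        raise ValueError(f"unknown restriction {restriction!r}")

    base_cache: dict = {}
    rows, eff_rows, se_rows, dom_rows, dom_eff_rows = [], [], [], [], []
    skipped, tested_cols = [], []
    for chrom, pos in preds.positions:
        k = pos_index[(chrom, pos)]
        x = x_add[:, [k]]
        if np.var(x) < _MONO_TOL:
            skipped.append((chrom, pos, "monomorphic predictor"))
            continue
        keep = tuple(sorted(set(cof) - excluded(chrom, pos), key=str))
        if keep not in base_cache:
            zc = np.hstack([ones] + [x_add[:, [pos_index[c]]] for c in keep])
            try:
                _, _, q0 = _gls(y, zc, siginv)
            except ValidationError:
                raise ValidationError(
                    "cofactor set is collinear; reduce the cofactor list"
                )
            base_cache[keep] = (zc, q0)
        zc, q0 = base_cache[keep]
        z1 = np.hstack([zc, x])
        if np.linalg.matrix_rank(z1) < z1.shape[1]:
            skipped.append((chrom, pos, "collinear with cofactors"))
            continue
        beta, ainv, q1 = _gls(y, z1, siginv)
        stat, df, p = _chi2_record(q0, q1, j)
        alpha = beta[-j:]
        se = np.sqrt(np.diag(ainv)[-j:])
        rows.append((chrom, pos, stat, df, p, -np.log10(max(p, 1e-300))))
        eff_rows.append(alpha)
        se_rows.append(se)
        tested_cols.append((chrom, pos))
        if fit_dominance:
            xd = x_dom[:, [k]]
            if np.var(xd) < _MONO_TOL or np.linalg.matrix_rank(
                np.hstack([z1, xd])
            ) < z1.shape[1] + 1:
                dom_rows.append((chrom, pos, np.nan, j, np.nan, np.nan))
                dom_eff_rows.append(np.full(j, np.nan))
            else:
                beta2, _, q2 = _gls(y, np.hstack([z1, xd]), siginv)
                dstat, ddf, dp = _chi2_record(q1, q2, j)
                dom_rows.append(
                    (chrom, pos, dstat, ddf, dp, -np.log10(max(dp, 1e-300)))
                )
                dom_eff_rows.append(beta2[-j:])

    if not rows:
        raise ValidationError("no testable positions (all skipped)")
    cols = ["chromosome", "position_cM", "wald", "df", "p", "neglog10p"]
    labels = [f"{c}@{p:g}" for c, p in tested_cols]
    profile = pd.DataFrame(rows, columns=cols)
    xsub = preds.x_add.reindex(table.genotypes)
    xsub = xsub[[f"{c}@{p:g}" for c, p in tested_cols]]
    return ScanResult(
        profile=profile,
        effects=pd.DataFrame(eff_rows, index=labels, columns=env_ids),
        std_errors=pd.DataFrame(se_rows, index=labels, columns=env_ids),
        dom_profile=pd.DataFrame(dom_rows, columns=cols) if fit_dominance else None,
        dom_effects=(
            pd.DataFrame(dom_eff_rows, index=labels, columns=env_ids)
            if fit_dominance
            else None
        ),
        cofactors=cof,
        restriction=restriction,
        skipped=skipped,
        x_add_tested=xsub,
        sigma=sigma,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Multiple-testing thresholds and cofactor selection
# ---------------------------------------------------------------------------

def significance_threshold(
    result: ScanResult, method: str = "li-ji", alpha: float = 0.05
) -> float:
    """Point-wise P cutoff controlling the genome-wide error rate.

    ``bonferroni`` divides alpha by the number of tested positions.
    ``li-ji`` divides by the effective number of independent tests,
    estimated from the eigenvalues of the correlation matrix of the
    tested predictor columns: n* = sum_i [ 1(lambda_i >= 1) +
    (lambda_i - floor(lambda_i)) ].
    """
    n = len(result.profile)
    if n < 2:
        raise ValidationError("need at least 2 tested positions")
    if method == "bonferroni":
        cutoff = alpha / n
        record = {"method": method, "alpha": alpha, "n": n, "cutoff": cutoff}
    elif method == "li-ji":
        x = result.x_add_tested.to_numpy()
        corr = np.corrcoef(x, rowvar=False)
        lam = np.linalg.eigvalsh(corr)
        lam = np.clip(lam, 0.0, None)
        n_eff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
        cutoff = alpha / n_eff
        record = {
            "method": method, "alpha": alpha, "n": n, "n_star": n_eff,
            "cutoff": cutoff,
        }
    else:
        raise ValueError(f"unknown method {method!r}")
    result.threshold = record
    return cutoff


def select_cofactors(
    result: ScanResult, cutoff: float, min_separation: float = 30.0
) -> list:
    """Cofactor positions from a scan: local maxima of -log10 P above the
    cutoff, retained greedily (best first) subject to a minimum pairwise
    separation within a chromosome."""
    prof = result.profile
    candidates = []
    for chrom, sub in prof.groupby("chromosome", sort=False):
        sub = sub.sort_values("position_cM").reset_index(drop=True)
        v = sub["neglog10p"].to_numpy()
        for k in range(len(sub)):
            if sub.loc[k, "p"] > cutoff:
                continue
            left_ok = k == 0 or v[k] >= v[k - 1]
            right_ok = k == len(sub) - 1 or v[k] >= v[k + 1]
            if left_ok and right_ok:
                candidates.append(
                    (v[k], chrom, float(sub.loc[k, "position_cM"]))
                )
    candidates.sort(reverse=True, key=lambda t: t[0])
    kept: list = []
    for _, chrom, pos in candidates:
        if all(
            c != chrom or abs(p - pos) >= min_separation for c, p in kept
        ):
            kept.append((chrom, pos))
    return sorted(kept, key=str)


# ---------------------------------------------------------------------------
# Final multi-QTL model
# ---------------------------------------------------------------------------

@dataclass
class QEIPartition:
    """Sequential partition of one QTL's effects into a main effect and
    QTL-by-environment interaction."""

    alpha_main: float
    alpha_qei: pd.Series
    wald_main: tuple  # (stat, df=1, p)
    wald_qei: tuple  # (stat, df=J-1, p)


@dataclass
class MultiQTLFit:
    """Final multi-QTL model with environment-specific effects."""

    qtls: list  # [(chromosome, position_cM), ...]
    effects: pd.DataFrame  # QTL x environment
    std_errors: pd.DataFrame
    significant: pd.DataFrame  # |estimate| > 2 SE per cell
    wald: pd.DataFrame  # per-QTL conditional Wald (stat, df, p)
    dropped: list
    sigma: pd.DataFrame
    spec: VarianceStructureSpec
    env_means: pd.Series
    _table: GxETable
    _x: pd.DataFrame  # predictor columns of the surviving QTLs

    def qtl_label(self, qtl) -> str:
        if isinstance(qtl, str):
            return qtl
        c, p = qtl
        return f"{c}@{float(p):g}"


def fit_multi_qtl(
    table: GxETable,
    preds: PredictorSet,
    qtl_positions: list,
    spec: VarianceStructureSpec,
    drop_alpha: float = 0.05,
    sigma: pd.DataFrame | None = None,
) -> MultiQTLFit:
    """Fit all candidate QTLs jointly and backward-eliminate.

    All candidates enter with environment-specific additive effects; the
    least significant QTL (conditional Wald, given all others) is removed
    while its P exceeds ``drop_alpha``, refitting after each removal (at
    least one QTL is always retained).  Per-cell significance flags use
    the +-2 SE confidence rule.
    """
    if not qtl_positions:
        raise ValidationError("candidate QTL list is empty")
    if sigma is None:
        sigma = fit_mixed(table, spec).covariance
    env_ids = table.environments
    j = len(env_ids)
    siginv = np.linalg.inv(sigma.to_numpy())
    y = table.values()
    n_ind = y.shape[0]
    ones = np.ones((n_ind, 1))
    xcols = {}
    for c, p in qtl_positions:
        key = (c, float(p))
        xcols[key] = preds.column(key)
        x = preds.x_add.reindex(table.genotypes)
        xcols[key] = x[f"{c}@{float(p):g}"].to_numpy()
        if np.var(xcols[key]) < _MONO_TOL:
            raise ValidationError(f"candidate {key} is monomorphic")

    current = [(c, float(p)) for c, p in qtl_positions]
    dropped = []
    while True:
        z = np.hstack([ones] + [xcols[q][:, None] for q in current])
        beta, ainv, q_full = _gls(y, z, siginv)
        walds = []
        for idx, qtl in enumerate(current):
            zr = np.hstack(
                [ones] + [xcols[q][:, None] for q in current if q != qtl]
            )
            _, _, q_red = _gls(y, zr, siginv)
            walds.append(_chi2_record(q_red, q_full, j))
        worst = int(np.argmax([w[2] for w in walds]))
        if len(current) > 1 and walds[worst][2] > drop_alpha:
            dropped.append((current[worst], walds[worst][2]))
            current.pop(worst)
            continue
        break

    labels = [f"{c}@{p:g}" for c, p in current]
    eff = beta[j:].reshape(len(current), j)
    se = np.sqrt(np.diag(ainv)[j:]).reshape(len(current), j)
    effects = pd.DataFrame(eff, index=labels, columns=env_ids)
    ses = pd.DataFrame(se, index=labels, columns=env_ids)
    wald = pd.DataFrame(
        walds, index=labels, columns=["wald", "df", "p"]
    )
    xmat = pd.DataFrame(
        {lab: xcols[q] for lab, q in zip(labels, current)}, index=table.genotypes
    )
    return MultiQTLFit(
        qtls=current,
        effects=effects,
        std_errors=ses,
        significant=effects.abs() > 2.0 * ses,
        wald=wald,
        dropped=dropped,
        sigma=sigma,
        spec=spec,
        env_means=pd.Series(beta[:j], index=env_ids, name="env_mean"),
        _table=table,
        _x=xmat,
    )


def partition_qei(fit: MultiQTLFit, qtl) -> QEIPartition:
    """Sequential Wald partition of one QTL's environment-specific
    effects into a main effect (1 DF, tested first) and QEI (J-1 DF,
    conditional on the main effect)."""
    label = fit.qtl_label(qtl)
    if label not in fit._x.columns:
        raise ValidationError(f"QTL {qtl!r} not in the fitted model")
    env_ids = list(fit.effects.columns)
    j = len(env_ids)
    y = fit._table.values()
    siginv = np.linalg.inv(fit.sigma.to_numpy())
    ones = np.ones((y.shape[0], 1))
    others = [c for c in fit._x.columns if c != label]
    z_others = np.hstack([ones] + [fit._x[c].to_numpy()[:, None] for c in others])
    x = fit._x[label].to_numpy()[:, None]
    _, _, q0 = _gls(y, z_others, siginv)
    beta_m, _, q_main = _gls(y, z_others, siginv, z_main=x)
    _, _, q_full = _gls(y, np.hstack([z_others, x]), siginv)
    w_main = _chi2_record(q0, q_main, 1)
    w_qei = _chi2_record(q_main, q_full, j - 1)
    alpha_main = float(beta_m[-1])
    alpha_j = fit.effects.loc[label]
    return QEIPartition(
        alpha_main=alpha_main,
        alpha_qei=alpha_j - alpha_main,
        wald_main=w_main,
        wald_qei=w_qei,
    )


# ---------------------------------------------------------------------------
# QTL effect vs environmental covariate
# ---------------------------------------------------------------------------

@dataclass
class CovariateQTLFit:
    """Regression of one QTL's environment-specific effect on an
    environmental covariate: alpha_j = alpha* + beta* Z_j + a_j with
    a_j ~ N(0, sigma2_a)."""

    qtl: str
    covariate: str
    alpha_star: float
    beta_star: float
    se_alpha: float
    se_beta: float
    sigma2_a: float
    wald_beta: tuple  # (stat, df=1, p)
    env_effects: pd.Series  # fitted fixed part alpha* + beta* Z_j
    deviance: float


def qtl_covariate_model(
    table: GxETable,
    preds: PredictorSet,
    fit: MultiQTLFit,
    qtl,
    covariate: pd.Series | tuple,
) -> CovariateQTLFit:
    """Re-express one QTL's environment-specific effect as a linear
    function of an environmental covariate plus a random residual effect.

    The covariate must be centered across environments.  Other QTLs in
    the model keep their environment-specific effects.  The residual QTL
    effect adds variance ``sigma2_a * x_i^2`` to each environment, which
    is estimated by REML with the other variance parameters fixed at the
    step-1 values.
    """
    label = fit.qtl_label(qtl)
    if label not in fit._x.columns:
        raise ValidationError(f"QTL {qtl!r} not in the fitted model")
    if isinstance(covariate, tuple):
        covs, name = covariate
        z = covs.aligned_to(table)[name]
    else:
        z = covariate.reindex(table.environments)
        name = str(covariate.name)
    z = z.astype(float)
    if z.isna().any():
        raise ValidationError("covariate does not cover all environments")
    if float(z.std()) < 1e-12:
        raise ValidationError("covariate is constant across environments")
    if abs(float(z.sum())) > 1e-6 * max(1.0, float(z.abs().max())):
        warnings.warn(
            "covariate is not centered: alpha* is the effect at Z = 0, "
            "not in the average environment"
        )
    zv = z.to_numpy()

    env_ids = table.environments
    j = len(env_ids)
    y = table.values()
    n_ind = y.shape[0]
    sigma = fit.sigma.to_numpy()
    x_t = fit._x[label].to_numpy()
    others = [c for c in fit._x.columns if c != label]

    # per-genotype design: env means, other QTLs env-specific, then the
    # target QTL's intercept (x*1) and slope (x*Z) columns
    p_env = (1 + len(others)) * j
    designs = np.zeros((n_ind, j, p_env + 2))
    designs[:, :, :j] = np.eye(j)[None, :, :]
    for c_idx, c in enumerate(others):
        xo = fit._x[c].to_numpy()
        designs[:, :, (1 + c_idx) * j:(2 + c_idx) * j] = (
            xo[:, None, None] * np.eye(j)[None, :, :]
        )
    designs[:, :, p_env] = x_t[:, None] * np.ones(j)[None, :]
    designs[:, :, p_env + 1] = x_t[:, None] * zv[None, :]

    def reml_pieces(log_s2a: float):
        s2a = np.exp(log_s2a)
        a = np.zeros((p_env + 2, p_env + 2))
        b = np.zeros(p_env + 2)
        logdet = 0.0
        yquad = 0.0
        for i in range(n_ind):
            vi = sigma + s2a * x_t[i] ** 2 * np.eye(j)
            sign, ld = np.linalg.slogdet(vi)
            logdet += ld
            vinv_x = np.linalg.solve(vi, designs[i])
            vinv_y = np.linalg.solve(vi, y[i])
            a += designs[i].T @ vinv_x
            b += designs[i].T @ vinv_y
            yquad += float(y[i] @ vinv_y)
        ainv = np.linalg.pinv(a)
        beta = ainv @ b
        q = yquad - float(b @ beta)
        sign_a, ld_a = np.linalg.slogdet(a)
        dev = logdet + q + ld_a
        return dev, beta, ainv

    res = optimize.minimize_scalar(
        lambda t: reml_pieces(t)[0],
        bounds=(np.log(1e-10), np.log(10.0 * float(np.var(y)))),
        method="bounded",
        options={"xatol": 1e-8},
    )
    dev, beta, ainv = reml_pieces(res.x)
    s2a = float(np.exp(res.x))
    if s2a <= 1.5e-10:
        s2a = 0.0
    alpha_star = float(beta[p_env])
    beta_star = float(beta[p_env + 1])
    se_a = float(np.sqrt(max(ainv[p_env, p_env], 0.0)))
    se_b = float(np.sqrt(max(ainv[p_env + 1, p_env + 1], 0.0)))
    stat = (beta_star / se_b) ** 2 if se_b > 0 else np.inf
    wald_beta = (float(stat), 1, float(stats.chi2.sf(stat, 1)))
    return CovariateQTLFit(
        qtl=label,
        covariate=name,
        alpha_star=alpha_star,
        beta_star=beta_star,
        se_alpha=se_a,
        se_beta=se_b,
        sigma2_a=s2a,
        wald_beta=wald_beta,
        env_effects=pd.Series(
            alpha_star + beta_star * zv, index=env_ids, name=f"effect_{label}"
        ),
        deviance=float(dev),
    )
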