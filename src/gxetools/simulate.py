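"""Synthetic multi-environment trial generator.

Simulates a biparental cross (F2, backcross, RIL or DH) on a multi-
chromosome genetic map as a Markov chain of genotypes along each
chromosome (no crossover interference, consistent with the Haldane map
function used by the HMM), degrades marker scores to dominant or missing
observations, and generates genotype-by-environment phenotype tables
under the mixed-model structure

    y_ij = mu + E_j + sum_q X_add,iq * alpha_jq + sum_q X_dom,iq * delta_jq
           + G_i + eps_ij

with genotypic main effects G_i ~ N(0, sigma2_G) and residual vectors
eps_i drawn from a specified per-environment covariance (scalar, diagonal
or full matrix).  QTL effects can be given per environment directly or as
a linear law alpha_j = alpha + beta * Z_j in an environmental covariate,
which makes crossover (sign-flipping) interaction patterns easy to set up.

A single master seed drives independent sub-streams for the cross, the
marker degradation and the phenotypes, so each stage is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    GeneticMap,
    GxETable,
    MarkerMatrix,
    PopulationType,
    ValidationError,
)
from .predictors import recomb_fraction, transition_matrix

__all__ = [
    "QTL",
    "ChromosomeSpec",
    "SimulationSpec",
    "build_map",
    "simulate_cross",
    "degrade_markers",
    "simulate_phenotypes",
    "simulate_dataset",
    "maize_stress_spec",
]


@dataclass
class QTL:
    """A simulated QTL: position plus per-environment effects.

    ``additive`` is either a length-J array of environment-specific
    allele-substitution effects alpha_j, or a tuple ``(alpha, beta,
    covariate_values)`` generating alpha_j = alpha + beta * Z_j.
    ``dominance`` (optional) is a length-J array of dominance deviations.
    """

    chromosome: str
    position_cM: float
    additive: object
    dominance: object = None

    def additive_effects(self, n_env: int) -> np.ndarray:
        if isinstance(self.additive, tuple):
            alpha, beta, z = self.additive
            z = np.asarray(z, dtype=float)
            if len(z) != n_env:
                raise ValidationError("covariate length does not match J")
            return alpha + beta * z
        arr = np.asarray(self.additive, dtype=float)
        if arr.ndim == 0:
            return np.full(n_env, float(arr))
        if len(arr) != n_env:
            raise ValidationError("additive effect vector length must be J")
        return arr

    def dominance_effects(self, n_env: int) -> np.ndarray:
        if self.dominance is None:
            return np.zeros(n_env)
        arr = np.asarray(self.dominance, dtype=float)
        if arr.ndim == 0:
            return np.full(n_env, float(arr))
        if len(arr) != n_env:
            raise ValidationError("dominance effect vector length must be J")
        return arr


@dataclass
class ChromosomeSpec:
    """Markers on one chromosome: equally spaced by default, or at
    explicit (non-decreasing) positions."""

    name: str
    length_cM: float
    n_markers: int
    positions: object = None

    def marker_positions(self) -> np.ndarray:
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            if np.any(np.diff(pos) < 0):
                raise ValidationError("marker positions must be non-decreasing")
            return pos
        if self.n_markers < 1:
            raise ValidationError("need at least one marker per chromosome")
        if self.length_cM == 0 and self.n_markers > 1:
            raise ValidationError(
                f"chromosome {self.name}: zero length with several markers"
            )
        if self.n_markers == 1:
            return np.array([0.0])
        return np.linspace(0.0, self.length_cM, self.n_markers)


@dataclass
class SimulationSpec:
    """Full description of a simulated multi-environment QTL experiment."""

    population_type: PopulationType = PopulationType.F2
    n_individuals: int = 200
    chromosomes: list = field(
        default_factory=lambda: [ChromosomeSpec(f"C{i + 1}", 100.0, 11) for i in range(3)]
    )
    qtls: list = field(default_factory=list)
    env_ids: list = field(default_factory=lambda: [f"E{j + 1}" for j in range(8)])
    mu: float = 2.0
    env_effects: object = None  # length-J array; default linear spread
    sigma2_G: float = 0.3
    residual: object = 0.55  # scalar, length-J diagonal, or J x J matrix
    missing_rate: float = 0.0
    dominant_rate: float = 0.0
    map_function: str = "haldane"
    seed: int = 0

    def __post_init__(self) -> None:
        self.population_type = PopulationType(self.population_type)
        if not 0 <= self.missing_rate <= 1 or not 0 <= self.dominant_rate <= 1:
            raise ValidationError("rates must be in [0, 1]")
        if self.sigma2_G < 0:
            raise ValidationError("sigma2_G must be non-negative")

    @property
    def n_env(self) -> int:
        return len(self.env_ids)

    def env_effect_vector(self) -> np.ndarray:
        if self.env_effects is None:
            j = self.n_env
            return np.linspace(-1.0, 1.0, j) if j > 1 else np.zeros(1)
        arr = np.asarray(self.env_effects, dtype=float)
        if len(arr) != self.n_env:
            raise ValidationError("env_effects length must be J")
        return arr

    def residual_covariance(self) -> np.ndarray:
        j = self.n_env
        r = np.asarray(self.residual, dtype=float)
        if r.ndim == 0:
            cov = float(r) * np.eye(j)
        elif r.ndim == 1:
            if len(r) != j:
                raise ValidationError("residual variance vector length must be J")
            cov = np.diag(r)
        else:
            if r.shape != (j, j):
                raise ValidationError("residual covariance must be J x J")
            cov = (r + r.T) / 2
        vals = np.linalg.eigvalsh(cov)
        if vals.min() < -1e-10:
            raise ValidationError("residual covariance is not PSD")
        return cov

    def rngs(self):
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(3)
        return tuple(np.random.default_rng(k) for k in kids)


def build_map(spec: SimulationSpec) -> GeneticMap:
    """Genetic map implied by the chromosome specs (markers M<chrom>_<k>)."""
    rows = []
    for chrom in spec.chromosomes:
        for k, pos in enumerate(chrom.marker_positions()):
            rows.append((f"M{chrom.name}_{k + 1}", chrom.name, float(pos)))
    return GeneticMap(
        pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"])
    )


_CODE_OF_COUNT = {0: "A", 1: "H", 2: "B"}


def _simulate_chain(
    rng: np.random.Generator,
    positions: np.ndarray,
    n_ind: int,
    poptype: PopulationType,
    map_function: str,
) -> np.ndarray:
    """Paternal-allele counts (n_ind x n_loci) along one chromosome."""
    from .predictors import _INIT, _STATES  # state conventions shared with the HMM

    states = _STATES[poptype]
    init = _INIT[poptype]
    n_loci = len(positions)
    idx = np.zeros((n_ind, n_loci), dtype=int)
    idx[:, 0] = rng.choice(len(states), size=n_ind, p=init)
    for k in range(1, n_loci):
        r = recomb_fraction(positions[k] - positions[k - 1], map_function)
        t = transition_matrix(r, poptype)
        u = rng.random(n_ind)
        cum = np.cumsum(t[idx[:, k - 1]], axis=1)
        idx[:, k] = (u[:, None] > cum).sum(axis=1)
    return states[idx]


def simulate_cross(spec: SimulationSpec):
    """Simulate marker genotypes and true QTL genotypes for a cross.

    Returns ``(MarkerMatrix, truth)`` where ``truth`` is a DataFrame of
    paternal-allele counts at the QTL positions (columns ``q1, q2, ...``),
    for use as an oracle in downstream tests.  The marker matrix is fully
    observed and codominant; apply :func:`degrade_markers` for realism.
    """
    rng, _, _ = spec.rngs()
    gmap = build_map(spec)
    ids = [f"G{i + 1:03d}" for i in range(spec.n_individuals)]
    marker_cols: dict = {}
    truth_cols: dict = {}
    for chrom in spec.chromosomes:
        mpos = chrom.marker_positions()
        qtls = [
            (qi, q) for qi, q in enumerate(spec.qtls) if q.chromosome == chrom.name
        ]
        qpos = np.array([q.position_cM for _, q in qtls])
        allpos = np.unique(np.concatenate([mpos, qpos])) if len(qtls) else mpos
        counts = _simulate_chain(
            rng, allpos, spec.n_individuals, spec.population_type, spec.map_function
        )
        pos_index = {p: k for k, p in enumerate(allpos)}
        for k, p in enumerate(mpos):
            marker_cols[f"M{chrom.name}_{k + 1}"] = counts[:, pos_index[p]]
        for qi, q in qtls:
            truth_cols[f"q{qi + 1}"] = counts[:, pos_index[q.position_cM]]
    codes = pd.DataFrame(
        {m: [_CODE_OF_COUNT[c] for c in col] for m, col in marker_cols.items()},
        index=ids,
    )[gmap.markers]
    truth = pd.DataFrame(
        {k: truth_cols[k] for k in sorted(truth_cols, key=lambda s: int(s[1:]))},
        index=ids,
        dtype=float,
    )
    markers = MarkerMatrix(codes, spec.population_type)
    return markers, truth


def degrade_markers(
    markers: MarkerMatrix,
    missing_rate: float,
    dominant_rate: float,
    seed=None,
    rng: np.random.Generator | None = None,
) -> MarkerMatrix:
    """Degrade codominant scores to missing or dominant observations.

    Each score independently becomes missing with ``missing_rate``, else
    is collapsed with ``dominant_rate`` to ``C`` (not-A) or ``D`` (not-B)
    with equal probability, where compatible with the true score.
    """
    if not (0 <= missing_rate <= 1 and 0 <= dominant_rate <= 1):
        raise ValidationError("rates must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = markers.scores.to_numpy().copy()
    u = rng.random(arr.shape)
    direction = rng.random(arr.shape) < 0.5
    miss = u < missing_rate
    dom = (~miss) & (u < missing_rate + (1 - missing_rate) * dominant_rate)
    arr[miss] = "-"
    # collapse: direction True hides the A-side (score becomes not-A when
    # compatible), False hides the B-side
    to_c = dom & direction & np.isin(arr, ["H", "B"])
    to_d = dom & ~direction & np.isin(arr, ["A", "H"])
    if markers.population_type == PopulationType.BC:
        # B cannot occur in a backcross, so "not-A" is uninformative and
        # not a legal code; only the not-B collapse applies.
        to_c &= False
    arr[to_c] = "C"
    arr[to_d] = "D"
    out = pd.DataFrame(arr, index=markers.scores.index, columns=markers.scores.columns)
    return MarkerMatrix(out, markers.population_type)


def simulate_phenotypes(truth: pd.DataFrame, spec: SimulationSpec) -> GxETable:
    """Phenotype table from true QTL genotypes under the mixed model.

    ``truth`` holds paternal-allele counts per QTL (as returned by
    :func:`simulate_cross`); X_add is the count itself and X_dom the
    heterozygosity indicator.
    """
    _, _, rng = spec.rngs()
    n, j = spec.n_individuals, spec.n_env
    if len(truth) != n:
        raise ValidationError("truth matrix does not match n_individuals")
    y = np.full((n, j), spec.mu) + spec.env_effect_vector()[None, :]
    for qi, q in enumerate(spec.qtls):
        x = truth[f"q{qi + 1}"].to_numpy(float)
        y += np.outer(x, q.additive_effects(j))
        y += np.outer((x == 1).astype(float), q.dominance_effects(j))
    g = rng.normal(0.0, np.sqrt(spec.sigma2_G), size=n)
    y += g[:, None]
    cov = spec.residual_covariance()
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(j))
    y += rng.standard_normal((n, j)) @ chol.T
    return GxETable(pd.DataFrame(y, index=truth.index, columns=spec.env_ids))


def simulate_dataset(spec: SimulationSpec):
    """Convenience wrapper: map, (possibly degraded) markers, phenotypes
    and the truth record, from one seed."""
    markers, truth = simulate_cross(spec)
    if spec.missing_rate > 0 or spec.dominant_rate > 0:
        _, rng_deg, _ = spec.rngs()
        markers = degrade_markers(
            markers, spec.missing_rate, spec.dominant_rate, rng=rng_deg
        )
    table = simulate_phenotypes(truth, spec)
    return build_map(spec), markers, table, truth


def maize_stress_spec(seed: int = 0) -> SimulationSpec:
    """A preset that mimics the scale of a published maize drought-stress
    experiment: 211 F2-derived families, 10 chromosomes with 132 markers,
    8 environments, a large crossover QTL plus a constant-effect QTL, and
    environment-heterogeneous residual variance.  For demonstrations
    only; the numbers are realistic magnitudes, not a reconstruction of
    any real data set.
    """
    n_markers = [14, 14, 14, 13, 13, 13, 13, 13, 13, 12]  # 132 total
    chroms = [
        ChromosomeSpec(f"C{i + 1}", 160.0, n_markers[i]) for i in range(10)
    ]
    env_ids = ["SS92a", "IS92a", "NS92a", "IS94a", "SS94a", "LN96a", "LN96b", "HN96b"]
    qtls = [
        QTL("C1", 141.0, np.array([0.47, 0.35, 0.37, 0.37, 0.21, -0.005, -0.002, -0.23])),
        QTL("C10", 67.0, np.array([0.06, 0.32, 0.26, 0.25, 0.32, 0.07, 0.05, 0.56])),
        QTL("C3", 155.0, np.full(8, -0.13)),
    ]
    resid = np.array([0.55, 0.69, 1.40, 0.67, 0.70, 0.14, 0.15, 0.76])
    return SimulationSpec(
        population_type=PopulationType.F2,
        n_individuals=211,
        chromosomes=chroms,
        qtls=qtls,
        env_ids=env_ids,
        mu=4.0,
        env_effects=np.array([-1.2, -0.3, 1.8, -0.5, -0.9, -1.6, -1.4, 1.5]),
        sigma2_G=0.125,
        residual=resid,
        missing_rate=0.05,
        dominant_rate=0.05,
        seed=seed,
    )
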