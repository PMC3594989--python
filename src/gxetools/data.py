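"""Data containers and file I/O for multi-environment trial analysis.

The central object is the :class:`GxETable`, a genotype-by-environment
table of adjusted means (one cell per genotype/environment combination,
typically produced by a first-stage per-trial analysis).  Companion
containers hold environmental covariates, a genetic map, and a marker
score matrix for a biparental mapping population.

All tables read and write plain CSV so that results can be inspected and
re-used outside Python.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GxETable",
    "EnvCovariates",
    "GeneticMap",
    "MarkerMatrix",
    "PopulationType",
    "MARKER_CODES",
    "load_gxe_table",
    "save_gxe_table",
    "load_env_covariates",
    "save_env_covariates",
    "load_genetic_map",
    "save_genetic_map",
    "load_marker_matrix",
    "save_marker_matrix",
    "two_way_center",
    "environment_index",
    "impute_low_rank",
]


class PopulationType(str, enum.Enum):
    """Biparental population types supported by the genetic machinery."""

    F2 = "F2"
    BC = "BC"
    RIL = "RIL"
    DH = "DH"


#: Marker score codes.  ``A`` = maternal homozygote (m1m1, zero paternal
#: alleles), ``H`` = heterozygote (M1m1), ``B`` = paternal homozygote
#: (M1M1, two paternal alleles), ``C`` = dominant "not-A" (H or B),
#: ``D`` = dominant "not-B" (A or H), ``-`` = missing.
MARKER_CODES = ("A", "H", "B", "C", "D", "-")

# Codes that are impossible given the population type.  RIL and DH lines
# are fully inbred, so heterozygotes cannot occur; a backcross to the
# maternal parent cannot produce paternal homozygotes.
_ILLEGAL_CODES = {
    PopulationType.F2: set(),
    PopulationType.BC: {"B", "C"},
    PopulationType.RIL: {"H"},
    PopulationType.DH: {"H"},
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(labels: Sequence, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} labels: {dup}")


@dataclass
class GxETable:
    """Genotype x environment table of adjusted means.

    Parameters
    ----------
    means
        DataFrame with genotypes in rows and environments in columns.
        ``NaN`` cells are treated as missing.
    weights
        Optional DataFrame of strictly positive per-cell weights (same
        shape as ``means``); defaults to all ones.
    """

    means: pd.DataFrame
    weights: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.means = pd.DataFrame(self.means).astype(float)
        if self.n_genotypes < 2 or self.n_environments < 2:
            raise ValidationError(
                "a GxE table needs at least 2 genotypes and 2 environments"
            )
        _check_unique(self.means.index, "genotype")
        _check_unique(self.means.columns, "environment")
        if self.weights is not None:
            self.weights = pd.DataFrame(self.weights).astype(float)
            if self.weights.shape != self.means.shape:
                raise ValidationError("weights shape does not match means")
            self.weights = self.weights.set_axis(self.means.index, axis=0)
            self.weights = self.weights.set_axis(self.means.columns, axis=1)
            bad = (self.weights.to_numpy() <= 0) & ~self.missing_mask.to_numpy()
            if bad.any():
                raise ValidationError("weights must be strictly positive")

    # -- basic geometry ------------------------------------------------
    @property
    def genotypes(self) -> list:
        return list(self.means.index)

    @property
    def environments(self) -> list:
        return list(self.means.columns)

    @property
    def n_genotypes(self) -> int:
        return self.means.shape[0]

    @property
    def n_environments(self) -> int:
        return self.means.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.means.isna()

    @property
    def is_complete(self) -> bool:
        return not bool(self.means.isna().to_numpy().any())

    def values(self) -> np.ndarray:
        return self.means.to_numpy()

    def require_complete(self, context: str = "this operation") -> None:
        if not self.is_complete:
            n = int(self.means.isna().to_numpy().sum())
            raise ValidationError(
                f"{context} requires a complete table but {n} cells are "
                "missing; impute first (see impute_low_rank)"
            )


@dataclass
class EnvCovariates:
    """Environmental covariate table, environments in rows."""

    values: pd.DataFrame
    centered: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        _check_unique(self.values.index, "environment")
        _check_unique(self.values.columns, "covariate")
        for name in self.values.columns:
            self.centered.setdefault(
                name, bool(abs(self.values[name].sum()) < 1e-9)
            )

    @property
    def environments(self) -> list:
        return list(self.values.index)

    @property
    def names(self) -> list:
        return list(self.values.columns)

    def center(self, names: Iterable | None = None) -> "EnvCovariates":
        """Return a copy with the selected columns centered to zero mean."""
        out = self.values.copy()
        for name in names if names is not None else out.columns:
            out[name] = out[name] - out[name].mean()
        cov = EnvCovariates(out)
        for name in out.columns:
            cov.centered[name] = True if (names is None or name in set(names)) else self.centered[name]
        return cov

    def aligned_to(self, table: GxETable) -> pd.DataFrame:
        missing = set(table.environments) - set(self.environments)
        if missing:
            raise ValidationError(
                f"covariate table lacks environments {sorted(missing)}"
            )
        return self.values.loc[table.environments]


@dataclass
class GeneticMap:
    """Ordered marker map: name, chromosome, position in centimorgan."""

    table: pd.DataFrame  # columns: marker, chromosome, position_cM

    def __post_init__(self) -> None:
        required = ["marker", "chromosome", "position_cM"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"genetic map lacks columns {missing}")
        self.table = self.table[required].copy()
        self.table["marker"] = self.table["marker"].astype(str)
        self.table["chromosome"] = self.table["chromosome"].astype(str)
        self.table["position_cM"] = self.table["position_cM"].astype(float)
        _check_unique(self.table["marker"], "marker")
        for chrom, sub in self.table.groupby("chromosome", sort=False):
            pos = sub["position_cM"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValidationError(
                    f"marker positions on chromosome {chrom} are not "
                    "non-decreasing"
                )

    @property
    def markers(self) -> list:
        return list(self.table["marker"])

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chromosome"]))

    def chromosome(self, chrom) -> pd.DataFrame:
        sub = self.table[self.table["chromosome"] == str(chrom)]
        if sub.empty:
            raise ValidationError(f"no markers on chromosome {chrom!r}")
        return sub.reset_index(drop=True)

    def position_of(self, marker) -> tuple:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise ValidationError(f"marker {marker!r} not on the map")
        r = row.iloc[0]
        return (r["chromosome"], float(r["position_cM"]))


@dataclass
class MarkerMatrix:
    """Coded marker observations, individuals in rows.

    Codes are ``A`` (maternal homozygote), ``H`` (heterozygote), ``B``
    (paternal homozygote), ``C`` (not-A), ``D`` (not-B) and ``-``
    (missing).
    """

    scores: pd.DataFrame
    population_type: PopulationType

    def __post_init__(self) -> None:
        self.population_type = PopulationType(self.population_type)
        self.scores = pd.DataFrame(self.scores).astype(str)
        _check_unique(self.scores.index, "individual")
        _check_unique(self.scores.columns, "marker")
        legal = set(MARKER_CODES) - _ILLEGAL_CODES[self.population_type]
        arr = self.scores.to_numpy()
        bad = ~np.isin(arr, sorted(legal))
        if bad.any():
            i, m = np.argwhere(bad)[0]
            raise ValidationError(
                f"illegal code {arr[i, m]!r} for population type "
                f"{self.population_type.value} (individual "
                f"{self.scores.index[i]!r}, marker {self.scores.columns[m]!r})"
            )

    @property
    def individuals(self) -> list:
        return list(self.scores.index)

    @property
    def markers(self) -> list:
        return list(self.scores.columns)

    def check_against_map(self, gmap: GeneticMap) -> None:
        extra = set(self.markers) - set(gmap.markers)
        if extra:
            raise ValidationError(
                f"markers absent from the map: {sorted(extra)[:5]}"
            )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_csv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, float_precision="round_trip", **kw)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"could not parse {path}: {exc}") from exc


def load_gxe_table(path, layout: str = "long") -> GxETable:
    """Read a phenotype table from CSV.

    ``long`` layout expects columns ``genotype, environment, mean`` and
    optionally ``weight``; ``wide`` layout expects genotypes in rows
    (first column) and environments in columns.
    """
    if layout == "long":
        df = _read_csv(path)
        required = ["genotype", "environment", "mean"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: long layout lacks columns {missing}")
        dup = df.duplicated(subset=["genotype", "environment"])
        if dup.any():
            line = int(df.index[dup][0]) + 2  # header + 1-based
            raise ValidationError(
                f"{path}: duplicate (genotype, environment) cell at line {line}"
            )
        means = df.pivot(index="genotype", columns="environment", values="mean")
        # keep the file's first-appearance ordering
        means = means.reindex(
            index=list(dict.fromkeys(df["genotype"])),
            columns=list(dict.fromkeys(df["environment"])),
        )
        weights = None
        if "weight" in df.columns:
            weights = df.pivot(
                index="genotype", columns="environment", values="weight"
            ).reindex(index=means.index, columns=means.columns)
        return GxETable(means, weights)
    if layout == "wide":
        df = _read_csv(path, index_col=0)
        return GxETable(df)
    raise ValueError(f"unknown layout {layout!r}")


def save_gxe_table(table: GxETable, path, layout: str = "long") -> None:
    path = Path(path)
    if layout == "long":
        long = table.means.stack(future_stack=True).rename("mean").reset_index()
        long.columns = ["genotype", "environment", "mean"]
        if table.weights is not None:
            w = table.weights.stack(future_stack=True).rename("weight").reset_index()
            long["weight"] = w["weight"]
        long = long.dropna(subset=["mean"])
        long.to_csv(path, index=False)
    elif layout == "wide":
        table.means.rename_axis("genotype").to_csv(path)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def load_env_covariates(path) -> EnvCovariates:
    return EnvCovariates(_read_csv(path, index_col=0))


def save_env_covariates(covs: EnvCovariates, path) -> None:
    covs.values.rename_axis("environment").to_csv(path)


def load_genetic_map(path) -> GeneticMap:
    return GeneticMap(_read_csv(path))


def save_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, index=False)


def load_marker_matrix(path, population_type) -> MarkerMatrix:
    df = _read_csv(path, index_col=0, dtype=str)
    return MarkerMatrix(df, PopulationType(population_type))


def save_marker_matrix(markers: MarkerMatrix, path) -> None:
    markers.scores.rename_axis("individual").to_csv(path)


# ---------------------------------------------------------------------------
# Two-way utilities
# ---------------------------------------------------------------------------

def two_way_center(table: GxETable) -> pd.DataFrame:
    """Residual interaction matrix after removing both main effects.

    Returns ``mu_ij - rowmean_i - colmean_j + grandmean``; every row and
    column of the result sums to zero.  Requires a complete table.
    """
    table.require_complete("two-way centering")
    y = table.values()
    out = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    return pd.DataFrame(out, index=table.means.index, columns=table.means.columns)


def environment_index(table: GxETable) -> pd.Series:
    """Environmental quality index: column mean minus grand mean.

    This is the estimate of the environmental main effect used as the
    regressor in the Finlay-Wilkinson regression; it sums to zero on a
    balanced table.
    """
    table.require_complete("the environment index")
    y = table.values()
    return pd.Series(
        y.mean(axis=0) - y.mean(), index=table.means.columns, name="env_index"
    )


def impute_low_rank(
    table: GxETable, k: int = 2, tol: float = 1e-8, max_iter: int = 500
) -> GxETable:
    """EM-style imputation of missing cells by low-rank reconstruction.

    Missing cells are initialised from the additive (main-effects) fit
    and then iteratively replaced by the rank-``k`` SVD reconstruction of
    the interaction until the filled values change by less than ``tol``
    (relative).
    """
    y = table.values().copy()
    miss = np.isnan(y)
    if not miss.any():
        return table
    # additive start: row/col means on observed cells
    grand = np.nanmean(y)
    row = np.where(np.isnan(np.nanmean(y, axis=1)), grand, np.nanmean(y, axis=1))
    col = np.where(np.isnan(np.nanmean(y, axis=0)), grand, np.nanmean(y, axis=0))
    y[miss] = (row[:, None] + col[None, :] - grand)[miss]
    for _ in range(max_iter):
        rmean = y.mean(axis=1, keepdims=True)
        cmean = y.mean(axis=0, keepdims=True)
        g = y.mean()
        resid = y - rmean - cmean + g
        u, s, vt = np.linalg.svd(resid, full_matrices=False)
        recon = (u[:, :k] * s[:k]) @ vt[:k]
        filled = (rmean + cmean - g + recon)[miss]
        delta = np.max(np.abs(filled - y[miss])) / max(1.0, np.max(np.abs(y)))
        y[miss] = filled
        if delta < tol:
            break
    out = pd.DataFrame(y, index=table.means.index, columns=table.means.columns)
    return GxETable(out, table.weights)
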