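"""Conditional genotype probabilities and genetic predictors.

Marker observations on a biparental population are incomplete: dominant
scores, missing values, and evaluation positions between markers all
leave the underlying genotype uncertain.  A hidden Markov model along
each chromosome (hidden states = genotypes at a locus, transitions from
the recombination fraction between loci, emissions from the observed
marker codes) yields, for every individual and genome position, the
conditional probabilities of being M1M1, M1m1 or m1m1 given all markers
on the chromosome.

The probabilities are turned into genetic predictors: the additive
predictor is the expected number of paternal (M1) alleles,

    X_add = 2 * P(M1M1 | markers) + 1 * P(M1m1 | markers)

and the dominance predictor is the heterozygosity probability,

    X_dom = P(M1m1 | markers).

Population types: F2 (three states, transition = tensor product of two
independent meioses), backcross to the maternal parent and doubled
haploids (two-state chains in r), and RILs by selfing (two-state chain in
the fixed-line recombination R = 2r / (1 + 2r)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GeneticMap, MarkerMatrix, PopulationType, ValidationError

__all__ = [
    "PredictorSet",
    "recomb_fraction",
    "conditional_probs",
    "make_grid",
    "genetic_predictors",
]

# hidden states indexed by number of paternal alleles: 0 = m1m1 (A),
# 1 = M1m1 (H), 2 = M1M1 (B)
_STATES = {
    PopulationType.F2: np.array([0, 1, 2]),
    PopulationType.BC: np.array([0, 1]),
    PopulationType.DH: np.array([0, 2]),
    PopulationType.RIL: np.array([0, 2]),
}

_INIT = {
    PopulationType.F2: np.array([0.25, 0.5, 0.25]),
    PopulationType.BC: np.array([0.5, 0.5]),
    PopulationType.DH: np.array([0.5, 0.5]),
    PopulationType.RIL: np.array([0.5, 0.5]),
}

# emission support per marker code over paternal-allele counts {0, 1, 2}
_CODE_SUPPORT = {
    "A": {0},
    "H": {1},
    "B": {2},
    "C": {1, 2},  # not-A
    "D": {0, 1},  # not-B
    "-": {0, 1, 2},
}


def recomb_fraction(d, map_function: str = "haldane"):
    """Recombination fraction for a map distance in centimorgan.

    Haldane (no interference): r = (1 - exp(-2d/100)) / 2.
    Kosambi: r = tanh(2d/100) / 2.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("map distance must be non-negative")
    m = 2.0 * d / 100.0
    if map_function == "haldane":
        r = (1.0 - np.exp(-m)) / 2.0
    elif map_function == "kosambi":
        r = np.tanh(m) / 2.0
    else:
        raise ValueError(f"unknown map function {map_function!r}")
    return r if r.ndim else float(r)


def transition_matrix(r: float, poptype: PopulationType) -> np.ndarray:
    """One-step transition matrix between hidden genotype states."""
    poptype = PopulationType(poptype)
    if poptype == PopulationType.F2:
        s = 1.0 - r
        return np.array(
            [
                [s * s, 2 * r * s, r * r],
                [r * s, s * s + r * r, r * s],
                [r * r, 2 * r * s, s * s],
            ]
        )
    if poptype == PopulationType.RIL:
        rr = 2.0 * r / (1.0 + 2.0 * r)
        return np.array([[1 - rr, rr], [rr, 1 - rr]])
    # BC and DH: a single meiosis
    return np.array([[1 - r, r], [r, 1 - r]])


def _emissions(codes: np.ndarray, states: np.ndarray) -> np.ndarray:
    """n_ind x n_states indicator emissions for one marker column."""
    out = np.zeros((len(codes), len(states)))
    for code in np.unique(codes):
        support = _CODE_SUPPORT[code]
        mask = codes == code
        for s_idx, s in enumerate(states):
            if int(s) in support:
                out[mask, s_idx] = 1.0
    return out


@dataclass
class _ChromosomeHMM:
    """Scaled forward-backward quantities for one chromosome."""

    positions: np.ndarray  # marker positions, cM
    forward: list  # per marker: n_ind x S, scaled filtering P(state | y_1..k)
    backward: list  # per marker: n_ind x S, scaled P(y_k+1.. | state)
    states: np.ndarray
    poptype: PopulationType
    map_function: str


def _normalize(p: np.ndarray) -> np.ndarray:
    tot = p.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValidationError(
            "marker observations are inconsistent (zero-probability path)"
        )
    return p / tot


def _run_hmm(
    codes: np.ndarray,
    positions: np.ndarray,
    poptype: PopulationType,
    map_function: str,
) -> _ChromosomeHMM:
    """Scaled forward-backward over the ordered markers of a chromosome.

    ``forward[k]`` is proportional to P(state_k, y_1..k); ``backward[k]``
    is proportional to P(y_{k+1}..n | state_k) (emission at k excluded).
    Scaling per locus keeps everything in range for long chromosomes.
    """
    states = _STATES[poptype]
    n_loci = len(positions)
    emis = [_emissions(codes[:, k], states) for k in range(n_loci)]
    trans = [
        transition_matrix(
            recomb_fraction(positions[k + 1] - positions[k], map_function), poptype
        )
        for k in range(n_loci - 1)
    ]
    fwd = []
    f = _INIT[poptype][None, :] * emis[0]
    fwd.append(_normalize(f))
    for k in range(1, n_loci):
        f = (fwd[-1] @ trans[k - 1]) * emis[k]
        fwd.append(_normalize(f))
    bwd = [None] * n_loci
    b = np.ones((codes.shape[0], len(states)))
    bwd[-1] = b
    for k in range(n_loci - 2, -1, -1):
        b = (bwd[k + 1] * emis[k + 1]) @ trans[k].T
        tot = b.sum(axis=1, keepdims=True)
        bwd[k] = b / np.maximum(tot, 1e-300)
    hmm = _ChromosomeHMM(
        positions=positions, forward=fwd, backward=bwd, states=states,
        poptype=poptype, map_function=map_function,
    )
    hmm._emission_cache = emis
    return hmm


def _triple(prob: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Expand posterior over the population's states to the
    (P(M1M1), P(M1m1), P(m1m1)) triple."""
    out = np.zeros((prob.shape[0], 3))
    for s_idx, s in enumerate(states):
        col = {2: 0, 1: 1, 0: 2}[int(s)]
        out[:, col] += prob[:, s_idx]
    return out


def _chromosome_data(markers: MarkerMatrix, gmap: GeneticMap, chrom):
    sub = gmap.chromosome(chrom)
    names = [m for m in sub["marker"] if m in set(markers.markers)]
    if not names:
        raise ValidationError(f"no scored markers on chromosome {chrom!r}")
    pos = sub.set_index("marker").loc[names, "position_cM"].to_numpy(float)
    codes = markers.scores[names].to_numpy()
    return codes, pos


def conditional_probs(
    markers: MarkerMatrix,
    gmap: GeneticMap,
    position: tuple,
    map_function: str = "haldane",
) -> np.ndarray:
    """Per-individual (P(M1M1), P(M1m1), P(m1m1)) at one genome position.

    ``position`` is a (chromosome, cM) pair on a mapped chromosome.
    """
    chrom, pos = position
    codes, mpos = _chromosome_data(markers, gmap, chrom)
    hmm = _run_hmm(codes, mpos, markers.population_type, map_function)
    return _triple(_posterior_at(hmm, float(pos)), hmm.states)


def _posterior_at(hmm: _ChromosomeHMM, pos: float) -> np.ndarray:
    p = hmm.positions
    init = _INIT[hmm.poptype][None, :]
    if pos <= p[0]:
        if pos == p[0]:
            return _normalize(hmm.forward[0] * hmm.backward[0])
        t = transition_matrix(
            recomb_fraction(p[0] - pos, hmm.map_function), hmm.poptype
        )
        # P(state at pos) prop to init * P(all marker data | state at pos)
        down = (hmm.backward[0] * hmm._emission_cache[0]) @ t.T
        return _normalize(init * down)
    if pos >= p[-1]:
        if pos == p[-1]:
            return _normalize(hmm.forward[-1] * hmm.backward[-1])
        t = transition_matrix(
            recomb_fraction(pos - p[-1], hmm.map_function), hmm.poptype
        )
        return _normalize(hmm.forward[-1] @ t)
    k = int(np.searchsorted(p, pos, side="right")) - 1
    if pos == p[k]:
        return _normalize(hmm.forward[k] * hmm.backward[k])
    t_left = transition_matrix(
        recomb_fraction(pos - p[k], hmm.map_function), hmm.poptype
    )
    t_right = transition_matrix(
        recomb_fraction(p[k + 1] - pos, hmm.map_function), hmm.poptype
    )
    left = hmm.forward[k] @ t_left
    right = (hmm.backward[k + 1] * hmm._emission_cache[k + 1]) @ t_right.T
    return _normalize(left * right)


def make_grid(
    gmap: GeneticMap, step: float, include_markers: bool = True
) -> list:
    """Evaluation grid: per chromosome, equally spaced points every
    ``step`` cM from the first to the last marker, optionally merged with
    the marker positions themselves (deduplicated within 1e-6 cM)."""
    if step <= 0:
        raise ValidationError("grid step must be positive")
    if gmap.table.empty:
        raise ValidationError("empty genetic map")
    grid = []
    for chrom in gmap.chromosomes:
        sub = gmap.chromosome(chrom)
        lo = float(sub["position_cM"].min())
        hi = float(sub["position_cM"].max())
        pts = list(np.arange(lo, hi + 1e-9, step))
        if pts[-1] < hi - 1e-9:
            pts.append(hi)
        if include_markers:
            pts.extend(float(x) for x in sub["position_cM"])
        pts = sorted(pts)
        dedup = []
        for x in pts:
            if not dedup or x - dedup[-1] > 1e-6:
                dedup.append(x)
        grid.extend((chrom, x) for x in dedup)
    return grid


@dataclass
class PredictorSet:
    """Conditional genotype probabilities and genetic predictors on a grid.

    ``x_add`` has entries in [0, 2] (expected paternal allele count) and
    ``x_dom`` in [0, 1] (heterozygosity probability; identically zero for
    DH and RIL populations).
    """

    positions: list  # [(chromosome, cM), ...]
    probs: np.ndarray  # n_ind x n_pos x 3 triples (M1M1, M1m1, m1m1)
    x_add: pd.DataFrame  # n_ind x n_pos
    x_dom: pd.DataFrame  # n_ind x n_pos
    population_type: PopulationType

    @property
    def individuals(self) -> list:
        return list(self.x_add.index)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def position_labels(self) -> list:
        return [f"{c}@{p:g}" for c, p in self.positions]

    def column(self, position: tuple) -> np.ndarray:
        try:
            idx = self.positions.index((position[0], float(position[1])))
        except ValueError as exc:
            raise ValidationError(f"position {position} not on the grid") from exc
        return self.x_add.to_numpy()[:, idx]

    def to_csv(self, prefix) -> None:
        """Write positions, additive and dominance predictors as CSVs."""
        pd.DataFrame(self.positions, columns=["chromosome", "position_cM"]).to_csv(
            f"{prefix}_positions.csv", index=False
        )
        self.x_add.to_csv(f"{prefix}_xadd.csv")
        self.x_dom.to_csv(f"{prefix}_xdom.csv")


def genetic_predictors(
    markers: MarkerMatrix,
    gmap: GeneticMap,
    grid: list,
    map_function: str = "haldane",
) -> PredictorSet:
    """Genetic predictors at every grid position.

    Runs the chromosome HMMs once and evaluates the posterior genotype
    triples at each requested position, then applies the linear maps to
    additive and dominance predictors.
    """
    markers.check_against_map(gmap)
    n_ind = len(markers.individuals)
    by_chrom: dict = {}
    for chrom, pos in grid:
        by_chrom.setdefault(chrom, []).append(float(pos))
    probs = np.zeros((n_ind, len(grid), 3))
    col = {}
    for idx, (chrom, pos) in enumerate(grid):
        col[(chrom, float(pos))] = idx
    for chrom, positions in by_chrom.items():
        codes, mpos = _chromosome_data(markers, gmap, chrom)
        hmm = _run_hmm(codes, mpos, markers.population_type, map_function)
        for pos in positions:
            probs[:, col[(chrom, pos)], :] = _triple(
                _posterior_at(hmm, pos), hmm.states
            )
    x_add = 2.0 * probs[:, :, 0] + probs[:, :, 1]
    x_dom = probs[:, :, 1].copy()
    labels = [f"{c}@{p:g}" for c, p in grid]
    idx = markers.scores.index
    return PredictorSet(
        positions=[(c, float(p)) for c, p in grid],
        probs=probs,
        x_add=pd.DataFrame(x_add, index=idx, columns=labels),
        x_dom=pd.DataFrame(x_dom, index=idx, columns=labels),
        population_type=markers.population_type,
    )
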