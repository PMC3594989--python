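import numpy as np
import pandas as pd
import pytest

from gxetools import ChromosomeSpec, GxETable, QTL, SimulationSpec


@pytest.fixture
def random_table():
    """Factory for complete random I x J mean tables."""

    def make(i=12, j=5, seed=0, scale=1.0, loc=3.0):
        rng = np.random.default_rng(seed)
        y = rng.normal(loc, scale, (i, j))
        return GxETable(
            pd.DataFrame(
                y,
                index=[f"G{k + 1:03d}" for k in range(i)],
                columns=[f"E{k + 1}" for k in range(j)],
            )
        )

    return make


@pytest.fixture
def additive_table():
    """Exactly additive table: mu + G_i + E_j, no interaction."""
    gi = np.array([-1.0, 0.5, 0.5, 2.0, -2.0])
    ej = np.array([0.0, -1.0, 1.0, 0.0])
    y = 5.0 + gi[:, None] + ej[None, :]
    return GxETable(
        pd.DataFrame(
            y, index=[f"G{k}" for k in range(5)], columns=[f"E{k}" for k in range(4)]
        )
    )


@pytest.fixture
def small_cross_spec():
    """A small, fast F2 simulation: 3 chromosomes, one crossover QTL."""

    def make(seed=0, n=200, qtls=None, **kw):
        if qtls is None:
            qtls = [QTL("C1", 50.0, np.array([0.4] * 5 + [-0.3] * 3))]
        defaults = dict(
            population_type="F2",
            n_individuals=n,
            chromosomes=[ChromosomeSpec(f"C{c + 1}", 100.0, 11) for c in range(3)],
            qtls=qtls,
            sigma2_G=0.3,
            residual=0.55,
            seed=seed,
        )
        defaults.update(kw)
        return SimulationSpec(**defaults)

    return make
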