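import numpy as np
import pandas as pd
import pytest

from keyreg import ExpressionMatrix, PWM, PeptideCountTable, SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_expression(values, population, cell_line="", genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = [f"{population}_{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols), population, cell_line)


def make_peptides(observed, observable, population, cell_line="", proteins=None):
    observed = np.asarray(observed, dtype=int)
    proteins = proteins or [f"p{i}" for i in range(observed.shape[0])]
    cols = [f"{population}_{j + 1}" for j in range(observed.shape[1])]
    return PeptideCountTable(
        pd.DataFrame(observed, index=proteins, columns=cols),
        pd.Series(observable, index=proteins),
        population,
        cell_line,
    )


def random_pwm(rng, length=6, concentration=None):
    """A random PWM; concentrated around a random consensus when asked."""
    if concentration is None:
        probs = rng.dirichlet(np.full(4, 1.0), size=length).T
        probs = np.clip(probs, 1e-3, None)
        probs /= probs.sum(axis=0)
    else:
        probs = np.full((4, length), (1 - concentration) / 3)
        for j, b in enumerate(rng.integers(0, 4, size=length)):
            probs[b, j] = concentration
    return PWM(matrix_id=f"T{rng.integers(1e6)}", probs=probs)


@pytest.fixture(scope="session")
def small_bundle():
    """One fixed synthetic study reused by read-only tests."""
    return simulate_study(SimulationConfig(seed=7))
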