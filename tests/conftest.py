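import numpy as np
import pytest

from gdparent import (
    SimConfig,
    encode,
    run_triad_analysis,
    simulate_population,
)


@pytest.fixture
def write_table(tmp_path):
    """Write a genotype table from (id, class, tokens) rows; returns the path."""

    def _write(rows, name="pop.tsv"):
        path = tmp_path / name
        with path.open("w") as fh:
            for ind_id, key, tokens in rows:
                fh.write("\t".join([ind_id, key, *tokens]) + "\n")
        return path

    return _write


@pytest.fixture(scope="session")
def default_sim():
    """One validation-design population (62 founders + 5x3 offspring, 1000 SNPs)."""
    table, truth = simulate_population(SimConfig(seed=424242))
    return table, truth


@pytest.fixture(scope="session")
def default_gm(default_sim):
    table, _ = default_sim
    return encode(table)


@pytest.fixture(scope="session")
def default_triad_result(default_gm):
    return run_triad_analysis(default_gm, seed=99)


def random_states(rng, shape, p_missing=0.15):
    """Random genotype-state array with missing calls."""
    states = rng.integers(0, 3, size=shape).astype(np.int8)
    states[rng.random(shape) < p_missing] = -1
    return states
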