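import numpy as np
import pandas as pd
import pytest

from polycross import simulate as sim
from polycross.io_core import DosageMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    """4 individuals (2 parents, 2 progeny) x 3 markers, one missing cell."""
    data = pd.DataFrame(
        [[0.0, 2.0, 4.0], [1.0, 0.0, 2.0], [0.0, 1.0, 3.0], [1.0, np.nan, 3.0]],
        index=["P1", "P2", "ind1", "ind2"],
        columns=["m1", "m2", "m3"],
    )
    return DosageMatrix(data, ploidy=4, parent1="P1", parent2="P2")


@pytest.fixture(scope="session")
def tiny_map():
    """One chromosome, 50 cM, 40 markers — cheap meiosis for unit tests."""
    rng = np.random.default_rng(7)
    return sim.build_genetic_map(
        rng, n_chromosomes=1, length_range=(50, 50), markers_per_chrom_range=(40, 40)
    )


@pytest.fixture(scope="session")
def worked_example():
    """The 150 HP + 10 AC + 10 SP + 10 HS1 + 10 HS2 + 10 FC population at
    2,758 markers, with 5% error and 1-5% missingness (study conditions)."""
    rng = np.random.default_rng(11)
    gmap = sim.build_genetic_map(rng)
    parents = {
        p: sim.simulate_parent(gmap, sim.default_dosage_rates(4, p), 4, rng)
        for p in ("P1", "P2", "P3", "P4")
    }
    sub_map, sub_parents = sim.subsample_map(gmap, parents, 2758, rng)
    spec = sim.ScenarioSpec(
        counts={"HP": 150, "AC_P1": 10, "SP_P1": 10, "HS1": 10, "HS2": 10, "FC": 10}
    )
    matrix, truth = sim.build_population(spec, sub_map, sub_parents, rng)
    return matrix, truth


@pytest.fixture(scope="session")
def clean_population():
    """Error-free, fully observed 30-hybrid population on a small map."""
    rng = np.random.default_rng(5)
    gmap = sim.build_genetic_map(
        rng, n_chromosomes=2, length_range=(80, 100), markers_per_chrom_range=(150, 200)
    )
    parents = {
        p: sim.simulate_parent(gmap, sim.default_dosage_rates(4, p), 4, rng)
        for p in ("P1", "P2", "P3", "P4")
    }
    spec = sim.ScenarioSpec(counts={"HP": 30}, error_rate=0.0, missing_range=(0.0, 0.0))
    matrix, truth = sim.build_population(spec, gmap, parents, rng)
    return matrix, truth, gmap, parents
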