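import io

import numpy as np
import pandas as pd
import pytest

from fungal_assembly import (
    CommunityTable,
    SyntheticScenario,
    read_phylogeny,
)
from fungal_assembly.pipeline import generate_scenario, assembly_analysis

# Conditions for the end-to-end calibration / recovery experiments:
# 2 groups x 8 samples, 150 taxa, depth 2000, 199 null replicates,
# three replicate datasets per regime (fixed seeds), one fixed null seed.
SCENARIO_SEEDS = (101, 102, 103)
NULL_SEED = 7
RECOVERY_REPS = 199


def toy_tree(newick: str):
    return read_phylogeny(io.StringIO(newick))


@pytest.fixture
def three_tip_tree():
    return toy_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[1, 2], [3, 4]],
        index=["OTU_1", "OTU_2"],
        columns=["S1", "S2"],
        dtype=np.int64,
    )
    return CommunityTable(counts)


def _run_regime(regime: str):
    runs = []
    for seed in SCENARIO_SEEDS:
        scenario = SyntheticScenario(
            regime=regime,
            n_taxa=150,
            n_groups=2,
            samples_per_group=8,
            depth=2000,
            seed=seed,
        )
        table, tree, metadata, truth = generate_scenario(scenario)
        result = assembly_analysis(
            table, tree, metadata, reps=RECOVERY_REPS, seed=NULL_SEED
        )
        runs.append((result, metadata))
    return runs


@pytest.fixture(scope="session")
def selection_runs():
    return _run_regime("selection")


@pytest.fixture(scope="session")
def drift_runs():
    return _run_regime("drift")


@pytest.fixture(scope="session")
def dispersal_runs():
    return _run_regime("dispersal_limitation")


@pytest.fixture(scope="session")
def homogenizing_runs():
    return _run_regime("homogenizing_dispersal")


def between_group_mask(pairwise: pd.DataFrame, metadata: pd.DataFrame) -> pd.Series:
    groups = metadata["group"]
    return pairwise.apply(
        lambda r: groups[r.sample_i] != groups[r.sample_j], axis=1
    )
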