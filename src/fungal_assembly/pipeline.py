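"""End-to-end drivers tying the modules together.

``generate_scenario`` builds tree + traits + table for a scenario;
``assembly_analysis`` runs the two-stage null-model classification on any
table/tree/metadata triple and returns per-pair labels plus the per-module
percentage table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from skbio import TreeNode

from fungal_assembly.assembly_processes import (
    classify_results,
    enumerate_modules,
    fractions_table,
)
from fungal_assembly.community_io import CommunityTable, check_metadata
from fungal_assembly.phylo_null import null_beta_nti, raup_crick_bray
from fungal_assembly.synthetic_community import (
    SyntheticScenario,
    simulate_table,
    simulate_traits,
    simulate_tree,
)


def generate_scenario(
    scenario: SyntheticScenario,
) -> tuple[CommunityTable, TreeNode, pd.DataFrame, dict]:
    """Simulate tree, Brownian traits and OTU table for one scenario.

    Tree, traits and table use distinct substreams of the scenario seed.
    """
    tree = simulate_tree(scenario.n_taxa, seed=scenario.seed + 1_000_003)
    traits = simulate_traits(tree, scenario.trait_rate, seed=scenario.seed + 2_000_003)
    table, metadata, truth = simulate_table(scenario, tree, traits)
    return table, tree, metadata, truth


@dataclass
class AssemblyAnalysis:
    pairwise: pd.DataFrame   # per-pair betaNTI, RCbray, process label
    fractions: pd.DataFrame  # per-module process percentages


def assembly_analysis(
    table: CommunityTable,
    tree: TreeNode,
    metadata: pd.DataFrame,
    reps: int = 999,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
) -> AssemblyAnalysis:
    """betaNTI + RCbray for the requested pairs, classified and aggregated.

    With ``pairs=None`` all unordered sample pairs are analysed and the
    fractions table covers every within- and between-group module present
    in the metadata.
    """
    check_metadata(table, metadata)
    modules = enumerate_modules(metadata.loc[table.samples])
    if pairs is None:
        seen: set[frozenset] = set()
        pairs = []
        for module_pairs in modules.values():
            for p in module_pairs:
                key = frozenset(p)
                if key not in seen:
                    seen.add(key)
                    pairs.append(p)
    nti = null_beta_nti(table, tree, reps=reps, seed=seed, pairs=pairs)
    rc = raup_crick_bray(table, reps=reps, seed=seed, pairs=pairs)
    classified = classify_results(nti, rc)
    fractions = fractions_table(classified, modules)
    return AssemblyAnalysis(pairwise=classified, fractions=fractions)
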