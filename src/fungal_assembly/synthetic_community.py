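"""Synthetic communities with known assembly regimes.

Emulates the sampling design of an elevational-gradient soil survey — a
handful of sample groups (sites) with ~8-10 replicate samples each, an OTU
table at fixed sequencing depth, and a phylogeny carrying phylogenetically
conserved (Brownian) traits — so that the betaNTI / RCbray pipeline can be
validated end-to-end against ground truth:

* ``selection`` — each group Gaussian-filters the shared species pool in
  trait space around its own environmental optimum; with distant optima and
  conserved traits, between-group turnover is deterministic (variable
  selection).
* ``drift`` — all samples draw from one shared metacommunity whose
  composition is perturbed per sample by mean-one log-normal noise
  (demographic stochasticity); expected abundances stay proportional to
  the pool.
* ``dispersal_limitation`` — access to the pool is split across groups:
  each taxon's accessibility is a Dirichlet draw over groups with
  concentration ``dispersal`` (smaller = stronger limitation, less overlap
  between group-specific pools), producing strong taxonomic turnover
  without phylogenetic structure.
* ``homogenizing_dispersal`` — every sample draws from one tight shared
  composition (very low compositional variance), so observed dissimilarity
  falls below the Raup-Crick null.

Counts are multinomial draws at exactly ``depth`` reads per sample; every
stage is deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from fungal_assembly.community_io import CommunityTable

REGIMES = ("selection", "drift", "dispersal_limitation", "homogenizing_dispersal")

# Per-sample compositional (log-normal sigma) noise by regime. The drift value
# is the generator's definition of "demographic stochasticity": large enough
# that observed Bray-Curtis sits inside the Raup-Crick null envelope rather
# than below it, small enough that no phylogenetic signal is induced.
DEFAULT_NOISE_SD = {
    "selection": 0.3,
    "drift": 0.3,
    "dispersal_limitation": 0.3,
    "homogenizing_dispersal": 0.05,
}

# Group-level (shared by all samples of a group) compositional divergence,
# applied only under dispersal limitation: restricted movement lets whole
# groups drift apart compositionally while replicates within a group stay
# coherent — the classic "dispersal limitation acting alongside drift"
# signature that pushes observed dissimilarity beyond the Raup-Crick null.
DEFAULT_GROUP_NOISE_SD = {
    "selection": 0.0,
    "drift": 0.0,
    "dispersal_limitation": 0.0,
    "homogenizing_dispersal": 0.0,
}

# Log-normal sigma of the metacommunity (pool) abundance distribution. The
# homogenizing-dispersal scenario uses a more uneven pool: stronger dominance
# lowers the sampling noise floor of observed Bray-Curtis relative to the
# Raup-Crick null, sharpening the below-null (RC -> -1) signature at
# moderate sequencing depth.
DEFAULT_BASE_SD = {
    "selection": 1.5,
    "drift": 1.5,
    "dispersal_limitation": 1.5,
    "homogenizing_dispersal": 2.5,
}


@dataclass
class SyntheticScenario:
    """Parameters and ground truth for one generated dataset."""

    regime: str
    n_taxa: int = 150
    n_groups: int = 2
    samples_per_group: int | tuple[int, ...] = 8
    depth: int = 10_000
    trait_rate: float = 1.0      # Brownian variance per unit branch length
    env_values: tuple[float, ...] | None = None  # trait-sd units; auto-spaced
    sigma: float = 0.6           # Gaussian filter width, trait-sd units
    dispersal: float = 0.3       # Dirichlet access concentration across groups
    noise_sd: float | None = None  # per-sample log-normal sigma; regime default
    group_noise_sd: float | None = None  # group-level log-normal sigma; regime default
    base_abundance_sd: float | None = None  # pool log-normal sigma; regime default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {REGIMES}")
        if self.n_taxa < 2 or self.n_groups < 1 or self.depth < 1:
            raise ValueError("sizes must be positive")
        if self.regime == "selection" and self.sigma <= 0:
            raise ValueError("selection regime requires sigma > 0")
        if self.dispersal <= 0:
            raise ValueError("dispersal concentration must be > 0")

    @property
    def group_sizes(self) -> tuple[int, ...]:
        if isinstance(self.samples_per_group, int):
            return (self.samples_per_group,) * self.n_groups
        sizes = tuple(self.samples_per_group)
        if len(sizes) != self.n_groups:
            raise ValueError("samples_per_group length must equal n_groups")
        return sizes

    @property
    def resolved_noise_sd(self) -> float:
        return DEFAULT_NOISE_SD[self.regime] if self.noise_sd is None else self.noise_sd

    @property
    def resolved_group_noise_sd(self) -> float:
        if self.group_noise_sd is None:
            return DEFAULT_GROUP_NOISE_SD[self.regime]
        return self.group_noise_sd

    @property
    def resolved_base_sd(self) -> float:
        if self.base_abundance_sd is None:
            return DEFAULT_BASE_SD[self.regime]
        return self.base_abundance_sd

    @property
    def resolved_env_values(self) -> tuple[float, ...]:
        if self.env_values is not None:
            if len(self.env_values) != self.n_groups:
                raise ValueError("env_values length must equal n_groups")
            return tuple(self.env_values)
        if self.n_groups == 1:
            return (0.0,)
        return tuple(np.linspace(-1.2, 1.2, self.n_groups))


def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Pure-birth (Yule) tree with ``n_taxa`` tips, labeled OTU_1..OTU_n.

    Forward simulation at birth rate 1: exponential waits between
    speciations, a uniformly chosen lineage splits at each event, and a
    final waiting time extends all pendant branches (no zero-length tips).
    Branch lengths are rescaled to unit mean.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None)
    active: list[TreeNode] = []
    for _ in range(2):
        child = TreeNode(length=0.0)
        root.append(child)
        active.append(child)
    while len(active) < n_taxa:
        k = len(active)
        wait = rng.exponential(1.0 / k)
        for node in active:
            node.length += wait
        split = active.pop(int(rng.integers(k)))
        for _ in range(2):
            child = TreeNode(length=0.0)
            split.append(child)
            active.append(child)
    final = rng.exponential(1.0 / n_taxa)
    for node in active:
        node.length += final
    for i, tip in enumerate(active, start=1):
        tip.name = f"OTU_{i}"
    lengths = [nd.length for nd in root.traverse(include_self=False)]
    scale = 1.0 / float(np.mean(lengths))
    for nd in root.traverse(include_self=False):
        nd.length *= scale
    return root


def simulate_traits(tree: TreeNode, rate: float, seed: int) -> pd.Series:
    """Brownian-motion trait values at the tips (root value 0).

    Each branch adds an independent Normal(0, rate * branch_length)
    increment, so tip covariance equals rate times shared path length.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        values[id(node)] = parent_val + rng.normal(0.0, np.sqrt(rate * node.length))
    tips = {tip.name: values[id(tip)] for tip in tree.tips()}
    return pd.Series(tips, name="trait")


def _group_weights(
    scenario: SyntheticScenario,
    base: np.ndarray,
    traits_z: np.ndarray,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Expected relative-abundance weights per group (before sample noise)."""
    g_weights = []
    env = scenario.resolved_env_values
    if scenario.regime == "dispersal_limitation":
        # per-taxon accessibility split across groups; concentration =
        # scenario.dispersal (small -> each taxon mostly reaches one group)
        access = rng.dirichlet(
            np.full(scenario.n_groups, scenario.dispersal), size=scenario.n_taxa
        )
    for g in range(scenario.n_groups):
        if scenario.regime == "selection":
            w = base * np.exp(-((traits_z - env[g]) ** 2) / (2 * scenario.sigma**2))
        elif scenario.regime == "dispersal_limitation":
            w = base * access[:, g]
        else:  # drift, homogenizing_dispersal: one shared metacommunity
            w = base.copy()
        gsd = scenario.resolved_group_noise_sd
        if gsd > 0:
            w = w * rng.lognormal(0.0, gsd, scenario.n_taxa)
        if w.sum() <= 0:
            raise RuntimeError("degenerate group weights")
        g_weights.append(w / w.sum())
    return g_weights


def simulate_table(
    scenario: SyntheticScenario, tree: TreeNode, traits: pd.Series
) -> tuple[CommunityTable, pd.DataFrame, dict]:
    """Generate the OTU table, sample metadata and ground-truth record."""
    taxa = [tip.name for tip in tree.tips()]
    if len(taxa) != scenario.n_taxa:
        raise ValueError("tree tip count does not match scenario n_taxa")
    rng = np.random.default_rng(scenario.seed)
    base = rng.lognormal(0.0, scenario.resolved_base_sd, scenario.n_taxa)
    t = traits.loc[taxa].to_numpy(dtype=float)
    traits_z = (t - t.mean()) / t.std()

    g_weights = _group_weights(scenario, base, traits_z, rng)
    noise_sd = scenario.resolved_noise_sd

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    env = scenario.resolved_env_values
    for g, size in enumerate(scenario.group_sizes):
        group = f"G{g + 1}"
        for s in range(size):
            w = g_weights[g] * rng.lognormal(0.0, noise_sd, scenario.n_taxa)
            p = w / w.sum()
            sample = f"{group}_S{s + 1}"
            columns[sample] = rng.multinomial(scenario.depth, p)
            meta_rows.append(
                {"sample": sample, "group": group,
                 "elevation": 1030.0 + 430.0 * g, "env": env[g]}
            )

    counts = pd.DataFrame(columns, index=taxa, dtype=np.int64)
    counts.index.name = "#OTU_ID"
    table = CommunityTable(counts)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    truth = {
        "regime": scenario.regime,
        "scenario": asdict(scenario),
        "noise_sd": noise_sd,
        "env_values": list(env),
    }
    return table, metadata, truth
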