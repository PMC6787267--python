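"""Five-way classification of pairwise turnover into ecological processes.

Decision rule (applied to each sample pair):

* betaNTI > +2       -> variable selection (deterministic divergence)
* betaNTI < -2       -> homogenizing selection (deterministic convergence)
* otherwise, consult RCbray:
    RCbray > +0.95   -> dispersal limitation (acting alongside drift)
    RCbray < -0.95   -> homogenizing dispersal
    |RCbray| <= 0.95 -> drift ("undominated" in some formulations)

Boundary values exactly at betaNTI = +/-2 fall through to the RCbray
branch, and RCbray exactly at +/-0.95 classifies as drift; both events are
measure-zero in practice.

Percentages per module (one group, or one ordered group pair) are
100 * count / n_pairs, rounded half-up to two decimals; stochastic and
deterministic totals are computed from the raw counts before rounding so
they cannot drift from the parts by accumulation.
"""

from __future__ import annotations

import itertools
import logging
import math
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BETA_NTI_THRESHOLD = 2.0
RC_BRAY_THRESHOLD = 0.95


class ProcessLabel(str, Enum):
    VARIABLE_SELECTION = "variable_selection"
    HOMOGENIZING_SELECTION = "homogenizing_selection"
    DISPERSAL_LIMITATION = "dispersal_limitation"
    HOMOGENIZING_DISPERSAL = "homogenizing_dispersal"
    DRIFT = "drift"


STOCHASTIC = (
    ProcessLabel.DISPERSAL_LIMITATION,
    ProcessLabel.HOMOGENIZING_DISPERSAL,
    ProcessLabel.DRIFT,
)
DETERMINISTIC = (
    ProcessLabel.VARIABLE_SELECTION,
    ProcessLabel.HOMOGENIZING_SELECTION,
)


def classify_pair(beta_nti: float, rc_bray: float | None = None) -> ProcessLabel:
    """Assign one ecological process to a pair from its betaNTI and RCbray."""
    if not np.isfinite(beta_nti):
        raise ValueError("beta_nti is not finite; exclude undefined pairs upstream")
    if beta_nti > BETA_NTI_THRESHOLD:
        return ProcessLabel.VARIABLE_SELECTION
    if beta_nti < -BETA_NTI_THRESHOLD:
        return ProcessLabel.HOMOGENIZING_SELECTION
    if rc_bray is None or not np.isfinite(rc_bray):
        raise ValueError(
            f"|beta_nti| <= {BETA_NTI_THRESHOLD} requires an RCbray value"
        )
    if rc_bray > RC_BRAY_THRESHOLD:
        return ProcessLabel.DISPERSAL_LIMITATION
    if rc_bray < -RC_BRAY_THRESHOLD:
        return ProcessLabel.HOMOGENIZING_DISPERSAL
    return ProcessLabel.DRIFT


def enumerate_modules(metadata: pd.DataFrame) -> dict[str, list[tuple[str, str]]]:
    """Within-group and between-group sample-pair modules.

    Returns a mapping from module name (a group label, or "G1-G2") to the
    list of unordered sample pairs in that module: C(n, 2) pairs within a
    group of n samples, n1*n2 pairs between two groups. Group order follows
    first appearance in the metadata.
    """
    groups: dict[str, list[str]] = {}
    for sample, row in metadata.iterrows():
        groups.setdefault(str(row["group"]), []).append(str(sample))
    modules: dict[str, list[tuple[str, str]]] = {}
    names = list(groups)
    for g in names:
        if len(groups[g]) < 2:
            logger.warning("group %s has < 2 samples; no within-group module", g)
            continue
        modules[g] = list(itertools.combinations(groups[g], 2))
    for g1, g2 in itertools.combinations(names, 2):
        modules[f"{g1}-{g2}"] = [(a, b) for a in groups[g1] for b in groups[g2]]
    return modules


def _round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def process_fractions(
    labels: list[ProcessLabel], module: str = ""
) -> dict[str, float | int | str]:
    """Percentage of pairs per process in one module.

    ``labels`` holds one ProcessLabel per classifiable pair (pairs with
    undefined betaNTI are excluded upstream and reduce n_pairs). Totals are
    computed from raw counts, then rounded.
    """
    n = len(labels)
    if n == 0:
        raise ValueError(f"empty module {module!r}")
    counts = {lab: 0 for lab in ProcessLabel}
    for lab in labels:
        counts[ProcessLabel(lab)] += 1
    out: dict[str, float | int | str] = {"module": module, "n_pairs": n}
    for lab in ProcessLabel:
        out[lab.value] = _round_half_up(100.0 * counts[lab] / n)
    stoch = sum(counts[lab] for lab in STOCHASTIC)
    det = sum(counts[lab] for lab in DETERMINISTIC)
    out["stochastic_total"] = _round_half_up(100.0 * stoch / n)
    out["deterministic_total"] = _round_half_up(100.0 * det / n)
    assert math.isclose(
        out["stochastic_total"] + out["deterministic_total"], 100.0, abs_tol=0.011
    )
    return out


def fractions_from_counts(
    module: str,
    n_pairs: int,
    *,
    variable_selection: int = 0,
    homogenizing_selection: int = 0,
    dispersal_limitation: int = 0,
    homogenizing_dispersal: int = 0,
    drift: int = 0,
) -> dict[str, float | int | str]:
    """process_fractions from integer per-process counts (must sum to n_pairs)."""
    named = {
        ProcessLabel.VARIABLE_SELECTION: variable_selection,
        ProcessLabel.HOMOGENIZING_SELECTION: homogenizing_selection,
        ProcessLabel.DISPERSAL_LIMITATION: dispersal_limitation,
        ProcessLabel.HOMOGENIZING_DISPERSAL: homogenizing_dispersal,
        ProcessLabel.DRIFT: drift,
    }
    if sum(named.values()) != n_pairs:
        raise ValueError("process counts must sum to n_pairs")
    labels: list[ProcessLabel] = []
    for lab, c in named.items():
        labels.extend([lab] * c)
    return process_fractions(labels, module)


def classify_results(
    nti_results, rc_results
) -> pd.DataFrame:
    """Join betaNTI and RCbray results per pair and classify each pair.

    Pairs with undefined betaNTI are dropped with a logged warning. RCbray
    is only required for pairs with |betaNTI| <= 2.
    """
    rc_map = {frozenset((r.sample_i, r.sample_j)): r.rc_bray for r in rc_results}
    rows = []
    for res in nti_results:
        key = frozenset((res.sample_i, res.sample_j))
        if not res.defined:
            logger.warning(
                "excluding pair (%s, %s): undefined betaNTI",
                res.sample_i, res.sample_j,
            )
            continue
        rc = rc_map.get(key)
        label = classify_pair(res.beta_nti, rc)
        rows.append(
            {
                "sample_i": res.sample_i,
                "sample_j": res.sample_j,
                "beta_mntd_obs": res.beta_mntd_obs,
                "beta_nti": res.beta_nti,
                "rc_bray": rc if rc is not None else np.nan,
                "process": label.value,
            }
        )
    return pd.DataFrame(rows)


def fractions_table(
    classified: pd.DataFrame, modules: dict[str, list[tuple[str, str]]]
) -> pd.DataFrame:
    """Per-module process percentages (one row per module, Table-2 shape)."""
    label_map = {
        frozenset((r.sample_i, r.sample_j)): ProcessLabel(r.process)
        for r in classified.itertuples()
    }
    rows = []
    for module, pairs in modules.items():
        labels = [
            label_map[frozenset(p)] for p in pairs if frozenset(p) in label_map
        ]
        if not labels:
            logger.warning("module %s has no classified pairs; skipped", module)
            continue
        rows.append(process_fractions(labels, module))
    return pd.DataFrame(rows)
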