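"""Reading, writing and aligning OTU tables, phylogenies and sample metadata.

On-disk conventions
-------------------
* Community tables are tab-separated in the QIIME "classic" dialect: taxa as
  rows, samples as columns, first header cell ``#OTU_ID``. Both orientations
  can be parsed; in memory the table is always taxa x samples.
* Phylogenies are newick files with branch lengths; tips are OTU identifiers.
* Metadata is a TSV with one row per sample, first column the sample id,
  a ``group`` column, and arbitrary numeric covariates (elevation, pH, ...).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

OTU_ID_HEADER = "#OTU_ID"


@dataclass
class CommunityTable:
    """An OTU-by-sample matrix of sequence counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, index = taxon identifiers,
        columns = sample identifiers.
    """

    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if df.shape[0] == 0:
            raise ValueError("no taxa in community table")
        if df.shape[1] == 0:
            raise ValueError("no samples in community table")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at taxon {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_counts(self, sample: str) -> np.ndarray:
        return self.counts[sample].to_numpy()

    def drop_empty_taxa(self) -> "CommunityTable":
        """Remove taxa with zero total count (required before null models)."""
        keep = self.counts.sum(axis=1) > 0
        if not keep.any():
            raise ValueError("all taxa have zero total count")
        return CommunityTable(self.counts.loc[keep])

    def subset_samples(self, samples: list[str]) -> "CommunityTable":
        missing = [s for s in samples if s not in self.counts.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return CommunityTable(self.counts[samples])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return self.counts.equals(other.counts)


def _parse_counts(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Validate that every cell is a non-negative integer, naming offenders."""
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            numeric[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            for row, val in df[col].items():
                try:
                    float(val)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"{path}: non-numeric count {val!r} "
                        f"at row {row!r}, column {col!r}"
                    ) from None
            raise
    arr = numeric.to_numpy()
    for bad, what in (((arr % 1) != 0, "non-integer"), (arr < 0, "negative")):
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"{path}: {what} count {df.iat[i, j]!r} "
                f"at row {df.index[i]!r}, column {df.columns[j]!r}"
            )
    return numeric.astype(np.int64)


def read_community_table(
    path, orientation: str = "taxa_rows"
) -> CommunityTable:
    """Read a tab-separated OTU table.

    Parameters
    ----------
    path : str or file-like
        TSV with one header row and one identifier column.
    orientation : {"taxa_rows", "samples_rows"}
        Whether rows of the file are taxa (QIIME classic) or samples.
        The returned table is always taxa x samples.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    name = getattr(path, "name", str(path))
    if df.shape[0] == 0:
        raise ValueError(f"{name}: no taxa (header-only file)")
    if df.isna().any().any():
        raise ValueError(f"{name}: ragged or missing entries")
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    counts = _parse_counts(df, name)
    if orientation == "samples_rows":
        counts = counts.T
    counts.index.name = OTU_ID_HEADER
    return CommunityTable(counts)


def write_community_table(table: CommunityTable, path) -> None:
    """Write in canonical orientation (taxa rows, ``#OTU_ID`` first column)."""
    df = table.counts.copy()
    df.index.name = OTU_ID_HEADER
    df.to_csv(path, sep="\t")


def read_phylogeny(path) -> TreeNode:
    """Read a rooted newick tree with branch lengths.

    Raises on duplicate tip labels or missing branch lengths (the root
    itself may lack one). The file's root is taken as the root; basal
    multifurcations (e.g. star trees) are accepted.
    """
    tree = TreeNode.read(path, format="newick", convert_underscores=False)
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        seen, dups = set(), []
        for t in tips:
            if t in seen:
                dups.append(t)
            seen.add(t)
        raise ValueError(f"duplicate tip labels: {sorted(set(dups))}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(
                f"missing branch length at node {node.name or '<internal>'}"
            )
        if node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    return tree


def write_phylogeny(tree: TreeNode, path) -> None:
    tree.write(path, format="newick")


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata TSV (index = sample id).

    Requires a non-empty ``group`` column; other columns are read as-is
    (numeric where possible).
    """
    md = pd.read_csv(path, sep="\t", index_col=0)
    md.index = md.index.astype(str)
    if md.index.has_duplicates:
        raise ValueError("duplicate sample identifiers in metadata")
    if "group" not in md.columns:
        raise ValueError("metadata must contain a 'group' column")
    if md["group"].isna().any() or (md["group"].astype(str) == "").any():
        raise ValueError("empty group labels in metadata")
    md["group"] = md["group"].astype(str)
    return md


def write_metadata(md: pd.DataFrame, path) -> None:
    md.to_csv(path, sep="\t")


def check_metadata(table: CommunityTable, md: pd.DataFrame) -> None:
    """Every sample in the table must have exactly one metadata row."""
    missing = [s for s in table.samples if s not in md.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")


def align_table_and_tree(
    table: CommunityTable, tree: TreeNode, allow_prune: bool = False
) -> CommunityTable:
    """Restrict a table to taxa that are tips of the tree.

    Tips absent from the table are ignored (the tree may be a supertree).
    Table taxa absent from the tree raise by default, because dropping
    them silently would bias betaMNTD; with ``allow_prune=True`` they are
    dropped with a logged warning.
    """
    tips = {t.name for t in tree.tips()}
    present = [t for t in table.taxa if t in tips]
    absent = [t for t in table.taxa if t not in tips]
    if not present:
        raise ValueError("no overlap between table taxa and tree tips")
    if absent and not allow_prune:
        raise ValueError(
            f"{len(absent)} table taxa missing from tree (e.g. {absent[:5]}); "
            "pass allow_prune=True to drop them"
        )
    if absent:
        logger.warning("pruned %d taxa absent from the tree", len(absent))
        return CommunityTable(table.counts.loc[present])
    return table


def write_result_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a result table as TSV, floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
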