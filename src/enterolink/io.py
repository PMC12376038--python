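"""Plain-text readers and writers: TSV count tables (samples in rows, header
= taxon IDs), metadata/phenotype TSV, Newick trees, and flat key-value ground
truth files."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from skbio import TreeNode

from .community import CommunityMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_community",
    "write_community",
]


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="sample")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick", convert_underscores=False)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_community(counts_path, metadata_path) -> CommunityMatrix:
    return CommunityMatrix(read_counts(counts_path), read_metadata(metadata_path))


def write_community(m: CommunityMatrix, counts_path, metadata_path) -> None:
    write_counts(m.counts, counts_path)
    write_metadata(m.metadata, metadata_path)
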