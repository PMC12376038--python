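import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from enterolink.community import CommunityMatrix


@pytest.fixture
def toy_community() -> CommunityMatrix:
    """4 animals x 1 timepoint, 4 taxa, hand-set counts for filter rules."""
    counts = pd.DataFrame(
        {
            "tA": [50, 60, 40, 55],   # abundant, everywhere
            "tB": [5, 0, 7, 0],       # abundant enough, 2/4 animals
            "tC": [1, 0, 0, 0],       # rare, 1/4 animals
            "tD": [0, 0, 0, 0],       # absent
        },
        index=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {
            "animal": ["a1", "a2", "a3", "a4"],
            "timepoint": ["T1"] * 4,
            "site": ["rumen"] * 4,
        },
        index=counts.index,
    )
    return CommunityMatrix(counts, meta)


@pytest.fixture
def five_leaf_tree() -> TreeNode:
    """Fixed 5-leaf tree with stated branch lengths for UniFrac oracles."""
    nwk = "((L1:0.1,L2:0.2):0.3,(L3:0.15,(L4:0.05,L5:0.25):0.1):0.2);"
    return TreeNode.read([nwk], convert_underscores=False)


@pytest.fixture
def repeated_measures_community() -> CommunityMatrix:
    """3 animals x 3 timepoints with simple profiles for per-animal averaging."""
    rows, ids, meta = [], [], []
    profiles = {
        "a1": [[8, 2, 0], [6, 4, 0], [4, 6, 0]],
        "a2": [[1, 1, 8], [2, 2, 6], [3, 3, 4]],
        "a3": [[5, 5, 0], [5, 5, 0], [5, 5, 0]],
    }
    for animal, per_tp in profiles.items():
        for t, counts in enumerate(per_tp):
            rows.append(counts)
            ids.append(f"{animal}_T{t}")
            meta.append((animal, f"T{t}", "rumen"))
    counts = pd.DataFrame(rows, index=ids, columns=["x", "y", "z"])
    metadata = pd.DataFrame(meta, index=ids, columns=["animal", "timepoint", "site"])
    return CommunityMatrix(counts, metadata)


def blob_distance_matrix(seed: int = 0, n_per: int = 6, gap: float = 10.0) -> pd.DataFrame:
    """Two well-separated Euclidean blobs as a distance matrix (planted k=2)."""
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.normal(0, 1, size=(n_per, 2)), rng.normal(gap, 1, size=(n_per, 2))])
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    ids = [f"p{i}" for i in range(2 * n_per)]
    return pd.DataFrame(d, index=ids, columns=ids)
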