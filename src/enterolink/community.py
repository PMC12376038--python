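"""Count-table container, abundance/prevalence filtering, rarefaction,
alpha diversity, Good's coverage, weighted UniFrac and PERMANOVA.

The container couples an integer count table (samples x taxa) with per-sample
metadata (animal, timepoint, gut site).  All downstream stages — enterotyping,
network ecology, assembly partitioning, host links — consume this container or
products derived from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CommunityMatrix",
    "FilterParams",
    "filter_taxa",
    "rarefy",
    "shannon",
    "goods_coverage",
    "weighted_unifrac",
    "permanova",
]

REQUIRED_METADATA = ("animal", "timepoint", "site")


@dataclass
class CommunityMatrix:
    """Samples x taxa count table with aligned sample metadata.

    Parameters
    ----------
    counts:
        Nonnegative integer DataFrame; index = sample IDs, columns = taxon IDs.
    metadata:
        DataFrame indexed by the same sample IDs with at least the columns
        ``animal``, ``timepoint`` and ``site``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate taxon IDs")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.index) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)[:5]}")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        # keep metadata aligned to the count table's sample order
        self.metadata = self.metadata.loc[self.counts.index]

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1; zero-total rows stay 0)."""
        totals = self.counts.sum(axis=1)
        safe = totals.replace(0, 1)
        return self.counts.div(safe, axis=0)

    def subset_samples(self, sample_ids) -> "CommunityMatrix":
        ids = list(sample_ids)
        return CommunityMatrix(self.counts.loc[ids].copy(), self.metadata.loc[ids].copy())

    def subset_taxa(self, taxon_ids) -> "CommunityMatrix":
        ids = list(taxon_ids)
        return CommunityMatrix(self.counts[ids].copy(), self.metadata.copy())


@dataclass
class FilterParams:
    """Abundance/prevalence inclusion rule.

    ``min_rel_abund`` is an overall mean relative-abundance floor (strict '>';
    default 0.0001, i.e. 0.01%); ``min_prevalence`` is the fraction of distinct
    animals in which a taxon must be detected (inclusive 'at least'; detection
    is pooled across an animal's samples).
    """

    min_rel_abund: float = 1e-4
    min_prevalence: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_rel_abund", "min_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def filter_taxa(m: CommunityMatrix, params: FilterParams | None = None) -> CommunityMatrix:
    """Keep taxa that clear both the mean-abundance and prevalence rules.

    A taxon is retained when its mean relative abundance across all samples
    exceeds ``min_rel_abund`` AND it is detected (count > 0 in any of the
    animal's samples) in at least ``min_prevalence`` of distinct animals.
    Column order is preserved.
    """
    if params is None:
        params = FilterParams()
    if m.n_samples == 0 or m.n_taxa == 0:
        raise ValueError("empty community matrix")

    rel = m.relative_abundance()
    abundant = rel.mean(axis=0) > params.min_rel_abund

    detected = (m.counts > 0).groupby(m.metadata["animal"]).any()
    n_animals = detected.shape[0]
    # inclusive boundary with a float guard: 2 of 4 animals passes at 0.5
    prevalent = detected.sum(axis=0) + 1e-9 >= params.min_prevalence * n_animals

    keep = [t for t in m.taxon_ids if abundant[t] and prevalent[t]]
    return m.subset_taxa(keep)


def rarefy(m: CommunityMatrix, depth: int, seed: int = 0) -> CommunityMatrix:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total falls below ``depth`` are dropped with a warning.
    Sampling is multivariate hypergeometric and deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = m.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = [s for s in m.sample_ids if s not in set(keep)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped[:5]}",
            stacklevel=2,
        )
    rows = []
    for s in keep:
        c = m.counts.loc[s].to_numpy()
        if c.sum() == depth:
            rows.append(c)
        else:
            rows.append(rng.multivariate_hypergeometric(c, depth))
    counts = pd.DataFrame(rows, index=keep, columns=m.counts.columns, dtype=int)
    return CommunityMatrix(counts, m.metadata.loc[keep].copy())


def shannon(abund) -> float:
    """Shannon entropy H = -sum p_i ln p_i over positive proportions (natural log)."""
    a = np.asarray(abund, dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundances")
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N: estimated fraction of reads from seen taxa."""
    c = np.asarray(counts)
    total = c.sum()
    if total <= 0:
        raise ValueError("zero total count")
    singletons = int((c == 1).sum())
    return 1.0 - singletons / total


def _branch_table(tree: TreeNode, taxon_ids: list) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch lengths and tip-membership indicator matrix (branches x taxa)."""
    tip_index = {t: i for i, t in enumerate(taxon_ids)}
    tips_in_tree = {t.name for t in tree.tips()}
    missing = [t for t in taxon_ids if t not in tips_in_tree]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:5]}")
    lengths = []
    members = []
    for node in tree.postorder(include_self=False):
        length = node.length or 0.0
        row = np.zeros(len(taxon_ids), dtype=float)
        for tip in node.tips(include_self=True):
            if tip.name in tip_index:
                row[tip_index[tip.name]] = 1.0
        lengths.append(length)
        members.append(row)
    return np.asarray(lengths), np.asarray(members)


def weighted_unifrac(
    m: CommunityMatrix, tree: TreeNode, normalized: bool = True
) -> pd.DataFrame:
    """Weighted UniFrac distance matrix over all sample pairs.

    For each branch b with length l_b let A_b, B_b be the proportion of each
    sample's reads descending from b; the distance is sum l_b |A_b - B_b|,
    divided by sum l_b (A_b + B_b) when ``normalized``.
    """
    lengths, members = _branch_table(tree, m.taxon_ids)
    rel = m.relative_abundance().to_numpy()
    # branch proportions per sample: (branches x samples)
    bp = members @ rel.T
    n = m.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(bp[:, i, None] - bp[:, i + 1 :])
        num = lengths @ diff
        if normalized:
            den = lengths @ (bp[:, i, None] + bp[:, i + 1 :])
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        else:
            vals = num
        d[i, i + 1 :] = vals
        d[i + 1 :, i] = vals
    return pd.DataFrame(d, index=m.sample_ids, columns=m.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA (distance-based multivariate ANOVA, sequential sums of squares)
# ---------------------------------------------------------------------------


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10).sum())
    q = q[:, :rank]
    return q @ q.T


def _design_columns(labels: pd.Series) -> np.ndarray:
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValueError(f"factor {labels.name!r} has a single level")
    # drop-first dummy coding; rank handled downstream via QR
    return np.column_stack([(labels == lv).to_numpy(float) for lv in levels[1:]])


def permanova(
    d: pd.DataFrame,
    factors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    interaction: bool = True,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    Sequential (type I) sums of squares via Gower centering and hat-matrix
    projections: each factor column of ``factors`` enters in order, followed by
    the all-way interaction when ``interaction`` and >= 2 factors.  P-values
    come from free permutation of sample labels: the distance matrix rows and
    columns are permuted jointly and every term's pseudo-F recomputed.

    Returns a DataFrame with one row per term plus Residual and Total, columns
    ``df``, ``SS``, ``R2``, ``F``, ``p``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if list(d.index) != list(d.columns):
        raise ValueError("distance matrix index/columns mismatch")
    factors = factors.loc[d.index]
    n = d.shape[0]
    g = _gower_center(d.to_numpy(float))
    ss_total = float(np.trace(g))

    terms: list[tuple[str, np.ndarray]] = []
    for col in factors.columns:
        terms.append((col, _design_columns(factors[col].astype(str).rename(col))))
    if interaction and len(factors.columns) >= 2:
        inter = factors.astype(str).agg(":".join, axis=1)
        inter.name = ":".join(factors.columns)
        terms.append((inter.name, _design_columns(inter)))

    ones = np.ones((n, 1))
    hats = [_hat(ones)]
    x = ones
    for _, cols in terms:
        x = np.hstack([x, cols])
        hats.append(_hat(x))
    h_full = hats[-1]
    resid_proj = np.eye(n) - h_full
    term_projs = [hats[i + 1] - hats[i] for i in range(len(terms))]
    dfs = [int(round(np.trace(p))) for p in term_projs]
    df_res = n - int(round(np.trace(h_full)))
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def f_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(p * gmat.T)) for p in term_projs])
        ss_res = float(np.sum(resid_proj * gmat.T))
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / np.array(dfs)) / (ss_res / df_res)
        return f, ss_res

    f_obs, ss_res = f_stats(g)
    ss_terms = np.array([float(np.sum(p * g.T)) for p in term_projs])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_perm, _ = f_stats(g[np.ix_(perm, perm)])
        exceed += f_perm >= f_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for (name, _), df_t, ss_t, f_t, p_t in zip(terms, dfs, ss_terms, f_obs, pvals):
        rows.append((name, df_t, ss_t, ss_t / ss_total, f_t, p_t))
    rows.append(("Residual", df_res, ss_res, ss_res / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["term", "df", "SS", "R2", "F", "p"]).set_index("term")
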