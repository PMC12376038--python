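"""Phylogenetic-bin null-model partitioning of community assembly.

Taxa are grouped into phylogenetic bins by a greedy abundance-seeded rule:
the most abundant unassigned taxon becomes a bin centroid, and the nearest
unassigned taxa within a patristic-distance threshold (default 0.2) join it,
nearest first, until the bin holds ``bin_size`` taxa (default 24).  For every
sample pair and bin, an abundance-weighted beta mean-nearest-taxon-distance
(betaMNTD) is standardized against a within-bin taxa-shuffle null to give
betaNTI; pairs with |betaNTI| below the significance cutoff fall through to a
Raup-Crick test on Bray-Curtis (RCbray) under a richness- and
abundance-preserving null.  Each (pair, bin) is then labeled with one of five
processes — heterogeneous selection (HeS), homogeneous selection (HoS),
dispersal limitation (DL), homogenizing dispersal (HD), drift-and-others
(DR) — and bin labels aggregate to community-level fractions with per-pair
abundance weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community import CommunityMatrix

__all__ = [
    "BinningParams",
    "AssemblyResult",
    "phylo_bins",
    "beta_mntd",
    "beta_nti",
    "rc_bray",
    "classify_process",
    "partition_assembly",
    "community_fractions",
    "permutational_ttest",
]

PROCESSES = ("HeS", "HoS", "DL", "HD", "DR")


@dataclass
class BinningParams:
    """Greedy phylogenetic binning rule.

    ``phylo_signal_threshold``: patristic distance within which taxa may join
    a centroid's bin (default 0.2).  ``bin_size``: maximum taxa per bin,
    centroid included (default 24).  ``min_bin_size``/``small_bin_policy``:
    bins finishing below the minimum are merged into the bin with the nearest
    centroid when the policy is on.
    """

    phylo_signal_threshold: float = 0.2
    bin_size: int = 24
    small_bin_policy: bool = True
    min_bin_size: int = 12

    def __post_init__(self) -> None:
        if self.phylo_signal_threshold <= 0:
            raise ValueError("phylo_signal_threshold must be > 0")
        if self.bin_size < 2:
            raise ValueError("bin_size must be >= 2")


def _patristic(tree: TreeNode, taxa: list) -> np.ndarray:
    dm = tree.tip_tip_distances()
    names = list(dm.ids)
    missing = [t for t in taxa if t not in set(names)]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:5]}")
    pos = [names.index(t) for t in taxa]
    return dm.data[np.ix_(pos, pos)]


def phylo_bins(
    tree: TreeNode, mean_abundances: pd.Series, params: BinningParams | None = None
) -> pd.Series:
    """Assign every taxon to a phylogenetic bin (greedy, abundance-seeded).

    Returns a Series mapping taxon -> bin id (0-based, in creation order
    after merging).  The first centroid is the globally most abundant taxon.
    """
    if params is None:
        params = BinningParams()
    taxa = list(mean_abundances.index)
    if (mean_abundances < 0).any():
        raise ValueError("negative abundances")
    d = _patristic(tree, taxa)
    abund = mean_abundances.to_numpy(float)
    n = len(taxa)
    unassigned = np.ones(n, dtype=bool)
    bins: list[list[int]] = []
    centroids: list[int] = []
    while unassigned.any():
        cand = np.flatnonzero(unassigned)
        centroid = cand[np.argmax(abund[cand])]
        members = [centroid]
        unassigned[centroid] = False
        near = [
            (d[centroid, j], j)
            for j in np.flatnonzero(unassigned)
            if d[centroid, j] < params.phylo_signal_threshold
        ]
        for _, j in sorted(near):
            if len(members) >= params.bin_size:
                break
            members.append(j)
            unassigned[j] = False
        bins.append(members)
        centroids.append(centroid)

    if params.small_bin_policy and len(bins) > 1:
        merged = True
        while merged and len(bins) > 1:
            merged = False
            sizes = [len(b) for b in bins]
            small = [i for i, s in enumerate(sizes) if s < params.min_bin_size]
            if not small:
                break
            i = min(small, key=lambda i: sizes[i])
            others = [j for j in range(len(bins)) if j != i]
            target = min(others, key=lambda j: d[centroids[i], centroids[j]])
            bins[target].extend(bins[i])
            del bins[i], centroids[i]
            merged = True

    assignment = np.empty(n, dtype=int)
    for bid, members in enumerate(bins):
        for j in members:
            assignment[j] = bid
    return pd.Series(assignment, index=taxa, name="bin")


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------


def beta_mntd(a: np.ndarray, b: np.ndarray, d: np.ndarray) -> float:
    """Abundance-weighted beta mean nearest taxon distance between two
    communities sharing the taxon order of the distance matrix ``d``."""
    pa = np.flatnonzero(a > 0)
    pb = np.flatnonzero(b > 0)
    if len(pa) == 0 or len(pb) == 0:
        return float("nan")
    wa = a[pa] / a[pa].sum()
    wb = b[pb] / b[pb].sum()
    min_ab = d[np.ix_(pa, pb)].min(axis=1)
    min_ba = d[np.ix_(pb, pa)].min(axis=1)
    return float(0.5 * (wa @ min_ab + wb @ min_ba))


def beta_nti(
    a, b, d: np.ndarray, n_null: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Observed betaMNTD and its null z-score (betaNTI) for one bin.

    The null shuffles taxon identities across the bin's tips (rows/columns of
    ``d`` permuted jointly) ``n_null`` times.  A zero null sd yields a NaN
    betaNTI sentinel so the caller can route the pair to the Raup-Crick step.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    present = (a > 0) | (b > 0)
    if present.sum() < 2:
        raise ValueError("bin needs >= 2 taxa present in the pair")
    obs = beta_mntd(a, b, d)
    rng = np.random.default_rng(seed)
    n = len(a)
    null = np.empty(n_null)
    for i in range(n_null):
        perm = rng.permutation(n)
        dp = d[np.ix_(perm, perm)]
        null[i] = beta_mntd(a, b, dp)
    sd = null.std()
    if sd <= 1e-12:
        return obs, float("nan")
    return obs, float((obs - null.mean()) / sd)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------


def _bray(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(np.abs(a - b).sum() / denom)


def _null_community(
    rng: np.random.Generator, richness: int, total: int,
    occ_freq: np.ndarray, pool_rel: np.ndarray,
) -> np.ndarray:
    """One null assembly: draw ``richness`` taxa by occurrence frequency, then
    distribute ``total`` individuals by regional relative abundance."""
    n = len(occ_freq)
    k = min(richness, int((occ_freq > 0).sum()))
    out = np.zeros(n)
    if k == 0 or total == 0:
        return out
    chosen = rng.choice(n, size=k, replace=False, p=occ_freq / occ_freq.sum())
    probs = pool_rel[chosen]
    if probs.sum() <= 0:
        probs = np.ones(k)
    probs = probs / probs.sum()
    out[chosen] = rng.multinomial(total, probs)
    return out


def rc_bray(
    a, b, pool: np.ndarray | None = None, n_null: int = 1000, seed: int = 0
) -> float:
    """Raup-Crick standardized Bray-Curtis within one bin, in [-1, 1].

    The null assembles each community from the bin's regional pool preserving
    its observed richness and total abundance; taxa are drawn with probability
    proportional to occurrence frequency and filled by regional relative
    abundance.  RC = 2 (F_lower + F_ties / 2) - 1 where F compares null
    Bray-Curtis values against the observed one.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if pool is None:
        pool = np.vstack([a, b])
    pool = np.asarray(pool, float)
    occ = (pool > 0).mean(axis=0)
    pool_rel = pool.sum(axis=0)
    if pool_rel.sum() > 0:
        pool_rel = pool_rel / pool_rel.sum()
    obs = _bray(a, b)
    rng = np.random.default_rng(seed)
    ra, ta = int((a > 0).sum()), int(round(a.sum()))
    rb, tb = int((b > 0).sum()), int(round(b.sum()))
    below = ties = 0
    for _ in range(n_null):
        na = _null_community(rng, ra, ta, occ, pool_rel)
        nb = _null_community(rng, rb, tb, occ, pool_rel)
        v = _bray(na, nb)
        if v < obs - 1e-12:
            below += 1
        elif abs(v - obs) <= 1e-12:
            ties += 1
    return float(2.0 * ((below + 0.5 * ties) / n_null) - 1.0)


def classify_process(
    bnti: float, rc: float | None = None,
    nti_cut: float = 1.96, rc_cut: float = 0.95,
) -> str:
    """Map (betaNTI, RCbray) to one of the five assembly processes."""
    if np.isfinite(bnti):
        if bnti > nti_cut:
            return "HeS"
        if bnti < -nti_cut:
            return "HoS"
    if rc is None or not np.isfinite(rc):
        raise ValueError("RC value required when |betaNTI| does not signal selection")
    if rc > rc_cut:
        return "DL"
    if rc < -rc_cut:
        return "HD"
    return "DR"


# ---------------------------------------------------------------------------
# whole-community driver
# ---------------------------------------------------------------------------


@dataclass
class AssemblyResult:
    """Process partition for one group of samples."""

    bins: pd.Series                      # taxon -> bin id
    pair_bin: pd.DataFrame               # one row per (pair, bin): stats + label + weight
    fractions: pd.Series                 # process -> community-level fraction
    bin_fractions: pd.DataFrame          # bin x process contribution matrix


def _pair_table(
    comm: np.ndarray, taxa: list, bins: pd.Series, d_full: np.ndarray,
    sample_ids: list, n_null: int, rng: np.random.Generator,
) -> pd.DataFrame:
    """betaNTI/RC/process for every sample pair x bin of one group.

    Null permutations of tip identities are drawn once per bin per null
    replicate and shared across pairs, which keeps the cost linear in
    ``n_null`` rather than in pairs x ``n_null``.
    """
    n_samp = comm.shape[0]
    taxa_idx = {t: i for i, t in enumerate(taxa)}
    records = []
    for bid in sorted(bins.unique()):
        bin_taxa = [t for t in taxa if bins[t] == bid]
        cols = np.array([taxa_idx[t] for t in bin_taxa])
        sub = comm[:, cols].astype(float)
        d = d_full[np.ix_(cols, cols)]
        nb = len(cols)
        pairs = [(i, j) for i in range(n_samp) for j in range(i + 1, n_samp)]

        obs = np.array([beta_mntd(sub[i], sub[j], d) for i, j in pairs])
        null = np.full((n_null, len(pairs)), np.nan)
        for r in range(n_null):
            perm = rng.permutation(nb)
            dp = d[np.ix_(perm, perm)]
            null[r] = [beta_mntd(sub[i], sub[j], dp) for i, j in pairs]
        null_mean = np.nanmean(null, axis=0)
        null_sd = np.nanstd(null, axis=0)

        # richness/abundance-preserving nulls for RC, also shared per replicate
        occ = (sub > 0).mean(axis=0)
        pool_rel = sub.sum(axis=0)
        if pool_rel.sum() > 0:
            pool_rel = pool_rel / pool_rel.sum()
        rich = (sub > 0).sum(axis=1)
        tot = sub.sum(axis=1).round().astype(int)
        null_comms = np.empty((n_null, n_samp, nb))
        if occ.sum() > 0:
            for r in range(n_null):
                for s in range(n_samp):
                    null_comms[r, s] = _null_community(
                        rng, int(rich[s]), int(tot[s]), occ, pool_rel
                    )
        else:
            null_comms[:] = 0.0

        for pi, (i, j) in enumerate(pairs):
            present = (sub[i] > 0) | (sub[j] > 0)
            weight_basis = 0.5 * (
                comm[i, cols].sum() / max(comm[i].sum(), 1)
                + comm[j, cols].sum() / max(comm[j].sum(), 1)
            )
            if present.sum() < 2 or not np.isfinite(obs[pi]):
                records.append((sample_ids[i], sample_ids[j], bid, np.nan, np.nan,
                                np.nan, np.nan, np.nan, "DR", weight_basis))
                continue
            sd = null_sd[pi]
            bnti = (obs[pi] - null_mean[pi]) / sd if sd > 1e-12 else float("nan")
            rc = np.nan
            if not (np.isfinite(bnti) and abs(bnti) > 1.96):
                obs_bc = _bray(sub[i], sub[j])
                null_bc = np.array([_bray(null_comms[r, i], null_comms[r, j])
                                    for r in range(n_null)])
                below = (null_bc < obs_bc - 1e-12).sum()
                ties = (np.abs(null_bc - obs_bc) <= 1e-12).sum()
                rc = 2.0 * ((below + 0.5 * ties) / n_null) - 1.0
            label = classify_process(
                bnti if np.isfinite(bnti) else 0.0,
                rc if np.isfinite(rc) else None,
            )
            records.append((sample_ids[i], sample_ids[j], bid, obs[pi],
                            null_mean[pi], sd, bnti, rc, label, weight_basis))
    df = pd.DataFrame(records, columns=[
        "sample_a", "sample_b", "bin", "bmntd_obs", "bmntd_null_mean",
        "bmntd_null_sd", "bnti", "rc", "process", "weight",
    ])
    # per-pair bin weights sum to 1
    key = df["sample_a"] + "|" + df["sample_b"]
    tot = df.groupby(key)["weight"].transform("sum")
    df["weight"] = np.where(tot > 0, df["weight"] / np.where(tot > 0, tot, 1.0),
                            1.0 / df.groupby(key)["weight"].transform("count"))
    return df


def community_fractions(pair_bin: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Aggregate (pair, bin) labels to community-level process fractions.

    Fraction of process P = sum over pairs and bins of weight * 1[label = P]
    divided by the number of pairs; bin-level contributions are reported per
    process.  Fractions sum to 1 because per-pair weights do.
    """
    if pair_bin.empty:
        raise ValueError("no classified pairs")
    n_pairs = pair_bin.groupby(["sample_a", "sample_b"]).ngroups
    frac = {}
    for p in PROCESSES:
        frac[p] = pair_bin.loc[pair_bin["process"] == p, "weight"].sum() / n_pairs
    fractions = pd.Series(frac, name="fraction")
    bin_rows = []
    for bid, grp in pair_bin.groupby("bin"):
        row = {p: grp.loc[grp["process"] == p, "weight"].sum() / n_pairs for p in PROCESSES}
        row["bin"] = bid
        bin_rows.append(row)
    bin_fractions = pd.DataFrame(bin_rows).set_index("bin")[list(PROCESSES)]
    return fractions, bin_fractions


def partition_assembly(
    m: CommunityMatrix,
    tree: TreeNode,
    params: BinningParams | None = None,
    groupby: list[str] | None = None,
    n_null: int = 1000,
    seed: int = 0,
) -> dict[tuple, AssemblyResult]:
    """Run the full binning + null-model partition per sample group.

    Groups default to all samples together; pass metadata column names (e.g.
    ``["site", "timepoint"]``) to partition within groups.  Deterministic
    given ``seed``.
    """
    if params is None:
        params = BinningParams()
    mean_ab = m.relative_abundance().mean(axis=0)
    bins = phylo_bins(tree, mean_ab, params)
    d_full = _patristic(tree, m.taxon_ids)
    rng = np.random.default_rng(seed)
    if groupby:
        groups = m.metadata.groupby(groupby).groups
    else:
        groups = {("all",): m.counts.index}
    results: dict[tuple, AssemblyResult] = {}
    for key, idx in groups.items():
        ids = list(idx)
        if len(ids) < 2:
            continue
        comm = m.counts.loc[ids].to_numpy(float)
        table = _pair_table(comm, m.taxon_ids, bins, d_full, ids, n_null, rng)
        fractions, bin_fr = community_fractions(table)
        k = key if isinstance(key, tuple) else (key,)
        results[k] = AssemblyResult(bins=bins, pair_bin=table,
                                    fractions=fractions, bin_fractions=bin_fr)
    return results


def permutational_ttest(
    values_a, values_b, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Welch t with a permutation p-value (two-sided).

    p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm) under random relabeling.
    Two identical constant groups give p = 1.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 values")

    def welch(x, y):
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        denom = np.sqrt(vx / len(x) + vy / len(y))
        if denom == 0:
            return 0.0
        return (x.mean() - y.mean()) / denom

    t_obs = welch(a, b)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        t_p = welch(pooled[perm[: len(a)]], pooled[perm[len(a):]])
        if abs(t_p) >= abs(t_obs) - 1e-12:
            exceed += 1
    return float(t_obs), float((1 + exceed) / (1 + n_perm))
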