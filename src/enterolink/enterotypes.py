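"""Enterotype discovery and validation.

Per-animal averaged genus profiles are compared with the Jensen-Shannon
distance (square root of the base-2 Jensen-Shannon divergence, a metric
bounded by 1), clustered by partitioning around medoids (PAM), and the number
of clusters selected by a distance-based Calinski-Harabasz pseudo-F.
Validation adds silhouette widths recomputed under Jaccard, Kulczynski and
Bray-Curtis dissimilarities, bootstrap assignment stability (adjusted Rand
index), and between-class taxon weights that name each enterotype by its
dominant genus.  A chi-square test of independence relates the enterotypes of
two gut sites.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .community import CommunityMatrix

__all__ = [
    "EnterotypeModel",
    "average_per_animal",
    "jsd_matrix",
    "pam_cluster",
    "calinski_harabasz",
    "validate_clustering",
    "between_class_weights",
    "enterotype_independence",
    "fit_enterotypes",
]


def average_per_animal(m: CommunityMatrix) -> pd.DataFrame:
    """Average per-sample relative abundances across each animal's timepoints.

    Zero-total samples are excluded with a warning.  Output rows (one per
    animal) sum to 1.
    """
    totals = m.counts.sum(axis=1)
    bad = totals[totals == 0].index
    if len(bad):
        warnings.warn(f"excluding {len(bad)} zero-total sample(s)", stacklevel=2)
    keep = totals[totals > 0].index
    rel = m.counts.loc[keep].div(totals[keep], axis=0)
    prof = rel.groupby(m.metadata.loc[keep, "animal"]).mean()
    if prof.empty:
        raise ValueError("no usable samples")
    return prof


def jsd_matrix(profiles: pd.DataFrame, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Pairwise Jensen-Shannon distances between probability profiles.

    D(p, q) = sqrt(H(m) - (H(p) + H(q)) / 2) with m = (p + q)/2 and entropies
    in bits, so D is a metric in [0, 1].  Zeros are handled by adding
    ``pseudocount`` and renormalizing each row.
    """
    x = profiles.to_numpy(float)
    if (x < 0).any():
        raise ValueError("negative entries in profiles")
    x = x + pseudocount
    x /= x.sum(axis=1, keepdims=True)

    def h_bits(p: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return -t.sum(axis=-1)

    hx = h_bits(x)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        mix = 0.5 * (x[i] + x[i + 1 :])
        div = h_bits(mix) - 0.5 * (hx[i] + hx[i + 1 :])
        div = np.clip(div, 0.0, None)
        d[i, i + 1 :] = np.sqrt(div)
        d[i + 1 :, i] = d[i, i + 1 :]
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


# ---------------------------------------------------------------------------
# PAM (k-medoids: BUILD + SWAP on an arbitrary distance matrix)
# ---------------------------------------------------------------------------


def _pam_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def pam_cluster(d: pd.DataFrame, k: int, seed: int = 0) -> tuple[pd.Series, list]:
    """Partitioning around medoids on a precomputed distance matrix.

    BUILD greedily seeds k medoids; SWAP exchanges (medoid, non-medoid) pairs
    while the total distance of points to their nearest medoid decreases.
    Ties break on the lowest index order so the result is deterministic; the
    ``seed`` argument is accepted for interface uniformity but unused.

    Returns (assignments indexed like ``d``, medoid labels).
    """
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n_points, got k={k}, n={n}")
    dm = d.to_numpy(float)

    # BUILD
    medoids = [int(np.argmin(dm.sum(axis=0)))]
    while len(medoids) < k:
        current = dm[:, medoids].min(axis=1)
        gains = np.array(
            [
                np.maximum(current - dm[:, j], 0.0).sum() if j not in medoids else -np.inf
                for j in range(n)
            ]
        )
        medoids.append(int(np.argmax(gains)))

    # SWAP
    best_cost = _pam_cost(dm, medoids)
    improved = True
    while improved:
        improved = False
        best_swap = None
        for mi, m_old in enumerate(medoids):
            for j in range(n):
                if j in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = j
                cost = _pam_cost(dm, trial)
                if cost < best_cost - 1e-12:
                    if best_swap is None or cost < best_swap[0] - 1e-12:
                        best_swap = (cost, mi, j)
        if best_swap is not None:
            best_cost, mi, j = best_swap
            medoids[mi] = j
            improved = True

    medoids = sorted(medoids)
    labels = np.argmin(dm[:, medoids], axis=1)
    assignments = pd.Series(labels, index=d.index, name="cluster")
    medoid_ids = [d.index[m] for m in medoids]
    return assignments, medoid_ids


def pam_exhaustive(d: pd.DataFrame, k: int) -> tuple[float, tuple]:
    """Optimal k-medoid cost by exhaustive search (oracle for small n)."""
    dm = d.to_numpy(float)
    best = (np.inf, None)
    for combo in itertools.combinations(range(dm.shape[0]), k):
        cost = _pam_cost(dm, list(combo))
        if cost < best[0]:
            best = (cost, combo)
    return best


def calinski_harabasz(d: pd.DataFrame, assignments: pd.Series) -> float:
    """Distance-based Calinski-Harabasz pseudo-F.

    Sums of squares come from pairwise squared distances (SS of a group =
    sum_{i<j} d_ij^2 / group size), so no centroid is needed — valid for any
    dissimilarity including JSD.  Perfect separation (SS_within = 0) returns
    +inf.
    """
    labels = assignments.loc[d.index].to_numpy()
    groups = pd.unique(labels)
    k = len(groups)
    n = d.shape[0]
    if k < 2:
        raise ValueError("need >= 2 clusters")
    if k >= n:
        raise ValueError("every point its own cluster: CH undefined")
    d2 = d.to_numpy(float) ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    if ss_within <= 1e-15:
        return float("inf")
    return float(((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k)))


# ---------------------------------------------------------------------------
# validation distances (quantitative, as used on abundance profiles)
# ---------------------------------------------------------------------------


def _braycurtis(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        den = (x[i] + x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
        d[i + 1 :, i] = d[i, i + 1 :]
    return d


def _jaccard_quant(x: np.ndarray) -> np.ndarray:
    b = _braycurtis(x)
    return 2 * b / (1 + b)


def _kulczynski(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    d = np.zeros((n, n))
    sums = x.sum(axis=1)
    for i in range(n):
        mins = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d[i, i + 1 :] = 1.0 - 0.5 * (mins / sums[i] + mins / sums[i + 1 :])
        d[i + 1 :, i] = d[i, i + 1 :]
    return np.clip(d, 0.0, 1.0)


_VALIDATION_METRICS = {
    "jaccard": _jaccard_quant,
    "kulczynski": _kulczynski,
    "braycurtis": _braycurtis,
}


def validate_clustering(
    profiles: pd.DataFrame,
    d: pd.DataFrame,
    k: int,
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    metrics: tuple[str, ...] = ("jaccard", "kulczynski", "braycurtis"),
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[dict[str, dict[int, float]], float]:
    """Silhouette widths under alternative dissimilarities plus bootstrap stability.

    For each k in ``k_range`` the PAM assignment on the JSD matrix is scored
    by its mean silhouette width under each named dissimilarity recomputed on
    the same profiles.  Stability (at the chosen ``k``) is the mean adjusted
    Rand index between the full-data assignment and assignments obtained from
    ``n_boot`` bootstrap resamples of animals, with out-of-bag animals mapped
    to their nearest bootstrap medoid.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    unknown = [m for m in metrics if m not in _VALIDATION_METRICS]
    if unknown:
        raise ValueError(f"unknown metric(s): {unknown}; choose from {sorted(_VALIDATION_METRICS)}")

    x = profiles.to_numpy(float)
    alt = {name: _VALIDATION_METRICS[name](x) for name in metrics}
    sil: dict[str, dict[int, float]] = {name: {} for name in metrics}
    for kk in k_range:
        if kk >= d.shape[0]:
            raise ValueError(f"k={kk} leaves singleton-only clustering: silhouette undefined")
        assign_k, _ = pam_cluster(d, kk)
        labels = assign_k.to_numpy()
        for name in metrics:
            sil[name][kk] = float(
                silhouette_score(alt[name], labels, metric="precomputed")
            )

    full_assign, _ = pam_cluster(d, k)
    rng = np.random.default_rng(seed)
    n = d.shape[0]
    dm = d.to_numpy(float)
    aris = []
    for _ in range(n_boot):
        boot = rng.integers(0, n, size=n)
        uniq = np.unique(boot)
        if len(uniq) <= k:
            continue
        sub = d.iloc[uniq, uniq]
        assign_b, medoid_ids = pam_cluster(sub, k)
        med_pos = [d.index.get_loc(mid) for mid in medoid_ids]
        # every animal (in-bag or out) goes to its nearest bootstrap medoid
        all_labels = np.argmin(dm[:, med_pos], axis=1)
        aris.append(adjusted_rand_score(full_assign.to_numpy(), all_labels))
    stability = float(np.mean(aris)) if aris else float("nan")
    return sil, stability


def between_class_weights(
    profiles: pd.DataFrame, assignments: pd.Series
) -> tuple[pd.Series, dict]:
    """Between-class taxon weights and each cluster's dominant taxon.

    The weight vector is the principal axis of the size-weighted,
    grand-mean-centered class-mean profiles; the dominant taxon of a cluster
    is the taxon with the largest weight oriented toward that cluster's mean.
    """
    labels = assignments.loc[profiles.index]
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 clusters for between-class analysis")
    x = profiles.to_numpy(float)
    grand = x.mean(axis=0)
    class_means = {}
    sizes = {}
    for g in groups:
        idx = labels.to_numpy() == g
        class_means[g] = x[idx].mean(axis=0) - grand
        sizes[g] = idx.sum()
    cm = np.array([class_means[g] * np.sqrt(sizes[g]) for g in groups])
    # principal axis of the between-class scatter
    _, sv, vt = np.linalg.svd(cm, full_matrices=False)
    axis = vt[0] if sv[0] > 1e-12 else np.zeros(cm.shape[1])
    weights = pd.Series(axis, index=profiles.columns, name="weight")
    dominant = {}
    for g in groups:
        orient = np.sign(class_means[g] @ axis) or 1.0
        dominant[g] = profiles.columns[int(np.argmax(orient * axis))]
    return weights, dominant


def enterotype_independence(
    table, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2x2 contingency table.

    Returns (statistic, df, p).  ``correction`` applies the Yates continuity
    correction.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    total = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(stat, 1))
    return stat, 1, p


@dataclass
class EnterotypeModel:
    """Fitted enterotype model for one gut site."""

    distance: pd.DataFrame
    k: int
    assignments: pd.Series
    medoids: list
    ch_by_k: dict[int, float]
    silhouette_by_metric: dict[str, dict[int, float]]
    stability: float
    taxon_weights: pd.Series
    dominant_taxon: dict

    def cluster_of(self, animal) -> int:
        return int(self.assignments.loc[animal])


def fit_enterotypes(
    m: CommunityMatrix,
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    pseudocount: float = 1e-6,
    n_boot: int = 100,
    seed: int = 0,
) -> EnterotypeModel:
    """End-to-end enterotype pipeline for one site.

    Averages profiles per animal, builds the JSD matrix, clusters with PAM
    for each k, selects k by the Calinski-Harabasz index, then validates with
    multi-metric silhouettes, bootstrap stability and between-class weights.
    """
    profiles = average_per_animal(m)
    d = jsd_matrix(profiles, pseudocount=pseudocount)
    ch_by_k: dict[int, float] = {}
    assigns: dict[int, pd.Series] = {}
    medoids: dict[int, list] = {}
    for k in k_range:
        a, med = pam_cluster(d, k, seed=seed)
        assigns[k], medoids[k] = a, med
        ch_by_k[k] = calinski_harabasz(d, a)
    best_k = max(ch_by_k, key=lambda k: (ch_by_k[k], -k))
    sil, stability = validate_clustering(
        profiles, d, best_k, k_range=k_range, n_boot=n_boot, seed=seed
    )
    weights, dominant = between_class_weights(profiles, assigns[best_k])
    return EnterotypeModel(
        distance=d,
        k=best_k,
        assignments=assigns[best_k],
        medoids=medoids[best_k],
        ch_by_k=ch_by_k,
        silhouette_by_metric=sil,
        stability=stability,
        taxon_weights=weights,
        dominant_taxon=dominant,
    )
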