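"""Co-occurrence network ecology.

Taxon-taxon correlation matrices are thresholded at a cutoff selected by a
random-matrix-theory criterion: scan candidate cutoffs and keep the smallest
one at which the thresholded matrix's nearest-neighbor eigenvalue-spacing
distribution is consistent with the Poisson (exponential) law — the
transition from GOE-like noise statistics to the modular, system-specific
regime.  On the resulting signed weighted graph we compute topology
summaries, within-module degree z-scores and participation coefficients
(generalists vs specialists), an abundance-weighted extinction-cascade
robustness, and per-sample positive/negative cohesion from null-corrected
correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .community import CommunityMatrix

__all__ = [
    "CooccurrenceNetwork",
    "NodeRole",
    "CohesionProfile",
    "correlation_matrix",
    "rmt_threshold",
    "spacing_poisson_pvalue",
    "poisson_wigner_loglik_gap",
    "build_network",
    "node_roles",
    "robustness",
    "cohesion",
]


def correlation_matrix(m: CommunityMatrix, method: str = "pearson") -> pd.DataFrame:
    """Pairwise taxon correlations on relative abundances.

    Constant taxa get r = 0 against all others (with a warning); the diagonal
    is always 1.
    """
    if m.n_samples < 4:
        raise ValueError("need >= 4 samples for correlations")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    rel = m.relative_abundance()
    x = rel.to_numpy(float)
    const = x.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant taxa set to r=0 against all others",
            stacklevel=2,
        )
    if method == "spearman":
        x = np.apply_along_axis(sps.rankdata, 0, x)
    xs = x.copy()
    sd = xs.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (xs - xs.mean(axis=0)) / sd
    r = xs.T @ xs / xs.shape[0]
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=m.taxon_ids, columns=m.taxon_ids)


# ---------------------------------------------------------------------------
# RMT threshold selection
# ---------------------------------------------------------------------------


def _unfolded_spacings(eigvals: np.ndarray, poly_degree: int = 5) -> np.ndarray:
    """Unfold a spectrum by a smooth polynomial fit to its empirical CDF.

    Extreme outlier eigenvalues (e.g. the Perron modes of dense modules, which
    would otherwise dominate the polynomial fit) are trimmed by a 3-IQR rule
    before unfolding.  Returns nearest-neighbor spacings normalized to unit
    mean.
    """
    lam = np.sort(eigvals)
    q1, q3 = np.percentile(lam, [25, 75])
    iqr = q3 - q1
    if iqr > 0:
        lam = lam[(lam > q1 - 3 * iqr) & (lam < q3 + 3 * iqr)]
    n = len(lam)
    if n < 3:
        return np.empty(0)
    cdf = (np.arange(1, n + 1) - 0.5) / n
    deg = min(poly_degree, max(1, n // 10))
    coef = np.polynomial.polynomial.polyfit(lam, cdf, deg)
    smooth = np.polynomial.polynomial.polyval(lam, coef)
    unfolded = n * smooth
    s = np.diff(unfolded)
    s = s[s > 0]
    if len(s) == 0:
        return s
    return s / s.mean()


def poisson_wigner_loglik_gap(spacings: np.ndarray) -> float:
    """Mean log-likelihood advantage of the Poisson law over the Wigner surmise.

    Positive values mean the exponential (Poisson) spacing law explains the
    unit-mean spacings better than the GOE Wigner surmise
    P(s) = (pi s / 2) exp(-pi s^2 / 4).
    """
    s = np.clip(spacings, 1e-12, None)
    lp = (-s).mean()
    lw = (np.log(np.pi * s / 2.0) - np.pi * s**2 / 4.0).mean()
    return float(lp - lw)


def spacing_poisson_pvalue(spacings: np.ndarray, n_bins: int = 10) -> float:
    """Chi-square goodness of fit of unit-mean spacings to the Exp(1) law.

    Bins are equiprobable under Exp(1) so expected counts are equal; degrees
    of freedom are n_bins - 2 (one for the total, one for the fitted mean).
    """
    n = len(spacings)
    if n < 2 * n_bins:
        return float("nan")
    edges = -np.log(1.0 - np.arange(1, n_bins) / n_bins)  # Exp(1) quantiles
    obs = np.histogram(spacings, bins=np.concatenate(([0.0], edges, [np.inf])))[0]
    expected = n / n_bins
    stat = ((obs - expected) ** 2 / expected).sum()
    return float(sps.chi2.sf(stat, n_bins - 2))


def rmt_threshold(
    corr: pd.DataFrame,
    scan=None,
    lik_margin: float = 0.1,
    min_nodes: int = 10,
    min_spacings: int = 20,
) -> float:
    """Smallest correlation cutoff whose spacing statistics look Poisson.

    For each candidate s (ascending), entries with \\|r\\| < s are zeroed,
    nodes without any remaining edge are dropped, and the surviving matrix's
    unfolded nearest-neighbor eigenvalue spacings are compared against the
    Poisson (exponential) law and the GOE Wigner surmise.  The first
    candidate where the Wigner surmise loses its decisive likelihood
    advantage — Poisson log-likelihood advantage above ``-lik_margin`` — is
    the GOE-to-Poisson transition point and is returned.

    The margin exists because a genuinely modular matrix with few modules
    yields a superposition of a small number of component spectra, which sits
    between the pure laws, while noise-dominated spectra prefer the Wigner
    surmise decisively.
    """
    n = corr.shape[0]
    if n < 20:
        raise ValueError("need >= 20 nodes for a meaningful spectrum")
    if scan is None:
        scan = np.round(np.arange(0.20, 0.96, 0.02), 2)
    r = corr.to_numpy(float).copy()
    np.fill_diagonal(r, 0.0)
    tested_any = False
    for s in scan:
        a = np.where(np.abs(r) >= s, r, 0.0)
        keep = np.abs(a).sum(axis=1) > 0
        if keep.sum() < min_nodes:
            continue
        sub = a[np.ix_(keep, keep)]
        np.fill_diagonal(sub, 1.0)
        eig = np.linalg.eigvalsh(sub)
        spacings = _unfolded_spacings(eig)
        if len(spacings) < min_spacings:
            continue
        tested_any = True
        if poisson_wigner_loglik_gap(spacings) >= -lik_margin:
            return float(s)
    if not tested_any:
        raise ValueError("no candidate threshold left a testable spectrum; widen the scan")
    raise ValueError("no candidate threshold reached Poisson spacing statistics; widen the scan")


@dataclass
class CooccurrenceNetwork:
    """Signed weighted co-occurrence graph at a fixed correlation cutoff."""

    graph: nx.Graph
    threshold: float
    modules: dict
    topology: dict

    @property
    def is_empty(self) -> bool:
        return self.graph.number_of_edges() == 0


def build_network(corr: pd.DataFrame, threshold: float, seed: int = 0) -> CooccurrenceNetwork:
    """Threshold a correlation matrix into a signed weighted graph.

    Edges keep the correlation as ``weight`` where \\|r\\| >= threshold;
    isolated nodes are dropped.  Modules come from greedy modularity
    maximization on \\|weight\\|; the topology summary reports node/edge
    counts, average degree, edge density, modularity, and mean shortest-path
    distance over the largest connected component.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    r = corr.to_numpy(float)
    taxa = list(corr.index)
    g = nx.Graph()
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(r[i, j]) >= threshold:
                g.add_edge(taxa[i], taxa[j], weight=float(r[i, j]))
    if g.number_of_edges() == 0:
        return CooccurrenceNetwork(
            graph=g, threshold=threshold, modules={},
            topology={"n_nodes": 0, "n_edges": 0, "avg_degree": 0.0,
                      "edge_density": 0.0, "mean_distance": float("nan"),
                      "modularity": float("nan")},
        )
    for u, v, data in g.edges(data=True):
        data["abs_weight"] = abs(data["weight"])
    comms = nx.community.greedy_modularity_communities(g, weight="abs_weight")
    modules = {}
    for mid, comm in enumerate(sorted(comms, key=lambda c: sorted(c)[0])):
        for node in comm:
            modules[node] = mid
    modularity = nx.community.modularity(g, comms, weight="abs_weight")
    nn = g.number_of_nodes()
    ne = g.number_of_edges()
    lcc = g.subgraph(max(nx.connected_components(g), key=len))
    mean_dist = nx.average_shortest_path_length(lcc) if lcc.number_of_nodes() > 1 else 0.0
    topology = {
        "n_nodes": nn,
        "n_edges": ne,
        "avg_degree": 2.0 * ne / nn,
        "edge_density": 2.0 * ne / (nn * (nn - 1)) if nn > 1 else 0.0,
        "mean_distance": float(mean_dist),
        "modularity": float(modularity),
    }
    return CooccurrenceNetwork(graph=g, threshold=threshold, modules=modules, topology=topology)


@dataclass
class NodeRole:
    zi: float
    pi: float
    role: str  # "generalist" | "specialist"


def node_roles(net: CooccurrenceNetwork, zi_cut: float = 2.5, pi_cut: float = 0.62) -> dict:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against its module's mean
    and sd (0 when the sd is 0); Pi = 1 - sum_t (k_it / k_i)^2 over modules t.
    Nodes with Zi > ``zi_cut`` or Pi > ``pi_cut`` are generalists (module hubs
    or connectors), the rest specialists.  Isolated nodes are excluded.
    """
    if not net.modules:
        raise ValueError("network has no module assignment")
    g = net.graph
    within = {}
    for node in g.nodes:
        mod = net.modules[node]
        within[node] = sum(1 for nb in g.neighbors(node) if net.modules[nb] == mod)
    by_module: dict[int, list] = {}
    for node, mod in net.modules.items():
        by_module.setdefault(mod, []).append(node)
    roles = {}
    for node in g.nodes:
        k = g.degree(node)
        if k == 0:
            continue
        peers = by_module[net.modules[node]]
        vals = np.array([within[p] for p in peers], dtype=float)
        sd = vals.std()
        zi = float((within[node] - vals.mean()) / sd) if sd > 0 else 0.0
        per_mod: dict[int, int] = {}
        for nb in g.neighbors(node):
            per_mod[net.modules[nb]] = per_mod.get(net.modules[nb], 0) + 1
        pi = 1.0 - sum((c / k) ** 2 for c in per_mod.values())
        role = "generalist" if (zi > zi_cut or pi > pi_cut) else "specialist"
        roles[node] = NodeRole(zi=zi, pi=pi, role=role)
    return roles


def robustness(
    net: CooccurrenceNetwork,
    abundances: pd.Series,
    removal_fraction: float = 0.5,
    n_rep: int = 100,
    survival_threshold: float = 0.5,
    seed: int = 0,
) -> float:
    """Mean surviving-node proportion after random removals plus cascades.

    Per replicate, floor(f * n) nodes are removed uniformly at random.  Each
    remaining node's support is its abundance-weighted sum of positive edge
    strengths; any node whose support falls to <= ``survival_threshold``
    times its original support is removed, iterating until stable.  Returns
    the mean proportion of the original nodes still present.
    """
    if net.is_empty:
        raise ValueError("empty network")
    if not 0.0 < removal_fraction < 1.0:
        raise ValueError("removal_fraction must be in (0, 1)")
    g = net.graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    ab = np.array([float(abundances.get(v, 0.0)) for v in nodes])
    w = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        if data["weight"] > 0:
            w[idx[u], idx[v]] = data["weight"]
            w[idx[v], idx[u]] = data["weight"]
    support0 = w @ ab
    rng = np.random.default_rng(seed)
    n_remove = int(np.floor(removal_fraction * n))
    survivors = []
    for _ in range(n_rep):
        alive = np.ones(n, dtype=bool)
        alive[rng.choice(n, size=n_remove, replace=False)] = False
        while True:
            support = w @ (ab * alive)
            doomed = alive & (support <= survival_threshold * support0 + 1e-12) & (support0 > 0)
            if not doomed.any():
                break
            alive &= ~doomed
        survivors.append(alive.sum() / n)
    return float(np.mean(survivors))


@dataclass
class CohesionProfile:
    """Null-corrected connectedness per taxon and cohesion per sample."""

    connectedness_pos: pd.Series
    connectedness_neg: pd.Series
    cohesion_pos: pd.Series  # >= 0
    cohesion_neg: pd.Series  # <= 0
    corrected: pd.DataFrame | None = None  # null-corrected correlations (diag 0)


def cohesion(
    m: CommunityMatrix, n_null: int = 200, seed: int = 0,
    corrected: pd.DataFrame | None = None,
) -> CohesionProfile:
    """Per-sample positive and negative cohesion from null-corrected correlations.

    Observed pairwise Pearson correlations on relative abundances are
    corrected by a taxa-shuffle null (each taxon's abundances permuted across
    samples independently, ``n_null`` times): corrected r = observed - null
    mean.  A taxon's positive (negative) connectedness is the mean of its
    positive (negative) corrected correlations with all other taxa, and a
    sample's positive (negative) cohesion is the abundance-weighted sum of
    the corresponding connectedness values.

    ``corrected`` bypasses the null entirely (used for worked fixtures).
    """
    if m.n_samples < 5:
        raise ValueError("need >= 5 samples")
    rel = m.relative_abundance()
    x = rel.to_numpy(float)
    if corrected is None:
        if n_null < 1:
            raise ValueError("n_null must be >= 1")
        obs = _pearson(x)
        rng = np.random.default_rng(seed)
        null_sum = np.zeros_like(obs)
        xs = x.copy()
        for _ in range(n_null):
            for j in range(xs.shape[1]):
                xs[:, j] = x[rng.permutation(x.shape[0]), j]
            # renormalize rows so null communities stay compositional and the
            # correction removes the closure bias of relative abundances
            totals = xs.sum(axis=1, keepdims=True)
            null_sum += _pearson(xs / np.where(totals > 0, totals, 1.0))
        corr = obs - null_sum / n_null
    else:
        corr = corrected.loc[m.taxon_ids, m.taxon_ids].to_numpy(float)
    np.fill_diagonal(corr, 0.0)

    pos_mask = corr > 0
    neg_mask = corr < 0
    with np.errstate(invalid="ignore"):
        conn_pos = np.where(
            pos_mask.sum(axis=1) > 0,
            np.where(pos_mask, corr, 0.0).sum(axis=1) / np.maximum(pos_mask.sum(axis=1), 1),
            0.0,
        )
        conn_neg = np.where(
            neg_mask.sum(axis=1) > 0,
            np.where(neg_mask, corr, 0.0).sum(axis=1) / np.maximum(neg_mask.sum(axis=1), 1),
            0.0,
        )
    coh_pos = x @ conn_pos
    coh_neg = x @ conn_neg
    taxa = m.taxon_ids
    return CohesionProfile(
        connectedness_pos=pd.Series(conn_pos, index=taxa),
        connectedness_neg=pd.Series(conn_neg, index=taxa),
        cohesion_pos=pd.Series(coh_pos, index=m.sample_ids),
        cohesion_neg=pd.Series(coh_neg, index=m.sample_ids),
        corrected=pd.DataFrame(corr, index=taxa, columns=taxa),
    )


def _pearson(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    safe = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=0)) / safe
    r = z.T @ z / x.shape[0]
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)
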