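"""Synthetic dairy-cow cohort generator with planted ground truth.

Emulates a herd sampled at three lactation timepoints (DIM -21 / 21 / 50) at
one or two gut sites.  Each site carries a planted enterotype structure: every
animal belongs to one of ``n_enterotypes`` groups, and each group's dominant
genus has its Dirichlet weight multiplied by ``dominant_boost``.  Counts are
Dirichlet-multinomial with a log-normal per-animal random effect shared across
the animal's timepoints, at sequencing depths drawn uniformly from
[depth_min, depth_max].  Host phenotypes follow a linear mediation chain
exposure (enterotype) -> mediator (fermentation parameter) -> outcome
(production/serum trait) with known path coefficients, so downstream
estimators can be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community import CommunityMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_enterotype_communities",
    "simulate_host_phenotypes",
    "simulate_neutral_pool",
    "simulate_filtering_scenario",
    "simulate_dispersal_limited",
]

TIMEPOINTS = ("DIM-21", "DIM21", "DIM50")


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the emulated study scale: 74 animals, 3 timepoints,
    sequencing depth at least 15,307 reads, two enterotypes per site.
    ``dominant_boost`` multiplies the Dirichlet weight of each enterotype's
    dominant genus; ``animal_sd`` is the log-normal scale of the per-animal
    random effect on taxon weights; mediation_a/b/direct are the planted path
    coefficients of the exposure -> mediator -> outcome chain.
    """

    n_animals: int = 74
    n_timepoints: int = 3
    n_taxa: int = 80
    n_enterotypes: int = 2
    dominant_boost: float = 8.0
    base_concentration: float = 50.0
    depth_min: int = 15307
    depth_max: int = 60000
    animal_sd: float = 0.3
    mediation_a: float = 0.5
    mediation_b: float = 0.5
    mediation_direct: float = 0.2
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_min < 1 or self.depth_min > self.depth_max:
            raise ValueError("need 1 <= depth_min <= depth_max")
        if self.n_enterotypes < 2:
            raise ValueError("need >= 2 enterotypes")
        if self.n_taxa <= self.n_enterotypes:
            raise ValueError("need n_taxa > n_enterotypes")
        for name in ("dominant_boost", "base_concentration", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.animal_sd < 0:
            raise ValueError("animal_sd must be nonnegative")
        if self.n_animals < 2 or self.n_timepoints < 1:
            raise ValueError("need >= 2 animals and >= 1 timepoint")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a synthetic cohort."""

    enterotype_of_animal: dict
    dominant_taxon_of_enterotype: dict
    true_effect_taxa: set
    mediation_a: float
    mediation_b: float
    mediation_direct: float
    exposure_enterotype: int = 1

    @property
    def true_acme(self) -> float:
        return self.mediation_a * self.mediation_b

    def to_frame(self) -> pd.DataFrame:
        rows = [("mediation_a", self.mediation_a), ("mediation_b", self.mediation_b),
                ("mediation_direct", self.mediation_direct), ("true_acme", self.true_acme),
                ("exposure_enterotype", self.exposure_enterotype)]
        for a, e in sorted(self.enterotype_of_animal.items()):
            rows.append((f"enterotype:{a}", e))
        for e, t in sorted(self.dominant_taxon_of_enterotype.items()):
            rows.append((f"dominant:{e}", t))
        return pd.DataFrame(rows, columns=["key", "value"])


def simulate_tree(n_taxa: int, seed: int = 0) -> TreeNode:
    """Random rooted binary tree with ``n_taxa`` uniquely named leaves.

    Built by random pairwise coalescence with exponential branch lengths
    (mean 0.06).  Leaf names are ``taxon_001``..; branch lengths are strictly
    positive, and the pairwise leaf distances are rescaled if necessary so
    they straddle 0.2 (the conventional phylogenetic-signal threshold) once
    n_taxa >= 8.
    """
    if n_taxa < 2:
        raise ValueError("need n_taxa >= 2")
    rng = np.random.default_rng(seed)
    names = [f"taxon_{i + 1:03d}" for i in range(n_taxa)]
    nodes = [TreeNode(name=n, length=float(rng.exponential(0.06)) + 1e-3) for n in names]
    # depth of each subtree's root below its eventual parent attachment
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.06)) + 1e-3)
        parent.extend([left, right])
        nodes.append(parent)
    tree = nodes[0]
    tree.length = None

    if n_taxa >= 8:
        dm = tree.tip_tip_distances()
        vals = dm.data[np.triu_indices(n_taxa, 1)]
        lo, hi = vals.min(), vals.max()
        if not lo < 0.2 < hi:
            # rescale so the geometric midpoint of the distance range sits at 0.2
            target = 0.2 / np.sqrt(lo * hi)
            for node in tree.postorder(include_self=False):
                node.length *= target
    return tree


def _base_weights(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[int]]:
    """Skewed baseline taxon weights and the indices of the dominant taxa."""
    u = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_taxa)
    u /= u.sum()
    dominant = list(np.argsort(u)[-cfg.n_enterotypes:][::-1])
    return u, dominant


def simulate_enterotype_communities(
    cfg: SyntheticConfig, site: str = "rumen", seed: int | None = None
) -> tuple[CommunityMatrix, GroundTruth]:
    """Simulate one gut site's count table with planted enterotypes.

    One sample per animal x timepoint.  Animal ``a`` in enterotype ``e`` draws
    per-sample taxon proportions from Dirichlet(alpha_a) where alpha_a is the
    skewed baseline weight vector scaled by ``base_concentration``, the
    dominant taxon of ``e`` boosted by ``dominant_boost``, and a per-animal
    log-normal perturbation (sd ``animal_sd``) shared across timepoints.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    u, dominant_idx = _base_weights(cfg, rng)
    taxa = [f"taxon_{i + 1:03d}" for i in range(cfg.n_taxa)]
    animals = [f"cow_{i + 1:03d}" for i in range(cfg.n_animals)]
    labels = rng.integers(0, cfg.n_enterotypes, size=cfg.n_animals)
    # guarantee every enterotype is populated
    for e in range(cfg.n_enterotypes):
        if not (labels == e).any():
            labels[rng.integers(0, cfg.n_animals)] = e

    timepoints = list(TIMEPOINTS[: cfg.n_timepoints])
    if cfg.n_timepoints > len(TIMEPOINTS):
        timepoints += [f"T{i}" for i in range(len(TIMEPOINTS), cfg.n_timepoints)]

    rows, sample_ids, meta_rows = [], [], []
    for ai, animal in enumerate(animals):
        boost = np.ones(cfg.n_taxa)
        boost[dominant_idx[labels[ai]]] = cfg.dominant_boost
        animal_effect = np.exp(rng.normal(0.0, cfg.animal_sd, size=cfg.n_taxa))
        alpha = cfg.base_concentration * u * boost * animal_effect
        for tp in timepoints:
            p = rng.dirichlet(alpha)
            depth = int(rng.integers(cfg.depth_min, cfg.depth_max + 1))
            rows.append(rng.multinomial(depth, p))
            sample_ids.append(f"{animal}_{site}_{tp}")
            meta_rows.append((animal, tp, site))

    counts = pd.DataFrame(rows, index=sample_ids, columns=taxa, dtype=int)
    metadata = pd.DataFrame(meta_rows, index=sample_ids, columns=["animal", "timepoint", "site"])
    truth = GroundTruth(
        enterotype_of_animal={a: int(e) for a, e in zip(animals, labels)},
        dominant_taxon_of_enterotype={e: taxa[dominant_idx[e]] for e in range(cfg.n_enterotypes)},
        true_effect_taxa={taxa[i] for i in dominant_idx},
        mediation_a=cfg.mediation_a,
        mediation_b=cfg.mediation_b,
        mediation_direct=cfg.mediation_direct,
    )
    return CommunityMatrix(counts, metadata), truth


def simulate_host_phenotypes(
    truth: GroundTruth, cfg: SyntheticConfig, seed: int = 0
) -> pd.DataFrame:
    """Phenotype table realizing the planted mediation chain.

    Per animal x timepoint: exposure X = 1 if the animal belongs to the
    designated enterotype; mediator M = a*X + N(0, noise_sd); outcome
    Y = direct*X + b*M + N(0, noise_sd).
    """
    rng = np.random.default_rng(seed)
    animals = sorted(truth.enterotype_of_animal)
    timepoints = list(TIMEPOINTS[: cfg.n_timepoints])
    rows = []
    for animal in animals:
        x = 1.0 if truth.enterotype_of_animal[animal] == truth.exposure_enterotype else 0.0
        for tp in timepoints:
            m = truth.mediation_a * x + rng.normal(0.0, cfg.noise_sd)
            y = truth.mediation_direct * x + truth.mediation_b * m + rng.normal(0.0, cfg.noise_sd)
            rows.append((animal, tp, x, m, y))
    return pd.DataFrame(rows, columns=["animal", "timepoint", "exposure", "mediator", "outcome"])


# ---------------------------------------------------------------------------
# assembly-process scenarios: planted neutral / selective / dispersal regimes
# ---------------------------------------------------------------------------


def _sample_metadata(sample_ids: list[str], site: str = "rumen") -> pd.DataFrame:
    return pd.DataFrame(
        {"animal": sample_ids, "timepoint": "DIM21", "site": site},
        index=sample_ids,
    )


def simulate_neutral_pool(
    n_samples: int = 15, n_taxa: int = 48, depth: int = 500, seed: int = 0
) -> tuple[CommunityMatrix, TreeNode]:
    """Neutral assembly: every sample is a multinomial draw from one regional
    pool, with no phylogenetic structure in abundances.  The pool is skewed
    (log-normal, sigma 1.5) and the depth moderate so that presence varies
    between samples and the taxa-shuffle null is non-degenerate.  Used to
    calibrate the null models (the selection fraction should stay near the
    nominal rate)."""
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_taxa, seed=seed)
    pool = rng.lognormal(0.0, 1.5, size=n_taxa)
    pool /= pool.sum()
    taxa = [f"taxon_{i + 1:03d}" for i in range(n_taxa)]
    ids = [f"s{i + 1:02d}" for i in range(n_samples)]
    counts = pd.DataFrame(
        rng.multinomial(depth, pool, size=n_samples), index=ids, columns=taxa
    )
    return CommunityMatrix(counts, _sample_metadata(ids)), tree


def _two_clade_tree(n_per_clade: int, seed: int = 0, sub_split: bool = True) -> TreeNode:
    """Balanced two-clade tree: within-clade tip distances < 0.2, between > 0.2.

    With ``sub_split`` each clade itself splits into two tight subclades
    (tips ~0.02 apart within, ~0.15 across), giving the within-bin contrast
    selection scenarios need.  Branch lengths carry a small jitter so
    patristic distances are non-degenerate and taxa-shuffle nulls have
    positive variance.
    """
    rng = np.random.default_rng(seed)

    def tip(n: str) -> str:
        return f"{n}:{rng.uniform(0.005, 0.02):.5f}"

    def clade(names: list[str]) -> str:
        if sub_split:
            half = len(names) // 2
            a = ",".join(tip(n) for n in names[:half])
            b = ",".join(tip(n) for n in names[half:])
            return (
                f"(({a}):{rng.uniform(0.04, 0.08):.5f},"
                f"({b}):{rng.uniform(0.04, 0.08):.5f}):0.4"
            )
        tips = ",".join(tip(n) for n in names)
        return f"({tips}):0.4"

    names = [f"taxon_{i + 1:03d}" for i in range(2 * n_per_clade)]
    nwk = f"({clade(names[:n_per_clade])},{clade(names[n_per_clade:])});"
    return TreeNode.read([nwk], convert_underscores=False)


def _ladder_clade(names: list[str], rng, n_sub: int, sub_size: int, gap: float = 0.022) -> str:
    """Pectinate clade of ``n_sub`` tight subclades along a gradient: tips of
    adjacent subclades sit ~2*gap apart, the two ends ~(n_sub-1)*gap apart."""
    subs = []
    for s in range(n_sub):
        ns = names[s * sub_size : (s + 1) * sub_size]
        tips = ",".join(f"{n}:{rng.uniform(0.003, 0.008):.5f}" for n in ns)
        subs.append(f"({tips}):{rng.uniform(0.008, 0.014):.5f}")
    inner = subs[-1]
    for s in range(n_sub - 2, -1, -1):
        inner = f"({subs[s]},{inner}):{gap:.5f}"
    return f"{inner}:0.4"


def simulate_filtering_scenario(
    n_per_habitat: int = 8,
    n_sub: int = 8,
    sub_size: int = 6,
    occupancy: int = 3,
    depth: int = 2000,
    seed: int = 0,
) -> tuple[CommunityMatrix, TreeNode]:
    """Strong selection: two habitats with opposed phylogenetic optima.

    The tree holds two pectinate clades (one per phylogenetic bin when the
    binning cap is set to the clade size, here ``n_sub * sub_size`` = 48):
    each clade is a ladder of ``n_sub`` tight subclades along a gradient.
    Habitat A selects the first subclade of every clade, habitat B the last,
    and each sample occupies ``occupancy`` random members of its habitat's
    subclade.  Within-habitat pairs are therefore phylogenetically far more
    similar than the within-bin shuffle null (homogeneous selection) and
    across-habitat pairs far more different (heterogeneous selection).
    """
    rng = np.random.default_rng(seed)
    n_per_clade = n_sub * sub_size
    n_taxa = 2 * n_per_clade
    names = [f"taxon_{i + 1:03d}" for i in range(n_taxa)]
    nwk = (
        f"({_ladder_clade(names[:n_per_clade], rng, n_sub, sub_size)},"
        f"{_ladder_clade(names[n_per_clade:], rng, n_sub, sub_size)});"
    )
    tree = TreeNode.read([nwk], convert_underscores=False)
    first_a = list(range(0, sub_size))
    first_b = list(range(n_per_clade, n_per_clade + sub_size))
    last_a = list(range(n_per_clade - sub_size, n_per_clade))
    last_b = list(range(n_taxa - sub_size, n_taxa))
    ids, rows = [], []
    for h, blocks in (("A", (first_a, first_b)), ("B", (last_a, last_b))):
        for s in range(n_per_habitat):
            occ = []
            for blk in blocks:
                occ += list(rng.permutation(blk)[:occupancy])
            w = np.zeros(n_taxa)
            w[occ] = rng.dirichlet(np.full(len(occ), 1.5))
            rows.append(rng.multinomial(depth, w))
            ids.append(f"{h}{s + 1:02d}")
    counts = pd.DataFrame(rows, index=ids, columns=names)
    return CommunityMatrix(counts, _sample_metadata(ids)), tree


def simulate_dispersal_limited(
    n_samples: int = 15, n_per_clade: int = 24, depth: int = 2000, seed: int = 0
) -> tuple[CommunityMatrix, TreeNode]:
    """Dispersal limitation: every sample is monopolized by one founder taxon
    per clade (clades match the default phylogenetic bins), founders distinct
    across samples, so compositional turnover between samples exceeds the
    richness/abundance-preserving null while phylogenetic turnover stays
    null-like (founders are random with respect to within-clade position)."""
    if n_samples > n_per_clade:
        raise ValueError("need n_samples <= n_per_clade for distinct founders")
    rng = np.random.default_rng(seed)
    tree = _two_clade_tree(n_per_clade, seed=seed, sub_split=False)
    n_taxa = 2 * n_per_clade
    taxa = [f"taxon_{i + 1:03d}" for i in range(n_taxa)]
    ids = [f"s{i + 1:02d}" for i in range(n_samples)]
    founders_1 = rng.permutation(n_per_clade)[:n_samples]
    founders_2 = n_per_clade + rng.permutation(n_per_clade)[:n_samples]
    rows = []
    for s in range(n_samples):
        # founder ~90% of its clade; background taxa present at low counts so
        # richness is high and the null assembles even, mutually similar
        # communities that the founder-skewed observations exceed
        w = np.full(n_taxa, 1.2)
        w[founders_1[s]] = 250.0
        w[founders_2[s]] = 250.0
        p = rng.dirichlet(w)
        rows.append(rng.multinomial(depth, p))
    counts = pd.DataFrame(rows, index=ids, columns=taxa)
    return CommunityMatrix(counts, _sample_metadata(ids)), tree
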