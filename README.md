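# enterolink

Statistical toolkit for enterotype-centred analysis of repeated-measures
livestock gut microbiota — written for microbial ecologists who have a
genus-level count table, a phylogeny and per-animal metadata (animal ID,
lactation timepoint, gut site) and want to run the full inference chain that
links community types to ecology and host phenotypes:

1. **Community core** — abundance/prevalence filtering (mean relative
   abundance > 0.01% in ≥ 50% of animals), rarefaction, Shannon entropy,
   Good's coverage, weighted UniFrac, multi-factor PERMANOVA.
2. **Enterotyping** — per-animal averaged profiles, Jensen–Shannon distance
   D(p,q) = √JSD₂(p,q), PAM clustering, Calinski–Harabasz selection of k,
   multi-metric silhouettes, bootstrap stability (adjusted Rand index), and
   between-class taxon weights that name each enterotype by its dominant
   genus; chi-square independence test between the enterotypes of two gut
   sites.
3. **Network ecology** — taxon co-occurrence networks at a correlation
   cutoff selected by random-matrix theory (the GOE→Poisson transition of
   the eigenvalue spacing distribution), topology summaries, Zi/Pi
   generalist–specialist roles, extinction-cascade robustness, and
   per-sample positive/negative cohesion from null-corrected correlations.
4. **Assembly** — phylogenetic-bin null models: abundance-seeded binning
   (distance threshold 0.2, bin size 24), per-pair per-bin βNTI and RC_bray,
   and the five-process partition HeS / HoS / DL / HD / DR with
   abundance-weighted aggregation and permutational t-tests.
5. **Host links** — per-taxon linear mixed models (enterotype × timepoint,
   animal random intercept, Wald χ² with Benjamini–Hochberg FDR) classifying
   taxa as enterotype-individualized vs common, and bi-directional linear
   mediation (ACME = a·b, ADE, bootstrap inference) for
   enterotype → fermentation → phenotype chains.

A first-class synthetic cohort generator plants known enterotype structure,
effect taxa, assembly regimes and mediation coefficients, so every stage is
testable end to end without any sequencing data.

## Worked example

```python
from enterolink import (SyntheticConfig, simulate_enterotype_communities,
                        filter_taxa, fit_enterotypes, enterotype_independence,
                        simulate_host_phenotypes, mediate)
from sklearn.metrics import adjusted_rand_score

# a 74-cow, 3-timepoint, 80-genus cohort with two planted enterotypes
cfg = SyntheticConfig(seed=42)
m, truth = simulate_enterotype_communities(cfg)

model = fit_enterotypes(filter_taxa(m), n_boot=100, seed=7)
planted = [truth.enterotype_of_animal[a] for a in model.assignments.index]
print("optimal k        :", model.k)
print("CH by k          :", {k: round(v, 1) for k, v in model.ch_by_k.items()})
print("ARI vs truth     : %.3f" % adjusted_rand_score(planted, model.assignments.to_numpy()))
print("stability        : %.3f" % model.stability)
print("dominant taxa    :", {int(k): v for k, v in model.dominant_taxon.items()})
```

```
optimal k        : 2
CH by k          : {2: 55.0, 3: 28.7, 4: 19.7, 5: 15.3}
ARI vs truth     : 1.000
stability        : 1.000
dominant taxa    : {0: 'taxon_031', 1: 'taxon_058'}
```

The Calinski–Harabasz index peaks at k = 2, the assignment matches the
planted labels perfectly (adjusted Rand index 1.0), bootstrap stability is
1.0, and between-class analysis names each enterotype by exactly the genus
whose Dirichlet weight the generator boosted.

Testing whether the enterotypes of two gut sites are associated, on a 2×2
cow-count cross-classification:

```python
stat, df, p = enterotype_independence([[15, 12], [18, 29]])
print("chi2=%.3f, df=%d, p=%.3f" % (stat, df, p))
# chi2=2.067, df=1, p=0.151  -> no association at alpha = 0.05
```

And quantifying an exposure → mediator → outcome chain (here with planted
paths a = b = 0.5, direct = 0.2, so the true indirect effect is 0.25):

```python
ph = simulate_host_phenotypes(truth, cfg, seed=1)
res = mediate(ph["exposure"], ph["mediator"], ph["outcome"], n_boot=1000, seed=2)
print("ACME = %.3f (95%% CI %.3f..%.3f, p = %.3f)" % (res.acme, *res.acme_ci, res.acme_p))
print("ADE  = %.3f, total = %.3f, prop. mediated = %.2f" % (res.ade, res.total, res.prop_mediated))
```

```
ACME = 0.173 (95% CI 0.093..0.265, p = 0.002)
ADE  = 0.379, total = 0.553, prop. mediated = 0.31
```

At a single cohort of 74 animals the indirect-effect estimate is noisy but
its 95% interval covers the truth; the point estimate converges to 0.25 as
n grows (see `tests/test_acceptance.py`).

## Command line

Each stage is also exposed as a thin CLI over the library:

```sh
enterolink simulate --n-animals 74 --seed 1 --out-dir cohort/
enterolink enterotype --counts cohort/counts.tsv --metadata cohort/metadata.tsv --out-dir et/
enterolink network --counts cohort/counts.tsv --metadata cohort/metadata.tsv --threshold auto --out-dir net/
enterolink assembly --counts cohort/counts.tsv --metadata cohort/metadata.tsv --tree cohort/tree.nwk --out-dir asm/
enterolink mediate --phenotypes cohort/phenotypes.tsv --out med.tsv
```

All formats are plain text: TSV tables, Newick trees, GraphML networks.

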