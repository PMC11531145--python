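# rootfungi

Statistical analysis of how root-associated fungal communities assemble in
forest soils.  The package asks, for every fungal OTU detected in a set of
root-tip samples: how much of its spatial distribution is explained by
**host-plant filtering (P)**, by the **fungal community structure of the
background soil (S)**, by **spatial autocorrelation (Sp)**, and by residual
**fungus–fungus covariance (Cov)** — and how those contributions differ
between functional guilds (ectomycorrhizal fungi, arbuscular mycorrhizal
fungi, root endophytes, ...).

It is written for community ecologists and microbiome researchers working
with paired root-tip / bulk-soil metabarcoding count tables (samples × OTUs)
plus sample metadata (sampling position, coordinates, host plant genus).

## What is inside

* **Joint species distribution model** (`rootfungi.jsdm`) — a latent-factor
  multivariate probit,

      P(y_is = 1 | u_i) = Φ(x_i'β_s + λ_s'u_i),   u_i ~ N(0, I_r),

  where `y_is` is occurrence of OTU *s* in root sample *i*, the covariates
  x_i hold host-plant dummies, Bray–Curtis PCoA axes of the soil community
  (cumulative contribution ≥ 90 %) and spatial eigenvectors, and the shared
  latent factors u_i carry inter-OTU covariance.  The marginal likelihood is
  maximised by Monte Carlo integration with common random numbers.  All 16
  models of the {P, S, Sp, Cov} lattice are fitted; per-OTU log-likelihood
  ratios between fixed model pairs attribute explanatory power to each
  factor, compared between guilds with Steel–Dwass tests.
* **Host-preference statistics** (`rootfungi.preference`) — Blüthgen's d′
  (standardized Kullback–Leibler specialization, rescaled by its exact
  integer-redistribution bounds), with permutation nulls that shuffle host
  labels only among root samples from the same sampling position, z-scores,
  two-dimensional pair preference, and Benjamini–Hochberg FDR.
* **Habitat and spatial analyses** (`rootfungi.habitat`) — root-vs-soil
  occurrence surfaces, a Poisson GLM with offset linking root occurrence to
  soil relative abundance, and Mantel correlograms of Jaccard β-diversity
  against geographic distance classes.
* **Association networks** (`rootfungi.network`) — sparse + low-rank inverse
  covariance estimation on CLR-transformed un-rarefied counts (latent-variable
  graphical lasso solved by ADMM), BIC selection over 0–20 latent variables,
  signed partial-correlation networks, Louvain modules, and Kendall-τ
  concordance of degree centrality with the jSDM covariance attribution.
* **Core data handling** (`rootfungi.community`, `rootfungi.ordination`) —
  TSV/CSV community-table I/O, read-depth filters, coverage-based
  rarefaction (Chao–Jost sample coverage), accumulation curves, Bray–Curtis /
  Jaccard dissimilarities, PCoA and Moran-style spatial eigenvectors.
* **Synthetic study designs** (`rootfungi.simulate`) — a seeded generator of
  root/soil datasets with known ground truth that emulates the sampling
  design (~124 positions ≥ 4 m apart, several root samples per position with
  host labels, one soil sample per position, guild-specific effect scales,
  overdispersed sequencing depths), plus a Gaussian-copula count generator
  with a known sparse + low-rank precision for network benchmarking.

## Worked example

```python
from rootfungi import (assembly_preset, generate_dataset, prepare_inputs,
                       fit_lattice, attribute_factors)

ds = generate_dataset(assembly_preset(), seed=7)        # ~300 root samples, 40 OTUs
y, designs = prepare_inputs(ds.root, ds.soil, ds.metadata, min_host_samples=30)
lattice = fit_lattice(y, designs, n_factors=2, seed=0, mc_samples=40,
                      eval_mc_samples=400, maxiter=120)
print(lattice.table.head(5)[["model", "log_likelihood"]].to_string(index=False))
```

```
                  model  log_likelihood
Full (P + S + Sp + Cov)    -4729.413601
            P + S + Cov    -4821.887176
             P + S + Sp    -5140.378727
                  P + S    -5246.149966
           S + Sp + Cov    -5325.260601
```

The full model explains the training occurrences best, and the top partial
models all involve fungus–fungus covariance.  Attribution per guild:

```python
import pandas as pd
attr = attribute_factors(lattice, guilds=ds.guilds)
guild = pd.Series(ds.guilds.guild_of(attr.llr.index), index=attr.llr.index)
print(attr.llr.groupby(guild).median().round(1))
```

```
              P     S   Sp   Cov
AMF        50.4  17.7  1.7 -13.7
EcMF        1.8  39.0  1.9 -14.5
Endophyte   5.8  15.1  0.5  13.6
```

Each cell is the guild-median per-OTU log-likelihood ratio for one factor
(P against `S + Sp`, S against `P + Sp`, Sp against `P + S`, all relative to
`P + S + Sp`; Cov is the full model against `P + S + Sp`).  The generator
planted exactly this contrast — host filtering on the AMF-like guild, soil
coupling on the EcMF-like guild, latent-factor covariance on the
endophyte-like guild — and the model attributes it accordingly.  The fitted
full model separates occupied from empty cells with an in-sample AUC of
0.914 (`lattice["Full (P + S + Sp + Cov)"].roc_auc()`).

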