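# phylocomm

Community-phylogenetic analysis of host-associated microbiomes under
transplant designs: phylogenetic ILR balances, crossed-factor PERMANOVA,
repeated-rarefaction richness, independent-swap null models with the net
relatedness index (NRI), and stability-selected discriminating balances —
with a synthetic-data generator that plants known structure so every stage
can be validated end to end.

## The scientific problem

Reciprocal-transplant experiments move hosts (here, eelgrass shoots) among
sites and ask whether their microbiomes track the **destination**
environment or remember their **origin**, how fast the transition happens,
and which ecological process — environmental filtering versus competition
or partitioning — assembles the communities. Answering those questions from
16S amplicon data requires four pieces of machinery, all of which this
package provides for anyone running a factorial microbiome field
experiment:

1. **Compositional geometry.** Amplicon counts are compositions. A rooted
   phylogeny over the ASVs defines a sequential binary partition; the
   balance at internal node *i*, splitting its tips into clades *R* (size
   *r*) and *S* (size *s*), is

   y_i = sqrt(rs/(r+s)) · ln( g(x_R) / g(x_S) ),

   with *g* the geometric mean of relative abundances. With uniform taxon
   weights the balance coordinates are an isometry of the Aitchison
   geometry: Euclidean distance between samples in balance space equals
   their clr-distance.

2. **Multivariate partitioning.** PERMANOVA with sequential (Type-I) sums
   of squares over crossed factors (destination, origin, their
   interaction; or site × transplant status), computed from the
   Gower-centered matrix G as SS(term) = tr((H_m − H_{m−1})G), with free
   permutation of sample labels and exact enumeration on tiny designs.
   Principal coordinates and a betadisper-style dispersion test (distances
   to group centroids, negative-eigenvalue corrected, ANOVA + Tukey HSD)
   accompany it.

3. **Community phylogenetics.** Mean pairwise patristic distance (MPD),
   abundance-weighted or not, compared against an independent-swap null
   (checkerboard swaps preserving sample richness and taxon occurrence
   frequency exactly). NRI = −SES; positive NRI means phylogenetic
   clustering, the signature of environmental filtering.

4. **Which clades moved.** L1-penalized multinomial regression of site
   labels on the balance table, with the cross-validation (fold draw →
   deviance curve → λ at minimum → refit) repeated many times; each
   balance's *selection frequency* across repetitions is the evidence that
   it discriminates sites. Selected nodes are annotated with clade size,
   depth and the lowest shared taxonomic rank, tested for tree placement
   (Welch t on log clade size), and the family sets implicated in two
   tissues are compared with Fisher's exact test.

## Worked example

Simulate one month of a four-site transplant (64 taxa, 4 origins × 4
destinations × 4 replicates, site-graded filtering, three planted
differential clades at fold-change 4), then run the core analyses:

```python
import phylocomm as pc

design = pc.SyntheticDesign(n_taxa=64, samples_per_cell=4, controls_per_cell=0,
                            tissues=("leaf",), timepoints=(1,), seed=42)
bundle, truth = pc.simulate_communities(design)

basis = pc.build_balance_basis(bundle.tree)
y = pc.philr(pc.close_with_pseudocount(bundle.counts), basis)
dm = pc.euclidean_distances(y)
print(pc.permanova(dm, bundle.metadata,
                   ["destination_site", "origin_site", "destination_site:origin_site"],
                   n_perm=999, seed=7).round(3))

res = pc.nri(bundle, n_null=99, n_swaps=1000, seed=7)
print(res.join(bundle.metadata["destination_site"])
         .groupby("destination_site")["nri"].mean().round(2))
```

prints

```
                              df  SumOfSquares     R2       F      p
term
destination_site               3      6330.662  0.378  12.287  0.001
origin_site                    3       516.918  0.031   1.003  0.438
destination_site:origin_site   9      1644.268  0.098   1.064  0.320
Residual                      48      8243.596  0.493     NaN    NaN
Total                         63     16735.443  1.000     NaN    NaN

destination_site
CC   -0.06
DB   -0.01
MM    2.29
WP   -0.40
```

Destination site explains 38% of the balance-space variance (p = 0.001)
while origin explains ~3% and is indistinguishable from noise — the
planted destination effects dominate, as designed. The NRI means recover
the planted filtering gradient: MM, the site simulated with the hardest
trait filter (σ_f = 0.5), is strongly phylogenetically clustered
(mean NRI +2.29) while the weakly filtered sites sit near zero.

The same stages run from the shell via the `phylocomm` CLI
(`simulate`, `validate`, `transform`, `permanova`, `dispersion`,
`richness`, `nri`, `balances`, `run-all`), each accepting a flat INI
config plus flag overrides; `run-all` writes one TSV report bundle whose
tables carry provenance headers and are byte-reproducible from the config
and master seed.

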