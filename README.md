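# phyloimpute

Pick a defensible imputation method for a **mixed-type species-trait
table** — continuous, count, binary and multicategorical traits together —
using a real-data-driven simulation strategy, with optional phylogenetic
information supplied as eigenvectors of a gene tree.

Trait compilations in comparative biology are gappy, and the gaps are
rarely harmless: they concentrate in hard-to-measure traits and
under-sampled clades. Rather than guessing which imputation method to
trust, this package selects one empirically for *your* dataset:

1. **Simulate missingness** in a near-complete subset of the data under
   three mechanisms — MCAR (completely at random, nested proportions
   0.10–0.40), MAR (at random: Bernoulli deletions driven by a logistic
   missingness model fitted to the full gappy compilation) and MNAR (not
   at random: deleting a distribution tail or a whole category).
2. **Impute** every simulated replicate with each candidate method —
   mean/mode, Gower-distance *k*-nearest-neighbour, iterative random
   forests (missForest-style), and MICE with predictive mean matching —
   with and without phylogenetic eigenvectors appended as predictors.
3. **Score** each run on the deliberately masked cells only: mean squared
   error (MSE) for numeric traits, proportion falsely classified (PFC)
   for categorical ones; average over replicates; pick the best-suited
   combination by a **majority vote** across traits, considering MAR
   first and falling back to MNAR then MCAR on ties.
4. **Apply** the winner to the original incomplete table and compare
   summary statistics of the complete-case, original and imputed data.

Phylogenetic structure enters as the leading principal-coordinate axes of
the patristic distance matrix (PVR-style), keeping the smallest set of
axes that explains ≥ 65 % of the positive-eigenvalue variance. Whether a
tree is *worth* adding is quantified per trait by the error ratio

```
error ratio = error without phylogeny / error with phylogeny
```

(> 1 means the tree helped) and by phylogenetic-signal estimators: Pagel's
λ (maximum likelihood on [0, 1]) for continuous traits and Fritz &
Purvis' D (permutation + threshold-Brownian nulls) for binary traits.

## Worked example

Real squamate-scale inputs cannot ship with the package, so the
`synthetic` module generates structurally faithful stand-ins (ultrametric
trees; correlated traits with tunable λ; realistic class imbalance).
`examples/04_impute_and_score.py` masks 20 % of a 100-tip, 7-trait table
with strong signal (λ = 0.9) and scores every method:

```
masked 140 cells; 3 eigenvectors appended

method                        MSE svl  MSE clutch  PFC activity
mean_mode+none                  0.631       0.743         0.450
knn+none                        0.653       0.668         0.750
knn+tree                        0.443       0.391         0.350
rf+none                         0.352       0.581         0.500
rf+tree                         0.354       0.427         0.250
mice+none                       0.380       0.618         0.350
mice+tree                       0.255       0.542         0.150
```

Each MSE is on the natural-log model scale over the masked cells of that
trait; the PFC column is the fraction of masked activity-time cells given
the wrong category. Here every model-based method beats the mean/mode
baseline and appending the tree's eigenvectors helps most combinations —
the pattern the selection strategy exploits. The other scripts in
`examples/` walk through table screening, eigenvector extraction and
signal estimation, the three missingness mechanisms, and the full
vote-and-apply loop.

A thin CLI mirrors the library for shell use:

```sh
phyloimpute synth --n-taxa 120 --outdir synthetic
phyloimpute run-strategy --config run.yaml --seed 1 --outdir results
```

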