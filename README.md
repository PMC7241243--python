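# diffconn

Differential connectivity analysis for feature–feature association
networks, with a permutation significance test and the simulation
machinery needed to study when the test works.

## The problem

In metabolomics (and other omics), features are compared between two
conditions not only by their mean levels but by how their *association
network* rewires. Build a weighted network per group — nodes are
metabolites, edge weights are pairwise association strengths — and ask,
per node, whether its total connectivity changed. The association measure
can be a correlation (Pearson's ρ, Spearman's ρ_S) or mutual information
(MI), estimated on binned data with one of four entropy estimators
(plug-in, Miller–Madow, James–Stein shrinkage, Schurmann–Grassberger).
Which measure detects rewiring more reliably is an empirical question this
package lets you answer by simulation.

## The statistic and its test

For a p × p weighted adjacency A in each group, the connectivity of node
*i* is

    χ_i = Σ_{j≠i} |a_ij|,

the degree in the unweighted case, and the differential connectivity is

    Δχ_i = χ_i^{G1} − χ_i^{G2}.

Significance is assessed with a column-permutation null: every column of
both data matrices is independently shuffled (marginals preserved,
associations destroyed), the permuted Δχ_i is recomputed N_perm times to
form a null sample D_i, and

    P_i = (1 + #{ |D_i| > |Δχ_i| }) / N_perm   (clipped to 1).

Supporting theory connects the measures: for bivariate Gaussian data
MI(ρ) = −½ ln(1−ρ²), which stays below ρ until ρ ≈ 0.916 — one reason
correlation-based networks flag more differentially connected nodes than
MI-based ones at realistic effect sizes — and the no-ties mapping
ρ_S = 6/(π(n+1)) · (arcsin ρ + (n−2) arcsin(ρ/2)) quantifies Spearman's
downward bias.

Data generators included: Toeplitz/AR(1) (ρ^|i−j|), hub, and vine-sampled
"average-ρ" correlation matrices (optionally roughened by the Hardin
unit-vector perturbation) with Gaussian sampling; and a kinetic-ODE
population sampler (a five-species negative-feedback oscillator with
Michaelis–Menten kinetics) in which individuals get ±10 % parameter
jitter and a condition is defined by a global multiplier ε on all rate
constants, Michaelis constants, and initial concentrations.

## Worked example

```python
import numpy as np
from diffconn import DifferentialConnectivity, sample_gaussian, toeplitz_matrix

rng = np.random.default_rng(42)
X1 = sample_gaussian(toeplitz_matrix(6, 0.8), 200, rng)   # correlated condition
X2 = rng.standard_normal((200, 6))                        # uncorrelated condition

model = DifferentialConnectivity(X1, X2, measure="pearson")
res = model.fit(n_perm=1000, alpha=0.05, seed=7)
print(res.summary())
```

```
Differential Connectivity Permutation Test
==========================================================
measure: pearson   n_perm: 1000   alpha: 0.05
features: 6   significant: 6
----------------------------------------------------------
feature            chi_G1   chi_G2    delta        p  sig
V1                  2.823    0.269    2.554   0.0010  *
V2                  3.217    0.377    2.841   0.0010  *
V3                  3.565    0.341    3.224   0.0010  *
V4                  3.455    0.279    3.176   0.0010  *
V5                  3.278    0.314    2.964   0.0010  *
V6                  2.646    0.192    2.454   0.0010  *
==========================================================
```

Each row is one feature: its connectivity in the two groups, the
difference Δχ, and the permutation p-value. Here every node of the
AR(1)-correlated condition is flagged (p = 1/N_perm, the smallest
attainable value) because its connectivity collapses in the uncorrelated
condition. `res.to_frame()` gives the same table as a DataFrame;
`res.adjusted_p_values()` adds optional Benjamini–Hochberg correction.

The same analysis from the shell:

```sh
diffconn run data.csv --group-column status \
    --measure pearson --measure mi:miller_madow --nperm 1000 --seed 7
diffconn simulate corr --kind toeplitz --rho 0.8 --p 20 --n 100 --out sim.csv
diffconn experiment type1 --n 100 --reps 20 --seed 7 --out report.csv
diffconn analytic crossing
```

When two or more measures are requested, `run` also writes an overlap
summary (features significant only under one measure, only under the
other, or under both).

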