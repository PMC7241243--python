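# Methods

## Differential connectivity

Given two samples-by-features matrices X1 (n1 × p) and X2 (n2 × p) over
the same p features, each group is summarised by a weighted association
network A whose entries are Pearson or Spearman correlations, or mutual
information (MI) of the binned data. Node connectivity is
χ_i = Σ_{j≠i} |a_ij| and the statistic of interest is
Δχ_i = χ_i^G1 − χ_i^G2.

Two deliberate readings of the defining formulas:

* χ sums over all partners j ≠ i, not only j > i. A half-triangle sum
  would make χ depend on node ordering and would not reproduce the
  degree interpretation on unweighted networks (a node with six incident
  edges must have χ = 6 regardless of its index). The diagonal never
  contributes; a correlation self-weight of 1 would merely add a constant
  to every node.
* The permutation p-value is P_i = (1 + #{|D_i| > |Δχ_i|}) / N_perm,
  clipped to 1. The count is two-sided on magnitude because Δχ can take
  either sign while the alternative concerns its size; ties count as
  non-exceeding; the denominator is N_perm (not N_perm + 1), so the
  smallest attainable p-value is 1/N_perm and the clipping only affects
  the all-exceed case. Under a continuous null the rejection probability
  at α = 0.05 with N_perm = 200 is 9/201 ≈ 0.045, slightly conservative,
  which is what the type-I-error simulations measure.

The null is built by independently permuting every column of both
groups in each of the N_perm replicates: marginal means, variances, and
full value multisets are preserved exactly while all between-feature
association is destroyed. For the MI measure the column labels (not the
raw values) are permuted — equal-frequency bin labels are a pure function
of value ranks, so this is identical to permuting the data and
re-binning, and it lets one discretization serve all replicates. Given a
seed the whole procedure is deterministic.

No multiple-testing correction is applied by default (reported counts
are raw α-level counts); Benjamini–Hochberg adjustment is available from
the results object.

## Association measures

Pearson and Spearman correlations are the standard sample quantities
(Spearman = Pearson on average ranks, so ties are handled by mid-ranks).
In `association_matrix`, constant features get zero weight against all
partners with a warning instead of aborting — permutation replicates of
near-constant metabolite data must not crash the pipeline.

MI is computed as H(X) + H(Y) − H(X, Y) on discretized data, in nats.
Continuous variables are binned into ⌈n^(1/3)⌉ equal-frequency bins by
default (configurable count and an equal-width alternative); bin edges
sit at empirical quantiles, ties always share a bin, and constant input
collapses to one occupied bin. The same binning is shared by marginal
and joint tabulations, which makes MI(x, x) = H(x) exact for the
plug-in estimator.

Entropy estimators operate on the occupied (nonzero-count) support of
the table, with |x| the number of occupied bins:

* empirical: −Σ (c/n) ln(c/n);
* Miller–Madow: empirical + (|x|−1)/(2n) — an exact offset, used as a
  test identity;
* shrinkage: plug-in entropy of p̂_λ = λ/|x| + (1−λ) p̂ with the
  closed-form James–Stein intensity
  λ* = (1 − Σ p̂²) / ((n−1) Σ (1/|x| − p̂)²), clipped to [0, 1]; a
  degenerate denominator (single occupied bin) maps to λ* = 1, giving
  entropy 0 on one bin as required;
* Schurmann–Grassberger: the Dirichlet-prior formula
  H = 1/(n+|x|N) Σ (c+N)(ψ(n+|x|N+1) − ψ(c+N+1)) with default prior
  weight N = 1/|x|.

Non-plug-in estimators can return slightly negative MI for weakly
dependent pairs; connectivity uses |a_ij|, so this only matters as a
small positive bias common to both groups that the permutation null
absorbs.

All-pairs MI matrices are computed vectorised (joint tables for all
p(p−1)/2 pairs via one bincount, entropies evaluated row-wise), which is
what keeps 200-replicate permutation runs at p = 20, n = 500 in the
sub-second range.

## Correlation-structure generators

All generators return an explicitly validated correlation matrix
(symmetric, unit diagonal, smallest eigenvalue > 1e−10). If a requested
structure is not positive definite, an eigenvalue-clip (at 1e−8) plus
re-normalisation fallback is applied with a warning — never silently.

* Toeplitz/AR(1): entries ρ^|i−j| exactly; positive definite for
  ρ ∈ [0, 1).
* Hub: blocks of sizes (15, 5) by default; within a block of size g the
  hub–member correlation is ρ − ((i−2)/(g−2))^γ (ρ − ρ_min) for member
  i = 2..g, with γ = 2 and ρ_min = 0 defaults; other pairs are zero. The
  raw hub star is only positive definite while the squared hub
  correlations sum below one, so at larger ρ the clip fallback
  necessarily engages; the closed-form entries are exposed separately as
  `hub_correlation` and tested exactly on a PD configuration.
* Hardin perturbation: R + ε(UUᵀ − I) with random unit rows U in
  `edim` dimensions (defaults ε = 0.01, edim = 2); every off-diagonal
  shift is bounded by ε, the diagonal is exactly preserved, and
  positive definiteness is guaranteed for ε < λ_min(R). Experiment code
  skips the perturbation (with a warning) when λ_min is already below ε,
  as happens for Toeplitz ρ ≳ 0.97 at p = 20.
* Vine ("average" model): partial correlations drawn i.i.d. from a Beta
  distribution mapped onto a support interval and assembled by the
  recursive C-vine construction, positive definite by construction.
  `vine_matrix` defaults to support (−1, 1), under which a symmetric
  Beta yields matrices with signed mean correlation zero.

### Calibrating the average correlation

The Beta shapes come from the standard moment inversion
α = μ(μ(1−μ)/σ² − 1), β = α(1/μ − 1) (round-trip tested to 1e−10), with
σ² = 0.1 fixed. `calibrate_mu` inverts the Monte-Carlo map from μ to the
mean absolute off-diagonal correlation (2/(p²−p) Σ_{i>j}|ρ_ij|) by
bracketed root finding, using common random
numbers so the objective is a deterministic function of μ.

Design choice: calibration draws the partial correlations on (0, 1)
rather than (−1, 1). With symmetric-support partials the μ-response is
U-shaped (both Beta extremes produce |partials| near 1), bottoming near
0.45 for p = 20 — targets below that are unreachable and the inverse map
is not monotone. With positive partials the response is monotone
increasing over the admissible μ range and spans average |ρ| ≈ 0.08–0.85,
and the realised matrices are predominantly positive — the natural
reading of an "average correlation ρ" model. The resulting calibrated μ
values at the low end (≈0.11 for target 0.1, ≈0.20 for target 0.4) are
of the magnitude reported for this construction in the literature; at
the high end the calibration saturates near the admissibility boundary
of σ² = 0.1.

## Kinetic population generator

The generator emulates cross-sectional ("snapshot") metabolomics data
from a population of individuals governed by shared nonlinear kinetics:

1. per individual, every rate constant k, Michaelis constant Km, and
   nonzero initial concentration is drawn uniformly from
   [(1−f)·base, (1+f)·base] with f = 0.10;
2. a condition is defined by one global multiplier ε applied to all of
   an individual's parameters (including initial concentrations);
3. each individual's ODE system is integrated (LSODA, rtol 1e−8,
   atol 1e−10 — part of the spec so runs are bit-reproducible) and the
   state at a single shared sampling time t_sample is one row of the
   feature matrix. Tiny negative concentrations from integration error
   are clipped to zero.

The packaged model is a five-species Goodwin-type negative-feedback
oscillator: S5 represses production of S1 through a Hill term
(coefficient 8, repression constant K_inh = 0.3), S1→S2→S3→S4→S5 is a
linear chain (rate 0.3 each), and S5 is removed by a Michaelis–Menten
reaction (Vmax 0.6, Km 0.2) whose near-zero-order saturation sustains a
relaxation limit cycle. Reference initial concentrations are
(1.0, 0.5, 0, 0, 0). Parameters were chosen so that the limit cycle
persists across ε ∈ [1/3, 10] with frequency increasing in ε (detrended
zero crossings over t ∈ [150, 300]: 4, 10, 26, 69 at ε = 1/3, 1, 3, 10)
— faster oscillations under up-scaled kinetics, flattened slow cycles
under down-scaled ones. The default t_sample = 200 lies several periods
past the transient, so individuals' ±10 % period differences spread
them around the cycle and the snapshot inherits strongly nonlinear
cross-sectional associations.

What this generator does **not** emulate: measurement noise, missing
values, non-oscillatory steady-state pathways, and the dimensionality of
a real metabolome (5 species, not dozens). Passing tests show the
pipeline's behaviour on clean, mechanistically correlated data; they do
not certify performance on noisy experimental matrices.

## Experiments

`type1_experiment` (both groups i.i.d. N(0, I)), `power_experiment`
(structured group vs uncorrelated, or vs a second structured draw behind
a flag), and `kinetic_experiment` (ε-perturbed vs ε = 1) sweep grids and
report, per cell, the median significant count and — where both groups
are exchangeable — the empirical type-I rate, in a long-format table
with all strata kept separate. The kinetic grid simulates one pool of
1000 individuals per ε (and one reference pool) and subsamples
replicate data sets from the pools without replacement. All randomness
descends from one master seed. Default grid sizes mirror the simulation
study the package is built around: p = 20, n ∈ {10, 25, 50, 100, 250,
500}, ε ∈ {1/10, 1/5, 1/3, 1/2, 1/1.5, 1, 1.5, 2, 3, 5, 10}, 10
replicates per cell; tests and the acceptance script run reduced grids
(e.g. 3–10 replicates, N_perm = 200) chosen as the smallest sizes at
which the qualitative conclusions are stable.

## Analytic relations

`gaussian_mi` is the closed form −½ ln(1−ρ²). `mi_correlation_crossing`
solves MI(ρ) = ρ on (0.5, 0.99) by Brent bracketing (root 0.91656…).
`spearman_of_pearson` is the no-ties finite-n mapping; its downward bias
ρ − ρ_S(ρ) is maximised numerically by `spearman_bias_argmax`, which in
the large-n limit has the closed-form argmax 2√(1 − 9/π²) ≈ 0.5937. A
commonly quoted location for this maximum is 0.577; the objective is
nearly flat there (the gap differs from its maximum by < 1e−3 for
n ≥ 50), so the function reports the computed argmax and the tests
assert the flatness property rather than either printed constant.

## Known limitations

* The hub structure is returned clipped whenever the requested ρ/block
  sizes make the raw star non-PD; entry-exactness then holds only for
  the closed-form helper, not the realised matrix.
* MI p-values inherit discretization: with very small n the bin count
  ⌈n^(1/3)⌉ is 2–3 and the MI network is coarse.
* The permutation test assumes exchangeability within columns; it does
  not model repeated measures or batch structure.
* The ε = 1 null of the kinetic design is only approximately calibrated
  at small n (both groups share connectivity but the observed Δχ
  fluctuates more than the permuted one on strongly dependent data);
  calibration is good by n = 500, which the acceptance-style test
  checks.
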