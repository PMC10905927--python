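# Methods

This note records the statistical model the package implements, the
numerical choices made along the way, and what the test suite does and
does not establish.

## Problem and model

The data are read counts for $n$ genes measured at $T$ time points in $J$
experimental conditions with $R$ replicates. The goal is to group genes
whose *relative* temporal behaviour is similar across all experiments
simultaneously, treating the (gene × time × experiment) array as the unit
of analysis rather than flattening it to a gene × sample matrix.

**Step 1 — normalised expression profiles.** Counts are depth-corrected by
median-of-ratios size factors $s_{tjr}$ (computed over genes with positive
counts in every sample and rescaled to geometric mean 1). The profile of
gene $i$ in experiment $j$ is

$$p_{itj} = \frac{x_{itj}/s_{tj} + c}{\sum_{t'} x_{it'j}/s_{t'j} + cT},$$

a composition over time ($\sum_t p_{itj} = 1$) after adding a pseudo-count
$c$ (default 1; a half-minimum-positive-count rule is available).
Replicates are averaged on the profile scale.

**Step 2 — log-ratio transform.** Profiles are compositional: only
relative information is meaningful and the unit-sum constraint makes the
usual Euclidean treatment inappropriate. The additive log-ratio (ALR)
transform with the first time point as reference maps each gene and
experiment to $\mathcal{T} = T - 1$ unconstrained coordinates
$z_{itj} = \ln(p_{itj}/p_{i1j})$. CLR and ILR (pivot-coordinate) variants
are provided for diagnostics and cross-checks; ILR is the isometric choice,
ALR is used in the workflow because its coordinates read directly as
"log-change relative to baseline".

**Step 3 — matrix-variate Gaussian mixture.** Each gene is now a
$J \times \mathcal{T}$ matrix $Y_i$. A $K$-component mixture of
matrix-normal distributions $\mathcal{MN}(M_k, \Sigma_k, \Psi_k)$ is
fitted by EM, where $\Sigma_k = \mathrm{diag}(\sigma^2_{k1}, \ldots,
\sigma^2_{kJ})$ captures experiment-specific dispersion and $\Psi_k$ is a
time correlation matrix — either a general correlation or the AR1 form
$\Psi_{ts} = \rho_k^{|t-s|}$. The log-density equals the
$J\mathcal{T}$-dimensional Gaussian of $\mathrm{vec}(Y)$ with covariance
$\Psi_k \otimes \Sigma_k$; the separable structure is the point: at
$J = 2$, $\mathcal{T} = 5$ it needs 18 covariance parameters instead of
the 55 of an unrestricted vectorised covariance. $K$ is selected by the
per-observation ICL (BIC also tabulated), and the AR1 model is fitted by
refining the general fit (initial $\rho$ = mean lag-1 correlation).

**Step 4 — diagnostics.** Separation in the transformed space is measured
by the density-based silhouette information (dbsi): the log-ratio of the
top two posterior probabilities, winsorized into $[10^{-5}, 1-10^{-5}]$
and normalised by the dataset maximum so values lie in $[-1, 1]$.
Compactness in the original space is the Euclidean distance of each
profile to its component mean mapped back through the inverse ALR, scaled
to $[0, 1]$. The cluster map plots one against the other per cluster with
convex hulls; partitions are compared externally by the adjusted Rand
index and contingency tables.

## Defaults and why

| Parameter | Default | Rationale |
|---|---|---|
| pseudo-count $c$ | 1 | keeps zero counts representable; half-min rule available when counts are sparse |
| ALR reference | first (T0) column | baseline interpretation; configurable |
| column structure | `ar1` (CLI) | fewest parameters; general fit used internally for initialisation |
| selection criterion | ICL | favours well-separated partitions; BIC also reported |
| `n_starts` | 10 (library), 2 (study harness) | k-means start plus random hard restarts; the study trades starts for runtime |
| EM `tol` | 1e-8 relative | loglik-change stopping rule |
| winsor bounds | $[10^{-5}, 1-10^{-5}]$ | keeps log-ratios finite for certain assignments |

## Numerical choices

- **Monotone EM under the unit-diagonal constraint.** The natural
  conditional update for a *correlation* $\Psi$ (normalise the weighted
  column cross-product and transfer its geometric-mean scale into
  $\sigma^2$) is a heuristic projection and is not guaranteed to increase
  the likelihood. Every covariance move is therefore subjected to a
  generalised-EM acceptance test: it is kept only if the component's
  $\tau$-weighted log-density does not decrease. To keep the general
  family's optimum above the AR1 sub-family's (nesting), the general
  M-step proposes the AR1 member of the correlation family as an
  additional ascent direction and finishes with an exact $\sigma^2$
  resweep given the accepted $\Psi$. The result: the log-likelihood trace
  is non-decreasing to 1e-8 on every fit, and AR1 refits stay within 1e-6
  of (below) the general fit.
- **AR1 M-step.** $\rho$ is updated by minimising the closed-form profile
  objective $(\mathcal{T}-1)\ln(1-\rho^2) + [s_0 + \rho^2 s_1 - 2\rho
  s_2]/(1-\rho^2)$ derived from the tridiagonal AR1 inverse (three
  precomputed scalars per evaluation), via bounded scalar minimisation on
  $[-0.999, 0.999]$, keeping the previous value if not improved.
- **Criteria scaling.** BIC and ICL are reported per observation
  ($-\ell/n + \nu \ln n / 2n$; ICL adds the mean classification entropy).
  This is a monotone transform of the conventional $-2\ell + \nu\ln n$
  (also reported), so selected $K$ is identical; the per-observation form
  is easier to compare across dataset sizes.
- **Floors and ties.** Variances are floored at 1e-10, $\Psi$ receives a
  1e-10 ridge before factorisation, MAP ties go to the lowest component
  index, and EM starts whose smallest component drops below $J +
  \mathcal{T}$ observations are abandoned and replaced from a bounded
  budget of random restarts.
- **dbsi plot ordering.** Clusters are displayed in decreasing order of a
  chosen per-cluster average width (by default the dbsi itself; classic
  silhouette widths can be supplied).

## The simulation study

`simulate.run_simulation_study` compares four routes on data drawn from a
known 10-component AR1 mixture (769 genes, $J = 2$, $\mathcal{T} = 5$):
three-way clustering with general correlation, three-way with AR1,
a Gaussian mixture with unrestricted covariances on the flattened
10-vector, and k-means with silhouette-based $K$ selection. Each method
selects $K \in \{1..15\}$ (k-means from 2) and is scored by ARI against
the generating labels; 10 datasets are summarised by ARI quartiles and the
modal selected $K$.

The generating model is the package's own choice (no external data ships
with the repository). Its component sizes (26–181 of 769), variance range
(0.08–0.8 across components, compact to noise-like), and AR1 range
(0.15–0.8) were fixed once to produce *moderately overlapping* clusters:
under the true model's own posteriors the average dbsi is ≈ 0.58, i.e.
assignments are informative but far from certain, which is the regime
where covariance structure should matter. Problem sizes (10 datasets
rather than a large replication) keep the full study under 15 minutes on
one CPU.

## What the tests show — and don't

The suite establishes: exact small-case algebra (transform closed forms
and round trips, parameter-count identities, hand-computed dbsi and
silhouette values), agreement of the matrix-normal density with an
independently assembled Kronecker multivariate normal, EM monotonicity
and AR1/general nesting on every fitted trace, parameter recovery on data
simulated from known mixtures, and the qualitative ordering of the four
methods (three-way AR1 above flattened GMM and k-means in median ARI,
modal $K$ closest to the truth) on the scaled-down study.

They do **not** establish: behaviour on real RNA-seq data (the end-to-end
test uses a Poisson-sampled synthetic count fixture), performance at
large replication counts or many more clusters, robustness to gross
model misspecification (e.g. heavy-tailed noise), or any claim about
differential-expression pre-filtering, which is outside the package's
scope (gene lists are accepted as input).

## Limitations

- The ALR reference time point is a modelling choice; coordinates (and
  hence Gaussian fit) are not invariant to it. ILR is provided but the
  mixture workflow operates on ALR coordinates.
- $\Sigma_k$ is diagonal by design; correlated experiments would be
  absorbed into $\Psi_k$ or violate the model.
- The general-correlation M-step is a generalised EM (ascent, not exact
  maximisation); convergence is to a local optimum and multiple starts
  remain important.
- Replicate averaging on the profile scale discards replicate-level
  dispersion; no uncertainty is propagated from Step 1 into the mixture.
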