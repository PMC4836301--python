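# Methods

## Model

The observation unit is the paired difference in methylation beta values,
`theta[i, j] = beta_case - beta_control`, for matched pair i (i = 1..n) and
probe j (j = 1..m). The hierarchy is

```
theta[i, j] ~ Normal(lambda[j] + delta[i], sigma2_eps)
lambda[j]   = beta[j] + Phi[j]
beta[j]     ~ Normal(b_Y, tau2_Y)   (probe in a CpG island)
beta[j]     ~ Normal(b_N, tau2_N)   (probe outside)
delta[i]    ~ Normal(0, tau2_delta)
```

with conjugate hyperpriors: `b_Y, b_N ~ Normal(b_mean, b_var)`, each
`gamma ~ Normal(gamma_mean, gamma_var)`, and inverse-gamma priors on every
variance component. Defaults are deliberately vague — `Normal(0, 10^2)` on
all location hyperparameters and `InvGamma(0.01, 0.01)` on all variances —
and are overridable through `Priors` or a YAML config. They are
conventional reference choices, not calibrated to any particular dataset.

Assumptions worth stating explicitly:

* Gaussian observation noise on theta, although theta is bounded in
  [-1, 1]. At typical effect and noise scales (|effects| <= 0.3, noise SD
  0.05-0.2) boundary mass is negligible; the generator logs any clipping.
* A single shared `sigma2_eps` by default. `ModelSpec(stratified_noise=True)`
  estimates separate CGI / non-CGI noise variances, motivated by the larger
  dispersion of CGI probes; the sampler handles both through one code path
  (sigma2 is carried internally as a per-stratum pair).
* The pair effect `delta[i]` absorbs subject-level heterogeneity left after
  matching. It can be disabled (`include_pair_effect=False`).
* Each probe maps to exactly one gene. Multi-mapping probes are not
  supported; annotate them to a single symbol upstream or drop them.

## Pathway-effect forms

`Phi[j] = sum_k f_k(P_j)` with per-pathway parameters gamma. Forms `a`
(null), `b1`/`b2` (constant, CGI-independent / CGI-split), `c1`/`c2`
(degree-weighted) and `c1_inv`/`c2_inv` (inverse-degree, down-weighting
hubs) are all linear in gamma, so every form shares the same conjugate
machinery. Degrees count distinct neighbor genes in the pathway's
undirected simple graph; a member gene with no recorded interactions has
degree 0, contributing nothing under degree forms (and, by the 0-convention
for 1/E, nothing under inverse-degree forms) while still contributing under
constant forms. A probe whose gene sits in several pathways sums their
contributions. CGI-dependent forms order parameters as all Y-stratum
components first, then all N-stratum components.

## Fitting

The sampler is pure Gibbs — every full conditional is closed-form — with
one essential refinement: the location parameters are drawn as a single
exact block, factored as

1. `(gamma, b_Y, b_N)` with both the probe effects beta and the pair
   effects delta integrated out analytically. The probe means are then
   jointly Gaussian with covariance `diag(tau2_s + sigma2_s/n) +
   (tau2_delta/n) * J`, inverted by Sherman-Morrison.
2. `delta | gamma, b` with beta integrated out; the conditional precision
   has the form `a*I + b*J` and is sampled exactly via its two eigenspaces.
3. `beta | gamma, b, delta` from its ordinary full conditional.

Without this blocking, one-at-a-time updates crawl along the posterior
ridges that connect the pathway effects, the stratum base levels, and the
mean pair effect, and the chain can report a biased lambda surface at any
feasible run length. With it, default chains (12,000 iterations, 2,000
burn-in, thinning 5, 2 chains) mix well; split R-hat is available via
`gelman_rubin`, and small studies fit in seconds.

Correctness is tested three independent ways: a closed-form conjugate
posterior for gamma in a fixed-variance single-pathway toy (itself verified
against brute-force quadrature), a Geweke-style successive-conditional
simulation whose parameter draws must reproduce the prior marginals
(Kolmogorov-Smirnov distance below 0.08 on every component), and
parameter-recovery runs on simulated studies with known truth.

Numerical choices: per-sweep cost is O(m*p + n + m) after precomputing
stratum-wise row/column sums and Gram matrices, so chain length is cheap.
Prior-draw initialization clips variance draws into [1e-4, 10] and scales
location-draw SDs to at most 1 — vague inverse-gamma draws can be
astronomically large and would start chains at numerically absurd states;
the stationary distribution is unaffected. A `zeros` initialization exists
for debugging. Any parameter can be held fixed via `MCMCConfig.fixed`,
which is how the toy models and oracle checks are constructed.

## Model comparison and decisions

DIC = D-bar + p_D, with D-bar the mean per-draw deviance and
p_D = D-bar - D(posterior means). Negative p_D, a known DIC pathology, is
flagged but reported. `rank_models` orders forms by DIC; forms within a
configurable indifference margin (default 2) of the minimum are treated as
ties, resolved in favor of fewer pathway parameters. Note that the free
probe effects absorb constant pathway shifts almost entirely, so DIC
separates nested constant forms only weakly; it discriminates clearly when
the data carry a real topology (degree) signal.

Pathway decisions use `P(gamma_k > 0 | theta)` (strictly positive draws;
exact zeros count for neither side) and the score of strength
`2*|P - 0.5|`. Probe/gene decisions use `P(lambda_j > 0)` and
`P(lambda_j < 0)` computed from the sampled lambda vectors stored with the
draws, flagged at a threshold of 0.975 by default; the comparison is `>=`
(at Monte-Carlo resolution the distinction from a strict inequality is
immaterial). A gene is called a DMG when any of its probes is flagged
(`gene_rule="any"`; an `"all"` option exists), and genes with probes
flagged in both directions carry both labels.

## Matching and preprocessing

`match_pairs` is greedy nearest-age matching: cases sorted by age, each
assigned the eligible control (strict `|age gap| < caliper`, exact equality
on requested covariates, control reused at most `max_cases_per_control`
times) with the smallest gap, ties broken by lexicographic control id —
deterministic by construction. Greedy matching is not guaranteed optimal in
the total-gap sense; it was chosen for reproducibility and because caliper
feasibility, not gap minimization, defines the design. Constraints are
re-asserted on every constructed pairing. Quality-control steps beyond
matching are reduced to two documented hooks, both off by default:
per-sample median-centering and dropping probes with missing paired
differences (always logged). The paired-t + Bonferroni baseline
(`paired_t_baseline`) reports per-probe t statistics with the per-test
threshold `alpha / m`; zero-variance probes get p = 1 and a degenerate
flag. `cgi_dispersion_summary` provides the descriptive CGI check: pooled
stratum moments plus a Welch test on probe-level mean theta.

## Synthetic studies

The generator emulates the structure of an array-based matched study:

* K overlapping pathways (default 3 x 16 genes, 20% shared between
  consecutive sets) with Erdős–Rényi intra-set edges (default p = 0.15);
* 10 background genes outside every pathway; their probes carry all-zero
  membership rows. Background probes anchor the CGI-stratum base levels
  b_Y/b_N, which in a panel where every gene belongs to a candidate set are
  identified only through inter-pathway overlap — a genuine limitation of
  candidate-panel designs worth knowing about;
* 1-5 probes per gene (uniform), CGI probability 0.76;
* truth scales: b_Y = b_N = 0, tau_Y = 0.2, tau_N = 0.05 (CGI probes
  disperse more), noise SD 0.1, pair-effect SD 0.05, n = 50 pairs; effect
  sizes up to |gamma| = 0.3. Theta is clipped to [-1, 1] with the count
  recorded in the emitted truth.

Defaults were chosen once as a realistic small candidate-panel study and
give ~150 probes — large enough to exercise multi-membership, topology,
orphan probes, and both CGI strata, small enough that a full fit takes
about a second. What the generator does **not** emulate: genomic
coordinates and probe spatial correlation, array batch effects and
normalization artifacts, non-Gaussian beta-difference noise near the
boundaries, and missingness patterns. Passing recovery tests on this
generator therefore demonstrates correctness of the inference machinery
under the stated model, not robustness to those real-data features.

## Statistical behavior worth knowing

Under the vague default gamma prior, the posterior sign probability of a
truly null pathway parameter is approximately uniform across replicate
studies (it is a posterior tail probability at a point the likelihood
centers on). Consequently ~5% of null sign probabilities look "decisive" at
the 0.975/0.025 level and ~20% fall outside (0.1, 0.9) — users should treat
mid-range probabilities as indifference, not weak evidence, and can tighten
the gamma prior when genuine shrinkage is wanted.

## Limitations

* Exact priors, chain lengths, and initialization used by any particular
  published analysis are generally unavailable; defaults here are
  documented reference choices.
* The Gaussian likelihood ignores the [-1, 1] bound on theta; severe
  boundary pile-up (very large effects or noise) would need a truncated or
  transformed model.
* One gene per probe; no cross-pathway "network of networks" topology —
  each pathway's graph is used in isolation.
* DIC's weak separation of nested constant forms means model choice between
  `b1`/`b2` and `a` often rests on the parsimony rule rather than a clear
  deviance gap; this mirrors the behavior of such models on real panels.
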