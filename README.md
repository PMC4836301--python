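# cgiset

Bayesian gene-set analysis of differential DNA methylation for matched
case-control studies, with CpG-island (CGI) aware priors and pathway
topology.

## The problem

Array- or sequencing-based methylation studies compare beta values
(methylated / total signal, in [0, 1]) between cases and matched controls
across candidate pathways. Two features of such data are usually ignored by
gene-set tools: probes inside CpG islands behave differently (larger
dispersion, distinct baseline) from probes outside them, and genes inside a
pathway are not exchangeable — a hub gene connected to many neighbors may
matter more (or, for ancient hubs, less) than a peripheral one. `cgiset`
implements a hierarchical Bayesian model that addresses both at once and
ranks candidate pathways by posterior probability rather than p-value.

## The model

For matched pair *i* and probe *j*, the observed paired difference is

```
theta_ij ~ Normal(mu_ij, sigma2_eps),   mu_ij = lambda_j + delta_i
lambda_j = beta_j + Phi_j
beta_j   ~ Normal(b_Y, tau2_Y)  if probe j is in a CGI
beta_j   ~ Normal(b_N, tau2_N)  otherwise
delta_i  ~ Normal(0, tau2_delta)        (pair random effect, optional)
```

The pathway effect `Phi_j = sum_k f_k(P_j)` sums over the K candidate
pathways and takes one of several forms, where `I[j,k]` indicates membership
of probe j's gene in pathway k and `E[j,k]` is that gene's degree (number of
neighbor genes) in pathway k's undirected interaction graph:

| form     | f_k(P_j)                                  | interpretation |
|----------|-------------------------------------------|----------------|
| `a`      | 0                                         | null effect |
| `b1`     | `I[j,k] * gamma_k`                        | constant effect |
| `b2`     | `I[j,k] * gamma_k^{Y or N}`               | CGI-dependent constant |
| `c1`     | `E[j,k] * gamma_k`                        | degree-weighted |
| `c2`     | `E[j,k] * gamma_k^{Y or N}`               | CGI-dependent degree |
| `c1_inv` | `(1/E[j,k]) * gamma_k`                    | inverse-degree (hub down-weight) |
| `c2_inv` | `(1/E[j,k]) * gamma_k^{Y or N}`           | CGI-dependent inverse-degree |

All layers are conjugate (normal / inverse-gamma), so the model is fitted by
a blocked Gibbs sampler with exact full conditionals — no tuning. Forms are
compared by DIC with a parsimony tie-break. Decisions come from posterior
sign probabilities:

* `P(gamma_k > 0 | theta)` near 1 means pathway k's genes tend to be
  hypermethylated in cases, near 0 hypomethylated; the **score of
  strength** `2 * |P - 0.5|` rescales the distance from indifference to
  [0, 1] for ranking.
* A probe with `P(lambda_j > 0)` or `P(lambda_j < 0)` at or above a Bayesian
  posterior probability threshold (default 0.975) is a methylation-variable
  probe; any gene carrying one is a **differentially methylated gene
  (DMG)**, reported with its direction(s).

The package also provides age-caliper matching (strict `|age difference| <
caliper`, optional exact covariates, one-to-many control reuse), the
paired-t + Bonferroni single-marker baseline, CGI dispersion diagnostics,
and a fully seeded synthetic-study generator with ground truth.

## Worked example

```python
import cgiset as cg

study = cg.simulate_study(cg.ModelSpec(form="b2"), seed=42,
                          gamma=[0.3, 0.0, -0.3, 0, 0, 0])
cfg = cg.MCMCConfig(n_iter=6000, n_burnin=1000, thin=2, n_chains=2, seed=7)
samples = cg.run_gibbs(study.theta, study.spec, cg.Priors(),
                       study.features, cfg)
print(cg.pathway_report(samples).round(3).to_string(index=False))
```

```
pathway_id stratum form  p_positive  score_of_strength  post_mean  ci_low  ci_high
      PW01       Y   b2       1.000              1.000      0.323   0.227    0.419
      PW02       Y   b2       0.263              0.474     -0.029  -0.115    0.057
      PW03       Y   b2       0.000              1.000     -0.309  -0.395   -0.220
      PW01       N   b2       0.392              0.215     -0.005  -0.046    0.036
      PW02       N   b2       0.646              0.292      0.008  -0.034    0.049
      PW03       N   b2       0.493              0.014     -0.001  -0.051    0.050
```

The generating truth had a CGI-stratum effect of +0.3 in pathway PW01, -0.3
in PW03, and no effect anywhere else: the report recovers both signs with
sign probabilities 1.0 and 0.0 (scores of strength 1.0), leaves the null
pathway and all non-CGI strata near indifference, and the 95% credible
intervals cover the true values. `cg.compute_dic(...)` and
`cg.rank_models(...)` compare alternative forms; `cg.call_dmps_dmgs(...)`
flags probes and genes (in this synthetic study the CGI probe effects are
deliberately dispersed, so most probes are genuinely methylation-variable).

The same workflow is available from the shell:

```sh
cgiset simulate --out-dir study --seed 42 --form b2 --gamma 0.3,0,-0.3,0,0,0
cgiset fit --theta study/theta.tsv --annotation study/annotation.tsv \
    --gmt study/pathways.gmt --edges study/edges.tsv \
    --forms a,b1,b2 --out-dir results --seed 7
```

`fit` writes a DIC table, pathway / probe / gene reports, stored draws, and
a run manifest sufficient to reproduce the job. `cgiset match`,
`prepare-theta`, and `baseline` cover the preprocessing path from raw beta
matrices and sample metadata.

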