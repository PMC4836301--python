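"""Decision quantities from posterior samples.

Pathway level: P(gamma_k > 0 | theta) ranks pathways — values near 1 mean the
pathway's genes tend to be hypermethylated in cases, near 0 hypomethylated.
The "score of strength" rescales the distance from indifference,
2*|P - 0.5|, into [0, 1]. Probe/gene level: a probe is methylation-variable
when P(lambda_j > 0) or P(lambda_j < 0) reaches a Bayesian posterior
probability threshold (default 0.975); a gene with any flagged probe is a
differentially methylated gene (DMG), reported with its direction(s).
Model forms are compared by DIC with a parsimony tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PairedDifferenceMatrix, ProbeAnnotation
from .errors import ValidationError
from .gibbs import PosteriorSamples
from .model import FORM_PARAM_MULT, ModelSpec, ParameterState, deviance, design_matrix
from .topology import ProbeFeatures


def posterior_sign_probability(draws) -> float:
    """Fraction of draws strictly greater than zero."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValidationError("need at least one draw")
    return float(np.mean(draws > 0.0))


def posterior_negative_probability(draws) -> float:
    """Fraction of draws strictly less than zero (exact zeros count for neither)."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValidationError("need at least one draw")
    return float(np.mean(draws < 0.0))


def score_of_strength(p: float) -> float:
    """2 * |p - 0.5|: 0 at indifference, 1 at a sure sign either way."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"probability must be in [0, 1], got {p}")
    return 2.0 * abs(p - 0.5)


def pathway_report(samples: PosteriorSamples, ci: float = 0.95) -> pd.DataFrame:
    """One row per pathway parameter: sign probability, score, mean, CI.

    CGI-dependent forms yield two rows per pathway (strata Y and N)."""
    if not 0 < ci < 1:
        raise ValidationError("ci must be in (0, 1)")
    lo_q, hi_q = 50 * (1 - ci), 100 - 50 * (1 - ci)
    rows = []
    pooled = samples.pooled("gamma")
    for i, label in enumerate(samples.gamma_labels):
        pid, _, stratum = label.partition(":")
        draws = pooled[:, i]
        p_pos = posterior_sign_probability(draws)
        lo, hi = np.percentile(draws, [lo_q, hi_q])
        rows.append(
            {
                "pathway_id": pid,
                "stratum": stratum or "all",
                "form": samples.spec.form,
                "p_positive": p_pos,
                "score_of_strength": score_of_strength(p_pos),
                "post_mean": float(draws.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(
        rows, columns=["pathway_id", "stratum", "form", "p_positive",
                       "score_of_strength", "post_mean", "ci_low", "ci_high"],
    )


def call_dmps_dmgs(samples: PosteriorSamples, annotation: ProbeAnnotation,
                   threshold: float = 0.975, gene_rule: str = "any"):
    """Flag methylation-variable probes and differentially methylated genes.

    A probe is flagged when P(lambda_j > 0) >= threshold (hyper) or
    P(lambda_j < 0) >= threshold (hypo). A gene is a DMG when ``gene_rule``
    of its probes are flagged ("any", the default, or "all"); genes with
    probes in both directions carry both labels.

    Returns ``(probe_report, gene_report)`` DataFrames.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValidationError("threshold must be in (0.5, 1]")
    if gene_rule not in ("any", "all"):
        raise ValidationError(f"unknown gene_rule {gene_rule!r}")
    gene_of = dict(zip(annotation.probe_ids, annotation.gene_symbols))
    missing = [p for p in samples.probe_ids if p not in gene_of]
    if missing:
        raise ValidationError(f"annotation does not cover probes: {missing[:5]}")
    lam = samples.pooled("lam")
    p_pos = (lam > 0.0).mean(axis=0)
    p_neg = (lam < 0.0).mean(axis=0)
    hyper = p_pos >= threshold
    hypo = p_neg >= threshold
    probe_df = pd.DataFrame(
        {
            "probe_id": list(samples.probe_ids),
            "gene_symbol": [gene_of[p] for p in samples.probe_ids],
            "p_lambda_positive": p_pos,
            "p_lambda_negative": p_neg,
            "methylation_variable": hyper | hypo,
            "direction": np.where(hyper, "hyper", np.where(hypo, "hypo", "-")),
        }
    )
    gene_rows = []
    for gene, grp in probe_df.groupby("gene_symbol", sort=True):
        dirs = grp["direction"]
        if gene_rule == "any":
            has_hyper = bool((dirs == "hyper").any())
            has_hypo = bool((dirs == "hypo").any())
        else:
            has_hyper = bool((dirs == "hyper").all())
            has_hypo = bool((dirs == "hypo").all())
        direction = "-"
        if has_hyper and has_hypo:
            direction = "hyper+hypo"
        elif has_hyper:
            direction = "hyper"
        elif has_hypo:
            direction = "hypo"
        gene_rows.append(
            {
                "gene_symbol": gene,
                "n_probes": len(grp),
                "n_flagged": int(grp["methylation_variable"].sum()),
                "dmg": direction != "-",
                "direction": direction,
            }
        )
    gene_df = pd.DataFrame(
        gene_rows, columns=["gene_symbol", "n_probes", "n_flagged", "dmg", "direction"]
    )
    return probe_df, gene_df


@dataclass(frozen=True)
class DicResult:
    dic: float
    p_d: float
    mean_deviance: float
    deviance_at_mean: float
    negative_p_d: bool


def compute_dic(samples: PosteriorSamples, theta: PairedDifferenceMatrix,
                spec: ModelSpec, features: ProbeFeatures) -> DicResult:
    """Deviance information criterion: DIC = D-bar + p_D.

    D-bar is the mean per-draw deviance; p_D = D-bar - D(posterior-mean
    parameters). A negative p_D (a known DIC pathology under strong
    nonlinearity or multimodality) is flagged with a warning but reported.
    """
    d_bar = float(samples.pooled("deviance").mean())
    state = ParameterState(
        beta=samples.pooled("beta").mean(axis=0),
        gamma=samples.pooled("gamma").mean(axis=0),
        b_Y=float(samples.pooled("b_Y").mean()),
        b_N=float(samples.pooled("b_N").mean()),
        tau2_Y=float(samples.pooled("tau2_Y").mean()),
        tau2_N=float(samples.pooled("tau2_N").mean()),
        sigma2_eps=np.array([
            float(samples.pooled("sigma2_Y").mean()),
            float(samples.pooled("sigma2_N").mean()),
        ]),
        delta=(samples.pooled("delta").mean(axis=0)
               if samples.delta is not None else None),
        tau2_delta=(float(samples.pooled("tau2_delta").mean())
                    if samples.tau2_delta is not None else None),
    )
    X = design_matrix(spec, features)
    lam = state.beta + (X @ state.gamma if X.shape[1] else 0.0)
    mu = np.tile(lam, (theta.n_pairs, 1))
    if spec.include_pair_effect and state.delta is not None:
        mu = mu + state.delta[:, None]
    d_hat = deviance(theta, mu, state.sigma2_eps, cgi=features.cgi,
                     stratified=True)  # per-probe sigma2 is exact either way
    p_d = d_bar - d_hat
    if p_d < 0:
        warnings.warn(f"negative p_D ({p_d:.3f}) — known DIC pathology")
    return DicResult(dic=d_bar + p_d, p_d=p_d, mean_deviance=d_bar,
                     deviance_at_mean=d_hat, negative_p_d=p_d < 0)


def rank_models(dics: dict, n_pathways: int | None = None,
                margin: float = 2.0):
    """Order model forms by DIC; near-ties go to the smaller model.

    ``dics`` maps form name -> DIC. Forms whose DIC is within ``margin`` of
    the minimum are candidates; the candidate with the fewest pathway
    parameters wins (parsimony), ties broken by DIC then name. With
    ``margin=0`` the strict minimum is selected.

    Returns ``(ordered, selected)`` where ordered is a list of (form, DIC)
    ascending.
    """
    if len(dics) < 2:
        raise ValidationError("rank_models needs at least two forms")
    unknown = sorted(set(dics) - set(FORM_PARAM_MULT))
    if unknown:
        raise ValidationError(f"unknown model forms: {unknown}")
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    ordered = sorted(dics.items(), key=lambda kv: (kv[1], kv[0]))
    best = ordered[0][1]
    if margin == 0:
        candidates = [ordered[0]]
    else:
        candidates = [(f, d) for f, d in ordered if d - best < margin]
    selected = min(candidates, key=lambda kv: (FORM_PARAM_MULT[kv[0]], kv[1], kv[0]))[0]
    return ordered, selected
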