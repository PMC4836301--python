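"""Synthetic study generator with ground truth for recovery testing.

Emulates the structure of an array-based matched case-control methylation
study: overlapping gene sets with Erdős–Rényi intra-set topology, genes
carrying 1–10 probes, ~76% of probes inside CpG islands, and paired beta
differences drawn from the hierarchical model itself. Default scales —
CGI probe-effect SD 0.2 vs 0.05 outside CGIs, observation noise SD 0.1,
pair-effect SD 0.05, |gamma| <= 0.3 — keep theta well inside [-1, 1] so
clipping is rare (the clip count is logged and recorded in the truth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .containers import (
    GROUP_CASE,
    GROUP_CONTROL,
    BetaMatrix,
    PairedDifferenceMatrix,
    Pathway,
    PathwayCollection,
    ProbeAnnotation,
    SampleMetadata,
)
from .errors import ValidationError
from .model import ModelSpec, gamma_labels
from .topology import ProbeFeatures, assemble_features

logger = logging.getLogger(__name__)

#: generator defaults: stratum base levels, probe-effect variances
#: (CGI probes disperse more), observation noise, and pair-effect variance
DEFAULT_TRUTH_PARAMS = {
    "b_Y": 0.0,
    "b_N": 0.0,
    "tau2_Y": 0.04,     # SD 0.2 for CGI probes
    "tau2_N": 0.0025,   # SD 0.05 outside CGIs
    "sigma2_eps": 0.01,  # observation noise SD 0.1
    "tau2_delta": 0.0025,  # pair-effect SD 0.05
}


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters behind one simulated theta matrix."""

    form: str
    gamma: tuple
    gamma_labels: tuple
    b_Y: float
    b_N: float
    tau2_Y: float
    tau2_N: float
    sigma2_eps: float
    tau2_delta: float | None
    beta: tuple
    lam: tuple
    delta: tuple | None
    seed: int
    n_clipped: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def simulate_pathways(K: int, genes_per_pathway: int, overlap_fraction: float = 0.0,
                      edge_prob: float = 0.2, seed: int = 0) -> PathwayCollection:
    """K gene sets with Erdős–Rényi intra-set edges.

    ``overlap_fraction`` of each pathway's genes are shared with the previous
    pathway (rounded to a count), so multi-membership occurs as in curated
    pathway databases.
    """
    if not 0.0 <= edge_prob <= 1.0:
        raise ValidationError("edge_prob must be in [0, 1]")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValidationError("overlap_fraction must be in [0, 1)")
    if K < 1 or genes_per_pathway < 1:
        raise ValidationError("need K >= 1 and genes_per_pathway >= 1")
    rng = np.random.default_rng([seed, 101])
    n_shared = int(round(overlap_fraction * genes_per_pathway))
    next_gene = 0
    prev_genes: tuple = ()
    pathways = []
    for k in range(K):
        shared = prev_genes[-n_shared:] if (k > 0 and n_shared) else ()
        fresh = tuple(
            f"G{next_gene + i:04d}" for i in range(genes_per_pathway - len(shared))
        )
        next_gene += len(fresh)
        genes = tuple(shared) + fresh
        graph = nx.gnp_random_graph(
            len(genes), edge_prob, seed=int(rng.integers(2**31 - 1))
        )
        edges = tuple((genes[a], genes[b]) for a, b in graph.edges())
        pathways.append(Pathway(f"PW{k + 1:02d}", f"simulated pathway {k + 1}", genes, edges))
        prev_genes = genes
    return PathwayCollection(tuple(pathways))


def simulate_probes(pathways: PathwayCollection, probes_per_gene_range=(1, 10),
                    cgi_prob: float = 0.76, seed: int = 0,
                    extra_genes=()) -> ProbeAnnotation:
    """Probes for every member gene: count uniform in range, CGI ~ Bernoulli.

    ``extra_genes`` adds genes outside every pathway (their probes get
    all-zero membership rows downstream); such background probes anchor the
    CGI-stratum base levels, which are otherwise identified only through
    inter-pathway overlap.
    """
    lo, hi = probes_per_gene_range
    if lo < 1 or hi < lo:
        raise ValidationError("probes_per_gene_range bounds must satisfy 1 <= lo <= hi")
    if not 0.0 <= cgi_prob <= 1.0:
        raise ValidationError("cgi_prob must be in [0, 1]")
    rng = np.random.default_rng([seed, 202])
    probe_ids, genes, cgi = [], [], []
    i = 0
    for gene in tuple(pathways.all_genes) + tuple(extra_genes):
        for _ in range(int(rng.integers(lo, hi + 1))):
            probe_ids.append(f"cg{i:06d}")
            genes.append(gene)
            cgi.append(bool(rng.random() < cgi_prob))
            i += 1
    return ProbeAnnotation(tuple(probe_ids), tuple(genes), np.array(cgi, dtype=bool))


def simulate_theta(features: ProbeFeatures, spec: ModelSpec, n_pairs: int,
                   seed: int = 0, gamma=None, **params):
    """Draw a theta matrix from the generative model.

    ``gamma`` defaults to zeros (null pathway effects); other parameters
    default to :data:`DEFAULT_TRUTH_PARAMS` and can be overridden by keyword
    (b_Y, b_N, tau2_Y, tau2_N, sigma2_eps, tau2_delta). theta is clipped to
    [-1, 1]; the clip count is logged and stored in the returned truth.

    Returns ``(PairedDifferenceMatrix, SimulationTruth)``.
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    unknown = sorted(set(params) - set(DEFAULT_TRUTH_PARAMS))
    if unknown:
        raise ValidationError(f"unknown truth parameters: {unknown}")
    pars = {**DEFAULT_TRUTH_PARAMS, **params}
    from .model import pathway_effect  # local import avoids cycle at module load

    p = spec.n_gamma(features.n_pathways)
    gamma = np.zeros(p) if gamma is None else np.asarray(gamma, dtype=float).ravel()
    if gamma.shape[0] != p:
        raise ValidationError(f"gamma must have {p} components for form {spec.form!r}")
    rng = np.random.default_rng([seed, 303])
    m = features.n_probes
    beta = np.where(
        features.cgi,
        rng.normal(pars["b_Y"], np.sqrt(pars["tau2_Y"]), size=m),
        rng.normal(pars["b_N"], np.sqrt(pars["tau2_N"]), size=m),
    )
    lam = beta + pathway_effect(spec, features, gamma)
    if spec.include_pair_effect:
        delta = rng.normal(0.0, np.sqrt(pars["tau2_delta"]), size=n_pairs)
    else:
        delta = np.zeros(n_pairs)
    theta = lam[None, :] + delta[:, None] + rng.normal(
        0.0, np.sqrt(pars["sigma2_eps"]), size=(n_pairs, m)
    )
    n_clipped = int(((theta < -1.0) | (theta > 1.0)).sum())
    if n_clipped:
        logger.info("clipped %d theta value(s) into [-1, 1]", n_clipped)
        theta = np.clip(theta, -1.0, 1.0)
    pdm = PairedDifferenceMatrix(
        pair_ids=tuple(f"pair{i + 1:03d}" for i in range(n_pairs)),
        probe_ids=features.probe_ids,
        theta=theta,
    )
    truth = SimulationTruth(
        form=spec.form, gamma=tuple(float(g) for g in gamma),
        gamma_labels=gamma_labels(spec, features.pathway_ids),
        b_Y=pars["b_Y"], b_N=pars["b_N"], tau2_Y=pars["tau2_Y"],
        tau2_N=pars["tau2_N"], sigma2_eps=pars["sigma2_eps"],
        tau2_delta=pars["tau2_delta"] if spec.include_pair_effect else None,
        beta=tuple(map(float, beta)), lam=tuple(map(float, lam)),
        delta=tuple(map(float, delta)) if spec.include_pair_effect else None,
        seed=seed, n_clipped=n_clipped,
    )
    return pdm, truth


@dataclass(frozen=True)
class SyntheticStudy:
    pathways: PathwayCollection
    annotation: ProbeAnnotation
    features: ProbeFeatures
    theta: PairedDifferenceMatrix
    truth: SimulationTruth
    spec: ModelSpec


def simulate_study(spec: ModelSpec, K: int = 3, genes_per_pathway: int = 16,
                   overlap_fraction: float = 0.2, edge_prob: float = 0.15,
                   probes_per_gene_range=(1, 5), cgi_prob: float = 0.76,
                   n_pairs: int = 50, seed: int = 0, gamma=None,
                   background_genes: int = 10, **params) -> SyntheticStudy:
    """End-to-end bundle: topology + probes + features + theta + truth.

    The default study — 3 pathways of 16 genes with 20% overlap plus 10
    background genes outside every set (~50 genes, ~150 probes at 1–5
    probes per gene), 50 pairs — is small enough for minutes-scale MCMC
    while exercising multi-membership, topology, and orphan probes.
    """
    pathways = simulate_pathways(K, genes_per_pathway, overlap_fraction, edge_prob, seed)
    n_member = len(pathways.all_genes)
    extra = tuple(f"G{9000 + i:04d}" for i in range(background_genes))
    annotation = simulate_probes(pathways, probes_per_gene_range, cgi_prob, seed,
                                 extra_genes=extra)
    features = assemble_features(annotation, pathways)
    theta, truth = simulate_theta(features, spec, n_pairs, seed, gamma=gamma, **params)
    return SyntheticStudy(pathways, annotation, features, theta, truth, spec)


def simulate_matched_cohort(n_cases: int = 30, n_controls: int = 30, m_probes: int = 80,
                            cgi_prob: float = 0.76, effect_sd: float = 0.05,
                            ethnicities=("A", "B"), seed: int = 0):
    """Unmatched cohort with beta matrices, for exercising the matching path.

    Controls get baseline beta values; cases get the same baselines shifted
    by a per-probe effect, so downstream matching + differencing has signal.
    Returns ``(metadata, case_beta, control_beta, annotation)``.
    """
    import pandas as pd

    rng = np.random.default_rng([seed, 404])
    probe_ids = tuple(f"cg{i:06d}" for i in range(m_probes))
    genes = tuple(f"G{i // 2:04d}" for i in range(m_probes))
    cgi = rng.random(m_probes) < cgi_prob
    annotation = ProbeAnnotation(probe_ids, genes, cgi)
    base = rng.uniform(0.15, 0.85, size=m_probes)
    effect = rng.normal(0.0, effect_sd, size=m_probes)

    def _samples(prefix, count, shift):
        ids, ages, eth, cols = [], [], [], []
        for i in range(count):
            ids.append(f"{prefix}{i + 1:03d}")
            ages.append(int(rng.integers(40, 76)))
            eth.append(str(rng.choice(ethnicities)))
            noise = rng.normal(0.0, 0.03, size=m_probes)
            cols.append(np.clip(base + shift + noise, 0.0, 1.0))
        return ids, ages, eth, np.column_stack(cols)

    case_ids, case_ages, case_eth, case_vals = _samples("case", n_cases, effect)
    ctrl_ids, ctrl_ages, ctrl_eth, ctrl_vals = _samples("ctrl", n_controls, 0.0)
    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": case_ids + ctrl_ids,
                "group": [GROUP_CASE] * n_cases + [GROUP_CONTROL] * n_controls,
                "age": case_ages + ctrl_ages,
                "ethnicity": case_eth + ctrl_eth,
            }
        )
    )
    return (
        metadata,
        BetaMatrix(probe_ids, tuple(case_ids), case_vals),
        BetaMatrix(probe_ids, tuple(ctrl_ids), ctrl_vals),
        annotation,
    )


def write_study(study: SyntheticStudy, out_dir) -> dict:
    """Write the full io bundle; byte-identical for identical seeds."""
    from . import io as io_formats

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "theta": io_formats.write_theta_matrix(study.theta, out_dir / "theta.tsv"),
        "annotation": io_formats.write_probe_annotation(
            study.annotation, out_dir / "annotation.tsv"
        ),
        "gmt": io_formats.write_gmt(study.pathways, out_dir / "pathways.gmt"),
        "edges": io_formats.write_edge_list(study.pathways, out_dir / "edges.tsv"),
    }
    truth_path = out_dir / "truth.yaml"
    study.truth.to_yaml(truth_path)
    paths["truth"] = truth_path
    return paths
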