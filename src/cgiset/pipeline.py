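"""End-to-end orchestration: inputs -> features -> fits -> DIC -> reports.

Single entry point :func:`run_analysis` used by the CLI ``fit`` command.
The run manifest (YAML) echoes the full configuration, the seed, and every
file written, so a job can be re-run from the manifest alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as io_formats
from .errors import ValidationError
from .gibbs import MCMCConfig, run_gibbs, save_samples
from .inference import call_dmps_dmgs, compute_dic, pathway_report, rank_models
from .model import ModelSpec, Priors
from .containers import ProbeAnnotation
from .topology import assemble_features

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    theta_path: str
    annotation_path: str
    gmt_path: str
    edges_path: str
    out_dir: str
    forms: tuple = ("a", "b1", "b2")
    include_pair_effect: bool = True
    stratified_noise: bool = False
    priors: Priors = field(default_factory=Priors)
    n_iter: int = 12_000
    n_burnin: int = 2_000
    thin: int = 5
    n_chains: int = 2
    seed: int = 0
    dmg_threshold: float = 0.975
    dic_margin: float = 2.0
    save_draws: bool = True

    def __post_init__(self):
        self.forms = tuple(self.forms)
        if not self.forms:
            raise ValidationError("at least one model form is required")
        for name in ("theta_path", "annotation_path", "gmt_path", "edges_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"input file does not exist: {p}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["priors"] = self.priors.to_dict()
        d["forms"] = list(self.forms)
        return d


@dataclass
class RunResult:
    selected_form: str
    dic_table: pd.DataFrame
    pathway_report: pd.DataFrame
    probe_report: pd.DataFrame
    gene_report: pd.DataFrame
    output_paths: dict
    samples_by_form: dict


def _subset_annotation(annotation: ProbeAnnotation, probe_ids) -> ProbeAnnotation:
    lookup = {p: i for i, p in enumerate(annotation.probe_ids)}
    missing = [p for p in probe_ids if p not in lookup]
    if missing:
        raise ValidationError(f"annotation does not cover theta probes: {missing[:5]}")
    idx = [lookup[p] for p in probe_ids]
    return ProbeAnnotation(
        tuple(probe_ids),
        tuple(annotation.gene_symbols[i] for i in idx),
        annotation.cgi[idx],
    )


def run_analysis(config: RunConfig) -> RunResult:
    """Fit every requested form, rank by DIC, report on the selected form."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load inputs"
    try:
        theta = io_formats.read_theta_matrix(config.theta_path)
        annotation = io_formats.read_probe_annotation(config.annotation_path)
        membership = io_formats.read_gmt(config.gmt_path)
        pathways = io_formats.read_edge_list(config.edges_path, membership)
        annotation = _subset_annotation(annotation, theta.probe_ids)
        stage = "assemble features"
        features = assemble_features(annotation, pathways)

        samples_by_form, dic_rows = {}, []
        for i, form in enumerate(config.forms):
            stage = f"fit form {form}"
            spec = ModelSpec(
                form=form,
                include_pair_effect=config.include_pair_effect,
                stratified_noise=config.stratified_noise,
            )
            mcmc = MCMCConfig(
                n_iter=config.n_iter, n_burnin=config.n_burnin, thin=config.thin,
                n_chains=config.n_chains, seed=config.seed + i,
            )
            logger.info("fitting form %s (seed %d)", form, mcmc.seed)
            samples = run_gibbs(theta, spec, config.priors, features, mcmc)
            dic = compute_dic(samples, theta, spec, features)
            samples_by_form[form] = samples
            dic_rows.append(
                {"form": form, "dic": dic.dic, "p_d": dic.p_d,
                 "mean_deviance": dic.mean_deviance, "negative_p_d": dic.negative_p_d}
            )

        stage = "model ranking"
        dics = {r["form"]: r["dic"] for r in dic_rows}
        if len(dics) >= 2:
            ordered, selected = rank_models(dics, margin=config.dic_margin)
        else:
            selected = config.forms[0]
            ordered = list(dics.items())
        dic_table = pd.DataFrame(dic_rows).sort_values("dic", kind="stable").reset_index(drop=True)
        dic_table["selected"] = dic_table["form"] == selected

        stage = "reports"
        best = samples_by_form[selected]
        pw_report = pathway_report(best)
        probe_rep, gene_rep = call_dmps_dmgs(
            best, annotation, threshold=config.dmg_threshold
        )
        run_summary = {
            "selected_form": selected,
            "dic_ranking": [[f, float(d)] for f, d in ordered],
            "seed": config.seed,
            "n_iter": config.n_iter,
            "n_burnin": config.n_burnin,
            "thin": config.thin,
            "n_chains": config.n_chains,
            "dmg_threshold": config.dmg_threshold,
            "dic_margin": config.dic_margin,
            "n_pairs": theta.n_pairs,
            "n_probes": theta.n_probes,
            "n_pathways": len(pathways),
        }
        paths = io_formats.write_reports(pw_report, probe_rep, run_summary,
                                         out_dir, gene_report=gene_rep)
        dic_path = out_dir / "dic.tsv"
        dic_table.to_csv(dic_path, sep="\t", index=False)
        paths["dic"] = dic_path
        if config.save_draws:
            draws_path = out_dir / f"samples_{selected}.npz"
            save_samples(best, draws_path)
            paths["samples"] = draws_path

        stage = "manifest"
        from importlib.metadata import version as _pkg_version

        try:
            pkg_version = _pkg_version("cgiset")
        except Exception:  # not installed, e.g. running from a checkout
            pkg_version = "unknown"
        manifest = {
            "package": {"name": "cgiset", "version": pkg_version},
            "config": config.to_dict(),
            "outputs": {k: str(v) for k, v in paths.items()},
        }
        manifest_path = out_dir / "run_manifest.yaml"
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        paths["manifest"] = manifest_path
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return RunResult(
        selected_form=selected, dic_table=dic_table, pathway_report=pw_report,
        probe_report=probe_rep, gene_report=gene_rep,
        output_paths=paths, samples_by_form=samples_by_form,
    )
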