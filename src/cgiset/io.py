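"""Delimited-text readers and writers for the study bundle.

Formats
-------
beta / theta matrices
    TSV, first column probe id, remaining columns sample (or pair) ids.
    Missing values are written as ``NA``.
probe annotation
    TSV with columns ``probe_id``, ``gene_symbol``, ``cgi_status`` (0/1).
gene-set membership
    Standard GMT: ``pathway_id<TAB>description<TAB>gene1<TAB>gene2...``.
pathway topology
    Three-column TSV ``pathway_id  gene_a  gene_b`` listing undirected edges;
    GMT cannot carry edges, so topology travels in its own file.
reports / run summary
    TSV tables plus a YAML run summary.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    BetaMatrix,
    PairedDifferenceMatrix,
    Pathway,
    PathwayCollection,
    ProbeAnnotation,
    SampleMetadata,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

NA_VALUE = "NA"


def _read_matrix_frame(path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file does not exist: {path}")
    df = pd.read_csv(
        path, sep=delimiter, index_col=0, dtype=str, na_values=[NA_VALUE],
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    # locate non-numeric cells precisely before converting
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    return num


def read_beta_matrix(path, delimiter: str = "\t", clip_tol: float = 0.0) -> BetaMatrix:
    """Read a probes x samples beta-value matrix.

    ``clip_tol`` permits values straying outside [0, 1] by at most that much
    (e.g. machine epsilon after upstream arithmetic); they are clipped back.
    Anything farther out is a hard error.
    """
    num = _read_matrix_frame(path, delimiter)
    vals = num.to_numpy(dtype=float)
    if clip_tol > 0:
        with np.errstate(invalid="ignore"):
            within = (vals >= -clip_tol) & (vals <= 1.0 + clip_tol)
        out_of_band = ~np.isnan(vals) & ~within
        if out_of_band.any():
            r, c = np.argwhere(out_of_band)[0]
            raise ValidationError(
                f"beta value {vals[r, c]} outside [0, 1] beyond clip tolerance "
                f"at probe {num.index[r]!r}, sample {num.columns[c]!r}"
            )
        vals = np.clip(vals, 0.0, 1.0)
    return BetaMatrix(tuple(num.index), tuple(map(str, num.columns)), vals)


def write_beta_matrix(beta: BetaMatrix, path, delimiter: str = "\t") -> Path:
    path = Path(path)
    beta.to_frame().to_csv(path, sep=delimiter, na_rep=NA_VALUE, index_label="probe_id")
    return path


def read_theta_matrix(path, delimiter: str = "\t") -> PairedDifferenceMatrix:
    """Read a theta matrix (rows = probes, columns = pair ids)."""
    num = _read_matrix_frame(path, delimiter)
    return PairedDifferenceMatrix(
        pair_ids=tuple(map(str, num.columns)),
        probe_ids=tuple(num.index),
        theta=num.to_numpy(dtype=float).T,
    )


def write_theta_matrix(theta: PairedDifferenceMatrix, path, delimiter: str = "\t") -> Path:
    path = Path(path)
    theta.to_frame().to_csv(path, sep=delimiter, na_rep=NA_VALUE, index_label="probe_id")
    return path


def read_probe_annotation(path, delimiter: str = "\t") -> ProbeAnnotation:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file does not exist: {path}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in ("probe_id", "gene_symbol", "cgi_status"):
        if col not in df.columns:
            raise ValidationError(f"annotation file missing column {col!r}: {path}")
    raw = df["cgi_status"].str.strip().str.lower()
    mapping = {"0": False, "1": True, "true": True, "false": False}
    bad = sorted(set(raw) - set(mapping))
    if bad:
        raise ValidationError(f"cgi_status must be 0/1, got {bad} in {path}")
    return ProbeAnnotation(
        probe_ids=tuple(df["probe_id"]),
        gene_symbols=tuple(df["gene_symbol"]),
        cgi=raw.map(mapping).to_numpy(),
    )


def write_probe_annotation(annotation: ProbeAnnotation, path, delimiter: str = "\t") -> Path:
    path = Path(path)
    annotation.to_frame().to_csv(path, sep=delimiter, index=False)
    return path


def read_sample_metadata(path, delimiter: str = "\t") -> SampleMetadata:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file does not exist: {path}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    return SampleMetadata(df)


def write_sample_metadata(metadata: SampleMetadata, path, delimiter: str = "\t") -> Path:
    path = Path(path)
    metadata.table.to_csv(path, sep=delimiter, index=False)
    return path


def read_gmt(path):
    """Parse a GMT file into ``[(pathway_id, description, genes), ...]``.

    Genes are deduplicated preserving first occurrence. Lines with fewer than
    three fields, empty gene lists, and repeated pathway ids are errors.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file does not exist: {path}")
    out = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"GMT line {lineno} has {len(fields)} field(s); "
                    f"expected id, description, genes...: {path}"
                )
            pid, desc, *genes = fields
            genes = tuple(dict.fromkeys(g for g in genes if g.strip()))
            if not genes:
                raise ValidationError(f"GMT line {lineno}: pathway {pid!r} has no genes")
            if pid in seen:
                raise ValidationError(f"GMT line {lineno}: duplicate pathway id {pid!r}")
            seen.add(pid)
            out.append((pid, desc, genes))
    return out


def write_gmt(pathways: PathwayCollection, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.description or "-", *p.genes]) + "\n")
    return path


def read_edge_list(path, membership, delimiter: str = "\t") -> PathwayCollection:
    """Combine GMT membership with a 3-column undirected edge file.

    ``membership`` is the output of :func:`read_gmt`. Edges are deduplicated
    regardless of orientation; pathways with no edge rows keep an empty edge
    set (all their genes isolated, degree 0). Edges naming a non-member gene,
    self-edges, and unknown pathway ids are errors.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file does not exist: {path}")
    members = {pid: set(genes) for pid, _, genes in membership}
    edges: dict[str, set] = {pid: set() for pid in members}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) != 3:
                raise ValidationError(
                    f"edge file line {lineno}: expected 3 columns, got {len(fields)}"
                )
            pid, a, b = (f.strip() for f in fields)
            if pid not in members:
                raise ValidationError(f"edge file line {lineno}: unknown pathway id {pid!r}")
            if a == b:
                raise ValidationError(f"edge file line {lineno}: self-edge on {a!r}")
            for g in (a, b):
                if g not in members[pid]:
                    raise ValidationError(
                        f"edge file line {lineno}: gene {g!r} is not a member of "
                        f"pathway {pid!r}"
                    )
            edges[pid].add((a, b) if a < b else (b, a))
    return PathwayCollection(
        tuple(
            Pathway(pid, desc, genes, tuple(sorted(edges[pid])))
            for pid, desc, genes in membership
        )
    )


def write_edge_list(pathways: PathwayCollection, path, delimiter: str = "\t") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for p in pathways:
            for a, b in p.edges:
                fh.write("\t".join([p.pathway_id, a, b]) + "\n")
    return path


def write_reports(pathway_report: pd.DataFrame, probe_report: pd.DataFrame,
                  run_summary: dict, out_dir, gene_report: pd.DataFrame | None = None):
    """Write the report bundle; returns the mapping of report name -> path.

    Column order is preserved as given (deterministic), floats use pandas'
    shortest round-trip representation, and the run summary is YAML.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / "probe_report.tsv"
        pathway = out_dir / "pathway_report.tsv"
        summary = out_dir / "run_summary.yaml"
        pathway_report.to_csv(pathway, sep="\t", index=False, na_rep=NA_VALUE)
        probe_report.to_csv(probe, sep="\t", index=False, na_rep=NA_VALUE)
        paths = {"pathway_report": pathway, "probe_report": probe, "run_summary": summary}
        if gene_report is not None:
            gpath = out_dir / "gene_report.tsv"
            gene_report.to_csv(gpath, sep="\t", index=False, na_rep=NA_VALUE)
            paths["gene_report"] = gpath
        with open(summary, "w") as fh:
            yaml.safe_dump(run_summary, fh, sort_keys=True)
    except OSError as exc:
        raise ValidationError(f"cannot write reports to {out_dir}: {exc}") from exc
    return paths


def read_report(path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, na_values=[NA_VALUE], keep_default_na=False)


def read_run_summary(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
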