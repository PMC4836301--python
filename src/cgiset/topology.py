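"""Per-probe pathway features: membership indicators, degrees, inverse degrees.

For probe j with gene G_j, the model consumes
  I[j, k]  — 1 iff G_j belongs to pathway k (a gene may sit in several),
  E[j, k]  — number of distinct neighbor genes of G_j inside pathway k
             (undirected simple graph; isolated member genes have E = 0),
  1/E[j,k] — inverse degree, with the convention 0 where E = 0.
All probes of the same gene share identical feature rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import PathwayCollection, ProbeAnnotation
from .errors import ValidationError


@dataclass(frozen=True)
class ProbeFeatures:
    probe_ids: tuple
    gene_symbols: tuple
    pathway_ids: tuple
    membership: np.ndarray  # (m, K) int8
    degree: np.ndarray      # (m, K) int
    inv_degree: np.ndarray  # (m, K) float
    cgi: np.ndarray         # (m,) bool
    orphan_probes: tuple = ()  # probes whose gene is in no pathway

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)


def build_membership(annotation: ProbeAnnotation, pathways: PathwayCollection):
    """Binary m x K matrix of probe-in-pathway indicators.

    Returns ``(membership, orphan_probes)`` where orphans are probes whose
    gene belongs to no pathway (all-zero rows, flagged but kept).
    """
    member_sets = [set(p.genes) for p in pathways]
    m = annotation.n_probes
    mat = np.zeros((m, len(pathways.pathways)), dtype=np.int8)
    for j, gene in enumerate(annotation.gene_symbols):
        for k, members in enumerate(member_sets):
            if gene in members:
                mat[j, k] = 1
    orphans = tuple(
        p for p, row in zip(annotation.probe_ids, mat) if not row.any()
    )
    return mat, orphans


def compute_degree(pathways: PathwayCollection) -> dict:
    """Gene-level degree per pathway: ``{pathway_id: {gene: n_neighbors}}``.

    Counts distinct neighbors in the pathway's undirected simple graph;
    member genes touched by no edge have degree 0. The handshake lemma
    (sum of degrees = 2 x edge count) is asserted for every pathway.
    """
    out = {}
    for p in pathways:
        neighbors = {g: set() for g in p.genes}
        for a, b in p.edges:
            neighbors[a].add(b)
            neighbors[b].add(a)
        deg = {g: len(nb) for g, nb in neighbors.items()}
        if sum(deg.values()) != 2 * p.n_edges:
            raise AssertionError(
                f"handshake lemma violated in pathway {p.pathway_id!r}"
            )
        out[p.pathway_id] = deg
    return out


def assemble_features(annotation: ProbeAnnotation,
                      pathways: PathwayCollection) -> ProbeFeatures:
    """Build the full per-probe feature block the model consumes."""
    membership, orphans = build_membership(annotation, pathways)
    degrees = compute_degree(pathways)
    m, K = membership.shape
    deg = np.zeros((m, K), dtype=int)
    for j, gene in enumerate(annotation.gene_symbols):
        for k, p in enumerate(pathways.pathways):
            if membership[j, k]:
                deg[j, k] = degrees[p.pathway_id][gene]
    if ((deg > 0) & (membership == 0)).any():
        raise ValidationError("degree assigned to a non-member probe")
    inv = np.zeros((m, K), dtype=float)
    np.divide(1.0, deg, out=inv, where=deg > 0)
    return ProbeFeatures(
        probe_ids=annotation.probe_ids,
        gene_symbols=annotation.gene_symbols,
        pathway_ids=pathways.ids,
        membership=membership,
        degree=deg,
        inv_degree=inv,
        cgi=annotation.cgi.copy(),
        orphan_probes=orphans,
    )
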