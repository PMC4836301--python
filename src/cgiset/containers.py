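"""In-memory containers for the study bundle.

Every container validates its own invariants on construction, so downstream
code (matching, topology, the sampler) can assume structurally sound inputs.
All identifier comparisons are case-sensitive exact string matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

GROUP_CASE = "case"
GROUP_CONTROL = "control"


def _check_unique(ids, what: str) -> None:
    seen: dict[str, int] = {}
    dupes = []
    for x in ids:
        if x in seen:
            dupes.append(x)
        seen[x] = 1
    if dupes:
        raise ValidationError(f"duplicate {what}: {sorted(set(dupes))}")


@dataclass(frozen=True)
class BetaMatrix:
    """Methylation beta values, probes x samples, each value in [0, 1] or NaN."""

    probe_ids: tuple
    sample_ids: tuple
    values: np.ndarray  # shape (m_probes, n_samples)

    def __post_init__(self):
        object.__setattr__(self, "probe_ids", tuple(str(p) for p in self.probe_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        _check_unique(self.probe_ids, "probe ids")
        _check_unique(self.sample_ids, "sample ids")
        if vals.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta matrix shape {vals.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere((vals < 0) | (vals > 1))
            r, c = bad[0]
            raise ValidationError(
                f"beta value {vals[r, c]} outside [0, 1] at probe "
                f"{self.probe_ids[r]}, sample {self.sample_ids[c]}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.probe_ids), columns=list(self.sample_ids)
        )

    def sample_column(self, sample_id: str) -> np.ndarray:
        try:
            idx = self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"sample id not in beta matrix: {sample_id!r}")
        return self.values[:, idx]


@dataclass(frozen=True)
class SampleMetadata:
    """One row per sample: id, case/control label, age, optional covariates."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group", "age")

    def __post_init__(self):
        df = self.table.reset_index(drop=True).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"sample metadata missing column {col!r}")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample ids in metadata")
        bad_group = sorted(set(df["group"]) - {GROUP_CASE, GROUP_CONTROL})
        if bad_group:
            raise ValidationError(
                f"group labels must be '{GROUP_CASE}' or '{GROUP_CONTROL}', got {bad_group}"
            )
        df["age"] = pd.to_numeric(df["age"], errors="raise").astype(float)
        if (df["age"] < 0).any():
            raise ValidationError("negative age in sample metadata")
        object.__setattr__(self, "table", df)

    @property
    def covariate_names(self) -> tuple:
        return tuple(c for c in self.table.columns if c not in self.REQUIRED)

    def subset(self, group: str) -> pd.DataFrame:
        return self.table[self.table["group"] == group]


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe -> gene symbol and CpG-island status (True = probe lies in a CGI)."""

    probe_ids: tuple
    gene_symbols: tuple
    cgi: np.ndarray  # boolean, length m

    def __post_init__(self):
        object.__setattr__(self, "probe_ids", tuple(str(p) for p in self.probe_ids))
        object.__setattr__(self, "gene_symbols", tuple(str(g) for g in self.gene_symbols))
        cgi = np.asarray(self.cgi, dtype=bool)
        object.__setattr__(self, "cgi", cgi)
        _check_unique(self.probe_ids, "probe ids in annotation")
        if not (len(self.probe_ids) == len(self.gene_symbols) == cgi.shape[0]):
            raise ValidationError("annotation columns have inconsistent lengths")
        empty = [p for p, g in zip(self.probe_ids, self.gene_symbols) if not g.strip()]
        if empty:
            raise ValidationError(f"empty gene symbol for probes {empty}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": list(self.probe_ids),
                "gene_symbol": list(self.gene_symbols),
                "cgi_status": self.cgi.astype(int),
            }
        )


def _normalize_edge(a: str, b: str):
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class Pathway:
    """A gene set with undirected, simple edges among its member genes."""

    pathway_id: str
    description: str
    genes: tuple
    edges: tuple = ()

    def __post_init__(self):
        genes = tuple(dict.fromkeys(str(g) for g in self.genes))  # dedup, keep order
        if not genes:
            raise ValidationError(f"pathway {self.pathway_id!r} has no genes")
        members = set(genes)
        norm = []
        for a, b in self.edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValidationError(
                    f"self-edge {a!r} in pathway {self.pathway_id!r}"
                )
            for g in (a, b):
                if g not in members:
                    raise ValidationError(
                        f"edge endpoint {g!r} is not a member of pathway "
                        f"{self.pathway_id!r}"
                    )
            norm.append(_normalize_edge(a, b))
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "edges", tuple(sorted(set(norm))))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class PathwayCollection:
    """Ordered list of pathways; a gene may belong to several of them."""

    pathways: tuple

    def __post_init__(self):
        pws = tuple(self.pathways)
        _check_unique([p.pathway_id for p in pws], "pathway ids")
        object.__setattr__(self, "pathways", pws)

    @property
    def ids(self) -> tuple:
        return tuple(p.pathway_id for p in self.pathways)

    @property
    def all_genes(self) -> tuple:
        out: dict[str, None] = {}
        for p in self.pathways:
            for g in p.genes:
                out.setdefault(g)
        return tuple(out)

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)


@dataclass(frozen=True)
class Pairing:
    """Matched case-control pairs plus the constraints they were built under."""

    pairs: tuple  # of (case_id, control_id)
    caliper: float
    exact_on: tuple = ()
    max_cases_per_control: int = 1
    unmatched_cases: tuple = ()

    def __post_init__(self):
        pairs = tuple((str(a), str(b)) for a, b in self.pairs)
        cases = [a for a, _ in pairs]
        _check_unique(cases, "case ids in pairing")
        from collections import Counter

        ctrl_use = Counter(b for _, b in pairs)
        over = {c: n for c, n in ctrl_use.items() if n > self.max_cases_per_control}
        if over:
            raise ValidationError(
                f"controls used more than max_cases_per_control={self.max_cases_per_control}: {over}"
            )
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "exact_on", tuple(self.exact_on))
        object.__setattr__(self, "unmatched_cases", tuple(str(u) for u in self.unmatched_cases))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def pair_ids(self) -> tuple:
        return tuple(f"{a}|{b}" for a, b in self.pairs)


@dataclass(frozen=True)
class PairedDifferenceMatrix:
    """Paired beta differences theta[i, j] = beta_case - beta_control, in [-1, 1]."""

    pair_ids: tuple
    probe_ids: tuple
    theta: np.ndarray  # shape (n_pairs, m_probes)

    def __post_init__(self):
        object.__setattr__(self, "pair_ids", tuple(str(p) for p in self.pair_ids))
        object.__setattr__(self, "probe_ids", tuple(str(p) for p in self.probe_ids))
        th = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", th)
        _check_unique(self.pair_ids, "pair ids")
        _check_unique(self.probe_ids, "probe ids in theta")
        if th.shape != (len(self.pair_ids), len(self.probe_ids)):
            raise ValidationError(
                f"theta shape {th.shape} inconsistent with "
                f"{len(self.pair_ids)} pairs x {len(self.probe_ids)} probes"
            )
        finite = th[~np.isnan(th)]
        if finite.size and (finite.min() < -1.0 or finite.max() > 1.0):
            raise ValidationError("theta values must lie in [-1, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        """Disk orientation: rows = probes, columns = pair ids."""
        return pd.DataFrame(
            self.theta.T, index=list(self.probe_ids), columns=list(self.pair_ids)
        )
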