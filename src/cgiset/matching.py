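"""Matched-pair construction, paired differences, and descriptive baselines.

The matching design mirrors age-caliper case-control studies: each case is
paired with a control whose age differs by strictly less than the caliper
(3 years in a typical array study; 5 years with exact ethnicity matching in
a small sequencing study, where one control may serve several cases).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import (
    GROUP_CASE,
    GROUP_CONTROL,
    BetaMatrix,
    PairedDifferenceMatrix,
    Pairing,
    ProbeAnnotation,
    SampleMetadata,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)


def match_pairs(metadata: SampleMetadata, caliper: float,
                exact_on=(), max_cases_per_control: int = 1) -> Pairing:
    """Greedy nearest-age matching of cases to controls.

    Cases are visited in increasing age (ties by sample id); each receives the
    eligible control — strict ``|age_case - age_control| < caliper``, exact
    equality on every covariate in ``exact_on``, used fewer than
    ``max_cases_per_control`` times — with the smallest age gap, ties broken
    by lexicographic control id. Cases with no eligible control are returned
    in ``unmatched_cases``.
    """
    if caliper <= 0:
        raise ValidationError(f"caliper must be > 0, got {caliper}")
    if max_cases_per_control < 1:
        raise ValidationError("max_cases_per_control must be >= 1")
    exact_on = tuple(exact_on)
    missing = [c for c in exact_on if c not in metadata.table.columns]
    if missing:
        raise ValidationError(f"exact_on covariates not in metadata: {missing}")

    cases = metadata.subset(GROUP_CASE)
    controls = metadata.subset(GROUP_CONTROL)
    if cases.empty or controls.empty:
        raise ValidationError("metadata must contain at least one case and one control")

    ctrl_records = controls.sort_values("sample_id").to_dict("records")
    usage = {c["sample_id"]: 0 for c in ctrl_records}
    pairs, unmatched = [], []
    for case in cases.sort_values(["age", "sample_id"]).to_dict("records"):
        best = None
        best_gap = None
        for ctrl in ctrl_records:  # lexicographic id order -> deterministic ties
            if usage[ctrl["sample_id"]] >= max_cases_per_control:
                continue
            if any(case[c] != ctrl[c] for c in exact_on):
                continue
            gap = abs(case["age"] - ctrl["age"])
            if gap >= caliper:
                continue
            if best is None or gap < best_gap:
                best, best_gap = ctrl, gap
        if best is None:
            unmatched.append(case["sample_id"])
        else:
            usage[best["sample_id"]] += 1
            pairs.append((case["sample_id"], best["sample_id"]))

    if not pairs:
        warnings.warn("no matchable case-control pair under the given constraints")
    pairing = Pairing(
        pairs=tuple(pairs), caliper=float(caliper), exact_on=exact_on,
        max_cases_per_control=max_cases_per_control, unmatched_cases=tuple(unmatched),
    )
    _assert_pairing_valid(pairing, metadata)
    return pairing


def _assert_pairing_valid(pairing: Pairing, metadata: SampleMetadata) -> None:
    """Re-check caliper and covariate constraints on every constructed pairing."""
    tab = metadata.table.set_index("sample_id")
    for case_id, ctrl_id in pairing.pairs:
        gap = abs(tab.at[case_id, "age"] - tab.at[ctrl_id, "age"])
        if gap >= pairing.caliper:
            raise AssertionError(
                f"pair ({case_id}, {ctrl_id}) violates caliper: gap {gap}"
            )
        for cov in pairing.exact_on:
            if tab.at[case_id, cov] != tab.at[ctrl_id, cov]:
                raise AssertionError(
                    f"pair ({case_id}, {ctrl_id}) differs on covariate {cov!r}"
                )


def compute_theta(cases: BetaMatrix, controls: BetaMatrix,
                  pairing: Pairing, drop_missing: bool = True) -> PairedDifferenceMatrix:
    """theta[i, j] = beta_case[i, j] - beta_control[i, j] for each matched pair.

    Probes with any missing value across pairs are dropped (logged count)
    when ``drop_missing`` is True; otherwise NaNs propagate.
    """
    if cases.probe_ids != controls.probe_ids:
        raise ValidationError("case and control beta matrices must share probe order")
    case_cols = np.stack([cases.sample_column(a) for a, _ in pairing.pairs])
    ctrl_cols = np.stack([controls.sample_column(b) for _, b in pairing.pairs])
    theta = case_cols - ctrl_cols  # (n_pairs, m)
    probe_ids = cases.probe_ids
    if drop_missing:
        keep = ~np.isnan(theta).any(axis=0)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d probe(s) with missing paired differences", dropped)
            theta = theta[:, keep]
            probe_ids = tuple(p for p, k in zip(probe_ids, keep) if k)
    return PairedDifferenceMatrix(pairing.pair_ids, probe_ids, theta)


@dataclass(frozen=True)
class CgiDispersionSummary:
    """Pooled moments of theta per CGI stratum and a Welch test between strata.

    The Welch statistic compares probe-level mean theta between CGI and
    non-CGI probes; with a single stratum present it is undefined
    (``comparable`` is False) rather than an error.
    """

    n_probes_cgi: int
    n_probes_non_cgi: int
    mean_cgi: float
    mean_non_cgi: float
    var_cgi: float
    var_non_cgi: float
    welch_t: float
    welch_p: float
    comparable: bool


def cgi_dispersion_summary(theta: PairedDifferenceMatrix,
                           annotation: ProbeAnnotation) -> CgiDispersionSummary:
    cgi = _aligned_cgi(theta, annotation)
    vals_y = theta.theta[:, cgi]
    vals_n = theta.theta[:, ~cgi]

    def _pooled(v):
        if v.size == 0:
            return float("nan"), float("nan")
        return float(np.nanmean(v)), float(np.nanvar(v))

    mean_y, var_y = _pooled(vals_y)
    mean_n, var_n = _pooled(vals_n)
    comparable = vals_y.shape[1] >= 2 and vals_n.shape[1] >= 2
    if comparable:
        t, p = stats.ttest_ind(
            np.nanmean(vals_y, axis=0), np.nanmean(vals_n, axis=0), equal_var=False
        )
        t, p = float(t), float(p)
        if not np.isfinite(t):
            comparable, t, p = False, float("nan"), float("nan")
    else:
        t = p = float("nan")
    return CgiDispersionSummary(
        n_probes_cgi=int(cgi.sum()), n_probes_non_cgi=int((~cgi).sum()),
        mean_cgi=mean_y, mean_non_cgi=mean_n, var_cgi=var_y, var_non_cgi=var_n,
        welch_t=t, welch_p=p, comparable=comparable,
    )


def _aligned_cgi(theta: PairedDifferenceMatrix, annotation: ProbeAnnotation) -> np.ndarray:
    lookup = dict(zip(annotation.probe_ids, annotation.cgi))
    missing = [p for p in theta.probe_ids if p not in lookup]
    if missing:
        raise ValidationError(f"annotation does not cover probes: {missing[:5]}")
    return np.array([lookup[p] for p in theta.probe_ids], dtype=bool)


def paired_t_baseline(theta: PairedDifferenceMatrix, alpha: float = 0.05,
                      correction: str = "bonferroni"):
    """One-sample t-test of each probe's theta column against 0.

    This is the two-stage baseline's first stage: with Bonferroni correction
    the per-test threshold is ``alpha / m_probes`` (0.05 / 1,675 ≈ 2.985e-5
    for a ten-pathway array panel). Zero-variance columns get p = 1 and a
    ``degenerate`` flag instead of an error.

    Returns a DataFrame with columns probe_id, mean_theta, t_stat, p_value,
    threshold, significant, degenerate.
    """
    import pandas as pd

    if correction not in ("none", "bonferroni"):
        raise ValidationError(f"unknown correction {correction!r}")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    th = theta.theta
    n, m = th.shape
    if n < 2:
        raise ValidationError("paired t-test needs at least 2 pairs")
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_1samp(th, popmean=0.0, axis=0)
        t_stat = np.asarray(t_res.statistic, dtype=float)
        p_val = np.asarray(t_res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t_stat)
    p_val = np.where(degenerate, 1.0, p_val)
    threshold = alpha / m if correction == "bonferroni" else alpha
    significant = (p_val < threshold) & ~degenerate
    return pd.DataFrame(
        {
            "probe_id": list(theta.probe_ids),
            "mean_theta": th.mean(axis=0),
            "t_stat": np.where(degenerate, np.nan, t_stat),
            "p_value": p_val,
            "threshold": threshold,
            "significant": significant,
            "degenerate": degenerate,
        }
    )


def write_pairing(pairing: Pairing, path) -> None:
    """Persist a pairing as TSV; constraints travel in '#' header lines."""
    with open(path, "w") as fh:
        fh.write(f"# caliper: {pairing.caliper}\n")
        fh.write(f"# exact_on: {','.join(pairing.exact_on)}\n")
        fh.write(f"# max_cases_per_control: {pairing.max_cases_per_control}\n")
        fh.write(f"# unmatched_cases: {','.join(pairing.unmatched_cases)}\n")
        fh.write("case_id\tcontrol_id\n")
        for a, b in pairing.pairs:
            fh.write(f"{a}\t{b}\n")


def read_pairing(path) -> Pairing:
    meta = {"caliper": "1.0", "exact_on": "", "max_cases_per_control": "1",
            "unmatched_cases": ""}
    pairs = []
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                header_seen = True  # column header row
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(f"pairing row needs 2 columns: {line!r}")
            pairs.append((fields[0], fields[1]))
    split = lambda s: tuple(x for x in s.split(",") if x)
    return Pairing(
        pairs=tuple(pairs),
        caliper=float(meta["caliper"]),
        exact_on=split(meta["exact_on"]),
        max_cases_per_control=int(meta["max_cases_per_control"]),
        unmatched_cases=split(meta["unmatched_cases"]),
    )


def median_center(beta: BetaMatrix) -> BetaMatrix:
    """Optional per-sample median-centering hook (off by default in pipelines).

    Subtracts each sample's median beta and re-centers at the global median,
    clipping back into [0, 1]. A deliberately simple stand-in for array
    normalization; logged so its use is visible in run records.
    """
    vals = beta.values
    med = np.nanmedian(vals, axis=0, keepdims=True)
    centered = vals - med + np.nanmedian(vals)
    logger.info("median-centering applied to %d samples", beta.n_samples)
    return BetaMatrix(beta.probe_ids, beta.sample_ids, np.clip(centered, 0.0, 1.0))
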