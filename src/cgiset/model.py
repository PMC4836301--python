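"""The hierarchical model for paired methylation differences.

Observation layer
    theta[i, j] ~ Normal(mu[i, j], sigma2_eps),
    mu[i, j] = lambda[j] (+ delta[i] when pair random effects are on),
    lambda[j] = beta[j] + Phi[j].

Probe layer (CGI mixture)
    beta[j] ~ Normal(b_Y, tau2_Y) for probes inside a CpG island,
    beta[j] ~ Normal(b_N, tau2_N) otherwise — two separate distributions,
    reflecting the larger dispersion of CGI probes.

Pathway layer
    Phi[j] = sum_k f_k(P_j) with per-pathway parameters gamma:
      a      f_k = 0                                  (null effect)
      b1     f_k = I[j,k] * gamma_k                   (constant effect)
      b2     f_k = I[j,k] * (gamma_k^Y or gamma_k^N)  (CGI-dependent constant)
      c1     f_k = E[j,k] * gamma_k                   (degree effect)
      c2     f_k = E[j,k] * (gamma_k^Y or gamma_k^N)  (CGI-dependent degree)
      c1_inv / c2_inv replace E[j,k] by 1/E[j,k] (0 for isolated genes),
      for the hub-downweighting variant.
    A probe in several pathways sums their contributions.

Every form is linear in gamma, so the whole model is a conjugate
normal / inverse-gamma hierarchy — see :mod:`cgiset.gibbs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .containers import PairedDifferenceMatrix
from .errors import ValidationError
from .topology import ProbeFeatures

FORMS = ("a", "b1", "b2", "c1", "c2", "c1_inv", "c2_inv")
#: per-pathway parameter count multiplier for each form
FORM_PARAM_MULT = {"a": 0, "b1": 1, "c1": 1, "c1_inv": 1, "b2": 2, "c2": 2, "c2_inv": 2}
CGI_DEPENDENT = frozenset({"b2", "c2", "c2_inv"})


@dataclass(frozen=True)
class ModelSpec:
    """Which pathway-effect form is fitted, and the optional extras."""

    form: str = "b2"
    include_pair_effect: bool = True
    stratified_noise: bool = False  # separate sigma2_eps for CGI / non-CGI probes

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValidationError(f"unknown model form {self.form!r}; choose from {FORMS}")

    def n_gamma(self, n_pathways: int) -> int:
        return FORM_PARAM_MULT[self.form] * n_pathways

    @property
    def cgi_dependent(self) -> bool:
        return self.form in CGI_DEPENDENT

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the conjugate prior layer.

    Normal priors on the stratum base levels b_Y, b_N and on every gamma;
    inverse-gamma priors on all variance components. Defaults are
    conventional vague choices (N(0, 10^2), IG(0.01, 0.01)); override via
    keyword arguments or a YAML config.
    """

    b_mean: float = 0.0
    b_var: float = 100.0
    gamma_mean: float = 0.0
    gamma_var: float = 100.0
    tau2_shape: float = 0.01
    tau2_scale: float = 0.01
    sigma2_shape: float = 0.01
    sigma2_scale: float = 0.01
    tau2_delta_shape: float = 0.01
    tau2_delta_scale: float = 0.01

    def __post_init__(self):
        for name in ("b_var", "gamma_var", "tau2_shape", "tau2_scale",
                     "sigma2_shape", "sigma2_scale", "tau2_delta_shape",
                     "tau2_delta_scale"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"prior hyperparameter {name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "Priors":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ParameterState:
    """One point in parameter space; ``sigma2_eps`` is the (Y, N) stratum pair.

    Under shared observation noise both entries are equal.
    """

    beta: np.ndarray            # (m,)
    gamma: np.ndarray           # (p,)
    b_Y: float
    b_N: float
    tau2_Y: float
    tau2_N: float
    sigma2_eps: np.ndarray      # shape (2,): [CGI stratum, non-CGI stratum]
    delta: np.ndarray | None = None  # (n,) pair effects
    tau2_delta: float | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.sigma2_eps = np.broadcast_to(
            np.asarray(self.sigma2_eps, dtype=float).ravel(), (2,)
        ).copy() if np.ndim(self.sigma2_eps) == 0 or np.size(self.sigma2_eps) == 1 \
            else np.asarray(self.sigma2_eps, dtype=float)
        if self.sigma2_eps.shape != (2,):
            raise ValidationError("sigma2_eps must be a scalar or length-2 array")
        for v in (self.tau2_Y, self.tau2_N, *self.sigma2_eps):
            if v <= 0:
                raise ValidationError("variance components must be > 0")
        if self.delta is not None:
            self.delta = np.asarray(self.delta, dtype=float)


def gamma_labels(spec: ModelSpec, pathway_ids) -> tuple:
    """Names of the gamma components, in design-matrix column order.

    CGI-dependent forms order all Y-stratum parameters first, then all N."""
    pathway_ids = tuple(pathway_ids)
    if spec.form == "a":
        return ()
    if spec.cgi_dependent:
        return tuple(f"{pid}:Y" for pid in pathway_ids) + tuple(
            f"{pid}:N" for pid in pathway_ids
        )
    return pathway_ids


def design_matrix(spec: ModelSpec, features: ProbeFeatures) -> np.ndarray:
    """m x p design X such that Phi = X @ gamma for the given form."""
    base = {
        "a": None,
        "b1": features.membership, "b2": features.membership,
        "c1": features.degree, "c2": features.degree,
        "c1_inv": features.inv_degree, "c2_inv": features.inv_degree,
    }[spec.form]
    if base is None:
        return np.zeros((features.n_probes, 0))
    base = np.asarray(base, dtype=float)
    if not spec.cgi_dependent:
        return base.copy()
    cgi = features.cgi.astype(float)[:, None]
    return np.hstack([base * cgi, base * (1.0 - cgi)])


def pathway_effect(spec: ModelSpec, features: ProbeFeatures,
                   gamma: np.ndarray) -> np.ndarray:
    """Phi[j] = sum_k f_k(P_j); linear in gamma for every form."""
    X = design_matrix(spec, features)
    gamma = np.asarray(gamma, dtype=float).ravel()
    if gamma.shape[0] != X.shape[1]:
        raise ValidationError(
            f"gamma has {gamma.shape[0]} components; form {spec.form!r} with "
            f"{features.n_pathways} pathways needs {X.shape[1]}"
        )
    return X @ gamma


def lambda_vector(state: ParameterState, spec: ModelSpec,
                  features: ProbeFeatures) -> np.ndarray:
    """lambda[j] = beta[j] + Phi[j], the total probe effect."""
    if state.beta.shape[0] != features.n_probes:
        raise ValidationError("beta length does not match probe count")
    return state.beta + pathway_effect(spec, features, state.gamma)


def mean_surface(state: ParameterState, spec: ModelSpec,
                 features: ProbeFeatures, n_pairs: int) -> np.ndarray:
    """mu[i, j] = lambda[j] (+ delta[i] if pair effects are enabled)."""
    lam = lambda_vector(state, spec, features)
    mu = np.tile(lam, (n_pairs, 1))
    if spec.include_pair_effect:
        if state.delta is None:
            raise ValidationError("pair effects enabled but state.delta is None")
        if state.delta.shape[0] != n_pairs:
            raise ValidationError("delta length does not match n_pairs")
        mu = mu + state.delta[:, None]
    return mu


def _sigma2_per_probe(sigma2_eps, cgi: np.ndarray, stratified: bool) -> np.ndarray:
    s = np.broadcast_to(np.asarray(sigma2_eps, dtype=float).ravel(), (2,))
    if not stratified and s[0] != s[1]:
        raise ValidationError("shared-noise model got two distinct sigma2 values")
    return np.where(cgi, s[0], s[1])


def log_likelihood(theta, mu: np.ndarray, sigma2_eps,
                   cgi: np.ndarray | None = None,
                   stratified: bool = False) -> float:
    """Gaussian log-likelihood sum_ij log N(theta_ij | mu_ij, sigma2).

    ``sigma2_eps`` may be a scalar (shared noise) or the (Y, N) pair with
    ``stratified=True`` and a per-probe ``cgi`` vector.
    """
    th = theta.theta if isinstance(theta, PairedDifferenceMatrix) else np.asarray(theta)
    mu = np.asarray(mu, dtype=float)
    if th.shape != mu.shape:
        raise ValidationError(f"theta shape {th.shape} != mu shape {mu.shape}")
    if np.ndim(sigma2_eps) == 0 or np.size(sigma2_eps) == 1:
        s2 = np.full(th.shape[1], float(np.asarray(sigma2_eps).ravel()[0]))
    else:
        if cgi is None:
            raise ValidationError("per-stratum sigma2 requires the cgi vector")
        s2 = _sigma2_per_probe(sigma2_eps, np.asarray(cgi, dtype=bool), stratified)
    if (s2 <= 0).any():
        raise ValidationError("sigma2_eps must be > 0")
    n = th.shape[0]
    resid2 = ((th - mu) ** 2).sum(axis=0)
    return float(-0.5 * (n * np.log(2.0 * np.pi * s2) + resid2 / s2).sum())


def deviance(theta, mu, sigma2_eps, cgi=None, stratified: bool = False) -> float:
    """-2 x log-likelihood; the quantity DIC is built from."""
    return -2.0 * log_likelihood(theta, mu, sigma2_eps, cgi=cgi, stratified=stratified)
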