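"""Gibbs sampler for the CGI-mixture pathway model.

Every layer of the model is conjugate (normal observation, normal probe and
pathway effects, inverse-gamma variances), so all full conditionals are
closed-form and the sampler is pure Gibbs — no Metropolis steps, no tuning.

Per-sweep cost is O(m*p + n + m) after an O(n*m) precomputation of
sufficient statistics (column/row sums of theta per CGI stratum and the
stratum Gram matrices X'X), which makes long chains cheap even at array
scale. Any parameter can be held fixed via ``MCMCConfig.fixed`` — used for
fixed-variance toy models and oracle checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import linalg

from .containers import PairedDifferenceMatrix
from .errors import SamplerError, ValidationError
from .model import ModelSpec, ParameterState, Priors, design_matrix, gamma_labels
from .topology import ProbeFeatures

logger = logging.getLogger(__name__)

_FIXABLE = (
    "beta", "gamma", "b_Y", "b_N", "tau2_Y", "tau2_N",
    "sigma2_eps", "tau2_delta", "delta",
)


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 12_000
    n_burnin: int = 2_000
    thin: int = 5
    n_chains: int = 2
    seed: int = 0
    init: str = "prior"  # "prior" | "zeros"
    fixed: dict | None = None

    def __post_init__(self):
        if not self.n_iter > self.n_burnin >= 0:
            raise ValidationError("need n_iter > n_burnin >= 0")
        if self.thin < 1 or self.n_chains < 1:
            raise ValidationError("thin and n_chains must be >= 1")
        if self.init not in ("prior", "zeros"):
            raise ValidationError(f"unknown init strategy {self.init!r}")
        if self.fixed:
            unknown = sorted(set(self.fixed) - set(_FIXABLE))
            if unknown:
                raise ValidationError(f"cannot fix unknown parameters: {unknown}")

    @property
    def n_draws_per_chain(self) -> int:
        return -(-(self.n_iter - self.n_burnin) // self.thin)  # ceil

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["fixed"]:
            d["fixed"] = {k: np.asarray(v).tolist() for k, v in d["fixed"].items()}
        return d


@dataclass
class PosteriorSamples:
    """Post-burn-in, thinned draws, one block per chain (axis 0 = chain)."""

    gamma: np.ndarray        # (C, T, p)
    beta: np.ndarray         # (C, T, m)
    lam: np.ndarray          # (C, T, m) -- sampled lambda = beta + Phi
    b_Y: np.ndarray          # (C, T)
    b_N: np.ndarray
    tau2_Y: np.ndarray
    tau2_N: np.ndarray
    sigma2_Y: np.ndarray
    sigma2_N: np.ndarray
    deviance: np.ndarray     # (C, T)
    delta: np.ndarray | None
    tau2_delta: np.ndarray | None
    gamma_labels: tuple
    probe_ids: tuple
    pair_ids: tuple
    spec: ModelSpec
    config: MCMCConfig

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    @property
    def n_draws(self) -> int:
        """Total pooled draw count across chains."""
        return self.deviance.shape[0] * self.deviance.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one quantity with chains concatenated along axis 0."""
        arr = getattr(self, name)
        if arr is None:
            raise ValidationError(f"{name!r} was not sampled in this run")
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def scalar_chains(self) -> dict:
        """Per-chain arrays of every scalar quantity, gammas unpacked by label."""
        out = {
            "b_Y": self.b_Y, "b_N": self.b_N, "tau2_Y": self.tau2_Y,
            "tau2_N": self.tau2_N, "sigma2_Y": self.sigma2_Y,
            "sigma2_N": self.sigma2_N, "deviance": self.deviance,
        }
        for i, lab in enumerate(self.gamma_labels):
            out[f"gamma[{lab}]"] = self.gamma[:, :, i]
        if self.tau2_delta is not None:
            out["tau2_delta"] = self.tau2_delta
        return out


class GibbsSampler:
    """Systematic-scan Gibbs sampler; also usable sweep-by-sweep for testing."""

    def __init__(self, theta, spec: ModelSpec, priors: Priors,
                 features: ProbeFeatures, fixed: dict | None = None):
        th = theta.theta if isinstance(theta, PairedDifferenceMatrix) else np.asarray(theta, float)
        if th.ndim != 2 or th.shape[0] < 2 or th.shape[1] < 2:
            raise ValidationError("need at least 2 pairs and 2 probes")
        if th.shape[1] != features.n_probes:
            raise ValidationError("theta probe dimension does not match features")
        if np.isnan(th).any():
            raise ValidationError("theta contains missing values; drop them upstream")
        if spec.form != "a":
            dead = [features.pathway_ids[k]
                    for k in range(features.n_pathways)
                    if not features.membership[:, k].any()]
            if dead:
                raise ValidationError(f"pathway(s) with zero member probes: {dead}")
        self.spec = spec
        self.priors = priors
        self.features = features
        self.fixed = dict(fixed or {})
        self.X = design_matrix(spec, features)
        self.p = self.X.shape[1]
        self.cgi = features.cgi.astype(bool)
        self.strata = (self.cgi, ~self.cgi)           # (Y, N) probe masks
        self.m_s = np.array([int(s.sum()) for s in self.strata])
        self.X_s = [self.X[s] for s in self.strata]
        self.XtX_s = [Xs.T @ Xs for Xs in self.X_s]
        self._prior_gamma_prec = 1.0 / priors.gamma_var
        self.set_theta(th)

    # -- sufficient statistics ------------------------------------------------
    def set_theta(self, th: np.ndarray) -> None:
        th = np.asarray(th, dtype=float)
        self.n, self.m = th.shape
        self.colsum = th.sum(axis=0)
        self.colsum_s = [self.colsum[s] for s in self.strata]
        self.rowsum_s = [th[:, s].sum(axis=1) for s in self.strata]
        self.sumsq_s = [float((th[:, s] ** 2).sum()) for s in self.strata]

    def _stratum_ss(self, lam, delta_sum, delta_sq_sum, delta) -> np.ndarray:
        """Residual sum of squares per CGI stratum, via expanded products."""
        ss = np.empty(2)
        for k, s in enumerate(self.strata):
            lam_s = lam[s]
            lsum = lam_s.sum()
            ss[k] = (
                self.sumsq_s[k]
                - 2.0 * float(lam_s @ self.colsum_s[k])
                - 2.0 * float(delta @ self.rowsum_s[k])
                + self.n * float(lam_s @ lam_s)
                + self.m_s[k] * delta_sq_sum
                + 2.0 * lsum * delta_sum
            )
        return ss

    # -- initialization -------------------------------------------------------
    def init_state(self, rng: np.random.Generator, strategy: str = "prior") -> ParameterState:
        pr = self.priors

        def ig_draw(shape, scale):
            # clipped into a sane window: vague IG draws can be astronomically
            # large and would start chains at numerically absurd states
            return float(np.clip(scale / rng.gamma(shape), 1e-4, 10.0))

        if strategy == "prior":
            tau2_Y = ig_draw(pr.tau2_shape, pr.tau2_scale)
            tau2_N = ig_draw(pr.tau2_shape, pr.tau2_scale)
            s2 = ig_draw(pr.sigma2_shape, pr.sigma2_scale)
            sigma2 = np.array([s2, ig_draw(pr.sigma2_shape, pr.sigma2_scale)
                               if self.spec.stratified_noise else s2])
            loc_sd = min(np.sqrt(pr.b_var), 1.0)
            b_Y = float(rng.normal(pr.b_mean, loc_sd))
            b_N = float(rng.normal(pr.b_mean, loc_sd))
            g_sd = min(np.sqrt(pr.gamma_var), 1.0)
            gam = rng.normal(pr.gamma_mean, g_sd, size=self.p)
            beta = np.where(
                self.cgi,
                rng.normal(b_Y, np.sqrt(tau2_Y), size=self.m),
                rng.normal(b_N, np.sqrt(tau2_N), size=self.m),
            )
            tau2_delta = ig_draw(pr.tau2_delta_shape, pr.tau2_delta_scale)
            delta = (rng.normal(0.0, np.sqrt(tau2_delta), size=self.n)
                     if self.spec.include_pair_effect else None)
        else:  # zeros
            tau2_Y = tau2_N = 0.1
            sigma2 = np.array([0.1, 0.1])
            b_Y = b_N = 0.0
            gam = np.zeros(self.p)
            beta = np.zeros(self.m)
            tau2_delta = 0.1
            delta = np.zeros(self.n) if self.spec.include_pair_effect else None
        state = ParameterState(
            beta=beta, gamma=gam, b_Y=b_Y, b_N=b_N, tau2_Y=tau2_Y,
            tau2_N=tau2_N, sigma2_eps=sigma2,
            delta=delta,
            tau2_delta=tau2_delta if self.spec.include_pair_effect else None,
        )
        self._apply_fixed(state)
        return state

    def _apply_fixed(self, state: ParameterState) -> None:
        fx = self.fixed
        for name in ("b_Y", "b_N", "tau2_Y", "tau2_N", "tau2_delta"):
            if name in fx:
                setattr(state, name, float(fx[name]))
        if "sigma2_eps" in fx:
            v = np.asarray(fx["sigma2_eps"], dtype=float).ravel()
            state.sigma2_eps = np.array([v[0], v[-1]])
        if "beta" in fx:
            state.beta = np.asarray(fx["beta"], dtype=float).copy()
        if "gamma" in fx:
            state.gamma = np.asarray(fx["gamma"], dtype=float).copy()
        if "delta" in fx:
            state.delta = np.asarray(fx["delta"], dtype=float).copy()

    # -- one full conditional sweep -------------------------------------------
    def sweep(self, state: ParameterState, rng: np.random.Generator) -> ParameterState:
        """One systematic scan.

        Location parameters are drawn as one exact joint block, factored as
        p(gamma, b | variances) * p(delta | gamma, b, variances) *
        p(beta | gamma, b, delta, variances):

        * (gamma, b_Y, b_N): with beta AND delta integrated out, the probe
          means ybar_j are jointly Gaussian with covariance
          diag(tau2_s + sigma2_s/n) + (tau2_delta/n) * J, inverted by
          Sherman-Morrison.
        * delta: with beta integrated out, its conditional precision has the
          form a*I + b*J, sampled exactly via its two eigenspaces.
        * beta: ordinary full conditional.

        Blocking is essential: pathway effects, stratum base levels, and the
        pair-effect mean are mutually confounded, and one-at-a-time updates
        crawl along those posterior ridges. Variance components follow with
        their inverse-gamma full conditionals.
        """
        pr, fx = self.priors, self.fixed
        n, m = self.n, self.m
        beta_fixed = "beta" in fx
        delta_on = self.spec.include_pair_effect
        delta_free = delta_on and "delta" not in fx

        tau2_probe = np.where(self.cgi, state.tau2_Y, state.tau2_N)
        s2_probe = np.where(self.cgi, state.sigma2_eps[0], state.sigma2_eps[1])
        tau2_eff = np.zeros(m) if beta_fixed else tau2_probe

        # -- block 1: (gamma, b_Y, b_N) with beta and delta collapsed out
        ybar = self.colsum / n
        if delta_on and not delta_free:  # delta fixed: a known offset
            ybar = ybar - float(np.mean(fx["delta"]))
        v = tau2_eff + s2_probe / n
        c = (state.tau2_delta / n) if delta_free else 0.0
        offset = np.asarray(fx["beta"], dtype=float) if beta_fixed else np.zeros(m)
        cols, prior_prec, prior_mean = [], [], []
        if self.p and "gamma" not in fx:
            cols.append(self.X)
            prior_prec += [self._prior_gamma_prec] * self.p
            prior_mean += [pr.gamma_mean] * self.p
        elif self.p:
            offset = offset + self.X @ np.asarray(fx["gamma"], dtype=float)
        ones = {}
        for name, mask in (("b_Y", self.strata[0]), ("b_N", self.strata[1])):
            if beta_fixed or name in fx:
                if not beta_fixed and name in fx:
                    offset = offset + np.where(mask, float(fx[name]), 0.0)
                continue
            ones[name] = len(prior_prec)  # column index in eta
            cols.append(mask.astype(float)[:, None])
            prior_prec.append(1.0 / pr.b_var)
            prior_mean.append(pr.b_mean)
        if cols:
            Z = np.hstack(cols)
            q = Z.shape[1]
            inv_v = 1.0 / v
            Zv = Z * inv_v[:, None]
            resid = ybar - offset
            if c > 0:  # Sherman-Morrison for diag(v) + c*J
                coef = c / (1.0 + c * inv_v.sum())
                WZ = Zv - coef * np.outer(inv_v, Zv.sum(axis=0))
                w_resid = resid * inv_v - coef * inv_v * float(resid @ inv_v)
            else:
                WZ = Zv
                w_resid = resid * inv_v
            prec = WZ.T @ Z
            prec[np.diag_indices_from(prec)] += np.asarray(prior_prec)
            lin = Z.T @ w_resid + np.asarray(prior_prec) * np.asarray(prior_mean)
            cho = linalg.cho_factor(prec, lower=True)
            mean = linalg.cho_solve(cho, lin)
            eta = mean + linalg.solve_triangular(
                cho[0].T, rng.standard_normal(q), lower=False
            )
            if self.p and "gamma" not in fx:
                state.gamma = eta[:self.p]
            for name in ("b_Y", "b_N"):
                if name in ones:
                    setattr(state, name, float(eta[ones[name]]))
        if beta_fixed:
            # beta held fixed: b falls out of the likelihood, but its
            # conditional given beta (hierarchy layer) remains well defined
            for name_b, name_t, mask in (("b_Y", "tau2_Y", self.strata[0]),
                                         ("b_N", "tau2_N", self.strata[1])):
                if name_b in fx:
                    continue
                beta_s = np.asarray(fx["beta"], dtype=float)[mask]
                tau2 = getattr(state, name_t)
                prec_b = beta_s.size / tau2 + 1.0 / pr.b_var
                mean_b = (beta_s.sum() / tau2 + pr.b_mean / pr.b_var) / prec_b
                setattr(state, name_b, float(rng.normal(mean_b, 1.0 / np.sqrt(prec_b))))

        phi = self.X @ state.gamma if self.p else np.zeros(m)
        b_probe = np.where(self.cgi, state.b_Y, state.b_N)
        # prior-mean surface of lambda given (gamma, b): fixed beta replaces b
        mu = (np.asarray(fx["beta"], dtype=float) if beta_fixed else b_probe) + phi

        # -- block 2: delta | gamma, b with beta collapsed out
        if delta_free:
            s2 = state.sigma2_eps
            tau2_s = np.array([0.0, 0.0]) if beta_fixed else np.array(
                [state.tau2_Y, state.tau2_N]
            )
            musum_s = np.array([float(mu[s].sum()) for s in self.strata])
            ybarsum_s = np.array([cs.sum() / n for cs in self.colsum_s])
            kappa = tau2_s / (s2 * (s2 + n * tau2_s))
            lvec = ((self.rowsum_s[0] - musum_s[0]) / s2[0]
                    + (self.rowsum_s[1] - musum_s[1]) / s2[1])
            lvec = lvec - float(
                n * (kappa * (ybarsum_s - musum_s)).sum()
            )
            a = self.m_s[0] / s2[0] + self.m_s[1] / s2[1] + 1.0 / state.tau2_delta
            b_coef = -float((self.m_s * kappa).sum())
            # P = a*I + b*J: mean by Sherman-Morrison, draw via eigenspaces
            mean_d = lvec / a - (b_coef / (a * (a + n * b_coef))) * lvec.sum()
            u = rng.standard_normal(n)
            ubar = u.mean()
            noise = (u - ubar) / np.sqrt(a) + ubar / np.sqrt(a + n * b_coef)
            state.delta = mean_d + noise

        delta = state.delta if state.delta is not None else np.zeros(n)
        dsum = float(delta.sum())
        dsq = float(delta @ delta)

        # -- beta | everything
        if not beta_fixed:
            lik_lin = (self.colsum - dsum - n * phi) / s2_probe
            prec_b = n / s2_probe + 1.0 / tau2_probe
            mean_b = (lik_lin + b_probe / tau2_probe) / prec_b
            state.beta = mean_b + rng.standard_normal(m) / np.sqrt(prec_b)

        # -- variance components
        for name_t, name_b, mask in (("tau2_Y", "b_Y", self.strata[0]),
                                     ("tau2_N", "b_N", self.strata[1])):
            if name_t in fx:
                continue
            beta_s = state.beta[mask]
            resid_b = beta_s - getattr(state, name_b)
            shape = pr.tau2_shape + 0.5 * beta_s.size
            scale = pr.tau2_scale + 0.5 * float(resid_b @ resid_b)
            setattr(state, name_t, float(scale / rng.gamma(shape)))

        lam = state.beta + phi
        if delta_on and "tau2_delta" not in fx:
            shape = pr.tau2_delta_shape + 0.5 * n
            scale = pr.tau2_delta_scale + 0.5 * dsq
            state.tau2_delta = float(scale / rng.gamma(shape))

        # observation noise
        if "sigma2_eps" not in fx:
            ss = self._stratum_ss(lam, dsum, dsq, delta if delta.size else np.zeros(self.n))
            if self.spec.stratified_noise:
                s2 = np.empty(2)
                for k in range(2):
                    shape = pr.sigma2_shape + 0.5 * n * self.m_s[k]
                    scale = pr.sigma2_scale + 0.5 * ss[k]
                    s2[k] = scale / rng.gamma(shape)
                state.sigma2_eps = s2
            else:
                shape = pr.sigma2_shape + 0.5 * n * m
                scale = pr.sigma2_scale + 0.5 * float(ss.sum())
                s2 = scale / rng.gamma(shape)
                state.sigma2_eps = np.array([s2, s2])
        return state

    def current_deviance(self, state: ParameterState) -> float:
        phi = self.X @ state.gamma if self.p else np.zeros(self.m)
        lam = state.beta + phi
        delta = state.delta if state.delta is not None else np.zeros(self.n)
        ss = self._stratum_ss(lam, float(delta.sum()), float(delta @ delta), delta)
        dev = 0.0
        for k in range(2):
            if self.m_s[k]:
                dev += (self.n * self.m_s[k] * np.log(2.0 * np.pi * state.sigma2_eps[k])
                        + ss[k] / state.sigma2_eps[k])
        return float(dev)


def run_gibbs(theta, spec: ModelSpec, priors: Priors, features: ProbeFeatures,
              config: MCMCConfig) -> PosteriorSamples:
    """Fit the model by systematic-scan Gibbs sampling.

    Reproducible: chain c uses ``np.random.default_rng([seed, c])``, so the
    same config yields bit-identical draws. The sampled lambda vector and the
    deviance are stored per kept draw, so all downstream probabilities use
    exactly the sampled states.
    """
    sampler = GibbsSampler(theta, spec, priors, features, fixed=config.fixed)
    n, m, p = sampler.n, sampler.m, sampler.p
    C, T = config.n_chains, config.n_draws_per_chain
    pair_effect = spec.include_pair_effect

    out = {
        "gamma": np.empty((C, T, p)), "beta": np.empty((C, T, m)),
        "lam": np.empty((C, T, m)), "b_Y": np.empty((C, T)),
        "b_N": np.empty((C, T)), "tau2_Y": np.empty((C, T)),
        "tau2_N": np.empty((C, T)), "sigma2_Y": np.empty((C, T)),
        "sigma2_N": np.empty((C, T)), "deviance": np.empty((C, T)),
        "delta": np.empty((C, T, n)) if pair_effect else None,
        "tau2_delta": np.empty((C, T)) if pair_effect else None,
    }

    for c in range(C):
        rng = np.random.default_rng([config.seed, c])
        state = sampler.init_state(rng, config.init)
        t = 0
        for it in range(config.n_iter):
            state = sampler.sweep(state, rng)
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                if not (np.isfinite(state.beta).all()
                        and np.isfinite(state.gamma).all()
                        and np.isfinite(state.sigma2_eps).all()):
                    raise SamplerError(f"non-finite state at iteration {it}, chain {c}")
                phi = sampler.X @ state.gamma if p else np.zeros(m)
                out["gamma"][c, t] = state.gamma
                out["beta"][c, t] = state.beta
                out["lam"][c, t] = state.beta + phi
                out["b_Y"][c, t] = state.b_Y
                out["b_N"][c, t] = state.b_N
                out["tau2_Y"][c, t] = state.tau2_Y
                out["tau2_N"][c, t] = state.tau2_N
                out["sigma2_Y"][c, t] = state.sigma2_eps[0]
                out["sigma2_N"][c, t] = state.sigma2_eps[1]
                out["deviance"][c, t] = sampler.current_deviance(state)
                if pair_effect:
                    out["delta"][c, t] = state.delta
                    out["tau2_delta"][c, t] = state.tau2_delta
                t += 1
        logger.info("chain %d finished: %d kept draws", c, t)

    theta_obj = theta if isinstance(theta, PairedDifferenceMatrix) else None
    return PosteriorSamples(
        gamma=out["gamma"], beta=out["beta"], lam=out["lam"],
        b_Y=out["b_Y"], b_N=out["b_N"], tau2_Y=out["tau2_Y"],
        tau2_N=out["tau2_N"], sigma2_Y=out["sigma2_Y"], sigma2_N=out["sigma2_N"],
        deviance=out["deviance"], delta=out["delta"], tau2_delta=out["tau2_delta"],
        gamma_labels=gamma_labels(spec, features.pathway_ids),
        probe_ids=features.probe_ids,
        pair_ids=theta_obj.pair_ids if theta_obj is not None else tuple(
            f"pair{i}" for i in range(n)
        ),
        spec=spec, config=config,
    )


def conjugate_posterior_oracle(theta, b, tau2, sigma2, features: ProbeFeatures | None = None,
                               x: np.ndarray | None = None,
                               gamma_mean: float = 0.0, gamma_var: float = 100.0):
    """Exact Gaussian posterior of gamma in the fixed-variance single-pathway model.

    With all variances known, no pair effects, and form b1 with one pathway,
    the probe effects integrate out: the per-probe mean
    ``mean_i theta[:, j] ~ Normal(b_j + x_j * gamma, tau2_j + sigma2 / n)``
    gives a conjugate normal posterior. Returns ``(post_mean, post_var)``.
    Used as the sampler's independent test oracle.
    """
    th = theta.theta if isinstance(theta, PairedDifferenceMatrix) else np.asarray(theta, float)
    n, m = th.shape
    if x is None:
        if features is None:
            raise ValidationError("provide either features or an explicit x vector")
        if features.n_pathways != 1:
            raise ValidationError("oracle is defined for a single pathway (K=1)")
        x = features.membership[:, 0].astype(float)
    x = np.asarray(x, dtype=float).ravel()
    theta_bar = th.mean(axis=0)
    v = np.broadcast_to(np.asarray(tau2, float), (m,)) + float(sigma2) / n
    b_vec = np.broadcast_to(np.asarray(b, float), (m,))
    prec = float((x * x / v).sum()) + 1.0 / gamma_var
    lin = float((x * (theta_bar - b_vec) / v).sum()) + gamma_mean / gamma_var
    return lin / prec, 1.0 / prec


def save_samples(samples: PosteriorSamples, path) -> None:
    """Persist draws as a compressed .npz column store (runtime artifact)."""
    import yaml

    arrays = {
        name: getattr(samples, name)
        for name in ("gamma", "beta", "lam", "b_Y", "b_N", "tau2_Y", "tau2_N",
                     "sigma2_Y", "sigma2_N", "deviance")
    }
    if samples.delta is not None:
        arrays["delta"] = samples.delta
        arrays["tau2_delta"] = samples.tau2_delta
    meta = {
        "gamma_labels": list(samples.gamma_labels),
        "probe_ids": list(samples.probe_ids),
        "pair_ids": list(samples.pair_ids),
        "spec": samples.spec.to_dict(),
        "config": samples.config.to_dict(),
    }
    arrays["meta_yaml"] = np.array([yaml.safe_dump(meta)])
    np.savez_compressed(path, **arrays)


def load_samples(path) -> PosteriorSamples:
    import yaml

    with np.load(path, allow_pickle=False) as z:
        meta = yaml.safe_load(str(z["meta_yaml"][0]))
        get = lambda k: z[k] if k in z.files else None
        config_d = meta["config"]
        return PosteriorSamples(
            gamma=z["gamma"], beta=z["beta"], lam=z["lam"],
            b_Y=z["b_Y"], b_N=z["b_N"], tau2_Y=z["tau2_Y"], tau2_N=z["tau2_N"],
            sigma2_Y=z["sigma2_Y"], sigma2_N=z["sigma2_N"],
            deviance=z["deviance"], delta=get("delta"), tau2_delta=get("tau2_delta"),
            gamma_labels=tuple(meta["gamma_labels"]),
            probe_ids=tuple(meta["probe_ids"]),
            pair_ids=tuple(meta["pair_ids"]),
            spec=ModelSpec(**meta["spec"]),
            config=MCMCConfig(**config_d),
        )


def _split_rhat(chains: np.ndarray) -> float:
    """Classic split-R-hat for one scalar parameter; chains is (C, T)."""
    C, T = chains.shape
    half = T // 2
    if half < 2:
        return float("nan")
    split = chains[:, : 2 * half].reshape(C * 2, half)
    within = split.var(axis=1, ddof=1).mean()
    between = half * split.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else float("inf")
    var_hat = (half - 1) / half * within + between / half
    return float(np.sqrt(var_hat / within))


def gelman_rubin(samples: PosteriorSamples) -> dict:
    """Split-R-hat per scalar parameter (gammas unpacked by label)."""
    if samples.n_chains < 2:
        raise ValidationError("R-hat requires at least 2 chains")
    return {name: _split_rhat(arr) for name, arr in samples.scalar_chains().items()}
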