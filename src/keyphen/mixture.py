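"""Bounded Gaussian mixture model for daily backspace rates.

The model: subject i contributes n_i daily rates y_ij in (0, 1). A latent
phenotype z_i in {1..K} lives at the *subject* level; given z_i = k, days
are iid draws from a normal distribution with component mean mu_k and a
single shared standard deviation sigma, truncated to the unit interval
("bounded support"). Mixture weights pi follow a Dirichlet prior, means a
diffuse normal prior, and the variance an inverse-gamma prior — the
noninformative conjugate setup.

Inference is a Gibbs sampler. With the truncation correction on (the
default), the truncation normalizer breaks exact conjugacy for mu and
sigma^2, so those updates are Metropolis-within-Gibbs steps that propose
from the untruncated conjugate full conditional and accept with the ratio
of truncation normalizers. Label switching is resolved after sampling by
reordering components by ascending mean within every draw. Model fit is
summarized by the deviance information criterion,

    DIC = Dbar + pD,  pD = Dbar - D(theta_bar),  D(theta) = -2 log L(y | theta),

computed on the observed-data (z-marginalized) likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr

_LOG_2PI = math.log(2.0 * math.pi)

#: Rates exactly on the boundary of [0, 1] are clamped inside by this much.
BOUNDARY_EPS = 1e-6


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of a K-component equal-variance mixture on (0, 1)."""

    means: np.ndarray
    sigma: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.means.ndim != 1 or self.means.shape != self.weights.shape:
            raise ValueError("means and weights must be 1-d arrays of equal length")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if np.any(self.weights < 0) or not math.isclose(
            float(self.weights.sum()), 1.0, abs_tol=1e-8
        ):
            raise ValueError("weights must be a probability simplex")

    @property
    def K(self) -> int:
        return len(self.means)

    def sorted(self) -> "MixtureParams":
        order = np.argsort(self.means, kind="stable")
        return MixtureParams(self.means[order], self.sigma, self.weights[order])


@dataclass(frozen=True)
class PriorSpec:
    """Conjugate priors: mu_k ~ N(mean_loc, mean_var) on (0,1), sigma^2 ~
    InvGamma(var_shape, var_rate), pi ~ Dirichlet(dirichlet)."""

    mean_loc: float = 0.5
    mean_var: float = 10.0
    var_shape: float = 0.001
    var_rate: float = 0.001
    dirichlet: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_var <= 0 or self.var_shape <= 0 or self.var_rate <= 0:
            raise ValueError("prior variance parameters must be positive")
        if self.dirichlet <= 0:
            raise ValueError("Dirichlet concentration must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings: 5000 burn-in iterations, then 2 chains of 10,000
    retained iterations each, by default."""

    n_burn: int = 5000
    n_iter: int = 10000
    n_chains: int = 2
    seed: int = 0
    truncation_correction: bool = True
    subject_level: bool = True

    def __post_init__(self) -> None:
        if min(self.n_burn, self.n_iter, self.n_chains) < 0 or self.n_iter == 0 or self.n_chains == 0:
            raise ValueError("iteration and chain counts must be positive")


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC draws (chains concatenated)."""

    means: np.ndarray  # (n_draws, K)
    sigma: np.ndarray  # (n_draws,)
    weights: np.ndarray  # (n_draws, K)
    z: np.ndarray  # (n_draws, n_subjects), values in 0..K-1
    chain: np.ndarray  # (n_draws,)
    subject_ids: list
    truncation_correction: bool = True
    subject_level: bool = True

    @property
    def K(self) -> int:
        return self.means.shape[1]

    @property
    def n_draws(self) -> int:
        return self.means.shape[0]


@dataclass
class FitResult:
    """Posterior summary of one K-component fit."""

    K: int
    params: MixtureParams  # posterior means, relabeled ascending
    dic: float
    dbar: float
    p_d: float
    subject_ids: list
    class_probs: np.ndarray  # (n_subjects, K), rows sum to 1
    modal_class: np.ndarray  # (n_subjects,), values in 0..K-1
    smallest_class_size: int
    rhat: dict
    converged: bool
    param_sd: tuple | None = None  # (sd of means, sd of sigma, sd of weights)
    draws: PosteriorDraws | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# sufficient statistics and likelihood


def _rates_by_subject(data, subject_level: bool = True):
    """Return (subject_ids, n, s1, s2): per-unit counts and sums of y, y^2.

    ``data`` is a daily-rate DataFrame (subject_id, rate) or a mapping of
    subject -> array of rates. With ``subject_level=False`` every
    observation is its own mixing unit.
    """
    if isinstance(data, pd.DataFrame):
        pairs = [(sid, grp["rate"].to_numpy(float)) for sid, grp in data.groupby("subject_id", sort=True)]
    elif isinstance(data, dict):
        pairs = [(sid, np.asarray(v, dtype=float)) for sid, v in data.items()]
    else:  # flat sequence of rates: one subject
        pairs = [("subject", np.asarray(data, dtype=float))]
    if not subject_level:
        pairs = [
            (f"{sid}.{j}", np.array([y]))
            for sid, ys in pairs
            for j, y in enumerate(ys)
        ]
    ids, ns, s1s, s2s = [], [], [], []
    clamped = 0
    for sid, ys in pairs:
        if len(ys) == 0:
            continue
        if np.any(~np.isfinite(ys)) or np.any(ys < 0) or np.any(ys > 1):
            raise ValueError(f"rates for subject {sid!r} must be finite and in [0, 1]")
        onb = (ys <= 0) | (ys >= 1)
        if onb.any():
            clamped += int(onb.sum())
            ys = np.clip(ys, BOUNDARY_EPS, 1 - BOUNDARY_EPS)
        ids.append(sid)
        ns.append(len(ys))
        s1s.append(ys.sum())
        s2s.append((ys**2).sum())
    if clamped:
        warnings.warn(
            f"{clamped} rate(s) on the boundary of [0, 1] clamped to "
            f"({BOUNDARY_EPS}, 1 - {BOUNDARY_EPS})"
        )
    if not ids:
        raise ValueError("no observations supplied")
    return ids, np.array(ns, float), np.array(s1s), np.array(s2s)


def _log_trunc_normalizer(means: np.ndarray, sigma: float) -> np.ndarray:
    """log of Phi((1-mu)/sigma) - Phi((0-mu)/sigma), floored for stability."""
    z = ndtr((1.0 - means) / sigma) - ndtr((0.0 - means) / sigma)
    return np.log(np.maximum(z, 1e-300))


def _unit_class_loglik(n, s1, s2, means, sigma, truncation: bool) -> np.ndarray:
    """(n_units, K) matrix of sum_j log f(y_ij | mu_k, sigma)."""
    means = np.atleast_1d(np.asarray(means, float))
    sig2 = sigma * sigma
    quad = s2[:, None] - 2.0 * means[None, :] * s1[:, None] + n[:, None] * means[None, :] ** 2
    ll = -n[:, None] * (math.log(sigma) + 0.5 * _LOG_2PI) - quad / (2.0 * sig2)
    if truncation:
        ll = ll - n[:, None] * _log_trunc_normalizer(means, sigma)[None, :]
    return ll


def loglik(
    params: MixtureParams,
    data,
    truncation: bool = False,
    subject_level: bool = True,
) -> float:
    """Observed-data log likelihood of the subject-level mixture.

    log L = sum_i log sum_k pi_k prod_j f(y_ij | mu_k, sigma), with f a
    normal density, truncated to (0, 1) when ``truncation`` is on.
    Computed with log-sum-exp stability.
    """
    _, n, s1, s2 = _rates_by_subject(data, subject_level=subject_level)
    ll = _unit_class_loglik(n, s1, s2, params.means, params.sigma, truncation)
    with np.errstate(divide="ignore"):
        logw = np.log(params.weights)
    return float(logsumexp(ll + logw[None, :], axis=1).sum())


# ---------------------------------------------------------------------------
# Gibbs sampler


def _run_chain(rng, n, s1, s2, K, priors: PriorSpec, cfg: MCMCConfig):
    N = len(n)
    n_total = float(n.sum())
    trunc = cfg.truncation_correction

    # Moment-based initialization from subject means, jittered per chain.
    ybar = s1 / n
    means = np.quantile(ybar, (np.arange(K) + 0.5) / K) + rng.normal(0.0, 0.005, K)
    means = np.clip(means, 0.01, 0.99)
    # Initialize sigma^2 from the pooled within-subject variance: it
    # estimates the component variance directly whatever K is, and keeps
    # the truncation-corrected Metropolis steps (independence proposals)
    # from starting at a point they cannot escape.
    overall = s1.sum() / n_total
    var_all = max(s2.sum() / n_total - overall**2, 1e-6)
    denom = np.sum(n - 1)
    within = float(np.sum(s2 - s1**2 / n) / denom) if denom > 0 else 0.0
    sig2 = within if within > 1e-8 else var_all * (0.5 if K > 1 else 1.0)
    weights = np.full(K, 1.0 / K)

    keep = cfg.n_iter
    out_means = np.empty((keep, K))
    out_sigma = np.empty(keep)
    out_weights = np.empty((keep, K))
    out_z = np.empty((keep, N), dtype=np.int8)

    a0, b0 = priors.var_shape, priors.var_rate
    m0, v0 = priors.mean_loc, priors.mean_var
    alpha = priors.dirichlet

    for it in range(cfg.n_burn + keep):
        sigma = math.sqrt(sig2)

        # z_i | rest ~ Categorical( pi_k * prod_j f(y_ij | mu_k, sigma) )
        ll = _unit_class_loglik(n, s1, s2, means, sigma, trunc)
        logp = ll + np.log(weights)[None, :]
        if not np.all(np.isfinite(logp.max(axis=1))):
            raise FloatingPointError("non-finite class density during sampling")
        z = np.argmax(logp + rng.gumbel(size=(N, K)), axis=1)

        m_k = np.bincount(z, minlength=K).astype(float)  # subjects per class
        n_k = np.bincount(z, weights=n, minlength=K)  # observations per class
        s1_k = np.bincount(z, weights=s1, minlength=K)
        s2_k = np.bincount(z, weights=s2, minlength=K)

        # mu_k | rest: conjugate normal; MH-corrected for truncation.
        prec = 1.0 / v0 + n_k / sig2
        cond_var = 1.0 / prec
        cond_mean = cond_var * (m0 / v0 + s1_k / sig2)
        prop = rng.normal(cond_mean, np.sqrt(cond_var))
        if trunc:
            inside = (prop > 0.0) & (prop < 1.0)
            log_acc = np.full(K, -np.inf)
            if inside.any():
                log_acc[inside] = n_k[inside] * (
                    _log_trunc_normalizer(means[inside], sigma)
                    - _log_trunc_normalizer(prop[inside], sigma)
                )
            accept = np.log(rng.random(K)) < log_acc
            means = np.where(accept, prop, means)
        else:
            means = prop

        # sigma^2 | rest: conjugate inverse-gamma; MH-corrected for truncation.
        sse = float(np.sum(s2_k - 2.0 * means * s1_k + n_k * means**2))
        shape = a0 + 0.5 * n_total
        rate = b0 + 0.5 * sse
        prop_sig2 = rate / rng.gamma(shape)
        if trunc:
            log_acc_s = float(
                np.sum(
                    n_k
                    * (
                        _log_trunc_normalizer(means, sigma)
                        - _log_trunc_normalizer(means, math.sqrt(prop_sig2))
                    )
                )
            )
            if math.log(rng.random()) < log_acc_s:
                sig2 = prop_sig2
        else:
            sig2 = prop_sig2

        # pi | rest ~ Dirichlet(alpha + subject counts)
        weights = rng.dirichlet(alpha + m_k)

        if it >= cfg.n_burn:
            j = it - cfg.n_burn
            out_means[j] = means
            out_sigma[j] = math.sqrt(sig2)
            out_weights[j] = weights
            out_z[j] = z

    return out_means, out_sigma, out_weights, out_z


def gibbs_fit(data, K: int, priors: PriorSpec | None = None, config: MCMCConfig | None = None) -> PosteriorDraws:
    """Run the Gibbs sampler and return post-burn-in draws (unrelabeled).

    Identical data, priors, and config (including seed) give bit-identical
    draws.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    ids, n, s1, s2 = _rates_by_subject(data, subject_level=config.subject_level)
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(ids) < K:
        raise ValueError(f"need at least K={K} mixing units, got {len(ids)}")
    parts = []
    for c in range(config.n_chains):
        rng = np.random.default_rng([int(config.seed), c])
        parts.append(_run_chain(rng, n, s1, s2, K, priors, config))
    means = np.concatenate([p[0] for p in parts])
    sigma = np.concatenate([p[1] for p in parts])
    weights = np.concatenate([p[2] for p in parts])
    z = np.concatenate([p[3] for p in parts])
    chain = np.repeat(np.arange(config.n_chains), config.n_iter)
    return PosteriorDraws(
        means=means,
        sigma=sigma,
        weights=weights,
        z=z,
        chain=chain,
        subject_ids=list(ids),
        truncation_correction=config.truncation_correction,
        subject_level=config.subject_level,
    )


def relabel(draws: PosteriorDraws) -> PosteriorDraws:
    """Resolve label switching: sort components by mean within every draw.

    Weights are permuted alongside the means and the latent class
    indicators are remapped consistently. Idempotent.
    """
    order = np.argsort(draws.means, axis=1, kind="stable")
    inv = np.argsort(order, axis=1)
    z_new = np.take_along_axis(inv, draws.z.astype(np.intp), axis=1).astype(np.int8)
    return replace(
        draws,
        means=np.take_along_axis(draws.means, order, axis=1),
        weights=np.take_along_axis(draws.weights, order, axis=1),
        z=z_new,
    )


def posterior_mean_params(draws: PosteriorDraws) -> MixtureParams:
    """Posterior-mean parameters from (relabeled) draws."""
    w = draws.weights.mean(axis=0)
    return MixtureParams(draws.means.mean(axis=0), float(draws.sigma.mean()), w / w.sum())


def deviances(draws: PosteriorDraws, data, chunk: int = 2000) -> np.ndarray:
    """Per-draw deviance D = -2 log L(y | theta), z marginalized out."""
    _, n, s1, s2 = _rates_by_subject(data, subject_level=draws.subject_level)
    trunc = draws.truncation_correction
    out = np.empty(draws.n_draws)
    for lo in range(0, draws.n_draws, chunk):
        hi = min(lo + chunk, draws.n_draws)
        mu = draws.means[lo:hi]  # (C, K)
        sig = draws.sigma[lo:hi]  # (C,)
        w = draws.weights[lo:hi]
        sig2 = sig * sig
        quad = (
            s2[None, :, None]
            - 2.0 * mu[:, None, :] * s1[None, :, None]
            + n[None, :, None] * mu[:, None, :] ** 2
        )
        ll = (
            -n[None, :, None] * (np.log(sig)[:, None, None] + 0.5 * _LOG_2PI)
            - quad / (2.0 * sig2[:, None, None])
        )
        if trunc:
            logz = np.empty_like(mu)
            for j in range(hi - lo):
                logz[j] = _log_trunc_normalizer(mu[j], sig[j])
            ll = ll - n[None, :, None] * logz[:, None, :]
        with np.errstate(divide="ignore"):
            logw = np.log(w)
        out[lo:hi] = -2.0 * logsumexp(ll + logw[:, None, :], axis=2).sum(axis=1)
    return out


def dic(draws: PosteriorDraws, data) -> tuple[float, float, float]:
    """Deviance information criterion from posterior draws.

    Returns ``(DIC, Dbar, pD)`` with DIC = Dbar + pD and
    pD = Dbar - D(theta_bar); theta_bar is the posterior mean of the
    relabeled draws. Draws with non-finite deviance are excluded with a
    warning. DIC may be negative: continuous densities can exceed 1.
    """
    if draws.n_draws < 2:
        raise ValueError("DIC requires at least 2 draws")
    rel = relabel(draws)
    dev = deviances(rel, data)
    bad = ~np.isfinite(dev)
    if bad.any():
        warnings.warn(f"excluded {int(bad.sum())} draw(s) with non-finite deviance")
        dev = dev[~bad]
        if dev.size == 0:
            raise FloatingPointError("all deviances non-finite")
    dbar = float(dev.mean())
    theta_bar = posterior_mean_params(rel)
    d_hat = -2.0 * loglik(
        theta_bar, data, truncation=rel.truncation_correction, subject_level=rel.subject_level
    )
    p_d = dbar - d_hat
    return dbar + p_d, dbar, p_d


def split_rhat(x: np.ndarray, chain: np.ndarray) -> float:
    """Split-R-hat convergence diagnostic for a scalar parameter's draws."""
    halves = []
    for c in np.unique(chain):
        xs = x[chain == c]
        h = len(xs) // 2
        if h < 2:
            return float("nan")
        halves.append(xs[:h])
        halves.append(xs[h : 2 * h])
    seq = np.array(halves)  # (m, L)
    m, L = seq.shape
    chain_means = seq.mean(axis=1)
    b = L * chain_means.var(ddof=1)
    w = seq.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    var_hat = (L - 1) / L * w + b / L
    return float(math.sqrt(var_hat / w))


def fit_mixture(
    data,
    K: int,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    keep_draws: bool = False,
    rhat_threshold: float = 1.05,
) -> FitResult:
    """Fit the K-component mixture end to end and summarize the posterior.

    Runs the Gibbs sampler, relabels draws by ascending mean, computes
    DIC, per-subject posterior class probabilities and modal classes, and
    split-R-hat diagnostics (convergence warning above ``rhat_threshold``
    when more than one chain is run).
    """
    config = config or MCMCConfig()
    draws = relabel(gibbs_fit(data, K, priors=priors, config=config))
    dic_val, dbar, p_d = dic(draws, data)
    params = posterior_mean_params(draws)
    param_sd = None
    if draws.n_draws > 1:
        sd_w = draws.weights.std(axis=0)
        param_sd = (draws.means.std(axis=0), float(draws.sigma.std()), sd_w)

    n_subj = draws.z.shape[1]
    probs = np.zeros((n_subj, K))
    for k in range(K):
        probs[:, k] = (draws.z == k).mean(axis=0)
    probs /= probs.sum(axis=1, keepdims=True)
    modal = probs.argmax(axis=1)  # ties resolve to the lower class
    sizes = np.bincount(modal, minlength=K)

    rhat = {}
    for k in range(K):
        rhat[f"mu[{k + 1}]"] = split_rhat(draws.means[:, k], draws.chain)
        rhat[f"pi[{k + 1}]"] = split_rhat(draws.weights[:, k], draws.chain)
    rhat["sigma"] = split_rhat(draws.sigma, draws.chain)
    finite = [v for v in rhat.values() if np.isfinite(v)]
    converged = bool(finite) and max(finite) < rhat_threshold
    if config.n_chains > 1 and not converged:
        warnings.warn(
            f"split-R-hat above {rhat_threshold} for K={K}; treat downstream use with caution"
        )

    return FitResult(
        K=K,
        params=params,
        dic=dic_val,
        dbar=dbar,
        p_d=p_d,
        subject_ids=draws.subject_ids,
        class_probs=probs,
        modal_class=modal,
        smallest_class_size=int(sizes.min()),
        rhat=rhat,
        converged=converged,
        param_sd=param_sd,
        draws=draws if keep_draws else None,
    )
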