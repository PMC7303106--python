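"""Hierarchical Bayesian regression of clinical severity on daily features.

Model (per target, fitted independently):

    alpha_j, beta_j ~ Normal(mu, diag(tau)^2)          subject coefficients
    y_ji           ~ Normal(alpha_j + beta_j' x_ji, sigma)

with weakly informative hyperpriors mu_k ~ Normal(0, s_k) (s = 10 for the
intercept, 5 for weights), tau_k ~ HalfNormal(5) and sigma ~ HalfNormal(5).
tau is a per-weight SD (diagonal population covariance): a small tau_k
shrinks every subject's k-th weight toward the population mean mu_k
(partial pooling); a large tau_k lets subjects differ freely.

Inference is by a blocked Gibbs sampler: the subject coefficient vectors
and the population means have exact conditionally conjugate normal
updates, while tau_k and sigma (half-normal priors, not conjugate) are
updated by univariate slice sampling on the log scale.  Because the
centered Gibbs kernel mixes slowly when tau is small, every sweep is
followed by an ancillarity-sufficiency interweaving step: (mu, tau) are
re-drawn jointly in the non-centered parameterization theta_j = mu +
tau * e_j, where they are ordinary linear-regression coefficients with a
conjugate normal conditional (the sign ambiguity of tau in that
parameterization is resolved by folding onto tau >= 0, which leaves the
half-normal prior invariant).  Multiple chains with over-dispersed
initialisation support R-hat/ESS diagnostics (arviz).

The pooled Bayesian counterpart shares a single (alpha, beta) across
subjects and has no tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import linalg

from .features import n_weights
from .preprocess import ModelDataset

__all__ = [
    "PriorSpec",
    "SamplerSpec",
    "PosteriorSamples",
    "fit_hierarchical",
    "fit_pooled_bayesian",
    "posterior_predict",
    "point_predict",
    "convergence_report",
]


@dataclass(frozen=True)
class PriorSpec:
    """Scales of the weakly informative hyperpriors (all > 0)."""

    mu_scale_intercept: float = 10.0
    mu_scale_weight: float = 5.0
    tau_scale: float = 5.0
    sigma_scale: float = 5.0

    def __post_init__(self) -> None:
        if min(self.mu_scale_intercept, self.mu_scale_weight, self.tau_scale, self.sigma_scale) <= 0:
            raise ValueError("all prior scales must be positive")

    def mu_scales(self, n_features: int) -> np.ndarray:
        return np.array([self.mu_scale_intercept] + [self.mu_scale_weight] * n_features)


@dataclass(frozen=True)
class SamplerSpec:
    """MCMC run configuration.

    ``target_accept`` is kept for interface compatibility with gradient
    samplers; the Gibbs kernel used here has no accept/reject step.
    """

    chains: int = 4
    warmup: int = 500
    draws: int = 500
    seed: int = 0
    target_accept: float = 0.9

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for convergence diagnostics")
        if self.warmup < 0 or self.draws < 1:
            raise ValueError("warmup must be >= 0 and draws >= 1")


@dataclass
class PosteriorSamples:
    """Posterior draws indexed by (chain, draw).

    For the hierarchical model ``alpha`` has shape (C, S, J) and ``beta``
    (C, S, J, p).  For the pooled model the single coefficient vector is
    stored in ``mu`` and ``tau``/``alpha``/``beta`` are ``None``.
    """

    kind: str  # "hierarchical" | "pooled"
    mu: np.ndarray  # (C, S, 1 + p)
    sigma: np.ndarray  # (C, S)
    tau: np.ndarray | None
    alpha: np.ndarray | None
    beta: np.ndarray | None
    feature_names: list[str]
    subject_ids: list[str]
    target_name: str

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened into the leading axis."""
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"{name} not present in a {self.kind} posterior")
        return arr.reshape((-1,) + arr.shape[2:])

    def to_inferencedata(self, include_subject_params: bool = True) -> az.InferenceData:
        data = {"mu": self.mu, "sigma": self.sigma}
        if self.tau is not None:
            data["tau"] = self.tau
        if include_subject_params and self.alpha is not None:
            data["alpha"] = self.alpha
            data["beta"] = self.beta
        return az.from_dict(posterior=data)

    def save(self, path) -> None:
        self.to_inferencedata().to_netcdf(str(path))


# ---------------------------------------------------------------------------
# slice sampler for the non-conjugate scale parameters


def _slice_sample_positive(x0: float, logpdf, rng: np.random.Generator, w: float = 1.0) -> float:
    """One slice-sampling update of a positive scalar, on the log scale."""
    u0 = np.log(x0)

    def g(u: float) -> float:
        return logpdf(np.exp(u)) + u  # Jacobian of the log transform

    g0 = g(u0)
    log_y = g0 - rng.exponential()
    left = u0 - w * rng.random()
    right = left + w
    for _ in range(50):
        if g(left) <= log_y:
            break
        left -= w
    for _ in range(50):
        if g(right) <= log_y:
            break
        right += w
    for _ in range(100):
        u1 = left + (right - left) * rng.random()
        if g(u1) > log_y:
            return float(np.exp(u1))
        if u1 < u0:
            left = u1
        else:
            right = u1
    return float(np.exp(u0))  # pragma: no cover - pathological shrinkage


# ---------------------------------------------------------------------------
# fitting


def _design_blocks(dataset: ModelDataset, check_design: bool):
    X, y, subj = dataset.design()
    if len(y) == 0:
        raise ValueError("dataset is empty")
    if check_design:
        constant = [
            name
            for k, name in enumerate(dataset.feature_names)
            if np.ptp(X[:, k]) == 0.0
        ]
        if constant:
            raise ValueError(f"singular design: constant feature(s) {constant}")
    Xt = np.column_stack([np.ones(len(y)), X])
    return Xt, y, subj


def _chain_seeds(seed: int, chains: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(chains)]


def fit_hierarchical(
    dataset: ModelDataset,
    priors: PriorSpec = PriorSpec(),
    sampler: SamplerSpec = SamplerSpec(),
    sigma_fixed: float | None = None,
    check_design: bool = True,
    diagnostics: bool = True,
) -> PosteriorSamples:
    """Fit the partial-pooling model by blocked Gibbs sampling.

    ``sigma_fixed`` freezes the residual SD (used by closed-form oracle
    comparisons).  With ``diagnostics=True`` an R-hat/ESS check on the
    population parameters emits a warning naming poorly mixing parameters.
    """
    Xt, y, subj = _design_blocks(dataset, check_design)
    d = Xt.shape[1]
    J = int(subj.max()) + 1
    mu_scales = priors.mu_scales(d - 1)

    # sufficient statistics per subject
    XtX = np.stack([Xt[subj == j].T @ Xt[subj == j] for j in range(J)])
    Xty = np.stack([Xt[subj == j].T @ y[subj == j] for j in range(J)])
    yty = float(y @ y)
    N = len(y)

    pooled_theta, *_ = np.linalg.lstsq(Xt, y, rcond=None)
    resid_sd = max(float(np.std(y - Xt @ pooled_theta)), 0.1)

    C, W, S = sampler.chains, sampler.warmup, sampler.draws
    out_mu = np.empty((C, S, d))
    out_tau = np.empty((C, S, d))
    out_sigma = np.empty((C, S))
    out_alpha = np.empty((C, S, J))
    out_beta = np.empty((C, S, J, d - 1))

    for c, rng in enumerate(_chain_seeds(sampler.seed, C)):
        mu = pooled_theta + rng.normal(0, 0.2, size=d) * np.maximum(np.abs(pooled_theta), 0.5)
        tau = np.abs(rng.normal(1.0, 0.3, size=d)) + 0.1
        sigma = sigma_fixed if sigma_fixed is not None else resid_sd * np.exp(rng.normal(0, 0.3))
        theta = np.tile(mu, (J, 1))

        for it in range(W + S):
            inv_tau2 = 1.0 / tau**2
            # subject coefficients: conjugate normal
            for j in range(J):
                prec = XtX[j] / sigma**2 + np.diag(inv_tau2)
                L = linalg.cholesky(prec, lower=True)
                b = Xty[j] / sigma**2 + mu * inv_tau2
                m = linalg.cho_solve((L, True), b)
                z = rng.standard_normal(d)
                theta[j] = m + linalg.solve_triangular(L, z, lower=True, trans="T")
            # population means: conjugate normal
            prec_mu = J * inv_tau2 + 1.0 / mu_scales**2
            mean_mu = theta.sum(axis=0) * inv_tau2 / prec_mu
            mu = mean_mu + rng.standard_normal(d) / np.sqrt(prec_mu)
            # population SDs: slice
            ss = ((theta - mu) ** 2).sum(axis=0)
            for k in range(d):
                ss_k = ss[k]
                tau[k] = _slice_sample_positive(
                    tau[k],
                    lambda t, ss_k=ss_k: -J * np.log(t)
                    - ss_k / (2 * t**2)
                    - t**2 / (2 * priors.tau_scale**2),
                    rng,
                )
            # interweaving: joint conjugate redraw of (mu, tau) given the
            # non-centered residuals e_j = (theta_j - mu) / tau
            e = (theta - mu) / tau
            Wnc = np.concatenate([Xt, Xt * e[subj]], axis=1)
            prior_prec = np.concatenate([1.0 / mu_scales**2, np.full(d, 1.0 / priors.tau_scale**2)])
            prec = Wnc.T @ Wnc / sigma**2 + np.diag(prior_prec)
            L = linalg.cholesky(prec, lower=True)
            m = linalg.cho_solve((L, True), Wnc.T @ y / sigma**2)
            v = m + linalg.solve_triangular(L, rng.standard_normal(2 * d), lower=True, trans="T")
            mu = v[:d]
            tau_signed = v[d:]
            tau = np.maximum(np.abs(tau_signed), 1e-10)
            e = e * np.sign(tau_signed + (tau_signed == 0))
            theta = mu + tau * e
            # residual SD: slice
            if sigma_fixed is None:
                rss = (
                    yty
                    - 2.0 * float(np.einsum("jd,jd->", theta, Xty))
                    + float(np.einsum("jd,jde,je->", theta, XtX, theta))
                )
                rss = max(rss, 1e-9)
                sigma = max(
                    _slice_sample_positive(
                        sigma,
                        lambda s: -N * np.log(s) - rss / (2 * s**2) - s**2 / (2 * priors.sigma_scale**2),
                        rng,
                    ),
                    1e-5,  # keep the kernel proper when residuals vanish
                )
            if it >= W:
                t = it - W
                out_mu[c, t] = mu
                out_tau[c, t] = tau
                out_sigma[c, t] = sigma
                out_alpha[c, t] = theta[:, 0]
                out_beta[c, t] = theta[:, 1:]

    subjects = dataset.subjects
    post = PosteriorSamples(
        kind="hierarchical",
        mu=out_mu,
        sigma=out_sigma,
        tau=out_tau,
        alpha=out_alpha,
        beta=out_beta,
        feature_names=list(dataset.feature_names),
        subject_ids=subjects,
        target_name=dataset.target_name,
    )
    if diagnostics:
        _warn_if_unconverged(post)
    return post


def fit_pooled_bayesian(
    dataset: ModelDataset,
    priors: PriorSpec = PriorSpec(),
    sampler: SamplerSpec = SamplerSpec(),
    sigma_fixed: float | None = None,
    check_design: bool = True,
    diagnostics: bool = True,
) -> PosteriorSamples:
    """Fit the fully pooled counterpart (one shared coefficient vector)."""
    Xt, y, _ = _design_blocks(dataset, check_design)
    d = Xt.shape[1]
    N = len(y)
    scales = priors.mu_scales(d - 1)
    XtX = Xt.T @ Xt
    Xty = Xt.T @ y

    ols_theta, *_ = np.linalg.lstsq(Xt, y, rcond=None)
    resid_sd = max(float(np.std(y - Xt @ ols_theta)), 0.1)

    C, W, S = sampler.chains, sampler.warmup, sampler.draws
    out_theta = np.empty((C, S, d))
    out_sigma = np.empty((C, S))

    for c, rng in enumerate(_chain_seeds(sampler.seed, C)):
        sigma = sigma_fixed if sigma_fixed is not None else resid_sd * np.exp(rng.normal(0, 0.3))
        theta = ols_theta + rng.normal(0, 0.2, size=d)
        for it in range(W + S):
            prec = XtX / sigma**2 + np.diag(1.0 / scales**2)
            L = linalg.cholesky(prec, lower=True)
            m = linalg.cho_solve((L, True), Xty / sigma**2)
            theta = m + linalg.solve_triangular(L, rng.standard_normal(d), lower=True, trans="T")
            if sigma_fixed is None:
                r = y - Xt @ theta
                rss = max(float(r @ r), 1e-9)
                sigma = max(
                    _slice_sample_positive(
                        sigma,
                        lambda s: -N * np.log(s) - rss / (2 * s**2) - s**2 / (2 * priors.sigma_scale**2),
                        rng,
                    ),
                    1e-5,
                )
            if it >= W:
                out_theta[c, it - W] = theta
                out_sigma[c, it - W] = sigma

    post = PosteriorSamples(
        kind="pooled",
        mu=out_theta,
        sigma=out_sigma,
        tau=None,
        alpha=None,
        beta=None,
        feature_names=list(dataset.feature_names),
        subject_ids=dataset.subjects,
        target_name=dataset.target_name,
    )
    if diagnostics:
        _warn_if_unconverged(post)
    return post


# ---------------------------------------------------------------------------
# prediction


def _linear_predictor_draws(
    post: PosteriorSamples, X: np.ndarray, subject_ids, rng: np.random.Generator | None
) -> np.ndarray:
    """Draws of alpha_j + beta_j' x for each row, shape (n_draws, n_rows).

    Unseen subjects use a fresh (alpha, beta) ~ Normal(mu, tau) per draw
    when ``rng`` is given, or the population mean draws when ``rng`` is
    None (the exact predictive mean path).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != post.n_features:
        raise ValueError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else 'bad'} columns; "
            f"expected {post.n_features} in canonical order {post.feature_names}"
        )
    n = X.shape[0]
    if post.kind == "pooled":
        theta = post.stacked("mu")  # (S, d)
        return theta[:, :1] + theta[:, 1:] @ X.T

    alpha = post.stacked("alpha")  # (S, J)
    beta = post.stacked("beta")  # (S, J, p)
    mu = post.stacked("mu")
    tau = post.stacked("tau")
    S = alpha.shape[0]
    index = {s: i for i, s in enumerate(post.subject_ids)}
    out = np.empty((S, n))
    subject_ids = list(subject_ids)
    unseen = sorted({s for s in subject_ids if s not in index})
    fresh: dict[str, np.ndarray] = {}
    for s in unseen:
        if rng is None:
            fresh[s] = mu
        else:
            fresh[s] = mu + tau * rng.standard_normal(mu.shape)
    for i, (sid, x) in enumerate(zip(subject_ids, X)):
        if sid in index:
            j = index[sid]
            out[:, i] = alpha[:, j] + beta[:, j, :] @ x
        else:
            th = fresh[sid]
            out[:, i] = th[:, 0] + th[:, 1:] @ x
    return out


def posterior_predict(
    post: PosteriorSamples,
    X: np.ndarray,
    subject_ids,
    seed: int = 0,
) -> np.ndarray:
    """Posterior predictive draws y~ = alpha_j + beta_j' x + Normal(0, sigma).

    Returns an array of shape (n_draws, n_rows).  Subjects absent from the
    training data receive a fresh coefficient vector drawn from the
    population distribution in every posterior draw.
    """
    rng = np.random.default_rng(seed)
    lin = _linear_predictor_draws(post, X, subject_ids, rng)
    sigma = post.stacked("sigma")
    return lin + sigma[:, None] * rng.standard_normal(lin.shape)


def point_predict(post: PosteriorSamples, X: np.ndarray, subject_ids) -> np.ndarray:
    """Posterior predictive mean per row (deterministic given the draws).

    Equals the mean of the predictive draws exactly: the observation noise
    has mean zero, so the expectation reduces to the posterior mean of the
    linear predictor (unseen subjects: the population mean weights).
    """
    lin = _linear_predictor_draws(post, X, subject_ids, rng=None)
    return lin.mean(axis=0)


# ---------------------------------------------------------------------------
# diagnostics


def convergence_report(post: PosteriorSamples, include_subject_params: bool = True) -> pd.DataFrame:
    """R-hat and bulk ESS per parameter, with a ``flagged`` column.

    Parameters with R-hat > 1.05 or ESS < 100, or undefined diagnostics
    (degenerate chains), are flagged.
    """
    idata = post.to_inferencedata(include_subject_params=include_subject_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = az.summary(idata, kind="diagnostics")
    report = summary[["r_hat", "ess_bulk"]].copy()
    report["flagged"] = (
        (report["r_hat"] > 1.05) | (report["ess_bulk"] < 100) | report["r_hat"].isna()
    )
    return report


def _warn_if_unconverged(post: PosteriorSamples) -> None:
    report = convergence_report(post, include_subject_params=False)
    bad = report.index[report["flagged"]].tolist()
    if bad:
        warnings.warn(
            f"possible poor mixing (R-hat > 1.05 or ESS < 100) for: {bad}",
            RuntimeWarning,
            stacklevel=3,
        )
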