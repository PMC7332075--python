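"""Likelihood evaluation, per-session maximum likelihood, and the
mixed-effects empirical-Bayes EM.

Parameters bounded to (0, 1) (learning rates, eligibility trace, the MS
weight omega, the Forward3 weight zeta) are fitted through a logistic
transform, positive inverse temperatures through a log transform, and the
unbounded perseveration and Hybrid+ boost parameters through the identity.
All optimisation runs unconstrained in the transformed space.

The hierarchical procedure treats per-session parameters as draws from a
diagonal Gaussian prior in transformed space.  An EM loop alternates
Laplace-approximated per-session MAP fits (E-step) with moment updates of the
prior mean and SD (M-step); it is initialised from trimmed moments of the
per-session ML fits and iterates until the MAP estimates stop moving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from ._likelihood import PackedSession, pack_session, session_loglik
from .agents import Agent, AgentParams, ModelSpec
from .task import SessionData, TaskConfig

_BOUNDED01 = {"alpha1", "alpha2", "lam", "omega", "zeta"}
_POSITIVE = {"beta1", "beta2"}

_HUGE = 1e10
_SIGMA_FLOOR = 1e-3


def transform_kind(name: str) -> str:
    if name in _BOUNDED01:
        return "logistic"
    if name in _POSITIVE:
        return "log"
    return "identity"


def to_unconstrained(name: str, x: float) -> float:
    kind = transform_kind(name)
    if kind == "logistic":
        x = min(max(x, 1e-12), 1 - 1e-12)
        return float(np.log(x / (1.0 - x)))
    if kind == "log":
        return float(np.log(max(x, 1e-12)))
    return float(x)


def to_natural(name: str, u: float) -> float:
    kind = transform_kind(name)
    if kind == "logistic":
        return float(1.0 / (1.0 + np.exp(-np.clip(u, -500, 500))))
    if kind == "log":
        return float(np.exp(np.clip(u, -500, 50)))
    return float(u)


def vector_to_natural(spec: ModelSpec, u: Sequence[float]) -> np.ndarray:
    return np.array(
        [to_natural(n, v) for n, v in zip(spec.free_params, u)]
    )


def vector_to_unconstrained(spec: ModelSpec, x: Sequence[float]) -> np.ndarray:
    return np.array(
        [to_unconstrained(n, v) for n, v in zip(spec.free_params, x)]
    )


def params_from_unconstrained(spec: ModelSpec, u: Sequence[float]) -> AgentParams:
    return spec.expand(vector_to_natural(spec, u))


@dataclass
class PriorHyper:
    """Diagonal Gaussian empirical prior in transformed space."""

    names: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("prior sigma must be positive")

    def neg_log_pdf(self, u: np.ndarray) -> float:
        z = (np.asarray(u) - self.mu) / self.sigma
        return float(0.5 * np.sum(z * z) + np.sum(np.log(self.sigma)))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.mu + self.sigma * rng.standard_normal((size, len(self.mu)))

    def natural_means(self, spec: ModelSpec) -> dict[str, float]:
        return {
            n: to_natural(n, m) for n, m in zip(self.names, self.mu)
        }


@dataclass
class PosteriorFit:
    """Per-session Laplace posterior: MAP and inverse-Hessian variances."""

    m: np.ndarray               # MAP, transformed space
    sigma2: np.ndarray          # posterior variances, transformed space
    loglik: float               # data log-likelihood at the MAP
    log_posterior: float        # log lik + log prior at the MAP
    converged: bool = True
    restart_index: int = 0
    hessian_ok: bool = True


@dataclass
class EmpiricalBayesResult:
    prior: PriorHyper
    fits: list[PosteriorFit]
    spec: ModelSpec
    n_iterations: int = 0
    converged: bool = True

    def map_params(self) -> list[AgentParams]:
        return [params_from_unconstrained(self.spec, f.m) for f in self.fits]

    def total_loglik(self) -> float:
        return float(sum(f.loglik for f in self.fits))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def session_negloglik(
    params: AgentParams,
    session: SessionData | PackedSession,
    spec: ModelSpec,
    config: Optional[TaskConfig] = None,
    use_kernel: bool = True,
) -> float:
    """Negative log-likelihood of all free stage choices in the session.

    Forced stages contribute probability 1 and error trials are skipped for
    likelihood while the learner's state is carried through.
    """
    if np.any(~np.isfinite(params.as_array())):
        raise ValueError("non-finite parameters")
    if use_kernel:
        packed = session if isinstance(session, PackedSession) else pack_session(session)
        return -session_loglik(params, packed, spec, config)
    if isinstance(session, PackedSession):
        raise TypeError("python path requires a SessionData")
    agent = Agent(params, spec, config)
    rewards = session.normalized_rewards()
    total = 0.0
    for i, rec in enumerate(session.trials):
        if rec.is_error:
            continue
        lp1, lp2 = agent.evaluate_trial(rec, float(rewards[i]))
        total += lp1 + lp2
    return -total


def _objective(
    u: np.ndarray,
    packed: PackedSession,
    spec: ModelSpec,
    config: Optional[TaskConfig],
    prior: Optional[PriorHyper],
) -> float:
    params = params_from_unconstrained(spec, u)
    nll = -session_loglik(params, packed, spec, config)
    if prior is not None:
        nll += prior.neg_log_pdf(u)
    if not np.isfinite(nll):
        return _HUGE
    return nll


_START_BASE = {"beta1": np.log(2.0), "beta2": np.log(2.0)}


def _random_start(
    spec: ModelSpec, rng: np.random.Generator, prior: Optional[PriorHyper]
) -> np.ndarray:
    if prior is not None:
        return prior.mu + prior.sigma * rng.standard_normal(len(prior.mu))
    base = np.array([_START_BASE.get(n, 0.0) for n in spec.free_params])
    return base + rng.standard_normal(spec.n_free)


def _minimize(fun, u0: np.ndarray) -> optimize.OptimizeResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return optimize.minimize(fun, u0, method="BFGS",
                                 options={"maxiter": 500, "gtol": 1e-5})


def _best_of_restarts(
    packed: PackedSession,
    spec: ModelSpec,
    starts: list[np.ndarray],
    config: Optional[TaskConfig],
    prior: Optional[PriorHyper],
) -> tuple[np.ndarray, float, int, bool]:
    best_u, best_f, best_i, best_ok = None, np.inf, -1, False
    failures = []
    fun = lambda u: _objective(u, packed, spec, config, prior)
    for i, u0 in enumerate(starts):
        try:
            res = _minimize(fun, np.asarray(u0, dtype=float))
        except Exception as exc:  # pragma: no cover - optimizer blowups
            failures.append((i, str(exc)))
            continue
        if res.fun < best_f:
            best_u, best_f, best_i = res.x, float(res.fun), i
            best_ok = bool(res.success)
    if best_u is None:
        raise RuntimeError(f"all restarts failed: {failures}")
    return best_u, best_f, best_i, best_ok


def fit_ml_session(
    session: SessionData | PackedSession,
    spec: ModelSpec,
    n_restarts: int = 20,
    rng: Optional[np.random.Generator] = None,
    config: Optional[TaskConfig] = None,
    start: Optional[AgentParams] = None,
) -> tuple[AgentParams, float]:
    """Fixed-effects maximum likelihood for one session.

    Runs ``n_restarts`` quasi-Newton searches in transformed space from
    random starting points (plus an optional warm start) and keeps the best.
    Returns the fitted parameters and the attained negative log-likelihood.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = rng or np.random.default_rng(0)
    packed = session if isinstance(session, PackedSession) else pack_session(session)
    starts = []
    if start is not None:
        starts.append(vector_to_unconstrained(spec, spec.shrink(start)))
    while len(starts) < n_restarts:
        starts.append(_random_start(spec, rng, None))
    u, f, _, _ = _best_of_restarts(packed, spec, starts, config, None)
    return params_from_unconstrained(spec, u), f


# ---------------------------------------------------------------------------
# Laplace approximation
# ---------------------------------------------------------------------------

def _fd_hessian(fun, u: np.ndarray, h: float = 1e-3) -> np.ndarray:
    k = len(u)
    H = np.empty((k, k))
    f0 = fun(u)
    steps = h * np.maximum(1.0, np.abs(u))
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = steps[i]
        fp[i] = fun(u + e)
        fm[i] = fun(u - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = fun(u + ei + ej)
            fmm = fun(u - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * steps[i] * steps[j])
    return H


def laplace_variances(fun, u: np.ndarray) -> tuple[np.ndarray, bool]:
    """Posterior variances from the diagonal of the inverse Hessian of the
    negative log posterior; falls back to per-coordinate curvature when the
    Hessian is not positive definite."""
    H = _fd_hessian(fun, u)
    try:
        eigvals = np.linalg.eigvalsh(H)
        if np.all(eigvals > 0):
            return np.diag(np.linalg.inv(H)).copy(), True
    except np.linalg.LinAlgError:
        pass
    diag = np.diag(H)
    var = np.where(diag > 0, 1.0 / np.maximum(diag, 1e-8), 1.0)
    return var, False


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def em_estep(
    sessions: Sequence[SessionData | PackedSession],
    prior: PriorHyper,
    spec: ModelSpec,
    n_restarts: int = 101,
    rng: Optional[np.random.Generator] = None,
    config: Optional[TaskConfig] = None,
    warm_starts: Optional[Sequence[np.ndarray]] = None,
) -> list[PosteriorFit]:
    """Per-session MAP fits under the current prior with Laplace variances.

    One restart warm-starts from the previous iteration's MAP (or the ML fit),
    the rest start from prior draws.
    """
    rng = rng or np.random.default_rng(0)
    packs = [
        s if isinstance(s, PackedSession) else pack_session(s)
        for s in sessions
    ]
    fits: list[PosteriorFit] = []
    for i, packed in enumerate(packs):
        starts: list[np.ndarray] = []
        if warm_starts is not None and warm_starts[i] is not None:
            starts.append(np.asarray(warm_starts[i], dtype=float))
        while len(starts) < n_restarts:
            starts.append(_random_start(spec, rng, prior))
        u, f, ridx, ok = _best_of_restarts(packed, spec, starts, config, prior)
        fun = lambda v: _objective(v, packed, spec, config, prior)
        var, hess_ok = laplace_variances(fun, u)
        var = np.maximum(var, _SIGMA_FLOOR**2)
        ll = session_loglik(
            params_from_unconstrained(spec, u), packed, spec, config
        )
        fits.append(PosteriorFit(
            m=u, sigma2=var, loglik=float(ll), log_posterior=-f,
            converged=ok, restart_index=ridx, hessian_ok=hess_ok,
        ))
    return fits


def em_mstep(fits: Sequence[PosteriorFit], names: tuple[str, ...]) -> PriorHyper:
    """Moment update of the prior: the mean of the MAPs and the second moment
    of MAPs plus posterior variances around it."""
    if len(fits) == 0:
        raise ValueError("need at least one session")
    M = np.stack([f.m for f in fits])
    V = np.stack([f.sigma2 for f in fits])
    mu = M.mean(axis=0)
    var = (M**2 + V).mean(axis=0) - mu**2
    if np.any(var <= _SIGMA_FLOOR**2):
        warnings.warn(
            "prior variance floored for some parameters", RuntimeWarning
        )
        var = np.maximum(var, _SIGMA_FLOOR**2)
    return PriorHyper(names=names, mu=mu, sigma=np.sqrt(var))


def _trimmed_moments(
    M: np.ndarray, proportion_per_tail: float
) -> tuple[np.ndarray, np.ndarray]:
    n, k = M.shape
    cut = int(np.floor(n * proportion_per_tail))
    mu = np.empty(k)
    var = np.empty(k)
    for j in range(k):
        col = np.sort(M[:, j])
        trimmed = col[cut: n - cut] if n - 2 * cut >= 1 else col
        mu[j] = trimmed.mean()
        var[j] = trimmed.var(ddof=1) if len(trimmed) > 1 else 1.0
    return mu, np.maximum(var, 0.04)


def fit_empirical_bayes(
    sessions: Sequence[SessionData],
    spec: ModelSpec,
    rng: Optional[np.random.Generator] = None,
    config: Optional[TaskConfig] = None,
    n_restarts_ml: int = 20,
    n_restarts_e: int = 101,
    tol: float = 0.005,
    max_iter: int = 50,
    trim: float = 0.125,
) -> EmpiricalBayesResult:
    """Empirical-Bayes EM over sessions.

    The prior is initialised from the trimmed mean/variance (25% trimmed in
    total, i.e. 12.5% per tail, by default) of the per-session ML estimates,
    then E and M steps alternate until the largest absolute change in any MAP
    estimate falls below ``tol``; a final E-step refreshes the MAPs under the
    converged prior.
    """
    rng = rng or np.random.default_rng(0)
    packs = [pack_session(s) for s in sessions]
    names = spec.free_params
    ml_fits = [
        fit_ml_session(p, spec, n_restarts=n_restarts_ml, rng=rng, config=config)
        for p in packs
    ]
    M0 = np.stack([
        vector_to_unconstrained(spec, spec.shrink(params))
        for params, _ in ml_fits
    ])
    mu0, var0 = _trimmed_moments(M0, trim)
    prior = PriorHyper(names=names, mu=mu0, sigma=np.sqrt(var0))
    warm = [row for row in M0]
    prev_m = M0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        fits = em_estep(
            packs, prior, spec, n_restarts=n_restarts_e, rng=rng,
            config=config, warm_starts=warm,
        )
        M = np.stack([f.m for f in fits])
        prior = em_mstep(fits, names)
        delta = np.max(np.abs(M - prev_m))
        prev_m = M
        warm = [f.m for f in fits]
        if delta < tol:
            converged = True
            break
    fits = em_estep(
        packs, prior, spec, n_restarts=n_restarts_e, rng=rng,
        config=config, warm_starts=warm,
    )
    return EmpiricalBayesResult(
        prior=prior, fits=fits, spec=spec,
        n_iterations=n_iter, converged=converged,
    )
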