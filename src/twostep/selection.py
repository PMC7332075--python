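"""Model comparison: BIC, integrated BIC, random-effects Bayesian model
selection with protected exceedance probabilities, likelihood-ratio tests and
per-choice predictive probability.

The subject-level integrated BIC scores a model by the Monte-Carlo estimate of
each session's likelihood averaged over the empirical prior (log-domain),
penalised by the number of fitted prior parameters (a mean and a variance per
free parameter).  Protected exceedance probabilities come from the variational
Dirichlet treatment of random-effects model selection, mixed with the
equal-frequency null hypothesis via its posterior probability (the
Bayes-omnibus risk).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from ._likelihood import PackedSession, pack_session, session_loglik
from .agents import ModelSpec
from .fitting import PriorHyper, params_from_unconstrained
from .task import SessionData, TaskConfig


def bic(loglik: float, k_params: int, n_obs: int) -> float:
    """Schwarz criterion -2 logL + k ln n."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * float(loglik) + k_params * np.log(n_obs)


def integrated_session_loglik(
    packed: PackedSession,
    prior: PriorHyper,
    spec: ModelSpec,
    K: int,
    rng: np.random.Generator,
    config: Optional[TaskConfig] = None,
) -> float:
    """log of the prior-averaged session likelihood, via K prior draws."""
    draws = prior.sample(rng, K)
    lls = np.empty(K)
    for k in range(K):
        params = params_from_unconstrained(spec, draws[k])
        lls[k] = session_loglik(params, packed, spec, config)
    return float(special.logsumexp(lls) - np.log(K))


def bic_int(
    sessions: Sequence[SessionData | PackedSession],
    prior: PriorHyper,
    spec: ModelSpec,
    K: int = 1000,
    rng: Optional[np.random.Generator] = None,
    config: Optional[TaskConfig] = None,
    return_sessions: bool = False,
):
    """Subject-level integrated BIC.

    ``|M|`` counts two prior parameters (mean and variance) per free model
    parameter; ``|A|`` is the total number of analysed trials.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = rng or np.random.default_rng(0)
    packs = [
        s if isinstance(s, PackedSession) else pack_session(s)
        for s in sessions
    ]
    per_session = np.array([
        integrated_session_loglik(p, prior, spec, K, rng, config)
        for p in packs
    ])
    n_trials = int(sum(int(p.valid.sum()) for p in packs))
    size_m = 2 * spec.n_free
    value = -2.0 * per_session.sum() + size_m * np.log(n_trials)
    if return_sessions:
        return float(value), per_session
    return float(value)


# ---------------------------------------------------------------------------
# random-effects Bayesian model selection
# ---------------------------------------------------------------------------

@dataclass
class BmsResult:
    alpha: np.ndarray            # Dirichlet posterior over model frequencies
    expected_freq: np.ndarray
    exceedance: np.ndarray
    bor: float                   # posterior probability of the null
    pep: np.ndarray


def _vb_dirichlet(L: np.ndarray, alpha0: np.ndarray, max_iter: int = 500,
                  tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    n, k = L.shape
    alpha = alpha0.copy()
    z = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        e_ln_r = special.digamma(alpha) - special.digamma(alpha.sum())
        logu = L + e_ln_r
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        z_new = u / u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + z_new.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha, z = alpha_new, z_new
            break
        alpha, z = alpha_new, z_new
    return alpha, z


def _vb_free_energy(L: np.ndarray, alpha0: np.ndarray, alpha: np.ndarray,
                    z: np.ndarray) -> float:
    e_ln_r = special.digamma(alpha) - special.digamma(alpha.sum())
    zs = np.clip(z, 1e-300, None)
    data = float(np.sum(z * (L + e_ln_r - np.log(zs))))
    ln_b0 = float(np.sum(special.gammaln(alpha0)) - special.gammaln(alpha0.sum()))
    ln_b = float(np.sum(special.gammaln(alpha)) - special.gammaln(alpha.sum()))
    prior_term = float(np.sum((alpha0 - 1) * e_ln_r)) - ln_b0
    entropy_q = -ln_b - float(np.sum((alpha - 1) * e_ln_r))
    return data + prior_term + entropy_q


def _exceedance(alpha: np.ndarray, rng: np.random.Generator,
                n_samples: int) -> np.ndarray:
    k = len(alpha)
    if k == 2:
        # P(r1 > r2) = P(Beta(a1, a2) > 1/2), exact
        p1 = float(stats.beta.sf(0.5, alpha[0], alpha[1]))
        return np.array([p1, 1.0 - p1])
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=k) / n_samples


def protected_exceedance_probability(
    log_evidence: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    n_samples: int = 200_000,
) -> BmsResult:
    """Random-effects BMS over a sessions x models log-evidence matrix.

    Exceedance probabilities are protected by mixing with the null hypothesis
    of equal model frequencies, weighted by the null's posterior probability
    (computed from the variational free energy against the null evidence).
    A single model is defined to have PEP 1.
    """
    L = np.atleast_2d(np.asarray(log_evidence, dtype=float))
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    n, k = L.shape
    if k == 1:
        one = np.ones(1)
        return BmsResult(one, one, one, 0.0, one)
    rng = rng or np.random.default_rng(0)
    alpha0 = np.ones(k)
    alpha, z = _vb_dirichlet(L, alpha0)
    f1 = _vb_free_energy(L, alpha0, alpha, z)
    # null: every session draws its model uniformly
    f0 = float(np.sum(special.logsumexp(L, axis=1) - np.log(k)))
    bor = float(1.0 / (1.0 + np.exp(np.clip(f1 - f0, -700, 700))))
    phi = _exceedance(alpha, rng, n_samples)
    pep = phi * (1.0 - bor) + bor / k
    return BmsResult(
        alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        exceedance=phi,
        bor=bor,
        pep=pep,
    )


def exact_exceedance_2models(log_evidence: np.ndarray,
                             n_grid: int = 20001) -> float:
    """Brute-force P(r1 > 1/2 | data) for two models, by numerical integration
    of the exact random-effects posterior over the model frequency."""
    L = np.atleast_2d(np.asarray(log_evidence, dtype=float))
    assert L.shape[1] == 2
    r = np.linspace(1e-9, 1 - 1e-9, n_grid)
    # log p(y | r) = sum_n log(r e^{L_n1} + (1-r) e^{L_n2})
    ref = L.max(axis=1, keepdims=True)
    e = np.exp(L - ref)
    log_post = np.zeros_like(r)
    for i in range(L.shape[0]):
        log_post += np.log(r * e[i, 0] + (1 - r) * e[i, 1]) + ref[i, 0]
    log_post -= log_post.max()
    w = np.exp(log_post)
    w /= np.trapezoid(w, r)
    mask = r > 0.5
    return float(np.trapezoid(w[mask], r[mask]))


# ---------------------------------------------------------------------------
# nested-model tests and predictive accuracy
# ---------------------------------------------------------------------------

def is_nested(full: ModelSpec, nested: ModelSpec) -> bool:
    """True when ``nested`` is a constrained version of ``full``: compatible
    learner variants and a free-parameter set reachable by fixing parameters
    of the full model (tied or zeroed)."""
    if nested.mf_variant is not None and nested.mf_variant != full.mf_variant:
        return False
    if nested.ms_variant is not None and nested.ms_variant != full.ms_variant:
        return False
    if nested.hybrid_plus and not full.hybrid_plus:
        return False
    # a pure learner nests inside a hybrid (omega pinned at 0 or 1); otherwise
    # require the free parameters to be a subset
    if full.is_hybrid and not nested.is_hybrid:
        return True
    return set(nested.free_params) <= set(full.free_params)


def likelihood_ratio_test(
    loglik_full: float,
    loglik_nested: float,
    df: int,
    spec_full: Optional[ModelSpec] = None,
    spec_nested: Optional[ModelSpec] = None,
) -> tuple[float, float]:
    """2 * delta logL against chi-square with ``df`` degrees of freedom.

    A negative likelihood gain flags an optimizer failure of the full model.
    """
    if spec_full is not None and spec_nested is not None:
        if not is_nested(spec_full, spec_nested):
            raise ValueError("models are not nested")
    delta = float(loglik_full) - float(loglik_nested)
    if delta < -1e-8:
        raise RuntimeError(
            f"full model fits worse than nested (delta logL = {delta:.4g}); "
            "optimizer likely failed"
        )
    statistic = 2.0 * max(delta, 0.0)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, p


def predictive_probability(
    choice_probs: Sequence[float],
) -> tuple[float, float]:
    """Geometric-mean probability of the realized choices and a one-sided
    binomial test of above-chance prediction (chance 0.5 per two-option
    choice; a choice counts as predicted when its probability exceeds 0.5,
    ties counting half)."""
    p = np.asarray(choice_probs, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one choice")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("choice probabilities must lie in (0, 1]")
    gm = float(np.exp(np.mean(np.log(p))))
    n = p.size
    k = int(round(np.sum(p > 0.5) + 0.5 * np.sum(p == 0.5)))
    pval = float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)
    return gm, pval


def compare_models(
    evidence: dict[str, np.ndarray],
    bics: Optional[dict[str, float]] = None,
    bic_ints: Optional[dict[str, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Long-format comparison table across models.

    ``evidence`` maps model name to the per-session log evidences fed to the
    random-effects BMS (by default the MAP likelihoods from the hierarchical
    fit).
    """
    names = list(evidence)
    L = np.column_stack([np.asarray(evidence[m]) for m in names])
    bms = protected_exceedance_probability(L, rng=rng)
    rows = []
    for j, m in enumerate(names):
        rows.append({
            "model": m,
            "total_loglik": float(L[:, j].sum()),
            "bic": None if bics is None else bics.get(m),
            "bic_int": None if bic_ints is None else bic_ints.get(m),
            "expected_freq": bms.expected_freq[j],
            "exceedance": bms.exceedance[j],
            "pep": bms.pep[j],
        })
    return pd.DataFrame(rows)
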