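"""Compiled per-session likelihood kernel.

The canonical, readable trial loop lives in :mod:`twostep.agents`; this module
re-implements it as a numba kernel over packed per-session arrays so that the
thousands of likelihood evaluations needed by the optimizers stay cheap.  A
test asserts exact agreement between the two paths across model variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .agents import AgentParams, ModelSpec
from .task import SessionData, TaskConfig

_MS_CODE = {None: 0, "forward1": 1, "forward2": 2, "forward3": 3}


@dataclass(frozen=True)
class PackedSession:
    """Session flattened to arrays; invalid (error) trials carry -1 markers."""

    a1: np.ndarray
    s2: np.ndarray
    a2: np.ndarray
    level: np.ndarray
    r2: np.ndarray
    forced: np.ndarray
    valid: np.ndarray
    n_free_choices: int  # number of likelihood-bearing stage choices

    @property
    def n_trials(self) -> int:
        return self.a1.shape[0]


def pack_session(session: SessionData) -> PackedSession:
    n = session.n_trials
    a1 = np.full(n, -1, dtype=np.int64)
    s2 = np.full(n, -1, dtype=np.int64)
    a2 = np.full(n, -1, dtype=np.int64)
    level = np.full(n, -1, dtype=np.int64)
    r2 = np.zeros(n)
    forced = np.zeros(n, dtype=np.int64)
    valid = np.zeros(n, dtype=np.int64)
    rewards = session.normalized_rewards()
    n_free = 0
    for i, t in enumerate(session.trials):
        if t.is_error:
            continue
        if t.a2 is None or t.outcome_level is None:
            raise ValueError(
                f"trial {t.trial_index}: incomplete non-error trial"
            )
        valid[i] = 1
        a1[i], s2[i], a2[i] = t.a1, t.s2, t.a2
        level[i] = t.outcome_level
        r2[i] = rewards[i]
        forced[i] = t.forced_stage
        n_free += 2 - (1 if t.forced_stage in (1, 2) else 0)
    return PackedSession(a1, s2, a2, level, r2, forced, valid, n_free)


@njit(cache=True)
def _log_softmax2(z0, z1, a):
    """log P(choose action a) for a 2-option softmax with logits z0, z1."""
    d = (z1 - z0) if a == 1 else (z0 - z1)
    if d > 0.0:
        return -math.log1p(math.exp(-d))
    return d - math.log1p(math.exp(d))


@njit(cache=True)
def _session_logprobs(
    a1, s2, a2, level, r2, forced, valid,
    theta, use_mf, mf_q, ms_code, hyb_plus, p_common, mirror,
):
    n = a1.shape[0]
    lp1 = np.zeros(n)
    lp2 = np.zeros(n)
    alpha1, alpha2 = theta[0], theta[1]
    beta1, beta2 = theta[2], theta[3]
    kappa1, kappa2 = theta[4], theta[5]
    lam, omega, zeta = theta[6], theta[7], theta[8]
    L1, L2, L3 = theta[9], theta[10], theta[11]

    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    c_true = 0.0
    c_swap = 0.0
    last1 = -1
    last2 = np.full(2, -1, dtype=np.int64)
    have_prev = False
    prev_common = False
    prev_level = 0
    prev_a1 = -1

    for t in range(n):
        if valid[t] == 0:
            continue
        at1 = a1[t]
        st = s2[t]
        at2 = a2[t]

        # ---- first-stage action values
        v0 = q1[0]
        v1 = q1[1]
        if ms_code > 0:
            best0 = q2[0, 0] if q2[0, 0] > q2[0, 1] else q2[0, 1]
            best1 = q2[1, 0] if q2[1, 0] > q2[1, 1] else q2[1, 1]
            if ms_code == 1:
                p_major = p_common
            elif ms_code == 2:
                if c_true > c_swap:
                    p_major = p_common
                elif c_swap > c_true:
                    p_major = 1.0 - p_common
                else:
                    p_major = 0.5
            else:
                lp = math.log(p_common)
                lq = math.log(1.0 - p_common)
                ls_a = c_true * lp + c_swap * lq
                ls_b = c_true * lq + c_swap * lp
                log_struct = ls_a if ls_a > ls_b else ls_b
                log_unif = (c_true + c_swap) * math.log(0.5)
                z = zeta
                if z < 1e-12:
                    z = 1e-12
                if z > 1.0 - 1e-12:
                    z = 1.0 - 1e-12
                lw = math.log(z) + log_struct
                lu = math.log(1.0 - z) + log_unif
                m = lw if lw > lu else lu
                w = math.exp(lw - m) / (math.exp(lw - m) + math.exp(lu - m))
                if c_true >= c_swap:
                    p_major = w * p_common + (1.0 - w) * 0.5
                else:
                    p_major = w * (1.0 - p_common) + (1.0 - w) * 0.5
            ms0 = p_major * best0 + (1.0 - p_major) * best1
            ms1 = p_major * best1 + (1.0 - p_major) * best0
            if use_mf == 1:
                v0 = (1.0 - omega) * q1[0] + omega * ms0
                v1 = (1.0 - omega) * q1[1] + omega * ms1
            else:
                v0 = ms0
                v1 = ms1
        if hyb_plus == 1 and have_prev:
            if prev_level == 3:
                L = L1
            elif prev_level == 2:
                L = L2
            else:
                L = L3
            sgn = 1.0 if prev_common else -1.0
            if prev_a1 == 0:
                v0 += sgn * L
                if mirror == 1:
                    v1 -= sgn * L
            else:
                v1 += sgn * L
                if mirror == 1:
                    v0 -= sgn * L

        # ---- first-stage choice
        z0 = beta1 * (v0 + (kappa1 if last1 == 0 else 0.0))
        z1 = beta1 * (v1 + (kappa1 if last1 == 1 else 0.0))
        if forced[t] != 1:
            lp1[t] = _log_softmax2(z0, z1, at1)
        last1 = at1

        # ---- second-stage choice
        z0 = beta2 * (q2[st, 0] + (kappa2 if last2[st] == 0 else 0.0))
        z1 = beta2 * (q2[st, 1] + (kappa2 if last2[st] == 1 else 0.0))
        if forced[t] != 2:
            lp2[t] = _log_softmax2(z0, z1, at2)
        last2[st] = at2

        # ---- learning
        if mf_q == 1:
            nxt = q2[st, 0] if q2[st, 0] > q2[st, 1] else q2[st, 1]
        else:
            nxt = q2[st, at2]
        d1 = nxt - q1[at1]
        d2 = r2[t] - q2[st, at2]
        if use_mf == 1:
            q1[at1] += alpha1 * d1
            q2[st, at2] += alpha2 * d2
            q1[at1] += alpha1 * lam * d2
        else:
            q2[st, at2] += alpha2 * d2
        if ms_code >= 2:
            if st == at1:
                c_true += 1.0
            else:
                c_swap += 1.0
        have_prev = True
        prev_common = st == at1
        prev_level = level[t]
        prev_a1 = at1

    return lp1, lp2


def session_logprobs(
    params: AgentParams,
    packed: PackedSession,
    spec: ModelSpec,
    config: TaskConfig | None = None,
    mirror_unchosen: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial log-probabilities of the realized stage-1/stage-2 actions."""
    p_common = (config or TaskConfig()).p_common
    theta = params.as_array()
    return _session_logprobs(
        packed.a1, packed.s2, packed.a2, packed.level, packed.r2,
        packed.forced, packed.valid, theta,
        1 if spec.mf_variant is not None else 0,
        1 if spec.mf_variant == "q" else 0,
        _MS_CODE[spec.ms_variant],
        1 if spec.hybrid_plus else 0,
        p_common,
        1 if mirror_unchosen else 0,
    )


def session_loglik(
    params: AgentParams,
    packed: PackedSession,
    spec: ModelSpec,
    config: TaskConfig | None = None,
) -> float:
    lp1, lp2 = session_logprobs(params, packed, spec, config)
    return float(lp1.sum() + lp2.sum())
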