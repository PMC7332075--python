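"""Value-learning models and the stochastic choice rule.

The model family combines a model-free (MF) temporal-difference learner
(SARSA or Q-learning, with an optional within-trial eligibility trace) with a
model-sensitive (MS) learner that evaluates first-stage actions through a
transition model (``Forward1``: true probabilities known; ``Forward2``:
majority counting; ``Forward3``: hypothesis test between structured and
uniform transitions).  The Hybrid model mixes their first-stage values with
weight ``omega``; Hybrid+ adds a one-trial boost of the previously chosen
first-stage action, signed by the previous transition type and scaled per
outcome level (L1 high, L2 medium, L3 low).  Choices at both stages follow a
softmax with inverse temperature ``beta`` and a perseveration bonus ``kappa``
for repeating the action taken on the previous visit to the same state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .task import TaskConfig

PARAM_NAMES = (
    "alpha1", "alpha2", "beta1", "beta2", "kappa1", "kappa2",
    "lam", "omega", "zeta", "L1", "L2", "L3",
)


@dataclass(frozen=True)
class AgentParams:
    """The full parameter vector theta; unused entries sit at neutral values."""

    alpha1: float = 0.5
    alpha2: float = 0.5
    beta1: float = 1.0
    beta2: float = 1.0
    kappa1: float = 0.0
    kappa2: float = 0.0
    lam: float = 0.0
    omega: float = 0.0
    zeta: float = 0.5
    L1: float = 0.0
    L2: float = 0.0
    L3: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, vec: Sequence[float]) -> "AgentParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, vec))))

    def validate(self) -> None:
        for name in ("alpha1", "alpha2", "lam", "omega", "zeta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("inverse temperatures must be >= 0")


MF_VARIANTS = ("sarsa", "q")
MS_VARIANTS = ("forward1", "forward2", "forward3")
TIE_OPTIONS = ("alpha", "beta", "kappa")
ZERO_OPTIONS = ("kappa1", "kappa2", "lam")


@dataclass(frozen=True)
class ModelSpec:
    """Which learners are active and which parameters are free, tied or fixed.

    Pure MF fixes ``omega = 0``; pure MS fixes ``omega = 1`` (and has no
    first-stage TD learning, so ``alpha1`` and ``lam`` are inert); Hybrid
    requires both variants and frees ``omega``; ``hybrid_plus`` additionally
    frees L1-L3.
    """

    name: str = "custom"
    mf_variant: Optional[str] = "sarsa"
    ms_variant: Optional[str] = None
    hybrid_plus: bool = False
    ties: frozenset = frozenset()
    zeros: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.mf_variant is not None and self.mf_variant not in MF_VARIANTS:
            raise ValueError(f"unknown mf_variant {self.mf_variant!r}")
        if self.ms_variant is not None and self.ms_variant not in MS_VARIANTS:
            raise ValueError(f"unknown ms_variant {self.ms_variant!r}")
        if self.mf_variant is None and self.ms_variant is None:
            raise ValueError("at least one of mf_variant/ms_variant required")
        if self.hybrid_plus and not self.is_hybrid:
            raise ValueError("hybrid_plus requires both MF and MS variants")
        bad = set(self.ties) - set(TIE_OPTIONS)
        if bad:
            raise ValueError(f"unknown ties {bad}")
        bad = set(self.zeros) - set(ZERO_OPTIONS)
        if bad:
            raise ValueError(f"unknown zeros {bad}")

    @property
    def is_hybrid(self) -> bool:
        return self.mf_variant is not None and self.ms_variant is not None

    @property
    def free_params(self) -> tuple[str, ...]:
        """Names of the free parameters, tied pairs represented by their head."""
        names: list[str] = []
        has_mf_stage1 = self.mf_variant is not None
        if has_mf_stage1:
            names.append("alpha1")
            if "alpha" not in self.ties:
                names.append("alpha2")
        else:
            names.append("alpha2")
        names.append("beta1")
        if "beta" not in self.ties:
            names.append("beta2")
        if "kappa1" not in self.zeros:
            names.append("kappa1")
        if "kappa" not in self.ties and "kappa2" not in self.zeros:
            names.append("kappa2")
        if has_mf_stage1 and "lam" not in self.zeros:
            names.append("lam")
        if self.is_hybrid:
            names.append("omega")
        if self.ms_variant == "forward3":
            names.append("zeta")
        if self.hybrid_plus:
            names.extend(["L1", "L2", "L3"])
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def expand(self, free: Sequence[float]) -> AgentParams:
        """Map a free-parameter vector (natural space) to a full AgentParams."""
        free = list(map(float, free))
        if len(free) != self.n_free:
            raise ValueError(
                f"expected {self.n_free} free parameters, got {len(free)}"
            )
        vals = dict(zip(self.free_params, free))
        if self.mf_variant is not None and "alpha" in self.ties:
            vals["alpha2"] = vals["alpha1"]
        if self.mf_variant is None:
            vals["alpha1"] = 0.5  # inert: no first-stage TD learning
        if "beta" in self.ties:
            vals["beta2"] = vals["beta1"]
        if "kappa" in self.ties and "kappa1" in vals:
            vals["kappa2"] = vals["kappa1"]
        vals.setdefault("kappa1", 0.0)
        vals.setdefault("kappa2", 0.0)
        vals.setdefault("lam", 0.0)
        if not self.is_hybrid:
            vals["omega"] = 0.0 if self.ms_variant is None else 1.0
        vals.setdefault("zeta", 0.5)
        for L in ("L1", "L2", "L3"):
            vals.setdefault(L, 0.0)
        return AgentParams(**vals)

    def shrink(self, params: AgentParams) -> np.ndarray:
        """Project a full AgentParams onto this spec's free vector."""
        return np.array([getattr(params, n) for n in self.free_params])


def _registry() -> dict[str, ModelSpec]:
    return {
        # pure MF learners, full 7-parameter form
        "sarsa": ModelSpec(name="sarsa", mf_variant="sarsa"),
        "q": ModelSpec(name="q", mf_variant="q"),
        # pure MS learners: alpha2, beta1, beta2, shared kappa
        "forward1": ModelSpec(
            name="forward1", mf_variant=None, ms_variant="forward1",
            ties=frozenset({"kappa"}),
        ),
        "forward2": ModelSpec(
            name="forward2", mf_variant=None, ms_variant="forward2",
            ties=frozenset({"kappa"}),
        ),
        "forward3": ModelSpec(
            name="forward3", mf_variant=None, ms_variant="forward3",
            ties=frozenset({"kappa"}),
        ),
        # best hybrid form: shared alpha, shared kappa, no eligibility trace
        "hybrid": ModelSpec(
            name="hybrid", mf_variant="sarsa", ms_variant="forward1",
            ties=frozenset({"alpha", "kappa"}), zeros=frozenset({"lam"}),
        ),
        "hybrid_plus": ModelSpec(
            name="hybrid_plus", mf_variant="sarsa", ms_variant="forward1",
            hybrid_plus=True,
            ties=frozenset({"alpha", "kappa"}), zeros=frozenset({"lam"}),
        ),
    }


MODEL_REGISTRY = _registry()


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; choose from {sorted(MODEL_REGISTRY)}"
        ) from None


@dataclass
class AgentState:
    """Mutable per-session learner state; everything resets at session start."""

    q1: np.ndarray = field(default_factory=lambda: np.zeros(2))
    q2: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    # transition-mapping evidence counts for Forward2/3:
    # counts[0] tallies trials consistent with the true mapping (s2 == a1),
    # counts[1] trials consistent with the swapped mapping.
    counts: np.ndarray = field(default_factory=lambda: np.zeros(2))
    last1: int = -1
    last2: np.ndarray = field(default_factory=lambda: np.full(2, -1))
    # (was_common, outcome_level, a1) of the last completed trial
    prev_summary: Optional[tuple[bool, int, int]] = None

    def copy(self) -> "AgentState":
        return AgentState(
            q1=self.q1.copy(), q2=self.q2.copy(), counts=self.counts.copy(),
            last1=self.last1, last2=self.last2.copy(),
            prev_summary=self.prev_summary,
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def prediction_error(
    variant: str,
    stage: int,
    state: AgentState,
    a1: int,
    s2: int,
    a2: int,
    r2: float,
) -> float:
    """Temporal-difference error at the given stage.

    Stage 1 pays no reward; its error is driven by the second-stage value --
    the value of the action actually taken (SARSA) or of the better action
    (Q-learning).  Stage 2 has no successor value (the fictitious terminal
    state is worth 0), so its error is just ``r2 - Q(s2, a2)``.
    """
    if stage == 1:
        if variant == "sarsa":
            nxt = state.q2[s2, a2]
        elif variant == "q":
            nxt = state.q2[s2].max()
        else:
            raise ValueError(f"unknown MF variant {variant!r}")
        return float(nxt - state.q1[a1])
    if stage == 2:
        return float(r2 - state.q2[s2, a2])
    raise ValueError("stage must be 1 or 2")


def mf_update(
    state: AgentState,
    a1: int,
    s2: int,
    a2: int,
    delta1: float,
    delta2: float,
    params: AgentParams,
) -> None:
    """Apply the TD updates; the eligibility trace passes the second-stage
    error through to the first-stage value within the trial only."""
    state.q1[a1] += params.alpha1 * delta1
    state.q2[s2, a2] += params.alpha2 * delta2
    state.q1[a1] += params.alpha1 * params.lam * delta2


def update_transition_model(
    variant: str, state: AgentState, a1: int, s2: int
) -> None:
    """Accumulate transition evidence (Forward2/3); Forward1 keeps none."""
    if variant in ("forward2", "forward3"):
        state.counts[0 if s2 == a1 else 1] += 1
    elif variant != "forward1":
        raise ValueError(f"unknown MS variant {variant!r}")


def transition_beliefs(
    variant: str,
    state: AgentState,
    a1: int,
    p_common: float = 0.7,
    zeta: float = 0.5,
) -> np.ndarray:
    """P(s2 | a1) over the two second-stage states under the MS variant.

    Forward1 knows the true probabilities.  Forward2 assigns ``p_common`` to
    whichever action-state mapping has been observed more often (0.5/0.5 on
    ties).  Forward3 weighs the structured mapping against the uniform
    50/50 hypothesis: the prior weight ``zeta`` on the structured hypothesis
    is updated by the likelihood ratio of the observed transition counts, and
    the belief is the posterior-weighted mixture of the two transition rows.
    """
    major = a1  # true mapping: action 0 -> state 0, action 1 -> state 1
    out = np.empty(2)
    if variant == "forward1":
        out[major] = p_common
        out[1 - major] = 1.0 - p_common
        return out
    n_true, n_swap = state.counts
    if variant == "forward2":
        if n_true > n_swap:
            out[major] = p_common
        elif n_swap > n_true:
            out[major] = 1.0 - p_common
        else:
            out[major] = 0.5
        out[1 - major] = 1.0 - out[major]
        return out
    if variant == "forward3":
        lp, lq = math.log(p_common), math.log(1.0 - p_common)
        log_struct = max(n_true * lp + n_swap * lq, n_true * lq + n_swap * lp)
        log_unif = (n_true + n_swap) * math.log(0.5)
        # posterior weight of the structured hypothesis
        z = max(min(zeta, 1.0 - 1e-12), 1e-12)
        log_w = math.log(z) + log_struct
        log_u = math.log(1.0 - z) + log_unif
        m = max(log_w, log_u)
        w = math.exp(log_w - m) / (math.exp(log_w - m) + math.exp(log_u - m))
        if n_true >= n_swap:
            p_major = w * p_common + (1.0 - w) * 0.5
        else:
            p_major = w * (1.0 - p_common) + (1.0 - w) * 0.5
        out[major] = p_major
        out[1 - major] = 1.0 - p_major
        return out
    raise ValueError(f"unknown MS variant {variant!r}")


def ms_first_stage_values(
    state: AgentState,
    variant: str,
    p_common: float = 0.7,
    zeta: float = 0.5,
) -> np.ndarray:
    """First-stage MS values: transition-weighted best second-stage values."""
    best = state.q2.max(axis=1)  # per second-stage state
    vals = np.empty(2)
    for a in range(2):
        p = transition_beliefs(variant, state, a, p_common, zeta)
        vals[a] = p @ best
    return vals


def combine_hybrid(
    q_mf: np.ndarray, q_ms: np.ndarray, omega: float
) -> np.ndarray:
    if not (0.0 <= omega <= 1.0):
        raise ValueError("omega must lie in [0, 1]")
    return (1.0 - omega) * np.asarray(q_mf) + omega * np.asarray(q_ms)


def hybridplus_bonus(
    q_hyb: np.ndarray,
    prev_summary: Optional[tuple[bool, int, int]],
    params: AgentParams,
    mirror_unchosen: bool = False,
) -> np.ndarray:
    """Transient boost of the previously chosen first-stage action.

    ``prev_summary`` is (was_common, outcome_level, a1) from the immediately
    preceding completed trial; with no such trial the values pass through.
    The boost is +L_j after a common transition and -L_j after a rare one,
    with j indexing the outcome level (L1 high, L2 medium, L3 low).  It is
    recomputed fresh each trial and never accumulates.  ``mirror_unchosen``
    applies the opposite adjustment to the unchosen action as well.
    """
    q = np.asarray(q_hyb, dtype=float).copy()
    if prev_summary is None:
        return q
    was_common, level, a_prev = prev_summary
    L = {3: params.L1, 2: params.L2, 1: params.L3}[level]
    sgn = 1.0 if was_common else -1.0
    q[a_prev] += sgn * L
    if mirror_unchosen:
        q[1 - a_prev] -= sgn * L
    return q


def choice_probabilities(
    q: np.ndarray, beta: float, kappa: float, rep: np.ndarray
) -> np.ndarray:
    """Softmax over beta * (Q + kappa * rep), guarded in the log domain."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    z = beta * (np.asarray(q, dtype=float) + kappa * np.asarray(rep, dtype=float))
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite action values in softmax")
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _rep_vector(last: int) -> np.ndarray:
    rep = np.zeros(2)
    if last >= 0:
        rep[last] = 1.0
    return rep


class Agent:
    """Stateful wrapper running the per-trial pipeline.

    The same code path serves simulation (sampling choices from the softmax)
    and likelihood evaluation (returning the probabilities of realized
    actions); error trials are passed through untouched, forced stages
    contribute probability 1 but still update perseveration, values and the
    Hybrid+ summary.
    """

    def __init__(
        self,
        params: AgentParams,
        spec: ModelSpec,
        config: Optional[TaskConfig] = None,
        reward_norm: Optional[float] = None,
        mirror_unchosen: bool = False,
    ) -> None:
        params.validate()
        self.params = params
        self.spec = spec
        self.config = config or TaskConfig()
        # normalizer used when simulating (the session max is unknown online)
        self.reward_norm = (
            reward_norm
            if reward_norm is not None
            else self.config.reward_window_high[1]
        )
        self.mirror_unchosen = mirror_unchosen
        self.state = AgentState()

    # -- value computation ---------------------------------------------------
    def first_stage_values(self) -> np.ndarray:
        p = self.params
        spec = self.spec
        if spec.ms_variant is None:
            q = self.state.q1.copy()
        else:
            q_ms = ms_first_stage_values(
                self.state, spec.ms_variant, self.config.p_common, p.zeta
            )
            if spec.mf_variant is None:
                q = q_ms
            else:
                q = combine_hybrid(self.state.q1, q_ms, p.omega)
        if spec.hybrid_plus:
            q = hybridplus_bonus(
                q, self.state.prev_summary, p, self.mirror_unchosen
            )
        return q

    def first_stage_probs(self) -> np.ndarray:
        return choice_probabilities(
            self.first_stage_values(),
            self.params.beta1,
            self.params.kappa1,
            _rep_vector(self.state.last1),
        )

    def second_stage_probs(self, s2: int) -> np.ndarray:
        return choice_probabilities(
            self.state.q2[s2],
            self.params.beta2,
            self.params.kappa2,
            _rep_vector(int(self.state.last2[s2])),
        )

    # -- simulation hooks (used by task.run_session) --------------------------
    def simulate_first_stage(self, rec, rng) -> int:
        if rec.forced_stage == 1:
            a1 = int(rec.forced_option1)
        else:
            a1 = int(rng.random() < self.first_stage_probs()[1])
        self.state.last1 = a1
        return a1

    def simulate_second_stage(self, rec, rng) -> int:
        if rec.forced_stage == 2:
            a2 = int(rec.forced_option2)
        else:
            a2 = int(rng.random() < self.second_stage_probs(rec.s2)[1])
        self.state.last2[rec.s2] = a2
        return a2

    def observe_outcome(self, rec) -> None:
        r2 = (rec.juice_ms or 0.0) / self.reward_norm
        self._learn(rec.a1, rec.s2, rec.a2, rec.outcome_level, r2)

    # -- likelihood ------------------------------------------------------------
    def evaluate_trial(self, rec, r2: float) -> tuple[float, float]:
        """Log-probabilities of the realized actions (0.0 for forced stages);
        updates the learner exactly as in simulation."""
        if rec.is_error:
            return 0.0, 0.0
        if rec.transition is not None:
            expected = "common" if rec.s2 == self.config.common_successor(rec.a1) else "rare"
            if rec.transition != expected:
                raise ValueError(
                    f"trial {rec.trial_index}: transition label contradicts s2"
                )
        if rec.a2 is None:
            raise ValueError(
                f"trial {rec.trial_index}: missing second-stage action"
            )
        if rec.forced_stage == 1:
            lp1 = 0.0
        else:
            lp1 = float(np.log(self.first_stage_probs()[rec.a1]))
        self.state.last1 = rec.a1
        if rec.forced_stage == 2:
            lp2 = 0.0
        else:
            lp2 = float(np.log(self.second_stage_probs(rec.s2)[rec.a2]))
        self.state.last2[rec.s2] = rec.a2
        self._learn(rec.a1, rec.s2, rec.a2, rec.outcome_level, r2)
        return lp1, lp2

    # -- shared learning step --------------------------------------------------
    def _learn(self, a1: int, s2: int, a2: int, level: int, r2: float) -> None:
        spec, p = self.spec, self.params
        mf_variant = spec.mf_variant or "sarsa"
        d1 = prediction_error(mf_variant, 1, self.state, a1, s2, a2, r2)
        d2 = prediction_error(mf_variant, 2, self.state, a1, s2, a2, r2)
        if spec.mf_variant is not None:
            mf_update(self.state, a1, s2, a2, d1, d2, p)
        else:
            # pure MS: second-stage values still track immediate reward
            self.state.q2[s2, a2] += p.alpha2 * d2
        if spec.ms_variant is not None:
            update_transition_model(spec.ms_variant, self.state, a1, s2)
        self.state.prev_summary = (s2 == a1, level, a1)


def agent_trial_step(
    state: AgentState,
    params: AgentParams,
    spec: ModelSpec,
    record,
    r2: float,
    config: Optional[TaskConfig] = None,
) -> tuple[float, float, AgentState]:
    """Functional single-trial step: returns the two stage log-probabilities of
    the realized actions and the updated state (input state is not mutated)."""
    agent = Agent(params, spec, config)
    agent.state = state.copy()
    lp1, lp2 = agent.evaluate_trial(record, r2)
    return lp1, lp2, agent.state
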