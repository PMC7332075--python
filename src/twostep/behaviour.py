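"""Descriptive and regression analyses of choice and response-time data.

Variable coding follows the study conventions: C is the first-stage choice
(1 for the reference picture, here action 0), R the outcome level treated as
continuous (low = 1, medium = 2, high = 3) and T the transition type
(rare = 1, common = 0).  Predictors are mean-centred within session and
continuous ones additionally divided by twice their (population) SD before
interactions are formed, so coefficient magnitudes are directly comparable.

Error trials and forced trials are excluded from analysis; by default the
lagged history is built over the remaining analysed sequence (a ``calendar``
policy that keeps original trial adjacency is available as a switch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .task import SessionData

CHOICE_TERMS = ("C", "R", "T", "RxT", "RxC", "TxC", "RxTxC")
RT_TERMS = ("R", "T", "RxT")


@dataclass
class DesignMatrix:
    y: np.ndarray
    X: pd.DataFrame
    session_ids: np.ndarray
    n_dropped: int = 0
    degenerate_columns: tuple[str, ...] = ()

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class RegressionResult:
    """Per-session coefficients plus across-session summaries."""

    per_session: pd.DataFrame           # sessions x terms
    per_session_se: pd.DataFrame
    mean: pd.Series
    se: pd.Series
    tstat: pd.Series
    pvalue: pd.Series
    flags: dict = field(default_factory=dict)
    method: str = "fixed"


@dataclass
class DecayFit:
    amplitude: float
    decay: float
    adj_r2: float
    fitted: np.ndarray


# ---------------------------------------------------------------------------
# trial sequences
# ---------------------------------------------------------------------------

def analyzed_trials(session: SessionData, policy: str = "analyzed"):
    """Trials usable for analysis (non-error, fully free), with their calendar
    indices.  ``policy='calendar'`` returns all trials, leaving exclusion to
    the caller row-wise."""
    out = []
    for rec in session.trials:
        if rec.is_error:
            continue
        if policy == "analyzed" and rec.forced_stage != 0:
            continue
        out.append(rec)
    return out


def stay_table(
    sessions: Sequence[SessionData], policy: str = "analyzed"
) -> dict:
    """P(repeat previous first-stage choice) by previous outcome level and
    previous transition type.

    Returns per-session tables plus the across-session mean and SEM; empty
    cells are NaN, never zero.
    """
    index = pd.MultiIndex.from_product(
        [[1, 2, 3], ["common", "rare"]], names=["prev_level", "prev_transition"]
    )
    per_session = []
    for sess in sessions:
        recs = analyzed_trials(sess, policy)
        num = pd.Series(0.0, index=index)
        den = pd.Series(0.0, index=index)
        for prev, cur in zip(recs[:-1], recs[1:]):
            key = (prev.outcome_level, prev.transition)
            den[key] += 1
            num[key] += float(cur.a1 == prev.a1)
        with np.errstate(invalid="ignore"):
            tab = num / den.replace(0.0, np.nan)
        tab.name = sess.session_id
        per_session.append(tab)
    table = pd.DataFrame(per_session)
    return {
        "per_session": table,
        "mean": table.mean(axis=0, skipna=True),
        "sem": table.sem(axis=0, ddof=1),
    }


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _centre(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def _centre_scale(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    c = x - x.mean()
    return c / (2.0 * sd) if sd > 0 else c


def _session_cvars(recs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    C = np.array([1.0 if r.a1 == 0 else 0.0 for r in recs])
    R = np.array([float(r.outcome_level) for r in recs])
    T = np.array([1.0 if r.transition == "rare" else 0.0 for r in recs])
    return C, R, T


def build_choice_design(
    sessions: Sequence[SessionData],
    n_lags: int = 5,
    policy: str = "analyzed",
) -> DesignMatrix:
    """Lagged logistic design for first-stage choice.

    Columns: a constant plus, for each lag i in 1..n_lags, the centred and
    scaled C, R, T, RxT, RxC, TxC and RxTxC terms (interactions computed
    after the centring/scaling of their components).  Rows without a full lag
    history are dropped.
    """
    frames, ys, sids = [], [], []
    degenerate: set[str] = set()
    n_dropped = 0
    for sess in sessions:
        recs = analyzed_trials(sess, policy)
        n = len(recs)
        if n < n_lags + 1:
            n_dropped += n
            continue
        C, R, T = _session_cvars(recs)
        Cc, Rc, Tc = _centre(C), _centre_scale(R), _centre(T)
        cols: dict[str, np.ndarray] = {"const": np.ones(n - n_lags)}
        rows = slice(n_lags, n)
        for i in range(1, n_lags + 1):
            lag = slice(n_lags - i, n - i)
            terms = {
                "C": Cc[lag],
                "R": Rc[lag],
                "T": Tc[lag],
                "RxT": Rc[lag] * Tc[lag],
                "RxC": Rc[lag] * Cc[lag],
                "TxC": Tc[lag] * Cc[lag],
                "RxTxC": Rc[lag] * Tc[lag] * Cc[lag],
            }
            for name, col in terms.items():
                label = f"{name}_t-{i}"
                cols[label] = col
                if np.std(col) == 0:
                    degenerate.add(label)
        frames.append(pd.DataFrame(cols))
        ys.append(C[rows])
        sids.append(np.repeat(sess.session_id, n - n_lags))
        n_dropped += n_lags
    if not frames:
        return DesignMatrix(
            y=np.empty(0), X=pd.DataFrame(), session_ids=np.empty(0, dtype=object),
            n_dropped=n_dropped,
        )
    return DesignMatrix(
        y=np.concatenate(ys),
        X=pd.concat(frames, ignore_index=True),
        session_ids=np.concatenate(sids),
        n_dropped=n_dropped,
        degenerate_columns=tuple(sorted(degenerate)),
    )


def preprocess_rt(
    session: SessionData, kind: str = "rt1", policy: str = "analyzed"
) -> pd.Series:
    """Log-transform and z-score response times.

    First-stage RTs are z-scored separately per response side (sides differ
    systematically); fixation RTs within session only.  Points more than
    3 SDs from the individual mean are removed.  Indexed by calendar trial.
    """
    recs = analyzed_trials(session, policy)
    if kind == "rt1":
        vals = {r.trial_index: (r.rt1, r.side1) for r in recs if r.rt1}
    elif kind == "fixrt":
        vals = {r.trial_index: (r.fix_rt, 0) for r in recs if r.fix_rt}
    else:
        raise ValueError("kind must be 'rt1' or 'fixrt'")
    if not vals:
        return pd.Series(dtype=float)
    idx = np.array(sorted(vals))
    raw = np.array([vals[i][0] for i in idx], dtype=float)
    side = np.array([vals[i][1] for i in idx])
    if np.any(raw <= 0):
        raise ValueError("response times must be positive")
    logv = np.log(raw)
    z = np.full_like(logv, np.nan)
    for s in np.unique(side):
        mask = side == s
        if mask.sum() < 2:
            warnings.warn(
                f"side {s} has fewer than 2 observations; excluded",
                RuntimeWarning,
            )
            continue
        mu, sd = logv[mask].mean(), logv[mask].std(ddof=1)
        z[mask] = (logv[mask] - mu) / sd if sd > 0 else 0.0
    z[np.abs(z) > 3] = np.nan  # outlier rule
    return pd.Series(z, index=idx)


def build_rt_design(
    sessions: Sequence[SessionData],
    kind: str = "rt1",
    n_lags: int = 5,
    policy: str = "analyzed",
) -> DesignMatrix:
    """Lagged linear design for preprocessed RT/fixRT.

    Columns: constant, a linearly increasing fatigue term (scaled calendar
    trial count) and, per lag, R, T and RxT -- no interaction with the
    previous first-stage choice.
    """
    frames, ys, sids = [], [], []
    degenerate: set[str] = set()
    n_dropped = 0
    for sess in sessions:
        recs = analyzed_trials(sess, policy)
        n = len(recs)
        if n < n_lags + 1:
            n_dropped += n
            continue
        rt = preprocess_rt(sess, kind=kind, policy=policy)
        _, R, T = _session_cvars(recs)
        Rc, Tc = _centre_scale(R), _centre(T)
        fatigue = _centre_scale(
            np.array([float(r.trial_index) for r in recs])
        )
        cols: dict[str, np.ndarray] = {
            "const": np.ones(n - n_lags),
            "F": fatigue[n_lags:],
        }
        for i in range(1, n_lags + 1):
            lag = slice(n_lags - i, n - i)
            for name, col in {
                "R": Rc[lag], "T": Tc[lag], "RxT": Rc[lag] * Tc[lag],
            }.items():
                label = f"{name}_t-{i}"
                cols[label] = col
                if np.std(col) == 0:
                    degenerate.add(label)
        y = np.array([
            rt.get(r.trial_index, np.nan) for r in recs[n_lags:]
        ])
        keep = np.isfinite(y)
        n_dropped += int((~keep).sum()) + n_lags
        frames.append(pd.DataFrame(cols)[keep])
        ys.append(y[keep])
        sids.append(np.repeat(sess.session_id, int(keep.sum())))
    if not frames:
        return DesignMatrix(
            y=np.empty(0), X=pd.DataFrame(), session_ids=np.empty(0, dtype=object),
            n_dropped=n_dropped,
        )
    return DesignMatrix(
        y=np.concatenate(ys),
        X=pd.concat(frames, ignore_index=True),
        session_ids=np.concatenate(sids),
        n_dropped=n_dropped,
        degenerate_columns=tuple(sorted(degenerate)),
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _summarize(per_session: pd.DataFrame, per_se: pd.DataFrame,
               flags: dict, method: str) -> RegressionResult:
    mean = per_session.mean(axis=0)
    se = per_session.sem(axis=0, ddof=1)
    n = per_session.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    p = pd.Series(
        2 * stats.t.sf(np.abs(t.values), df=max(n - 1, 1)), index=mean.index
    )
    return RegressionResult(
        per_session=per_session, per_session_se=per_se,
        mean=mean, se=se, tstat=t, pvalue=p, flags=flags, method=method,
    )


def _fit_sessions(design: DesignMatrix, family: str) -> RegressionResult:
    rows, ses, flags = [], [], {}
    for sid in pd.unique(design.session_ids):
        mask = design.session_ids == sid
        X = design.X[mask]
        y = design.y[mask]
        try:
            if family == "logistic":
                model = sm.GLM(y, X, family=sm.families.Binomial())
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(maxiter=200)
                if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e3):
                    raise sm.tools.sm_exceptions.PerfectSeparationError
            else:
                res = sm.OLS(y, X).fit()
            coefs, bse = res.params, res.bse
        except Exception:
            # separation or failure: small ridge penalty, flagged
            flags[sid] = "penalized"
            if family == "logistic":
                res = sm.Logit(y, X).fit_regularized(
                    alpha=1.0, disp=0, maxiter=500
                )
                coefs = res.params
            else:
                res = sm.OLS(y, X).fit_regularized(alpha=1.0, L1_wt=0.0)
                coefs = res.params
            bse = pd.Series(np.nan, index=design.X.columns)
        rows.append(pd.Series(coefs, index=design.X.columns, name=sid))
        ses.append(pd.Series(bse, index=design.X.columns, name=sid))
    per_session = pd.DataFrame(rows)
    per_se = pd.DataFrame(ses)
    return _summarize(per_session, per_se, flags, "fixed")


def fit_logistic_fixed(design: DesignMatrix) -> RegressionResult:
    """Per-session ML logistic fits with across-session one-sample t-tests."""
    if design.X.empty:
        raise ValueError("empty design")
    return _fit_sessions(design, "logistic")


def fit_linear_fixed(design: DesignMatrix) -> RegressionResult:
    if design.X.empty:
        raise ValueError("empty design")
    return _fit_sessions(design, "linear")


def contrast_ttest(
    result: RegressionResult, term_a: str, term_b: str, absolute: bool = True
) -> tuple[float, float]:
    """Across-session paired t-test on a coefficient contrast, by default on
    the magnitudes |b_a| - |b_b|."""
    a = result.per_session[term_a].values
    b = result.per_session[term_b].values
    d = (np.abs(a) - np.abs(b)) if absolute else (a - b)
    t, p = stats.ttest_1samp(d, 0.0)
    return float(t), float(p)


def coefficient_set_ftest(
    result: RegressionResult, terms: Sequence[str]
) -> tuple[float, float]:
    """Wald chi-square test that a set of mixed/mean coefficients is zero."""
    stat = 0.0
    for term in terms:
        stat += (result.mean[term] / result.se[term]) ** 2
    p = float(stats.chi2.sf(stat, len(terms)))
    return float(stat), p


def fit_mixed_regression(
    design: DesignMatrix, family: str = "logistic"
) -> RegressionResult:
    """Random-effects summary treating per-session coefficients as draws from
    a population distribution.

    Each coefficient is combined across sessions with a DerSimonian-Laird
    random-effects model (between-session variance estimated by moments);
    sessions where the per-session fit failed fall back to the fixed-effects
    summary with a flag.
    """
    fixed = _fit_sessions(design, family)
    B = fixed.per_session
    S = fixed.per_session_se
    if B.shape[0] < 2:
        raise ValueError("mixed-effects summary needs at least 2 sessions")
    mean, se = {}, {}
    fallback = []
    for col in B.columns:
        b = B[col].values
        s = S[col].values
        ok = np.isfinite(b) & np.isfinite(s) & (s > 0)
        if ok.sum() < 2:
            fallback.append(col)
            mean[col] = fixed.mean[col]
            se[col] = fixed.se[col]
            continue
        b, v = b[ok], s[ok] ** 2
        w = 1.0 / v
        bbar = np.sum(w * b) / np.sum(w)
        q = np.sum(w * (b - bbar) ** 2)
        df = ok.sum() - 1
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        w_star = 1.0 / (v + tau2)
        mean[col] = float(np.sum(w_star * b) / np.sum(w_star))
        se[col] = float(np.sqrt(1.0 / np.sum(w_star)))
    mean_s = pd.Series(mean)[B.columns]
    se_s = pd.Series(se)[B.columns]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_s / se_s
    p = pd.Series(2 * stats.norm.sf(np.abs(t.values)), index=B.columns)
    flags = dict(fixed.flags)
    if fallback:
        flags["fallback_columns"] = tuple(fallback)
    return RegressionResult(
        per_session=B, per_session_se=S, mean=mean_s, se=se_s,
        tstat=t, pvalue=p, flags=flags, method="mixed",
    )


# ---------------------------------------------------------------------------
# exponential decay of lag profiles
# ---------------------------------------------------------------------------

def fit_decay(mean_coefficients: Sequence[float]) -> DecayFit:
    """Least-squares fit of A * exp(b * lag) to the mean coefficients over
    lags 1..n; ``b`` is the decay constant (negative for decaying magnitude).
    """
    c = np.asarray(mean_coefficients, dtype=float)
    n = len(c)
    lags = np.arange(1, n + 1, dtype=float)
    if np.allclose(c, c[0]):
        fitted = np.full(n, c[0])
        return DecayFit(amplitude=float(c[0]), decay=0.0, adj_r2=1.0,
                        fitted=fitted)

    def model(lag, A, b):
        return A * np.exp(b * lag)

    # log-linear warm start on magnitudes when the sign is consistent
    p0 = (c[0] if c[0] != 0 else 1.0, 0.0)
    if np.all(c > 0) or np.all(c < 0):
        sgn = np.sign(c[0])
        slope, intercept = np.polyfit(lags, np.log(np.abs(c)), 1)
        p0 = (sgn * np.exp(intercept), slope)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(model, lags, c, p0=p0, maxfev=20000)
    except Exception:
        popt = p0
    fitted = model(lags, *popt)
    ss_res = float(np.sum((c - fitted) ** 2))
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - 3, 1)
    return DecayFit(amplitude=float(popt[0]), decay=float(popt[1]),
                    adj_r2=float(adj), fitted=fitted)
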