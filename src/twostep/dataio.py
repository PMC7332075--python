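"""Dataset I/O: the tidy per-trial CSV dialect and a glossary-driven reader
for deposited behavioural data.

Deposited datasets arrive as a MATLAB container of per-trial numeric vectors
whose internal names are only documented in an accompanying glossary table
(xlsx or csv with ``variable``, ``field`` and optional ``description``
columns).  The reader maps glossary entries onto :class:`TrialRecord` fields
rather than hard-coding names; unmapped variables are preserved as
passthrough columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io

from .task import ERROR_CODES, SessionData, TrialRecord

#: TrialRecord fields a deposited dataset must provide (glossary `field`
#: values), with human-readable names for error messages.
MANDATORY_FIELDS = {
    "session_index": "session index",
    "a1": "first-stage choice",
    "s2": "second-stage state",
    "a2": "second-stage choice",
    "outcome_level": "outcome level",
    "juice_ms": "juice amount",
}

OPTIONAL_FIELDS = (
    "forced_stage", "error_code", "rt1", "rt2", "fix_rt", "side1", "side2",
    "transition",
)

_INT_FIELDS = {"a1", "s2", "a2", "outcome_level", "forced_stage",
               "side1", "side2"}
_FLOAT_FIELDS = {"juice_ms", "rt1", "rt2", "fix_rt"}


@dataclass
class DatasetBundle:
    """Typed sessions plus raw passthrough columns for one subject."""

    sessions: list[SessionData]
    passthrough: pd.DataFrame
    subject_id: str = "unknown"
    n_error_trials: int = 0
    n_forced_trials: int = 0

    def analyzed_sessions(self) -> list[SessionData]:
        """Sessions with error and forced trials dropped (raw rows retained
        in the bundle)."""
        out = []
        for sess in self.sessions:
            keep = [
                t for t in sess.trials
                if not t.is_error and t.forced_stage == 0
            ]
            out.append(SessionData(
                trials=keep, subject_id=sess.subject_id,
                session_id=sess.session_id,
            ))
        return out


# ---------------------------------------------------------------------------
# tidy CSV dialect
# ---------------------------------------------------------------------------

def sessions_to_csv(sessions: Sequence[SessionData], path) -> None:
    frames = [s.to_frame() for s in sessions]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def sessions_from_csv(path) -> list[SessionData]:
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("session_id", sort=False):
        trials = []
        for _, row in grp.iterrows():
            kwargs = {}
            for f in TrialRecord.__dataclass_fields__:
                if f not in row.index:
                    continue
                v = row[f]
                if pd.isna(v):
                    kwargs[f] = None
                elif f in _INT_FIELDS or f in ("trial_index", "forced_option1",
                                               "forced_option2"):
                    kwargs[f] = int(v)
                elif f in _FLOAT_FIELDS:
                    kwargs[f] = float(v)
                else:
                    kwargs[f] = v
            kwargs["forced_stage"] = int(row.get("forced_stage", 0) or 0)
            trials.append(TrialRecord(**kwargs))
        subject = grp["subject_id"].iloc[0] if "subject_id" in grp else "unknown"
        out.append(SessionData(trials=trials, session_id=str(sid),
                               subject_id=str(subject)))
    return out


# ---------------------------------------------------------------------------
# deposited container
# ---------------------------------------------------------------------------

def read_glossary(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".xlsx", ".xls"):
        gl = pd.read_excel(path)
    else:
        gl = pd.read_csv(path)
    gl.columns = [c.strip().lower() for c in gl.columns]
    if not {"variable", "field"} <= set(gl.columns):
        raise ValueError("glossary must have 'variable' and 'field' columns")
    dup = gl["field"][gl["field"].notna() & gl["field"].duplicated()]
    dup = [d for d in dup if d]
    if dup:
        raise ValueError(f"glossary maps multiple variables to fields {dup}")
    return gl


def _coerce(field_name: str, values: np.ndarray):
    if field_name == "error_code":
        out = []
        for v in values:
            if isinstance(v, str):
                out.append(v if v else None)
            else:
                v = int(v) if np.isfinite(v) else 0
                out.append(None if v <= 0 else ERROR_CODES[(v - 1) % len(ERROR_CODES)])
        return out
    if field_name in _INT_FIELDS:
        # negative values are the container's "missing" sentinel
        return [None if (not np.isfinite(v) or v < 0) else int(v)
                for v in values]
    if field_name in _FLOAT_FIELDS:
        return [None if not np.isfinite(v) else float(v) for v in values]
    return list(values)


def read_deposited_dataset(
    path, glossary_path, subject_id: Optional[str] = None
) -> DatasetBundle:
    """Load a deposited .mat behavioural file through its glossary.

    Every glossary-mapped variable lands in exactly one TrialRecord field;
    variables without a ``field`` entry are kept as passthrough columns.
    Missing mandatory fields raise an error naming the quantity.
    """
    glossary = read_glossary(glossary_path)
    mat = scipy.io.loadmat(path, squeeze_me=True)
    data = {k: np.atleast_1d(v) for k, v in mat.items()
            if not k.startswith("__")}

    mapped: dict[str, np.ndarray] = {}
    passthrough: dict[str, np.ndarray] = {}
    for _, row in glossary.iterrows():
        var = str(row["variable"]).strip()
        fld = row["field"]
        if var not in data:
            if isinstance(fld, str) and fld in MANDATORY_FIELDS:
                raise ValueError(
                    f"missing mandatory column for {MANDATORY_FIELDS[fld]!r} "
                    f"(variable {var!r})"
                )
            continue
        if isinstance(fld, str) and fld and fld != "nan":
            mapped[fld] = data[var]
        else:
            passthrough[var] = data[var]
    for var in data:
        if var not in set(glossary["variable"].astype(str).str.strip()):
            passthrough[var] = data[var]

    for fld, label in MANDATORY_FIELDS.items():
        if fld not in mapped:
            raise ValueError(f"missing mandatory column for {label!r}")

    n = len(mapped["session_index"])
    for fld, vals in mapped.items():
        if len(vals) != n:
            raise ValueError(
                f"variable for field {fld!r} has length {len(vals)} != {n}"
            )
    cols = {fld: _coerce(fld, np.asarray(vals, dtype=object if
                                         vals.dtype.kind in "US" else float))
            for fld, vals in mapped.items()}

    session_idx = np.asarray(mapped["session_index"], dtype=float).astype(int)
    sessions: list[SessionData] = []
    n_err = n_forced = 0
    sid_name = subject_id or Path(path).stem
    for sid in pd.unique(session_idx):
        rows = np.where(session_idx == sid)[0]
        trials = []
        for j, i in enumerate(rows):
            kwargs = {"session_id": f"s{sid}", "trial_index": j}
            for fld in set(cols) - {"session_index"}:
                kwargs[fld] = cols[fld][i]
            kwargs["forced_stage"] = int(kwargs.get("forced_stage") or 0)
            rec = TrialRecord(**kwargs)
            if rec.is_error:
                n_err += 1
            elif rec.forced_stage:
                n_forced += 1
            if rec.transition is None and not rec.is_error:
                rec.transition = "common" if rec.s2 == rec.a1 else "rare"
            trials.append(rec)
        sessions.append(SessionData(trials=trials, session_id=f"s{sid}",
                                    subject_id=sid_name))
    pt = pd.DataFrame({k: list(v) for k, v in passthrough.items()})
    return DatasetBundle(
        sessions=sessions, passthrough=pt, subject_id=sid_name,
        n_error_trials=n_err, n_forced_trials=n_forced,
    )


def write_deposited_dataset(
    sessions: Sequence[SessionData], path, glossary_path
) -> None:
    """Write sessions in the deposited-container reference layout (a .mat of
    per-trial vectors plus a CSV glossary).  Used to build synthetic fixtures
    that exercise the reader; the layout is this package's reference dialect,
    not a copy of any third-party file."""
    rows = []
    for k, sess in enumerate(sessions):
        for t in sess.trials:
            rows.append({
                "sess_num": k,
                "choice1": -1 if t.a1 is None else t.a1,
                "state2": -1 if t.s2 is None else t.s2,
                "choice2": -1 if t.a2 is None else t.a2,
                "outcome": -1 if t.outcome_level is None else t.outcome_level,
                "juice": np.nan if t.juice_ms is None else t.juice_ms,
                "forced": t.forced_stage,
                "err": 0 if t.error_code is None
                       else ERROR_CODES.index(t.error_code) + 1,
                "rt_first": np.nan if t.rt1 is None else t.rt1,
                "rt_second": np.nan if t.rt2 is None else t.rt2,
                "rt_fix": np.nan if t.fix_rt is None else t.fix_rt,
                "side_first": -1 if t.side1 is None else t.side1,
                "side_second": -1 if t.side2 is None else t.side2,
            })
    df = pd.DataFrame(rows)
    # error trials: blank downstream fields are encoded as NaN / -1
    mat = {c: df[c].to_numpy(dtype=float) for c in df.columns}
    scipy.io.savemat(path, mat)
    glossary = pd.DataFrame({
        "variable": ["sess_num", "choice1", "state2", "choice2", "outcome",
                     "juice", "forced", "err", "rt_first", "rt_second",
                     "rt_fix", "side_first", "side_second"],
        "field": ["session_index", "a1", "s2", "a2", "outcome_level",
                  "juice_ms", "forced_stage", "error_code", "rt1", "rt2",
                  "fix_rt", "side1", "side2"],
        "description": ["session number"] + ["see field"] * 12,
    })
    glossary.to_csv(glossary_path, index=False)
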