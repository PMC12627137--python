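"""Trial-level data: reading, filtering, and attentional-control roles.

The pipeline operates on a tidy trial table with one row per trial:
``subject``, ``task``, ``condition`` (congruent / incongruent / neutral /
other), ``rt`` in seconds and binary ``correct``.  Before modeling, data are
cleaned the way censored-response-window designs require:

1. per task, participants are excluded when more than a small fraction of
   their trials fell beyond the task's response window (their remaining
   distribution is censored, which biases diffusion estimates);
2. remaining trials faster than ``rt_min`` or slower than the window are
   dropped.

Participant exclusion runs strictly before trial trimming, the exclusion
fraction counts trials strictly beyond the window, and boundary response
times are retained (the stated cutoffs are strict inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "TrialDataset",
    "FilterConfig",
    "ControlRoleMap",
    "ExclusionReport",
    "read_trials",
    "apply_filters",
]

CONDITIONS = ("congruent", "incongruent", "neutral", "other")

_COLUMNS = ["subject", "task", "condition", "rt", "correct"]


class TrialDataset:
    """Tidy trial table plus the provenance of filters applied to it."""

    def __init__(self, df: pd.DataFrame, provenance: list | None = None):
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df[_COLUMNS].copy()
        df["rt"] = df["rt"].astype(float)
        df["correct"] = df["correct"].astype(int)
        if len(df) and (not np.all(np.isfinite(df["rt"])) or (df["rt"] <= 0).any()):
            raise ValueError("rt must be finite and positive")
        if len(df) and not df["correct"].isin([0, 1]).all():
            raise ValueError("correct must be binary")
        unknown = ~df["condition"].isin(CONDITIONS)
        if unknown.any():
            labels = sorted(df.loc[unknown, "condition"].unique())
            warnings.warn(
                f"condition labels {labels} mapped to 'other'", stacklevel=2
            )
            df.loc[unknown, "condition"] = "other"
        self.df = df.reset_index(drop=True)
        self.provenance = list(provenance or [])

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, TrialDataset) and self.df.equals(other.df)

    @property
    def subjects(self):
        return list(pd.unique(self.df["subject"]))

    @property
    def tasks(self):
        return list(pd.unique(self.df["task"]))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass(frozen=True)
class FilterConfig:
    """Response-window filters.

    rt_min : lower cutoff in seconds (trials strictly faster are dropped).
    rt_max : upper response-window edge; either one number for every task or
        a per-task mapping (with ``default_rt_max`` for unlisted tasks).
    beyond_window_max_frac : per task, participants with a strictly larger
        fraction of trials beyond the window are excluded entirely.
    accuracy_floor : optional; participant-by-task combinations with
        accuracy strictly below this value are excluded (no default is
        asserted; pass a value to enable).
    """

    rt_min: float = 0.2
    rt_max: float | dict = 2.0
    beyond_window_max_frac: float = 0.025
    accuracy_floor: float | None = None
    default_rt_max: float = 2.0

    def __post_init__(self):
        if not (0 <= self.beyond_window_max_frac <= 1):
            raise ValueError("beyond_window_max_frac must be in [0, 1]")
        maxima = (
            list(self.rt_max.values())
            if isinstance(self.rt_max, dict)
            else [self.rt_max]
        )
        if not all(0 < self.rt_min < m for m in maxima + [self.default_rt_max]):
            raise ValueError("need 0 < rt_min < every rt_max")

    def rt_max_for(self, task) -> float:
        if isinstance(self.rt_max, dict):
            return float(self.rt_max.get(task, self.default_rt_max))
        return float(self.rt_max)


@dataclass
class ExclusionReport:
    n_input: int = 0
    participants_excluded: list = field(default_factory=list)  # (subject, task, reason)
    n_trials_participant_step: int = 0
    n_trials_fast: int = 0
    n_trials_slow: int = 0
    n_retained: int = 0

    @property
    def empty_result(self) -> bool:
        return self.n_retained == 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "participants_excluded": [
                {"subject": s, "task": t, "reason": r}
                for s, t, r in self.participants_excluded
            ],
            "n_trials_participant_step": self.n_trials_participant_step,
            "n_trials_fast": self.n_trials_fast,
            "n_trials_slow": self.n_trials_slow,
            "n_retained": self.n_retained,
        }


class ControlRoleMap:
    """Which condition of each task demands attentional control.

    By default the incongruent condition is the high-control condition and
    congruent the baseline; tasks built around negative compatibility invert
    this (their congruent trials require re-activating a suppressed
    response, so congruent is the high-control condition).
    """

    def __init__(self, roles: dict):
        self.roles = {}
        for task, pair in roles.items():
            if isinstance(pair, dict):
                high, base = pair["high_control"], pair["baseline"]
            else:
                high, base = pair
            if high == base:
                raise ValueError(f"task {task!r}: high-control == baseline")
            self.roles[task] = (high, base)

    @classmethod
    def default_for(cls, tasks, inverted=()):
        """incongruent = high-control everywhere except ``inverted`` tasks."""
        inverted = set(inverted)
        return cls(
            {
                t: (("congruent", "incongruent") if t in inverted
                    else ("incongruent", "congruent"))
                for t in tasks
            }
        )

    def high_control(self, task) -> str:
        return self.roles[task][0]

    def baseline(self, task) -> str:
        return self.roles[task][1]

    def __contains__(self, task) -> bool:
        return task in self.roles


def read_trials(path, schema: dict | None = None) -> TrialDataset:
    """Read a delimited trial file, collecting (not silencing) bad rows.

    ``schema`` maps canonical column names to the file's column names, e.g.
    ``{"subject": "id", "rt": "rt_ms"}``.  Rows with unparseable or
    nonpositive response times are rejected and reported via the dataset's
    provenance; a missing column raises a configuration error.
    """
    raw = pd.read_csv(path, sep=None, engine="python")
    schema = schema or {}
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in _COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(
            f"file {path} lacks required columns {missing} (after schema mapping)"
        )
    rt = pd.to_numeric(raw["rt"], errors="coerce")
    correct = pd.to_numeric(raw["correct"], errors="coerce")
    bad = rt.isna() | (rt <= 0) | ~correct.isin([0, 1])
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"rejected {n_bad} unparseable rows from {path}", stacklevel=2)
    df = raw.loc[~bad, _COLUMNS].copy()
    df["rt"] = rt[~bad]
    df["correct"] = correct[~bad].astype(int)
    ds = TrialDataset(df)
    ds.provenance.append(
        {"step": "read", "path": str(path), "n_rows": int(len(raw)), "n_rejected": n_bad}
    )
    return ds


def apply_filters(ds: TrialDataset, cfg: FilterConfig) -> tuple[TrialDataset, ExclusionReport]:
    """Apply the two-step response-window filter (and the optional accuracy
    floor); returns the filtered dataset and a count-by-count report."""
    df = ds.df
    report = ExclusionReport(n_input=len(df))

    rt_max = df["task"].map(cfg.rt_max_for).to_numpy()
    beyond = df["rt"].to_numpy() > rt_max

    # step 1: participant-by-task exclusion for censoring
    keep = np.ones(len(df), dtype=bool)
    grp = pd.DataFrame({"subject": df["subject"], "task": df["task"], "beyond": beyond})
    frac = grp.groupby(["subject", "task"], sort=False)["beyond"].mean()
    for (subj, task), f in frac.items():
        if f > cfg.beyond_window_max_frac:
            report.participants_excluded.append((subj, task, "beyond_response_window"))
            keep &= ~((df["subject"] == subj) & (df["task"] == task)).to_numpy()

    if cfg.accuracy_floor is not None:
        acc = df.groupby(["subject", "task"], sort=False)["correct"].mean()
        for (subj, task), a in acc.items():
            if a < cfg.accuracy_floor:
                report.participants_excluded.append((subj, task, "low_accuracy"))
                keep &= ~((df["subject"] == subj) & (df["task"] == task)).to_numpy()

    report.n_trials_participant_step = int((~keep).sum())

    # step 2: trial-level trimming (strict inequalities; boundaries kept)
    fast = keep & (df["rt"].to_numpy() < cfg.rt_min)
    slow = keep & beyond
    report.n_trials_fast = int(fast.sum())
    report.n_trials_slow = int(slow.sum())
    keep &= ~(fast | slow)

    out = TrialDataset(df.loc[keep], provenance=ds.provenance)
    report.n_retained = len(out)
    out.provenance.append({"step": "filter", **report.to_dict()})
    if report.empty_result and report.n_input > 0:
        warnings.warn("all trials removed by filtering", stacklevel=2)
    return out, report
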