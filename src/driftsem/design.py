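"""Fixed-effect design construction for the hierarchical diffusion model.

Two parametrizations of the drift rate are supported:

* ``difference`` coding - only baseline and high-control trials enter; each
  task contributes a baseline drift mean and a congruency-difference
  parameter, with the sign convention that a *positive* difference means a
  *lower* drift under high attentional-control demand (the difference is the
  attentional-control measure).
* ``condition`` coding - all trial types enter; each task contributes one
  drift mean per trial type.

Both schemes estimate one boundary-separation and one non-decision-time
fixed effect per task.  Every fixed effect carries a subject-level random
effect; the full set of random effects shares one (optionally
block-structured) correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prep import CONDITIONS, ControlRoleMap, TrialDataset

__all__ = ["DesignSpec", "build_design", "DesignError"]


class DesignError(ValueError):
    pass


@dataclass
class DesignSpec:
    """Trial-to-parameter index maps for the likelihood."""

    coding: str
    param_names: list[str]          # length K, order: drift params, a params, t0 params
    param_kind: list[str]           # per param: v_mean | v_delta | a | t0
    tasks: list[str]
    subjects: list                  # subject ids, fixed order
    # per-trial arrays
    subj_idx: np.ndarray
    vb_idx: np.ndarray              # baseline / condition drift parameter
    vd_idx: np.ndarray              # difference parameter (-1 when absent)
    vd_coef: np.ndarray             # coefficient on the difference (0 or -1)
    a_idx: np.ndarray
    t0_idx: np.ndarray
    rt: np.ndarray
    correct: np.ndarray
    blocks: list[np.ndarray] = field(default_factory=list)  # param-index blocks for the correlation matrix

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_trials(self) -> int:
        return len(self.rt)

    def param_index(self, names) -> np.ndarray:
        """Resolve parameter names or a name prefix to indices."""
        if isinstance(names, str):
            idx = [i for i, n in enumerate(self.param_names)
                   if n == names or n.startswith(names + "[")]
            if not idx:
                raise KeyError(f"no parameter matches {names!r}")
            return np.asarray(idx)
        out = []
        for n in names:
            try:
                out.append(self.param_names.index(n))
            except ValueError as err:
                raise KeyError(f"unknown parameter {n!r}") from err
        return np.asarray(out)


def build_design(
    ds: TrialDataset,
    coding: str = "difference",
    roles: ControlRoleMap | None = None,
    block_corr: bool = False,
) -> DesignSpec:
    """Build the fixed-effect design for ``ds`` under a coding scheme.

    With ``block_corr`` the random-effect correlation matrix is restricted
    to within-diffusion-parameter blocks (drift / boundary / non-decision),
    the cheaper structure used when the full matrix is too expensive.
    """
    if coding not in ("difference", "condition"):
        raise ValueError("coding must be 'difference' or 'condition'")
    df = ds.df
    if df.empty:
        raise DesignError("empty dataset")
    tasks = list(pd.unique(df["task"]))
    roles = roles or ControlRoleMap.default_for(tasks)

    v_names: list[str] = []
    v_kinds: list[str] = []
    trial_vb = {}
    trial_vd = {}

    if coding == "difference":
        masks = []
        for task in tasks:
            if task not in roles:
                raise DesignError(f"no control roles declared for task {task!r}")
            high, base = roles.high_control(task), roles.baseline(task)
            present = set(df.loc[df["task"] == task, "condition"])
            if high not in present or base not in present:
                raise DesignError(
                    f"task {task!r} lacks condition {high!r} or {base!r} "
                    "required by difference coding"
                )
            vb = len(v_names)
            v_names.append(f"v_base[{task}]")
            v_kinds.append("v_mean")
            vd = len(v_names)
            v_names.append(f"v_delta[{task}]")
            v_kinds.append("v_delta")
            trial_vb[task] = vb
            trial_vd[task] = vd
            masks.append(
                (df["task"] == task) & df["condition"].isin([high, base])
            )
        keep = np.logical_or.reduce([m.to_numpy() for m in masks])
        df = df.loc[keep]
    else:
        order = {c: k for k, c in enumerate(CONDITIONS)}
        for task in tasks:
            conds = sorted(
                set(df.loc[df["task"] == task, "condition"]), key=order.get
            )
            for c in conds:
                trial_vb[(task, c)] = len(v_names)
                v_names.append(f"v[{task}:{c}]")
                v_kinds.append("v_mean")

    a_names = [f"a[{t}]" for t in tasks]
    t0_names = [f"t0[{t}]" for t in tasks]
    param_names = v_names + a_names + t0_names
    param_kind = v_kinds + ["a"] * len(tasks) + ["t0"] * len(tasks)
    nv = len(v_names)
    a_of = {t: nv + k for k, t in enumerate(tasks)}
    t0_of = {t: nv + len(tasks) + k for k, t in enumerate(tasks)}

    subjects = list(pd.unique(df["subject"]))
    s_of = {s: k for k, s in enumerate(subjects)}

    n = len(df)
    subj_idx = df["subject"].map(s_of).to_numpy()
    task_arr = df["task"].to_numpy()
    cond_arr = df["condition"].to_numpy()
    vb_idx = np.empty(n, dtype=int)
    vd_idx = np.full(n, -1, dtype=int)
    vd_coef = np.zeros(n)
    if coding == "difference":
        for k in range(n):
            task = task_arr[k]
            vb_idx[k] = trial_vb[task]
            if cond_arr[k] == roles.high_control(task):
                vd_idx[k] = trial_vd[task]
                vd_coef[k] = -1.0  # positive difference -> lower drift
    else:
        for k in range(n):
            vb_idx[k] = trial_vb[(task_arr[k], cond_arr[k])]
    a_idx = np.array([a_of[t] for t in task_arr])
    t0_idx = np.array([t0_of[t] for t in task_arr])

    K = len(param_names)
    if block_corr:
        kind_arr = np.asarray(param_kind)
        is_v = np.isin(kind_arr, ["v_mean", "v_delta"])
        blocks = [np.where(is_v)[0], np.where(kind_arr == "a")[0],
                  np.where(kind_arr == "t0")[0]]
        blocks = [b for b in blocks if b.size]
    else:
        blocks = [np.arange(K)]

    return DesignSpec(
        coding=coding,
        param_names=param_names,
        param_kind=param_kind,
        tasks=tasks,
        subjects=subjects,
        subj_idx=subj_idx,
        vb_idx=vb_idx,
        vd_idx=vd_idx,
        vd_coef=vd_coef,
        a_idx=a_idx,
        t0_idx=t0_idx,
        rt=df["rt"].to_numpy(float),
        correct=df["correct"].to_numpy(int),
        blocks=blocks,
    )
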