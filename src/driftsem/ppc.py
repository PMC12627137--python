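"""Posterior-predictive checks with the concordance correlation coefficient.

For each retained posterior draw, a replicated dataset of exactly the
observed shape (same subjects, cells and trial counts) is simulated from
the Wiener process at that draw's subject-level parameters.  Observed and
replicated datasets are reduced to per-subject summary statistics - mean RT
of correct responses and accuracy per condition, and the RT/accuracy
congruency effects - and agreement is scored with the concordance
correlation coefficient (CCC), both against the posterior-predictive mean
and across individual predictive draws (2.5% / 50% / 97.5% quantiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import ControlRoleMap, TrialDataset
from .wiener import DiffusionParams, wiener_sample

__all__ = ["subject_stats", "ccc", "ppc_report", "CCCReport"]


def subject_stats(ds: TrialDataset, roles: ControlRoleMap) -> pd.DataFrame:
    """Per-subject, per-task summary statistics.

    Columns: ``mean_rt[<condition>]`` (correct responses only),
    ``accuracy[<condition>]``, ``rt_effect`` (high-control minus baseline,
    correct trials) and ``acc_effect`` (baseline minus high-control).
    Cells without any correct response get a missing mean RT, never zero.
    """
    df = ds.df
    if df.empty:
        raise ValueError("empty dataset")
    acc = df.groupby(["subject", "task", "condition"], sort=False)["correct"].mean()
    corr = df[df["correct"] == 1]
    mrt = corr.groupby(["subject", "task", "condition"], sort=False)["rt"].mean()
    out = {}
    for (s, t, c), val in acc.items():
        out.setdefault((s, t), {})[f"accuracy[{c}]"] = val
    for (s, t, c), val in mrt.items():
        out.setdefault((s, t), {})[f"mean_rt[{c}]"] = val
    table = pd.DataFrame.from_dict(out, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["subject", "task"])
    # every observed condition gets both columns, even if no cell anywhere
    # had a correct response (all-missing mean RT, never dropped)
    for c in pd.unique(df["condition"]):
        for col in (f"accuracy[{c}]", f"mean_rt[{c}]"):
            if col not in table.columns:
                table[col] = np.nan
    rt_eff, acc_eff = [], []
    for s, t in table.index:
        if t in roles:
            hi, lo = roles.high_control(t), roles.baseline(t)
            row = table.loc[(s, t)]
            r_hi, r_lo = row.get(f"mean_rt[{hi}]", np.nan), row.get(f"mean_rt[{lo}]", np.nan)
            a_hi, a_lo = row.get(f"accuracy[{hi}]", np.nan), row.get(f"accuracy[{lo}]", np.nan)
            rt_eff.append(r_hi - r_lo)
            acc_eff.append(a_lo - a_hi)
        else:
            rt_eff.append(np.nan)
            acc_eff.append(np.nan)
    table["rt_effect"] = rt_eff
    table["acc_effect"] = acc_eff
    return table.sort_index()


def ccc(x, y) -> float:
    """Concordance correlation coefficient with population (1/n) moments:

        2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2).

    Pairs with a missing value are dropped.  Returns NaN (with a warning)
    when both variances vanish and the means coincide, where the
    coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if x.size < 2:
        raise ValueError("need at least 2 finite pairs")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population normalization
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        warnings.warn("CCC undefined: zero variance and equal means")
        return float("nan")
    return float(2.0 * cov / denom)


@dataclass
class CCCReport:
    """CCC of observed vs posterior-predictive statistics.

    ``table`` has one row per (task, statistic) with the CCC against the
    predictive mean and the quantiles of the per-draw CCC distribution;
    ``observed`` / ``predicted_mean`` hold the underlying per-subject
    points (one frame layout per scatter panel).
    """

    table: pd.DataFrame
    observed: pd.DataFrame
    predicted_mean: pd.DataFrame
    n_draws: int

    def panel(self, task: str, stat: str) -> pd.DataFrame:
        """Observed-vs-predicted scatter data for one panel."""
        obs = self.observed.xs(task, level="task")[stat]
        pred = self.predicted_mean.xs(task, level="task")[stat]
        return pd.DataFrame({"observed": obs, "predicted": pred}).dropna()

    def plot_panel(self, task: str, stat: str, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        data = self.panel(task, stat)
        ax.scatter(data["observed"], data["predicted"], alpha=0.5, s=12)
        lims = [data.min().min(), data.max().max()]
        ax.plot(lims, lims, "k--", lw=0.8)
        row = self.table.loc[(task, stat)]
        ax.set_title(f"{task} / {stat}  CCC={row['ccc_mean']:.2f}")
        ax.set_xlabel("observed")
        ax.set_ylabel("predicted")
        return ax


def _simulate_replicate(theta, param_names, cells, rng):
    """One replicated dataset with the observed cell layout."""
    name_of = {n: k for k, n in enumerate(param_names)}
    rows = []
    for (subj, s_row, task, cond, high, n) in cells:
        th = theta[s_row]
        v = th[name_of[f"v_base[{task}]"]] if f"v_base[{task}]" in name_of else th[
            name_of[f"v[{task}:{cond}]"]]
        if f"v_delta[{task}]" in name_of and cond == high:
            v = v - th[name_of[f"v_delta[{task}]"]]
        a = th[name_of[f"a[{task}]"]]
        t0 = th[name_of[f"t0[{task}]"]]
        if a <= 0 or t0 < 0:
            continue
        rt, correct = wiener_sample(DiffusionParams(float(v), float(a), float(t0)), n, rng)
        rows.append(pd.DataFrame({"subject": subj, "task": task,
                                  "condition": cond, "rt": rt, "correct": correct}))
    return TrialDataset(pd.concat(rows, ignore_index=True))


def ppc_report(results, n_draws: int = 500, seed: int | None = None,
               roles: ControlRoleMap | None = None) -> CCCReport:
    """Posterior-predictive CCC report for a fitted hierarchical model.

    ``results`` is a DiffusionResults with stored subject effects.  For each
    of ``n_draws`` posterior draws a same-shape dataset is simulated; the
    report scores each summary statistic per task.
    """
    draws = results.draws
    if draws.u is None:
        raise ValueError("posterior draws lack subject effects; refit with store_subject_effects=True")
    total = draws.n_chains * draws.n_draws
    if n_draws > total:
        raise ValueError(f"n_draws={n_draws} exceeds available draws ({total})")
    data = results.model.data
    design = results.model.design
    roles = roles or ControlRoleMap.default_for(design.tasks)

    obs = subject_stats(data, roles)
    s_of = {s: k for k, s in enumerate(draws.subjects)}
    counts = data.df.groupby(["subject", "task", "condition"], sort=False).size()
    cells = []
    for (subj, task, cond), n in counts.items():
        if subj not in s_of:
            continue
        if design.coding == "difference" and cond not in (
            roles.high_control(task), roles.baseline(task)
        ):
            continue
        cells.append((subj, s_of[subj], task, cond, roles.high_control(task), int(n)))

    rng = np.random.default_rng(seed)
    beta = draws.flat(draws.beta)
    u = draws.flat(draws.u)
    pick = np.sort(rng.choice(total, size=n_draws, replace=False))

    stat_cols = [c for c in obs.columns]
    sum_pred = None
    cnt_pred = None
    ccc_draws: dict[tuple[str, str], list[float]] = {}
    for d_i in pick:
        theta = beta[d_i][None, :] + u[d_i]
        rep = _simulate_replicate(theta, draws.param_names, cells, rng)
        stats = subject_stats(rep, roles).reindex(obs.index)
        if sum_pred is None:
            sum_pred = stats.fillna(0.0)
            cnt_pred = stats.notna().astype(float)
        else:
            stats = stats.reindex(columns=sum_pred.columns)
            sum_pred = sum_pred.add(stats.fillna(0.0), fill_value=0.0)
            cnt_pred = cnt_pred.add(stats.notna().astype(float), fill_value=0.0)
        for task in design.tasks:
            o_t = obs.xs(task, level="task")
            p_t = stats.xs(task, level="task").reindex(o_t.index)
            for col in stat_cols:
                if col not in p_t.columns or col not in o_t.columns:
                    continue
                pair = pd.DataFrame({"o": o_t[col], "p": p_t[col]}).dropna()
                if len(pair) < 2 or (pair["o"].var() == 0 and pair["p"].var() == 0
                                     and pair["o"].mean() == pair["p"].mean()):
                    continue
                ccc_draws.setdefault((task, col), []).append(ccc(pair["o"], pair["p"]))

    pred_mean = sum_pred / cnt_pred.replace(0.0, np.nan)
    rows = []
    for (task, col), vals in ccc_draws.items():
        o_t = obs.xs(task, level="task")
        p_t = pred_mean.xs(task, level="task").reindex(o_t.index)
        pair = pd.DataFrame({"o": o_t[col], "p": p_t[col]}).dropna()
        c_mean = ccc(pair["o"], pair["p"]) if len(pair) >= 2 else np.nan
        vals = np.asarray(vals)
        rows.append({
            "task": task, "stat": col, "ccc_mean": c_mean,
            "ccc_q2.5": np.nanquantile(vals, 0.025),
            "ccc_median": np.nanquantile(vals, 0.5),
            "ccc_q97.5": np.nanquantile(vals, 0.975),
            "n_subjects": len(pair),
        })
    table = pd.DataFrame(rows).set_index(["task", "stat"]).sort_index()
    return CCCReport(table, obs, pred_mean, n_draws)
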