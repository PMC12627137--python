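"""Posterior-predictive statistics and the concordance correlation."""

import numpy as np
import pandas as pd
import pytest

from driftsem.ppc import ccc, ppc_report, subject_stats
from driftsem.prep import ControlRoleMap, TrialDataset
from driftsem.wiener import wiener_prob_correct


def _roles():
    return ControlRoleMap.default_for(["stroop"])


class TestSubjectStats:
    def test_effect_arithmetic(self):
        df = pd.DataFrame({
            "subject": "s1",
            "task": "stroop",
            "condition": ["incongruent"] * 2 + ["congruent"] * 2,
            "rt": [0.5, 0.7, 0.4, 0.4],
            "correct": 1,
        })
        stats = subject_stats(TrialDataset(df), _roles())
        row = stats.loc[("s1", "stroop")]
        assert row["rt_effect"] == pytest.approx(0.2)
        assert row["mean_rt[incongruent]"] == pytest.approx(0.6)
        assert row["acc_effect"] == pytest.approx(0.0)

    def test_all_correct_accuracy_one(self, five_trials):
        stats = subject_stats(five_trials, _roles())
        acc_cols = [c for c in stats.columns if c.startswith("accuracy")]
        assert (stats.loc[("s2", "stroop"), acc_cols] == 1.0).all()

    def test_zero_correct_cell_missing_not_zero(self):
        df = pd.DataFrame({
            "subject": "s1",
            "task": "stroop",
            "condition": ["incongruent"] * 2 + ["congruent"] * 2,
            "rt": [0.5, 0.7, 0.4, 0.4],
            "correct": [0, 0, 1, 1],
        })
        stats = subject_stats(TrialDataset(df), _roles())
        assert np.isnan(stats.loc[("s1", "stroop"), "mean_rt[incongruent]"])
        assert np.isnan(stats.loc[("s1", "stroop"), "rt_effect"])

    def test_empty_dataset_raises(self, five_trials):
        empty = TrialDataset(five_trials.df.iloc[0:0])
        with pytest.raises(ValueError):
            subject_stats(empty, _roles())


class TestCCC:
    def test_perfect_concordance(self, rng):
        x = rng.normal(size=50)
        assert ccc(x, x) == pytest.approx(1.0)

    def test_location_shift_closed_form(self, rng):
        """y = x + c with population variance s^2: CCC = 2 s^2/(2 s^2+c^2)."""
        x = rng.normal(size=2000)
        x = (x - x.mean()) / x.std()  # population var exactly 1
        assert ccc(x, x + 1.0) == pytest.approx(2 / 3, abs=1e-12)

    def test_perfect_reversal(self, rng):
        x = rng.normal(size=100)
        x = x - x.mean()
        assert ccc(x, -x) == pytest.approx(-1.0)

    def test_bounded_by_pearson(self, rng):
        for _ in range(10):
            x = rng.normal(size=60)
            y = 0.5 * x + rng.normal(size=60) + rng.normal() * 2
            assert abs(ccc(x, y)) <= abs(np.corrcoef(x, y)[0, 1]) + 1e-12

    def test_undefined_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = ccc([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert np.isnan(out)

    def test_length_checks(self):
        with pytest.raises(ValueError):
            ccc([1.0], [1.0])
        with pytest.raises(ValueError):
            ccc([1.0, 2.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def report(planted_fit):
    return ppc_report(planted_fit, n_draws=40, seed=3)


class TestPPCReport:

    def test_self_consistency_mean_rt(self, report):
        """Data simulated from the fitted model family: mean RT agreement
        with the posterior-predictive mean is high.  At the suite's desk
        scale (16 subjects, 24 trials/cell) per-replicate noise bounds the
        attainable concordance below the near-1 values seen with hundreds
        of trials per cell."""
        rows = report.table[
            report.table.index.get_level_values("stat").str.startswith("mean_rt")
        ]
        assert (rows["ccc_mean"] > 0.75).all()
        assert rows["ccc_mean"].mean() > 0.85

    def test_quantiles_ordered(self, report):
        t = report.table
        assert (t["ccc_q2.5"] <= t["ccc_median"] + 1e-12).all()
        assert (t["ccc_median"] <= t["ccc_q97.5"] + 1e-12).all()

    def test_permuted_observed_destroys_concordance(self, report, rng):
        obs = report.observed.xs("task1", level="task")["mean_rt[congruent]"]
        pred = report.predicted_mean.xs("task1", level="task")["mean_rt[congruent]"]
        pair = pd.DataFrame({"o": obs, "p": pred}).dropna()
        permuted = ccc(rng.permutation(pair["o"].to_numpy()), pair["p"])
        assert abs(permuted) < 0.5
        assert permuted < ccc(pair["o"], pair["p"])

    def test_replicates_preserve_cell_counts(self, planted_fit):
        """Replicated datasets use exactly the observed per-cell counts, so
        predicted statistics exist wherever observed ones do."""
        rep = ppc_report(planted_fit, n_draws=1, seed=0)
        obs, pred = rep.observed, rep.predicted_mean
        assert obs.index.equals(pred.index)
        acc_cols = [c for c in obs.columns if c.startswith("accuracy")]
        assert pred[acc_cols].notna().all().all()

    def test_single_draw_quantiles_collapse(self, planted_fit):
        rep = ppc_report(planted_fit, n_draws=1, seed=0)
        t = rep.table
        np.testing.assert_allclose(t["ccc_q2.5"], t["ccc_q97.5"], atol=1e-12)

    def test_too_many_draws_rejected(self, planted_fit):
        with pytest.raises(ValueError, match="exceeds"):
            ppc_report(planted_fit, n_draws=10 ** 6)

    def test_panel_and_plot(self, report):
        panel = report.panel("task1", "accuracy[incongruent]")
        assert {"observed", "predicted"} == set(panel.columns)
        import matplotlib

        matplotlib.use("Agg")
        ax = report.plot_panel("task1", "accuracy[incongruent]")
        assert ax is not None


def test_simulated_accuracy_matches_absorption_probability(planted_truth, planted_data):
    """Accuracy per cell in the synthetic data agrees with the closed-form
    absorption probability at the generating parameters."""
    from scipy.stats import binomtest

    stats = subject_stats(planted_data, ControlRoleMap.default_for(planted_truth.cfg.tasks))
    n = planted_truth.cfg.trials_per_cell
    checked = 0
    for (subj, task) in stats.index[:10]:
        s = planted_truth.subjects.index(subj)
        for cond in ("congruent", "incongruent"):
            p = planted_truth.cell_params(s, task, cond)
            expect = wiener_prob_correct(p.v, p.a)
            got = stats.loc[(subj, task), f"accuracy[{cond}]"]
            k = int(round(got * n))
            # exact binomial check (cells sit near ceiling; normal
            # approximation is unusable there)
            assert binomtest(k, n, expect).pvalue > 1e-4
            checked += 1
    assert checked == 20
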