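"""Reading, filtering and control-role mapping of trial-level data."""

import numpy as np
import pandas as pd
import pytest

from driftsem.prep import (
    ControlRoleMap,
    FilterConfig,
    TrialDataset,
    apply_filters,
    read_trials,
)


def _make_df(n_per_subject=100, rts=None):
    rows = []
    for s in ("s1", "s2"):
        rt = rts.get(s) if rts else np.full(n_per_subject, 0.6)
        for r in rt:
            rows.append({"subject": s, "task": "stroop",
                         "condition": "incongruent", "rt": r, "correct": 1})
    return pd.DataFrame(rows)


class TestReadTrials:
    def test_roundtrip_identity(self, tmp_path, five_trials):
        path = tmp_path / "t.csv"
        five_trials.to_csv(path)
        back = read_trials(path)
        pd.testing.assert_frame_equal(back.df, five_trials.df)

    def test_wellformed_file(self, tmp_path):
        path = tmp_path / "t.csv"
        _make_df(5).to_csv(path, index=False)
        ds = read_trials(path)
        assert len(ds) == 10
        assert ds.provenance[0]["n_rejected"] == 0

    def test_bad_rt_row_collected(self, tmp_path):
        df = _make_df(2).astype({"rt": object})
        df.loc[0, "rt"] = "oops"
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="rejected 1"):
            ds = read_trials(path)
        assert len(ds) == 3
        assert ds.provenance[0]["n_rejected"] == 1

    def test_missing_column_is_config_error(self, tmp_path):
        df = _make_df(2).drop(columns=["correct"])
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="correct"):
            read_trials(path)

    def test_schema_mapping(self, tmp_path):
        df = _make_df(2).rename(columns={"subject": "id", "rt": "resp_time"})
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        ds = read_trials(path, schema={"subject": "id", "rt": "resp_time"})
        assert len(ds) == 4


class TestFilters:
    def test_censored_participant_removed(self):
        """3% of one participant's trials beyond a 2 s window, threshold
        2.5% -> that participant leaves for that task."""
        rts = {"s1": np.r_[np.full(97, 0.6), np.full(3, 2.4)],
               "s2": np.full(100, 0.6)}
        ds = TrialDataset(_make_df(rts=rts))
        out, rep = apply_filters(ds, FilterConfig(rt_max=2.0))
        assert ("s1", "stroop", "beyond_response_window") in [
            tuple(x) for x in rep.participants_excluded
        ]
        assert set(out.df["subject"]) == {"s2"}
        assert rep.n_trials_participant_step == 100

    def test_below_threshold_participant_kept_trials_trimmed(self):
        rts = {"s1": np.r_[np.full(98, 0.6), np.full(2, 2.4)],
               "s2": np.full(100, 0.6)}
        ds = TrialDataset(_make_df(rts=rts))
        out, rep = apply_filters(ds, FilterConfig(rt_max=2.0))
        assert not rep.participants_excluded
        assert rep.n_trials_slow == 2
        assert len(out) == 198

    def test_fast_trial_removed(self):
        rts = {"s1": np.r_[np.full(99, 0.6), [0.15]], "s2": np.full(100, 0.6)}
        ds = TrialDataset(_make_df(rts=rts))
        out, rep = apply_filters(ds, FilterConfig(rt_min=0.2, rt_max=2.0))
        assert rep.n_trials_fast == 1
        assert len(out) == 199

    def test_boundary_rts_kept(self):
        """Cutoffs are strict inequalities: rt == rt_min or rt_max stays."""
        rts = {"s1": np.r_[np.full(98, 0.6), [0.2, 2.0]], "s2": np.full(100, 0.6)}
        ds = TrialDataset(_make_df(rts=rts))
        out, rep = apply_filters(ds, FilterConfig(rt_min=0.2, rt_max=2.0))
        assert len(out) == 200
        assert rep.n_trials_fast == rep.n_trials_slow == 0

    def test_noop_when_all_in_window(self):
        ds = TrialDataset(_make_df())
        out, rep = apply_filters(ds, FilterConfig(rt_max=2.0))
        pd.testing.assert_frame_equal(out.df, ds.df)
        assert rep.n_trials_fast == rep.n_trials_slow == 0
        assert rep.n_trials_participant_step == 0

    def test_idempotent(self):
        rts = {"s1": np.r_[np.full(95, 0.6), np.full(5, 2.4)],
               "s2": np.r_[np.full(99, 0.6), [0.1]]}
        cfg = FilterConfig(rt_max=2.0)
        ds = TrialDataset(_make_df(rts=rts))
        once, _ = apply_filters(ds, cfg)
        twice, rep2 = apply_filters(once, cfg)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert rep2.n_trials_fast == rep2.n_trials_slow == 0

    def test_counts_sum_to_input(self):
        rts = {"s1": np.r_[np.full(90, 0.6), np.full(10, 2.4)],
               "s2": np.r_[np.full(97, 0.6), [0.1, 2.5, 0.05]]}
        ds = TrialDataset(_make_df(rts=rts))
        out, rep = apply_filters(ds, FilterConfig(rt_max=2.0))
        removed = (rep.n_trials_participant_step + rep.n_trials_fast
                   + rep.n_trials_slow)
        assert rep.n_input == removed + rep.n_retained == 200

    def test_per_task_window(self):
        df = pd.concat([
            _make_df(rts={"s1": np.full(50, 1.8), "s2": np.full(50, 1.8)}),
            _make_df(rts={"s1": np.full(50, 1.8), "s2": np.full(50, 1.8)})
            .assign(task="flanker"),
        ])
        cfg = FilterConfig(rt_max={"flanker": 1.5}, default_rt_max=2.0)
        ds = TrialDataset(df)
        out, rep = apply_filters(ds, cfg)
        # all flanker trials beyond 1.5 s -> both participants excluded there
        assert set(out.df["task"]) == {"stroop"}

    def test_accuracy_floor_optional(self):
        df = _make_df()
        df.loc[df["subject"] == "s1", "correct"] = 0
        ds = TrialDataset(df)
        out, rep = apply_filters(ds, FilterConfig(accuracy_floor=0.5))
        assert ("s1", "stroop", "low_accuracy") in [
            tuple(x) for x in rep.participants_excluded
        ]
        assert set(out.df["subject"]) == {"s2"}

    def test_empty_result_flagged(self):
        ds = TrialDataset(_make_df(rts={"s1": np.full(10, 0.1),
                                        "s2": np.full(10, 0.1)}))
        with pytest.warns(UserWarning, match="all trials removed"):
            out, rep = apply_filters(ds, FilterConfig())
        assert rep.empty_result

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            FilterConfig(rt_min=2.5, rt_max=2.0)
        with pytest.raises(ValueError):
            FilterConfig(beyond_window_max_frac=1.5)


class TestDatasetAndRoles:
    def test_unknown_condition_maps_to_other(self):
        df = _make_df(2)
        df.loc[0, "condition"] = "mostly_congruent"
        with pytest.warns(UserWarning, match="mapped to 'other'"):
            ds = TrialDataset(df)
        assert (ds.df["condition"] == "other").sum() == 1

    def test_invalid_rt_rejected(self):
        df = _make_df(2)
        df.loc[0, "rt"] = -1.0
        with pytest.raises(ValueError):
            TrialDataset(df)

    def test_role_defaults_and_inversion(self):
        roles = ControlRoleMap.default_for(
            ["stroop", "negcomp"], inverted=["negcomp"]
        )
        assert roles.high_control("stroop") == "incongruent"
        assert roles.baseline("stroop") == "congruent"
        assert roles.high_control("negcomp") == "congruent"
        assert roles.baseline("negcomp") == "incongruent"

    def test_role_validation(self):
        with pytest.raises(ValueError):
            ControlRoleMap({"t": ("congruent", "congruent")})
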