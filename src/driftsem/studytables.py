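"""Posterior-mean correlation matrices from published hierarchical Wiener
diffusion fits of six conflict-task datasets.

These matrices are the direct inputs of the covariance-structure worked
examples: each is the posterior mean of the estimated random-effect
correlation matrix for one diffusion parameter (drift-rate congruency
difference, boundary separation, or non-decision time) across the tasks of
one dataset, printed to two decimals.  Sample sizes are the numbers of
participants entering the corresponding SEM.

Matrices are exposed as DataFrames with task names on both axes, suitable
for ``CFAModel`` / ``kmo`` directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "dataset1_drift_diff",
    "dataset1_boundary",
    "dataset1_ndt",
    "threetask_drift_diff",
    "threetask_boundary",
    "dataset6_boundary",
    "SAMPLE_SIZES",
]

#: participants entering the SEM stage per dataset
SAMPLE_SIZES = {1: 120, 2: 140, 3: 178, 4: 195, 5: 210, 6: 443}

_D1_TASKS = [
    "color_stroop",
    "number_stroop",
    "arrow_flanker",
    "letter_flanker",
    "simon",
    "local",
    "positive_comp",
    "negative_comp",
]

_W_TASKS = ["color_stroop", "spatial_stroop", "flanker"]

_D6_TASKS = ["number_stroop", "spatial_stroop", "arrow_flanker", "letter_flanker"]


def _sym(tasks, lower_rows):
    p = len(tasks)
    R = np.eye(p)
    for i, row in enumerate(lower_rows, start=1):
        R[i, :i] = row
        R[:i, i] = row
    return pd.DataFrame(R, index=tasks, columns=tasks)


def dataset1_drift_diff() -> pd.DataFrame:
    """Dataset 1 (young adults, 8 tasks): drift-rate congruency differences,
    difference coding."""
    return _sym(
        _D1_TASKS,
        [
            [-0.02],
            [-0.14, 0.03],
            [-0.09, 0.10, 0.26],
            [-0.13, 0.04, 0.08, 0.21],
            [0.11, 0.03, 0.06, 0.09, 0.19],
            [-0.02, 0.03, 0.00, 0.16, 0.11, 0.07],
            [-0.04, 0.16, 0.06, 0.12, 0.02, 0.04, 0.09],
        ],
    )


def dataset1_boundary() -> pd.DataFrame:
    """Dataset 1: boundary separation, condition coding."""
    return _sym(
        _D1_TASKS,
        [
            [0.25],
            [0.31, 0.22],
            [0.21, 0.32, 0.31],
            [0.30, 0.13, 0.23, 0.40],
            [0.43, 0.20, 0.36, 0.32, 0.29],
            [0.06, 0.29, 0.12, 0.35, 0.22, 0.16],
            [0.09, 0.19, 0.13, 0.15, 0.11, 0.15, 0.27],
        ],
    )


def dataset1_ndt() -> pd.DataFrame:
    """Dataset 1: non-decision time, condition coding."""
    return _sym(
        _D1_TASKS,
        [
            [0.19],
            [0.19, 0.08],
            [0.06, 0.40, 0.20],
            [0.22, 0.16, 0.17, 0.34],
            [0.17, 0.10, 0.14, 0.21, 0.23],
            [0.02, 0.10, 0.19, 0.16, 0.15, -0.01],
            [0.06, 0.09, 0.22, 0.15, 0.10, -0.00, 0.35],
        ],
    )


def threetask_drift_diff(dataset: int) -> pd.DataFrame:
    """Datasets 3-5 (three tasks): drift-rate congruency differences."""
    rows = {
        3: [[0.14], [0.08, -0.02]],
        4: [[0.20], [0.14, 0.31]],
        5: [[0.17], [0.26, 0.30]],
    }[dataset]
    return _sym(_W_TASKS, rows)


def threetask_boundary(dataset: int) -> pd.DataFrame:
    """Datasets 3-5 (three tasks): boundary separation."""
    rows = {
        3: [[0.37], [0.46, 0.41]],
        4: [[0.53], [0.50, 0.49]],
        5: [[0.51], [0.56, 0.60]],
    }[dataset]
    return _sym(_W_TASKS, rows)


def dataset6_boundary() -> pd.DataFrame:
    """Dataset 6 (four tasks): boundary separation."""
    return _sym(
        _D6_TASKS,
        [
            [0.42],
            [0.63, 0.37],
            [0.32, 0.32, 0.43],
        ],
    )
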