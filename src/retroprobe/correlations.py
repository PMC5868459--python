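"""Trial-wise accuracy trade-off analysis.

If the two sequentially probed items compete for a shared resource on each
trial, the absolute errors of the two responses should be negatively
correlated across trials. The analysis computes the Pearson correlation of
|error1| vs |error2| per subject and condition, Fisher-transforms it, and
tests the transformed values at the group level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import InferenceResult, one_sample_t, rm_anova

__all__ = ["TradeoffResult", "trialwise_error_correlation", "tradeoff_group_test"]

_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class TradeoffResult:
    r: float
    z: float
    n_trials: int
    condition: str = ""


def trialwise_error_correlation(err1, err2, condition: str = "") -> TradeoffResult:
    """Pearson correlation of absolute errors across trials, with Fisher z.

    Inputs are paired signed errors in radians; absolute values are taken
    internally. r is clipped to ±(1 − 1e−12) before the arctanh transform
    so z stays finite for degenerate perfect correlations.
    """
    a = np.abs(np.asarray(err1, dtype=float))
    b = np.abs(np.asarray(err2, dtype=float))
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("err1 and err2 must be 1-d and paired")
    if a.size < 10:
        raise ValueError(f"trialwise_error_correlation needs n >= 10, got {a.size}")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("degenerate input: zero variance in absolute errors")
    r = float(stats.pearsonr(a, b).statistic)
    z = float(np.arctanh(np.clip(r, -_CLIP, _CLIP)))
    return TradeoffResult(r=r, z=z, n_trials=a.size, condition=condition)


def tradeoff_group_test(z_table: pd.DataFrame) -> list[InferenceResult]:
    """Group tests on a balanced subject × condition table of Fisher z values.

    ``z_table`` has columns ``subject``, ``condition``, ``z``. Returns one
    one-sample t test (with JZS BF10) per condition against 0, followed by a
    one-way repeated-measures ANOVA for the main effect of condition.
    """
    required = {"subject", "condition", "z"}
    if not required.issubset(z_table.columns):
        raise ValueError(f"z_table must have columns {sorted(required)}")
    counts = z_table.groupby(["subject", "condition"], observed=True).size()
    if (counts != 1).any():
        raise ValueError("unbalanced table: each subject needs exactly one z per condition")
    n_cond = z_table["condition"].nunique()
    per_subj = z_table.groupby("subject", observed=True)["condition"].nunique()
    if (per_subj != n_cond).any():
        raise ValueError("unbalanced table: some subjects miss conditions")

    results = [
        one_sample_t(grp["z"].to_numpy(), 0.0, effect=f"fisher z vs 0 [{cond}]")
        for cond, grp in z_table.groupby("condition", observed=True)
    ]
    if n_cond > 1:
        anova = rm_anova(z_table, dv="z", subject="subject", within=["condition"])
        results.extend(anova)
    return results
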