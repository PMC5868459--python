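"""Group-level inference: t tests with JZS Bayes factors and within-subject ANOVA.

The Bayes factor follows the default Jeffreys–Zellner–Siow construction for
the one-sample / paired t test: a Cauchy(0, r) prior on standardized effect
size under the alternative (default scale r = √2/2, the convention of the
BayesFactor R package), a Jeffreys prior on variance, and BF10 obtained by
integrating the scaled likelihood over the prior (Rouder et al.'s g-integral
representation) with adaptive quadrature.

Repeated-measures ANOVA uses the standard fully-within-subject decomposition
(each effect tested against its effect-by-subject interaction); partial eta
squared is SS_effect / (SS_effect + SS_error) = F·df1 / (F·df1 + df2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "InferenceResult",
    "one_sample_t",
    "paired_t",
    "jzs_bf_from_t",
    "rm_anova",
    "DEFAULT_CAUCHY_SCALE",
]

DEFAULT_CAUCHY_SCALE = np.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class InferenceResult:
    """One test: statistic, degrees of freedom, p, effect size, optional BF10.

    ``df2`` and ``bf10`` are ``None`` for t tests and F tests respectively;
    ``effect_size`` is Cohen's d for t tests and partial eta squared for F.
    """

    effect: str
    statistic: float
    df1: float
    df2: float | None
    p: float
    effect_size: float
    bf10: float | None

    @property
    def kind(self) -> str:
        return "t" if self.df2 is None else "F"


def jzs_bf_from_t(t: float, n: int, scale: float = DEFAULT_CAUCHY_SCALE) -> float:
    """JZS Bayes factor (BF10) for a one-sample or paired t statistic.

    Parameters
    ----------
    t : float
        Observed t statistic (the BF depends only on |t|).
    n : int
        Number of subjects (pairs); degrees of freedom are n − 1.
    scale : float
        Scale of the Cauchy prior on standardized effect size.

    The marginal likelihood under the alternative is

        m1 = ∫0∞ (1 + n g r²)^(−1/2) (1 + t²/((1 + n g r²) ν))^(−(ν+1)/2)
             (2π)^(−1/2) g^(−3/2) exp(−1/(2g)) dg

    with ν = n − 1, and BF10 = m1 / (1 + t²/ν)^(−(ν+1)/2).
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n < 3:
        raise ValueError(f"jzs_bf_from_t needs n >= 3, got {n}")
    nu = n - 1
    t2 = float(t) * float(t)
    r2 = scale * scale

    def integrand(g: float) -> float:
        c = 1.0 + n * g * r2
        return (
            c ** -0.5
            * (1.0 + t2 / (c * nu)) ** (-(nu + 1) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * g ** -1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    m1, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(m1) or (m1 > 0 and err / m1 > 1e-4):
        raise ArithmeticError("JZS quadrature failed to reach the required accuracy")
    m0 = (1.0 + t2 / nu) ** (-(nu + 1) / 2.0)
    return m1 / m0


def _t_result(effect: str, diffs: np.ndarray, with_bf: bool, scale: float) -> InferenceResult:
    n = diffs.size
    if n < 3:
        raise ValueError(f"t test needs n >= 3, got {n}")
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        if np.allclose(diffs, 0.0):
            # all differences identically zero: define t = 0, d = 0
            bf = jzs_bf_from_t(0.0, n, scale) if with_bf else None
            return InferenceResult(effect, 0.0, n - 1, None, 1.0, 0.0, bf)
        raise ValueError("degenerate input: zero variance with nonzero mean")
    t = diffs.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    d = diffs.mean() / sd
    bf = jzs_bf_from_t(t, n, scale) if with_bf else None
    return InferenceResult(effect, float(t), float(n - 1), None, float(p), float(d), bf)


def one_sample_t(
    values,
    popmean: float = 0.0,
    effect: str = "one-sample",
    with_bf: bool = True,
    scale: float = DEFAULT_CAUCHY_SCALE,
) -> InferenceResult:
    """Two-sided one-sample t test against ``popmean`` with JZS BF10."""
    v = np.asarray(values, dtype=float)
    return _t_result(effect, v - popmean, with_bf, scale)


def paired_t(
    a,
    b,
    effect: str = "paired",
    with_bf: bool = True,
    scale: float = DEFAULT_CAUCHY_SCALE,
) -> InferenceResult:
    """Two-sided paired t test on a − b with JZS BF10."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired_t requires equal-length paired samples")
    return _t_result(effect, a - b, with_bf, scale)


def rm_anova(table: pd.DataFrame, dv: str, subject: str, within: list[str]) -> list[InferenceResult]:
    """Fully-within-subject repeated-measures ANOVA (up to 3 crossed factors).

    ``table`` is long-format with one row per subject × cell. The design must
    be complete and balanced: every subject contributes exactly one value per
    cell. No sphericity correction is applied (uncorrected degrees of
    freedom are reported). Returns one :class:`InferenceResult` per main
    effect and interaction, with partial eta squared as the effect size and
    no Bayes factor.
    """
    if not 1 <= len(within) <= 3:
        raise ValueError("rm_anova supports 1 to 3 within-subject factors")
    counts = table.groupby([subject] + within, observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index[0]
        raise ValueError(f"incomplete or duplicated design cell: {subject}×cell {bad}")
    n_cells = int(np.prod([table[f].nunique() for f in within]))
    per_subj = table.groupby(subject, observed=True).size()
    if (per_subj != n_cells).any():
        missing = per_subj[per_subj != n_cells].index.tolist()
        raise ValueError(f"subjects missing cells: {missing}")

    with np.errstate(invalid="ignore", divide="ignore"):  # degenerate 0/0 cells
        fit = AnovaRM(table, depvar=dv, subject=subject, within=list(within)).fit()
    out: list[InferenceResult] = []
    for effect, row in fit.anova_table.iterrows():
        f, df1, df2, p = (
            float(row["F Value"]),
            float(row["Num DF"]),
            float(row["Den DF"]),
            float(row["Pr > F"]),
        )
        if not np.isfinite(f):
            # degenerate 0/0 cell pattern (no effect and no residual
            # variability): report no evidence of an effect
            f, p, pes = 0.0, 1.0, 0.0
        else:
            pes = f * df1 / (f * df1 + df2)
        out.append(InferenceResult(str(effect), f, df1, df2, p, pes, None))
    return out


def results_to_frame(results: list[InferenceResult]) -> pd.DataFrame:
    """Tidy export: one row per test (effect, statistic, dfs, p, effect size, bf10)."""
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "kind": r.kind,
                "statistic": r.statistic,
                "df1": r.df1,
                "df2": r.df2,
                "p": r.p,
                "effect_size": r.effect_size,
                "bf10": r.bf10,
            }
            for r in results
        ]
    )
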