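"""End-to-end analysis of one experiment's cohort.

Runs the full sequence — exclusion screening, response labelling,
condition-level accuracy, mixture fits, bias curves, trial-wise trade-off
correlations, and group inference — and collects everything in a
:class:`ResultsBundle` of tidy tables that can be written to CSV.

Analysis cells follow the recalled item's role: cue role (neutral, cued,
uncued) × response position (first, second). Sessions that mix order-cued
and uncued blocks (the E3 design) are analyzed per order-cue level, plus a
combined three-factor ANOVA (order cue × cue role × response).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias import area_difference, bias_group_test, sliding_bin_bias
from .circstats import recall_accuracy
from .correlations import tradeoff_group_test, trialwise_error_correlation
from .data_model import SessionData, exclude_participants, response_table
from .inference import InferenceResult, paired_t, results_to_frame, rm_anova
from .mixture import fit_mixture

__all__ = ["AnalysisConfig", "ResultsBundle", "analyze_experiment", "write_bundle"]

_ROLE_ORDER = ("neutral", "cued", "uncued")


@dataclass(frozen=True)
class AnalysisConfig:
    exclusion_alpha: float = 0.01
    exclusion_responses: str = "both"  # both | first | second
    apply_exclusion: bool = True
    min_fit_n: int = 20
    min_corr_n: int = 10


@dataclass
class ResultsBundle:
    accuracy_table: pd.DataFrame
    mixture_table: pd.DataFrame
    bias_curves: pd.DataFrame
    bias_stats: pd.DataFrame
    tradeoff_table: pd.DataFrame
    inference_table: pd.DataFrame
    exclusion_report: pd.DataFrame
    meta: dict = field(default_factory=dict)


def _cell_tables(table: pd.DataFrame, cfg: AnalysisConfig):
    """Per subject × order-cue level × role × response: accuracy and mixture fit."""
    acc_rows, mix_rows = [], []
    grouped = table.groupby(["subject", "order_cued", "role", "response_index"], observed=True)
    for (subj, oc, role, idx), grp in grouped:
        errors = grp["error"].to_numpy()
        if errors.size < 2:
            raise ValueError(f"empty/degenerate cell: subject {subj}, {role} response {idx}")
        acc_rows.append(
            {
                "subject": subj,
                "order_cued": oc,
                "role": role,
                "response_index": idx,
                "n": errors.size,
                "accuracy": recall_accuracy(errors),
            }
        )
        fit = fit_mixture(errors, min_n=cfg.min_fit_n)
        mix_rows.append(
            {
                "subject": subj,
                "order_cued": oc,
                "role": role,
                "response_index": idx,
                "n": fit.n,
                "p_mem": fit.params.p_mem,
                "kappa": fit.params.kappa,
                "loglik": fit.loglik,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(acc_rows), pd.DataFrame(mix_rows)


def _bias_tables(table: pd.DataFrame):
    curve_rows, stat_rows = [], []
    grouped = table.groupby(["subject", "order_cued", "role", "response_index"], observed=True)
    for (subj, oc, role, idx), grp in grouped:
        curve = sliding_bin_bias(grp["delta"].to_numpy(), grp["error"].to_numpy())
        stat = area_difference(curve)
        for c, b in zip(curve.centers, curve.mean_bias):
            curve_rows.append(
                {
                    "subject": subj,
                    "order_cued": oc,
                    "role": role,
                    "response_index": idx,
                    "center_deg": np.rad2deg(c),
                    "mean_bias_deg": np.rad2deg(b),
                    "occupancy": curve.occupancy,
                }
            )
        stat_rows.append(
            {
                "subject": subj,
                "order_cued": oc,
                "role": role,
                "response_index": idx,
                "n_trials": curve.n_trials,
                "area_diff": stat.area_diff,
            }
        )
    return pd.DataFrame(curve_rows), pd.DataFrame(stat_rows)


def _tradeoff_table(table: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Per subject × order-cue level × condition: r and Fisher z of |e1| vs |e2|."""
    paired = table.pivot_table(
        index=["subject", "order_cued", "condition", "block", "trial"],
        columns="response_index",
        values="error",
    ).dropna()
    rows = []
    for (subj, oc, cond), grp in paired.groupby(["subject", "order_cued", "condition"], observed=True):
        res = trialwise_error_correlation(grp[1].to_numpy(), grp[2].to_numpy(), condition=cond)
        rows.append(
            {
                "subject": subj,
                "order_cued": oc,
                "condition": cond,
                "n_trials": res.n_trials,
                "r": res.r,
                "z": res.z,
            }
        )
    return pd.DataFrame(rows)


def _accuracy_inference(acc: pd.DataFrame, level_name: str) -> list[InferenceResult]:
    """The accuracy test family for one order-cue level."""
    out: list[InferenceResult] = []
    tag = f"accuracy{level_name}"
    t = acc.rename(columns={"response_index": "response"})
    out += _prefix(rm_anova(t, "accuracy", "subject", ["role", "response"]), f"{tag} omnibus")
    for keep, label in ((["neutral", "cued"], "benefit"), (["neutral", "uncued"], "cost")):
        sub = t[t["role"].isin(keep)]
        out += _prefix(rm_anova(sub, "accuracy", "subject", ["role", "response"]), f"{tag} {label}")
        for idx in (1, 2):
            wide = sub[sub["response"] == idx].pivot(index="subject", columns="role", values="accuracy")
            res = paired_t(
                wide[keep[1]].to_numpy(),
                wide["neutral"].to_numpy(),
                effect=f"{tag} {label}: {keep[1]} vs neutral, response {idx}",
            )
            out.append(res)
    return out


def _prefix(results: list[InferenceResult], tag: str) -> list[InferenceResult]:
    return [
        InferenceResult(f"{tag}: {r.effect}", r.statistic, r.df1, r.df2, r.p, r.effect_size, r.bf10)
        for r in results
    ]


def analyze_experiment(
    sessions: list[SessionData], config: AnalysisConfig | None = None
) -> ResultsBundle:
    """Run the full analysis pipeline on one experiment's cohort.

    Deterministic given the input data and configuration. Raises if a
    subject is missing an analysis cell or the design is unbalanced.
    """
    cfg = config or AnalysisConfig()
    if not sessions:
        raise ValueError("empty cohort")
    if cfg.apply_exclusion:
        retained, report = exclude_participants(
            sessions, alpha=cfg.exclusion_alpha, responses=cfg.exclusion_responses
        )
    else:
        retained, report = sessions, pd.DataFrame(
            {"subject": [s.subject_id for s in sessions], "excluded": False}
        )
    if len(retained) < 3:
        raise ValueError("fewer than 3 subjects retained after exclusion")

    table = response_table(retained)
    acc, mix = _cell_tables(table, cfg)
    curves, stats = _bias_tables(table)
    tradeoff = _tradeoff_table(table, cfg)

    inference: list[InferenceResult] = []
    levels = sorted(table["order_cued"].unique())
    multi = len(levels) > 1
    for oc in levels:
        name = f" [order_cued={oc}]" if multi else ""
        acc_l = acc[acc["order_cued"] == oc]
        inference += _accuracy_inference(acc_l, name)
        # bias family: one-sample t on the area difference per cell
        for (role, idx), grp in stats[stats["order_cued"] == oc].groupby(
            ["role", "response_index"], observed=True
        ):
            inference.append(
                bias_group_test(
                    grp["area_diff"].to_numpy(),
                    effect=f"bias{name}: {role}, response {idx}",
                )
            )
        bias_r1 = stats[(stats["order_cued"] == oc) & (stats["response_index"] == 1)]
        inference += _prefix(
            rm_anova(bias_r1, "area_diff", "subject", ["role"]), f"bias{name} response 1"
        )
        inference += _prefix(
            tradeoff_group_test(tradeoff[tradeoff["order_cued"] == oc]), f"tradeoff{name}"
        )
    if multi:
        t = acc.rename(columns={"response_index": "response", "order_cued": "ordercue"})
        inference += _prefix(
            rm_anova(t, "accuracy", "subject", ["ordercue", "role", "response"]),
            "accuracy combined",
        )

    experiment = retained[0].experiment
    return ResultsBundle(
        accuracy_table=acc,
        mixture_table=mix,
        bias_curves=curves,
        bias_stats=stats,
        tradeoff_table=tradeoff,
        inference_table=results_to_frame(inference),
        exclusion_report=report,
        meta={
            "experiment": experiment,
            "n_subjects_input": len(sessions),
            "n_subjects_retained": len(retained),
            "package_version": __version__,
        },
    )


_TABLE_FILES = {
    "accuracy_table": "accuracy.csv",
    "mixture_table": "mixture.csv",
    "bias_curves": "bias_curves.csv",
    "bias_stats": "bias_stats.csv",
    "tradeoff_table": "tradeoff.csv",
    "inference_table": "inference.csv",
    "exclusion_report": "exclusions.csv",
}


def write_bundle(bundle: ResultsBundle, outdir) -> Path:
    """Write every table as tidy CSV plus a small JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLE_FILES.items():
        getattr(bundle, attr).to_csv(outdir / fname, index=False)
    (outdir / "manifest.json").write_text(json.dumps(bundle.meta, indent=2, default=str))
    return outdir
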