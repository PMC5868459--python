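"""Trial-level data schema, CSV round-trip, response labelling and exclusion.

One row per trial: four memorized orientations, an optional retrocue, two
sequential probes and two continuous-report responses. Angles are stored in
degrees in files ([0, 360)) and converted to radians at this module's
boundary; item indices are 1-based (quadrant order upper-left, upper-right,
lower-left, lower-right). Missing responses are empty CSV fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .circstats import rayleigh_test, signed_error, wrap_angle

__all__ = [
    "CONDITIONS",
    "CSV_COLUMNS",
    "TrialRecord",
    "SessionData",
    "ResponseRole",
    "SchemaError",
    "ValidationError",
    "read_trials",
    "write_trials",
    "label_responses",
    "exclude_participants",
    "response_table",
]

CONDITIONS = ("neutral", "cued_first", "cued_second")

CSV_COLUMNS = [
    "subject_id",
    "experiment",
    "block",
    "trial",
    "condition",
    "order_cued",
    "item1_deg",
    "item2_deg",
    "item3_deg",
    "item4_deg",
    "cued_item",
    "probe1_item",
    "probe2_item",
    "response1_deg",
    "response2_deg",
    "rt1_ms",
    "rt2_ms",
]


class SchemaError(ValueError):
    """The CSV header does not match the trial schema."""


class ValidationError(ValueError):
    """One or more rows violate a trial invariant."""


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    experiment: str
    block: int
    trial: int
    condition: str
    order_cued: bool
    item_angles: tuple[float, float, float, float]  # degrees, each in [0, 360)
    cued_item: int | None  # 1-based; None iff neutral
    probe1_item: int
    probe2_item: int
    response1_deg: float | None
    response2_deg: float | None
    rt1_ms: float | None = None
    rt2_ms: float | None = None

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.block < 1 or self.trial < 1:
            raise ValidationError("block and trial must be positive")
        for a in self.item_angles:
            if not (0.0 <= a < 360.0):
                raise ValidationError(f"item angle {a} out of [0, 360)")
        for r in (self.response1_deg, self.response2_deg):
            if r is not None and not (0.0 <= r < 360.0):
                raise ValidationError(f"response angle {r} out of [0, 360)")
        for idx in (self.probe1_item, self.probe2_item):
            if idx not in (1, 2, 3, 4):
                raise ValidationError(f"probe index {idx} out of 1..4")
        if self.probe1_item == self.probe2_item:
            raise ValidationError("probe1_item must differ from probe2_item")
        if self.condition == "neutral":
            if self.cued_item is not None:
                raise ValidationError("neutral trials have no cued item")
        else:
            if self.cued_item not in (1, 2, 3, 4):
                raise ValidationError("cued trials need cued_item in 1..4")
            if self.condition == "cued_first" and self.probe1_item != self.cued_item:
                raise ValidationError("cued_first requires probe1_item == cued_item")
            if self.condition == "cued_second" and self.probe2_item != self.cued_item:
                raise ValidationError("cued_second requires probe2_item == cued_item")


@dataclass
class SessionData:
    """All trials of one subject in one experiment, plus design metadata."""

    records: list[TrialRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.records:
            sid = self.records[0].subject_id
            exp = self.records[0].experiment
            if any(r.subject_id != sid or r.experiment != exp for r in self.records):
                raise ValidationError("all records must share subject_id and experiment")
            seen = set()
            for r in self.records:
                key = (r.block, r.trial)
                if key in seen:
                    raise ValidationError(f"duplicate trial number {key}")
                seen.add(key)

    @property
    def subject_id(self) -> str:
        return self.records[0].subject_id

    @property
    def experiment(self) -> str:
        return self.records[0].experiment

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ResponseRole:
    role: str  # cued | uncued | neutral
    response_index: int  # 1 or 2


def label_responses(trial: TrialRecord) -> tuple[ResponseRole, ResponseRole]:
    """Assign cue roles to the two responses of a trial.

    cued_first → (cued, uncued); cued_second → (uncued, cued); neutral →
    (neutral, neutral).
    """
    if trial.condition == "cued_first":
        return ResponseRole("cued", 1), ResponseRole("uncued", 2)
    if trial.condition == "cued_second":
        return ResponseRole("uncued", 1), ResponseRole("cued", 2)
    return ResponseRole("neutral", 1), ResponseRole("neutral", 2)


def _record_to_row(r: TrialRecord) -> dict:
    return {
        "subject_id": r.subject_id,
        "experiment": r.experiment,
        "block": r.block,
        "trial": r.trial,
        "condition": r.condition,
        "order_cued": int(r.order_cued),
        "item1_deg": r.item_angles[0],
        "item2_deg": r.item_angles[1],
        "item3_deg": r.item_angles[2],
        "item4_deg": r.item_angles[3],
        "cued_item": r.cued_item if r.cued_item is not None else "",
        "probe1_item": r.probe1_item,
        "probe2_item": r.probe2_item,
        "response1_deg": r.response1_deg if r.response1_deg is not None else "",
        "response2_deg": r.response2_deg if r.response2_deg is not None else "",
        "rt1_ms": r.rt1_ms if r.rt1_ms is not None else "",
        "rt2_ms": r.rt2_ms if r.rt2_ms is not None else "",
    }


def write_trials(sessions: list[SessionData], path) -> None:
    """Write sessions to one UTF-8 comma-separated file (degrees, 6 decimals)."""
    rows = [_record_to_row(r) for s in sessions for r in s.records]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    for col in ("item1_deg", "item2_deg", "item3_deg", "item4_deg", "response1_deg", "response2_deg"):
        df[col] = df[col].map(lambda v: f"{v:.6f}" if v != "" else "")
    df.to_csv(path, index=False)


def _parse_row(row: pd.Series, rownum: int) -> TrialRecord:
    def opt_float(v):
        return None if pd.isna(v) or v == "" else float(v)

    def opt_int(v):
        return None if pd.isna(v) or v == "" else int(float(v))

    try:
        rec = TrialRecord(
            subject_id=str(row["subject_id"]),
            experiment=str(row["experiment"]),
            block=int(row["block"]),
            trial=int(row["trial"]),
            condition=str(row["condition"]),
            order_cued=bool(int(row["order_cued"])),
            item_angles=tuple(float(row[f"item{i}_deg"]) for i in (1, 2, 3, 4)),
            cued_item=opt_int(row["cued_item"]),
            probe1_item=int(row["probe1_item"]),
            probe2_item=int(row["probe2_item"]),
            response1_deg=opt_float(row["response1_deg"]),
            response2_deg=opt_float(row["response2_deg"]),
            rt1_ms=opt_float(row["rt1_ms"]),
            rt2_ms=opt_float(row["rt2_ms"]),
        )
        rec.validate()
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"row {rownum}: {exc}") from exc
    return rec


def read_trials(path) -> list[SessionData]:
    """Read a trial CSV into one SessionData per subject.

    The header must contain every schema column (extra columns are ignored
    with a warning); rows violating invariants raise a
    :class:`ValidationError` naming the first offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=object, keep_default_na=False, na_values=[""])
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown columns: {extra}", stacklevel=2)
    records: dict[tuple[str, str], list[TrialRecord]] = {}
    for i, row in df.iterrows():
        rec = _parse_row(row, rownum=i + 2)  # +2: header line + 1-based count
        records.setdefault((rec.subject_id, rec.experiment), []).append(rec)
    return [SessionData(records=recs) for recs in records.values()]


def response_table(sessions: list[SessionData]) -> pd.DataFrame:
    """Long-format table with one row per non-missing response.

    Columns: subject, experiment, condition, order_cued, block, trial,
    response_index, role, error (radians, (−π, π]), delta (radians: relative
    orientation of the *other* probed item with respect to the currently
    probed item), target_deg, response_deg. This is the working table every
    downstream analysis consumes.
    """
    rows = []
    for s in sessions:
        for r in s.records:
            roles = label_responses(r)
            probes = (r.probe1_item, r.probe2_item)
            responses = (r.response1_deg, r.response2_deg)
            for k in (0, 1):
                resp = responses[k]
                if resp is None:
                    continue
                target = r.item_angles[probes[k] - 1]
                other = r.item_angles[probes[1 - k] - 1]
                rows.append(
                    {
                        "subject": r.subject_id,
                        "experiment": r.experiment,
                        "condition": r.condition,
                        "order_cued": r.order_cued,
                        "block": r.block,
                        "trial": r.trial,
                        "response_index": k + 1,
                        "role": roles[k].role,
                        "error": float(signed_error(np.deg2rad(resp), np.deg2rad(target))),
                        "delta": float(wrap_angle(np.deg2rad(other) - np.deg2rad(target))),
                        "target_deg": target,
                        "response_deg": resp,
                    }
                )
    return pd.DataFrame(rows)


def exclude_participants(
    sessions: list[SessionData], alpha: float = 0.01, responses: str = "both"
) -> tuple[list[SessionData], pd.DataFrame]:
    """Screen subjects by a Rayleigh test on their pooled signed errors.

    A subject whose pooled error distribution is not significantly
    concentrated (Rayleigh p > ``alpha``) is excluded as performing at
    chance. ``responses`` selects which responses are pooled: "both"
    (default), "first" or "second". Returns the retained sessions and a
    report with each subject's Rayleigh z, p and decision.
    """
    if responses not in ("both", "first", "second"):
        raise ValueError("responses must be 'both', 'first' or 'second'")
    table = response_table(sessions)
    retained, rows = [], []
    for s in sessions:
        sub = table[table["subject"] == s.subject_id]
        if responses == "first":
            sub = sub[sub["response_index"] == 1]
        elif responses == "second":
            sub = sub[sub["response_index"] == 2]
        errs = sub["error"].to_numpy()
        if errs.size < 10:
            raise ValueError(
                f"subject {s.subject_id}: only {errs.size} non-missing responses (< 10)"
            )
        z, p = rayleigh_test(errs)
        excluded = p > alpha
        rows.append(
            {"subject": s.subject_id, "n_responses": errs.size, "rayleigh_z": z, "p": p,
             "excluded": excluded}
        )
        if not excluded:
            retained.append(s)
    return retained, pd.DataFrame(rows)
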