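"""Readers and writers for the CSV/JSON interchange formats.

Trial sets travel as long-format CSV (one row per study x arm, UTF-8,
header required) so arbitrary AE categories need no schema change:

    study_id, year, blinded, arm, n, events, mean, sd, follow_up_weeks

Binary rows fill ``events``; continuous rows fill ``mean``/``sd``; a row
may fill both. Classification schemes, scenarios and imputation problems
travel as JSON. Validation failures name the offending row.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .data_model import (
    AdverseEventRecord,
    ArmSummaryBinary,
    ArmSummaryContinuous,
    ClassificationScheme,
    EventDelta,
    HiddenStudy,
    Locality,
    ScenarioSpec,
    Severity,
    StudyRecord,
    TrialSet,
    ValidationError,
)
from .imputation import ImputationProblem

PathLike = Union[str, Path]

STUDY_COLUMNS = [
    "study_id", "year", "blinded", "arm", "n",
    "events", "mean", "sd", "follow_up_weeks",
]


def _opt(value, cast):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return cast(value)


def _parse_bool(value, line: int):
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"line {line}: cannot parse blinded flag {value!r}")


def read_trialset(path: PathLike, ae_category: str = "all_serious") -> TrialSet:
    """Read a long-format studies CSV into a validated TrialSet.

    Errors (missing columns, events > n, duplicate study/arm rows, a study
    without both arms) are reported with the 1-based data line number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"study_id", "arm", "n"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns: {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: no studies")

    rows_by_study: dict[str, dict[str, tuple[int, pd.Series]]] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        sid = str(row["study_id"])
        arm = str(row["arm"]).strip().lower()
        if arm not in ("treatment", "control"):
            raise ValidationError(f"line {line}: arm must be 'treatment' or 'control', got {arm!r}")
        arms = rows_by_study.setdefault(sid, {})
        if arm in arms:
            raise ValidationError(f"line {line}: duplicate arm {arm!r} for study {sid!r}")
        arms[arm] = (line, row)

    studies = []
    for sid, arms in rows_by_study.items():
        if set(arms) != {"treatment", "control"}:
            line = next(iter(arms.values()))[0]
            raise ValidationError(f"line {line}: study {sid!r} needs exactly one treatment and one control row")
        binary, continuous = [], []
        meta: dict = {}
        for arm_label in ("treatment", "control"):
            line, row = arms[arm_label]
            try:
                n = int(row["n"])
                events = _opt(row.get("events"), lambda v: int(float(v)))
                mean = _opt(row.get("mean"), float)
                sd = _opt(row.get("sd"), float)
                if events is not None:
                    binary.append(ArmSummaryBinary(arm_label, n, events))
                if mean is not None or sd is not None:
                    if mean is None or sd is None:
                        raise ValidationError("continuous rows need both mean and sd")
                    continuous.append(ArmSummaryContinuous(arm_label, n, mean, sd))
                if events is None and mean is None:
                    raise ValidationError("row has neither events nor mean/sd")
            except ValidationError as err:
                raise ValidationError(f"line {line} (study {sid!r}, {arm_label}): {err}") from None
            meta.setdefault("year", _opt(row.get("year"), lambda v: int(float(v))))
            meta.setdefault("follow_up_weeks", _opt(row.get("follow_up_weeks"), float))
            if "blinded" in row.index and _opt(row.get("blinded"), str) is not None:
                meta.setdefault("blinded", _parse_bool(row["blinded"], line))
        if len(binary) == 1 or len(continuous) == 1:
            line = arms["treatment"][0]
            raise ValidationError(f"line {line}: study {sid!r} mixes binary and continuous arms inconsistently")
        studies.append(
            StudyRecord(
                study_id=sid,
                year=meta.get("year"),
                blinded=meta.get("blinded", True),
                follow_up_weeks=meta.get("follow_up_weeks"),
                binary=tuple(binary) if binary else None,
                continuous=tuple(continuous) if continuous else None,
            )
        )
    return TrialSet(studies=tuple(studies), ae_category=ae_category)


def write_trialset(ts: TrialSet, path: PathLike) -> None:
    """Write a TrialSet to the long-format CSV dialect (round-trips)."""
    rows = []
    for s in ts.studies:
        for arm_label in ("treatment", "control"):
            row = {
                "study_id": s.study_id,
                "year": s.year,
                "blinded": s.blinded,
                "arm": arm_label,
                "n": None,
                "events": None,
                "mean": None,
                "sd": None,
                "follow_up_weeks": s.follow_up_weeks,
            }
            if s.binary is not None:
                a = s.treatment_binary if arm_label == "treatment" else s.control_binary
                row["n"], row["events"] = a.n, a.events
            if s.continuous is not None:
                a = s.treatment_continuous if arm_label == "treatment" else s.control_continuous
                row["n"], row["mean"], row["sd"] = a.n, repr(a.mean), repr(a.sd)
            rows.append(row)
    pd.DataFrame(rows, columns=STUDY_COLUMNS).to_csv(path, index=False)


def read_events(path: PathLike) -> list[AdverseEventRecord]:
    """Read raw AE records: study_id, arm, term, count, author_serious."""
    df = pd.read_csv(path)
    missing = {"study_id", "arm", "term", "count"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns: {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            records.append(
                AdverseEventRecord(
                    term=str(row["term"]),
                    study_id=str(row["study_id"]),
                    arm_label=str(row["arm"]).strip().lower(),
                    count=int(row["count"]),
                    author_serious=_parse_bool(row.get("author_serious", False), line),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"line {line}: {err}") from None
    return records


def read_scheme(path: PathLike) -> ClassificationScheme:
    """Read a classification scheme JSON, rejecting conflicting duplicates."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    rules: dict[str, tuple[Severity, Locality]] = {}
    for rule in payload.get("rules", []):
        term = rule["term"].strip().lower()
        try:
            sev = Severity(rule["severity"])
            loc = Locality(rule["locality"])
        except ValueError as err:
            raise ValidationError(f"{path}: term {rule['term']!r}: {err}") from None
        if term in rules and rules[term] != (sev, loc):
            raise ValidationError(f"{path}: conflicting rules for term {rule['term']!r}")
        rules[term] = (sev, loc)
    return ClassificationScheme(
        name=payload.get("name", Path(path).stem),
        rules=rules,
        fallback=payload.get("fallback", "use_author_flag"),
    )


def write_scheme(scheme: ClassificationScheme, path: PathLike) -> None:
    payload = {
        "name": scheme.name,
        "fallback": scheme.fallback,
        "rules": [
            {"term": term, "severity": sev.value, "locality": loc.value}
            for term, (sev, loc) in sorted(scheme.rules.items())
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def _scenario_from_dict(payload: dict) -> ScenarioSpec:
    deltas = tuple(
        EventDelta(
            study_id=d["study_id"],
            arm_label=d["arm"],
            change=int(d["change"]),
            label=d.get("label", ""),
        )
        for d in payload.get("deltas", [])
    )
    subgroup = payload.get("subgroup")
    return ScenarioSpec(
        name=payload["name"],
        excluded_study_ids=tuple(payload.get("exclude", [])),
        subgroup_predicate=subgroup,
        subgroup_params=payload.get("subgroup_params", {}),
        event_deltas=deltas,
    )


def read_scenarios(path: PathLike) -> list[ScenarioSpec]:
    """Read one scenario or a list of scenarios from JSON."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    return [_scenario_from_dict(p) for p in payload]


def write_scenarios(scenarios: Sequence[ScenarioSpec], path: PathLike) -> None:
    payload = [
        {
            "name": sc.name,
            "exclude": list(sc.excluded_study_ids),
            "subgroup": sc.subgroup_predicate,
            "subgroup_params": sc.subgroup_params,
            "deltas": [
                {"study_id": d.study_id, "arm": d.arm_label, "change": d.change, "label": d.label}
                for d in sc.event_deltas
            ],
        }
        for sc in scenarios
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def read_problem(path: PathLike) -> tuple[ImputationProblem, str]:
    """Read an imputation problem JSON; returns (problem, strategy)."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    observed = read_trialset(
        Path(path).parent / payload["observed_csv"], payload.get("ae_category", "all_serious")
    )
    hidden = tuple(
        HiddenStudy(
            study_id=h["study_id"], n_t=int(h["n_t"]), n_c=int(h["n_c"]),
            blinded=h.get("blinded", True),
        )
        for h in payload["hidden"]
    )
    t = payload["target"]
    kwargs = {}
    if "bounds" in payload:
        kwargs["bounds"] = tuple((int(b[0]), int(b[1])) for b in payload["bounds"])
    if "weights" in payload:
        kwargs["weights"] = tuple(float(w) for w in payload["weights"])
    problem = ImputationProblem(
        observed=observed,
        hidden=hidden,
        target=(float(t["point"]), float(t["ci_low"]), float(t["ci_high"])),
        method_tag=payload.get("method", "dl_random"),
        **kwargs,
    )
    return problem, payload.get("strategy", "exhaustive")


def report_records(results) -> list[dict]:
    """Normalize a ladder (LadderRow list) or PooledEstimate list to dicts."""
    records = []
    for item in results:
        if hasattr(item, "as_dict"):
            records.append(item.as_dict())
        else:  # PooledEstimate
            lo, hi = item.ratio_ci
            defined_lo = math.isfinite(item.ci_low)
            defined_hi = math.isfinite(item.ci_high)
            records.append(
                {
                    "scenario": "",
                    "method": item.method_tag,
                    "k": item.k,
                    "estimate": item.ratio if item.is_ratio else item.theta_pooled,
                    "ci_low": (lo if item.is_ratio else item.ci_low) if defined_lo else None,
                    "ci_high": (hi if item.is_ratio else item.ci_high) if defined_hi else None,
                    "ci_defined": defined_lo and defined_hi,
                    "scale": item.scale_tag,
                    "significant": item.significant,
                    "excluded": "",
                    "subgroup": "",
                    "deltas": "",
                    "n_excluded_both_zero": item.n_excluded_both_zero,
                }
            )
    return records


def write_report(results, path: PathLike, format: str = "csv") -> None:
    """Write pooled results / ladders as CSV or JSON (JSON round-trips).

    Non-finite CI bounds (undefined or one-sided intervals, e.g. all-zero
    strata at a support boundary) are written as empty cells with the row
    flagged ``ci_defined = False``.
    """
    if not results:
        raise ValidationError("cannot write an empty report")
    records = report_records(results)
    if format == "csv":
        pd.DataFrame(records).to_csv(path, index=False)
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=2)
    else:
        raise ValidationError(f"unknown report format {format!r}")


def read_report(path: PathLike) -> list[dict]:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
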