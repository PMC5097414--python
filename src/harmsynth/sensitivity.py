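"""Scenario-ladder sensitivity engine.

A scenario names a transformation of a trial set — exclude studies, restrict
to a subgroup, add or remove specific adverse events from specific arms —
and the ladder re-pools under every scenario x method combination, flagging
which rows keep a statistically significant pooled ratio. This is the
machinery behind "does the conclusion survive removing one outlier trial,
or moving eight debatable events across the seriousness line?".

Composition order is fixed: exclusions, then the subgroup predicate, then
event deltas applied to the surviving studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import pandas as pd

from .config import DEFAULT_CC, DEFAULT_LARGE_TRIAL_N, DEFAULT_LEVEL
from .data_model import (
    EventDelta,
    ScenarioSpec,
    StudyRecord,
    TrialSet,
    ValidationError,
)
from .pooling import METHOD_DL_RANDOM, PooledEstimate, pool_tables

# --- subgroup predicates -------------------------------------------------

def _pred_all(study: StudyRecord, **_: object) -> bool:
    return True


def _pred_blinded(study: StudyRecord, **_: object) -> bool:
    return study.blinded


def _pred_large_blinded(study: StudyRecord, min_total_n: int = DEFAULT_LARGE_TRIAL_N, **_: object) -> bool:
    return study.blinded and study.total_n >= min_total_n


SUBGROUP_PREDICATES: dict[str, Callable[..., bool]] = {
    "all": _pred_all,
    "blinded": _pred_blinded,
    "large_blinded": _pred_large_blinded,
}


def subgroup_filter(ts: TrialSet, predicate: str, **params: object) -> TrialSet:
    """Keep only studies passing a named predicate (e.g. ``large_blinded``).

    The size threshold for "large" is a parameter (``min_total_n``), since
    the subgroup definition in published reviews is rarely explicit.
    """
    if predicate not in SUBGROUP_PREDICATES:
        raise ValidationError(
            f"unknown subgroup predicate {predicate!r}; known: {sorted(SUBGROUP_PREDICATES)}"
        )
    fn = SUBGROUP_PREDICATES[predicate]
    kept = tuple(s for s in ts.studies if fn(s, **params))
    if not kept:
        raise ValidationError(f"empty subgroup: no study passes predicate {predicate!r}")
    return replace(ts, studies=kept)


def apply_deltas(ts: TrialSet, deltas: Sequence[EventDelta]) -> TrialSet:
    """Apply signed event-count changes; returns a new TrialSet.

    Each delta must target an existing study/arm and the adjusted count must
    stay within [0, n]. Applying a delta list and then its inverses restores
    the original counts exactly.
    """
    out = ts
    for d in deltas:
        try:
            study = out.get(d.study_id)
        except KeyError:
            raise ValidationError(f"delta {d.label!r} targets unknown study {d.study_id!r}")
        arm = study.treatment_binary if d.arm_label == "treatment" else study.control_binary
        new_events = arm.events + d.change
        if not (0 <= new_events <= arm.n):
            raise ValidationError(
                f"delta {d.label!r} on {d.study_id}/{d.arm_label} gives events={new_events} "
                f"outside [0, {arm.n}]"
            )
        out = out.replace_study(study.with_binary_events(d.arm_label, new_events))
    return out


def apply_scenario(ts: TrialSet, scenario: ScenarioSpec, strict_deltas: bool = False) -> TrialSet:
    """Exclusions -> subgroup -> deltas; deltas to removed studies are skipped.

    With ``strict_deltas=True`` a delta whose study was excluded raises
    instead of being skipped.
    """
    out = ts
    if scenario.excluded_study_ids:
        out = out.drop(scenario.excluded_study_ids)
    if scenario.subgroup_predicate:
        out = subgroup_filter(out, scenario.subgroup_predicate, **scenario.subgroup_params)
    surviving = set(out.study_ids)
    deltas = [d for d in scenario.event_deltas if d.study_id in surviving]
    if strict_deltas and len(deltas) != len(scenario.event_deltas):
        missing = [d for d in scenario.event_deltas if d.study_id not in surviving]
        raise ValidationError(f"deltas target excluded studies: {[d.study_id for d in missing]}")
    return apply_deltas(out, deltas)


def leave_one_out(
    ts: TrialSet,
    method: str = METHOD_DL_RANDOM,
    cc: float = DEFAULT_CC,
    level: float = DEFAULT_LEVEL,
) -> pd.DataFrame:
    """Re-pool excluding each study in turn; report each study's full weight.

    The weight column is the study's normalized weight in the full pooling
    under the chosen method (NaN for studies excluded by the both-zero
    rule), so an influential outlier shows up both as a large weight and as
    a large shift when its row's pooled estimate is compared to the full one.
    """
    if len(ts) < 2:
        raise ValidationError("leave-one-out needs at least two studies")
    full = pool_tables(ts.tables(), method=method, cc=cc, level=level, study_ids=ts.study_ids)
    informative = [s.study_id for s in ts.studies if not s.table().both_zero]
    weight_by_id = dict(zip(informative, full.weights))
    rows = []
    for s in ts.studies:
        rest = ts.drop([s.study_id])
        est = pool_tables(rest.tables(), method=method, cc=cc, level=level, study_ids=rest.study_ids)
        rlo, rhi = est.ratio_ci
        rows.append(
            {
                "excluded_study": s.study_id,
                "k": est.k,
                "estimate": est.ratio,
                "ci_low": rlo,
                "ci_high": rhi,
                "significant": est.significant,
                "weight_in_full": weight_by_id.get(s.study_id, math.nan),
                "method": method,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LadderRow:
    """One scenario x method entry of a sensitivity ladder."""

    scenario: str
    method: str
    estimate: PooledEstimate
    excluded: tuple[str, ...]
    subgroup: Optional[str]
    delta_labels: tuple[str, ...]

    def as_dict(self) -> dict:
        est = self.estimate
        rlo, rhi = est.ratio_ci
        # one-sided/undefined bounds (infinite on the analysis scale) become empty cells
        defined_lo = math.isfinite(est.ci_low)
        defined_hi = math.isfinite(est.ci_high)
        return {
            "scenario": self.scenario,
            "method": self.method,
            "k": est.k,
            "estimate": est.ratio if est.is_ratio else est.theta_pooled,
            "ci_low": (rlo if est.is_ratio else est.ci_low) if defined_lo else None,
            "ci_high": (rhi if est.is_ratio else est.ci_high) if defined_hi else None,
            "ci_defined": defined_lo and defined_hi,
            "scale": est.scale_tag,
            "significant": est.significant,
            "excluded": ";".join(self.excluded),
            "subgroup": self.subgroup or "",
            "deltas": ";".join(self.delta_labels),
            "n_excluded_both_zero": est.n_excluded_both_zero,
        }


def run_ladder(
    base: TrialSet,
    scenarios: Sequence[ScenarioSpec],
    methods: Sequence[str] = (METHOD_DL_RANDOM,),
    cc: float = DEFAULT_CC,
    level: float = DEFAULT_LEVEL,
) -> list[LadderRow]:
    """Pool every scenario under every method; rows carry full provenance.

    A pure function of (base, scenarios, methods, cc, level): repeated runs
    produce identical ladders.
    """
    if not scenarios:
        raise ValidationError("ladder needs at least one scenario")
    rows: list[LadderRow] = []
    for sc in scenarios:
        ts = apply_scenario(base, sc)
        for method in methods:
            est = pool_tables(ts.tables(), method=method, cc=cc, level=level, study_ids=ts.study_ids)
            rows.append(
                LadderRow(
                    scenario=sc.name,
                    method=method,
                    estimate=est,
                    excluded=tuple(sc.excluded_study_ids),
                    subgroup=sc.subgroup_predicate,
                    delta_labels=tuple(d.label for d in sc.event_deltas),
                )
            )
    return rows


def ladder_frame(rows: Sequence[LadderRow]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rows])
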