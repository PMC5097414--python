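"""Two-axis adverse-event classification and aggregation to 2x2 tables.

Every reported AE term is placed on a severity axis (serious / non-serious /
not an AE at all) and a locality axis (local to the injected joint, local
elsewhere, systemic "other"). Competing review teams resolve these axes
differently — one team's clinical-judgment scheme may call "joint sprain"
non-serious and "cancer" not an AE, while a scheme deferring to the original
trial authors keeps both as serious — and those choices propagate into the
pooled tables. This module applies a scheme, aggregates labeled events to
per-study 2x2 tables for any severity x locality cell, and diffs two schemes
term by term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .data_model import (
    CONTROL,
    FALLBACK_ERROR,
    FALLBACK_USE_AUTHOR_FLAG,
    TREATMENT,
    AdverseEventRecord,
    ArmSummaryBinary,
    ClassificationScheme,
    Locality,
    Severity,
    StudyRecord,
    TrialSet,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledEvent:
    """An AdverseEventRecord with its scheme-assigned labels attached."""

    record: AdverseEventRecord
    severity: Severity
    locality: Locality
    from_fallback: bool = False

    @property
    def excluded(self) -> bool:
        return self.severity is Severity.NOT_AN_AE


def classify_events(
    events: Sequence[AdverseEventRecord], scheme: ClassificationScheme
) -> list[LabeledEvent]:
    """Label every record with (severity, locality) under a scheme.

    Unknown terms follow the scheme's fallback: ``use_author_flag`` takes
    severity from the record's author_serious flag with locality "other"
    (systemic default) and logs a warning; ``error`` raises.
    """
    labeled: list[LabeledEvent] = []
    warned: set[str] = set()
    for rec in events:
        hit = scheme.lookup(rec.term)
        if hit is not None:
            sev, loc = hit
            labeled.append(LabeledEvent(record=rec, severity=sev, locality=loc))
            continue
        if scheme.fallback == FALLBACK_ERROR:
            raise ValidationError(
                f"term {rec.term!r} (study {rec.study_id}) is not in scheme {scheme.name!r}"
            )
        assert scheme.fallback == FALLBACK_USE_AUTHOR_FLAG
        sev = Severity.SERIOUS if rec.author_serious else Severity.NON_SERIOUS
        if rec.term.lower() not in warned:
            logger.warning(
                "scheme %s has no rule for term %r; falling back to author seriousness (%s)",
                scheme.name, rec.term, sev.value,
            )
            warned.add(rec.term.lower())
        labeled.append(LabeledEvent(record=rec, severity=sev, locality=Locality.OTHER, from_fallback=True))
    return labeled


def _cell_matches(ev: LabeledEvent, severity: Severity, locality: Optional[Locality]) -> bool:
    if ev.excluded:
        return False
    if ev.severity is not severity:
        return False
    return locality is None or ev.locality is locality


def aggregate_counts(
    labeled: Sequence[LabeledEvent],
    studies: Sequence[StudyRecord],
    severity: Severity,
    locality: Optional[Locality] = None,
    ae_category: Optional[str] = None,
) -> TrialSet:
    """Sum labeled person-counts into per-study 2x2 tables for one cell.

    ``locality=None`` selects the union over localities ("all serious" /
    "all non-serious"). Every study in ``studies`` appears in the result;
    studies with no matching events get zero counts (and are later dropped
    by the both-zero rule at pooling time). Counts are persons-with-event
    per term and are summed across terms within an arm, so the aggregate
    is checked against the arm size.
    """
    by_id = {s.study_id: s for s in studies}
    if len(by_id) != len(studies):
        raise ValidationError("duplicate study_id in studies")
    sums: dict[tuple[str, str], int] = {}
    for ev in labeled:
        rec = ev.record
        if rec.study_id not in by_id:
            raise ValidationError(f"event for unknown study {rec.study_id!r}")
        if _cell_matches(ev, severity, locality):
            key = (rec.study_id, rec.arm_label)
            sums[key] = sums.get(key, 0) + rec.count

    if ae_category is None:
        loc_part = "all" if locality is None else locality.value
        ae_category = f"{severity.value}:{loc_part}"

    out: list[StudyRecord] = []
    for s in studies:
        if s.binary is not None:
            n_t, n_c = s.treatment_binary.n, s.control_binary.n
        else:
            n_t, n_c = s.treatment_continuous.n, s.control_continuous.n
        r_t = sums.get((s.study_id, TREATMENT), 0)
        r_c = sums.get((s.study_id, CONTROL), 0)
        if r_t > n_t or r_c > n_c:
            raise ValidationError(
                f"study {s.study_id!r}: aggregated events exceed arm size "
                f"({r_t}/{n_t} treatment, {r_c}/{n_c} control) in cell {ae_category!r}"
            )
        out.append(
            replace(
                s,
                binary=(
                    ArmSummaryBinary(TREATMENT, n_t, r_t),
                    ArmSummaryBinary(CONTROL, n_c, r_c),
                ),
                continuous=None,
            )
        )
    return TrialSet(studies=tuple(out), ae_category=ae_category)


def scheme_diff(
    a: ClassificationScheme, b: ClassificationScheme, terms: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Tabulate terms the two schemes label differently.

    One row per disagreeing term with both labels; terms covered by only
    one scheme are flagged ``missing_in_a`` / ``missing_in_b``. With
    ``terms=None`` the union of both rule sets is compared.
    """
    if terms is None:
        keys = sorted(set(a.rules) | set(b.rules))
    else:
        keys = sorted({t.strip().lower() for t in terms})
    rows = []
    for term in keys:
        la, lb = a.rules.get(term), b.rules.get(term)
        if la == lb:
            continue
        status = "disagree"
        if la is None:
            status = "missing_in_a"
        elif lb is None:
            status = "missing_in_b"
        rows.append(
            {
                "term": term,
                "status": status,
                f"severity_{a.name}": la[0].value if la else None,
                f"locality_{a.name}": la[1].value if la else None,
                f"severity_{b.name}": lb[0].value if lb else None,
                f"locality_{b.name}": lb[1].value if lb else None,
            }
        )
    cols = [
        "term", "status",
        f"severity_{a.name}", f"locality_{a.name}",
        f"severity_{b.name}", f"locality_{b.name}",
    ]
    return pd.DataFrame(rows, columns=cols)
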