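"""Domain types for study-level harms meta-analysis.

The package works on *study-level summaries*: for binary adverse-event (AE)
outcomes, per-arm sample sizes and counts of persons with at least one event
in an AE category; for continuous function outcomes, per-arm mean/SD/n.
Types are frozen dataclasses validated at construction; transformations
(event deltas, exclusions) return new objects and never mutate inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional


class ValidationError(ValueError):
    """Raised when a domain invariant is violated at construction or IO."""


class Severity(str, Enum):
    SERIOUS = "serious"
    NON_SERIOUS = "non_serious"
    NOT_AN_AE = "not_an_AE"


class Locality(str, Enum):
    JOINT = "joint"
    LOCAL_NON_JOINT = "local_non_joint"
    OTHER = "other"
    NA = "n/a"


TREATMENT = "treatment"
CONTROL = "control"
ARM_LABELS = (TREATMENT, CONTROL)


@dataclass(frozen=True)
class ArmSummaryBinary:
    """Per-arm binary summary: persons with >=1 event in an AE category."""

    arm_label: str
    n: int
    events: int

    def __post_init__(self) -> None:
        if self.arm_label not in ARM_LABELS:
            raise ValidationError(f"arm_label must be one of {ARM_LABELS}, got {self.arm_label!r}")
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if not (0 <= self.events <= self.n):
            raise ValidationError(f"events must satisfy 0 <= events <= n, got events={self.events}, n={self.n}")


@dataclass(frozen=True)
class ArmSummaryContinuous:
    """Per-arm continuous summary (mean, SD, n) on the outcome scale."""

    arm_label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.arm_label not in ARM_LABELS:
            raise ValidationError(f"arm_label must be one of {ARM_LABELS}, got {self.arm_label!r}")
        if self.n < 2:
            raise ValidationError(f"continuous arm needs n >= 2, got {self.n}")
        if not self.sd > 0:
            raise ValidationError(f"sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class TwoByTwoTable:
    """One study's 2x2 table for a binary AE category.

    r_t / n_t: treated events and size; r_c / n_c: control events and size.
    """

    r_t: int
    n_t: int
    r_c: int
    n_c: int

    def __post_init__(self) -> None:
        if not (0 <= self.r_t <= self.n_t):
            raise ValidationError(f"need 0 <= r_t <= n_t, got r_t={self.r_t}, n_t={self.n_t}")
        if not (0 <= self.r_c <= self.n_c):
            raise ValidationError(f"need 0 <= r_c <= n_c, got r_c={self.r_c}, n_c={self.n_c}")

    @property
    def both_zero(self) -> bool:
        return self.r_t == 0 and self.r_c == 0

    @property
    def single_zero(self) -> bool:
        return (self.r_t == 0) != (self.r_c == 0)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.r_t, self.n_t, self.r_c, self.n_c)


@dataclass(frozen=True)
class StudyRecord:
    """One randomized trial: one treatment arm vs one control arm.

    `binary` holds the arm summaries for the trial set's AE category;
    `continuous` holds function-outcome summaries. Either may be absent.
    Follow-up and year are metadata only; pooling applies no time weighting.
    """

    study_id: str
    year: Optional[int] = None
    blinded: bool = True
    follow_up_weeks: Optional[float] = None
    binary: Optional[tuple[ArmSummaryBinary, ArmSummaryBinary]] = None
    continuous: Optional[tuple[ArmSummaryContinuous, ArmSummaryContinuous]] = None

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be nonempty")
        if self.binary is None and self.continuous is None:
            raise ValidationError(f"study {self.study_id!r} has no arm summaries")
        for pair in (self.binary, self.continuous):
            if pair is not None:
                labels = sorted(a.arm_label for a in pair)
                if labels != sorted(ARM_LABELS):
                    raise ValidationError(
                        f"study {self.study_id!r} needs exactly one treatment and one control arm, got {labels}"
                    )

    def _arm(self, pair, label):
        return next(a for a in pair if a.arm_label == label)

    @property
    def treatment_binary(self) -> ArmSummaryBinary:
        if self.binary is None:
            raise ValidationError(f"study {self.study_id!r} has no binary arms")
        return self._arm(self.binary, TREATMENT)

    @property
    def control_binary(self) -> ArmSummaryBinary:
        if self.binary is None:
            raise ValidationError(f"study {self.study_id!r} has no binary arms")
        return self._arm(self.binary, CONTROL)

    @property
    def treatment_continuous(self) -> ArmSummaryContinuous:
        if self.continuous is None:
            raise ValidationError(f"study {self.study_id!r} has no continuous arms")
        return self._arm(self.continuous, TREATMENT)

    @property
    def control_continuous(self) -> ArmSummaryContinuous:
        if self.continuous is None:
            raise ValidationError(f"study {self.study_id!r} has no continuous arms")
        return self._arm(self.continuous, CONTROL)

    @property
    def total_n(self) -> int:
        pair = self.binary if self.binary is not None else self.continuous
        return sum(a.n for a in pair)  # type: ignore[union-attr]

    def table(self) -> TwoByTwoTable:
        t, c = self.treatment_binary, self.control_binary
        return TwoByTwoTable(r_t=t.events, n_t=t.n, r_c=c.events, n_c=c.n)

    def with_binary_events(self, arm_label: str, events: int) -> "StudyRecord":
        """Return a copy with the named arm's event count replaced."""
        if self.binary is None:
            raise ValidationError(f"study {self.study_id!r} has no binary arms")
        new_pair = tuple(
            replace(a, events=events) if a.arm_label == arm_label else a for a in self.binary
        )
        return replace(self, binary=new_pair)  # type: ignore[arg-type]


@dataclass(frozen=True)
class TrialSet:
    """A nonempty collection of studies sharing one AE category label."""

    studies: tuple[StudyRecord, ...]
    ae_category: str = "all_serious"

    def __post_init__(self) -> None:
        if len(self.studies) == 0:
            raise ValidationError("TrialSet must contain at least one study (no studies)")
        ids = [s.study_id for s in self.studies]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate study_id: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    @property
    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    def get(self, study_id: str) -> StudyRecord:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def tables(self) -> list[TwoByTwoTable]:
        return [s.table() for s in self.studies]

    def drop(self, study_ids: Iterable[str]) -> "TrialSet":
        ids = set(study_ids)
        missing = ids - set(self.study_ids)
        if missing:
            raise ValidationError(f"cannot drop unknown studies: {sorted(missing)}")
        kept = tuple(s for s in self.studies if s.study_id not in ids)
        if not kept:
            raise ValidationError("dropping these studies leaves an empty trial set")
        return replace(self, studies=kept)

    def replace_study(self, study: StudyRecord) -> "TrialSet":
        new = tuple(study if s.study_id == study.study_id else s for s in self.studies)
        return replace(self, studies=new)


@dataclass(frozen=True)
class AdverseEventRecord:
    """One reported AE term in one arm of one study (persons affected)."""

    term: str
    study_id: str
    arm_label: str
    count: int
    author_serious: bool = False

    def __post_init__(self) -> None:
        if not self.term:
            raise ValidationError("term must be nonempty")
        if self.arm_label not in ARM_LABELS:
            raise ValidationError(f"arm_label must be one of {ARM_LABELS}, got {self.arm_label!r}")
        if self.count < 1:
            raise ValidationError(f"count must be >= 1, got {self.count}")


FALLBACK_USE_AUTHOR_FLAG = "use_author_flag"
FALLBACK_ERROR = "error"


@dataclass(frozen=True)
class ClassificationScheme:
    """Maps AE terms to (severity, locality) labels.

    Terms are matched case-insensitively. `fallback` governs unknown terms:
    ``use_author_flag`` derives severity from the record's author_serious flag
    (locality defaults to OTHER, the systemic bucket), ``error`` raises.
    """

    name: str
    rules: dict[str, tuple[Severity, Locality]]
    fallback: str = FALLBACK_USE_AUTHOR_FLAG

    def __post_init__(self) -> None:
        if self.fallback not in (FALLBACK_USE_AUTHOR_FLAG, FALLBACK_ERROR):
            raise ValidationError(f"unknown fallback {self.fallback!r}")
        norm: dict[str, tuple[Severity, Locality]] = {}
        for term, (sev, loc) in self.rules.items():
            key = term.strip().lower()
            sev, loc = Severity(sev), Locality(loc)
            if sev is Severity.NOT_AN_AE and loc is not Locality.NA:
                raise ValidationError(f"term {term!r}: not_an_AE entries must have locality 'n/a'")
            if sev is not Severity.NOT_AN_AE and loc is Locality.NA:
                raise ValidationError(f"term {term!r}: locality 'n/a' is reserved for not_an_AE")
            if key in norm and norm[key] != (sev, loc):
                raise ValidationError(f"conflicting rules for term {term!r}")
            norm[key] = (sev, loc)
        object.__setattr__(self, "rules", norm)

    def lookup(self, term: str) -> Optional[tuple[Severity, Locality]]:
        return self.rules.get(term.strip().lower())


@dataclass(frozen=True)
class EventDelta:
    """A signed change to one arm's event count, with a provenance label."""

    study_id: str
    arm_label: str
    change: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.arm_label not in ARM_LABELS:
            raise ValidationError(f"arm_label must be one of {ARM_LABELS}, got {self.arm_label!r}")

    def inverse(self) -> "EventDelta":
        return replace(self, change=-self.change)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named transformation of a trial set.

    Applied in a fixed order: study exclusions, then the subgroup predicate,
    then event deltas (to the surviving studies).
    """

    name: str
    excluded_study_ids: tuple[str, ...] = ()
    subgroup_predicate: Optional[str] = None
    subgroup_params: dict = field(default_factory=dict)
    event_deltas: tuple[EventDelta, ...] = ()


@dataclass(frozen=True)
class HiddenStudy:
    """A study whose per-arm event counts were withheld; sizes are known."""

    study_id: str
    n_t: int
    n_c: int
    blinded: bool = True

    def __post_init__(self) -> None:
        if self.n_t < 1 or self.n_c < 1:
            raise ValidationError("hidden study arm sizes must be >= 1")
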