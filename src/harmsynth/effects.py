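"""Per-study effect estimates for harms meta-analysis.

Binary harms are summarized as log risk ratios with an explicit zero-cell
policy: tables with zero events in *both* arms carry no information about a
ratio and are excluded; tables with a zero in exactly one arm stay in, with
a continuity correction applied so the log-RR and its variance are finite.
Continuous function outcomes are summarized as standardized mean
differences with the Hedges small-sample correction, signed so that
negative values favor the treatment arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .config import DEFAULT_CC
from .data_model import ArmSummaryContinuous, TwoByTwoTable, ValidationError

SCALE_LOG_RR = "log_rr"
SCALE_LOG_OR = "log_or"
SCALE_SMD = "smd"


@dataclass(frozen=True)
class EffectEstimate:
    """A per-study effect on its analysis scale with sampling variance."""

    theta: float
    var: float
    scale_tag: str
    cc_applied: bool = False
    study_id: str = ""

    def __post_init__(self) -> None:
        if not self.var > 0:
            raise ValidationError(f"variance must be > 0, got {self.var}")

    @property
    def se(self) -> float:
        return math.sqrt(self.var)


def zero_cell_filter(
    tables: Sequence[TwoByTwoTable],
) -> tuple[list[TwoByTwoTable], list[TwoByTwoTable]]:
    """Partition tables into (included, excluded) by the both-zero rule.

    Tables with zero events in both arms are excluded from ratio pooling;
    every other table (including single-zero tables) is included. The
    partition is exhaustive: every input lands in exactly one output list.
    """
    included = [t for t in tables if not t.both_zero]
    excluded = [t for t in tables if t.both_zero]
    return included, excluded


def rr_single(
    table: TwoByTwoTable, cc: float = DEFAULT_CC, study_id: str = ""
) -> EffectEstimate:
    """Log risk ratio for one 2x2 table with single-zero continuity correction.

    If exactly one of r_t, r_c is zero, ``cc`` is added to all four cells
    before computing the ratio and its delta-method variance

        var(log RR) = 1/r_t - 1/n_t + 1/r_c - 1/n_c .

    Tables with zeros in both arms have no defined ratio and must be removed
    with :func:`zero_cell_filter` first.
    """
    if table.both_zero:
        raise ValidationError("risk ratio undefined for a table with zero events in both arms")
    cc_applied = table.single_zero
    add = cc if cc_applied else 0.0
    r_t, n_t = table.r_t + add, table.n_t + add
    r_c, n_c = table.r_c + add, table.n_c + add
    theta = math.log((r_t / n_t) / (r_c / n_c))
    var = 1.0 / r_t - 1.0 / n_t + 1.0 / r_c - 1.0 / n_c
    return EffectEstimate(theta=theta, var=var, scale_tag=SCALE_LOG_RR, cc_applied=cc_applied, study_id=study_id)


def hedges_correction(df: int) -> float:
    """Small-sample correction factor J(df) = 1 - 3/(4 df - 1), < 1, -> 1."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def smd_hedges(
    t: ArmSummaryContinuous, c: ArmSummaryContinuous, study_id: str = ""
) -> EffectEstimate:
    """Hedges-corrected standardized mean difference, treatment minus control.

    Standardizes by the pooled SD; a negative value favors treatment when
    lower outcome scores are better (the convention for function indices
    like WOMAC). Variance is the standard large-sample expression
    (n_t+n_c)/(n_t n_c) + g^2 / (2 (n_t+n_c)).
    """
    df = t.n + c.n - 2
    sp2 = ((t.n - 1) * t.sd**2 + (c.n - 1) * c.sd**2) / df
    if sp2 <= 0:
        raise ValidationError("pooled SD is zero; SMD undefined")
    j = hedges_correction(df)
    g = j * (t.mean - c.mean) / math.sqrt(sp2)
    var = (t.n + c.n) / (t.n * c.n) + g**2 / (2.0 * (t.n + c.n))
    return EffectEstimate(theta=g, var=var, scale_tag=SCALE_SMD, study_id=study_id)


def exceeds_threshold(pooled_smd: float, threshold: float) -> bool:
    """True iff a pooled SMD is at least as large as a clinical threshold.

    Both values live on the SMD scale with negative favoring treatment;
    the pooled effect exceeds the threshold when the signs agree and its
    magnitude is >= the threshold's magnitude.
    """
    if pooled_smd == 0.0 or threshold == 0.0:
        return False
    same_sign = (pooled_smd < 0) == (threshold < 0)
    return same_sign and abs(pooled_smd) >= abs(threshold)
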