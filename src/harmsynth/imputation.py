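"""Inversion of withheld event counts from a published pooled estimate.

When a meta-analysis includes trials whose event counts were withheld (only
arm sizes are public) but prints the pooled estimate with its CI, the hidden
integer counts can often be recovered: complete the trial set with candidate
counts, re-pool, and score the distance between the resulting
(point, ci_low, ci_high) triple and the published one on the log-ratio
scale. This module formalizes that "trial-and-error" as a bounded integer
program, solved either by exhaustive enumeration or by coordinate descent
with random restarts, reporting ties and whether the published target is
attainable at its printed precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import (
    DEFAULT_CC,
    DEFAULT_LEVEL,
    EXHAUSTIVE_CAP,
    IMPUTATION_WEIGHTS,
    PUBLISHED_ROUNDING_TOL,
)
from .data_model import (
    ArmSummaryBinary,
    HiddenStudy,
    StudyRecord,
    TrialSet,
    ValidationError,
)
from .pooling import METHOD_DL_RANDOM, pool_tables

Assignment = tuple[tuple[int, int], ...]  # per hidden study (r_t, r_c)


@dataclass(frozen=True)
class ImputationProblem:
    """Observed studies, hidden studies with known sizes, and a target triple.

    ``target`` is the published pooled (point, ci_low, ci_high) on the ratio
    scale; ``bounds`` caps the per-arm event counts searched for each hidden
    study (defaults to the arm sizes). ``weights`` are the objective weights
    for (point, ci_low, ci_high) mismatch on the log scale.
    """

    observed: TrialSet
    hidden: tuple[HiddenStudy, ...]
    target: tuple[float, float, float]
    method_tag: str = METHOD_DL_RANDOM
    bounds: Optional[tuple[tuple[int, int], ...]] = None
    weights: tuple[float, float, float] = IMPUTATION_WEIGHTS
    cc: float = DEFAULT_CC
    level: float = DEFAULT_LEVEL
    tolerance: float = PUBLISHED_ROUNDING_TOL

    def __post_init__(self) -> None:
        if not self.hidden:
            raise ValidationError("ImputationProblem needs at least one hidden study")
        point, lo, hi = self.target
        if not (lo <= point <= hi):
            raise ValidationError("target point must lie inside its CI")
        if point <= 0 or lo <= 0:
            raise ValidationError("ratio-scale target components must be positive")
        if self.bounds is None:
            object.__setattr__(
                self, "bounds", tuple((h.n_t, h.n_c) for h in self.hidden)
            )
        if len(self.bounds) != len(self.hidden):
            raise ValidationError("one (r_t, r_c) bound pair per hidden study required")
        for h, (bt, bc) in zip(self.hidden, self.bounds):
            if bt > h.n_t or bc > h.n_c:
                raise ValidationError(f"bounds for {h.study_id!r} exceed arm sizes")

    @property
    def n_candidates(self) -> int:
        return math.prod((bt + 1) * (bc + 1) for bt, bc in self.bounds)

    def complete(self, assignment: Assignment) -> TrialSet:
        """Trial set with hidden studies filled in with candidate counts."""
        studies = list(self.observed.studies)
        for h, (r_t, r_c) in zip(self.hidden, assignment):
            studies.append(
                StudyRecord(
                    study_id=h.study_id,
                    blinded=h.blinded,
                    binary=(
                        ArmSummaryBinary("treatment", h.n_t, r_t),
                        ArmSummaryBinary("control", h.n_c, r_c),
                    ),
                )
            )
        return TrialSet(studies=tuple(studies), ae_category=self.observed.ae_category)


@dataclass(frozen=True)
class ImputationSolution:
    """Best assignment(s) found, their objective, and attainability flags."""

    assignments: Assignment
    objective: float
    unique: bool
    ties: tuple[Assignment, ...]
    target_attained: bool
    strategy: str
    n_evaluated: int
    restarts: int = 0

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValidationError("objective must be >= 0")


def _pool_triple(problem: ImputationProblem, assignment: Assignment) -> Optional[tuple[float, float, float]]:
    ts = problem.complete(assignment)
    try:
        est = pool_tables(
            ts.tables(), method=problem.method_tag, cc=problem.cc,
            level=problem.level, study_ids=ts.study_ids,
        )
    except ValidationError:
        return None
    lo, hi = est.ratio_ci
    if not (est.ratio > 0 and lo > 0 and math.isfinite(hi)):
        return None
    return est.ratio, lo, hi


def discrepancy(assignment: Assignment, problem: ImputationProblem) -> float:
    """Weighted squared log-scale distance to the target triple.

    Candidates for which the pooled triple is undefined (e.g. every
    completed table both-zero) score infinity. With CI weights zero this
    reduces to the squared log-point error.
    """
    for (r_t, r_c), (bt, bc) in zip(assignment, problem.bounds):
        if not (0 <= r_t <= bt and 0 <= r_c <= bc):
            raise ValidationError(f"candidate {assignment} violates bounds")
    triple = _pool_triple(problem, assignment)
    if triple is None:
        return math.inf
    w = problem.weights
    return sum(
        wi * (math.log(a) - math.log(b)) ** 2 for wi, a, b in zip(w, triple, problem.target)
    )


def _attained(problem: ImputationProblem, assignment: Assignment) -> bool:
    triple = _pool_triple(problem, assignment)
    if triple is None:
        return False
    return all(abs(a - b) <= problem.tolerance + 1e-12 for a, b in zip(triple, problem.target))


def _total_events(a: Assignment) -> int:
    return sum(r_t + r_c for r_t, r_c in a)


def _finalize(
    problem: ImputationProblem,
    best: list[tuple[float, Assignment]],
    strategy: str,
    n_evaluated: int,
    restarts: int = 0,
    tie_eps: float = 1e-12,
) -> ImputationSolution:
    best_obj = min(o for o, _ in best)
    tied = sorted(
        {a for o, a in best if o <= best_obj + tie_eps},
        key=lambda a: (_total_events(a), a),
    )
    winner = tied[0]
    return ImputationSolution(
        assignments=winner,
        objective=best_obj,
        unique=len(tied) == 1,
        ties=tuple(tied),
        target_attained=_attained(problem, winner),
        strategy=strategy,
        n_evaluated=n_evaluated,
        restarts=restarts,
    )


def _invert_exhaustive(problem: ImputationProblem) -> ImputationSolution:
    if problem.n_candidates > EXHAUSTIVE_CAP:
        raise ValidationError(
            f"exhaustive search space ({problem.n_candidates} candidates) exceeds the cap "
            f"({EXHAUSTIVE_CAP}); use strategy='coordinate_descent'"
        )
    per_study = [
        [(r_t, r_c) for r_t in range(bt + 1) for r_c in range(bc + 1)]
        for bt, bc in problem.bounds
    ]
    best: list[tuple[float, Assignment]] = []
    best_obj = math.inf
    n_eval = 0
    for combo in itertools.product(*per_study):
        obj = discrepancy(combo, problem)
        n_eval += 1
        if obj < best_obj - 1e-12:
            best = [(obj, combo)]
            best_obj = obj
        elif obj <= best_obj + 1e-12:
            best.append((obj, combo))
    return _finalize(problem, best, "exhaustive", n_eval)


# per-study grids at or below this size are scanned exhaustively inside a
# block-coordinate update
_BLOCK_SCAN_CAP = 4096


def _invert_coordinate_descent(
    problem: ImputationProblem, n_restarts: int, seed: int
) -> ImputationSolution:
    rng = np.random.default_rng(seed)

    def starts():
        # heuristic start: hidden arms at the observed pooled event rates
        obs_tables = problem.observed.tables()
        p_t = sum(t.r_t for t in obs_tables) / sum(t.n_t for t in obs_tables)
        p_c = sum(t.r_c for t in obs_tables) / sum(t.n_c for t in obs_tables)
        heur = tuple(
            (min(round(p_t * h.n_t), bt), min(round(p_c * h.n_c), bc))
            for h, (bt, bc) in zip(problem.hidden, problem.bounds)
        )
        yield heur
        yield tuple((0, 0) for _ in problem.hidden)
        for _ in range(max(0, n_restarts - 2)):
            yield tuple(
                (int(rng.integers(0, bt + 1)), int(rng.integers(0, bc + 1)))
                for bt, bc in problem.bounds
            )

    best: list[tuple[float, Assignment]] = []
    n_eval = 0
    n_restart_done = 0
    for start in starts():
        cur = start
        cur_obj = discrepancy(cur, problem)
        n_eval += 1
        improved = True
        while improved:
            improved = False
            for i in range(len(problem.hidden)):
                bt, bc = problem.bounds[i]
                candidates = []
                if (bt + 1) * (bc + 1) <= _BLOCK_SCAN_CAP:
                    # exact block move: scan the study's whole (r_t, r_c) grid,
                    # so each block update is globally optimal given the rest
                    moves = [(vt, vc) for vt in range(bt + 1) for vc in range(bc + 1)]
                else:
                    # large grid: axis scans plus the diagonal, which tracks
                    # the ratio ridge where r_t and r_c trade off
                    r_t, r_c = cur[i]
                    moves = {(vt, r_c) for vt in range(bt + 1)}
                    moves |= {(r_t, vc) for vc in range(bc + 1)}
                    moves |= {
                        (r_t + d, r_c + d)
                        for d in range(-min(r_t, r_c), min(bt - r_t, bc - r_c) + 1)
                    }
                    moves |= {
                        (r_t + dt, r_c + dc)
                        for dt in range(-3, 4)
                        for dc in range(-3, 4)
                        if 0 <= r_t + dt <= bt and 0 <= r_c + dc <= bc
                    }
                for vt, vc in moves:
                    cand = list(map(list, cur))
                    cand[i] = [vt, vc]
                    cand_t = tuple(tuple(p) for p in cand)
                    obj = discrepancy(cand_t, problem)
                    n_eval += 1
                    candidates.append((obj, cand_t))
                obj, cand_t = min(candidates, key=lambda t: (t[0], _total_events(t[1])))
                if obj < cur_obj - 1e-15:
                    cur, cur_obj = cand_t, obj
                    improved = True
        best.append((cur_obj, cur))
        n_restart_done += 1
    return _finalize(problem, best, "coordinate_descent", n_eval, restarts=n_restart_done)


def invert_counts(
    problem: ImputationProblem,
    strategy: str = "exhaustive",
    n_restarts: int = 6,
    seed: int = 0,
) -> ImputationSolution:
    """Recover hidden per-arm event counts matching a published pooled result.

    ``exhaustive`` enumerates the full candidate grid (global minimizers,
    ties reported, refused above the candidate cap); ``coordinate_descent``
    runs block-coordinate descent over the hidden studies (exhaustive block
    scans for small per-study grids, axis/diagonal/window moves for large
    ones) from a heuristic start plus random restarts. Reporting order among ties is smallest total events
    first. ``target_attained`` is False when no candidate reproduces the
    target within the printed-rounding tolerance.
    """
    if strategy == "exhaustive":
        return _invert_exhaustive(problem)
    if strategy == "coordinate_descent":
        return _invert_coordinate_descent(problem, n_restarts=n_restarts, seed=seed)
    raise ValidationError(f"unknown strategy {strategy!r}")
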