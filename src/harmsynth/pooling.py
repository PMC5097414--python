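"""Pooling engines for study-level effect estimates.

Four methods, exposed both as scikit-learn-style estimators (``fit`` on a
list of per-study inputs, fitted attributes with trailing underscores,
``get_params``/``set_params``) and as thin module-level functions:

* inverse-variance fixed effect (``iv_fixed``),
* DerSimonian–Laird random effects (``dl_random``): method-of-moments
  between-study variance tau^2, weights 1/(v_i + tau^2),
* Mantel–Haenszel risk ratio (``mh``) with the Greenland–Robins variance,
  stable with sparse strata and needing no continuity correction for
  single-zero tables,
* exact conditional common-odds-ratio inference (``exact_conditional``),
  delegating to :mod:`harmsynth.exact`.

Ratio results are reported back-transformed (RR / OR with CI on the ratio
scale); internal arithmetic stays on the log scale and is never rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator

from . import exact as _exact
from .config import DEFAULT_CC, DEFAULT_LEVEL
from .data_model import TwoByTwoTable, ValidationError
from .effects import (
    SCALE_LOG_OR,
    SCALE_LOG_RR,
    EffectEstimate,
    rr_single,
    zero_cell_filter,
)

METHOD_IV_FIXED = "iv_fixed"
METHOD_DL_RANDOM = "dl_random"
METHOD_MH = "mh"
METHOD_EXACT = "exact_conditional"
RATIO_METHODS = (METHOD_IV_FIXED, METHOD_DL_RANDOM, METHOD_MH, METHOD_EXACT)


def _psum(x: np.ndarray) -> float:
    """Permutation-invariant float sum (summands sorted before adding)."""
    return float(np.sum(np.sort(np.asarray(x, dtype=float))))


@dataclass(frozen=True)
class PooledEstimate:
    """A pooled effect with CI, weights and heterogeneity statistics.

    ``theta_pooled`` and the CI bounds live on the analysis scale (log-RR,
    log-OR, or SMD); ``ratio``/``ratio_ci`` expose the back-transformed
    values for ratio scales. Heterogeneity fields are NaN where the method
    does not define them (MH, exact).
    """

    theta_pooled: float
    ci_low: float
    ci_high: float
    method_tag: str
    scale_tag: str
    k: int
    weights: tuple[float, ...]
    Q: float = math.nan
    tau2: float = math.nan
    I2: float = math.nan
    level: float = DEFAULT_LEVEL
    study_ids: tuple[str, ...] = ()
    n_excluded_both_zero: int = 0

    def __post_init__(self) -> None:
        # normalize to plain Python floats (JSON-safe, hashable, comparable)
        for name in ("theta_pooled", "ci_low", "ci_high", "Q", "tau2", "I2", "level"):
            object.__setattr__(self, name, float(getattr(self, name)))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if self.weights and abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("pooling weights must sum to 1")
        if not (self.ci_low <= self.theta_pooled <= self.ci_high):
            raise ValidationError("CI must bracket the pooled effect on the analysis scale")
        if not math.isnan(self.tau2) and self.tau2 < 0:
            raise ValidationError("tau2 must be >= 0")
        if not math.isnan(self.I2) and not (0 <= self.I2 <= 100):
            raise ValidationError("I2 must lie in [0, 100]")

    @property
    def is_ratio(self) -> bool:
        return self.scale_tag in (SCALE_LOG_RR, SCALE_LOG_OR)

    @property
    def ratio(self) -> float:
        return math.exp(self.theta_pooled) if self.is_ratio else math.nan

    @property
    def ratio_ci(self) -> tuple[float, float]:
        if not self.is_ratio:
            return (math.nan, math.nan)
        return (math.exp(self.ci_low), math.exp(self.ci_high))

    @property
    def significant(self) -> bool:
        """CI excludes the null (1 on the ratio scale, 0 otherwise)."""
        null = 0.0
        return self.ci_low > null or self.ci_high < null


def heterogeneity(effects: Sequence[EffectEstimate]) -> tuple[float, float, float]:
    """Cochran Q, DerSimonian–Laird tau^2 and I^2 for k >= 2 estimates.

    Q is computed against the fixed-effect mean; tau^2 = max(0, (Q - df)/C)
    with C = sum(w) - sum(w^2)/sum(w); I^2 = max(0, (Q - df)/Q) * 100.
    """
    if len(effects) < 2:
        raise ValidationError("heterogeneity needs at least two studies")
    theta = np.array([e.theta for e in effects])
    w = 1.0 / np.array([e.var for e in effects])
    wsum = _psum(w)
    mean_fe = _psum(w * theta) / wsum
    Q = _psum(w * (theta - mean_fe) ** 2)
    df = len(effects) - 1
    C = wsum - _psum(w**2) / wsum
    tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return Q, tau2, I2


class _PoolerMixin:
    """Shared summary/CI plumbing for the pooling estimators."""

    def _check_fitted(self) -> None:
        if not hasattr(self, "theta_"):
            raise ValidationError(f"{type(self).__name__} is not fitted yet; call fit first")

    def summary(self) -> PooledEstimate:
        self._check_fitted()
        return self.result_


class InverseVariancePooler(BaseEstimator, _PoolerMixin):
    """Inverse-variance pooling, fixed effect or DerSimonian–Laird random.

    Parameters
    ----------
    model : {"fixed", "dl_random"}
        Fixed effect weights are 1/v_i; DL adds the method-of-moments
        between-study variance, weights 1/(v_i + tau^2).
    level : float
        Two-sided confidence level for the Wald interval.

    ``fit`` accepts a sequence of :class:`EffectEstimate` sharing one
    scale_tag. Fitted attributes: ``theta_``, ``ci_low_``, ``ci_high_``,
    ``weights_``, ``tau2_``, ``q_``, ``i2_``, ``k_``, ``result_``.
    """

    def __init__(self, model: str = "dl_random", level: float = DEFAULT_LEVEL):
        self.model = model
        self.level = level

    def fit(self, X: Sequence[EffectEstimate], y=None) -> "InverseVariancePooler":
        if self.model not in ("fixed", "dl_random"):
            raise ValidationError(f"unknown model {self.model!r}")
        effects = list(X)
        if not effects:
            raise ValidationError("cannot pool an empty list of effects")
        scales = {e.scale_tag for e in effects}
        if len(scales) > 1:
            raise ValidationError(f"mixed effect scales: {sorted(scales)}")
        theta = np.array([e.theta for e in effects])
        v = np.array([e.var for e in effects])
        if not np.all(np.isfinite(theta)) or not np.all(np.isfinite(v)):
            raise ValidationError("effects must have finite theta and variance")

        if len(effects) >= 2:
            Q, tau2, I2 = heterogeneity(effects)
        else:
            Q, tau2, I2 = 0.0, 0.0, 0.0
        tau2_used = tau2 if self.model == "dl_random" else 0.0
        w = 1.0 / (v + tau2_used)
        wsum = _psum(w)
        pooled = _psum(w * theta) / wsum
        se = math.sqrt(1.0 / wsum)
        z = norm.ppf(0.5 + self.level / 2.0)

        self.k_ = len(effects)
        self.theta_ = pooled
        self.se_ = se
        self.ci_low_ = pooled - z * se
        self.ci_high_ = pooled + z * se
        self.weights_ = w / wsum
        self.q_, self.tau2_, self.i2_ = Q, tau2, I2
        self.result_ = PooledEstimate(
            theta_pooled=pooled,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            method_tag=METHOD_IV_FIXED if self.model == "fixed" else METHOD_DL_RANDOM,
            scale_tag=effects[0].scale_tag,
            k=self.k_,
            weights=tuple(self.weights_),
            Q=Q,
            tau2=tau2,
            I2=I2,
            level=self.level,
            study_ids=tuple(e.study_id for e in effects),
        )
        return self


class MantelHaenszelPooler(BaseEstimator, _PoolerMixin):
    """Mantel–Haenszel pooled risk ratio over stratified 2x2 tables.

    RR_MH = sum(r_t n_c / N) / sum(r_c n_t / N) with the Greenland–Robins
    variance for log RR_MH. Single-zero tables need no correction; tables
    with zero events in both arms are excluded (recorded in the result).
    A single stratum reduces exactly to the crude risk ratio.
    """

    def __init__(self, level: float = DEFAULT_LEVEL):
        self.level = level

    def fit(self, X: Sequence[TwoByTwoTable], y=None) -> "MantelHaenszelPooler":
        included, excluded = zero_cell_filter(list(X))
        if not included:
            raise ValidationError("no tables left after excluding both-zero strata")
        a = np.array([t.r_t for t in included], dtype=float)
        n1 = np.array([t.n_t for t in included], dtype=float)
        c = np.array([t.r_c for t in included], dtype=float)
        n0 = np.array([t.n_c for t in included], dtype=float)
        N = n1 + n0
        R = a * n0 / N
        S = c * n1 / N
        sum_R, sum_S = _psum(R), _psum(S)
        if sum_S == 0 or sum_R == 0:
            raise ValidationError("Mantel–Haenszel RR undefined: one arm has no events in any stratum")
        rr = sum_R / sum_S
        P = (n1 * n0 * (a + c) - a * c * N) / N**2
        var_log = _psum(P) / (sum_R * sum_S)
        theta = math.log(rr)
        z = norm.ppf(0.5 + self.level / 2.0)
        se = math.sqrt(var_log)
        weights = S / sum_S  # control-expectation weights, the MH weighting of stratum RRs

        self.k_ = len(included)
        self.theta_ = theta
        self.se_ = se
        self.ci_low_ = theta - z * se
        self.ci_high_ = theta + z * se
        self.weights_ = weights
        self.result_ = PooledEstimate(
            theta_pooled=theta,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            method_tag=METHOD_MH,
            scale_tag=SCALE_LOG_RR,
            k=self.k_,
            weights=tuple(weights),
            level=self.level,
            n_excluded_both_zero=len(excluded),
        )
        return self


class ExactConditionalPooler(BaseEstimator, _PoolerMixin):
    """Exact conditional inference on the common odds ratio.

    Wraps :func:`harmsynth.exact.exact_conditional`. The pooled effect is
    the conditional MLE on the log-OR scale with the exact central CI;
    per-stratum weights are Fisher-information shares at the MLE. Boundary
    cases (observed total on the edge of the conditional support) yield a
    one-sided interval with the open end at 0 or infinity.
    """

    def __init__(self, level: float = DEFAULT_LEVEL):
        self.level = level

    def fit(self, X: Sequence[TwoByTwoTable], y=None) -> "ExactConditionalPooler":
        tables = list(X)
        included, excluded = zero_cell_filter(tables)
        res = _exact.exact_conditional(tables, level=self.level)
        theta = math.log(res.psi_hat) if 0 < res.psi_hat < math.inf else (
            -math.inf if res.psi_hat == 0 else math.inf
        )
        ci_low = math.log(res.ci_low) if res.ci_low > 0 else -math.inf
        ci_high = math.log(res.ci_high) if res.ci_high < math.inf else math.inf

        self.k_ = res.k_informative
        self.theta_ = theta
        self.ci_low_ = ci_low
        self.ci_high_ = ci_high
        self.weights_ = res.stratum_weights
        self.exact_ = res
        self.result_ = PooledEstimate(
            theta_pooled=theta,
            ci_low=ci_low,
            ci_high=ci_high,
            method_tag=METHOD_EXACT,
            scale_tag=SCALE_LOG_OR,
            k=res.k_informative,
            weights=tuple(res.stratum_weights),
            level=self.level,
            n_excluded_both_zero=len(excluded),
        )
        return self


def pool_iv(
    effects: Sequence[EffectEstimate],
    model: str = "dl_random",
    level: float = DEFAULT_LEVEL,
) -> PooledEstimate:
    """Inverse-variance pooling (fixed or DL random effects)."""
    return InverseVariancePooler(model=model, level=level).fit(effects).summary()


def pool_mh_rr(tables: Sequence[TwoByTwoTable], level: float = DEFAULT_LEVEL) -> PooledEstimate:
    """Mantel–Haenszel pooled risk ratio."""
    return MantelHaenszelPooler(level=level).fit(tables).summary()


def pool_exact(tables: Sequence[TwoByTwoTable], level: float = DEFAULT_LEVEL) -> PooledEstimate:
    """Exact conditional common-odds-ratio pooling."""
    return ExactConditionalPooler(level=level).fit(tables).summary()


def pool_tables(
    tables: Sequence[TwoByTwoTable],
    method: str = METHOD_DL_RANDOM,
    cc: float = DEFAULT_CC,
    level: float = DEFAULT_LEVEL,
    study_ids: Optional[Sequence[str]] = None,
) -> PooledEstimate:
    """Pool binary 2x2 tables by any supported ratio method.

    For the inverse-variance routes this filters both-zero tables, forms
    per-study log risk ratios (continuity correction ``cc`` on single-zero
    tables) and pools them; MH and exact consume the tables directly.
    """
    if method not in RATIO_METHODS:
        raise ValidationError(f"unknown pooling method {method!r}; choose from {RATIO_METHODS}")
    if method == METHOD_MH:
        return pool_mh_rr(tables, level=level)
    if method == METHOD_EXACT:
        return pool_exact(tables, level=level)
    ids = list(study_ids) if study_ids is not None else [""] * len(tables)
    pairs = [(t, i) for t, i in zip(tables, ids) if not t.both_zero]
    n_excl = len(tables) - len(pairs)
    if not pairs:
        raise ValidationError("no tables left after excluding both-zero strata")
    effects = [rr_single(t, cc=cc, study_id=i) for t, i in pairs]
    est = pool_iv(effects, model="fixed" if method == METHOD_IV_FIXED else "dl_random", level=level)
    if n_excl:
        from dataclasses import replace as _replace

        est = _replace(est, n_excluded_both_zero=n_excl)
    return est
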