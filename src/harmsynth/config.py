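"""Package-wide defaults and clinically derived thresholds.

Every constant an analysis depends on but that the source trial reports do
not fix is surfaced here and overridable at the call site or via the CLI
config file.
"""

# Minimum clinically important difference / improvement thresholds on the
# SMD scale (negative favors treatment). MCID_STRICT is the conservative
# threshold used by the comparison review; the two MCII values come from
# anchor-based derivations in the knee-OA literature.
MCID_STRICT = -0.37
MCII_TUBACH = -0.12
MCII_BANNURU = -0.20

# Continuity correction added to all four cells of a 2x2 table when exactly
# one arm has zero events (ratio estimators stay finite).
DEFAULT_CC = 0.5

# Two-sided confidence level for every interval in the package.
DEFAULT_LEVEL = 0.95

# "Large" trial threshold (total randomized n across both arms) for the
# large-blinded subgroup predicate; the source reviews never define "large",
# so this is an explicit, configurable choice.
DEFAULT_LARGE_TRIAL_N = 200

# Exhaustive imputation search refuses candidate spaces above this cap.
EXHAUSTIVE_CAP = 10_000_000

# Printed-precision tolerance for matching a published pooled estimate
# rounded to two decimals (half a unit in the last place, RR scale).
PUBLISHED_ROUNDING_TOL = 0.005

# Default component weights for the imputation objective:
# (point, ci_low, ci_high).
IMPUTATION_WEIGHTS = (2.0, 1.0, 1.0)

# Exact conditional inference: bisection bracket on log odds ratio and
# tail-probability tolerance for CI inversion.
EXACT_LOG_PSI_BRACKET = (-15.0, 15.0)
EXACT_TAIL_TOL = 1e-8
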