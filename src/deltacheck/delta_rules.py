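"""Delta-check metrics, rule representation, and RCV-based rule construction.

Four univariate delta-check metrics are supported:

``DD``
    delta difference, ``current - previous`` in analyte units.
``DPC``
    delta percent change, ``100 * (current - previous) / previous`` in %.
``RD``
    rate difference, DD divided by the inter-test interval, units/day.
``RPC``
    rate percent change, DPC divided by the interval, %/day.

Metrics are kept *signed* and compared against a signed pair of limits
``lower_limit <= 0 <= upper_limit``; asymmetric conventional cutoffs (for
example AST, with a far larger positive than negative allowance) are only
meaningful on signed metrics.  A metric can be *non-evaluable* — DPC/RPC
when the previous result is zero or negative, RD/RPC when the interval is
below a half-day floor — in which case the pair is never flagged but is
still counted.

:func:`build_rcv_rule` turns a reference change value into a delta-check
rule in three variants: the plain percent-change cutoff, a time-scaled
rate-percent-change cutoff, and an absolute-difference cutoff obtained by
anchoring the percentage at twice the upper normal limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .panel_model import AnalyteSpec, ResultPair
    from .uncertainty_rcv import RCVResult

__all__ = [
    "METHODS",
    "MIN_RATE_INTERVAL_DAYS",
    "DeltaRule",
    "DeltaVerdict",
    "delta_difference",
    "delta_percent_change",
    "rate_difference",
    "rate_percent_change",
    "compute_metric",
    "evaluate_rule",
    "evaluate_pairs",
    "build_rcv_rule",
]

METHODS = ("DD", "DPC", "RD", "RPC")

#: Rate metrics (units/day, %/day) are non-evaluable below this interval;
#: same-day repeats remain evaluable by DD/DPC but a rate over a fraction
#: of a day would be dominated by the division.
MIN_RATE_INTERVAL_DAYS = 0.5

_METHOD_UNITS = {
    "DD": "{units}",
    "DPC": "%",
    "RD": "{units}/day",
    "RPC": "%/day",
}


@dataclass(frozen=True)
class DeltaRule:
    """A univariate delta-check rule with signed, possibly asymmetric limits.

    Parameters
    ----------
    analyte
        Analyte name the rule applies to.
    method
        One of ``DD``, ``DPC``, ``RD``, ``RPC``.
    upper_limit, lower_limit
        Signed cutoffs; a pair flags when the metric is strictly above
        ``upper_limit`` or strictly below ``lower_limit``.  Values exactly
        at a cutoff do not flag.
    limit_units
        Units of the limits, consistent with the method.
    exclude_within_ri
        When true, pairs whose results both lie inside the closed reference
        interval are excluded from flagging (reported separately).
    divide_limits_by_interval
        Literal reading of the time modification: the limits themselves are
        divided by the interval in days before comparison with the metric.
        The default time-scaled construction uses an RPC rule instead.
    label
        Free-form tag used in detection reports.
    """

    analyte: str
    method: str
    upper_limit: float
    lower_limit: float
    limit_units: str = ""
    exclude_within_ri: bool = False
    divide_limits_by_interval: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"{self.analyte}: unknown delta-check method {self.method!r}; "
                f"expected one of {METHODS}"
            )
        if not (self.lower_limit <= 0.0 <= self.upper_limit):
            raise ValueError(
                f"{self.analyte}: limits must satisfy lower <= 0 <= upper, "
                f"got [{self.lower_limit}, {self.upper_limit}]"
            )


@dataclass(frozen=True)
class DeltaVerdict:
    """Outcome of one rule applied to one result pair.

    ``metric_value`` is ``None`` when the metric is non-evaluable; a
    non-evaluable pair is never flagged.  ``excluded_within_ri`` marks pairs
    suppressed because both results sit inside the reference interval.
    """

    pair: "ResultPair"
    rule: DeltaRule
    metric_value: Optional[float]
    flagged: bool
    excluded_within_ri: bool = False

    @property
    def evaluable(self) -> bool:
        return self.metric_value is not None


def delta_difference(pair: "ResultPair") -> float:
    """Signed difference ``current - previous`` in analyte units."""
    return pair.current.value - pair.previous.value


def delta_percent_change(pair: "ResultPair") -> Optional[float]:
    """``100 * (current - previous) / previous``; ``None`` if previous <= 0."""
    prev = pair.previous.value
    if prev <= 0:
        return None
    return 100.0 * (pair.current.value - prev) / prev


def rate_difference(
    pair: "ResultPair", min_interval_days: float = MIN_RATE_INTERVAL_DAYS
) -> Optional[float]:
    """Delta difference per day; ``None`` below the interval floor."""
    if pair.delta_days < min_interval_days:
        return None
    return delta_difference(pair) / pair.delta_days


def rate_percent_change(
    pair: "ResultPair", min_interval_days: float = MIN_RATE_INTERVAL_DAYS
) -> Optional[float]:
    """Delta percent change per day; ``None`` if DPC is non-evaluable or the
    interval is below the floor."""
    if pair.delta_days < min_interval_days:
        return None
    dpc = delta_percent_change(pair)
    if dpc is None:
        return None
    return dpc / pair.delta_days


def compute_metric(method: str, pair: "ResultPair") -> Optional[float]:
    """Dispatch one of the four metrics by name."""
    if method == "DD":
        return delta_difference(pair)
    if method == "DPC":
        return delta_percent_change(pair)
    if method == "RD":
        return rate_difference(pair)
    if method == "RPC":
        return rate_percent_change(pair)
    raise ValueError(f"unknown delta-check method {method!r}")


def _both_within_ri(pair: "ResultPair", spec: "AnalyteSpec") -> bool:
    lo, hi = spec.ref_low, spec.ref_high
    return (lo <= pair.previous.value <= hi) and (lo <= pair.current.value <= hi)


def evaluate_rule(
    rule: DeltaRule, pair: "ResultPair", spec: Optional["AnalyteSpec"] = None
) -> DeltaVerdict:
    """Apply one delta-check rule to one result pair.

    A pair flags when its signed metric exceeds ``upper_limit`` or falls
    below ``lower_limit`` (strict comparisons).  When the rule carries the
    within-reference-interval exclusion, pairs with both results inside the
    closed interval ``[ref_low, ref_high]`` are excluded — never flagged —
    and marked as such; ``spec`` must then be provided.
    """
    if spec is not None and rule.analyte and spec.name != rule.analyte:
        raise ValueError(
            f"rule for {rule.analyte!r} evaluated against spec {spec.name!r}"
        )
    metric = compute_metric(rule.method, pair)

    if rule.exclude_within_ri:
        if spec is None:
            raise ValueError(
                "exclude_within_ri rule requires the AnalyteSpec for the "
                "reference interval"
            )
        if _both_within_ri(pair, spec):
            return DeltaVerdict(
                pair=pair, rule=rule, metric_value=metric,
                flagged=False, excluded_within_ri=True,
            )

    if metric is None:
        return DeltaVerdict(pair=pair, rule=rule, metric_value=None, flagged=False)

    upper, lower = rule.upper_limit, rule.lower_limit
    if rule.divide_limits_by_interval:
        if pair.delta_days < MIN_RATE_INTERVAL_DAYS:
            return DeltaVerdict(pair=pair, rule=rule, metric_value=None, flagged=False)
        upper = upper / pair.delta_days
        lower = lower / pair.delta_days

    flagged = metric > upper or metric < lower
    return DeltaVerdict(pair=pair, rule=rule, metric_value=metric, flagged=flagged)


def evaluate_pairs(
    rule: DeltaRule,
    pairs: Iterable["ResultPair"],
    spec: Optional["AnalyteSpec"] = None,
) -> list[DeltaVerdict]:
    """Vector form of :func:`evaluate_rule` over many pairs."""
    return [evaluate_rule(rule, p, spec) for p in pairs]


def build_rcv_rule(
    spec: "AnalyteSpec",
    rcv: "RCVResult",
    variant: str = "base",
    exclude_within_ri: bool = False,
    literal_time_scaling: bool = False,
    label: str = "",
) -> DeltaRule:
    """Construct a delta-check rule from a reference change value.

    Variants
    --------
    ``base``
        DPC rule with symmetric limits ±RCV%.
    ``time_scaled``
        The time-factor modification.  By default an RPC rule with limits
        ±RCV interpreted as %/day, so a pair flags when |DPC| > RCV·Δt — the
        direction that relaxes the cutoff for long intervals.  With
        ``literal_time_scaling`` the rule stays a DPC rule whose limits are
        divided by Δt at evaluation time (the opposite scaling).
    ``abs_2uln``
        DD rule with limits ±(RCV/100)·2·ULN in analyte units, anchoring the
        percentage cutoff at twice the upper normal limit so analytes with
        narrow reference intervals are not over-flagged by percent changes.
    """
    if rcv.analyte and rcv.analyte != spec.name:
        raise ValueError(f"RCV for {rcv.analyte!r} used with spec {spec.name!r}")
    r = rcv.rcv_percent
    if variant == "base":
        return DeltaRule(
            analyte=spec.name, method="DPC", upper_limit=r, lower_limit=-r,
            limit_units="%", exclude_within_ri=exclude_within_ri,
            label=label or "rcv_dpc",
        )
    if variant == "time_scaled":
        if literal_time_scaling:
            return DeltaRule(
                analyte=spec.name, method="DPC", upper_limit=r, lower_limit=-r,
                limit_units="%", exclude_within_ri=exclude_within_ri,
                divide_limits_by_interval=True, label=label or "rcv_dpc_per_day_literal",
            )
        return DeltaRule(
            analyte=spec.name, method="RPC", upper_limit=r, lower_limit=-r,
            limit_units="%/day", exclude_within_ri=exclude_within_ri,
            label=label or "rcv_rpc",
        )
    if variant == "abs_2uln":
        if spec.ref_high <= 0:
            raise ValueError(
                f"{spec.name}: abs_2uln variant needs a positive upper normal limit"
            )
        limit = (r / 100.0) * 2.0 * spec.ref_high
        return DeltaRule(
            analyte=spec.name, method="DD", upper_limit=limit, lower_limit=-limit,
            limit_units=spec.units, exclude_within_ri=exclude_within_ri,
            label=label or "rcv_dd_2uln",
        )
    raise ValueError(
        f"unknown RCV rule variant {variant!r}; expected base, time_scaled or abs_2uln"
    )
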