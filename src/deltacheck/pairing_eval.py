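"""Pair longitudinal results and compute detection-rate reports.

Pairing follows the screening workflow: each incoming result is compared
with the *most recent* prior result of the same patient and analyte, and
only if that prior result is recent enough — within a lookback window that
depends on the care setting (40 days for inpatients, 60 days for
outpatients; health-examination recipients reuse the outpatient window).
A result is "current" in at most one pair but may serve as the "previous"
of a later result, so serial visits produce a chain of pairs.

The detection rate of a rule is the percentage of pairs it flags.  By
default the denominator counts *all* pairs, including non-evaluable pairs
and pairs excluded by the within-reference-interval modification (both as
unflagged) — this makes the exclusion a guaranteed, monotone reduction of
the rate; an evaluable-only denominator is available.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .delta_rules import DeltaRule, DeltaVerdict, build_rcv_rule, evaluate_rule
from .panel_model import AnalyteSpec, PatientResult, ResultPair
from .uncertainty_rcv import K_95, K_99, compute_rcv

__all__ = [
    "DEFAULT_WINDOWS",
    "DEFAULT_VARIANTS",
    "pair_results",
    "detection_rate",
    "build_variant_rule",
    "compare_rules",
    "write_report_csv",
    "pivot_report",
]

logger = logging.getLogger(__name__)

#: Setting-specific lookback windows in days.
DEFAULT_WINDOWS: dict[str, float] = {
    "inpatient": 40.0,
    "outpatient": 60.0,
    "health_exam": 60.0,
}

#: Rule variants compared in the standard report: the laboratory's
#: conventional rule, plain RCV cutoffs at 95%/99% confidence, and the
#: three modifications of the 99% rule (within-RI exclusion, time scaling,
#: absolute cutoff at twice the upper normal limit).
DEFAULT_VARIANTS = ("current", "rcv95", "rcv99", "rcv99_m1", "rcv99_m2", "rcv99_m3")

REPORT_COLUMNS = [
    "analyte",
    "setting",
    "rule_label",
    "n_pairs",
    "n_evaluable",
    "n_excluded_within_ri",
    "n_flagged",
    "detection_rate_percent",
]


def pair_results(
    results: Sequence[PatientResult],
    windows: Optional[Mapping[str, float]] = None,
) -> list[ResultPair]:
    """Pair each result with its most recent prior result within the window.

    The window is looked up by the *current* result's care setting.  Results
    are processed in (patient, analyte, time) order; for tied prior
    timestamps the one later in stable input order wins.
    """
    windows = dict(DEFAULT_WINDOWS if windows is None else windows)
    groups: dict[tuple[str, str], list[PatientResult]] = {}
    for r in results:
        groups.setdefault((r.patient_id, r.analyte), []).append(r)

    pairs: list[ResultPair] = []
    for key in sorted(groups):
        series = sorted(groups[key], key=lambda r: r.time)  # stable on ties
        for prev, curr in zip(series, series[1:]):
            if curr.setting not in windows:
                raise KeyError(
                    f"no lookback window configured for setting {curr.setting!r}"
                )
            if curr.time <= prev.time:
                logger.debug(
                    "tied timestamps for %s/%s at %s; keeping later input",
                    curr.patient_id, curr.analyte, curr.time,
                )
                continue
            gap_days = (curr.time - prev.time).total_seconds() / 86400.0
            if gap_days <= windows[curr.setting]:
                pairs.append(ResultPair(previous=prev, current=curr))
    return pairs


def detection_rate(
    verdicts: Sequence[DeltaVerdict],
    analyte: str = "",
    setting: str = "",
    rule_label: str = "",
    denominator: str = "all",
) -> dict:
    """Summarise verdicts of one rule on one analyte x setting stratum.

    ``denominator="all"`` divides flags by every pair seen (excluded and
    non-evaluable pairs count as unflagged); ``"evaluable"`` divides by
    evaluable, non-excluded pairs only.  An empty stratum yields
    ``n_pairs=0`` and a NaN rate.
    """
    if denominator not in ("all", "evaluable"):
        raise ValueError(f"denominator must be 'all' or 'evaluable', got {denominator!r}")
    n_pairs = len(verdicts)
    n_excluded = sum(v.excluded_within_ri for v in verdicts)
    n_evaluable = sum(v.evaluable and not v.excluded_within_ri for v in verdicts)
    n_flagged = sum(v.flagged for v in verdicts)
    denom = n_pairs if denominator == "all" else n_evaluable
    rate = float("nan") if denom == 0 else 100.0 * n_flagged / denom
    if verdicts:
        rule_label = rule_label or verdicts[0].rule.label
        analyte = analyte or verdicts[0].pair.analyte
        setting = setting or verdicts[0].pair.current.setting
    return {
        "analyte": analyte,
        "setting": setting,
        "rule_label": rule_label,
        "n_pairs": n_pairs,
        "n_evaluable": n_evaluable,
        "n_excluded_within_ri": n_excluded,
        "n_flagged": n_flagged,
        "detection_rate_percent": rate,
    }


def build_variant_rule(
    variant: str,
    spec: AnalyteSpec,
    setting: str,
    k95: float = K_95,
    k99: float = K_99,
    literal_time_scaling: bool = False,
) -> Optional[DeltaRule]:
    """Materialise one named rule variant for an analyte and setting.

    Returns ``None`` when the variant is the conventional rule and the
    panel defines none for that setting.  RCV-based variants require the
    spec to carry a ``cva_percent``.
    """
    if variant == "current":
        return spec.conventional_rules.get(setting)
    if spec.cva_percent is None:
        raise ValueError(f"{spec.name}: RCV variants need cva_percent on the spec")
    if variant == "rcv95":
        rcv = compute_rcv(spec.cvi_percent, spec.cva_percent, k95, analyte=spec.name)
        return build_rcv_rule(spec, rcv, variant="base", label="rcv95")
    rcv99 = compute_rcv(spec.cvi_percent, spec.cva_percent, k99, analyte=spec.name)
    if variant == "rcv99":
        return build_rcv_rule(spec, rcv99, variant="base", label="rcv99")
    if variant == "rcv99_m1":
        return build_rcv_rule(
            spec, rcv99, variant="base", exclude_within_ri=True, label="rcv99_m1"
        )
    if variant == "rcv99_m2":
        return build_rcv_rule(
            spec, rcv99, variant="time_scaled",
            literal_time_scaling=literal_time_scaling, label="rcv99_m2",
        )
    if variant == "rcv99_m3":
        return build_rcv_rule(spec, rcv99, variant="abs_2uln", label="rcv99_m3")
    raise ValueError(f"unknown rule variant {variant!r}")


def compare_rules(
    pairs: Sequence[ResultPair],
    specs: Sequence[AnalyteSpec],
    variants: Sequence[str] = DEFAULT_VARIANTS,
    denominator: str = "all",
    k95: float = K_95,
    k99: float = K_99,
    literal_time_scaling: bool = False,
) -> pd.DataFrame:
    """Long-format detection report: one row per analyte x setting x variant.

    Analytes lacking a conventional rule for a setting have that variant
    skipped with a warning; strata with no pairs are omitted.
    """
    by_spec = {s.name: s for s in specs}
    strata: dict[tuple[str, str], list[ResultPair]] = {}
    for p in pairs:
        if p.analyte not in by_spec:
            raise KeyError(f"pair analyte {p.analyte!r} not in panel")
        strata.setdefault((p.analyte, p.current.setting), []).append(p)

    rows = []
    for (analyte, setting) in sorted(strata):
        spec = by_spec[analyte]
        stratum = strata[(analyte, setting)]
        for variant in variants:
            rule = build_variant_rule(
                variant, spec, setting, k95=k95, k99=k99,
                literal_time_scaling=literal_time_scaling,
            )
            if rule is None:
                logger.warning(
                    "%s/%s: no conventional rule; variant %r skipped",
                    analyte, setting, variant,
                )
                continue
            verdicts = [evaluate_rule(rule, p, spec) for p in stratum]
            rows.append(
                detection_rate(
                    verdicts, analyte=analyte, setting=setting,
                    rule_label=variant, denominator=denominator,
                )
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report_csv(report: pd.DataFrame, path: Union[str, Path]) -> None:
    report.to_csv(path, index=False)


def pivot_report(report: pd.DataFrame) -> pd.DataFrame:
    """Wide pivot: analytes as rows, (setting, rule) detection rates as columns."""
    return report.pivot_table(
        index="analyte",
        columns=["setting", "rule_label"],
        values="detection_rate_percent",
        sort=False,
    )
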