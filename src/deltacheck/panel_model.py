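"""Domain types for the analyte panel and longitudinal patient results.

The panel is a set of :class:`AnalyteSpec` records — units, reference
interval, within-subject biological variation (CVi), optionally
between-subject variation (CVg) and a laboratory-measured analytical
imprecision (CVa), plus the laboratory's conventional delta-check rules per
care setting.  A packaged default panel covers 17 routine serum chemistry
analytes.

Patient data are :class:`PatientResult` rows (patient, care setting,
analyte, value, timestamp) exchanged as plain CSV, and
:class:`ResultPair` couples a result with the most recent prior result of
the same patient and analyte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

__all__ = [
    "SETTINGS",
    "HIGH_INDIVIDUALITY_THRESHOLD",
    "PanelConfigError",
    "AnalyteSpec",
    "PatientResult",
    "ResultPair",
    "load_panel",
    "panel_to_dict",
    "write_config",
    "index_of_individuality",
    "is_high_individuality",
    "read_results_csv",
    "write_results_csv",
]

#: Care settings distinguished by the evaluation: hospitalised patients,
#: ambulatory patients, and general health-examination recipients.
SETTINGS = ("inpatient", "outpatient", "health_exam")

#: An analyte whose index of individuality (CVi/CVg) falls below this value
#: is considered highly individual: serial results hug a personal set point,
#: so delta checks outperform population reference intervals.
HIGH_INDIVIDUALITY_THRESHOLD = 0.60


class PanelConfigError(ValueError):
    """Raised when a panel configuration is missing fields or inconsistent."""


@dataclass(frozen=True)
class AnalyteSpec:
    """One analyte's measurement and biological-variation parameters.

    ``ref_high`` doubles as the upper normal limit (ULN) used by the
    absolute-difference rule variant.  One-sided reference intervals
    (e.g. cholesterol "0 ~ 199") are stored with ``ref_low = 0``; the
    within-reference-interval test is closed on both bounds.
    """

    name: str
    units: str
    ref_low: float
    ref_high: float
    cvi_percent: float
    cvg_percent: Optional[float] = None
    cva_percent: Optional[float] = None
    conventional_rules: Mapping[str, "DeltaRule"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelConfigError("analyte name must be non-empty")
        if not (self.ref_low < self.ref_high):
            raise PanelConfigError(
                f"{self.name}: ref_low ({self.ref_low}) must be < ref_high "
                f"({self.ref_high})"
            )
        for fname in ("cvi_percent", "cvg_percent", "cva_percent"):
            v = getattr(self, fname)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise PanelConfigError(
                    f"{self.name}: {fname} must be a finite non-negative "
                    f"number, got {v}"
                )

    def within_reference_interval(self, value: float) -> bool:
        return self.ref_low <= value <= self.ref_high


@dataclass(frozen=True)
class PatientResult:
    """A single analyte result for one patient at one time."""

    patient_id: str
    setting: str
    analyte: str
    value: float
    time: datetime

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(
                f"unknown care setting {self.setting!r}; expected one of {SETTINGS}"
            )
        if not math.isfinite(self.value):
            raise ValueError(f"{self.patient_id}/{self.analyte}: value must be finite")


@dataclass(frozen=True)
class ResultPair:
    """A (previous, current) pair of results for the same patient and analyte.

    ``delta_days`` is the inter-test interval as fractional days and is
    derived from the timestamps on construction.
    """

    previous: PatientResult
    current: PatientResult
    delta_days: float = field(init=False)

    def __post_init__(self) -> None:
        if self.previous.patient_id != self.current.patient_id:
            raise ValueError("pair must belong to one patient")
        if self.previous.analyte != self.current.analyte:
            raise ValueError("pair must belong to one analyte")
        if not self.current.time > self.previous.time:
            raise ValueError("current result must be strictly later than previous")
        dt = (self.current.time - self.previous.time).total_seconds() / 86400.0
        object.__setattr__(self, "delta_days", dt)

    @property
    def analyte(self) -> str:
        return self.current.analyte

    @property
    def patient_id(self) -> str:
        return self.current.patient_id


# ---------------------------------------------------------------------------
# Panel configuration


def _rule_from_mapping(analyte: str, setting: str, raw: Mapping) -> "DeltaRule":
    from .delta_rules import _METHOD_UNITS, DeltaRule

    for key in ("method", "upper", "lower"):
        if key not in raw:
            raise PanelConfigError(
                f"{analyte}: conventional rule for {setting} is missing {key!r}"
            )
    try:
        return DeltaRule(
            analyte=analyte,
            method=str(raw["method"]),
            upper_limit=float(raw["upper"]),
            lower_limit=float(raw["lower"]),
            limit_units=str(raw.get("units", "")),
            label=f"current_{setting}",
        )
    except ValueError as exc:
        raise PanelConfigError(f"{analyte}: invalid rule for {setting}: {exc}") from exc


def _spec_from_mapping(raw: Mapping) -> AnalyteSpec:
    name = raw.get("name")
    if not name:
        raise PanelConfigError("analyte block without a name")
    for key in ("units", "ref_low", "ref_high", "cvi_percent"):
        if key not in raw:
            raise PanelConfigError(f"{name}: missing required field {key!r}")
    rules_raw = raw.get("conventional_rules") or {}
    unknown = set(rules_raw) - set(SETTINGS)
    if unknown:
        raise PanelConfigError(f"{name}: unknown settings in rules: {sorted(unknown)}")
    rules = {
        setting: _rule_from_mapping(name, setting, rule_raw)
        for setting, rule_raw in rules_raw.items()
    }
    return AnalyteSpec(
        name=str(name),
        units=str(raw["units"]),
        ref_low=float(raw["ref_low"]),
        ref_high=float(raw["ref_high"]),
        cvi_percent=float(raw["cvi_percent"]),
        cvg_percent=None if raw.get("cvg_percent") is None else float(raw["cvg_percent"]),
        cva_percent=None if raw.get("cva_percent") is None else float(raw["cva_percent"]),
        conventional_rules=rules,
    )


def load_panel(
    config_source: Union[None, str, Path, Mapping] = None
) -> list[AnalyteSpec]:
    """Load and validate an analyte panel.

    ``config_source`` may be a path to a YAML file, an already-parsed
    mapping, or ``None`` for the packaged default panel of 17 serum
    chemistry analytes.
    """
    if config_source is None:
        text = (resources.files("deltacheck") / "data" / "panel.yaml").read_text()
        doc = yaml.safe_load(text)
    elif isinstance(config_source, Mapping):
        doc = config_source
    else:
        doc = yaml.safe_load(Path(config_source).read_text())
    if not isinstance(doc, Mapping) or "analytes" not in doc:
        raise PanelConfigError("panel config must be a mapping with an 'analytes' list")
    specs = [_spec_from_mapping(block) for block in doc["analytes"]]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise PanelConfigError(f"duplicate analytes in panel: {dupes}")
    return specs


def panel_to_dict(specs: Sequence[AnalyteSpec]) -> dict:
    """Serialise a panel back to the configuration mapping."""
    out = []
    for s in specs:
        block: dict = {
            "name": s.name,
            "units": s.units,
            "ref_low": s.ref_low,
            "ref_high": s.ref_high,
            "cvi_percent": s.cvi_percent,
        }
        if s.cvg_percent is not None:
            block["cvg_percent"] = s.cvg_percent
        if s.cva_percent is not None:
            block["cva_percent"] = s.cva_percent
        if s.conventional_rules:
            block["conventional_rules"] = {
                setting: {
                    "method": r.method,
                    "upper": r.upper_limit,
                    "lower": r.lower_limit,
                }
                for setting, r in s.conventional_rules.items()
            }
        out.append(block)
    return {"analytes": out}


def write_config(specs: Sequence[AnalyteSpec], path: Union[str, Path]) -> None:
    """Write a panel to a YAML file that :func:`load_panel` round-trips."""
    Path(path).write_text(
        yaml.safe_dump(panel_to_dict(specs), sort_keys=False, default_flow_style=False)
    )


# ---------------------------------------------------------------------------
# Index of individuality


def index_of_individuality(cvi_percent: float, cvg_percent: float) -> float:
    """Ratio of within-subject to between-subject biological variation.

    Low values mean an individual's results occupy a narrow band inside the
    population reference interval, so a population interval is insensitive
    to within-person change and delta checks are the better screen.
    """
    if cvi_percent < 0:
        raise ValueError(f"cvi_percent must be >= 0, got {cvi_percent}")
    if cvg_percent <= 0:
        raise ValueError(f"cvg_percent must be > 0, got {cvg_percent}")
    return cvi_percent / cvg_percent


def is_high_individuality(index: float) -> bool:
    """True when the index of individuality is below 0.60."""
    return index < HIGH_INDIVIDUALITY_THRESHOLD


# ---------------------------------------------------------------------------
# Patient-result CSV dialect: patient_id,setting,analyte,value,time

_RESULT_COLUMNS = ["patient_id", "setting", "analyte", "value", "time"]


def read_results_csv(path: Union[str, Path]) -> list[PatientResult]:
    """Read patient results from CSV with ISO-8601 timestamps."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results CSV missing columns: {missing}")
    times = pd.to_datetime(df["time"])
    return [
        PatientResult(
            patient_id=str(row.patient_id),
            setting=str(row.setting),
            analyte=str(row.analyte),
            value=float(row.value),
            time=t.to_pydatetime(),
        )
        for row, t in zip(df.itertuples(index=False), times)
    ]


def write_results_csv(results: Iterable[PatientResult], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "setting": r.setting,
                "analyte": r.analyte,
                "value": r.value,
                "time": r.time.isoformat(),
            }
            for r in results
        ],
        columns=_RESULT_COLUMNS,
    )
    df.to_csv(path, index=False)
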