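"""Synthetic QC series and longitudinal patient cohorts with error injection.

No patient-level data accompany the delta-check methodology, so this module
generates cohorts with exactly the statistical structure the reference-
change-value model assumes, letting every downstream stage be tested with
known truth:

* each patient carries a homeostatic **set point** drawn around the
  population mean with between-subject variation CVg;
* each visit's true value fluctuates around the set point with
  within-subject variation CVi;
* the measurement adds analytical imprecision CVa.

All three act multiplicatively: ``value = set_point * (1 + e_i + e_a)``
with independent zero-mean Gaussian ``e_i`` (sd CVi/100) and ``e_a``
(sd CVa/100).  A lognormal option multiplies exponentiated Gaussians
instead, for right-skewed analytes (bilirubins, aminotransferases).
Visit intervals are uniform within a per-setting range, a fraction of
patients may have set points displaced outside the reference interval, and
a fraction may drift log-linearly in time (pathological change).

Specimen mix-ups — the classical target of delta checks — are injected by
swapping measured values between two random patients with the same analyte
on the same collection day, and detection can be scored against the
injected truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .panel_model import AnalyteSpec, PatientResult, ResultPair
from .uncertainty_rcv import QCSeries

__all__ = [
    "DEFAULT_INTERVAL_DAYS",
    "AnalyteSimParams",
    "CohortSimConfig",
    "params_from_spec",
    "simulate_qc",
    "simulate_cohort",
    "inject_mixups",
    "label_pairs",
    "score_error_detection",
]

#: Typical revisit intervals (days) by care setting: inpatients are sampled
#: every one to seven days, outpatients return after one to eight weeks,
#: health-exam recipients only within the 60-day pairing horizon by chance.
DEFAULT_INTERVAL_DAYS: dict[str, tuple[float, float]] = {
    "inpatient": (1.0, 7.0),
    "outpatient": (7.0, 56.0),
    "health_exam": (30.0, 60.0),
}

_EPOCH = datetime(2018, 8, 1)


@dataclass(frozen=True)
class AnalyteSimParams:
    """Generative parameters for one analyte.

    CVs are percentages.  ``lognormal`` switches the noise model from
    additive-on-the-multiplier to exponentiated Gaussians.
    """

    name: str
    set_point_mean: float
    cvg_percent: float
    cvi_percent: float
    cva_percent: float
    lognormal: bool = False
    ref_low: Optional[float] = None
    ref_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.set_point_mean <= 0:
            raise ValueError(f"{self.name}: set_point_mean must be positive")
        for fname in ("cvg_percent", "cvi_percent", "cva_percent"):
            if getattr(self, fname) < 0:
                raise ValueError(f"{self.name}: {fname} must be >= 0")


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of one simulated cohort.

    ``abnormal_fraction`` of patients get set points displaced outside the
    reference interval (when the analyte defines one); ``drift_fraction``
    of patients change log-linearly by ``drift_percent_per_day`` per day.
    A fixed seed reproduces the cohort exactly.
    """

    n_patients: int
    analytes: tuple[AnalyteSimParams, ...]
    setting: str = "inpatient"
    visits_per_patient: int = 5
    interval_days: Optional[tuple[float, float]] = None
    abnormal_fraction: float = 0.0
    drift_fraction: float = 0.0
    drift_percent_per_day: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.visits_per_patient < 1:
            raise ValueError("visits_per_patient must be >= 1")
        for fname in ("abnormal_fraction", "drift_fraction"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{fname} must be in [0, 1], got {v}")
        iv = self.interval_days
        if iv is not None and not (0 < iv[0] <= iv[1]):
            raise ValueError(f"interval_days must be 0 < lo <= hi, got {iv}")
        object.__setattr__(self, "analytes", tuple(self.analytes))


def params_from_spec(
    spec: AnalyteSpec,
    set_point_mean: Optional[float] = None,
    cvg_percent: Optional[float] = None,
    lognormal: bool = False,
) -> AnalyteSimParams:
    """Simulation preset derived from a panel entry.

    Defaults: set point at the reference-interval midpoint (or 70% of the
    upper limit for one-sided intervals), and — since the panel ships no
    between-subject CVs — a preset CVg of twice CVi.
    """
    if set_point_mean is None:
        if spec.ref_low > 0:
            set_point_mean = 0.5 * (spec.ref_low + spec.ref_high)
        else:
            set_point_mean = 0.7 * spec.ref_high
    if cvg_percent is None:
        cvg_percent = spec.cvg_percent if spec.cvg_percent is not None else 2.0 * spec.cvi_percent
    if spec.cva_percent is None:
        raise ValueError(f"{spec.name}: spec has no cva_percent for simulation")
    return AnalyteSimParams(
        name=spec.name,
        set_point_mean=set_point_mean,
        cvg_percent=cvg_percent,
        cvi_percent=spec.cvi_percent,
        cva_percent=spec.cva_percent,
        lognormal=lognormal,
        ref_low=spec.ref_low,
        ref_high=spec.ref_high,
    )


def simulate_qc(
    analyte: str,
    instrument: str,
    level: str,
    true_mean: float,
    true_cv_percent: float,
    n: int,
    seed: int = 0,
) -> QCSeries:
    """I.i.d. Gaussian QC series with the given mean and CV."""
    if true_mean <= 0:
        raise ValueError("true_mean must be positive")
    if true_cv_percent < 0:
        raise ValueError("true_cv_percent must be >= 0")
    if n < 2:
        raise ValueError("need n >= 2 QC values")
    rng = np.random.default_rng(seed)
    sd = true_mean * true_cv_percent / 100.0
    vals = rng.normal(true_mean, sd, size=n)
    # QC values are concentrations; an (astronomically unlikely at sane CVs)
    # non-positive draw is clipped to a tiny positive value.
    vals = np.maximum(vals, 1e-9 * true_mean)
    return QCSeries(analyte=analyte, instrument=instrument, level=level,
                    values=tuple(float(v) for v in vals))


def _multipliers(rng: np.random.Generator, cv_percent: float, size) -> np.ndarray:
    return rng.normal(0.0, cv_percent / 100.0, size=size)


def simulate_cohort(config: CohortSimConfig) -> list[PatientResult]:
    """Generate one cohort of longitudinal results.

    Each patient receives a set point per analyte, a visit schedule with
    uniform inter-visit intervals, and one measured result per analyte per
    visit following the multiplicative noise model.  Output is sorted by
    (patient, analyte, time) and byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n, v = config.n_patients, config.visits_per_patient
    if n == 0:
        return []
    lo, hi = config.interval_days or DEFAULT_INTERVAL_DAYS[config.setting]

    # Visit schedule: staggered start within one week, then uniform gaps.
    starts = rng.uniform(0.0, 7.0, size=n)
    gaps = rng.uniform(lo, hi, size=(n, max(v - 1, 0)))
    offsets = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(gaps, axis=1)], axis=1
    ) + starts[:, None]

    abnormal = rng.random(n) < config.abnormal_fraction
    drifting = rng.random(n) < config.drift_fraction

    results: list[PatientResult] = []
    patient_ids = [f"P{i:06d}" for i in range(n)]
    for params in config.analytes:
        e_between = _multipliers(rng, params.cvg_percent, n)
        if params.lognormal:
            set_points = params.set_point_mean * np.exp(e_between)
        else:
            set_points = params.set_point_mean * (1.0 + e_between)
        set_points = np.maximum(set_points, 1e-9 * params.set_point_mean)

        if config.abnormal_fraction > 0 and params.ref_high is not None:
            # Displace abnormal set points just beyond the upper normal
            # limit (below the lower limit for the second half, when the
            # interval is two-sided).
            k = int(abnormal.sum())
            if k:
                above = rng.uniform(1.1, 1.6, size=k) * params.ref_high
                if params.ref_low is not None and params.ref_low > 0:
                    below = rng.uniform(0.5, 0.9, size=k) * params.ref_low
                    pick_low = rng.random(k) < 0.5
                    displaced = np.where(pick_low, below, above)
                else:
                    displaced = above
                set_points = set_points.copy()
                set_points[abnormal] = displaced

        e_i = _multipliers(rng, params.cvi_percent, (n, v))
        e_a = _multipliers(rng, params.cva_percent, (n, v))
        if params.lognormal:
            values = set_points[:, None] * np.exp(e_i) * np.exp(e_a)
        else:
            values = set_points[:, None] * (1.0 + e_i + e_a)
        if config.drift_fraction > 0 and config.drift_percent_per_day != 0.0:
            slope = math.log1p(config.drift_percent_per_day / 100.0)
            t_rel = offsets - offsets[:, [0]]
            values = values * np.where(
                drifting[:, None], np.exp(slope * t_rel), 1.0
            )
        values = np.maximum(values, 0.0)

        for i in range(n):
            pid = patient_ids[i]
            for j in range(v):
                results.append(
                    PatientResult(
                        patient_id=pid,
                        setting=config.setting,
                        analyte=params.name,
                        value=float(values[i, j]),
                        time=_EPOCH + timedelta(days=float(offsets[i, j])),
                    )
                )
    results.sort(key=lambda r: (r.patient_id, r.analyte, r.time))
    return results


ResultKey = tuple[str, str, datetime]


def _result_key(r: PatientResult) -> ResultKey:
    return (r.patient_id, r.analyte, r.time)


def inject_mixups(
    results: Sequence[PatientResult],
    rate: float,
    seed: int = 0,
) -> tuple[list[PatientResult], set[ResultKey]]:
    """Swap measured values between random same-day, same-analyte patients.

    Each result instant is independently marked with probability ``rate``;
    marked instants within one (analyte, collection day) group are paired
    up and their *values* exchanged, emulating a specimen mix-up.  Returns
    the modified results and the set of affected (patient, analyte, time)
    keys.  If marking leaves no swappable partner anywhere, a warning is
    emitted and no values change.
    """
    import warnings

    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    out = list(results)
    swapped: set[ResultKey] = set()
    if rate == 0.0 or not out:
        return out, swapped

    rng = np.random.default_rng(seed)
    marked = rng.random(len(out)) < rate
    groups: dict[tuple[str, datetime], list[int]] = {}
    for idx, r in enumerate(out):
        if marked[idx]:
            day = datetime(r.time.year, r.time.month, r.time.day)
            groups.setdefault((r.analyte, day), []).append(idx)

    n_swaps = 0
    for key in sorted(groups):
        idxs = groups[key]
        rng.shuffle(idxs)
        for a, b in zip(idxs[::2], idxs[1::2]):
            if out[a].patient_id == out[b].patient_id:
                continue
            va, vb = out[a].value, out[b].value
            out[a] = replace(out[a], value=vb)
            out[b] = replace(out[b], value=va)
            swapped.add(_result_key(out[a]))
            swapped.add(_result_key(out[b]))
            n_swaps += 1
    if n_swaps == 0:
        warnings.warn(
            "mix-up injection found no swappable same-day partners; "
            "results unchanged", stacklevel=2,
        )
    return out, swapped


def label_pairs(
    pairs: Sequence[ResultPair], swapped: set[ResultKey]
) -> list[bool]:
    """True for pairs touched by an injected error (either member swapped)."""
    return [
        _result_key(p.previous) in swapped or _result_key(p.current) in swapped
        for p in pairs
    ]


def score_error_detection(
    verdicts: Sequence["DeltaVerdict"],
    truth_labels: Sequence[bool],
) -> dict[str, Optional[float]]:
    """Sensitivity, specificity and positive predictive value over pairs.

    ``truth_labels[i]`` says whether pair ``i`` contains an injected error;
    a verdict's flag is the prediction.  Undefined ratios (no positives, no
    negatives, no flags) are returned as ``None``.
    """
    if len(verdicts) != len(truth_labels):
        raise ValueError("verdicts and truth_labels must align one-to-one")
    tp = fp = fn = tn = 0
    for v, truth in zip(verdicts, truth_labels):
        if v.flagged and truth:
            tp += 1
        elif v.flagged:
            fp += 1
        elif truth:
            fn += 1
        else:
            tn += 1
    return {
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
        "ppv": tp / (tp + fp) if (tp + fp) else None,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }
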