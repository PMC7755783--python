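"""Top-down analytical imprecision and reference change values.

The analytical imprecision CVa of each analyte is estimated *top-down*: the
coefficient of variation of a year of internal quality-control results, one
series per instrument and control level, with no exclusion of out-of-control
points.  With two analysers and two control levels this yields up to four CV
estimates per analyte; the largest is taken as CVa.

The reference change value (RCV) is the smallest difference between two
serial results in one patient that is distinguishable from the combination
of analytical imprecision and within-subject biological variation::

    RCV = k * sqrt(2) * sqrt(CVa^2 + CVi^2)

where ``sqrt(CVa^2 + CVi^2)`` is the combined uncertainty of a single
result (as a CV around the patient's homeostatic set point), ``sqrt(2)``
accounts for the difference of two such results, and the coverage factor
``k`` is the standard-normal multiplier of the chosen two-sided confidence
level: 1.96 for 95%, 2.58 for 99%.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .panel_model import AnalyteSpec

__all__ = [
    "K_95",
    "K_99",
    "QC_LEVELS",
    "QCSeries",
    "RCVResult",
    "qc_cv",
    "max_cva",
    "cva_from_qc",
    "compute_rcv",
    "rcv_table",
    "read_qc_csv",
    "write_rcv_csv",
]

K_95 = 1.96
K_99 = 2.58

QC_LEVELS = ("level1", "level2")


@dataclass(frozen=True)
class QCSeries:
    """One internal QC series: analyte x instrument x control level."""

    analyte: str
    instrument: str
    level: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.level not in QC_LEVELS:
            raise ValueError(
                f"{self.analyte}/{self.instrument}: level must be one of "
                f"{QC_LEVELS}, got {self.level!r}"
            )
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2:
            raise ValueError(
                f"{self.analyte}/{self.instrument}/{self.level}: need at least "
                f"2 QC values, got {len(vals)}"
            )
        if any(not math.isfinite(v) or v <= 0 for v in vals):
            raise ValueError(
                f"{self.analyte}/{self.instrument}/{self.level}: QC values must "
                f"be finite and positive"
            )
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class RCVResult:
    """A reference change value together with every input that produced it."""

    analyte: str
    cvi_percent: float
    cva_percent: float
    k: float
    combined_u_percent: float
    rcv_percent: float
    n_cva_sources: int = 0


def qc_cv(series: QCSeries) -> float:
    """Coefficient of variation of a QC series, in percent.

    Uses the sample (n-1) standard deviation over the raw values; no
    outlier or out-of-control exclusion is applied.
    """
    vals = np.asarray(series.values, dtype=float)
    mean = vals.mean()
    if mean <= 0:
        raise ValueError(
            f"{series.analyte}/{series.instrument}/{series.level}: "
            f"mean must be positive"
        )
    return 100.0 * vals.std(ddof=1) / mean


def max_cva(cvs: Sequence[float]) -> float:
    """Largest of the per-instrument x per-level CV estimates.

    Intended for the (up to four) QC CVs of a single analyte; accepts any
    non-empty collection.
    """
    cvs = list(cvs)
    if not cvs:
        raise ValueError("max_cva requires at least one CV estimate")
    if any(c < 0 for c in cvs):
        raise ValueError("CV estimates must be non-negative")
    return max(cvs)


def cva_from_qc(
    qc: Iterable[QCSeries], per_instrument: bool = False
) -> dict:
    """Aggregate QC series into analytical-imprecision estimates.

    Returns ``{analyte: (cva_percent, n_sources)}`` with the max-of-series
    rule, or ``{(analyte, instrument): (cva_percent, n_sources)}`` when
    ``per_instrument`` is set (max over control levels within each
    instrument only).
    """
    groups: dict = {}
    for s in qc:
        key = (s.analyte, s.instrument) if per_instrument else s.analyte
        groups.setdefault(key, []).append(qc_cv(s))
    return {key: (max_cva(cvs), len(cvs)) for key, cvs in groups.items()}


def compute_rcv(
    cvi_percent: float, cva_percent: float, k: float, analyte: str = ""
) -> RCVResult:
    """Reference change value ``k * sqrt(2) * sqrt(CVa^2 + CVi^2)``.

    All quantities are percentages of the homeostatic set point; the result
    carries every input for audit.
    """
    for label, v in (("cvi_percent", cvi_percent), ("cva_percent", cva_percent)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{analyte or 'analyte'}: {label} must be finite "
                             f"and >= 0, got {v}")
    if not k > 0:
        raise ValueError(f"coverage factor k must be positive, got {k}")
    combined = math.hypot(cvi_percent, cva_percent)
    return RCVResult(
        analyte=analyte,
        cvi_percent=cvi_percent,
        cva_percent=cva_percent,
        k=k,
        combined_u_percent=combined,
        rcv_percent=k * math.sqrt(2.0) * combined,
    )


def rcv_table(
    specs: Sequence[AnalyteSpec],
    qc: Optional[Iterable[QCSeries]] = None,
    cva_map: Optional[Mapping[str, float]] = None,
    k_values: Sequence[float] = (K_95, K_99),
    on_missing: str = "skip",
) -> list[RCVResult]:
    """One :class:`RCVResult` per analyte and coverage factor.

    The CVa source is, in order of precedence: ``cva_map`` (precomputed
    percentages), ``qc`` series aggregated by the max rule, or the
    ``cva_percent`` stored on each spec.  Analytes with no CVa source are
    skipped with a warning (``on_missing="skip"``) or raise
    (``on_missing="error"``).
    """
    import warnings

    qc_cvas: dict[str, tuple[float, int]] = dict(cva_from_qc(qc)) if qc else {}
    out: list[RCVResult] = []
    for spec in specs:
        n_sources = 0
        if cva_map is not None and spec.name in cva_map:
            cva = float(cva_map[spec.name])
            n_sources = 1
        elif spec.name in qc_cvas:
            cva, n_sources = qc_cvas[spec.name]
        elif spec.cva_percent is not None:
            cva = spec.cva_percent
            n_sources = 1
        else:
            msg = f"{spec.name}: no analytical-imprecision (CVa) source; skipped"
            if on_missing == "error":
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        for k in k_values:
            res = compute_rcv(spec.cvi_percent, cva, k, analyte=spec.name)
            out.append(dataclasses.replace(res, n_cva_sources=n_sources))
    return out


# ---------------------------------------------------------------------------
# CSV dialects


def read_qc_csv(path: Union[str, Path]) -> list[QCSeries]:
    """Read QC values from CSV with header ``analyte,instrument,level,value``."""
    df = pd.read_csv(path)
    missing = [c for c in ("analyte", "instrument", "level", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"QC CSV missing columns: {missing}")
    series = []
    for (analyte, instrument, level), grp in df.groupby(
        ["analyte", "instrument", "level"], sort=True
    ):
        series.append(
            QCSeries(
                analyte=str(analyte),
                instrument=str(instrument),
                level=str(level),
                values=tuple(float(v) for v in grp["value"]),
            )
        )
    return series


def rcv_report_frame(results: Sequence[RCVResult]) -> pd.DataFrame:
    """Wide report: one row per analyte, one RCV column per coverage factor."""
    rows: dict[str, dict] = {}
    order: list[str] = []
    for r in results:
        if r.analyte not in rows:
            rows[r.analyte] = {
                "analyte": r.analyte,
                "cvi_percent": r.cvi_percent,
                "cva_percent": r.cva_percent,
            }
            order.append(r.analyte)
        rows[r.analyte][f"rcv_percent_k{r.k:g}"] = round(r.rcv_percent, 2)
    return pd.DataFrame([rows[a] for a in order])


def write_rcv_csv(results: Sequence[RCVResult], path: Union[str, Path]) -> None:
    rcv_report_frame(results).to_csv(path, index=False)
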