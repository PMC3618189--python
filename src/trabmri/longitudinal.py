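"""Per-subject longitudinal change and measurement-precision statistics.

Absolute change is follow-up − baseline per variable; percent change is
100 × absolute change / baseline. Changes are computed between the two
slice-averaged per-visit profiles (not per-slice changes averaged
afterwards; the order matters for ratio variables).

Precision over replicate measurements is summarized per variable by the
root-mean-square coefficient of variation,

    RMSCV% = 100 · sqrt( mean over subjects of (SD_i / mean_i)² ),

and by the one-way random-effects, single-measurement intraclass correlation
coefficient ICC(1,1) = (MSB − MSW) / (MSB + (k − 1)·MSW).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphometry import VARIABLES, MicroarchitectureProfile


class ChangeError(RuntimeError):
    pass


@dataclass(frozen=True)
class ChangeRecord:
    """Per-subject absolute and percent changes between two visits.

    ``percent[v]`` is ``None`` where the baseline value is zero (explicitly
    undefined, never silently dropped).
    """

    subject_id: str
    absolute: dict[str, float]
    percent: dict[str, float | None]
    months_between_visits: float | None = None


def absolute_change(baseline: MicroarchitectureProfile,
                    followup: MicroarchitectureProfile,
                    subject_id: str = "",
                    months_between_visits: float | None = None) -> ChangeRecord:
    """Elementwise follow-up − baseline over the nine outcome variables."""
    absolute = {}
    for v in VARIABLES:
        b, f = getattr(baseline, v, None), getattr(followup, v, None)
        if b is None or f is None or not (np.isfinite(b) and np.isfinite(f)):
            raise ChangeError(f"variable {v!r} missing or invalid in a profile")
        absolute[v] = float(f) - float(b)
    record = ChangeRecord(subject_id=subject_id, absolute=absolute, percent={},
                          months_between_visits=months_between_visits)
    return percent_change(record, baseline)


def percent_change(record: ChangeRecord,
                   baseline: MicroarchitectureProfile) -> ChangeRecord:
    """Fill the percent-change part: 100 × absolute / baseline per variable."""
    percent: dict[str, float | None] = {}
    for v, a in record.absolute.items():
        b = float(getattr(baseline, v))
        percent[v] = None if b == 0 else 100.0 * a / b
    return ChangeRecord(subject_id=record.subject_id, absolute=record.absolute,
                        percent=percent,
                        months_between_visits=record.months_between_visits)


def changes_frame(records) -> pd.DataFrame:
    """ChangeRecords → tidy frame (one row per subject, columns abs_*/pct_*)."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id,
               "months_between_visits": r.months_between_visits}
        row.update({f"abs_{v}": r.absolute[v] for v in VARIABLES})
        row.update({f"pct_{v}": r.percent[v] for v in VARIABLES})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PrecisionReport:
    """Per-variable short-term precision over replicate measurements."""

    table: pd.DataFrame         # columns: variable, rmscv_pct, icc, icc_negative

    def rmscv(self, variable: str) -> float:
        return float(self.table.set_index("variable").loc[variable, "rmscv_pct"])

    def icc(self, variable: str) -> float:
        return float(self.table.set_index("variable").loc[variable, "icc"])


def _icc_oneway(values: np.ndarray) -> float:
    """ICC(1,1) from a (subjects × replicates) array, one-way random effects."""
    n, k = values.shape
    subject_means = values.mean(axis=1)
    grand = values.mean()
    msb = k * ((subject_means - grand) ** 2).sum() / (n - 1)
    msw = ((values - subject_means[:, None]) ** 2).sum() / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return 1.0 if msb > 0 else np.nan
    return float((msb - msw) / denom)


def precision(replicates: pd.DataFrame,
              variables=VARIABLES) -> PrecisionReport:
    """Precision report from replicate profiles.

    ``replicates`` has one row per subject-replicate with a ``subject_id``
    column and one column per variable; every subject needs the same number
    (≥ 2) of replicates and there must be ≥ 2 subjects.
    """
    groups = replicates.groupby("subject_id")
    sizes = groups.size()
    if len(sizes) < 2:
        raise ChangeError("precision needs at least 2 subjects")
    if sizes.min() < 2 or sizes.nunique() != 1:
        raise ChangeError("every subject needs the same number (>=2) of replicates")

    rows = []
    for v in variables:
        wide = np.stack([g[v].to_numpy(dtype=float) for _, g in groups])
        means = wide.mean(axis=1)
        if np.any(means == 0):
            raise ChangeError(f"subject with zero mean for {v!r}: CV undefined")
        sds = wide.std(axis=1, ddof=1)
        rmscv = 100.0 * float(np.sqrt(np.mean((sds / means) ** 2)))
        icc = _icc_oneway(wide)
        rows.append({"variable": v, "rmscv_pct": rmscv, "icc": icc,
                     "icc_negative": bool(icc < 0)})
    return PrecisionReport(table=pd.DataFrame(rows))
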