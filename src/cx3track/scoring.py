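"""CX3CR1 score computation.

The CX3CR1 score of a patient at a follow-up week is the change of the
CX3CR1+ fraction of peripheral-blood CD8+ T cells relative to the
pretreatment (week-0) baseline.  The windowed score at ``window_weeks`` is
the maximum score over all on-treatment measurements taken no later than
that week; patients with no on-treatment measurement inside the window are
not evaluable for it.

By default "change" means a percentage-point difference (follow-up % minus
baseline %): fixed cutoffs of 10 and 20 points are applied across baselines
spanning roughly 4-85%, which only makes sense on the additive scale.  A
relative-change mode ((follow-up - baseline) / baseline x 100) is available
for sensitivity analysis via ``relative=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "BiomarkerSeries",
    "ScoreResult",
    "MissingMeasurementError",
    "cx3cr1_score",
    "max_score_by",
    "classify",
    "score_table",
    "read_biomarker_csv",
    "write_score_csv",
]


class MissingMeasurementError(KeyError):
    """Raised when a score is requested at a week with no measurement."""


@dataclass(frozen=True)
class BiomarkerSeries:
    """One patient's longitudinal CX3CR1+ %-of-CD8 measurements.

    Parameters
    ----------
    patient_id
        Patient identifier.
    measurements
        Sequence of ``(week, cx3cr1_pct)`` pairs.  Exactly one baseline
        (week 0) is required, weeks must be strictly increasing and values
        must lie in [0, 100].
    """

    patient_id: str
    measurements: tuple = field(default_factory=tuple)

    def __post_init__(self):
        meas = tuple((float(w), float(v)) for w, v in self.measurements)
        object.__setattr__(self, "measurements", meas)
        weeks = [w for w, _ in meas]
        if weeks.count(0.0) != 1:
            raise ValueError(
                f"patient {self.patient_id}: exactly one week-0 baseline required"
            )
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError(f"patient {self.patient_id}: weeks must strictly increase")
        if any(w < 0 for w in weeks):
            raise ValueError(f"patient {self.patient_id}: negative week")
        if any(not 0.0 <= v <= 100.0 for _, v in meas):
            raise ValueError(f"patient {self.patient_id}: values must be in [0, 100]")

    @property
    def baseline(self) -> float:
        return dict(self.measurements)[0.0]

    @property
    def weeks(self) -> tuple:
        return tuple(w for w, _ in self.measurements)

    def value_at(self, week: float) -> float:
        try:
            return dict(self.measurements)[float(week)]
        except KeyError:
            raise MissingMeasurementError(
                f"patient {self.patient_id}: no measurement at week {week}"
            ) from None


@dataclass(frozen=True)
class ScoreResult:
    """Windowed maximal CX3CR1 score for one patient."""

    patient_id: str
    window_weeks: float
    score: float | None
    evaluable: bool


def cx3cr1_score(series: BiomarkerSeries, week: float, relative: bool = False) -> float:
    """Score at one follow-up week: measurement minus baseline.

    Raises :class:`MissingMeasurementError` if the week was not measured —
    a missing draw is never treated as zero change.
    """
    value = series.value_at(week)
    base = series.baseline
    if relative:
        if base == 0:
            raise ZeroDivisionError(
                f"patient {series.patient_id}: relative change undefined at baseline 0"
            )
        return (value - base) / base * 100.0
    return value - base


def max_score_by(
    series: BiomarkerSeries, window_weeks: float, relative: bool = False
) -> ScoreResult:
    """Maximal score over on-treatment weeks in the window (0, window_weeks].

    Not evaluable (``score=None``) when no on-treatment measurement falls
    inside the window; this is what makes the evaluable n vary across
    windows in a cohort with missed draws.
    """
    if window_weeks <= 0:
        raise ValueError("window_weeks must be positive")
    in_window = [w for w in series.weeks if 0 < w <= window_weeks]
    if not in_window:
        return ScoreResult(series.patient_id, window_weeks, None, False)
    best = max(cx3cr1_score(series, w, relative=relative) for w in in_window)
    return ScoreResult(series.patient_id, window_weeks, best, True)


def classify(result: ScoreResult, theta: float = 10.0) -> str:
    """Dichotomize an evaluable score: ``"high"`` iff score >= theta."""
    if not result.evaluable:
        raise ValueError(
            f"patient {result.patient_id}: not evaluable at window {result.window_weeks}"
        )
    return "high" if result.score >= theta else "low"


def score_table(
    series_list: Iterable[BiomarkerSeries],
    windows: Sequence[float] = (3, 4, 6, 9),
    thetas: Sequence[float] = (10.0, 20.0),
    relative: bool = False,
) -> pd.DataFrame:
    """Long-format table of windowed scores and dichotomizations."""
    rows = []
    for s in series_list:
        for w in windows:
            r = max_score_by(s, w, relative=relative)
            row = {
                "patient_id": s.patient_id,
                "window": w,
                "score": r.score,
                "evaluable": r.evaluable,
            }
            for th in thetas:
                key = f"class_at_{th:g}"
                row[key] = classify(r, th) if r.evaluable else None
            rows.append(row)
    return pd.DataFrame(rows)


def read_biomarker_csv(path) -> list[BiomarkerSeries]:
    """Read a long-format biomarker CSV (patient_id, week, cx3cr1_pct)."""
    df = pd.read_csv(path)
    required = {"patient_id", "week", "cx3cr1_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"biomarker CSV missing columns: {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("week")
        out.append(
            BiomarkerSeries(str(pid), tuple(zip(grp["week"], grp["cx3cr1_pct"])))
        )
    return out


def write_score_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
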