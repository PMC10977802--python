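"""Clinical efficacy indices and cohort descriptive summaries.

Quantitative indices (all from three orthogonal MRI axis measurements):

* lesion volume ≈ 0.523 × length × width × height (prolate-ellipsoid rule;
  0.523 ≈ π/6 applied to full axis lengths);
* NPVR — nonperfused volume ratio, the unenhancing (ablated) volume divided
  by a reference lesion volume, in %;
* AVSR — volume shrinkage ratio, 100 × (1 − V_after / V_before), in %
  (negative if the lesion grew).

Qualitative index: the dysmenorrhea improvement index (DII), ordinal 1–5
(1 complete relief … 4 ineffective, 5 exacerbated); a score ≤ 3 counts as
clinically effective.

Summaries are reported as medians (quartiles 1–3) for continuous indices
and percentage (count/total) for effective DII, per group × timepoint with
complete-case denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "LesionMeasurement",
    "ParticipantRecord",
    "ellipsoid_volume",
    "avsr",
    "npvr",
    "dii_effective",
    "summarize_cohort",
    "records_to_frame",
    "frame_to_records",
    "round_display",
]

TIMEPOINTS = ("screening", "immediate", "1m", "3m", "1y", "3y")

ELLIPSOID_FACTOR = 0.523


def ellipsoid_volume(length_cm: float, width_cm: float, height_cm: float) -> float:
    """Lesion volume [cm³] from three orthogonal axis lengths [cm]."""
    if length_cm < 0 or width_cm < 0 or height_cm < 0:
        raise ValueError("axis lengths must be non-negative")
    return ELLIPSOID_FACTOR * length_cm * width_cm * height_cm


def avsr(v_before_cm3: float, v_after_cm3: float) -> float:
    """Volume shrinkage ratio, %: 100 × (1 − V_after/V_before).

    Negative when the lesion grew.
    """
    if v_before_cm3 <= 0:
        raise ValueError("baseline volume must be positive")
    if v_after_cm3 < 0:
        raise ValueError("follow-up volume must be non-negative")
    return 100.0 * (1.0 - v_after_cm3 / v_before_cm3)


def npvr(nonperfused_cm3: float, reference_cm3: float) -> float:
    """Nonperfused volume ratio, %: 100 × NPV / reference volume.

    The reference is the lesion volume; by definition the *original*
    (pre-treatment) volume, but callers may pass the same-timepoint volume
    instead (both conventions appear in practice — see the methods note).
    """
    if reference_cm3 <= 0:
        raise ValueError("reference volume must be positive")
    if nonperfused_cm3 < 0:
        raise ValueError("nonperfused volume must be non-negative")
    return 100.0 * nonperfused_cm3 / reference_cm3


def dii_effective(score: int) -> bool:
    """Clinically effective dysmenorrhea improvement: DII score ≤ 3."""
    if score not in (1, 2, 3, 4, 5):
        raise ValueError("DII score must be an integer in 1..5")
    return score <= 3


def round_display(x: float, decimals: int = 1) -> float:
    """Presentation rounding: round half away from zero (printed-table style)."""
    if not math.isfinite(x):
        return x
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass
class LesionMeasurement:
    """One MRI measurement: three orthogonal axes [cm], optional NPV [cm³]."""

    timepoint: str
    length_cm: float
    width_cm: float
    height_cm: float
    nonperfused_cm3: float | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if min(self.length_cm, self.width_cm, self.height_cm) < 0:
            raise ValueError("axis lengths must be non-negative")
        if self.nonperfused_cm3 is not None and self.nonperfused_cm3 < 0:
            raise ValueError("nonperfused volume must be non-negative")

    @property
    def volume_cm3(self) -> float:
        return ellipsoid_volume(self.length_cm, self.width_cm, self.height_cm)


@dataclass
class ParticipantRecord:
    """One participant: group, anesthesia, measurements and ordinal scores.

    ``measurements`` maps timepoint → LesionMeasurement, ``scores`` maps
    timepoint → dict with keys ``dii``, ``dysmenorrhea``, ``menorrhagia``
    (each 1–5).  Missing timepoints (dropout) are simply absent.
    """

    participant_id: str
    group: str
    anesthesia: str = "MAC"
    measurements: dict[str, LesionMeasurement] = field(default_factory=dict)
    scores: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("A", "B"):
            raise ValueError("group must be 'A' or 'B'")
        for tp, sc in self.scores.items():
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r}")
            for key, val in sc.items():
                if val is not None and val not in (1, 2, 3, 4, 5):
                    raise ValueError(f"{key} score {val!r} outside 1..5")

    def baseline_volume_cm3(self) -> float | None:
        m = self.measurements.get("screening")
        return m.volume_cm3 if m else None


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median and quartiles 1/3 with linear interpolation (type-7)."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def summarize_cohort(
    records: list[ParticipantRecord],
    npvr_reference: str = "original",
) -> dict[str, pd.DataFrame]:
    """Descriptive tables per group × timepoint.

    Returns ``{"continuous": df, "dii": df}``:

    * ``continuous`` — median/q1/q3/n per (measure, group, timepoint) for
      lesion volume, NPVR (reference per ``npvr_reference``: ``"original"``
      = screening volume, ``"same_timepoint"``) and AVSR vs screening;
    * ``dii`` — effective-DII percentage with ``count/total`` strings.

    Complete-case: a participant contributes to a cell only if the needed
    quantities exist at that timepoint; empty cells are flagged missing.
    """
    if not records:
        raise ValueError("empty cohort")
    if npvr_reference not in ("original", "same_timepoint"):
        raise ValueError("npvr_reference must be 'original' or 'same_timepoint'")

    cont_rows, dii_rows = [], []
    groups = sorted({r.group for r in records})
    for g in groups:
        grp = [r for r in records if r.group == g]
        for tp in TIMEPOINTS:
            cells: dict[str, list[float]] = {"volume_cm3": [], "npvr_pct": [], "avsr_pct": []}
            for r in grp:
                m = r.measurements.get(tp)
                if m is None:
                    continue
                cells["volume_cm3"].append(m.volume_cm3)
                if m.nonperfused_cm3 is not None:
                    v0 = r.baseline_volume_cm3()
                    ref = v0 if npvr_reference == "original" else m.volume_cm3
                    if ref and ref > 0:
                        cells["npvr_pct"].append(npvr(m.nonperfused_cm3, ref))
                if tp not in ("screening", "immediate"):
                    v0 = r.baseline_volume_cm3()
                    if v0 and v0 > 0:
                        cells["avsr_pct"].append(avsr(v0, m.volume_cm3))
            for measure, vals in cells.items():
                if vals:
                    med, q1, q3 = _quartiles(np.asarray(vals))
                    cont_rows.append(
                        dict(measure=measure, group=g, timepoint=tp,
                             median=med, q1=q1, q3=q3, n=len(vals), missing=False)
                    )
                else:
                    cont_rows.append(
                        dict(measure=measure, group=g, timepoint=tp,
                             median=np.nan, q1=np.nan, q3=np.nan, n=0, missing=True)
                    )
            dii_scores = [
                r.scores[tp]["dii"]
                for r in grp
                if tp in r.scores and r.scores[tp].get("dii") is not None
            ]
            if dii_scores:
                n_eff = sum(dii_effective(s) for s in dii_scores)
                n_tot = len(dii_scores)
                dii_rows.append(
                    dict(group=g, timepoint=tp,
                         effective_pct=round_display(100.0 * n_eff / n_tot),
                         counts=f"{n_eff}/{n_tot}", n=n_tot, missing=False)
                )
            else:
                dii_rows.append(
                    dict(group=g, timepoint=tp, effective_pct=np.nan,
                         counts="", n=0, missing=True)
                )
    return {"continuous": pd.DataFrame(cont_rows), "dii": pd.DataFrame(dii_rows)}


_CSV_COLUMNS = [
    "participant_id", "group", "anesthesia", "timepoint",
    "length_cm", "width_cm", "height_cm", "npv_cm3",
    "dii", "dysmenorrhea", "menorrhagia",
]


def records_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Long-format table: one row per participant × timepoint."""
    rows = []
    for r in records:
        tps = sorted(
            set(r.measurements) | set(r.scores), key=TIMEPOINTS.index
        )
        for tp in tps:
            m = r.measurements.get(tp)
            sc = r.scores.get(tp, {})
            rows.append(
                dict(
                    participant_id=r.participant_id, group=r.group,
                    anesthesia=r.anesthesia, timepoint=tp,
                    length_cm=m.length_cm if m else np.nan,
                    width_cm=m.width_cm if m else np.nan,
                    height_cm=m.height_cm if m else np.nan,
                    npv_cm3=(
                        m.nonperfused_cm3
                        if m and m.nonperfused_cm3 is not None
                        else np.nan
                    ),
                    dii=sc.get("dii", np.nan),
                    dysmenorrhea=sc.get("dysmenorrhea", np.nan),
                    menorrhagia=sc.get("menorrhagia", np.nan),
                )
            )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    """Inverse of :func:`records_to_frame`."""
    records = []
    for pid, sub in df.groupby("participant_id", sort=False):
        first = sub.iloc[0]
        rec = ParticipantRecord(
            participant_id=str(pid), group=str(first["group"]),
            anesthesia=str(first["anesthesia"]),
        )
        for _, row in sub.iterrows():
            tp = row["timepoint"]
            if not pd.isna(row["length_cm"]):
                rec.measurements[tp] = LesionMeasurement(
                    timepoint=tp,
                    length_cm=float(row["length_cm"]),
                    width_cm=float(row["width_cm"]),
                    height_cm=float(row["height_cm"]),
                    nonperfused_cm3=(
                        None if pd.isna(row["npv_cm3"]) else float(row["npv_cm3"])
                    ),
                )
            sc = {
                key: int(row[key])
                for key in ("dii", "dysmenorrhea", "menorrhagia")
                if not pd.isna(row[key])
            }
            if sc:
                rec.scores[tp] = sc
        records.append(rec)
    return records
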