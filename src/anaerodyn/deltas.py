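"""Regression dataset of per-day log changes in anaerobe density.

Each observation ("delta") is the natural-log change in absolute anaerobe
density between two adjacent samples of one patient, at most 2 days
apart and both within the first hospitalization, divided by the gap:

    y = (ln N(t_end) − ln N(t_start)) / Δt        [1/day]

Binary covariates mark whether each antibiotic covariate class, and each
transplant phase, was active during the interval [t_start, t_end]
(interval intersection).  Zero anaerobe densities are replaced by a
detection floor before logging so below-detection intervals — exactly
the regime of interest — are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import DensitySeries
from .io import (EMPIRICAL_LABELS, PROPHYLACTIC_LABELS, ExposureRecord,
                 PatientMeta)

#: Reference density used to scale the capacity regressor so its
#: coefficient is O(1) under the regularizing prior; the order of
#: magnitude of a healthy gut's 16S density (copies/g).
DEFAULT_N_REF = 1e11


@dataclass(frozen=True)
class DeltaObservation:
    """One regression row."""

    patient_id: str
    t_start: int
    t_end: int
    y: float  # per-day natural-log change, 1/day
    n_start_scaled: float  # N(t_start) / N_ref, dimensionless
    phase1: int
    phase2: int
    empirical: tuple[int, ...] = field(default=(0,) * 7)  # EMPIRICAL_LABELS order
    prophylactic: tuple[int, ...] = field(default=(0,) * 4)  # PROPHYLACTIC_LABELS order

    def __post_init__(self) -> None:
        if self.t_end - self.t_start not in (1, 2):
            raise ValueError("delta must span 1 or 2 days")
        flags = ((self.phase1, self.phase2) + self.empirical + self.prophylactic)
        if any(f not in (0, 1) for f in flags):
            raise ValueError("covariates must be binary")

    @property
    def delta_t(self) -> int:
        return self.t_end - self.t_start


def _intersects(a0: int, a1: int, b0: int, b1: int) -> bool:
    """Closed integer interval [a0,a1] meets closed [b0,b1]."""
    return a0 <= b1 and b0 <= a1


def _phase_flag(t0: int, t1: int, lo: int, hi: int) -> int:
    """Closed sample interval [t0,t1] meets half-open phase window [lo,hi)."""
    return int(t1 >= lo and t0 < hi)


def cohort_floor(series: dict[str, DensitySeries]) -> float:
    """Half the smallest nonzero anaerobe density observed in the cohort."""
    nonzero = [p[1] for ser in series.values() for p in ser.points if p[1] > 0]
    if not nonzero:
        raise ValueError("no nonzero anaerobe densities in cohort")
    return min(nonzero) / 2.0


def build_deltas(
    series: dict[str, DensitySeries],
    exposures: list[ExposureRecord],
    metas: list[PatientMeta],
    n_ref: float = DEFAULT_N_REF,
    floor: float | None = None,
) -> list[DeltaObservation]:
    """Build the regression rows for a cohort.

    Pairs are adjacent samples only (no all-pairs within the window),
    with gap ≤ 2 days and both endpoints inside
    [admit_day, discharge_day].  ``floor`` defaults to half the smallest
    nonzero anaerobe density in the cohort.
    """
    if n_ref <= 0:
        raise ValueError("n_ref must be positive")
    if floor is None:
        floor = cohort_floor(series)
    if floor <= 0:
        raise ValueError("floor must be positive")

    meta_by_id = {m.patient_id: m for m in metas}
    expo_by_pid: dict[str, list[ExposureRecord]] = {}
    for e in exposures:
        expo_by_pid.setdefault(e.patient_id, []).append(e)

    out: list[DeltaObservation] = []
    for pid, ser in series.items():
        meta = meta_by_id.get(pid)
        if meta is None:
            continue
        pts = ser.points
        if any(b[0] <= a[0] for a, b in zip(pts, pts[1:])):
            raise ValueError(f"non-monotone days for patient {pid}")
        for (d0, n0, _, _), (d1, n1, _, _) in zip(pts, pts[1:]):
            dt = d1 - d0
            if dt > 2:
                continue
            if d0 < meta.admit_day or d1 > meta.discharge_day:
                continue
            n0f = max(n0, floor)
            n1f = max(n1, floor)
            y = (np.log(n1f) - np.log(n0f)) / dt
            active = set()
            for e in expo_by_pid.get(pid, ()):
                if _intersects(d0, d1, e.start_day, e.end_day):
                    active.add(e.covariate)
            out.append(
                DeltaObservation(
                    patient_id=pid,
                    t_start=d0,
                    t_end=d1,
                    y=float(y),
                    n_start_scaled=n0f / n_ref,
                    phase1=_phase_flag(d0, d1, meta.conditioning_start_day, 0),
                    phase2=_phase_flag(d0, d1, 0, meta.engraftment_day),
                    empirical=tuple(int(lbl in active) for lbl in EMPIRICAL_LABELS),
                    prophylactic=tuple(
                        int(lbl in active) for lbl in PROPHYLACTIC_LABELS),
                )
            )
    return out


def deltas_frame(obs: list[DeltaObservation]) -> pd.DataFrame:
    """Tidy table with one column per covariate."""
    rows = []
    for o in obs:
        row = {
            "patient_id": o.patient_id, "t_start": o.t_start, "t_end": o.t_end,
            "delta_t": o.delta_t, "y": o.y, "n_start_scaled": o.n_start_scaled,
            "phase1": o.phase1, "phase2": o.phase2,
        }
        row.update(dict(zip(EMPIRICAL_LABELS, o.empirical)))
        row.update(dict(zip(PROPHYLACTIC_LABELS, o.prophylactic)))
        rows.append(row)
    cols = (["patient_id", "t_start", "t_end", "delta_t", "y",
             "n_start_scaled", "phase1", "phase2"]
            + list(EMPIRICAL_LABELS) + list(PROPHYLACTIC_LABELS))
    return pd.DataFrame(rows, columns=cols)


def deltas_from_frame(df: pd.DataFrame) -> list[DeltaObservation]:
    """Inverse of :func:`deltas_frame`."""
    out = []
    for _, r in df.iterrows():
        out.append(
            DeltaObservation(
                patient_id=str(r["patient_id"]), t_start=int(r["t_start"]),
                t_end=int(r["t_end"]), y=float(r["y"]),
                n_start_scaled=float(r["n_start_scaled"]),
                phase1=int(r["phase1"]), phase2=int(r["phase2"]),
                empirical=tuple(int(r[lbl]) for lbl in EMPIRICAL_LABELS),
                prophylactic=tuple(int(r[lbl]) for lbl in PROPHYLACTIC_LABELS),
            )
        )
    return out
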