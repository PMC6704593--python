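"""Compositional volatility between consecutive samples of one patient.

V(t + Δt/2) = (1 / 2Δt) Σ_i |x_i(t+Δt) − x_i(t)|

i.e. half the Manhattan (L1) distance between the two genus-level
compositions, divided by the gap in days.  V lies in [0, 1/Δt] ⊆ [0, 1]:
0 means no compositional change, 1 a complete replacement of the
community between two day-adjacent samples.  The 1/Δt scaling makes V an
average compositional turnover per day, so "consecutive" needs no upper
bound on the gap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import CommunitySample, TaxonLineage


@dataclass(frozen=True)
class VolatilityPoint:
    patient_id: str
    midpoint_time: float  # t + Δt/2
    delta_t: int
    V: float

    def __post_init__(self) -> None:
        if self.delta_t < 1:
            raise ValueError("delta_t must be >= 1 day")
        if not (-1e-12 <= self.V <= 1 + 1e-12):
            raise ValueError(f"V={self.V} outside [0, 1]")


def genus_composition(sample: CommunitySample) -> dict[str, float]:
    """Group a sample's composition at genus level.

    Taxa lacking a genus name are pooled under their lowest named rank
    prefixed ``unclassified-`` so no abundance mass is discarded.
    """
    out: dict[str, float] = {}
    for lin, frac in sample.abundances.items():
        key = lin.genus if lin.genus else f"unclassified-{lin.label()}"
        out[key] = out.get(key, 0.0) + frac
    return out


def volatility(x_t: dict[str, float], x_next: dict[str, float],
               delta_t: float) -> float:
    """Volatility between two compositions separated by ``delta_t`` days.

    Compositions are dicts over genus labels; a genus absent from one
    composition contributes its full abundance in the other.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    genera = set(x_t) | set(x_next)
    l1 = sum(abs(x_next.get(g, 0.0) - x_t.get(g, 0.0)) for g in genera)
    return l1 / (2.0 * delta_t)


def volatility_series(samples: list[CommunitySample]) -> list[VolatilityPoint]:
    """One point per consecutive sample pair of a single patient.

    Consecutive means adjacent in collection order; fewer than two
    samples yields an empty list.
    """
    pids = {s.patient_id for s in samples}
    if len(pids) > 1:
        raise ValueError(f"samples from more than one patient: {sorted(pids)}")
    ordered = sorted(samples, key=lambda s: s.day)
    points = []
    for a, b in zip(ordered, ordered[1:]):
        dt = b.day - a.day
        points.append(
            VolatilityPoint(
                patient_id=a.patient_id,
                midpoint_time=a.day + dt / 2.0,
                delta_t=dt,
                V=volatility(genus_composition(a), genus_composition(b), dt),
            )
        )
    return points
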