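"""Absolute densities, obligate-anaerobe classification and diversity.

Relative abundances from 16S sequencing are scaled by each sample's qPCR
total (16S copies per gram wet stool) to yield absolute densities.  The
copies-per-gram axis is used directly as the cell-density axis, without
16S copy-number correction; output headers say so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CommunitySample, TaxonLineage

#: Ranks defining the commensal obligate-anaerobe group: the classes
#: Clostridia and Negativicutes plus the phyla Bacteroidetes and
#: Fusobacteria, pooled into a single community density N.
ANAEROBE_CLASSES = frozenset({"Clostridia", "Negativicutes"})
ANAEROBE_PHYLA = frozenset({"Bacteroidetes", "Fusobacteria"})


@dataclass
class DensitySeries:
    """Per-patient time course of anaerobe density, total density, diversity."""

    patient_id: str
    points: list[tuple[int, float, float, float]]  # (day, N, total, diversity)

    def __post_init__(self) -> None:
        days = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        for day, n, total, _ in self.points:
            if not (0.0 <= n <= total * (1 + 1e-9)):
                raise ValueError(f"day {day}: anaerobe density {n} > total {total}")

    @property
    def days(self) -> list[int]:
        return [p[0] for p in self.points]


def is_obligate_anaerobe(lineage: TaxonLineage) -> bool:
    """True iff the taxon falls in the pooled commensal anaerobe group."""
    return lineage.class_ in ANAEROBE_CLASSES or lineage.phylum in ANAEROBE_PHYLA


def absolute_abundances(sample: CommunitySample) -> dict[TaxonLineage, float]:
    """Per-taxon density in copies/g; densities sum to ``qpcr_total``."""
    return {lin: frac * sample.qpcr_total
            for lin, frac in sample.abundances.items()}


def anaerobe_density(sample: CommunitySample) -> float:
    """Pooled obligate-anaerobe density N, copies/g."""
    frac = sum(f for lin, f in sample.abundances.items()
               if is_obligate_anaerobe(lin))
    return frac * sample.qpcr_total


def inverse_simpson(rel_abundances) -> float:
    """Inverse Simpson diversity 1 / sum(p_i^2), an effective taxon count."""
    p = np.asarray(list(rel_abundances), dtype=float)
    ss = float(np.sum(p**2))
    if ss == 0.0:
        raise ValueError("all-zero composition has undefined diversity")
    return 1.0 / ss


def density_series(samples: list[CommunitySample]) -> dict[str, DensitySeries]:
    """Assemble per-patient density series from a cohort's samples.

    Diversity is computed at the taxonomic grain of the input table.
    """
    by_patient: dict[str, list[CommunitySample]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, []).append(s)
    out = {}
    for pid, group in by_patient.items():
        group = sorted(group, key=lambda s: s.day)
        points = [
            (s.day, anaerobe_density(s), s.qpcr_total,
             inverse_simpson(s.abundances.values()))
            for s in group
        ]
        out[pid] = DensitySeries(patient_id=pid, points=points)
    return out


def density_frame(series: dict[str, DensitySeries]) -> pd.DataFrame:
    """Tidy table: patient_id, day, anaerobe_copies_per_g,
    total_copies_per_g (uncorrected 16S copies), inverse_simpson."""
    rows = [
        {"patient_id": pid, "day": day, "anaerobe_copies_per_g": n,
         "total_copies_per_g": total, "inverse_simpson": div}
        for pid, ser in series.items()
        for day, n, total, div in ser.points
    ]
    cols = ["patient_id", "day", "anaerobe_copies_per_g",
            "total_copies_per_g", "inverse_simpson"]
    return pd.DataFrame(rows, columns=cols)
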