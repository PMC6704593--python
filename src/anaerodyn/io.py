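"""Cohort table input/output and schema enforcement.

All four cohort tables are plain UTF-8 CSV/TSV with documented headers;
taxonomy is carried as a 7-rank semicolon-joined lineage string
(domain;phylum;class;order;family;genus;species). Study days are integers
relative to the day of hematopoietic cell infusion (day 0, negative =
pre-infusion); drug administration intervals are closed on both ends, in
whole days.

Tables
------
``cohort.taxa.tsv``   sample_id, patient_id, day, lineage, rel_abundance
``cohort.qpcr.csv``   sample_id, copies_per_g
``cohort.meds.csv``   patient_id, drug, route, start_day, end_day
``cohort.meta.csv``   patient_id, transplant_type, conditioning_start_day,
                      engraftment_day, admit_day, discharge_day
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class_", "order", "family", "genus", "species")

#: Relative-abundance rows whose fractions sum within this distance of 1
#: are renormalized; anything further off is rejected as a malformed sample.
ABUNDANCE_SUM_TOL = 0.05

ROUTES = ("iv", "po", "aerosolized")

#: The seven empirical (fever-triggered, unpooled) covariate labels.
EMPIRICAL_LABELS = (
    "piperacillin-tazobactam",
    "meropenem",
    "metronidazole",
    "cephalosporins-1-3",
    "vancomycin-po",
    "cefepime",
    "linezolid",
)

#: The four prophylactic covariate labels, partially pooled in the model.
PROPHYLACTIC_LABELS = (
    "fluoroquinolones",
    "vancomycin-iv",
    "trimethoprim-sulfamethoxazole",
    "atovaquone",
)

# drug name -> covariate label, either per-route or for any route.  The
# shipped table covers drugs named in the source cohort's practice
# (prophylactic ciprofloxacin, i.v. vancomycin for allo recipients, PJP
# prophylaxis, and the usual empirical broad-spectrum agents); it is
# user-extensible via ``register_drug``.
_DRUG_MAP: dict[tuple[str, str | None], str] = {
    ("piperacillin-tazobactam", None): "piperacillin-tazobactam",
    ("meropenem", None): "meropenem",
    ("metronidazole", None): "metronidazole",
    ("cefazolin", None): "cephalosporins-1-3",
    ("cephalexin", None): "cephalosporins-1-3",
    ("cefuroxime", None): "cephalosporins-1-3",
    ("ceftriaxone", None): "cephalosporins-1-3",
    ("ceftazidime", None): "cephalosporins-1-3",
    ("cefpodoxime", None): "cephalosporins-1-3",
    ("cefepime", None): "cefepime",
    ("linezolid", None): "linezolid",
    ("vancomycin", "po"): "vancomycin-po",
    ("vancomycin", "iv"): "vancomycin-iv",
    ("ciprofloxacin", None): "fluoroquinolones",
    ("levofloxacin", None): "fluoroquinolones",
    ("moxifloxacin", None): "fluoroquinolones",
    ("trimethoprim-sulfamethoxazole", None): "trimethoprim-sulfamethoxazole",
    ("atovaquone", None): "atovaquone",
}


class UnmappedDrugError(ValueError):
    """A medication record names a drug absent from the covariate map."""


@dataclass(frozen=True)
class TaxonLineage:
    """One taxon's rank-wise classification; lower ranks may be empty."""

    phylum: str
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""
    domain: str = "Bacteria"

    def __post_init__(self) -> None:
        if not self.phylum:
            raise ValueError("lineage must name a phylum")
        ranks = [self.class_, self.order, self.family, self.genus, self.species]
        seen_empty = False
        for r in ranks:
            if seen_empty and r:
                raise ValueError(
                    f"rank below a missing rank must also be missing: {self}"
                )
            seen_empty = seen_empty or not r

    def to_string(self) -> str:
        return ";".join(
            [self.domain, self.phylum, self.class_, self.order,
             self.family, self.genus, self.species]
        )

    @classmethod
    def from_string(cls, s: str) -> "TaxonLineage":
        parts = (s.split(";") + [""] * 7)[:7]
        return cls(domain=parts[0], phylum=parts[1], class_=parts[2],
                   order=parts[3], family=parts[4], genus=parts[5],
                   species=parts[6])

    def label(self) -> str:
        """Lowest named rank, for display."""
        for r in (self.species, self.genus, self.family, self.order,
                  self.class_, self.phylum):
            if r:
                return r
        return self.domain


@dataclass
class CommunitySample:
    """One stool sample: composition plus total 16S density from qPCR."""

    patient_id: str
    day: int
    abundances: dict[TaxonLineage, float]
    qpcr_total: float  # 16S copies per gram wet stool
    consistency: str | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.qpcr_total <= 0:
            raise ValueError("qpcr_total must be positive")
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"abundances sum to {total}, expected 1")


@dataclass(frozen=True)
class ExposureRecord:
    """One drug administration interval (closed, whole days)."""

    patient_id: str
    drug: str
    route: str
    start_day: int
    end_day: int
    covariate: str = field(default="", compare=False)
    category: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise ValueError("exposure start_day must be <= end_day")
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if not self.covariate:
            label, cat = abx_class_map(self.drug, self.route)
            object.__setattr__(self, "covariate", label)
            object.__setattr__(self, "category", cat)


@dataclass(frozen=True)
class PatientMeta:
    """Transplant timeline anchors for one patient."""

    patient_id: str
    transplant_type: str  # "auto" | "allo"
    conditioning_start_day: int
    engraftment_day: int
    admit_day: int
    discharge_day: int

    def __post_init__(self) -> None:
        if self.transplant_type not in ("auto", "allo"):
            raise ValueError(f"unknown transplant type {self.transplant_type!r}")
        if not (self.conditioning_start_day < 0 <= self.engraftment_day):
            raise ValueError("need conditioning_start_day < 0 <= engraftment_day")
        if not (self.admit_day <= self.conditioning_start_day <= self.discharge_day):
            raise ValueError("conditioning must fall within the hospitalization")


def abx_class_map(drug: str, route: str) -> tuple[str, str]:
    """Map a canonical drug name and route to its model covariate.

    Returns ``(covariate_label, category)`` where category is
    ``"empirical"`` or ``"prophylactic"``.  Vancomycin splits by route
    (oral = empirical anti-C. difficile use; intravenous = prophylaxis
    against viridans streptococci); every other shipped drug maps
    regardless of route.

    Raises
    ------
    UnmappedDrugError
        If the drug (or drug/route combination) is not in the map.
    """
    key = drug.strip().lower()
    label = _DRUG_MAP.get((key, route)) or _DRUG_MAP.get((key, None))
    if label is None:
        raise UnmappedDrugError(
            f"drug {drug!r} (route {route!r}) has no covariate mapping; "
            "register it with anaerodyn.io.register_drug"
        )
    category = "empirical" if label in EMPIRICAL_LABELS else "prophylactic"
    return label, category


def register_drug(drug: str, label: str, route: str | None = None) -> None:
    """Extend the drug→covariate map (label must be a shipped covariate)."""
    if label not in EMPIRICAL_LABELS + PROPHYLACTIC_LABELS:
        raise ValueError(f"unknown covariate label {label!r}")
    _DRUG_MAP[(drug.strip().lower(), route)] = label


def read_cohort(
    taxa_path: str | Path,
    qpcr_path: str | Path,
    meds_path: str | Path,
    meta_path: str | Path,
) -> tuple[list[CommunitySample], list[ExposureRecord], list[PatientMeta]]:
    """Load and join the four cohort tables.

    Sequenced samples lacking a qPCR measurement are dropped with a
    warning; compositions off unity by at most ``ABUNDANCE_SUM_TOL`` are
    renormalized; an unmappable drug raises :class:`UnmappedDrugError`;
    exposure intervals that do not intersect the patient's hospitalization
    are dropped with a warning.
    """
    taxa = pd.read_csv(taxa_path, sep="\t", dtype={"patient_id": str, "sample_id": str})
    qpcr = pd.read_csv(qpcr_path, dtype={"sample_id": str})
    meds = pd.read_csv(meds_path, dtype={"patient_id": str})
    meta = pd.read_csv(meta_path, dtype={"patient_id": str})

    metas = [
        PatientMeta(
            patient_id=row.patient_id,
            transplant_type=row.transplant_type,
            conditioning_start_day=int(row.conditioning_start_day),
            engraftment_day=int(row.engraftment_day),
            admit_day=int(row.admit_day),
            discharge_day=int(row.discharge_day),
        )
        for row in meta.itertuples()
    ]
    meta_by_id = {m.patient_id: m for m in metas}

    qpcr_by_sample = dict(zip(qpcr["sample_id"], qpcr["copies_per_g"]))
    samples: list[CommunitySample] = []
    for sid, grp in taxa.groupby("sample_id", sort=False):
        if sid not in qpcr_by_sample:
            logger.warning("sample %s has no qPCR measurement; dropped", sid)
            continue
        total = grp["rel_abundance"].sum()
        if abs(total - 1.0) > ABUNDANCE_SUM_TOL:
            raise ValueError(
                f"sample {sid}: abundances sum to {total:.4f}, "
                f"outside tolerance {ABUNDANCE_SUM_TOL}"
            )
        abund = {
            TaxonLineage.from_string(row.lineage): row.rel_abundance / total
            for row in grp.itertuples()
        }
        consistency = None
        if "consistency" in grp.columns:
            c = grp["consistency"].iloc[0]
            consistency = None if pd.isna(c) else str(c)
        samples.append(
            CommunitySample(
                patient_id=str(grp["patient_id"].iloc[0]),
                day=int(grp["day"].iloc[0]),
                abundances=abund,
                qpcr_total=float(qpcr_by_sample[sid]),
                consistency=consistency,
                sample_id=str(sid),
            )
        )

    exposures: list[ExposureRecord] = []
    for row in meds.itertuples():
        rec = ExposureRecord(
            patient_id=row.patient_id,
            drug=row.drug,
            route=row.route,
            start_day=int(row.start_day),
            end_day=int(row.end_day),
        )
        m = meta_by_id.get(rec.patient_id)
        if m is not None and (
            rec.end_day < m.admit_day or rec.start_day > m.discharge_day
        ):
            logger.warning(
                "exposure %s %s [%d, %d] outside hospitalization of %s; dropped",
                rec.drug, rec.route, rec.start_day, rec.end_day, rec.patient_id,
            )
            continue
        exposures.append(rec)

    return samples, exposures, metas


def write_cohort(
    samples: list[CommunitySample],
    exposures: list[ExposureRecord],
    metas: list[PatientMeta],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the four cohort tables; inverse of :func:`read_cohort`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxa": out / "cohort.taxa.tsv",
        "qpcr": out / "cohort.qpcr.csv",
        "meds": out / "cohort.meds.csv",
        "meta": out / "cohort.meta.csv",
    }

    taxa_rows = []
    qpcr_rows = []
    for s in samples:
        sid = s.sample_id or f"{s.patient_id}_d{s.day}"
        for lin, frac in s.abundances.items():
            taxa_rows.append(
                {"sample_id": sid, "patient_id": s.patient_id, "day": s.day,
                 "lineage": lin.to_string(), "rel_abundance": frac,
                 "consistency": s.consistency}
            )
        qpcr_rows.append({"sample_id": sid, "copies_per_g": s.qpcr_total})
    taxa_cols = ["sample_id", "patient_id", "day", "lineage",
                 "rel_abundance", "consistency"]
    pd.DataFrame(taxa_rows, columns=taxa_cols).to_csv(
        paths["taxa"], sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(qpcr_rows, columns=["sample_id", "copies_per_g"]).to_csv(
        paths["qpcr"], index=False, float_format="%.17g")

    meds_cols = ["patient_id", "drug", "route", "start_day", "end_day"]
    pd.DataFrame(
        [{k: getattr(e, k) for k in meds_cols} for e in exposures],
        columns=meds_cols,
    ).to_csv(paths["meds"], index=False)

    meta_cols = ["patient_id", "transplant_type", "conditioning_start_day",
                 "engraftment_day", "admit_day", "discharge_day"]
    pd.DataFrame(
        [{k: getattr(m, k) for k in meta_cols} for m in metas],
        columns=meta_cols,
    ).to_csv(paths["meta"], index=False)
    return paths
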