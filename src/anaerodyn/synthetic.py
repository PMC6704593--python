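"""Synthetic HCT cohorts with known ground truth.

Emulates the structure the analysis assumes: 18 patients (14 allogeneic)
hospitalized 20–38 days around infusion day 0, conditioning starting
7–10 days pre-infusion, engraftment 10–20 days post; prophylactic
ciprofloxacin from day −2 and i.v. vancomycin for allogeneic recipients;
a fever during post-infusion neutropenia triggering an empirical
broad-spectrum course (piperacillin-tazobactam, cefepime or meropenem,
5–10 days); near-daily sampling thinned by collection (0.77) and
amplification (0.87) success, leaving ~67% of inpatient days with a
usable sample.

Latent anaerobe density evolves daily by the growth model's own mean
law plus Normal(0, sigma_m) shocks in log space, so the fitted
likelihood matches the generative process and parameter recovery is
well-posed.  Non-anaerobe density follows an independent log-space
random walk.  Each sample's composition is a Dirichlet draw around the
latent anaerobe/other split across a fixed panel of ~25 taxa spanning
the anaerobe classes (Clostridia, Negativicutes), the anaerobe phyla
(Bacteroidetes, Fusobacteria) and common facultative groups; qPCR totals
carry multiplicative log-normal measurement noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .io import (EMPIRICAL_LABELS, PROPHYLACTIC_LABELS, CommunitySample,
                 ExposureRecord, PatientMeta, TaxonLineage)

_L = TaxonLineage

# fixed taxon panel: genus-level lineages covering every grouped clade
ANAEROBE_PANEL = (
    _L("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Blautia"),
    _L("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Faecalibacterium"),
    _L("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Roseburia"),
    _L("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcus"),
    _L("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium"),
    _L("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Anaerostipes"),
    _L("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Coprococcus"),
    _L("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Dorea"),
    _L("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),  # unclassified genus
    _L("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Veillonella"),
    _L("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Dialister"),
    _L("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
    _L("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Tannerellaceae", "Parabacteroides"),
    _L("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    _L("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae", "Alistipes"),
    _L("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium"),
)
OTHER_PANEL = (
    _L("Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae", "Enterococcus"),
    _L("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    _L("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    _L("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus"),
    _L("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia"),
    _L("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Klebsiella"),
    _L("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Enterobacter"),
    _L("Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium"),
    _L("Actinobacteria", "Actinomycetia", "Actinomycetales", "Actinomycetaceae", "Actinomyces"),
)


def _default_beta_a() -> dict[str, float]:
    b = {lbl: 0.0 for lbl in EMPIRICAL_LABELS}
    b["piperacillin-tazobactam"] = -1.5
    b["meropenem"] = -1.2
    b["cefepime"] = -0.8
    return b


def _default_o_dev() -> dict[str, float]:
    return dict(zip(PROPHYLACTIC_LABELS, (0.03, -0.05, 0.0, 0.02)))


@dataclass
class GeneratorConfig:
    """Cohort-level and generative-model parameters."""

    n_patients: int = 18
    n_allo: int = 14
    conditioning_days: tuple[int, int] = (7, 10)   # days before day 0
    engraftment_range: tuple[int, int] = (10, 20)
    hospitalization_range: tuple[int, int] = (20, 38)
    retention_p: float = 0.77       # a stool sample is collected
    amplification_p: float = 0.87   # the sample yields 16S amplicons
    fever_p: float = 0.9            # a phase-II fever triggers empirical abx
    fever_day_range: tuple[int, int] = (1, 6)  # deep-neutropenia fevers
    #                                  cluster in the first post-HCT week
    empirical_probs: dict[str, float] = field(default_factory=lambda: {
        "piperacillin-tazobactam": 0.45, "meropenem": 0.35, "cefepime": 0.2})
    course_length_range: tuple[int, int] = (5, 10)
    pjp_probs: tuple[float, float] = (0.3, 0.2)  # TMP-SMX, atovaquone
    # generative model parameters
    r: float = 0.05
    beta_p1: float = -0.05
    beta_p2: float = -0.3
    beta_a: dict[str, float] = field(default_factory=_default_beta_a)
    beta_o: float = -0.05
    o_dev: dict[str, float] = field(default_factory=_default_o_dev)
    patient_sd: float = 0.1
    beta_c: float = 0.0
    sigma_m: float = 0.5
    n_ref: float = 1e11
    # observation layer
    log10_n0_anaerobe: tuple[float, float] = (11.2, 0.2)  # mean, sd
    log10_n0_other: tuple[float, float] = (9.8, 0.3)
    other_rw_sd: float = 0.35        # ln-space daily sd of non-anaerobes
    other_abx_effect: float = -1.2   # per-day ln effect of empirical abx
    #                                  on the non-anaerobe community, so
    #                                  total density also crashes
    read_depth: int = 100_000        # 16S reads per sample; the composition
    #                                  is multinomial counts / depth, so
    #                                  fractions below ~1/depth censor to 0
    composition_conc: float | None = None  # optional Dirichlet overdispersion
    #                                  of the expected composition (None =
    #                                  multinomial sampling noise only)
    latent_floor: float = 1e2        # copies/g; residual anaerobe population
    #                                  (spores, dormant cells, re-seeding)
    #                                  below which the community does not fall
    latent_ceiling: float = 5e11     # copies/g; gut carrying capacity the
    #                                  random walk cannot exceed
    qpcr_noise_sd: float = 0.03      # log10-scale
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.retention_p, self.amplification_p, self.fever_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sigma_m < 0:
            raise ValueError("sigma_m must be >= 0")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")


@dataclass
class GroundTruth:
    """Generative parameters and latent daily densities."""

    params: dict[str, float]
    latent: pd.DataFrame  # patient_id, day, anaerobe, other


def _truth_params(cfg: GeneratorConfig,
                  intercepts: dict[str, float]) -> dict[str, float]:
    p = {"r": cfg.r, "phase1": cfg.beta_p1, "phase2": cfg.beta_p2,
         "prophylactic_pooled": cfg.beta_o, "capacity": cfg.beta_c,
         "sigma_m": cfg.sigma_m}
    for lbl in EMPIRICAL_LABELS:
        p[lbl] = cfg.beta_a.get(lbl, 0.0)
    for lbl in PROPHYLACTIC_LABELS:
        p[f"o_dev[{lbl}]"] = cfg.o_dev.get(lbl, 0.0)
    for pid, v in intercepts.items():
        p[f"patient[{pid}]"] = v
    return p


def generate_cohort(
    config: GeneratorConfig | None = None,
) -> tuple[list[CommunitySample], list[ExposureRecord],
           list[PatientMeta], GroundTruth]:
    """Generate one synthetic cohort with known ground truth."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    panel = ANAEROBE_PANEL + OTHER_PANEL
    n_an = len(ANAEROBE_PANEL)

    metas: list[PatientMeta] = []
    exposures: list[ExposureRecord] = []
    samples: list[CommunitySample] = []
    intercepts: dict[str, float] = {}
    latent_rows = []

    for i in range(cfg.n_patients):
        pid = f"p{i + 1:02d}"
        allo = i < cfg.n_allo
        cond_start = -int(rng.integers(cfg.conditioning_days[0],
                                       cfg.conditioning_days[1] + 1))
        engraft = int(rng.integers(cfg.engraftment_range[0],
                                   cfg.engraftment_range[1] + 1))
        admit = cond_start - 1
        hosp_len = int(rng.integers(cfg.hospitalization_range[0],
                                    cfg.hospitalization_range[1] + 1))
        discharge = max(admit + hosp_len - 1, engraft + 3)
        if discharge <= admit:
            raise ValueError("degenerate configuration: no inpatient days")
        meta = PatientMeta(patient_id=pid,
                           transplant_type="allo" if allo else "auto",
                           conditioning_start_day=cond_start,
                           engraftment_day=engraft,
                           admit_day=admit, discharge_day=discharge)
        metas.append(meta)

        pex = [ExposureRecord(pid, "ciprofloxacin", "po", -2, engraft)]
        if allo:
            pex.append(ExposureRecord(pid, "vancomycin", "iv",
                                      cond_start, engraft))
        u = rng.random()
        if u < cfg.pjp_probs[0]:
            pex.append(ExposureRecord(pid, "trimethoprim-sulfamethoxazole",
                                      "po", engraft + 1, discharge))
        elif u < cfg.pjp_probs[0] + cfg.pjp_probs[1]:
            pex.append(ExposureRecord(pid, "atovaquone", "po",
                                      engraft + 1, discharge))
        if rng.random() < cfg.fever_p and engraft >= 2:
            fever_day = int(rng.integers(cfg.fever_day_range[0],
                                         min(cfg.fever_day_range[1],
                                             engraft - 1) + 1))
            drugs = list(cfg.empirical_probs)
            probs = np.array([cfg.empirical_probs[d] for d in drugs])
            drug = drugs[rng.choice(len(drugs), p=probs / probs.sum())]
            length = int(rng.integers(cfg.course_length_range[0],
                                      cfg.course_length_range[1] + 1))
            pex.append(ExposureRecord(pid, drug, "iv", fever_day,
                                      min(fever_day + length - 1, discharge)))
        exposures.extend(pex)

        # latent daily dynamics
        pint = float(rng.normal(0, cfg.patient_sd))
        intercepts[pid] = pint
        log_n = float(np.log(10.0) * rng.normal(*cfg.log10_n0_anaerobe))
        log_other = float(np.log(10.0) * rng.normal(*cfg.log10_n0_other))
        days = list(range(admit, discharge + 1))
        n_by_day = {}
        other_by_day = {}
        for d in days:
            n_by_day[d] = np.exp(log_n)
            other_by_day[d] = np.exp(log_other)
            latent_rows.append({"patient_id": pid, "day": d,
                                "anaerobe": np.exp(log_n),
                                "other": np.exp(log_other)})
            if d == discharge:
                break
            mu = cfg.r + pint + cfg.beta_c * np.exp(log_n) / cfg.n_ref
            if d + 1 >= cond_start and d < 0:
                mu += cfg.beta_p1
            if d + 1 >= 0 and d < engraft:
                mu += cfg.beta_p2
            empirical_active = False
            for e in pex:
                if e.start_day <= d + 1 and e.end_day >= d:
                    if e.category == "empirical":
                        mu += cfg.beta_a.get(e.covariate, 0.0)
                        empirical_active = True
                    else:
                        mu += cfg.beta_o + cfg.o_dev.get(e.covariate, 0.0)
            log_n = log_n + mu + float(rng.normal(0, cfg.sigma_m))
            log_n = min(max(log_n, float(np.log(cfg.latent_floor))),
                        float(np.log(cfg.latent_ceiling)))
            drift = cfg.other_abx_effect if empirical_active else 0.0
            log_other += drift + float(rng.normal(0, cfg.other_rw_sd))

        # observation layer
        w_an = rng.dirichlet(np.full(n_an, 1.5))
        w_other = rng.dirichlet(np.full(len(OTHER_PANEL), 1.5))
        for d in days:
            if rng.random() >= cfg.retention_p * cfg.amplification_p:
                continue
            n, other = n_by_day[d], other_by_day[d]
            f_an = n / (n + other)
            target = np.concatenate([w_an * f_an, w_other * (1 - f_an)])
            if cfg.composition_conc is not None:
                target = rng.dirichlet(cfg.composition_conc * target + 1e-8)
                target = target / target.sum()
            counts = rng.multinomial(cfg.read_depth, target)
            comp = counts / counts.sum()
            qpcr = (n + other) * 10.0 ** float(
                rng.normal(0, cfg.qpcr_noise_sd))
            samples.append(CommunitySample(
                patient_id=pid, day=d,
                abundances=dict(zip(panel, comp)),
                qpcr_total=qpcr,
                sample_id=f"{pid}_d{d:+04d}",
            ))

    truth = GroundTruth(
        params=_truth_params(cfg, intercepts),
        latent=pd.DataFrame(latent_rows,
                            columns=["patient_id", "day", "anaerobe", "other"]))
    return samples, exposures, metas, truth


def write_fixtures(cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four cohort tables plus ground truth; round-trips via
    :func:`anaerodyn.io.read_cohort`."""
    samples, exposures, metas, truth = cohort
    out = Path(out_dir)
    paths = cio.write_cohort(samples, exposures, metas, out)
    paths["truth_params"] = out / "truth.json"
    with open(paths["truth_params"], "w") as fh:
        json.dump(truth.params, fh, indent=1, sort_keys=True)
    paths["truth_latent"] = out / "truth_latent.csv"
    truth.latent.to_csv(paths["truth_latent"], index=False,
                        float_format="%.17g")
    return paths
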