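"""End-to-end orchestration: simulate → densities → volatility → deltas →
fit → predict → report, with a reproducibility manifest.

A run is driven by a YAML config (see README for the schema).  Every
stage writes plain-text outputs into the run directory; figures are
optional and headless-safe.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as cio
from .abundance import density_frame, density_series
from .deltas import build_deltas, deltas_frame
from .io import EMPIRICAL_LABELS
from .model import HierarchicalGrowthModel, PosteriorDraws, summarize
from .predict import (compile_courses, forward_simulate_patient, loss_frame,
                      predict_course_loss)
from .synthetic import GeneratorConfig, generate_cohort, write_fixtures
from .volatility import volatility_series

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {"source": "synthetic"},  # or paths: taxa/qpcr/meds/meta
    "n_ref": 1e11,
    "sampler": {"chains": 3, "draws": 10_000, "warmup": 1000, "steps": 1000},
    "predict": {"n_resamples": 10_000, "n_draws": 100,
                "drugs": ["piperacillin-tazobactam", "meropenem"]},
    "figures": False,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run every stage; returns the output directory.

    Outputs: the cohort tables (for synthetic runs), density.csv,
    volatility.csv, deltas.csv, posterior.csv, summary.csv, loss.csv,
    forward_sim.csv, optional figures, manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    inputs: dict[str, str] = {}

    stage = "io"
    try:
        cohort_cfg = config.get("cohort", {})
        if cohort_cfg.get("source", "synthetic") == "synthetic":
            gen_kwargs = {k: v for k, v in cohort_cfg.items()
                          if k not in ("source",)}
            gen = GeneratorConfig(seed=seed, **gen_kwargs)
            cohort = generate_cohort(gen)
            paths = write_fixtures(cohort, out / "cohort")
            samples, exposures, metas, _truth = cohort
        else:
            paths = {k: Path(cohort_cfg[k])
                     for k in ("taxa", "qpcr", "meds", "meta")}
            samples, exposures, metas = cio.read_cohort(
                paths["taxa"], paths["qpcr"], paths["meds"], paths["meta"])
        inputs = {k: _sha256(Path(p)) for k, p in paths.items()}
    except KeyError as e:
        raise StageError(stage, e) from e
    except OSError as e:
        raise StageError(stage, e) from e

    try:
        stage = "densities"
        series = density_series(samples)
        dens = density_frame(series)
        dens.to_csv(out / "density.csv", index=False)

        stage = "volatility"
        by_pid: dict[str, list] = {}
        for s in samples:
            by_pid.setdefault(s.patient_id, []).append(s)
        vol_rows = [
            {"patient_id": p.patient_id, "midpoint_time": p.midpoint_time,
             "delta_t": p.delta_t, "V": p.V}
            for pid in sorted(by_pid)
            for p in volatility_series(by_pid[pid])
        ]
        vol = pd.DataFrame(vol_rows, columns=["patient_id", "midpoint_time",
                                              "delta_t", "V"])
        vol.to_csv(out / "volatility.csv", index=False)

        stage = "deltas"
        n_ref = float(config.get("n_ref", 1e11))
        obs = build_deltas(series, exposures, metas, n_ref=n_ref)
        deltas_frame(obs).to_csv(out / "deltas.csv", index=False)

        stage = "fit"
        scfg = config.get("sampler", {})
        est = HierarchicalGrowthModel(seed=seed, **scfg)
        est.fit(obs)
        posterior = est.posterior_
        posterior.to_frame().to_csv(out / "posterior.csv", index=False,
                                    float_format="%.10g")
        summary = summarize(posterior)
        summary.to_csv(out / "summary.csv", index=False)

        stage = "predict"
        pcfg = config.get("predict", {})
        rng = np.random.default_rng(seed + 1)
        courses = compile_courses(exposures, metas)
        losses = []
        for drug in pcfg.get("drugs", ["piperacillin-tazobactam"]):
            if any(c.drug == drug for c in courses):
                losses.append(predict_course_loss(
                    posterior, courses, drug,
                    n_resamples=int(pcfg.get("n_resamples", 10_000)),
                    rng=rng))
        loss_frame(losses).to_csv(out / "loss.csv", index=False)

        meta_by_id = {m.patient_id: m for m in metas}
        sims = []
        for pid, ser in series.items():
            if len(ser.points) < 2:
                continue
            df = forward_simulate_patient(
                posterior, ser, exposures, meta_by_id[pid],
                n_draws=int(pcfg.get("n_draws", 100)),
                n_ref=n_ref, rng=rng)
            df.insert(0, "patient_id", pid)
            sims.append(df)
        pd.concat(sims, ignore_index=True).to_csv(
            out / "forward_sim.csv", index=False)

        if config.get("figures", False):
            stage = "report"
            _render_figures(out, dens, vol, summary, losses)
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, e) from e

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "python": platform.python_version(),
        "inputs": inputs,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _render_figures(out: Path, dens: pd.DataFrame, vol: pd.DataFrame,
                    summary: pd.DataFrame, losses: list) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # cohort density and diversity over time
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for pid, grp in dens.groupby("patient_id"):
        axes[0].plot(grp["day"], grp["inverse_simpson"], alpha=0.4, lw=0.8)
        axes[1].semilogy(grp["day"], grp["total_copies_per_g"],
                         alpha=0.4, lw=0.8)
    axes[0].set(xlabel="day relative to infusion", ylabel="inverse Simpson")
    axes[1].set(xlabel="day relative to infusion",
                ylabel="16S copies / g (uncorrected)")
    fig.tight_layout()
    fig.savefig(out / "fig_density_diversity.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.scatter(vol["midpoint_time"], vol["V"], s=8, alpha=0.5)
    ax.set(xlabel="day relative to infusion", ylabel="volatility V",
           ylim=(-0.02, 1.02))
    fig.tight_layout()
    fig.savefig(out / "fig_volatility.png", dpi=120)
    plt.close(fig)

    # forest plot of effects
    keep = [r for _, r in summary.iterrows()
            if r["parameter"] in ("r", "phase1", "phase2", "capacity")
            or r["parameter"] in EMPIRICAL_LABELS
            or not any(ch in r["parameter"] for ch in "[]_")]
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(keep) + 1))
    for k, row in enumerate(keep):
        ax.plot([row["lo_2.5"], row["hi_97.5"]], [k, k], color="C0")
        ax.plot(row["mean"], k, "o", color="C0")
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(range(len(keep)))
    ax.set_yticklabels([r["parameter"] for r in keep])
    ax.set_xlabel("effect on per-day log growth rate")
    fig.tight_layout()
    fig.savefig(out / "fig_forest.png", dpi=120)
    plt.close(fig)

    if losses:
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for est in losses:
            ax.hist(np.log10(est.fold_changes), bins=50, alpha=0.6,
                    label=est.drug)
        ax.set(xlabel="log10 fold change over course", ylabel="resamples")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "fig_course_loss.png", dpi=120)
        plt.close(fig)
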