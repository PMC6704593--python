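"""Bayesian hierarchical growth model of antibiotic effects on anaerobes.

The per-day log change y of the pooled obligate-anaerobe density is
modeled as Gaussian around a linear predictor:

    y_j ~ Normal(mu_j, sigma_m)
    mu_j = r + beta_p1 * phase1_j + beta_p2 * phase2_j
         + sum_i beta_a[i] * A_ij                       (7 empirical drugs)
         + sum_g O_gj * (beta_o + o_dev[g])             (4 prophylactic groups)
         + patient_intercept[patient_j]
         + beta_c * N_start_scaled_j                    (capacity term)

Priors: wide Normal(0, 100^2) on the growth rate r, the phase effects and
the empirical antibiotic effects; regularizing Normal(0, 0.1) (variance
0.1) on the pooled prophylactic effect and the capacity coefficient.
Prophylactic deviations o_dev and patient intercepts are partially
pooled, implemented non-centered (dev = eta * tau, eta ~ N(0,1)) with
half-Normal(0.316) hyper-scales; the residual scale sigma_m gets a
half-Normal(1) prior.

The posterior is sampled with `emcee` (differential-evolution ensemble
moves, vectorized log-probability); "chains" are independent ensembles
and the retained draws are thinned from each ensemble's post-warmup
history.  Convergence is summarized by split-R-hat and bulk ESS via
`arviz`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .deltas import DeltaObservation, deltas_from_frame
from .io import EMPIRICAL_LABELS, PROPHYLACTIC_LABELS

logger = logging.getLogger(__name__)

SD_WIDE = 100.0           # prior sd for r, phases, empirical effects
SD_REG = float(np.sqrt(0.1))  # regularizing prior sd (variance 0.1)
SD_SIGMA = 1.0            # half-Normal scale for the residual sd

FIXED_LABELS = ("r", "phase1", "phase2") + EMPIRICAL_LABELS


@dataclass
class ModelSpec:
    """Prior scales; defaults follow the source model."""

    sd_wide: float = SD_WIDE
    sd_reg: float = SD_REG
    sd_sigma: float = SD_SIGMA

    def __post_init__(self) -> None:
        if min(self.sd_wide, self.sd_reg, self.sd_sigma) <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class Design:
    """Response and covariate arrays for one cohort."""

    y: np.ndarray                # (n,)
    x_fixed: np.ndarray          # (n, 10): intercept, phase1, phase2, 7 drugs
    o_mat: np.ndarray            # (n, 4): prophylactic group indicators
    n_scaled: np.ndarray         # (n,)
    patient_idx: np.ndarray      # (n,) integer codes
    patient_ids: tuple[str, ...]
    flagged: tuple[str, ...] = ()  # zero-variance covariates

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


@dataclass(frozen=True)
class EffectSummary:
    parameter: str
    mean: float
    lo: float  # 2.5% quantile
    hi: float  # 97.5% quantile

    def __post_init__(self) -> None:
        tol = 1e-9 * max(1.0, abs(self.mean))
        if not (self.lo - tol <= self.mean <= self.hi + tol):
            raise ValueError(f"inconsistent summary for {self.parameter}")


@dataclass
class PosteriorDraws:
    """Joint posterior samples with chain/draw indexing and diagnostics."""

    params: dict[str, np.ndarray]  # each (chains, draws)
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    patient_ids: tuple[str, ...] = ()

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def joint(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """n jointly indexed draws of every parameter."""
        total = self.n_chains * self.n_draws
        idx = rng.integers(0, total, size=n)
        return {k: v.reshape(-1)[idx] for k, v in self.params.items()}

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, draw, parameter, value."""
        rows = []
        for name, arr in self.params.items():
            c, d = arr.shape
            rows.append(pd.DataFrame({
                "chain": np.repeat(np.arange(c), d),
                "draw": np.tile(np.arange(d), c),
                "parameter": name,
                "value": arr.reshape(-1),
            }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorDraws":
        params = {}
        for name, grp in df.groupby("parameter", sort=False):
            c = int(grp["chain"].max()) + 1
            d = int(grp["draw"].max()) + 1
            arr = np.empty((c, d))
            arr[grp["chain"].to_numpy(), grp["draw"].to_numpy()] = (
                grp["value"].to_numpy())
            params[name] = arr
        pids = tuple(
            n[len("patient["):-1] for n in params if n.startswith("patient["))
        return cls(params=params, patient_ids=pids)


def build_design(deltas: list[DeltaObservation] | pd.DataFrame) -> Design:
    """Assemble the regression design from delta observations.

    Zero-variance covariate columns are kept but flagged (their
    posteriors simply return the prior).
    """
    if isinstance(deltas, pd.DataFrame):
        deltas = deltas_from_frame(deltas)
    n = len(deltas)
    y = np.array([o.y for o in deltas], dtype=float)
    x_fixed = np.ones((n, 10))
    o_mat = np.zeros((n, 4))
    n_scaled = np.array([o.n_start_scaled for o in deltas], dtype=float)
    for j, o in enumerate(deltas):
        x_fixed[j, 1] = o.phase1
        x_fixed[j, 2] = o.phase2
        x_fixed[j, 3:10] = o.empirical
        o_mat[j, :] = o.prophylactic
    patient_ids = tuple(sorted({o.patient_id for o in deltas}))
    code = {p: i for i, p in enumerate(patient_ids)}
    patient_idx = np.array([code[o.patient_id] for o in deltas], dtype=int)

    flagged = []
    for k, lbl in enumerate(FIXED_LABELS[1:], start=1):
        if n and x_fixed[:, k].var() == 0:
            flagged.append(lbl)
    for g, lbl in enumerate(PROPHYLACTIC_LABELS):
        if n and o_mat[:, g].var() == 0 and not o_mat[:, g].any():
            flagged.append(lbl)
    for lbl in flagged:
        logger.warning(
            "covariate %r has zero variance; its posterior returns the prior",
            lbl)
    return Design(y=y, x_fixed=x_fixed, o_mat=o_mat, n_scaled=n_scaled,
                  patient_idx=patient_idx, patient_ids=patient_ids,
                  flagged=tuple(flagged))


def log_likelihood(design: Design, params: dict) -> float:
    """Gaussian log-likelihood of the data at one parameter point.

    ``params`` holds: r, phase1, phase2, beta_a (7,), beta_o,
    o_dev (4,), patient_intercept (n_patients,), beta_c, sigma_m.
    """
    mu = _mean_model(design, params)
    sm = float(params["sigma_m"])
    resid = design.y - mu
    return float(-0.5 * np.sum(resid**2) / sm**2
                 - design.n_obs * np.log(sm)
                 - 0.5 * design.n_obs * np.log(2 * np.pi))


def _mean_model(design: Design, params: dict) -> np.ndarray:
    coefs = np.concatenate([
        [params["r"], params["phase1"], params["phase2"]],
        np.asarray(params["beta_a"], dtype=float),
    ])
    pint = np.asarray(params["patient_intercept"], dtype=float)
    return (design.x_fixed @ coefs
            + design.o_mat @ (params["beta_o"] + np.asarray(params["o_dev"]))
            + pint[design.patient_idx]
            + params["beta_c"] * design.n_scaled)


# ---------------------------------------------------------------------------
# parameter packing for the sampler:
#   [0:10]   r, phase1, phase2, beta_a[7]
#   [10]     beta_o
#   [11:15]  eta_o (non-centered prophylactic deviations)
#   [15]     log tau_o
#   [16:16+P]   eta_p (non-centered patient intercepts)
#   [16+P]   log tau_p
#   [17+P]   beta_c
#   [18+P]   log sigma_m
# ---------------------------------------------------------------------------

def _make_log_prob(design: Design, spec: ModelSpec):
    P = design.n_patients
    n = design.n_obs
    Xf, O = design.x_fixed, design.o_mat
    nscaled, y = design.n_scaled, design.y
    patmat = np.zeros((n, P))
    if n:
        patmat[np.arange(n), design.patient_idx] = 1.0
    logcols = np.array([15, 16 + P, 18 + P])
    sd_w, sd_r, sd_s = spec.sd_wide, spec.sd_reg, spec.sd_sigma

    def log_prob(th: np.ndarray) -> np.ndarray:
        th = np.atleast_2d(th)
        bad = (~np.all(np.isfinite(th), axis=1)
               | (np.abs(th).max(axis=1) > 1e6)
               | (np.abs(th[:, logcols]).max(axis=1) > 30.0))
        th = np.where(bad[:, None], 0.0, th)
        fixed = th[:, :10]
        bo = th[:, 10]
        eta_o = th[:, 11:15]
        ltau_o = th[:, 15]
        eta_p = th[:, 16:16 + P]
        ltau_p = th[:, 16 + P]
        bc = th[:, 17 + P]
        lsm = th[:, 18 + P]
        tau_o, tau_p, sm = np.exp(ltau_o), np.exp(ltau_p), np.exp(lsm)
        # half-Normal hyper-priors with log-scale Jacobian
        lp = (-0.5 * np.sum(fixed**2, axis=1) / sd_w**2
              - 0.5 * bo**2 / sd_r**2
              - 0.5 * np.sum(eta_o**2, axis=1)
              - 0.5 * np.sum(eta_p**2, axis=1)
              - 0.5 * bc**2 / sd_r**2
              - 0.5 * tau_o**2 / sd_r**2 + ltau_o
              - 0.5 * tau_p**2 / sd_r**2 + ltau_p
              - 0.5 * sm**2 / sd_s**2 + lsm)
        if n:
            odev = eta_o * tau_o[:, None]
            pint = eta_p * tau_p[:, None]
            mu = (fixed @ Xf.T + (bo[:, None] + odev) @ O.T
                  + pint @ patmat.T + bc[:, None] * nscaled[None, :])
            resid = y[None, :] - mu
            lp = lp - 0.5 * np.sum(resid**2, axis=1) / sm**2 - n * np.log(sm)
        lp[bad] = -np.inf
        return lp

    return log_prob


class HierarchicalGrowthModel(BaseEstimator):
    """Sklearn-style estimator for the hierarchical growth regression.

    Parameters
    ----------
    chains : int
        Number of independent sampler runs ("traces").
    draws : int
        Total retained posterior draws across all chains.
    warmup : int
        Discarded ensemble steps per chain.
    steps : int
        Retained ensemble steps per chain from which draws are thinned.
    walkers : int
        Ensemble size.
    seed : int or None
        Seed for initialization and proposals.
    spec : ModelSpec or None
        Prior scales; defaults follow the source model.

    Attributes (after ``fit``)
    --------------------------
    design_ : Design
    posterior_ : PosteriorDraws
    rhat_, ess_ : dict of convergence diagnostics
    acceptance_ : mean proposal acceptance per chain
    """

    def __init__(self, chains: int = 3, draws: int = 10_000,
                 warmup: int = 1000, steps: int = 1000, walkers: int = 96,
                 seed: int | None = None, spec: ModelSpec | None = None):
        self.chains = chains
        self.draws = draws
        self.warmup = warmup
        self.steps = steps
        self.walkers = walkers
        self.seed = seed
        self.spec = spec

    # -- internal ----------------------------------------------------------
    def _init_walkers(self, design: Design, spec: ModelSpec,
                      rng: np.random.Generator) -> np.ndarray:
        W, P = self.walkers, design.n_patients
        D = 19 + P
        th0 = np.empty((W, D))
        if design.n_obs == 0:
            # no data: start from the prior itself (already stationary)
            th0[:, :10] = rng.normal(0, spec.sd_wide, (W, 10))
            th0[:, 10] = rng.normal(0, spec.sd_reg, W)
            th0[:, 17 + P] = rng.normal(0, spec.sd_reg, W)
            th0[:, 18 + P] = np.log(np.abs(rng.normal(0, spec.sd_sigma, W))
                                    + 1e-3)
        else:
            # start near the ridge solution to shorten burn-in
            A = np.column_stack([design.x_fixed, design.o_mat,
                                 design.n_scaled])
            lam = 1e-3 * max(design.n_obs, 1)
            sol = np.linalg.solve(A.T @ A + lam * np.eye(A.shape[1]),
                                  A.T @ design.y)
            resid_sd = float(np.std(design.y - A @ sol)) or 1.0
            th0[:, :10] = sol[:10] + rng.normal(0, 0.3, (W, 10))
            # unexposed covariates keep their wide prior; start them there
            for k, lbl in enumerate(FIXED_LABELS):
                if lbl in design.flagged:
                    th0[:, k] = rng.normal(0, spec.sd_wide, W)
            th0[:, 10] = (np.clip(sol[10:14].mean(), -1, 1)
                          + rng.normal(0, 0.2, W))
            th0[:, 17 + P] = (np.clip(sol[14], -1, 1)
                              + rng.normal(0, 0.1, W))
            th0[:, 18 + P] = np.log(resid_sd) + rng.normal(0, 0.3, W)
        th0[:, 11:15] = rng.normal(0, 0.5, (W, 4))
        th0[:, 15] = np.log(np.abs(rng.normal(0, spec.sd_reg, W)) + 1e-3)
        th0[:, 16:16 + P] = rng.normal(0, 0.5, (W, P))
        th0[:, 16 + P] = np.log(np.abs(rng.normal(0, spec.sd_reg, W)) + 1e-3)
        return th0

    def _unpack(self, arr: np.ndarray, design: Design) -> dict[str, np.ndarray]:
        """(chains, draws, D) raw samples -> named natural-scale params."""
        P = design.n_patients
        out: dict[str, np.ndarray] = {}
        for k, lbl in enumerate(FIXED_LABELS):
            out[lbl] = arr[..., k]
        out["prophylactic_pooled"] = arr[..., 10]
        tau_o = np.exp(arr[..., 15])
        for g, lbl in enumerate(PROPHYLACTIC_LABELS):
            out[f"o_dev[{lbl}]"] = arr[..., 11 + g] * tau_o
        out["tau_prophylactic"] = tau_o
        tau_p = np.exp(arr[..., 16 + P])
        for i, pid in enumerate(design.patient_ids):
            out[f"patient[{pid}]"] = arr[..., 16 + i] * tau_p
        out["tau_patient"] = tau_p
        out["capacity"] = arr[..., 17 + P]
        out["sigma_m"] = np.exp(arr[..., 18 + P])
        return out

    # -- api ---------------------------------------------------------------
    def fit(self, X, y=None) -> "HierarchicalGrowthModel":
        """Sample the posterior.  X is a list of DeltaObservation or the
        deltas table (one column per covariate); y is ignored."""
        if self.chains < 1 or self.draws < self.chains or self.walkers < 40:
            raise ValueError("need chains >= 1, draws >= chains, walkers >= 40")
        spec = self.spec or ModelSpec()
        design = build_design(X)
        log_prob = _make_log_prob(design, spec)
        D = 19 + design.n_patients
        seed = 0 if self.seed is None else int(self.seed)
        per_chain = int(np.ceil(self.draws / self.chains))
        moves = [(emcee.moves.DEMove(), 0.8),
                 (emcee.moves.DESnookerMove(), 0.2)]

        raw = np.empty((self.chains, per_chain, D))
        acc = []
        for c in range(self.chains):
            rng = np.random.default_rng((seed, c))
            sampler = emcee.EnsembleSampler(
                self.walkers, D, log_prob, vectorize=True, moves=moves)
            sampler.random_state = np.random.RandomState(
                (seed * 1009 + c) % (2**31)).get_state()
            sampler.run_mcmc(self._init_walkers(design, spec, rng),
                             self.warmup + self.steps, progress=False)
            chain = sampler.get_chain(discard=self.warmup)  # (steps, W, D)
            flat = chain.reshape(-1, D)
            idx = np.linspace(0, flat.shape[0] - 1, per_chain).astype(int)
            raw[c] = flat[idx]
            acc.append(float(sampler.acceptance_fraction.mean()))

        params = self._unpack(raw, design)
        idata = az.from_dict({k: v for k, v in params.items()})
        summ = az.summary(idata, kind="diagnostics")
        rhat = dict(zip(summ.index, summ["r_hat"]))
        ess = dict(zip(summ.index, summ["ess_bulk"]))

        self.design_ = design
        self.posterior_ = PosteriorDraws(
            params=params, rhat=rhat, ess=ess,
            patient_ids=design.patient_ids)
        self.rhat_ = rhat
        self.ess_ = ess
        self.acceptance_ = acc
        bad_rhat = {k: v for k, v in rhat.items()
                    if v > 1.05 and not any(f in k for f in design.flagged)}
        if bad_rhat:
            logger.warning("R-hat above 1.05 for %s; consider more steps",
                           sorted(bad_rhat))
        return self

    def summarize(self) -> pd.DataFrame:
        """Posterior means and central 95% intervals (forest-plot data)."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "posterior_")
        return summarize(self.posterior_)


def fit(deltas, spec: ModelSpec | None = None, **sampler_cfg) -> PosteriorDraws:
    """Functional wrapper: fit the model and return the posterior draws."""
    est = HierarchicalGrowthModel(spec=spec, **sampler_cfg)
    est.fit(deltas)
    return est.posterior_


def summarize(posterior: PosteriorDraws) -> pd.DataFrame:
    """EffectSummary rows: mean and central 95% credibility interval.

    Each prophylactic drug is additionally reported as the pooled effect
    plus its deviation (the quantity plotted on the forest panel).
    """
    if posterior.n_chains * posterior.n_draws < 100:
        raise ValueError("need at least 100 total draws to summarize")
    rows = []

    def add(name: str, draws: np.ndarray) -> None:
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append(EffectSummary(name, float(draws.mean()),
                                  float(lo), float(hi)))

    for name in posterior.params:
        add(name, posterior.flat(name))
    pooled = posterior.flat("prophylactic_pooled")
    for lbl in PROPHYLACTIC_LABELS:
        add(lbl, pooled + posterior.flat(f"o_dev[{lbl}]"))
    return pd.DataFrame(
        [(s.parameter, s.mean, s.lo, s.hi) for s in rows],
        columns=["parameter", "mean", "lo_2.5", "hi_97.5"])
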