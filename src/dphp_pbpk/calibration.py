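"""Hierarchical Bayesian calibration against blood and urine biomonitoring data.

Observations from each volunteer — blood concentrations of parent and
monoester, and per-void urinary deposition rates of the two second-order
metabolites — are compared with model predictions through zero-truncated
normal likelihoods with stream-specific error standard deviations.  The
calibrated parameter vector splits into global parameters shared by all
volunteers (partition coefficients, metabolised fractions, half-lives,
binding, recirculation and urinary rates) and per-volunteer parameters
(uptake lags, permeabilities, dose fractions, physiology); the four error
standard deviations carry diffuse gamma(0.01, 0.01) priors.

Sampling is adaptive random-walk Metropolis within Gibbs blocks: one joint
proposal per block (global block; one block per volunteer; error-SD block),
with per-coordinate scales adapted toward a target acceptance rate during
burn-in only.  Per-volunteer model predictions are cached so that a block
update re-simulates only the volunteers it touches and the error-SD block
costs no simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import model
from .parameters import ExposureScenario, PriorSpec, build_subject_from_flat, default_priors

__all__ = [
    "SubjectData",
    "BMDataset",
    "CalibrationSpec",
    "PosteriorSample",
    "urine_rates",
    "truncnorm_loglik",
    "log_likelihood",
    "mcmc_calibrate",
    "posterior_summaries",
    "credible_band",
]

STREAMS = ("RUrine_OH", "RUrine_cx", "CBlood_DPHP", "CBlood_MPHP")


# ---------------------------------------------------------------------------
# Data containers and I/O


@dataclass
class SubjectData:
    """One volunteer's biomonitoring record."""

    subject: str
    BW: float  # kg
    dose: float  # mg/kg
    blood: pd.DataFrame  # columns: time_h, CBlood_DPHP, CBlood_MPHP (mg/L)
    urine: pd.DataFrame  # columns: time_h, volume_ml, conc_OH, conc_cx (mg/L)
    excluded: bool = False

    def __post_init__(self) -> None:
        for frame, label in ((self.blood, "blood"), (self.urine, "urine")):
            t = frame["time_h"].to_numpy()
            if len(t) and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
                raise ValueError(f"{label} times for {self.subject} must be non-negative and strictly increasing")
        if len(self.urine) and np.any(self.urine["volume_ml"].to_numpy() <= 0):
            raise ValueError(f"urine volumes for {self.subject} must be positive")


@dataclass
class BMDataset:
    subjects: list[SubjectData]

    def active(self) -> list[SubjectData]:
        return [s for s in self.subjects if not s.excluded]

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for s in self.subjects:
            rows.append({"subject": s.subject, "stream": "BW", "time_h": 0.0, "value": s.BW, "unit": "kg", "volume_ml": ""})
            rows.append({"subject": s.subject, "stream": "dose", "time_h": 0.0, "value": s.dose, "unit": "mg/kg", "volume_ml": ""})
            if s.excluded:
                rows.append({"subject": s.subject, "stream": "excluded", "time_h": 0.0, "value": 1.0, "unit": "", "volume_ml": ""})
            for _, rec in s.blood.iterrows():
                for stream, col in (("blood_DPHP", "CBlood_DPHP"), ("blood_MPHP", "CBlood_MPHP")):
                    rows.append({"subject": s.subject, "stream": stream, "time_h": rec["time_h"], "value": rec[col], "unit": "mg/L", "volume_ml": ""})
            for _, rec in s.urine.iterrows():
                for stream, col in (("urine_OH", "conc_OH"), ("urine_cx", "conc_cx")):
                    rows.append({"subject": s.subject, "stream": stream, "time_h": rec["time_h"], "value": rec[col], "unit": "mg/L", "volume_ml": rec["volume_ml"]})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BMDataset":
        df = pd.read_csv(path)
        subjects = []
        for sid, grp in df.groupby("subject", sort=True):
            meta = {s: grp[grp.stream == s]["value"].iloc[0] for s in ("BW", "dose")}
            excluded = "excluded" in set(grp.stream)
            bd = grp[grp.stream == "blood_DPHP"].sort_values("time_h")
            bm = grp[grp.stream == "blood_MPHP"].sort_values("time_h")
            blood = pd.DataFrame({
                "time_h": bd["time_h"].to_numpy(),
                "CBlood_DPHP": bd["value"].to_numpy(),
                "CBlood_MPHP": bm["value"].to_numpy(),
            })
            uo = grp[grp.stream == "urine_OH"].sort_values("time_h")
            uc = grp[grp.stream == "urine_cx"].sort_values("time_h")
            urine = pd.DataFrame({
                "time_h": uo["time_h"].to_numpy(),
                "volume_ml": uo["volume_ml"].astype(float).to_numpy(),
                "conc_OH": uo["value"].to_numpy(),
                "conc_cx": uc["value"].to_numpy(),
            })
            subjects.append(SubjectData(str(sid), float(meta["BW"]), float(meta["dose"]), blood, urine, excluded))
        return cls(subjects)


def urine_rates(subject: SubjectData) -> pd.DataFrame:
    """Per-void deposition rates (mg/h) from void concentration, volume and
    inter-void interval; the first interval starts at the dose time."""
    u = subject.urine
    if len(u) < 2:
        raise ValueError("need at least two voids to compute deposition rates")
    t = u["time_h"].to_numpy()
    dt = np.diff(np.concatenate([[0.0], t]))
    if np.any(dt <= 0):
        raise ValueError("void times must be strictly increasing")
    vol_L = u["volume_ml"].to_numpy() / 1000.0
    return pd.DataFrame({
        "time_h": t,
        "interval_h": dt,
        "RUrine_OH": u["conc_OH"].to_numpy() * vol_L / dt,
        "RUrine_cx": u["conc_cx"].to_numpy() * vol_L / dt,
    })


# ---------------------------------------------------------------------------
# Likelihood


def truncnorm_loglik(y: np.ndarray, mu: np.ndarray, sigma: float) -> float:
    """Sum of zero-truncated normal log-densities of y around mu."""
    if sigma <= 0:
        return -math.inf
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    z = (y - mu) / sigma
    # normaliser: P(Y > 0) = Phi(mu/sigma)
    log_norm = stats.norm.logcdf(mu / sigma)
    return float(np.sum(-0.5 * z**2 - math.log(sigma) - 0.5 * math.log(2 * math.pi) - log_norm))


@dataclass
class CalibrationSpec:
    """Which parameters are calibrated and at which level of the hierarchy."""

    theta_names: list[str]
    omega_names: list[str]
    priors: Mapping[str, PriorSpec] = field(default_factory=default_priors)
    sigma_prior_shape: float = 0.01
    sigma_prior_rate: float = 0.01
    t_end: float = 48.0
    engine: str = "rk4"
    dt: float = 0.005  # matches the synthetic generator's step

    def __post_init__(self) -> None:
        overlap = set(self.theta_names) & set(self.omega_names)
        if overlap:
            raise ValueError(f"parameters cannot be both global and subject-specific: {sorted(overlap)}")
        missing = [n for n in [*self.theta_names, *self.omega_names] if n not in self.priors]
        if missing:
            raise ValueError(f"no prior for: {missing}")


def _predict_subject(
    spec: CalibrationSpec, subject: SubjectData, flat: dict[str, float]
) -> dict[str, np.ndarray] | None:
    """Model predictions at the subject's observation times, or None on failure."""
    scen = ExposureScenario(dose=subject.dose, BW=subject.BW, t_end=spec.t_end, output_dt=0.25)
    tb = subject.blood["time_h"].to_numpy()
    tu = subject.urine["time_h"].to_numpy()
    grid = np.unique(np.concatenate([[0.0], tb, tu, [spec.t_end]]))
    try:
        p = build_subject_from_flat(flat, scen)
        res = model.simulate(p, scen, t_grid=grid, engine=spec.engine, dt=spec.dt)
    except Exception:
        return None
    cd = np.interp(tb, res.t, res.cblood_dphp)
    cm = np.interp(tb, res.t, res.cblood_mphp)
    # per-void mean deposition rate from the cumulative urinary outputs
    cum_oh = np.interp(np.concatenate([[0.0], tu]), res.t, res.state("OHUrine"))
    cum_cx = np.interp(np.concatenate([[0.0], tu]), res.t, res.state("CXUrine"))
    dt_voids = np.diff(np.concatenate([[0.0], tu]))
    return {
        "CBlood_DPHP": cd,
        "CBlood_MPHP": cm,
        "RUrine_OH": np.diff(cum_oh) / dt_voids,
        "RUrine_cx": np.diff(cum_cx) / dt_voids,
    }


def _subject_loglik(subject: SubjectData, preds: dict[str, np.ndarray], sigmas: dict[str, float]) -> float:
    rates = urine_rates(subject)
    ll = truncnorm_loglik(rates["RUrine_OH"].to_numpy(), preds["RUrine_OH"], sigmas["RUrine_OH"])
    ll += truncnorm_loglik(rates["RUrine_cx"].to_numpy(), preds["RUrine_cx"], sigmas["RUrine_cx"])
    ll += truncnorm_loglik(subject.blood["CBlood_DPHP"].to_numpy(), preds["CBlood_DPHP"], sigmas["CBlood_DPHP"])
    ll += truncnorm_loglik(subject.blood["CBlood_MPHP"].to_numpy(), preds["CBlood_MPHP"], sigmas["CBlood_MPHP"])
    return ll


def log_likelihood(
    spec: CalibrationSpec,
    ds: BMDataset,
    theta: Mapping[str, float],
    omegas: Sequence[Mapping[str, float]],
    sigmas: Mapping[str, float],
) -> float:
    """Joint log-likelihood over active subjects and all four streams."""
    total = 0.0
    for subject, omega in zip(ds.active(), omegas):
        preds = _predict_subject(spec, subject, {**theta, **omega})
        if preds is None:
            return -math.inf
        total += _subject_loglik(subject, preds, dict(sigmas))
    return total


# ---------------------------------------------------------------------------
# Sampler


@dataclass
class PosteriorSample:
    """Retained draws and chain metadata."""

    theta: pd.DataFrame  # columns = theta names
    omegas: list[pd.DataFrame]  # one frame per subject, columns = omega names
    sigmas: pd.DataFrame  # columns = stream names
    logpost: np.ndarray
    subjects: list[str]
    iterations: int
    thin: int
    seed: int
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.theta)

    def best_draw(self) -> tuple[dict[str, float], list[dict[str, float]]]:
        """Highest-posterior retained draw (used as the central curve)."""
        i = int(np.argmax(self.logpost))
        theta = self.theta.iloc[i].to_dict()
        omegas = [om.iloc[i].to_dict() for om in self.omegas]
        return theta, omegas


def _gamma_sd_logprior(sigma: float, shape: float, rate: float) -> float:
    if sigma <= 0:
        return -math.inf
    return (shape - 1.0) * math.log(sigma) - rate * sigma


def mcmc_calibrate(
    spec: CalibrationSpec,
    ds: BMDataset,
    iterations: int = 2000,
    thin: int = 2,
    seed: int = 0,
    burn_frac: float = 0.2,
    target_accept: float = 0.3,
    use_likelihood: bool = True,
    init_jitter: float = 0.0,
) -> PosteriorSample:
    """Adaptive Metropolis-within-Gibbs over (theta, {omega_j}, {sigma_k}).

    Burn-in is the first ``burn_frac`` of iterations; proposal scales adapt
    only there.  ``use_likelihood=False`` samples the prior (used to verify
    sampler invariance).  With ``iterations=0`` the initial state is
    returned unchanged.
    """
    rng = np.random.default_rng(seed)
    subjects = ds.active()
    n_sub = len(subjects)
    if use_likelihood and n_sub == 0:
        raise ValueError("dataset has no active subjects")

    th_names, om_names = spec.theta_names, spec.omega_names
    n_blocks = n_sub if use_likelihood else max(n_sub, 1)
    theta = {n: float(spec.priors[n].median()) for n in th_names}
    omegas = [{n: float(spec.priors[n].median()) for n in om_names} for _ in range(n_blocks)]
    if init_jitter > 0:
        for d in (theta, *omegas):
            for n in d:
                lo, hi = spec.priors[n].support
                d[n] = float(np.clip(d[n] + init_jitter * (hi - lo) * rng.standard_normal(), lo, hi))

    def data_sd(stream: str) -> float:
        vals = []
        for s in subjects:
            if stream.startswith("CBlood"):
                vals.append(s.blood[stream].to_numpy())
            else:
                vals.append(urine_rates(s)[stream].to_numpy())
        v = np.concatenate(vals) if vals else np.array([1.0])
        return float(max(np.std(v), 1e-4))

    sigmas = {k: (data_sd(k) if use_likelihood else 1.0) for k in STREAMS}

    # cached per-subject predictions and likelihood contributions
    preds: list[dict[str, np.ndarray] | None] = [None] * n_sub
    lls = np.zeros(n_sub)
    if use_likelihood:
        for j, s in enumerate(subjects):
            preds[j] = _predict_subject(spec, s, {**theta, **omegas[j]})
            if preds[j] is None:
                raise RuntimeError(f"initial simulation failed for subject {s.subject}")
            lls[j] = _subject_loglik(s, preds[j], sigmas)

    def prior_lp(values: Mapping[str, float]) -> float:
        return sum(spec.priors[n].logpdf(v) for n, v in values.items())

    scales = {
        "theta": np.array([0.1 * (spec.priors[n].support[1] - spec.priors[n].support[0]) for n in th_names]),
        "omega": np.array([0.1 * (spec.priors[n].support[1] - spec.priors[n].support[0]) for n in om_names]),
        "sigma": np.full(len(STREAMS), 0.2),
    }
    acc = {k: 0 for k in ("theta", "omega", "sigma")}
    tries = {k: 0 for k in ("theta", "omega", "sigma")}
    burn = int(burn_frac * iterations)
    adapt_window = 25
    window_acc = {k: [0, 0] for k in acc}

    # covariance-adapted block proposals: step = factor * L z, with L the
    # Cholesky factor of the scaled empirical covariance of the burn-in
    # history (refreshed during burn-in only) and factor tuned on the
    # windowed acceptance rate
    theta_chol = np.diag(scales["theta"]) if th_names else None
    theta_factor = 1.0
    omega_chols = [np.diag(scales["omega"]) for _ in range(n_blocks)] if om_names else []
    omega_factor = 1.0
    theta_hist: list[np.ndarray] = []
    omega_hists: list[list[np.ndarray]] = [[] for _ in range(n_blocks)]

    def _refresh_chol(history: list[np.ndarray], init_diag: np.ndarray) -> np.ndarray | None:
        if len(history) < 50:
            return None
        arr = np.asarray(history[-500:])
        d = arr.shape[1]
        cov = np.atleast_2d(np.cov(arr.T)) * (2.38**2 / d)
        cov += np.diag((1e-3 * init_diag) ** 2)  # regularisation floor
        try:
            return np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            return None

    kept_theta, kept_omegas, kept_sigmas, kept_lp = [], [[] for _ in range(n_blocks)], [], []

    def record(i: int) -> None:
        if i >= burn and (i - burn) % thin == 0:
            kept_theta.append(dict(theta))
            for j in range(n_blocks):
                kept_omegas[j].append(dict(omegas[j]))
            kept_sigmas.append(dict(sigmas))
            lp = prior_lp(theta) + sum(prior_lp(om) for om in omegas)
            if use_likelihood:
                lp += float(np.sum(lls)) + sum(
                    _gamma_sd_logprior(sigmas[k], spec.sigma_prior_shape, spec.sigma_prior_rate)
                    for k in STREAMS
                )
            kept_lp.append(lp)

    if iterations == 0:
        kept_theta.append(dict(theta))
        for j in range(n_blocks):
            kept_omegas[j].append(dict(omegas[j]))
        kept_sigmas.append(dict(sigmas))
        kept_lp.append(prior_lp(theta))

    for i in range(iterations):
        # ---- global block ----
        if th_names:
            tries["theta"] += 1
            window_acc["theta"][1] += 1
            step = theta_factor * theta_chol @ rng.standard_normal(len(th_names))
            prop = {n: theta[n] + step[a] for a, n in enumerate(th_names)}
            lp_prior_new, lp_prior_old = prior_lp(prop), prior_lp(theta)
            if math.isfinite(lp_prior_new):
                if use_likelihood:
                    new_preds = [
                        _predict_subject(spec, s, {**prop, **omegas[j]})
                        for j, s in enumerate(subjects)
                    ]
                    if any(p is None for p in new_preds):
                        new_lls = None
                    else:
                        new_lls = np.array(
                            [_subject_loglik(s, new_preds[j], sigmas) for j, s in enumerate(subjects)]
                        )
                else:
                    new_preds, new_lls = preds, lls
                if (not use_likelihood) or new_lls is not None:
                    delta = (lp_prior_new - lp_prior_old) + (
                        float(np.sum(new_lls) - np.sum(lls)) if use_likelihood else 0.0
                    )
                    if math.log(rng.uniform()) < delta:
                        theta = prop
                        if use_likelihood:
                            preds, lls = list(new_preds), new_lls
                        acc["theta"] += 1
                        window_acc["theta"][0] += 1

        # ---- per-subject blocks ----
        if om_names:
            for j in range(n_blocks):
                s = subjects[j] if use_likelihood else None
                tries["omega"] += 1
                window_acc["omega"][1] += 1
                cur = omegas[j]
                step = omega_factor * omega_chols[j] @ rng.standard_normal(len(om_names))
                prop = {n: cur[n] + step[a] for a, n in enumerate(om_names)}
                lp_new, lp_old = prior_lp(prop), prior_lp(cur)
                if not math.isfinite(lp_new):
                    continue
                if use_likelihood:
                    new_pred = _predict_subject(spec, s, {**theta, **prop})
                    if new_pred is None:
                        continue
                    new_ll = _subject_loglik(s, new_pred, sigmas)
                    delta = (lp_new - lp_old) + (new_ll - lls[j])
                else:
                    delta = lp_new - lp_old
                if math.log(rng.uniform()) < delta:
                    omegas[j] = prop
                    if use_likelihood:
                        preds[j], lls[j] = new_pred, new_ll
                    acc["omega"] += 1
                    window_acc["omega"][0] += 1

        # ---- error-SD block (no simulations) ----
        if use_likelihood:
            tries["sigma"] += 1
            window_acc["sigma"][1] += 1
            prop_s = {
                k: sigmas[k] * math.exp(scales["sigma"][a] * rng.standard_normal())
                for a, k in enumerate(STREAMS)
            }
            lp_new = sum(
                _gamma_sd_logprior(prop_s[k], spec.sigma_prior_shape, spec.sigma_prior_rate)
                + math.log(prop_s[k])  # Jacobian of the log-scale walk
                for k in STREAMS
            )
            lp_old = sum(
                _gamma_sd_logprior(sigmas[k], spec.sigma_prior_shape, spec.sigma_prior_rate)
                + math.log(sigmas[k])
                for k in STREAMS
            )
            new_lls = np.array([_subject_loglik(s, preds[j], prop_s) for j, s in enumerate(subjects)])
            delta = (lp_new - lp_old) + float(np.sum(new_lls) - np.sum(lls))
            if math.isfinite(delta) and math.log(rng.uniform()) < delta:
                sigmas, lls = prop_s, new_lls
                acc["sigma"] += 1
                window_acc["sigma"][0] += 1

        # ---- adaptation during burn-in ----
        if i < burn:
            if th_names:
                theta_hist.append(np.array([theta[n] for n in th_names]))
            if om_names:
                for j in range(n_blocks):
                    omega_hists[j].append(np.array([omegas[j][n] for n in om_names]))
            if (i + 1) % adapt_window == 0:
                for key, setter in (("theta", "t"), ("omega", "o"), ("sigma", "s")):
                    got, tried = window_acc[key]
                    if tried == 0:
                        continue
                    factor = math.exp(0.5 * (got / tried - target_accept))
                    if setter == "t":
                        theta_factor *= factor
                    elif setter == "o":
                        omega_factor *= factor
                    else:
                        scales["sigma"] = scales["sigma"] * factor
                    window_acc[key] = [0, 0]
                if th_names:
                    new = _refresh_chol(theta_hist, scales["theta"])
                    if new is not None:
                        theta_chol, theta_factor = new, max(theta_factor, 0.5)
                for j in range(n_blocks):
                    if om_names:
                        new = _refresh_chol(omega_hists[j], scales["omega"])
                        if new is not None:
                            omega_chols[j] = new
                if i + 1 >= 4 * adapt_window and all(
                    acc[k] == 0 for k in ("theta", "omega") if tries[k] > 0
                ):
                    raise RuntimeError(
                        "sampler accepted no moves during adaptation; check the model/data scales"
                    )
        record(i)

    def frame(records: list[dict[str, float]], cols: list[str]) -> pd.DataFrame:
        return pd.DataFrame(records, columns=cols) if records else pd.DataFrame(columns=cols)

    return PosteriorSample(
        theta=frame(kept_theta, th_names),
        omegas=[frame(kept_omegas[j], om_names) for j in range(len(kept_omegas))],
        sigmas=frame(kept_sigmas, list(STREAMS)),
        logpost=np.array(kept_lp),
        subjects=[s.subject for s in subjects],
        iterations=iterations,
        thin=thin,
        seed=seed,
        acceptance={k: (acc[k] / tries[k] if tries[k] else math.nan) for k in acc},
    )


# ---------------------------------------------------------------------------
# Posterior summaries


def posterior_summaries(ps: PosteriorSample, min_draws: int = 100) -> pd.DataFrame:
    """Posterior median and central 95% credible interval per parameter."""
    if ps.n_draws < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws, have {ps.n_draws}")
    rows = []

    def add(frame: pd.DataFrame, label: str) -> None:
        for col in frame.columns:
            q = np.percentile(frame[col].to_numpy(), [2.5, 50.0, 97.5])
            rows.append({"parameter": f"{label}{col}", "median": q[1], "ci_lo": q[0], "ci_hi": q[2]})

    add(ps.theta, "")
    for j, om in enumerate(ps.omegas):
        add(om, f"{ps.subjects[j]}:")
    add(ps.sigmas, "sigma:")
    return pd.DataFrame(rows)


def credible_band(
    ps: PosteriorSample,
    spec: CalibrationSpec,
    subject: SubjectData,
    subject_index: int,
    output: str,
    grid: np.ndarray,
    max_draws: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Pointwise 95% posterior band for one output of one subject.

    Simulates per retained draw (subsampled to ``max_draws``), orders the
    predictions at each time point, and reads off the 2.5th and 97.5th
    percentiles; the central curve is the highest-posterior draw.
    """
    if ps.n_draws == 0:
        raise ValueError("posterior sample is empty")
    n = min(max_draws, ps.n_draws)
    if n < 50:
        import warnings

        warnings.warn(f"credible band from only {n} draws")
    idx = np.linspace(0, ps.n_draws - 1, n).astype(int)
    scen = ExposureScenario(dose=subject.dose, BW=subject.BW, t_end=float(grid[-1]))
    curves = np.empty((n, len(grid)))
    for row, i in enumerate(idx):
        flat = {**ps.theta.iloc[i].to_dict(), **(ps.omegas[subject_index].iloc[i].to_dict() if ps.omegas else {})}
        p = build_subject_from_flat(flat, scen)
        res = model.simulate(p, scen, t_grid=grid, engine=spec.engine, dt=spec.dt)
        curves[row] = res.series(output)
    theta_best, omegas_best = ps.best_draw()
    flat = {**theta_best, **(omegas_best[subject_index] if omegas_best else {})}
    res = model.simulate(build_subject_from_flat(flat, scen), scen, t_grid=grid, engine=spec.engine, dt=spec.dt)
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    return pd.DataFrame({"time_h": grid, "lo": lo, "hi": hi, "central": res.series(output)})
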