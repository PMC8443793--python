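"""Synthetic six-volunteer biomonitoring datasets.

Emulates the single-oral-dose study design: six male volunteers (body
weights 74-108 kg, doses 0.639-0.783 mg/kg), blood sampled over 48 h and
irregular urine voids over 48 h, with zero-truncated normal measurement
noise around the model predictions — the same error structure the
calibration likelihood assumes.  Subject-level truth is drawn from the
parameter priors so that generate -> calibrate -> recover round trips are
testable without any external data.

The real study's sampling times are not public; the default schedules here
are package conventions: blood sampled densely through the absorption phase
(half-hourly to 4 h) then at 5, 6, 8, 12, 24, 36 and 48 h, and urine voids
every 2-4 h (uniform jitter), frequent enough to resolve recirculation
harmonics at roughly 8 h spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import model
from .calibration import BMDataset, SubjectData
from .parameters import (
    ExposureScenario,
    PriorSpec,
    STUDY_BODY_WEIGHTS,
    STUDY_DOSES,
    STUDY_VOLUNTEERS,
    build_subject_from_flat,
)

__all__ = ["StudyDesign", "generate_dataset", "perturb_truth", "DEFAULT_BLOOD_TIMES"]

DEFAULT_BLOOD_TIMES = tuple(
    [0.5 * k for k in range(1, 9)] + [5.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0]
)

#: error standard deviations at the calibrated study scale
#: (urinary rates in mg/h, blood concentrations in mg/L)
DEFAULT_SIGMAS = {
    "RUrine_OH": 0.01,
    "RUrine_cx": 0.0005,
    "CBlood_DPHP": 0.018,
    "CBlood_MPHP": 0.019,
}


@dataclass(frozen=True)
class StudyDesign:
    """Subjects, schedules and noise levels of a synthetic study."""

    subjects: tuple[str, ...] = STUDY_VOLUNTEERS
    body_weights: dict = field(default_factory=lambda: dict(STUDY_BODY_WEIGHTS))
    doses: dict = field(default_factory=lambda: dict(STUDY_DOSES))
    blood_times: tuple[float, ...] = DEFAULT_BLOOD_TIMES
    void_gap: tuple[float, float] = (2.0, 4.0)  # h, uniform inter-void interval
    void_volume: tuple[float, float] = (100.0, 350.0)  # mL, uniform
    horizon: float = 48.0
    sigmas: dict = field(default_factory=lambda: dict(DEFAULT_SIGMAS))

    def __post_init__(self) -> None:
        if max(self.blood_times) > self.horizon:
            raise ValueError("blood sampling schedule extends beyond the study horizon")
        if any(s <= 0 for s in self.sigmas.values()):
            raise ValueError("noise standard deviations must be positive")


def _truncnorm_rvs(mu: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated normal draws around mu (vectorised)."""
    a = (0.0 - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, random_state=rng)


def perturb_truth(
    base: dict[str, float],
    subject_priors: dict[str, PriorSpec],
    n_subjects: int,
    seed: int,
) -> tuple[list[dict[str, float]], pd.DataFrame]:
    """Per-subject true parameters: shared values from ``base`` plus
    subject-specific draws from ``subject_priors``.

    Returns the per-subject flat overrides and a tidy truth table.
    """
    rng = np.random.default_rng(seed)
    flats, rows = [], []
    for j in range(n_subjects):
        flat = dict(base)
        for name, prior in subject_priors.items():
            flat[name] = float(prior.sample(rng))
            rows.append({"subject_index": j, "parameter": name, "value": flat[name]})
        flats.append(flat)
    for name, value in base.items():
        rows.append({"subject_index": -1, "parameter": name, "value": value})
    return flats, pd.DataFrame(rows)


def generate_dataset(
    design: StudyDesign,
    truths: list[dict[str, float]] | dict[str, float] | None = None,
    seed: int = 0,
    engine: str = "rk4",
    sigma_scale: float = 1.0,
) -> BMDataset:
    """Simulate every subject and sample noisy observations.

    Blood concentrations are zero-truncated normal around the predicted
    values; urine voids get uniform-jittered times and volumes, with the
    void concentration chosen so that the observed deposition rate
    (concentration x volume / interval) is the noisy version of the model's
    mean deposition rate over that interval.  ``sigma_scale=0`` reproduces
    the model predictions exactly.
    """
    rng = np.random.default_rng(seed)
    if truths is None:
        truths = [{} for _ in design.subjects]
    if isinstance(truths, dict):
        truths = [dict(truths) for _ in design.subjects]
    if len(truths) != len(design.subjects):
        raise ValueError("one truth parameter set per subject is required")

    subjects = []
    for sid, flat in zip(design.subjects, truths):
        BW, dose = design.body_weights[sid], design.doses[sid]
        scen = ExposureScenario(dose=dose, BW=BW, t_end=design.horizon, output_dt=0.05)
        p = build_subject_from_flat(flat, scen)
        res = model.simulate(p, scen, engine=engine)

        tb = np.asarray(design.blood_times)
        mu_d = np.interp(tb, res.t, res.cblood_dphp)
        mu_m = np.interp(tb, res.t, res.cblood_mphp)
        if sigma_scale > 0:
            obs_d = _truncnorm_rvs(mu_d, sigma_scale * design.sigmas["CBlood_DPHP"], rng)
            obs_m = _truncnorm_rvs(mu_m, sigma_scale * design.sigmas["CBlood_MPHP"], rng)
        else:
            obs_d, obs_m = mu_d, mu_m
        blood = pd.DataFrame({"time_h": tb, "CBlood_DPHP": obs_d, "CBlood_MPHP": obs_m})

        # irregular voids
        times = []
        t = 0.0
        while True:
            t += rng.uniform(*design.void_gap)
            if t > design.horizon:
                break
            times.append(t)
        tu = np.array(times)
        vols = rng.uniform(*design.void_volume, size=len(tu))  # mL
        edges = np.concatenate([[0.0], tu])
        cum_oh = np.interp(edges, res.t, res.state("OHUrine"))
        cum_cx = np.interp(edges, res.t, res.state("CXUrine"))
        dt = np.diff(edges)
        mu_roh, mu_rcx = np.diff(cum_oh) / dt, np.diff(cum_cx) / dt
        if sigma_scale > 0:
            r_oh = _truncnorm_rvs(mu_roh, sigma_scale * design.sigmas["RUrine_OH"], rng)
            r_cx = _truncnorm_rvs(mu_rcx, sigma_scale * design.sigmas["RUrine_cx"], rng)
        else:
            r_oh, r_cx = mu_roh, mu_rcx
        urine = pd.DataFrame(
            {
                "time_h": tu,
                "volume_ml": vols,
                "conc_OH": r_oh * dt / (vols / 1000.0),
                "conc_cx": r_cx * dt / (vols / 1000.0),
            }
        )
        subjects.append(SubjectData(sid, BW, dose, blood, urine))
    return BMDataset(subjects)
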