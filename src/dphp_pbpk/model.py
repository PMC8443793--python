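"""Two-chemical PBPK core solved as a system of delay differential equations.

The parent diester (DPHP) is drunk over a short interval, empties from the
stomach into the gut lumen under a time-varying first-order coefficient, and
is absorbed along three competing routes: a hepatic-portal route (subject to
first-pass metabolism in gut wall and liver), a lymphatic route that bypasses
the liver and empties into venous blood after a lag, and an unabsorbed
fraction passing to the bowel.  The monoester (MPHP) is produced in gut wall
and liver, distributes through a mirrored compartment set (without lymph),
and is metabolised in the liver into second-order metabolites that are
eliminated into urine by first-order rates.  Both chemicals undergo
enterohepatic recirculation: first-order biliary uptake in the liver with a
transport delay before reappearing in the gut lumen, where reabsorption
competes with faecal elimination.

Every lagged transfer runs through an explicit transit pool whose inflow is
the instantaneous uptake flux and whose outflow is the same flux evaluated a
lag earlier, so mass is conserved exactly and the system reduces to a plain
ODE model when all lags are zero.  Integration is by the method of steps:
the horizon is split at propagated discontinuity points and capped at the
shortest positive lag, so lagged lookups always fall in already-integrated
segments, which are stored with dense interpolants.

States are masses in mg, time in hours, concentrations in mg/L.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from math import exp
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .constants import MW_CX_MPHP, MW_DPHP, MW_MPHP, MW_OH_MPHP
from .parameters import ExposureScenario, ModelParameters

__all__ = [
    "STATE_NAMES",
    "N_STATES",
    "derivatives",
    "simulate",
    "SimulationResult",
    "mass_balance",
    "SolverError",
]

STATE_NAMES = (
    # parent (DPHP)
    "ASt_hep",  # 0 stomach lumen, hepatic-route fraction
    "ASt_lym",  # 1 stomach lumen, lymphatic-route fraction
    "ASt_un",  # 2 stomach lumen, unabsorbed fraction
    "AGi_hep",  # 3 GI lumen, hepatic-route fraction
    "AGi_lym",  # 4 GI lumen, lymphatic-route fraction
    "AGi_un",  # 5 GI lumen, unabsorbed fraction
    "AGi_rec",  # 6 GI lumen, biliary-recirculated parent
    "ATrans_gut",  # 7 transit pool: lagged hepatic-route absorption
    "AGut",  # 8 gut tissue
    "ALiv",  # 9 liver
    "ASto",  # 10 stomach tissue
    "AFat",  # 11 adipose
    "ASpd",  # 12 slowly perfused
    "ARpd",  # 13 rapidly perfused
    "ABld",  # 14 blood (bound+free, equilibrium split)
    "ALymph",  # 15 lymph
    "ADuct",  # 16 transit pool: lymph -> venous blood
    "ABile",  # 17 bile transit, parent
    "ABowel",  # 18 cumulative faecal parent
    "AMet",  # 19 cumulative parent metabolised (counter)
    # monoester (MPHP)
    "MGi",  # 20 GI lumen (from bile)
    "MGut",  # 21 gut tissue
    "MLiv",  # 22 liver
    "MSto",  # 23 stomach tissue
    "MFat",  # 24 adipose
    "MSpd",  # 25 slowly perfused
    "MRpd",  # 26 rapidly perfused
    "MBld",  # 27 blood
    "MBile",  # 28 bile transit, monoester
    "MBowel",  # 29 cumulative faecal monoester
    "MMet",  # 30 cumulative monoester metabolised (counter)
    # second-order metabolites
    "OHPool",  # 31 OH-MPHP central pool
    "OHUrine",  # 32 cumulative urinary OH-MPHP
    "CXPool",  # 33 cx-MPHP central pool
    "CXUrine",  # 34 cumulative urinary cx-MPHP
    "OtherMet",  # 35 cumulative other metabolites (monoester-equivalent mg)
)
N_STATES = len(STATE_NAMES)
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}

_R_DM = MW_MPHP / MW_DPHP
_R_OH = MW_OH_MPHP / MW_MPHP
_R_CX = MW_CX_MPHP / MW_MPHP


class SolverError(RuntimeError):
    """Raised when the integrator fails or produces a structurally bad state."""


def derivatives(
    t: float,
    y: np.ndarray,
    history: Callable[[float], np.ndarray],
    p: ModelParameters,
) -> np.ndarray:
    """Right-hand side of the delay system.

    ``history(s)`` must return the full state vector at time ``s`` (zeros
    for s <= 0).  Lagged quantities looked up: GI-lumen hepatic pool at
    t - Gutlag, lymph at t - Lymphlag, and both livers at t - Bilelag.
    """
    k = p.kin
    dy = np.zeros(N_STATES)

    # oral input: zero-order over the drink duration, split across routes
    drink = p.dose_total / p.drink_duration if 0.0 <= t < p.drink_duration else 0.0
    fH, fL = k.FracDOSEHep, k.FracDOSELymph
    fU = 1.0 - fH - fL

    # gastric emptying relaxes from k_max toward k_min
    k_ge = k.k_min + (k.k_max - k.k_min) * exp(-t / k.tau_ge)

    # lagged lookups
    if k.Gutlag > 0.0:
        gi_hep_lag = history(t - k.Gutlag)[3]
    else:
        gi_hep_lag = y[3]
    if k.Lymphlag > 0.0:
        lymph_lag = history(t - k.Lymphlag)[15]
    else:
        lymph_lag = y[15]
    if k.Bilelag > 0.0:
        h_bile = history(t - k.Bilelag)
        liv_lag, mliv_lag = h_bile[9], h_bile[22]
    else:
        liv_lag, mliv_lag = y[9], y[22]

    # ---------------- parent ----------------
    pc = p.pc
    CfD = p.fu_D * y[14] / p.Vbld  # free blood concentration
    CvGu = y[8] / (p.Vgu * pc.PguD)
    CvLi = y[9] / (p.Vli * pc.PliD)
    CvSt = y[10] / (p.Vst * pc.PstD)
    CvFa = y[11] / (p.Vfa * pc.PfaD)
    CvSp = y[12] / (p.Vspd * pc.PspdD)
    CvRp = y[13] / (p.Vrpd * pc.PrpdD)

    dy[0] = fH * drink - (k_ge + k.BELLYPERM) * y[0]
    dy[1] = fL * drink - (k_ge + k.BELLYPERMLymph) * y[1]
    dy[2] = fU * drink - k_ge * y[2]
    dy[3] = k_ge * y[0] - k.GIPERM * y[3]
    dy[4] = k_ge * y[1] - k.GIPERMLymph * y[4]
    dy[5] = k_ge * y[2] - k.k1_DPHP_gut * y[5]
    dy[6] = k.k1_DPHP_liver * liv_lag - (k.GIPERM + k.k1_DPHP_gut) * y[6]
    dy[7] = k.GIPERM * y[3] - k.GIPERM * gi_hep_lag

    uptake_hep = k.GIPERM * gi_hep_lag + k.GIPERM * y[6]
    rmet_gut_D = p.clint_D_gut * CvGu
    rmet_liv_D = p.clint_D_liver * CvLi
    bile_out_D = k.k1_DPHP_liver * y[9]

    dy[8] = p.Qgu * (CfD - CvGu) + uptake_hep - rmet_gut_D
    dy[9] = (
        p.Qli * CfD
        + p.Qgu * CvGu
        + p.Qst * CvSt
        + k.BELLYPERM * y[0]
        - (p.Qli + p.Qgu + p.Qst) * CvLi
        - rmet_liv_D
        - bile_out_D
    )
    dy[10] = p.Qst * (CfD - CvSt)
    dy[11] = p.Qfa * (CfD - CvFa)
    dy[12] = p.Qspd * (CfD - CvSp)
    dy[13] = p.Qrpd * (CfD - CvRp)
    dy[14] = (
        p.Qfa * CvFa
        + p.Qspd * CvSp
        + p.Qrpd * CvRp
        + (p.Qli + p.Qgu + p.Qst) * CvLi
        - p.QC * CfD
        + k.K1Lymph * lymph_lag
    )
    dy[15] = k.BELLYPERMLymph * y[1] + k.GIPERMLymph * y[4] - k.K1Lymph * y[15]
    dy[16] = k.K1Lymph * y[15] - k.K1Lymph * lymph_lag
    dy[17] = bile_out_D - k.k1_DPHP_liver * liv_lag
    dy[18] = k.k1_DPHP_gut * (y[5] + y[6])
    dy[19] = rmet_gut_D + rmet_liv_D

    # ---------------- monoester ----------------
    CfM = p.fu_M * y[27] / p.Vbld
    CvGuM = y[21] / (p.Vgu * pc.PguM)
    CvLiM = y[22] / (p.Vli * pc.PliM)
    CvStM = y[23] / (p.Vst * pc.PstM)
    CvFaM = y[24] / (p.Vfa * pc.PfaM)
    CvSpM = y[25] / (p.Vspd * pc.PspdM)
    CvRpM = y[26] / (p.Vrpd * pc.PrpdM)

    rmet_M = p.clint_M_liver * CvLiM
    bile_out_M = k.k1_MPHP_liver * y[22]

    # optionally divert gut-wall-formed monoester straight to blood (where
    # binding applies) instead of exposing it to first-pass metabolism
    gut_to_blood = k.gut_mphp_to_blood * _R_DM * rmet_gut_D
    dy[20] = k.k1_MPHP_liver * mliv_lag - (k.k_Ga + k.k1_MPHP_gut) * y[20]
    dy[21] = p.Qgu * (CfM - CvGuM) + k.k_Ga * y[20] + _R_DM * rmet_gut_D - gut_to_blood
    dy[22] = (
        p.Qli * CfM
        + p.Qgu * CvGuM
        + p.Qst * CvStM
        + _R_DM * rmet_liv_D
        - (p.Qli + p.Qgu + p.Qst) * CvLiM
        - rmet_M
        - bile_out_M
    )
    dy[23] = p.Qst * (CfM - CvStM)
    dy[24] = p.Qfa * (CfM - CvFaM)
    dy[25] = p.Qspd * (CfM - CvSpM)
    dy[26] = p.Qrpd * (CfM - CvRpM)
    dy[27] = (
        p.Qfa * CvFaM
        + p.Qspd * CvSpM
        + p.Qrpd * CvRpM
        + (p.Qli + p.Qgu + p.Qst) * CvLiM
        - p.QC * CfM
        + gut_to_blood
    )
    dy[28] = bile_out_M - k.k1_MPHP_liver * mliv_lag
    dy[29] = k.k1_MPHP_gut * y[20]
    dy[30] = rmet_M

    # ---------------- second-order metabolites ----------------
    dy[31] = k.FracMetabOH * rmet_M * _R_OH - k.K1_MOH * y[31]
    dy[32] = k.K1_MOH * y[31]
    dy[33] = k.FracMetabcx * rmet_M * _R_CX - k.K1_cx * y[33]
    dy[34] = k.K1_cx * y[33]
    dy[35] = (1.0 - k.FracMetabOH - k.FracMetabcx) * rmet_M
    return dy


# ---------------------------------------------------------------------------
# Method-of-steps integration


def _breakpoints(p: ModelParameters, t_end: float) -> np.ndarray:
    """Discontinuity-propagation points plus a cap at the shortest lag."""
    k = p.kin
    lags = [l for l in (k.Gutlag, k.Lymphlag, k.Bilelag) if l > 0.0]
    pts = {0.0, min(p.drink_duration, t_end), t_end}
    seeds = [0.0, p.drink_duration]
    for _ in range(2):  # propagate discontinuities through two delay generations
        new = []
        for s in seeds:
            for l in lags:
                q = s + l
                if q < t_end:
                    new.append(q)
        pts.update(new)
        seeds = new
    pts = sorted(pts)
    if lags:
        # cap segment length so lagged lookups never reach into the live segment
        cap = min(lags)
        out = [pts[0]]
        for q in pts[1:]:
            while q - out[-1] > cap * (1 + 1e-9):
                out.append(out[-1] + cap)
            out.append(q)
        pts = out
    arr = np.array(sorted(set(round(q, 12) for q in pts)))
    return arr[arr <= t_end]


@dataclass
class _History:
    """Piecewise dense solution over already-integrated segments."""

    ends: list = field(default_factory=list)
    sols: list = field(default_factory=list)
    n: int = N_STATES

    def __call__(self, t: float) -> np.ndarray:
        if t <= 0.0 or not self.sols:
            return np.zeros(self.n)
        i = bisect_left(self.ends, t)
        if i >= len(self.sols):
            i = len(self.sols) - 1
        return self.sols[i](t)


@dataclass
class SimulationResult:
    """Trajectories on the output grid plus derived series.

    Blood concentrations are total (bound + free) in mg/L; urinary series
    are instantaneous deposition rates in mg/h.
    """

    t: np.ndarray  # h
    states: np.ndarray  # (n_t, N_STATES), mg
    params: ModelParameters

    def state(self, name: str) -> np.ndarray:
        return self.states[:, _IDX[name]]

    @property
    def cblood_dphp(self) -> np.ndarray:
        return self.state("ABld") / self.params.Vbld

    @property
    def cblood_mphp(self) -> np.ndarray:
        return self.state("MBld") / self.params.Vbld

    @property
    def rurine_oh(self) -> np.ndarray:
        return self.params.kin.K1_MOH * self.state("OHPool")

    @property
    def rurine_cx(self) -> np.ndarray:
        return self.params.kin.K1_cx * self.state("CXPool")

    @property
    def plasma_bound_dphp(self) -> np.ndarray:
        """Mass of parent bound to plasma proteins (mg)."""
        return (1.0 - self.params.fu_D) * self.state("ABld")

    @property
    def plasma_bound_mphp(self) -> np.ndarray:
        return (1.0 - self.params.fu_M) * self.state("MBld")

    @property
    def lymph_mass(self) -> np.ndarray:
        return self.state("ALymph")

    @property
    def bowel_mass(self) -> np.ndarray:
        return self.state("ABowel")

    def series(self, name: str) -> np.ndarray:
        """Derived output by registry name."""
        mapping = {
            "CBlood_DPHP": self.cblood_dphp,
            "CBlood_MPHP": self.cblood_mphp,
            "RUrine_OH": self.rurine_oh,
            "RUrine_cx": self.rurine_cx,
            "MPlasma_DPHP": self.plasma_bound_dphp,
            "MPlasma_MPHP": self.plasma_bound_mphp,
            "MLymph_DPHP": self.lymph_mass,
            "MBowel_DPHP": self.bowel_mass,
        }
        return mapping[name]

    @property
    def mass_balance_residual(self) -> np.ndarray:
        return mass_balance(self)

    def to_frame(self):
        """Tidy (time, variable, value) frame of the eight monitored outputs."""
        import pandas as pd

        frames = []
        units = {
            "CBlood_DPHP": "mg/L",
            "CBlood_MPHP": "mg/L",
            "RUrine_OH": "mg/h",
            "RUrine_cx": "mg/h",
            "MPlasma_DPHP": "mg",
            "MPlasma_MPHP": "mg",
            "MLymph_DPHP": "mg",
            "MBowel_DPHP": "mg",
        }
        for name, unit in units.items():
            frames.append(
                pd.DataFrame(
                    {"time_h": self.t, "variable": name, "value": self.series(name), "unit": unit}
                )
            )
        return pd.concat(frames, ignore_index=True)


def simulate(
    p: ModelParameters,
    scen: ExposureScenario | None = None,
    *,
    t_grid: np.ndarray | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-10,
    method: str = "LSODA",
    engine: str = "adaptive",
    dt: float = 0.005,
) -> SimulationResult:
    """Integrate the delay system and return trajectories on an output grid.

    ``t_grid`` overrides the scenario's uniform grid (it must start at or
    after 0 and end at or before the scenario horizon).  ``engine`` selects
    the adaptive method-of-steps reference integrator or the compiled
    fixed-step scheme (``"rk4"``, see :mod:`.fast`) used by the
    simulation-hungry batch stages; ``dt`` applies to the latter.
    """
    scen = scen or ExposureScenario()
    grid = np.asarray(t_grid, dtype=float) if t_grid is not None else scen.grid()
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("output grid must be strictly increasing with >= 2 points")
    t_end = float(grid[-1])

    if engine == "rk4":
        from .fast import integrate_rk4

        _, out = integrate_rk4(p, t_end, dt=dt, grid=grid)
        return SimulationResult(t=grid, states=out, params=p)
    if engine != "adaptive":
        raise ValueError(f"unknown engine {engine!r}")

    history = _History()
    rhs = lambda t, y: derivatives(t, y, history, p)

    pts = _breakpoints(p, t_end)
    if pts[-1] < t_end:
        pts = np.append(pts, t_end)
    y0 = np.zeros(N_STATES)
    out = np.empty((grid.size, N_STATES))
    filled = 0
    if grid[0] == 0.0:
        out[0] = y0
        filled = 1

    for a, b in zip(pts[:-1], pts[1:]):
        sol = solve_ivp(
            rhs,
            (a, b),
            y0,
            method=method,
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise SolverError(f"integration failed at t={sol.t[-1]:.4g} h: {sol.message}")
        y0 = sol.y[:, -1]
        if np.min(y0) < -1e4 * atol - 1e-12 * p.dose_total:
            worst = STATE_NAMES[int(np.argmin(y0))]
            raise SolverError(f"state {worst} went negative ({np.min(y0):.3g} mg) at t={b:.4g} h")
        history.ends.append(b)
        history.sols.append(sol.sol)
        while filled < grid.size and grid[filled] <= b + 1e-12:
            out[filled] = sol.sol(min(grid[filled], b))
            filled += 1
    if filled < grid.size:
        raise SolverError("output grid extends beyond the integrated horizon")
    return SimulationResult(t=grid, states=out, params=p)


def mass_balance(res: SimulationResult, scen: ExposureScenario | None = None) -> np.ndarray:
    """Molar balance residual (in mg parent-equivalents) per output time.

    Dose delivered so far minus parent-equivalents summed over every
    compartment, transit pool, cumulative faecal and urinary output and the
    unexcreted metabolite pools.  Should vanish to solver tolerance.
    """
    p = res.params
    s = res.states
    mol = np.zeros(res.t.size)
    dphp_states = [
        "ASt_hep", "ASt_lym", "ASt_un", "AGi_hep", "AGi_lym", "AGi_un", "AGi_rec",
        "ATrans_gut", "AGut", "ALiv", "ASto", "AFat", "ASpd", "ARpd", "ABld",
        "ALymph", "ADuct", "ABile", "ABowel",
    ]
    mphp_states = [
        "MGi", "MGut", "MLiv", "MSto", "MFat", "MSpd", "MRpd", "MBld", "MBile", "MBowel",
    ]
    for name in dphp_states:
        mol += s[:, _IDX[name]] / MW_DPHP
    for name in mphp_states:
        mol += s[:, _IDX[name]] / MW_MPHP
    mol += (s[:, _IDX["OHPool"]] + s[:, _IDX["OHUrine"]]) / MW_OH_MPHP
    mol += (s[:, _IDX["CXPool"]] + s[:, _IDX["CXUrine"]]) / MW_CX_MPHP
    mol += s[:, _IDX["OtherMet"]] / MW_MPHP
    delivered = p.dose_total * np.clip(res.t / p.drink_duration, 0.0, 1.0) / MW_DPHP
    return (delivered - mol) * MW_DPHP
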