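"""Model parameterisation: defaults, prior distributions and subject building.

The flat parameter dictionary mirrors the published physiological/kinetic
table names exactly (``FracDOSEHep``, ``K1Lymph``, ``VLiC`` ...) so the
configuration can be grepped against the table.  ``build_subject`` turns the
flat set plus an exposure scenario into the absolute volumes, flows and
scaled clearances the PBPK right-hand side consumes.

Notes on deliberately preserved oddities of the shipped defaults:

* ``FBDPHP``/``FBMPHP`` hold the plasma fraction *unbound* (0.0025, 0.0146)
  as printed; the model's bound fraction is 1 minus these values.  The
  calibration layer also parameterises by the unbound fraction.
* ``T_half_DPHP`` default 3 min with prior U(15, 60), ``T_half_MPHP``
  default 8.05 min with prior N(30.54, 2.39), ``GIPERM`` default 5.1 with
  prior U(0.1, 0.3): the default/prior pairs are shipped verbatim as
  published and are not reconciled here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from . import constants, ivive

__all__ = [
    "PriorSpec",
    "PhysiologicalParameters",
    "KineticParameters",
    "PartitionTable",
    "ExposureScenario",
    "ModelParameters",
    "default_flat",
    "default_priors",
    "sensitivity_registry",
    "build_subject",
    "build_subject_from_flat",
    "STUDY_BODY_WEIGHTS",
    "STUDY_DOSES",
    "STUDY_VOLUNTEERS",
]

# ---------------------------------------------------------------------------
# Oral-dose study: volunteer body weights (kg) and doses (mg/kg).
STUDY_VOLUNTEERS = ("A", "B", "C", "D", "E", "F")
STUDY_BODY_WEIGHTS = {"A": 83.0, "B": 75.0, "C": 76.0, "D": 74.0, "E": 90.0, "F": 108.0}
STUDY_DOSES = {"A": 0.717, "B": 0.639, "C": 0.781, "D": 0.783, "E": 0.775, "F": 0.733}
STUDY_FRACMETAB_CX = {"A": 0.02, "B": 0.017, "C": 0.02, "D": 0.023, "E": 0.018, "F": 0.018}
STUDY_FRACMETAB_OH = {"A": 0.396, "B": 0.340, "C": 0.374, "D": 0.359, "E": 0.334, "F": 0.329}


# ---------------------------------------------------------------------------
# Prior distributions


@dataclass(frozen=True)
class PriorSpec:
    """One parameter's prior.

    ``kind`` is ``uniform`` (args = lower, upper), ``normal`` (args = mean,
    sd) or ``lognormal`` (args = meanlog, sdlog).  Normal and lognormal laws
    are truncated at the 5th and 95th percentiles of the untruncated
    distribution; uniforms are their own truncation.
    """

    kind: str
    args: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "normal", "lognormal"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "uniform" and not self.args[0] < self.args[1]:
            raise ValueError("uniform bounds must satisfy lower < upper")
        if self.kind in ("normal", "lognormal") and self.args[1] <= 0:
            raise ValueError("scale parameter must be positive")

    @property
    def _frozen(self):
        if self.kind == "normal":
            return stats.norm(self.args[0], self.args[1])
        if self.kind == "lognormal":
            return stats.lognorm(s=self.args[1], scale=math.exp(self.args[0]))
        return stats.uniform(self.args[0], self.args[1] - self.args[0])

    @property
    def support(self) -> tuple[float, float]:
        if self.kind == "uniform":
            return self.args
        d = self._frozen
        return float(d.ppf(0.05)), float(d.ppf(0.95))

    def ppf(self, u):
        """Quantile of the (truncated) law for u in [0, 1]."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError("quantile argument must lie in [0, 1]")
        if self.kind == "uniform":
            lo, hi = self.args
            return lo + u * (hi - lo)
        return self._frozen.ppf(0.05 + 0.9 * u)

    def sample(self, rng: np.random.Generator, n: int | None = None):
        u = rng.uniform(size=n)
        return self.ppf(u)

    def logpdf(self, x: float) -> float:
        lo, hi = self.support
        if x < lo or x > hi:
            return -math.inf
        if self.kind == "uniform":
            return -math.log(hi - lo)
        # renormalised for the central 90% of mass
        return float(self._frozen.logpdf(x)) - math.log(0.9)

    def median(self) -> float:
        return float(self.ppf(0.5))


def default_priors() -> dict[str, PriorSpec]:
    """Prior/uncertainty distributions for every varied model parameter.

    Published table entries are verbatim; entries without a published
    distribution (microsomal protein yield of the liver, dose fractions,
    fractions metabolised, the three delay terms, the gastric-emptying
    relaxation time and the partition coefficients) carry package defaults
    documented in the methods note.
    """
    U, N, LN = (
        lambda a, b: PriorSpec("uniform", (a, b)),
        lambda m, s: PriorSpec("normal", (m, s)),
        lambda m, s: PriorSpec("lognormal", (m, s)),
    )
    priors = {
        "BW": N(72.3, 9.05),
        "VLiC": N(3.09, 0.8),
        "VFaC": LN(3.42, 0.43),
        "VGuC": U(1.19, 1.84),
        "VStC": N(0.22, 0.07),
        "VSpdC": N(60.7, 9.4),
        "VRpdC": N(3.7, 0.26),
        "VBldC": U(2.5, 10.0),
        "VLymphC": U(0.18, 0.72),
        "QCC": N(13.8, 2.5),
        "QHepartC": N(6.89, 0.52),
        "QFaC": N(5.3, 0.3),
        "QGuC": U(13.2, 16.6),
        "QStC": N(1.1, 0.08),
        "QSpdC": N(28.7, 1.91),
        "QRpdC": N(43.1, 2.78),
        "QLymphC": U(0.02, 0.08),
        "T_half_DPHP": U(15.0, 60.0),
        "T_half_MPHP": N(30.54, 2.39),
        "T_half_DPHP_gut": U(15.0, 60.0),
        "k1_DPHP_gut": U(0.05, 0.15),
        "k1_MPHP_gut": U(0.05, 0.15),
        "k1_DPHP_liver": U(5.0, 15.0),
        "k1_MPHP_liver": U(0.5, 1.5),
        "MPY_gut": U(1.95, 7.8),
        "FBDPHP": U(1e-5, 0.01),
        "FBMPHP": U(0.001, 0.01),
        "k_max": U(5.1, 20.4),
        "k_min": U(0.0025, 0.01),
        "k_Ga": U(12.55, 50.2),
        "DRINKTIME": U(0.125, 0.5),
        "BELLYPERM": U(0.34, 0.99),
        "GIPERM": U(0.1, 0.3),
        "BELLYPERMLymph": U(0.34, 0.99),
        "GIPERMLymph": U(2.6, 7.6),
        "K1Lymph": U(0.1, 0.3),
        "K1_MOH": U(0.05, 0.15),
        "K1_cx": U(0.05, 0.15),
        # --- package defaults (no published distribution) ---
        "MPY": U(17.0, 68.0),
        "FracDOSEHep": U(0.02, 0.2),
        "FracDOSELymph": U(0.01, 0.1),
        "FracMetabOH": U(0.2, 0.45),
        "FracMetabcx": U(0.01, 0.03),
        "Gutlag": U(0.25, 2.0),
        "Lymphlag": U(2.0, 10.0),
        "Bilelag": U(3.0, 9.0),
        "tau_ge": U(0.5, 2.0),
    }
    # factor-2 uniforms around the predicted partition coefficients
    for name, default in _PC_DEFAULTS.items():
        if name in ("PstD", "PstM"):
            continue  # surrogate-tied: the stomach coefficient follows the gut
        priors[name] = U(default / 2.0, default * 2.0)
    return priors


# tissue:blood partition coefficients predicted from log P(ow); the stomach
# uses the gut value and the rapidly perfused pool the spleen value
# (surrogate assignments), the slowly perfused pool the muscle value.
_PC_DEFAULTS = {
    "PfaD": 63.4,
    "PliD": 5.89,
    "PspdD": 3.29,
    "PbcD": 3.01,
    "PguD": 7.4,
    "PrpdD": 3.7,
    "PstD": 7.4,
    "PfaM": 29.10,
    "PliM": 54.8,
    "PspdM": 7.51,
    "PbcM": 6.67,
    "PguM": 25.2,
    "PrpdM": 12.20,
    "PstM": 25.2,
}


def default_flat() -> dict[str, float]:
    """Default (baseline) value of every model parameter, flat key -> value."""
    flat = {
        "BW": 72.3,
        "VT": 0.95,  # fraction of BW that is vascularised tissue
        "VLiC": 3.09,
        "VFaC": 19.5,
        "VGuC": 1.50,
        "VStC": 0.22,
        "VSpdC": 60.7,
        "VRpdC": 3.71,
        "VBldC": 5.0,
        "VLymphC": 0.36,
        "QCC": 14.0,
        "QHepartC": 6.0,
        "QFaC": 5.0,
        "QGuC": 14.9,
        "QStC": 1.1,
        "QSpdC": 27.0,
        "QRpdC": 42.0,
        "QLymphC": 0.04,
        "T_half_DPHP": 3.0,
        "T_half_MPHP": 8.05,
        "T_half_DPHP_gut": 60.0,
        "k1_DPHP_gut": 0.1,
        "k1_MPHP_gut": 0.1,
        "k1_DPHP_liver": 10.0,
        "k1_MPHP_liver": 1.0,
        "MPY": 34.0,
        "MPY_gut": 3.9,
        # plasma fraction *unbound* as printed; bound fraction = 1 - value
        "FBDPHP": 0.0025,
        "FBMPHP": 0.0146,
        "k_max": 10.2,
        "k_min": 0.005,
        "k_Ga": 25.1,
        "DRINKTIME": 0.25,
        "BELLYPERM": 0.685,
        "GIPERM": 5.1,
        "BELLYPERMLymph": 0.685,
        "GIPERMLymph": 5.1,
        "K1Lymph": 0.2,
        "FracDOSEHep": 0.1,
        "FracDOSELymph": 0.05,
        "FracMetabOH": 0.35,
        "FracMetabcx": 0.02,
        "K1_MOH": 0.1,
        "K1_cx": 0.1,
        "Gutlag": 0.75,
        "Lymphlag": 6.0,
        "Bilelag": 7.8,
        "tau_ge": constants.TAU_GASTRIC_DEFAULT,
        "incubation_ml_per_mg": constants.INCUBATION_ML_PER_MG,
        "gut_mphp_to_blood": 0.0,
    }
    flat.update(_PC_DEFAULTS)
    return flat


def sensitivity_registry() -> list[str]:
    """Names of the 59 parameters varied in uncertainty/sensitivity analysis."""
    return list(default_priors().keys())


# ---------------------------------------------------------------------------
# Structured parameter views


@dataclass(frozen=True)
class PhysiologicalParameters:
    BW: float = 72.3
    VT: float = 0.95
    VLiC: float = 3.09
    VFaC: float = 19.5
    VGuC: float = 1.50
    VStC: float = 0.22
    VSpdC: float = 60.7
    VRpdC: float = 3.71
    VBldC: float = 5.0
    VLymphC: float = 0.36
    QCC: float = 14.0
    QHepartC: float = 6.0
    QFaC: float = 5.0
    QGuC: float = 14.9
    QStC: float = 1.1
    QSpdC: float = 27.0
    QRpdC: float = 42.0
    QLymphC: float = 0.04


@dataclass(frozen=True)
class KineticParameters:
    T_half_DPHP: float = 3.0
    T_half_MPHP: float = 8.05
    T_half_DPHP_gut: float = 60.0
    MPY: float = 34.0
    MPY_gut: float = 3.9
    FBDPHP: float = 0.0025  # plasma fraction unbound (printed value)
    FBMPHP: float = 0.0146
    k_max: float = 10.2
    k_min: float = 0.005
    k_Ga: float = 25.1
    DRINKTIME: float = 0.25
    BELLYPERM: float = 0.685
    GIPERM: float = 5.1
    BELLYPERMLymph: float = 0.685
    GIPERMLymph: float = 5.1
    K1Lymph: float = 0.2
    Lymphlag: float = 6.0
    Gutlag: float = 0.75
    Bilelag: float = 7.8
    FracDOSEHep: float = 0.1
    FracDOSELymph: float = 0.05
    k1_DPHP_gut: float = 0.1
    k1_MPHP_gut: float = 0.1
    k1_DPHP_liver: float = 10.0
    k1_MPHP_liver: float = 1.0
    FracMetabOH: float = 0.35
    FracMetabcx: float = 0.02
    K1_MOH: float = 0.1
    K1_cx: float = 0.1
    tau_ge: float = constants.TAU_GASTRIC_DEFAULT
    incubation_ml_per_mg: float = constants.INCUBATION_ML_PER_MG
    #: route monoester formed in the gut wall straight into the (bound)
    #: blood pool instead of leaving it available for first-pass hepatic
    #: metabolism (0 = first-pass available, the default behaviour)
    gut_mphp_to_blood: float = 0.0


@dataclass(frozen=True)
class PartitionTable:
    """Tissue:blood partition coefficients for parent (D) and monoester (M)."""

    PfaD: float = 63.4
    PliD: float = 5.89
    PspdD: float = 3.29
    PbcD: float = 3.01
    PguD: float = 7.4
    PrpdD: float = 3.7
    PstD: float = 7.4
    PfaM: float = 29.10
    PliM: float = 54.8
    PspdM: float = 7.51
    PbcM: float = 6.67
    PguM: float = 25.2
    PrpdM: float = 12.20
    PstM: float = 25.2

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"partition coefficient {name} must be positive")


@dataclass(frozen=True)
class ExposureScenario:
    """A single oral dose delivered as a drink over a short duration."""

    dose: float = 0.738  # mg per kg body weight
    BW: float | None = None  # kg; falls back to the physiological BW
    drink_duration: float | None = None  # h; falls back to DRINKTIME
    t_end: float = 48.0  # h
    output_dt: float = 0.1  # h, spacing of the derived-output grid

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.output_dt <= 0:
            raise ValueError("output_dt must be positive")

    def grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.output_dt))
        return np.linspace(0.0, self.t_end, n + 1)


@dataclass(frozen=True)
class ModelParameters:
    """Absolute (per-subject) quantities consumed by the PBPK right-hand side."""

    BW: float
    dose_total: float  # mg
    drink_duration: float  # h
    # volumes, L (tissue density taken as 1 kg/L)
    Vli: float
    Vfa: float
    Vgu: float
    Vst: float
    Vspd: float
    Vrpd: float
    Vbld: float
    Vlymph: float
    # blood flows, L/h
    QC: float
    Qli: float  # hepatic artery
    Qfa: float
    Qgu: float
    Qst: float
    Qspd: float
    Qrpd: float
    # whole-organ intrinsic clearances, L/h
    clint_D_liver: float
    clint_D_gut: float
    clint_M_liver: float
    # binding (free fractions in blood)
    fu_D: float
    fu_M: float
    # partition coefficients
    pc: PartitionTable
    kin: KineticParameters
    flat: Mapping[str, float] = field(default_factory=dict, repr=False)


def _validate_fractions(kin: KineticParameters) -> None:
    bad = []
    if not 0.0 <= kin.FracDOSEHep <= 1.0:
        bad.append("FracDOSEHep")
    if not 0.0 <= kin.FracDOSELymph <= 1.0:
        bad.append("FracDOSELymph")
    if kin.FracDOSEHep + kin.FracDOSELymph > 1.0:
        bad.append("FracDOSEHep+FracDOSELymph>1")
    if kin.FracMetabOH + kin.FracMetabcx > 1.0:
        bad.append("FracMetabOH+FracMetabcx>1")
    if not 0.0 < kin.FBDPHP <= 1.0:
        bad.append("FBDPHP")
    if not 0.0 < kin.FBMPHP <= 1.0:
        bad.append("FBMPHP")
    for name in ("Gutlag", "Lymphlag", "Bilelag"):
        if getattr(kin, name) < 0:
            bad.append(name)
    if bad:
        raise ValueError(f"invalid kinetic parameters: {', '.join(bad)}")


def build_subject(
    phys: PhysiologicalParameters,
    kin: KineticParameters,
    pc: PartitionTable,
    scen: ExposureScenario,
) -> ModelParameters:
    """Resolve fractional parameters into absolute volumes, flows and clearances.

    Cardiac output scales allometrically as QCC * BW^0.75.  Regional flow
    fractions are renormalised to sum to cardiac output, and the slowly and
    rapidly perfused masses take the residual of the vascularised fraction
    (VT * BW) after the named organs, split in the tabulated ratio.
    """
    _validate_fractions(kin)
    BW = scen.BW if scen.BW is not None else phys.BW
    if BW <= 0:
        raise ValueError("body weight must be positive")

    named = phys.VLiC + phys.VFaC + phys.VGuC + phys.VStC + phys.VBldC + phys.VLymphC
    if named / 100.0 > phys.VT:
        raise ValueError("named organ mass fractions exceed the vascularised fraction VT")
    residual = phys.VT - named / 100.0  # fraction of BW left for spd+rpd
    w_spd = phys.VSpdC / (phys.VSpdC + phys.VRpdC)

    Vli = phys.VLiC / 100.0 * BW
    Vfa = phys.VFaC / 100.0 * BW
    Vgu = phys.VGuC / 100.0 * BW
    Vst = phys.VStC / 100.0 * BW
    Vbld = phys.VBldC / 100.0 * BW
    Vlymph = phys.VLymphC / 100.0 * BW
    Vspd = residual * w_spd * BW
    Vrpd = residual * (1.0 - w_spd) * BW

    QC = phys.QCC * BW**0.75
    qsum = phys.QHepartC + phys.QFaC + phys.QGuC + phys.QStC + phys.QSpdC + phys.QRpdC
    scale = QC / qsum
    Qli = phys.QHepartC * scale
    Qfa = phys.QFaC * scale
    Qgu = phys.QGuC * scale
    Qst = phys.QStC * scale
    Qspd = phys.QSpdC * scale
    Qrpd = phys.QRpdC * scale

    ratio = kin.incubation_ml_per_mg
    cl_inv_D = ivive.LN2 / kin.T_half_DPHP * ratio
    cl_inv_Dg = ivive.LN2 / kin.T_half_DPHP_gut * ratio
    cl_inv_M = ivive.LN2 / kin.T_half_MPHP * ratio
    liver_ctx = ivive.ScalingContext(
        MPY=kin.MPY, tissue_mass=Vli * 1000.0, Q_H=Qli, fu=kin.FBDPHP, rbc_plasma_ratio=pc.PbcD
    )
    gut_ctx = ivive.ScalingContext(
        MPY=kin.MPY_gut, tissue_mass=Vgu * 1000.0, Q_H=Qgu, fu=kin.FBDPHP, rbc_plasma_ratio=pc.PbcD
    )
    clint_D_liver = ivive.scale_intrinsic_clearance(cl_inv_D, liver_ctx)
    clint_D_gut = ivive.scale_intrinsic_clearance(cl_inv_Dg, gut_ctx)
    clint_M_liver = ivive.scale_intrinsic_clearance(cl_inv_M, liver_ctx)

    drink = scen.drink_duration if scen.drink_duration is not None else kin.DRINKTIME
    if drink <= 0:
        raise ValueError("drink duration must be positive")

    return ModelParameters(
        BW=BW,
        dose_total=scen.dose * BW,
        drink_duration=drink,
        Vli=Vli,
        Vfa=Vfa,
        Vgu=Vgu,
        Vst=Vst,
        Vspd=Vspd,
        Vrpd=Vrpd,
        Vbld=Vbld,
        Vlymph=Vlymph,
        QC=QC,
        Qli=Qli,
        Qfa=Qfa,
        Qgu=Qgu,
        Qst=Qst,
        Qspd=Qspd,
        Qrpd=Qrpd,
        clint_D_liver=clint_D_liver,
        clint_D_gut=clint_D_gut,
        clint_M_liver=clint_M_liver,
        fu_D=kin.FBDPHP,
        fu_M=kin.FBMPHP,
        pc=pc,
        kin=kin,
    )


_PHYS_FIELDS = set(PhysiologicalParameters.__dataclass_fields__)
_KIN_FIELDS = set(KineticParameters.__dataclass_fields__)
_PC_FIELDS = set(PartitionTable.__dataclass_fields__)


def structured_from_flat(
    flat: Mapping[str, float], tie_surrogates: bool = True
) -> tuple[PhysiologicalParameters, KineticParameters, PartitionTable]:
    """Split a flat name -> value mapping into the three structured views.

    With ``tie_surrogates`` the stomach partition coefficient follows the gut
    value and the rapidly perfused value follows the spleen surrogate when
    only the independent coefficient was overridden.
    """
    merged = dict(default_flat())
    unknown = set(flat) - set(merged)
    if unknown:
        raise KeyError(f"unknown parameter names: {sorted(unknown)}")
    merged.update(flat)
    if tie_surrogates:
        if "PstD" not in flat:
            merged["PstD"] = merged["PguD"]
        if "PstM" not in flat:
            merged["PstM"] = merged["PguM"]
    phys = PhysiologicalParameters(**{k: merged[k] for k in _PHYS_FIELDS})
    kin = KineticParameters(**{k: merged[k] for k in _KIN_FIELDS})
    pc = PartitionTable(**{k: merged[k] for k in _PC_FIELDS})
    return phys, kin, pc


def build_subject_from_flat(
    flat: Mapping[str, float] | None = None, scen: ExposureScenario | None = None
) -> ModelParameters:
    """Convenience: defaults overridden by ``flat``, built for ``scen``."""
    flat = dict(flat or {})
    scen = scen or ExposureScenario()
    phys, kin, pc = structured_from_flat(flat)
    mp = build_subject(phys, kin, pc, scen)
    object.__setattr__(mp, "flat", flat)
    return mp
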