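"""Independently coded ODE-only right-hand side of the PBPK model.

The lag-free reduction of the model (delays zero: lymph empties straight
into venous blood, bile reappears in the gut lumen immediately, GI
absorption is undelayed) written from scratch in a dictionary style, used
as the oracle for the DDE -> ODE reduction checks.  No transit pools exist
here; in the full model those pools are constant (zero) when every lag is
zero, so the shared compartments must agree.
"""

from __future__ import annotations

import math

import numpy as np

from dphp_pbpk.constants import MW_CX_MPHP, MW_DPHP, MW_MPHP, MW_OH_MPHP
from dphp_pbpk.parameters import ModelParameters

# reference states and the full-model state each one corresponds to
REF_STATES = [
    ("st_hep", "ASt_hep"), ("st_lym", "ASt_lym"), ("st_un", "ASt_un"),
    ("gi_hep", "AGi_hep"), ("gi_lym", "AGi_lym"), ("gi_un", "AGi_un"),
    ("gi_rec", "AGi_rec"),
    ("gut", "AGut"), ("liv", "ALiv"), ("sto", "ASto"), ("fat", "AFat"),
    ("spd", "ASpd"), ("rpd", "ARpd"), ("bld", "ABld"), ("lymph", "ALymph"),
    ("bowel", "ABowel"), ("met", "AMet"),
    ("m_gi", "MGi"), ("m_gut", "MGut"), ("m_liv", "MLiv"), ("m_sto", "MSto"),
    ("m_fat", "MFat"), ("m_spd", "MSpd"), ("m_rpd", "MRpd"), ("m_bld", "MBld"),
    ("m_bowel", "MBowel"), ("m_met", "MMet"),
    ("oh", "OHPool"), ("oh_urine", "OHUrine"), ("cx", "CXPool"),
    ("cx_urine", "CXUrine"), ("other", "OtherMet"),
]
REF_NAMES = [r for r, _ in REF_STATES]
FULL_NAMES = [f for _, f in REF_STATES]


def reference_rhs(t: float, s: dict[str, float], p: ModelParameters) -> dict[str, float]:
    """Derivatives of the lag-free model, one entry per reference state."""
    k = p.kin
    r_dm = MW_MPHP / MW_DPHP
    r_oh = MW_OH_MPHP / MW_MPHP
    r_cx = MW_CX_MPHP / MW_MPHP

    rate_in = p.dose_total / p.drink_duration if 0.0 <= t < p.drink_duration else 0.0
    f_hep, f_lym = k.FracDOSEHep, k.FracDOSELymph
    kge = k.k_min + (k.k_max - k.k_min) * math.exp(-t / k.tau_ge)

    c_free = k.FBDPHP * s["bld"] / p.Vbld  # FBDPHP holds the unbound fraction
    cv = {
        "gut": s["gut"] / (p.Vgu * p.pc.PguD),
        "liv": s["liv"] / (p.Vli * p.pc.PliD),
        "sto": s["sto"] / (p.Vst * p.pc.PstD),
        "fat": s["fat"] / (p.Vfa * p.pc.PfaD),
        "spd": s["spd"] / (p.Vspd * p.pc.PspdD),
        "rpd": s["rpd"] / (p.Vrpd * p.pc.PrpdD),
    }
    met_gut = p.clint_D_gut * cv["gut"]
    met_liv = p.clint_D_liver * cv["liv"]
    bile_d = k.k1_DPHP_liver * s["liv"]
    portal = p.Qli + p.Qgu + p.Qst

    d = {}
    d["st_hep"] = f_hep * rate_in - kge * s["st_hep"] - k.BELLYPERM * s["st_hep"]
    d["st_lym"] = f_lym * rate_in - kge * s["st_lym"] - k.BELLYPERMLymph * s["st_lym"]
    d["st_un"] = (1 - f_hep - f_lym) * rate_in - kge * s["st_un"]
    d["gi_hep"] = kge * s["st_hep"] - k.GIPERM * s["gi_hep"]
    d["gi_lym"] = kge * s["st_lym"] - k.GIPERMLymph * s["gi_lym"]
    d["gi_un"] = kge * s["st_un"] - k.k1_DPHP_gut * s["gi_un"]
    d["gi_rec"] = bile_d - k.GIPERM * s["gi_rec"] - k.k1_DPHP_gut * s["gi_rec"]
    d["gut"] = (
        p.Qgu * (c_free - cv["gut"])
        + k.GIPERM * (s["gi_hep"] + s["gi_rec"])
        - met_gut
    )
    d["liv"] = (
        p.Qli * c_free + p.Qgu * cv["gut"] + p.Qst * cv["sto"]
        + k.BELLYPERM * s["st_hep"] - portal * cv["liv"] - met_liv - bile_d
    )
    d["sto"] = p.Qst * (c_free - cv["sto"])
    d["fat"] = p.Qfa * (c_free - cv["fat"])
    d["spd"] = p.Qspd * (c_free - cv["spd"])
    d["rpd"] = p.Qrpd * (c_free - cv["rpd"])
    d["bld"] = (
        p.Qfa * cv["fat"] + p.Qspd * cv["spd"] + p.Qrpd * cv["rpd"] + portal * cv["liv"]
        - p.QC * c_free + k.K1Lymph * s["lymph"]
    )
    d["lymph"] = (
        k.BELLYPERMLymph * s["st_lym"] + k.GIPERMLymph * s["gi_lym"] - k.K1Lymph * s["lymph"]
    )
    d["bowel"] = k.k1_DPHP_gut * (s["gi_un"] + s["gi_rec"])
    d["met"] = met_gut + met_liv

    c_free_m = k.FBMPHP * s["m_bld"] / p.Vbld
    cvm = {
        "gut": s["m_gut"] / (p.Vgu * p.pc.PguM),
        "liv": s["m_liv"] / (p.Vli * p.pc.PliM),
        "sto": s["m_sto"] / (p.Vst * p.pc.PstM),
        "fat": s["m_fat"] / (p.Vfa * p.pc.PfaM),
        "spd": s["m_spd"] / (p.Vspd * p.pc.PspdM),
        "rpd": s["m_rpd"] / (p.Vrpd * p.pc.PrpdM),
    }
    met_m = p.clint_M_liver * cvm["liv"]
    bile_m = k.k1_MPHP_liver * s["m_liv"]
    d["m_gi"] = bile_m - k.k_Ga * s["m_gi"] - k.k1_MPHP_gut * s["m_gi"]
    d["m_gut"] = p.Qgu * (c_free_m - cvm["gut"]) + k.k_Ga * s["m_gi"] + r_dm * met_gut
    d["m_liv"] = (
        p.Qli * c_free_m + p.Qgu * cvm["gut"] + p.Qst * cvm["sto"] + r_dm * met_liv
        - portal * cvm["liv"] - met_m - bile_m
    )
    d["m_sto"] = p.Qst * (c_free_m - cvm["sto"])
    d["m_fat"] = p.Qfa * (c_free_m - cvm["fat"])
    d["m_spd"] = p.Qspd * (c_free_m - cvm["spd"])
    d["m_rpd"] = p.Qrpd * (c_free_m - cvm["rpd"])
    d["m_bld"] = (
        p.Qfa * cvm["fat"] + p.Qspd * cvm["spd"] + p.Qrpd * cvm["rpd"] + portal * cvm["liv"]
        - p.QC * c_free_m
    )
    d["m_bowel"] = k.k1_MPHP_gut * s["m_gi"]
    d["m_met"] = met_m

    d["oh"] = k.FracMetabOH * met_m * r_oh - k.K1_MOH * s["oh"]
    d["oh_urine"] = k.K1_MOH * s["oh"]
    d["cx"] = k.FracMetabcx * met_m * r_cx - k.K1_cx * s["cx"]
    d["cx_urine"] = k.K1_cx * s["cx"]
    d["other"] = (1 - k.FracMetabOH - k.FracMetabcx) * met_m
    return d


def reference_rhs_vector(t: float, y: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Array-in/array-out wrapper in the REF_STATES ordering (for solve_ivp)."""
    s = dict(zip(REF_NAMES, y))
    d = reference_rhs(t, s, p)
    return np.array([d[name] for name in REF_NAMES])
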