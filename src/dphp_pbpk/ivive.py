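"""In vitro / in silico to in vivo extrapolation of kinetic parameters.

Turns microsomal substrate-depletion measurements and octanol-water
partitioning predictions into the clearance, binding and metabolite-fraction
parameters consumed by the PBPK core:

* substrate-depletion half-life  <->  first-order decay constant,
* in vitro intrinsic clearance per mg microsomal protein,
* scaling to whole-organ intrinsic clearance via microsomal protein yield,
* whole-organ plasma clearance under the well-stirred liver model,
* plasma fraction unbound from log P(ow),
* fractions of the monoester metabolised to each measured second-order
  metabolite, from molar amounts.

Units policy: minutes inside the in vitro expressions, litres/hour for every
in vivo clearance; the single minute->hour conversion lives in
:func:`scale_intrinsic_clearance`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "InVitroClearanceInput",
    "ScalingContext",
    "MetaboliteAmounts",
    "half_life_from_decay",
    "decay_from_half_life",
    "intrinsic_clearance_invitro",
    "scale_intrinsic_clearance",
    "well_stirred_clearance",
    "fraction_unbound",
    "fraction_metabolised",
    "write_derived_parameter_report",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class InVitroClearanceInput:
    """A microsomal substrate-depletion measurement.

    Either the decay constant ``k`` (per minute) or the half-life ``T_half``
    (minutes) may be given; when both are present they must satisfy
    k*T_half = ln 2.
    """

    incubation_volume: float  # mL
    microsomal_protein: float  # mg
    k: float | None = None  # per minute
    T_half: float | None = None  # minutes

    def __post_init__(self) -> None:
        if self.incubation_volume <= 0:
            raise ValueError("incubation_volume must be positive")
        if self.microsomal_protein <= 0:
            raise ValueError("microsomal_protein must be positive")
        if self.k is None and self.T_half is None:
            raise ValueError("one of k or T_half is required")
        if self.k is not None and self.k <= 0:
            raise ValueError("decay constant k must be positive")
        if self.T_half is not None and self.T_half <= 0:
            raise ValueError("half-life must be positive")
        if self.k is not None and self.T_half is not None:
            if abs(self.k * self.T_half - LN2) > 1e-9 * LN2:
                raise ValueError("k and T_half are inconsistent (k*T_half != ln 2)")

    @property
    def half_life(self) -> float:
        """Half-life in minutes, derived from ``k`` when not given."""
        if self.T_half is not None:
            return self.T_half
        return half_life_from_decay(self.k)  # type: ignore[arg-type]


@dataclass(frozen=True)
class ScalingContext:
    """Organ-level context for scaling intrinsic clearance in vivo.

    MPY is the microsomal protein yield of the organ (mg microsomal protein
    per g tissue), ``tissue_mass`` the organ mass in g, ``Q_H`` the organ
    blood flow in L/h, ``fu`` the plasma fraction unbound, and
    ``rbc_plasma_ratio`` the red-blood-cell to plasma concentration ratio.
    """

    MPY: float  # mg microsomal protein / g tissue
    tissue_mass: float  # g
    Q_H: float  # L/h
    fu: float  # unitless, (0, 1]
    rbc_plasma_ratio: float  # unitless C_RBC/C_P

    def __post_init__(self) -> None:
        if self.MPY <= 0 or self.tissue_mass <= 0:
            raise ValueError("MPY and tissue_mass must be positive")
        if self.Q_H <= 0:
            raise ValueError("organ blood flow must be positive")
        if not (0.0 < self.fu <= 1.0):
            raise ValueError("fu must lie in (0, 1]")
        if self.rbc_plasma_ratio <= 0:
            raise ValueError("rbc_plasma_ratio must be positive")


@dataclass(frozen=True)
class MetaboliteAmounts:
    """Molar amounts of the four measured metabolites of the parent diester."""

    mphp: float
    oh_mphp: float
    cx_mphp: float
    oxo_mphp: float

    def __post_init__(self) -> None:
        for name in ("mphp", "oh_mphp", "cx_mphp", "oxo_mphp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} amount must be non-negative")

    @property
    def total(self) -> float:
        return self.mphp + self.oh_mphp + self.cx_mphp + self.oxo_mphp


def half_life_from_decay(k: float) -> float:
    """Half-life (minutes) from a first-order decay constant (per minute)."""
    if k <= 0:
        raise ValueError("decay constant must be positive")
    return LN2 / k


def decay_from_half_life(T_half: float) -> float:
    """First-order decay constant (per minute) from a half-life (minutes)."""
    if T_half <= 0:
        raise ValueError("half-life must be positive")
    return LN2 / T_half


def intrinsic_clearance_invitro(inp: InVitroClearanceInput) -> float:
    """In vitro intrinsic clearance, mL min^-1 per mg microsomal protein.

    (ln 2 / T_half) * (incubation volume / mg microsomes).
    """
    return (LN2 / inp.half_life) * (inp.incubation_volume / inp.microsomal_protein)


def scale_intrinsic_clearance(cl_invitro: float, ctx: ScalingContext) -> float:
    """Whole-organ intrinsic clearance in L/h.

    cl_invitro (mL/min/mg) * MPY (mg/g) * organ mass (g) * 60, converted to
    litres.  The gut variant is the same formula evaluated with the gut
    microsomal protein yield and gut mass.
    """
    if cl_invitro < 0:
        raise ValueError("cl_invitro must be non-negative")
    return cl_invitro * ctx.MPY * ctx.tissue_mass * 60.0 / 1000.0


def well_stirred_clearance(clint: float, ctx: ScalingContext) -> float:
    """Whole-organ plasma clearance (L/h) under the well-stirred model.

    Q_H * fu * CLint / (Q_H + fu * CLint / R) with R the red-cell to plasma
    concentration ratio.  Bounded above by both the flow limit Q_H*R and the
    capacity limit fu*CLint.
    """
    if clint < 0:
        raise ValueError("clint must be non-negative")
    return ctx.Q_H * ctx.fu * clint / (ctx.Q_H + ctx.fu * clint / ctx.rbc_plasma_ratio)


def fraction_unbound(logP: float) -> float:
    """Plasma fraction unbound predicted from log P(ow).

    fu = 1 / (10^x + 1) with x = 0.4485*logP - 0.4782; strictly decreasing
    in logP, maps the real line onto (0, 1).
    """
    if not math.isfinite(logP):
        raise ValueError("logP must be finite")
    x = 0.4485 * logP - 0.4782
    return 1.0 / (10.0**x + 1.0)


def fraction_metabolised(amounts: MetaboliteAmounts) -> tuple[float, float]:
    """Fractions of parent metabolised to (OH-, cx-) monoester metabolites.

    Each is the molar amount of that metabolite divided by the sum of all
    four measured metabolites.
    """
    total = amounts.total
    if total <= 0:
        raise ValueError("total metabolite amount must be positive")
    return amounts.oh_mphp / total, amounts.cx_mphp / total


def write_derived_parameter_report(path: str | Path, rows: dict[str, tuple[float, str]]) -> None:
    """Write a flat key/value/units CSV of derived kinetic parameters."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["parameter", "value", "units"])
        for key, (value, units) in rows.items():
            writer.writerow([key, repr(float(value)), units])
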