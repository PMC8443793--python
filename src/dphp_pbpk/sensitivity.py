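"""Uncertainty and global sensitivity analysis.

Three designs over the parameter priors: maxi-min Latin hypercube designs
for uncertainty (bounding-behaviour) analysis, Morris elementary-effects
trajectories for screening with the mu*/sigma measures, and the extended
Fourier Amplitude Sensitivity Test (eFAST) for variance-based first-order
and total indices on the retained parameter set.

Retention follows the screening rule: a parameter is kept if, for any
studied metric, its mu* comes within a fraction (default 0.2) of that
metric's largest mu*.

All evaluators map a flat name->value parameter dictionary to a metric
dictionary; the PBPK evaluator is one such, and analytic test functions
slot in the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from . import model
from .parameters import ExposureScenario, PriorSpec, build_subject_from_flat

__all__ = [
    "DesignMatrix",
    "MorrisResult",
    "EFASTResult",
    "sample_priors",
    "lhd_maximin",
    "PBPKEvaluator",
    "run_batch",
    "morris_screen",
    "retain_parameters",
    "efast",
]


@dataclass
class DesignMatrix:
    """Runs-by-parameters design in native units."""

    names: list[str]
    values: np.ndarray  # (n_runs, n_params)
    provenance: str  # "LHD" | "random" | "Morris" | "eFAST"
    seed: int | None = None
    unit_values: np.ndarray | None = None  # same design in [0,1]^k, if applicable

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("design shape does not match parameter names")

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    def row(self, i: int) -> dict[str, float]:
        return dict(zip(self.names, self.values[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


def _check_support(design: DesignMatrix, priors: Mapping[str, PriorSpec]) -> None:
    for j, name in enumerate(design.names):
        lo, hi = priors[name].support
        col = design.values[:, j]
        if np.any(col < lo - 1e-9) or np.any(col > hi + 1e-9):
            raise ValueError(f"design values for {name} fall outside the prior support")


def sample_priors(priors: Mapping[str, PriorSpec], n: int, seed: int) -> DesignMatrix:
    """Independent draws from each (truncated) prior; reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(priors)
    unit = rng.uniform(size=(n, len(names)))
    vals = np.column_stack([priors[name].ppf(unit[:, j]) for j, name in enumerate(names)])
    return DesignMatrix(names, vals, "random", seed, unit_values=unit)


def lhd_maximin(
    priors: Mapping[str, PriorSpec], n: int, seed: int, n_candidates: int = 20
) -> DesignMatrix:
    """Maxi-min Latin hypercube: best of ``n_candidates`` random LHDs.

    Each dimension is stratified into n equal-probability bins with one
    point per bin; the candidate maximising the minimal pairwise distance
    in the unit cube is kept and mapped through the prior quantiles.
    """
    if n < 2:
        raise ValueError("a Latin hypercube needs n >= 2")
    rng = np.random.default_rng(seed)
    names = list(priors)
    k = len(names)
    best_unit, best_score = None, -np.inf
    for _ in range(n_candidates):
        unit = np.empty((n, k))
        for j in range(k):
            unit[:, j] = (rng.permutation(n) + rng.uniform(size=n)) / n
        from scipy.spatial.distance import pdist

        score = float(pdist(unit).min())
        if score > best_score:
            best_unit, best_score = unit, score
    vals = np.column_stack([priors[name].ppf(best_unit[:, j]) for j, name in enumerate(names)])
    return DesignMatrix(names, vals, "LHD", seed, unit_values=best_unit)


# ---------------------------------------------------------------------------
# Model evaluation


class PBPKEvaluator:
    """Maps a flat parameter-override dict to the screening metrics.

    Uses the compiled fixed-step engine by default; adaptive integration
    can be requested for audit runs.  ``check_balance`` records the worst
    relative mass-balance residual of each run.
    """

    def __init__(
        self,
        scen: ExposureScenario | None = None,
        registry: Sequence[metrics_mod.MetricSpec] | None = None,
        engine: str = "rk4",
        check_balance: bool = True,
        rtol: float = 1e-7,
        atol: float = 1e-10,
    ) -> None:
        self.scen = scen or ExposureScenario()
        self.registry = list(registry) if registry is not None else metrics_mod.screening_registry()
        self.engine = engine
        self.check_balance = check_balance
        self.rtol, self.atol = rtol, atol
        self.last_balance: float | None = None

    def simulate(self, flat: Mapping[str, float]) -> model.SimulationResult:
        p = build_subject_from_flat(flat, self.scen)
        return model.simulate(
            p, self.scen, engine=self.engine, rtol=self.rtol, atol=self.atol
        )

    def __call__(self, flat: Mapping[str, float]) -> dict[str, float]:
        res = self.simulate(flat)
        if self.check_balance:
            self.last_balance = float(
                np.max(np.abs(model.mass_balance(res))) / max(res.params.dose_total, 1e-300)
            )
        return metrics_mod.extract_metrics(res, self.registry).values


@dataclass
class BatchResult:
    """Per-row metric records of a design run; failures recorded, not raised."""

    design: DesignMatrix
    metrics: pd.DataFrame  # one row per design row (NaN where failed)
    balance: np.ndarray  # worst relative mass-balance residual per run
    errors: dict[int, str] = field(default_factory=dict)

    @property
    def balance_ok(self) -> np.ndarray:
        return self.balance < 1e-6


def run_batch(
    design: DesignMatrix,
    evaluator: Callable[[Mapping[str, float]], dict[str, float]] | None = None,
    scen: ExposureScenario | None = None,
    **eval_kwargs,
) -> BatchResult:
    """One simulation per design row, in row order; failures are recorded
    per row and the batch continues."""
    evaluator = evaluator or PBPKEvaluator(scen=scen, **eval_kwargs)
    records: list[dict[str, float]] = []
    balance = np.full(design.n_runs, np.nan)
    errors: dict[int, str] = {}
    for i in range(design.n_runs):
        try:
            rec = dict(evaluator(design.row(i)))
            if getattr(evaluator, "last_balance", None) is not None:
                balance[i] = evaluator.last_balance
        except Exception as exc:  # failure of one run must not kill the batch
            rec = {}
            errors[i] = f"{type(exc).__name__}: {exc}"
        records.append(rec)
    return BatchResult(design, pd.DataFrame(records), balance, errors)


# ---------------------------------------------------------------------------
# Morris elementary effects


@dataclass
class MorrisResult:
    mu_star: pd.DataFrame  # parameters x metrics, >= 0
    sigma: pd.DataFrame
    n_evaluations: int
    design: DesignMatrix


def morris_screen(
    priors: Mapping[str, PriorSpec],
    r: int = 5,
    levels: int = 8,
    seed: int = 0,
    evaluator: Callable[[Mapping[str, float]], dict[str, float]] | None = None,
    scen: ExposureScenario | None = None,
) -> MorrisResult:
    """Elementary-effects screening with ``r`` trajectories on a
    ``levels``-level grid (r*(k+1) model evaluations for k parameters).

    mu* is the mean absolute elementary effect per metric (overall
    influence), sigma their standard deviation (non-linearity/interaction).
    """
    if r < 2:
        raise ValueError("need at least two trajectories")
    rng = np.random.default_rng(seed)
    names = list(priors)
    k = len(names)
    delta = levels / (2.0 * (levels - 1))
    base_levels = np.arange(levels // 2) / (levels - 1)  # grid points with room for +delta

    unit_rows: list[np.ndarray] = []
    for _ in range(r):
        x = base_levels[rng.integers(0, len(base_levels), size=k)].astype(float)
        signs = np.where(rng.uniform(size=k) < 0.5, -1.0, 1.0)
        # start each coordinate where the signed step stays inside [0, 1]
        for j in range(k):
            if signs[j] < 0:
                x[j] = x[j] + delta  # mirror: step down from the upper half
        order = rng.permutation(k)
        unit_rows.append(x.copy())
        for j in order:
            x = x.copy()
            x[j] = x[j] + signs[j] * delta
            unit_rows.append(x)
    unit = np.vstack(unit_rows)
    vals = np.column_stack([priors[name].ppf(np.clip(unit[:, j], 0, 1)) for j, name in enumerate(names)])
    design = DesignMatrix(names, vals, "Morris", seed, unit_values=unit)

    evaluator = evaluator or PBPKEvaluator(scen=scen)
    ys: list[dict[str, float]] = [dict(evaluator(design.row(i))) for i in range(design.n_runs)]
    metric_names = list(ys[0].keys())

    ee: dict[str, dict[str, list[float]]] = {m: {n: [] for n in names} for m in metric_names}
    row = 0
    for _ in range(r):
        for step in range(k):
            before, after = ys[row + step], ys[row + step + 1]
            j = int(np.argmax(np.abs(unit[row + step + 1] - unit[row + step])))
            d = unit[row + step + 1, j] - unit[row + step, j]
            for m in metric_names:
                ee[m][names[j]].append((after[m] - before[m]) / d)
        row += k + 1

    mu_star = pd.DataFrame(
        {m: [float(np.mean(np.abs(ee[m][n]))) for n in names] for m in metric_names}, index=names
    )
    sigma = pd.DataFrame(
        {m: [float(np.std(ee[m][n], ddof=1)) for n in names] for m in metric_names}, index=names
    )
    if (mu_star.to_numpy().max(axis=0) == 0).any():
        import warnings

        warnings.warn("at least one metric is constant across the Morris design")
    return MorrisResult(mu_star, sigma, design.n_runs, design)


def retain_parameters(
    result: MorrisResult, frac: float = 0.2, mode: str = "relative"
) -> list[str]:
    """Parameters retained for the variance-based phase.

    ``relative`` (default): mu* within ``frac`` of the per-metric maximum,
    i.e. mu* >= (1 - frac) * max mu*; ``absolute``: mu*, normalised by the
    per-metric maximum, within ``frac`` of 1.  The union over all metrics
    is returned in registry order.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    keep: set[str] = set()
    for m in result.mu_star.columns:
        col = result.mu_star[m]
        top = col.max()
        if top <= 0:
            continue
        if mode == "relative":
            keep |= set(col.index[col >= (1.0 - frac) * top])
        else:
            keep |= set(col.index[col / top >= 1.0 - frac])
    return [n for n in result.mu_star.index if n in keep]


# ---------------------------------------------------------------------------
# eFAST


@dataclass
class EFASTResult:
    Si: pd.DataFrame  # parameters x metrics, first-order indices
    STi: pd.DataFrame  # total indices
    n_evaluations: int


def efast(
    priors: Mapping[str, PriorSpec],
    runs_per_param: int = 1000,
    seed: int = 0,
    M: int = 4,
    evaluator: Callable[[Mapping[str, float]], dict[str, float]] | None = None,
    scen: ExposureScenario | None = None,
) -> EFASTResult:
    """Extended FAST first-order (Si) and total (STi) indices.

    For each parameter in turn a search curve of ``runs_per_param`` points
    assigns it the highest frequency and spreads the complementary set over
    low frequencies; Si reads the variance at the driven frequency's first
    M harmonics, STi the complement of the low-frequency variance.  Total
    cost is n_params * runs_per_param model evaluations.
    """
    names = list(priors)
    k = len(names)
    if k < 3:
        raise ValueError("eFAST needs at least 3 parameters for frequency assignment")
    Ns = runs_per_param
    omega_max = (Ns - 1) // (2 * M)
    if omega_max < 2 * M:
        raise ValueError(
            f"runs_per_param={Ns} too small for interference factor M={M}; "
            f"need at least {4 * M * M + 1}"
        )
    rng = np.random.default_rng(seed)
    evaluator = evaluator or PBPKEvaluator(scen=scen)

    omega_comp_max = max(1, omega_max // (2 * M))
    s = (2.0 * np.pi / Ns) * np.arange(Ns) - np.pi  # Ns points over (-pi, pi]

    Si_cols: dict[str, dict[str, float]] = {}
    STi_cols: dict[str, dict[str, float]] = {}
    n_eval = 0
    for i, driven in enumerate(names):
        freqs = np.empty(k, dtype=int)
        freqs[i] = omega_max
        others = [j for j in range(k) if j != i]
        freqs[others] = 1 + (np.arange(k - 1) % omega_comp_max)
        phase = rng.uniform(0, 2 * np.pi, size=k)
        unit = 0.5 + (1.0 / np.pi) * np.arcsin(np.sin(freqs[None, :] * s[:, None] + phase[None, :]))
        unit = np.clip(unit, 0.0, 1.0)
        vals = np.column_stack([priors[n].ppf(unit[:, j]) for j, n in enumerate(names)])
        ys: dict[str, np.ndarray] = {}
        for row in range(Ns):
            rec = evaluator(dict(zip(names, vals[row])))
            n_eval += 1
            for m, v in rec.items():
                ys.setdefault(m, np.empty(Ns))[row] = v
        for m, y in ys.items():
            F = np.fft.fft(y)
            spec = (np.abs(F[1 : (Ns + 1) // 2]) / Ns) ** 2  # one-sided power, freq 1..(Ns-1)//2
            V = 2.0 * spec.sum()
            Di = 2.0 * sum(spec[p * omega_max - 1] for p in range(1, M + 1))
            Dlo = 2.0 * spec[: omega_max // 2].sum()  # frequencies <= omega_max/2
            Si_cols.setdefault(m, {})[driven] = Di / V if V > 0 else 0.0
            STi_cols.setdefault(m, {})[driven] = 1.0 - Dlo / V if V > 0 else 0.0

    metric_names = list(Si_cols)
    Si = pd.DataFrame({m: [Si_cols[m][n] for n in names] for m in metric_names}, index=names)
    STi = pd.DataFrame({m: [STi_cols[m][n] for n in names] for m in metric_names}, index=names)
    return EFASTResult(Si, STi, n_eval)
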