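"""Summary tables and figures assembled from stage outputs.

Reads whatever artifacts earlier pipeline stages wrote into a results
directory and emits a compact report: the parameter table with defaults
and priors, uncertainty fans, mu*-sigma screening scatters, calibration
summary tables and fit-plus-credible-band figures, and the hepatic-only
versus lymph-only route comparison.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import model
from .parameters import ExposureScenario, default_flat, default_priors, build_subject_from_flat

__all__ = ["parameter_table", "route_comparison", "write_report"]


def parameter_table() -> pd.DataFrame:
    """Defaults and prior distributions in one greppable table."""
    flat = default_flat()
    priors = default_priors()
    rows = []
    for name, value in flat.items():
        spec = priors.get(name)
        rows.append(
            {
                "parameter": name,
                "default": value,
                "distribution": f"{spec.kind}{spec.args}" if spec else "-",
            }
        )
    return pd.DataFrame(rows)


def route_comparison(
    flat: dict[str, float] | None = None,
    scen: ExposureScenario | None = None,
    engine: str = "adaptive",
) -> dict[str, model.SimulationResult]:
    """Simulations with the lymphatic or the hepatic dose fraction zeroed.

    The hepatic-only run shows the sharp, recirculation-marked urinary
    peaks; the lymph-only run only a shallow peak with a long tail.
    """
    flat = dict(flat or {})
    scen = scen or ExposureScenario(dose=0.717, BW=83.0)
    out = {}
    for label, kill in (("hepatic_only", "FracDOSELymph"), ("lymph_only", "FracDOSEHep")):
        f = dict(flat)
        f[kill] = 0.0
        out[label] = model.simulate(build_subject_from_flat(f, scen), scen, engine=engine)
    return out


def _fig_route(results: dict[str, model.SimulationResult], path: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    colors = {"hepatic_only": "k", "lymph_only": "tab:blue"}
    for label, res in results.items():
        axes[0].plot(res.t, res.cblood_dphp, colors[label], label=label)
        axes[1].plot(res.t, res.rurine_oh, colors[label], label=label)
    axes[0].set(xlabel="time (h)", ylabel="blood DPHP (mg/L)")
    axes[1].set(xlabel="time (h)", ylabel="urinary OH-MPHP (mg/h)")
    axes[1].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(results_dir: str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Assemble tables/figures from whatever stage outputs are present."""
    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir else results_dir / "report"
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    notes: list[str] = []

    p = out_dir / "parameter_table.csv"
    parameter_table().to_csv(p, index=False)
    written.append(p)

    traj = results_dir / "uncertainty_trajectories.csv"
    if traj.exists():
        df = pd.read_csv(traj)
        fig, ax = plt.subplots(figsize=(6, 4))
        for run, grp in df[df.variable == "RUrine_OH"].groupby("run"):
            ax.plot(grp.time_h, grp.value, color="tab:blue", alpha=0.15, lw=0.8)
        ax.set(xlabel="time (h)", ylabel="urinary OH-MPHP (mg/h)", title="uncertainty fan")
        f = out_dir / "uncertainty_fan.png"
        fig.tight_layout(); fig.savefig(f, dpi=120); plt.close(fig)
        written.append(f)
    else:
        notes.append("uncertainty outputs absent; fan figure omitted")

    mu = results_dir / "morris_mu_star.csv"
    sg = results_dir / "morris_sigma.csv"
    if mu.exists() and sg.exists():
        mu_df = pd.read_csv(mu, index_col=0)
        sg_df = pd.read_csv(sg, index_col=0)
        metric = mu_df.columns[0]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(mu_df[metric], sg_df[metric], s=12)
        top = mu_df[metric].nlargest(8)
        for name in top.index:
            ax.annotate(name, (mu_df.loc[name, metric], sg_df.loc[name, metric]), fontsize=7)
        ax.set(xlabel="mu*", ylabel="sigma", title=metric)
        f = out_dir / "morris_scatter.png"
        fig.tight_layout(); fig.savefig(f, dpi=120); plt.close(fig)
        written.append(f)
    else:
        notes.append("screening outputs absent; mu*-sigma scatter omitted")

    summ = results_dir / "posterior_summary.csv"
    if summ.exists():
        df = pd.read_csv(summ)
        df["posterior median (95% credible interval)"] = [
            f"{m:.3g} ({lo:.3g}, {hi:.3g})" for m, lo, hi in zip(df["median"], df["ci_lo"], df["ci_hi"])
        ]
        f = out_dir / "calibration_table.csv"
        df[["parameter", "posterior median (95% credible interval)"]].to_csv(f, index=False)
        written.append(f)
    else:
        notes.append("calibration outputs absent; posterior table omitted")

    routes = route_comparison()
    f = out_dir / "route_comparison.png"
    _fig_route(routes, f)
    written.append(f)

    (out_dir / "README.txt").write_text(
        "report artifacts\n================\n"
        + "\n".join(str(w.name) for w in written)
        + ("\n\nomitted sections:\n" + "\n".join(notes) if notes else "")
        + "\n"
    )
    written.append(out_dir / "README.txt")
    return written
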