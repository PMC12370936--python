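"""Reproduction harness: presets, seeding, manifests and figure regeneration.

Each experiment id maps to a callable that runs the corresponding pipeline
at either ``paper`` scale (the agent counts of the original study) or
``desk`` scale (reduced counts that keep a workstation run tractable; the
CNN here is pure numpy, so even desk-scale ANN grids take hours — see
docs/methods.md).  Every run writes tidy CSV results, a figure and a JSON
manifest recording the configuration, the seed ledger and the artifacts.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .dual_module import Hyperparams
from .pathways import classify, fit_inflection, logistic, summarize_cell
from .protocols import (ProbeSchedule, run_intermediate, run_phases,
                        run_reversal, trajectories_frame)
from . import reduced as rm

FIGURES = ("fig2", "fig4", "fig5a", "fig5b", "fig6", "fig7", "fig8")

# agent counts / grids per scale; "paper" follows the original study,
# "desk" is the reduced preset
PRESETS = {
    "fig2": {"paper": {"n_agents": 100, "alphas": [0.1, 0.2, 0.3, 0.4, 0.5,
                                                   0.6, 0.7, 0.8, 0.9, 1.0]},
             "desk": {"n_agents": 5, "alphas": [0.1, 0.5, 1.0]}},
    "fig4": {"paper": {"n_agents": 100}, "desk": {"n_agents": 2}},
    "fig5a": {"paper": {"n_agents": 100,
                        "alphas": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8]},
              "desk": {"n_agents": 20,
                       "alphas": [0.15, 0.25, 0.3, 0.35, 0.4, 0.5, 0.8]}},
    "fig5b": {"paper": {"n_agents": 50,
                        "grid": [0.25, 0.5, 0.75, 1.0, 1.5, 2.0]},
              "desk": {"n_agents": 10, "grid": [0.25, 0.5, 1.0, 2.0]}},
    "fig6": {"paper": {"n_agents": 50,
                       "alphas": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8],
                       "betas": [-0.8, -0.4, -0.1, 0.1, 0.4, 0.8]},
             "desk": {"n_agents": 10, "alphas": [0.15, 0.25, 0.35, 0.5],
                      "betas": [-0.4, -0.1, 0.1, 0.4]}},
}


def _manifest(out_dir: Path, figure: str, scale: str, seed: int,
              config: dict, artifacts: list[str], t0: float) -> None:
    man = {"figure": figure, "scale": scale, "base_seed": seed,
           "config": config, "artifacts": sorted(artifacts),
           "version": __version__, "runtime_s": round(time.time() - t0, 1)}
    (out_dir / f"{figure}_manifest.json").write_text(json.dumps(man, indent=2))


def reproduce(figure: str, scale: str = "desk", out_dir="results",
              base_seed: int = 0, hyper: Hyperparams | None = None,
              side: int = 224, n_pairs: int = 160) -> dict:
    """Re-run the experiment behind one figure and write its artifacts."""
    if figure not in FIGURES:
        raise ValueError(f"unknown figure id {figure!r}; choose from {FIGURES}")
    if scale not in ("paper", "desk"):
        raise ValueError("scale must be 'paper' or 'desk'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hyper = hyper or Hyperparams()
    t0 = time.time()
    fn = globals()[f"_run_{figure}"]
    summary = fn(out, scale, base_seed, hyper, side, n_pairs)
    _manifest(out, figure, scale, base_seed, summary.pop("_config"),
              summary.pop("_artifacts"), t0)
    return summary


# ---------------------------------------------------------------------------
# ANN experiments
# ---------------------------------------------------------------------------

def _run_fig2(out, scale, seed, hyper, side, n_pairs):
    cfg = PRESETS["fig2"][scale]
    frames, final = [], []
    for alpha in cfg["alphas"]:
        trajs = run_phases([alpha], cfg["n_agents"], hyper, base_seed=seed,
                           side=side, n_pairs=n_pairs,
                           schedule=ProbeSchedule(dense_until_pairs=n_pairs,
                                                  every_batches=1))
        df = trajectories_frame(trajs)
        df["alpha"] = alpha
        frames.append(df)
        final.append({"alpha": alpha,
                      "accuracy": df[df.pairs_seen == df.pairs_seen.max()]
                      .accuracy.mean()})
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(out / "fig2_trajectories.csv", index=False)
    pd.DataFrame(final).to_csv(out / "fig2_final_accuracy.csv", index=False)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for alpha, sub in df.groupby("alpha"):
        curve = sub.groupby("pairs_seen").accuracy.mean()
        axes[0].plot(curve.index, curve.values, label=f"α={alpha}")
    axes[0].set(xlabel="image pairs", ylabel="test accuracy")
    axes[0].legend(fontsize=7)
    axes[1].plot([f["alpha"] for f in final], [f["accuracy"] for f in final],
                 "o-")
    axes[1].set(xlabel="α", ylabel="final accuracy", ylim=(0.4, 1.02))
    fig.tight_layout()
    fig.savefig(out / "fig2.png", dpi=150)
    plt.close(fig)
    return {"final_accuracy": final, "_config": cfg,
            "_artifacts": ["fig2.png", "fig2_trajectories.csv",
                           "fig2_final_accuracy.csv"]}


def _run_fig4(out, scale, seed, hyper, side, n_pairs):
    cfg = PRESETS["fig4"][scale]
    frames = []
    for alpha in (0.8, 0.2):
        trajs = run_reversal(alpha, alpha, cfg["n_agents"], hyper,
                             base_seed=seed, side=side, n_pairs=n_pairs)
        df = trajectories_frame(trajs)
        df["alpha"] = alpha
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(out / "fig4_trajectories.csv", index=False)

    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    for col, alpha in enumerate((0.8, 0.2)):
        sub = df[df.alpha == alpha]
        acc = sub.dropna(subset=["accuracy"]).groupby("pairs_seen")
        axes[0, col].plot(acc.accuracy.mean().index, acc.accuracy.mean().values)
        axes[0, col].axvline(n_pairs, ls="--", c="gray")
        axes[0, col].set(title=f"α={alpha}", xlabel="image pairs",
                         ylabel="accuracy")
        one = sub[sub.agent_seed == sub.agent_seed.min()]
        axes[1, col].plot(one.pairs_seen, one.theta, "b-", label="θ")
        probed = one.dropna(subset=["mean_dz"])
        axes[1, col].plot(probed.pairs_seen, probed.mean_dz, "r.-",
                          label="ΔZ")
        axes[1, col].axvline(n_pairs, ls="--", c="gray")
        axes[1, col].legend()
    fig.tight_layout()
    fig.savefig(out / "fig4.png", dpi=150)
    plt.close(fig)
    return {"_config": cfg,
            "_artifacts": ["fig4.png", "fig4_trajectories.csv"]}


def reversal_fractions(alphas, n_agents, hyper, base_seed=0, side=224,
                       n_pairs=160, symmetric=True, alpha2=None):
    """Relational fractions over an α grid of (symmetric) reversals."""
    rows = []
    for i, alpha in enumerate(alphas):
        a2 = alpha if symmetric else alpha2
        trajs = run_reversal(alpha, a2, n_agents, hyper,
                             base_seed=base_seed + 1000 * i, side=side,
                             n_pairs=n_pairs)
        cell = summarize_cell([classify(t) for t in trajs])
        cell["alpha"] = alpha
        rows.append(cell)
    return pd.DataFrame(rows)


def _run_fig5a(out, scale, seed, hyper, side, n_pairs):
    cfg = PRESETS["fig5a"][scale]
    cells = reversal_fractions(cfg["alphas"], cfg["n_agents"], hyper,
                               base_seed=seed, side=side, n_pairs=n_pairs)
    cells.to_csv(out / "fig5a_cells.csv", index=False)
    fit = fit_inflection(cells.alpha, cells.fraction)
    (out / "fig5a_fit.json").write_text(json.dumps(
        {"c": fit.c, "d": fit.d, "se_d": fit.se_d, "ci95_d": fit.ci95_d},
        indent=2))

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.errorbar(cells.alpha, cells.fraction,
                yerr=[cells.fraction - cells.ci_lo,
                      cells.ci_hi - cells.fraction], fmt="ko", capsize=3)
    aa = np.linspace(min(cells.alpha), max(cells.alpha), 200)
    ax.plot(aa, fit(aa), "g-", label=f"ᾱ = {fit.d:.2f} ± {fit.ci95_d:.2f}")
    ax.set(xlabel="α", ylabel="fraction relational")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "fig5a.png", dpi=150)
    plt.close(fig)
    return {"d": fit.d, "ci95_d": fit.ci95_d, "_config": cfg,
            "_artifacts": ["fig5a.png", "fig5a_cells.csv", "fig5a_fit.json"]}


def _run_fig5b(out, scale, seed, hyper, side, n_pairs):
    cfg = PRESETS["fig5b"][scale]
    grid = cfg["grid"]
    rows = []
    for i, a1 in enumerate(grid):
        for j, a2 in enumerate(grid):
            trajs = run_reversal(a1, a2, cfg["n_agents"], hyper,
                                 base_seed=seed + 10_000 * i + 100 * j,
                                 side=side, n_pairs=n_pairs)
            cell = summarize_cell([classify(t) for t in trajs])
            cell.update({"alpha_1": a1, "alpha_2": a2})
            rows.append(cell)
    cells = pd.DataFrame(rows)
    cells.to_csv(out / "fig5b_cells.csv", index=False)

    fig, ax = plt.subplots(figsize=(4.5, 3.8))
    sc = ax.scatter(cells.alpha_1, cells.alpha_2, c=cells.fraction,
                    cmap="coolwarm_r", vmin=0, vmax=1, s=120,
                    marker="s", edgecolor="k")
    xs = np.linspace(min(grid), max(grid), 100)
    ax.plot(xs, 1.0 / xs, "k-", lw=1, label="α₁α₂ = 1")
    ax.set(xlabel="α₁", ylabel="α₂")
    fig.colorbar(sc, label="fraction relational")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "fig5b.png", dpi=150)
    plt.close(fig)
    return {"_config": cfg,
            "_artifacts": ["fig5b.png", "fig5b_cells.csv"]}


def _run_fig6(out, scale, seed, hyper, side, n_pairs):
    cfg = PRESETS["fig6"][scale]
    rows = []
    for bi, beta in enumerate(cfg["betas"]):
        for ai, alpha in enumerate(cfg["alphas"]):
            trajs = run_intermediate(alpha, beta, cfg["n_agents"], hyper,
                                     base_seed=seed + 10_000 * bi + 100 * ai,
                                     side=side, n_pairs=n_pairs)
            cell = summarize_cell([classify(t) for t in trajs])
            cell.update({"alpha": alpha, "beta": beta})
            rows.append(cell)
    cells = pd.DataFrame(rows)
    cells.to_csv(out / "fig6_cells.csv", index=False)
    fits = []
    for beta, sub in cells.groupby("beta"):
        try:
            fit = fit_inflection(sub.alpha, sub.fraction)
            fits.append({"beta": beta, "d": fit.d, "ci95_d": fit.ci95_d})
        except ValueError as err:
            fits.append({"beta": beta, "d": np.nan, "error": str(err)})
    pd.DataFrame(fits).to_csv(out / "fig6_inflections.csv", index=False)

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ok = [f for f in fits if np.isfinite(f.get("d", np.nan))]
    ax.plot([f["beta"] for f in ok], [f["d"] for f in ok], "o-")
    ax.set(xlabel="intermediate rule β", ylabel="ᾱ")
    fig.tight_layout()
    fig.savefig(out / "fig6.png", dpi=150)
    plt.close(fig)
    return {"fits": fits, "_config": cfg,
            "_artifacts": ["fig6.png", "fig6_cells.csv",
                           "fig6_inflections.csv"]}


# ---------------------------------------------------------------------------
# reduced-model figures (fast on any scale)
# ---------------------------------------------------------------------------

def _phase_portrait(ax, alpha, lam=rm.DEFAULT_LAMBDA, r_sq=rm.DEFAULT_R_SQ):
    params = rm.ReducedParams(alpha=alpha, lambda_reg=lam, r_sq=r_sq)
    lim = 1.8 * params.r
    g = np.linspace(-lim, lim, 25)
    DZ, TH = np.meshgrid(g, g)
    U, V = rm.flow((DZ, TH), params)
    ax.streamplot(g, g, U, V, color="0.8", density=1.0, linewidth=0.6)
    fine = np.linspace(-lim, lim, 400)
    FZ, FT = np.meshgrid(fine, fine)
    U2, V2 = rm.flow((FZ, FT), params)
    ax.contour(fine, fine, U2, levels=[0], colors="tab:blue", linewidths=1)
    ax.contour(fine, fine, V2, levels=[0], colors="tab:red", linewidths=1)
    res = rm.integrate(rm.reversal_start(params.r), params)
    ax.plot(res.states[0], res.states[1], "k-", lw=2)
    ax.plot(*rm.reversal_start(params.r), "o", c="gold", mec="k", ms=8)
    for fp in rm.find_fixed_points(params):
        marker = "o" if fp.stability == "stable" else "x"
        ax.plot(fp.delta_z, fp.theta, marker, c="k", ms=7)
    ax.set(title=f"α = {alpha}", xlabel="ΔZ", ylabel="θ",
           xlim=(-lim, lim), ylim=(-lim, lim))


def _run_fig7(out, scale, seed, hyper, side, n_pairs):
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, alpha in zip(axes, (2.0, 0.5)):
        _phase_portrait(ax, alpha)
    fig.tight_layout()
    fig.savefig(out / "fig7.png", dpi=150)
    plt.close(fig)
    return {"_config": {"alphas": [2.0, 0.5],
                        "lambda": rm.DEFAULT_LAMBDA, "r_sq": rm.DEFAULT_R_SQ},
            "_artifacts": ["fig7.png"]}


def _run_fig8(out, scale, seed, hyper, side, n_pairs):
    lam, r_sq = rm.DEFAULT_LAMBDA, rm.DEFAULT_R_SQ
    r = float(np.sqrt(r_sq))
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.8))
    # a: same α₂, different starting ratios;  b: same start, different α₂
    for a1, a2, c in ((2.0, 1.0, "tab:blue"), (0.5, 1.0, "tab:red")):
        res = rm.integrate(rm.reversal_start(r, a1, a2),
                           rm.ReducedParams(a2, lam, r_sq))
        axes[0].plot(res.states[0], res.states[1], c=c,
                     label=f"α₁={a1}, α₂={a2}")
    for a, c in ((0.5, "tab:blue"), (2.0, "tab:red")):
        res = rm.integrate(rm.reversal_start(r, a, a),
                           rm.ReducedParams(a, lam, r_sq))
        axes[1].plot(res.states[0], res.states[1], c=c, label=f"α₁=α₂={a}")
    for ax in axes[:2]:
        ax.axhline(0, c="0.8")
        ax.axvline(0, c="0.8")
        ax.set(xlabel="ΔZ", ylabel="θ")
        ax.legend(fontsize=7)
    # c: pathway map with boundary
    grid = np.linspace(0.25, 4.0, 16)
    labels = rm.pathway_map(grid, grid, lambda_reg=lam, r_sq=r_sq)
    k, a2s = rm.boundary_fit(grid, lambda_reg=lam, r_sq=r_sq)
    colors = {"relational": 0.0, "representational": 1.0, "nonconverged": 0.5}
    img = np.vectorize(colors.get)(labels)
    axes[2].pcolormesh(grid, grid, img, cmap="coolwarm", shading="nearest")
    xs = np.linspace(0.25, 4, 200)
    axes[2].plot(xs, 1.0 / xs, "k-", label="α₁α₂ = 1")
    axes[2].plot(grid, a2s, "g--", label=f"empirical (k={k:.3f})")
    axes[2].set(xlabel="α₁", ylabel="α₂", ylim=(0.25, 4))
    axes[2].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "fig8.png", dpi=150)
    plt.close(fig)
    np.savetxt(out / "fig8c_boundary.csv",
               np.column_stack([grid, a2s]), delimiter=",",
               header="alpha_1,boundary_alpha_2", comments="")
    return {"boundary_k": k, "_config": {"grid": grid.tolist(),
                                         "lambda": lam, "r_sq": r_sq},
            "_artifacts": ["fig8.png", "fig8c_boundary.csv"]}
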