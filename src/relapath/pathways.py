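"""Adaptation-pathway classification and the logistic inflection estimate.

After a rule reversal the stimulus order flips, so the probe ΔZ flips sign
immediately while θ is continuous.  The learner can resolve the resulting
mismatch in two ways: flip θ to match the new ΔZ (*relational* adaptation)
or re-learn the encoder so ΔZ returns to its pre-reversal sign
(*representational* adaptation).  Classification compares the end of the
first phase with the end of the final phase; the ΔZ reference is the
post-reversal sign, i.e. minus the end-of-phase-1 probe mean.  Agents in
which θ and ΔZ kept or flipped sign together are excluded — those networks
necessarily fail the task.

The fraction of relational adapters as a function of α is summarized by the
two-parameter logistic 1 / (1 + exp(c (α − d))); the inflection point
ᾱ = d marks the crossover between the two pathways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import beta as beta_dist

from .protocols import Trajectory

SIGN_DEAD_ZONE = 1e-6   # |x| below this has no usable sign

__all__ = ["PathwayOutcome", "LogisticFit", "classify", "relational_fraction",
           "fit_inflection", "logistic", "binomial_ci"]


@dataclass(frozen=True)
class PathwayOutcome:
    label: str               # relational | representational | excluded
    theta_before: float
    theta_after: float
    dz_before: float         # post-reversal reference (−ΔZ at end of phase 1)
    dz_after: float          # probe mean at end of final phase
    dead_zone_hit: bool = False
    flagged_failed: bool = False


def _kept(before: float, after: float) -> bool:
    # sign kept only when both values carry a usable sign
    if abs(before) < SIGN_DEAD_ZONE or abs(after) < SIGN_DEAD_ZONE:
        return False
    return np.sign(before) == np.sign(after)


def classify(traj: Trajectory) -> PathwayOutcome:
    """Label one agent's adaptation pathway from its trajectory.

    Requires at least two phases; compares end-of-first-phase with
    end-of-final-phase.
    """
    if traj.n_phases < 2:
        raise ValueError("classification needs a trajectory with >= 2 phases")
    first = traj.phase_end(0)
    last = traj.phase_end(traj.n_phases - 1)
    if np.isnan(first.mean_dz) or np.isnan(last.mean_dz):
        raise ValueError("end-of-phase checkpoints must carry probe values")
    theta_b, theta_a = first.theta, last.theta
    # the reversal itself flips the sign of the probe ΔZ while w is unchanged
    dz_b, dz_a = -first.mean_dz, last.mean_dz

    theta_kept = _kept(theta_b, theta_a)
    dz_kept = _kept(dz_b, dz_a)
    if (not theta_kept) and dz_kept:
        label = "relational"
    elif theta_kept and not dz_kept:
        label = "representational"
    else:
        label = "excluded"
    dead = min(abs(theta_b), abs(theta_a), abs(dz_b), abs(dz_a)) < SIGN_DEAD_ZONE
    return PathwayOutcome(label=label, theta_before=theta_b,
                          theta_after=theta_a, dz_before=dz_b, dz_after=dz_a,
                          dead_zone_hit=bool(dead),
                          flagged_failed=traj.flagged_failed)


def relational_fraction(outcomes) -> float:
    """#θ / (#Z + #θ), with excluded outcomes removed from both counts."""
    n_rel = sum(1 for o in outcomes if o.label == "relational")
    n_rep = sum(1 for o in outcomes if o.label == "representational")
    if n_rel + n_rep == 0:
        raise ValueError("all outcomes excluded: empty cell")
    return n_rel / (n_rel + n_rep)


def logistic(alpha, c, d):
    """Decreasing logistic 1 / (1 + exp(c (α − d))); crosses 1/2 at α = d."""
    return 1.0 / (1.0 + np.exp(np.clip(c * (np.asarray(alpha) - d),
                                       -500, 500)))


@dataclass(frozen=True)
class LogisticFit:
    c: float        # slope parameter
    d: float        # inflection point ᾱ
    se_d: float
    ci95_d: float   # 1.96 · se(d)

    def __call__(self, alpha):
        return logistic(alpha, self.c, self.d)


def fit_inflection(alphas, fractions, n_per_cell: int | None = None,
                   c0: float = 10.0, d0: float | None = None) -> LogisticFit:
    """Least-squares logistic fit of relational fractions over α.

    The point estimate is unweighted.  When ``n_per_cell`` is given, the
    parameter covariance is recomputed with per-point binomial standard
    errors taken from the fitted curve (absolute sigma), which calibrates
    the 95% CI on d against binomial sampling noise; otherwise the plain
    residual-scaled covariance is used.

    Needs at least 4 grid points and fractions on both sides of 1/2;
    non-convergence or an absent transition raises rather than extrapolating.
    """
    alphas = np.asarray(alphas, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if alphas.size < 4:
        raise ValueError("need >= 4 grid points for the logistic fit")
    if fractions.min() > 0.5 or fractions.max() < 0.5:
        raise ValueError("fractions do not straddle 1/2: no transition to fit")
    if d0 is None:
        d0 = float(alphas.mean())
    try:
        popt, pcov = curve_fit(logistic, alphas, fractions, p0=(c0, d0),
                               maxfev=20_000)
        if n_per_cell is not None:
            ph = logistic(alphas, *popt)
            sig = np.sqrt(np.clip(ph * (1 - ph), 0.25 / n_per_cell, None)
                          / n_per_cell)
            popt, pcov = curve_fit(logistic, alphas, fractions, p0=popt,
                                   sigma=sig, absolute_sigma=True,
                                   maxfev=20_000)
    except RuntimeError as err:
        raise ValueError(f"logistic fit did not converge: {err}") from err
    se_d = float(np.sqrt(pcov[1, 1]))
    if not np.isfinite(se_d):
        raise ValueError("logistic fit is degenerate (unbounded se of d)")
    return LogisticFit(c=float(popt[0]), d=float(popt[1]), se_d=se_d,
                       ci95_d=1.96 * se_d)


def binomial_ci(k: int, n: int, level: float = 0.95):
    """Equal-tailed Jeffreys interval for a per-cell binomial fraction."""
    if n == 0:
        raise ValueError("empty cell")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    lo = 0.0 if k == 0 else float(beta_dist.ppf(lo_q, k + 0.5, n - k + 0.5))
    hi = 1.0 if k == n else float(beta_dist.ppf(hi_q, k + 0.5, n - k + 0.5))
    return lo, hi


def summarize_cell(outcomes) -> dict:
    """Per-cell summary: counts, relational fraction and its binomial CI.

    An all-excluded cell is reported with a NaN fraction rather than raised,
    so grid summaries stay total.
    """
    outcomes = list(outcomes)
    n_rel = sum(1 for o in outcomes if o.label == "relational")
    n_rep = sum(1 for o in outcomes if o.label == "representational")
    n_exc = sum(1 for o in outcomes if o.label == "excluded")
    if n_rel + n_rep:
        frac = relational_fraction(outcomes)
        lo, hi = binomial_ci(n_rel, n_rel + n_rep)
    else:
        frac = lo = hi = float("nan")
    return {"n": len(outcomes), "n_relational": n_rel,
            "n_representational": n_rep, "n_excluded": n_exc,
            "fraction": frac, "ci_lo": lo, "ci_hi": hi}
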