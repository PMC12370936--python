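"""Reduced scalar model: gradient flow in the (ΔZ, θ) plane.

Replacing images by scalars x, x' with x' − x = α and the encoder by a
single weight (Z(x) = w x, so ΔZ = w α) turns learning into the gradient
flow of

    L(ΔZ, θ) = (ΔZ − θ)² + λ (ΔZ² + θ² − r²)²

with the α²-anisotropic metric

    dΔZ/dt = α² [ (θ − ΔZ) − 2λ (ΔZ² + θ² − r²) ΔZ ]
    dθ/dt  =      (ΔZ − θ) − 2λ (ΔZ² + θ² − r²) θ .

Fixed points: the origin (unstable), ±(r/√2, r/√2) (the two attractors),
and — only when λ > 1/r² — an unstable anti-diagonal pair
ΔZ = −θ = ±√((r² − 1/λ)/2).  With λ = 0 the flow is confined to lines
ΔZ + α²θ = const (a line attractor), which yields closed forms for the
post-reversal endpoint and the α₁α₂ = 1 pathway boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["ReducedParams", "FixedPoint", "flow", "jacobian", "reduced_loss",
           "integrate", "line_attractor_point", "general_endpoint",
           "find_fixed_points", "predict_pathway", "pathway_map",
           "symmetric_inflection", "reversal_start"]

DEFAULT_LAMBDA = 0.1   # weak-regularization reference configuration
DEFAULT_R_SQ = 0.1
BOUNDARY_BAND = 0.02   # |α₁α₂ − 1| below this is called "boundary"


@dataclass(frozen=True)
class ReducedParams:
    alpha: float
    lambda_reg: float = DEFAULT_LAMBDA
    r_sq: float = DEFAULT_R_SQ

    def __post_init__(self):
        if self.r_sq <= 0 or self.lambda_reg < 0:
            raise ValueError("need r_sq > 0 and lambda_reg >= 0")

    @property
    def r(self) -> float:
        return float(np.sqrt(self.r_sq))


@dataclass(frozen=True)
class FixedPoint:
    delta_z: float
    theta: float
    stability: str   # "stable" | "unstable"


def flow(state, params: ReducedParams) -> np.ndarray:
    """(dΔZ/dt, dθ/dt) at a point; vectorized over trailing dimensions."""
    dz, th = np.asarray(state[0], float), np.asarray(state[1], float)
    lam, a2 = params.lambda_reg, params.alpha ** 2
    ring = dz * dz + th * th - params.r_sq
    return np.array([a2 * ((th - dz) - 2.0 * lam * ring * dz),
                     (dz - th) - 2.0 * lam * ring * th])


def jacobian(state, params: ReducedParams) -> np.ndarray:
    dz, th = float(state[0]), float(state[1])
    lam, a2 = params.lambda_reg, params.alpha ** 2
    ring = dz * dz + th * th - params.r_sq
    return np.array([
        [a2 * (-1.0 - 2.0 * lam * (ring + 2.0 * dz * dz)),
         a2 * (1.0 - 4.0 * lam * dz * th)],
        [1.0 - 4.0 * lam * dz * th,
         -1.0 - 2.0 * lam * (ring + 2.0 * th * th)],
    ])


def reduced_loss(state, params: ReducedParams):
    dz, th = np.asarray(state[0], float), np.asarray(state[1], float)
    ring = dz * dz + th * th - params.r_sq
    return (dz - th) ** 2 + params.lambda_reg * ring ** 2


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class IntegrationResult:
    t: np.ndarray
    states: np.ndarray            # (2, n) trajectory samples
    terminal: tuple[float, float]
    converged: bool
    fixed_point: FixedPoint | None   # nearest fixed point within match_tol


def integrate(start, params: ReducedParams, horizon: float = 1e6,
              flow_tol: float = 1e-8, match_tol: float = 1e-3,
              rtol: float = 1e-9, atol: float = 1e-9) -> IntegrationResult:
    """Integrate the gradient flow until ‖flow‖ < flow_tol or the horizon.

    Horizon exhaustion without convergence is reported via ``converged``.
    """
    start = np.asarray(start, dtype=float)
    if not np.all(np.isfinite(start)):
        raise ValueError("start state must be finite")

    def rhs(_, y):
        return flow(y, params)

    def settled(_, y):
        return float(np.linalg.norm(flow(y, params))) - flow_tol

    settled.terminal = True
    settled.direction = -1
    sol = solve_ivp(rhs, (0.0, horizon), start, method="LSODA",
                    rtol=rtol, atol=atol, events=settled, dense_output=False)
    terminal = (float(sol.y[0, -1]), float(sol.y[1, -1]))
    converged = bool(sol.t_events[0].size) or \
        float(np.linalg.norm(flow(terminal, params))) < flow_tol
    fp_hit = None
    if converged:
        for fp in find_fixed_points(params):
            if np.hypot(terminal[0] - fp.delta_z,
                        terminal[1] - fp.theta) < match_tol:
                fp_hit = fp
                break
    return IntegrationResult(t=sol.t, states=sol.y, terminal=terminal,
                             converged=converged, fixed_point=fp_hit)


# ---------------------------------------------------------------------------
# closed forms (λ = 0) and fixed-point census
# ---------------------------------------------------------------------------

def line_attractor_point(dz0: float, theta0: float, alpha: float) -> float:
    """Terminal value ΔZ = θ of the unregularized flow.

    ΔZ + α²θ is conserved, so the flow lands on the ΔZ = θ line at
    (α²θ₀ + ΔZ₀) / (α² + 1).
    """
    a2 = alpha ** 2
    return (a2 * theta0 + dz0) / (a2 + 1.0)


def reversal_start(r: float, alpha_1: float = 1.0,
                   alpha_2: float = 1.0) -> tuple[float, float]:
    """State right after the rule switch +α₁ → −α₂, assuming phase-1
    convergence to the positive attractor: w* α₁ = r/√2 is unchanged while
    ΔZ is re-expressed with the new rule, so ΔZ(0) = −(r/√2)(α₂/α₁)."""
    a = r / np.sqrt(2.0)
    return (-a * alpha_2 / alpha_1, a)


def general_endpoint(alpha_1: float, alpha_2: float, r: float) -> float:
    """λ→0 endpoint on the ΔZ = θ line after +α₁ → −α₂.

    (r/√2) (α₂² − α₂/α₁) / (α₂² + 1); positive iff α₁α₂ > 1, so its sign
    predicts the winning pathway.
    """
    if alpha_1 <= 0 or alpha_2 <= 0:
        raise ValueError("rules must be positive")
    a22 = alpha_2 ** 2
    return (r / np.sqrt(2.0)) * (a22 - alpha_2 / alpha_1) / (a22 + 1.0)


def find_fixed_points(params: ReducedParams) -> list[FixedPoint]:
    """All fixed points with stability from the linearization.

    Origin and ±(r/√2)·(1, 1) always; the anti-diagonal pair
    ±√((r² − 1/λ)/2)·(1, −1) appears only for λ > 1/r².
    """
    pts = [(0.0, 0.0)]
    a = params.r / np.sqrt(2.0)
    pts += [(a, a), (-a, -a)]
    lam = params.lambda_reg
    if lam > 0 and lam > 1.0 / params.r_sq:
        q = np.sqrt((params.r_sq - 1.0 / lam) / 2.0)
        pts += [(q, -q), (-q, q)]
    out = []
    for dz, th in pts:
        eig = np.linalg.eigvals(jacobian((dz, th), params))
        stable = bool(np.all(eig.real < 0))
        out.append(FixedPoint(delta_z=dz, theta=th,
                              stability="stable" if stable else "unstable"))
    return out


# ---------------------------------------------------------------------------
# pathway prediction
# ---------------------------------------------------------------------------

def predict_pathway(alpha_1: float, alpha_2: float,
                    band: float = BOUNDARY_BAND) -> str:
    """Weak-regularization rule: representational iff α₁α₂ > 1."""
    if alpha_1 <= 0 or alpha_2 <= 0:
        raise ValueError("rules must be positive")
    prod = alpha_1 * alpha_2
    if abs(prod - 1.0) < band:
        return "boundary"
    return "representational" if prod > 1.0 else "relational"


def _terminal_label(alpha_1, alpha_2, lam, r_sq, **ikw) -> str:
    params = ReducedParams(alpha=alpha_2, lambda_reg=lam, r_sq=r_sq)
    res = integrate(reversal_start(params.r, alpha_1, alpha_2), params, **ikw)
    if not res.converged or res.fixed_point is None:
        return "nonconverged"
    th = res.fixed_point.theta
    if th > 0:
        return "representational"   # θ kept its positive sign
    if th < 0:
        return "relational"         # θ flipped
    return "nonconverged"           # settled on the origin/separatrix


def pathway_map(alphas_1, alphas_2, lambda_reg: float = DEFAULT_LAMBDA,
                r_sq: float = DEFAULT_R_SQ, **ikw):
    """Label every (α₁, α₂) cell by full integration from the
    post-reversal state; returns an (n₂, n₁) array of labels."""
    labels = np.empty((len(alphas_2), len(alphas_1)), dtype=object)
    for i, a2 in enumerate(alphas_2):
        for j, a1 in enumerate(alphas_1):
            labels[i, j] = _terminal_label(a1, a2, lambda_reg, r_sq, **ikw)
    return labels


def _boundary_alpha2(alpha_1, lam, r_sq, lo, hi, tol=1e-3) -> float:
    """Bisect the α₂ at which the terminal pathway flips, for fixed α₁."""
    lab_lo = _terminal_label(alpha_1, lo, lam, r_sq)
    lab_hi = _terminal_label(alpha_1, hi, lam, r_sq)
    if lab_lo == lab_hi or "nonconverged" in (lab_lo, lab_hi):
        raise ValueError(f"no pathway boundary in α₂ ∈ [{lo}, {hi}] "
                         f"at α₁ = {alpha_1}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lab = _terminal_label(alpha_1, mid, lam, r_sq)
        if lab == lab_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def boundary_fit(alphas_1, lambda_reg: float = DEFAULT_LAMBDA,
                 r_sq: float = DEFAULT_R_SQ, alpha2_range=(0.05, 20.0),
                 tol: float = 1e-3):
    """Locate the empirical boundary α₂*(α₁) and fit α₂ = k/α₁.

    Returns (k, boundary α₂ values).  k is the least-squares solution of
    log α₂* = log k − log α₁.
    """
    a2s = np.array([_boundary_alpha2(a1, lambda_reg, r_sq, *alpha2_range,
                                     tol=tol) for a1 in alphas_1])
    logk = float(np.mean(np.log(a2s) + np.log(alphas_1)))
    return float(np.exp(logk)), a2s


def symmetric_inflection(lambda_reg: float = DEFAULT_LAMBDA,
                         r_sq: float = DEFAULT_R_SQ,
                         bracket=(0.25, 4.0), tol: float = 1e-4) -> float:
    """The ᾱ at which the terminal sign of θ switches in the symmetric
    reversal α → −α (start (−r/√2, r/√2)), found by bisection."""
    r = float(np.sqrt(r_sq))
    start = (-r / np.sqrt(2.0), r / np.sqrt(2.0))

    def terminal_theta_sign(alpha):
        params = ReducedParams(alpha=alpha, lambda_reg=lambda_reg, r_sq=r_sq)
        res = integrate(start, params)
        return np.sign(res.terminal[1])

    lo, hi = bracket
    s_lo, s_hi = terminal_theta_sign(lo), terminal_theta_sign(hi)
    if s_lo == s_hi:
        raise ValueError("bracket does not straddle the inflection")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if terminal_theta_sign(mid) == s_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
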