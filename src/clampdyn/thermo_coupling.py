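"""Two-state thermodynamic coupling of clamp stability to constitutive
channel current.

The resting-state current density of a mutant panel is modeled as

    I0 = c0 · (1 / (1 + c1·exp(ΔG_unb/RT)))^n

where ΔG_unb is the clamp unbinding free energy, c0 sets the current scale,
c1 encodes the free-energy difference between the detached and fully open
states via ΔG_unb→open = RT·ln(c1), and n is a cooperativity exponent
(n < 1: anti-cooperative channel engagement).  The relation follows from a
Boltzmann occupancy of the open state with ΔG_quiesc→open = ΔG_unb +
ΔG_unb→open, raised to the cooperativity power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .free_energy import KB, DEFAULT_T


@dataclass(frozen=True)
class MutantPoint:
    """One mutant: unbinding free energy and resting current density."""

    label: str
    dg_unb: float          # kcal/mol
    i0: float              # pA/pF
    dg_sem: float = 0.0
    i0_sem: float = 0.0

    def __post_init__(self) -> None:
        if self.i0 < 0:
            raise ValueError("current density must be >= 0")


@dataclass(frozen=True)
class ThermoFit:
    c0: float              # pA/pF
    c1: float
    n: float
    dg_unb_to_open: float  # = RT·ln(c1), kcal/mol
    rt: float
    stderr: dict = field(default_factory=dict)  # c0, c1, n, dg_unb_to_open
    residual: float = float("nan")

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.c1 <= 0:
            raise ValueError("c0 and c1 must be positive")
        if abs(self.dg_unb_to_open - self.rt * np.log(self.c1)) > 1e-9:
            raise ValueError("dg_unb_to_open inconsistent with RT·ln(c1)")


def model_current(dg_unb, c0: float, c1: float, n: float,
                  rt: float = KB * DEFAULT_T):
    """I0 = c0·(1/(1 + c1·e^{ΔG_unb/RT}))^n."""
    if c0 <= 0 or c1 <= 0 or rt <= 0:
        raise ValueError("c0, c1, RT must be positive")
    dg_unb = np.asarray(dg_unb, float)
    out = c0 * (1.0 / (1.0 + c1 * np.exp(dg_unb / rt))) ** n
    return float(out) if out.ndim == 0 else out


def dg_unb_to_open(c1: float, rt: float = KB * DEFAULT_T) -> float:
    """Free energy from the detached to the fully open state: RT·ln(c1)."""
    if c1 <= 0:
        raise ValueError("c1 must be > 0")
    return rt * float(np.log(c1))


def fit_thermo(
    points: list[MutantPoint], rt: float = KB * DEFAULT_T,
    n_bounds: tuple[float, float] = (0.0, 5.0), weighted: bool = True,
) -> ThermoFit:
    """Weighted nonlinear least squares for (c0, c1, n).

    Optimizes in (log c0, log c1, n) to enforce positivity, with n bounded.
    Weights are 1/SEM² on I0 when all SEMs are given (and ``weighted``),
    uniform otherwise.  Multi-start over log-spaced c1 initializations; the
    best final residual wins.  Parameter standard errors come from the
    Jacobian at the optimum via the delta method.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 mutant points (3 parameters)")
    dg = np.array([p.dg_unb for p in points])
    i0 = np.array([p.i0 for p in points])
    if len(np.unique(dg)) < 4:
        raise ValueError("need at least 4 distinct ΔG_unb values")
    if np.ptp(i0) < 1e-12 * max(i0.max(), 1.0):
        raise ValueError("all currents identical: n is unidentifiable")
    sems = np.array([p.i0_sem for p in points])
    if weighted and np.all(sems > 0):
        sqrt_w = 1.0 / sems
    else:
        sqrt_w = np.ones_like(i0)

    def residuals(theta):
        log_c0, log_c1, n = theta
        pred = np.exp(log_c0) * (
            1.0 / (1.0 + np.exp(log_c1) * np.exp(dg / rt))
        ) ** n
        return sqrt_w * (pred - i0)

    lo = np.array([-np.inf, -np.inf, n_bounds[0]])
    hi = np.array([np.inf, np.inf, n_bounds[1]])
    best = None
    diagnostics = []
    for log_c1_init in np.log(np.logspace(-8, 2, 11)):
        for n_init in (0.3, 0.5, 1.0):
            x0 = np.array([np.log(max(i0.max(), 1e-6)), log_c1_init,
                           np.clip(n_init, *n_bounds)])
            try:
                sol = least_squares(residuals, x0, bounds=(lo, hi),
                                    method="trf", xtol=1e-14, ftol=1e-14,
                                    gtol=1e-14)
            except Exception as exc:  # pragma: no cover - optimizer failure
                diagnostics.append(str(exc))
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise RuntimeError(
            "thermo fit failed to converge from every start: "
            + "; ".join(diagnostics[:3])
        )

    log_c0, log_c1, n = best.x
    dof = max(len(points) - 3, 1)
    s2 = 2 * best.cost / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    stderr = {
        "c0": float(np.exp(log_c0) * se[0]),
        "c1": float(np.exp(log_c1) * se[1]),
        "n": float(se[2]),
        "dg_unb_to_open": float(rt * se[1]),
    }
    return ThermoFit(
        c0=float(np.exp(log_c0)), c1=float(np.exp(log_c1)), n=float(n),
        dg_unb_to_open=dg_unb_to_open(float(np.exp(log_c1)), rt),
        rt=rt, stderr=stderr, residual=float(best.cost),
    )


def generate_thermo_panel(
    c0: float, c1: float, n: float, dg_grid, noise_cv: float, seed: int,
    rt: float = KB * DEFAULT_T,
) -> list[MutantPoint]:
    """Synthetic mutant panel: I0 = model·(1 + ε), ε ~ N(0, noise_cv), ≥ 0."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    dg_grid = np.asarray(dg_grid, float)
    ideal = model_current(dg_grid, c0, c1, n, rt)
    noisy = np.maximum(ideal * (1.0 + noise_cv * rng.standard_normal(len(dg_grid))),
                       0.0)
    return [
        MutantPoint(label=f"m{k}", dg_unb=float(dg_grid[k]), i0=float(noisy[k]),
                    i0_sem=float(noise_cv * ideal[k]))
        for k in range(len(dg_grid))
    ]
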