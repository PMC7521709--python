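"""Operations on the linear homeostatic network: compounding, steady states,
symptoms, growth capacity, relaxation dynamics, time averaging and
therapeutic regimen design.

The model is deliberately linear — a small-perturbation expansion around the
healthy equilibrium — so steady states, symptoms and growth capacities are
exact matrix expressions and superposition holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import lsq_linear

from .errors import (DimensionError, DomainError, StabilityError, UsageError,
                     ValidationError)
from .system import (CompoundedSystem, DiseaseState, FeatureSystem,
                     GrowthSystem, Regimen, Trajectory)

__all__ = [
    "compound_potencies",
    "steady_state",
    "symptoms",
    "growth_capacity",
    "relax_dynamics",
    "time_average",
    "design_regimen",
    "DesignOptions",
    "RegimenDesign",
]


def compound_potencies(
    system: FeatureSystem,
    mode: Literal["one_pass", "self_consistent"] = "one_pass",
) -> CompoundedSystem:
    """Fold feature couplings into effective potencies and virulences.

    The default ``one_pass`` mode performs a single substitution of each
    feature's direct chemical response into its neighbours' coupling terms:
    ``nu_c = eps @ nu`` (unit diagonal included), and likewise for the
    virulences.  ``self_consistent`` instead solves the coupled linear
    response to all orders, ``nu_c = (I - eps_off)^{-1} nu`` with ``eps_off``
    the off-diagonal coupling part; the two agree to first order in the
    off-diagonal couplings.

    The true homeostatic baseline absorbs the healthy reference regimen:
    ``h = h0 - nu_c @ n_ref``.
    """
    eps, nu, delta = system.eps, system.nu, system.delta
    if mode == "one_pass":
        nu_c = eps @ nu
        delta_c = eps @ delta
    elif mode == "self_consistent":
        # I - eps_off = 2I - eps  (unit diagonal)
        M = 2.0 * np.eye(system.c) - eps
        nu_c = np.linalg.solve(M, nu)
        delta_c = np.linalg.solve(M, delta)
    else:
        raise UsageError(f"unknown compounding mode {mode!r}")
    h = system.h0 - nu_c @ system.n_ref
    return CompoundedSystem(nu_c=nu_c, delta_c=delta_c, h=h)


def _check_exposure(comp: CompoundedSystem, regimen: Regimen,
                    disease: DiseaseState | None) -> tuple[np.ndarray, np.ndarray]:
    if regimen.n_N != comp.n_N:
        raise DimensionError(
            f"regimen has {regimen.n_N} doses, system expects {comp.n_N}")
    if disease is None:
        D = np.zeros(comp.n_D)
    else:
        if disease.n_D != comp.n_D:
            raise DimensionError(
                f"disease has {disease.n_D} features, system expects {comp.n_D}")
        D = disease.D
    return regimen.N, D


def steady_state(comp: CompoundedSystem, regimen: Regimen,
                 disease: DiseaseState | None = None) -> np.ndarray:
    """Steady-state feature values ``E = h + nu_c @ N - delta_c @ D``.

    Exactly linear in both the dose vector and the disease intensities.
    """
    N, D = _check_exposure(comp, regimen, disease)
    return comp.h + comp.nu_c @ N - comp.delta_c @ D


def symptoms(comp: CompoundedSystem, regimen: Regimen,
             disease: DiseaseState | None = None) -> np.ndarray:
    """Symptoms ``S = E - h``: departure of each feature from homeostasis.

    The zero vector iff the nutritional and disease contributions cancel
    featurewise — the nutrition/disease symmetry: an unbalanced regimen can
    mimic a disease, and a suitably unbalanced regimen can cancel one.
    """
    return steady_state(comp, regimen, disease) - comp.h


def growth_capacity(gs: GrowthSystem, regimen: Regimen) -> np.ndarray:
    """Pathogen growth capacities ``G = hG + nuG_c @ N``.

    The agent is suppressed on feature ``m`` when ``G_m <= 0``.
    """
    if regimen.n_N != gs.n_N:
        raise DimensionError(
            f"regimen has {regimen.n_N} doses, growth system expects {gs.n_N}")
    return gs.hG + gs.nuG_c @ regimen.N


def relax_dynamics(system: FeatureSystem, comp: CompoundedSystem,
                   E0: np.ndarray, regimen: Regimen,
                   disease: DiseaseState | None,
                   t_grid: Sequence[float]) -> Trajectory:
    """Homeostatic relaxation of the features from an initial state.

    Each feature relaxes at its own rate toward a homeostatic target coupled
    to the other features' deviations, so the deviation ``x = E - E*`` from
    the steady state obeys the linear system ``dx/dt = -K (I - eps_off) x``
    with ``K = diag(k)``.  The trajectory is propagated exactly with the
    matrix exponential on the requested grid, anchored at the algebraic
    steady state of ``comp``, so the terminal state converges to
    :func:`steady_state` for any stable system.

    Raises
    ------
    StabilityError
        If any eigenvalue of ``K (I - eps_off)`` has non-positive real part
        (equivalently the relaxation matrix has a non-negative spectral
        abscissa); the message reports the offending bound.
    """
    E0 = np.asarray(E0, dtype=float)
    if E0.shape != (system.c,):
        raise DimensionError(f"E0 must have shape ({system.c},)")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValidationError("t_grid must be a strictly increasing 1-d grid")

    eps_off = system.eps - np.eye(system.c)
    A = -np.diag(system.k) @ (np.eye(system.c) - eps_off)
    abscissa = float(np.max(np.linalg.eigvals(A).real))
    if abscissa >= 0:
        raise StabilityError(
            "unstable relaxation dynamics: spectral abscissa of the system "
            f"matrix is {abscissa:.6g} >= 0 (spectral radius of the "
            "off-diagonal coupling part must be < 1)")

    E_star = steady_state(comp, regimen, disease)
    x0 = E0 - E_star
    E = np.empty((t.size, system.c))
    for i, ti in enumerate(t):
        E[i] = E_star + scipy.linalg.expm(A * (ti - t[0])) @ x0
    return Trajectory(t=t, E=E)


def time_average(traj: Trajectory, T: float) -> np.ndarray:
    """Trapezoidal average of each feature over the trailing window ``T``.

    The window is ``[t_end - T, t_end]``; the left edge is interpolated
    linearly if it falls between grid points.
    """
    if T <= 0:
        raise DomainError("averaging window T must be positive")
    if T > traj.span * (1 + 1e-12):
        raise DomainError(
            f"window T={T} exceeds trajectory span {traj.span}")
    t_end = traj.t[-1]
    t0 = t_end - T
    i0 = int(np.searchsorted(traj.t, t0, side="right"))
    # interpolated left edge + remaining grid points
    E0 = np.array([np.interp(t0, traj.t, traj.E[:, j])
                   for j in range(traj.E.shape[1])])
    tt = np.concatenate(([t0], traj.t[i0:]))
    EE = np.vstack([E0, traj.E[i0:]])
    return np.trapezoid(EE, tt, axis=0) / T


# ---------------------------------------------------------------------------
# Regimen design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignOptions:
    """Options for :func:`design_regimen`.

    nonneg
        Constrain doses to be nonnegative (edible amounts).  Disable to
        reproduce pure rank-style existence arguments.
    host_weight, growth_weight
        Relative least-squares weights of the host-neutrality/symptom rows
        and the growth-suppression rows.
    growth_sign
        ``"suppress"`` targets ``nuG_c @ N = -hG`` so the pathogen capacity
        is driven to zero; ``"literal"`` targets ``+hG`` (the alternative
        reading of the therapeutic condition).
    """

    nonneg: bool = True
    host_weight: float = 1.0
    growth_weight: float = 1.0
    growth_sign: Literal["suppress", "literal"] = "suppress"
    tol: float = 1e-10


@dataclass(frozen=True)
class RegimenDesign:
    """Result of a regimen design: the dose vector and an auditable residual
    report (per-row residuals of every objective block)."""

    regimen: Regimen
    host_residuals: np.ndarray
    growth_residuals: np.ndarray | None
    options: DesignOptions

    @property
    def max_residual(self) -> float:
        parts = [np.abs(self.host_residuals)]
        if self.growth_residuals is not None:
            parts.append(np.abs(self.growth_residuals))
        return float(max(p.max() if p.size else 0.0 for p in parts))

    def summary(self) -> str:
        lines = ["Regimen design",
                 "--------------",
                 f"doses (Q = {self.regimen.Q:.6g}): "
                 + np.array2string(self.regimen.N, precision=4),
                 f"host/symptom rows: {self.host_residuals.size}, "
                 f"max |residual| = {np.abs(self.host_residuals).max() if self.host_residuals.size else 0:.3e}"]
        if self.growth_residuals is not None:
            lines.append(
                f"growth rows: {self.growth_residuals.size}, "
                f"max |residual| = {np.abs(self.growth_residuals).max():.3e}")
        lines.append(f"nonnegative doses: {self.options.nonneg}")
        return "\n".join(lines)


def design_regimen(comp: CompoundedSystem,
                   gs: GrowthSystem | None = None,
                   disease: DiseaseState | None = None,
                   options: DesignOptions | None = None) -> RegimenDesign:
    """Assemble a dose vector that cancels disease symptoms and/or suppresses
    pathogen growth while keeping host features unperturbed.

    Solves the weighted least-squares problem over doses ``N`` (nonnegative
    by default)::

        minimize  w_h * || nu_c @ N - delta_c @ D ||^2
                + w_g * || nuG_c @ N -+ hG ||^2

    With no disease the first block enforces host neutrality
    (``nu_c @ N = 0``).  At least one of ``gs`` or ``disease`` must be
    given.  Infeasibility under the nonnegativity constraint is not an
    error: the per-row residuals in the returned report say how close the
    best admissible regimen comes.
    """
    if gs is None and disease is None:
        raise UsageError(
            "design_regimen needs an objective: a disease to cancel, a "
            "growth system to suppress, or both")
    options = options or DesignOptions()

    n_N = comp.n_N
    if gs is not None and gs.n_N != n_N:
        raise DimensionError("growth system and host system disagree on n_N")

    b_host = np.zeros(comp.c)
    if disease is not None:
        if disease.n_D != comp.n_D:
            raise DimensionError("disease dimension mismatch")
        b_host = comp.delta_c @ disease.D
    blocks_A = [np.sqrt(options.host_weight) * comp.nu_c]
    blocks_b = [np.sqrt(options.host_weight) * b_host]
    if gs is not None:
        sign = -1.0 if options.growth_sign == "suppress" else 1.0
        blocks_A.append(np.sqrt(options.growth_weight) * gs.nuG_c)
        blocks_b.append(np.sqrt(options.growth_weight) * sign * gs.hG)
    A = np.vstack(blocks_A)
    b = np.concatenate(blocks_b)

    if options.nonneg:
        sol = lsq_linear(A, b, bounds=(0.0, np.inf), tol=options.tol)
        N = np.maximum(sol.x, 0.0)
    else:
        N, *_ = np.linalg.lstsq(A, b, rcond=None)

    host_res = comp.nu_c @ N - b_host
    growth_res = None
    if gs is not None:
        sign = -1.0 if options.growth_sign == "suppress" else 1.0
        growth_res = gs.nuG_c @ N - sign * gs.hG
    if np.all(N >= 0):
        regimen = Regimen(N=N)
    else:
        regimen = _SignedRegimen(N)
    return RegimenDesign(regimen=regimen, host_residuals=host_res,
                         growth_residuals=growth_res, options=options)


class _SignedRegimen:
    """Dose vector from an unconstrained design; may contain negative doses
    (formally a depletion of the reference regimen)."""

    def __init__(self, N: np.ndarray):
        self.N = np.asarray(N, dtype=float)
        self.labels = None

    @property
    def Q(self) -> float:
        return float(self.N.sum())

    @property
    def n_N(self) -> int:
        return self.N.size
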