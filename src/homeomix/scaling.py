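"""Monte-Carlo verification of the diversity/complexity scaling laws.

The statistical claims under test, for random ensembles of compounded
potencies and dose shares:

* the dose-share fluctuation of the normalized activity has RMS
  ``sigma_eps / sqrt(n_N)`` — diversity averages dose noise away;
* the difference between the activities seen by two slightly different
  organisms (or two slightly different batches of the same regimen) also
  shrinks as ``1/sqrt(n_N)`` — diverse regimens are robust;
* the spread of the absolute activity scales as ``Q * sqrt(c / n_N) / s``:
  up with organism complexity, down with regimen diversity, linearly with
  total dose and inversely with synergy.

Distribution choices (only means and variances are prescribed by the model):
raw and compounded potencies are centered normals; off-diagonal feature
couplings are unit-variance normals so the compounded-potency magnitude
grows as ``sqrt(c)``; dose shares are Gamma with mean 1 and standard
deviation ``sigma_eps_dose``, which guarantees positivity.

Normalized activity follows the row-RMS convention: the potency row is
scaled by its own root-mean-square over chemicals.  With that convention
``sum_k u_k^2 = n_N`` identically, so the dose-conditional variance of the
activity equals ``sigma_eps^2 / n_N`` *exactly*, not just on ensemble
average; the ``rms`` statistic below measures that dose-fluctuation
component (activity minus its expectation over dose shares).  The full
ensemble spread of the activity carries an additional composition term
``~1/sqrt(n_N)`` with the same exponent.

All runs are reproducible: one root seed deterministically spawns one
substream per grid cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, UsageError, ValidationError

__all__ = [
    "EnsembleSpec",
    "ScalingResult",
    "sample_dose_shares",
    "sample_doses",
    "normalized_activity",
    "rms_activity_scaling",
    "robustness_difference",
    "absolute_activity_scaling",
    "synergy_exponent",
    "fit_loglog_slope",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Monte-Carlo ensemble configuration.

    Parameters
    ----------
    c : organism complexity (number of endogenous features).
    n_N : regimen diversity (number of distinct chemicals).
    Q : total dose per period.
    sigma_nu : spread of the raw potencies.
    sigma_eps_dose : standard deviation of the (mean-1, positive) dose shares.
    sigma_e1, sigma_e2 : spreads of the relative potency / dose-share
        perturbations used in robustness comparisons.
    s : synergy factor (total dose is reduced to Q/s at equal observed
        activity; s > 1 synergy, 0 < s < 1 antagonism).
    reps : Monte-Carlo repetitions per grid cell.
    seed : root seed.
    """

    c: int = 64
    n_N: int = 100
    Q: float = 1.0
    sigma_nu: float = 1.0
    sigma_eps_dose: float = 0.5
    sigma_e1: float = 0.1
    sigma_e2: float = 0.1
    s: float = 1.0
    reps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 1 or self.n_N < 1:
            raise ValidationError("c and n_N must be >= 1")
        if self.Q <= 0 or self.s <= 0:
            raise ValidationError("Q and s must be positive")
        if min(self.sigma_nu, self.sigma_eps_dose,
               self.sigma_e1, self.sigma_e2) < 0:
            raise ValidationError("spreads must be nonnegative")
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")


@dataclass(frozen=True)
class ScalingResult:
    """Estimated scaling statistics on a parameter grid.

    ``table`` is long-format (one row per grid cell) with the RMS and
    mean-absolute statistics and their standard errors; ``exponents`` maps
    parameter name -> (fitted log-log slope, 95% confidence half-width);
    ``warnings`` flags wide confidence intervals from too few repetitions.
    """

    table: pd.DataFrame
    exponents: dict
    n_eff: int
    warnings: tuple = ()

    def summary(self) -> str:
        lines = ["Scaling study", "-------------",
                 self.table.to_string(index=False, float_format="%.4g"), ""]
        for name, (slope, hw) in self.exponents.items():
            lines.append(f"log-log slope vs {name}: {slope:+.4f} +/- {hw:.4f}")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "exponents": {k: {"slope": v[0], "half_width": v[1]}
                          for k, v in self.exponents.items()},
            "n_eff": self.n_eff,
            "warnings": list(self.warnings),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------

def sample_dose_shares(n_N: int, sigma: float, rng: np.random.Generator,
                       size: int | tuple = ()) -> np.ndarray:
    """Positive dose shares with mean 1 and standard deviation ``sigma``.

    Gamma-distributed (shape 1/sigma^2, scale sigma^2); degenerates to all
    ones at sigma = 0.
    """
    if sigma < 0:
        raise DomainError("share spread must be nonnegative")
    shape = size if isinstance(size, tuple) else (size,)
    full = shape + (n_N,)
    if sigma == 0:
        return np.ones(full)
    k = 1.0 / sigma**2
    return rng.gamma(shape=k, scale=1.0 / k, size=full)


def sample_doses(spec: EnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    """One dose vector ``N_k = (Q / n_N) * eps_k`` with random positive
    shares of mean 1; the total concentrates on Q as diversity grows."""
    shares = sample_dose_shares(spec.n_N, spec.sigma_eps_dose, rng)
    return (spec.Q / spec.n_N) * shares


def normalized_activity(nu_c_row: np.ndarray, N: np.ndarray,
                        Q: float) -> float:
    """Dimensionless activity of a regimen on one feature.

    ``A~ = (1 / (Q * rms(nu_c_row))) * sum_k nu_c_row[k] * N[k]`` — the
    potency row is normalized by its own RMS over chemicals, so the value is
    invariant to rescaling doses and potencies jointly.
    """
    row = np.asarray(nu_c_row, dtype=float)
    N = np.asarray(N, dtype=float)
    if row.shape != N.shape:
        raise DomainError("potency row and dose vector must have equal length")
    rms = np.sqrt(np.mean(row**2))
    if rms == 0:
        raise DomainError("normalized activity undefined for an all-zero "
                          "potency row")
    return float(row @ N / (Q * rms))


def _normalized_rows(rng: np.random.Generator, reps: int,
                     n_N: int) -> np.ndarray:
    """Null-ensemble compounded-potency rows, each normalized to unit RMS."""
    u = rng.standard_normal((reps, n_N))
    return u / np.sqrt(np.mean(u**2, axis=1, keepdims=True))


def fit_loglog_slope(x: np.ndarray, y: np.ndarray,
                     y_se: np.ndarray | None = None) -> tuple[float, float]:
    """Weighted OLS slope of log10(y) on log10(x) with a 95% half-width.

    Standard errors of y are propagated to the log scale; with none given
    the fit is unweighted and the half-width comes from the residuals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise DomainError("need at least two grid points to fit a slope")
    lx, ly = np.log10(x), np.log10(y)
    if y_se is not None:
        var = (np.asarray(y_se, dtype=float) / (y * np.log(10)))**2
        var = np.where(var <= 0, np.min(var[var > 0], initial=1e-30), var)
        w = 1.0 / var
    else:
        w = np.ones_like(lx)
    W = w.sum()
    xb = (w * lx).sum() / W
    yb = (w * ly).sum() / W
    sxx = (w * (lx - xb)**2).sum()
    slope = (w * (lx - xb) * (ly - yb)).sum() / sxx
    if y_se is not None:
        se = np.sqrt(1.0 / sxx)
    else:
        resid = ly - yb - slope * (lx - xb)
        dof = max(x.size - 2, 1)
        se = np.sqrt((resid**2).sum() / dof / sxx)
    return float(slope), float(1.96 * se)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _half_stats(d: np.ndarray) -> tuple[float, float, float, float]:
    """RMS and mean-|.| of a sample with standard errors."""
    n = d.size
    m2 = np.mean(d**2)
    rms = np.sqrt(m2)
    rms_se = np.std(d**2) / (2 * rms * np.sqrt(n)) if rms > 0 else 0.0
    mean_abs = np.mean(np.abs(d))
    mean_abs_se = np.std(np.abs(d)) / np.sqrt(n)
    return float(rms), float(rms_se), float(mean_abs), float(mean_abs_se)


def _maybe_warn(exponents: dict, reps: int, warnings: list) -> None:
    for name, (_, hw) in exponents.items():
        if hw > 0.2:
            warnings.append(
                f"wide confidence interval on the {name} exponent "
                f"(+/- {hw:.2f}); increase reps (currently {reps})")


# ---------------------------------------------------------------------------
# Scaling studies
# ---------------------------------------------------------------------------

def rms_activity_scaling(spec: EnsembleSpec,
                         n_N_grid: Sequence[int]) -> ScalingResult:
    """Dose-fluctuation RMS of the normalized activity across a diversity grid.

    For each diversity ``n_N``, draws ``reps`` (normalized potency row,
    dose share) pairs and measures the activity minus its dose-share
    expectation — the component whose RMS the model predicts to be exactly
    ``sigma_eps_dose / sqrt(n_N)``.  Fits the log-log slope vs ``n_N``
    (predicted exponent -1/2).
    """
    grid = [int(n) for n in n_N_grid]
    if len(grid) < 3 or max(grid) < 10 * min(grid):
        raise DomainError("n_N grid must have >= 3 points spanning >= 1 decade")
    rows = []
    for rng, n_N in zip(_spawn(spec.seed, len(grid)), grid):
        u = _normalized_rows(rng, spec.reps, n_N)
        shares = sample_dose_shares(n_N, spec.sigma_eps_dose, rng, spec.reps)
        a = np.mean(u * shares, axis=1)          # A~ per system
        a0 = np.mean(u, axis=1)                  # dose-share expectation
        d = a - a0
        rms, rms_se, mabs, mabs_se = _half_stats(d)
        rows.append({"parameter": "n_N", "value": n_N, "rms": rms,
                     "rms_se": rms_se, "mean_abs": mabs,
                     "mean_abs_se": mabs_se, "n_eff": spec.reps})
    table = pd.DataFrame(rows)
    slope = fit_loglog_slope(table["value"], table["rms"], table["rms_se"])
    warnings: list = []
    exponents = {"n_N": slope}
    _maybe_warn(exponents, spec.reps, warnings)
    return ScalingResult(table=table, exponents=exponents, n_eff=spec.reps,
                         warnings=tuple(warnings))


def robustness_difference(spec: EnsembleSpec,
                          n_N_grid: Sequence[int]) -> ScalingResult:
    """Mean absolute difference between two perturbed activities vs diversity.

    Two versions of the same regimen/organism are built by perturbing the
    compounded potencies by ``-+ e1`` (relative, spread ``sigma_e1``) and the
    dose shares by ``-+ e2`` (spread ``sigma_e2``); each perturbed activity
    is normalized by its own perturbed row RMS.  The mean absolute
    difference falls as ``1/sqrt(n_N)``: diverse regimens are robust to
    organism-to-organism and batch-to-batch variation.  The measured
    prefactor (mean-abs-difference * sqrt(n_N)) is recorded next to the
    model's printed product form ``sigma_eps * sigma_e1 * sigma_e2``, which
    a direct expansion does not reproduce (the perturbations combine in
    quadrature); only the diversity law is asserted.
    """
    if spec.sigma_e1 <= 0 or spec.sigma_e2 <= 0:
        raise ValidationError("robustness comparison needs sigma_e1, sigma_e2 > 0")
    grid = [int(n) for n in n_N_grid]
    if len(grid) < 3:
        raise DomainError("n_N grid must have >= 3 points")
    rows = []
    for rng, n_N in zip(_spawn(spec.seed, len(grid)), grid):
        u = _normalized_rows(rng, spec.reps, n_N)
        shares = sample_dose_shares(n_N, spec.sigma_eps_dose, rng, spec.reps)
        e1 = spec.sigma_e1 * rng.standard_normal((spec.reps, n_N))
        e2 = spec.sigma_e2 * rng.standard_normal((spec.reps, n_N))
        ua, ub = u * (1 - e1), u * (1 + e1)
        sa, sb = shares * (1 - e2), shares * (1 + e2)
        ra = np.sqrt(np.mean(ua**2, axis=1))
        rb = np.sqrt(np.mean(ub**2, axis=1))
        aa = np.mean(ua * sa, axis=1) / ra
        ab = np.mean(ub * sb, axis=1) / rb
        d = aa - ab
        rms, rms_se, mabs, mabs_se = _half_stats(d)
        rows.append({"parameter": "n_N", "value": n_N, "rms": rms,
                     "rms_se": rms_se, "mean_abs": mabs,
                     "mean_abs_se": mabs_se,
                     "prefactor_measured": mabs * np.sqrt(n_N),
                     "prefactor_printed":
                         spec.sigma_eps_dose * spec.sigma_e1 * spec.sigma_e2,
                     "n_eff": spec.reps})
    table = pd.DataFrame(rows)
    slope = fit_loglog_slope(table["value"], table["mean_abs"],
                             table["mean_abs_se"])
    warnings: list = []
    exponents = {"n_N": slope}
    _maybe_warn(exponents, spec.reps, warnings)
    return ScalingResult(table=table, exponents=exponents, n_eff=spec.reps,
                         warnings=tuple(warnings))


def _absolute_activity_sample(spec: EnsembleSpec,
                              rng: np.random.Generator) -> np.ndarray:
    """Pool of absolute activities A_i from one ensemble cell.

    Each repetition builds a fresh organism: raw potencies N(0, sigma_nu^2),
    off-diagonal couplings N(0, 1), one-pass compounding, and one random
    dose vector at effective total dose Q/s.
    """
    out = np.empty((spec.reps, spec.c))
    for r in range(spec.reps):
        nu = spec.sigma_nu * rng.standard_normal((spec.c, spec.n_N))
        eps = rng.standard_normal((spec.c, spec.c))
        np.fill_diagonal(eps, 1.0)
        nu_c = eps @ nu
        shares = sample_dose_shares(spec.n_N, spec.sigma_eps_dose, rng)
        N = (spec.Q / (spec.s * spec.n_N)) * shares
        out[r] = nu_c @ N
    return out.ravel()


def absolute_activity_scaling(spec: EnsembleSpec,
                              c_grid: Sequence[int] = (),
                              n_N_grid: Sequence[int] = ()) -> ScalingResult:
    """Spread of the absolute activity across complexity/diversity grids.

    Predicted exponents: +1/2 in the organism complexity ``c`` (compounded
    potency magnitudes grow as sqrt(c)), -1/2 in the diversity ``n_N``, +1
    in the total dose ``Q`` and -1 in the synergy ``s`` (both exact by
    linearity).  Fits the log-log slope of the activity RMS on each grid.
    """
    c_grid = [int(v) for v in c_grid]
    n_N_grid = [int(v) for v in n_N_grid]
    if not c_grid and not n_N_grid:
        raise UsageError("provide a c grid, an n_N grid, or both")
    if c_grid and (len(c_grid) < 3 or max(c_grid) < 10 * min(c_grid)):
        raise DomainError("c grid must have >= 3 points spanning >= 1 decade")
    if c_grid and min(c_grid) < 2:
        raise DomainError("c grid degenerate: complexity must be >= 2")
    if n_N_grid and (len(n_N_grid) < 3 or max(n_N_grid) < 10 * min(n_N_grid)):
        raise DomainError("n_N grid must have >= 3 points spanning >= 1 decade")

    cells = ([("c", v) for v in c_grid] + [("n_N", v) for v in n_N_grid])
    rows = []
    for rng, (param, value) in zip(_spawn(spec.seed, len(cells)), cells):
        cell_spec = replace(spec, **{param: value})
        pool = _absolute_activity_sample(cell_spec, rng)
        rms, rms_se, mabs, mabs_se = _half_stats(pool)
        rows.append({"parameter": param, "value": value, "rms": rms,
                     "rms_se": rms_se, "mean_abs": mabs,
                     "mean_abs_se": mabs_se, "n_eff": pool.size})
    table = pd.DataFrame(rows)
    exponents = {}
    for param in ("c", "n_N"):
        sub = table[table["parameter"] == param]
        if len(sub) >= 2:
            exponents[param] = fit_loglog_slope(sub["value"], sub["rms"],
                                                sub["rms_se"])
    warnings: list = []
    _maybe_warn(exponents, spec.reps, warnings)
    return ScalingResult(table=table, exponents=exponents, n_eff=spec.reps,
                         warnings=tuple(warnings))


def synergy_exponent(spec: EnsembleSpec,
                     s_values: Sequence[float]) -> tuple[float, float]:
    """Fitted exponent of the activity RMS in the synergy factor s.

    The activity is exactly linear in Q/s, so with a shared random
    substream across s values the fitted exponent is -1 to machine
    precision.  Returns (slope, 95% half-width).
    """
    s_values = [float(s) for s in s_values]
    if len(s_values) < 2 or min(s_values) <= 0:
        raise DomainError("need >= 2 positive synergy values")
    rms = []
    for s in s_values:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
        pool = _absolute_activity_sample(replace(spec, s=s), rng)
        rms.append(np.sqrt(np.mean(pool**2)))
    return fit_loglog_slope(np.asarray(s_values), np.asarray(rms))
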