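"""Deterministic random feature-system construction.

Three modes:

* ``generic`` — unconstrained random organism;
* ``perfect-regimen-consistent`` — potencies projected so the reference
  regimen is exactly neutral (``nu_c @ n_ref = 0``): the admissibility
  constraint behind the notion of a perfect regimen, which random systems
  do not satisfy by accident;
* ``therapy-solvable`` — the disease's compounded virulence contribution is
  planted inside the column space of the compounded potencies through a
  nonnegative dose vector, so symptom-cancelling regimen design succeeds at
  numerical zero residual.  When growth features are requested the planted
  dose also exactly suppresses the pathogen (``nuG_c @ N = -hG``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import UsageError, ValidationError
from .model import compound_potencies
from .system import DiseaseState, FeatureSystem, GrowthSystem

__all__ = ["FixtureSpec", "Fixture", "generate_fixture"]

Mode = Literal["generic", "perfect-regimen-consistent", "therapy-solvable"]


@dataclass(frozen=True)
class FixtureSpec:
    """Construction parameters for a synthetic feature system.

    ``coupling`` scales the off-diagonal feature couplings (keep below
    ~1/sqrt(c) for stable relaxation dynamics); ``potency_spread`` scales
    raw potencies and virulences.
    """

    c: int = 8
    n_N: int = 5
    n_D: int = 1
    n_G: int = 0
    coupling: float = 0.1
    potency_spread: float = 1.0
    mode: Mode = "generic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 1 or self.n_N < 1 or self.n_D < 0 or self.n_G < 0:
            raise ValidationError("dimensions must be positive")
        if self.mode not in ("generic", "perfect-regimen-consistent",
                             "therapy-solvable"):
            raise UsageError(f"unknown fixture mode {self.mode!r}")
        if self.mode == "therapy-solvable" and self.n_D < 1:
            raise UsageError("therapy-solvable mode needs at least one "
                             "disease feature")


@dataclass(frozen=True)
class Fixture:
    system: FeatureSystem
    disease: DiseaseState
    growth: GrowthSystem | None


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build a random feature system deterministically from the seed."""
    rng = np.random.default_rng(spec.seed)
    c, n_N, n_D = spec.c, spec.n_N, spec.n_D

    eps = spec.coupling * rng.standard_normal((c, c))
    np.fill_diagonal(eps, 1.0)
    nu = spec.potency_spread * rng.standard_normal((c, n_N))
    delta = spec.potency_spread * rng.standard_normal((c, max(n_D, 1)))[:, :n_D] \
        if n_D else np.zeros((c, 0))
    h0 = rng.uniform(1.0, 10.0, size=c)
    k = rng.uniform(0.5, 2.0, size=c)
    n_ref = rng.uniform(0.5, 1.5, size=n_N)

    if spec.mode == "perfect-regimen-consistent":
        # project the requirement vector out of the potency row space:
        # nu' @ n_ref = 0 row by row, hence (eps @ nu') @ n_ref = 0 too
        nu = nu - np.outer(nu @ n_ref, n_ref) / (n_ref @ n_ref)

    disease = DiseaseState(D=np.zeros(n_D))
    planted = None
    if spec.mode == "therapy-solvable":
        planted = rng.uniform(0.1, 1.0, size=n_N)
        # delta @ D = nu @ planted with D = e_0 -> compounded images match
        delta = delta.copy()
        delta[:, 0] = nu @ planted
        D = np.zeros(n_D)
        D[0] = 1.0
        disease = DiseaseState(D=D)

    growth = None
    if spec.n_G:
        nuG_c = spec.potency_spread * rng.standard_normal((spec.n_G, n_N))
        if planted is not None:
            # orient rows so the basal capacities stay positive while the
            # planted dose exactly suppresses the agent (nuG_c @ N = -hG)
            flip = np.sign(nuG_c @ planted)
            flip[flip == 0] = 1.0
            nuG_c = -flip[:, None] * nuG_c
            hG = -(nuG_c @ planted)
        else:
            hG = rng.uniform(0.5, 2.0, size=spec.n_G)
        growth = GrowthSystem(hG=hG, nuG_c=nuG_c)

    system = FeatureSystem(h0=h0, eps=eps, k=k, nu=nu, delta=delta,
                           n_ref=n_ref)

    if spec.mode == "perfect-regimen-consistent":
        comp = compound_potencies(system)
        achieved = np.max(np.abs(comp.nu_c @ n_ref)) if n_N else 0.0
        if achieved > 1e-10:
            raise ValidationError(
                f"perfect-regimen construction failed: |nu_c @ n_ref| = "
                f"{achieved:.3e}")
    return Fixture(system=system, disease=disease, growth=growth)
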