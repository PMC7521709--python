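"""Edible-mixture bookkeeping.

Mixing r edibles at constant total dose Q dilutes every compound (each
edible contributes Q/r) while increasing chemical diversity only by the
overlap-limited factor gamma < r.  Two consequences are tracked here: the
compound-level dose vector of a mix, and the mass-action rate reduction for
bimolecular reactions involving compounds unique to single edibles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError, ValidationError
from .system import Regimen

__all__ = ["Edible", "MixtureDesign", "mix", "diversity_factor",
           "reaction_rate_factor", "read_edibles_csv", "write_edibles_csv"]


@dataclass(frozen=True)
class Edible:
    """One edible: a set of compounds with relative amounts.

    Amounts must be positive; they are normalized to sum to 1 so dose
    accounting is by mass fraction of the edible.
    """

    id: str
    compounds: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.compounds:
            raise ValidationError(f"edible {self.id!r} has no compounds")
        amounts = np.array(list(self.compounds.values()), dtype=float)
        if np.any(amounts <= 0):
            raise ValidationError(
                f"edible {self.id!r} has non-positive compound amounts")
        total = amounts.sum()
        normalized = {str(k): float(v) / total
                      for k, v in self.compounds.items()}
        object.__setattr__(self, "compounds", normalized)

    @property
    def size(self) -> int:
        return len(self.compounds)


@dataclass(frozen=True)
class MixtureDesign:
    """r edibles mixed at constant total dose Q, each dosed at Q/r."""

    edibles: tuple[Edible, ...]
    Q: float

    def __post_init__(self) -> None:
        if not self.edibles:
            raise UsageError("a mixture needs at least one edible")
        if self.Q <= 0:
            raise ValidationError("total dose Q must be positive")
        object.__setattr__(self, "edibles", tuple(self.edibles))

    @property
    def r(self) -> int:
        return len(self.edibles)

    @property
    def per_edible_dose(self) -> float:
        return self.Q / self.r


def mix(edibles: Sequence[Edible], Q: float) -> Regimen:
    """Compound-level dose vector of a constant-total-dose mix.

    Each of the r edibles contributes Q/r distributed over its compounds by
    mass fraction; shared compounds accumulate.  The regimen total is
    exactly Q.
    """
    design = MixtureDesign(edibles=tuple(edibles), Q=Q)
    doses: dict[str, float] = {}
    for e in design.edibles:
        for compound, fraction in e.compounds.items():
            doses[compound] = doses.get(compound, 0.0) \
                + design.per_edible_dose * fraction
    labels = sorted(doses)
    return Regimen(N=np.array([doses[c] for c in labels]),
                   labels=tuple(labels))


def diversity_factor(edibles: Sequence[Edible]) -> float:
    """Realized chemical-diversity factor gamma of a mix.

    gamma = (distinct compounds in the union) / (mean distinct compounds
    per edible).  Equals 1 for a single edible or identical edibles, and
    reaches r only for pairwise-disjoint equal-sized edibles; overlap keeps
    it strictly below r.
    """
    edibles = tuple(edibles)
    if not edibles:
        raise UsageError("need at least one edible")
    union = set()
    for e in edibles:
        union.update(e.compounds)
    mean_size = float(np.mean([e.size for e in edibles]))
    return len(union) / mean_size


def reaction_rate_factor(design_a: MixtureDesign, design_b: MixtureDesign,
                         pair: Literal["unique_vs_organism",
                                       "unique_vs_unique"]) -> float:
    """Fold reduction of a bimolecular mass-action rate from design a to b.

    The concentration of a compound unique to one edible scales as the
    per-edible dose over the edible's compound count.  ``unique_vs_organism``
    rates are linear in that concentration (the organism partner is fixed),
    so the factor is the ratio of mean unique-compound concentrations;
    ``unique_vs_unique`` rates involve two such compounds from two different
    edibles and the factor is the corresponding ratio of mean pairwise
    concentration products — the square of the linear factor when edible
    sizes are equal.  Going from 2 to 20 equal edibles at constant Q gives
    10x and 100x.
    """
    if not np.isclose(design_a.Q, design_b.Q):
        raise UsageError("designs must share the same total dose Q")

    def concentrations(d: MixtureDesign) -> np.ndarray:
        return np.array([d.per_edible_dose / e.size for e in d.edibles])

    ca, cb = concentrations(design_a), concentrations(design_b)
    if pair == "unique_vs_organism":
        return float(ca.mean() / cb.mean())
    if pair == "unique_vs_unique":
        def mean_pair_product(c: np.ndarray) -> float:
            if c.size < 2:
                raise UsageError(
                    "unique_vs_unique needs at least two edibles per design")
            total = c.sum()
            # mean over unordered distinct pairs of c_i * c_j
            return float((total**2 - (c**2).sum()) / (c.size * (c.size - 1)))
        return mean_pair_product(ca) / mean_pair_product(cb)
    raise UsageError(f"unknown pair kind {pair!r}")


def read_edibles_csv(path: str | Path) -> list[Edible]:
    """Read edible compositions from (edible_id, compound_id, amount) CSV."""
    df = pd.read_csv(path)
    out = []
    for eid, sub in df.groupby(df.columns[0], sort=True):
        out.append(Edible(id=str(eid),
                          compounds=dict(zip(sub.iloc[:, 1].astype(str),
                                             sub.iloc[:, 2].astype(float)))))
    return out


def write_edibles_csv(edibles: Sequence[Edible], path: str | Path) -> None:
    rows = [(e.id, comp, amt) for e in edibles
            for comp, amt in sorted(e.compounds.items())]
    pd.DataFrame(rows, columns=["edible_id", "compound_id", "amount"]).to_csv(
        path, index=False)
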