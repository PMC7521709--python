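"""Containers for the linear homeostatic feature-network model.

An organism is reduced to ``c`` endogenous (E-type) biological features that
relax toward coupled homeostatic targets.  Environmental chemical exposure —
nutrients and drugs, the N-type features — shifts those targets linearly
through a potency matrix; disease agents (D-type features) do the same
through a virulence matrix.  ``c`` is the organism's *complexity* and the
number of distinct chemicals in a regimen its *diversity* ``n_N``.

Conventions
-----------
* The coupling matrix ``eps`` has unit diagonal: a feature tracks its own
  homeostatic target with sensitivity one, off-diagonal entries are the
  first-order sensitivities to the other features' departures.
* Compounded potencies/virulences (``nu_c``, ``delta_c``) fold the feature
  couplings into effective per-chemical coefficients; the *true* homeostatic
  value ``h`` absorbs the contribution of the reference (healthy) regimen
  ``n_ref``, so steady states read ``E = h + nu_c @ N - delta_c @ D``.
* All values are in arbitrary feature/dose units; relaxation rates ``k`` are
  inverse time.

Serialization: systems round-trip losslessly (double precision) through JSON
and through a directory of CSV matrices with a small JSON manifest; regimens
and disease states through two-column (label, value) CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, ValidationError

__all__ = [
    "FeatureSystem",
    "CompoundedSystem",
    "Regimen",
    "DiseaseState",
    "GrowthSystem",
    "Trajectory",
]


def _vec(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise DimensionError(f"{name} must be one-dimensional, got shape {a.shape}")
    return a


def _mat(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2:
        raise DimensionError(f"{name} must be two-dimensional, got shape {a.shape}")
    return a


def _set(obj, **arrays) -> None:
    # frozen dataclasses: assign coerced arrays in __post_init__
    for k, v in arrays.items():
        object.__setattr__(obj, k, v)


@dataclass(frozen=True)
class FeatureSystem:
    """The organism: baselines, couplings, potencies, virulences, rates.

    Parameters
    ----------
    h0 : (c,) array
        Basal homeostatic values ``h_i^0`` (healthy equilibrium under the
        reference regimen, before compounding).
    eps : (c, c) array
        Feature-coupling matrix; diagonal must equal 1 exactly.
    k : (c,) array
        Positive relaxation rates (1/time).
    nu : (c, n_N) array
        Raw potencies of each chemical on each feature.
    delta : (c, n_D) array
        Raw virulences of each disease feature.
    n_ref : (n_N,) array
        Homeostatic requirements ``n_k`` (>= 0; zero for chemicals that are
        not needed to maintain health).
    """

    h0: np.ndarray
    eps: np.ndarray
    k: np.ndarray
    nu: np.ndarray
    delta: np.ndarray
    n_ref: np.ndarray

    def __post_init__(self) -> None:
        h0 = _vec(self.h0, "h0")
        eps = _mat(self.eps, "eps")
        k = _vec(self.k, "k")
        nu = _mat(self.nu, "nu")
        delta = _mat(self.delta, "delta")
        n_ref = _vec(self.n_ref, "n_ref")
        c = h0.size
        if eps.shape != (c, c):
            raise DimensionError(f"eps must be ({c}, {c}), got {eps.shape}")
        if k.size != c:
            raise DimensionError(f"k must have length {c}, got {k.size}")
        if nu.shape[0] != c:
            raise DimensionError(f"nu must have {c} rows, got {nu.shape[0]}")
        if delta.shape[0] != c:
            raise DimensionError(f"delta must have {c} rows, got {delta.shape[0]}")
        if n_ref.size != nu.shape[1]:
            raise DimensionError(
                f"n_ref must have length {nu.shape[1]}, got {n_ref.size}"
            )
        if not np.all(np.diag(eps) == 1.0):
            raise ValidationError("diagonal of the coupling matrix eps must equal 1")
        if not np.all(k > 0):
            raise ValidationError("all relaxation rates k must be positive")
        if not np.all(n_ref >= 0):
            raise ValidationError("reference requirements n_ref must be >= 0")
        _set(self, h0=h0, eps=eps, k=k, nu=nu, delta=delta, n_ref=n_ref)

    @property
    def c(self) -> int:
        """Number of endogenous features (organism complexity)."""
        return self.h0.size

    @property
    def n_N(self) -> int:
        """Number of chemical (N-type) features."""
        return self.nu.shape[1]

    @property
    def n_D(self) -> int:
        """Number of disease (D-type) features."""
        return self.delta.shape[1]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "h0": self.h0.tolist(),
            "eps": self.eps.tolist(),
            "k": self.k.tolist(),
            "nu": self.nu.tolist(),
            "delta": self.delta.tolist(),
            "n_ref": self.n_ref.tolist(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSystem":
        return cls(
            h0=d["h0"], eps=d["eps"], k=d["k"],
            nu=d["nu"], delta=d["delta"], n_ref=d["n_ref"],
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "FeatureSystem":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    _CSV_FIELDS = ("h0", "eps", "k", "nu", "delta", "n_ref")

    def to_csv_dir(self, directory: str | Path) -> None:
        """Write one CSV per matrix/vector plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"format": "homeomix.FeatureSystem", "files": {}}
        for name in self._CSV_FIELDS:
            fname = f"{name}.csv"
            np.savetxt(directory / fname, np.atleast_2d(getattr(self, name)),
                       delimiter=",")
            manifest["files"][name] = fname
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))

    @classmethod
    def from_csv_dir(cls, directory: str | Path) -> "FeatureSystem":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        arrays = {}
        for name, fname in manifest["files"].items():
            a = np.loadtxt(directory / fname, delimiter=",", ndmin=2)
            if name in ("h0", "k", "n_ref"):
                a = a.ravel()
            arrays[name] = a
        return cls(**arrays)


@dataclass(frozen=True)
class CompoundedSystem:
    """Effective (coupling-compounded) potencies/virulences and true baselines.

    ``nu_c[i, k] = sum_j eps[i, j] * nu[j, k]`` and likewise ``delta_c``;
    ``h = h0 - nu_c @ n_ref`` absorbs the healthy reference regimen, so a
    zero regimen and no disease leaves every feature at ``h``.
    """

    nu_c: np.ndarray
    delta_c: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        nu_c = _mat(self.nu_c, "nu_c")
        delta_c = _mat(self.delta_c, "delta_c")
        h = _vec(self.h, "h")
        c = h.size
        if nu_c.shape[0] != c or delta_c.shape[0] != c:
            raise DimensionError("nu_c and delta_c must have one row per feature")
        _set(self, nu_c=nu_c, delta_c=delta_c, h=h)

    @property
    def c(self) -> int:
        return self.h.size

    @property
    def n_N(self) -> int:
        return self.nu_c.shape[1]

    @property
    def n_D(self) -> int:
        return self.delta_c.shape[1]


def _two_column_csv(labels: Sequence[str], values: np.ndarray,
                    names: tuple[str, str], path: str | Path) -> None:
    pd.DataFrame({names[0]: list(labels), names[1]: values}).to_csv(
        path, index=False)


@dataclass(frozen=True)
class Regimen:
    """A nonnegative dose vector over the ``n_N`` chemical features.

    ``Q`` is the total dose over the reference period; it is always the sum
    of the per-chemical doses.
    """

    N: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        N = _vec(self.N, "N")
        if np.any(N < 0):
            raise ValidationError("doses must be nonnegative")
        labels = self.labels
        if labels is not None:
            labels = tuple(str(x) for x in labels)
            if len(labels) != N.size:
                raise DimensionError("labels must match the dose vector length")
        _set(self, N=N, labels=labels)

    @property
    def Q(self) -> float:
        """Total dose."""
        return float(self.N.sum())

    @property
    def n_N(self) -> int:
        return self.N.size

    def _label_list(self) -> list[str]:
        return list(self.labels) if self.labels is not None else [
            f"N{i}" for i in range(self.n_N)]

    def to_csv(self, path: str | Path) -> None:
        _two_column_csv(self._label_list(), self.N, ("label", "dose"), path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Regimen":
        df = pd.read_csv(path)
        return cls(N=df.iloc[:, 1].to_numpy(float),
                   labels=tuple(df.iloc[:, 0].astype(str)))

    @classmethod
    def zero(cls, n_N: int) -> "Regimen":
        return cls(N=np.zeros(n_N))


@dataclass(frozen=True)
class DiseaseState:
    """Disease-feature intensities; the healthy value of every entry is 0.

    ``kind`` distinguishes endogenous disease features (mutations, injuries,
    accumulated toxins — intrinsic to the patient) from exogenous ones
    (infectious agents, allergens — clearable from the organism).
    """

    D: np.ndarray
    kind: tuple[str, ...] | None = None

    _KINDS = ("endogenous", "exogenous")

    def __post_init__(self) -> None:
        D = _vec(self.D, "D")
        if np.any(D < 0):
            raise ValidationError("disease intensities must be nonnegative")
        kind = self.kind
        if kind is None:
            kind = ("endogenous",) * D.size
        kind = tuple(kind)
        if len(kind) != D.size:
            raise DimensionError("kind must match the disease vector length")
        for x in kind:
            if x not in self._KINDS:
                raise ValidationError(f"unknown disease kind {x!r}")
        _set(self, D=D, kind=kind)

    @property
    def n_D(self) -> int:
        return self.D.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"label": [f"D{i}" for i in range(self.n_D)],
                      "intensity": self.D,
                      "kind": list(self.kind)}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DiseaseState":
        df = pd.read_csv(path)
        kind = tuple(df["kind"]) if "kind" in df else None
        return cls(D=df["intensity"].to_numpy(float), kind=kind)

    @classmethod
    def none(cls, n_D: int) -> "DiseaseState":
        return cls(D=np.zeros(n_D))


@dataclass(frozen=True)
class GrowthSystem:
    """Growth capacity of a disease-causing agent (G-type features).

    ``G = hG + nuG_c @ N``: basal capacities plus the compounded action of
    the chemical regimen on the agent.  The agent is suppressed on feature
    ``m`` when ``G_m <= 0``.
    """

    hG: np.ndarray
    nuG_c: np.ndarray

    def __post_init__(self) -> None:
        hG = _vec(self.hG, "hG")
        nuG_c = _mat(self.nuG_c, "nuG_c")
        if nuG_c.shape[0] != hG.size:
            raise DimensionError("nuG_c must have one row per growth feature")
        _set(self, hG=hG, nuG_c=nuG_c)

    @property
    def n_G(self) -> int:
        return self.hG.size

    @property
    def n_N(self) -> int:
        return self.nuG_c.shape[1]

    def to_dict(self) -> dict:
        return {"hG": self.hG.tolist(), "nuG_c": self.nuG_c.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthSystem":
        return cls(hG=d["hG"], nuG_c=d["nuG_c"])


@dataclass(frozen=True)
class Trajectory:
    """Time course of the endogenous features on a grid."""

    t: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        t = _vec(self.t, "t")
        E = _mat(self.E, "E")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time grid must be strictly increasing")
        if E.shape[0] != t.size:
            raise DimensionError("E must have one row per time point")
        _set(self, t=t, E=E)

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.E, columns=[f"E{i}" for i in range(self.E.shape[1])])
        df.insert(0, "t", self.t)
        return df
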