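"""Face-centered central composite designs and coded-factor arithmetic.

A face-centered central composite design (CCFD) for ``n`` factors consists of
the full two-level factorial cube (2^n points at coded levels -1/+1), 2n axial
points on the face centers (one coordinate at -1 or +1, the rest at 0) and
``n_c`` replicated center points (all coordinates 0), for

    N = 2^n + 2n + n_c

runs in total.  Because the axial distance is 1, every factor is exercised at
exactly three levels, which is what allows the quadratic response surface of
:mod:`fermopt.response_surface` to be estimated.

Factors live in *actual* units (days, pH units, degrees C, % w/v ...) and are
mapped to dimensionless *coded* units by the linear transform

    coded = (actual - center) / ((high - low) / 2)

so that low/center/high become -1/0/+1.
"""

from __future__ import annotations

import itertools
import numbers
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DesignError",
    "FactorSpec",
    "DesignSpec",
    "DesignTable",
    "count_runs",
    "code_factor",
    "decode_factor",
    "generate_ccfd",
    "read_factor_config",
    "write_design",
    "read_design",
    "POINT_CLASSES",
]

POINT_CLASSES = ("factorial", "axial", "center")


class DesignError(ValueError):
    """Invalid factor specification or design construction request."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its low / center / high actual levels.

    The three levels map to coded -1 / 0 / +1.  ``center`` is expected to be
    the midpoint of ``low`` and ``high``; an off-midpoint center is accepted
    with a warning (the coded transform then uses the stated center, so the
    map is still linear but -1 and +1 are asymmetric around 0).
    """

    name: str
    low: float
    center: float
    high: float

    def __post_init__(self) -> None:
        for attr in ("low", "center", "high"):
            v = getattr(self, attr)
            if not isinstance(v, numbers.Real) or not np.isfinite(v):
                raise DesignError(f"factor {self.name!r}: {attr} must be a finite number, got {v!r}")
        if not (self.low < self.center < self.high):
            raise DesignError(
                f"factor {self.name!r}: levels must satisfy low < center < high, "
                f"got {self.low} / {self.center} / {self.high}"
            )
        midpoint = 0.5 * (self.low + self.high)
        if abs(self.center - midpoint) > 1e-9 * max(1.0, self.high - self.low):
            warnings.warn(
                f"factor {self.name!r}: center {self.center} is not the midpoint "
                f"{midpoint} of (low, high); coded levels will be asymmetric",
                stacklevel=2,
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, actual):
        """Map actual units to coded units."""
        half = self.half_range
        if half <= 0:
            raise DesignError(f"factor {self.name!r}: zero half-range")
        return (np.asarray(actual, dtype=float) - self.center) / half

    def decode(self, coded):
        """Map coded units back to actual units (inverse of :meth:`code`)."""
        return self.center + np.asarray(coded, dtype=float) * self.half_range


@dataclass(frozen=True)
class DesignSpec:
    """An ordered set of factors plus the number of center replicates."""

    factors: tuple[FactorSpec, ...]
    n_center: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        if len(self.factors) < 2:
            raise DesignError("a central composite design needs at least 2 factors")
        if not isinstance(self.n_center, numbers.Integral) or isinstance(self.n_center, bool):
            raise DesignError("n_center must be an integer")
        if self.n_center < 1:
            raise DesignError("n_center must be >= 1")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise DesignError(f"duplicate factor names: {names}")

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return count_runs(self.n_factors, self.n_center)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)


def count_runs(n, n_c) -> int:
    """Total number of runs of a CCFD: ``2**n + 2*n + n_c``.

    Parameters
    ----------
    n : int
        Number of factors (>= 1).
    n_c : int
        Number of replicated center points (>= 0).
    """
    for label, v, lo in (("n", n, 1), ("n_c", n_c, 0)):
        if isinstance(v, bool) or not isinstance(v, numbers.Integral):
            raise DesignError(f"{label} must be an integer, got {v!r}")
        if v < lo:
            raise DesignError(f"{label} must be >= {lo}, got {v}")
    return 2**int(n) + 2 * int(n) + int(n_c)


def code_factor(actual, spec: FactorSpec):
    """Coded value of ``actual`` under ``spec`` (low/center/high -> -1/0/+1)."""
    return spec.code(actual)


def decode_factor(coded, spec: FactorSpec):
    """Actual value of a coded coordinate; inverse of :func:`code_factor`."""
    return spec.decode(coded)


@dataclass(frozen=True)
class DesignTable:
    """A realized design: coded run matrix plus per-run point classes.

    Attributes
    ----------
    factors : tuple of FactorSpec
        Factor definitions, fixing column order and the coded<->actual map.
    coded : ndarray of shape (n_runs, n_factors)
        Coded coordinates, each in [-1, 1].
    point_class : ndarray of str
        One of ``factorial | axial | center`` per run.
    """

    factors: tuple[FactorSpec, ...]
    coded: np.ndarray
    point_class: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        coded = np.atleast_2d(np.asarray(self.coded, dtype=float))
        classes = np.asarray(self.point_class, dtype=object)
        if coded.shape[1] != len(self.factors):
            raise DesignError(
                f"coded matrix has {coded.shape[1]} columns for {len(self.factors)} factors"
            )
        if classes.shape[0] != coded.shape[0]:
            raise DesignError("point_class length does not match run count")
        bad = set(classes) - set(POINT_CLASSES)
        if bad:
            raise DesignError(f"unknown point classes: {sorted(bad)}")
        object.__setattr__(self, "coded", coded)
        object.__setattr__(self, "point_class", classes)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def actual(self) -> np.ndarray:
        """Run matrix in actual units."""
        cols = [f.decode(self.coded[:, j]) for j, f in enumerate(self.factors)]
        return np.column_stack(cols)

    def validate_ccfd(self) -> None:
        """Check the canonical CCFD point-count invariants."""
        cls = self.point_class
        n = self.n_factors
        n_fact = int(np.sum(cls == "factorial"))
        n_axial = int(np.sum(cls == "axial"))
        n_center = int(np.sum(cls == "center"))
        if n_fact != 2**n or n_axial != 2 * n or n_center < 1:
            raise DesignError(
                f"not a CCFD: {n_fact} factorial / {n_axial} axial / {n_center} center "
                f"points for {n} factors"
            )
        if self.n_runs != count_runs(n, n_center):
            raise DesignError("run count does not match 2^n + 2n + n_c")
        fact = self.coded[cls == "factorial"]
        if not np.all(np.isin(fact, (-1.0, 1.0))):
            raise DesignError("factorial coded entries must be +-1")
        axial = self.coded[cls == "axial"]
        if not np.all(np.sum(axial != 0, axis=1) == 1):
            raise DesignError("axial points must have exactly one nonzero coordinate")
        if not np.all(self.coded[cls == "center"] == 0):
            raise DesignError("center points must be all-zero")

    def to_frame(self) -> pd.DataFrame:
        """Long table: run, class, one coded and one actual column per factor."""
        data: dict[str, object] = {
            "run": np.arange(1, self.n_runs + 1),
            "class": self.point_class,
        }
        actual = self.actual
        for j, f in enumerate(self.factors):
            data[f"coded_{f.name}"] = self.coded[:, j]
        for j, f in enumerate(self.factors):
            data[f"actual_{f.name}"] = actual[:, j]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, factors: tuple[FactorSpec, ...]) -> "DesignTable":
        coded = np.column_stack([frame[f"coded_{f.name}"].to_numpy(float) for f in factors])
        classes = frame["class"].to_numpy(object) if "class" in frame else np.array(
            ["factorial"] * len(frame), dtype=object
        )
        return cls(factors=tuple(factors), coded=coded, point_class=classes)


def generate_ccfd(spec: DesignSpec, randomize: bool = False, seed: int | None = None) -> DesignTable:
    """Build the face-centered central composite design for ``spec``.

    Canonical order is factorial block (lexicographic over levels, -1 first),
    then axial block (per factor, -1 face then +1 face), then the center
    replicates.  With ``randomize=True`` the run order is permuted
    reproducibly by ``seed``; point-class labels travel with their rows.
    """
    n = spec.n_factors
    factorial = np.array(list(itertools.product((-1.0, 1.0), repeat=n)))
    axial = np.zeros((2 * n, n))
    for j in range(n):
        axial[2 * j, j] = -1.0
        axial[2 * j + 1, j] = 1.0
    center = np.zeros((spec.n_center, n))
    coded = np.vstack([factorial, axial, center])
    classes = np.array(
        ["factorial"] * len(factorial) + ["axial"] * len(axial) + ["center"] * spec.n_center,
        dtype=object,
    )
    if randomize:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(coded))
        coded = coded[order]
        classes = classes[order]
    table = DesignTable(factors=spec.factors, coded=coded, point_class=classes)
    table.validate_ccfd()
    return table


# ---------------------------------------------------------------------------
# text I/O

def read_factor_config(path) -> tuple[FactorSpec, ...]:
    """Read factor specs from a YAML file.

    Expected layout::

        factors:
          - {name: time_days, low: 10, center: 11, high: 12}
          - {name: pH, low: 7, center: 8, high: 9}

    A top-level list (without the ``factors`` key) is also accepted.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        doc = doc.get("factors", doc)
    if not isinstance(doc, list):
        raise DesignError(f"{path}: expected a list of factor mappings")
    specs = []
    for entry in doc:
        try:
            specs.append(
                FactorSpec(
                    name=str(entry["name"]),
                    low=float(entry["low"]),
                    center=float(entry["center"]),
                    high=float(entry["high"]),
                )
            )
        except KeyError as exc:
            raise DesignError(f"{path}: factor entry missing key {exc}") from exc
    return tuple(specs)


def write_design(design: DesignTable, path) -> None:
    """Write a design as comma-separated text (see :meth:`DesignTable.to_frame`)."""
    design.to_frame().to_csv(path, index=False)


def read_design(path, factors: tuple[FactorSpec, ...] | None = None) -> DesignTable:
    """Read a design written by :func:`write_design`.

    If ``factors`` is omitted, each factor's center and half-range are
    recovered by regressing the actual column on the coded column, which is
    exact for any table produced by this module.
    """
    frame = pd.read_csv(path)
    if factors is None:
        names = [c[len("coded_"):] for c in frame.columns if c.startswith("coded_")]
        factors = []
        for name in names:
            coded = frame[f"coded_{name}"].to_numpy(float)
            actual = frame[f"actual_{name}"].to_numpy(float)
            if np.ptp(coded) == 0:
                raise DesignError(f"{path}: cannot infer levels for factor {name!r} "
                                  "(coded column is constant); pass factors explicitly")
            half, center = np.polyfit(coded, actual, 1)
            factors.append(FactorSpec(name=name, low=center - half, center=center, high=center + half))
        factors = tuple(factors)
    return DesignTable.from_frame(frame, factors)
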