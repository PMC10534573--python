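"""Experimental plans for chromatographic method development.

Two plans are supported: the three-factor Box-Behnken design (BBD) with
replicated centre points used for response-surface optimisation of the
gradient programme, and the 12-run Plackett-Burman design (PB12) used for
quantitative robustness screening with dummy columns.

Factors are handled on two scales: *natural* units (%, min, mL/min, ...)
and *coded* units, where the low/centre/high levels of a factor map to
-1/0/+1.  All model fitting downstream works on the coded scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FactorSpec", "DesignMatrix", "bbd3_design", "pb12_design"]


@dataclass(frozen=True)
class FactorSpec:
    """A controllable method parameter with its experimental range.

    ``center`` and ``half_range`` are in natural units; the coded level of a
    natural value x is ``(x - center) / half_range`` so that
    ``center - half_range`` -> -1, ``center`` -> 0, ``center + half_range`` -> +1.
    """

    name: str
    center: float
    half_range: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not (self.half_range > 0 and math.isfinite(self.half_range)):
            raise ValueError(f"half_range must be positive and finite, got {self.half_range}")
        if not math.isfinite(self.center):
            raise ValueError(f"center must be finite, got {self.center}")

    def to_coded(self, natural):
        """Map natural-unit value(s) to the coded scale."""
        natural = np.asarray(natural, dtype=float)
        if not np.all(np.isfinite(natural)):
            raise ValueError(f"non-finite natural value for factor {self.name!r}: {natural}")
        out = (natural - self.center) / self.half_range
        return float(out) if out.ndim == 0 else out

    def from_coded(self, coded):
        """Map coded level(s) back to natural units (inverse of :meth:`to_coded`)."""
        coded = np.asarray(coded, dtype=float)
        out = self.center + coded * self.half_range
        return float(out) if out.ndim == 0 else out

    @property
    def low(self) -> float:
        return self.center - self.half_range

    @property
    def high(self) -> float:
        return self.center + self.half_range


@dataclass
class DesignMatrix:
    """A coded experimental plan: runs x factors with entries in {-1, 0, +1}."""

    kind: str  # "bbd3" or "pb12"
    factor_names: list[str]
    coded_levels: np.ndarray
    run_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coded_levels = np.asarray(self.coded_levels, dtype=float)
        if self.coded_levels.ndim != 2:
            raise ValueError("coded_levels must be a 2-D runs x factors array")
        if self.coded_levels.shape[1] != len(self.factor_names):
            raise ValueError("factor_names length does not match coded_levels columns")
        if not self.run_ids:
            self.run_ids = list(range(1, self.n_runs + 1))
        if len(self.run_ids) != self.n_runs:
            raise ValueError("run_ids length does not match number of runs")

    @property
    def n_runs(self) -> int:
        return self.coded_levels.shape[0]

    @property
    def n_factors(self) -> int:
        return self.coded_levels.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.coded_levels[:, self.factor_names.index(name)]

    def validate(self) -> None:
        """Check the structural invariants of the plan; raise on violation."""
        x = self.coded_levels
        if self.kind == "bbd3":
            if self.n_factors != 3:
                raise ValueError("bbd3 design must have exactly 3 factors")
            is_center = np.all(x == 0, axis=1)
            edges = x[~is_center]
            if edges.shape[0] != 12:
                raise ValueError("bbd3 design must have exactly 12 edge runs")
            zeros_per_edge = np.sum(edges == 0, axis=1)
            if not np.all(zeros_per_edge == 1):
                raise ValueError("each bbd3 edge run must have exactly one factor at level 0")
            if not np.allclose(x.sum(axis=0), 0):
                raise ValueError("bbd3 factor columns must each sum to zero")
        elif self.kind == "pb12":
            if x.shape != (12, 11):
                raise ValueError("pb12 design must be 12 runs x 11 columns")
            if not np.all(np.isin(x, (-1.0, 1.0))):
                raise ValueError("pb12 entries must be -1 or +1")
            if not np.all(x.sum(axis=0) == 0):
                raise ValueError("each pb12 column must have six +1 and six -1")
            gram = x.T @ x
            if not np.allclose(gram - np.diag(np.diag(gram)), 0):
                raise ValueError("pb12 columns must be pairwise orthogonal")
        else:
            raise ValueError(f"unknown design kind {self.kind!r}")

    def to_frame(self, factors: list[FactorSpec] | None = None) -> pd.DataFrame:
        """Tabulate the plan; with ``factors`` given, in natural units."""
        if factors is None:
            values = self.coded_levels
        else:
            if [f.name for f in factors] != self.factor_names:
                raise ValueError("factors do not match design columns")
            values = np.column_stack(
                [f.from_coded(self.coded_levels[:, j]) for j, f in enumerate(factors)]
            )
        df = pd.DataFrame(values, columns=self.factor_names)
        df.insert(0, "run_id", self.run_ids)
        return df

    def to_csv(self, path, factors: list[FactorSpec] | None = None) -> None:
        self.to_frame(factors).to_csv(path, index=False)


# Edge-run sign patterns of the 3-factor Box-Behnken design: the (+/-1, +/-1)
# combinations over each factor pair, third factor held at the centre.
_BBD3_PAIRS = ((0, 1), (0, 2), (1, 2))
_SIGNS = ((-1, -1), (1, -1), (-1, 1), (1, 1))


def bbd3_design(factors: list[FactorSpec], n_center: int = 4) -> DesignMatrix:
    """Three-factor Box-Behnken plan: 12 edge runs plus replicated centre.

    Runs are emitted in a canonical order (pairs (x1,x2), (x1,x3), (x2,x3),
    centre runs last); execution order carries no meaning for the fit.
    """
    if len(factors) != 3:
        raise ValueError(f"Box-Behnken plan requires exactly 3 factors, got {len(factors)}")
    if n_center < 1:
        raise ValueError("at least one centre run is required")
    rows = []
    for i, j in _BBD3_PAIRS:
        for si, sj in _SIGNS:
            row = [0.0, 0.0, 0.0]
            row[i], row[j] = si, sj
            rows.append(row)
    rows.extend([[0.0, 0.0, 0.0]] * n_center)
    design = DesignMatrix("bbd3", [f.name for f in factors], np.array(rows))
    design.validate()
    return design


# Classical cyclic generating row of the 12-run Plackett-Burman design.
_PB12_GENERATOR = (1, 1, -1, 1, 1, 1, -1, -1, -1, 1, -1)

# Column letters as conventionally printed for an 11-column PB12 plan
# (the letter I is skipped to avoid confusion with the numeral 1).
PB12_LETTERS = ["A", "B", "C", "D", "E", "F", "G", "H", "J", "K", "L"]

# Columns conventionally left unassigned ("dummy") in the 7-real-factor layout.
PB12_DUMMY_LETTERS = ("B", "E", "G", "J")


def pb12_design(n_real: int = 7, n_dummy: int = 4) -> DesignMatrix:
    """12-run Plackett-Burman plan from the classical cyclic generator.

    The plan has 11 mutually orthogonal +/-1 columns labelled A..L (skipping
    I); with the default 7+4 split, columns B, E, G and J are dummies.  Any
    published PB12 plan is equivalent to this one up to row/column permutation
    and sign switches, so equivalence checks should use column signatures
    (balance, orthogonality), not row order.
    """
    if n_real + n_dummy != 11:
        raise ValueError(f"n_real + n_dummy must equal 11, got {n_real} + {n_dummy}")
    gen = np.array(_PB12_GENERATOR, dtype=float)
    rows = [np.roll(gen, k) for k in range(11)]
    rows.append(-np.ones(11))
    design = DesignMatrix("pb12", list(PB12_LETTERS), np.array(rows))
    design.validate()
    return design
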