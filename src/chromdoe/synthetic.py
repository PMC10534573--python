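"""Synthetic study generators.

Both generators emulate the data-generating process the analysis assumes,
so every pipeline stage is testable without an instrument:

* :func:`simulate_bbd_study` — responses are exact polynomials in the coded
  factors plus homoscedastic Gaussian replicate noise.  The default ground
  truth is the published coefficient set, with per-response noise standard
  deviations calibrated to the spread of the four replicated centre runs of
  the real study (0.03-0.07 min for retention responses, 0.003 min for the
  mean peak width, whose printed replicates round to identical values).

* :func:`simulate_pb_study` — peak areas are a baseline plus half-effect
  times the coded level for each planted active factor, plus Gaussian
  noise.  Dummy columns carry zero true effect by construction.  The
  default planted pattern mirrors the screening conclusion of the real
  study: flow rate (H) acting on P_imp_II and gradient duration (D) acting
  on P_imp_V, each with magnitude five times the response noise SD.

What the generators deliberately do not emulate: mechanistic chromatography
(plate theory, gradient retention models), drifts or run-order effects, and
heteroscedastic or correlated detector noise.  Conclusions from passing
tests therefore concern the statistical pipeline, not instrument physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import DesignMatrix
from .robustness import PBStudy, default_roles
from .rsm import ResponseTable, polynomial_terms

__all__ = [
    "SurfaceTruth",
    "PBTruth",
    "default_surface_truth",
    "default_pb_truth",
    "simulate_bbd_study",
    "simulate_pb_study",
]

#: Per-response replicate noise SD (natural units), calibrated to the
#: centre-point spread of the real gradient study.
DEFAULT_NOISE_SD = {
    "t_e_imp_x": 0.066,
    "t_b_imp_III": 0.056,
    "t_imp_V": 0.035,
    "W_USP": 0.003,
    "t_range": 0.026,
}

#: Baseline peak areas of the magnitude observed in the real robustness
#: study, and per-response noise SDs back-calculated from its dummy-effect
#: spread (sigma = RMS dummy effect x sqrt(3)).
DEFAULT_PB_BASELINE = {
    "P_imp_I": 1430.0,
    "P_imp_II": 312.0,
    "P_API": 8850.0,
    "P_imp_III": 320.0,
    "P_imp_IV": 253.0,
    "P_imp_V": 1330.0,
}
DEFAULT_PB_NOISE_SD = {
    "P_imp_I": 232.0,
    "P_imp_II": 55.0,
    "P_API": 767.0,
    "P_imp_III": 89.0,
    "P_imp_IV": 23.0,
    "P_imp_V": 105.0,
}


@dataclass
class SurfaceTruth:
    """Ground-truth polynomial surfaces and replicate noise per response."""

    coefficients: dict[str, dict[str, float]]
    noise_sd: dict[str, float]
    seed: int = 0

    def __post_init__(self):
        for r, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd must be >= 0, got {sd} for {r!r}")


def default_surface_truth(seed: int = 0) -> SurfaceTruth:
    """Truth = the published coefficient set with calibrated noise."""
    from .datasets import table3_reference

    ref = table3_reference()
    return SurfaceTruth(
        coefficients={r: dict(c) for r, c in ref["coefficients"].items()},
        noise_sd=dict(DEFAULT_NOISE_SD),
        seed=seed,
    )


def simulate_bbd_study(truth: SurfaceTruth, design: DesignMatrix,
                       rng: np.random.Generator | None = None) -> ResponseTable:
    """Draw one synthetic Box-Behnken study from the ground truth.

    Each run's response is the exact polynomial value at its coded row plus
    Gaussian(0, noise_sd) noise.  Deterministic given (truth, seed).
    """
    if design.kind != "bbd3":
        raise ValueError("simulate_bbd_study requires a bbd3 design")
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    data = {}
    for resp, coeffs in truth.coefficients.items():
        terms = list(coeffs)
        x = polynomial_terms(design.coded_levels, terms)
        mean = x @ np.array([coeffs[t] for t in terms])
        sd = truth.noise_sd.get(resp, 0.0)
        data[resp] = mean + rng.normal(0.0, sd, size=design.n_runs) if sd > 0 else mean
    return ResponseTable(design, pd.DataFrame(data))


@dataclass
class PBTruth:
    """Ground truth of a synthetic robustness screening study.

    ``active`` maps response -> {factor letter: effect size}; effects may
    only be planted on real-factor columns (dummies are noise by
    definition).
    """

    baseline: dict[str, float]
    active: dict[str, dict[str, float]]
    noise_sd: dict[str, float]
    seed: int = 0
    roles: dict = field(default_factory=default_roles)

    def __post_init__(self):
        dummies = {n for n, r in self.roles.items() if r.kind == "dummy"}
        for resp, effects in self.active.items():
            bad = dummies.intersection(effects)
            if bad:
                raise ValueError(
                    f"active effects assigned to dummy column(s) {sorted(bad)} "
                    f"for response {resp!r}"
                )
        for r, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd must be >= 0, got {sd} for {r!r}")


def default_pb_truth(seed: int = 0, effect_multiple: float = 5.0) -> PBTruth:
    """Two planted factor-response pairs at ``effect_multiple`` x noise SD.

    The planted pattern is flow rate (H) depressing P_imp_II and gradient
    duration (D) depressing P_imp_V, matching the conclusion of the real
    screening study.
    """
    noise = dict(DEFAULT_PB_NOISE_SD)
    return PBTruth(
        baseline=dict(DEFAULT_PB_BASELINE),
        active={
            "P_imp_II": {"H": -effect_multiple * noise["P_imp_II"]},
            "P_imp_V": {"D": -effect_multiple * noise["P_imp_V"]},
        },
        noise_sd=noise,
        seed=seed,
    )


def simulate_pb_study(truth: PBTruth, design: DesignMatrix,
                      rng: np.random.Generator | None = None) -> PBStudy:
    """Draw one synthetic Plackett-Burman study from the ground truth.

    response = baseline + sum(effect/2 x coded level) + Gaussian noise.
    """
    if design.kind != "pb12":
        raise ValueError("simulate_pb_study requires a pb12 design")
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    data = {}
    for resp, base in truth.baseline.items():
        y = np.full(design.n_runs, float(base))
        for factor, effect in truth.active.get(resp, {}).items():
            y = y + (effect / 2.0) * design.column(factor)
        sd = truth.noise_sd.get(resp, 0.0)
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=design.n_runs)
        data[resp] = y
    return PBStudy(design, truth.roles, pd.DataFrame(data))
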