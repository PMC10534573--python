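"""Monte Carlo design-space probability mapping.

The design space (DS) is the region of method-parameter settings in which
every critical method attribute (CMA) meets its acceptance bound with at
least a target probability pi.  Coefficient uncertainty of the fitted
response-surface models is propagated by Monte Carlo: in each iteration a
uniform perturbation of half-width one standard error is added to every
coefficient estimate (independently across coefficients and models), all
CMA predictions are re-evaluated on a discretised factor grid, and pi at a
grid point is the fraction of iterations in which all criteria hold jointly.

The separation factor S of the critical peak pair is modelled *indirectly*:
it is never fitted to per-run S values but computed as the difference of two
separately fitted retention models (beginning of the impurity-III peak minus
end of the unknown-impurity peak).
"""

from __future__ import annotations

import json
import operator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import FactorSpec
from .rsm import RSMResults, polynomial_terms

__all__ = [
    "CMACriterion",
    "DEFAULT_CMA_SET",
    "GridSpec",
    "MonteCarloConfig",
    "ProbabilityGrid",
    "DSRegion",
    "DesignSpace",
    "perturb_coefficients",
    "extract_ds",
]

_COMPARATORS = {"<": operator.lt, "<=": operator.le, ">=": operator.ge}

#: Default seed recorded in all probability-map outputs.
DEFAULT_SEED = 20230914


@dataclass(frozen=True)
class CMACriterion:
    """One acceptance bound on a predicted critical method attribute.

    ``kind="direct"`` compares the prediction of a single response with the
    threshold; ``kind="difference"`` compares ``minuend - subtrahend`` of two
    fitted models (used for the indirectly modelled separation factor).
    """

    name: str
    comparator: str
    threshold: float
    kind: str = "direct"
    response: str | None = None
    minuend: str | None = None
    subtrahend: str | None = None

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"comparator must be one of {sorted(_COMPARATORS)}")
        if self.kind == "direct":
            if not self.response:
                raise ValueError("direct criterion requires a response name")
        elif self.kind == "difference":
            if not (self.minuend and self.subtrahend):
                raise ValueError("difference criterion requires minuend and subtrahend")
        else:
            raise ValueError(f"unknown criterion kind {self.kind!r}")

    @property
    def responses(self) -> tuple[str, ...]:
        if self.kind == "direct":
            return (self.response,)
        return (self.minuend, self.subtrahend)

    def evaluate(self, predictions: dict[str, np.ndarray]) -> np.ndarray:
        if self.kind == "direct":
            value = predictions[self.response]
        else:
            value = predictions[self.minuend] - predictions[self.subtrahend]
        return _COMPARATORS[self.comparator](value, self.threshold)

    def describe(self) -> str:
        lhs = self.response if self.kind == "direct" else f"{self.minuend} - {self.subtrahend}"
        return f"{lhs} {self.comparator} {self.threshold}"


#: The acceptance criteria of the gradient-elution method: last-peak
#: retention, elution span, critical-pair separation, mean USP peak width.
DEFAULT_CMA_SET = (
    CMACriterion("t_imp_V", "<", 15.5, response="t_imp_V"),
    CMACriterion("t_range", "<", 12.0, response="t_range"),
    CMACriterion("S", ">=", 0.0, kind="difference", minuend="t_b_imp_III", subtrahend="t_e_imp_x"),
    CMACriterion("W_USP", "<=", 0.235, response="W_USP"),
)


@dataclass(frozen=True)
class GridSpec:
    """Per-factor inclusive arithmetic discretisation, in natural units.

    ``axes`` maps factor name -> (min, step, max).  (max - min) / step must
    be integral; levels are generated by integer index (min + k * step) so
    the sequence does not accumulate floating error.
    """

    axes: dict[str, tuple[float, float, float]]

    @property
    def factor_names(self) -> list[str]:
        return list(self.axes)

    def levels(self, name: str) -> np.ndarray:
        lo, step, hi = self.axes[name]
        if step <= 0:
            raise ValueError(f"step must be positive for factor {name!r}")
        n = (hi - lo) / step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"(max - min) / step = {n} is not integral for factor {name!r}"
            )
        return lo + step * np.arange(round(n) + 1)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(self.levels(n)) for n in self.axes)

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def points(self) -> np.ndarray:
        """Cartesian product of the level sequences, last factor fastest."""
        grids = np.meshgrid(*(self.levels(n) for n in self.axes), indexing="ij")
        return np.column_stack([g.ravel() for g in grids])


@dataclass(frozen=True)
class MonteCarloConfig:
    """Settings of the coefficient-perturbation Monte Carlo.

    ``perturbation`` selects the error model added to each coefficient:
    ``uniform_halfwidth_se`` (default) draws uniformly on
    [estimate - SE, estimate + SE]; ``uniform_fullwidth_se`` uses an interval
    of total width SE; ``none`` keeps estimates fixed (degenerate Monte
    Carlo, pi in {0, 1}).  One draw per iteration is shared across all grid
    points, which leaves the marginal pi at each point unchanged.
    """

    n_iterations: int = 5000
    seed: int = DEFAULT_SEED
    perturbation: str = "uniform_halfwidth_se"

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.perturbation not in ("uniform_halfwidth_se", "uniform_fullwidth_se", "none"):
            raise ValueError(f"unknown perturbation mode {self.perturbation!r}")


def perturb_coefficients(
    results: RSMResults,
    rng: np.random.Generator,
    n_draws: int = 1,
    perturbation: str = "uniform_halfwidth_se",
) -> np.ndarray:
    """Draw coefficient vectors around the estimates (n_draws x n_terms).

    Each coefficient is drawn independently and uniformly, centred on its
    estimate, with half-width equal to its standard error (or SE/2 in
    ``uniform_fullwidth_se`` mode).  ``none`` returns the estimates exactly.
    """
    est = results.params.to_numpy()
    p = len(est)
    if perturbation == "none":
        return np.tile(est, (n_draws, 1))
    half = results.bse.to_numpy().copy()
    if perturbation == "uniform_fullwidth_se":
        half = half / 2.0
    elif perturbation != "uniform_halfwidth_se":
        raise ValueError(f"unknown perturbation mode {perturbation!r}")
    return est + rng.uniform(-1.0, 1.0, size=(n_draws, p)) * half


@dataclass
class DSRegion:
    """The extracted design space: mask over the grid plus summaries."""

    mask: np.ndarray
    pi_min: float
    axes: dict[str, np.ndarray]

    @property
    def n_points(self) -> int:
        return int(self.mask.sum())

    @property
    def bounding_box(self) -> dict[str, tuple[float, float]] | None:
        if self.n_points == 0:
            return None
        idx = np.nonzero(self.mask)
        box = {}
        for d, name in enumerate(self.axes):
            lv = self.axes[name]
            box[name] = (float(lv[idx[d].min()]), float(lv[idx[d].max()]))
        return box


@dataclass
class ProbabilityGrid:
    """Joint CMA-satisfaction probability pi over a discretised factor grid."""

    axes: dict[str, np.ndarray]
    pi: np.ndarray
    criteria: tuple[CMACriterion, ...]
    mc: MonteCarloConfig
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        expected = tuple(len(v) for v in self.axes.values())
        if self.pi.shape != expected:
            raise ValueError(f"pi shape {self.pi.shape} does not match axes {expected}")
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ValueError("pi must lie in [0, 1]")

    def design_space(self, pi_min: float) -> DSRegion:
        return extract_ds(self, pi_min)

    def pi_at(self, natural_point: dict[str, float]) -> float:
        """pi at a grid point given by exact natural-unit coordinates."""
        idx = []
        for name, levels in self.axes.items():
            j = np.where(np.isclose(levels, natural_point[name], atol=1e-9))[0]
            if len(j) == 0:
                raise KeyError(f"{natural_point[name]} is not a grid level of {name!r}")
            idx.append(int(j[0]))
        return float(self.pi[tuple(idx)])

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per grid point, factor columns plus pi."""
        names = list(self.axes)
        grids = np.meshgrid(*(self.axes[n] for n in names), indexing="ij")
        df = pd.DataFrame({n: g.ravel() for n, g in zip(names, grids)})
        df["pi"] = self.pi.ravel()
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def metadata(self) -> dict:
        return {
            "seed": self.mc.seed,
            "n_iterations": self.mc.n_iterations,
            "perturbation": self.mc.perturbation,
            "criteria": [c.describe() for c in self.criteria],
            "axes": {n: [float(v[0]), float(v[-1]), len(v)] for n, v in self.axes.items()},
            "fixed": self.fixed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def extract_ds(pg: ProbabilityGrid, pi_min: float) -> DSRegion:
    """Threshold the probability map: the DS is the region with pi >= pi_min."""
    if not 0 <= pi_min <= 1:
        raise ValueError("pi_min must lie in [0, 1]")
    return DSRegion(pg.pi >= pi_min, pi_min, dict(pg.axes))


class DesignSpace:
    """Design-space computation over a set of fitted response-surface models.

    Parameters
    ----------
    models : dict of response name -> RSMResults
        Fitted models for every response referenced by the criteria.
    factors : list of FactorSpec
        The three method parameters, in model order; used to convert
        natural-unit grids to the coded scale of the fits.
    criteria : sequence of CMACriterion
        The acceptance bounds defining method quality.
    """

    def __init__(self, models: dict[str, RSMResults], factors: list[FactorSpec],
                 criteria=DEFAULT_CMA_SET):
        self.criteria = tuple(criteria)
        needed = sorted({r for c in self.criteria for r in c.responses})
        missing = [r for r in needed if r not in models]
        if missing:
            raise KeyError(f"no fitted model for response(s): {', '.join(missing)}")
        if len(factors) != 3:
            raise ValueError("exactly 3 factors are required")
        self.models = dict(models)
        self.factors = list(factors)
        self._responses = needed  # canonical order: draws are seed-stable

    # -- coordinate handling ----------------------------------------------

    def to_coded(self, natural_points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(natural_points, dtype=float))
        return np.column_stack(
            [f.to_coded(pts[:, j]) for j, f in enumerate(self.factors)]
        )

    def _factor_index(self, name: str) -> int:
        for j, f in enumerate(self.factors):
            if f.name == name:
                return j
        raise KeyError(f"unknown factor {name!r}")

    # -- Monte Carlo internals --------------------------------------------

    def _draws(self, mc: MonteCarloConfig) -> dict[str, np.ndarray]:
        """Coefficient draws per response, (n_iterations x n_terms).

        Draws depend only on (seed, n_iterations, perturbation) and the
        canonical response order, never on the grid, so a 2-D slice and the
        3-D map share identical draws for the same configuration.
        """
        rng = np.random.default_rng(mc.seed)
        return {
            r: perturb_coefficients(self.models[r], rng, mc.n_iterations, mc.perturbation)
            for r in self._responses
        }

    def _joint_counts(self, coded: np.ndarray, draws: dict[str, np.ndarray],
                      chunk: int = 1000) -> tuple[np.ndarray, np.ndarray]:
        """Count iterations where all criteria hold jointly, per point.

        Also returns per-criterion marginal counts from the same draws, so
        the joint count is bounded by each marginal by construction.
        """
        xmats = {
            r: polynomial_terms(coded, self.models[r].model.terms) for r in self._responses
        }
        n_iter = next(iter(draws.values())).shape[0]
        counts = np.zeros(coded.shape[0], dtype=np.int64)
        marginals = np.zeros((len(self.criteria), coded.shape[0]), dtype=np.int64)
        for start in range(0, n_iter, chunk):
            sl = slice(start, min(start + chunk, n_iter))
            preds = {r: xmats[r] @ draws[r][sl].T for r in self._responses}
            ok = np.ones(preds[self._responses[0]].shape, dtype=bool)
            for k, crit in enumerate(self.criteria):
                crit_ok = crit.evaluate(preds)
                marginals[k] += crit_ok.sum(axis=1)
                ok &= crit_ok
            counts += ok.sum(axis=1)
        return counts, marginals

    # -- public operations -------------------------------------------------

    def cma_satisfied(self, coded_point, coefficients: dict[str, np.ndarray] | None = None,
                      ) -> dict[str, bool]:
        """Evaluate each criterion at one coded point.

        ``coefficients`` optionally supplies one coefficient vector per
        response (e.g. a Monte Carlo draw); by default the unperturbed
        estimates are used.
        """
        coded_point = np.asarray(coded_point, dtype=float).reshape(1, 3)
        preds = {}
        for r in self._responses:
            res = self.models[r]
            x = polynomial_terms(coded_point, res.model.terms)
            beta = res.params.to_numpy() if coefficients is None else np.asarray(coefficients[r])
            preds[r] = x @ beta
        return {c.name: bool(c.evaluate(preds)[0]) for c in self.criteria}

    def predict_cmas(self, coded_point) -> dict[str, float]:
        """Mean-model value of each criterion's left-hand side at a point."""
        coded_point = np.asarray(coded_point, dtype=float)
        preds = {r: self.models[r].predict(coded_point) for r in self._responses}
        out = {}
        for c in self.criteria:
            if c.kind == "direct":
                out[c.name] = preds[c.response]
            else:
                out[c.name] = preds[c.minuend] - preds[c.subtrahend]
        return out

    def probability_map(self, grid: GridSpec, mc: MonteCarloConfig | None = None,
                        per_criterion: bool = False):
        """pi over the full factor grid.

        pi(point) = (#iterations with all criteria jointly satisfied) /
        n_iterations.  The same seed yields a bit-identical map.  With
        ``per_criterion=True`` additionally returns one marginal
        probability grid per criterion, computed from the same draws.
        """
        mc = mc or MonteCarloConfig()
        if grid.factor_names != [f.name for f in self.factors]:
            raise ValueError("grid factors must match model factors in order")
        coded = self.to_coded(grid.points())
        counts, marg = self._joint_counts(coded, self._draws(mc))
        axes = {n: grid.levels(n) for n in grid.factor_names}
        pi = (counts / mc.n_iterations).reshape(grid.shape)
        joint = ProbabilityGrid(axes, pi, self.criteria, mc)
        if not per_criterion:
            return joint
        marginals = {
            c.name: ProbabilityGrid(
                axes, (marg[k] / mc.n_iterations).reshape(grid.shape), (c,), mc
            )
            for k, c in enumerate(self.criteria)
        }
        return joint, marginals

    def slice_2d(self, fixed_factor: str, fixed_value: float,
                 grid2: GridSpec, mc: MonteCarloConfig | None = None) -> ProbabilityGrid:
        """pi over a 2-D grid with one factor held at a fixed natural value.

        The fixed value may lie between grid levels (off-grid); it must stay
        within the factor's experimental range.
        """
        mc = mc or MonteCarloConfig()
        j = self._factor_index(fixed_factor)
        spec = self.factors[j]
        if not (spec.low - 1e-9 <= fixed_value <= spec.high + 1e-9):
            raise ValueError(
                f"fixed value {fixed_value} outside experimental range "
                f"[{spec.low}, {spec.high}] of {fixed_factor!r}"
            )
        free = [n for n in (f.name for f in self.factors) if n != fixed_factor]
        if grid2.factor_names != free:
            raise ValueError(f"2-D grid must cover factors {free} in order")
        pts2 = grid2.points()
        natural = np.empty((pts2.shape[0], 3))
        natural[:, j] = fixed_value
        natural[:, [k for k in range(3) if k != j]] = pts2
        coded = self.to_coded(natural)
        counts, _ = self._joint_counts(coded, self._draws(mc))
        pi = (counts / mc.n_iterations).reshape(grid2.shape)
        axes = {n: grid2.levels(n) for n in free}
        return ProbabilityGrid(axes, pi, self.criteria, mc, fixed={fixed_factor: fixed_value})

    def working_point_report(self, natural_point, observed: dict[str, float] | None = None,
                             ) -> pd.DataFrame:
        """Tabulate predicted value, bound and pass/fail per criterion.

        ``observed`` optionally supplies verification-experiment values per
        criterion name; they are reported as deltas, never asserted on.
        """
        natural_point = np.asarray(natural_point, dtype=float)
        for j, f in enumerate(self.factors):
            if not (f.low - 1e-9 <= natural_point[j] <= f.high + 1e-9):
                raise ValueError(
                    f"working point coordinate {natural_point[j]} outside "
                    f"experimental range of {f.name!r}"
                )
        coded = self.to_coded(natural_point)[0]
        values = self.predict_cmas(coded)
        rows = []
        for c in self.criteria:
            v = values[c.name]
            row = {
                "criterion": c.describe(),
                "predicted": v,
                "bound": c.threshold,
                "pass": bool(_COMPARATORS[c.comparator](v, c.threshold)),
            }
            if observed is not None and c.name in observed:
                row["observed"] = observed[c.name]
                row["delta"] = observed[c.name] - v
            rows.append(row)
        return pd.DataFrame(rows)


def plot_slice(pg: ProbabilityGrid, pi_min: float = 0.8, path=None, working_point=None):
    """Render a 2-D probability map with the pi >= pi_min region highlighted.

    Returns the matplotlib figure; saves to ``path`` when given.  Import of
    the plotting backend is deferred so headless pipelines without a display
    can still compute maps.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if pg.pi.ndim != 2:
        raise ValueError("plot_slice expects a 2-D probability grid")
    (xname, xlev), (yname, ylev) = pg.axes.items()
    fig, ax = plt.subplots(figsize=(6, 5))
    mesh = ax.pcolormesh(ylev, xlev, pg.pi, shading="nearest", cmap="viridis",
                         vmin=0.0, vmax=1.0)
    ax.contour(ylev, xlev, pg.pi, levels=[pi_min], colors="yellow", linewidths=2)
    if working_point is not None:
        ax.plot(working_point[1], working_point[0], "r*", markersize=12)
    ax.set_xlabel(yname)
    ax.set_ylabel(xname)
    title = f"pi map ({', '.join(f'{k}={v}' for k, v in pg.fixed.items())})" if pg.fixed else "pi map"
    ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="pi")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
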