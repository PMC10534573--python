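"""Response-surface modelling on coded factors.

Fits linear (main-effects) or full-quadratic polynomials to the responses of
a Box-Behnken study by ordinary least squares and computes the regression
diagnostics used to judge model adequacy: R-squared, adjusted R-squared,
PRESS and predicted R-squared (leave-one-out), and the lack-of-fit F test
against pure error from replicated centre runs.

The public surface follows the Model -> Results convention: build a
:class:`ResponseSurfaceModel` from a :class:`ResponseTable`, call ``fit()``,
and read estimates, standard errors and diagnostics off the returned
:class:`RSMResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .designs import DesignMatrix

__all__ = [
    "ResponseTable",
    "ResponseSurfaceModel",
    "RSMResults",
    "QUADRATIC_TERMS",
    "LINEAR_TERMS",
    "polynomial_terms",
]

#: Term order of the full quadratic model in three coded factors:
#: intercept; main effects; two-way interactions; pure quadratics.
QUADRATIC_TERMS = ["b0", "b1", "b2", "b3", "b12", "b13", "b23", "b11", "b22", "b33"]
LINEAR_TERMS = ["b0", "b1", "b2", "b3"]

# term -> exponents of (x1, x2, x3)
_TERM_POWERS = {
    "b0": (0, 0, 0),
    "b1": (1, 0, 0),
    "b2": (0, 1, 0),
    "b3": (0, 0, 1),
    "b12": (1, 1, 0),
    "b13": (1, 0, 1),
    "b23": (0, 1, 1),
    "b11": (2, 0, 0),
    "b22": (0, 2, 0),
    "b33": (0, 0, 2),
}


def polynomial_terms(coded: np.ndarray, terms: list[str]) -> np.ndarray:
    """Expand coded points (n x 3) into the model matrix for ``terms``."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    if coded.shape[1] != 3:
        raise ValueError("coded points must have 3 columns")
    cols = []
    for t in terms:
        p = _TERM_POWERS[t]
        cols.append(coded[:, 0] ** p[0] * coded[:, 1] ** p[1] * coded[:, 2] ** p[2])
    return np.column_stack(cols)


class ResponseTable:
    """Measured responses keyed by name, one value per design run."""

    def __init__(self, design: DesignMatrix, responses: pd.DataFrame):
        responses = pd.DataFrame(responses)
        if len(responses) != design.n_runs:
            raise ValueError(
                f"responses have {len(responses)} rows for a {design.n_runs}-run design"
            )
        self.design = design
        self.responses = responses.reset_index(drop=True)

    @property
    def response_names(self) -> list[str]:
        return list(self.responses.columns)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.responses[name].to_numpy(dtype=float)


class ResponseSurfaceModel:
    """Polynomial response-surface model on coded factors, fit by OLS.

    Parameters
    ----------
    study : ResponseTable
        The designed study providing coded levels and measured responses.
    response : str
        Which response column to model.
    terms : {"quadratic", "linear"} or explicit list of term names
        Model complexity.  ``"quadratic"`` is the full 10-term model
        (intercept, 3 main effects, 3 two-way interactions, 3 quadratics);
        ``"linear"`` is intercept plus main effects.  An explicit list must
        contain the intercept, and interactions/quadratics require the
        corresponding main effects (model hierarchy).
    """

    def __init__(self, study: ResponseTable, response: str, terms="quadratic"):
        if response not in study.response_names:
            raise KeyError(f"response {response!r} not present in study")
        self.study = study
        self.response = response
        self.terms = self._resolve_terms(terms)
        self.endog = study[response]
        self.exog = polynomial_terms(study.design.coded_levels, self.terms)
        if len(self.endog) < len(self.terms):
            raise ValueError(
                f"{len(self.terms)}-term model needs at least that many runs, "
                f"have {len(self.endog)}"
            )
        self._check_rank()

    @staticmethod
    def _resolve_terms(terms) -> list[str]:
        if terms == "quadratic":
            return list(QUADRATIC_TERMS)
        if terms == "linear":
            return list(LINEAR_TERMS)
        terms = list(terms)
        unknown = [t for t in terms if t not in _TERM_POWERS]
        if unknown:
            raise ValueError(f"unknown model terms: {unknown}")
        if "b0" not in terms:
            raise ValueError("the intercept b0 is always part of the model")
        mains = {"1": "b1", "2": "b2", "3": "b3"}
        for t in terms:
            for digit in set(t[1:]):
                if t != "b0" and mains[digit] not in terms:
                    raise ValueError(f"term {t} requires main effect {mains[digit]}")
        return [t for t in QUADRATIC_TERMS if t in terms]

    def _check_rank(self) -> None:
        # incremental rank check so the offending term can be named
        rank = 0
        for j in range(self.exog.shape[1]):
            new_rank = np.linalg.matrix_rank(self.exog[:, : j + 1], tol=None)
            if new_rank == rank:
                raise ValueError(
                    f"design does not support term {self.terms[j]!r} "
                    "(column linearly dependent on earlier terms)"
                )
            rank = new_rank

    def fit(self) -> "RSMResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return RSMResults(self, res)


@dataclass
class LackOfFit:
    """Lack-of-fit F test against pure error from replicated runs."""

    f_value: float
    p_value: float
    ss_lack_of_fit: float
    df_lack_of_fit: int
    ss_pure_error: float
    df_pure_error: int

    @property
    def pure_error_ms(self) -> float:
        return self.ss_pure_error / self.df_pure_error


class RSMResults:
    """Fitted response-surface model: estimates, uncertainty, diagnostics."""

    def __init__(self, model: ResponseSurfaceModel, sm_results):
        self.model = model
        self._sm = sm_results
        terms = model.terms
        self.params = pd.Series(sm_results.params, index=terms, name="estimate")
        self.bse = pd.Series(sm_results.bse, index=terms, name="std_error")
        self.tvalues = pd.Series(sm_results.tvalues, index=terms, name="t")
        self.pvalues = pd.Series(sm_results.pvalues, index=terms, name="p")
        self.df_resid = int(sm_results.df_resid)
        self.mse_resid = float(sm_results.mse_resid)
        self.resid = np.asarray(sm_results.resid)
        self.fittedvalues = np.asarray(sm_results.fittedvalues)
        self.nobs = int(sm_results.nobs)
        self.rsquared = float(sm_results.rsquared)
        self.rsquared_adj = float(sm_results.rsquared_adj)
        self.press = self._compute_press()
        sst = float(np.sum((model.endog - model.endog.mean()) ** 2))
        self.rsquared_pred = 1.0 - self.press / sst if sst > 0 else np.nan
        self.lack_of_fit = self._compute_lack_of_fit()

    # -- diagnostics -------------------------------------------------------

    def _compute_press(self) -> float:
        """PRESS via the leverage identity: sum of (e_i / (1 - h_ii))^2."""
        h = self._sm.get_influence().hat_matrix_diag
        # leverage of 1 means the point determines its own fit; deletion
        # residual is undefined there and PRESS diverges
        if np.any(h >= 1 - 1e-12):
            return float("inf")
        return float(np.sum((self.resid / (1.0 - h)) ** 2))

    def _compute_lack_of_fit(self) -> LackOfFit | None:
        """Partition SSres into pure error (replicates) and lack of fit.

        Replicates are runs with identical *coded* rows.  Returns None when
        the design has no replicates or no lack-of-fit degrees of freedom.
        """
        coded = self.model.study.design.coded_levels
        y = self.model.endog
        groups: dict[tuple, list[int]] = {}
        for i, row in enumerate(coded):
            groups.setdefault(tuple(row), []).append(i)
        ss_pe = 0.0
        df_pe = 0
        for idx in groups.values():
            if len(idx) > 1:
                vals = y[idx]
                ss_pe += float(np.sum((vals - vals.mean()) ** 2))
                df_pe += len(idx) - 1
        if df_pe == 0:
            return None
        ss_res = float(np.sum(self.resid**2))
        df_lof = self.df_resid - df_pe
        if df_lof <= 0:
            return None
        ss_lof = max(ss_res - ss_pe, 0.0)
        if ss_pe == 0.0:
            f = np.inf if ss_lof > 0 else np.nan
            p = 0.0 if ss_lof > 0 else np.nan
        else:
            f = (ss_lof / df_lof) / (ss_pe / df_pe)
            p = float(stats.f.sf(f, df_lof, df_pe))
        return LackOfFit(float(f), float(p), ss_lof, df_lof, ss_pe, df_pe)

    # -- interface ---------------------------------------------------------

    def predict(self, coded_points) -> np.ndarray | float:
        """Evaluate the fitted polynomial at coded point(s).

        Points outside the [-1, 1]^3 experimental cube are extrapolations;
        they are evaluated but a warning is emitted.
        """
        pts = np.atleast_2d(np.asarray(coded_points, dtype=float))
        if np.any(np.abs(pts) > 1.0 + 1e-9):
            warnings.warn(
                "prediction outside the coded [-1, 1]^3 experimental region",
                stacklevel=2,
            )
        out = polynomial_terms(pts, self.model.terms) @ self.params.to_numpy()
        return float(out[0]) if np.asarray(coded_points).ndim == 1 else out

    def significant_terms(self, alpha: float = 0.05) -> pd.Series:
        """Boolean flag per term: p strictly below ``alpha``."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        return self.pvalues < alpha

    def coefficients_table(self, alpha: float = 0.05) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "estimate": self.params,
                "std_error": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )
        df["significant"] = self.significant_terms(alpha)
        return df

    def summary(self, alpha: float = 0.05) -> str:
        lines = [
            f"Response surface fit: {self.model.response}",
            f"terms: {', '.join(self.model.terms)}   "
            f"n = {self.nobs}, df_resid = {self.df_resid}",
            "",
            f"{'term':>5} {'estimate':>10} {'std_err':>9} {'t':>8} {'p':>8}  sig",
        ]
        for t in self.model.terms:
            star = "*" if self.pvalues[t] < alpha else ""
            lines.append(
                f"{t:>5} {self.params[t]:>10.4f} {self.bse[t]:>9.4f} "
                f"{self.tvalues[t]:>8.2f} {self.pvalues[t]:>8.4f}  {star}"
            )
        lines.append("")
        lines.append(
            f"R2 = {self.rsquared:.4f}   adj R2 = {self.rsquared_adj:.4f}   "
            f"pred R2 = {self.rsquared_pred:.4f}   PRESS = {self.press:.5g}"
        )
        if self.lack_of_fit is not None:
            lof = self.lack_of_fit
            lines.append(
                f"lack of fit: F({lof.df_lack_of_fit}, {lof.df_pure_error}) = "
                f"{lof.f_value:.3f}, p = {lof.p_value:.4f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "response": self.model.response,
            "terms": {
                t: {
                    "estimate": float(self.params[t]),
                    "std_error": float(self.bse[t]),
                    "t": float(self.tvalues[t]),
                    "p": float(self.pvalues[t]),
                }
                for t in self.model.terms
            },
            "mse_resid": self.mse_resid,
            "df_resid": self.df_resid,
            "rsquared": self.rsquared,
            "rsquared_adj": self.rsquared_adj,
            "rsquared_pred": self.rsquared_pred,
            "press": self.press,
        }
        if self.lack_of_fit is not None:
            d["lack_of_fit"] = {
                "F": self.lack_of_fit.f_value,
                "p": self.lack_of_fit.p_value,
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
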