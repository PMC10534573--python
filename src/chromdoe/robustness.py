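"""Plackett-Burman robustness screening of quantitative method performance.

A saturated 12-run Plackett-Burman plan estimates up to 11 main effects on
each peak-area response.  Columns left unassigned to real factors ("dummy"
columns) estimate only noise; the root-mean-square of the dummy effects
serves as the standard error of an effect, giving a t test with as many
degrees of freedom as there are dummies.  Lenth's pseudo-standard-error is
available as an alternative that needs no dummy columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .designs import DesignMatrix, PB12_DUMMY_LETTERS

__all__ = ["FactorRole", "PBStudy", "PlackettBurmanModel", "PBResults"]


@dataclass(frozen=True)
class FactorRole:
    """Assignment of one design column: a real factor or a dummy."""

    kind: str  # "real" or "dummy"
    label: str = ""
    low: float | None = None
    high: float | None = None
    unit: str = ""

    def __post_init__(self):
        if self.kind not in ("real", "dummy"):
            raise ValueError("kind must be 'real' or 'dummy'")
        if self.kind == "real" and (self.low is None or self.high is None):
            raise ValueError("real factors need natural low/high levels")


class PBStudy:
    """A Plackett-Burman screening study: plan, column roles, responses."""

    def __init__(self, design: DesignMatrix, roles: dict[str, FactorRole],
                 responses: pd.DataFrame):
        design.validate()
        if design.kind != "pb12":
            raise ValueError("PBStudy requires a pb12 design")
        if set(roles) != set(design.factor_names):
            raise ValueError("roles must cover exactly the design columns")
        responses = pd.DataFrame(responses).reset_index(drop=True)
        if len(responses) != design.n_runs:
            raise ValueError(f"responses must have {design.n_runs} rows")
        self.design = design
        self.roles = dict(roles)
        self.responses = responses

    @property
    def real_factors(self) -> list[str]:
        return [n for n in self.design.factor_names if self.roles[n].kind == "real"]

    @property
    def dummy_factors(self) -> list[str]:
        return [n for n in self.design.factor_names if self.roles[n].kind == "dummy"]

    @property
    def response_names(self) -> list[str]:
        return list(self.responses.columns)

    def factor_label(self, name: str) -> str:
        role = self.roles[name]
        return role.label or name


def default_roles() -> dict[str, FactorRole]:
    """The 7-real + 4-dummy column layout of the robustness study."""
    roles = {
        "A": FactorRole("real", "initial methanol content", 37.5, 39.5, "% v/v"),
        "C": FactorRole("real", "final methanol content", 76.5, 78.5, "% v/v"),
        "D": FactorRole("real", "gradient duration", 16.0, 16.5, "min"),
        "F": FactorRole("real", "re-equilibration duration", 5.0, 10.0, "min"),
        "H": FactorRole("real", "flow rate", 0.9, 1.1, "mL/min"),
        "K": FactorRole("real", "column temperature", 25.0, 35.0, "degC"),
        "L": FactorRole("real", "detection wavelength", 229.0, 231.0, "nm"),
    }
    for d in PB12_DUMMY_LETTERS:
        roles[d] = FactorRole("dummy", f"dummy {1 + PB12_DUMMY_LETTERS.index(d)}")
    return roles


class PlackettBurmanModel:
    """Main-effects screening model for a :class:`PBStudy`."""

    def __init__(self, study: PBStudy):
        self.study = study

    def fit(self, method: str = "dummy") -> "PBResults":
        """Estimate effects and their error.

        ``method="dummy"`` (default) derives the effect standard error from
        the root-mean-square of the dummy-column effects, with one degree of
        freedom per dummy.  ``method="lenth"`` uses Lenth's pseudo-standard
        error computed from all 11 effects, with 11/3 effective degrees of
        freedom.
        """
        study = self.study
        coded = study.design.coded_levels
        counts = (coded > 0).sum(axis=0)
        if not np.all(counts * 2 == study.design.n_runs):
            raise ValueError("unbalanced design column: effects are not estimable")
        y = study.responses.to_numpy(dtype=float)
        n = study.design.n_runs
        # effect = mean at high level - mean at low level = 2/n * x'y
        effects = pd.DataFrame(
            (2.0 / n) * coded.T @ y,
            index=study.design.factor_names,
            columns=study.response_names,
        )
        if method == "dummy":
            dummies = study.dummy_factors
            if not dummies:
                raise ValueError("dummy-based error estimation needs >= 1 dummy column")
            se = np.sqrt((effects.loc[dummies] ** 2).mean(axis=0))
            df = len(dummies)
        elif method == "lenth":
            se, df = _lenth_pse(effects)
        else:
            raise ValueError(f"unknown method {method!r}")
        return PBResults(study, effects, pd.Series(se, index=study.response_names), df, method)


def _lenth_pse(effects: pd.DataFrame) -> tuple[pd.Series, float]:
    """Lenth's pseudo-standard-error per response; df = m/3 for m effects."""
    pse = {}
    for col in effects.columns:
        a = effects[col].abs().to_numpy()
        s0 = 1.5 * np.median(a)
        trimmed = a[a < 2.5 * s0] if s0 > 0 else a
        pse[col] = 1.5 * np.median(trimmed) if len(trimmed) else 0.0
    return pd.Series(pse), effects.shape[0] / 3.0


class PBResults:
    """Estimated Plackett-Burman effects with dummy-derived significance."""

    def __init__(self, study: PBStudy, effects: pd.DataFrame, se_effect: pd.Series,
                 df: float, method: str):
        self.study = study
        self.effects = effects
        self.se_effect = se_effect
        self.df = df
        self.method = method
        self.tvalues = pd.DataFrame(index=effects.index, columns=effects.columns, dtype=float)
        self.pvalues = pd.DataFrame(index=effects.index, columns=effects.columns, dtype=float)
        for col in effects.columns:
            se = se_effect[col]
            # a spread at floating rounding level counts as zero
            scale = max(1.0, float(effects[col].abs().max()))
            if se <= 1e-12 * scale:
                warnings.warn(
                    f"zero dummy-effect spread for response {col!r}; "
                    "any nonzero effect is reported as significant",
                    stacklevel=2,
                )
                nonzero = effects[col].abs() > 1e-12 * scale
                self.tvalues[col] = np.where(nonzero, np.inf * np.sign(effects[col]), 0.0)
                self.pvalues[col] = np.where(nonzero, 0.0, 1.0)
            else:
                t = effects[col] / se
                self.tvalues[col] = t
                self.pvalues[col] = 2.0 * stats.t.sf(np.abs(t), df)

    def significant(self, alpha: float = 0.05, include_dummies: bool = False) -> pd.DataFrame:
        """Boolean flags, p strictly below alpha; real factors only by default."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        flags = self.pvalues < alpha
        if not include_dummies:
            flags = flags.loc[self.study.real_factors]
        return flags

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        """(factor, response) pairs flagged among real factors."""
        flags = self.significant(alpha)
        return [
            (f, r)
            for f in flags.index
            for r in flags.columns
            if flags.loc[f, r]
        ]

    def table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Long-format effect table with roles, t, p and flags."""
        rows = []
        for f in self.effects.index:
            role = self.study.roles[f]
            for r in self.effects.columns:
                rows.append(
                    {
                        "factor": f,
                        "label": self.study.factor_label(f),
                        "role": role.kind,
                        "response": r,
                        "effect": self.effects.loc[f, r],
                        "se_effect": self.se_effect[r],
                        "t": self.tvalues.loc[f, r],
                        "p": self.pvalues.loc[f, r],
                        "significant": bool(
                            role.kind == "real" and self.pvalues.loc[f, r] < alpha
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self, alpha: float = 0.05) -> str:
        lines = [
            f"Plackett-Burman screening ({self.method} error, df = {self.df:g}, "
            f"alpha = {alpha})",
            "",
        ]
        for r in self.effects.columns:
            lines.append(f"response {r}  (SE of effect = {self.se_effect[r]:.4g})")
            for f in self.effects.index:
                role = self.study.roles[f]
                star = "*" if (role.kind == "real" and self.pvalues.loc[f, r] < alpha) else ""
                lines.append(
                    f"  {f} ({self.study.factor_label(f)}): effect = "
                    f"{self.effects.loc[f, r]:>10.3f}  t = {self.tvalues.loc[f, r]:>7.2f}  "
                    f"p = {self.pvalues.loc[f, r]:.4f} {star}"
                )
            lines.append("")
        sig = self.significant_pairs(alpha)
        if sig:
            lines.append("significant (factor -> response): " + ", ".join(
                f"{self.study.factor_label(f)} -> {r}" for f, r in sig))
        else:
            lines.append("no significant real-factor effects")
        return "\n".join(lines)
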