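"""Bundled study data and reference values.

Ships the two published study tables as plain CSV — the 16-run Box-Behnken
gradient-optimisation study and the 12-run Plackett-Burman robustness
screening — together with JSON reference files of the published model
coefficients and validation parameters.

Numeric parsing normalises thousands separators: the robustness table mixes
formats such as ``10,040.28`` and ``10624.03`` in the same column, so commas
are stripped before conversion and a decimal point is required.
"""

from __future__ import annotations

import json
import re
from importlib import resources

import numpy as np
import pandas as pd

from .designs import DesignMatrix, FactorSpec, PB12_LETTERS
from .robustness import PBStudy, default_roles
from .rsm import ResponseTable

__all__ = [
    "bbd_factors",
    "load_bbd_study",
    "load_pb_study",
    "table3_reference",
    "table5_reference",
    "BBD_RESPONSES",
    "PB_RESPONSES",
]

BBD_RESPONSES = ["t_e_imp_x", "t_b_imp_III", "t_imp_V", "W_USP", "t_range"]
PB_RESPONSES = ["P_imp_I", "P_imp_II", "P_API", "P_imp_III", "P_imp_IV", "P_imp_V"]

#: Default model complexity per response: full quadratic for the retention
#: responses, main effects only for the mean USP peak width.
DEFAULT_MODEL_TERMS = {
    "t_e_imp_x": "quadratic",
    "t_b_imp_III": "quadratic",
    "t_imp_V": "quadratic",
    "W_USP": "linear",
    "t_range": "quadratic",
}

_NUMBER = re.compile(r"^-?\d+(\.\d+)?$")


def _data_path(name: str):
    return resources.files("chromdoe.data").joinpath(name)


def parse_numeric(cell, row=None, column=None) -> float:
    """Parse one numeric cell, stripping thousands separators.

    Raises with the offending row/column on malformed input.
    """
    s = str(cell).strip().replace(",", "")
    if not _NUMBER.match(s):
        where = f" at row {row}, column {column}" if column is not None else ""
        raise ValueError(f"malformed numeric cell {cell!r}{where}")
    return float(s)


def _read_numeric_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    out = {}
    for col in df.columns:
        out[col] = [
            parse_numeric(v, row=i + 1, column=col) for i, v in enumerate(df[col])
        ]
    return pd.DataFrame(out)


def bbd_factors() -> list[FactorSpec]:
    """The three gradient-programme factors with their study ranges."""
    return [
        FactorSpec("methanol_initial", 37.5, 2.5, "% v/v"),
        FactorSpec("methanol_final", 80.0, 5.0, "% v/v"),
        FactorSpec("gradient_duration", 17.5, 2.5, "min"),
    ]


def load_bbd_study(path=None) -> ResponseTable:
    """The 16-run Box-Behnken gradient study (bundled by default).

    A CSV must carry a run_id column, the three factor columns in natural
    units, and the five response columns.  Retention responses must be
    strictly positive and the elution span smaller than the last-peak
    retention time on every run.
    """
    df = _read_numeric_csv(path if path is not None else _data_path("table2.csv"))
    factors = bbd_factors()
    expected = ["run_id"] + [f.name for f in factors] + BBD_RESPONSES
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"study file missing columns: {missing}")
    coded = np.column_stack([f.to_coded(df[f.name].to_numpy()) for f in factors])
    design = DesignMatrix("bbd3", [f.name for f in factors], coded,
                          run_ids=[int(r) for r in df["run_id"]])
    design.validate()
    responses = df[BBD_RESPONSES]
    for col in ("t_e_imp_x", "t_b_imp_III", "t_imp_V", "t_range"):
        if not (responses[col] > 0).all():
            raise ValueError(f"retention response {col!r} must be strictly positive")
    if not (responses["t_range"] < responses["t_imp_V"]).all():
        raise ValueError("elution span t_range must be below t_imp_V on every run")
    return ResponseTable(design, responses)


def load_pb_study(path=None, roles=None) -> PBStudy:
    """The 12-run Plackett-Burman robustness study (bundled by default).

    Real-factor columns are given in natural units and coded to +/-1 from
    their observed low/high levels; dummy columns are already +/-1.
    """
    df = _read_numeric_csv(path if path is not None else _data_path("table4.csv"))
    roles = roles or default_roles()
    missing = [c for c in PB12_LETTERS + PB_RESPONSES if c not in df.columns]
    if missing:
        raise ValueError(f"study file missing columns: {missing}")
    coded = np.empty((len(df), 11))
    for j, letter in enumerate(PB12_LETTERS):
        col = df[letter].to_numpy(dtype=float)
        lo, hi = col.min(), col.max()
        if lo == hi:
            raise ValueError(f"column {letter!r} is constant; two levels required")
        coded[:, j] = 2.0 * (col - lo) / (hi - lo) - 1.0
    design = DesignMatrix("pb12", list(PB12_LETTERS), coded,
                          run_ids=[int(r) for r in df["run_id"]])
    return PBStudy(design, roles, df[PB_RESPONSES])


def table3_reference() -> dict:
    """Published coded-factor coefficients and R-squared values."""
    with _data_path("table3_reference.json").open() as fh:
        return json.load(fh)


def table5_reference() -> dict:
    """Published validation parameters (reference metadata)."""
    with _data_path("table5_reference.json").open() as fh:
        return json.load(fh)
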