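"""End-to-end workflow: configuration, pipeline stages, reports.

Ties the stages together the way a method-development run proceeds: fit the
response-surface models, map the design-space probability, verify the
working point, and screen quantitative robustness.  Every artifact embeds
the seed and a hash of the configuration so a run is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .datasets import (
    DEFAULT_MODEL_TERMS,
    bbd_factors,
    load_bbd_study,
    load_pb_study,
)
from .design_space import (
    CMACriterion,
    DesignSpace,
    GridSpec,
    MonteCarloConfig,
)
from .designs import FactorSpec
from .robustness import PlackettBurmanModel
from .rsm import ResponseSurfaceModel, ResponseTable

__all__ = ["WorkflowConfig", "run_pipeline", "fit_all_models", "table3_style_report"]

log = logging.getLogger("chromdoe")


@dataclass
class WorkflowConfig:
    """Validated configuration of the full pipeline."""

    factors: list[FactorSpec]
    models: dict[str, str]
    cmas: list[CMACriterion]
    grid: GridSpec
    monte_carlo: MonteCarloConfig
    pi_min: float = 0.8
    working_point: tuple[float, ...] | None = None
    slice_factor: str | None = None
    slice_value: float | None = None
    seed: int = 20230914
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "WorkflowConfig":
        factors = [FactorSpec(**f) for f in d["factors"]]
        models = dict(d.get("models", DEFAULT_MODEL_TERMS))
        cmas = []
        for c in d["cmas"]:
            c = dict(c)
            name = c.pop("name")
            cmas.append(CMACriterion(name=name, **c))
        # axis order follows the declared factors, not config key order
        # (YAML serialisers may sort mapping keys)
        factor_names = [f.name for f in factors]
        if set(d["grid"]) != set(factor_names):
            raise ValueError(
                f"grid must cover exactly the declared factors {factor_names}"
            )
        grid = GridSpec({k: tuple(d["grid"][k]) for k in factor_names})
        mc_d = dict(d.get("monte_carlo", {}))
        seed = int(d.get("seed", 20230914))
        mc = MonteCarloConfig(
            n_iterations=int(mc_d.get("n_iterations", 5000)),
            seed=int(mc_d.get("seed", seed)),
            perturbation=mc_d.get("perturbation", "uniform_halfwidth_se"),
        )
        sl = d.get("slice", {}) or {}
        cfg = cls(
            factors=factors,
            models=models,
            cmas=cmas,
            grid=grid,
            monte_carlo=mc,
            pi_min=float(d.get("pi_min", 0.8)),
            working_point=tuple(d["working_point"]) if d.get("working_point") else None,
            slice_factor=sl.get("fixed_factor"),
            slice_value=sl.get("fixed_value"),
            seed=seed,
            raw=d,
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "WorkflowConfig":
        from importlib import resources

        path = resources.files("chromdoe.data").joinpath("default_config.yaml")
        with path.open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        names = [f.name for f in self.factors]
        if len(names) != 3:
            raise ValueError("configuration must declare exactly 3 factors")
        if self.grid.factor_names != names:
            raise ValueError("grid factors must match declared factors in order")
        for c in self.cmas:
            for r in c.responses:
                if r not in self.models:
                    raise ValueError(
                        f"criterion {c.name!r} references response {r!r} "
                        "with no declared model"
                    )
        if not 0 <= self.pi_min <= 1:
            raise ValueError("pi_min must lie in [0, 1]")
        if self.slice_factor is not None and self.slice_factor not in names:
            raise ValueError(f"slice factor {self.slice_factor!r} is not a declared factor")

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def fit_all_models(study: ResponseTable, model_terms: dict[str, str]):
    """Fit every configured response; returns name -> RSMResults."""
    fitted = {}
    for resp, terms in model_terms.items():
        if resp not in study.response_names:
            raise ValueError(f"configured response {resp!r} absent from the study")
        fitted[resp] = ResponseSurfaceModel(study, resp, terms).fit()
    return fitted


def table3_style_report(fitted: dict) -> str:
    """Coefficient/diagnostics table: 13 statistic rows x one column per response.

    Rows: the ten polynomial terms (cells without the term show "/") and the
    three determination coefficients.
    """
    from .rsm import QUADRATIC_TERMS

    responses = list(fitted)
    width = max(len(r) for r in responses) + 2
    header = f"{'':>8}" + "".join(f"{r:>{width}}" for r in responses)
    lines = [header]
    for t in QUADRATIC_TERMS:
        cells = []
        for r in responses:
            res = fitted[r]
            if t in res.model.terms:
                star = "*" if res.pvalues[t] < 0.05 else ""
                cells.append(f"{res.params[t]:.4f}{star}")
            else:
                cells.append("/")
        lines.append(f"{t:>8}" + "".join(f"{c:>{width}}" for c in cells))
    for label, attr in (("R2", "rsquared"), ("adj.R2", "rsquared_adj"),
                        ("pred.R2", "rsquared_pred")):
        cells = [f"{getattr(fitted[r], attr):.4f}" for r in responses]
        lines.append(f"{label:>8}" + "".join(f"{c:>{width}}" for c in cells))
    return "\n".join(lines)


def run_pipeline(config: WorkflowConfig, outdir, bbd_path=None, pb_path=None,
                 validation_path=None) -> dict:
    """Run fit -> design space -> working point -> robustness; write artifacts.

    Returns a dict of artifact paths.  Any stage failure aborts with the
    stage name and cause.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    artifacts: dict[str, Path] = {}

    def stage(name):
        log.info("stage %s starting", name)

    try:
        stage("fit")
        study = load_bbd_study(bbd_path)
        fitted = fit_all_models(study, config.models)
        models_json = {r: res.to_dict() for r, res in fitted.items()}
        models_json["_meta"] = meta
        artifacts["models"] = outdir / "models.json"
        artifacts["models"].write_text(json.dumps(models_json, indent=2))
        artifacts["coefficient_report"] = outdir / "coefficient_report.txt"
        artifacts["coefficient_report"].write_text(
            table3_style_report(fitted) + f"\n\n# config {meta['config_hash']} seed {meta['seed']}\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    try:
        stage("design_space")
        ds = DesignSpace(fitted, config.factors, config.cmas)
        log.info("Monte Carlo: %d points x %d iterations, seed %d",
                 config.grid.n_points, config.monte_carlo.n_iterations,
                 config.monte_carlo.seed)
        pg = ds.probability_map(config.grid, config.monte_carlo)
        artifacts["pi_map"] = outdir / "pi_map.csv"
        pg.to_csv(artifacts["pi_map"])
        region = pg.design_space(config.pi_min)
        ds_meta = pg.metadata() | meta | {
            "pi_min": config.pi_min,
            "ds_points": region.n_points,
            "ds_fraction": region.n_points / config.grid.n_points,
            "bounding_box": region.bounding_box,
        }
        artifacts["ds_summary"] = outdir / "ds_summary.json"
        artifacts["ds_summary"].write_text(json.dumps(ds_meta, indent=2))
        if config.slice_factor is not None:
            free = {n: config.grid.axes[n] for n in config.grid.factor_names
                    if n != config.slice_factor}
            pg2 = ds.slice_2d(config.slice_factor, config.slice_value,
                              GridSpec(free), config.monte_carlo)
            artifacts["pi_slice"] = outdir / "pi_slice.csv"
            pg2.to_csv(artifacts["pi_slice"])
        if config.working_point is not None:
            report = ds.working_point_report(config.working_point)
            artifacts["working_point"] = outdir / "working_point.csv"
            report.to_csv(artifacts["working_point"], index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'design_space' failed: {exc}") from exc

    try:
        stage("robustness")
        pb = load_pb_study(pb_path)
        pbres = PlackettBurmanModel(pb).fit()
        artifacts["pb_effects"] = outdir / "pb_effects.csv"
        pbres.table().to_csv(artifacts["pb_effects"], index=False)
        artifacts["pb_report"] = outdir / "pb_report.txt"
        artifacts["pb_report"].write_text(
            pbres.summary() + f"\n\n# config {meta['config_hash']} seed {meta['seed']}\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'robustness' failed: {exc}") from exc

    if validation_path is not None:
        try:
            stage("validation")
            artifacts["validation"] = outdir / "validation_report.json"
            artifacts["validation"].write_text(
                json.dumps(validation_report_from_csv(validation_path), indent=2)
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'validation' failed: {exc}") from exc

    return artifacts


def validation_report_from_csv(path) -> dict:
    """Accuracy/precision report from a CSV of (analyte, class, level, found, nominal)."""
    import pandas as pd

    from .validation import recovery, rsd, rsd_acceptable

    df = pd.read_csv(path)
    required = {"analyte", "class", "level", "found", "nominal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"validation input missing columns: {sorted(missing)}")
    report: dict = {}
    for (analyte, cls), grp in df.groupby(["analyte", "class"]):
        levels = {}
        for level, lg in grp.groupby("level"):
            recs = [recovery(f, n, cls) for f, n in zip(lg["found"], lg["nominal"])]
            mean_rec = sum(r.percent for r in recs) / len(recs)
            entry = {
                "recovery_percent": mean_rec,
                "recovery_acceptable": all(r.acceptable for r in recs),
            }
            if len(lg) >= 2:
                entry["rsd_percent"] = rsd(lg["found"])
                entry["rsd_acceptable"] = rsd_acceptable(entry["rsd_percent"], cls)
            levels[str(level)] = entry
        report[analyte] = {"class": cls, "levels": levels}
    return report
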