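"""Run configuration and the calibrate -> fit -> compare -> breakdown pipeline."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibrate import ElectrodeModel, calibrate_electrode
from .errors import ConfigurationError, ProtospecError
from .fit import WeightingScheme, compare_models, fit_protonation_model
from .groups import DEFAULT_LOGK_THRESHOLD, breakdown_from_composition
from .io import read_composition, read_electrode, read_model, read_titration

logger = logging.getLogger("protospec")

__all__ = ["RunConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "stages",
    "titration",
    "calibration_titration",
    "electrode",
    "models",
    "composition",
    "weighting",
    "threshold_logk",
    "refine",
    "refine_strong_acid",
    "ph_min",
    "ph_max",
    "outdir",
    "log_level",
}

_STAGES = ("calibrate", "fit", "compare", "breakdown")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    stages: list[str] = field(default_factory=list)
    titration: str | None = None
    calibration_titration: str | None = None
    electrode: str | dict | None = None
    models: list[str] = field(default_factory=list)
    composition: str | None = None
    weighting: dict = field(default_factory=dict)
    threshold_logk: float = DEFAULT_LOGK_THRESHOLD
    refine: list[str] = field(default_factory=lambda: ["e0"])
    refine_strong_acid: bool = False
    ph_min: float | None = None
    ph_max: float | None = None
    outdir: str = "protospec_out"
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        bad = [s for s in cfg.stages if s not in _STAGES]
        if bad:
            raise ConfigurationError(f"unknown stages: {bad}; allowed {_STAGES}")
        if "fit" in cfg.stages or "compare" in cfg.stages:
            if not cfg.titration:
                raise ConfigurationError("fit/compare stages need a titration file")
            if not cfg.models:
                raise ConfigurationError("fit/compare stages need model files")
        if "calibrate" in cfg.stages and not cfg.calibration_titration:
            raise ConfigurationError("calibrate stage needs calibration_titration")
        if "breakdown" in cfg.stages and not cfg.composition:
            raise ConfigurationError("breakdown stage needs a composition file")
        return cfg

    def resolved(self) -> dict:
        return {
            k: getattr(self, k)
            for k in sorted(_KNOWN_KEYS)
        }


def _load_electrode(cfg: RunConfig) -> ElectrodeModel:
    if cfg.electrode is None:
        raise ConfigurationError("an electrode (file or inline dict) is required")
    if isinstance(cfg.electrode, dict):
        return ElectrodeModel(**cfg.electrode)
    return read_electrode(cfg.electrode)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in workflow order; return the report.

    Writes ``report.json`` plus fit/breakdown CSV tables into
    ``config.outdir``.  Raises with the failing stage named; a run with
    no stages enabled is a warning-level no-op.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.resolved(), "version": __version__, "stages": {}}

    if not config.stages:
        logger.warning("no stages enabled; nothing to do")
        report["stages"] = {}
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        return report

    electrode: ElectrodeModel | None = None
    weighting = WeightingScheme(**config.weighting) if config.weighting else WeightingScheme()

    try:
        if "calibrate" in config.stages:
            stage = "calibrate"
            data = read_titration(config.calibration_titration)
            electrode, sds = calibrate_electrode(
                data, refine=tuple(config.refine), weighting=weighting
            )
            report["stages"]["calibrate"] = {
                "e0": electrode.e0,
                "slope": electrode.slope,
                "j_a": electrode.j_a,
                "pKw": electrode.pKw,
                "std_devs": sds,
            }
        if electrode is None and config.electrode is not None:
            electrode = _load_electrode(config)

        fit_results = {}
        if "fit" in config.stages or "compare" in config.stages:
            stage = "fit"
            if electrode is None:
                raise ConfigurationError("fit stage needs an electrode")
            data = read_titration(config.titration)
            structures = [read_model(p) for p in config.models]
            if "compare" in config.stages and len(structures) >= 2:
                stage = "compare"
                table, results = compare_models(
                    data,
                    electrode,
                    structures,
                    weighting,
                    refine_strong_acid=config.refine_strong_acid,
                    ph_min=config.ph_min,
                    ph_max=config.ph_max,
                )
                report["stages"]["compare"] = table.to_dict(orient="records")
                fit_results = {
                    k: v for k, v in results.items() if not isinstance(v, Exception)
                }
            else:
                res = fit_protonation_model(
                    data,
                    electrode,
                    structures[0],
                    weighting,
                    refine_strong_acid=config.refine_strong_acid,
                    ph_min=config.ph_min,
                    ph_max=config.ph_max,
                )
                fit_results = {structures[0].name: res}
            stage = "fit"
            fit_report = {}
            frames = []
            for name, res in fit_results.items():
                frame = res.summary()
                frame.insert(0, "model", name)
                frames.append(frame)
                fit_report[name] = {
                    "sigma_fit": res.sigma_fit,
                    "n_points": res.n_points,
                    "n_params": res.n_params,
                    "c_strong_acid": res.c_strong_acid,
                    "converged": res.converged,
                    "flagged": res.flagged,
                    "parameters": frame.drop(columns="model").to_dict(orient="records"),
                }
            report["stages"]["fit"] = fit_report
            pd.concat(frames).to_csv(outdir / "fit_parameters.csv", index=False)

        if "breakdown" in config.stages:
            stage = "breakdown"
            comp = read_composition(config.composition)
            if fit_results:
                best = min(fit_results.values(), key=lambda r: r.sigma_fit)
                source = best
            elif config.models:
                source = read_model(config.models[0])
            else:
                raise ConfigurationError(
                    "breakdown stage needs a fit result or a model file"
                )
            bd = breakdown_from_composition(comp, source, config.threshold_logk)
            report["stages"]["breakdown"] = {comp.name: bd.as_dict()}
            pd.DataFrame([{"SBO": comp.name, **bd.as_dict()}]).round(2).to_csv(
                outdir / "functional_groups.csv", index=False
            )
    except ProtospecError as err:
        raise ProtospecError(f"stage {stage!r} failed: {err}") from err

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
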