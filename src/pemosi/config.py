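"""Configuration loading, unit handling and the pipeline driver.

Config files are YAML (JSON is a YAML subset and therefore accepted).
Rates and concentrations may be written either as plain numbers (taken
in the field's native unit) or as ``{value: ..., unit: ...}`` mappings;
day/hour mixes are converted on load so the model always sees one
consistent internal scale.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from . import scenarios, synth
from .calibration import (fit_4pl, fit_egfr_recovery, fit_simeoni_control,
                          fit_two_compartment, TimeSeries)
from .model import derived_metrics, simulate
from .params import (EgfrPDParams, FolatePDParams, ModelParams, OsiPKParams,
                     PemPKParams, TGIParams)
from .regimen import build_regimen

log = logging.getLogger(__name__)

_BLOCK_TYPES = {"pem": PemPKParams, "osi": OsiPKParams,
                "folate": FolatePDParams, "egfr": EgfrPDParams,
                "tgi": TGIParams}

#: native unit of each dimensioned field, used for conversion/validation
NATIVE_UNITS = {
    "ka_pem": "1/h", "k12_pem": "1/h", "k21_pem": "1/h", "kel_pem": "1/h",
    "V1_pem": "L/kg",
    "ka_osi": "1/h", "k12_osi": "1/h", "k21_osi": "1/h", "kel_osi": "1/h",
    "V1_osi": "L/kg",
    "kout_enzyme": "1/h", "kout_folate": "1/h", "EC50_pem": "mg/L",
    "kout_EGFR": "1/day", "EC50_osi": "ug/L",
    "lambda0": "1/day", "lambda1": "mm^3/day", "k1": "1/day", "k2": "1/day",
    "V0": "mm^3",
}

_RATE_FACTORS = {("1/day", "1/h"): 1.0 / 24.0, ("1/h", "1/day"): 24.0,
                 ("mm^3/day", "mm^3/h"): 1.0 / 24.0,
                 ("mm^3/h", "mm^3/day"): 24.0}


def _convert(name: str, value: float, unit: str | None,
             problems: list[str]) -> float:
    native = NATIVE_UNITS.get(name)
    if unit is None or native is None or unit == native:
        return value
    factor = _RATE_FACTORS.get((unit, native))
    if factor is None:
        problems.append(f"{name}: cannot convert unit {unit!r} to "
                        f"{native!r}")
        return value
    return value * factor


@dataclass(frozen=True)
class RunConfig:
    params: ModelParams
    stages: tuple[str, ...] = ("simulate",)
    strategy: str = "sequential"
    interval_h: float = 48.0
    n_cycles: int = 3
    cycle_length_days: float = 7.0
    out_dir: Path = Path("pemosi_out")
    seed: int = 0
    engine: str = "lsoda"
    n_subjects: int = 2000
    gsa_n_samples: int = 256
    config_hash: str = ""


KNOWN_TOP_KEYS = {"parameters", "stages", "regimen", "out_dir", "seed",
                  "engine", "population", "gsa"}
KNOWN_STAGES = ("synth", "fit", "simulate", "intervals", "gsa", "population")


def load_config(path: str | Path) -> RunConfig:
    """Parse, validate and unit-convert a run configuration.

    All problems are collected and reported in a single error.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    problems: list[str] = []
    unknown = set(raw) - KNOWN_TOP_KEYS
    if unknown:
        problems.append(f"unknown top-level key(s): {sorted(unknown)}")

    blocks = {}
    for block_name, cls in _BLOCK_TYPES.items():
        entries = (raw.get("parameters") or {}).get(block_name, {}) or {}
        valid_fields = {f.name for f in dc_fields(cls)}
        kwargs = {}
        for key, val in entries.items():
            if key not in valid_fields:
                problems.append(f"parameters.{block_name}: unknown key "
                                f"{key!r}")
                continue
            if isinstance(val, dict):
                if "value" not in val:
                    problems.append(f"parameters.{block_name}.{key}: "
                                    "mapping form requires 'value'")
                    continue
                if set(val) - {"value", "unit"}:
                    problems.append(f"parameters.{block_name}.{key}: "
                                    "only 'value' and 'unit' allowed")
                    continue
                kwargs[key] = _convert(key, float(val["value"]),
                                       val.get("unit"), problems)
            elif isinstance(val, (int, float)):
                kwargs[key] = float(val)
            else:
                problems.append(f"parameters.{block_name}.{key}: malformed "
                                f"entry {val!r}")
        try:
            blocks[block_name] = cls(**kwargs)
        except ValueError as exc:
            problems.append(str(exc))
            blocks[block_name] = None

    stages = tuple(raw.get("stages", ["simulate"]))
    for s in stages:
        if s not in KNOWN_STAGES:
            problems.append(f"unknown stage {s!r}")
    reg = raw.get("regimen", {}) or {}
    pop = raw.get("population", {}) or {}
    gsa = raw.get("gsa", {}) or {}
    if problems:
        raise ValueError("invalid configuration:\n  - "
                         + "\n  - ".join(problems))
    params = ModelParams(pem=blocks["pem"], osi=blocks["osi"],
                         folate=blocks["folate"], egfr=blocks["egfr"],
                         tgi=blocks["tgi"])
    return RunConfig(
        params=params, stages=stages,
        strategy=reg.get("strategy", "sequential"),
        interval_h=float(reg.get("interval_h", 48.0)),
        n_cycles=int(reg.get("n_cycles", 3)),
        cycle_length_days=float(reg.get("cycle_length_days", 7.0)),
        out_dir=Path(raw.get("out_dir", "pemosi_out")),
        seed=int(raw.get("seed", 0)),
        engine=raw.get("engine", "lsoda"),
        n_subjects=int(pop.get("n_subjects", 2000)),
        gsa_n_samples=int(gsa.get("n_samples", 256)),
        config_hash=hashlib.sha256(text.encode()).hexdigest()[:16])


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

def _write_csv(df, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (f"# pemosi output; config_hash={cfg.config_hash}; "
              f"seed={cfg.seed}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the selected stages in calibration order.

    Writes CSV/JSON artifacts plus a manifest carrying the config hash
    and master seed; a stage failure aborts downstream stages and the
    partial manifest is still written.
    """
    order = [s for s in KNOWN_STAGES if s in cfg.stages]
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash,
                      "stages": {}, "outputs": []}
    results: dict = {"manifest": manifest}
    params = cfg.params
    try:
        for stage in order:
            t0 = time.perf_counter()
            log.info("stage %s starting", stage)
            if stage == "synth":
                reg = build_regimen(cfg.strategy, cfg.interval_h,
                                    n_cycles=cfg.n_cycles,
                                    cycle_length_days=cfg.cycle_length_days)
                curves, truth = synth.gen_tumor_curves(
                    params, build_regimen("control", n_cycles=cfg.n_cycles),
                    noise=synth.NoiseModel("lognormal",
                                           synth.TUMOR_NOISE_CV,
                                           seed=cfg.seed))
                import pandas as pd
                df = pd.concat([
                    pd.DataFrame({"time_h": c.times, "value": c.values,
                                  "animal": i})
                    for i, c in enumerate(curves)])
                _write_csv(df, out / "synthetic_control_volumes.csv", cfg)
                (out / "synthetic_control_volumes.truth.json").write_text(
                    truth.to_json())
                manifest["outputs"] += ["synthetic_control_volumes.csv",
                                        "synthetic_control_volumes.truth.json"]
                results["synth"] = curves
            elif stage == "fit":
                curves = results.get("synth")
                if curves is None:
                    curves, _ = synth.gen_tumor_curves(
                        params,
                        build_regimen("control", n_cycles=cfg.n_cycles),
                        noise=synth.NoiseModel("none", 0.0, seed=cfg.seed))
                mean_curve = TimeSeries(
                    curves[0].times,
                    np.mean([c.values for c in curves], axis=0))
                fit = fit_simeoni_control(mean_curve, V0=params.tgi.V0,
                                          k1_day=params.tgi.k1,
                                          k2_day=params.tgi.k2,
                                          psi=params.tgi.psi)
                payload = {"estimates": fit.estimates, "se": fit.se,
                           "objective": fit.objective,
                           "converged": fit.converged, "seed": cfg.seed}
                (out / "fit_simeoni_control.json").write_text(
                    json.dumps(payload, indent=2, default=float))
                manifest["outputs"].append("fit_simeoni_control.json")
                results["fit"] = fit
            elif stage == "simulate":
                reg = build_regimen(cfg.strategy, cfg.interval_h,
                                    n_cycles=cfg.n_cycles,
                                    cycle_length_days=cfg.cycle_length_days)
                ctrl = build_regimen("control", n_cycles=cfg.n_cycles,
                                     cycle_length_days=cfg.cycle_length_days)
                traj = simulate(reg, params, engine_name=cfg.engine)
                control = simulate(ctrl, params, engine_name=cfg.engine)
                df = traj.to_frame()
                df["TGIPct"] = derived_metrics(traj, control)["TGIPct"]
                _write_csv(df, out / "trajectory.csv", cfg)
                manifest["outputs"].append("trajectory.csv")
                results["simulate"] = traj
            elif stage == "intervals":
                import pandas as pd
                res = scenarios.compare_intervals(
                    params, [0.0, 24.0, 48.0, 72.0, 96.0],
                    n_cycles=cfg.n_cycles, engine_name=cfg.engine)
                df = pd.DataFrame({
                    "interval_h": res["intervals_h"],
                    "final_volume_mm3": [res["final_volume"][i]
                                         for i in res["intervals_h"]],
                    "total_dead_mm3": [res["total_dead"][i]
                                       for i in res["intervals_h"]]})
                _write_csv(df, out / "interval_comparison.csv", cfg)
                manifest["outputs"].append("interval_comparison.csv")
                results["intervals"] = res
            elif stage == "gsa":
                import pandas as pd
                spec = scenarios.default_sobol_spec(
                    params, n_samples=cfg.gsa_n_samples, seed=cfg.seed)
                reg = build_regimen(cfg.strategy, cfg.interval_h,
                                    n_cycles=cfg.n_cycles)
                res = scenarios.sobol_gsa(spec, params, reg)
                df = pd.DataFrame({"parameter": res.names,
                                   "first_order": res.first_order,
                                   "total_order": res.total_order})
                _write_csv(df, out / "sobol_indices.csv", cfg)
                manifest["outputs"].append("sobol_indices.csv")
                results["gsa"] = res
            elif stage == "population":
                import pandas as pd
                pspec = scenarios.PopulationSpec(n_subjects=cfg.n_subjects,
                                                 seed=cfg.seed)
                res = scenarios.run_population(pspec, params)
                df = pd.DataFrame({"time_h": res.times})
                for label, orr in res.responder_curves.items():
                    df[f"orr_{label}"] = orr
                _write_csv(df, out / "orr_curves.csv", cfg)
                (out / "population_summary.json").write_text(json.dumps(
                    {"time_averaged_orr": res.time_averaged_orr,
                     "excluded": res.excluded, "seed": cfg.seed,
                     "config_hash": cfg.config_hash},
                    indent=2, default=float))
                manifest["outputs"] += ["orr_curves.csv",
                                        "population_summary.json"]
                results["population"] = res
            manifest["stages"][stage] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3)}
            log.info("stage %s done in %.1fs", stage,
                     time.perf_counter() - t0)
    except Exception as exc:   # abort downstream, keep partial manifest
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        raise
    finally:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
    return results
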