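"""End-to-end run orchestration: simulate -> preprocess -> covariates ->
fit -> report -> project, with provenance and structured logging.

Every stochastic stage draws from the run seed, so rerunning a manifest
reproduces the simulated CSVs and the posterior draws bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cohort import simulate_cohort
from .covariates import build_covariates
from .inference import fit, posterior_histograms, summarize
from .io import RunConfig, load_config, write_dataset, write_params
from .preprocessing import preprocess
from .projection import example_scenario, magnitude_ratio, project_forward
from .types import Task

__all__ = ["run_all", "StageError"]

log = logging.getLogger("headerlag")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return obj.value
    return obj


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _draws_frame(result) -> pd.DataFrame:
    names = list(result.draws)
    n_chains, n_draws = result.draws[names[0]].shape
    cols = {
        "chain": np.repeat(np.arange(n_chains), n_draws),
        "draw": np.tile(np.arange(n_draws), n_chains),
    }
    for name in names:
        cols[name] = result.draws[name].reshape(-1)
    return pd.DataFrame(cols)


def run_all(config: RunConfig | str | Path, out_dir: str | Path) -> Path:
    """Execute the full pipeline into ``out_dir``; returns the directory.

    The manifest (config snapshot, seeds, file digests, stage timings) is
    written last, so its presence marks a complete run.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "stages": {},
        "files": {},
    }
    written: list[Path] = []

    def stage(name: str, fn):
        t0 = time.perf_counter()
        log.info("stage %s: start (seed=%d)", name, config.seed)
        try:
            result = fn()
        except Exception as exc:  # surface the failing stage
            log.error("stage %s: failed: %s", name, exc)
            raise StageError(name, exc) from exc
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"seconds": round(dt, 3)}
        log.info("stage %s: done in %.2fs", name, dt)
        return result

    try:
        # -- simulate ------------------------------------------------------
        def _simulate():
            cohort = simulate_cohort(config.generator)
            raw = out / "raw"
            paths = write_dataset(cohort.dataset, raw)
            write_params(config.generator.true_params, raw / "true_params.json")
            (raw / "provenance.json").write_text(
                json.dumps(
                    {
                        "seed": config.generator.seed,
                        "generator": _jsonable(config.generator),
                        "n_trials": cohort.dataset.n_trials(),
                    },
                    indent=1,
                )
            )
            written.extend(list(paths.values()) + [raw / "true_params.json", raw / "provenance.json"])
            return cohort

        cohort = stage("simulate", _simulate)

        # -- preprocess ----------------------------------------------------
        def _preprocess():
            clean, report = preprocess(cohort.dataset, config.preprocessing)
            pre = out / "preprocessed"
            paths = write_dataset(clean, pre)
            (pre / "preprocess_report.json").write_text(json.dumps(report.to_dict(), indent=1))
            written.extend(list(paths.values()) + [pre / "preprocess_report.json"])
            return clean, report

        clean, report = stage("preprocess", _preprocess)
        log.info(
            "preprocess: removed %.2f%% incorrect, %.2f%% of correct as outliers",
            100 * report.frac_incorrect,
            100 * report.frac_outliers,
        )

        # -- covariates (diagnostic export at generating half-lives) -------
        def _covariates():
            p = config.generator.true_params
            cov = build_covariates(
                clean,
                {Task.pro_point: p.hl_short_pro, Task.anti_point: p.hl_short_anti},
                {Task.pro_point: p.hl_long_pro, Task.anti_point: p.hl_long_anti},
                {Task.pro_point: p.hl_carry_pro, Task.anti_point: p.hl_carry_anti},
                base=config.decay_base,
            )
            rows = [
                {
                    "athlete_id": k[0],
                    "day_index": k[1],
                    "phase": k[2],
                    "task": k[3],
                    **dataclasses.asdict(c),
                }
                for k, c in cov.items()
            ]
            path = out / "covariates.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            written.append(path)
            return cov

        stage("covariates", _covariates)

        # -- fit -----------------------------------------------------------
        def _fit():
            return fit(clean, config.model_config(), config.sampler)

        result = stage("fit", _fit)
        if not result.converged:
            log.warning("fit: convergence warnings: %s", "; ".join(result.messages))

        # -- report --------------------------------------------------------
        def _report():
            frame = _draws_frame(result)
            frame.to_csv(out / "draws.csv", index=False)
            table = summarize(result)
            table.to_csv(out / "summary.csv", index=False)
            (out / "summary.json").write_text(
                json.dumps(_jsonable(table.to_dict(orient="records")), indent=1)
            )
            (out / "diagnostics.json").write_text(
                json.dumps(
                    {"converged": result.converged, "messages": result.messages,
                     "per_parameter": result.diagnostics},
                    indent=1,
                )
            )
            (out / "histograms.json").write_text(
                json.dumps(posterior_histograms(result), indent=1)
            )
            write_params(result.posterior_mean_params(), out / "posterior_means.json")
            written.extend(
                out / n
                for n in (
                    "draws.csv", "summary.csv", "summary.json",
                    "diagnostics.json", "histograms.json", "posterior_means.json",
                )
            )
            return table

        stage("report", _report)

        # -- project -------------------------------------------------------
        def _project():
            params = result.posterior_mean_params()
            frames = []
            for task in (Task.pro_point, Task.anti_point):
                scn = example_scenario(params, task)
                traj = project_forward(scn, [0, 10, 30])
                traj.insert(0, "task", task.value)
                traj["beta_ratio_long_over_short"] = magnitude_ratio(params, task)
                frames.append(traj)
            path = out / "projection.csv"
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
            written.append(path)

        stage("project", _project)

        manifest["files"] = {str(p.relative_to(out)): _digest(p) for p in written}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
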