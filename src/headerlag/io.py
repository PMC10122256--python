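"""CSV interchange for datasets, and YAML/JSON run configuration.

One file per entity, human-inspectable and diffable:

* ``athletes.csv``  — athlete_id, group, age_years
* ``trials.csv``    — athlete_id, day_index, phase, task, trial_index, rt_ms, correct
* ``exposures.csv`` — athlete_id, day_index, n_short, n_long

Occasions are carried by their trials (an occasion with no surviving trials
is not representable).  Reading and writing both canonicalize row order, so
``read_dataset(write_dataset(d))`` is the identity on canonically ordered
datasets and writing is byte-stable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import GeneratorConfig
from .covariates import _occasion_sort_key
from .inference import SamplerConfig
from .model import HALF_LIFE_PARAMS, ModelConfig, PriorSpec, default_priors
from .preprocessing import PreprocessConfig
from .types import (
    Athlete,
    Dataset,
    Group,
    HeaderExposure,
    ModelParameters,
    Phase,
    Task,
    TestOccasion,
    Trial,
    ValidationError,
)

__all__ = [
    "write_dataset",
    "read_dataset",
    "RunConfig",
    "load_config",
    "write_params",
    "read_params",
]

ATHLETE_COLS = ["athlete_id", "group", "age_years"]
TRIAL_COLS = ["athlete_id", "day_index", "phase", "task", "trial_index", "rt_ms", "correct"]
EXPOSURE_COLS = ["athlete_id", "day_index", "n_short", "n_long"]


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three entity CSVs; returns the paths keyed by entity."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    athletes = pd.DataFrame(
        [
            # repr() is the shortest representation that parses back to the
            # identical float, which pandas' default float formatting is not
            {"athlete_id": a.athlete_id, "group": a.group.value, "age_years": repr(a.age_years)}
            for a in sorted(dataset.athletes, key=lambda a: a.athlete_id)
        ],
        columns=ATHLETE_COLS,
    )
    trial_rows = []
    for occ in sorted(dataset.occasions, key=_occasion_sort_key):
        for i, t in enumerate(occ.trials):
            trial_rows.append(
                {
                    "athlete_id": occ.athlete_id,
                    "day_index": occ.day_index,
                    "phase": occ.phase.value,
                    "task": occ.task.value,
                    "trial_index": i,
                    "rt_ms": repr(t.rt_ms),
                    "correct": int(t.correct),
                }
            )
    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLS)
    exposures = pd.DataFrame(
        [
            {
                "athlete_id": e.athlete_id,
                "day_index": e.day_index,
                "n_short": e.n_short,
                "n_long": e.n_long,
            }
            for e in sorted(dataset.exposures, key=lambda e: (e.athlete_id, e.day_index))
        ],
        columns=EXPOSURE_COLS,
    )
    paths = {
        "athletes": out / "athletes.csv",
        "trials": out / "trials.csv",
        "exposures": out / "exposures.csv",
    }
    athletes.to_csv(paths["athletes"], index=False)
    trials.to_csv(paths["trials"], index=False)
    exposures.to_csv(paths["exposures"], index=False)
    return paths


def _check_columns(df: pd.DataFrame, expected: list[str], name: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing column(s) {missing}")


def read_dataset(
    in_dir: str | Path,
    *,
    require_complete: bool = False,
    min_trials: int = 48,
) -> Dataset:
    """Load and validate a dataset directory written by :func:`write_dataset`.

    ``require_complete`` enforces the raw-block invariant of at least
    ``min_trials`` trials per occasion; leave it off for preprocessed data.
    """
    d = Path(in_dir)
    # float_precision="round_trip": pandas' default float parser is not
    # correctly rounded, which would corrupt RTs in the last bit
    opts = dict(dtype={"athlete_id": str}, keep_default_na=False, float_precision="round_trip")
    athletes_df = pd.read_csv(d / "athletes.csv", **opts)
    trials_df = pd.read_csv(d / "trials.csv", **opts)
    exposures_df = pd.read_csv(d / "exposures.csv", **opts)
    _check_columns(athletes_df, ATHLETE_COLS, "athletes.csv")
    _check_columns(trials_df, TRIAL_COLS, "trials.csv")
    _check_columns(exposures_df, EXPOSURE_COLS, "exposures.csv")

    athletes = [
        Athlete(str(r.athlete_id), Group(r.group), float(r.age_years))
        for r in athletes_df.itertuples()
    ]
    occ_map: dict[tuple, TestOccasion] = {}
    if len(trials_df):
        trials_df = trials_df.sort_values(
            ["athlete_id", "day_index", "phase", "task", "trial_index"],
            kind="stable",
        )
        for r in trials_df.itertuples():
            key = (str(r.athlete_id), int(r.day_index), str(r.phase), str(r.task))
            occ = occ_map.get(key)
            if occ is None:
                occ = TestOccasion(
                    str(r.athlete_id), int(r.day_index), Phase(r.phase), Task(r.task), []
                )
                occ_map[key] = occ
            occ.trials.append(Trial(float(r.rt_ms), bool(int(r.correct))))
    occasions = sorted(occ_map.values(), key=_occasion_sort_key)
    exposures = [
        HeaderExposure(str(r.athlete_id), int(r.day_index), int(r.n_short), int(r.n_long))
        for r in exposures_df.itertuples()
    ]
    athletes.sort(key=lambda a: a.athlete_id)
    exposures.sort(key=lambda e: (e.athlete_id, e.day_index))
    dataset = Dataset(athletes, occasions, exposures)
    dataset.validate(require_complete=require_complete, min_trials=min_trials)
    return dataset


def write_params(params: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=1, sort_keys=True))


def read_params(path: str | Path) -> ModelParameters:
    return ModelParameters.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything a reproducible run needs: generator, priors, sampler,
    preprocessing, and the top-level seed (which overrides stage seeds)."""

    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    priors: dict[str, PriorSpec] = field(default_factory=default_priors)
    hl_lower: float = 0.5
    hl_upper: float = 500.0
    decay_base: float = 2.0
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __post_init__(self) -> None:
        if not self.hl_upper > 0 or not self.hl_upper > self.hl_lower or self.hl_lower < 0:
            raise ValidationError(
                f"half-life bounds ({self.hl_lower}, {self.hl_upper}] are not a valid support"
            )
        for name in HALF_LIFE_PARAMS:
            spec = self.priors[name]
            if spec.family == "uniform" and (spec.a, spec.b) != (self.hl_lower, self.hl_upper):
                self.priors[name] = PriorSpec("uniform", self.hl_lower, self.hl_upper)
        self.generator = dataclasses.replace(self.generator, seed=self.seed)
        self.sampler = dataclasses.replace(self.sampler, seed=self.seed)

    def model_config(self, **kw) -> ModelConfig:
        return ModelConfig(priors=dict(self.priors), decay_base=self.decay_base, **kw)


def _coerce_dataclass(cls, data: dict, context: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - field_names
    if unknown:
        raise ValidationError(f"{context}: unknown key(s) {sorted(unknown)}")
    return cls(**data)


_TOP_KEYS = {"seed", "generator", "model_priors", "sampler", "preprocessing"}


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML (or JSON) run configuration with strict key checking.

    Absent keys fall back to package defaults; unknown keys raise rather
    than being silently ignored.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"config: unknown top-level key(s) {sorted(unknown)}")

    seed = int(raw.get("seed", 0))

    gen_raw = dict(raw.get("generator", {}))
    if "true_params" in gen_raw:
        partial = dict(gen_raw["true_params"])
        unknown = set(partial) - {f.name for f in dataclasses.fields(ModelParameters)}
        if unknown:
            raise ValidationError(f"generator.true_params: unknown key(s) {sorted(unknown)}")
        # unspecified generating values keep the generator's defaults
        merged = GeneratorConfig().true_params.to_dict()
        merged.update(partial)
        gen_raw["true_params"] = ModelParameters.from_dict(merged)
    if "sessions_per_week" in gen_raw:
        gen_raw["sessions_per_week"] = tuple(gen_raw["sessions_per_week"])
    if "age_range" in gen_raw:
        gen_raw["age_range"] = tuple(gen_raw["age_range"])
    generator = _coerce_dataclass(GeneratorConfig, gen_raw, "generator")

    priors_raw = dict(raw.get("model_priors", {}))
    hl_lower = float(priors_raw.pop("hl_lower", 0.5))
    hl_upper = float(priors_raw.pop("hl_upper", 500.0))
    decay_base = float(priors_raw.pop("decay_base", 2.0))
    priors = default_priors()
    for name, spec in priors_raw.items():
        if name not in priors:
            raise ValidationError(f"model_priors: unknown parameter {name!r}")
        spec = dict(spec)
        unknown = set(spec) - {"family", "a", "b"}
        if unknown:
            raise ValidationError(f"model_priors.{name}: unknown key(s) {sorted(unknown)}")
        priors[name] = PriorSpec(**spec)

    sampler = _coerce_dataclass(SamplerConfig, dict(raw.get("sampler", {})), "sampler")
    preprocessing = _coerce_dataclass(
        PreprocessConfig, dict(raw.get("preprocessing", {})), "preprocessing"
    )
    return RunConfig(
        seed=seed,
        generator=generator,
        priors=priors,
        hl_lower=hl_lower,
        hl_upper=hl_upper,
        decay_base=decay_base,
        sampler=sampler,
        preprocessing=preprocessing,
    )
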