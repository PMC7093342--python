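"""Dataset I/O, pipeline configuration, and the end-to-end pipeline.

The on-disk interchange format is a long-format CSV with one row per
trial (``participant, block, block_type, trial, cue, left_image,
right_image, target_side, rating``).  ``run_pipeline`` chains the whole
analysis — design generation, cohort simulation, LOOCV model comparison
for both trial-type families, reliability, and variance — into a single
JSON-serialisable report that embeds the configuration hash and seed so
any report can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .design import build_design, select_stimuli, synthetic_rating_table, validate_design
from .models import ComparisonError, InsufficientDataError, compare, default_specs
from .observers import GENERATIVE_MODELS, _participant_seeds, simulate_cohort
from .reliability import ReliabilityError, reliability_report
from .variance import VarianceError, compare_sds, rating_sds

logger = logging.getLogger("glimpse")

DATASET_COLUMNS = [
    "participant",
    "block",
    "block_type",
    "trial",
    "cue",
    "left_image",
    "right_image",
    "target_side",
    "rating",
]

_BLOCK_TYPES = {"training", "precued", "postcued", "baseline"}


class DatasetError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def write_dataset(dataset: pd.DataFrame, path) -> None:
    missing = [c for c in DATASET_COLUMNS if c not in dataset.columns]
    if missing:
        raise DatasetError(f"dataset missing columns: {missing}")
    dataset[DATASET_COLUMNS].to_csv(path, index=False)


def read_dataset(path, require_integer: bool = True) -> pd.DataFrame:
    """Read and validate a long-format rating CSV.

    Ratings must be on the 1-9 scale (integers unless
    ``require_integer=False``); the offending row number is reported on
    failure.  Row order is preserved.
    """
    try:
        df = pd.read_csv(path, dtype={"left_image": "string", "right_image": "string"})
    except pd.errors.EmptyDataError:
        raise DatasetError(f"{path}: empty dataset file") from None
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: malformed header, missing columns {missing}")
    if df.empty:
        raise DatasetError(f"{path}: dataset has no trials")
    bad_block = ~df["block_type"].isin(_BLOCK_TYPES)
    if bad_block.any():
        row = int(df.index[bad_block][0]) + 2  # 1-based, after header
        raise DatasetError(f"{path}: unknown block_type at row {row}")
    ratings = pd.to_numeric(df["rating"], errors="coerce")
    invalid = ratings.isna() | (ratings < 1) | (ratings > 9)
    if require_integer:
        invalid |= ratings.notna() & (ratings != ratings.round())
    if invalid.any():
        row = int(df.index[invalid][0]) + 2
        raise DatasetError(f"{path}: invalid rating {df['rating'].iloc[df.index[invalid][0]]!r} at row {row}")
    df["rating"] = ratings
    df["left_image"] = df["left_image"].astype(object).where(df["left_image"].notna(), None)
    df["right_image"] = df["right_image"].astype(object).where(df["right_image"].notna(), None)
    return df


@dataclass
class PipelineConfig:
    """Everything needed to regenerate a full simulated analysis."""

    seed: int = 0
    n_participants: int = 25
    model: str = "faithful"
    early_noise_sd: float = 0.0
    late_noise_sd: float = 1.4
    latent_scheme: str = "linear_map"
    latent_jitter_sd: float = 0.75
    discretize: bool = False
    n_images: int = 900
    n_per_quintile: int = 8
    n_training: int = 4
    pool_cue_timing: bool = False
    correlation_unit: str = "participant"

    def validate(self) -> None:
        if self.model not in GENERATIVE_MODELS:
            raise DatasetError(f"unknown generative model {self.model!r}")
        if self.n_participants < 1:
            raise DatasetError("n_participants must be >= 1")
        if self.n_training >= self.n_per_quintile:
            raise DatasetError("n_training must be smaller than n_per_quintile")
        if self.n_images < 5 * self.n_per_quintile:
            raise DatasetError("n_images too small for quintile selection")
        if self.early_noise_sd < 0 or self.late_noise_sd < 0:
            raise DatasetError("noise SDs must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DatasetError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name: str):
    logger.info("pipeline stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run design -> simulate -> fit/compare -> reliability -> variance.

    Domain-level shortfalls (e.g. too few participants for a comparison)
    are recorded in the report under the stage's key; unexpected errors
    propagate as :class:`PipelineStageError` naming the stage.  The
    report is a plain dict, stable under repeated runs with the same
    config.
    """
    config.validate()
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
    }
    table_seed = int(
        np.random.SeedSequence([config.seed, 0x5EED]).generate_state(1)[0] & 0x7FFFFFFF
    )

    try:
        _stage("design")
        table = synthetic_rating_table(config.n_images, seed=table_seed)
        catalog = select_stimuli(table, config.n_per_quintile, config.n_training)
        checks = []
        for idx, (design_seed, _, _) in enumerate(
            _participant_seeds(config.seed, config.n_participants)
        ):
            rep = validate_design(build_design(catalog, idx, design_seed))
            checks.append(rep.passed)
        report["design"] = {
            "n_main_images": len(catalog.main_images),
            "n_training_images": len(catalog.training_images),
            "all_designs_valid": bool(all(checks)),
            "n_designs_checked": len(checks),
        }
    except Exception as exc:  # design failures are always fatal
        raise PipelineStageError("design", exc) from exc

    try:
        _stage("simulate")
        dataset = simulate_cohort(
            config.n_participants,
            catalog,
            model_name=config.model,
            early_noise_sd=config.early_noise_sd,
            late_noise_sd=config.late_noise_sd,
            seed=config.seed,
            latent_scheme=config.latent_scheme,
            latent_jitter_sd=config.latent_jitter_sd,
            discretize=config.discretize,
        )
        report["simulate"] = {"n_trials": int(len(dataset))}
    except Exception as exc:
        raise PipelineStageError("simulate", exc) from exc

    _stage("models")
    try:
        comparison = compare(
            dataset, default_specs(), pool_cue_timing=config.pool_cue_timing
        )
        report["model_comparison"] = {
            "summary": comparison.summary.round(6).to_dict(orient="records"),
            "winners": {
                f"{tt}/{ct}": name for (tt, ct), name in sorted(comparison.winners.items())
            },
        }
    except (ComparisonError, InsufficientDataError) as exc:
        report["model_comparison"] = {"error": str(exc)}
    except Exception as exc:
        raise PipelineStageError("models", exc) from exc

    _stage("reliability")
    try:
        report["reliability"] = reliability_report(dataset, unit=config.correlation_unit)
    except ReliabilityError as exc:
        report["reliability"] = {"error": str(exc)}
    except Exception as exc:
        raise PipelineStageError("reliability", exc) from exc

    _stage("variance")
    try:
        table_sd = rating_sds(dataset)
        report["variance"] = {"sd_comparison": compare_sds(table_sd)}
    except VarianceError as exc:
        report["variance"] = {"error": str(exc)}
    except Exception as exc:
        raise PipelineStageError("variance", exc) from exc

    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=2, default=float)
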