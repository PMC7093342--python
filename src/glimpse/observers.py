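"""Synthetic observers: generative models of trial-level pleasure ratings.

An observer carries a latent pleasure for every image and produces a
rating on each trial through the weighted linear combination rule

    rating = a + b * (w * P1 + (1 - w) * P2) + late noise,

where P1/P2 are noisy samples of the relevant latent pleasures
(target/distractor on one-pleasure trials, left/right with w = 0.5 on
combined trials).  Two noise stages are distinguished because they make
different predictions: *early* noise is drawn independently per image
before combination (so averaging two samples reduces its SD by sqrt(2)),
while *late* noise is added once at the response stage (so averaging
does not reduce it).  Baseline trials report the single image's latent
pleasure untransformed and, by default, noise-free: the baseline block
is the reference measurement that defines an observer's
single-pleasures, and the printed fit quality reported for human raters
is only attainable with references substantially more reliable than
single cued ratings.  Set ``baseline_noise=True`` to subject baseline
trials to the same early/late noise as cued trials.

Ratings are optionally discretized to the 1-9 keypad by rounding half
away from zero and clipping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    BEAUTY_SCALE,
    RESPONSE_SCALE,
    ExperimentDesign,
    StimulusCatalog,
    build_design,
)

logger = logging.getLogger("glimpse")


class SimulationError(ValueError):
    pass


#: Generative parameter presets.  One-pleasure behaviour is governed by w
#: (1 = faithful, 0.5 = compulsory averaging, in between = partial);
#: combined-trial behaviour by (a, b) around the fixed combination weight
#: 0.5 (a = 0, b = 1 faithful averaging; 0 < b < 1 with a > 0 compressive;
#: b > 1 with a < 0 expansive).  The non-unit presets use the mean
#: best-fit values observed for human raters (w = 0.8; a = 0.39, b = 0.85;
#: a = -0.70, b = 1.05).
GENERATIVE_MODELS: dict[str, dict[str, float]] = {
    "faithful": {"w": 1.0, "a": 0.0, "b": 1.0},
    "averaging": {"w": 0.5, "a": 0.0, "b": 1.0},
    "partial": {"w": 0.8, "a": 0.0, "b": 1.0},
    "compressive": {"w": 1.0, "a": 0.39, "b": 0.85},
    "expansive": {"w": 1.0, "a": -0.70, "b": 1.05},
}


def discretize_ratings(x: np.ndarray) -> np.ndarray:
    """Round half away from zero and clip to the 1-9 response scale."""
    x = np.asarray(x, dtype=float)
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return np.clip(rounded, RESPONSE_SCALE[0], RESPONSE_SCALE[1])


def sample_latent_pleasures(
    catalog: StimulusCatalog,
    seed: int,
    scheme: str = "linear_map",
    jitter_sd: float = 0.0,
) -> dict[str, float]:
    """Draw an observer's latent pleasure for every catalog image.

    ``linear_map`` rescales catalog beauty (1-7) affinely onto the 1-9
    response scale; ``uniform`` draws i.i.d. from the scale.  An
    optional Gaussian ``jitter_sd`` models idiosyncratic taste on top of
    the shared mapping (clipped to the scale).  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    ids = catalog.table["image_id"].tolist()
    beauty = catalog.table["beauty"].to_numpy(dtype=float)
    lo_r, hi_r = RESPONSE_SCALE
    if scheme == "linear_map":
        lo_b, hi_b = BEAUTY_SCALE
        latent = lo_r + (beauty - lo_b) * (hi_r - lo_r) / (hi_b - lo_b)
    elif scheme == "uniform":
        latent = rng.uniform(lo_r, hi_r, size=len(ids))
    else:
        raise SimulationError(f"unknown latent-pleasure scheme: {scheme!r}")
    if jitter_sd > 0:
        latent = np.clip(latent + rng.normal(0.0, jitter_sd, size=len(ids)), lo_r, hi_r)
    return dict(zip(ids, latent.tolist(), strict=True))


@dataclass
class ObserverSpec:
    """Latent pleasures plus generative parameters for one observer."""

    latent_pleasures: dict[str, float]
    w: float = 1.0
    a: float = 0.0
    b: float = 1.0
    early_noise_sd: float = 0.0
    late_noise_sd: float = 0.0
    seed: int = 0
    discretize: bool = True
    baseline_noise: bool = False

    def __post_init__(self) -> None:
        if not 0.5 <= self.w <= 1.0:
            raise SimulationError(f"target weight w={self.w} outside [0.5, 1]")
        if self.b <= 0:
            raise SimulationError(f"slope b={self.b} must be positive")
        if self.early_noise_sd < 0 or self.late_noise_sd < 0:
            raise SimulationError("noise SDs must be non-negative")
        if not np.isfinite([self.early_noise_sd, self.late_noise_sd, self.a]).all():
            raise SimulationError("noise SDs and intercept must be finite")


def simulate_ratings(design: ExperimentDesign, obs: ObserverSpec) -> pd.DataFrame:
    """Simulate one observer's rating for every trial of a design.

    Returns the design in long format with a ``rating`` column appended.
    """
    frame = design.to_frame()
    rng = np.random.default_rng(obs.seed)

    def latent(img: pd.Series) -> np.ndarray:
        out = np.full(len(img), np.nan)
        for i, name in enumerate(img):
            if name is None or (isinstance(name, float) and np.isnan(name)):
                continue
            try:
                out[i] = obs.latent_pleasures[name]
            except KeyError:
                raise SimulationError(
                    f"no latent pleasure for image {name!r}"
                ) from None
        return out

    p_left = latent(frame["left_image"])
    p_right = latent(frame["right_image"])
    n = len(frame)
    eps_left = rng.normal(0.0, obs.early_noise_sd, size=n) if obs.early_noise_sd else np.zeros(n)
    eps_right = rng.normal(0.0, obs.early_noise_sd, size=n) if obs.early_noise_sd else np.zeros(n)
    late = rng.normal(0.0, obs.late_noise_sd, size=n) if obs.late_noise_sd else np.zeros(n)

    cue = frame["cue"].to_numpy()
    single = cue == "none"
    if not obs.baseline_noise:
        # Baseline ratings are the reference measurement; keep them clean.
        eps_left[single] = 0.0
        eps_right[single] = 0.0
        late[single] = 0.0

    s_left = p_left + eps_left
    s_right = p_right + eps_right

    rating = np.empty(n)
    # Baseline: the single image's sample, reported directly.
    rating[single] = np.where(
        np.isnan(s_left[single]), s_right[single], s_left[single]
    )

    left_cue = cue == "left"
    right_cue = cue == "right"
    both_cue = cue == "both"
    w, a, b = obs.w, obs.a, obs.b
    rating[left_cue] = a + b * (w * s_left[left_cue] + (1 - w) * s_right[left_cue])
    rating[right_cue] = a + b * (w * s_right[right_cue] + (1 - w) * s_left[right_cue])
    rating[both_cue] = a + b * 0.5 * (s_left[both_cue] + s_right[both_cue])

    rating = rating + late
    if np.isnan(rating).any():
        bad = frame.loc[np.isnan(rating)].iloc[0]
        raise SimulationError(f"missing latent pleasure on trial {int(bad['trial'])}")
    if obs.discretize:
        rating = discretize_ratings(rating)

    out = frame.copy()
    out["rating"] = rating
    return out


def sample_noise_multipliers(
    n_participants: int, seed: int, log_sd: float = 0.25
) -> np.ndarray:
    """Per-participant noise multipliers (careful vs sloppy raters).

    Observers differ stably in how reliably they rate: that shared
    person-level component is what makes error matrices internally
    consistent across images (high Cronbach's alpha), as seen in human
    cohorts.  Multipliers are lognormal with the given log-scale SD,
    normalised so the cohort mean squared multiplier is exactly 1 (the
    cohort-average rating variance is unchanged).  ``log_sd = 0`` gives
    a vector of ones.
    """
    if log_sd < 0:
        raise SimulationError("log_sd must be non-negative")
    if log_sd == 0:
        return np.ones(n_participants)
    rng = np.random.default_rng(seed)
    m = np.exp(rng.normal(0.0, log_sd, size=n_participants))
    return m / np.sqrt(np.mean(m**2))


def _participant_seeds(master_seed: int, n: int) -> list[tuple[int, int, int]]:
    """Independent (design, latent, observer) sub-seeds per participant."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    out = []
    for child in children:
        s = child.generate_state(3) & 0x7FFFFFFF
        out.append((int(s[0]), int(s[1]), int(s[2])))
    return out


def simulate_cohort(
    n_participants: int,
    catalog: StimulusCatalog,
    model_name: str = "faithful",
    early_noise_sd: float = 0.0,
    late_noise_sd: float = 1.4,
    seed: int = 0,
    latent_scheme: str = "linear_map",
    latent_jitter_sd: float = 0.75,
    discretize: bool = True,
    baseline_noise: bool = False,
    participant_noise_scale_sd: float = 0.25,
    model_params: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a full cohort under one generative model.

    Each participant gets an independent design (counterbalanced by
    participant parity), independent latent pleasures, and independent
    noise, all derived from ``seed`` so the dataset is fully
    reproducible.  ``model_params`` overrides entries of the named
    preset.  Defaults mirror the study conditions: 1.4 rating-scale
    units of late (response-stage) noise, no early noise, and
    taste jitter of 0.75 units around the shared beauty-to-pleasure
    mapping.
    """
    if n_participants < 1:
        raise SimulationError("n_participants must be >= 1")
    if model_name not in GENERATIVE_MODELS:
        raise SimulationError(
            f"unknown generative model {model_name!r}; "
            f"choose from {sorted(GENERATIVE_MODELS)}"
        )
    params = dict(GENERATIVE_MODELS[model_name])
    if model_params:
        params.update(model_params)

    scale_seed = int(
        np.random.SeedSequence([seed, 0xD1F]).generate_state(1)[0] & 0x7FFFFFFF
    )
    multipliers = sample_noise_multipliers(
        n_participants, scale_seed, log_sd=participant_noise_scale_sd
    )

    frames = []
    for idx, (design_seed, latent_seed, obs_seed) in enumerate(
        _participant_seeds(seed, n_participants)
    ):
        design = build_design(catalog, idx, design_seed)
        latent = sample_latent_pleasures(
            catalog, latent_seed, scheme=latent_scheme, jitter_sd=latent_jitter_sd
        )
        obs = ObserverSpec(
            latent_pleasures=latent,
            w=params["w"],
            a=params["a"],
            b=params["b"],
            early_noise_sd=early_noise_sd * multipliers[idx],
            late_noise_sd=late_noise_sd * multipliers[idx],
            seed=obs_seed,
            discretize=discretize,
            baseline_noise=baseline_noise,
        )
        frames.append(simulate_ratings(design, obs))
    dataset = pd.concat(frames, ignore_index=True)
    logger.info(
        "simulated cohort: model=%s n=%d trials=%d", model_name, n_participants, len(dataset)
    )
    return dataset
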