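"""Stimulus selection and trial-structure generation.

The experiment shows pairs of images briefly and asks observers to rate
the pleasure of one image (cued left or right) or the combined pleasure
of both (double cue), with the cue appearing either before (precued) or
after (postcued) the stimulus.  A final baseline block collects each
image's single-pleasure rating in isolation.

This module reproduces that design as a deterministic, seedable
generator: quintile-based stimulus selection from a normative beauty
table, counterbalanced left/right set assignment, and per-block trial
construction in which every main image serves once as target, once as
distractor, and once as a member of a combined-pleasure pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("glimpse")

# Scales and design constants.
BEAUTY_SCALE = (1.0, 7.0)       # normative beauty ratings
RESPONSE_SCALE = (1, 9)         # pleasure keypad
N_PER_QUINTILE = 8
N_TRAINING = 4
N_MAIN = 36
N_CUED_BLOCKS = 8               # 4 precued + 4 postcued
TRIALS_PER_CUED_BLOCK = 54      # 36 one-pleasure + 18 combined
N_TRAINING_TRIALS = 6

# Display timing, carried as design metadata only (never simulated).
TIMING_METADATA = {"image_duration_ms": 200, "cue_duration_ms": 1000}


class SelectionError(ValueError):
    """Raised when a ratings table cannot support stimulus selection."""


class DesignError(ValueError):
    """Raised when a catalog cannot support design construction."""


def synthetic_rating_table(
    n_images: int = 900,
    seed: int = 0,
    scale: tuple[float, float] = BEAUTY_SCALE,
) -> pd.DataFrame:
    """Generate a normative-style image rating table.

    Emulates a large normed image set whose mean beauty ratings are
    unimodal around mid-scale but span the whole 1-7 range, which is
    what makes quintile-based selection of extreme and mid images
    meaningful.  Returns a DataFrame with columns ``image_id, beauty``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = scale
    beauty = lo + (hi - lo) * rng.beta(2.2, 2.2, size=n_images)
    ids = [f"img_{i:04d}" for i in range(n_images)]
    return pd.DataFrame({"image_id": ids, "beauty": beauty})


def _validate_ratings(ratings: pd.DataFrame, scale: tuple[float, float]) -> pd.DataFrame:
    if not {"image_id", "beauty"}.issubset(ratings.columns):
        raise SelectionError("ratings table needs columns 'image_id' and 'beauty'")
    df = ratings[["image_id", "beauty"]].copy()
    df["image_id"] = df["image_id"].astype(str)
    if df["image_id"].duplicated().any():
        dup = df.loc[df["image_id"].duplicated(), "image_id"].iloc[0]
        raise SelectionError(f"duplicate image_id in ratings table: {dup!r}")
    beauty = df["beauty"].to_numpy(dtype=float)
    if not np.all(np.isfinite(beauty)):
        raise SelectionError("non-finite beauty values in ratings table")
    lo, hi = scale
    if beauty.min() < lo or beauty.max() > hi:
        raise SelectionError(f"beauty values outside declared scale [{lo}, {hi}]")
    return df


@dataclass(frozen=True)
class StimulusCatalog:
    """Selected stimuli: 36 main images (sets A/B) plus 4 training images.

    ``table`` has columns ``image_id, beauty, role, set_label`` where
    ``role`` is ``main`` or ``training`` and ``set_label`` is ``A``/``B``
    for main images and ``None`` for training images.
    """

    table: pd.DataFrame

    @property
    def main(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "main"].reset_index(drop=True)

    @property
    def training(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "training"].reset_index(drop=True)

    def set_images(self, label: str) -> list[str]:
        m = self.main
        return m.loc[m["set_label"] == label, "image_id"].tolist()

    @property
    def main_images(self) -> list[str]:
        return self.main["image_id"].tolist()

    @property
    def training_images(self) -> list[str]:
        return self.training["image_id"].tolist()

    def beauty_of(self, image_id: str) -> float:
        row = self.table[self.table["image_id"] == image_id]
        if row.empty:
            raise KeyError(image_id)
        return float(row["beauty"].iloc[0])


def _nearest_median(df: pd.DataFrame, n: int) -> pd.DataFrame:
    """The n rows nearest the quintile's median beauty, ties by image_id."""
    med = df["beauty"].median()
    dist = (df["beauty"] - med).abs()
    order = df.assign(_dist=dist).sort_values(["_dist", "image_id"])
    return order.head(n).drop(columns="_dist")


def select_stimuli(
    ratings: pd.DataFrame,
    n_per_quintile: int = N_PER_QUINTILE,
    n_training: int = N_TRAINING,
    scale: tuple[float, float] = BEAUTY_SCALE,
) -> StimulusCatalog:
    """Select main and training stimuli spanning the beauty range.

    The pool is split into five beauty quintiles (quintile 1 = most
    beautiful).  The ``n_per_quintile`` most beautiful images come from
    quintile 1 and the ``n_per_quintile`` least beautiful from quintile
    5, covering the extremes; quintiles 2 and 4 each contribute the
    ``n_per_quintile`` images nearest their median.  The middle quintile
    contributes ``n_per_quintile`` nearest-median images of which the
    first ``n_per_quintile - n_training`` are main stimuli and the
    remaining ``n_training`` are reserved for training trials, giving
    36 main + 4 training at the defaults.

    Main images are assigned to sets A and B alternately by beauty rank
    so that both sets span the full range.  Selection is deterministic
    and invariant to the row order of ``ratings``.
    """
    df = _validate_ratings(ratings, scale)
    if n_training >= n_per_quintile:
        raise SelectionError("n_training must be smaller than n_per_quintile")
    if len(df) < 5 * n_per_quintile:
        raise SelectionError(
            f"need at least {5 * n_per_quintile} rated images, got {len(df)}"
        )
    if df["beauty"].nunique() == 1:
        raise SelectionError("beauty values are all identical; quintiles undefined")

    # Quintile 1 = most beautiful.  Ties broken by image_id for determinism.
    ranked = df.sort_values(["beauty", "image_id"], ascending=[False, True]).reset_index(
        drop=True
    )
    idx_chunks = np.array_split(np.arange(len(ranked)), 5)
    quintiles = [ranked.iloc[chunk] for chunk in idx_chunks]

    top = quintiles[0].head(n_per_quintile)  # most beautiful overall
    bottom = quintiles[4].tail(n_per_quintile)  # least beautiful overall
    q2 = _nearest_median(quintiles[1], n_per_quintile)
    q4 = _nearest_median(quintiles[3], n_per_quintile)
    mid = _nearest_median(quintiles[2], n_per_quintile)
    mid_main = mid.head(n_per_quintile - n_training)
    training = mid.tail(n_training)

    main = pd.concat([top, q2, mid_main, q4, bottom], ignore_index=True)
    assert len(main) == 5 * n_per_quintile - n_training

    # Alternate A/B down the beauty ranking so both sets span the range.
    main = main.sort_values(["beauty", "image_id"], ascending=[False, True]).reset_index(
        drop=True
    )
    main["set_label"] = ["A" if i % 2 == 0 else "B" for i in range(len(main))]
    main["role"] = "main"

    training = training.copy()
    training["set_label"] = None
    training["role"] = "training"

    table = pd.concat([main, training], ignore_index=True)
    return StimulusCatalog(table=table)


@dataclass(frozen=True)
class Trial:
    block_index: int
    block_type: str  # precued | postcued | baseline | training
    cue: str  # left | right | both | none
    left_image: str | None
    right_image: str | None
    target_side: str  # left | right | both | single


@dataclass
class ExperimentDesign:
    participant_index: int
    side_mapping: str  # "A_left" or "B_left"
    seed: int
    trials: list[Trial]
    catalog: StimulusCatalog
    metadata: dict = field(default_factory=lambda: dict(TIMING_METADATA))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant": self.participant_index,
                "block": t.block_index,
                "block_type": t.block_type,
                "trial": i,
                "cue": t.cue,
                "left_image": t.left_image,
                "right_image": t.right_image,
                "target_side": t.target_side,
            }
            for i, t in enumerate(self.trials)
        ]
        return pd.DataFrame(rows)


def _cue_timing(index: int) -> str:
    # Cued blocks alternate precued/postcued starting with precued.
    return "precued" if index % 2 == 0 else "postcued"


def build_design(
    catalog: StimulusCatalog, participant_index: int, seed: int
) -> ExperimentDesign:
    """Build one participant's full trial sequence.

    Blocks, in order: one training block of 6 trials (cues left, right,
    both; first precued-style then postcued-style), 8 cued blocks of 54
    trials alternating precued/postcued, and one baseline block showing
    each main image alone on its counterbalanced side.

    Within every cued block each main image appears exactly once as
    target, once as distractor, and once inside a combined-pleasure
    pair.  This is realised by three independent uniform random
    bijections between the left-set and right-set images: one for
    left-target trials, one for right-target trials, and one for
    combined trials.  Even-indexed participants see set A on the left,
    odd-indexed participants set B.
    """
    set_a = catalog.set_images("A")
    set_b = catalog.set_images("B")
    if len(set_a) != len(set_b):
        raise DesignError(f"unequal set sizes: |A|={len(set_a)}, |B|={len(set_b)}")
    n_side = len(set_a)

    rng = np.random.default_rng([seed, participant_index])
    a_left = participant_index % 2 == 0
    left_set, right_set = (set_a, set_b) if a_left else (set_b, set_a)

    trials: list[Trial] = []

    # Training block: pairs of training images, one trial per cue shape,
    # first under precue instructions then under postcue instructions.
    train = catalog.training_images
    if len(train) < 2:
        raise DesignError("need at least two training images")
    for cue in ("left", "right", "both", "left", "right", "both"):
        pair = rng.choice(len(train), size=2, replace=False)
        trials.append(
            Trial(
                block_index=0,
                block_type="training",
                cue=cue,
                left_image=train[pair[0]],
                right_image=train[pair[1]],
                target_side="both" if cue == "both" else cue,
            )
        )

    # Cued blocks.
    for b in range(N_CUED_BLOCKS):
        block_index = b + 1
        block_type = _cue_timing(b)
        perm_left_target = rng.permutation(n_side)
        perm_right_target = rng.permutation(n_side)
        perm_combined = rng.permutation(n_side)
        block: list[Trial] = []
        for i in range(n_side):
            block.append(
                Trial(
                    block_index=block_index,
                    block_type=block_type,
                    cue="left",
                    left_image=left_set[i],
                    right_image=right_set[perm_left_target[i]],
                    target_side="left",
                )
            )
            block.append(
                Trial(
                    block_index=block_index,
                    block_type=block_type,
                    cue="right",
                    left_image=left_set[perm_right_target[i]],
                    right_image=right_set[i],
                    target_side="right",
                )
            )
            block.append(
                Trial(
                    block_index=block_index,
                    block_type=block_type,
                    cue="both",
                    left_image=left_set[i],
                    right_image=right_set[perm_combined[i]],
                    target_side="both",
                )
            )
        order = rng.permutation(len(block))
        trials.extend(block[j] for j in order)

    # Baseline block: each main image once, alone, on its assigned side.
    baseline: list[Trial] = []
    baseline_index = N_CUED_BLOCKS + 1
    for img in left_set:
        baseline.append(
            Trial(baseline_index, "baseline", "none", img, None, "single")
        )
    for img in right_set:
        baseline.append(
            Trial(baseline_index, "baseline", "none", None, img, "single")
        )
    order = rng.permutation(len(baseline))
    trials.extend(baseline[j] for j in order)

    return ExperimentDesign(
        participant_index=participant_index,
        side_mapping="A_left" if a_left else "B_left",
        seed=seed,
        trials=trials,
        catalog=catalog,
    )


@dataclass
class DesignReport:
    checks: dict[str, bool]
    details: dict

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def validate_design(design: ExperimentDesign) -> DesignReport:
    """Audit a design against the study's structural invariants.

    Violations are reported, never raised, so malformed designs can be
    inspected.  Checks per-block trial counts, target/distractor/pair
    tallies per main image per cued block, target-side balance, set
    opposition on cued trials, and baseline/training structure.
    """
    catalog = design.catalog
    main = set(catalog.main_images)
    set_of = dict(
        zip(catalog.main["image_id"], catalog.main["set_label"], strict=True)
    )
    checks: dict[str, bool] = {}
    details: dict = {}

    cued = [t for t in design.trials if t.block_type in ("precued", "postcued")]
    blocks: dict[int, list[Trial]] = {}
    for t in cued:
        blocks.setdefault(t.block_index, []).append(t)

    checks["eight_cued_blocks"] = len(blocks) == N_CUED_BLOCKS
    checks["cued_block_size_54"] = all(
        len(b) == TRIALS_PER_CUED_BLOCK for b in blocks.values()
    )
    details["cued_block_sizes"] = {k: len(v) for k, v in sorted(blocks.items())}

    per_block_ok = True
    balance_ok = True
    opposite_sets_ok = True
    composition_ok = True
    for b in blocks.values():
        one = [t for t in b if t.cue in ("left", "right")]
        comb = [t for t in b if t.cue == "both"]
        composition_ok &= len(one) == 36 and len(comb) == 18
        balance_ok &= (
            sum(t.cue == "left" for t in one) == 18
            and sum(t.cue == "right" for t in one) == 18
        )
        target_count: dict[str, int] = dict.fromkeys(main, 0)
        distractor_count: dict[str, int] = dict.fromkeys(main, 0)
        pair_count: dict[str, int] = dict.fromkeys(main, 0)
        for t in b:
            if t.left_image is None or t.right_image is None:
                per_block_ok = False
                continue
            li, ri = t.left_image, t.right_image
            if set_of.get(li) == set_of.get(ri):
                opposite_sets_ok = False
            if t.cue == "both":
                pair_count[li] = pair_count.get(li, 0) + 1
                pair_count[ri] = pair_count.get(ri, 0) + 1
            else:
                tgt = li if t.cue == "left" else ri
                dis = ri if t.cue == "left" else li
                target_count[tgt] = target_count.get(tgt, 0) + 1
                distractor_count[dis] = distractor_count.get(dis, 0) + 1
        per_block_ok &= (
            all(target_count.get(m, 0) == 1 for m in main)
            and all(distractor_count.get(m, 0) == 1 for m in main)
            and all(pair_count.get(m, 0) == 1 for m in main)
        )
    checks["one_pleasure_and_combined_counts"] = composition_ok
    checks["target_side_balance"] = balance_ok
    checks["each_image_target_distractor_pair_once"] = per_block_ok
    checks["cued_images_from_opposite_sets"] = opposite_sets_ok

    baseline = [t for t in design.trials if t.block_type == "baseline"]
    shown = [t.left_image if t.left_image is not None else t.right_image for t in baseline]
    single_image = all(
        (t.left_image is None) != (t.right_image is None) for t in baseline
    )
    a_left = design.side_mapping == "A_left"
    side_ok = True
    for t in baseline:
        img = t.left_image if t.left_image is not None else t.right_image
        on_left = t.left_image is not None
        expected_left = (set_of.get(img) == "A") == a_left
        side_ok &= on_left == expected_left
    checks["baseline_block_size"] = len(baseline) == len(main)
    checks["baseline_each_main_once"] = sorted(shown) == sorted(main)
    checks["baseline_single_image_counterbalanced"] = single_image and side_ok

    training = [t for t in design.trials if t.block_type == "training"]
    checks["six_training_trials"] = len(training) == N_TRAINING_TRIALS
    checks["cue_both_iff_target_both"] = all(
        (t.cue == "both") == (t.target_side == "both")
        for t in design.trials
        if t.block_type != "baseline"
    )

    details["n_trials"] = len(design.trials)
    return DesignReport(checks=checks, details=details)
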