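"""Variance-conservation analysis of rating SDs.

If a combined-pleasure report were the average of two independently
sampled pleasures, its SD would be smaller than a one-pleasure report's
by sqrt(2); if instead the variance arises at a shared response stage
(late noise), one-pleasure and combined SDs are equal.  This module
computes per-cell rating SDs (participant x trial type x cue timing x
target-pleasure level), compares the per-participant mean SDs of the
two trial types with a paired t-test, and provides the predicted
one-vs-combined SD ratio

    sqrt((sd_early^2 + sd_late^2) / (sd_early^2 / 2 + sd_late^2))

both in closed form and by Monte-Carlo simulation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .models import COMBINED, ONE_PLEASURE, single_pleasures
from .observers import discretize_ratings

logger = logging.getLogger("glimpse")


class VarianceError(ValueError):
    pass


def rating_sds(dataset: pd.DataFrame, min_cell: int = 2) -> pd.DataFrame:
    """Sample SD of ratings per participant/trial-type/timing/pleasure level.

    The target-pleasure level of a trial is the relevant single-pleasure
    (target's baseline rating on one-pleasure trials, the pair's mean on
    combined trials) rounded to the nearest integer 1-9.  Cells with
    fewer than ``min_cell`` ratings are excluded; SDs use the n-1
    denominator.
    """
    records = []
    for p in sorted(dataset["participant"].unique()):
        sp = single_pleasures(dataset, p)
        sub = dataset[
            (dataset["participant"] == p)
            & (dataset["block_type"].isin(["precued", "postcued"]))
        ]
        for _, row in sub.iterrows():
            li, ri = row["left_image"], row["right_image"]
            if row["cue"] in ("left", "right"):
                target = li if row["cue"] == "left" else ri
                if target not in sp:
                    continue
                level = float(discretize_ratings(np.array([sp[target]]))[0])
                trial_type = ONE_PLEASURE
            elif row["cue"] == "both":
                if li not in sp or ri not in sp:
                    continue
                level = float(discretize_ratings(np.array([0.5 * (sp[li] + sp[ri])]))[0])
                trial_type = COMBINED
            else:
                continue
            records.append(
                {
                    "participant": p,
                    "trial_type": trial_type,
                    "cue_timing": row["block_type"],
                    "level": level,
                    "rating": float(row["rating"]),
                }
            )
    if not records:
        raise VarianceError("no cued trials with usable single-pleasures")
    df = pd.DataFrame(records)
    grouped = df.groupby(["participant", "trial_type", "cue_timing", "level"])
    table = grouped["rating"].agg(sd=lambda s: s.std(ddof=1), n="count").reset_index()
    table = table[table["n"] >= min_cell].reset_index(drop=True)
    if table.empty:
        raise VarianceError(f"no cells with at least {min_cell} ratings")
    return table


def participant_mean_sds(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean SD over populated cells, per condition."""
    return (
        table.groupby(["participant", "trial_type", "cue_timing"])["sd"]
        .mean()
        .rename("mean_sd")
        .reset_index()
    )


def compare_sds(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Paired two-tailed t-test of one-pleasure vs combined mean SDs.

    Within each cue timing, each participant contributes one mean SD per
    trial type; the paired test asks whether averaging two pleasures
    reduces rating variability.  Requires >= 3 participants with both
    conditions.
    """
    means = participant_mean_sds(table)
    out: dict[str, dict[str, float]] = {}
    for timing in ("precued", "postcued"):
        sub = means[means["cue_timing"] == timing]
        wide = sub.pivot(index="participant", columns="trial_type", values="mean_sd")
        if ONE_PLEASURE not in wide.columns or COMBINED not in wide.columns:
            continue
        wide = wide.dropna()
        if len(wide) < 3:
            raise VarianceError(
                f"{timing}: need >= 3 participants with both trial types, got {len(wide)}"
            )
        one = wide[ONE_PLEASURE].to_numpy()
        comb = wide[COMBINED].to_numpy()
        diffs = one - comb
        if np.allclose(diffs, 0.0):
            t_stat, p_val = 0.0, 1.0  # identical conditions: no effect by definition
        else:
            res = stats.ttest_rel(one, comb)
            t_stat, p_val = float(res.statistic), float(res.pvalue)
        out[timing] = {
            "t": t_stat,
            "p": p_val,
            "mean_sd_one_pleasure": float(one.mean()),
            "mean_sd_combined": float(comb.mean()),
            "n": int(len(wide)),
        }
    if not out:
        raise VarianceError("no cue timing with both trial types present")
    return out


def variance_reduction_theory(early_sd: float, late_sd: float) -> float:
    """Closed-form one-pleasure/combined SD ratio under the noise model."""
    if early_sd < 0 or late_sd < 0:
        raise VarianceError("noise SDs must be non-negative")
    if early_sd == 0 and late_sd == 0:
        raise VarianceError("at least one noise SD must be positive")
    return float(
        np.sqrt((early_sd**2 + late_sd**2) / (early_sd**2 / 2.0 + late_sd**2))
    )


def variance_reduction_ratio(
    early_sd: float, late_sd: float, n_trials: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo one-pleasure/combined SD ratio for a fixed latent pleasure.

    One-pleasure reports draw one early sample plus late noise; combined
    reports average two independent early samples before adding late
    noise.  With early noise only the ratio approaches sqrt(2); with
    late noise only it approaches 1.
    """
    if n_trials < 2:
        raise VarianceError("n_trials must be >= 2")
    if early_sd == 0 and late_sd == 0:
        raise VarianceError("at least one noise SD must be positive")
    rng = np.random.default_rng(seed)
    latent = 5.0  # fixed mid-scale pleasure; the ratio is location-free
    one = latent + rng.normal(0, early_sd, n_trials) + rng.normal(0, late_sd, n_trials)
    combined = (
        latent
        + 0.5
        * (rng.normal(0, early_sd, n_trials) + rng.normal(0, early_sd, n_trials))
        + rng.normal(0, late_sd, n_trials)
    )
    return float(one.std(ddof=1) / combined.std(ddof=1))
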