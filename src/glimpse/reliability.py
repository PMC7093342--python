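"""Error-based reliability statistics.

Rating accuracy is scored against each participant's own baseline
ratings: on one-pleasure trials the error is the absolute deviation of
the rating from the target's single-pleasure, on combined-pleasure
trials the absolute deviation from the mean of the two presented
images' single-pleasures (attributed to both images).  Averaging these
errors per participant x image gives, per condition, a cases-by-items
matrix on which Cronbach's alpha measures internal consistency.

Two reliabilities bound the correlation observable between two
conditions' error profiles by the attenuation ceiling

    r_max = sqrt(alpha_X * alpha_Y),

so observed inter-condition correlations are reported together with
their ceiling.  Agreement of raw baseline ratings across participants
is quantified by the intraclass correlation for absolute agreement
(two-way random effects, single measure, ICC(2,1)).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import COMBINED, ONE_PLEASURE, single_pleasures

logger = logging.getLogger("glimpse")

CONDITIONS: tuple[tuple[str, str], ...] = (
    (ONE_PLEASURE, "precued"),
    (ONE_PLEASURE, "postcued"),
    (COMBINED, "precued"),
    (COMBINED, "postcued"),
)


class ReliabilityError(ValueError):
    pass


def _main_images(dataset: pd.DataFrame) -> list[str]:
    """Main images = those shown in baseline blocks."""
    base = dataset[dataset["block_type"] == "baseline"]
    imgs = set(base["left_image"].dropna()) | set(base["right_image"].dropna())
    return sorted(imgs)


def error_matrix(
    dataset: pd.DataFrame, trial_type: str = ONE_PLEASURE, cue_timing: str = "precued"
) -> pd.DataFrame:
    """Participants x images matrix of mean absolute rating errors.

    One condition = one trial type (one_pleasure/combined) within one
    cue timing (precued/postcued).  Repeated errors for the same cell
    are averaged.  Participants missing any single-pleasure are dropped
    with a warning; cells without trials are left NaN (alpha and the
    correlation report apply complete-case filtering downstream).
    """
    images = _main_images(dataset)
    rows = {}
    for p in sorted(dataset["participant"].unique()):
        sp = single_pleasures(dataset, p)
        if not set(images) <= set(sp):
            logger.warning(
                "participant %r dropped from error matrix: missing single-pleasure(s)", p
            )
            continue
        sub = dataset[
            (dataset["participant"] == p) & (dataset["block_type"] == cue_timing)
        ]
        cells: dict[str, list[float]] = {img: [] for img in images}
        if trial_type == ONE_PLEASURE:
            sub = sub[sub["cue"].isin(["left", "right"])]
            for _, row in sub.iterrows():
                target = row["left_image"] if row["cue"] == "left" else row["right_image"]
                cells[target].append(abs(float(row["rating"]) - sp[target]))
        elif trial_type == COMBINED:
            sub = sub[sub["cue"] == "both"]
            for _, row in sub.iterrows():
                li, ri = row["left_image"], row["right_image"]
                err = abs(float(row["rating"]) - 0.5 * (sp[li] + sp[ri]))
                cells[li].append(err)
                cells[ri].append(err)
        else:
            raise ReliabilityError(f"unknown trial_type {trial_type!r}")
        rows[p] = {
            img: float(np.mean(v)) if v else np.nan for img, v in cells.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=images)


def cronbach_alpha(matrix: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha of a cases-by-items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of case
    totals), with unbiased (n-1) variances; items are columns.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ReliabilityError("alpha needs at least a 2x2 matrix")
    if np.isnan(x).any():
        raise ReliabilityError("alpha requires complete cases (no missing cells)")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ReliabilityError("alpha undefined: case totals have zero variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def baseline_matrix(dataset: pd.DataFrame) -> pd.DataFrame:
    """Participants x images matrix of baseline (single-pleasure) ratings."""
    images = _main_images(dataset)
    rows = {}
    for p in sorted(dataset["participant"].unique()):
        sp = single_pleasures(dataset, p)
        if not set(images) <= set(sp):
            logger.warning("participant %r dropped from baseline matrix", p)
            continue
        rows[p] = {img: sp[img] for img in images}
    return pd.DataFrame.from_dict(rows, orient="index", columns=images)


def icc_absolute_agreement(matrix: pd.DataFrame | np.ndarray) -> float:
    """Single-measure absolute-agreement ICC, two-way random effects.

    Rows are raters (participants), columns are targets (images).
    From the two-way ANOVA mean squares (MSR over targets, MSC over
    raters, MSE residual):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1)*MSE + k*(MSC - MSE)/n)

    with k raters and n targets.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ReliabilityError("ICC needs at least 2 raters and 2 targets")
    if np.isnan(x).any():
        raise ReliabilityError("ICC requires a complete matrix")
    if np.allclose(x, x.flat[0]):
        raise ReliabilityError("ICC undefined for a constant matrix")
    k, n = x.shape  # k raters, n targets
    grand = x.mean()
    target_means = x.mean(axis=0)
    rater_means = x.mean(axis=1)
    ss_targets = k * ((target_means - grand) ** 2).sum()
    ss_raters = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_error = ss_total - ss_targets - ss_raters
    msr = ss_targets / (n - 1)
    msc = ss_raters / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ReliabilityError("ICC undefined: zero denominator")
    return float((msr - mse) / denom)


def attenuation_ceiling(alpha_x: float, alpha_y: float) -> float:
    """Maximum attainable correlation between two measures, sqrt(ax*ay)."""
    for name, val in (("alpha_x", alpha_x), ("alpha_y", alpha_y)):
        if not 0.0 < val <= 1.0:
            raise ReliabilityError(f"{name}={val} outside (0, 1]")
    return float(np.sqrt(alpha_x * alpha_y))


@dataclass
class CorrelationReport:
    table: pd.DataFrame  # condition pair, observed r, alphas, ceiling, ratio
    alphas: dict[tuple[str, str], float]


def error_correlations(dataset: pd.DataFrame, unit: str = "participant") -> CorrelationReport:
    """Pearson correlations between conditions' error profiles.

    ``unit='participant'`` correlates per-participant mean absolute
    errors (row means of the error matrices); ``unit='item'``
    correlates per-image means (column means).  Each correlation is
    reported with the attenuation ceiling implied by the two
    conditions' alphas and the observed/ceiling ratio.
    """
    if unit not in ("participant", "item"):
        raise ReliabilityError(f"unknown unit {unit!r}")
    matrices = {}
    for cond in CONDITIONS:
        m = error_matrix(dataset, trial_type=cond[0], cue_timing=cond[1])
        incomplete = m.index[m.isna().any(axis=1)]
        for p in incomplete:
            logger.warning(
                "participant %r dropped from %s/%s matrix: empty cell(s)", p, *cond
            )
        matrices[cond] = m.dropna(axis=0)
    common = None
    for m in matrices.values():
        idx = set(m.index)
        common = idx if common is None else common & idx
    if common is None or len(common) < 3:
        raise ReliabilityError("need at least 3 participants present in all conditions")
    common = sorted(common)
    alphas = {cond: cronbach_alpha(m.loc[common]) for cond, m in matrices.items()}

    rows = []
    for cx, cy in itertools.combinations(CONDITIONS, 2):
        mx, my = matrices[cx].loc[common], matrices[cy].loc[common]
        if unit == "participant":
            px, py = mx.mean(axis=1).to_numpy(), my.mean(axis=1).to_numpy()
        else:
            px, py = mx.mean(axis=0).to_numpy(), my.mean(axis=0).to_numpy()
        if px.std() == 0 or py.std() == 0:
            raise ReliabilityError(f"zero-variance error profile in {cx} or {cy}")
        r = float(stats.pearsonr(px, py).statistic)
        # The ceiling is only defined for positive reliabilities; sample
        # alphas can dip below zero when there is no shared item structure.
        if alphas[cx] > 0 and alphas[cy] > 0:
            ceiling = attenuation_ceiling(min(alphas[cx], 1.0), min(alphas[cy], 1.0))
            ratio = r / ceiling
        else:
            ceiling = None
            ratio = None
        rows.append(
            {
                "condition_x": f"{cx[0]}/{cx[1]}",
                "condition_y": f"{cy[0]}/{cy[1]}",
                "r": r,
                "alpha_x": alphas[cx],
                "alpha_y": alphas[cy],
                "ceiling": ceiling,
                "r_over_ceiling": ratio,
            }
        )
    return CorrelationReport(table=pd.DataFrame(rows), alphas=alphas)


def reliability_report(dataset: pd.DataFrame, unit: str = "participant") -> dict:
    """Full reliability summary: alphas, baseline ICC, correlations/ceilings."""
    corr = error_correlations(dataset, unit=unit)
    icc = icc_absolute_agreement(baseline_matrix(dataset))
    return {
        "alpha": {f"{tt}/{ct}": a for (tt, ct), a in corr.alphas.items()},
        "icc_baseline_absolute_agreement": icc,
        "correlations": corr.table.to_dict(orient="records"),
    }
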