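"""The weighted-combination model family: fitting and LOOCV comparison.

Reported pleasure is modelled as a linear transformation of a weighted
sum of the two presented images' single-pleasures,

    P_hat = a + b * (w * P1 + (1 - w) * P2),        0.5 <= w <= 1,

where the single-pleasures come from the participant's own baseline
(one-image) block.  Named special cases:

one-pleasure trials (P1 = target, P2 = distractor; a = 0, b = 1):
    faithful              w = 1
    compulsory_averaging  w = 0.5
    partial_averaging     w free in [0.5, 1]   (alias: flexible)

combined-pleasure trials (P1 = left, P2 = right; w = 0.5):
    faithful      a = 0, b = 1    (averaging; summing would be b = 2)
    compressive   a > 0, 0 < b < 1
    expansive     a < 0, b > 1

Models are fitted per participant by minimising the root mean square
error between predictions and single-trial ratings, and compared by
leave-one-out cross-validation so extra free parameters must earn their
keep.  Every named spec is linear in its free parameters, so the
box-constrained least-squares problem is solved exactly (interior
solution or active-edge enumeration of the convex quadratic); a
multi-start bounded quasi-Newton path covers custom specs that free w
together with a or b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger("glimpse")

EPS = 1e-6  # margin turning the strict inequalities (a > 0, b < 1, ...) into closed boxes
_DEFAULT_A_MAX = 8.0
_DEFAULT_B_MAX = 3.0

ONE_PLEASURE = "one_pleasure"
COMBINED = "combined"

ParamSpec = float | tuple[float, float]


class FitError(ValueError):
    pass


class InsufficientDataError(FitError):
    pass


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Bounds/fixings for (a, b, w); a float fixes, a (lo, hi) pair frees."""

    name: str
    trial_type: str  # one_pleasure | combined
    a: ParamSpec = 0.0
    b: ParamSpec = 1.0
    w: ParamSpec = 1.0

    def __post_init__(self) -> None:
        if self.trial_type not in (ONE_PLEASURE, COMBINED):
            raise FitError(f"unknown trial_type {self.trial_type!r}")
        for pname in ("a", "b", "w"):
            v = getattr(self, pname)
            if isinstance(v, tuple):
                lo, hi = v
                if not lo < hi:
                    raise FitError(f"empty bounds for {pname}: {v}")

    @property
    def free_params(self) -> tuple[str, ...]:
        return tuple(p for p in ("a", "b", "w") if isinstance(getattr(self, p), tuple))

    @property
    def n_free(self) -> int:
        return len(self.free_params)


def one_pleasure_specs() -> list[ModelSpec]:
    """The three rival accounts of rating one image among two."""
    return [
        ModelSpec("faithful", ONE_PLEASURE, a=0.0, b=1.0, w=1.0),
        ModelSpec("compulsory_averaging", ONE_PLEASURE, a=0.0, b=1.0, w=0.5),
        ModelSpec("partial_averaging", ONE_PLEASURE, a=0.0, b=1.0, w=(0.5, 1.0)),
    ]


def combined_specs() -> list[ModelSpec]:
    """The three rival accounts of rating the combined pleasure of a pair."""
    return [
        ModelSpec("faithful", COMBINED, a=0.0, b=1.0, w=0.5),
        ModelSpec("compressive", COMBINED, a=(EPS, _DEFAULT_A_MAX), b=(EPS, 1.0 - EPS), w=0.5),
        ModelSpec(
            "expansive", COMBINED, a=(-_DEFAULT_A_MAX, -EPS), b=(1.0 + EPS, _DEFAULT_B_MAX), w=0.5
        ),
    ]


def default_specs() -> list[ModelSpec]:
    return one_pleasure_specs() + combined_specs()


def predict(a, b, w, p1, p2):
    """Predicted rating; exact arithmetic, no rounding or clipping."""
    return a + b * (w * np.asarray(p1, dtype=float) + (1.0 - w) * np.asarray(p2, dtype=float))


# ---------------------------------------------------------------------------
# Trial observations: (P1, P2, rating) triplets for one participant/condition
# ---------------------------------------------------------------------------


def single_pleasures(dataset: pd.DataFrame, participant) -> dict[str, float]:
    """A participant's baseline-block ratings, keyed by image."""
    base = dataset[
        (dataset["participant"] == participant) & (dataset["block_type"] == "baseline")
    ]
    out: dict[str, float] = {}
    for _, row in base.iterrows():
        img = row["left_image"] if pd.notna(row["left_image"]) else row["right_image"]
        out[img] = float(row["rating"])
    return out


@dataclass
class TrialObservations:
    """Per-trial (P1, P2, observed rating) for one participant and condition."""

    p1: np.ndarray
    p2: np.ndarray
    y: np.ndarray
    trial_type: str = ONE_PLEASURE
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def from_dataset(
        cls,
        dataset: pd.DataFrame,
        participant,
        trial_type: str = ONE_PLEASURE,
        cue_timing: str | None = None,
    ) -> "TrialObservations":
        """Assemble observations from a long-format rating dataset.

        ``cue_timing`` restricts to precued or postcued blocks (None
        pools both).  Trials whose images lack a baseline rating are
        dropped (counted in ``n_dropped``); an empty result raises
        :class:`InsufficientDataError`.
        """
        sp = single_pleasures(dataset, participant)
        rows = dataset[dataset["participant"] == participant]
        if cue_timing is not None:
            rows = rows[rows["block_type"] == cue_timing]
        else:
            rows = rows[rows["block_type"].isin(["precued", "postcued"])]
        if trial_type == ONE_PLEASURE:
            rows = rows[rows["cue"].isin(["left", "right"])]
        elif trial_type == COMBINED:
            rows = rows[rows["cue"] == "both"]
        else:
            raise FitError(f"unknown trial_type {trial_type!r}")

        p1, p2, y = [], [], []
        dropped = 0
        for _, row in rows.iterrows():
            li, ri = row["left_image"], row["right_image"]
            if trial_type == ONE_PLEASURE:
                first, second = (li, ri) if row["cue"] == "left" else (ri, li)
            else:
                first, second = li, ri
            if first not in sp or second not in sp:
                dropped += 1
                continue
            p1.append(sp[first])
            p2.append(sp[second])
            y.append(float(row["rating"]))
        if dropped:
            logger.warning(
                "participant %r: dropped %d %s trial(s) with missing single-pleasure",
                participant,
                dropped,
                trial_type,
            )
        if not y:
            raise InsufficientDataError(
                f"participant {participant!r}: no usable {trial_type} trials"
                + (f" in {cue_timing}" if cue_timing else "")
            )
        return cls(
            p1=np.asarray(p1, float),
            p2=np.asarray(p2, float),
            y=np.asarray(y, float),
            trial_type=trial_type,
            n_dropped=dropped,
        )


@dataclass
class FitResult:
    model: str
    params: dict[str, float]
    n_free: int
    rmse_train: float
    loo_sq_errors: np.ndarray | None = None
    rmse_loocv: float | None = None


# ---------------------------------------------------------------------------
# Exact box-constrained least squares for the linear-in-parameters specs
# ---------------------------------------------------------------------------


def _solve_1d(sgg: float, sgr: float, lo: float, hi: float) -> float:
    """Minimise sum((r - theta*g)^2) over theta in [lo, hi] (convex: clip)."""
    if sgg <= 0.0:
        return 0.5 * (lo + hi)  # no information; deterministic midpoint
    return float(np.clip(sgr / sgg, lo, hi))


def _solve_ab(
    n: float,
    sm: float,
    smm: float,
    sy: float,
    smy: float,
    a_bounds: tuple[float, float],
    b_bounds: tuple[float, float],
) -> tuple[float, float]:
    """Minimise sum((y - a - b*m)^2) over the (a, b) box from sufficient stats.

    The objective is a convex quadratic, so the minimum is either the
    unconstrained stationary point (if feasible) or lies on one of the
    four box edges, where the remaining 1-D problem is solved in closed
    form and clipped.  Ties go to the first candidate.
    """
    la, ha = a_bounds
    lb, hb = b_bounds

    def sse(a: float, b: float) -> float:
        return a * a * n + 2 * a * b * sm + b * b * smm - 2 * a * sy - 2 * b * smy

    det = n * smm - sm * sm
    if det > 1e-12 * max(n * smm, 1.0):
        a0 = (smm * sy - sm * smy) / det
        b0 = (n * smy - sm * sy) / det
        if la <= a0 <= ha and lb <= b0 <= hb:
            return float(a0), float(b0)

    candidates: list[tuple[float, float]] = []
    for a_fix in (la, ha):  # a pinned: 1-D in b
        b_hat = _solve_1d(smm, smy - a_fix * sm, lb, hb)
        candidates.append((a_fix, b_hat))
    for b_fix in (lb, hb):  # b pinned: 1-D in a
        a_hat = _solve_1d(n, sy - b_fix * sm, la, ha)
        candidates.append((a_hat, b_fix))
    best = min(enumerate(candidates), key=lambda kv: (sse(*kv[1]), kv[0]))
    return best[1]


def _combination(spec_w: ParamSpec, p1: np.ndarray, p2: np.ndarray, w: float) -> np.ndarray:
    return w * p1 + (1.0 - w) * p2


def _fit_linear(
    spec: ModelSpec, p1: np.ndarray, p2: np.ndarray, y: np.ndarray
) -> dict[str, float]:
    """Exact fit for specs linear in their free parameters."""
    free = set(spec.free_params)
    a, b, w = spec.a, spec.b, spec.w

    if free == {"w"}:
        # y - a - b*p2 = b*w*(p1 - p2) + noise
        g = b * (p1 - p2)
        r = y - a - b * p2
        w = _solve_1d(float(g @ g), float(g @ r), *spec.w)
    elif free == {"a"}:
        m = _combination(spec.w, p1, p2, w)
        r = y - b * m
        a = _solve_1d(float(len(y)), float(r.sum()), *spec.a)
    elif free == {"b"}:
        m = _combination(spec.w, p1, p2, w)
        r = y - a
        b = _solve_1d(float(m @ m), float(m @ r), *spec.b)
    elif free == {"a", "b"}:
        m = _combination(spec.w, p1, p2, w)
        a, b = _solve_ab(
            float(len(y)),
            float(m.sum()),
            float(m @ m),
            float(y.sum()),
            float(m @ y),
            spec.a,
            spec.b,
        )
    else:  # pragma: no cover - guarded by caller
        raise FitError(f"spec not linear in free params: {spec.free_params}")
    return {"a": float(a), "b": float(b), "w": float(w)}


_NONLINEAR_STARTS = (0.1, 0.3, 0.5, 0.7, 0.9)  # fractions along each free axis


def _fit_nonlinear(
    spec: ModelSpec, p1: np.ndarray, p2: np.ndarray, y: np.ndarray
) -> dict[str, float]:
    """Multi-start bounded minimisation for specs freeing w jointly with a/b."""
    free = spec.free_params
    bounds = [getattr(spec, p) for p in free]
    fixed = {p: getattr(spec, p) for p in ("a", "b", "w") if p not in free}

    def cost(theta: np.ndarray) -> float:
        params = dict(fixed)
        params.update(zip(free, theta, strict=True))
        resid = y - predict(params["a"], params["b"], params["w"], p1, p2)
        return float(np.sqrt(np.mean(resid**2)))

    best = None
    for frac in _NONLINEAR_STARTS:
        x0 = np.array([lo + frac * (hi - lo) for lo, hi in bounds])
        res = minimize(
            cost,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    params = dict(fixed)
    params.update(zip(free, best.x, strict=True))
    return {k: float(params[k]) for k in ("a", "b", "w")}


def _is_linear(spec: ModelSpec) -> bool:
    free = set(spec.free_params)
    return free <= {"a", "b"} or free == {"w"}


def _fit_params(spec: ModelSpec, p1, p2, y) -> dict[str, float]:
    if spec.n_free == 0:
        return {"a": float(spec.a), "b": float(spec.b), "w": float(spec.w)}
    if _is_linear(spec):
        return _fit_linear(spec, p1, p2, y)
    return _fit_nonlinear(spec, p1, p2, y)


def _rmse(params: dict[str, float], p1, p2, y) -> float:
    resid = y - predict(params["a"], params["b"], params["w"], p1, p2)
    return float(np.sqrt(np.mean(resid**2)))


def fit(obs: TrialObservations, spec: ModelSpec) -> FitResult:
    """Fit a model spec to one participant's trials (training fit only)."""
    n = len(obs)
    if n < max(3, spec.n_free + 1):
        raise InsufficientDataError(
            f"{spec.name}: need at least {max(3, spec.n_free + 1)} trials, got {n}"
        )
    params = _fit_params(spec, obs.p1, obs.p2, obs.y)
    return FitResult(
        model=spec.name,
        params=params,
        n_free=spec.n_free,
        rmse_train=_rmse(params, obs.p1, obs.p2, obs.y),
    )


def loocv(obs: TrialObservations, spec: ModelSpec) -> FitResult:
    """Leave-one-out cross-validation of a model spec.

    For each trial i the model is refitted on the remaining trials and
    its squared prediction error on trial i recorded; the LOOCV RMSE is
    the root of the mean of those held-out squared errors.  For specs
    with no free parameters this equals the training RMSE exactly.
    Refits reuse downdated sufficient statistics for the linear specs,
    so the whole loop costs O(n).
    """
    n = len(obs)
    if n < spec.n_free + 2 or n < 3:
        raise InsufficientDataError(
            f"{spec.name}: need at least {max(3, spec.n_free + 2)} trials for LOOCV, got {n}"
        )
    result = fit(obs, spec)
    p1, p2, y = obs.p1, obs.p2, obs.y
    free = set(spec.free_params)

    if spec.n_free == 0:
        resid = y - predict(spec.a, spec.b, spec.w, p1, p2)
        sq = resid**2
    elif free == {"w"}:
        a, b = spec.a, spec.b
        g = b * (p1 - p2)
        r = y - a - b * p2
        sgg, sgr = float(g @ g), float(g @ r)
        lo, hi = spec.w
        den = sgg - g * g
        num = sgr - g * r
        w_loo = np.where(
            den > 0.0,
            np.clip(num / np.where(den > 0.0, den, 1.0), lo, hi),
            0.5 * (lo + hi),
        )
        sq = (r - w_loo * g) ** 2
    elif free <= {"a", "b"}:
        w = float(spec.w)
        m = _combination(spec.w, p1, p2, w)
        a_bounds = spec.a if isinstance(spec.a, tuple) else (spec.a, spec.a)
        b_bounds = spec.b if isinstance(spec.b, tuple) else (spec.b, spec.b)
        sm, smm = float(m.sum()), float(m @ m)
        sy, smy = float(y.sum()), float(m @ y)
        sq = np.empty(n)
        for i in range(n):
            a_i, b_i = _solve_ab(
                n - 1,
                sm - m[i],
                smm - m[i] * m[i],
                sy - y[i],
                smy - m[i] * y[i],
                a_bounds,
                b_bounds,
            )
            sq[i] = (y[i] - a_i - b_i * m[i]) ** 2
    else:
        sq = np.empty(n)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            params_i = _fit_nonlinear(spec, p1[mask], p2[mask], y[mask])
            sq[i] = (y[i] - predict(params_i["a"], params_i["b"], params_i["w"], p1[i], p2[i])) ** 2
            mask[i] = True

    result.loo_sq_errors = sq
    result.rmse_loocv = float(np.sqrt(np.mean(sq)))
    return result


# ---------------------------------------------------------------------------
# Cohort-level model comparison
# ---------------------------------------------------------------------------


@dataclass
class ModelComparison:
    """Cohort LOOCV comparison, per trial-type family and cue timing."""

    summary: pd.DataFrame  # trial_type, cue_timing, model, mean/SEM LOOCV RMSE
    per_participant: pd.DataFrame
    winners: dict[tuple[str, str], str]  # (trial_type, cue_timing) -> model name
    excluded: dict[tuple[str, str], list] = field(default_factory=dict)


def compare(
    dataset: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    cue_timings: tuple[str, ...] = ("precued", "postcued"),
    pool_cue_timing: bool = False,
) -> ModelComparison:
    """LOOCV model comparison across a cohort.

    Models are fitted per participant, separately per trial-type family
    and (unless ``pool_cue_timing``) per cue timing.  The cohort score
    of a model is the mean of per-participant LOOCV RMSEs with its
    standard error (SD/sqrt(n)).  The winner per condition follows a
    paired one-standard-error rule: a model is tied with the best if
    its mean excess LOOCV RMSE over the best model is within one
    standard error of those per-participant paired differences (nested
    models can differ by arbitrarily little, so a strict minimum would
    flip on hairline noise); among tied models the fewest free
    parameters wins, then the lowest mean, then spec order.
    Participants without usable trials in a condition are excluded from
    that condition with a warning.
    """
    if specs is None:
        specs = default_specs()
    participants = sorted(dataset["participant"].unique())
    timings: tuple[str | None, ...] = (None,) if pool_cue_timing else cue_timings

    rows = []
    excluded: dict[tuple[str, str], list] = {}
    by_family: dict[str, list[ModelSpec]] = {}
    for spec in specs:
        by_family.setdefault(spec.trial_type, []).append(spec)

    for trial_type, family in by_family.items():
        for timing in timings:
            timing_label = timing if timing is not None else "pooled"
            obs_by_participant = {}
            for p in participants:
                try:
                    obs_by_participant[p] = TrialObservations.from_dataset(
                        dataset, p, trial_type=trial_type, cue_timing=timing
                    )
                except InsufficientDataError:
                    excluded.setdefault((trial_type, timing_label), []).append(p)
                    logger.warning(
                        "excluding participant %r from %s/%s comparison",
                        p,
                        trial_type,
                        timing_label,
                    )
            if len(obs_by_participant) < 2:
                raise ComparisonError(
                    f"fewer than 2 participants usable for {trial_type}/{timing_label}"
                )
            for spec in family:
                for p, obs in obs_by_participant.items():
                    res = loocv(obs, spec)
                    rows.append(
                        {
                            "participant": p,
                            "trial_type": trial_type,
                            "cue_timing": timing_label,
                            "model": spec.name,
                            "n_free": spec.n_free,
                            "rmse_train": res.rmse_train,
                            "rmse_loocv": res.rmse_loocv,
                            **{f"param_{k}": v for k, v in res.params.items()},
                        }
                    )

    per_participant = pd.DataFrame(rows)
    grouped = per_participant.groupby(["trial_type", "cue_timing", "model"], sort=False)
    summary = grouped.agg(
        n_free=("n_free", "first"),
        mean_loocv_rmse=("rmse_loocv", "mean"),
        sd_loocv_rmse=("rmse_loocv", lambda s: s.std(ddof=1)),
        n_participants=("participant", "nunique"),
    ).reset_index()
    summary["sem_loocv_rmse"] = summary["sd_loocv_rmse"] / np.sqrt(
        summary["n_participants"]
    )

    winners: dict[tuple[str, str], str] = {}
    for (trial_type, timing_label), grp in summary.groupby(
        ["trial_type", "cue_timing"], sort=False
    ):
        cond = per_participant[
            (per_participant["trial_type"] == trial_type)
            & (per_participant["cue_timing"] == timing_label)
        ]
        wide = cond.pivot(index="participant", columns="model", values="rmse_loocv")
        best_model = str(grp.loc[grp["mean_loocv_rmse"].idxmin(), "model"])
        tied = []
        for _, row in grp.iterrows():
            model = str(row["model"])
            diff = (wide[model] - wide[best_model]).to_numpy()
            se = diff.std(ddof=1) / np.sqrt(len(diff)) if len(diff) > 1 else 0.0
            if diff.mean() <= se:
                tied.append((int(row["n_free"]), float(row["mean_loocv_rmse"]), model))
        order = {str(m): i for i, m in enumerate(grp["model"])}
        tied.sort(key=lambda t: (t[0], t[1], order[t[2]]))
        winners[(trial_type, timing_label)] = tied[0][2]

    return ModelComparison(
        summary=summary,
        per_participant=per_participant,
        winners=winners,
        excluded=excluded,
    )
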