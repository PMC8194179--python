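"""Spheroid invasion scoring.

Turns time-lapse matrigel-invasion measurements into a per-clone invasion
factor (IF) and a cohort ranking. The IF combines two observations made on
each spheroid: how *early* invasive growth starts (onset time ``t``, hours)
and how *much* area is invaded by 48 h (relative area ``A``, normalized to
the cohort mean). The two are averaged on a common scale by mapping the
onset time through an exponential calibrated on a reference cohort:

    IF = (A + exp(beta0 + beta1 * t)) / 2

with published calibration constants ``beta0 = 86539/44760`` and
``beta1 = -250/1119`` (per hour). The exponential is the back-transform of a
log-linear regression of invaded area on onset time, so an early-starting
clone scores high even if its 48-h area is modest, and vice versa.

Relative invasiveness is IF normalized to the cohort mean (mean 1 by
construction); clones above the 75th percentile are classed "high", below
the 25th "low", otherwise "mid".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .stats import RegressionFit, linear_fit, anova_dunnett, AnovaResult

__all__ = [
    "DEFAULT_BETA0",
    "DEFAULT_BETA1",
    "InvasionTimecourse",
    "InvasionCoefficients",
    "InvasionScore",
    "WoundTimecourse",
    "detect_invasion_start",
    "relative_invasion_area",
    "calibrate_invasion_model",
    "invasion_factor",
    "rank_clones",
    "outer_vs_mid_anova",
    "wound_closure_rate",
    "spheroid_volume_increase",
    "read_invasion_csv",
    "read_wound_csv",
    "scores_to_frame",
]

#: Published calibration constants of the onset-time exponential.
DEFAULT_BETA0 = float(Fraction(86539, 44760))
DEFAULT_BETA1 = float(Fraction(-250, 1119))


@dataclass(frozen=True)
class InvasionTimecourse:
    """Area-versus-time series for one clone's invasion assay."""

    clone_id: str
    times: np.ndarray  # hours, strictly increasing, times[0] == 0
    areas: np.ndarray  # same length, >= 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        if t.ndim != 1 or a.ndim != 1 or len(t) != len(a):
            raise ValueError("times and areas must be equal-length 1-D arrays")
        if len(t) < 2:
            raise ValueError("need at least 2 time points")
        if t[0] != 0:
            raise ValueError("timecourse must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("areas must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "areas", a)


@dataclass(frozen=True)
class InvasionCoefficients:
    """Coefficients of ln(A) = beta0 + beta1 * t."""

    beta0: float = DEFAULT_BETA0
    beta1: float = DEFAULT_BETA1
    r_squared: float = float("nan")


@dataclass(frozen=True)
class InvasionScore:
    clone_id: str
    t_start: float
    area_rel: float
    invasion_factor: float
    relative_invasiveness: float
    rank: int
    invasiveness_class: str | None  # "high" / "mid" / "low", None if unclassed


@dataclass(frozen=True)
class WoundTimecourse:
    """Wound-density (%) versus time for one scratch-assay well."""

    sample_id: str
    times: np.ndarray
    wound_density: np.ndarray  # percent, in [0, 100]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.wound_density, dtype=float)
        if len(t) != len(d):
            raise ValueError("times and wound_density must match in length")
        if np.any((d < 0) | (d > 100)):
            raise ValueError("wound density must lie in [0, 100]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "wound_density", d)


def detect_invasion_start(tc: InvasionTimecourse,
                          rel_threshold: float = 0.05,
                          consecutive: int = 2) -> float | None:
    """Earliest time the area exceeds (1 + rel_threshold) x baseline and
    stays above from then on. ``None`` if growth never starts.

    The baseline is the area at t = 0. Because invasive growth, once
    started, does not revert, the run of above-threshold frames must
    persist through the end of the series (isolated noise excursions are
    thereby rejected) and must span at least ``consecutive`` frames.
    """
    if rel_threshold <= 0:
        raise ValueError("rel_threshold must be positive")
    if consecutive < 1:
        raise ValueError("consecutive must be >= 1")
    baseline = tc.areas[0]
    if baseline == 0:
        raise ValueError(f"clone {tc.clone_id}: baseline area is zero")
    above = tc.areas > (1.0 + rel_threshold) * baseline
    n = len(above)
    for i in range(1, n - consecutive + 1):
        if above[i:].all():
            return float(tc.times[i])
    return None


def _area_at(tc: InvasionTimecourse, t_eval: float) -> float:
    """Area at t_eval, linearly interpolated between bracketing frames."""
    t = tc.times
    if t_eval < t[0] or t_eval > t[-1]:
        raise ValueError(
            f"clone {tc.clone_id}: no coverage at t = {t_eval} h "
            f"(observed window {t[0]}–{t[-1]} h)")
    return float(np.interp(t_eval, t, tc.areas))


def relative_invasion_area(cohort: Sequence[InvasionTimecourse],
                           t_eval: float = 48.0) -> dict[str, float]:
    """Per-clone relative invasion area A at ``t_eval``.

    Fold-area = area(t_eval)/area(0) per clone; A = fold-area divided by the
    cohort mean fold-area, so mean(A) = 1 over the cohort.
    """
    if not cohort:
        raise ValueError("empty cohort")
    folds = {}
    for tc in cohort:
        if tc.areas[0] == 0:
            raise ValueError(f"clone {tc.clone_id}: baseline area is zero")
        folds[tc.clone_id] = _area_at(tc, t_eval) / tc.areas[0]
    mean_fold = float(np.mean(list(folds.values())))
    if mean_fold == 0:
        raise ValueError("cohort mean fold-area is zero")
    return {cid: f / mean_fold for cid, f in folds.items()}


def calibrate_invasion_model(
        pairs: Sequence[tuple[float, float]]) -> InvasionCoefficients:
    """Fit ln(A) = beta0 + beta1 * t on (t_start, A) pairs by least squares."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 (t_start, A) pairs")
    t = np.array([p[0] for p in pairs], dtype=float)
    a = np.array([p[1] for p in pairs], dtype=float)
    if np.any(a <= 0):
        raise ValueError("relative areas must be positive (log link)")
    fit = linear_fit(t, np.log(a))
    return InvasionCoefficients(beta0=fit.intercept, beta1=fit.slope,
                                r_squared=fit.r_squared)


def invasion_factor(A: float, t: float,
                    coef: InvasionCoefficients | None = None) -> float:
    """IF = (A + exp(beta0 + beta1 * t)) / 2 with the default calibration."""
    if A < 0:
        raise ValueError("relative area must be non-negative")
    if t < 0:
        raise ValueError("onset time must be non-negative")
    c = coef or InvasionCoefficients()
    return (A + np.exp(c.beta0 + c.beta1 * t)) / 2.0


def rank_clones(entries: Sequence[tuple[str, float, float]],
                coef: InvasionCoefficients | None = None) -> list[InvasionScore]:
    """Score, normalize, rank and class a cohort.

    Parameters
    ----------
    entries
        ``(clone_id, A, t_start)`` per clone.
    coef
        Calibration; defaults to the published constants.

    Returns scores in input order. Rank 1 is the most invasive clone; ties
    broken by clone label. Classification (high above the 75th percentile of
    relative invasiveness, low below the 25th) requires >= 4 clones;
    with fewer the class is ``None`` and a warning is issued.
    """
    if not entries:
        raise ValueError("empty cohort")
    ids = [e[0] for e in entries]
    ifs = np.array([invasion_factor(a, t, coef) for _, a, t in entries])
    rel = ifs / ifs.mean()
    # descending relative invasiveness, clone label breaks ties
    order = sorted(range(len(rel)), key=lambda i: (-rel[i], ids[i]))
    ranks = np.empty(len(rel), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    if len(entries) >= 4:
        q25, q75 = np.percentile(rel, [25, 75])
        classes = ["high" if v > q75 else "low" if v < q25 else "mid"
                   for v in rel]
    else:
        warnings.warn("fewer than 4 clones: quartile classification skipped")
        classes = [None] * len(entries)
    return [InvasionScore(clone_id=ids[i], t_start=float(entries[i][2]),
                          area_rel=float(entries[i][1]),
                          invasion_factor=float(ifs[i]),
                          relative_invasiveness=float(rel[i]),
                          rank=int(ranks[i]), invasiveness_class=classes[i])
            for i in range(len(entries))]


def outer_vs_mid_anova(scores: Sequence[InvasionScore],
                       replicates: dict[str, Sequence[float]],
                       seed: int = 0) -> dict[str, AnovaResult]:
    """Compare each high/low clone against the pooled mid-quartile clones.

    ``replicates`` maps clone_id to its replicate invasion factors. The
    pooled mid clones form the control group of a Dunnett comparison.
    """
    mid_vals: list[float] = []
    outer: list[str] = []
    for s in scores:
        if s.invasiveness_class == "mid":
            mid_vals.extend(replicates[s.clone_id])
        elif s.invasiveness_class in ("high", "low"):
            outer.append(s.clone_id)
    if len(mid_vals) < 2:
        raise ValueError("need >= 2 pooled mid-quartile replicate values")
    out = {}
    for cid in outer:
        res = anova_dunnett([mid_vals, list(replicates[cid])],
                            control_index=0, seed=seed)
        out[cid] = res
    return out


def wound_closure_rate(tc: WoundTimecourse) -> tuple[float, RegressionFit]:
    """Slope (%/h) of wound density until the wound closes.

    Frames from the first attainment of 100% onward are censored at the
    ceiling and excluded; the regression runs on the frames strictly before
    it (all frames if the wound never closes). Needs >= 3 such frames.
    """
    reached = np.flatnonzero(tc.wound_density >= 100.0)
    end = int(reached[0]) if reached.size else len(tc.times)
    if end < 3:
        raise ValueError(
            f"{tc.sample_id}: wound closed by frame {end + 1}; "
            "not enough pre-closure points to regress a closure rate")
    fit = linear_fit(tc.times[:end], tc.wound_density[:end])
    return fit.slope, fit


def spheroid_volume_increase(area_start: float, area_end: float) -> float:
    """Fold volume change of a sphere given its projected-area change.

    Projected area scales as r^2 and volume as r^3, hence the 3/2 power.
    """
    if area_start <= 0 or area_end <= 0:
        raise ValueError("areas must be positive")
    return (area_end / area_start) ** 1.5


# ---------------------------------------------------------------------------
# file formats

def read_invasion_csv(path) -> list[InvasionTimecourse]:
    """Read a long-format CSV (clone_id, time_h, area) into timecourses."""
    df = pd.read_csv(path)
    required = {"clone_id", "time_h", "area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"invasion CSV missing columns: {sorted(missing)}")
    out = []
    for cid, grp in df.groupby("clone_id", sort=True):
        grp = grp.sort_values("time_h")
        out.append(InvasionTimecourse(clone_id=str(cid),
                                      times=grp["time_h"].to_numpy(),
                                      areas=grp["area"].to_numpy()))
    return out


def read_wound_csv(path) -> list[WoundTimecourse]:
    df = pd.read_csv(path)
    required = {"sample_id", "time_h", "wound_density_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"wound CSV missing columns: {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        grp = grp.sort_values("time_h")
        out.append(WoundTimecourse(sample_id=str(sid),
                                   times=grp["time_h"].to_numpy(),
                                   wound_density=grp["wound_density_pct"].to_numpy()))
    return out


def scores_to_frame(scores: Sequence[InvasionScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"clone_id": s.clone_id, "t_start_h": s.t_start,
          "area_rel": s.area_rel, "invasion_factor": s.invasion_factor,
          "relative_invasiveness": s.relative_invasiveness,
          "rank": s.rank, "class": s.invasiveness_class}
         for s in scores])
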