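"""Expression normalization and expression–invasiveness association.

qPCR Ct values are converted to relative expression by the efficiency-2
delta-Ct method against the arithmetic mean Ct of a reference-gene panel
(RPLP0, PPIA, POLR2A by default), optionally re-normalized so each gene
averages 1 over the clone cohort. Protein/transcript marker ratios
(e.g. Vimentin/E-cadherin) and a deterministic two-means split of clones in
the (Vimentin, N-cadherin) plane support the mesenchymal subgrouping, and
per-gene regressions of expression on the invasion factor quantify
association with invasiveness — overall and within each subgroup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .invasion import InvasionScore
from .stats import linear_fit

__all__ = [
    "DEFAULT_REFERENCE_GENES",
    "SubgroupLabel",
    "normalize_qpcr",
    "marker_ratio",
    "split_subgroups",
    "correlate_with_invasion",
]

DEFAULT_REFERENCE_GENES = ("RPLP0", "PPIA", "POLR2A")


@dataclass(frozen=True)
class SubgroupLabel:
    clone_id: str
    label: str  # "high_high" or "low_low"
    basis: tuple[float, float]  # (vimentin level, n-cadherin level)


def normalize_qpcr(ct: pd.DataFrame,
                   reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
                   cohort_normalize: bool = True) -> pd.DataFrame:
    """Delta-Ct normalization with efficiency 2.

    Parameters
    ----------
    ct
        Long table with columns ``sample_id, gene, ct``.
    reference_genes
        Panel whose arithmetic mean Ct anchors each sample. Every sample
        must carry every reference gene.
    cohort_normalize
        If True, each gene's expression is additionally divided by its mean
        over all samples, so the cohort mean is exactly 1 per gene.

    Returns a long table ``sample_id, gene, value`` for the non-reference
    genes, where ``value = 2**(-(Ct(gene) - mean Ct(references)))``.
    """
    required = {"sample_id", "gene", "ct"}
    if missing := required - set(ct.columns):
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    refs = set(reference_genes)
    rows = []
    for sid, grp in ct.groupby("sample_id", sort=True):
        present = set(grp["gene"])
        if not refs <= present:
            raise ValueError(
                f"sample {sid} lacks reference genes: {sorted(refs - present)}")
        ref_mean = grp.loc[grp["gene"].isin(refs), "ct"].mean()
        targets = grp[~grp["gene"].isin(refs)]
        for _, r in targets.iterrows():
            rows.append({"sample_id": sid, "gene": r["gene"],
                         "value": 2.0 ** (-(r["ct"] - ref_mean))})
    out = pd.DataFrame(rows)
    if cohort_normalize and not out.empty:
        out["value"] = out["value"] / out.groupby("gene")["value"].transform("mean")
    return out


def marker_ratio(expr: pd.DataFrame, numerator: str,
                 denominator: str) -> pd.Series:
    """Per-sample ratio of two markers from a long (sample_id, gene, level)
    table. A zero denominator yields NaN for that sample, not a failure."""
    required = {"sample_id", "gene", "level"}
    if missing := required - set(expr.columns):
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    wide = expr.pivot(index="sample_id", columns="gene", values="level")
    for g in (numerator, denominator):
        if g not in wide.columns:
            raise ValueError(f"gene {g!r} not in abundance table")
    num, den = wide[numerator], wide[denominator]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den.where(den != 0, np.nan)
    ratio.name = f"{numerator}/{denominator}"
    return ratio


def _two_means(points: np.ndarray) -> np.ndarray:
    """Deterministic 2-means on standardized coordinates.

    Centroids are initialized at the points with the extreme coordinate
    sums; Lloyd iterations run to convergence. Returns 0/1 labels where
    cluster 1 has the larger standardized centroid sum.
    """
    std = points.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    z = (points - points.mean(axis=0)) / std
    sums = z.sum(axis=1)
    centroids = np.vstack([z[np.argmin(sums)], z[np.argmax(sums)]])
    labels = np.full(len(z), -1, dtype=int)
    for _ in range(100):
        d = ((z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new = d.argmin(axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        for c in (0, 1):
            if (labels == c).any():
                centroids[c] = z[labels == c].mean(axis=0)
    if centroids[0].sum() > centroids[1].sum():
        labels = 1 - labels
    return labels


def split_subgroups(vim: Mapping[str, float], ncad: Mapping[str, float],
                    method: str = "two_means") -> list[SubgroupLabel]:
    """Partition clones into Vim^high/N-cad^high and Vim^low/N-cad^low.

    ``two_means`` (default): deterministic 2-means in the standardized
    (vim, ncad) plane, initialized at the extreme coordinate-sum points.
    ``median``: high_high iff both markers exceed their cohort medians.
    """
    clones = sorted(vim)
    if set(ncad) != set(vim):
        raise ValueError("vim and ncad must cover the same clones")
    if len(clones) < 4:
        raise ValueError("need at least 4 clones to split subgroups")
    pts = np.array([[vim[c], ncad[c]] for c in clones], dtype=float)
    if np.allclose(pts, pts[0]):
        warnings.warn("all clones identical: single subgroup")
        return [SubgroupLabel(c, "low_low", tuple(p)) for c, p in zip(clones, pts)]
    if method == "two_means":
        labels = _two_means(pts)
        names = np.where(labels == 1, "high_high", "low_low")
    elif method == "median":
        med = np.median(pts, axis=0)
        both_high = (pts[:, 0] > med[0]) & (pts[:, 1] > med[1])
        names = np.where(both_high, "high_high", "low_low")
    else:
        raise ValueError(f"unknown method {method!r}")
    return [SubgroupLabel(c, str(n), (float(p[0]), float(p[1])))
            for c, n, p in zip(clones, names, pts)]


def correlate_with_invasion(expr: pd.DataFrame,
                            scores: Sequence[InvasionScore],
                            subgroups: Sequence[SubgroupLabel] | None = None,
                            log_predictor: bool = False) -> pd.DataFrame:
    """Per-gene regression of expression on the invasion factor.

    Fits expression ~ IF for every gene over the full cohort and, when
    ``subgroups`` is given, within each subgroup with >= 3 clones (smaller
    subgroups are skipped with a warning). ``log_predictor`` regresses on
    ln(IF) instead, for cohorts whose area–onset coupling is log-linear.

    Returns a tidy frame: gene, subgroup ("all" or label), slope,
    r_squared, p_slope, n.
    """
    required = {"sample_id", "gene", "value"}
    if missing := required - set(expr.columns):
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if_by_clone = {s.clone_id: s.invasion_factor for s in scores}
    groups: dict[str, list[str]] = {"all": sorted(if_by_clone)}
    if subgroups is not None:
        for lab in sorted({s.label for s in subgroups}):
            groups[lab] = sorted(s.clone_id for s in subgroups if s.label == lab)
    rows = []
    for gene, gdf in expr.groupby("gene", sort=True):
        vals = dict(zip(gdf["sample_id"], gdf["value"]))
        for gname, members in groups.items():
            members = [c for c in members if c in vals and c in if_by_clone]
            if len(members) < 3:
                warnings.warn(
                    f"subgroup {gname!r} has < 3 clones with data for "
                    f"{gene}; skipped")
                continue
            x = np.array([if_by_clone[c] for c in members])
            y = np.array([vals[c] for c in members])
            if log_predictor:
                x = np.log(x)
            if np.ptp(x) == 0:
                warnings.warn(f"constant invasion factor in {gname!r}; skipped")
                continue
            fit = linear_fit(x, y)
            rows.append({"gene": gene, "subgroup": gname, "slope": fit.slope,
                         "r_squared": fit.r_squared, "p_slope": fit.p_slope,
                         "n": fit.n})
    return pd.DataFrame(rows)
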