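"""Junction-to-cytoplasm fluorescence enrichment from line scans.

A contact segment is a straight line of roughly 150 px drawn across a
bicellular contact with the junction at its center. The intensity profile
along the segment is averaged over a 20 px band perpendicular to it
(bilinear sub-pixel sampling), and the enrichment factor (EF) is

    EF = mean(central 10 px window) / mean(first 10 px + last 10 px)

i.e. junctional signal over pooled cytoplasmic signal at the two segment
ends. EF = 1 means no junctional accumulation; E-cadherin recruited into
adherens junctions gives EF well above 1. Being a ratio, EF is invariant
under multiplicative intensity rescaling (exposure, gain).

Coordinates are 0-based (row, col) pixel positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .stats import anova_dunnett, AnovaResult

__all__ = [
    "ContactSegment",
    "LineScan",
    "EnrichmentFactor",
    "extract_profile",
    "enrichment_factor",
    "batch_enrichment",
    "compare_conditions",
    "read_segments_csv",
    "load_images",
]

JUNCTION_WINDOW = 10  # px
END_WINDOW = 10       # px per cytoplasmic end
BAND_WIDTH = 20.0     # px perpendicular to the segment
MIN_LENGTH = 2 * END_WINDOW + JUNCTION_WINDOW  # two ends + junction


@dataclass(frozen=True)
class ContactSegment:
    """One line scan location: endpoints across a bicellular contact."""

    image_id: str
    p0: tuple[float, float]  # (row, col)
    p1: tuple[float, float]
    condition: str = ""

    @property
    def length(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))

    def __post_init__(self):
        if self.length < MIN_LENGTH:
            raise ValueError(
                f"segment shorter than {MIN_LENGTH} px "
                f"(two {END_WINDOW} px ends + {JUNCTION_WINDOW} px junction)")


@dataclass(frozen=True)
class LineScan:
    """Width-averaged intensity profile along one segment."""

    image_id: str
    profile: np.ndarray
    condition: str = ""


@dataclass(frozen=True)
class EnrichmentFactor:
    value: float
    junction_window: int = JUNCTION_WINDOW
    cytoplasm_windows: tuple[int, int] = (END_WINDOW, END_WINDOW)


def extract_profile(image: np.ndarray, seg: ContactSegment) -> LineScan:
    """Width-averaged line scan.

    One sample per unit step along the segment (``round(length)`` samples);
    each sample averages 20 bilinear interpolations evenly spaced across
    the perpendicular +-10 px band (at the centers of 20 unit-width strips).

    Raises a bounds error if any point of the band leaves the image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be a 2-D intensity grid")
    p0 = np.asarray(seg.p0, dtype=float)
    p1 = np.asarray(seg.p1, dtype=float)
    length = seg.length
    n = int(round(length))
    u = (p1 - p0) / length                      # unit vector along segment
    v = np.array([-u[1], u[0]])                 # unit perpendicular
    steps = np.arange(n)[:, None] * u[None, :] + p0[None, :]   # (n, 2)
    offsets = (np.arange(20) - 9.5)[:, None] * v[None, :]      # (20, 2)
    pts = steps[:, None, :] + offsets[None, :, :]              # (n, 20, 2)
    rows, cols = pts[..., 0], pts[..., 1]
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() > img.shape[0] - 1 or cols.max() > img.shape[1] - 1):
        raise ValueError(
            f"segment band exits image bounds {img.shape} "
            f"(rows {rows.min():.1f}–{rows.max():.1f}, "
            f"cols {cols.min():.1f}–{cols.max():.1f})")
    sampled = ndimage.map_coordinates(
        img, [rows.ravel(), cols.ravel()], order=1, mode="nearest")
    profile = sampled.reshape(n, 20).mean(axis=1)
    return LineScan(image_id=seg.image_id, profile=profile,
                    condition=seg.condition)


def enrichment_factor(scan: LineScan, align: str = "midpoint") -> EnrichmentFactor:
    """Junction/cytoplasm intensity ratio of one profile.

    ``align="midpoint"`` centers the 10 px junction window at the profile
    midpoint (segments are drawn with the contact at their center);
    ``align="peak"`` centers it on the intensity maximum within the central
    third, for segments whose contact is slightly off-center.
    """
    p = np.asarray(scan.profile, dtype=float)
    L = len(p)
    if L < MIN_LENGTH:
        raise ValueError(f"profile shorter than {MIN_LENGTH} px")
    if align == "midpoint":
        start = (L - JUNCTION_WINDOW) // 2
    elif align == "peak":
        third = L // 3
        center = third + int(np.argmax(p[third:L - third]))
        start = int(np.clip(center - JUNCTION_WINDOW // 2,
                            END_WINDOW, L - END_WINDOW - JUNCTION_WINDOW))
    else:
        raise ValueError(f"unknown align mode {align!r}")
    junction = p[start:start + JUNCTION_WINDOW].mean()
    cytoplasm = np.concatenate([p[:END_WINDOW], p[-END_WINDOW:]]).mean()
    if cytoplasm <= 0:
        raise ValueError("cytoplasmic mean is not positive; EF undefined")
    return EnrichmentFactor(value=float(junction / cytoplasm))


def batch_enrichment(images: Mapping[str, np.ndarray],
                     segments: Sequence[ContactSegment],
                     align: str = "midpoint") -> pd.DataFrame:
    """EF for every segment, grouped by condition.

    Segments that fail (out of bounds, zero cytoplasm) are skipped with a
    warning, not fatal. Returns a tidy frame: condition, image_id, ef.
    """
    rows = []
    for seg in segments:
        try:
            scan = extract_profile(images[seg.image_id], seg)
            ef = enrichment_factor(scan, align=align)
        except (KeyError, ValueError) as exc:
            warnings.warn(f"segment on {seg.image_id!r} skipped: {exc}")
            continue
        rows.append({"condition": seg.condition, "image_id": seg.image_id,
                     "ef": ef.value})
    return pd.DataFrame(rows, columns=["condition", "image_id", "ef"])


def summarize_enrichment(efs: pd.DataFrame) -> pd.DataFrame:
    """Violin-ready per-condition summary: n, mean, median, quartiles."""
    return (efs.groupby("condition")["ef"]
            .agg(n="count", mean="mean", median="median",
                 q25=lambda s: s.quantile(0.25),
                 q75=lambda s: s.quantile(0.75))
            .reset_index())


def compare_conditions(efs: pd.DataFrame, control: str,
                       seed: int = 0) -> AnovaResult:
    """One-way ANOVA with Dunnett comparisons of each condition vs control."""
    conditions = sorted(efs["condition"].unique())
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not present")
    ordered = [control] + [c for c in conditions if c != control]
    groups = [efs.loc[efs["condition"] == c, "ef"].to_numpy() for c in ordered]
    return anova_dunnett(groups, control_index=0, seed=seed)


# ---------------------------------------------------------------------------
# file formats

def read_segments_csv(path) -> list[ContactSegment]:
    """Segments CSV: image_id, r0, c0, r1, c1[, condition]."""
    df = pd.read_csv(path)
    required = {"image_id", "r0", "c0", "r1", "c1"}
    if missing := required - set(df.columns):
        raise ValueError(f"segments CSV missing columns: {sorted(missing)}")
    cond = df["condition"] if "condition" in df.columns else [""] * len(df)
    return [ContactSegment(image_id=str(r.image_id),
                           p0=(float(r.r0), float(r.c0)),
                           p1=(float(r.r1), float(r.c1)),
                           condition=str(c))
            for r, c in zip(df.itertuples(), cond)]


def load_images(paths: Mapping[str, str]) -> dict[str, np.ndarray]:
    """Load single-channel TIFFs keyed by image_id."""
    return {iid: np.asarray(tifffile.imread(p), dtype=float)
            for iid, p in paths.items()}
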