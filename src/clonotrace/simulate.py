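"""Synthetic data with known ground truth for every pipeline stage.

The study's raw data (sequencing runs, time-lapse stacks, confocal images)
are not deposited, so each analysis stage is exercised on simulated inputs
that emulate the corresponding assay:

* negative-binomial RNA-seq counts for the five contrasts (m, c, s, l, d;
  3 vs 3 replicates) with planted genes following the LCK-consistent
  direction pattern (up in m and c, down in s, l, d);
* exponential-onset invasion area series and linear-until-plateau wound
  closure series;
* membrane-ridge contact images with an analytically known junction /
  cytoplasm enrichment factor;
* qPCR Ct tables under efficiency-2 amplification.

Every generator is a pure function of its parameters and a seed; a single
global seed fans out to independent named substreams. The planted
parameters travel alongside the data in a :class:`SyntheticTruth` so tests
can score recovery.

The bundled differential-expression test (:func:`simple_de`) is a
moderated two-sample t on log2CPM: gene-wise pooled variances are shrunk
toward a common prior fitted by the scaled-F moment method, which lends the
test the extra degrees of freedom that triplicate designs need. It is a
minimal moderated-t DE test, not an edgeR-style negative-binomial GLM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .integration import DATASETS, DETable, INVASION_DATASETS
from .invasion import InvasionTimecourse, WoundTimecourse
from .junction import ContactSegment
from .stats import bh_fdr

__all__ = [
    "SyntheticTruth",
    "CountMatrix",
    "simulate_counts",
    "simple_de",
    "simulate_invasion_timecourse",
    "simulate_invasion_cohort",
    "simulate_wound",
    "simulate_contact_image",
    "simulate_contact_batch",
    "analytic_ef",
    "amplitude_for_ef",
    "simulate_qpcr",
]

# fixed substream indices so generators stay independent of call order
_STREAMS = {"counts": 0, "invasion": 1, "wound": 2, "image": 3, "qpcr": 4}


def _rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream], index)))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted parameters recorded next to generated data."""

    seed: int
    planted_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    true_t0: dict[str, float] = field(default_factory=dict)
    true_ef: dict[str, float] = field(default_factory=dict)
    true_fold: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples counts with a two-group design."""

    counts: pd.DataFrame  # index: genes; columns: samples
    groups: tuple[str, ...]  # one label per column

    def __post_init__(self):
        if len(self.groups) != self.counts.shape[1]:
            raise ValueError("one group label per sample column required")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("library sizes must be positive")


def _nb_counts(means: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """NB draws with var = mu + dispersion * mu^2 (gamma–Poisson mixture)."""
    lam = rng.gamma(shape=1.0 / dispersion, scale=means * dispersion)
    return rng.poisson(lam)


def simulate_counts(n_genes: int = 5000,
                    n_planted: int = 20,
                    n_replicates: int = 3,
                    effect_log2fc: float = 2.0,
                    dispersion: float = 0.1,
                    lib_size: float = 1.5e6,
                    seed: int = 0) -> tuple[dict[str, CountMatrix], SyntheticTruth]:
    """NB count matrices for the five contrasts with planted LCK-pattern genes.

    Planted genes move up by ``effect_log2fc`` in the invasion contrasts
    (m, c) and down in the inhibition contrasts (s, l, d). Baseline
    expression is log-normal, scaled so each sample's expected library size
    is ``lib_size``. The signal is planted among genes of at least median
    baseline abundance: the planted set emulates the study's candidate
    genes, which are moderately-to-well expressed, and keeps the planted
    direction pattern identifiable at triplicate depth. Group "ref" is the
    reference condition of every contrast; group "alt" carries the effect.
    """
    if not 0 <= n_planted < n_genes:
        raise ValueError("need 0 <= n_planted < n_genes")
    if dispersion <= 0 or lib_size <= 0 or n_replicates < 2:
        raise ValueError("dispersion, lib_size must be positive; n_replicates >= 2")
    rng = _rng(seed, "counts")
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    base = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n_genes)
    base *= lib_size / base.sum()
    eligible = np.flatnonzero(base >= np.median(base))
    planted_idx = rng.choice(eligible, size=min(n_planted, len(eligible)),
                             replace=False)

    planted: dict[str, dict[str, float]] = {
        genes[i]: {} for i in sorted(planted_idx)}
    matrices: dict[str, CountMatrix] = {}
    for k, contrast in enumerate(DATASETS):
        crng = _rng(seed, "counts", index=k + 1)
        fc = np.zeros(n_genes)
        sign = 1.0 if contrast in INVASION_DATASETS else -1.0
        fc[planted_idx] = sign * effect_log2fc
        for i in planted_idx:
            planted[genes[i]][contrast] = float(fc[i])
        mu_ref = np.repeat(base[:, None], n_replicates, axis=1)
        mu_alt = np.repeat((base * 2.0 ** fc)[:, None], n_replicates, axis=1)
        c_ref = _nb_counts(mu_ref, dispersion, crng)
        c_alt = _nb_counts(mu_alt, dispersion, crng)
        cols = ([f"{contrast}_ref{j+1}" for j in range(n_replicates)]
                + [f"{contrast}_alt{j+1}" for j in range(n_replicates)])
        df = pd.DataFrame(np.hstack([c_ref, c_alt]), index=genes, columns=cols)
        matrices[contrast] = CountMatrix(
            counts=df, groups=("ref",) * n_replicates + ("alt",) * n_replicates)
    truth = SyntheticTruth(seed=seed, planted_genes=planted)
    return matrices, truth


def _fit_scaled_f(s2: np.ndarray, df: float,
                  covariate: np.ndarray | None = None
                  ) -> tuple[np.ndarray, float]:
    """Moment fit of gene-wise variances to s0^2(x) * F(df, d0).

    ``covariate`` (mean log2CPM) makes the prior scale a lowess trend on
    abundance, absorbing the mean–variance relationship of count data so
    that low-abundance genes are not moderated toward too small a prior.
    Returns (per-gene s0^2, d0); d0 = inf when the observed log-variance
    spread around the trend is no wider than the sampling spread.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    if covariate is not None and len(np.unique(covariate)) > 10:
        from statsmodels.nonparametric.smoothers_lowess import lowess
        e0 = lowess(e, covariate, frac=0.4, return_sorted=False)
    else:
        e0 = np.full_like(e, e.mean())
    evar = np.var(e - e0, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.exp(e0), float("inf")
    # invert trigamma by Newton iteration
    y = 0.5 + 1.0 / evar
    for _ in range(100):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / evar) / special.polygamma(2, y)
        y += step
        if abs(step) < 1e-10:
            break
    d0 = 2.0 * y
    s0 = np.exp(e0 + special.digamma(y) - np.log(y))
    return s0, float(d0)


def simple_de(counts: CountMatrix, group_a: str = "ref",
              group_b: str = "alt", dataset_id: str = "x") -> DETable:
    """Moderated-t differential expression of group_b versus group_a.

    log2CPM with pseudo-count 0.5 per sample; per-gene pooled variance
    shrunk toward an abundance-trended prior (scaled-F moment fit on a
    lowess trend of log variance against mean log2CPM); t statistic on the
    shrunken variance with ``d0 + n - 2`` degrees of freedom; BH FDR.
    log2FC is the difference of group mean log2CPM (b minus a).
    """
    groups = np.asarray(counts.groups)
    a_cols = groups == group_a
    b_cols = groups == group_b
    if a_cols.sum() < 2 or b_cols.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    c = counts.counts.to_numpy(dtype=float)
    lib = c.sum(axis=0)
    y = np.log2((c + 0.5) / (lib + 1.0) * 1e6)
    ya, yb = y[:, a_cols], y[:, b_cols]
    na, nb = ya.shape[1], yb.shape[1]
    df_res = na + nb - 2
    s2 = (ya.var(axis=1, ddof=1) * (na - 1)
          + yb.var(axis=1, ddof=1) * (nb - 1)) / df_res
    s0, d0 = _fit_scaled_f(s2, df_res, covariate=y.mean(axis=1))
    if np.isinf(d0):
        # variance fully explained by the trend: effectively normal reference
        s2_post, df_total = s0, 1e6
    else:
        s2_post = (d0 * s0 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    log2fc = yb.mean(axis=1) - ya.mean(axis=1)
    t = log2fc / np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    fdr = bh_fdr(p)
    log2cpm = y.mean(axis=1)
    table = pd.DataFrame({"gene": counts.counts.index, "log2fc": log2fc,
                          "p_value": p, "fdr": fdr, "log2cpm": log2cpm})
    return DETable(dataset_id=dataset_id, data=table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# invasion and wound timecourses

def simulate_invasion_timecourse(clone_id: str = "clone",
                                 t0: float = 12.0,
                                 growth_rate: float = 0.1,
                                 noise_sd: float = 0.02,
                                 sampling: str = "hourly",
                                 duration: float = 48.0,
                                 baseline_area: float = 1.0e4,
                                 seed: int = 0,
                                 _index: int = 0) -> tuple[InvasionTimecourse, SyntheticTruth]:
    """Exponential-onset invasion area series.

    ``t0`` is the onset as time-lapse imaging reports it: the time of the
    first frame showing invasive growth. The underlying continuous growth
    starts one sampling interval earlier, so the frame at ``t0`` is already
    elevated: area(t) = A0 for t < t0 and
    A0 * exp(growth_rate * (t - t0 + step)) from ``t0`` on, with
    multiplicative Gaussian noise of relative sd ``noise_sd``. ``sampling``
    is "hourly" (onset characterization) or "6-hourly" (routine assay).
    """
    if not 0 <= t0 <= duration:
        raise ValueError("t0 must lie within the imaging window")
    if growth_rate < 0:
        raise ValueError("growth rate must be non-negative")
    step = {"hourly": 1.0, "6-hourly": 6.0}.get(sampling)
    if step is None:
        raise ValueError("sampling must be 'hourly' or '6-hourly'")
    rng = _rng(seed, "invasion", index=_index)
    times = np.arange(0.0, duration + step / 2, step)
    clean = np.where(times < t0, baseline_area,
                     baseline_area * np.exp(growth_rate * (times - t0 + step)))
    noisy = clean * (1.0 + rng.normal(0.0, noise_sd, size=len(times)))
    tc = InvasionTimecourse(clone_id=clone_id, times=times,
                            areas=np.maximum(noisy, 0.0))
    return tc, SyntheticTruth(seed=seed, true_t0={clone_id: t0})


def simulate_invasion_cohort(n_clones: int = 20,
                             t0_range: tuple[float, float] = (4.0, 40.0),
                             growth_rate: float = 0.1,
                             noise_sd: float = 0.02,
                             sampling: str = "hourly",
                             seed: int = 0) -> tuple[list[InvasionTimecourse], SyntheticTruth]:
    """A cohort of clones with onset times spread over ``t0_range``."""
    rng = _rng(seed, "invasion")
    t0s = np.sort(rng.uniform(*t0_range, size=n_clones))
    cohort, truth_t0 = [], {}
    for i, t0 in enumerate(t0s):
        cid = f"clone_{chr(ord('A') + i) if i < 26 else i}"
        tc, _ = simulate_invasion_timecourse(
            clone_id=cid, t0=float(t0), growth_rate=growth_rate,
            noise_sd=noise_sd, sampling=sampling, seed=seed, _index=i + 1)
        cohort.append(tc)
        truth_t0[cid] = float(t0)
    return cohort, SyntheticTruth(seed=seed, true_t0=truth_t0)


def simulate_wound(sample_id: str = "well",
                   rate: float = 10.0,
                   noise_sd: float = 1.0,
                   step_h: float = 4.0,
                   duration: float = 24.0,
                   seed: int = 0) -> WoundTimecourse:
    """Wound density = rate * t plus noise, saturating at the 100% ceiling.

    Noise applies to the underlying closure signal; frames beyond full
    closure read exactly 100, as a confluence measure saturates.
    """
    if rate <= 0:
        raise ValueError("closure rate must be positive")
    rng = _rng(seed, "wound")
    times = np.arange(0.0, duration + step_h / 2, step_h)
    density = np.clip(rate * times + rng.normal(0.0, noise_sd, len(times)),
                      0, 100)
    return WoundTimecourse(sample_id=sample_id, times=times,
                           wound_density=density)


# ---------------------------------------------------------------------------
# contact images

_SCAN_LENGTH = 150


def _window_gauss_mean(a: float, b: float, sigma: float) -> float:
    """Mean of exp(-x^2 / 2 sigma^2) over the interval [a, b]."""
    z = sigma * np.sqrt(2.0 * np.pi)
    return z * (sps.norm.cdf(b / sigma) - sps.norm.cdf(a / sigma)) / (b - a)


def analytic_ef(cytoplasm_level: float, amplitude: float, sigma: float,
                length: int = _SCAN_LENGTH) -> float:
    """Closed-form EF of the noiseless Gaussian-ridge model.

    The profile along the scan is c + j * exp(-x^2 / 2 sigma^2) with the
    ridge at the scan midpoint; window means are continuous integrals over
    the 10 px junction window and the two pooled 10 px end windows.
    """
    half = length / 2.0
    j_lo, j_hi = -5.0, 5.0
    junction = cytoplasm_level + amplitude * _window_gauss_mean(j_lo, j_hi, sigma)
    # ends span [-half, -half+10] and [half-10, half] around the ridge
    end = _window_gauss_mean(half - 10.0, half, sigma)  # symmetric ends
    cytoplasm = cytoplasm_level + amplitude * end
    return junction / cytoplasm


def amplitude_for_ef(target_ef: float, cytoplasm_level: float, sigma: float,
                     length: int = _SCAN_LENGTH) -> float:
    """Ridge amplitude giving a prescribed analytic EF (exact inversion)."""
    wj = _window_gauss_mean(-5.0, 5.0, sigma)
    wc = _window_gauss_mean(length / 2.0 - 10.0, length / 2.0, sigma)
    denom = wj - target_ef * wc
    if denom <= 0:
        raise ValueError("target EF not attainable with this geometry")
    return cytoplasm_level * (target_ef - 1.0) / denom


def simulate_contact_image(size: tuple[int, int] = (64, 180),
                           cytoplasm_level: float = 100.0,
                           junction_amplitude: float = 200.0,
                           ridge_sigma: float = 3.0,
                           noise_sd: float = 0.0,
                           image_id: str = "img",
                           condition: str = "",
                           seed: int = 0,
                           _index: int = 0
                           ) -> tuple[np.ndarray, list[ContactSegment], SyntheticTruth]:
    """One contact image: a vertical Gaussian ridge on constant cytoplasm.

    The scan segment is horizontal, 150 px long, with the ridge centered on
    the junction window of the midpoint-aligned profile. True EF is the
    analytic window value of the noiseless model.
    """
    if cytoplasm_level <= 0:
        raise ValueError("cytoplasm level must be positive")
    h, w = size
    c0 = (w - _SCAN_LENGTH) // 2
    if c0 < 0 or h < 21:
        raise ValueError("image too small for a 150 x 20 px scan")
    ridge_col = c0 + (_SCAN_LENGTH - 1) / 2.0  # scan midpoint
    cols = np.arange(w, dtype=float)
    profile = cytoplasm_level + junction_amplitude * np.exp(
        -((cols - ridge_col) ** 2) / (2.0 * ridge_sigma ** 2))
    image = np.tile(profile, (h, 1))
    if noise_sd > 0:
        rng = _rng(seed, "image", index=_index)
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    row = h // 2
    seg = ContactSegment(image_id=image_id, p0=(row, float(c0)),
                         p1=(row, float(c0 + _SCAN_LENGTH)),
                         condition=condition)
    ef = analytic_ef(cytoplasm_level, junction_amplitude, ridge_sigma)
    truth = SyntheticTruth(seed=seed, true_ef={condition or image_id: ef})
    return image, [seg], truth


def simulate_contact_batch(n_contacts: int = 500,
                           true_ef: float = 2.0,
                           cytoplasm_level: float = 100.0,
                           ridge_sigma: float = 3.0,
                           noise_sd: float = 5.0,
                           condition: str = "cond",
                           seed: int = 0
                           ) -> tuple[dict[str, np.ndarray], list[ContactSegment], SyntheticTruth]:
    """A batch of noisy contact images sharing one planted EF."""
    amp = amplitude_for_ef(true_ef, cytoplasm_level, ridge_sigma)
    images: dict[str, np.ndarray] = {}
    segments: list[ContactSegment] = []
    for i in range(n_contacts):
        iid = f"{condition}_{i:04d}"
        img, segs, _ = simulate_contact_image(
            cytoplasm_level=cytoplasm_level, junction_amplitude=amp,
            ridge_sigma=ridge_sigma, noise_sd=noise_sd, image_id=iid,
            condition=condition, seed=seed, _index=i + 1)
        images[iid] = img
        segments.extend(segs)
    return images, segments, SyntheticTruth(seed=seed,
                                            true_ef={condition: true_ef})


# ---------------------------------------------------------------------------
# qPCR

def simulate_qpcr(true_fold: Mapping[str, Mapping[str, float]],
                  reference_genes: Sequence[str] = ("RPLP0", "PPIA", "POLR2A"),
                  ref_ct: float = 20.0,
                  noise_sd: float = 0.0,
                  seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Ct table under efficiency-2 amplification.

    ``true_fold[sample][gene]`` is the planted expression relative to the
    reference level; Ct(gene) = ref_ct - log2(fold) + noise, and every
    reference gene is measured at ref_ct + noise.
    """
    rng = _rng(seed, "qpcr")
    rows = []
    folds: dict[str, float] = {}
    for sample in sorted(true_fold):
        for ref in reference_genes:
            rows.append({"sample_id": sample, "gene": ref,
                         "ct": ref_ct + rng.normal(0.0, noise_sd)})
        for gene, fold in sorted(true_fold[sample].items()):
            if fold <= 0:
                raise ValueError("true fold changes must be positive")
            rows.append({"sample_id": sample, "gene": gene,
                         "ct": ref_ct - np.log2(fold) + rng.normal(0.0, noise_sd)})
            folds[f"{sample}:{gene}"] = float(fold)
    return pd.DataFrame(rows), SyntheticTruth(seed=seed, true_fold=folds)
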