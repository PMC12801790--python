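"""Fragment Size Distribution features: per-arm histograms of fragment
length over 110-220 bp at 5-bp resolution (24 half-open bins per arm,
covering [110, 230)), LOESS GC-corrected across arms, then z-scored
against training-cohort statistics.

Under the hg19 arm preset this yields 39 arms x 24 bins = 936 features,
ordered arm-major, bin-minor ("1p_110", "1p_115", ..., "22q_225").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .fragments import ReferenceGenome, SampleFragments
from .manifests import ArmTable

__all__ = [
    "SizeBinScheme",
    "FsdRaw",
    "FsdNormalizer",
    "fsd_raw",
    "fsd_gc_correct",
    "fit_fsd_normalizer",
    "fsd_features",
    "arm_gc_from_reference",
]


@dataclass(frozen=True)
class SizeBinScheme:
    """Half-open length bins [lower + k*width, lower + (k+1)*width)."""

    lower: int = 110
    width: int = 5
    n_bins: int = 24

    @property
    def upper(self) -> int:
        return self.lower + self.width * self.n_bins

    def bin_of(self, length: np.ndarray) -> np.ndarray:
        """Bin index per length; -1 when outside the supported range."""
        length = np.asarray(length)
        k = (length - self.lower) // self.width
        k = np.where((length >= self.lower) & (length < self.upper), k, -1)
        return k.astype(np.int64)

    def labels(self, arm_ids) -> list[str]:
        return [f"{a}_{self.lower + k * self.width}" for a in arm_ids for k in range(self.n_bins)]


@dataclass(frozen=True)
class FsdRaw:
    sample_id: str
    counts: np.ndarray  # (n_arms, n_bins) int64, included arms only
    arm_ids: tuple[str, ...]
    scheme: SizeBinScheme

    @property
    def n_in_support(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FsdNormalizer:
    """Per-feature mean and sample standard deviation (ddof=1) fitted on
    the training cohort; features with zero spread are flagged and forced
    to z = 0."""

    mean: np.ndarray
    std: np.ndarray
    degenerate: np.ndarray  # bool mask where std == 0

    def transform(self, corrected: np.ndarray) -> np.ndarray:
        x = np.asarray(corrected, dtype=float).ravel()
        if x.shape != self.mean.shape:
            raise ValueError(f"feature length {x.shape} != normalizer {self.mean.shape}")
        safe = np.where(self.degenerate, 1.0, self.std)
        z = (x - self.mean) / safe
        return np.where(self.degenerate, 0.0, z)

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * np.where(self.degenerate, 1.0, self.std) + self.mean


def fsd_raw(
    frags: SampleFragments, arms: ArmTable, scheme: SizeBinScheme = SizeBinScheme()
) -> FsdRaw:
    """Count fragments per (included arm, size bin) by fragment midpoint.

    Fragments outside the size support or on excluded arms are ignored.
    """
    inc = arms.included
    counts = np.zeros((len(inc), scheme.n_bins), dtype=np.int64)
    mid = (frags.start + frags.end) // 2
    kbin = scheme.bin_of(frags.length)
    in_support = kbin >= 0
    chrom_of = np.asarray(frags.chrom_names)[frags.chrom_codes]
    for ai, arm in enumerate(inc.itertuples(index=False)):
        on_arm = (
            in_support
            & (chrom_of == arm.chrom)
            & (mid >= arm.start)
            & (mid < arm.end)
        )
        if on_arm.any():
            counts[ai] = np.bincount(kbin[on_arm], minlength=scheme.n_bins)
    return FsdRaw(
        sample_id=frags.sample_id,
        counts=counts,
        arm_ids=tuple(inc["arm_id"]),
        scheme=scheme,
    )


def arm_gc_from_reference(arms: ArmTable, reference: ReferenceGenome) -> np.ndarray:
    """GC fraction of each included arm, N bases excluded."""
    out = []
    for arm in arms.included.itertuples(index=False):
        codes = reference.codes(arm.chrom)[arm.start : arm.end]
        acgt = int((codes < 4).sum())
        gc = int(((codes == 1) | (codes == 2)).sum())
        out.append(gc / acgt if acgt else 0.5)
    return np.asarray(out)


def fsd_gc_correct(
    raw: FsdRaw | np.ndarray, arm_gc: np.ndarray, span: float = 0.75
) -> np.ndarray:
    """Per size bin, LOESS-regress counts on arm GC across arms and rescale:
    corrected = count * (bin median / fitted). Requires >= 10 arms;
    degenerate GC (or too few arms) returns the counts unchanged with a
    warning."""
    counts = np.asarray(raw.counts if isinstance(raw, FsdRaw) else raw, dtype=float)
    arm_gc = np.asarray(arm_gc, dtype=float)
    n_arms, n_bins = counts.shape
    if len(arm_gc) != n_arms:
        raise ValueError("arm_gc length mismatch")
    if n_arms < 10:
        warnings.warn("fewer than 10 arms; FSD GC correction skipped")
        return counts.copy()
    if np.unique(arm_gc).size < 2:
        warnings.warn("all arms share one GC value; FSD GC correction skipped")
        return counts.copy()
    out = np.empty_like(counts)
    for k in range(n_bins):
        y = counts[:, k]
        med = float(np.median(y))
        fit = lowess(y, arm_gc, frac=span, return_sorted=True)
        fitted = np.interp(arm_gc, fit[:, 0], fit[:, 1])
        fitted = np.maximum(fitted, max(med, 1.0) * 1e-3)
        out[:, k] = y * med / fitted if med > 0 else y
    return np.maximum(out, 0.0)


def fit_fsd_normalizer(training: list[np.ndarray]) -> FsdNormalizer:
    """Fit per-feature mean/sd over training samples only (no leakage into
    validation); sd uses ddof=1."""
    if len(training) < 3:
        raise ValueError(f"need >= 3 training samples, got {len(training)}")
    mat = np.stack([np.asarray(t, dtype=float).ravel() for t in training])
    mean = mat.mean(axis=0)
    std = mat.std(axis=0, ddof=1)
    degenerate = std == 0.0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} degenerate FSD features (sd=0); z forced to 0")
    return FsdNormalizer(mean=mean, std=std, degenerate=degenerate)


def fsd_features(corrected: np.ndarray, normalizer: FsdNormalizer) -> np.ndarray:
    """Flattened arm-major z-score vector (arms x n_bins long)."""
    return normalizer.transform(np.asarray(corrected, dtype=float).ravel())
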