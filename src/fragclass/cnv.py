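"""Copy-number features: per-bin fragment counts -> GC correction ->
mappability correction -> panel-of-normals normalization -> centered log2
ratios over the kept bins of a manifest.

The profile handed to the classifier is the per-bin log2 ratio vector
itself (2,475 values under the hg19 preset); no segmentation or absolute
copy-number calling is performed. Autosomes are the diploid baseline: the
profile is median-centered so a copy-neutral genome sits at log2 ratio 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .fragments import SampleFragments
from .manifests import BinManifest

__all__ = [
    "BinCounts",
    "PanelOfNormals",
    "CnvProfile",
    "count_fragments_per_bin",
    "gc_correct",
    "build_pon",
    "cnv_profile",
]

DEFAULT_LOESS_SPAN = 0.75


@dataclass(frozen=True)
class BinCounts:
    """Fragment counts over the kept bins of a manifest, in manifest order."""

    sample_id: str
    counts: np.ndarray  # int64, kept bins only
    n_off_manifest: int = 0

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class PanelOfNormals:
    """Per-bin median of corrected, depth-normalized counts across a
    healthy panel; the denominator that cancels platform bias."""

    manifest_id: str
    medians: np.ndarray  # float64, kept bins, all > 0
    panel_size: int


@dataclass(frozen=True)
class CnvProfile:
    sample_id: str
    log2_ratios: np.ndarray

    def __len__(self) -> int:
        return len(self.log2_ratios)


def count_fragments_per_bin(frags: SampleFragments, manifest: BinManifest) -> BinCounts:
    """Assign each fragment to the bin containing its midpoint.

    A fragment straddling a bin boundary is counted once, in the midpoint's
    bin. Fragments whose midpoint lands in a dropped bin or off the
    manifest are discarded but counted (``n_off_manifest``).
    """
    kept = manifest.kept
    mid = (frags.start + frags.end) // 2
    counts = np.zeros(len(kept), dtype=np.int64)
    off = 0
    # manifest bins are a left-to-right tiling per chromosome, so the bin
    # index is mid // bin_width looked up against the kept subset
    kept_index: dict[tuple[str, int], int] = {
        (r.chrom, int(r.start) // manifest.bin_width): i
        for i, r in enumerate(kept.itertuples(index=False))
    }
    w = manifest.bin_width
    for code, chrom in enumerate(frags.chrom_names):
        mask = frags.chrom_codes == code
        if not mask.any():
            continue
        bins = mid[mask] // w
        for b, c in zip(*np.unique(bins, return_counts=True)):
            i = kept_index.get((chrom, int(b)))
            if i is None:
                off += int(c)
            else:
                counts[i] += int(c)
    return BinCounts(sample_id=frags.sample_id, counts=counts, n_off_manifest=off)


def _loess_fit(y: np.ndarray, x: np.ndarray, span: float) -> np.ndarray:
    """Locally-weighted regression of y on x, evaluated at every x."""
    fit = lowess(y, x, frac=span, return_sorted=True)
    return np.interp(x, fit[:, 0], fit[:, 1])


def gc_correct(
    counts: np.ndarray | BinCounts,
    manifest: BinManifest,
    span: float = DEFAULT_LOESS_SPAN,
) -> np.ndarray:
    """Remove GC bias: corrected_i = count_i * median(counts) / fit(gc_i).

    The fit is a LOESS of count on bin GC over kept bins. Degenerate GC
    (a single unique value) skips the correction with a warning. Fitted
    values are floored at a small positive fraction of the median so the
    profile keeps its fixed length even where the fit collapses.
    """
    c = np.asarray(counts.counts if isinstance(counts, BinCounts) else counts, dtype=float)
    gc = manifest.kept["gc"].to_numpy(dtype=float)
    if len(c) != len(gc):
        raise ValueError(f"counts length {len(c)} != kept bins {len(gc)}")
    if np.unique(gc).size < 2:
        warnings.warn("all bins share one GC value; GC correction skipped")
        return c.copy()
    if len(c) < 20:
        warnings.warn("fewer than 20 bins; GC correction skipped")
        return c.copy()
    med = float(np.median(c))
    fit = _loess_fit(c, gc, span)
    floor = max(med, 1.0) * 1e-3
    if (fit <= 0).any():
        warnings.warn("non-positive LOESS fit in GC correction; flooring")
    fit = np.maximum(fit, floor)
    return c * med / fit


def _corrected_normalized(counts: BinCounts, manifest: BinManifest, span: float) -> np.ndarray:
    """gc-correct, divide by mappability, scale to sum 1."""
    corr = gc_correct(counts, manifest, span=span)
    mp = manifest.kept["mappability"].to_numpy(dtype=float)
    corr = corr / np.maximum(mp, 1e-6)
    total = corr.sum()
    if total <= 0:
        raise ValueError(f"sample {counts.sample_id}: no usable fragments on manifest")
    return corr / total


def build_pon(
    panel: list[BinCounts], manifest: BinManifest, span: float = DEFAULT_LOESS_SPAN
) -> PanelOfNormals:
    """Panel of Normals: per-bin median of corrected, depth-normalized
    healthy profiles. Requires at least 3 samples."""
    if len(panel) < 3:
        raise ValueError(f"panel too small: {len(panel)} samples (need >= 3)")
    mat = np.stack([_corrected_normalized(bc, manifest, span) for bc in panel])
    med = np.median(mat, axis=0)
    if (med <= 0).any():
        positive = med[med > 0]
        floor = positive.min() if positive.size else 1e-12
        warnings.warn(f"{int((med <= 0).sum())} zero-median PoN bins floored")
        med = np.maximum(med, floor)
    return PanelOfNormals(manifest_id="kept", medians=med, panel_size=len(panel))


def cnv_profile(
    counts: BinCounts,
    pon: PanelOfNormals,
    manifest: BinManifest,
    span: float = DEFAULT_LOESS_SPAN,
) -> CnvProfile:
    """Centered log2 ratio of the sample's normalized profile over the PoN.

    r_i = log2(corrected_i / sum / pon_i), then median-centered over the
    (autosomal) kept bins so the diploid baseline is exactly 0.
    """
    if len(pon.medians) != manifest.n_kept:
        raise ValueError("panel of normals does not match manifest")
    norm = _corrected_normalized(counts, manifest, span)
    with np.errstate(divide="ignore"):
        r = np.log2(np.maximum(norm, 1e-12) / pon.medians)
    r = r - np.median(r)
    return CnvProfile(sample_id=counts.sample_id, log2_ratios=r)
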