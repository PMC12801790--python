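"""FRAGMA: fragment-based methylation analysis via 5' end motifs.

Methylated CpG sites bias nuclease cleavage so that cfDNA fragments
preferentially start immediately at the cytosine (producing CGN end
motifs), while unmethylated sites favor cleavage one base upstream (NCG
motifs). Alu repeats, which are densely methylated, are used as the
genomic substrate. Twenty-one features are derived per sample:

* 9 Alu-wide ratios — the frequency of each CGN motif (CGA/CGC/CGG/CGT)
  and each NCG motif (ACG/CCG/GCG/TCG) among all Alu 5' end events, plus
  the CGN/NCG count ratio.
* 12 CGCG-context ratios — around every CGCG occurrence in Alu regions
  (both strands; CGCG is its own reverse complement) four cleavage
  registers are distinguished by the motif they generate: position p-1 ->
  NCG (split by the upstream base N), p -> CGC, p+1 -> GCG, p+2 -> CGN
  (split by the base after the CGCG). The ten register counts are divided
  by the total number of CGCG-register events (so they partition to 1),
  and the CGC/NCG and CGN/CGC count ratios are appended.

Zero denominators fall back to a pseudo-count of 1 with a warning; the
feature matrix never contains NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fragments import N_CODE, ReferenceGenome, SampleFragments
from .manifests import RegionSet

__all__ = [
    "EndEvents",
    "FragmaFeatures",
    "FRAGMA_FEATURE_NAMES",
    "collect_end_events",
    "fragma_alu_ratios",
    "fragma_cgcg_ratios",
    "fragma_features",
]

# base codes: A=0 C=1 G=2 T=3
_C, _G = 1, 2
_BASE = "ACGT"
_COMP = (3, 2, 1, 0)

ALU_FEATURE_NAMES = (
    "r_CGA", "r_CGC", "r_CGG", "r_CGT",
    "r_ACG", "r_CCG", "r_GCG", "r_TCG",
    "r_CGN_over_NCG",
)
CGCG_FEATURE_NAMES = (
    "c_NCG_A", "c_NCG_C", "c_NCG_G", "c_NCG_T",
    "c_CGC", "c_GCG",
    "c_CGN_A", "c_CGN_C", "c_CGN_G", "c_CGN_T",
    "c_CGC_over_NCG", "c_CGN_over_CGC",
)
FRAGMA_FEATURE_NAMES = ALU_FEATURE_NAMES + CGCG_FEATURE_NAMES

# indices into the 10 CGCG register counters
_REG_NCG = {b: b for b in range(4)}  # N -> counter 0..3
_REG_CGC = 4
_REG_GCG = 5
_REG_CGN = {b: 6 + b for b in range(4)}  # N -> counter 6..9


@dataclass
class EndEvents:
    """5' end events inside the region set, columnar per sample.

    ``pos`` is the 0-based position of the 5' terminal base on the event's
    strand; ``motif`` rows are 3-base code triplets read 5'->3' on that
    strand. N-containing motifs are dropped on construction.
    """

    chrom_codes: np.ndarray  # int16, indexes chrom_names
    chrom_names: tuple[str, ...]
    pos: np.ndarray  # int64
    minus: np.ndarray  # bool: True for reverse-strand (right) ends
    motif: np.ndarray  # (n, 3) uint8, all codes < 4

    def __len__(self) -> int:
        return len(self.pos)


def _in_regions(pos: np.ndarray, ivals: np.ndarray) -> np.ndarray:
    """Membership of positions in sorted non-overlapping [start, end) rows."""
    if len(ivals) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(ivals[:, 0], pos, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos[ok] < ivals[idx[ok], 1]
    return ok


def collect_end_events(
    frags: SampleFragments, regions: RegionSet, ends: str = "both"
) -> EndEvents:
    """Per fragment, up to two 5' end events (left/forward and
    right/reverse); an event is retained iff its terminal base lies inside
    a region and its motif is N-free."""
    if len(regions) == 0:
        raise ValueError("no regions: the region set is empty")
    if ends not in ("both", "left_only"):
        raise ValueError(f"ends must be 'both' or 'left_only', got {ends!r}")
    if frags.motif_left is None or frags.motif_right is None:
        raise ValueError("fragments lack end motifs; attach a reference first")
    by_chrom = regions.per_chrom()
    codes_l, pos_l, minus_l, motif_l = [], [], [], []
    for code, chrom in enumerate(frags.chrom_names):
        ivals = by_chrom.get(chrom)
        mask = frags.chrom_codes == code
        if ivals is None or not mask.any():
            continue
        idx = np.flatnonzero(mask)
        # left (forward) ends: terminal base at start
        p = frags.start[idx]
        keep = _in_regions(p, ivals) & (frags.motif_left[idx] < N_CODE).all(axis=1)
        codes_l.append(np.full(keep.sum(), code, dtype=np.int16))
        pos_l.append(p[keep])
        minus_l.append(np.zeros(keep.sum(), dtype=bool))
        motif_l.append(frags.motif_left[idx[keep]])
        if ends == "both":
            # right (reverse) ends: terminal base at end - 1
            p = frags.end[idx] - 1
            keep = _in_regions(p, ivals) & (frags.motif_right[idx] < N_CODE).all(axis=1)
            codes_l.append(np.full(keep.sum(), code, dtype=np.int16))
            pos_l.append(p[keep])
            minus_l.append(np.ones(keep.sum(), dtype=bool))
            motif_l.append(frags.motif_right[idx[keep]])
    if pos_l:
        return EndEvents(
            chrom_codes=np.concatenate(codes_l),
            chrom_names=frags.chrom_names,
            pos=np.concatenate(pos_l),
            minus=np.concatenate(minus_l),
            motif=np.concatenate(motif_l),
        )
    return EndEvents(
        chrom_codes=np.empty(0, dtype=np.int16),
        chrom_names=frags.chrom_names,
        pos=np.empty(0, dtype=np.int64),
        minus=np.empty(0, dtype=bool),
        motif=np.empty((0, 3), dtype=np.uint8),
    )


def _ratio(num: float, den: float, what: str) -> float:
    if den > 0:
        return num / den
    warnings.warn(f"zero denominator for {what}; using pseudo-count 1")
    return num / 1.0


def fragma_alu_ratios(events: EndEvents) -> dict[str, float]:
    """The 9 Alu-wide features: 4 CGN + 4 NCG motif frequencies over all
    events, and the CGN/NCG count ratio."""
    total = len(events)
    if total == 0:
        warnings.warn("no Alu end events; Alu-wide ratios all 0")
        return {name: 0.0 for name in ALU_FEATURE_NAMES}
    m = events.motif
    out: dict[str, float] = {}
    cgn_total = 0
    ncg_total = 0
    for n_code, base in enumerate(_BASE):
        cnt = int(((m[:, 0] == _C) & (m[:, 1] == _G) & (m[:, 2] == n_code)).sum())
        out[f"r_CG{base}"] = cnt / total
        cgn_total += cnt
    for n_code, base in enumerate(_BASE):
        cnt = int(((m[:, 0] == n_code) & (m[:, 1] == _C) & (m[:, 2] == _G)).sum())
        out[f"r_{base}CG"] = cnt / total
        ncg_total += cnt
    out["r_CGN_over_NCG"] = _ratio(cgn_total, ncg_total, "r_CGN_over_NCG")
    return out


def _cgcg_registers(reference: ReferenceGenome, chrom: str, regions: np.ndarray):
    """Map (pos, strand) -> register counter index for every CGCG
    occurrence inside the region rows of one chromosome.

    Returns two (positions, counter) pairs, one per strand, sorted by
    position. Overlapping occurrences (CGCGCG...) are resolved
    first-come: a position already claimed by a left-er occurrence keeps
    its register.
    """
    arr = reference.codes(chrom)
    if len(arr) < 4:
        return (np.empty(0, np.int64), np.empty(0, np.int64)), (np.empty(0, np.int64), np.empty(0, np.int64))
    is_cgcg = (arr[:-3] == _C) & (arr[1:-2] == _G) & (arr[2:-1] == _C) & (arr[3:] == _G)
    cand = np.flatnonzero(is_cgcg)
    if len(cand) and len(regions):
        idx = np.searchsorted(regions[:, 0], cand, side="right") - 1
        ok = idx >= 0
        ok[ok] &= cand[ok] + 4 <= regions[idx[ok], 1]
        cand = cand[ok]
    else:
        cand = cand[:0]
    plus: dict[int, int] = {}
    minus: dict[int, int] = {}
    L = len(arr)
    for p in cand:
        p = int(p)
        up = int(arr[p - 1]) if p >= 1 else N_CODE  # base before the CGCG
        dn = int(arr[p + 4]) if p + 4 < L else N_CODE  # base after it
        # forward-strand registers
        if up < N_CODE:
            plus.setdefault(p - 1, _REG_NCG[up])
        plus.setdefault(p, _REG_CGC)
        plus.setdefault(p + 1, _REG_GCG)
        if dn < N_CODE:
            plus.setdefault(p + 2, _REG_CGN[dn])
        # reverse-strand registers (CGCG is palindromic; mirror mapping)
        if dn < N_CODE:
            minus.setdefault(p + 4, _REG_NCG[_COMP[dn]])
        minus.setdefault(p + 3, _REG_CGC)
        minus.setdefault(p + 2, _REG_GCG)
        if up < N_CODE:
            minus.setdefault(p + 1, _REG_CGN[_COMP[up]])

    def _sorted(d: dict[int, int]):
        if not d:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        pos = np.fromiter(d.keys(), dtype=np.int64)
        reg = np.fromiter(d.values(), dtype=np.int64)
        order = np.argsort(pos)
        return pos[order], reg[order]

    return _sorted(plus), _sorted(minus)


def fragma_cgcg_ratios(
    events: EndEvents, regions: RegionSet, reference: ReferenceGenome
) -> dict[str, float]:
    """The 12 CGCG-context features (see module docstring)."""
    by_chrom = regions.per_chrom()
    counts = np.zeros(10, dtype=np.int64)
    any_occurrence = False
    for code, chrom in enumerate(events.chrom_names):
        ivals = by_chrom.get(chrom)
        if ivals is None or chrom not in reference:
            continue
        (pp, pr), (mp, mr) = _cgcg_registers(reference, chrom, ivals)
        if len(pp) or len(mp):
            any_occurrence = True
        mask = events.chrom_codes == code
        if not mask.any():
            continue
        for strand_minus, (rpos, rreg) in ((False, (pp, pr)), (True, (mp, mr))):
            if len(rpos) == 0:
                continue
            sel = mask & (events.minus == strand_minus)
            p = events.pos[sel]
            j = np.searchsorted(rpos, p)
            hit = (j < len(rpos)) & (rpos[np.minimum(j, len(rpos) - 1)] == p)
            if hit.any():
                counts += np.bincount(rreg[j[hit]], minlength=10)
    if not any_occurrence:
        warnings.warn("no CGCG occurrences inside the region set; CGCG features all 0")
        return {name: 0.0 for name in CGCG_FEATURE_NAMES}
    total = int(counts.sum())
    out: dict[str, float] = {}
    if total == 0:
        warnings.warn("no end events at CGCG registers; CGCG ratios all 0")
        for i, name in enumerate(CGCG_FEATURE_NAMES[:10]):
            out[name] = 0.0
    else:
        for i, name in enumerate(CGCG_FEATURE_NAMES[:10]):
            out[name] = counts[i] / total
    ncg_sum = int(counts[0:4].sum())
    cgc = int(counts[_REG_CGC])
    cgn_sum = int(counts[6:10].sum())
    out["c_CGC_over_NCG"] = _ratio(cgc, ncg_sum, "c_CGC_over_NCG") if total else 0.0
    out["c_CGN_over_CGC"] = _ratio(cgn_sum, cgc, "c_CGN_over_CGC") if total else 0.0
    return out


@dataclass(frozen=True)
class FragmaFeatures:
    """The 21 named FRAGMA features in canonical order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (21,):
            raise ValueError("FRAGMA feature vector must have exactly 21 entries")

    @property
    def names(self) -> tuple[str, ...]:
        return FRAGMA_FEATURE_NAMES

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FRAGMA_FEATURE_NAMES, map(float, self.values)))

    def __getitem__(self, name: str) -> float:
        return float(self.values[FRAGMA_FEATURE_NAMES.index(name)])


def fragma_features(
    frags: SampleFragments,
    regions: RegionSet,
    reference: ReferenceGenome,
    ends: str = "both",
) -> FragmaFeatures:
    """All 21 FRAGMA features for one sample."""
    events = collect_end_events(frags, regions, ends=ends)
    feats = fragma_alu_ratios(events)
    feats.update(fragma_cgcg_ratios(events, regions, reference))
    return FragmaFeatures(np.array([feats[n] for n in FRAGMA_FEATURE_NAMES], dtype=float))
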