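"""Synthetic cfDNA cohorts: toy genomes plus healthy/cancer fragment
populations with a tumor-fraction dial.

The generator emulates the three signal axes the extractors read out:

* fragment size — healthy fragments follow a truncated normal mixture
  (mononucleosomal mode 167 bp, minor dinucleosomal mode 320 bp at weight
  0.05); tumor-derived fragments are shorter (mode 145 bp);
* copy number — tumor-derived fragment origins are weighted by planted
  segment dosage (copy numbers 0/1/3/4 against the diploid 2), diluted by
  tumor fraction tf, so a CN=3 segment carries density 1 + tf/2;
* end motifs — a fraction of fragment left ends snaps to the nearest CpG
  cytosine inside Alu-like regions (baseline cleavage rate for all
  fragments, multiplied by ``motif_effect`` for tumor-derived ones),
  which elevates CGN end motifs the way methylated CpG cleavage does.

A cancer sample at tf = 0 is distributionally identical to a healthy
sample by construction. Everything is reproducible from the config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import ReferenceGenome, SampleFragments, from_arrays
from .manifests import ArmTable, BinManifest, ChromTable, RegionSet, build_bin_manifest

__all__ = [
    "GenomeConfig",
    "HealthyModel",
    "TumorModel",
    "SimulationConfig",
    "ToyGenome",
    "CohortSample",
    "Cohort",
    "build_toy_genome",
    "simulate_sample",
    "simulate_cohort",
]

_LENGTH_MIN, _LENGTH_MAX = 60, 500


@dataclass(frozen=True)
class GenomeConfig:
    n_chroms: int = 4
    chrom_length: int = 3_000_000
    gc_low: float = 0.38          # smooth GC field bounds
    gc_high: float = 0.52
    alu_density_per_mb: int = 30  # planted Alu-like repeats per Mb
    alu_length: int = 300
    cgcg_enrichment: float = 5.0  # CGCG planting multiplier inside Alu


@dataclass(frozen=True)
class HealthyModel:
    size_mode: float = 167.0
    size_sd: float = 10.0
    minor_mode: float = 320.0
    minor_sd: float = 30.0
    minor_weight: float = 0.05
    baseline_cleavage: float = 0.02  # P(left end snaps to a CpG in Alu)

    @property
    def mean_length(self) -> float:
        return (1 - self.minor_weight) * self.size_mode + self.minor_weight * self.minor_mode


@dataclass(frozen=True)
class TumorModel:
    size_mode: float = 145.0
    size_sd: float = 12.0
    # (chrom, start, end, copy_number) with copy_number in {0, 1, 3, 4}
    cnv_segments: tuple = (
        ("toy1", 500_000, 2_500_000, 3),
        ("toy2", 200_000, 1_700_000, 1),
        ("toy4", 1_000_000, 2_800_000, 4),
    )
    motif_effect: float = 4.0  # multiplier on baseline_cleavage for tumor fragments


@dataclass(frozen=True)
class SimulationConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    healthy: HealthyModel = field(default_factory=HealthyModel)
    tumor: TumorModel = field(default_factory=TumorModel)
    depth: float = 5.0  # target mean coverage
    seed: int = 0

    def __post_init__(self) -> None:
        for seg in self.tumor.cnv_segments:
            if seg[3] not in (0, 1, 3, 4):
                raise ValueError(f"copy_number must be in {{0,1,3,4}}, got {seg[3]}")


@dataclass
class ToyGenome:
    """A realized toy genome plus all coordinate manifests."""

    reference: ReferenceGenome
    sequences: dict  # chrom -> str (kept for FASTA export)
    chroms: ChromTable
    arms: ArmTable
    bins: BinManifest
    alu: RegionSet

    @property
    def total_length(self) -> int:
        return self.chroms.total_length

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for name in self.chroms.names:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(out / "chroms.tsv", "w") as fh:
            for name, length in zip(self.chroms.names, self.chroms.lengths):
                fh.write(f"{name}\t{length}\n")
        self.arms.arms.to_csv(out / "arms.tsv", sep="\t", index=False)
        self.bins.to_tsv(out / "bins.tsv")
        self.alu.intervals.to_csv(out / "alu.bed", sep="\t", header=False, index=False)


def build_toy_genome(cfg: SimulationConfig) -> ToyGenome:
    """Realize a toy genome: smooth GC field, planted Alu-like repeats with
    enriched CGCG content, arms split at chromosome midpoints, 1-Mb bins."""
    g = cfg.genome
    if g.chrom_length < 2_000_000:
        raise ValueError("chrom_length must be >= 2 Mb (arms degenerate below that)")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11]))
    names = tuple(f"toy{i + 1}" for i in range(g.n_chroms))
    window = 10_000
    sequences: dict[str, str] = {}
    alu_rows = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for name in names:
        n_win = math.ceil(g.chrom_length / window)
        # smooth GC field: clipped random walk over windows
        steps = rng.normal(0.0, 0.01, n_win).cumsum()
        gc = np.clip((g.gc_low + g.gc_high) / 2 + steps, g.gc_low, g.gc_high)
        gc_per_base = np.repeat(gc, window)[: g.chrom_length]
        u = rng.random(g.chrom_length)
        is_gc = u < gc_per_base
        pick = rng.integers(0, 2, g.chrom_length, dtype=np.uint8)
        codes = np.where(is_gc, 1 + pick, 3 * pick).astype(np.uint8)  # C/G vs A/T
        seq = bases[codes]
        # plant Alu-like repeats with CGCG enrichment
        n_alu = int(g.alu_density_per_mb * g.chrom_length / 1_000_000)
        starts = np.sort(rng.integers(0, g.chrom_length - g.alu_length, n_alu))
        n_cgcg = max(1, int(round(g.alu_length / 150 * g.cgcg_enrichment)))
        for s in starts:
            alu_rows.append((name, int(s), int(s + g.alu_length)))
            offsets = rng.choice(np.arange(0, g.alu_length - 4, 6), size=n_cgcg, replace=False)
            for off in offsets:
                seq[s + off : s + off + 4] = np.frombuffer(b"CGCG", dtype=np.uint8)
        sequences[name] = seq.tobytes().decode("ascii")
    chroms = ChromTable(names, tuple([g.chrom_length] * g.n_chroms))
    mid = g.chrom_length // 2
    arm_rows = []
    for name in names:
        arm_rows.append((f"{name}p", name, 0, mid, False))
        arm_rows.append((f"{name}q", name, mid, g.chrom_length, False))
    arms = ArmTable(pd.DataFrame(arm_rows, columns=["arm_id", "chrom", "start", "end", "excluded"]))
    reference = ReferenceGenome(sequences)
    bins = build_bin_manifest(chroms, gc_source=sequences, mappability=1.0)
    from .manifests import _merge_intervals

    alu = RegionSet(_merge_intervals(pd.DataFrame(alu_rows, columns=["chrom", "start", "end"])))
    return ToyGenome(
        reference=reference, sequences=sequences, chroms=chroms, arms=arms, bins=bins, alu=alu
    )


def _segment_table(genome: ToyGenome, segments) -> tuple[np.ndarray, ...]:
    """Split the genome at planted-segment boundaries; returns parallel
    arrays (chrom_code, start, end, copy_number) covering every base."""
    rows = []
    seg_by_chrom: dict[str, list] = {}
    for chrom, s, e, cn in segments:
        seg_by_chrom.setdefault(chrom, []).append((s, e, cn))
    for code, name in enumerate(genome.chroms.names):
        L = genome.chroms.lengths[code]
        cuts = {0, L}
        for s, e, _ in seg_by_chrom.get(name, ()):
            cuts.update((s, e))
        edges = sorted(cuts)
        for a, b in zip(edges[:-1], edges[1:]):
            cn = 2
            for s, e, c in seg_by_chrom.get(name, ()):
                if s <= a and b <= e:
                    cn = c
                    break
            rows.append((code, a, b, cn))
    arr = np.array(rows, dtype=np.int64)
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


def _cg_positions_in_alu(genome: ToyGenome) -> dict[str, np.ndarray]:
    """Positions of CpG cytosines inside Alu intervals, per chromosome."""
    out = {}
    by_chrom = genome.alu.per_chrom()
    for name in genome.chroms.names:
        arr = genome.reference.codes(name)
        cg = np.flatnonzero((arr[:-1] == 1) & (arr[1:] == 2))
        ivals = by_chrom.get(name)
        if ivals is None or len(cg) == 0:
            out[name] = np.empty(0, dtype=np.int64)
            continue
        idx = np.searchsorted(ivals[:, 0], cg, side="right") - 1
        ok = idx >= 0
        ok[ok] &= cg[ok] < ivals[idx[ok], 1]
        out[name] = cg[ok]
    return out


def simulate_sample(
    genome: ToyGenome,
    cfg: SimulationConfig,
    label: str,
    tf: float,
    sample_id: str,
    seed: int | np.random.SeedSequence,
    attach_motifs: bool = True,
) -> SampleFragments:
    """One sample's fragment population.

    ``label`` is "healthy" or "cancer"; healthy samples must have tf = 0.
    Fragment count = depth x genome length / healthy mean fragment length.
    """
    if label not in ("healthy", "cancer"):
        raise ValueError(f"label must be healthy|cancer, got {label!r}")
    if label == "healthy" and tf != 0.0:
        raise ValueError("healthy samples must have tumor fraction 0")
    if not 0.0 <= tf <= 1.0:
        raise ValueError("tf must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, t = cfg.healthy, cfg.tumor
    n = int(round(cfg.depth * genome.total_length / h.mean_length))

    is_tumor = rng.random(n) < tf if label == "cancer" else np.zeros(n, dtype=bool)

    # lengths: the minor dinucleosomal mode persists in tumor cfDNA; only
    # the mononucleosomal mode shifts (167 -> 145 bp). Truncated to [60, 500].
    minor = rng.random(n) < h.minor_weight
    lengths = np.where(
        minor,
        rng.normal(h.minor_mode, h.minor_sd, n),
        rng.normal(h.size_mode, h.size_sd, n),
    )
    shift = is_tumor & ~minor
    n_s = int(shift.sum())
    if n_s:
        lengths[shift] = rng.normal(t.size_mode, t.size_sd, n_s)
    n_t = int(is_tumor.sum())
    lengths = np.clip(np.round(lengths), _LENGTH_MIN, _LENGTH_MAX).astype(np.int64)

    # origins: healthy uniform; tumor weighted by copy dosage
    chrom_lengths = np.asarray(genome.chroms.lengths, dtype=np.int64)
    codes = np.empty(n, dtype=np.int16)
    start = np.empty(n, dtype=np.int64)
    nh = n - n_t
    if nh:
        p = chrom_lengths / chrom_lengths.sum()
        codes[~is_tumor] = rng.choice(len(chrom_lengths), nh, p=p).astype(np.int16)
        start[~is_tumor] = (rng.random(nh) * chrom_lengths[codes[~is_tumor]]).astype(np.int64)
    if n_t:
        sc, ss, se, scn = _segment_table(genome, t.cnv_segments)
        w = (se - ss).astype(float) * scn
        seg = rng.choice(len(w), n_t, p=w / w.sum())
        codes[is_tumor] = sc[seg].astype(np.int16)
        start[is_tumor] = ss[seg] + (rng.random(n_t) * (se[seg] - ss[seg])).astype(np.int64)

    # CpG end snapping inside Alu regions
    p_snap = np.full(n, h.baseline_cleavage)
    if n_t:
        p_snap[is_tumor] = min(1.0, h.baseline_cleavage * t.motif_effect)
    snap = rng.random(n) < p_snap
    cg = _cg_positions_in_alu(genome)
    max_shift = 25
    for code, name in enumerate(genome.chroms.names):
        pos_arr = cg[name]
        if len(pos_arr) == 0:
            continue
        sel = np.flatnonzero(snap & (codes == code))
        if len(sel) == 0:
            continue
        s = start[sel]
        j = np.clip(np.searchsorted(pos_arr, s), 0, len(pos_arr) - 1)
        jl = np.maximum(j - 1, 0)
        nearer_left = np.abs(pos_arr[jl] - s) < np.abs(pos_arr[j] - s)
        best = np.where(nearer_left, pos_arr[jl], pos_arr[j])
        ok = np.abs(best - s) <= max_shift
        start[sel[ok]] = best[ok]

    start = np.clip(start, 0, chrom_lengths[codes] - lengths)
    end = start + lengths
    frags = from_arrays(
        sample_id,
        genome.chroms.names,
        codes,
        start,
        end,
        reference=genome.reference if attach_motifs else None,
        label=label,
        tf=tf,
    )
    frags.source_depth = frags.mean_coverage(genome.total_length)
    return frags


@dataclass(frozen=True)
class CohortSample:
    """Deferred sample: fragments are regenerated on demand from the seed,
    so large cohorts never sit in memory at once."""

    sample_id: str
    label: str  # healthy | cancer
    split: str  # train | validation
    tf: float
    seed_entropy: tuple  # SeedSequence entropy, JSON-serializable

    def simulate(self, genome: ToyGenome, cfg: SimulationConfig) -> SampleFragments:
        ss = np.random.SeedSequence(list(self.seed_entropy))
        return simulate_sample(genome, cfg, self.label, self.tf, self.sample_id, ss)


@dataclass
class Cohort:
    cfg: SimulationConfig
    samples: list
    tf_range: tuple

    @property
    def sheet(self) -> pd.DataFrame:
        cancer_tfs = sorted(s.tf for s in self.samples if s.label == "cancer")
        def stage(tf: float) -> str:
            if not cancer_tfs or tf == 0:
                return "NA"
            q1, q2 = np.quantile(cancer_tfs, [1 / 3, 2 / 3])
            return "I" if tf <= q1 else ("II" if tf <= q2 else "III")
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "label": s.label,
                    "split": s.split,
                    "tf": s.tf,
                    "stage": stage(s.tf) if s.label == "cancer" else "NA",
                }
                for s in self.samples
            ]
        )

    def truth(self) -> dict:
        return {
            "seed": self.cfg.seed,
            "tf_range": list(self.tf_range),
            "cnv_segments": [list(s) for s in self.cfg.tumor.cnv_segments],
            "motif_effect": self.cfg.tumor.motif_effect,
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "label": s.label,
                    "split": s.split,
                    "tf": s.tf,
                    "seed_entropy": list(s.seed_entropy),
                }
                for s in self.samples
            ],
        }

    def write(self, genome: ToyGenome, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genome.write(out / "genome")
        frag_dir = out / "fragments"
        frag_dir.mkdir(exist_ok=True)
        for s in self.samples:
            s.simulate(genome, self.cfg).to_bed(frag_dir / f"{s.sample_id}.bed")
        self.sheet.to_csv(out / "cohort_sheet.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth(), fh, indent=1)


def simulate_cohort(
    cfg: SimulationConfig,
    n_train: tuple[int, int] = (119, 112),
    n_validation: tuple[int, int] = (85, 79),
    tf_range: tuple[float, float] = (0.05, 0.3),
    seed: int | None = None,
) -> Cohort:
    """Lay out a two-split cohort (default shape 119+112 training, 85+79
    validation) with per-cancer-sample tumor fractions drawn uniformly
    from ``tf_range``. Fragment generation is deferred per sample.

    ``seed`` overrides the config seed for cohort layout and fragment
    sampling, so several cohorts can share one realized genome.
    """
    for n_c, n_h in (n_train, n_validation):
        if n_c < 2 or n_h < 2:
            raise ValueError("need >= 2 samples per class and split")
    eff_seed = cfg.seed if seed is None else int(seed)
    root = np.random.SeedSequence(eff_seed)
    tf_rng = np.random.default_rng(root.spawn(1)[0])
    samples: list[CohortSample] = []
    idx = 0
    for split, (n_c, n_h) in (("train", n_train), ("validation", n_validation)):
        for label, count in (("cancer", n_c), ("healthy", n_h)):
            for _ in range(count):
                tf = float(tf_rng.uniform(*tf_range)) if label == "cancer" else 0.0
                samples.append(
                    CohortSample(
                        sample_id=f"{split[:1]}{label[:1]}{idx:04d}",
                        label=label,
                        split=split,
                        tf=tf,
                        seed_entropy=(eff_seed, 0x5A17, idx),
                    )
                )
                idx += 1
    return Cohort(cfg=cfg, samples=samples, tf_range=tuple(tf_range))
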