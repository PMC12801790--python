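"""Cohort-level orchestration: extract the three feature families for
every sample, fit the training-only normalizers (panel of normals for
CNV, z-score statistics for FSD), assemble the feature matrix, train the
stacked ensemble and score the validation split.

Samples are processed one at a time and reduced to their small summaries
(bin counts, corrected size histogram, 21 motif ratios), so cohorts never
hold raw fragments in memory simultaneously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cnv, fragma, fsd
from .ensemble import FeatureMatrix, TrainedEnsemble, train_ensemble
from .fragments import ReferenceGenome, SampleFragments
from .manifests import ArmTable, BinManifest, RegionSet
from .simulate import Cohort, SimulationConfig, ToyGenome

__all__ = ["SampleSummary", "ModelBundle", "summarize_sample", "build_feature_matrix", "run_training"]


@dataclass
class SampleSummary:
    """The per-sample reductions all three extractors produce."""

    sample_id: str
    label: str
    split: str
    bin_counts: cnv.BinCounts
    fsd_corrected: np.ndarray  # (arms, bins), GC-corrected counts
    fragma_values: np.ndarray  # 21


def summarize_sample(
    frags: SampleFragments,
    bins: BinManifest,
    arms: ArmTable,
    alu: RegionSet,
    reference: ReferenceGenome,
    arm_gc: np.ndarray,
    label: str,
    split: str,
    scheme: fsd.SizeBinScheme = fsd.SizeBinScheme(),
) -> SampleSummary:
    counts = cnv.count_fragments_per_bin(frags, bins)
    raw = fsd.fsd_raw(frags, arms, scheme)
    corrected = fsd.fsd_gc_correct(raw, arm_gc)
    fm = fragma.fragma_features(frags, alu, reference)
    return SampleSummary(
        sample_id=frags.sample_id,
        label=label,
        split=split,
        bin_counts=counts,
        fsd_corrected=corrected,
        fragma_values=fm.values,
    )


def build_feature_matrix(
    summaries: list,
    bins: BinManifest,
    scheme: fsd.SizeBinScheme = fsd.SizeBinScheme(),
    arm_ids: tuple = (),
    normalization: str = "train_only",
) -> tuple[FeatureMatrix, cnv.PanelOfNormals, fsd.FsdNormalizer]:
    """Assemble cnv/fsd/fragma blocks.

    The panel of normals comes from healthy *training* samples. FSD
    z-score statistics come from the training split only by default
    (``normalization="train_only"``), so validation samples touch no
    fitted parameter; ``"all"`` pools both splits for exact replication
    of cohort-wide standardization at the cost of leakage.
    """
    if normalization not in ("train_only", "all"):
        raise ValueError("normalization must be 'train_only' or 'all'")
    train_healthy = [s.bin_counts for s in summaries if s.split == "train" and s.label == "healthy"]
    pon = cnv.build_pon(train_healthy, bins)
    if normalization == "train_only":
        train_fsd = [s.fsd_corrected for s in summaries if s.split == "train"]
    else:
        train_fsd = [s.fsd_corrected for s in summaries]
    normalizer = fsd.fit_fsd_normalizer(train_fsd)
    cnv_block = np.stack(
        [cnv.cnv_profile(s.bin_counts, pon, bins).log2_ratios for s in summaries]
    )
    fsd_block = np.stack([fsd.fsd_features(s.fsd_corrected, normalizer) for s in summaries])
    fragma_block = np.stack([s.fragma_values for s in summaries])
    kept = bins.kept
    fm = FeatureMatrix(
        sample_ids=[s.sample_id for s in summaries],
        labels=np.array([s.label == "cancer" for s in summaries]),
        split=np.array([s.split for s in summaries]),
        blocks={"cnv": cnv_block, "fsd": fsd_block, "fragma": fragma_block},
        feature_names={
            "cnv": [f"{r.chrom}_{r.start}" for r in kept.itertuples(index=False)],
            "fsd": scheme.labels(arm_ids) if arm_ids else [],
            "fragma": list(fragma.FRAGMA_FEATURE_NAMES),
        },
    )
    return fm, pon, normalizer


@dataclass
class ModelBundle:
    """Everything needed to score new samples: normalizers + ensemble."""

    ensemble: TrainedEnsemble
    pon: cnv.PanelOfNormals
    fsd_normalizer: fsd.FsdNormalizer
    feature_matrix: FeatureMatrix  # the cohort matrix used for training/validation


def summarize_cohort(cohort: Cohort, genome: ToyGenome) -> list:
    arm_gc = fsd.arm_gc_from_reference(genome.arms, genome.reference)
    summaries = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small toy manifests trip the LOESS guards
        for s in cohort.samples:
            frags = s.simulate(genome, cohort.cfg)
            summaries.append(
                summarize_sample(
                    frags, genome.bins, genome.arms, genome.alu, genome.reference,
                    arm_gc, s.label, s.split,
                )
            )
            del frags
    return summaries


def run_training(
    cohort: Cohort,
    genome: ToyGenome,
    k: int = 5,
    seed: int = 0,
    combination: str = "mean",
    grid_budget: int = 1,
) -> tuple[ModelBundle, pd.DataFrame]:
    """Simulate/extract every sample, train on the training split, score
    the validation split. Returns (bundle, validation ScoreTable)."""
    summaries = summarize_cohort(cohort, genome)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="fewer than")  # toy-scale LOESS guards
        fm, pon, normalizer = build_feature_matrix(
            summaries, genome.bins, arm_ids=tuple(genome.arms.included["arm_id"])
        )
    ens = train_ensemble(fm.training(), k=k, seed=seed, combination=combination,
                         grid_budget=grid_budget)
    bundle = ModelBundle(ensemble=ens, pon=pon, fsd_normalizer=normalizer, feature_matrix=fm)
    score_table = ens.predict(fm.validation())
    return bundle, score_table


@dataclass
class CohortDir:
    """A cohort directory on disk (as written by the simulator): genome
    FASTA + manifests + per-sample fragment BEDs + cohort sheet."""

    reference: ReferenceGenome
    chroms: "object"
    arms: ArmTable
    bins: BinManifest
    alu: RegionSet
    sheet: pd.DataFrame
    fragments_dir: "object"


def load_cohort_dir(path) -> CohortDir:
    from pathlib import Path

    from .manifests import load_arm_table, load_chrom_table, load_region_set

    p = Path(path)
    gdir = p / "genome"
    return CohortDir(
        reference=ReferenceGenome(gdir / "genome.fa"),
        chroms=load_chrom_table(gdir / "chroms.tsv"),
        arms=load_arm_table(gdir / "arms.tsv"),
        bins=BinManifest(pd.read_csv(gdir / "bins.tsv", sep="\t")),
        alu=load_region_set(gdir / "alu.bed"),
        sheet=pd.read_csv(p / "cohort_sheet.tsv", sep="\t"),
        fragments_dir=p / "fragments",
    )


def train_from_cohort_dir(path, k: int = 5, seed: int = 0, combination: str = "mean",
                          grid_budget: int = 1) -> tuple[ModelBundle, pd.DataFrame, CohortDir]:
    """Train from on-disk fragment BEDs + cohort sheet; returns the model
    bundle, validation score table, and the loaded cohort directory."""
    from .fragments import read_fragments_bed

    cd = load_cohort_dir(path)
    arm_gc = fsd.arm_gc_from_reference(cd.arms, cd.reference)
    summaries = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for row in cd.sheet.itertuples(index=False):
            frags = read_fragments_bed(
                cd.fragments_dir / f"{row.sample_id}.bed", cd.reference, sample_id=row.sample_id
            )
            summaries.append(
                summarize_sample(frags, cd.bins, cd.arms, cd.alu, cd.reference,
                                 arm_gc, row.label, row.split)
            )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="fewer than")
        fm, pon, normalizer = build_feature_matrix(
            summaries, cd.bins, arm_ids=tuple(cd.arms.included["arm_id"])
        )
    ens = train_ensemble(fm.training(), k=k, seed=seed, combination=combination,
                         grid_budget=grid_budget)
    bundle = ModelBundle(ensemble=ens, pon=pon, fsd_normalizer=normalizer, feature_matrix=fm)
    return bundle, ens.predict(fm.validation()), cd


def score_samples(
    bundle: ModelBundle,
    sample_frags: list,
    bins: BinManifest,
    arms: ArmTable,
    alu: RegionSet,
    reference: ReferenceGenome,
) -> pd.DataFrame:
    """Score new samples with a trained bundle: bundled panel of normals
    and FSD normalizer are applied, never refit."""
    arm_gc = fsd.arm_gc_from_reference(arms, reference)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for frags in sample_frags:
            s = summarize_sample(frags, bins, arms, alu, reference, arm_gc,
                                 label="unknown", split="predict")
            rows.append(s)
    fm = FeatureMatrix(
        sample_ids=[s.sample_id for s in rows],
        labels=np.zeros(len(rows), dtype=bool),
        split=np.array(["predict"] * len(rows)),
        blocks={
            "cnv": np.stack(
                [cnv.cnv_profile(s.bin_counts, bundle.pon, bins).log2_ratios for s in rows]
            ),
            "fsd": np.stack(
                [fsd.fsd_features(s.fsd_corrected, bundle.fsd_normalizer) for s in rows]
            ),
            "fragma": np.stack([s.fragma_values for s in rows]),
        },
    )
    st = bundle.ensemble.predict(fm)
    return st.drop(columns=["true_label"])
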