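"""Fragment-level I/O: read cfDNA fragments from BAM or BED, attach 5'
end motifs from the reference, filter, and down-sample.

A sequenced cfDNA fragment is the template between the two 5' ends of a
read pair. Both termini carry a 5' end motif: the left end read on the
forward strand (reference bases at [start, start+3)) and the right end on
the reverse strand (reverse complement of the bases at [end-3, end)), each
reported 5'->3' on its own strand.

Fragments are stored columnar (numpy arrays) for speed; `records()` yields
:class:`FragmentRecord` views for record-level inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "FragmentRecord",
    "SampleFragments",
    "ReferenceGenome",
    "FragmentError",
    "read_fragments_bed",
    "read_fragments_bam",
    "subsample_fragments",
]

# base encoding shared across the package: A C G T N -> 0..4
BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
N_CODE = 4


class FragmentError(ValueError):
    """Malformed fragment input."""


def encode_seq(seq: str) -> np.ndarray:
    """ASCII sequence -> uint8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_codes(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][..., ::-1]


class ReferenceGenome:
    """Uniform access to a reference: FASTA path, pyfaidx handle, or a
    plain ``{chrom: sequence}`` mapping. Per-chromosome code arrays are
    cached, so repeated motif lookups are O(1) gathers."""

    def __init__(self, source):
        if isinstance(source, (str, Path)):
            import pyfaidx

            self._fa = pyfaidx.Fasta(str(source), as_raw=True)
            self._seqs = None
        elif isinstance(source, Mapping):
            self._fa = None
            self._seqs = dict(source)
        else:  # assume pyfaidx.Fasta-like
            self._fa = source
            self._seqs = None
        self._codes: dict[str, np.ndarray] = {}

    def keys(self):
        return list(self._seqs) if self._seqs is not None else list(self._fa.keys())

    def __contains__(self, chrom: str) -> bool:
        return chrom in (self._seqs if self._seqs is not None else self._fa)

    def length(self, chrom: str) -> int:
        return len(self.codes(chrom))

    def seq(self, chrom: str, start: int, end: int) -> str:
        return decode_codes(self.codes(chrom)[start:end])

    def codes(self, chrom: str) -> np.ndarray:
        if chrom not in self._codes:
            raw = self._seqs[chrom] if self._seqs is not None else str(self._fa[chrom][:])
            self._codes[chrom] = encode_seq(raw)
        return self._codes[chrom]


@dataclass(frozen=True)
class FragmentRecord:
    """One cfDNA fragment with strand-oriented 5' end motifs."""

    chrom: str
    start: int
    end: int
    motif_left: str
    motif_right: str
    mapq: int = 60

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SampleFragments:
    """All fragments of one sample, columnar.

    ``chrom_names``/``chrom_codes`` give each fragment's chromosome;
    motif arrays are (n, 3) uint8 base codes (4 = N / unavailable).
    """

    sample_id: str
    chrom_names: tuple[str, ...]
    chrom_codes: np.ndarray  # int16
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    motif_left: np.ndarray | None = None  # (n, 3) uint8
    motif_right: np.ndarray | None = None
    mapq: np.ndarray | None = None
    source_depth: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.start)

    @property
    def length(self) -> np.ndarray:
        return self.end - self.start

    def mean_coverage(self, genome_length: int) -> float:
        return float(self.length.sum()) / genome_length

    def records(self) -> Iterator[FragmentRecord]:
        mq = self.mapq if self.mapq is not None else np.full(len(self), 60)
        for i in range(len(self)):
            yield FragmentRecord(
                chrom=self.chrom_names[self.chrom_codes[i]],
                start=int(self.start[i]),
                end=int(self.end[i]),
                motif_left=decode_codes(self.motif_left[i]) if self.motif_left is not None else "NNN",
                motif_right=decode_codes(self.motif_right[i]) if self.motif_right is not None else "NNN",
                mapq=int(mq[i]),
            )

    def take(self, index: np.ndarray, sample_id: str | None = None) -> "SampleFragments":
        return SampleFragments(
            sample_id=sample_id or self.sample_id,
            chrom_names=self.chrom_names,
            chrom_codes=self.chrom_codes[index],
            start=self.start[index],
            end=self.end[index],
            motif_left=None if self.motif_left is None else self.motif_left[index],
            motif_right=None if self.motif_right is None else self.motif_right[index],
            mapq=None if self.mapq is None else self.mapq[index],
            source_depth=self.source_depth,
            metadata=dict(self.metadata),
        )

    def to_bed(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "chrom": np.asarray(self.chrom_names)[self.chrom_codes],
                "start": self.start,
                "end": self.end,
            }
        ).to_csv(path, sep="\t", header=False, index=False)


def attach_motifs(frags: SampleFragments, reference: ReferenceGenome) -> SampleFragments:
    """Fill motif_left / motif_right from the reference, in place.

    Ends whose 3-base window falls off the chromosome get all-N motifs.
    """
    n = len(frags)
    left = np.full((n, 3), N_CODE, dtype=np.uint8)
    right = np.full((n, 3), N_CODE, dtype=np.uint8)
    offs = np.arange(3)
    for code, chrom in enumerate(frags.chrom_names):
        mask = frags.chrom_codes == code
        if not mask.any():
            continue
        arr = reference.codes(chrom)
        L = len(arr)
        s = frags.start[mask]
        e = frags.end[mask]
        ok_l = (s >= 0) & (s + 3 <= L)
        ok_r = (e - 3 >= 0) & (e <= L)
        idx = np.flatnonzero(mask)
        if ok_l.any():
            left[idx[ok_l]] = arr[s[ok_l, None] + offs]
        if ok_r.any():
            right[idx[ok_r]] = revcomp_codes(arr[e[ok_r, None] - 3 + offs])
    frags.motif_left = left
    frags.motif_right = right
    return frags


def from_arrays(
    sample_id: str,
    chrom_names,
    chrom_codes,
    start,
    end,
    reference: ReferenceGenome | None = None,
    **meta,
) -> SampleFragments:
    """Assemble a SampleFragments from raw arrays (simulator entry point)."""
    frags = SampleFragments(
        sample_id=sample_id,
        chrom_names=tuple(chrom_names),
        chrom_codes=np.asarray(chrom_codes, dtype=np.int16),
        start=np.asarray(start, dtype=np.int64),
        end=np.asarray(end, dtype=np.int64),
        metadata=meta,
    )
    if (frags.end - frags.start < 1).any():
        raise FragmentError("fragment length must be >= 1")
    if reference is not None:
        attach_motifs(frags, reference)
    return frags


def read_fragments_bed(
    path: str | Path,
    reference: ReferenceGenome | str | Path | Mapping,
    sample_id: str | None = None,
) -> SampleFragments:
    """Read a BED3(+) fragment file and attach end motifs.

    Behaves identically to the BAM path downstream: same coordinate
    convention (0-based half-open), same motif lookup.
    """
    if not isinstance(reference, ReferenceGenome):
        reference = ReferenceGenome(reference)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FragmentError(f"{path}:{lineno}: BED needs >= 3 columns")
        chrom = parts[0]
        try:
            s, e = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FragmentError(f"{path}:{lineno}: non-integer coordinates") from exc
        if s >= e:
            raise FragmentError(f"{path}:{lineno}: start >= end")
        if chrom not in reference:
            raise FragmentError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if e > reference.length(chrom):
            raise FragmentError(f"{path}:{lineno}: interval beyond chromosome end")
        chroms.append(chrom)
        starts.append(s)
        ends.append(e)
    names = tuple(reference.keys())
    code_of = {c: i for i, c in enumerate(names)}
    codes = np.array([code_of[c] for c in chroms], dtype=np.int16)
    sid = sample_id or Path(path).stem
    return from_arrays(sid, names, codes, starts, ends, reference=reference)


def read_fragments_bam(
    path: str | Path,
    reference: ReferenceGenome | str | Path | Mapping,
    sample_id: str | None = None,
    min_mapq: int = 30,
    max_template_length: int = 1000,
) -> SampleFragments:
    """Extract fragments from a coordinate-sorted, indexed, paired-end BAM.

    One fragment per properly-paired, primary, non-duplicate pair: the
    interval [leftmost start, leftmost start + template length). Pairs
    failing filters, or with template length <= 0 or > the maximum, are
    skipped and counted in ``metadata['skipped']``.
    """
    import pysam

    if not isinstance(reference, ReferenceGenome):
        reference = ReferenceGenome(reference)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    mapqs: list[int] = []
    skipped = {"flags": 0, "mapq": 0, "tlen": 0}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        if not bam.has_index():
            raise OSError(f"{path}: missing BAM index")
        for read in bam.fetch():
            # count each pair once, from its leftmost (forward) mate
            if read.is_reverse:
                continue
            if (
                not read.is_proper_pair
                or read.is_duplicate
                or read.is_secondary
                or read.is_supplementary
                or read.is_qcfail
                or read.is_unmapped
            ):
                skipped["flags"] += 1
                continue
            if read.mapping_quality < min_mapq:
                skipped["mapq"] += 1
                continue
            tlen = read.template_length
            if tlen <= 0 or tlen > max_template_length:
                skipped["tlen"] += 1
                continue
            chroms.append(read.reference_name)
            starts.append(read.reference_start)
            ends.append(read.reference_start + tlen)
            mapqs.append(read.mapping_quality)
    names = tuple(reference.keys())
    code_of = {c: i for i, c in enumerate(names)}
    codes = np.array([code_of[c] for c in chroms], dtype=np.int16)
    frags = from_arrays(
        sample_id or Path(path).stem, names, codes, starts, ends, reference=reference
    )
    frags.mapq = np.asarray(mapqs, dtype=np.int32)
    frags.metadata["skipped"] = skipped
    return frags


def subsample_fragments(
    frags: SampleFragments, target_fraction: float, seed: int
) -> SampleFragments:
    """Keep each fragment independently with probability ``target_fraction``.

    Deterministic given the seed; record order is preserved. Mirrors
    uniform depth down-sampling (5x -> 4x, 3x, 2x, 1x) as Bernoulli
    thinning of fragments.
    """
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError(f"target_fraction must be in (0, 1], got {target_fraction}")
    if target_fraction == 1.0:
        return frags.take(np.arange(len(frags)))
    rng = np.random.default_rng(seed)
    keep = rng.random(len(frags)) < target_fraction
    sub = frags.take(np.flatnonzero(keep))
    sub.metadata["subsampled_fraction"] = target_fraction
    return sub
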