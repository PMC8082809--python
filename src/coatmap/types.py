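"""Core containers shared across the pipeline.

Coordinate convention: all genomic positions are 1-based and intervals are
closed on both ends, so ``length = end - start + 1`` (e.g. the interval
63,599,803..63,600,957 spans 1155 bp).  A :class:`ReferenceSequence` carries a
genomic ``offset`` so that a short synthetic fragment can stand in for a slice
of a chromosome: base ``i`` (0-based into ``bases``) sits at genomic
coordinate ``offset + i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "ReferenceSequence",
    "Read",
    "ReadSet",
    "AlignedRead",
    "interval_length",
]


def interval_length(start: int, end: int) -> int:
    """Length in bp of the 1-based closed interval ``[start, end]``."""
    if start > end:
        raise ValueError(f"interval start {start} > end {end}")
    return end - start + 1


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for ``n`` individuals at ``m`` markers.

    Parameters
    ----------
    samples
        Sample identifiers, length ``n``.
    markers
        Marker map with columns ``chrom``, ``pos`` (1-based), ``id``,
        ``ref``, ``alt``; positions strictly increasing within chromosome.
    dosages
        ``n x m`` float array counting copies of the alternative allele
        (0/1/2); missing genotypes are ``nan``.
    haplotypes
        Optional phased calls, ``n x 2 x m`` int8 of 0/1 (-1 for missing).
        When present, ``haplotypes.sum(axis=1) == dosages`` wherever called.
    """

    samples: list[str]
    markers: pd.DataFrame
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError("sample count does not match dosage rows")
        if len(self.markers) != m:
            raise ValueError("marker map length does not match dosage columns")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (n, 2, m):
                raise ValueError("haplotype array must be n x 2 x m")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per marker."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alternative-allele frequency per marker (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def marker_index(self, marker_id: str) -> int:
        idx = self.markers.index[self.markers["id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"marker {marker_id!r} not found")
        return int(self.markers.index.get_indexer(idx)[0])

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, mask],
        )


@dataclass
class PhenotypeVector:
    """Per-individual averaged rater score on the bounded scale."""

    samples: list[str]
    scores: np.ndarray
    scale_min: float = 0.0
    scale_max: float = 3.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.samples) != len(self.scores):
            raise ValueError("sample ids and scores differ in length")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class ReferenceSequence:
    """A contiguous genome fragment anchored at a genomic offset.

    ``offset`` is the 1-based genomic coordinate of ``bases[0]``; the genomic
    coordinate of ``bases[i]`` is ``offset + i``.
    """

    name: str
    offset: int
    bases: str

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise ValueError("offset must be >= 1")
        if not self.bases:
            raise ValueError("empty reference sequence")
        invalid = set(self.bases) - set("ACGTN")
        if invalid:
            raise ValueError(f"invalid bases: {sorted(invalid)}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def start(self) -> int:
        return self.offset

    @property
    def end(self) -> int:
        """Genomic coordinate of the last base."""
        return self.offset + len(self.bases) - 1

    def to_local(self, genomic_pos: int) -> int:
        """0-based index into ``bases`` for a 1-based genomic coordinate."""
        i = genomic_pos - self.offset
        if not 0 <= i < len(self.bases):
            raise IndexError(f"genomic position {genomic_pos} outside {self.name}")
        return i

    def to_genomic(self, local_index: int) -> int:
        if not 0 <= local_index < len(self.bases):
            raise IndexError("local index out of range")
        return self.offset + local_index

    def slice_genomic(self, start: int, end: int) -> str:
        """Bases of the closed genomic interval ``[start, end]``."""
        return self.bases[self.to_local(start) : self.to_local(end) + 1]


@dataclass
class Read:
    """A simulated read with its truth origin."""

    read_id: str
    sequence: str
    quality: int  # single Phred-like proxy for the whole read
    mate: int  # 0 = unpaired, 1 = first of pair, 2 = second of pair
    origin_contig: str
    origin_start: int  # 1-based genomic position on the source sequence
    origin_strand: str  # '+' or '-'
    haplotype: str = ""  # label of the source haplotype (e.g. 'wt', 'mut')


@dataclass
class ReadSet:
    """Collection of simulated reads; paired mates share ``read_id``."""

    reads: list[Read] = field(default_factory=list)
    paired: bool = False

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def pairs(self) -> list[tuple[Read, Read]]:
        if not self.paired:
            raise ValueError("read set is not paired")
        by_id: dict[str, dict[int, Read]] = {}
        for r in self.reads:
            by_id.setdefault(r.read_id, {})[r.mate] = r
        out = []
        for rid, mates in by_id.items():
            if set(mates) != {1, 2}:
                raise ValueError(f"read {rid} lacks a mate")
            out.append((mates[1], mates[2]))
        return out


@dataclass
class AlignedRead:
    """One alignment record (primary or supplementary) in genomic coordinates.

    ``pos`` is the 1-based genomic coordinate of the leftmost aligned base;
    ``clip_left``/``clip_right`` count soft-clipped read bases on the
    reference-left / reference-right side of the alignment, and
    ``span`` aligned bases, so ``clip_left + span + clip_right`` equals the
    read length.
    """

    read_id: str
    contig: str
    pos: int
    strand: str
    clip_left: int
    clip_right: int
    span: int
    mapq: int = 60
    mate: int = 0
    supplementary: bool = False
    mate_contig: str | None = None
    mate_pos: int | None = None
    mate_strand: str | None = None
    tlen: int = 0
    mismatches: int = 0

    @property
    def read_length(self) -> int:
        return self.clip_left + self.span + self.clip_right

    @property
    def end(self) -> int:
        """Genomic coordinate of the last aligned base."""
        return self.pos + self.span - 1
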