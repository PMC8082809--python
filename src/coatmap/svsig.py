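"""Structural-variant signature engine.

This module reconstructs complex rearrangements from read alignments the way
a human analyst works through an IGV screenshot: candidate rearrangements are
applied to a reference in silico, reads are simulated from each mutant and
mapped back to the *unedited* reference, and the resulting alignment
signature — read-pair orientation classes, insert sizes, soft-clip clusters,
chimeric (supplementary) anchors and the depth profile — is compared with the
observed signature.  The candidate whose simulated signature is closest to
the observation is the best-supported hypothesis.

Orientation nomenclature (fixed; conventions vary across tools):
``RL`` = inward proper pair (leftmost mate forward, rightmost reverse);
``RR`` = both mates forward; ``LL`` = both mates reverse; ``RF`` = outward;
``cross`` = mate unaligned or on another contig.  RR and LL pairs flanking a
locus, with inserts far beyond the library insert, are the hallmark of an
inverted-duplication insertion: one mate falls inside inserted sequence whose
reverse complement lives elsewhere, so it maps to the distant source locus
with flipped strand.

Coordinates are 1-based closed intervals throughout
(``length = end - start + 1``; e.g. 63,600,957 - 63,599,803 + 1 = 1155).
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AlignedRead, ReadSet, ReferenceSequence, interval_length

__all__ = [
    "Deletion",
    "Insertion",
    "InvertedDupInsertion",
    "RearrangementEdit",
    "CoordinateMap",
    "SVSignature",
    "SVGenotypeCall",
    "ClipCluster",
    "apply_edits",
    "revcomp",
    "map_reads",
    "classify_pairs",
    "cluster_clips",
    "depth_scan",
    "signature_profile",
    "signature_distance",
    "rank_hypotheses",
    "locate_deletion_breakpoints",
    "long_read_junction_insert",
    "genotype_sv",
    "genotype_r2",
    "interval_length",
]

_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"invalid characters for revcomp: {sorted(invalid)}")
    return seq.encode().translate(_COMP).decode()[::-1]


# ---------------------------------------------------------------------------
# Rearrangement edits and coordinate bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Deletion:
    """Remove the closed genomic interval [start, end]."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("deletion start > end")


@dataclass(frozen=True)
class Insertion:
    """Insert ``sequence`` immediately before genomic position ``position``."""

    position: int
    sequence: str


@dataclass(frozen=True)
class InvertedDupInsertion:
    """Insert the reverse complement of [source_start, source_end] before
    ``target``; the source copy itself is untouched."""

    source_start: int
    source_end: int
    target: int

    def __post_init__(self) -> None:
        if self.source_start > self.source_end:
            raise ValueError("source start > end")


@dataclass
class RearrangementEdit:
    """An ordered, non-overlapping set of genome edits."""

    operations: list
    name: str = ""


@dataclass
class CoordinateMap:
    """Piecewise reference<->mutant coordinate mapping.

    ``segments`` is a list of ``(ref_start, ref_end, mut_start, kind)`` in
    genomic coordinates; ``kind`` is ``retained`` for bases present in both
    sequences, ``inserted`` / ``duplicated_inverted`` for mutant-only bases
    (``ref_start``/``ref_end`` then describe the source interval or are 0),
    and ``deleted`` for reference-only bases (``mut_start`` is 0).
    Retained bases map bijectively in both directions.
    """

    segments: list[tuple[int, int, int, str]] = field(default_factory=list)

    def ref_to_mut(self, pos: int) -> int | None:
        """Mutant coordinate of a reference base; None if deleted."""
        for rs, re_, ms, kind in self.segments:
            if kind == "retained" and rs <= pos <= re_:
                return ms + (pos - rs)
            if kind == "deleted" and rs <= pos <= re_:
                return None
        raise IndexError(f"reference position {pos} not covered by the map")

    def mut_to_ref(self, pos: int) -> int | None:
        """Reference coordinate of a mutant base; None if inserted."""
        for rs, re_, ms, kind in self.segments:
            if kind == "retained":
                if ms <= pos <= ms + (re_ - rs):
                    return rs + (pos - ms)
            elif kind in ("inserted", "duplicated_inverted"):
                if ms <= pos <= ms + re_ - 1:  # re_ stores the inserted length
                    return None
        raise IndexError(f"mutant position {pos} not covered by the map")


def apply_edits(
    ref: ReferenceSequence, edit: RearrangementEdit
) -> tuple[ReferenceSequence, CoordinateMap]:
    """Apply a rearrangement to a reference, with full coordinate bookkeeping.

    Deletions remove closed intervals; insertions (including inverted
    duplications) add sequence immediately before their target position.
    Operations must fall inside the reference and deleted intervals must not
    overlap each other.  Returns the mutant sequence (same name with a
    ``|`` -separated edit tag, offset preserved) and the
    :class:`CoordinateMap`.
    """
    L = len(ref)
    events: list[tuple[int, int, str, str]] = []  # (start, end, kind, seq)
    for op in edit.operations:
        if isinstance(op, Deletion):
            ref.to_local(op.start), ref.to_local(op.end)  # bounds check
            events.append((op.start, op.end, "deleted", ""))
        elif isinstance(op, Insertion):
            if not ref.offset <= op.position <= ref.end + 1:
                raise ValueError("insertion position outside reference")
            seq = op.sequence.upper()
            if set(seq) - set("ACGTN"):
                raise ValueError("insertion sequence has invalid characters")
            events.append((op.position, op.position - 1, "inserted", seq))
        elif isinstance(op, InvertedDupInsertion):
            src = ref.slice_genomic(op.source_start, op.source_end)
            if not ref.offset <= op.target <= ref.end + 1:
                raise ValueError("insertion target outside reference")
            events.append(
                (op.target, op.target - 1, "duplicated_inverted", revcomp(src))
            )
        else:
            raise TypeError(f"unknown edit operation: {op!r}")
    # overlap check on reference-consuming operations
    dels = sorted((s, e) for s, e, k, _ in events if k == "deleted")
    for (s1, e1), (s2, e2) in zip(dels, dels[1:]):
        if s2 <= e1:
            raise ValueError("overlapping deletions")
    # insertions sorted before the deletion starting at the same position:
    # an insertion at P lands between P-1 and P, i.e. before any deleted run
    events.sort(key=lambda ev: (ev[0], ev[1] >= ev[0]))

    pieces: list[str] = []
    segments: list[tuple[int, int, int, str]] = []
    cursor = ref.offset  # next unprocessed reference position
    mut_cursor = ref.offset  # mutant genomic coordinate of the next base
    for start, end, kind, seq in events:
        if start < cursor:
            raise ValueError("overlapping operations")
        if start > cursor:
            pieces.append(ref.slice_genomic(cursor, start - 1))
            segments.append((cursor, start - 1, mut_cursor, "retained"))
            mut_cursor += start - cursor
            cursor = start
        if kind == "deleted":
            segments.append((start, end, 0, "deleted"))
            cursor = end + 1
        else:
            pieces.append(seq)
            segments.append((0, len(seq), mut_cursor, kind))
            mut_cursor += len(seq)
    if cursor <= ref.end:
        pieces.append(ref.slice_genomic(cursor, ref.end))
        segments.append((cursor, ref.end, mut_cursor, "retained"))
    mutant_bases = "".join(pieces)
    expected = L - sum(e - s + 1 for s, e, k, _ in events if k == "deleted") + sum(
        len(seq) for _, _, k, seq in events if k != "deleted"
    )
    assert len(mutant_bases) == expected, "edit length bookkeeping failed"
    name = ref.name if not edit.name else f"{ref.name}|{edit.name}"
    mutant = ReferenceSequence(name=name, offset=ref.offset, bases=mutant_bases)
    return mutant, CoordinateMap(segments=segments)


# ---------------------------------------------------------------------------
# Toy read mapper: exact k-mer anchoring + ungapped extension
# ---------------------------------------------------------------------------


class ReferenceIndex:
    """Exact k-mer index of a reference for the toy mapper."""

    def __init__(self, ref: ReferenceSequence, k: int = 31, max_hits: int = 8):
        self.ref = ref
        self.k = k
        self.max_hits = max_hits
        idx: dict[bytes, list[int]] = defaultdict(list)
        b = ref.bases.encode()
        for i in range(len(b) - k + 1):
            hits = idx[b[i : i + k]]
            if len(hits) <= max_hits:
                hits.append(i)
        self.index = idx
        self.encoded = b

    def lookup(self, kmer: bytes) -> list[int]:
        return self.index.get(kmer, [])


def _extend(
    read: bytes,
    refb: bytes,
    offset: int,
    anchor_start: int,
    anchor_len: int,
    max_mismatch: int,
    max_consec: int = 2,
) -> tuple[int, int, int] | None:
    """Ungapped extension of an exact anchor along one diagonal.

    ``offset`` maps read index i to reference index offset + i.  Extension
    stops at the reference boundary, when the mismatch budget is exhausted, or
    at ``max_consec`` consecutive mismatches; trailing mismatches are trimmed
    so the alignment ends on matches.  Returns (start, end_exclusive,
    mismatches) in read coordinates, or None.
    """
    L = len(read)
    R = len(refb)
    mm = 0
    # right extension
    right = anchor_start + anchor_len
    last_match_r = right
    consec = 0
    i = right
    while i < L:
        j = offset + i
        if j >= R:
            break
        if read[i] == refb[j]:
            consec = 0
            last_match_r = i + 1
        else:
            mm += 1
            consec += 1
            if mm > max_mismatch or consec >= max_consec:
                break
        i += 1
    mm_r = mm
    # left extension
    left = anchor_start
    last_match_l = left
    consec = 0
    mm = 0
    i = left - 1
    while i >= 0:
        j = offset + i
        if j < 0:
            break
        if read[i] == refb[j]:
            consec = 0
            last_match_l = i
        else:
            mm += 1
            consec += 1
            if mm_r + mm > max_mismatch or consec >= max_consec:
                break
        i -= 1
    # recount mismatches inside the trimmed alignment
    seg_mm = sum(
        1
        for i in range(last_match_l, last_match_r)
        if read[i] != refb[offset + i]
    )
    if last_match_r - last_match_l < anchor_len:
        return None
    return last_match_l, last_match_r, seg_mm


def _map_single(
    seq: str,
    index: ReferenceIndex,
    max_mismatch: int,
    anchor_stride: int | None = None,
) -> list[dict]:
    """All candidate ungapped alignments of one read, both strands."""
    k = index.k
    refb = index.encoded
    candidates: dict[tuple[str, int], dict] = {}
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        b = s.encode()
        L = len(b)
        if L < k:
            continue
        stride = anchor_stride or max(1, k // 2)
        starts = list(range(0, L - k + 1, stride))
        if starts[-1] != L - k:
            starts.append(L - k)
        for a in starts:
            for hit in index.lookup(b[a : a + k]):
                diag = hit - a
                key = (strand, diag)
                if key in candidates:
                    continue
                ext = _extend(b, refb, diag, a, k, max_mismatch)
                if ext is None:
                    continue
                ls, re_, mm = ext
                candidates[key] = {
                    "strand": strand,
                    "diag": diag,
                    "read_start": ls,
                    "read_end": re_,
                    "mismatches": mm,
                    "span": re_ - ls,
                    "ref_local_start": diag + ls,
                }
    return sorted(
        candidates.values(),
        key=lambda c: (-c["span"], c["mismatches"], c["ref_local_start"]),
    )


def _read_interval_in_original(cand: dict, read_len: int) -> tuple[int, int]:
    """Aligned read interval in original-read coordinates (half-open)."""
    if cand["strand"] == "+":
        return cand["read_start"], cand["read_end"]
    return read_len - cand["read_end"], read_len - cand["read_start"]


def map_reads(
    reads: ReadSet,
    ref: ReferenceSequence,
    k: int = 31,
    max_mismatch: int = 6,
    index: ReferenceIndex | None = None,
) -> list[AlignedRead]:
    """Map reads with exact k-mer anchoring and ungapped extension.

    The best diagonal by aligned span (ties: fewer mismatches, then leftmost
    position) becomes the primary alignment; unalignable tails are soft clips.
    If a second diagonal aligns at least ``k`` read bases not covered by the
    primary, it is emitted as a supplementary (chimeric) record.  Reads whose
    best placement is shared by several diagonals are flagged with MAPQ 0 but
    kept.  For paired input, mate fields and TLEN are filled on primary
    records.
    """
    if index is None:
        index = ReferenceIndex(ref, k=k)
    out: list[AlignedRead] = []
    for read in reads:
        if k > len(read.sequence):
            raise ValueError("anchor length exceeds read length")
        cands = _map_single(read.sequence, index, max_mismatch)
        if not cands:
            continue
        best = cands[0]
        ambiguous = (
            len(cands) > 1
            and cands[1]["span"] == best["span"]
            and cands[1]["mismatches"] == best["mismatches"]
        )
        L = len(read.sequence)

        def to_record(c: dict, supplementary: bool) -> AlignedRead:
            clip_left = c["read_start"]
            clip_right = L - c["read_end"]
            return AlignedRead(
                read_id=read.read_id,
                contig=ref.name,
                pos=ref.offset + c["ref_local_start"],
                strand=c["strand"],
                clip_left=clip_left,
                clip_right=clip_right,
                span=c["span"],
                mapq=0 if ambiguous and not supplementary else 60,
                mate=read.mate,
                supplementary=supplementary,
                mismatches=c["mismatches"],
            )

        out.append(to_record(best, supplementary=False))
        prim_iv = _read_interval_in_original(best, L)
        for c in cands[1:]:
            iv = _read_interval_in_original(c, L)
            novel = max(0, min(iv[1], prim_iv[0]) - iv[0]) + max(
                0, iv[1] - max(iv[0], prim_iv[1])
            )
            if novel >= index.k:
                out.append(to_record(c, supplementary=True))
                break
    _fill_mate_info(out)
    return out


def _fill_mate_info(alignments: list[AlignedRead]) -> None:
    primaries: dict[tuple[str, int], AlignedRead] = {}
    for a in alignments:
        if not a.supplementary and a.mate in (1, 2):
            primaries[(a.read_id, a.mate)] = a
    for a in alignments:
        if a.supplementary or a.mate not in (1, 2):
            continue
        other = primaries.get((a.read_id, 3 - a.mate))
        if other is None:
            continue
        a.mate_contig = other.contig
        a.mate_pos = other.pos
        a.mate_strand = other.strand
        if other.contig == a.contig:
            lo = min(a.pos, other.pos)
            hi = max(a.end, other.end)
            outer = hi - lo + 1
            a.tlen = outer if a.pos <= other.pos else -outer


# ---------------------------------------------------------------------------
# Signature extraction
# ---------------------------------------------------------------------------


def classify_pairs(alignments: list[AlignedRead]) -> pd.DataFrame:
    """Orientation class and outer insert size per read pair.

    RL = inward (leftmost mate forward), RF = outward, RR = both forward,
    LL = both reverse, cross = mate missing or on another contig.
    """
    prim: dict[str, dict[int, AlignedRead]] = defaultdict(dict)
    for a in alignments:
        if not a.supplementary and a.mate in (1, 2):
            prim[a.read_id][a.mate] = a
    rows = []
    for rid, mates in prim.items():
        if set(mates) != {1, 2}:
            a = next(iter(mates.values()))
            rows.append(
                {"read_id": rid, "klass": "cross", "insert": np.nan,
                 "pos1": a.pos, "pos2": np.nan}
            )
            continue
        a, b = mates[1], mates[2]
        if a.contig != b.contig:
            rows.append(
                {"read_id": rid, "klass": "cross", "insert": np.nan,
                 "pos1": a.pos, "pos2": b.pos}
            )
            continue
        left, right = (a, b) if a.pos <= b.pos else (b, a)
        if a.strand == "+" and b.strand == "+":
            klass = "RR"
        elif a.strand == "-" and b.strand == "-":
            klass = "LL"
        elif left.strand == "+":
            klass = "RL"
        else:
            klass = "RF"
        insert = right.end - left.pos + 1
        rows.append(
            {"read_id": rid, "klass": klass, "insert": float(insert),
             "pos1": left.pos, "pos2": right.pos}
        )
    return pd.DataFrame(rows, columns=["read_id", "klass", "insert", "pos1", "pos2"])


@dataclass
class ClipCluster:
    """A pile of reads clipped at (nearly) the same reference coordinate."""

    side: str  # 'left' = clip precedes the alignment; 'right' = follows it
    coord: int  # modal junction coordinate (first clipped reference position)
    support: int
    coords: list[int] = field(default_factory=list)


def _cluster_coords(coords: list[int], window: int, min_support: int, side: str):
    clusters = []
    for c in sorted(coords):
        if clusters and c - clusters[-1][-1] <= window:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    out = []
    for cl in clusters:
        if len(cl) < min_support:
            continue
        mode = Counter(cl).most_common()
        best = min(m for m, n in mode if n == mode[0][1])
        out.append(ClipCluster(side=side, coord=best, support=len(cl), coords=cl))
    return out


def _clip_events(
    alignments: list[AlignedRead], min_clip: int
) -> tuple[list[int], list[int], list[int]]:
    """Raw (left-clip, right-clip, supplementary-anchor) coordinates.

    Supplementary (split) alignments contribute both an anchor (their mapped
    position) and their own clip coordinates: for a read whose larger part
    maps elsewhere, the split piece at a junction is the only record carrying
    the breakpoint clip.
    """
    lefts: list[int] = []
    rights: list[int] = []
    anchors: list[int] = []
    for a in alignments:
        if a.supplementary:
            anchors.append(a.pos)
        if a.clip_left >= min_clip:
            lefts.append(a.pos)
        if a.clip_right >= min_clip:
            rights.append(a.end + 1)
    return lefts, rights, anchors


def cluster_clips(
    alignments: list[AlignedRead],
    window: int = 10,
    min_support: int = 3,
    min_clip: int = 5,
) -> tuple[list[ClipCluster], list[ClipCluster]]:
    """Group soft-clipped read ends and chimeric anchors by coordinate.

    Left-side clips are registered at the alignment start (the clipped bases
    precede ``pos``); right-side clips at ``end + 1`` (the first reference
    position past the aligned bases).  Returns (clip clusters, chimeric
    anchor clusters); anchors are the aligned start positions of
    supplementary records, clustered with the same parameters but
    ``min_support`` floored at 1 is not applied (same threshold).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    lefts, rights, anchors = _clip_events(alignments, min_clip)
    clusters = _cluster_coords(lefts, window, min_support, "left")
    clusters += _cluster_coords(rights, window, min_support, "right")
    clusters.sort(key=lambda c: c.coord)
    anchor_clusters = _cluster_coords(anchors, window, min_support, "anchor")
    return clusters, anchor_clusters


def depth_scan(
    alignments: list[AlignedRead],
    ref: ReferenceSequence,
    window: int = 200,
    min_ratio: float = 0.5,
    min_median_depth: float = 4.0,
) -> tuple[list[tuple[int, int, float]], np.ndarray]:
    """Windowed depth drop detector for deletion candidates.

    Depth is accumulated per base from primary alignments, averaged in
    non-overlapping windows and normalized by the median window depth.
    Maximal runs of windows with normalized depth < ``min_ratio`` are
    reported as candidate deletions with their mean depth ratio.  Returns
    ``(candidates, normalized window depths)``.
    """
    L = len(ref)
    diff = np.zeros(L + 1)
    for a in alignments:
        if a.supplementary:
            continue
        s = max(0, a.pos - ref.offset)
        e = min(L, a.end - ref.offset + 1)
        if e > s:
            diff[s] += 1
            diff[e] -= 1
    depth = np.cumsum(diff[:-1])
    nwin = L // window
    if nwin < 1:
        raise ValueError("reference shorter than one window")
    wd = depth[: nwin * window].reshape(nwin, window).mean(axis=1)
    med = np.median(wd)
    if med <= 0 or med < min_median_depth:
        if med < min_median_depth:
            warnings.warn("median depth below the no-call floor; no candidates",
                          stacklevel=2)
        return [], wd / med if med > 0 else wd
    norm = wd / med
    low = norm < min_ratio
    candidates = []
    i = 0
    while i < nwin:
        if low[i]:
            j = i
            while j + 1 < nwin and low[j + 1]:
                j += 1
            # runs touching the contig edges are coverage fall-off, not SVs
            if i > 0 and j < nwin - 1:
                start = ref.offset + i * window
                end = ref.offset + (j + 1) * window - 1
                candidates.append((start, end, float(norm[i : j + 1].mean())))
            i = j + 1
        else:
            i += 1
    return candidates, norm


PAIR_CLASSES = ("RL", "RR", "LL", "RF", "cross")


@dataclass
class SVSignature:
    """Region-level alignment signature used to compare hypotheses.

    ``clip_clusters`` / ``chimeric_anchors`` hold the thresholded clusters
    for reporting; ``clip_events`` / ``anchor_events`` keep every raw clipped
    end and supplementary anchor so that signature comparison can weight
    evidence by support instead of relying on a hard cluster cut-off.
    """

    window: tuple[int, int]
    pair_counts: dict[str, int]
    insert_stats: dict[str, dict[str, float]]  # class -> n/mean/median/max
    clip_clusters: list[ClipCluster]
    chimeric_anchors: list[ClipCluster]
    depth_profile: np.ndarray  # median-normalized windowed depth
    depth_window: int
    clip_events: dict[str, list[int]] = field(default_factory=dict)
    anchor_events: list[int] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return sum(self.pair_counts.values())

    def pair_freqs(self) -> np.ndarray:
        tot = max(1, self.n_pairs)
        return np.array([self.pair_counts.get(c, 0) / tot for c in PAIR_CLASSES])


def signature_profile(
    alignments: list[AlignedRead],
    ref: ReferenceSequence,
    window: tuple[int, int] | None = None,
    depth_window: int = 200,
    clip_window: int = 10,
    min_support: int = 3,
    min_clip: int = 5,
    discordant_insert: float | None = None,
) -> SVSignature:
    """Assemble the orientation/insert/clip/depth signature of a region."""
    if window is None:
        window = (ref.start, ref.end)
    if not (ref.start <= window[0] <= window[1] <= ref.end):
        raise ValueError("window outside the reference")
    pairs = classify_pairs(alignments)
    counts = {c: 0 for c in PAIR_CLASSES}
    stats: dict[str, dict[str, float]] = {}
    if len(pairs):
        inw = pairs[
            (pairs["pos1"].between(window[0], window[1]))
            | (pairs["pos2"].between(window[0], window[1]))
        ]
        for c in PAIR_CLASSES:
            sub = inw[inw["klass"] == c]
            counts[c] = int(len(sub))
            ins = sub["insert"].dropna()
            if len(ins):
                stats[c] = {
                    "n": float(len(ins)),
                    "mean": float(ins.mean()),
                    "median": float(ins.median()),
                    "max": float(ins.max()),
                }
    clips, anchors = cluster_clips(
        alignments, window=clip_window, min_support=min_support, min_clip=min_clip
    )
    lefts, rights, anchor_events = _clip_events(alignments, min_clip)
    _, norm_depth = depth_scan(
        alignments, ref, window=depth_window, min_ratio=0.5, min_median_depth=0.0
    )
    return SVSignature(
        window=window,
        pair_counts=counts,
        insert_stats=stats,
        clip_clusters=clips,
        chimeric_anchors=anchors,
        depth_profile=norm_depth,
        depth_window=depth_window,
        clip_events={"left": lefts, "right": rights},
        anchor_events=anchor_events,
    )


def _weighted_clusters(events: list[int], window: int = 10) -> list[tuple[int, int]]:
    """(coordinate, support) pairs from raw events grouped within ``window``."""
    return [
        (c.coord, c.support)
        for c in _cluster_coords(list(events), window, 1, "any")
    ]


def _position_set_distance(
    a: list[tuple[int, int]], b: list[tuple[int, int]], cap: float
) -> float:
    """Support-weighted symmetric distance between coordinate sets in [0, 1].

    Every cluster is matched to its nearest counterpart (distance capped at
    ``cap``); the means are weighted by cluster support, so well-supported
    pileups dominate and stray single-read events barely move the score.
    """
    if not a and not b:
        return 0.0
    if not a or not b:
        return 1.0

    def one_way(x, y):
        yv = np.array([c for c, _ in y], float)
        num = sum(w * min(abs(c - yv).min(), cap) for c, w in x)
        den = sum(w for _, w in x)
        return num / den / cap

    return 0.5 * (one_way(a, b) + one_way(b, a))


def _pair_class_divergence(
    observed: SVSignature, simulated: SVSignature, min_count: int = 3
) -> float:
    """Largest normalized per-class frequency contrast in [0, 1].

    For each orientation class the contrast |f_obs - f_sim| / (f_obs + f_sim)
    is 1 when a class present in one signature is absent from the other and 0
    when frequencies agree; classes with fewer than ``min_count`` reads in
    both signatures combined are ignored as noise.  Taking the maximum keeps
    rare but diagnostic classes (RR/LL discordant pairs are a fraction of a
    percent of a library) from being drowned out by the RL bulk.
    """
    fo, fs = observed.pair_freqs(), simulated.pair_freqs()
    best = 0.0
    for i, klass in enumerate(PAIR_CLASSES):
        n_tot = observed.pair_counts.get(klass, 0) + simulated.pair_counts.get(
            klass, 0
        )
        if n_tot < min_count:
            continue
        denom = fo[i] + fs[i]
        if denom > 0:
            best = max(best, abs(fo[i] - fs[i]) / denom)
    return best


def signature_distance(
    observed: SVSignature,
    simulated: SVSignature,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    position_cap: float = 1000.0,
    depth_deadzone: float = 0.3,
    tolerance: float = 0.0,
) -> float:
    """Nonnegative divergence between two signatures over the same window.

    Components, each normalized to [0, 1] before (equal by default)
    weighting: (i) pair-orientation class divergence, (ii) support-weighted
    distance between clip coordinate sets (per side), (iii) the same for
    chimeric anchors, (iv) mean L1 gap of the normalized depth profiles,
    ignoring per-window gaps below ``depth_deadzone`` (counting noise at
    typical coverage).  Zero iff every component agrees within ``tolerance``.
    """
    if observed.window != simulated.window:
        raise ValueError("signatures cover different windows")
    class_d = _pair_class_divergence(observed, simulated)
    clip_d = 0.0
    for side in ("left", "right"):
        clip_d += _position_set_distance(
            _weighted_clusters(observed.clip_events.get(side, [])),
            _weighted_clusters(simulated.clip_events.get(side, [])),
            position_cap,
        )
    clip_d /= 2.0
    anchor_d = _position_set_distance(
        _weighted_clusters(observed.anchor_events),
        _weighted_clusters(simulated.anchor_events),
        position_cap,
    )
    n = min(len(observed.depth_profile), len(simulated.depth_profile))
    if n == 0:
        depth_d = 1.0
    else:
        gap = np.abs(observed.depth_profile[:n] - simulated.depth_profile[:n])
        gap = np.where(gap <= depth_deadzone, 0.0, np.minimum(gap, 1.0))
        depth_d = float(gap.mean())
    comps = np.array([class_d, clip_d, anchor_d, depth_d])
    comps[comps <= tolerance] = 0.0
    w = np.asarray(weights, float)
    return float((comps * w).sum() / w.sum())


# ---------------------------------------------------------------------------
# Hypothesis ranking
# ---------------------------------------------------------------------------


def rank_hypotheses(
    observed: SVSignature,
    ref: ReferenceSequence,
    candidates: list[RearrangementEdit],
    seed: int,
    coverage: float = 10.0,
    read_len: int = 100,
    insert_mean: float = 350.0,
    insert_sd: float = 35.0,
    error_rate: float = 0.001,
    k: int = 31,
    index: ReferenceIndex | None = None,
    **profile_kwargs,
) -> pd.DataFrame:
    """Score candidate rearrangements against an observed signature.

    For each candidate: apply the edit, simulate paired-end reads from the
    mutant, map them back to the *unedited* reference, profile the signature
    and compute its distance to ``observed``.  Candidates are returned sorted
    ascending by distance (invalid candidates score ``inf`` with the reason).
    Every candidate uses the same seed, so the ranking does not depend on the
    order of the list.
    """
    from .synthdata import simulate_paired_reads

    if not candidates:
        raise ValueError("need at least one candidate")
    if index is None:
        index = ReferenceIndex(ref, k=k)
    rows = []
    for i, cand in enumerate(candidates):
        name = cand.name or f"candidate_{i}"
        try:
            mutant, _ = apply_edits(ref, cand)
            reads = simulate_paired_reads(
                mutant, coverage, read_len, insert_mean, insert_sd,
                error_rate, seed=seed,
            )
            alns = map_reads(reads, ref, k=k, index=index)
            sig = signature_profile(
                alns, ref, window=observed.window,
                depth_window=observed.depth_window, **profile_kwargs,
            )
            score = signature_distance(observed, sig)
            reason = ""
        except (ValueError, IndexError) as exc:
            score, reason = float("inf"), str(exc)
        rows.append({"candidate": name, "distance": score, "note": reason})
    df = pd.DataFrame(rows).sort_values(
        ["distance", "candidate"], kind="mergesort"
    )
    return df.reset_index(drop=True)


def locate_deletion_breakpoints(
    alignments: list[AlignedRead],
    ref: ReferenceSequence,
    depth_window: int = 200,
    min_ratio: float = 0.75,
    clip_window: int = 10,
    min_support: int = 1,
    min_clip: int = 5,
    search_pad: int = 2000,
) -> tuple[int, int, tuple[int, int]]:
    """Breakpoint coordinates of the strongest deletion candidate.

    The windowed depth scan proposes a deleted interval; soft-clip clusters
    then refine its junctions: the 5' breakpoint is the modal coordinate of
    the best-supported *right*-side clip cluster near the interval start
    (reads running off the left flank into missing sequence), the 3'
    breakpoint that of the best *left*-side cluster near the interval end.
    Because the search is restricted to the depth-supported neighbourhood,
    ``min_support`` defaults to 1 here (stray single clips essentially never
    out-support a genuine junction pile-up); ties favour the cluster nearest
    the interval.  Returns ``(five_prime, three_prime, depth_interval)``.
    """
    candidates, _ = depth_scan(
        alignments, ref, window=depth_window, min_ratio=min_ratio
    )
    if not candidates:
        raise ValueError("no depth-supported deletion candidate")
    start, end, _ratio = min(candidates, key=lambda c: c[2])
    clips, _ = cluster_clips(
        alignments, window=clip_window, min_support=min_support, min_clip=min_clip
    )
    right = [
        c for c in clips
        if c.side == "right" and start - search_pad <= c.coord <= end + search_pad
    ]
    left = [
        c for c in clips
        if c.side == "left" and start - search_pad <= c.coord <= end + search_pad
    ]
    if not right or not left:
        raise ValueError("no clip support at the candidate breakpoints")
    five = max(right, key=lambda c: (c.support, -abs(c.coord - start))).coord
    three = max(left, key=lambda c: (c.support, -abs(c.coord - end))).coord
    return five, three, (start, end)


# ---------------------------------------------------------------------------
# Long-read junction sizing
# ---------------------------------------------------------------------------


def long_read_junction_insert(
    reads: ReadSet,
    del_ref: ReferenceSequence,
    junction: int,
    k: int = 21,
    flank: int = 200,
) -> list[float]:
    """Per-read insertion length at a junction of a deletion-applied reference.

    Each long read is anchored to ``del_ref`` by unique exact k-mers on both
    strands; the nearest anchors on either side of ``junction`` extrapolate
    the read coordinates where the left flank ends and the right flank
    begins, and their gap is the inserted length carried by that read.  Reads
    must be anchored at least ``flank`` bases into both flanks.  On a mutant
    haplotype whose insertion replaced the deleted segment the estimates
    cluster at the true insert size; wild-type haplotypes (which still carry
    the deleted sequence) show up as estimates of at least the deletion
    length.
    """
    index = ReferenceIndex(del_ref, k=k)
    jl = junction - del_ref.offset  # local 0-based index of the junction base
    if not 0 <= jl < len(del_ref):
        raise ValueError("junction outside the reference")
    estimates: list[float] = []
    for read in reads:
        best = None
        for strand in ("+", "-"):
            s = read.sequence if strand == "+" else revcomp(read.sequence)
            b = s.encode()
            if len(b) < k:
                continue
            left_anchor = None  # (read_pos, ref_local) with max ref end < jl
            right_anchor = None  # min ref start >= jl
            left_min = None
            right_max = None
            for i in range(0, len(b) - k + 1):
                hits = index.lookup(b[i : i + k])
                if len(hits) != 1:
                    continue
                r = hits[0]
                if r + k - 1 < jl:
                    if left_anchor is None or r > left_anchor[1]:
                        left_anchor = (i, r)
                    if left_min is None or r < left_min:
                        left_min = r
                elif r >= jl:
                    if right_anchor is None or r < right_anchor[1]:
                        right_anchor = (i, r)
                    if right_max is None or r + k - 1 > right_max:
                        right_max = r + k - 1
            if left_anchor is None or right_anchor is None:
                continue
            if jl - left_min < flank or right_max - jl + 1 < flank:
                continue  # does not span deep enough into both flanks
            ql, rl = left_anchor
            qr, rr = right_anchor
            # read index of the last left-flank base / first right-flank base
            pred_left = ql + (k - 1) + ((jl - 1) - (rl + k - 1))
            pred_right = qr - (rr - jl)
            est = float(pred_right - pred_left - 1)
            if best is None or abs(est) < abs(best):
                best = est
        if best is not None:
            estimates.append(best)
    if not estimates:
        raise ValueError("no reads span the junction")
    return estimates


# ---------------------------------------------------------------------------
# Genotyping
# ---------------------------------------------------------------------------


@dataclass
class SVGenotypeCall:
    sample: str
    genotype: str  # 'hom-ref' | 'het' | 'hom-alt' | 'no-call'
    discordant_pairs: int
    clip_support: int
    depth_ratio: float
    note: str = ""


def genotype_sv(
    signature: SVSignature,
    sv_interval: tuple[int, int],
    sample: str = "sample",
    min_pairs: int = 50,
    min_support: int = 3,
    hom_alt_depth: float = 0.25,
    hom_ref_depth: float = 0.75,
) -> SVGenotypeCall:
    """Call an SV genotype from one sample's signature.

    Combines the depth ratio over the deleted interval with discordant-pair
    (RR/LL) and breakpoint clip support: a clean signature with normal depth
    is hom-ref, strong support with depth near zero hom-alt, intermediate
    depth het.  Too few pairs in the window, or conflicting evidence, yields
    a no-call.
    """
    win_lo = signature.window[0]
    w = signature.depth_window
    lo = max(0, (sv_interval[0] - win_lo) // w)
    hi = min(len(signature.depth_profile), (sv_interval[1] - win_lo) // w + 1)
    if hi <= lo:
        raise ValueError("SV interval outside the signature window")
    depth_ratio = float(signature.depth_profile[lo:hi].mean())
    discordant = signature.pair_counts.get("RR", 0) + signature.pair_counts.get("LL", 0)
    pad = 500
    clip_support = sum(
        c.support
        for c in signature.clip_clusters
        if sv_interval[0] - pad <= c.coord <= sv_interval[1] + pad
    )
    support = discordant + clip_support
    if signature.n_pairs < min_pairs:
        return SVGenotypeCall(sample, "no-call", discordant, clip_support,
                              depth_ratio, note="insufficient pairs")
    if support >= min_support and depth_ratio < hom_alt_depth:
        gt = "hom-alt"
    elif support >= min_support and depth_ratio < hom_ref_depth:
        gt = "het"
    elif support < min_support and depth_ratio >= hom_ref_depth:
        gt = "hom-ref"
    else:
        return SVGenotypeCall(sample, "no-call", discordant, clip_support,
                              depth_ratio, note="conflicting evidence")
    return SVGenotypeCall(sample, gt, discordant, clip_support, depth_ratio)


def genotype_r2(calls_a, calls_b) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Pairs with a missing call in either vector are dropped; NaN is returned
    when fewer than two complete pairs remain or either site is monomorphic.
    """
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
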