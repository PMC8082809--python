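"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a mapping study of darkness of hair coat (DHC) in a
zebu cattle population: ~432 individuals genotyped on a dense SNP chip, a
biallelic QTL at alternative-allele frequency 0.481 acting with both additive
and dominance components, phenotypes recorded as the mean of six rater scores
on a 0-3 scale, plus short-read (wgsim-style paired-end) and nanopore-style
long-read sequencing of wild-type and rearranged haplotypes.

Variance bookkeeping for the QTL follows the classical single-locus
decomposition: with counted-allele frequency ``p`` (``q = 1 - p``), additive
genotypic value ``a`` and dominance deviation ``d``, the allele-substitution
effect is ``alpha = a + (q - p) d`` and the genetic variance splits into
``V_A = 2 p q alpha**2`` and ``V_D = (2 p q d)**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, PhenotypeVector, Read, ReadSet, ReferenceSequence

__all__ = [
    "QTLSpec",
    "RaterModel",
    "simulate_genotypes",
    "plant_haplotype_block",
    "simulate_phenotypes",
    "simulate_reference",
    "simulate_paired_reads",
    "simulate_long_reads",
]

# Defaults mirror the mapped DHC QTL: alt-allele frequency 48.1%,
# allele-substitution effect 0.702 score units, dominance deviation -0.467,
# residual variance 0.344 (gives V_G / (V_G + V_E) = 46.6%).
DEFAULT_QTL_P = 0.481
DEFAULT_ALPHA = 0.702
DEFAULT_D = -0.467
DEFAULT_RESID_VAR = 0.344


@dataclass
class QTLSpec:
    """A biallelic QTL parameterized by (p, a, d).

    ``p`` is the frequency of the counted (alternative) allele, ``a`` the
    additive genotypic value (half the homozygote difference) and ``d`` the
    dominance deviation, both in phenotype units.  The allele-substitution
    effect ``alpha = a + (q - p) d`` is derived.
    """

    p: float
    a: float
    d: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("allele frequency must be in (0, 1)")

    @classmethod
    def from_alpha(cls, p: float, alpha: float, d: float) -> "QTLSpec":
        """Build a spec from (p, alpha, d) by inverting alpha = a + (q-p) d."""
        q = 1.0 - p
        return cls(p=p, a=alpha - (q - p) * d, d=d)

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def alpha(self) -> float:
        return self.a + (self.q - self.p) * self.d

    def genotypic_values(self) -> np.ndarray:
        """Genotypic value for 0, 1, 2 copies of the counted allele."""
        return np.array([-self.a, self.d, self.a])

    def variance_components(self) -> tuple[float, float]:
        """(V_A, V_D) under Hardy-Weinberg proportions."""
        two_pq = 2.0 * self.p * self.q
        return two_pq * self.alpha**2, (two_pq * self.d) ** 2


@dataclass
class RaterModel:
    """Ordinal rating process: several raters score a latent trait 0..3.

    Each rater observes the latent value plus independent N(0, rater_sd^2)
    noise and converts it to an integer score via strictly increasing
    ``thresholds`` (score 0 below the first cut point, 3 above the last).
    The reported phenotype is the mean over raters.  ``thresholds=None``
    disables discretization: raters report the noisy latent value directly,
    which is the continuous mode used for variance-decomposition checks.
    """

    n_raters: int = 6
    scale_min: float = 0.0
    scale_max: float = 3.0
    rater_sd: float = 0.15
    thresholds: tuple[float, ...] | None = (0.9, 1.6, 2.3)

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise ValueError("need at least one rater")
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be < scale_max")
        if self.thresholds is not None:
            t = tuple(self.thresholds)
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ValueError("thresholds must be strictly increasing")
            self.thresholds = t

    def score(self, latent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Mean rater score per individual, clamped to the scale."""
        n = latent.shape[0]
        obs = latent[:, None] + rng.normal(0.0, self.rater_sd, size=(n, self.n_raters))
        if self.thresholds is not None:
            cuts = np.asarray(self.thresholds)
            obs = np.searchsorted(cuts, obs).astype(float)
        return np.clip(obs.mean(axis=1), self.scale_min, self.scale_max)


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if not np.all(np.isfinite(freqs)):
        raise ValueError("allele frequencies must be finite")
    if np.any((freqs < 0.0) | (freqs > 1.0)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return freqs


def simulate_genotypes(
    n: int,
    m: int,
    freqs,
    seed: int,
    chroms=None,
    spacing: int = 1000,
) -> GenotypeMatrix:
    """Phased genotypes for ``n`` individuals at ``m`` independent markers.

    Each individual receives two independent Bernoulli(freq) haplotypes per
    marker (Hardy-Weinberg by construction); dosage is the haplotype sum.
    ``freqs`` may be a scalar or a length-``m`` vector of alternative-allele
    frequencies.  ``chroms`` optionally assigns each marker to a chromosome
    (defaults to a single chromosome "1"); positions are laid out every
    ``spacing`` bp within chromosome.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 individuals and m >= 1 markers")
    freqs = np.broadcast_to(_check_freqs(np.asarray(freqs, dtype=float)), (m,))
    rng = np.random.default_rng(seed)
    haps = (rng.random((n, 2, m)) < freqs).astype(np.int8)
    if chroms is None:
        chroms = ["1"] * m
    chroms = [str(c) for c in chroms]
    if len(chroms) != m:
        raise ValueError("chroms must have one entry per marker")
    pos = np.empty(m, dtype=int)
    counter: dict[str, int] = {}
    for j, c in enumerate(chroms):
        counter[c] = counter.get(c, 0) + 1
        pos[j] = counter[c] * spacing
    alleles = np.array(["A", "C", "G", "T"])
    ref = rng.choice(alleles, size=m)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    markers = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "id": [f"snp_{c}_{p}" for c, p in zip(chroms, pos)],
            "ref": ref,
            "alt": alt,
        }
    )
    samples = [f"ind{i:04d}" for i in range(n)]
    return GenotypeMatrix(
        samples=samples,
        markers=markers,
        dosages=haps.sum(axis=1).astype(float),
        haplotypes=haps,
    )


def simulate_phenotypes(
    geno: GenotypeMatrix,
    qtl: QTLSpec,
    qtl_marker: str,
    seed: int,
    polygenic_h2: float = 0.0,
    resid_var: float = DEFAULT_RESID_VAR,
    rater: RaterModel | None = None,
    baseline: float = 1.5,
    grm: np.ndarray | None = None,
) -> PhenotypeVector:
    """Phenotypes driven by one QTL plus polygenic and residual noise.

    The latent trait is ``baseline + G(dosage) + u + e`` where ``G`` maps
    0/1/2 copies of the counted allele to (-a, d, +a), ``u`` is a polygenic
    deviate with covariance proportional to the GRM (variance chosen so that
    ``polygenic_h2`` is its share of the non-QTL variance) and
    ``e ~ N(0, resid_var)``.  When a :class:`RaterModel` is supplied the
    returned score is the mean rater score clamped to the scale; with
    ``rater=None`` the raw latent value is returned (useful for analytic
    variance checks; it may stray outside the nominal scale).
    """
    if not 0.0 <= polygenic_h2 < 1.0:
        raise ValueError("polygenic_h2 must be in [0, 1)")
    if resid_var < 0.0:
        raise ValueError("resid_var must be non-negative")
    j = geno.marker_index(qtl_marker)
    dosage = geno.dosages[:, j]
    if np.any(np.isnan(dosage)):
        raise ValueError("QTL marker has missing genotypes")
    rng = np.random.default_rng(seed)
    n = geno.n_samples
    gvals = qtl.genotypic_values()[dosage.astype(int)]
    latent = baseline + gvals
    if polygenic_h2 > 0.0:
        sigma2_u = resid_var * polygenic_h2 / (1.0 - polygenic_h2)
        if grm is None:
            from .assoc import compute_grm

            grm = compute_grm(geno).values
        jitter = 1e-6 * np.eye(n)
        chol = np.linalg.cholesky(sigma2_u * grm + jitter)
        latent = latent + chol @ rng.standard_normal(n)
    if resid_var > 0.0:
        latent = latent + rng.normal(0.0, math.sqrt(resid_var), size=n)
    if rater is None:
        scores = latent
    else:
        scores = rater.score(latent, rng)
    return PhenotypeVector(samples=list(geno.samples), scores=scores)


def plant_haplotype_block(
    geno: GenotypeMatrix,
    anchor_marker: str,
    block_size: int,
    seed: int,
    rare_rate: float = 0.2,
    max_rare_mutations: int = 3,
) -> tuple[GenotypeMatrix, dict[str, str], tuple[str, int, int]]:
    """Overwrite a marker block with two common haplotypes tagging the anchor.

    Independent markers carry no linkage disequilibrium, so haplotype-block
    analyses on raw simulated genotypes see only singletons.  This helper
    rewrites ``block_size`` markers centred on ``anchor_marker`` so that every
    chromosome copy carries one of two founder haplotypes — one cosegregating
    with the anchor's alternative allele, one with its reference allele —
    except that a fraction ``rare_rate`` of copies receives 1..n random
    off-anchor mutations, creating a tail of rare alleles.  Anchor-marker
    calls (hence QTL dosages and phenotypes) are preserved exactly.

    Returns the modified matrix, the founder allele strings keyed
    ``"alt"`` / ``"ref"`` (in the marker's ref/alt base characters), and the
    block interval as ``(chrom, start_pos, end_pos)``.
    """
    if not geno.phased:
        raise ValueError("planting a block requires phased genotypes")
    j = geno.marker_index(anchor_marker)
    chrom = geno.markers.loc[j, "chrom"]
    on_chrom = np.flatnonzero((geno.markers["chrom"] == chrom).to_numpy())
    center = int(np.where(on_chrom == j)[0][0])
    half = block_size // 2
    lo = max(0, min(center - half, len(on_chrom) - block_size))
    idx = on_chrom[lo : lo + block_size]
    rng = np.random.default_rng(seed)
    anchor_col = int(np.where(idx == j)[0][0])
    founders = {}
    for allele, bit in (("ref", 0), ("alt", 1)):
        h = rng.integers(0, 2, size=len(idx)).astype(np.int8)
        h[anchor_col] = bit
        founders[allele] = h
    haps = geno.haplotypes.copy()
    for i in range(geno.n_samples):
        for c in (0, 1):
            bit = haps[i, c, j]
            h = founders["alt" if bit == 1 else "ref"].copy()
            if rng.random() < rare_rate:
                k = 1 + rng.integers(max_rare_mutations)
                sites = rng.choice(
                    [x for x in range(len(idx)) if x != anchor_col],
                    size=min(k, len(idx) - 1), replace=False,
                )
                h[sites] = 1 - h[sites]
            haps[i, c, idx] = h
    out = GenotypeMatrix(
        samples=list(geno.samples),
        markers=geno.markers.copy(),
        dosages=haps.sum(axis=1).astype(float),
        haplotypes=haps,
    )
    ref_c = geno.markers["ref"].to_numpy()[idx]
    alt_c = geno.markers["alt"].to_numpy()[idx]
    strings = {
        k: "".join((alt_c if b else ref_c)[x] for x, b in enumerate(v))
        for k, v in founders.items()
    }
    pos = geno.markers["pos"].to_numpy()[idx]
    return out, strings, (str(chrom), int(pos.min()), int(pos.max()))


def simulate_reference(name: str, offset: int, length: int, seed: int) -> ReferenceSequence:
    """An i.i.d.-uniform random reference fragment anchored at ``offset``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
    return ReferenceSequence(name=name, offset=offset, bases=bases.tobytes().decode())


_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp(seq: str) -> str:
    return seq.encode().translate(_COMP).decode()[::-1]


def _apply_substitutions(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    if hit.any():
        choices = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in np.flatnonzero(hit):
            arr[i] = rng.choice(choices[choices != arr[i]])
    return arr.tobytes().decode()


def simulate_paired_reads(
    ref: ReferenceSequence,
    coverage: float,
    read_len: int,
    insert_mean: float,
    insert_sd: float,
    error_rate: float,
    seed: int,
    haplotype: str = "",
    gc_bias: float = 0.0,
) -> ReadSet:
    """wgsim-style paired-end reads from ``ref``.

    Fragments are drawn uniformly along the sequence with N(insert_mean,
    insert_sd) lengths; read 1 is the 5' ``read_len`` bases on the forward
    strand, read 2 the 3' ``read_len`` bases reverse-complemented, so truth
    pairs are inward (RL) oriented by construction.  Substitution errors are
    applied at ``error_rate`` per base.  ``gc_bias > 0`` optionally thins
    fragments in GC-rich windows (emulating PCR amplification bias); default
    off.
    """
    if coverage <= 0.0:
        raise ValueError("coverage must be positive")
    if read_len >= insert_mean:
        raise ValueError("read length must be shorter than the mean insert")
    L = len(ref)
    if insert_mean > L:
        raise ValueError("mean insert exceeds the reference length")
    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage * L / (2 * read_len)))
    reads: list[Read] = []
    made = 0
    while made < n_pairs:
        frag = int(round(rng.normal(insert_mean, insert_sd)))
        frag = max(read_len, min(frag, L))
        start = int(rng.integers(0, L - frag + 1))  # 0-based fragment start
        fragment = ref.bases[start : start + frag]
        if gc_bias > 0.0:
            gc = (fragment.count("G") + fragment.count("C")) / frag
            # GC-dependent thinning: keep probability falls with GC excess
            if rng.random() < gc_bias * max(0.0, gc - 0.5) * 2.0:
                continue
        rid = f"frag{made:07d}"
        r1_seq = _apply_substitutions(fragment[:read_len], error_rate, rng)
        r2_seq = _apply_substitutions(
            _revcomp(fragment[-read_len:]), error_rate, rng
        )
        reads.append(
            Read(
                read_id=rid,
                sequence=r1_seq,
                quality=30,
                mate=1,
                origin_contig=ref.name,
                origin_start=ref.offset + start,
                origin_strand="+",
                haplotype=haplotype,
            )
        )
        reads.append(
            Read(
                read_id=rid,
                sequence=r2_seq,
                quality=30,
                mate=2,
                origin_contig=ref.name,
                origin_start=ref.offset + start + frag - read_len,
                origin_strand="-",
                haplotype=haplotype,
            )
        )
        made += 1
    return ReadSet(reads=reads, paired=True)


@dataclass
class LongReadErrorModel:
    """Per-base error rates of a nanopore-style sequencer (indel-dominant)."""

    mismatch: float = 0.03
    insertion: float = 0.03
    deletion: float = 0.05

    def total(self) -> float:
        return self.mismatch + self.insertion + self.deletion


def _apply_indel_errors(seq: str, model: LongReadErrorModel, rng: np.random.Generator) -> str:
    if model.total() <= 0.0:
        return seq
    bases = "ACGT"
    out: list[str] = []
    for ch in seq:
        r = rng.random()
        if r < model.deletion:
            continue
        if r < model.deletion + model.insertion:
            out.append(bases[rng.integers(4)])
            out.append(ch)
            continue
        if r < model.total():
            out.append(bases[(bases.index(ch) + 1 + rng.integers(3)) % 4] if ch in bases else ch)
            continue
        out.append(ch)
    return "".join(out)


def simulate_long_reads(
    ref: ReferenceSequence,
    coverage: float,
    mean_len: float,
    seed: int,
    error_model: LongReadErrorModel | None = None,
    min_len: int = 200,
    haplotype: str = "",
) -> ReadSet:
    """Nanopore-style long reads: exponential-ish lengths, indel-heavy errors.

    Read lengths are drawn from an exponential distribution (floored at
    ``min_len`` and capped at the reference length) around ``mean_len``;
    strand is random; errors follow ``error_model`` (defaults emulate an ONT
    R9 flow cell: ~3% mismatch, ~3% insertion, ~5% deletion).
    """
    if coverage <= 0.0:
        raise ValueError("coverage must be positive")
    L = len(ref)
    if mean_len > L:
        raise ValueError("mean read length exceeds the reference length")
    if error_model is None:
        error_model = LongReadErrorModel()
    rng = np.random.default_rng(seed)
    target = coverage * L
    total = 0.0
    reads: list[Read] = []
    i = 0
    while total < target:
        rl = int(rng.exponential(mean_len))
        rl = max(min_len, min(rl, L))
        start = int(rng.integers(0, L - rl + 1))
        raw = ref.bases[start : start + rl]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = raw if strand == "+" else _revcomp(raw)
        seq = _apply_indel_errors(seq, error_model, rng)
        reads.append(
            Read(
                read_id=f"lr{i:06d}",
                sequence=seq,
                quality=12,
                mate=0,
                origin_contig=ref.name,
                origin_start=ref.offset + start,
                origin_strand=strand,
                haplotype=haplotype,
            )
        )
        total += rl
        i += 1
    return ReadSet(reads=reads, paired=False)
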