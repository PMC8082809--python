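"""Haplotype-block alleles and phenotype summaries conditional on diplotype.

Haplotype alleles are the per-chromosome strings of marker alleles over an
ordered block of phased SNPs (one character per marker, using the marker's
ref/alt characters so printed alleles are directly comparable to published
block strings).  Rare alleles are pooled into a residual class ("HN"); the
phenotype distribution is then summarized per diplotype group (the unordered
pair of grouped allele labels an individual carries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, PhenotypeVector

__all__ = [
    "HaplotypeTable",
    "extract_haplotypes",
    "group_rare",
    "ungroup",
    "phenotype_by_haplotype",
]

RESIDUAL_LABEL = "HN"


@dataclass
class HaplotypeTable:
    """Allele counts over a marker block (2n haplotypes total)."""

    chrom: str
    start: int
    end: int
    marker_ids: list[str]
    counts: dict[str, int]  # allele string (or group label) -> count
    labels: dict[str, str] = field(default_factory=dict)  # allele -> group label
    min_freq: float | None = None
    residual_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def block_size(self) -> int:
        return len(self.marker_ids)

    def frequencies(self) -> dict[str, Fraction]:
        """Exact allele frequencies as rationals (they sum to 1 exactly)."""
        tot = self.total
        return {a: Fraction(c, tot) for a, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        tot = self.total
        rows = [
            {
                "allele": a,
                "label": self.labels.get(a, a),
                "count": c,
                "frequency": c / tot,
            }
            for a, c in sorted(self.counts.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows)


def extract_haplotypes(
    geno: GenotypeMatrix, chrom: str, start: int, end: int
) -> HaplotypeTable:
    """Tabulate haplotype alleles in the closed interval ``[start, end]``.

    Requires phased genotypes: each of the 2n phased chromosome copies
    contributes one allele string (one character per marker, the ref or alt
    base according to the phased call).
    """
    if not geno.phased:
        raise ValueError("haplotype extraction requires phased genotypes")
    mk = geno.markers
    mask = (
        (mk["chrom"].astype(str) == str(chrom))
        & (mk["pos"] >= start)
        & (mk["pos"] <= end)
    ).to_numpy()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("interval contains no markers")
    if np.any(geno.haplotypes[:, :, idx] < 0):
        raise ValueError("missing phased calls inside the block")
    ref = mk["ref"].to_numpy()[idx]
    alt = mk["alt"].to_numpy()[idx]
    chars = np.stack([ref, alt])  # row 0 = ref char, row 1 = alt char
    counts: dict[str, int] = {}
    for i in range(geno.n_samples):
        for h in (0, 1):
            calls = geno.haplotypes[i, h, idx]
            allele = "".join(chars[c, j] for j, c in enumerate(calls))
            counts[allele] = counts.get(allele, 0) + 1
    ids = mk["id"].to_numpy()[idx].tolist()
    return HaplotypeTable(
        chrom=str(chrom), start=start, end=end, marker_ids=ids, counts=counts
    )


def group_rare(table: HaplotypeTable, min_freq: float = 0.05) -> HaplotypeTable:
    """Pool alleles at frequency <= ``min_freq`` into one residual class.

    Alleles strictly above the threshold keep their string and receive labels
    H1, H2, ... in descending frequency order; the rest are pooled as "HN".
    """
    if not 0.0 <= min_freq < 1.0:
        raise ValueError("min_freq must lie in [0, 1)")
    tot = table.total
    named = {
        a: c for a, c in table.counts.items() if Fraction(c, tot) > Fraction(min_freq)
    }
    rare = {a: c for a, c in table.counts.items() if a not in named}
    counts: dict[str, int] = {}
    labels: dict[str, str] = {}
    for rank, (a, c) in enumerate(
        sorted(named.items(), key=lambda kv: (-kv[1], kv[0])), start=1
    ):
        counts[a] = c
        labels[a] = f"H{rank}"
    if rare:
        counts[RESIDUAL_LABEL] = sum(rare.values())
        labels[RESIDUAL_LABEL] = RESIDUAL_LABEL
    return HaplotypeTable(
        chrom=table.chrom,
        start=table.start,
        end=table.end,
        marker_ids=list(table.marker_ids),
        counts=counts,
        labels=labels,
        min_freq=min_freq,
        residual_counts=dict(rare),
    )


def ungroup(table: HaplotypeTable) -> HaplotypeTable:
    """Invert :func:`group_rare`, restoring per-allele counts."""
    counts = {a: c for a, c in table.counts.items() if a != RESIDUAL_LABEL}
    if RESIDUAL_LABEL in table.counts:
        if not table.residual_counts:
            raise ValueError("grouped table lacks member counts; cannot ungroup")
        counts.update(table.residual_counts)
    return HaplotypeTable(
        chrom=table.chrom,
        start=table.start,
        end=table.end,
        marker_ids=list(table.marker_ids),
        counts=counts,
    )


def _diplotype_labels(
    table: HaplotypeTable, geno: GenotypeMatrix
) -> list[str]:
    """Grouped diplotype label ("H1/H2", "H2/HN", ...) per individual."""
    mk = geno.markers
    mask = (
        (mk["chrom"].astype(str) == table.chrom)
        & (mk["pos"] >= table.start)
        & (mk["pos"] <= table.end)
    ).to_numpy()
    idx = np.flatnonzero(mask)
    ref = mk["ref"].to_numpy()[idx]
    alt = mk["alt"].to_numpy()[idx]
    chars = np.stack([ref, alt])
    named = {a: lbl for a, lbl in table.labels.items() if lbl != RESIDUAL_LABEL}
    out = []
    for i in range(geno.n_samples):
        pair = []
        for h in (0, 1):
            calls = geno.haplotypes[i, h, idx]
            allele = "".join(chars[c, j] for j, c in enumerate(calls))
            pair.append(named.get(allele, RESIDUAL_LABEL))
        out.append("/".join(sorted(pair)))
    return out


def phenotype_by_haplotype(
    table: HaplotypeTable,
    geno: GenotypeMatrix,
    y: PhenotypeVector,
) -> pd.DataFrame:
    """Boxplot statistics of the phenotype per diplotype group.

    Individuals are grouped by the unordered pair of (grouped) haplotype
    labels they carry; per group the summary reports n, median, quartiles and
    range.  Groups with no members appear with n = 0 and NaN summaries.
    """
    if list(geno.samples) != list(y.samples):
        raise ValueError("samples of genotypes and phenotypes do not align")
    if not geno.phased:
        raise ValueError("diplotype grouping requires phased genotypes")
    labels = _diplotype_labels(table, geno)
    df = pd.DataFrame({"diplotype": labels, "score": y.scores})
    group_names = sorted(set(table.labels.values()) | {RESIDUAL_LABEL})
    all_pairs = sorted(
        "/".join(sorted((a, b)))
        for i, a in enumerate(group_names)
        for b in group_names[i:]
    )
    rows = []
    for gname in all_pairs:
        sub = df.loc[df["diplotype"] == gname, "score"]
        if len(sub) == 0:
            rows.append(
                {"diplotype": gname, "n": 0, "median": np.nan, "q1": np.nan,
                 "q3": np.nan, "min": np.nan, "max": np.nan}
            )
        else:
            rows.append(
                {
                    "diplotype": gname,
                    "n": int(len(sub)),
                    "median": float(sub.median()),
                    "q1": float(sub.quantile(0.25)),
                    "q3": float(sub.quantile(0.75)),
                    "min": float(sub.min()),
                    "max": float(sub.max()),
                }
            )
    return pd.DataFrame(rows)
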