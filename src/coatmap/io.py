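"""Plain-text format plumbing: FASTA, VCF subset, SAM subset, TSV.

Dialects are deliberately minimal but standard-conformant: VCF 4.2 with GT
only (phase preserved: ``0|1`` is distinct from ``0/1``, missing is ``.``),
SAM with QNAME/FLAG/RNAME/POS/MAPQ/CIGAR (M/S/H ops)/RNEXT/PNEXT/TLEN, FASTA
with the genomic anchor of a fragment carried as ``offset=<int>`` in the
description.  Positions are 1-based everywhere and no reader or writer shifts
coordinates.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import AlignedRead, GenotypeMatrix, PhenotypeVector, ReadSet, ReferenceSequence

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pheno_tsv",
    "write_pheno_tsv",
    "read_vcf_subset",
    "write_vcf_subset",
    "read_sam_subset",
    "write_sam_subset",
    "write_fastq",
    "parse_cigar_clips",
]


class FormatError(ValueError):
    """Malformed record, reported with its line number."""


# -- FASTA ------------------------------------------------------------------


def write_fasta(refs, path, width: int = 70) -> None:
    refs = [refs] if isinstance(refs, ReferenceSequence) else list(refs)
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.name} offset={ref.offset}\n")
            for i in range(0, len(ref.bases), width):
                fh.write(ref.bases[i : i + width] + "\n")


def read_fasta(path) -> list[ReferenceSequence]:
    refs: list[ReferenceSequence] = []
    name, offset, chunks = None, 1, []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    refs.append(ReferenceSequence(name, offset, "".join(chunks)))
                fields = line[1:].split()
                if not fields:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                name, offset, chunks = fields[0], 1, []
                for f in fields[1:]:
                    if f.startswith("offset="):
                        offset = int(f.split("=", 1)[1])
            elif line:
                if name is None:
                    raise FormatError(f"line {lineno}: sequence before header")
                chunks.append(line.upper())
    if name is not None:
        refs.append(ReferenceSequence(name, offset, "".join(chunks)))
    return refs


# -- phenotype TSV ----------------------------------------------------------


def write_pheno_tsv(y: PhenotypeVector, path) -> None:
    df = pd.DataFrame({"id": y.samples, "score": y.scores})
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_pheno_tsv(path) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA"])
    if not {"id", "score"} <= set(df.columns):
        raise FormatError("phenotype TSV needs 'id' and 'score' columns")
    return PhenotypeVector(samples=df["id"].tolist(),
                           scores=df["score"].to_numpy(float))


# -- VCF subset -------------------------------------------------------------


def write_vcf_subset(geno: GenotypeMatrix, path) -> None:
    """GT-only VCF 4.2; phased calls use '|', unphased '/', missing '.'."""
    mk = geno.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=coatmap\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(mk["chrom"]):
            maxpos = int(mk.loc[mk["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for j in range(geno.n_markers):
            row = mk.iloc[j]
            gts = []
            for i in range(geno.n_samples):
                if geno.phased:
                    h = geno.haplotypes[i, :, j]
                    gts.append("." if h[0] < 0 else f"{h[0]}|{h[1]}")
                else:
                    d = geno.dosages[i, j]
                    if np.isnan(d):
                        gts.append("./.")
                    else:
                        d = int(d)
                        gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf_subset(path) -> GenotypeMatrix:
    """Read a GT-only VCF via cyvcf2; phase is preserved when uniform."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, ids, refs, alts = [], [], [], [], []
    dosage_cols = []
    hap_cols = []
    all_phased = True
    for var in vcf:
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        g = np.array([row[:3] for row in var.genotypes], dtype=int)
        a, b, ph = g[:, 0], g[:, 1], g[:, 2]
        miss = (a < 0) | (b < 0)
        dose = (a + b).astype(float)
        dose[miss] = np.nan
        dosage_cols.append(dose)
        if not np.all(ph[~miss] == 1) or miss.all():
            all_phased = False
        h = np.stack([a, b], axis=1).astype(np.int8)
        h[miss] = -1
        hap_cols.append(h)
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "id": ids, "ref": refs, "alt": alts}
    )
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    # hap_cols entries are (n, 2); stack -> (m, n, 2) -> want (n, 2, m)
    haplotypes = np.stack(hap_cols, axis=0).transpose(1, 2, 0) if hap_cols else None
    return GenotypeMatrix(
        samples=samples,
        markers=markers,
        dosages=dosages,
        haplotypes=haplotypes if all_phased else None,
    )


# -- SAM subset -------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar_clips(cigar: str) -> tuple[int, int, int]:
    """(left clip, reference span, right clip) of a CIGAR string.

    Soft and hard clips both count as clip; M/=/X/D/N consume reference.
    """
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise FormatError(f"malformed CIGAR: {cigar!r}")
    left = 0
    i = 0
    while i < len(ops) and ops[i][1] in "SH":
        left += int(ops[i][0])
        i += 1
    right = 0
    j = len(ops) - 1
    while j >= i and ops[j][1] in "SH":
        right += int(ops[j][0])
        j -= 1
    span = sum(int(n) for n, o in ops[i : j + 1] if o in "M=XDN")
    return left, span, right


def write_sam_subset(alignments: list[AlignedRead], contigs: dict[str, int], path) -> None:
    """Write alignments as SAM; ``contigs`` maps name -> declared length."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for a in alignments:
            flag = 0
            if a.mate in (1, 2):
                flag |= 0x1 | (0x40 if a.mate == 1 else 0x80)
                if a.mate_contig is not None:
                    flag |= 0x20 if a.mate_strand == "-" else 0
                else:
                    flag |= 0x8
            if a.strand == "-":
                flag |= 0x10
            if a.supplementary:
                flag |= 0x800
            cigar = ""
            if a.clip_left:
                cigar += f"{a.clip_left}S"
            cigar += f"{a.span}M"
            if a.clip_right:
                cigar += f"{a.clip_right}S"
            rnext = "*"
            pnext = 0
            if a.mate_contig is not None:
                rnext = "=" if a.mate_contig == a.contig else a.mate_contig
                pnext = a.mate_pos
            fh.write(
                f"{a.read_id}\t{flag}\t{a.contig}\t{a.pos}\t{a.mapq}\t{cigar}\t"
                f"{rnext}\t{pnext}\t{a.tlen}\t*\t*\n"
            )


def read_sam_subset(path) -> list[AlignedRead]:
    """Read a SAM subset via pysam into :class:`AlignedRead` records."""
    import pysam

    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            left, span, right = parse_cigar_clips(rec.cigarstring)
            mate = 1 if rec.is_read1 else 2 if rec.is_read2 else 0
            out.append(
                AlignedRead(
                    read_id=rec.query_name,
                    contig=rec.reference_name,
                    pos=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    clip_left=left,
                    clip_right=right,
                    span=span,
                    mapq=rec.mapping_quality,
                    mate=mate,
                    supplementary=rec.is_supplementary,
                    mate_contig=(
                        None
                        if rec.mate_is_unmapped or rec.next_reference_id < 0
                        else rec.next_reference_name
                    ),
                    mate_pos=(
                        None if rec.mate_is_unmapped else rec.next_reference_start + 1
                    ),
                    mate_strand=(
                        None
                        if rec.mate_is_unmapped
                        else ("-" if rec.mate_is_reverse else "+")
                    ),
                    tlen=rec.template_length,
                )
            )
    return out


# -- FASTQ ------------------------------------------------------------------


def write_fastq(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            suffix = f"/{r.mate}" if r.mate else ""
            q = chr(min(126, r.quality + 33)) * len(r.sequence)
            fh.write(f"@{r.read_id}{suffix}\n{r.sequence}\n+\n{q}\n")
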