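"""End-to-end orchestration: simulate -> QC -> GWAS -> dominance -> haplotypes
-> SV scan -> hypothesis ranking, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assoc, haplo, io, qtl_effects, svsig, synthdata

__all__ = ["PipelineConfig", "run_end_to_end"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run; fully serializable."""

    seed: int = 1
    # cohort
    n_individuals: int = 432
    n_chromosomes: int = 5
    markers_per_chrom: int = 120
    # QTL (counted = alternative allele)
    qtl_freq: float = synthdata.DEFAULT_QTL_P
    qtl_alpha: float = synthdata.DEFAULT_ALPHA
    qtl_d: float = synthdata.DEFAULT_D
    resid_var: float = synthdata.DEFAULT_RESID_VAR
    use_rater_model: bool = True
    # QC
    min_call_rate: float = 0.90
    min_maf: float = 0.02
    # haplotype block
    block_markers: int = 24
    min_hap_freq: float = 0.05
    # SV stage (desk-scale window mirroring the candidate rearrangement)
    sv_ref_offset: int = 63_590_000
    sv_ref_length: int = 40_000
    sv_del_start: int = 63_599_803
    sv_del_end: int = 63_600_957
    sv_source_start: int = 63_592_000
    sv_source_end: int = 63_592_149
    sv_coverage: float = 10.0
    sv_read_len: int = 100
    sv_insert_mean: float = 350.0
    sv_insert_sd: float = 35.0
    sv_error_rate: float = 0.001

    def validate(self) -> None:
        if self.n_individuals < 2 or self.markers_per_chrom < 2:
            raise ValueError("cohort too small")
        if not 0.0 < self.qtl_freq < 1.0:
            raise ValueError("qtl_freq must be in (0, 1)")
        for t in (self.min_call_rate, self.min_maf, self.min_hap_freq):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        if self.resid_var < 0:
            raise ValueError("resid_var must be non-negative")
        if not (
            self.sv_ref_offset
            <= self.sv_source_start
            <= self.sv_source_end
            < self.sv_del_start
            <= self.sv_del_end
            <= self.sv_ref_offset + self.sv_ref_length - 1
        ):
            raise ValueError("SV intervals do not fit inside the SV reference")
        if self.sv_read_len >= self.sv_insert_mean:
            raise ValueError("read length must be below the mean insert")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_end_to_end(config: PipelineConfig, outdir) -> dict:
    """Run the whole pipeline and return (and write) the run manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "coatmap_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }

    # --- stage: simulate cohort ---------------------------------------------
    m = config.n_chromosomes * config.markers_per_chrom
    chroms = [
        str(c + 1)
        for c in range(config.n_chromosomes)
        for _ in range(config.markers_per_chrom)
    ]
    freqs = rng.uniform(0.05, 0.95, size=m)
    qtl_idx = m // 2  # middle of chromosome ceil(n/2)
    freqs[qtl_idx] = config.qtl_freq
    geno = synthdata.simulate_genotypes(
        config.n_individuals, m, freqs, seed=int(rng.integers(2**31)), chroms=chroms
    )
    qtl_marker = geno.markers.loc[qtl_idx, "id"]
    geno, founder_haps, block_iv = synthdata.plant_haplotype_block(
        geno, qtl_marker, config.block_markers, seed=int(rng.integers(2**31))
    )
    qtl = synthdata.QTLSpec.from_alpha(config.qtl_freq, config.qtl_alpha, config.qtl_d)
    rater = synthdata.RaterModel() if config.use_rater_model else None
    y = synthdata.simulate_phenotypes(
        geno, qtl, qtl_marker, seed=int(rng.integers(2**31)),
        resid_var=config.resid_var, rater=rater,
    )
    vcf_path = outdir / "genotypes.vcf"
    pheno_path = outdir / "phenotypes.tsv"
    io.write_vcf_subset(geno, vcf_path)
    io.write_pheno_tsv(y, pheno_path)
    manifest["stages"]["simulate"] = {
        "qtl_marker": qtl_marker,
        "n_markers": m,
        "founder_haplotypes": founder_haps,
        "block": {"chrom": block_iv[0], "start": block_iv[1], "end": block_iv[2]},
    }

    # --- stage: QC + GWAS ----------------------------------------------------
    geno_qc, qc_report = assoc.qc_filter(
        geno, min_call_rate=config.min_call_rate, min_maf=config.min_maf
    )
    scan = assoc.mlma_scan(y, geno_qc, loco=True)
    lam = assoc.inflation_factor(scan.table["chisq"].dropna())
    top = scan.top_hit()
    cond = assoc.conditional_scan(y, geno_qc, fixed_marker=top["id"], loco=True)
    assoc_path = outdir / "assoc.tsv"
    scan.table.to_csv(assoc_path, sep="\t", index=False, na_rep="NA",
                      float_format="%.6g")
    cond_path = outdir / "assoc_conditional.tsv"
    cond.table.to_csv(cond_path, sep="\t", index=False, na_rep="NA",
                      float_format="%.6g")
    manifest["stages"]["gwas"] = {
        "n_markers_after_qc": int(geno_qc.n_markers),
        "inflation_factor": round(float(lam), 4),
        "top_marker": str(top["id"]),
        "top_p": float(top["p"]),
        "conditional_min_p": float(cond.table["p"].min()),
    }

    # --- stage: dominance at the top hit -------------------------------------
    jtop = geno_qc.marker_index(top["id"])
    fit = qtl_effects.fit_additive_dominance(y, geno_qc.dosages[:, jtop])
    dom_path = outdir / "dominance.tsv"
    pd.DataFrame(
        [{
            "marker": top["id"], "mu": fit.mu, "alpha": fit.alpha,
            "alpha_se": fit.alpha_se, "alpha_p": fit.alpha_p, "d": fit.d,
            "d_se": fit.d_se, "d_p": fit.d_p, "r2": fit.r2, "a": fit.a,
        }]
    ).to_csv(dom_path, sep="\t", index=False, float_format="%.6g")
    manifest["stages"]["dominance"] = {
        "alpha": round(fit.alpha, 4), "d": round(fit.d, 4), "r2": round(fit.r2, 4)
    }

    # --- stage: haplotype block at the planted interval -----------------------
    table = haplo.extract_haplotypes(geno_qc, *block_iv)
    grouped = haplo.group_rare(table, min_freq=config.min_hap_freq)
    summaries = haplo.phenotype_by_haplotype(grouped, geno_qc, y)
    hap_path = outdir / "haplotypes.tsv"
    grouped.to_frame().to_csv(hap_path, sep="\t", index=False, float_format="%.6g")
    hap_sum_path = outdir / "haplotype_phenotypes.tsv"
    summaries.to_csv(hap_sum_path, sep="\t", index=False, na_rep="NA",
                     float_format="%.6g")
    manifest["stages"]["haplo"] = {
        "block_size": grouped.block_size,
        "n_alleles": len(table.counts),
        "named": {grouped.labels[a]: c for a, c in grouped.counts.items()},
    }

    # --- stage: SV signature + hypothesis ranking ----------------------------
    sv_ref = synthdata.simulate_reference(
        "CHR13", config.sv_ref_offset, config.sv_ref_length,
        seed=int(rng.integers(2**31)),
    )
    truth = svsig.RearrangementEdit(
        operations=[
            svsig.Deletion(config.sv_del_start, config.sv_del_end),
            svsig.InvertedDupInsertion(
                config.sv_source_start, config.sv_source_end, config.sv_del_start
            ),
        ],
        name="del+invdup",
    )
    mutant, _ = svsig.apply_edits(sv_ref, truth)
    reads = synthdata.simulate_paired_reads(
        mutant, config.sv_coverage, config.sv_read_len, config.sv_insert_mean,
        config.sv_insert_sd, config.sv_error_rate,
        seed=int(rng.integers(2**31)), haplotype="mut",
    )
    index = svsig.ReferenceIndex(sv_ref)
    alns = svsig.map_reads(reads, sv_ref, index=index)
    sig = svsig.signature_profile(alns, sv_ref)
    five, three, depth_iv = svsig.locate_deletion_breakpoints(alns, sv_ref)
    candidates = [
        svsig.RearrangementEdit(operations=[], name="identity"),
        svsig.RearrangementEdit(
            operations=[svsig.Deletion(config.sv_del_start, config.sv_del_end)],
            name="deletion-only",
        ),
        truth,
    ]
    ranking = svsig.rank_hypotheses(
        sig, sv_ref, candidates, seed=int(rng.integers(2**31)),
        coverage=config.sv_coverage, read_len=config.sv_read_len,
        insert_mean=config.sv_insert_mean, insert_sd=config.sv_insert_sd,
        error_rate=config.sv_error_rate, index=index,
    )
    call = svsig.genotype_sv(sig, (config.sv_del_start, config.sv_del_end))
    rank_path = outdir / "sv_hypotheses.tsv"
    ranking.to_csv(rank_path, sep="\t", index=False, float_format="%.6g")
    manifest["stages"]["svsig"] = {
        "five_prime_junction": five,
        "three_prime_junction": three,
        "depth_interval": list(depth_iv),
        "best_hypothesis": ranking.loc[0, "candidate"],
        "genotype": call.genotype,
        "pair_counts": sig.pair_counts,
    }

    # --- manifest -------------------------------------------------------------
    for p in (vcf_path, pheno_path, assoc_path, cond_path, dom_path, hap_path,
              hap_sum_path, rank_path):
        manifest["outputs"][p.name] = _sha256(p)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
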