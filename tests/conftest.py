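import numpy as np
import pandas as pd
import pytest

from coatmap import svsig, synthdata as sd
from coatmap.types import GenotypeMatrix

# Canonical rearrangement geometry used across SV tests: a 1155-bp deletion
# whose gap is filled by the reverse complement of a 150-bp segment duplicated
# from elsewhere on the same contig.
DEL_START, DEL_END = 63_599_803, 63_600_957
SRC_START, SRC_END = 63_592_000, 63_592_149


@pytest.fixture(scope="session")
def sv_ref():
    """40-kb random reference containing both SV loci."""
    return sd.simulate_reference("CHR13", 63_590_000, 40_000, seed=7)


@pytest.fixture(scope="session")
def sv_edit():
    return svsig.RearrangementEdit(
        operations=[
            svsig.Deletion(DEL_START, DEL_END),
            svsig.InvertedDupInsertion(SRC_START, SRC_END, DEL_START),
        ],
        name="del+invdup",
    )


@pytest.fixture(scope="session")
def sv_mutant(sv_ref, sv_edit):
    mutant, cmap = svsig.apply_edits(sv_ref, sv_edit)
    return mutant, cmap


@pytest.fixture(scope="session")
def sv_alignments(sv_ref, sv_mutant):
    """Mutant reads at 10x mapped back to the wild-type reference."""
    mutant, _ = sv_mutant
    reads = sd.simulate_paired_reads(
        mutant, 10, 100, 350, 35, error_rate=0.001, seed=31, haplotype="mut"
    )
    return svsig.map_reads(reads, sv_ref)


def toy_genotypes(dosages, chrom="1", phased=False):
    """GenotypeMatrix from an explicit n x m dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1) * 100,
            "id": [f"m{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    haps = None
    if phased:
        haps = np.zeros((n, 2, m), dtype=np.int8)
        haps[:, 0, :] = (dosages >= 1).astype(np.int8)
        haps[:, 1, :] = (dosages >= 2).astype(np.int8)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        markers=markers,
        dosages=dosages,
        haplotypes=haps,
    )
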