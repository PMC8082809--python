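import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coatmap import svsig, synthdata as sd
from coatmap.types import Read, ReadSet

from conftest import DEL_END, DEL_START, SRC_END, SRC_START


class TestRevcomp:
    def test_palindrome_and_hand_case(self):
        assert svsig.revcomp("ACGT") == "ACGT"
        # motif of the in-frame deletion in the gene's last exon
        assert svsig.revcomp("CGGACC") == "GGTCCG"

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=200))
    @settings(deadline=None, max_examples=50)
    def test_involution(self, s):
        assert svsig.revcomp(svsig.revcomp(s)) == s

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            svsig.revcomp("ACGU")


class TestIntervalLength:
    @pytest.mark.parametrize(
        "start,end,length",
        [
            (63_599_803, 63_600_957, 1155),  # the mapped deletion
            (63_667_797, 63_667_802, 6),  # in-frame deletion in the last exon
            (63_283_374, 63_283_523, 150),  # duplicated source fragment
            (5, 5, 1),
        ],
    )
    def test_closed_interval_arithmetic(self, start, end, length):
        assert svsig.interval_length(start, end) == length

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            svsig.interval_length(10, 9)


class TestApplyEdits:
    def test_deletion_shortens_by_interval_length(self, sv_ref):
        edit = svsig.RearrangementEdit([svsig.Deletion(DEL_START, DEL_END)])
        mutant, _ = svsig.apply_edits(sv_ref, edit)
        assert len(sv_ref) - len(mutant) == 1155

    def test_inverted_dup_insert_is_revcomp_of_source(self, sv_ref):
        edit = svsig.RearrangementEdit(
            [svsig.InvertedDupInsertion(SRC_START, SRC_END, DEL_START)]
        )
        mutant, cmap = svsig.apply_edits(sv_ref, edit)
        assert len(mutant) - len(sv_ref) == 150
        src = sv_ref.slice_genomic(SRC_START, SRC_END)
        ins_local = DEL_START - sv_ref.offset
        assert mutant.bases[ins_local : ins_local + 150] == svsig.revcomp(src)
        # source copy untouched
        assert mutant.bases[: SRC_END - sv_ref.offset + 1] == sv_ref.bases[
            : SRC_END - sv_ref.offset + 1
        ]

    def test_empty_edit_is_identity(self, sv_ref):
        mutant, cmap = svsig.apply_edits(sv_ref, svsig.RearrangementEdit([]))
        assert mutant.bases == sv_ref.bases
        for pos in (sv_ref.start, sv_ref.start + 1234, sv_ref.end):
            assert cmap.ref_to_mut(pos) == pos
            assert cmap.mut_to_ref(pos) == pos

    def test_full_rearrangement_bookkeeping(self, sv_ref, sv_edit, sv_mutant):
        mutant, cmap = sv_mutant
        assert len(sv_ref) - len(mutant) == 1155 - 150
        # retained base round-trips; deleted base maps to None
        for pos in (sv_ref.start, DEL_START - 1, DEL_END + 1, sv_ref.end):
            m = cmap.ref_to_mut(pos)
            assert m is not None and cmap.mut_to_ref(m) == pos
        assert cmap.ref_to_mut(DEL_START) is None
        assert cmap.ref_to_mut(DEL_END) is None
        # inserted bases map to None on the way back
        assert cmap.mut_to_ref(DEL_START) is None

    @given(st.data())
    @settings(deadline=None, max_examples=25)
    def test_coordinate_roundtrip_property(self, data):
        ref = sd.simulate_reference("r", 1000, 500, seed=3)
        s = data.draw(st.integers(1000, 1400))
        e = data.draw(st.integers(s, 1499))
        edit = svsig.RearrangementEdit([svsig.Deletion(s, e)])
        mutant, cmap = svsig.apply_edits(ref, edit)
        pos = data.draw(st.integers(1000, 1499))
        m = cmap.ref_to_mut(pos)
        if s <= pos <= e:
            assert m is None
        else:
            assert cmap.mut_to_ref(m) == pos

    def test_overlapping_and_out_of_bounds_rejected(self, sv_ref):
        with pytest.raises(ValueError):
            svsig.apply_edits(
                sv_ref,
                svsig.RearrangementEdit(
                    [svsig.Deletion(DEL_START, DEL_END),
                     svsig.Deletion(DEL_END - 10, DEL_END + 10)]
                ),
            )
        with pytest.raises((ValueError, IndexError)):
            svsig.apply_edits(
                sv_ref,
                svsig.RearrangementEdit([svsig.Deletion(1, 10)]),
            )


def _reads_from(specs, paired=False):
    return ReadSet(
        reads=[
            Read(read_id=f"r{i}", sequence=s, quality=30, mate=m,
                 origin_contig="CHR13", origin_start=o, origin_strand=st_)
            for i, (s, m, o, st_) in enumerate(specs)
        ],
        paired=paired,
    )


class TestMapReads:
    def test_error_free_reads_map_perfectly(self, sv_ref):
        reads = sd.simulate_paired_reads(sv_ref, 2, 100, 350, 35, 0.0, seed=41)
        alns = svsig.map_reads(reads, sv_ref)
        prim = {(a.read_id, a.mate): a for a in alns if not a.supplementary}
        assert len(prim) == len(reads)
        for r in reads:
            a = prim[(r.read_id, r.mate)]
            assert a.pos == r.origin_start
            assert a.strand == r.origin_strand
            assert a.clip_left == 0 and a.clip_right == 0

    def test_clip_lengths_plus_span_equal_read_length(self, sv_alignments):
        for a in sv_alignments:
            assert a.clip_left + a.span + a.clip_right == 100

    def test_junction_read_soft_clipped_at_the_break(self, sv_ref):
        # 60 bases of left flank + 40 bases of foreign sequence
        flank = sv_ref.slice_genomic(DEL_START - 60, DEL_START - 1)
        foreign = "ACGT" * 10
        reads = _reads_from([(flank + foreign, 0, DEL_START - 60, "+")])
        alns = svsig.map_reads(reads, sv_ref)
        a = [x for x in alns if not x.supplementary][0]
        assert a.pos == DEL_START - 60
        assert a.span >= 60
        assert a.clip_right >= 35  # clipped at (or within homology of) the junction

    def test_read_inside_duplicated_fragment_emits_chimeric_record(
        self, sv_ref, sv_mutant
    ):
        mutant, _ = sv_mutant
        # read spanning flank + inserted copy: primary on the flank, the
        # inserted part maps to the distant source locus as a supplementary
        loc = DEL_START - sv_ref.offset
        seq = mutant.bases[loc - 60 : loc + 40]
        alns = svsig.map_reads(
            _reads_from([(seq, 0, DEL_START - 60, "+")]), sv_ref
        )
        supp = [a for a in alns if a.supplementary]
        assert len(supp) == 1
        assert SRC_START - 10 <= supp[0].pos <= SRC_END
        assert supp[0].strand == "-"

    def test_anchor_longer_than_read_rejected(self, sv_ref):
        with pytest.raises(ValueError):
            svsig.map_reads(_reads_from([("ACGTACGT", 0, 1, "+")]), sv_ref, k=31)


class TestClassifyPairs:
    def test_clean_library_is_inward_only(self, sv_ref):
        reads = sd.simulate_paired_reads(sv_ref, 2, 100, 350, 35, 0.0, seed=42)
        pairs = svsig.classify_pairs(svsig.map_reads(reads, sv_ref))
        assert set(pairs["klass"]) == {"RL"}
        assert pairs["insert"].mean() == pytest.approx(350, abs=5)

    def test_mutant_reads_on_wildtype_show_rr_ll_with_long_inserts(
        self, sv_alignments
    ):
        pairs = svsig.classify_pairs(sv_alignments)
        odd = pairs[pairs["klass"].isin(["RR", "LL"])]
        assert len(odd) >= 3
        # inserts approach the breakpoint-to-source span (minus one library
        # insert of slack, since the flank-side mate sits near the junction)
        assert (odd["insert"] >= DEL_START - SRC_END - 1000).all()
        assert odd["insert"].median() >= DEL_START - SRC_END - 400

    def test_both_mates_forward_is_rr(self, sv_ref):
        s1 = sv_ref.slice_genomic(63_591_000, 63_591_099)
        s2 = sv_ref.slice_genomic(63_595_000, 63_595_099)
        rs = ReadSet(
            reads=[
                Read("pair0", s1, 30, 1, "CHR13", 63_591_000, "+"),
                Read("pair0", s2, 30, 2, "CHR13", 63_595_000, "+"),
            ],
            paired=True,
        )
        pairs = svsig.classify_pairs(svsig.map_reads(rs, sv_ref))
        assert pairs["klass"].item() == "RR"


class TestClipsAndDepth:
    def test_no_clips_gives_empty_clusters(self, sv_ref):
        reads = sd.simulate_paired_reads(sv_ref, 1, 100, 350, 35, 0.0, seed=43)
        clips, anchors = svsig.cluster_clips(svsig.map_reads(reads, sv_ref))
        assert clips == [] and anchors == []

    def test_ten_reads_clipped_at_one_base_form_one_cluster(self, sv_ref):
        flank_start = 63_594_000
        specs = []
        for off in range(10):
            flank = sv_ref.slice_genomic(flank_start - off, flank_start + 59)
            specs.append((flank + "TTTT" * 10, 0, flank_start - off, "+"))
        clips, _ = svsig.cluster_clips(
            svsig.map_reads(_reads_from(specs), sv_ref)
        )
        right = [c for c in clips if c.side == "right"]
        assert len(right) == 1
        assert right[0].support == 10
        assert abs(right[0].coord - (flank_start + 60)) <= 2

    def test_sv_simulation_clusters_at_breakpoints_and_source(
        self, sv_alignments
    ):
        clips, anchors = svsig.cluster_clips(sv_alignments)
        right = [c.coord for c in clips if c.side == "right"]
        left = [c.coord for c in clips if c.side == "left"]
        assert any(abs(c - DEL_START) <= 100 for c in right)
        assert any(abs(c - (DEL_END + 1)) <= 100 for c in left)
        assert anchors
        assert any(
            SRC_START - 200 <= a.coord <= SRC_END + 200
            or DEL_START - 200 <= a.coord <= DEL_END + 200
            for a in anchors
        )

    def test_uniform_coverage_yields_no_deletion_candidates(self, sv_ref):
        reads = sd.simulate_paired_reads(sv_ref, 10, 100, 350, 35, 0.001, seed=44)
        cands, _ = svsig.depth_scan(svsig.map_reads(reads, sv_ref), sv_ref)
        assert cands == []

    def test_homozygous_deletion_detected(self, sv_ref, sv_alignments):
        cands, _ = svsig.depth_scan(sv_alignments, sv_ref, min_ratio=0.5)
        assert any(
            s <= DEL_START <= e or s <= DEL_END <= e or
            (DEL_START <= s and e <= DEL_END)
            for s, e, _ in cands
        )

    def test_heterozygous_deletion_depth_ratio_near_half(self, sv_ref):
        delonly = svsig.RearrangementEdit([svsig.Deletion(DEL_START, DEL_END)])
        mutant, _ = svsig.apply_edits(sv_ref, delonly)
        r_mut = sd.simulate_paired_reads(mutant, 5, 100, 350, 35, 0.001, seed=45)
        r_wt = sd.simulate_paired_reads(sv_ref, 5, 100, 350, 35, 0.001, seed=46,
                                        haplotype="wt")
        alns = svsig.map_reads(
            ReadSet(
                reads=[
                    # mates keep distinct ids across the two sets
                    Read(r.read_id + "_m", r.sequence, r.quality, r.mate,
                         r.origin_contig, r.origin_start, r.origin_strand)
                    for r in r_mut
                ] + list(r_wt.reads),
                paired=True,
            ),
            sv_ref,
        )
        _, norm = svsig.depth_scan(alns, sv_ref, window=200)
        lo = (DEL_START - sv_ref.offset) // 200 + 1
        hi = (DEL_END - sv_ref.offset) // 200
        inside = norm[lo:hi]
        assert inside.mean() == pytest.approx(0.5, abs=0.15)


class TestSignature:
    def test_identical_signatures_have_zero_distance(self, sv_ref, sv_alignments):
        sig = svsig.signature_profile(sv_alignments, sv_ref)
        assert svsig.signature_distance(sig, sig) == 0.0

    def test_distance_symmetric_and_discriminates(self, sv_ref, sv_alignments):
        sig_mut = svsig.signature_profile(sv_alignments, sv_ref)
        delonly = svsig.RearrangementEdit([svsig.Deletion(DEL_START, DEL_END)])
        mutant, _ = svsig.apply_edits(sv_ref, delonly)
        reads = sd.simulate_paired_reads(mutant, 10, 100, 350, 35, 0.001, seed=47)
        sig_del = svsig.signature_profile(svsig.map_reads(reads, sv_ref), sv_ref)
        d1 = svsig.signature_distance(sig_mut, sig_del)
        d2 = svsig.signature_distance(sig_del, sig_mut)
        assert d1 == pytest.approx(d2)
        assert d1 > 0

    def test_signature_counts_additive_over_merged_readsets(self, sv_ref):
        r1 = sd.simulate_paired_reads(sv_ref, 2, 100, 350, 35, 0.0, seed=48)
        r2 = sd.simulate_paired_reads(sv_ref, 2, 100, 350, 35, 0.0, seed=49)
        renamed = [
            Read(r.read_id + "_b", r.sequence, r.quality, r.mate,
                 r.origin_contig, r.origin_start, r.origin_strand)
            for r in r2
        ]
        sig1 = svsig.signature_profile(svsig.map_reads(r1, sv_ref), sv_ref)
        sig2 = svsig.signature_profile(svsig.map_reads(r2, sv_ref), sv_ref)
        merged = ReadSet(reads=list(r1.reads) + renamed, paired=True)
        sig12 = svsig.signature_profile(svsig.map_reads(merged, sv_ref), sv_ref)
        for k in sig12.pair_counts:
            assert sig12.pair_counts[k] == sig1.pair_counts[k] + sig2.pair_counts[k]


class TestRankHypotheses:
    def test_true_rearrangement_beats_deletion_only(
        self, sv_ref, sv_edit, sv_mutant
    ):
        mutant, _ = sv_mutant
        index = svsig.ReferenceIndex(sv_ref)
        delonly = svsig.RearrangementEdit(
            [svsig.Deletion(DEL_START, DEL_END)], name="deletion-only"
        )
        wins = 0
        n_seeds = 10
        for s in range(n_seeds):
            reads = sd.simulate_paired_reads(
                mutant, 10, 100, 350, 35, 0.001, seed=500 + s
            )
            obs = svsig.signature_profile(
                svsig.map_reads(reads, sv_ref, index=index), sv_ref
            )
            ranking = svsig.rank_hypotheses(
                obs, sv_ref, [delonly, sv_edit], seed=900 + s, index=index
            )
            wins += ranking.loc[0, "candidate"] == "del+invdup"
        assert wins >= 9  # >= 90% of seeds

    def test_wildtype_observation_prefers_identity(self, sv_ref):
        reads = sd.simulate_paired_reads(sv_ref, 10, 100, 350, 35, 0.001, seed=50)
        index = svsig.ReferenceIndex(sv_ref)
        obs = svsig.signature_profile(
            svsig.map_reads(reads, sv_ref, index=index), sv_ref
        )
        cands = [
            svsig.RearrangementEdit([], name="identity"),
            svsig.RearrangementEdit(
                [svsig.Deletion(DEL_START, DEL_END)], name="deletion-only"
            ),
        ]
        ranking = svsig.rank_hypotheses(obs, sv_ref, cands, seed=51, index=index)
        assert ranking.loc[0, "candidate"] == "identity"

    def test_duplicate_candidates_score_identically_and_order_invariant(
        self, sv_ref, sv_edit
    ):
        index = svsig.ReferenceIndex(sv_ref)
        reads = sd.simulate_paired_reads(sv_ref, 5, 100, 350, 35, 0.001, seed=52)
        obs = svsig.signature_profile(
            svsig.map_reads(reads, sv_ref, index=index), sv_ref
        )
        a = svsig.RearrangementEdit([svsig.Deletion(DEL_START, DEL_END)], name="A")
        b = svsig.RearrangementEdit([svsig.Deletion(DEL_START, DEL_END)], name="B")
        r1 = svsig.rank_hypotheses(obs, sv_ref, [a, b], seed=53, index=index)
        r2 = svsig.rank_hypotheses(obs, sv_ref, [b, a], seed=53, index=index)
        assert r1.loc[0, "distance"] == pytest.approx(r1.loc[1, "distance"])
        assert list(r1["candidate"]) == list(r2["candidate"])

    def test_invalid_candidate_scores_infinite(self, sv_ref):
        reads = sd.simulate_paired_reads(sv_ref, 2, 100, 350, 35, 0.0, seed=54)
        obs = svsig.signature_profile(svsig.map_reads(reads, sv_ref), sv_ref)
        bad = svsig.RearrangementEdit([svsig.Deletion(1, 10)], name="oob")
        ranking = svsig.rank_hypotheses(obs, sv_ref, [bad], seed=55)
        assert np.isinf(ranking.loc[0, "distance"])
        assert ranking.loc[0, "note"] != ""


class TestBreakpointLocalizer:
    def test_recovers_both_junctions(self, sv_ref, sv_alignments):
        five, three, iv = svsig.locate_deletion_breakpoints(
            sv_alignments, sv_ref
        )
        # alignment evidence can shift junctions by chance micro-homology
        assert abs(five - DEL_START) <= 10
        assert abs(three - (DEL_END + 1)) <= 10
        assert iv[0] <= DEL_START and iv[1] >= DEL_END


@pytest.fixture(scope="module")
def junction_setup(sv_ref, sv_edit):
    mutant, _ = svsig.apply_edits(sv_ref, sv_edit)
    delonly = svsig.RearrangementEdit([svsig.Deletion(DEL_START, DEL_END)])
    del_ref, dmap = svsig.apply_edits(sv_ref, delonly)
    junction = dmap.ref_to_mut(DEL_END + 1)
    return mutant, del_ref, junction


class TestLongReadJunction:
    def test_error_free_estimates_exactly_150(self, junction_setup):
        mutant, del_ref, junction = junction_setup
        zero = sd.LongReadErrorModel(0, 0, 0)
        reads = sd.simulate_long_reads(mutant, 3, 5700, seed=60, error_model=zero)
        est = svsig.long_read_junction_insert(reads, del_ref, junction)
        assert est and all(e == 150.0 for e in est)

    def test_ont_errors_scatter_around_150(self, junction_setup):
        mutant, del_ref, junction = junction_setup
        ont = sd.LongReadErrorModel(mismatch=0.03, insertion=0.03, deletion=0.05)
        ests = []
        for s in range(4):
            reads = sd.simulate_long_reads(
                mutant, 8.73, 5700, seed=61 + s, error_model=ont
            )
            ests.extend(svsig.long_read_junction_insert(reads, del_ref, junction))
        ests = np.asarray(ests)
        assert len(ests) >= 10
        assert abs(np.median(ests) - 150) < 25
        assert np.all(np.abs(ests - 150) < 80)

    def test_wildtype_reads_show_the_full_deletion_as_insertion(
        self, sv_ref, junction_setup
    ):
        _, del_ref, junction = junction_setup
        zero = sd.LongReadErrorModel(0, 0, 0)
        reads = sd.simulate_long_reads(sv_ref, 8, 5700, seed=70, error_model=zero)
        est = svsig.long_read_junction_insert(reads, del_ref, junction)
        assert est and all(e > 1100 for e in est)

    def test_no_spanning_reads_is_an_error(self, junction_setup):
        _, del_ref, junction = junction_setup
        short = ReadSet(
            reads=[Read("x", del_ref.bases[:300], 12, 0, del_ref.name,
                        del_ref.offset, "+")]
        )
        with pytest.raises(ValueError):
            svsig.long_read_junction_insert(short, del_ref, junction)


class TestGenotypeSV:
    def test_clean_signature_is_hom_ref(self, sv_ref):
        reads = sd.simulate_paired_reads(sv_ref, 10, 100, 350, 35, 0.001, seed=80)
        sig = svsig.signature_profile(svsig.map_reads(reads, sv_ref), sv_ref)
        call = svsig.genotype_sv(sig, (DEL_START, DEL_END))
        assert call.genotype == "hom-ref"

    def test_homozygous_mutant_called(self, sv_ref, sv_alignments):
        sig = svsig.signature_profile(sv_alignments, sv_ref)
        call = svsig.genotype_sv(sig, (DEL_START, DEL_END))
        assert call.genotype == "hom-alt"

    def test_heterozygote_called_in_most_seeds(self, sv_ref, sv_mutant):
        mutant, _ = sv_mutant
        index = svsig.ReferenceIndex(sv_ref)
        het_calls = 0
        n_seeds = 5
        for s in range(n_seeds):
            r_mut = sd.simulate_paired_reads(
                mutant, 5, 100, 350, 35, 0.001, seed=700 + s
            )
            r_wt = sd.simulate_paired_reads(
                sv_ref, 5, 100, 350, 35, 0.001, seed=800 + s
            )
            merged = ReadSet(
                reads=[
                    Read(r.read_id + "_m", r.sequence, r.quality, r.mate,
                         r.origin_contig, r.origin_start, r.origin_strand)
                    for r in r_mut
                ] + list(r_wt.reads),
                paired=True,
            )
            sig = svsig.signature_profile(
                svsig.map_reads(merged, sv_ref, index=index), sv_ref
            )
            het_calls += svsig.genotype_sv(sig, (DEL_START, DEL_END)).genotype == "het"
        assert het_calls >= 4

    def test_sparse_window_yields_no_call(self, sv_ref):
        reads = sd.simulate_paired_reads(sv_ref, 10, 100, 350, 35, 0.001, seed=81)
        keep = ReadSet(reads=list(reads.reads)[:20], paired=True)
        sig = svsig.signature_profile(svsig.map_reads(keep, sv_ref), sv_ref)
        call = svsig.genotype_sv(sig, (DEL_START, DEL_END))
        assert call.genotype == "no-call"


class TestGenotypeR2:
    def test_identical_vectors_give_one(self):
        a = np.array([0, 1, 2, 1, 0, 2])
        assert svsig.genotype_r2(a, a) == pytest.approx(1.0)

    def test_independent_sites_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 10_000)
        b = rng.integers(0, 3, 10_000)
        assert svsig.genotype_r2(a, b) == pytest.approx(0.0, abs=0.01)

    def test_perfect_repulsion_closed_form(self):
        # haplotype counts: AB absent; r^2 = (pA pB)^2/(pA qA pB qB) for
        # dosages built from repulsed haplotypes
        # construct diploid dosages from haplotypes: site1 allele <-> not site2
        hapA = np.array([1, 1, 0, 0, 1, 0, 1, 0])
        hapB = 1 - hapA
        a = hapA[::2] + hapA[1::2]
        b = hapB[::2] + hapB[1::2]
        r = np.corrcoef(a, b)[0, 1]
        assert svsig.genotype_r2(a, b) == pytest.approx(r * r)
        assert svsig.genotype_r2(a, b) == pytest.approx(1.0)

    def test_monomorphic_site_gives_nan(self):
        assert np.isnan(svsig.genotype_r2([1, 1, 1], [0, 1, 2]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            svsig.genotype_r2([0, 1], [0, 1, 2])
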