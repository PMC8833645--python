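"""Unit and property tests for the two-stage TD detection."""

import pytest

from tdscan import (
    AlignedReadView,
    AlignmentStore,
    JunctionRegion,
    RunConfig,
    SimTDSpec,
    build_boundary_index,
    build_virtual_junction,
    evaluate_mate,
    frame_effect,
    scan_candidate_regions,
    select_region_reads,
    simulate_sample,
    verify_junction_read,
)
from tdscan.td_detect import parse_cigar

from conftest import td_spec


def make_read(pos, cigar, seq, flag=99, chrom="chrS", mapq=255, mate_pos=0, qname="r1"):
    return AlignedReadView(
        qname=qname, flag=flag, chrom=chrom, pos=pos, mapq=mapq,
        cigar=parse_cigar(cigar), seq=seq, mate_pos=mate_pos, isize=0,
    )


def region_and_vj(genome, first=3, last=5):
    gene = genome.gene("PTENL")
    exons = [gene.exon_by_ordinal(o) for o in range(first, last + 1)]
    region = JunctionRegion(
        chrom=gene.chrom, start=min(s for s, _ in exons), end=max(e for _, e in exons),
        gene_id=gene.gene_id, first_exon_ordinal=first, last_exon_ordinal=last,
    )
    return gene, region, build_virtual_junction(region, genome.reference)


def junction_read_at_3p(genome, region, clip, flag=99, mate_pos=0, read_len=75, qname="jr"):
    """Soft-clipped read ending exactly at the region 3' terminus."""
    ref = genome.reference
    matched = read_len - clip
    pos = region.end - matched + 1
    seq = ref.fetch(region.chrom, pos, region.end) + ref.fetch(
        region.chrom, region.start, region.start + clip - 1
    )
    return make_read(pos, f"{matched}M{clip}S", seq, flag=flag, mate_pos=mate_pos, qname=qname)


class TestCigarAndReadView:
    def test_parse_cigar(self):
        assert parse_cigar("50M25S") == (("M", 50), ("S", 25))
        assert parse_cigar("*") == ()
        with pytest.raises(ValueError):
            parse_cigar("50M25")

    def test_ref_end_and_clips(self):
        read = make_read(100, "10S50M200N15M", "A" * 75)
        assert read.ref_end == 100 + 50 + 200 + 15 - 1
        assert read.left_clip == 10 and read.right_clip == 0


class TestScanCandidates:
    def test_junction_read_proposes_exactly_its_region(self, pten_genome):
        """A clip at the exon-5 end matching the exon-3 start proposes exon3->5 only."""
        gene, region, _ = region_and_vj(pten_genome, 3, 5)
        read = junction_read_at_3p(pten_genome, region, clip=25)
        store = AlignmentStore([read])
        index = build_boundary_index(pten_genome.genes)
        regions = scan_candidate_regions(store, index, RunConfig(), pten_genome.reference)
        assert [(r.start, r.end, r.first_exon_ordinal, r.last_exon_ordinal) for r in regions] == [
            (region.start, region.end, 3, 5)
        ]

    def test_fully_matched_read_contributes_nothing(self, pten_genome):
        gene = pten_genome.gene("PTENL")
        pos = gene.exons[2][0]
        read = make_read(pos, "75M", pten_genome.reference.fetch(gene.chrom, pos, pos + 74))
        regions = scan_candidate_regions(
            AlignmentStore([read]), build_boundary_index(pten_genome.genes),
            RunConfig(), pten_genome.reference,
        )
        assert regions == []

    def test_one_bp_off_boundary_is_rejected(self, pten_genome):
        """Exact boundary matching: shifting the clip point by 1 bp kills the candidate."""
        gene, region, _ = region_and_vj(pten_genome, 3, 5)
        good = junction_read_at_3p(pten_genome, region, clip=25)
        shifted = make_read(good.pos - 1, "50M25S", good.seq)  # ref_end off by one
        regions = scan_candidate_regions(
            AlignmentStore([shifted]), build_boundary_index(pten_genome.genes),
            RunConfig(), pten_genome.reference,
        )
        assert regions == []

    def test_unsorted_input_is_fatal(self, pten_genome):
        r1 = make_read(500, "75M", "A" * 75)
        r2 = make_read(400, "75M", "A" * 75)
        with pytest.raises(ValueError, match="sorted"):
            AlignmentStore([r1, r2])


class TestVirtualJunction:
    def test_k_is_100_for_large_regions(self, pten_genome):
        _, region, vj = region_and_vj(pten_genome, 3, 5)
        assert region.size_bp == 7739
        assert len(vj.sequence) == 200
        ref = pten_genome.reference
        assert vj.sequence == (
            ref.fetch(region.chrom, region.end - 99, region.end)
            + ref.fetch(region.chrom, region.start, region.start + 99)
        )

    def test_k_min_rule_for_small_regions(self, three_exon_genome):
        """A region shorter than 100 bp uses K = region length (overlapping halves)."""
        gene = three_exon_genome.gene("TRI")
        s, e = gene.exon_by_ordinal(3)
        region = JunctionRegion(
            chrom=gene.chrom, start=s, end=e, gene_id=gene.gene_id,
            first_exon_ordinal=3, last_exon_ordinal=3,
        )
        vj = build_virtual_junction(region, three_exon_genome.reference)
        full = three_exon_genome.reference.fetch(gene.chrom, s, e)
        assert region.size_bp == 99
        assert vj.sequence == full + full
        assert len(vj.sequence) == 198


class TestSelectRegionReads:
    def _store(self, region, n, mapq=255):
        reads = [
            make_read(region.start + i, "75M", "A" * 75, mapq=mapq, qname=f"r{i}")
            for i in range(n)
        ]
        return AlignmentStore(reads)

    def test_cap_keeps_positional_first_and_last_halves(self, pten_genome):
        _, region, _ = region_and_vj(pten_genome, 3, 5)
        store = self._store(region, 5000)
        kept = select_region_reads(store, region, RunConfig())
        assert len(kept) == 4000
        positions = [r.pos for r in kept]
        assert positions[:2000] == [region.start + i for i in range(2000)]
        assert positions[2000:] == [region.start + i for i in range(3000, 5000)]

    def test_exactly_at_cap_keeps_all(self, pten_genome):
        _, region, _ = region_and_vj(pten_genome, 3, 5)
        kept = select_region_reads(self._store(region, 4000), region, RunConfig())
        assert len(kept) == 4000

    def test_low_mapq_excluded(self, pten_genome):
        _, region, _ = region_and_vj(pten_genome, 3, 5)
        assert select_region_reads(self._store(region, 10, mapq=3), region, RunConfig()) == []


class TestVerifyJunctionRead:
    def test_canonical_50m25s_verifies_anchored_3p(self, pten_genome):
        _, region, vj = region_and_vj(pten_genome, 3, 5)
        read = junction_read_at_3p(pten_genome, region, clip=25)
        assert verify_junction_read(read, vj, RunConfig()) == (True, "3p")

    def test_nine_clipped_bases_never_verify(self, pten_genome):
        _, region, vj = region_and_vj(pten_genome, 3, 5)
        read = junction_read_at_3p(pten_genome, region, clip=9)
        assert verify_junction_read(read, vj, RunConfig()) == (False, None)

    def test_single_clip_mismatch_fails(self, pten_genome):
        _, region, vj = region_and_vj(pten_genome, 3, 5)
        read = junction_read_at_3p(pten_genome, region, clip=25)
        seq = list(read.seq)
        i = len(seq) - 10  # inside the clipped segment
        seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        bad = make_read(read.pos, "50M25S", "".join(seq))
        assert verify_junction_read(bad, vj, RunConfig()) == (False, None)

    @pytest.mark.parametrize("clip", [10, 17, 25, 40, 64])
    def test_outcome_invariant_to_matched_length(self, pten_genome, clip):
        """Any matched-portion length verifies, given >= 10 exact clipped bases."""
        _, region, vj = region_and_vj(pten_genome, 3, 5)
        read = junction_read_at_3p(pten_genome, region, clip=clip)
        assert verify_junction_read(read, vj, RunConfig())[0]

    def test_5p_anchored_left_clip(self, pten_genome):
        ref = pten_genome.reference
        _, region, vj = region_and_vj(pten_genome, 3, 5)
        clip, matched = 20, 55
        seq = ref.fetch(region.chrom, region.end - clip + 1, region.end) + ref.fetch(
            region.chrom, region.start, region.start + matched - 1
        )
        read = make_read(region.start, f"{clip}S{matched}M", seq)
        assert verify_junction_read(read, vj, RunConfig()) == (True, "5p")

    def test_agrees_with_doubled_region_search_on_small_regions(self, three_exon_genome):
        """Oracle: on a small region a junction read's sequence must occur
        spanning the seam of the doubled region sequence."""
        genome = three_exon_genome
        gene = genome.gene("TRI")
        s, e = gene.exon_by_ordinal(1)[0], gene.exon_by_ordinal(2)[1]
        region = JunctionRegion(
            chrom=gene.chrom, start=s, end=e, gene_id=gene.gene_id,
            first_exon_ordinal=1, last_exon_ordinal=2,
        )
        vj = build_virtual_junction(region, genome.reference)
        doubled = genome.reference.fetch(gene.chrom, s, e) * 2
        seam = region.size_bp
        for clip in (10, 20, 33):
            matched = 75 - clip
            pos = e - matched + 1
            seq = genome.reference.fetch(gene.chrom, pos, e) + genome.reference.fetch(
                gene.chrom, s, s + clip - 1
            )
            read = make_read(pos, f"{matched}M{clip}S", seq)
            verified, _ = verify_junction_read(read, vj, RunConfig())
            idx = doubled.find(seq)
            spans_seam = idx != -1 and idx < seam < idx + len(seq)
            assert verified == spans_seam
            # corrupt one clipped base: both routes must reject
            mutated = seq[:-5] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[-5]] + seq[-4:]
            bad = make_read(pos, f"{matched}M{clip}S", mutated)
            assert verify_junction_read(bad, vj, RunConfig()) == (False, None)
            idx2 = doubled.find(mutated)
            assert not (idx2 != -1 and idx2 < seam < idx2 + len(mutated))


class TestEvaluateMate:
    @pytest.fixture
    def region(self, pten_genome):
        return region_and_vj(pten_genome, 3, 5)[1]

    def test_forward_read_mate_past_3prime_is_td(self, region):
        read = make_read(region.end - 49, "50M25S", "A" * 75, flag=99, mate_pos=region.end + 50)
        pair = evaluate_mate(read, region, RunConfig())
        assert pair is not None and pair.scenario.startswith("FWD_MATE_PAST_3PRIME")

    def test_forward_read_mate_partly_outside_counts(self, region):
        read = make_read(region.end - 49, "50M25S", "A" * 75, flag=163, mate_pos=region.end - 10)
        assert evaluate_mate(read, region, RunConfig()) is not None

    def test_forward_read_mate_inside_is_circ_compatible(self, region):
        read = make_read(region.end - 49, "50M25S", "A" * 75, flag=99, mate_pos=region.start + 5)
        assert evaluate_mate(read, region, RunConfig()) is None

    def test_reverse_read_mate_before_5prime_is_td(self, region):
        read = make_read(region.start, "25S50M", "A" * 75, flag=83, mate_pos=region.start - 200)
        pair = evaluate_mate(read, region, RunConfig())
        assert pair is not None and pair.scenario.startswith("REV_MATE_BEFORE_5PRIME")

    def test_reverse_read_mate_at_or_after_start_is_not_td(self, region):
        read = make_read(region.start, "25S50M", "A" * 75, flag=147, mate_pos=region.start)
        assert evaluate_mate(read, region, RunConfig()) is None

    def test_unpaired_read_yields_none(self, region):
        read = make_read(region.end - 49, "50M25S", "A" * 75, flag=0, mate_pos=0)
        assert evaluate_mate(read, region, RunConfig()) is None


class TestFrameEffect:
    def test_mod3_rule(self, three_exon_genome):
        gene = three_exon_genome.gene("TRI")  # exon lengths 100 + 101 + 99 = 300
        region = JunctionRegion(
            chrom=gene.chrom, start=gene.exons[0][0], end=gene.exons[-1][1],
            gene_id=gene.gene_id, first_exon_ordinal=1, last_exon_ordinal=3,
        )
        assert frame_effect(region, gene) == "in_frame"

    def test_single_exon_not_multiple_of_three(self, three_exon_genome):
        gene = three_exon_genome.gene("TRI")
        s, e = gene.exon_by_ordinal(1)  # 100 bp
        region = JunctionRegion(
            chrom=gene.chrom, start=s, end=e, gene_id=gene.gene_id,
            first_exon_ordinal=1, last_exon_ordinal=1,
        )
        assert frame_effect(region, gene) == "out_of_frame"

    def test_pten_like_exon3to5_is_out_of_frame(self, pten_genome):
        gene, region, _ = region_and_vj(pten_genome, 3, 5)
        total = sum(
            e - s + 1 for s, e in (gene.exon_by_ordinal(o) for o in (3, 4, 5))
        )
        assert total == 328  # 45 + 44 + 239
        assert frame_effect(region, gene) == "out_of_frame"

    def test_region_not_on_whole_exons_is_na(self, pten_genome):
        gene, region, _ = region_and_vj(pten_genome, 3, 5)
        off = JunctionRegion(
            chrom=region.chrom, start=region.start + 3, end=region.end,
            gene_id=region.gene_id, first_exon_ordinal=3, last_exon_ordinal=5,
        )
        assert frame_effect(off, gene) == "NA"


class TestCallTdRegions:
    def test_three_planted_tds_score_three(self, pten_genome, run_detection):
        profile = run_detection(
            pten_genome,
            [
                td_spec(3, 5, outside=4, seed=1),
                td_spec(4, 5, outside=3, seed=2),
                td_spec(7, 8, outside=2, seed=3),
            ],
        )
        assert profile.td_score == 3

    def test_canonical_reads_only_score_zero(self, pten_genome, run_detection):
        profile = run_detection(pten_genome, [td_spec(3, 5, background=60, seed=4)])
        assert profile.td_score == 0

    def test_pten_like_exemplar(self, pten_genome, run_detection):
        """Exon3-5 duplication with 6 outside-mate pairs: one call, 6 pairs, 7739 bp."""
        profile = run_detection(pten_genome, [td_spec(3, 5, outside=6, background=30, seed=5)])
        assert profile.td_score == 1
        (call,) = profile.calls
        assert call.n_td_read_pairs == 6
        assert call.size_bp == 7739
        assert call.frame_effect == "out_of_frame"
        assert (call.region.first_exon_ordinal, call.region.last_exon_ordinal) == (3, 5)

    def test_circ_pairs_never_called_at_any_coverage(self, pten_genome, run_detection):
        for n in (5, 40):
            profile = run_detection(pten_genome, [td_spec(3, 5, inside=n, seed=6)], sample_id=f"c{n}")
            assert profile.td_score == 0

    def test_adding_td_pairs_never_decreases_score(self, pten_genome, run_detection):
        scores = [
            run_detection(pten_genome, [td_spec(3, 5, outside=n, background=10, seed=7)],
                          sample_id=f"m{n}").td_score
            for n in (1, 2, 4, 8)
        ]
        assert scores == sorted(scores)

    def test_adding_canonical_reads_never_changes_score(self, pten_genome, run_detection):
        base = run_detection(pten_genome, [td_spec(3, 5, outside=3, seed=8)], sample_id="a")
        more = run_detection(
            pten_genome, [td_spec(3, 5, outside=3, background=80, seed=8)], sample_id="b"
        )
        assert base.td_score == more.td_score == 1

    def test_min_support_filters_weak_regions(self, pten_genome, run_detection):
        profile = run_detection(
            pten_genome, [td_spec(3, 5, outside=2, seed=9)],
            config=RunConfig(min_support=3),
        )
        assert profile.td_score == 0

    def test_determinism_byte_identical_tables(self, pten_genome, tmp_path):
        from tdscan import write_profile

        sam, _ = simulate_sample(pten_genome, [td_spec(3, 5, outside=5, background=20, seed=10)])
        out = []
        for name in ("run1", "run2"):
            d = tmp_path / name
            d.mkdir()
            p = tmp_path / f"{name}.sam"
            p.write_text(sam)
            from tdscan import AlignmentStore, call_td_regions

            profile = call_td_regions(
                "s", AlignmentStore.from_path(p), pten_genome.genes,
                pten_genome.reference, RunConfig(),
            )
            write_profile(profile, pten_genome.genes, d)
            out.append(
                (d / "sample_td_calls.tsv").read_bytes()
                + (d / "sample_summary.tsv").read_bytes()
            )
        assert out[0] == out[1]
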