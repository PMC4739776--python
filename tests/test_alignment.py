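import numpy as np
import pytest

from ribocall.alignment import (
    AlignedRead,
    AsiteProfile,
    CalibrationError,
    OffsetTable,
    assign_asites,
    calibrate_offsets,
    load_alignments,
    metagene,
)
from ribocall.annotation import GenomeInterval, Transcript

SAM_TOY = """\
@HD\tVN:1.6\tSO:unsorted
@SQ\tSN:chr1\tLN:5000
plus28\t0\tchr1\t1001\t255\t28M\t*\t0\t0\t{seq28}\t*
minus28\t16\tchr1\t1001\t255\t28M\t*\t0\t0\t{seq28}\t*
short20\t0\tchr1\t1001\t255\t20M\t*\t0\t0\t{seq20}\t*
unmapped\t4\t*\t0\t0\t*\t*\t0\t0\t{seq28}\t*
secondary\t256\tchr1\t1101\t255\t28M\t*\t0\t0\t{seq28}\t*
""".format(seq28="A" * 28, seq20="A" * 20)


class TestLoadAlignments:
    @pytest.fixture()
    def toy_sam(self, tmp_path):
        p = tmp_path / "toy.sam"
        p.write_text(SAM_TOY)
        return p

    def test_plus_strand_five_prime_is_alignment_start(self, toy_sam):
        reads = load_alignments(toy_sam)
        plus = [r for r in reads if r.strand == "+"]
        assert plus[0].five_prime == 1000 and plus[0].length == 28

    def test_minus_strand_five_prime_is_last_aligned_base(self, toy_sam):
        reads = load_alignments(toy_sam)
        (minus,) = [r for r in reads if r.strand == "-"]
        assert minus.five_prime == 1027

    def test_length_window_and_flag_filters(self, toy_sam):
        reads = load_alignments(toy_sam)
        # short20 dropped by the 24-31 window; unmapped/secondary skipped
        assert len(reads) == 2


def _single_exon_cds_transcript(tid="tx", length=600, cds=(90, 510)):
    return Transcript(
        tid,
        tid,
        [GenomeInterval("chr1", 0, length, "+")],
        cds_start=cds[0],
        cds_end=cds[1],
    )


def _reads_for(t, asites, length, offset):
    out = []
    for a in asites:
        five_t = a - offset
        if five_t < 0 or five_t + length > t.length:
            continue
        chrom, g = t.to_genome(five_t)
        out.append(AlignedRead(chrom, t.strand, g, length))
    return out


class TestCalibrateOffsets:
    def test_recovers_planted_offset(self):
        t = _single_exon_cds_transcript()
        rng = np.random.default_rng(0)
        codons = rng.integers(0, (510 - 90) // 3 - 1, size=400)
        # pure in-frame signal plus an initiation peak at the first codon,
        # which disambiguates offsets three apart
        asites = np.concatenate([90 + 3 * codons, np.full(30, 90)])
        reads = _reads_for(t, asites, length=29, offset=15)
        table = calibrate_offsets(reads, [t], support_min=100)
        assert table.offsets == {29: 15}
        assert table.in_frame_fraction[29] > 0.95

    def test_random_phase_length_excluded(self):
        t = _single_exon_cds_transcript()
        rng = np.random.default_rng(1)
        asites = rng.integers(90, 510, size=400)  # uniform phase
        reads = _reads_for(t, asites, length=24, offset=12)
        table = calibrate_offsets(reads, [t], support_min=100)
        assert 24 not in table

    def test_low_support_length_excluded(self):
        t = _single_exon_cds_transcript()
        asites = 90 + 3 * np.arange(30)
        reads = _reads_for(t, asites, length=29, offset=15)
        table = calibrate_offsets(reads, [t], support_min=100)
        assert 29 not in table

    def test_no_reads_raises_calibration_error(self):
        t = _single_exon_cds_transcript()
        with pytest.raises(CalibrationError):
            calibrate_offsets([], [t])

    def test_no_coding_transcripts_raises(self):
        t = Transcript("nc", "nc", [GenomeInterval("chr1", 0, 300, "+")])
        with pytest.raises(CalibrationError):
            calibrate_offsets([AlignedRead("chr1", "+", 10, 28)], [t])

    def test_exact_recovery_on_simulated_data(self, demo_run):
        """Every per-length offset is recovered exactly from simulation."""
        assert demo_run.run.offsets.offsets == demo_run.sim.truth.offsets
        assert all(
            n >= 100 for n in demo_run.run.offsets.support.values()
        )


class TestAssignAsites:
    def test_simple_shift(self):
        t = _single_exon_cds_transcript()
        reads = [AlignedRead("chr1", "+", 10, 28)]
        profiles = assign_asites(reads, OffsetTable({28: 15}), [t])
        assert profiles["tx"].counts[25] == 1
        assert profiles["tx"].n_reads == 1

    def test_shift_beyond_transcript_end_discarded(self):
        t = _single_exon_cds_transcript(length=600)
        reads = [AlignedRead("chr1", "+", 590, 28)]
        profiles = assign_asites(reads, OffsetTable({28: 15}), [t])
        assert profiles["tx"].n_reads == 0

    def test_uncalibrated_length_discarded(self):
        t = _single_exon_cds_transcript()
        reads = [AlignedRead("chr1", "+", 10, 30)]
        profiles = assign_asites(reads, OffsetTable({28: 15}), [t])
        assert profiles["tx"].n_reads == 0

    def test_splice_spanning_shift(self):
        # exon1 chr1:100-150, exon2 chr1:200-250; 5' end 3 nt before the
        # junction must land 12 nt into exon 2 after a 15-nt shift
        t = Transcript(
            "tx2",
            "g",
            [
                GenomeInterval("chr1", 100, 150, "+"),
                GenomeInterval("chr1", 200, 250, "+"),
            ],
        )
        reads = [AlignedRead("chr1", "+", 147, 28)]
        profiles = assign_asites(reads, OffsetTable({28: 15}), [t])
        assert profiles["tx2"].counts[62] == 1
        assert t.to_genome(62) == ("chr1", 212)

    def test_read_conservation_on_simulation(self, demo_run):
        """Profile sums equal the number of reads assigned per transcript."""
        total = sum(p.n_reads for p in demo_run.run.profiles.values())
        assignable = sum(
            1 for r in demo_run.reads if r.length in demo_run.run.offsets
        )
        # every read is exonic by construction; a few fall off transcript ends
        assert 0 < total <= len(demo_run.reads)
        assert total >= 0.95 * assignable

    def test_in_frame_fraction_dominates_after_offsetting(self, demo_run):
        feats = demo_run.run.features
        truth = feats[(demo_run.labels == 1) & (feats.n_reads > 100)]
        assert (truth.f1 > truth.f2).all()
        assert (truth.f1 > truth.f3).all()


class TestMetagene:
    def _profile(self, t, positions):
        counts = np.zeros(t.length, dtype=int)
        for p in positions:
            counts[p] += 1
        return {t.id: AsiteProfile(t.id, counts)}

    def test_zero_profiles_zero_vector(self):
        t = _single_exon_cds_transcript()
        m = metagene(self._profile(t, []), [t], window=9, library_size=10**6)
        assert np.all(m == 0)

    def test_single_asite_at_start_codon(self):
        t = _single_exon_cds_transcript()
        m = metagene(self._profile(t, [90]), [t], window=9, library_size=10**6)
        assert m[9] > 0
        assert np.count_nonzero(m) == 1

    def test_empty_anchor_set_raises(self):
        t = Transcript("nc", "nc", [GenomeInterval("chr1", 0, 300, "+")])
        with pytest.raises(ValueError):
            metagene({}, [t])

    def test_periodic_sawtooth_on_simulation(self, demo_run):
        """Phase mix 65/24/11 shows as a period-3 sawtooth, frame 1 high."""
        m = metagene(
            demo_run.run.profiles,
            demo_run.sim.transcripts,
            anchor="start",
            window=30,
            library_size=len(demo_run.reads),
        )
        downstream = m[30:]  # positions 0..30 relative to the start codon
        f0, f1, f2 = downstream[0:30:3], downstream[1:30:3], downstream[2:30:3]
        assert f0.mean() > f1.mean() > f2.mean()


def test_offset_table_round_trip(tmp_path):
    table = OffsetTable({28: 15, 29: 16}, support={28: 500, 29: 400})
    p = tmp_path / "offsets.tsv"
    table.to_tsv(p)
    assert OffsetTable.from_tsv(p).offsets == table.offsets
    table.to_json(tmp_path / "offsets.json")


def test_negative_offset_rejected():
    with pytest.raises(ValueError):
        OffsetTable({28: -1})
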