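"""Hybrid construction, read simulation, truth-alignment emission."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from introscan.io_alignment import parse_md, stream_alignments
from introscan.signal import accumulate_scores
from introscan.simulate import (
    HybridTruthLog,
    ReadPlacement,
    SyntenyBlock,
    apply_truth_log,
    emit_truth_alignments,
    generate_toy_parents,
    make_simulated_hybrids,
    pairs_for_depth,
    read_blocks_tsv,
    read_fasta_arrays,
    simulate_reads,
    subsample_placements,
    write_fasta,
)


class TestToyParents:
    def test_zero_divergence_identical_parents(self, tmp_path):
        toy = generate_toy_parents(
            tmp_path, chrom_length=5000, divergence_rate=0.0,
            n_blocks=2, block_length_range=(200, 300), seed=1,
        )
        m = read_fasta_arrays(toy.maternal_fasta)
        p = read_fasta_arrays(toy.paternal_fasta)
        assert all(np.array_equal(m[c], p[c]) for c in m)

    def test_divergence_within_binomial_bounds(self, tmp_path):
        n = 100_000
        toy = generate_toy_parents(
            tmp_path, chrom_length=n, divergence_rate=0.10,
            n_blocks=2, block_length_range=(1000, 2000), seed=2,
        )
        m = read_fasta_arrays(toy.maternal_fasta)["chr1"]
        p = read_fasta_arrays(toy.paternal_fasta)["chr1"]
        mismatches = int((m != p).sum())
        lo, hi = sp_stats.binom.interval(0.99, n, 0.10)
        assert lo <= mismatches <= hi

    def test_blocks_disjoint_and_in_bounds(self, tmp_path):
        toy = generate_toy_parents(
            tmp_path, chrom_length=20_000, divergence_rate=0.05,
            n_blocks=4, block_length_range=(500, 900), seed=3,
        )
        assert len(toy.blocks) == 4
        ordered = sorted(toy.blocks, key=lambda b: b.maternal_start)
        for b in ordered:
            assert 1 <= b.maternal_start <= b.maternal_end <= 20_000
        for a, b in zip(ordered, ordered[1:]):
            assert a.maternal_end < b.maternal_start
        assert read_blocks_tsv(toy.blocks_tsv) == toy.blocks

    def test_oversized_blocks_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="do not fit"):
            generate_toy_parents(
                tmp_path, chrom_length=5000, n_blocks=4,
                block_length_range=(2000, 3000), seed=4,
            )

    def test_indels_shift_paternal_blocks(self, tmp_path):
        toy = generate_toy_parents(
            tmp_path, chrom_length=30_000, divergence_rate=0.05,
            n_blocks=2, block_length_range=(500, 900),
            indel_rate=0.001, seed=5,
        )
        p = read_fasta_arrays(toy.paternal_fasta)["chr1"]
        assert len(p) != 30_000  # indels changed the length
        for b in toy.blocks:
            assert b.paternal_end <= len(p)


class TestHybrids:
    def _parents(self, tmp_path):
        rng = np.random.default_rng(7)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        m = {"chr1": bases[rng.integers(0, 4, 5000)]}
        p = {"chr1": bases[rng.integers(0, 4, 5000)]}
        m_fa = write_fasta(m, tmp_path / "m.fasta")
        p_fa = write_fasta(p, tmp_path / "p.fasta")
        return m_fa, p_fa, m, p

    def test_seeded_repeatability(self, tmp_path):
        m_fa, p_fa, _, _ = self._parents(tmp_path)
        blocks = [SyntenyBlock("chr1", 1001, 2000, "chr1", 1001, 2000)]
        out1, log1 = make_simulated_hybrids(
            m_fa, p_fa, blocks, seed=42, out_fasta=tmp_path / "h1.fasta"
        )
        out2, log2 = make_simulated_hybrids(
            m_fa, p_fa, blocks, seed=42, out_fasta=tmp_path / "h2.fasta"
        )
        assert out1.read_bytes() == out2.read_bytes()
        assert log1.to_json() == log2.to_json()

    def test_zero_selection_identity(self, tmp_path):
        m_fa, p_fa, m, _ = self._parents(tmp_path)
        blocks = [SyntenyBlock("chr1", 1001, 2000, "chr1", 1001, 2000)]
        out, log = make_simulated_hybrids(
            m_fa, p_fa, blocks, seed=1, inclusion_prob=0.0,
            out_fasta=tmp_path / "h.fasta",
        )
        assert log.selected_blocks == []
        assert np.array_equal(read_fasta_arrays(out)["chr1"], m["chr1"])

    def test_unequal_length_splice_arithmetic(self, tmp_path):
        m_fa, p_fa, m, p = self._parents(tmp_path)
        blocks = [SyntenyBlock("chr1", 1001, 2000, "chr1", 501, 1600)]
        out, log = make_simulated_hybrids(
            m_fa, p_fa, blocks, seed=1, inclusion_prob=1.0,
            out_fasta=tmp_path / "h.fasta",
        )
        hybrid = read_fasta_arrays(out)["chr1"]
        assert len(hybrid) == 5000 - 1000 + 1100
        assert np.array_equal(hybrid[1000:2100], p["chr1"][500:1600])
        (truth,) = log.truth_regions
        assert (truth.start, truth.end) == (1001, 2100)
        assert log.length_deltas == {"chr1": 100}

    def test_overlapping_selection_rejected(self, tmp_path):
        m_fa, p_fa, _, _ = self._parents(tmp_path)
        blocks = [
            SyntenyBlock("chr1", 1001, 2000, "chr1", 1001, 2000),
            SyntenyBlock("chr1", 1500, 2500, "chr1", 1500, 2500),
        ]
        with pytest.raises(ValueError, match="overlap"):
            make_simulated_hybrids(
                m_fa, p_fa, blocks, seed=1, inclusion_prob=1.0,
                out_fasta=tmp_path / "h.fasta",
            )

    def test_length_conservation(self, tmp_path):
        m_fa, p_fa, _, _ = self._parents(tmp_path)
        blocks = [
            SyntenyBlock("chr1", 501, 900, "chr1", 401, 1000),
            SyntenyBlock("chr1", 2001, 2500, "chr1", 2101, 2400),
        ]
        out, log = make_simulated_hybrids(
            m_fa, p_fa, blocks, seed=1, inclusion_prob=1.0,
            out_fasta=tmp_path / "h.fasta",
        )
        expected = 5000 - (400 + 500) + (600 + 300)
        assert len(read_fasta_arrays(out)["chr1"]) == expected
        assert log.length_deltas["chr1"] == expected - 5000

    def test_log_round_trip_and_sufficiency(self, tmp_path):
        m_fa, p_fa, _, _ = self._parents(tmp_path)
        blocks = [
            SyntenyBlock("chr1", 501, 900, "chr1", 401, 1000),
            SyntenyBlock("chr1", 2001, 2500, "chr1", 2101, 2400),
        ]
        out, log = make_simulated_hybrids(
            m_fa, p_fa, blocks, seed=9, inclusion_prob=1.0,
            out_fasta=tmp_path / "h.fasta", log_path=tmp_path / "h.log.json",
        )
        reloaded = HybridTruthLog.from_json(
            (tmp_path / "h.log.json").read_text()
        )
        rebuilt = apply_truth_log(reloaded)
        hybrid = read_fasta_arrays(out)
        assert all(np.array_equal(rebuilt[c], hybrid[c]) for c in hybrid)


class TestReadSimulation:
    def _genome(self, tmp_path, n=20_000):
        rng = np.random.default_rng(13)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs = {"chr1": bases[rng.integers(0, 4, n)]}
        return write_fasta(seqs, tmp_path / "g.fasta"), seqs

    def test_read_counts(self, tmp_path):
        fa, _ = self._genome(tmp_path)
        rs = simulate_reads(fa, n_pairs=1000, seed=3)
        assert len(rs.placements) == 1000
        assert rs.r1_fastq.read_text().count("@sim_") == 1000
        assert rs.r2_fastq.read_text().count("@sim_") == 1000

    def test_error_free_reads_match_reference(self, tmp_path):
        fa, seqs = self._genome(tmp_path)
        rs = simulate_reads(fa, n_pairs=50, base_error_rate=0.0, seed=4)
        seq = seqs["chr1"].tobytes().decode()
        for p in rs.placements:
            frag = seq[p.fragment_start - 1 : p.fragment_start - 1 + p.fragment_length]
            assert p.r1_seq == frag[: len(p.r1_seq)]
            assert p.r2_seq == frag[-len(p.r2_seq):]
            assert p.r1_subs == () and p.r2_subs == ()

    def test_depth_identity(self, tmp_path):
        fa, _ = self._genome(tmp_path, n=50_000)
        n_pairs = pairs_for_depth(15.0, 50_000)
        rs = simulate_reads(fa, n_pairs=n_pairs, seed=5)
        total_bases = sum(
            len(p.r1_seq) + len(p.r2_seq) for p in rs.placements
        )
        assert total_bases / 50_000 == pytest.approx(15.0, rel=0.05)

    def test_invalid_pair_count(self, tmp_path):
        fa, _ = self._genome(tmp_path)
        with pytest.raises(ValueError, match="n_pairs"):
            simulate_reads(fa, n_pairs=0)

    def test_subsample_seeded(self, tmp_path):
        fa, _ = self._genome(tmp_path)
        rs = simulate_reads(fa, n_pairs=200, seed=6)
        a = subsample_placements(rs.placements, 0.5, seed=1)
        b = subsample_placements(rs.placements, 0.5, seed=1)
        assert len(a) == 100
        assert [p.read_id for p in a] == [p.read_id for p in b]


class TestTruthAlignments:
    def _reference(self, tmp_path, n=2000):
        rng = np.random.default_rng(17)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs = {"chr1": bases[rng.integers(0, 4, n)]}
        return write_fasta(seqs, tmp_path / "ref.fasta"), seqs

    def test_perfect_read(self, tmp_path):
        fa, seqs = self._reference(tmp_path)
        seq = seqs["chr1"].tobytes().decode()
        p = ReadPlacement(
            "r0", "chr1", 101, 500, seq[100:175], seq[525:600]
        )
        sam, dropped = emit_truth_alignments([p], fa, tmp_path / "o.sam")
        assert dropped == 0
        text = sam.read_text()
        assert "75M" in text and "MD:Z:75" in text

    def test_substitution_md(self, tmp_path):
        fa, seqs = self._reference(tmp_path)
        seq = seqs["chr1"].tobytes().decode()
        r1 = list(seq[100:175])
        ref_base = r1[10]
        r1[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref_base]
        p = ReadPlacement(
            "r0", "chr1", 101, 500, "".join(r1), seq[525:600], r1_subs=(10,)
        )
        sam, _ = emit_truth_alignments([p], fa, tmp_path / "o.sam")
        assert f"MD:Z:10{ref_base}64" in sam.read_text()

    def test_md_round_trip_recovers_edit_positions(self, tmp_path):
        fa, seqs = self._reference(tmp_path)
        rng = np.random.default_rng(23)
        seq = seqs["chr1"].tobytes().decode()
        subs = tuple(sorted(rng.choice(75, size=5, replace=False).tolist()))
        r1 = list(seq[200:275])
        for s in subs:
            r1[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r1[s]]
        p = ReadPlacement(
            "r0", "chr1", 201, 500, "".join(r1), seq[625:700], r1_subs=subs
        )
        sam, _ = emit_truth_alignments([p], fa, tmp_path / "o.sam")
        reads = list(stream_alignments(sam, "chr1"))
        r1_view = [r for r in reads if r.start_pos == 201][0]
        vec = parse_md(r1_view.md_tag)
        assert tuple(np.flatnonzero(vec.values == 0).tolist()) == subs

    def test_out_of_range_pair_dropped(self, tmp_path):
        fa, seqs = self._reference(tmp_path)
        seq = seqs["chr1"].tobytes().decode()
        good = ReadPlacement("g", "chr1", 1, 500, seq[0:75], seq[425:500])
        bad = ReadPlacement("b", "chr1", 1950, 500, "A" * 75, "C" * 75)
        sam, dropped = emit_truth_alignments([good, bad], fa, tmp_path / "o.sam")
        assert dropped == 1
        assert "b\t" not in sam.read_text()

    def test_diverged_block_mean_score(self, tmp_path):
        """Reads simulated from a 10%-diverged sequence but aligned at their
        maternal coordinates score ~0.90 per covered base."""
        rng = np.random.default_rng(29)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        n = 20_000
        maternal = bases[rng.integers(0, 4, n)]
        diverged = maternal.copy()
        mask = rng.random(n) < 0.10
        idx = np.flatnonzero(mask)
        cur = np.searchsorted(bases, diverged[idx])
        diverged[idx] = bases[(cur + rng.integers(1, 4, len(idx))) % 4]
        ref_fa = write_fasta({"chr1": maternal}, tmp_path / "ref.fasta")
        div_fa = write_fasta({"chr1": diverged}, tmp_path / "div.fasta")
        rs = simulate_reads(
            div_fa, n_pairs=pairs_for_depth(10, n), base_error_rate=0.0,
            seed=31,
        )
        sam, _ = emit_truth_alignments(rs.placements, ref_fa, tmp_path / "o.sam")
        track = accumulate_scores(stream_alignments(sam, "chr1"), "chr1", n)
        covered = track.cover_count > 0
        mean_score = track.score[covered].mean()
        assert mean_score == pytest.approx(0.90, abs=0.01)
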