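"""Footprint processing: loading, length filtering, offsets, periodicity."""

import numpy as np
import pandas as pd
import pytest

from ptmd import footprints as fp
from ptmd import synthetic as syn
from ptmd.config import SimulationConfig


def _write_transcriptome(tmp_path, fasta_text, cds_rows):
    fa = tmp_path / "tx.fa"
    fa.write_text(fasta_text)
    cds = tmp_path / "cds.tsv"
    cds.write_text(
        "transcript_id\tcds_start\tcds_end\n"
        + "".join(f"{t}\t{s}\t{e}\n" for t, s, e in cds_rows)
    )
    return fa, cds


class TestLoadTranscriptome:
    def test_direct_cds_slice(self, tmp_path):
        fa, cds = _write_transcriptome(tmp_path, ">t1\nAAATGGCTTAAGG\n", [("t1", 2, 11)])
        tx = fp.load_transcriptome(fa, cds)
        assert tx["t1"].cds_sequence == "ATGGCTTAA"
        assert tx["t1"].n_codons == 3

    def test_non_triplet_cds_warns_but_keeps_record(self, tmp_path):
        fa, cds = _write_transcriptome(tmp_path, ">t1\nAAATGGCTTAAGG\n", [("t1", 2, 12)])
        with pytest.warns(UserWarning, match="divisible by 3"):
            tx = fp.load_transcriptome(fa, cds)
        assert "t1" in tx

    def test_u_and_t_fastas_equivalent(self, tmp_path):
        fa_t, cds = _write_transcriptome(tmp_path, ">t1\nAAATGGCTTAAGG\n", [("t1", 2, 11)])
        fa_u = tmp_path / "u.fa"
        fa_u.write_text(">t1\nAAAUGGCUUAAGG\n")
        assert fp.load_transcriptome(fa_t, cds)["t1"].sequence == \
            fp.load_transcriptome(fa_u, cds)["t1"].sequence

    def test_missing_id_is_hard_error(self, tmp_path):
        fa, cds = _write_transcriptome(tmp_path, ">t1\nAAATGGCTTAAGG\n",
                                       [("t1", 2, 11), ("t2", 0, 3)])
        with pytest.raises(ValueError, match="t2"):
            fp.load_transcriptome(fa, cds)


class TestFilterByLength:
    def test_default_length_selection(self):
        data = pd.DataFrame(
            {"transcript_id": "t1", "five_prime_pos": [0, 1, 2, 3],
             "length": [28, 29, 31, 35], "count": [10, 10, 5, 2]}
        )
        out = fp.filter_by_length(fp.FootprintSet("input", data))
        assert dict(zip(out.data["length"], out.data["count"])) == {29: 10, 35: 2}
        assert out.meta["excluded_by_length"] == 15

    def test_allow_everything_is_identity(self):
        data = pd.DataFrame(
            {"transcript_id": "t1", "five_prime_pos": [0, 1], "length": [17, 35],
             "count": [1, 1]}
        )
        out = fp.filter_by_length(fp.FootprintSet("input", data), allowed=range(17, 36))
        assert out.total == 2

    def test_empty_input_empty_output(self):
        empty = pd.DataFrame(columns=fp.FOOTPRINT_COLUMNS)
        with pytest.warns(UserWarning):
            out = fp.filter_by_length(fp.FootprintSet("input", empty))
        assert out.total == 0


class TestAssignPsite:
    @pytest.fixture()
    def transcript(self):
        cfg = SimulationConfig(seed=4, n_transcripts=1, cds_length_range=(60, 60))
        return list(syn.generate_transcriptome(cfg))[0]

    def test_29nt_offset_rule(self):
        tx = fp.TranscriptRecord("t", "A" * 100 + "ATG" + "GCT" * 30 + "TAA" + "A" * 40, 100, 196)
        ann = fp.assign_psite(tx, five_prime_pos=100, length=29)
        assert ann.p_start == 112  # 13th nucleotide of the read, 1-based
        assert ann.p_codon_index == 4
        assert ann.status == "ok"

    def test_32nt_offset_rule_and_boundary_flag(self):
        tx = fp.TranscriptRecord("t", "A" * 13 + "ATG" + "GCT" * 10 + "TAA" + "A" * 30, 13, 49)
        ann = fp.assign_psite(tx, five_prime_pos=0, length=32)
        assert ann.p_start == 13  # 14th nucleotide of the read
        assert ann.p_codon_index == 0
        assert ann.p_codon == "ATG"
        assert ann.e_codon is None  # E site upstream of the CDS

    def test_unsupported_length_errors(self):
        tx = fp.TranscriptRecord("t", "ATG" + "AAA" * 20 + "TAA", 0, 66)
        with pytest.raises(ValueError, match="offset"):
            fp.assign_psite(tx, 0, 31)

    def test_assigned_p_codon_matches_transcript_slice(self, transcript):
        # offset correctness: reading the transcript at p_start reproduces p_codon
        cfg = SimulationConfig(seed=4, n_transcripts=1, cds_length_range=(60, 60),
                               depth_input=3000)
        tx = syn.generate_transcriptome(cfg)
        annotated = fp.annotate_footprints(syn.simulate_footprints(tx, cfg, "input"), tx)
        for row in annotated.itertuples():
            seq = tx[row.transcript_id].sequence
            assert seq[row.p_start : row.p_start + 3] == row.p_codon


class TestPeriodicity:
    def test_frame0_construction(self):
        cfg = SimulationConfig(seed=6, n_transcripts=5, cds_length_range=(50, 60),
                               depth_input=2000)
        tx = syn.generate_transcriptome(cfg)
        fps = syn.simulate_footprints(tx, cfg, "input")
        frame_table, _ = fp.metacodon_periodicity(fps, tx)
        for row in frame_table.itertuples():
            # offsets 12/13 put all 5' ends in frame 0 or 2 depending on length
            expected_frame = (-fp.P_SITE_OFFSETS[row.length]) % 3
            assert getattr(row, f"frame{expected_frame}") == 1.0

    def test_uniform_placement_near_one_third(self):
        rng = np.random.default_rng(0)
        tx = fp.Transcriptome(
            [fp.TranscriptRecord("t", "A" * 30 + "ATG" + "GCA" * 200 + "TAA" + "A" * 40, 30, 636)]
        )
        pos = rng.integers(30, 600, size=3000)
        data = pd.DataFrame({"transcript_id": "t", "five_prime_pos": pos,
                             "length": 29, "count": 1})
        frame_table, _ = fp.metacodon_periodicity(fp.FootprintSet("input", data), tx)
        fracs = frame_table[["frame0", "frame1", "frame2"]].to_numpy().ravel()
        sd = np.sqrt((1 / 3) * (2 / 3) / 3000)
        assert np.abs(fracs - 1 / 3).max() < 3 * sd

    def test_periodicity_score_decreases_with_frame_jitter(self):
        rng = np.random.default_rng(1)
        tx = fp.Transcriptome(
            [fp.TranscriptRecord("t", "A" * 30 + "ATG" + "GCA" * 200 + "TAA" + "A" * 40, 30, 636)]
        )
        base = 30 + 3 * rng.integers(0, 190, size=4000)
        scores = []
        for jitter in (0.0, 0.3, 0.8):
            shift = rng.choice([0, 1, 2], size=base.size, p=[1 - jitter, jitter / 2, jitter / 2])
            data = pd.DataFrame({"transcript_id": "t", "five_prime_pos": base + shift,
                                 "length": 29, "count": 1})
            frame_table, _ = fp.metacodon_periodicity(fp.FootprintSet("input", data), tx)
            scores.append(fp.periodicity_score(frame_table).iloc[0])
        assert scores[0] > scores[1] > scores[2]


class TestSiteCodonCounts:
    def test_single_footprint_weighted_by_count(self):
        tx = fp.TranscriptRecord("t", "A" * 20 + "ATG" + "AAA" + "CGG" + "GCA" * 10 + "TAA", 20, 59)
        ann = fp.assign_psite(tx, 20 + 6 - 12, 29, count=3)
        df = pd.DataFrame([vars(ann)])
        counts = fp.site_codon_counts(df, "P")
        assert counts.to_dict() == {"CGG": 3}

    def test_totals_conserved_and_match_generator_tally(self):
        cfg = SimulationConfig(seed=12, n_transcripts=10, cds_length_range=(60, 90),
                               depth_input=20_000)
        tx = syn.generate_transcriptome(cfg)
        fps = syn.simulate_footprints(tx, cfg, "input")
        annotated = fp.annotate_footprints(fps, tx)
        qc = fp.annotation_qc(annotated)
        assert qc["total"] == fps.total
        assert qc["ok"] + qc["out_of_frame"] + qc["out_of_cds"] == qc["total"]
        counts = fp.site_codon_counts(annotated, "P")
        assert counts.to_dict() == fps.psite_truth


class TestBamEquivalence:
    def test_bam_and_tsv_yield_identical_annotations(self, tmp_path):
        cfg = SimulationConfig(seed=15, n_transcripts=5, cds_length_range=(40, 60),
                               depth_input=500)
        tx = syn.generate_transcriptome(cfg)
        fps = syn.simulate_footprints(tx, cfg, "input")
        sam = tmp_path / "reads.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            for rec in tx:
                fh.write(f"@SQ\tSN:{rec.id}\tLN:{len(rec.sequence)}\n")
            i = 0
            for row in fps.data.itertuples():
                seq = tx[row.transcript_id].sequence[
                    row.five_prime_pos : row.five_prime_pos + row.length
                ]
                for _ in range(row.count):
                    fh.write(
                        f"r{i}\t0\t{row.transcript_id}\t{row.five_prime_pos + 1}\t255\t"
                        f"{row.length}M\t*\t0\t0\t{seq}\t*\n"
                    )
                    i += 1
        from_bam = fp.FootprintSet.from_bam(sam, "input")
        ann_bam = fp.annotate_footprints(from_bam, tx)
        ann_tsv = fp.annotate_footprints(fps, tx)
        pd.testing.assert_frame_equal(
            ann_bam.sort_values(["transcript_id", "five_prime_pos", "length"]).reset_index(drop=True),
            ann_tsv.sort_values(["transcript_id", "five_prime_pos", "length"]).reset_index(drop=True),
        )
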