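"""Event-table dialect, FASTA/GFF3 round trips and coordinate conversion."""

import numpy as np
import pytest

from m6acall.event_io import (
    CoordinateError,
    EventRead,
    ParseError,
    TranscriptModel,
    events_to_frame,
    frame_to_events,
    genome_to_transcript,
    read_event_table,
    read_fasta,
    read_gff3,
    transcript_to_genome,
    write_event_table,
    write_fasta,
    write_gff3,
    write_site_calls,
)
from m6acall.quantify import SiteCall


class TestEventTable:
    def test_round_trip_identity(self, tmp_path, event_read_factory):
        reads = [
            event_read_factory("r1", "txA", start=0, length=15, mismatch_at=(3,)),
            event_read_factory("r2", "txA", start=5, length=10, gap_at=(7,)),
            event_read_factory("r3", "txB", start=2, length=12),
        ]
        path = tmp_path / "events.tsv"
        write_event_table(reads, path)
        back = read_event_table(path)
        assert len(back) == 3
        by_id = {r.read_id: r for r in back}
        for r in reads:
            b = by_id[r.read_id]
            assert b.transcript_id == r.transcript_id and b.start == r.start
            np.testing.assert_array_equal(b.features, r.features)
            np.testing.assert_array_equal(b.flags, r.flags)

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_event_table([], path)
        assert read_event_table(path) == []

    def test_negative_dwell_rejected(self, tmp_path, event_read_factory):
        path = tmp_path / "bad.tsv"
        df = events_to_frame([event_read_factory("r1", "t", length=5)])
        df.loc[2, "dwell"] = -1.0
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ParseError, match="dwell"):
            read_event_table(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("read_id\ttranscript_id\n")
        with pytest.raises(ParseError, match="missing column"):
            read_event_table(path)

    def test_non_numeric_field_names_line(self, tmp_path, event_read_factory):
        path = tmp_path / "bad.tsv"
        df = events_to_frame([event_read_factory("r1", "t", length=5)])
        df = df.astype({"event_mean": object})
        df.loc[3, "event_mean"] = "oops"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ParseError, match="line 5"):
            read_event_table(path)

    def test_non_contiguous_span_rejected(self, tmp_path, event_read_factory):
        df = events_to_frame([event_read_factory("r1", "t", length=6)])
        df = df.drop(index=3)  # puncture the span
        with pytest.raises(ParseError, match="contiguous"):
            frame_to_events(df)

    def test_invalid_flag_rejected(self):
        with pytest.raises(ValueError, match="flag"):
            EventRead("r", "t", 0, np.ones((2, 5)), np.array(["match", "bogus"]))


class TestFasta:
    def test_round_trip_and_u_normalisation(self, tmp_path):
        path = tmp_path / "ref.fasta"
        write_fasta({"tx1": "ACGTACGT", "tx2": "GGGACTTT"}, path)
        assert read_fasta(path) == {"tx1": "ACGTACGT", "tx2": "GGGACTTT"}
        path.write_text(">rna\nacgu\n")
        assert read_fasta(path) == {"rna": "ACGT"}


def _tm(strand="+", exons=((100, 200),), chrom="chr1"):
    return TranscriptModel(
        transcript_id="tx", gene_id="g", chrom=chrom, strand=strand, exons=exons
    )


class TestCoordinates:
    def test_single_exon_plus_strand(self):
        tm = _tm("+", ((100, 200),))
        assert transcript_to_genome(tm, 0) == ("chr1", 101, "+")

    def test_two_exon_junction(self):
        tm = _tm("+", ((0, 50), (100, 150)))
        # brute-force walk: tpos 50 is the first base of exon 2
        assert transcript_to_genome(tm, 50) == ("chr1", 101, "+")
        assert transcript_to_genome(tm, 49) == ("chr1", 50, "+")

    def test_minus_strand_counts_from_three_prime_end(self):
        tm = _tm("-", ((100, 200),))
        assert transcript_to_genome(tm, 0) == ("chr1", 200, "-")
        assert genome_to_transcript(tm, 200) == 0
        assert genome_to_transcript(tm, 101) == 99

    def test_intronic_position_maps_to_none(self):
        tm = _tm("+", ((0, 50), (100, 150)))
        assert genome_to_transcript(tm, 75) is None
        assert genome_to_transcript(tm, 500) is None

    def test_out_of_range_raises(self):
        tm = _tm("+", ((100, 200),))
        with pytest.raises(CoordinateError):
            transcript_to_genome(tm, 100)
        with pytest.raises(CoordinateError):
            transcript_to_genome(tm, -1)

    def test_round_trip_both_strands(self, rng):
        for strand in "+-":
            exons = [(0, 30), (50, 90), (120, 121)]
            if strand == "-":
                exons = exons[::-1]
            tm = _tm(strand, tuple(exons))
            for tpos in range(tm.length):
                chrom, gpos, s = transcript_to_genome(tm, tpos)
                assert genome_to_transcript(tm, gpos) == tpos

    def test_exon_order_validation(self):
        with pytest.raises(ValueError, match="transcription order"):
            _tm("-", ((0, 50), (100, 150)))
        with pytest.raises(ValueError, match="overlap"):
            _tm("+", ((0, 50), (40, 90)))


class TestGff3:
    def test_write_read_round_trip(self, tmp_path):
        models = {
            "tx.p": TranscriptModel("tx.p", "gene1", "chr2", "+", ((10, 50), (80, 120))),
            "tx.m": TranscriptModel("tx.m", "gene2", "chr2", "-", ((300, 350), (200, 250))),
        }
        path = tmp_path / "ann.gff3"
        write_gff3(models, path)
        back = read_gff3(path)
        for name, tm in models.items():
            assert back[name].exons == tm.exons
            assert back[name].strand == tm.strand
            assert back[name].chrom == tm.chrom
            assert back[name].gene_id == tm.gene_id


def _call(tx="tx1", pos=99, rate=0.25, tier="high_confidence", gpos=101,
          chrom="chr1", motif="GGACT"):
    return SiteCall(
        transcript_id=tx, position=pos, motif=motif, n_mod=25, n_unmod=75,
        rate=rate, tier=tier, chrom=chrom, genome_pos=gpos, strand="+",
    )


class TestSiteCalls:
    def test_bed_coordinate_convention(self, tmp_path):
        path = tmp_path / "sites.bed"
        write_site_calls([_call(gpos=101)], path)
        line = path.read_text().splitlines()[1].split("\t")
        assert (line[0], line[1], line[2]) == ("chr1", "100", "101")
        assert line[3] == "tx1:100:GGACT"  # 1-based transcript position in name

    def test_zero_calls_header_only(self, tmp_path):
        path = tmp_path / "sites.bed"
        write_site_calls([], path)
        assert len(path.read_text().splitlines()) == 1

    def test_shared_genomic_position_two_isoforms(self, tmp_path):
        path = tmp_path / "sites.bed"
        write_site_calls(
            [_call(tx="tx1", pos=99), _call(tx="tx2", pos=149)], path
        )
        lines = path.read_text().splitlines()[1:]
        assert len(lines) == 2
        names = {l.split("\t")[3] for l in lines}
        starts = {l.split("\t")[1] for l in lines}
        assert len(names) == 2 and starts == {"100"}

    def test_unmapped_calls_go_to_sidecar(self, tmp_path):
        path = tmp_path / "sites.bed"
        unmapped = SiteCall("txX", 10, "GGACT", 5, 45, 0.1, "low_confidence")
        write_site_calls([_call(), unmapped], path)
        assert len(path.read_text().splitlines()) == 2
        sidecar = (tmp_path / "sites.bed.unmapped").read_text().splitlines()
        assert len(sidecar) == 2 and "txX" in sidecar[1]
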