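"""Readers and writers for the pipeline's file formats.

The central format is the *event table*: a TSV with one row per
(read, reference position) carrying the signal summaries a re-squiggle
step produces (event mean/median/sd in pA, dwell time, Phred-like base
quality) plus the basecall-vs-reference match status.  It is the textual
stand-in for signal-annotated fast5 archives; a fast5 adapter is a
documented extension point, not implemented here.

Coordinate conventions: internal coordinates are 0-based half-open;
reported site coordinates are 1-based, matching the common site-naming
convention (e.g. "NM_001101-1216" style names refer to 1-based transcript
positions).  Both directions of the transcript<->genome conversion are
explicit and strand-aware.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "EVENT_COLUMNS",
    "MATCH_FLAGS",
    "EventRead",
    "TranscriptModel",
    "ParseError",
    "CoordinateError",
    "read_event_table",
    "write_event_table",
    "read_event_frame",
    "write_event_frame",
    "events_to_frame",
    "frame_to_events",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "transcript_to_genome",
    "genome_to_transcript",
    "write_site_calls",
    "read_site_calls",
    "read_known_sites",
    "write_known_sites",
]

#: Fixed column order of the event-table dialect.
EVENT_COLUMNS = (
    "read_id",
    "transcript_id",
    "position",
    "event_mean",
    "event_median",
    "event_sd",
    "dwell",
    "base_quality",
    "match_flag",
)

#: Allowed basecall-vs-reference states.  Deletion gaps carry no signal
#: features (all-zero columns) and are excluded from feature extraction.
MATCH_FLAGS = ("match", "mismatch", "gap")

_FEATURES = ("event_mean", "event_median", "event_sd", "dwell", "base_quality")


class ParseError(ValueError):
    """Malformed event table / annotation input."""


class CoordinateError(ValueError):
    """Coordinate outside the valid range of a transcript or genome."""


@dataclass
class EventRead:
    """One read's signal-aligned trace over a contiguous transcript span.

    ``features`` has one row per covered position (5' to 3' on the
    transcript) with columns (mean, median, sd, dwell, base quality);
    ``flags`` holds the per-position match status.
    """

    read_id: str
    transcript_id: str
    start: int  # 0-based transcript position of the first record
    features: np.ndarray  # (L, 5) float
    flags: np.ndarray  # (L,) unicode, values in MATCH_FLAGS

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.flags = np.asarray(self.flags)
        if self.features.ndim != 2 or self.features.shape[1] != 5:
            raise ValueError("features must be (L, 5)")
        if len(self.flags) != len(self.features):
            raise ValueError("flags and features length mismatch")
        bad = ~np.isin(self.flags, MATCH_FLAGS)
        if bad.any():
            raise ValueError(f"invalid match flag(s): {set(self.flags[bad])}")
        nongap = self.flags != "gap"
        if (self.features[nongap, 2] < 0).any():
            raise ValueError("negative signal sd")
        if (self.features[nongap, 3] <= 0).any():
            raise ValueError("non-positive dwell at a non-gap position")

    @property
    def span(self) -> tuple[int, int]:
        """Half-open 0-based interval covered on the transcript."""
        return (self.start, self.start + len(self.flags))

    def __len__(self) -> int:
        return len(self.flags)


# ---------------------------------------------------------------------------
# event tables


def events_to_frame(reads: Iterable[EventRead]) -> pd.DataFrame:
    """Flatten :class:`EventRead` objects into a long event-table frame."""
    parts = []
    for r in reads:
        n = len(r)
        parts.append(
            pd.DataFrame(
                {
                    "read_id": np.repeat(r.read_id, n),
                    "transcript_id": np.repeat(r.transcript_id, n),
                    "position": np.arange(r.start, r.start + n),
                    "event_mean": r.features[:, 0],
                    "event_median": r.features[:, 1],
                    "event_sd": r.features[:, 2],
                    "dwell": r.features[:, 3],
                    "base_quality": r.features[:, 4],
                    "match_flag": r.flags,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=list(EVENT_COLUMNS))
    return pd.concat(parts, ignore_index=True)


def _validate_frame(df: pd.DataFrame, origin: str = "<frame>") -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{origin}: missing column(s) {missing}")
    df = df[list(EVENT_COLUMNS)].copy()
    for col in ("position", *_FEATURES):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            line = int(np.argmax((bad | df[col].isna()).to_numpy())) + 2
            raise ParseError(f"{origin}: non-numeric value in column {col!r} at line {line}")
        df[col] = vals
    bad_flag = ~df["match_flag"].isin(MATCH_FLAGS)
    if bad_flag.any():
        line = int(np.argmax(bad_flag.to_numpy())) + 2
        raise ParseError(f"{origin}: invalid match_flag at line {line}")
    nongap = df["match_flag"] != "gap"
    bad_dwell = nongap & (df["dwell"] <= 0)
    if bad_dwell.any():
        line = int(np.argmax(bad_dwell.to_numpy())) + 2
        raise ParseError(f"{origin}: non-positive dwell at non-gap position, line {line}")
    bad_sd = nongap & (df["event_sd"] < 0)
    if bad_sd.any():
        line = int(np.argmax(bad_sd.to_numpy())) + 2
        raise ParseError(f"{origin}: negative event_sd at line {line}")
    return df


def read_event_frame(path: str | os.PathLike) -> pd.DataFrame:
    """Read an event table into a long DataFrame, validating the dialect."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "transcript_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file (missing header)") from exc
    return _validate_frame(df, origin=str(path))


def frame_to_events(df: pd.DataFrame) -> list[EventRead]:
    """Group a validated event frame into per-read :class:`EventRead` objects.

    Rows of each read must cover a contiguous position range (one row per
    position); otherwise a :class:`ParseError` is raised.
    """
    reads: list[EventRead] = []
    for (read_id, transcript_id), grp in df.groupby(
        ["read_id", "transcript_id"], sort=True, observed=True
    ):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy(dtype=int)
        if len(pos) != pos[-1] - pos[0] + 1 or len(np.unique(pos)) != len(pos):
            raise ParseError(
                f"read {read_id!r}: records do not cover a contiguous span "
                f"({len(pos)} records over [{pos[0]}, {pos[-1]}])"
            )
        feats = grp[list(_FEATURES)].to_numpy(dtype=float)
        reads.append(
            EventRead(
                read_id=str(read_id),
                transcript_id=str(transcript_id),
                start=int(pos[0]),
                features=feats,
                flags=grp["match_flag"].to_numpy(),
            )
        )
    return reads


def read_event_table(path: str | os.PathLike) -> list[EventRead]:
    """Read an event table as a list of per-read records."""
    return frame_to_events(read_event_frame(path))


def write_event_frame(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a long event frame in the event-table dialect."""
    df = df[list(EVENT_COLUMNS)]
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_event_table(reads: Iterable[EventRead], path: str | os.PathLike) -> None:
    write_event_frame(events_to_frame(reads), path)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a reference FASTA; sequences uppercased with U mapped to T."""
    return {
        rec.id: str(rec.seq).upper().replace("U", "T")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# transcript models and coordinate conversion


@dataclass(frozen=True)
class TranscriptModel:
    """Exon chain of one transcript isoform on the genome.

    ``exons`` are half-open 0-based genomic intervals listed in
    transcription order (ascending genomic start on '+', descending on '-').
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        starts = [e[0] for e in self.exons]
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty/inverted exon ({s}, {e})")
        ordered = sorted(starts) if self.strand == "+" else sorted(starts, reverse=True)
        if starts != ordered:
            raise ValueError("exons not in transcription order")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError("overlapping exons")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


def transcript_to_genome(tm: TranscriptModel, tpos: int) -> tuple[str, int, str]:
    """Map a 0-based transcript coordinate to (chrom, 1-based genomic, strand).

    Walks the exon chain in transcription order; on the minus strand the
    transcript's 5' end is the genomic 3' end of the chain.
    """
    if not 0 <= tpos < tm.length:
        raise CoordinateError(
            f"{tm.transcript_id}: transcript position {tpos} outside [0, {tm.length})"
        )
    remaining = tpos
    for s, e in tm.exons:
        exon_len = e - s
        if remaining < exon_len:
            if tm.strand == "+":
                g0 = s + remaining
            else:
                g0 = e - 1 - remaining
            return (tm.chrom, g0 + 1, tm.strand)
        remaining -= exon_len
    raise AssertionError("unreachable")


def genome_to_transcript(tm: TranscriptModel, gpos: int) -> int | None:
    """Inverse of :func:`transcript_to_genome`.

    ``gpos`` is 1-based.  Returns None for intronic or out-of-transcript
    positions.
    """
    g0 = gpos - 1
    offset = 0
    for s, e in tm.exons:
        if s <= g0 < e:
            if tm.strand == "+":
                return offset + (g0 - s)
            return offset + (e - 1 - g0)
        offset += e - s
    return None


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | os.PathLike) -> dict[str, TranscriptModel]:
    """Parse transcript models from a GFF3 annotation.

    Accepts feature types 'mRNA' and 'transcript'; exon order and strand
    come from the file.  Uses an in-memory gffutils database.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict[str, TranscriptModel] = {}
    for ftype in ("mRNA", "transcript"):
        for tx in db.features_of_type(ftype):
            exons = [
                (ex.start - 1, ex.end)  # GFF3 is 1-based closed
                for ex in db.children(tx, featuretype="exon", order_by="start")
            ]
            if not exons:
                continue
            if tx.strand == "-":
                exons = exons[::-1]
            gene_id = (tx.attributes.get("Parent") or tx.attributes.get("gene_id") or [tx.id])[0]
            models[tx.id] = TranscriptModel(
                transcript_id=tx.id,
                gene_id=gene_id,
                chrom=tx.seqid,
                strand=tx.strand,
                exons=tuple(exons),
            )
    return models


def write_gff3(models: Mapping[str, TranscriptModel], path: str | os.PathLike) -> None:
    """Write transcript models as a minimal GFF3 (gene/mRNA/exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tm in models.values():
            genomic = sorted(tm.exons)
            g_start, g_end = genomic[0][0] + 1, genomic[-1][1]
            fh.write(
                f"{tm.chrom}\tm6acall\tgene\t{g_start}\t{g_end}\t.\t{tm.strand}\t.\t"
                f"ID={tm.gene_id}\n"
            )
            fh.write(
                f"{tm.chrom}\tm6acall\tmRNA\t{g_start}\t{g_end}\t.\t{tm.strand}\t.\t"
                f"ID={tm.transcript_id};Parent={tm.gene_id}\n"
            )
            for i, (s, e) in enumerate(genomic, 1):
                fh.write(
                    f"{tm.chrom}\tm6acall\texon\t{s + 1}\t{e}\t.\t{tm.strand}\t.\t"
                    f"ID={tm.transcript_id}.exon{i};Parent={tm.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# site calls (BED-like) and known sites


_SITE_CALL_HEADER = (
    "#chrom", "start", "end", "name", "rate", "strand", "n_mod", "n_unmod",
    "coverage", "tier",
)


def write_site_calls(calls: Sequence, path: str | os.PathLike) -> None:
    """Write site calls as a BED-like table (0-based half-open intervals).

    The name field is ``transcript:position1based:motif`` so rows from
    different isoforms sharing one genomic position remain distinct.  Calls
    without a genome coordinate go to a ``<path>.unmapped`` sidecar rather
    than being dropped.
    """
    mapped, unmapped = [], []
    for c in calls:
        row = (
            c.chrom,
            None if c.genome_pos is None else c.genome_pos - 1,
            c.genome_pos,
            f"{c.transcript_id}:{c.position + 1}:{c.motif}",
            f"{c.rate:.3f}",
            c.strand,
            c.n_mod,
            c.n_unmod,
            c.coverage,
            c.tier,
        )
        (unmapped if c.genome_pos is None else mapped).append(row)
    mapped.sort(key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        fh.write("\t".join(_SITE_CALL_HEADER) + "\n")
        for r in mapped:
            fh.write("\t".join(str(x) for x in r) + "\n")
    if unmapped:
        with open(f"{path}.unmapped", "w") as fh:
            fh.write("\t".join(_SITE_CALL_HEADER) + "\n")
            for r in sorted(unmapped, key=lambda r: r[3]):
                fh.write("\t".join("." if x is None else str(x) for x in r) + "\n")


def read_site_calls(path: str | os.PathLike) -> pd.DataFrame:
    """Read a site-call table written by :func:`write_site_calls`."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"#chrom": "chrom"})
    parts = df["name"].str.rsplit(":", n=2, expand=True)
    df["transcript_id"] = parts[0]
    df["position"] = parts[1].astype(int) - 1  # back to 0-based
    df["motif"] = parts[2]
    return df


def read_known_sites(path: str | os.PathLike) -> list[tuple[str, int]]:
    """Read known anchor sites from a BED file on transcript coordinates.

    Column 1 is the transcript id, column 2 the 0-based centre-A position.
    """
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            sites.append((fields[0], int(fields[1])))
    return sites


def write_known_sites(sites: Iterable, path: str | os.PathLike) -> None:
    """Write anchored sites as BED (transcript coordinates, 0-based).

    The name field carries ``motif/support_count``.
    """
    with open(path, "w") as fh:
        for s in sites:
            n_support = len(getattr(s, "supports", ()))
            fh.write(
                f"{s.transcript_id}\t{s.position}\t{s.position + 1}\t"
                f"{s.motif}/{n_support}\t{n_support}\t+\n"
            )
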