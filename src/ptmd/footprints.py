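"""Footprint processing: transcript models, length filtering, P-site offsets.

Ribosome footprints are held as counted *species* — unique
(transcript, 5' position, read length) triples — because the downstream
enrichment test operates at that level.  Only read lengths 29, 30, 32 and
35 nt are analysed by default; for 29–30 nt footprints the 13th nucleotide
(1-based) is the first nucleotide of the P-site codon, for 32 and 35 nt
footprints the 14th.  All internal coordinates are 0-based, half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ptmd.genetics import STOP_CODONS

logger = logging.getLogger(__name__)

#: 0-based offset from the footprint 5' end to the first nucleotide of the
#: P-site codon (the published rule is stated 1-based: 13th nt for 29–30 nt
#: reads, 14th nt for 32 and 35 nt reads).
P_SITE_OFFSETS: dict[int, int] = {29: 12, 30: 12, 32: 13, 35: 13}

DEFAULT_LENGTHS: frozenset[int] = frozenset(P_SITE_OFFSETS)

FOOTPRINT_COLUMNS = ["transcript_id", "five_prime_pos", "length", "count"]


# ---------------------------------------------------------------------------
# transcript models
# ---------------------------------------------------------------------------

@dataclass
class TranscriptRecord:
    """One transcript: sequence (DNA alphabet, upper case) plus its CDS span."""

    id: str
    sequence: str
    cds_start: int
    cds_end: int

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def n_codons(self) -> int:
        return (self.cds_end - self.cds_start) // 3

    def codon(self, index: int) -> str:
        start = self.cds_start + 3 * index
        return self.sequence[start : start + 3]

    def codons(self) -> list[str]:
        return [self.codon(i) for i in range(self.n_codons)]


class Transcriptome:
    """An id-keyed collection of :class:`TranscriptRecord`."""

    def __init__(self, records: Iterable[TranscriptRecord]):
        self._records: dict[str, TranscriptRecord] = {}
        for rec in records:
            if rec.id in self._records:
                raise ValueError(f"duplicate transcript id {rec.id!r}")
            self._records[rec.id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self._records.values())

    def __contains__(self, tid: str) -> bool:
        return tid in self._records

    def __getitem__(self, tid: str) -> TranscriptRecord:
        return self._records[tid]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self:
                fh.write(f">{rec.id}\n{rec.sequence}\n")

    def to_cds_table(self, path: str | Path) -> None:
        pd.DataFrame(
            [(r.id, r.cds_start, r.cds_end) for r in self],
            columns=["transcript_id", "cds_start", "cds_end"],
        ).to_csv(path, sep="\t", index=False)


def _validate_transcript(rec: TranscriptRecord) -> None:
    bad = set(rec.sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"transcript {rec.id!r} contains non-ACGTN characters {sorted(bad)}")
    if not (0 <= rec.cds_start <= rec.cds_end <= len(rec.sequence)):
        raise ValueError(f"CDS span of {rec.id!r} falls outside the transcript")
    if (rec.cds_end - rec.cds_start) % 3 != 0:
        warnings.warn(f"CDS length of {rec.id!r} not divisible by 3", stacklevel=3)
    else:
        cds = rec.cds_sequence
        if cds and not cds.startswith("ATG"):
            warnings.warn(f"CDS of {rec.id!r} does not begin with ATG", stacklevel=3)
        if cds and cds[-3:] not in STOP_CODONS:
            warnings.warn(f"CDS of {rec.id!r} does not end with a stop codon", stacklevel=3)


def load_transcriptome(fasta_path: str | Path, cds_table_path: str | Path) -> Transcriptome:
    """Read transcript sequences (FASTA) and CDS coordinates (TSV).

    Sequences are upper-cased and U is normalized to T.  Every id in the CDS
    table must appear in the FASTA; violations are hard errors, whereas
    CDS-shape oddities (length not divisible by 3, missing start/stop) only
    warn, so imperfect annotations can still be processed.
    """
    seqs = {rec.id: str(rec.seq).upper().replace("U", "T") for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(cds_table_path, sep="\t")
    required = {"transcript_id", "cds_start", "cds_end"}
    if not required.issubset(table.columns):
        raise ValueError(f"CDS table must have columns {sorted(required)}")
    missing = [tid for tid in table["transcript_id"] if tid not in seqs]
    if missing:
        raise ValueError(f"CDS ids missing from FASTA: {missing}")
    records = []
    for row in table.itertuples(index=False):
        rec = TranscriptRecord(
            id=row.transcript_id,
            sequence=seqs[row.transcript_id],
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
        )
        _validate_transcript(rec)
        records.append(rec)
    return Transcriptome(records)


# ---------------------------------------------------------------------------
# footprint sets
# ---------------------------------------------------------------------------

def _normalize_footprint_frame(data: pd.DataFrame) -> pd.DataFrame:
    missing = set(FOOTPRINT_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"footprint table missing columns {sorted(missing)}")
    df = data[FOOTPRINT_COLUMNS].copy()
    df["five_prime_pos"] = df["five_prime_pos"].astype(np.int64)
    df["length"] = df["length"].astype(np.int64)
    df["count"] = df["count"].astype(np.int64)
    if (df["count"] < 1).any():
        raise ValueError("footprint counts must be >= 1")
    if ((df["length"] < 17) | (df["length"] > 35)).any():
        raise ValueError("footprint lengths must lie in 17..35 nt")
    # deduplicate species, summing counts
    df = (
        df.groupby(["transcript_id", "five_prime_pos", "length"], as_index=False, sort=True)["count"]
        .sum()
    )
    return df[FOOTPRINT_COLUMNS]


@dataclass
class FootprintSet:
    """Counted footprint species for one library ('input' or 'ip')."""

    library: str
    data: pd.DataFrame
    #: ground-truth per-codon P-site tallies, set by the simulator
    psite_truth: dict[str, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _normalize_footprint_frame(self.data)

    @property
    def total(self) -> int:
        return int(self.data["count"].sum())

    @property
    def n_species(self) -> int:
        return len(self.data)

    @classmethod
    def from_tsv(cls, path: str | Path, library: str) -> "FootprintSet":
        return cls(library=library, data=pd.read_csv(path, sep="\t"))

    @classmethod
    def from_bam(cls, path: str | Path, library: str) -> "FootprintSet":
        """Load transcriptome-aligned footprints from BAM/SAM.

        Primary, forward-strand alignments only; read length is the
        CIGAR-consumed query length.  Dropped-record tallies are kept in
        ``meta``.
        """
        import pysam

        dropped = {"unmapped": 0, "secondary_or_supplementary": 0, "antisense": 0}
        rows: dict[tuple[str, int, int], int] = {}
        with pysam.AlignmentFile(str(path), check_sq=False) as bam:
            for read in bam.fetch(until_eof=True):
                if read.is_unmapped:
                    dropped["unmapped"] += 1
                    continue
                if read.is_secondary or read.is_supplementary:
                    dropped["secondary_or_supplementary"] += 1
                    continue
                if read.is_reverse:
                    dropped["antisense"] += 1
                    continue
                key = (read.reference_name, read.reference_start, read.infer_query_length())
                rows[key] = rows.get(key, 0) + 1
        data = pd.DataFrame(
            [(t, p, l, c) for (t, p, l), c in rows.items()], columns=FOOTPRINT_COLUMNS
        )
        return cls(library=library, data=data, meta={"dropped": dropped})

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def filter_by_length(
    footprints: FootprintSet, allowed: Iterable[int] = DEFAULT_LENGTHS
) -> FootprintSet:
    """Retain only footprints of the given read lengths (counts untouched)."""
    allowed = set(allowed)
    kept = footprints.data[footprints.data["length"].isin(allowed)].reset_index(drop=True)
    if kept.empty:
        warnings.warn(f"no footprints left after length filter {sorted(allowed)}", stacklevel=2)
    out = FootprintSet(library=footprints.library, data=kept, psite_truth=footprints.psite_truth)
    out.meta = dict(footprints.meta)
    out.meta["excluded_by_length"] = footprints.total - out.total
    return out


# ---------------------------------------------------------------------------
# P-site assignment and annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedFootprint:
    transcript_id: str
    five_prime_pos: int
    length: int
    count: int
    p_start: int
    frame: int
    p_codon_index: int | None
    e_codon: str | None
    p_codon: str | None
    a_codon: str | None
    status: str  # 'ok', 'out_of_frame' or 'out_of_cds'


def _psite_offset(length: int) -> int:
    try:
        return P_SITE_OFFSETS[length]
    except KeyError:
        raise ValueError(
            f"no P-site offset for {length} nt footprints; the offset table covers "
            f"lengths {sorted(P_SITE_OFFSETS)}"
        ) from None


def assign_psite(
    transcript: TranscriptRecord,
    five_prime_pos: int,
    length: int,
    count: int = 1,
) -> AnnotatedFootprint:
    """Annotate one footprint with its P-site codon and flanking E/A codons.

    The P-site codon starts ``five_prime_pos + offset(length)``; the E and A
    codons sit one codon 5' and 3' of it.  Sites outside the CDS, or 5' ends
    out of the CDS reading frame, are flagged rather than raising.
    """
    offset = _psite_offset(length)
    p_start = five_prime_pos + offset
    n_codons = transcript.n_codons
    rel = p_start - transcript.cds_start
    frame = rel % 3
    if frame != 0:
        status = "out_of_frame"
        p_index = None
    else:
        p_index = rel // 3
        status = "ok" if 0 <= p_index < n_codons else "out_of_cds"
        if status == "out_of_cds":
            p_index = None

    def codon_at(idx: int | None) -> str | None:
        if idx is None or not (0 <= idx < n_codons):
            return None
        return transcript.codon(idx)

    base = rel // 3 if frame == 0 else None
    return AnnotatedFootprint(
        transcript_id=transcript.id,
        five_prime_pos=five_prime_pos,
        length=length,
        count=count,
        p_start=p_start,
        frame=frame,
        p_codon_index=p_index,
        e_codon=codon_at(None if base is None else base - 1),
        p_codon=codon_at(base),
        a_codon=codon_at(None if base is None else base + 1),
        status=status,
    )


def annotate_footprints(footprints: FootprintSet, transcriptome: Transcriptome) -> pd.DataFrame:
    """Vectorised annotation of a whole footprint set.

    Returns one row per footprint species with E/P/A codons (None where a site
    falls outside the CDS), the CDS-relative frame of the P-site start, and a
    status flag.  Footprints on transcripts absent from the transcriptome are
    a hard error.
    """
    rows = []
    missing = set(footprints.data["transcript_id"]) - set(transcriptome.ids)
    if missing:
        raise ValueError(f"footprints reference unknown transcripts: {sorted(missing)[:5]}")
    for tid, group in footprints.data.groupby("transcript_id", sort=True):
        tx = transcriptome[tid]
        for row in group.itertuples(index=False):
            ann = assign_psite(tx, int(row.five_prime_pos), int(row.length), int(row.count))
            rows.append(ann)
    df = pd.DataFrame([vars(a) if not hasattr(a, "_asdict") else a._asdict() for a in rows])
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "transcript_id", "five_prime_pos", "length", "count", "p_start",
                "frame", "p_codon_index", "e_codon", "p_codon", "a_codon", "status",
            ]
        )
    return df


def annotation_qc(annotated: pd.DataFrame) -> dict[str, int]:
    """Exclusion tallies (counts, not species) for the QC report."""
    by = annotated.groupby("status")["count"].sum().to_dict()
    return {
        "total": int(annotated["count"].sum()) if len(annotated) else 0,
        "ok": int(by.get("ok", 0)),
        "out_of_frame": int(by.get("out_of_frame", 0)),
        "out_of_cds": int(by.get("out_of_cds", 0)),
    }


# ---------------------------------------------------------------------------
# periodicity QC and site tallies
# ---------------------------------------------------------------------------

def metacodon_periodicity(
    footprints: FootprintSet,
    transcriptome: Transcriptome,
    profile_window: tuple[int, int] = (-24, 60),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triplet-periodicity QC.

    Returns ``(frame_table, meta_profile)``.  ``frame_table`` gives, per read
    length, the fraction of footprint counts whose 5' end falls in CDS frame
    0/1/2 (5' ends inside the CDS only; lengths with no in-CDS footprints are
    absent).  ``meta_profile`` is a count profile by 5'-end position relative
    to the CDS start, summed over transcripts, per read length.
    """
    df = footprints.data
    cds_start = df["transcript_id"].map(lambda t: transcriptome[t].cds_start)
    cds_end = df["transcript_id"].map(lambda t: transcriptome[t].cds_end)
    rel = df["five_prime_pos"] - cds_start
    in_cds = (df["five_prime_pos"] >= cds_start) & (df["five_prime_pos"] < cds_end)

    frame_rows = []
    for length, grp in df[in_cds].assign(frame=rel[in_cds] % 3).groupby("length"):
        counts = grp.groupby("frame")["count"].sum().reindex([0, 1, 2], fill_value=0)
        total = counts.sum()
        frame_rows.append(
            {
                "length": int(length),
                "frame0": counts[0] / total,
                "frame1": counts[1] / total,
                "frame2": counts[2] / total,
                "n": int(total),
            }
        )
    frame_table = pd.DataFrame(frame_rows, columns=["length", "frame0", "frame1", "frame2", "n"])

    lo, hi = profile_window
    win = (rel >= lo) & (rel < hi)
    prof = (
        df[win]
        .assign(rel_pos=rel[win])
        .groupby(["length", "rel_pos"], as_index=False)["count"]
        .sum()
    )
    return frame_table, prof


def periodicity_score(frame_table: pd.DataFrame) -> pd.Series:
    """Max frame fraction per read length (1.0 = perfect phasing, 1/3 = none)."""
    return frame_table.set_index("length")[["frame0", "frame1", "frame2"]].max(axis=1)


_SITE_COLUMNS: Mapping[str, str] = {"E": "e_codon", "P": "p_codon", "A": "a_codon"}


def site_codon_counts(annotated: pd.DataFrame, site: str) -> pd.Series:
    """Count-weighted codon tally at one ribosomal site.

    Out-of-frame and out-of-CDS P-sites are excluded; E/A codons that fall
    outside the CDS are excluded for those sites.  Stop codons are retained
    under their own codon string so callers can report them separately from
    the 61 sense codons.
    """
    col = _SITE_COLUMNS[site.upper()]
    ok = annotated[(annotated["status"] == "ok") & annotated[col].notna()]
    return ok.groupby(col)["count"].sum().sort_index()
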