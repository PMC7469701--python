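"""Plain-text I/O: FASTA transcriptomes, BED-like fragment tables, count and
design TSVs. Coordinates on disk are 0-based half-open; strand is written as
``+`` (sense) / ``-`` (antisense); U is mapped to T on input."""

from __future__ import annotations

import os
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import normalize
from .errors import ParseError
from .types import (
    ANTISENSE,
    SENSE,
    CountMatrix,
    FragmentSet,
    SampleDesign,
    Transcript,
    TranscriptomeModel,
)

_STRAND_OUT = {SENSE: "+", ANTISENSE: "-"}
_STRAND_IN = {"+": SENSE, "-": ANTISENSE}

FRAGMENT_HEADER = ["transcript_id", "start", "end", "strand", "sample_id", "flag"]


def write_fasta(model: TranscriptomeModel, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description=f"abundance={t.base_abundance:.6g}")
        for t in model.transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_sequences(path: str | os.PathLike) -> dict[str, str]:
    """Transcript id -> normalised sequence (U mapped to T)."""
    return {rec.id: normalize(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def read_transcriptome(
    path: str | os.PathLike,
    target_id: str,
    abundances: dict[str, float] | None = None,
) -> TranscriptomeModel:
    """Load a transcriptome FASTA; abundances default to 1 (or come from the
    ``abundance=`` tag this package writes)."""
    transcripts = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ab = 1.0
        if abundances and rec.id in abundances:
            ab = abundances[rec.id]
        else:
            for token in rec.description.split():
                if token.startswith("abundance="):
                    ab = float(token.split("=", 1)[1])
        transcripts.append(Transcript(rec.id, str(rec.seq), ab))
    return TranscriptomeModel(tuple(transcripts), target_id)


def write_fragments(frags: FragmentSet, path: str | os.PathLike) -> None:
    """BED-like TSV with a header row; transcript lengths are carried in
    ``#transcript_length`` comment lines so the file round-trips alone."""
    with open(path, "w") as fh:
        for tid in sorted(frags.transcript_lengths):
            fh.write(f"#transcript_length\t{tid}\t{frags.transcript_lengths[tid]}\n")
        fh.write("\t".join(FRAGMENT_HEADER) + "\n")
        df = frags.df
        out = pd.DataFrame(
            {
                "transcript_id": df["transcript_id"],
                "start": df["start"],
                "end": df["end"],
                "strand": df["strand"].map(_STRAND_OUT),
                "sample_id": df["sample_id"],
                "flag": df["flag"],
            }
        )
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_fragments(path: str | os.PathLike) -> FragmentSet:
    lengths: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#transcript_length"):
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError("malformed #transcript_length line", lineno)
                lengths[parts[1]] = int(parts[2])
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                if parts != FRAGMENT_HEADER:
                    raise ParseError(f"expected header {FRAGMENT_HEADER}, got {parts}", lineno)
                header = parts
                continue
            if len(parts) != len(FRAGMENT_HEADER):
                raise ParseError(f"expected {len(FRAGMENT_HEADER)} columns, got {len(parts)}", lineno)
            tid, start_s, end_s, strand_s, sample, flag = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno) from exc
            if end <= start or start < 0:
                raise ParseError(f"invalid interval [{start}, {end})", lineno)
            if strand_s not in _STRAND_IN:
                raise ParseError(f"unknown strand {strand_s!r}", lineno)
            if tid in lengths and end > lengths[tid]:
                raise ParseError(f"fragment end {end} exceeds length of {tid}", lineno)
            rows.append((sample, tid, start, end, _STRAND_IN[strand_s], flag))
        if header is None:
            raise ParseError("missing header line", 1)
    df = pd.DataFrame(rows, columns=["sample_id", "transcript_id", "start", "end", "strand", "flag"])
    if not lengths:
        lengths = df.groupby("transcript_id")["end"].max().astype(int).to_dict() if len(df) else {}
    for tid in df["transcript_id"].unique():
        lengths.setdefault(tid, int(df.loc[df["transcript_id"] == tid, "end"].max()))
    return FragmentSet(df, lengths)


def read_variant_positions(path: str | os.PathLike, transcript_id: str) -> list[int]:
    """0-based positions of VCF variant records on one transcript (for spacer
    polymorphism avoidance)."""
    from cyvcf2 import VCF

    return [v.POS - 1 for v in VCF(str(path)) if v.CHROM == transcript_id]


def write_counts(cm: CountMatrix, path: str | os.PathLike) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | os.PathLike) -> CountMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot parse count matrix: {exc}") from exc
    if not len(df.columns):
        raise ParseError("count matrix has no sample columns", 1)
    try:
        df = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-integer counts: {exc}") from exc
    return CountMatrix(df)


def write_design(design: SampleDesign, path: str | os.PathLike) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path: str | os.PathLike) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "condition", "batch", "timepoint", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"design file missing columns {missing}", 1)
    df["replicate"] = df["replicate"].astype(int)
    return SampleDesign.from_frame(df)
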