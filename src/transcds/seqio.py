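"""Nucleotide sequence primitives plus FASTA/GTF readers and writers.

Internal coordinates are always 0-based half-open on the input transcript in
input orientation; everything serialized to GTF is 1-based inclusive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Tuple

ALPHABET = frozenset("ACGTN")
STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TOOL_NAME = "transcds"


class FastaParseError(ValueError):
    """Malformed FASTA input (bad layout or disallowed characters)."""


@dataclass(frozen=True)
class ReferenceCds:
    """Annotated CDS interval on a transcript, in input orientation.

    ``start``/``end`` are 0-based half-open and cover the start codon and the
    stop codon when the corresponding completeness flag is set.  ``frame`` is
    the codon phase of the first base of the interval read in coding
    orientation (0 when the start codon is present).
    """

    start: int
    end: int
    strand: str = "+"  # "+" or "-"
    has_start: bool = True
    has_stop: bool = True
    frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid CDS interval [{self.start},{self.end})")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {self.frame}")
        if self.has_start and self.frame != 0:
            raise ValueError("a CDS that retains its start codon has frame 0")
        if self.has_start and self.has_stop and (self.end - self.start) % 3:
            raise ValueError("complete CDS length must be a multiple of 3")

    def validate_against(self, seq_len: int) -> None:
        if self.end > seq_len:
            raise ValueError(
                f"CDS end {self.end} beyond sequence length {seq_len}"
            )


@dataclass(frozen=True)
class Transcript:
    """A single transcript: identifier, uppercase ACGTN sequence, optional
    reference CDS annotation."""

    id: str
    seq: str
    annotation: Optional[ReferenceCds] = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"transcript id must be a non-empty word: {self.id!r}")
        if not self.seq:
            raise ValueError(f"transcript {self.id}: empty sequence")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id}: disallowed characters {sorted(bad)}"
            )
        if self.annotation is not None:
            self.annotation.validate_against(len(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    up = seq.upper()
    bad = set(up) - ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return up.translate(_COMPLEMENT)[::-1]


def _iter_fasta(handle: TextIO) -> Iterator[Tuple[str, str, int]]:
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks), header_line
            header = line[1:].split()[0] if len(line) > 1 else ""
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise FastaParseError(
                    f"line {lineno}: sequence data before any FASTA header"
                )
            chunks.append(line)
    if header is not None:
        yield header, "".join(chunks), header_line


def read_fasta(path: str | os.PathLike) -> list[Transcript]:
    """Read transcripts from a (possibly wrapped, possibly lowercase) FASTA file.

    Raises :class:`FastaParseError` naming the line for layout problems and the
    record id for alphabet problems.
    """
    out: list[Transcript] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for rec_id, seq, lineno in _iter_fasta(fh):
            if not rec_id:
                raise FastaParseError(f"line {lineno}: empty FASTA header")
            up = seq.upper()
            bad = set(up) - ALPHABET
            if bad:
                raise FastaParseError(
                    f"record {rec_id!r}: disallowed characters {sorted(bad)}"
                )
            try:
                out.append(Transcript(id=rec_id, seq=up))
            except ValueError as exc:
                raise FastaParseError(f"record {rec_id!r}: {exc}") from exc
    return out


def write_fasta(records: Iterable[Tuple[str, str]], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _oriented_regions(seq: str, call) -> Tuple[str, str, str]:
    """(utr5, cds, utr3) in reading orientation for a CdsCall-like object."""
    left, mid, right = seq[: call.start], seq[call.start: call.end], seq[call.end:]
    if call.strand == "-":
        return reverse_complement(right), reverse_complement(mid), reverse_complement(left)
    return left, mid, right


def write_outputs(calls: Sequence[tuple], outdir: str | os.PathLike,
                  source: str = TOOL_NAME) -> Tuple[str, str, str, str]:
    """Write the four-file output contract: CDS.fasta, UTR5.fasta, UTR3.fasta
    and predictions.gtf.

    ``calls`` is a sequence of ``(Transcript, CdsCall-or-None)``.  A FASTA
    record is emitted only when the corresponding region is non-empty; a GTF
    CDS line is emitted for every transcript with a call.  Minus-strand calls
    are reported in input-transcript coordinates with strand "-"; their FASTA
    regions are reverse-complemented into reading orientation.
    """
    seen: set[str] = set()
    for t, _ in calls:
        if t.id in seen:
            raise ValueError(f"duplicate transcript id {t.id!r}")
        seen.add(t.id)

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = tuple(
        os.path.join(outdir, name)
        for name in ("CDS.fasta", "UTR5.fasta", "UTR3.fasta", "predictions.gtf")
    )
    cds_rec, u5_rec, u3_rec, gtf_lines = [], [], [], []
    for t, call in calls:
        if call is None:
            continue
        utr5, cds, utr3 = _oriented_regions(t.seq, call)
        if cds:
            cds_rec.append((t.id, cds))
        if utr5:
            u5_rec.append((t.id, utr5))
        if utr3:
            u3_rec.append((t.id, utr3))
        gtf_frame = (3 - call.frame) % 3
        attrs = (
            f'has_start "{str(call.has_start).lower()}"; '
            f'has_stop "{str(call.has_stop).lower()}"; '
            f'model "{getattr(call, "model_tag", "full")}"; '
            f'gc_bin "{getattr(call, "gc_bin", 0)}";'
        )
        gtf_lines.append(
            "\t".join(
                (
                    t.id,
                    source,
                    "CDS",
                    str(call.start + 1),
                    str(call.end),
                    f"{call.log_score:.3f}",
                    call.strand,
                    str(gtf_frame),
                    attrs,
                )
            )
        )
    write_fasta(cds_rec, paths[0])
    write_fasta(u5_rec, paths[1])
    write_fasta(u3_rec, paths[2])
    with open(paths[3], "wt", encoding="utf-8") as fh:
        for line in gtf_lines:
            fh.write(line + "\n")
    return paths


def read_annotations_gtf(path: str | os.PathLike) -> dict[str, ReferenceCds]:
    """Read CDS feature lines from a 9-column GTF (the dialect written by
    :func:`write_outputs`) into per-transcript :class:`ReferenceCds`."""
    out: dict[str, ReferenceCds] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 GTF columns, got {len(cols)}")
            seqname, _src, feature, start, end, _score, strand, frame, attrs = cols
            if feature != "CDS":
                continue
            has_start = 'has_start "true"' in attrs
            has_stop = 'has_stop "true"' in attrs
            gtf_frame = int(frame) if frame in ("0", "1", "2") else 0
            out[seqname] = ReferenceCds(
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                has_start=has_start,
                has_stop=has_stop,
                frame=(3 - gtf_frame) % 3,
            )
    return out
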