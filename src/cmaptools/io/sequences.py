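"""Sequence and alignment format support: FASTA, A3M, Stockholm, JONES.

FASTA/A3M parsing is delegated to Bio.SeqIO and Stockholm to Bio.AlignIO;
this module only maps their records onto the package's two-tier sequence
hierarchy and applies the house conventions: gap characters '-' and '.'
are both accepted on read and normalized to '-', and A3M lowercase insert
states are kept verbatim unless ``strip_inserts`` is requested.
"""

from __future__ import annotations

from io import StringIO
from typing import TextIO

from Bio import AlignIO, SeqIO

from ..core import Sequence, SequenceFile
from ._registry import FormatError, FormatSpec, registry

_WRAP = 60


def _normalize_gaps(seq: str) -> str:
    return seq.replace(".", "-")


def _finalize(sf: SequenceFile) -> SequenceFile:
    lengths = {len(s) for s in sf.sequences}
    sf.is_alignment = len(lengths) == 1
    return sf


def read_fasta(stream: TextIO) -> SequenceFile:
    sf = SequenceFile(id="")
    for rec in SeqIO.parse(stream, "fasta"):
        header = rec.description or rec.id
        sf.add(Sequence(id=header, seq=_normalize_gaps(str(rec.seq))))
    if not sf.sequences:
        raise FormatError("no FASTA records found in stream")
    return _finalize(sf)


def write_fasta(stream: TextIO, sf: SequenceFile) -> None:
    for s in sf:
        stream.write(f">{s.id}\n")
        for pos in range(0, len(s.seq), _WRAP):
            stream.write(s.seq[pos : pos + _WRAP] + "\n")


def read_a3m(stream: TextIO, strip_inserts: bool = False) -> SequenceFile:
    """Read an A3M alignment.

    Lowercase letters are insert states relative to the match columns.  By
    default they are kept verbatim (sequences then differ in length); with
    ``strip_inserts`` they are removed, yielding a rectangular alignment
    over match columns only.
    """
    sf = SequenceFile(id="")
    for rec in SeqIO.parse(stream, "fasta"):
        body = _normalize_gaps(str(rec.seq))
        if strip_inserts:
            body = "".join(ch for ch in body if not ch.islower())
        sf.add(Sequence(id=rec.description or rec.id, seq=body))
    if not sf.sequences:
        raise FormatError("no A3M records found in stream")
    return _finalize(sf)


def write_a3m(stream: TextIO, sf: SequenceFile) -> None:
    # identical on-disk layout to FASTA; lowercase insert states pass through
    write_fasta(stream, sf)


def read_stockholm(stream: TextIO) -> SequenceFile:
    """Read a Stockholm alignment.

    Only sequence lines and the terminator are interpreted; ``#=`` markup
    lines are preserved verbatim as opaque remarks and are not regenerated
    on write.
    """
    text = stream.read()
    remarks = [
        line for line in text.splitlines() if line.startswith("#=")
    ]
    try:
        aln = AlignIO.read(StringIO(text), "stockholm")
    except ValueError as exc:
        raise FormatError(f"could not parse Stockholm stream: {exc}") from None
    sf = SequenceFile(id="", remarks=remarks)
    for rec in aln:
        sf.add(Sequence(id=rec.id, seq=_normalize_gaps(str(rec.seq))))
    return _finalize(sf)


def write_stockholm(stream: TextIO, sf: SequenceFile) -> None:
    lengths = {len(s) for s in sf.sequences}
    if len(lengths) > 1:
        raise FormatError(
            "Stockholm requires an alignment; sequences have unequal lengths"
        )
    stream.write("# STOCKHOLM 1.0\n")
    width = max((len(s.id) for s in sf), default=0)
    for s in sf:
        stream.write(f"{s.id.ljust(width)}  {s.seq}\n")
    stream.write("//\n")


def read_jones(stream: TextIO) -> SequenceFile:
    """Read a JONES (PSICOV-style) alignment: one sequence per line, no headers."""
    sf = SequenceFile(id="")
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if not all(ch.isalpha() or ch in "-." for ch in line):
            raise FormatError(
                f"unexpected characters in JONES sequence line {line!r}",
                line=lineno,
            )
        sf.add(Sequence(id=f"seq_{len(sf.sequences) + 1}", seq=_normalize_gaps(line)))
    if not sf.sequences:
        raise FormatError("no JONES sequence lines found in stream")
    return _finalize(sf)


def write_jones(stream: TextIO, sf: SequenceFile) -> None:
    for s in sf:
        stream.write(s.seq + "\n")


registry.register(
    FormatSpec(
        name="fasta",
        kind="sequence",
        columns=("header", "body"),
        lossy_fields=frozenset({"file.remarks"}),
        reader=read_fasta,
        writer=write_fasta,
        description="FASTA: '>' header plus wrapped sequence body",
    )
)
registry.register(
    FormatSpec(
        name="a3m",
        kind="sequence",
        columns=("header", "body"),
        lossy_fields=frozenset({"file.remarks"}),
        reader=read_a3m,
        writer=write_a3m,
        description="A3M: FASTA-like with lowercase insert states",
    )
)
registry.register(
    FormatSpec(
        name="stockholm",
        kind="sequence",
        columns=("id", "body"),
        lossy_fields=frozenset(),
        reader=read_stockholm,
        writer=write_stockholm,
        description="Stockholm 1.0 alignment ('# STOCKHOLM 1.0' ... '//')",
    )
)
registry.register(
    FormatSpec(
        name="jones",
        kind="sequence",
        columns=("body",),
        lossy_fields=frozenset({"sequence.id", "file.remarks"}),
        reader=read_jones,
        writer=write_jones,
        description="JONES: one aligned sequence per line, no headers",
    )
)
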