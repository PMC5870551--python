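"""Read, write and convert contact-prediction and sequence file formats.

Three entry points cover all registered dialects:

``read(source, format)``
    parse a path or text stream into a :class:`~cmaptools.core.ContactFile`
    or :class:`~cmaptools.core.SequenceFile`,
``write(target, format, obj)``
    render the hierarchy back out,
``convert(infile, informat, outfile, outformat)``
    the composition of the two.

``sniff_format`` guesses a format from structural signatures and refuses
(returns ``"unknown"``) rather than guessing when dialects are
indistinguishable.  The registry currently holds 17 contact dialects and 4
sequence formats; new dialects register a :class:`FormatSpec` and become
available to all three entry points and the command line.
"""

from __future__ import annotations

import contextlib
import logging
import os
from dataclasses import replace as _dc_replace
from typing import Union

from ..core import Contact, ContactFile, ContactMap, ContactStatus, Sequence, SequenceFile
from ._registry import FormatError, FormatRegistry, FormatSpec, registry
from . import contacts as _contacts  # noqa: F401  (registers contact dialects)
from . import sequences as _sequences  # noqa: F401  (registers sequence formats)

__all__ = [
    "read",
    "write",
    "convert",
    "sniff_format",
    "registry",
    "FormatSpec",
    "FormatRegistry",
    "FormatError",
    "restrict_to_representable",
]

logger = logging.getLogger(__name__)

PathOrStream = Union[str, os.PathLike, object]


def _open(source: PathOrStream, mode: str):
    if hasattr(source, "read") or hasattr(source, "write"):
        return contextlib.nullcontext(source)
    return open(source, mode)


def read(source: PathOrStream, format: str, **kwargs):
    """Parse ``source`` (path or text stream) in the named format.

    Returns a ContactFile for contact dialects and a SequenceFile for
    sequence formats.  Format-specific keywords (e.g. ``strip_inserts`` for
    A3M) are passed through to the dialect reader.
    """
    spec = registry.get(format)
    with _open(source, "r") as fh:
        return spec.reader(fh, **kwargs)


def write(target: PathOrStream, format: str, obj) -> None:
    """Render ``obj`` to ``target`` in the named format.

    Fields the dialect cannot carry are dropped and logged.  The output is
    guaranteed parseable by :func:`read` of the same format.
    """
    spec = registry.get(format)
    _check_kind(spec, obj)
    if spec.lossy_fields:
        logger.info(
            "%s cannot carry fields: %s", spec.name, ", ".join(sorted(spec.lossy_fields))
        )
    with _open(target, "w") as fh:
        spec.writer(fh, obj)


def _check_kind(spec: FormatSpec, obj) -> None:
    if spec.kind == "contact" and not isinstance(obj, ContactFile):
        raise ValueError(f"format {spec.name!r} expects a ContactFile")
    if spec.kind == "sequence" and not isinstance(obj, SequenceFile):
        raise ValueError(f"format {spec.name!r} expects a SequenceFile")


def convert(
    in_source: PathOrStream,
    in_format: str,
    out_target: PathOrStream,
    out_format: str,
):
    """Convert between two registered formats of the same kind.

    Behaviourally identical to ``write(out, out_format, read(in, in_format))``;
    the parsed object is returned for inspection.
    """
    in_spec = registry.get(in_format)
    out_spec = registry.get(out_format)
    if in_spec.kind != out_spec.kind:
        raise ValueError(
            f"cannot convert {in_spec.kind} format {in_spec.name!r} to "
            f"{out_spec.kind} format {out_spec.name!r}"
        )
    obj = read(in_source, in_format)
    write(out_target, out_format, obj)
    return obj


def sniff_format(source: PathOrStream) -> str:
    """Best-effort format detection from structural signatures.

    Recognizes the unambiguous signatures (CASP RR header, Stockholm magic,
    '>' records, square numeric matrices) and returns ``"unknown"`` instead
    of guessing between indistinguishable dialects (e.g. psicov vs
    metapsicov five-column tables).
    """
    with _open(source, "r") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return "unknown"
    first = lines[0].strip()
    if first.startswith("# STOCKHOLM"):
        return "stockholm"
    if first.upper().startswith("PFRMAT RR"):
        return "casprr"
    if first.upper().startswith("PFRMAT EPC"):
        return "epcmap"
    if first.startswith(">"):
        bodies = [ln for ln in lines if not ln.startswith(">")]
        if any(ch.islower() for body in bodies for ch in body):
            return "a3m"
        return "fasta"
    # square all-numeric matrix => ccmpred
    try:
        rows = [[float(tok) for tok in ln.split()] for ln in lines]
    except ValueError:
        return "unknown"
    n = len(rows)
    if n >= 2 and all(len(r) == n for r in rows):
        return "ccmpred"
    return "unknown"


# ---------------------------------------------------------------------------
# Round-trip support
# ---------------------------------------------------------------------------

def restrict_to_representable(obj, format: str):
    """Project a hierarchy onto the fields a dialect can carry.

    The result is what a lossless round-trip through ``format`` preserves:
    ``read(write(X, F), F) == restrict_to_representable(X, F)``.  Scores are
    rounded to the six decimals the writers emit; fields the dialect cannot
    carry are reset to their defaults.
    """
    spec = registry.get(format)
    if isinstance(obj, ContactFile):
        return _restrict_contact_file(obj, spec)
    if isinstance(obj, SequenceFile):
        return _restrict_sequence_file(obj, spec)
    raise TypeError(f"cannot restrict object of type {type(obj).__name__}")


def _restrict_contact_file(cfile: ContactFile, spec: FormatSpec) -> ContactFile:
    lossy = spec.lossy_fields
    out = ContactFile(
        id="",
        target=None if "file.target" in lossy else cfile.target,
        method=None if "file.method" in lossy else cfile.method,
        remarks=[] if "file.remarks" in lossy else list(cfile.remarks),
    )
    for k, cmap in enumerate(cfile.maps, start=1):
        seq = None
        if "map.sequence" not in lossy and cmap.sequence is not None:
            seq = Sequence(id=cfile.target or "seq", seq=cmap.sequence.seq)
        new = ContactMap(
            id=f"map_{k}",
            sequence=seq,
            length_hint=None if "map.length_hint" in lossy else cmap.length_hint,
        )
        for c in cmap:
            if "raw_score" in lossy:
                score = spec.lossy_score_value if spec.lossy_score_value is not None else 0.0
            else:
                score = round(c.raw_score, 6)
            new.add(
                Contact(
                    res1_index=c.pair[0],
                    res2_index=c.pair[1],
                    raw_score=score,
                    res1_code="X" if "res1_code" in lossy else c.canonicalize().res1_code,
                    res2_code="X" if "res2_code" in lossy else c.canonicalize().res2_code,
                    dist_lower=0.0 if "dist_lower" in lossy else c.dist_lower,
                    dist_upper=8.0 if "dist_upper" in lossy else c.dist_upper,
                )
            )
        out.add(new)
    return out


def _restrict_sequence_file(sf: SequenceFile, spec: FormatSpec) -> SequenceFile:
    lossy = spec.lossy_fields
    sequences = []
    for k, s in enumerate(sf.sequences, start=1):
        sid = f"seq_{k}" if "sequence.id" in lossy else s.id
        sequences.append(Sequence(id=sid, seq=s.seq.replace(".", "-")))
    lengths = {len(s.seq) for s in sequences}
    return SequenceFile(id="", sequences=sequences, is_alignment=len(lengths) == 1)
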