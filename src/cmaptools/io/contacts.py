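"""Parsers and writers for the 17 supported contact-prediction dialects.

Most predictor outputs are line-oriented tables differing only in column
order and delimiters, so they share one table-driven implementation
(:class:`ColumnDialect`).  CASP RR (stateful header/sequence/model blocks)
and the CCMpred square score matrix get dedicated readers/writers.

All indices are 1-based.  Contacts are canonicalized on read and duplicate
pairs follow the keep-first policy (a score-sorted file's first occurrence
is its best-ranked one).  Scores are written with six decimal places so
round-trips are bit-stable without scientific-notation surprises.
"""

from __future__ import annotations

import warnings
from io import StringIO
from typing import List, Optional, TextIO, Tuple

import numpy as np

from ..core import Contact, ContactFile, ContactMap, Sequence
from ._registry import FormatError, FormatSpec, registry

SCORE_FMT = "{:.6f}"

#: Contact/file fields a dialect could in principle carry.
_FIELD_UNIVERSE = frozenset(
    {
        "raw_score",
        "dist_lower",
        "dist_upper",
        "res1_code",
        "res2_code",
        "chain1",
        "chain2",
        "file.target",
        "file.method",
        "file.remarks",
        "map.sequence",
        "map.length_hint",
    }
)

_ROLE_TO_FIELD = {
    "score": "raw_score",
    "dlow": "dist_lower",
    "dup": "dist_upper",
    "aa1": "res1_code",
    "aa2": "res2_code",
}


def _single_map(cfile: ContactFile, name: str) -> ContactMap:
    if len(cfile.maps) != 1:
        raise FormatError(
            f"{name} holds exactly one contact map per file, got {len(cfile.maps)}"
        )
    return cfile.maps[0]


class ColumnDialect:
    """A line-oriented contact dialect described by an ordered column recipe.

    ``columns`` is a sequence of role tokens: ``i``/``j`` (indices),
    ``score``, ``dlow``/``dup`` (distance bounds), ``aa1``/``aa2``
    (one-letter codes), or ``=text`` for a fixed filler column that is
    written verbatim and ignored on read.
    """

    def __init__(
        self,
        name: str,
        columns: Tuple[str, ...],
        *,
        delimiter: Optional[str] = None,
        header_lines: Tuple[str, ...] = (),
        comment_prefixes: Tuple[str, ...] = ("#",),
        skip_first_line: bool = False,
        skip_nonrecord_lines: bool = False,
        missing_score: Optional[float] = None,
        description: str = "",
    ) -> None:
        self.name = name
        self.columns = columns
        self.delimiter = delimiter
        self.header_lines = header_lines
        self.comment_prefixes = comment_prefixes
        self.skip_first_line = skip_first_line
        self.skip_nonrecord_lines = skip_nonrecord_lines
        self.missing_score = missing_score
        roles = {c for c in columns if not c.startswith("=")}
        represented = {"res1_index", "res2_index"}
        represented |= {_ROLE_TO_FIELD[r] for r in roles if r in _ROLE_TO_FIELD}
        if missing_score is not None:
            represented.discard("raw_score")
        self.lossy_fields = frozenset(_FIELD_UNIVERSE - represented)
        self.description = description

    # -- reading ------------------------------------------------------------

    def _parse_line(self, tokens: List[str], lineno: int) -> Contact:
        if len(tokens) != len(self.columns):
            raise FormatError(
                f"expected {len(self.columns)} fields for {self.name}, "
                f"got {len(tokens)}",
                line=lineno,
            )
        fields = {}
        try:
            for role, tok in zip(self.columns, tokens):
                if role.startswith("="):
                    continue
                if role in ("i", "j"):
                    fields[role] = int(tok)
                elif role in ("score", "dlow", "dup"):
                    fields[role] = float(tok)
                elif role in ("aa1", "aa2"):
                    fields[role] = tok[:1].upper() or "X"
        except ValueError as exc:
            raise FormatError(str(exc), line=lineno) from None
        return Contact(
            res1_index=fields["i"],
            res2_index=fields["j"],
            raw_score=fields.get(
                "score", self.missing_score if self.missing_score is not None else 0.0
            ),
            res1_code=fields.get("aa1", "X"),
            res2_code=fields.get("aa2", "X"),
            dist_lower=fields.get("dlow", 0.0),
            dist_upper=fields.get("dup", 8.0),
        )

    def read(self, stream: TextIO) -> ContactFile:
        cmap = ContactMap(id="map_1")
        seen_record = False
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line:
                continue
            if self.skip_first_line and lineno == 1:
                continue
            if any(line.startswith(p) for p in self.comment_prefixes):
                continue
            tokens = (
                [t.strip() for t in line.split(self.delimiter)]
                if self.delimiter
                else line.split()
            )
            if self.skip_nonrecord_lines:
                first_role = self.columns[0]
                try:
                    int(tokens[0]) if first_role in ("i", "j") else None
                except ValueError:
                    continue
            cmap.add(self._parse_line(tokens, lineno))
            seen_record = True
        if not seen_record:
            raise FormatError(f"no {self.name} contact records found in stream")
        return ContactFile(id="", maps=[cmap])

    # -- writing ------------------------------------------------------------

    def _format_contact(self, c: Contact) -> str:
        sep = self.delimiter if self.delimiter else " "
        out = []
        for role in self.columns:
            if role.startswith("="):
                out.append(role[1:])
            elif role == "i":
                out.append(str(c.res1_index))
            elif role == "j":
                out.append(str(c.res2_index))
            elif role == "score":
                out.append(SCORE_FMT.format(c.raw_score))
            elif role == "dlow":
                out.append(f"{c.dist_lower:g}")
            elif role == "dup":
                out.append(f"{c.dist_upper:g}")
            elif role == "aa1":
                out.append(c.res1_code or "X")
            elif role == "aa2":
                out.append(c.res2_code or "X")
        return sep.join(out)

    def write(self, stream: TextIO, cfile: ContactFile) -> None:
        cmap = _single_map(cfile, self.name)
        for line in self.header_lines:
            stream.write(line + "\n")
        for c in cmap:
            stream.write(self._format_contact(c) + "\n")

    def spec(self) -> FormatSpec:
        return FormatSpec(
            name=self.name,
            kind="contact",
            columns=self.columns,
            lossy_fields=self.lossy_fields,
            reader=self.read,
            writer=self.write,
            description=self.description,
            lossy_score_value=self.missing_score,
        )


# ---------------------------------------------------------------------------
# CASP RR: header block, optional target sequence, one or more MODEL blocks
# ---------------------------------------------------------------------------

_CASP_LOSSY = frozenset(
    {"res1_code", "res2_code", "chain1", "chain2", "map.length_hint"}
)


def _is_sequence_line(line: str) -> bool:
    return bool(line) and all(ch.isalpha() or ch == "-" for ch in line)


def read_casprr(stream: TextIO) -> ContactFile:
    """Parse a CASP RR stream (PFRMAT RR header, sequence lines, records, END)."""
    cfile = ContactFile(id="")
    target: Optional[str] = None
    method_parts: List[str] = []
    remarks: List[str] = []
    cmap: Optional[ContactMap] = None
    seqbuf: List[str] = []
    n_maps = 0

    def close_map() -> None:
        nonlocal cmap, seqbuf
        if cmap is None:
            return
        if seqbuf:
            cmap.sequence = Sequence(id=target or "seq", seq="".join(seqbuf))
        cfile.add(cmap)
        cmap, seqbuf = None, []

    def open_map() -> ContactMap:
        nonlocal cmap, n_maps
        if cmap is None:
            n_maps += 1
            cmap = ContactMap(id=f"map_{n_maps}")
        return cmap

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        key = line.split()[0].upper()
        if key == "PFRMAT":
            continue
        if key == "TARGET":
            target = line.split(None, 1)[1].strip() if " " in line else None
            continue
        if key == "AUTHOR":
            continue
        if key == "REMARK":
            remarks.append(line.split(None, 1)[1].strip() if " " in line else "")
            continue
        if key == "METHOD":
            method_parts.append(line.split(None, 1)[1].strip() if " " in line else "")
            continue
        if key == "MODEL":
            close_map()
            open_map()
            continue
        if key in ("END", "ENDMDL"):
            close_map()
            continue
        tokens = line.split()
        if _is_sequence_line(line):
            open_map()
            seqbuf.append(line)
            continue
        if len(tokens) == 5:
            try:
                i, j = int(tokens[0]), int(tokens[1])
                dlow, dup, score = map(float, tokens[2:5])
            except ValueError as exc:
                raise FormatError(str(exc), line=lineno) from None
            open_map().add(
                Contact(i, j, raw_score=score, dist_lower=dlow, dist_upper=dup)
            )
            continue
        raise FormatError(f"unrecognized CASP RR line {line!r}", line=lineno)

    close_map()
    cfile.target = target
    cfile.method = "; ".join(method_parts) if method_parts else None
    cfile.remarks = remarks
    if not cfile.maps:
        # an empty RR file (header + END) is legal: one empty map
        cfile.add(ContactMap(id="map_1"))
    return cfile


def write_casprr(stream: TextIO, cfile: ContactFile) -> None:
    stream.write("PFRMAT RR\n")
    if cfile.target:
        stream.write(f"TARGET {cfile.target}\n")
    for r in cfile.remarks:
        stream.write(f"REMARK {r}\n")
    if cfile.method:
        stream.write(f"METHOD {cfile.method}\n")
    maps = cfile.maps or [ContactMap(id="map_1")]
    for k, cmap in enumerate(maps, start=1):
        stream.write(f"MODEL  {k}\n")
        if cmap.sequence is not None:
            body = cmap.sequence.seq
            for pos in range(0, len(body), 50):
                stream.write(body[pos : pos + 50] + "\n")
        for c in cmap:
            stream.write(
                f"{c.res1_index} {c.res2_index} {c.dist_lower:g} "
                f"{c.dist_upper:g} {SCORE_FMT.format(c.raw_score)}\n"
            )
        if k < len(maps):
            stream.write("ENDMDL\n")
    stream.write("END\n")


# ---------------------------------------------------------------------------
# CCMpred: dense L x L score matrix
# ---------------------------------------------------------------------------

_CCMPRED_LOSSY = frozenset(
    _FIELD_UNIVERSE - {"raw_score", "map.length_hint"}
)


def read_ccmpred(stream: TextIO) -> ContactFile:
    """Parse a square score matrix; strict-upper-triangle entries become contacts.

    Exact-zero off-diagonal cells are treated as "no prediction" and
    skipped.  On asymmetric input the upper-triangle value wins; a warning
    is raised when |m[i,j] - m[j,i]| exceeds 1e-6.
    """
    text = stream.read()
    if not text.strip():
        raise FormatError("empty ccmpred matrix stream")
    try:
        mat = np.loadtxt(StringIO(text), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"could not parse ccmpred matrix: {exc}") from None
    if mat.shape[0] != mat.shape[1]:
        raise FormatError(
            f"ccmpred matrix must be square, got shape {mat.shape[0]}x{mat.shape[1]}"
        )
    L = mat.shape[0]
    if not np.allclose(mat, mat.T, atol=1e-6):
        warnings.warn(
            "asymmetric ccmpred matrix: upper-triangle values take precedence"
        )
    cmap = ContactMap(id="map_1", length_hint=L)
    for i in range(L):
        for j in range(i + 1, L):
            if mat[i, j] != 0.0:
                cmap.add(Contact(i + 1, j + 1, raw_score=float(mat[i, j])))
    return ContactFile(id="", maps=[cmap])


def write_ccmpred(stream: TextIO, cfile: ContactFile) -> None:
    cmap = _single_map(cfile, "ccmpred")
    if cmap.length_hint is not None:
        L = cmap.length_hint
    elif cmap.sequence is not None:
        L = cmap.sequence.ungapped_length
    else:
        raise FormatError(
            "ccmpred output needs the sequence length: set length_hint or a sequence"
        )
    mat = np.zeros((L, L))
    for c in cmap:
        if c.res2_index > L:
            raise FormatError(
                f"contact ({c.res1_index}, {c.res2_index}) exceeds matrix size {L}"
            )
        mat[c.res1_index - 1, c.res2_index - 1] = c.raw_score
        mat[c.res2_index - 1, c.res1_index - 1] = c.raw_score
    for row in mat:
        stream.write(" ".join(SCORE_FMT.format(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Registry population
# ---------------------------------------------------------------------------

_COLUMN_DIALECTS = [
    ColumnDialect(
        "psicov",
        ("i", "j", "dlow", "dup", "score"),
        description="PSICOV: 'i j 0 8 score'",
    ),
    ColumnDialect(
        "metapsicov",
        ("i", "j", "dlow", "dup", "score"),
        header_lines=("# MetaPSICOV contact predictions",),
        description="MetaPSICOV: commented header then 'i j 0 8 score'",
    ),
    ColumnDialect(
        "gremlin",
        ("i", "j", "score"),
        header_lines=("i j score",),
        skip_first_line=True,
        description="Gremlin: one-line header then 'i j score'",
    ),
    ColumnDialect(
        "pconsc",
        ("i", "j", "score"),
        header_lines=("# Generated by PconsC",),
        description="PconsC: 'i j score'",
    ),
    ColumnDialect(
        "pconsc2",
        ("i", "j", "score"),
        header_lines=("# Generated by PconsC2",),
        description="PconsC2: 'i j score'",
    ),
    ColumnDialect(
        "pconsc3",
        ("i", "j", "score"),
        header_lines=("# Generated by PconsC3",),
        description="PconsC3: 'i j score'",
    ),
    ColumnDialect(
        "epcmap",
        ("i", "j", "score"),
        header_lines=("PFRMAT EPC-MAP", "METHOD EPC-Map"),
        skip_nonrecord_lines=True,
        description="EPC-Map: PFRMAT-like preamble then 'i j score' triples",
    ),
    ColumnDialect(
        "evfold",
        ("i", "aa1", "j", "aa2", "=0", "score"),
        delimiter=",",
        description="EVfold: 'i,aa_i,j,aa_j,f,score' (comma-separated)",
    ),
    ColumnDialect(
        "plmdca",
        ("i", "aa1", "j", "aa2", "=0", "score"),
        delimiter=",",
        description="plmDCA: 'i,aa_i,j,aa_j,f,score' (comma-separated)",
    ),
    ColumnDialect(
        "freecontact",
        ("i", "aa1", "j", "aa2", "=0.000000", "score"),
        description="FreeContact: 'i aa_i j aa_j mi_score score'",
    ),
    ColumnDialect(
        "bbcontacts",
        ("=bb", "=0.300", "=A", "score", "=1", "=first", "j", "i"),
        description=(
            "bbcontacts: '# header' then "
            "'identifier diversity direction viterbi_score indexpred state j i'"
        ),
        header_lines=(
            "#identifier diversity direction viterbi_score indexpred state res2 res1",
        ),
    ),
    ColumnDialect(
        "bclcontact",
        ("i", "aa1", "j", "aa2", "=0.0", "=0.0", "=0.0", "=0.0", "=0.0", "score"),
        description="BCL::Contact: 'i aa_i j aa_j s1 s2 s3 s4 s5 score'",
    ),
    ColumnDialect(
        "comsat",
        ("i", "aa1", "j", "aa2", "=Hx-Hy"),
        missing_score=1.0,
        description="COMSAT: 'i aa_i j aa_j helix_info' (no score column)",
    ),
    ColumnDialect(
        "mempack",
        ("i", "j", "score", "=H1-H2"),
        description="MEMPACK: 'i j score helix_pair'",
    ),
    ColumnDialect(
        "flib",
        ("i", "aa1", "j", "aa2", "score", "=flib"),
        description="FLIB: 'i aa_i j aa_j score source'",
    ),
]

for _d in _COLUMN_DIALECTS:
    registry.register(_d.spec())

registry.register(
    FormatSpec(
        name="casprr",
        kind="contact",
        columns=("i", "j", "dlow", "dup", "score"),
        lossy_fields=_CASP_LOSSY,
        reader=read_casprr,
        writer=write_casprr,
        description="CASP RR: PFRMAT RR header, target sequence, MODEL blocks, END",
    )
)

registry.register(
    FormatSpec(
        name="ccmpred",
        kind="contact",
        columns=("matrix",),
        lossy_fields=_CCMPRED_LOSSY,
        reader=read_ccmpred,
        writer=write_ccmpred,
        description="CCMpred: dense L x L whitespace-separated score matrix",
    )
)
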