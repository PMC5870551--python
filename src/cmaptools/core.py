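"""Core data model for residue-residue contact predictions.

Contact information lives in a three-tier hierarchy:

``Contact``
    a single scored residue pair,
``ContactMap``
    the ordered set of pairs making up one prediction (optionally carrying
    the target :class:`Sequence`),
``ContactFile``
    one or more maps plus file-level metadata.

Sequences use a two-tier hierarchy: ``Sequence`` inside ``SequenceFile``.

All residue indices are 1-based positions in the target sequence.  Pairs are
stored in canonical form (``res1_index < res2_index``); self-pairs are
rejected at construction because they indicate malformed input.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, List, Optional, Set, Tuple

__all__ = [
    "ContactStatus",
    "Contact",
    "ContactMap",
    "ContactFile",
    "Sequence",
    "SequenceFile",
    "DuplicateContactError",
    "satisfied_long_range_count",
    "DEFAULT_MIN_SEPARATION",
    "LONG_RANGE_SEPARATION",
]

#: Minimum sequence separation used when pruning trivial near-diagonal pairs
#: before evaluation (community convention).
DEFAULT_MIN_SEPARATION = 5

#: Conventional threshold above which a pair counts as "long range".
LONG_RANGE_SEPARATION = 23


class DuplicateContactError(ValueError):
    """Raised when a duplicate residue pair is added under policy ``error``."""


class ContactStatus(enum.Enum):
    """Classification of a predicted contact after comparison with a structure."""

    UNKNOWN = "unknown"
    TRUE_POSITIVE = "true_positive"
    FALSE_POSITIVE = "false_positive"


@dataclass
class Contact:
    """One residue pair with its score, distance bounds and match status.

    Parameters
    ----------
    res1_index, res2_index
        1-based residue positions in sequence numbering.
    raw_score
        Score on the predictor's native scale.
    res1_code, res2_code
        One-letter amino-acid codes, ``'X'`` when unknown.
    chain1, chain2
        Single-character chain identifiers, blank when unknown.
    scaled_score
        Min-max rescaled score in [0, 1]; ``None`` until set.
    dist_lower, dist_upper
        Distance bounds in Angstrom defining the contact (default 0-8).
    status
        Match classification; ``UNKNOWN`` unless set by :meth:`ContactMap.match`.
    """

    res1_index: int
    res2_index: int
    raw_score: float = 0.0
    res1_code: str = "X"
    res2_code: str = "X"
    chain1: str = ""
    chain2: str = ""
    scaled_score: Optional[float] = None
    dist_lower: float = 0.0
    dist_upper: float = 8.0
    status: ContactStatus = ContactStatus.UNKNOWN

    def __post_init__(self) -> None:
        if self.res1_index < 1 or self.res2_index < 1:
            raise ValueError(
                f"residue indices must be >= 1, got "
                f"({self.res1_index}, {self.res2_index})"
            )
        if self.res1_index == self.res2_index:
            raise ValueError(
                f"self-pair ({self.res1_index}, {self.res2_index}) is forbidden"
            )
        if not self.dist_lower < self.dist_upper:
            raise ValueError(
                f"dist_lower ({self.dist_lower}) must be < dist_upper "
                f"({self.dist_upper})"
            )

    @property
    def pair(self) -> Tuple[int, int]:
        """Canonical ``(min, max)`` index pair."""
        if self.res1_index < self.res2_index:
            return (self.res1_index, self.res2_index)
        return (self.res2_index, self.res1_index)

    @property
    def separation(self) -> int:
        """Sequence separation ``|res2 - res1|``."""
        return abs(self.res2_index - self.res1_index)

    @property
    def is_canonical(self) -> bool:
        return self.res1_index < self.res2_index

    def canonicalize(self) -> "Contact":
        """Return this contact with ``res1_index < res2_index``.

        Residue codes and chain labels are swapped consistently; scores and
        bounds are untouched.  A canonical contact is returned unchanged
        (same object).
        """
        if self.is_canonical:
            return self
        return replace(
            self,
            res1_index=self.res2_index,
            res2_index=self.res1_index,
            res1_code=self.res2_code,
            res2_code=self.res1_code,
            chain1=self.chain2,
            chain2=self.chain1,
        )


@dataclass
class Sequence:
    """A named amino-acid sequence; ``'-'`` marks alignment gaps."""

    id: str
    seq: str

    GAP = "-"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ungapped_length(self) -> int:
        return len(self.seq) - self.seq.count(self.GAP)

    @property
    def is_gapped(self) -> bool:
        return self.GAP in self.seq


class SequenceFile:
    """Ordered collection of :class:`Sequence` objects, optionally an alignment.

    When ``is_alignment`` is true all member sequences must have equal length
    (one column per position).  ``remarks`` holds opaque annotation lines
    preserved from formats that carry them (e.g. Stockholm markup).
    """

    def __init__(
        self,
        id: str = "",
        sequences: Optional[Iterable[Sequence]] = None,
        is_alignment: bool = False,
        remarks: Optional[List[str]] = None,
    ) -> None:
        self.id = id
        self.sequences: List[Sequence] = list(sequences or [])
        self.is_alignment = is_alignment
        self.remarks: List[str] = list(remarks or [])
        if self.is_alignment:
            self._check_rectangular()

    def _check_rectangular(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.sequences)

    def __getitem__(self, i: int) -> Sequence:
        return self.sequences[i]

    def add(self, seq: Sequence) -> None:
        self.sequences.append(seq)
        if self.is_alignment:
            self._check_rectangular()

    @property
    def alignment_length(self) -> int:
        if not self.sequences:
            return 0
        self._check_rectangular()
        return len(self.sequences[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceFile):
            return NotImplemented
        return (
            self.id == other.id
            and self.sequences == other.sequences
            and self.is_alignment == other.is_alignment
        )

    def __repr__(self) -> str:
        return (
            f"SequenceFile(id={self.id!r}, n={len(self)}, "
            f"is_alignment={self.is_alignment})"
        )


class ContactMap:
    """An ordered, duplicate-free collection of contacts for one prediction."""

    def __init__(
        self,
        id: str = "map_1",
        contacts: Optional[Iterable[Contact]] = None,
        sequence: Optional[Sequence] = None,
        length_hint: Optional[int] = None,
    ) -> None:
        self.id = id
        self.sequence = sequence
        self.length_hint = length_hint
        self._contacts: List[Contact] = []
        self._index: dict = {}
        for c in contacts or []:
            self.add(c)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._contacts)

    def __iter__(self) -> Iterator[Contact]:
        return iter(self._contacts)

    def __getitem__(self, i: int) -> Contact:
        return self._contacts[i]

    def __contains__(self, pair: Tuple[int, int]) -> bool:
        return tuple(sorted(pair)) in self._index

    @property
    def contacts(self) -> List[Contact]:
        return list(self._contacts)

    def pairs(self) -> Set[Tuple[int, int]]:
        """The set of canonical residue-index pairs."""
        return set(self._index)

    def get(self, pair: Tuple[int, int]) -> Optional[Contact]:
        i = self._index.get(tuple(sorted(pair)))
        return None if i is None else self._contacts[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactMap):
            return NotImplemented
        return (
            self.id == other.id
            and self._contacts == other._contacts
            and self.sequence == other.sequence
            and self.length_hint == other.length_hint
        )

    def __repr__(self) -> str:
        return f"ContactMap(id={self.id!r}, n={len(self)})"

    # -- construction -------------------------------------------------------

    def add(self, contact: Contact, on_duplicate: str = "keep_first") -> "ContactMap":
        """Add a contact (canonicalized first).

        ``on_duplicate`` governs pairs already present: ``keep_first``
        (default) discards the newcomer with a warning, ``replace`` swaps it
        in at the original position, ``error`` raises
        :class:`DuplicateContactError`.
        """
        if on_duplicate not in ("keep_first", "replace", "error"):
            raise ValueError(f"unknown duplicate policy {on_duplicate!r}")
        contact = contact.canonicalize()
        key = contact.pair
        if key in self._index:
            if on_duplicate == "error":
                raise DuplicateContactError(f"duplicate contact pair {key}")
            if on_duplicate == "replace":
                self._contacts[self._index[key]] = contact
            else:
                warnings.warn(f"duplicate contact pair {key} ignored (keep_first)")
        else:
            self._index[key] = len(self._contacts)
            self._contacts.append(contact)
        return self

    def _spawn(self, contacts: Iterable[Contact]) -> "ContactMap":
        new = ContactMap(
            id=self.id,
            sequence=self.sequence,
            length_hint=self.length_hint,
        )
        for c in contacts:
            new.add(c)
        return new

    # -- selection and transformation ---------------------------------------

    def sort(self, key: str = "raw_score_desc") -> "ContactMap":
        """Return a sorted copy.

        ``raw_score_desc`` orders by descending score, ties broken by
        ascending ``(res1_index, res2_index)`` for cross-platform
        determinism; ``pair_asc`` orders by the index pair alone.
        """
        if key == "raw_score_desc":
            ordered = sorted(self._contacts, key=lambda c: (-c.raw_score, c.pair))
        elif key == "pair_asc":
            ordered = sorted(self._contacts, key=lambda c: c.pair)
        else:
            raise ValueError(f"unknown sort key {key!r}")
        return self._spawn(ordered)

    def top_n(self, n: int) -> "ContactMap":
        """The ``n`` highest-scoring contacts (all of them when ``n`` >= size)."""
        if n < 0:
            raise ValueError(f"n must be >= 0, got {n}")
        return self._spawn(self.sort("raw_score_desc")._contacts[:n])

    def _resolve_length(self, L: Optional[int]) -> int:
        if L is not None:
            return L
        if self.length_hint is not None:
            return self.length_hint
        if self.sequence is not None:
            return self.sequence.ungapped_length
        raise ValueError(
            "target sequence length unknown: provide L, a length_hint or a sequence"
        )

    def select_by_l_factor(self, factor: float, L: Optional[int] = None) -> "ContactMap":
        """The top ``floor(factor * L)`` contacts.

        The count is rounded down to the nearest whole number of contacts.
        ``L`` defaults to the map's ``length_hint`` or the attached
        sequence's ungapped length.
        """
        if factor <= 0:
            raise ValueError(f"factor must be > 0, got {factor}")
        L = self._resolve_length(L)
        if L < 1:
            raise ValueError(f"L must be >= 1, got {L}")
        # round() guards against binary-float products like 0.3*10 = 2.999...96
        n = int(math.floor(round(factor * L, 9)))
        return self.top_n(n)

    def remove_neighbors(self, min_separation: int = DEFAULT_MIN_SEPARATION) -> "ContactMap":
        """Drop short-range pairs; keep ``res2 - res1 >= min_separation``."""
        if min_separation < 1:
            raise ValueError(f"min_separation must be >= 1, got {min_separation}")
        return self._spawn(
            c for c in self._contacts if c.separation >= min_separation
        )

    def rescale_scores(self) -> "ContactMap":
        """Min-max rescale raw scores into ``scaled_score`` in [0, 1].

        When all raw scores are equal the map carries no discriminative
        information; every scaled score is set to 0.0 with a warning.
        """
        if not self._contacts:
            raise ValueError("cannot rescale an empty contact map")
        lo = min(c.raw_score for c in self._contacts)
        hi = max(c.raw_score for c in self._contacts)
        if hi == lo:
            warnings.warn(
                "all raw scores identical; scaled_score set to 0.0 throughout"
            )
            return self._spawn(
                replace(c, scaled_score=0.0) for c in self._contacts
            )
        span = hi - lo
        return self._spawn(
            replace(c, scaled_score=(c.raw_score - lo) / span)
            for c in self._contacts
        )

    def shift_indices(self, offset: int) -> "ContactMap":
        """Renumber every contact by a constant offset (both indices)."""
        return self._spawn(
            replace(c, res1_index=c.res1_index + offset, res2_index=c.res2_index + offset)
            for c in self._contacts
        )

    # -- sequence association -----------------------------------------------

    def assign_sequence(self, seq: Sequence, validate: bool = False) -> "ContactMap":
        """Attach the target sequence; optionally validate indices and codes."""
        if seq.is_gapped:
            raise ValueError("target sequence must be gap-free")
        if validate:
            n = len(seq)
            for c in self._contacts:
                for idx, code in ((c.res1_index, c.res1_code), (c.res2_index, c.res2_code)):
                    if idx > n:
                        raise ValueError(
                            f"contact index {idx} exceeds sequence length {n}"
                        )
                    if code != "X" and seq.seq[idx - 1] != code:
                        raise ValueError(
                            f"residue code mismatch at position {idx}: "
                            f"contact says {code!r}, sequence says {seq.seq[idx - 1]!r}"
                        )
        self.sequence = seq
        return self

    # -- evaluation ---------------------------------------------------------

    def match(self, reference: "ContactMap", resolved: Set[int]) -> "ContactMap":
        """Classify every contact against a structure-derived reference map.

        A pair present in ``reference`` is a true positive; a pair absent
        from it with both residues in the ``resolved`` set is a false
        positive; a pair touching an unresolved residue is unevaluable and
        stays ``UNKNOWN``.  Returns a classified copy; neither input is
        modified.
        """
        refpairs = reference.pairs()
        classified = []
        for c in self._contacts:
            if c.res1_index in resolved and c.res2_index in resolved:
                status = (
                    ContactStatus.TRUE_POSITIVE
                    if c.pair in refpairs
                    else ContactStatus.FALSE_POSITIVE
                )
            else:
                status = ContactStatus.UNKNOWN
            classified.append(replace(c, status=status))
        return self._spawn(classified)

    @property
    def precision(self) -> float:
        """TP / (TP + FP) over classified contacts.

        Contacts with ``UNKNOWN`` status (unresolved structure residues) are
        unevaluable, not wrong: they are excluded from both numerator and
        denominator.  Raises when no contact has been classified.
        """
        tp = sum(1 for c in self._contacts if c.status is ContactStatus.TRUE_POSITIVE)
        fp = sum(1 for c in self._contacts if c.status is ContactStatus.FALSE_POSITIVE)
        if tp + fp == 0:
            raise ValueError(
                "nothing to evaluate: no contact has true/false-positive status "
                "(run match() first)"
            )
        return tp / (tp + fp)


def satisfied_long_range_count(
    model_map: ContactMap,
    predicted: ContactMap,
    min_separation: int = LONG_RANGE_SEPARATION,
) -> int:
    """Count predicted long-range pairs realized in a model's contact map.

    A predicted pair counts when its sequence separation is at least
    ``min_separation`` and the same pair occurs in ``model_map``.  Useful for
    scoring ab initio models by how many long-range predictions they fulfil.
    """
    model_pairs = model_map.pairs()
    return sum(
        1
        for c in predicted
        if c.separation >= min_separation and c.pair in model_pairs
    )


class ContactFile:
    """Top tier: one or more contact maps plus file-level metadata."""

    def __init__(
        self,
        id: str = "",
        maps: Optional[Iterable[ContactMap]] = None,
        method: Optional[str] = None,
        target: Optional[str] = None,
        remarks: Optional[List[str]] = None,
    ) -> None:
        self.id = id
        self.method = method
        self.target = target
        self.remarks: List[str] = list(remarks or [])
        self.maps: List[ContactMap] = []
        for m in maps or []:
            self.add(m)

    def add(self, cmap: ContactMap) -> None:
        if any(m.id == cmap.id for m in self.maps):
            raise ValueError(f"duplicate map id {cmap.id!r} within file")
        self.maps.append(cmap)

    def __len__(self) -> int:
        return len(self.maps)

    def __iter__(self) -> Iterator[ContactMap]:
        return iter(self.maps)

    def __getitem__(self, i: int) -> ContactMap:
        return self.maps[i]

    @property
    def top_map(self) -> ContactMap:
        if not self.maps:
            raise ValueError(f"contact file {self.id!r} holds no maps")
        return self.maps[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactFile):
            return NotImplemented
        return (
            self.id == other.id
            and self.method == other.method
            and self.target == other.target
            and self.remarks == other.remarks
            and self.maps == other.maps
        )

    def __repr__(self) -> str:
        return f"ContactFile(id={self.id!r}, n_maps={len(self)})"
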