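"""Observed contacts from protein structures and prediction evaluation.

A residue's representative point is its Cβ atom, falling back to Cα for
glycine or when Cβ is missing — the CASP convention.  Two residues are in
contact when their representative atoms lie within a distance cutoff
(default 8.0 Å, boundary inclusive).  Only the first MODEL of an ensemble
and a single chain are used per evaluation; alternate locations resolve to
the highest-occupancy conformer.

Precision curves follow the standard top-``floor(f·L)`` protocol: the
prediction is pruned of near-diagonal pairs, sorted by score, cut at each
``L``-factor, matched against the structure-derived reference map (built
with the same separation filter so the comparison is like-for-like) and
scored as TP/(TP+FP).  Factors whose selection contains no classifiable
contact are reported as gaps, not errors, so curves over many factors
still render.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence as Seq, Set, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import Contact, ContactMap, Sequence, DEFAULT_MIN_SEPARATION

__all__ = [
    "ResidueSite",
    "EvaluationResult",
    "read_structure",
    "renumber_sites",
    "apply_renumbering",
    "resolved_indices",
    "contacts_from_structure",
    "evaluate",
    "DEFAULT_DISTANCE_CUTOFF",
]

DEFAULT_DISTANCE_CUTOFF = 8.0


@dataclass(frozen=True)
class ResidueSite:
    """One residue's representative coordinate extracted from a structure."""

    chain: str
    residue_number: int  # author numbering as given in the coordinate file
    residue_name: str  # 3-letter code
    x: float
    y: float
    z: float
    atom_used: str  # "CB" or "CA"

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def _three_to_one(resname: str) -> str:
    from Bio.Data.IUPACData import protein_letters_3to1

    return protein_letters_3to1.get(resname.capitalize(), "X")


def read_structure(source, chain: Optional[str] = None) -> List[ResidueSite]:
    """Extract one ResidueSite per residue of a chain from PDB coordinates.

    Uses Cβ coordinates with Cα fallback (glycine, or Cβ absent); residues
    lacking both atoms are skipped as unresolved.  Only the first MODEL is
    read.  ``chain`` may be omitted for single-chain structures.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate minor PDB irregularities
        structure = PDBParser(QUIET=True).get_structure("structure", source)
    models = list(structure)
    if not models:
        raise ValueError("no ATOM records found in structure stream")
    model = models[0]
    chains = {c.id: c for c in model}
    if chain is None:
        if len(chains) != 1:
            raise ValueError(
                f"structure has chains {sorted(chains)}; specify one"
            )
        chain = next(iter(chains))
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} absent; structure has {sorted(chains)}"
        )
    sites: List[ResidueSite] = []
    for residue in chains[chain]:
        if residue.id[0] != " ":  # skip waters / hetero groups
            continue
        if "CB" in residue:
            atom, used = residue["CB"], "CB"
        elif "CA" in residue:
            atom, used = residue["CA"], "CA"
        else:
            continue
        x, y, z = (float(v) for v in atom.get_coord())
        sites.append(
            ResidueSite(
                chain=chain,
                residue_number=residue.id[1],
                residue_name=residue.resname,
                x=x,
                y=y,
                z=z,
                atom_used=used,
            )
        )
    if not sites:
        raise ValueError(f"chain {chain!r} contains no usable residues")
    return sites


def renumber_sites(
    sites: Seq[ResidueSite], target_sequence: Sequence
) -> Dict[int, int]:
    """Map author residue numbers onto 1-based target-sequence positions.

    Scans every constant offset and accepts the one at which each site's
    residue identity matches the target sequence exactly (sites with
    unknown identity match anything).  Refuses — demanding a manual offset
    — when no offset matches or several do; silent re-alignment would hide
    registration bugs.
    """
    if target_sequence.is_gapped:
        raise ValueError("target sequence must be gap-free")
    if len({s.chain for s in sites}) > 1:
        raise ValueError("renumbering expects sites from a single chain")
    target = target_sequence.seq
    numbers = [s.residue_number for s in sites]
    codes = [_three_to_one(s.residue_name) for s in sites]
    lo, hi = min(numbers), max(numbers)
    valid_offsets = []
    for offset in range(1 - lo, len(target) - hi + 1):
        if all(
            code == "X" or target[num + offset - 1] == code
            for num, code in zip(numbers, codes)
        ):
            valid_offsets.append(offset)
    if not valid_offsets:
        raise ValueError(
            "structure residues match no window of the target sequence; "
            "supply a manual offset"
        )
    if len(valid_offsets) > 1:
        raise ValueError(
            f"ambiguous placement: offsets {valid_offsets} all match; "
            "supply a manual offset"
        )
    offset = valid_offsets[0]
    return {num: num + offset for num in numbers}


def apply_renumbering(
    sites: Seq[ResidueSite], mapping: Dict[int, int]
) -> List[ResidueSite]:
    """Return sites renumbered through an author->sequence index mapping."""
    from dataclasses import replace

    return [replace(s, residue_number=mapping[s.residue_number]) for s in sites]


def resolved_indices(sites: Iterable[ResidueSite]) -> Set[int]:
    """The set of residue indices observed in the structure."""
    return {s.residue_number for s in sites}


def contacts_from_structure(
    sites: Seq[ResidueSite],
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    min_separation: int = 1,
) -> ContactMap:
    """All residue pairs within ``distance_cutoff`` Å (boundary inclusive).

    Pair indices are the sites' residue numbers; pairs closer in sequence
    than ``min_separation`` are excluded.  The extracted set is invariant
    to the input site order.
    """
    if len(sites) < 2:
        raise ValueError("need at least two residue sites")
    ordered = sorted(sites, key=lambda s: s.residue_number)
    coords = np.array([s.coord for s in ordered])
    dist = squareform(pdist(coords))
    cmap = ContactMap(id="structure")
    for a in range(len(ordered)):
        for b in range(a + 1, len(ordered)):
            i, j = ordered[a].residue_number, ordered[b].residue_number
            if j - i >= min_separation and dist[a, b] <= distance_cutoff:
                cmap.add(
                    Contact(
                        i,
                        j,
                        raw_score=1.0,
                        res1_code=_three_to_one(ordered[a].residue_name),
                        res2_code=_three_to_one(ordered[b].residue_name),
                        chain1=ordered[a].chain,
                        chain2=ordered[b].chain,
                        dist_lower=0.0,
                        dist_upper=distance_cutoff,
                    )
                )
    return cmap


@dataclass(frozen=True)
class EvaluationResult:
    """Precision of a prediction cut at one ``L``-factor."""

    factor: float
    n_selected: int
    n_tp: int
    n_fp: int
    n_unknown: int
    precision: Optional[float]  # None when no contact was classifiable

    def __post_init__(self) -> None:
        if self.n_selected != self.n_tp + self.n_fp + self.n_unknown:
            raise ValueError(
                "inconsistent counts: n_selected must equal n_tp + n_fp + n_unknown"
            )


def evaluate(
    predicted: ContactMap,
    sites: Seq[ResidueSite],
    L: Optional[int] = None,
    factors: Tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    min_separation: int = DEFAULT_MIN_SEPARATION,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
) -> List[EvaluationResult]:
    """Stepwise precision of a prediction against a structure.

    For each factor ``f`` (strictly increasing) the top ``floor(f·L)``
    contacts of the separation-filtered, score-sorted prediction are
    matched against the structure's contact map and scored as TP/(TP+FP);
    contacts touching unresolved residues count as unknown and are
    excluded from the ratio.
    """
    if not factors:
        raise ValueError("need at least one factor")
    if any(b <= a for a, b in zip(factors, factors[1:])):
        raise ValueError(f"factors must be strictly increasing, got {factors}")
    reference = contacts_from_structure(sites, distance_cutoff, min_separation)
    resolved = resolved_indices(sites)
    pool = predicted.remove_neighbors(min_separation).sort("raw_score_desc")
    if L is None:
        L = predicted._resolve_length(None)
    results = []
    for f in factors:
        selected = pool.select_by_l_factor(f, L)
        matched = selected.match(reference, resolved)
        n_tp = sum(1 for c in matched if c.status.value == "true_positive")
        n_fp = sum(1 for c in matched if c.status.value == "false_positive")
        n_unknown = len(matched) - n_tp - n_fp
        precision = n_tp / (n_tp + n_fp) if (n_tp + n_fp) else None
        results.append(
            EvaluationResult(
                factor=f,
                n_selected=len(matched),
                n_tp=n_tp,
                n_fp=n_fp,
                n_unknown=n_unknown,
                precision=precision,
            )
        )
    return results
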