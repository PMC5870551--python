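"""Deterministic synthetic data: toy chains, predictions, alignments.

Everything the package consumes can be generated here, so the full stack
is testable offline:

* ``synth_chain`` — a self-avoiding 3.8 Å-step walk in 3D.  ``compactness``
  interpolates between a persistent, nearly straight chain (0: only
  near-diagonal residue pairs fall within contact range) and a globule
  pulled toward its start (1: many long-range contacts).  This emulates
  chain connectivity and packing density only; it is not a physical fold.
* ``synth_prediction`` — a scored contact list with an exactly constructed
  true-positive fraction: TPs are drawn from a reference map and ranked
  above decoy pairs, so downstream precision values are known by
  construction rather than sampled.
* ``synth_alignment`` — an ancestor sequence with independent per-position
  mutations and gaps per member, giving direct control over redundancy
  (hence Neff) and coverage.

All generators draw from ``numpy.random.Generator(PCG64)`` seeded
explicitly; identical parameters yield byte-identical fixtures on every
platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Tuple

import numpy as np

from .core import Contact, ContactFile, ContactMap, Sequence, SequenceFile
from .structure import ResidueSite

__all__ = [
    "FixtureSpec",
    "synth_chain",
    "chain_to_pdb",
    "synth_prediction",
    "synth_alignment",
    "synth_contact_file",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

STEP_LENGTH = 3.8  # Å, the canonical Cα-Cα virtual bond length
_CLASH_DISTANCE = 3.9  # Å, minimum approach between non-bonded residues


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic scenario (chain + prediction)."""

    length: int = 50
    seed: int = 0
    step: float = STEP_LENGTH
    compactness: float = 0.0
    tp_fraction: float = 1.0
    n_predicted: int = 25


def synth_chain(
    length: int,
    seed: int = 0,
    step: float = STEP_LENGTH,
    compactness: float = 0.0,
) -> Tuple[List[ResidueSite], Sequence]:
    """Generate a self-avoiding chain of residue sites plus its sequence.

    ``compactness`` in [0, 1] trades chain persistence for a pull toward
    the chain origin: 0 gives an almost straight chain with few or no
    long-range contacts, values near 1 give a compact globule rich in
    them.  Deterministic for a given seed; raises after bounded retries if
    self-avoidance cannot be satisfied (lower the compactness).
    """
    if length < 2:
        raise ValueError(f"chain length must be >= 2, got {length}")
    if not 0 <= compactness <= 1:
        raise ValueError(f"compactness must be in [0, 1], got {compactness}")
    for attempt in range(25):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        coords = _attempt_walk(rng, length, step, compactness)
        if coords is not None:
            break
    else:
        raise RuntimeError(
            "self-avoiding walk failed after bounded retries; "
            "lower the compactness"
        )
    letters = rng.choice(list(AMINO_ACIDS), size=length)
    seq = Sequence(id=f"chain_{seed}", seq="".join(letters))
    sites = [
        ResidueSite(
            chain="A",
            residue_number=i + 1,
            residue_name=_ONE_TO_THREE[letters[i]],
            x=float(coords[i, 0]),
            y=float(coords[i, 1]),
            z=float(coords[i, 2]),
            atom_used="CA" if letters[i] == "G" else "CB",
        )
        for i in range(length)
    ]
    return sites, seq


def _attempt_walk(
    rng: np.random.Generator, length: int, step: float, compactness: float
) -> Optional[np.ndarray]:
    coords = np.zeros((length, 3))
    direction = _unit(rng.normal(size=3))
    # confinement radius: a sphere scaled to hold `length` residues at clash
    # spacing; compactness shrinks it toward the dense-packing limit
    radius = step * length ** (1 / 3) * (3.2 - 2.2 * compactness)
    for k in range(1, length):
        placed = False
        for t in range(300):
            # escalating noise lets the walk escape when the center pull
            # keeps steering it into its own chain
            noise = _unit(rng.normal(size=3))
            heading = (1.0 - compactness) * direction + (0.35 + 0.03 * t) * noise
            prev = coords[k - 1]
            if compactness > 0 and np.linalg.norm(prev) > radius:
                heading = heading + 1.5 * compactness * _unit(-prev)
            proposal = _unit(heading)
            candidate = prev + step * proposal
            if k < 2 or _clear(candidate, coords[: k - 1]):
                coords[k] = candidate
                direction = proposal
                placed = True
                break
        if not placed:
            return None
    return coords


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _clear(candidate: np.ndarray, others: np.ndarray) -> bool:
    return bool(
        np.all(np.linalg.norm(others - candidate, axis=1) >= _CLASH_DISTANCE)
    )


def chain_to_pdb(sites: List[ResidueSite], serial_start: int = 1) -> str:
    """Render residue sites as a PDB-format coordinate stream.

    Each residue gets a Cα record and (except glycine) a Cβ record at the
    site coordinate, which is what structure extraction reads back.
    """
    lines = []
    serial = serial_start
    for s in sites:
        for atom in ("CA", "CB"):
            if atom == "CB" and s.residue_name == "GLY":
                continue
            lines.append(
                f"ATOM  {serial:5d}  {atom:<3s}{s.residue_name:>4s} "
                f"{s.chain}{s.residue_number:4d}    "
                f"{s.x:8.3f}{s.y:8.3f}{s.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def synth_prediction(
    reference: ContactMap,
    n_predicted: int,
    tp_fraction: float,
    seed: int = 0,
    L: Optional[int] = None,
    min_separation: int = 1,
) -> ContactMap:
    """A scored prediction with an exactly constructed TP/FP composition.

    ``round(tp_fraction * n_predicted)`` pairs are sampled without
    replacement from the reference map and receive the highest scores
    (descending from 1.0); the remainder are decoys sampled from
    non-contact pairs at separation >= ``min_separation``.  Matched
    against the reference with all residues resolved, the prediction's
    precision at full selection equals the constructed fraction exactly.
    """
    if n_predicted < 1:
        raise ValueError("n_predicted must be >= 1")
    if not 0 <= tp_fraction <= 1:
        raise ValueError(f"tp_fraction must be in [0, 1], got {tp_fraction}")
    n_tp = round(tp_fraction * n_predicted)
    ref_pairs = sorted(reference.pairs())
    if n_tp > len(ref_pairs):
        raise ValueError(
            f"requested {n_tp} true pairs but reference holds only {len(ref_pairs)}"
        )
    if L is None:
        L = max((p[1] for p in ref_pairs), default=0)
        if L == 0:
            raise ValueError("cannot infer L from an empty reference; pass L")
    candidates = [
        p
        for p in combinations(range(1, L + 1), 2)
        if p[1] - p[0] >= min_separation and p not in reference.pairs()
    ]
    n_fp = n_predicted - n_tp
    if n_fp > len(candidates):
        raise ValueError(
            f"cannot draw {n_fp} decoys from {len(candidates)} non-contact pairs"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    tp_idx = rng.choice(len(ref_pairs), size=n_tp, replace=False)
    fp_idx = rng.choice(len(candidates), size=n_fp, replace=False)
    chosen = [ref_pairs[i] for i in sorted(tp_idx)] + [
        candidates[i] for i in sorted(fp_idx)
    ]
    cmap = ContactMap(id=f"prediction_{seed}", length_hint=L)
    for rank, (i, j) in enumerate(chosen):
        # strictly descending scores keep TPs ranked above every decoy
        score = round(1.0 - rank * 1e-3, 6)
        cmap.add(Contact(i, j, raw_score=score))
    return cmap


def synth_alignment(
    n: int,
    length: int,
    mutation_rate: float = 0.0,
    gap_rate: float = 0.0,
    seed: int = 0,
) -> SequenceFile:
    """An alignment of ``n`` descendants of one random ancestor.

    Each position of each non-query member independently mutates to a
    different residue with probability ``mutation_rate`` and is replaced
    by a gap with probability ``gap_rate``.  The first sequence is the
    ungapped ancestor (the query).
    """
    if n < 1:
        raise ValueError("need at least one sequence")
    for name, rate in (("mutation_rate", mutation_rate), ("gap_rate", gap_rate)):
        if not 0 <= rate < 1:
            raise ValueError(f"{name} must be in [0, 1), got {rate}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    alphabet = np.array(list(AMINO_ACIDS))
    ancestor = rng.choice(alphabet, size=length)
    sequences = [Sequence(id="seq_1", seq="".join(ancestor))]
    for k in range(2, n + 1):
        member = ancestor.copy()
        mutate = rng.random(length) < mutation_rate
        if mutate.any():
            # draw replacements guaranteed different from the original
            shifts = rng.integers(1, len(alphabet), size=int(mutate.sum()))
            original = np.searchsorted(alphabet, member[mutate])
            member[mutate] = alphabet[(original + shifts) % len(alphabet)]
        member[rng.random(length) < gap_rate] = "-"
        sequences.append(Sequence(id=f"seq_{k}", seq="".join(member)))
    return SequenceFile(id=f"aln_{seed}", sequences=sequences, is_alignment=True)


def synth_contact_file(
    n_contacts: int,
    L: int,
    seed: int = 0,
    n_maps: int = 1,
    with_sequence: bool = False,
) -> ContactFile:
    """A randomized ContactFile for round-trip and conversion testing.

    Scores are pre-rounded to the six decimals the writers emit; residue
    codes are drawn consistently per position so code-carrying dialects
    round-trip them.
    """
    if n_contacts > L * (L - 1) // 2:
        raise ValueError("more contacts requested than pairs available")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    letters = rng.choice(list(AMINO_ACIDS), size=L)
    cfile = ContactFile(id="", target=f"T{seed:04d}", method="synthetic scores")
    all_pairs = list(combinations(range(1, L + 1), 2))
    for m in range(1, n_maps + 1):
        idx = rng.choice(len(all_pairs), size=n_contacts, replace=False)
        cmap = ContactMap(id=f"map_{m}", length_hint=L)
        for k in sorted(idx):
            i, j = all_pairs[k]
            score = round(float(rng.uniform(0.000001, 1.0)), 6)
            cmap.add(
                Contact(
                    i,
                    j,
                    raw_score=score,
                    res1_code=str(letters[i - 1]),
                    res2_code=str(letters[j - 1]),
                )
            )
        if with_sequence:
            cmap.sequence = Sequence(id=cfile.target, seq="".join(letters))
        cfile.add(cmap)
    return cfile
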