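"""Independent brute-force oracles the implementation is checked against.

Deliberately naive: plain Python loops and set arithmetic, sharing no code
path with the package internals they verify.
"""

import math
from fractions import Fraction


def precision_oracle(predicted_pairs, reference_pairs, resolved):
    """TP/(TP+FP) by direct set membership; None when nothing classifiable."""
    tp = fp = 0
    for i, j in predicted_pairs:
        if i in resolved and j in resolved:
            if (i, j) in reference_pairs:
                tp += 1
            else:
                fp += 1
    if tp + fp == 0:
        return None
    return tp / (tp + fp)


def identity_oracle(a, b):
    """Matching non-gap columns over full length, by character loop."""
    assert len(a) == len(b)
    hits = 0
    for x, y in zip(a, b):
        if x == y and x != "-":
            hits += 1
    return hits / len(a)


def neff_oracle(rows, threshold):
    """Sum of inverse neighbourhood sizes over all O(N^2) pairs.

    The self-sequence always counts as a neighbour; accumulation is exact
    rational arithmetic.
    """
    n = len(rows)
    neff = Fraction(0)
    for i in range(n):
        neighbours = 0
        for j in range(n):
            if j == i or identity_oracle(rows[i], rows[j]) >= threshold - 1e-12:
                neighbours += 1
        neff += Fraction(1, neighbours)
    return float(neff)


def structure_contacts_oracle(sites, cutoff, min_separation):
    """All-pairs Euclidean distances; the set of in-contact index pairs."""
    pairs = set()
    for a in sites:
        for b in sites:
            i, j = a.residue_number, b.residue_number
            if j - i < min_separation:
                continue
            d = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
            if d <= cutoff:
                pairs.add((i, j))
    return pairs


def floor_l_factor_oracle(factor_tenths, L):
    """floor(f*L) in exact rational arithmetic, f given in tenths."""
    return int(Fraction(factor_tenths, 10) * L)
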