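"""Brute-force oracles kept independent of the library implementations."""

from __future__ import annotations

import math

WOBBLE = {
    ("A", "T"), ("T", "A"), ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"), ("G", "U"), ("U", "G"),
}


def can_pair(seq: str, i: int, j: int, unpaired=frozenset(), min_loop: int = 3) -> bool:
    if j - i <= min_loop or i in unpaired or j in unpaired:
        return False
    return (seq[i].upper(), seq[j].upper()) in WOBBLE


def enumerate_structures(seq: str, unpaired=frozenset()) -> list[frozenset]:
    """All legal nested structures (sets of pairs) by explicit recursion."""

    def rec(i: int, j: int) -> list[frozenset]:
        # half-open span [i, j)
        if j - i <= 0:
            return [frozenset()]
        b = j - 1
        out = list(rec(i, b))  # b unpaired
        for k in range(i, b):
            if can_pair(seq, k, b, unpaired):
                for left in rec(i, k):
                    for inner in rec(k + 1, b):
                        out.append(left | inner | {(k, b)})
        return out

    return rec(0, len(seq))


def max_pairs(seq: str, unpaired=frozenset()) -> int:
    """Exhaustive maximum pair count (no memoization, pure recursion)."""

    def rec(i: int, j: int) -> int:
        if j - i <= 1:
            return 0
        b = j - 1
        best = rec(i, b)
        for k in range(i, b):
            if can_pair(seq, k, b, unpaired):
                best = max(best, 1 + rec(i, k) + rec(k + 1, b))
        return best

    return rec(0, len(seq))


def ensemble_pair_prob(seq: str, beta: float, unpaired=frozenset()) -> dict:
    """Boltzmann pair probabilities by explicit enumeration."""
    structs = enumerate_structures(seq, unpaired)
    weights = [math.exp(beta * len(s)) for s in structs]
    z = sum(weights)
    probs: dict = {}
    for s, w in zip(structs, weights):
        for pair in s:
            probs[pair] = probs.get(pair, 0.0) + w / z
    return probs


def auc_rank_sum(scores, labels) -> float:
    """Probability-of-correct-ordering AUC with tie correction."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def tai_bruteforce(seq: str, w: dict) -> float:
    """Plain-product geometric mean over internal codons."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    body = codons[1:-1]
    prod = 1.0
    for c in body:
        prod *= w[c]
    return prod ** (1.0 / len(body))
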