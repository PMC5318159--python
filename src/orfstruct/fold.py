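"""Constraint-guided RNA secondary-structure prediction and the ORF-boundary
folding statistics built on it.

Two engines share one contract (MFE structure + base-pair probability
matrix, with hard unpaired constraints):

* the internal engine scores -1 per Watson-Crick or GU pair with a minimum
  hairpin loop of 3 nt and no stacking terms.  It is deliberately simple so
  that exhaustive enumeration is tractable and its optima and ensemble
  frequencies can be checked exactly;
* a thermodynamic adapter around the ViennaRNA bindings (optional import)
  for nearest-neighbor energies in kcal/mol.

Boundary statistics: for each adjacent ORF pair on one message, the window
-flank..+flank around the downstream start codon is folded (constrained by
DMS-derived unpaired calls when signal is available).  The per-position sum
of pairing probability into the downstream versus the upstream 60 nt
diagnoses the direction in which each position prefers to fold; a sharp
crossover at the start codon is the signature of ORF-centric structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dms import UNPAIRED_THRESHOLD, call_unpaired, normalize_reactivity
from .model import (
    CountTrack,
    GenomeAnnotation,
    Orf,
    StructureModel,
    region_profile,
    region_sequence,
)

MIN_LOOP = 3  # minimum hairpin loop length (nt between the arms of a pair)

_PAIRABLE = {
    ("A", "T"), ("T", "A"), ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"), ("G", "U"), ("U", "G"),
}


def pairable_matrix(seq: str, unpaired: set[int] | frozenset[int] = frozenset()) -> np.ndarray:
    """Boolean matrix: allowed[i, j] iff i<j can legally pair."""
    s = seq.upper()
    n = len(s)
    b = np.array(list(s))
    allowed = np.zeros((n, n), dtype=bool)
    for x, y in _PAIRABLE:
        allowed |= (b[:, None] == x) & (b[None, :] == y)
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    allowed &= jj - ii > MIN_LOOP
    if unpaired:
        idx = np.fromiter(unpaired, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValueError("constraint position outside sequence")
        allowed[idx, :] = False
        allowed[:, idx] = False
    return allowed


def _mfe_matrix(allowed: np.ndarray) -> np.ndarray:
    """Max-pairs DP table over half-open spans: M[i, j] = max pairs in [i, j)."""
    n = allowed.shape[0]
    M = np.full((n + 1, n + 1), -np.inf)  # invalid spans must not enter the max
    M[np.arange(n + 1), np.arange(n + 1)] = 0.0  # empty spans
    M[np.arange(n), np.arange(1, n + 1)] = 0.0  # single bases
    for j in range(2, n + 1):
        b = j - 1  # candidate 3' partner
        # score of closing pair (k, b): 1 + M[k+1, b]
        col = np.full(n, -np.inf)
        ks = np.flatnonzero(allowed[:, b])
        if ks.size:
            col[ks] = 1.0 + M[ks + 1, b]
        # M[i, j] = max(M[i, b], max_k>=i M[i, k] + col[k])
        with np.errstate(invalid="ignore"):
            cand = M[:j, :j] + col[None, :j]
            best = cand.max(axis=1)
            M[:j, j] = np.maximum(M[:j, b], best)
    return M


def _traceback(M: np.ndarray, allowed: np.ndarray) -> str:
    """Deterministic traceback; co-optimal ties prefer the pair with the
    smallest opening index."""
    n = allowed.shape[0]
    db = ["."] * n
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        while j - i >= 2:
            b = j - 1
            target = M[i, j]
            ks = np.flatnonzero(allowed[i:b, b]) + i
            hit = None
            for k in ks:
                if M[i, k] + 1.0 + M[k + 1, b] == target:
                    hit = k
                    break
            if hit is not None:
                db[hit], db[b] = "(", ")"
                stack.append((hit + 1, b))
                j = hit  # continue with [i, hit)
            else:
                j = b  # b unpaired
    return "".join(db)


def fold_constrained(
    seq: str,
    unpaired: set[int] | frozenset[int] = frozenset(),
    engine: str = "internal",
) -> StructureModel:
    """Minimum-free-energy structure subject to hard unpaired constraints.

    Internal engine: energy = -(number of pairs).  ``engine="vienna"``
    delegates to the ViennaRNA bindings (kcal/mol).
    """
    if engine == "vienna":
        return _vienna_fold(seq, unpaired)
    allowed = pairable_matrix(seq, unpaired)
    M = _mfe_matrix(allowed)
    db = _traceback(M, allowed)
    return StructureModel(
        seq=seq, dotbracket=db, energy=-float(M[0, len(seq)]),
        constraints=frozenset(unpaired), engine="internal",
    )


def _scaled_partition(
    allowed: np.ndarray, beta: float, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inside pass.  Q[i, j] is the scaled partition function of span [i, j);
    Qb[k, b] the scaled weight of all structures closed by pair (k, b)."""
    n = allowed.shape[0]
    u = 1.0 / scale
    wp = math.exp(beta) / scale**2
    Q = np.zeros((n + 1, n + 1))
    np.fill_diagonal(Q, 1.0)
    Qb = np.zeros((n, n))
    for j in range(1, n + 1):
        b = j - 1
        ks = np.flatnonzero(allowed[:, b])
        if ks.size:
            Qb[ks, b] = wp * Q[ks + 1, b]
        Q[:j, j] = u * Q[:j, b] + Q[:j, : b + 1] @ Qb[: b + 1, b]
    return Q, Qb


def pair_probabilities(
    seq: str,
    unpaired: set[int] | frozenset[int] = frozenset(),
    beta: float = 2.0,
    scale: float | None = None,
) -> np.ndarray:
    """Equilibrium base-pair probability matrix under the internal model.

    McCaskill-style inside/outside over the -1-per-pair energy model with
    Boltzmann weight exp(beta) per pair.  The matrix is symmetric, rows sum
    to at most 1, and constrained positions have zero pairing probability.
    Per-base scaling keeps the partition function in floating range; the
    scale is retried automatically on overflow/underflow.
    """
    n = len(seq)
    allowed = pairable_matrix(seq, unpaired)
    if n == 0:
        return np.zeros((0, 0))
    trial = scale if scale is not None else 1.0 + 0.6 * min(1.0, math.exp(beta) / 5.0)
    for _ in range(8):
        with np.errstate(over="ignore", invalid="ignore"):
            Q, Qb = _scaled_partition(allowed, beta, trial)
        qtot = Q[0, n]
        if not np.isfinite(qtot) or not np.isfinite(Qb).all():
            trial *= 1.6
            continue
        if qtot == 0.0:
            trial /= 1.6
            continue
        with np.errstate(over="ignore", invalid="ignore"):
            P = _outside(Q, Qb, allowed, beta, trial)
        if np.isfinite(P).all():
            return P
        trial *= 1.3
    raise FloatingPointError("partition function scaling failed to converge")


def _outside(
    Q: np.ndarray, Qb: np.ndarray, allowed: np.ndarray, beta: float, scale: float
) -> np.ndarray:
    n = allowed.shape[0]
    u = 1.0 / scale
    wp = math.exp(beta) / scale**2
    qtot = Q[0, n]
    OQ = np.zeros((n + 1, n + 1))  # OQ[i, m]: outside value of span [i, m)
    OQ[0, n] = 1.0
    P = np.zeros((n, n))
    for m in range(n - 1, -1, -1):
        # outside of helix-closing nonterminals with 3' index m: pair (a, m):
        # OB[a] = sum_{i <= a} OQ[i, m+1] * Q[i, a)   (Q is upper triangular)
        OB = Q[:n, :n].T @ OQ[:n, m + 1]
        a_idx = np.flatnonzero(allowed[:, m])
        if a_idx.size:
            P[a_idx, m] = OB[a_idx] * Qb[a_idx, m] / qtot
        # spans [i, m): base m unpaired in the enclosing span [i, m+1)
        OQ[: m + 1, m] = u * OQ[: m + 1, m + 1]
        # span [i, m) as the prefix left of a pair (m, b)
        bs = np.flatnonzero(allowed[m, :])
        if bs.size:
            OQ[: m + 1, m] += OQ[: m + 1, bs + 1] @ Qb[m, bs]
        # span [a+1, m) as the interior of a pair (a, m)
        if a_idx.size:
            OQ[a_idx + 1, m] += wp * OB[a_idx]
    return P + P.T  # values accumulated in the upper triangle (a < m)


def energy_per_nt(
    seq: str,
    unpaired: set[int] | frozenset[int] = frozenset(),
    engine: str = "internal",
) -> float:
    """-MFE/nt: pairs per nucleotide (internal) or kcal/mol/nt (vienna)."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    model = fold_constrained(seq, unpaired, engine=engine)
    return -model.energy / len(seq)


# ---------------------------------------------------------------------------
# ViennaRNA adapter

def _vienna_fold(seq: str, unpaired: set[int] | frozenset[int]) -> StructureModel:
    import RNA  # deferred: optional engine

    fc = RNA.fold_compound(seq.replace("T", "U").replace("t", "u"))
    for pos in unpaired:
        fc.hc_add_up(pos + 1)  # ViennaRNA positions are 1-based
    db, mfe = fc.mfe()
    return StructureModel(
        seq=seq, dotbracket=db, energy=float(mfe),
        constraints=frozenset(unpaired), engine="vienna",
    )


def vienna_pair_probabilities(
    seq: str, unpaired: set[int] | frozenset[int] = frozenset()
) -> np.ndarray:
    import RNA

    fc = RNA.fold_compound(seq.replace("T", "U").replace("t", "u"))
    for pos in unpaired:
        fc.hc_add_up(pos + 1)
    fc.pf()
    bpp = np.array(fc.bpp())[1:, 1:]  # drop the 0th padding row/column
    return bpp + bpp.T


# ---------------------------------------------------------------------------
# Boundary statistics


@dataclass
class BoundaryWindows:
    """Folded window around one downstream start codon."""

    upstream_id: str
    downstream_id: str
    seq: str
    constraints: frozenset[int]
    pair_prob: np.ndarray
    flank: int

    def per_base_pairing(self) -> np.ndarray:
        return self.pair_prob.sum(axis=1)


def fold_boundary(
    annotation: GenomeAnnotation,
    upstream: Orf,
    downstream: Orf,
    dms_track: CountTrack | None = None,
    flank: int = 250,
    threshold: float = UNPAIRED_THRESHOLD,
    beta: float = 2.0,
    engine: str = "internal",
) -> BoundaryWindows:
    """Fold -flank..+flank around the downstream start codon.

    When a DMS track is given, signal over the window is normalized (within
    the window) and A/C bases called unpaired at the threshold become hard
    constraints, mirroring constraint-guided prediction on real data.
    """
    seq = region_sequence(annotation, downstream, -flank, flank)
    constraints: frozenset[int] = frozenset()
    if dms_track is not None:
        raw = region_profile(dms_track, downstream, -flank, flank)
        profile = call_unpaired(normalize_reactivity(raw, seq), threshold=threshold)
        constraints = frozenset(np.flatnonzero(profile.unpaired_call).tolist())
    if engine == "vienna":
        P = vienna_pair_probabilities(seq, constraints)
    else:
        P = pair_probabilities(seq, constraints, beta=beta)
    return BoundaryWindows(
        upstream_id=upstream.id, downstream_id=downstream.id, seq=seq,
        constraints=constraints, pair_prob=P, flank=flank,
    )


def directionality_profile(
    boundaries: list[BoundaryWindows], window: int = 60
) -> pd.DataFrame:
    """Cross-pair down/up folding-directionality ratio per position.

    For each position the pairing probability into the downstream ``window``
    nt and into the upstream ``window`` nt is summed; sums are pooled across
    pairs and their ratio reported per offset from the downstream start
    codon.  Offsets where the pooled upstream sum is zero yield NaN.
    """
    if not boundaries:
        raise ValueError("no boundary windows given")
    flank = boundaries[0].flank
    L = 2 * flank
    down = np.zeros(L)
    up = np.zeros(L)
    for bw in boundaries:
        P = bw.pair_prob
        for i in range(L):
            down[i] += P[i, i + 1 : min(L, i + 1 + window)].sum()
            up[i] += P[i, max(0, i - window) : i].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(up > 0, down / up, np.nan)
    return pd.DataFrame(
        {"offset": np.arange(-flank, flank), "down_sum": down, "up_sum": up,
         "ratio": ratio, "n_pairs": len(boundaries)}
    )


def metagene_pairing(boundaries: list[BoundaryWindows]) -> pd.DataFrame:
    """Mean per-position total pairing probability across boundaries,
    aligned at the downstream start codon."""
    if not boundaries:
        return pd.DataFrame({"offset": [], "mean_pairing": []})
    flank = boundaries[0].flank
    acc = np.zeros(2 * flank)
    for bw in boundaries:
        acc += bw.per_base_pairing()
    return pd.DataFrame(
        {"offset": np.arange(-flank, flank), "mean_pairing": acc / len(boundaries)}
    )
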