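"""tRNA adaptation index (tAI).

The tAI of a gene is the geometric mean, over its codons (start and stop
excluded), of per-codon relative adaptiveness weights w.  Each codon's
absolute weight is the wobble-discounted tRNA supply

    W(codon) = sum over decoding anticodons of (1 - s) * tGCN(anticodon)

where tGCN is the tRNA gene copy number and s the selective inefficiency of
the codon:anticodon interaction (0 for Watson-Crick reading; larger for
wobble reading).  Weights are scaled to max 1, and codons with W = 0 take
the geometric mean of the nonzero weights so a single unmatched codon does
not zero an entire gene.  Computation is in log space to avoid underflow on
long genes.

Anticodons are indexed here by the codon they read via Watson-Crick pairing
(i.e. their reverse complement), which makes the wobble bookkeeping explicit:
a codon ending in U is also read by the anticodon that is Watson-Crick for
the synonymous C-ending codon (G:U wobble), C-ending codons by the
A34->inosine anticodon of the U-ending codon, A-ending codons by the same
inosine anticodon, and G-ending codons by the U34 anticodon of the A-ending
codon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenomeAnnotation, reverse_complement

BASES = "TCAG"
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
)

#: wobble inefficiencies (dos Reis parameterization): Watson-Crick readings
#: first (third base U, C, A, G), then the wobble readings G:U, I:C, I:A, U:G.
DEFAULT_S = {
    "wc_u": 0.0, "wc_c": 0.0, "wc_a": 0.0, "wc_g": 0.0,
    "gu": 0.41, "ic": 0.28, "ia": 0.9999, "ug": 0.68,
}

#: Synthetic illustrative tRNA gene copy numbers (one entry per anticodon,
#: keyed by the codon it reads Watson-Crick).  Deterministic, non-biological:
#: a fixed spread of small integers so that weights cover (0, 1] and some
#: anticodons are absent, as in real genomes.  Replace with a measured table
#: for organism-specific work.
SYNTHETIC_TGCN: dict[str, int] = {
    codon: int(1 + (7 * i + 3) % 6) if (i % 4) != 3 else 0
    for i, codon in enumerate(SENSE_CODONS)
}


@dataclass
class CodonWeights:
    """Relative adaptiveness per sense codon, scaled so max(w) = 1."""

    w: dict[str, float]
    s: dict[str, float]
    tgcn: dict[str, int]

    def __getitem__(self, codon: str) -> float:
        return self.w[codon.upper().replace("U", "T")]


def _wobble_partner(codon: str) -> tuple[str, str] | None:
    """(synonym codon whose WC anticodon wobble-reads this codon, s-key)."""
    head, third = codon[:2], codon[2]
    if third == "T":
        return head + "C", "gu"
    if third == "C":
        return head + "T", "ic"
    if third == "A":
        return head + "T", "ia"
    return head + "A", "ug"


def relative_adaptiveness(
    tgcn: dict[str, int] | None = None, s: dict[str, float] | None = None
) -> CodonWeights:
    """Codon weights w = W / max(W) from tRNA gene copy numbers.

    ``tgcn`` is keyed by the codon each anticodon reads Watson-Crick (use
    ``anticodon_to_codon_key`` to convert anticodon-keyed tables).  Codons
    with W = 0 are assigned the geometric mean of the nonzero weights.
    """
    tgcn = dict(SYNTHETIC_TGCN if tgcn is None else tgcn)
    s = dict(DEFAULT_S if s is None else s)
    for key, val in s.items():
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"s[{key!r}] outside [0, 1]")
    if any(v < 0 for v in tgcn.values()):
        raise ValueError("tGCN values must be >= 0")
    if all(v == 0 for v in tgcn.values()):
        raise ValueError("all tRNA gene copy numbers are zero")
    wc_key = {"T": "wc_u", "C": "wc_c", "A": "wc_a", "G": "wc_g"}
    W = {}
    for codon in SENSE_CODONS:
        total = (1.0 - s[wc_key[codon[2]]]) * tgcn.get(codon, 0)
        partner = _wobble_partner(codon)
        if partner is not None:
            syn, skey = partner
            if syn not in STOP_CODONS:
                total += (1.0 - s[skey]) * tgcn.get(syn, 0)
        W[codon] = total
    wmax = max(W.values())
    w = {c: v / wmax for c, v in W.items()}
    nonzero = [v for v in w.values() if v > 0]
    gm = math.exp(np.mean(np.log(nonzero)))
    w = {c: (v if v > 0 else gm) for c, v in w.items()}
    return CodonWeights(w=w, s=s, tgcn=tgcn)


def anticodon_to_codon_key(tgcn_by_anticodon: dict[str, int]) -> dict[str, int]:
    """Re-key an anticodon-indexed tGCN table by the codon read WC."""
    return {
        reverse_complement(ac.upper().replace("U", "T")): n
        for ac, n in tgcn_by_anticodon.items()
    }


def tai(sequence: str, weights: CodonWeights) -> float:
    """tAI of one coding sequence: geometric mean of w over codons 2..L-1.

    The start codon and the stop codon are excluded.  Raises on internal
    stop codons or a length that is not a multiple of 3.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) % 3 != 0 or len(seq) < 9:
        raise ValueError("coding sequence must be >= 3 codons and a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    body = codons[1:-1] if codons[-1] in STOP_CODONS else codons[1:]
    logs = []
    for c in body:
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c}")
        logs.append(math.log(weights.w[c]))
    return math.exp(float(np.mean(logs)))


def tai_table(
    annotation: GenomeAnnotation, weights: CodonWeights | None = None
) -> pd.DataFrame:
    """Per-gene tAI; genes with internal stops are flagged with NaN."""
    weights = weights or relative_adaptiveness()
    rows = []
    for orf in annotation.orfs:
        seq = annotation.orf_sequence(orf)
        try:
            value, flagged = tai(seq, weights), False
        except ValueError:
            value, flagged = math.nan, True
        rows.append({"orf_id": orf.id, "tai": value, "internal_stop": flagged})
    return pd.DataFrame(rows)
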