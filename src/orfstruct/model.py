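"""Shared domain types and coordinate conventions.

All internal coordinates are 0-based, half-open ``[start, end)``, on the
forward strand of a replicon.  Position 0 of any per-ORF vector is the first
nucleotide of the start codon in transcript (5'->3') orientation; minus-strand
ORFs are therefore reported reversed relative to genome order.

Intergenic spacing between adjacent ORFs A and B (same strand, A upstream in
transcript order) is ``start_B - end_A`` in these coordinates, so overlapping
stop/start codons give spacing <= 0 and the overlap test is a sign test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Orf:
    """One open reading frame.

    ``start``/``end`` are 0-based half-open genome coordinates; ``strand`` is
    ``"+"`` or ``"-"``; ``operon`` groups consecutive same-strand ORFs that
    are annotated as one transcription unit (may be ``None``).
    """

    id: str
    replicon: str
    start: int
    end: int
    strand: str
    operon: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_codons(self) -> int:
        return self.length // 3


@dataclass
class GenomeAnnotation:
    """Replicon sequences plus ORF/operon structure.

    ``sequences`` maps replicon name to its forward-strand sequence;
    ``orfs`` are sorted by (replicon, start).
    """

    sequences: dict[str, str]
    orfs: list[Orf]

    def __post_init__(self) -> None:
        self.orfs = sorted(self.orfs, key=lambda o: (o.replicon, o.start))
        self._by_id = {o.id: o for o in self.orfs}
        if len(self._by_id) != len(self.orfs):
            raise ValueError("duplicate ORF ids in annotation")
        self.validate()

    def validate(self) -> None:
        for orf in self.orfs:
            if orf.replicon not in self.sequences:
                raise ValueError(f"ORF {orf.id}: unknown replicon {orf.replicon!r}")
            n = len(self.sequences[orf.replicon])
            if not (0 <= orf.start < orf.end <= n):
                raise ValueError(
                    f"ORF {orf.id}: coordinates [{orf.start},{orf.end}) outside "
                    f"replicon {orf.replicon!r} of length {n}"
                )
            if orf.strand not in ("+", "-"):
                raise ValueError(f"ORF {orf.id}: bad strand {orf.strand!r}")
        for operon_id, members in self.operons().items():
            strands = {o.strand for o in members}
            if len(strands) > 1:
                raise ValueError(f"operon {operon_id}: mixed strands")

    def orf(self, orf_id: str) -> Orf:
        return self._by_id[orf_id]

    def operons(self) -> dict[str, list[Orf]]:
        """Operon id -> member ORFs sorted by genome position."""
        out: dict[str, list[Orf]] = {}
        for orf in self.orfs:
            if orf.operon is not None:
                out.setdefault(orf.operon, []).append(orf)
        return out

    def adjacent_pairs(self) -> list[tuple[Orf, Orf]]:
        """Consecutive ORF pairs within each operon, in transcript order.

        For minus-strand operons the transcript-upstream member is the one
        with the larger genome coordinate.
        """
        pairs = []
        for members in self.operons().values():
            if members and members[0].strand == "-":
                members = members[::-1]
            pairs.extend(zip(members[:-1], members[1:]))
        return pairs

    def orf_sequence(self, orf: Orf | str) -> str:
        """ORF sequence 5'->3' in transcript orientation."""
        if isinstance(orf, str):
            orf = self.orf(orf)
        s = self.sequences[orf.replicon][orf.start : orf.end]
        return reverse_complement(s) if orf.strand == "-" else s

    def in_frame_positions(self, orf: Orf) -> np.ndarray:
        """Transcript offsets of codon starts: 0, 3, 6, ..."""
        return np.arange(0, orf.length - orf.length % 3, 3)


def spacing(upstream: Orf, downstream: Orf) -> int:
    """Nt from the 3' end of the upstream stop codon to the 5' of the
    downstream start codon; <= 0 when the two ORFs overlap."""
    if upstream.strand != downstream.strand:
        raise ValueError("spacing is defined for same-strand pairs")
    if upstream.strand == "+":
        return downstream.start - upstream.end
    return upstream.start - downstream.end


class CountTrack:
    """Per-base non-negative counts for one sample over one genome.

    Counts are stored densely per (replicon, strand); ``total_assigned`` is
    the library size (sum over all positions, both strands).
    """

    def __init__(self, sample_id: str, sizes: dict[str, int]):
        self.sample_id = sample_id
        self.sizes = dict(sizes)
        self.counts: dict[tuple[str, str], np.ndarray] = {
            (rep, strand): np.zeros(n, dtype=float)
            for rep, n in sizes.items()
            for strand in ("+", "-")
        }

    @classmethod
    def from_annotation(cls, sample_id: str, annotation: GenomeAnnotation) -> "CountTrack":
        return cls(sample_id, {r: len(s) for r, s in annotation.sequences.items()})

    def array(self, replicon: str, strand: str) -> np.ndarray:
        return self.counts[(replicon, strand)]

    @property
    def total_assigned(self) -> float:
        return float(sum(a.sum() for a in self.counts.values()))

    def add(self, replicon: str, strand: str, start: int, end: int, value: float) -> None:
        if value < 0:
            raise ValueError("counts must be non-negative")
        arr = self.counts[(replicon, strand)]
        if not (0 <= start <= end <= arr.size):
            raise ValueError(f"interval [{start},{end}) outside replicon {replicon!r}")
        arr[start:end] += value

    def validate(self) -> None:
        for arr in self.counts.values():
            if (arr < 0).any():
                raise ValueError("negative count in track")


def orf_profile(track: CountTrack, orf: Orf) -> np.ndarray:
    """Per-base counts over an ORF in transcript orientation.

    Index 0 is the first nucleotide of the start codon.
    """
    arr = track.array(orf.replicon, orf.strand)
    window = arr[orf.start : orf.end]
    return window[::-1].copy() if orf.strand == "-" else window.copy()


def region_profile(
    track: CountTrack, orf: Orf, offset_start: int, offset_end: int
) -> np.ndarray:
    """Counts over ``[offset_start, offset_end)`` relative to the start codon,
    in transcript orientation.  Offsets may be negative (upstream)."""
    arr = track.array(orf.replicon, orf.strand)
    if orf.strand == "+":
        lo, hi = orf.start + offset_start, orf.start + offset_end
        if lo < 0 or hi > arr.size:
            raise ValueError("window outside replicon bounds")
        return arr[lo:hi].copy()
    # transcript 5' end of a minus-strand ORF is genome coordinate end-1
    hi, lo = orf.end - offset_start, orf.end - offset_end
    if lo < 0 or hi > arr.size:
        raise ValueError("window outside replicon bounds")
    return arr[lo:hi][::-1].copy()


def region_sequence(
    annotation: GenomeAnnotation, orf: Orf, offset_start: int, offset_end: int
) -> str:
    """Sequence over a start-codon-relative window, transcript orientation."""
    seq = annotation.sequences[orf.replicon]
    if orf.strand == "+":
        lo, hi = orf.start + offset_start, orf.start + offset_end
        if lo < 0 or hi > len(seq):
            raise ValueError("window outside replicon bounds")
        return seq[lo:hi]
    hi, lo = orf.end - offset_start, orf.end - offset_end
    if lo < 0 or hi > len(seq):
        raise ValueError("window outside replicon bounds")
    return reverse_complement(seq[lo:hi])


@dataclass
class ReactivityProfile:
    """Normalized DMS reactivities over one region, transcript orientation.

    ``values`` lie in [0, 1]; ``bases`` is the region sequence; calls are
    defined only where the base is A or C (DMS chemistry), tracked by
    ``is_ac``.  ``coverage`` is mean raw reads per nucleotide of the source
    region, used by depth filters.
    """

    values: np.ndarray
    bases: str
    coverage: float = 0.0
    unpaired_call: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.bases):
            raise ValueError("values and bases length mismatch")

    @property
    def is_ac(self) -> np.ndarray:
        b = np.array(list(self.bases.upper()))
        return (b == "A") | (b == "C")

    def ac_values(self) -> np.ndarray:
        return self.values[self.is_ac]


@dataclass
class StructureModel:
    """One secondary-structure model of a folded window.

    ``dotbracket`` is a balanced-parenthesis string; ``pair_prob`` is the
    symmetric base-pairing probability matrix (may be ``None`` when only the
    MFE structure was computed); ``energy`` is in the engine's units
    (pair-count units for the internal engine, kcal/mol for a thermodynamic
    engine); ``constraints`` are positions forced unpaired.
    """

    seq: str
    dotbracket: str
    energy: float
    pair_prob: np.ndarray | None = None
    constraints: frozenset[int] = field(default_factory=frozenset)
    engine: str = "internal"

    def __post_init__(self) -> None:
        if len(self.dotbracket) != len(self.seq):
            raise ValueError("dotbracket/sequence length mismatch")
        for i in self.constraints:
            if self.dotbracket[i] != ".":
                raise ValueError(f"constrained position {i} is paired in dotbracket")

    @property
    def n_pairs(self) -> int:
        return self.dotbracket.count("(")

    def pairs(self) -> list[tuple[int, int]]:
        stack: list[int] = []
        out: list[tuple[int, int]] = []
        for i, c in enumerate(self.dotbracket):
            if c == "(":
                stack.append(i)
            elif c == ")":
                out.append((stack.pop(), i))
        if stack:
            raise ValueError("unbalanced dotbracket")
        return sorted(out)

    def per_base_pairing(self) -> np.ndarray:
        """Total pairing probability per base, Sum_j P(i, j)."""
        if self.pair_prob is None:
            raise ValueError("no pair-probability matrix on this model")
        return self.pair_prob.sum(axis=1)
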