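"""Synthetic genomes, ground-truth structures, and count tracks.

The generator emulates the statistical structure the analysis assumes:

* operons of consecutive same-strand ORFs, most adjacent pairs separated by
  25 nt or less, a configurable fraction overlapping (spacing <= 0);
* per-ORF secondary structure built from tiled hairpins so that per-base
  paired/unpaired labels are exact ground truth, with an unstructured zone
  at each translation start;
* DMS-seq counts high at unpaired A/C, low (a "leak") at paired A/C, and at
  background level on G/U, drawn from a negative-binomial (Poisson-gamma)
  law to emulate library overdispersion;
* mRNA-seq counts uniform-with-noise along each transcription unit, with
  optional internal promoter/terminator breaks that split a unit's level;
* ribosome footprint counts proportional to mRNA level times a latent
  translation efficiency that is log-linearly anti-correlated with the
  ground-truth paired fraction.

Hairpin sequence design: 5' arms are drawn from {A, C}, 3' arms are their
reverse complements (in {T, G}), and every non-stem transcribed base is
drawn from {A, C}.  Consequences that the rest of the pipeline relies on:
the paired fraction over A/C bases is exactly the 5'-arm content and is
controllable analytically; noiseless reactivity plus the 0.2 call threshold
recovers the ground truth perfectly; and {A, C}-only spacer regions cannot
base-pair with each other, so designed hairpins are the only strong helices
available to a folding engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .model import (
    CountTrack,
    GenomeAnnotation,
    Orf,
    ReactivityProfile,
    reverse_complement,
    spacing,
)

AC = np.array(list("AC"))
DEFAULT_PAIRED_LEAK = 0.1
DEFAULT_GU_BACKGROUND = 0.05


# ---------------------------------------------------------------------------
# Truth container


@dataclass
class SimulationTruth:
    """Latent quantities behind a simulated dataset.

    ``per_orf`` columns: orf_id, operon, target_paired_fraction,
    realized_paired_fraction, and (after expression simulation) true_te and
    mrna_level.  ``paired`` maps (replicon, strand) to a genome-length
    boolean array of ground-truth paired positions.  ``pairs`` has one row
    per adjacent ORF pair within an operon: upstream_id, downstream_id,
    operon, spacing, same_message.
    """

    per_orf: pd.DataFrame
    paired: dict[tuple[str, str], np.ndarray]
    pairs: pd.DataFrame
    dotbrackets: dict[str, str] = field(default_factory=dict)

    def orf_paired(self, annotation: GenomeAnnotation, orf: Orf | str) -> np.ndarray:
        """Transcript-oriented per-base paired labels for one ORF."""
        if isinstance(orf, str):
            orf = annotation.orf(orf)
        lab = self.paired[(orf.replicon, orf.strand)][orf.start : orf.end]
        return lab[::-1].copy() if orf.strand == "-" else lab.copy()

    def paired_fraction(self, annotation: GenomeAnnotation, orf: Orf | str) -> float:
        """Realized fraction of A/C bases that are paired."""
        if isinstance(orf, str):
            orf = annotation.orf(orf)
        seq = np.array(list(annotation.orf_sequence(orf)))
        ac = (seq == "A") | (seq == "C")
        lab = self.orf_paired(annotation, orf)
        return float(lab[ac].mean()) if ac.any() else math.nan


# ---------------------------------------------------------------------------
# Genome layout


def _rand_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Random codons avoiding in-frame stop codons."""
    stops = {"TAA", "TAG", "TGA"}
    out = []
    bases = np.array(list("ACGT"))
    while len(out) < n_codons:
        c = "".join(rng.choice(bases, size=3))
        if c not in stops:
            out.append(c)
    return "".join(out)


def make_genome(
    n_operons: int,
    orfs_per_operon: tuple[int, int] = (2, 4),
    orf_len: tuple[int, int] = (300, 600),
    spacing_mean: float = 20.0,
    overlap_fraction: float = 0.15,
    seed: int = 0,
    pad: int = 300,
    operon_gap: int = 300,
    minus_fraction: float = 0.3,
    replicon: str = "chr",
) -> GenomeAnnotation:
    """Random operon-structured genome, deterministic for a fixed seed.

    ORF lengths are uniform multiples of 3 in ``orf_len``; intergenic
    spacings within operons are geometric with the given mean (so most
    pairs sit within ~25 nt), and a requested fraction of pairs overlaps
    with spacing -1 or -4 (stop/start sharing).  Operons are placed on the
    minus strand with probability ``minus_fraction``.
    """
    if orf_len[0] < 60 or orf_len[0] > orf_len[1]:
        raise ValueError("bad ORF length range")
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be a proportion")
    rng = np.random.default_rng(seed)
    chunks: list[str] = []
    orfs: list[Orf] = []
    cursor = 0

    def emit(block: str) -> int:
        nonlocal cursor
        chunks.append(block)
        start = cursor
        cursor += len(block)
        return start

    emit("".join(rng.choice(np.array(list("ACGT")), size=pad)))
    for op_idx in range(n_operons):
        n_orfs = int(rng.integers(orfs_per_operon[0], orfs_per_operon[1] + 1))
        strand = "-" if rng.random() < minus_fraction else "+"
        op_id = f"op{op_idx + 1:04d}"
        # build the operon block in transcript orientation
        lengths = [
            int(rng.integers(orf_len[0] // 3, orf_len[1] // 3 + 1)) * 3
            for _ in range(n_orfs)
        ]
        gaps = []
        for _ in range(max(0, n_orfs - 1)):
            if rng.random() < overlap_fraction:
                gaps.append(int(rng.choice([-1, -4])))
            else:
                gaps.append(1 + int(rng.geometric(1.0 / spacing_mean)))
        block = ""
        rel_coords = []
        for k, L in enumerate(lengths):
            if k > 0:
                g = gaps[k - 1]
                if g < 0:
                    block = block[:g]  # overlap eats into the upstream ORF end
                else:
                    block += "".join(rng.choice(AC, size=g))
            rel_start = len(block)
            block += "ATG" + _rand_codons(rng, L // 3 - 2) + "TAA"
            rel_coords.append((rel_start, rel_start + L))
        B = len(block)
        g0 = emit(block if strand == "+" else reverse_complement(block))
        for k, (rs, re_) in enumerate(rel_coords):
            if strand == "+":
                gs, ge = g0 + rs, g0 + re_
            else:
                gs, ge = g0 + B - re_, g0 + B - rs
            orfs.append(
                Orf(id=f"{op_id}_g{k + 1}", replicon=replicon, start=gs, end=ge,
                    strand=strand, operon=op_id)
            )
        emit("".join(rng.choice(np.array(list("ACGT")), size=operon_gap)))
    sequence = "".join(chunks)
    return GenomeAnnotation(sequences={replicon: sequence}, orfs=orfs)


# ---------------------------------------------------------------------------
# Ground-truth structures


def _resolve_paired_fraction(
    annotation: GenomeAnnotation,
    paired_fraction: float | tuple[float, float] | dict[str, float],
    rng: np.random.Generator,
) -> dict[str, float]:
    if isinstance(paired_fraction, dict):
        targets = dict(paired_fraction)
    elif isinstance(paired_fraction, tuple):
        lo, hi = paired_fraction
        targets = {o.id: float(rng.uniform(lo, hi)) for o in annotation.orfs}
    else:
        targets = {o.id: float(paired_fraction) for o in annotation.orfs}
    for oid, p in targets.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"paired fraction for {oid} outside [0, 1]")
    return targets


def _build_orf_structure(
    L: int,
    target: float,
    rng: np.random.Generator,
    hairpin_stem: int,
    loop: int,
    start_clear: int,
) -> tuple[str, np.ndarray, str]:
    """One ORF's transcript sequence, paired labels and dot-bracket.

    Solves for the total 5'-arm content x so that the realized fraction of
    A/C bases paired, x / (L - x - 3), hits the target (the 3 accounts for
    the non-A/C bases of the ATG/TAA codons).
    """
    clear = max(3, start_clear)
    interior_lo, interior_hi = clear, L - 3
    Li = interior_hi - interior_lo
    x = int(round(target * (L - 3) / (1.0 + target)))
    seq = np.empty(L, dtype="<U1")
    seq[:] = rng.choice(AC, size=L)
    seq[0:3] = list("ATG")
    seq[L - 3 : L] = list("TAA")
    paired = np.zeros(L, dtype=bool)
    db = np.full(L, ".", dtype="<U1")
    if x > 0:
        if 2 * x + loop > Li:
            raise ValueError(
                f"paired fraction {target:.2f} infeasible for ORF of length {L}"
            )
        n_h = max(1, min(x // max(1, hairpin_stem), (Li - 2 * x) // loop))
        arms = [x // n_h] * n_h
        for k in range(x % n_h):
            arms[k] += 1
        arms = [a for a in arms if a > 0]
        footprint = sum(2 * a + loop for a in arms)
        slack = Li - footprint
        # anchor the first hairpin at the start-clear edge and the last at
        # the stop codon; slack goes into the gaps between hairpins
        if len(arms) > 1:
            gaps = np.diff(np.floor(np.linspace(0, slack, len(arms))).astype(int))
            gap_sizes = [0] + list(gaps)
        else:
            gap_sizes = [slack]  # single big hairpin: anchor its 3' arm
        pos = interior_lo
        for a, g in zip(arms, gap_sizes):
            pos += int(g)
            arm1 = rng.choice(AC, size=a)
            seq[pos : pos + a] = arm1
            db[pos : pos + a] = "("
            paired[pos : pos + a] = True
            lp = pos + a
            seq[lp : lp + loop] = rng.choice(AC, size=loop)
            arm2_start = lp + loop
            seq[arm2_start : arm2_start + a] = list(
                reverse_complement("".join(arm1))
            )
            db[arm2_start : arm2_start + a] = ")"
            paired[arm2_start : arm2_start + a] = True
            pos = arm2_start + a
    return "".join(seq), paired, "".join(db)


def make_structures(
    annotation: GenomeAnnotation,
    paired_fraction: float | tuple[float, float] | dict[str, float],
    hairpin_stem: int = 6,
    loop: int = 4,
    start_clear: int = 25,
    boundary_violation: bool = False,
    seed: int = 0,
) -> tuple[GenomeAnnotation, SimulationTruth]:
    """Rewrite ORF sequences with tiled ground-truth hairpins.

    Returns a new annotation (sequences rewritten; coordinates unchanged)
    and the truth object with per-base paired labels, per-ORF realized
    paired fractions, and the adjacent-pair table.  Hairpins never span ORF
    boundaries unless ``boundary_violation`` is set, which adds one
    start-codon-crossing stem per operon (first junction).
    """
    rng = np.random.default_rng(seed)
    targets = _resolve_paired_fraction(annotation, paired_fraction, rng)
    seqs = {rep: np.array(list(s)) for rep, s in annotation.sequences.items()}
    paired = {
        (rep, strand): np.zeros(len(s), dtype=bool)
        for rep, s in annotation.sequences.items()
        for strand in ("+", "-")
    }
    # transcribed non-ORF sequence becomes {A,C} in transcript orientation
    for op_id, members in annotation.operons().items():
        strand = members[0].strand
        span = (min(o.start for o in members), max(o.end for o in members))
        block = rng.choice(AC, size=span[1] - span[0])
        if strand == "-":
            block = np.array(list(reverse_complement("".join(block))))
        seqs[members[0].replicon][span[0] : span[1]] = block

    dotbrackets: dict[str, str] = {}
    rows = []
    for orf in annotation.orfs:
        t = targets[orf.id]
        seq_t, paired_t, db = _build_orf_structure(
            orf.length, t, rng, hairpin_stem, loop, start_clear
        )
        if orf.strand == "+":
            seqs[orf.replicon][orf.start : orf.end] = list(seq_t)
            paired[(orf.replicon, "+")][orf.start : orf.end] = paired_t
        else:
            seqs[orf.replicon][orf.start : orf.end] = list(reverse_complement(seq_t))
            paired[(orf.replicon, "-")][orf.start : orf.end] = paired_t[::-1]
        dotbrackets[orf.id] = db
        rows.append({"orf_id": orf.id, "operon": orf.operon,
                     "target_paired_fraction": t})

    new_ann = GenomeAnnotation(
        sequences={rep: "".join(a) for rep, a in seqs.items()},
        orfs=list(annotation.orfs),
    )
    pair_rows = []
    for up, down in new_ann.adjacent_pairs():
        pair_rows.append(
            {"upstream_id": up.id, "downstream_id": down.id, "operon": up.operon,
             "spacing": spacing(up, down), "same_message": True}
        )
    truth = SimulationTruth(
        per_orf=pd.DataFrame(rows),
        paired=paired,
        pairs=pd.DataFrame(
            pair_rows,
            columns=["upstream_id", "downstream_id", "operon", "spacing", "same_message"],
        ),
        dotbrackets=dotbrackets,
    )
    if boundary_violation:
        _add_boundary_violations(new_ann, truth, rng, stem=8)
    truth.per_orf["realized_paired_fraction"] = [
        truth.paired_fraction(new_ann, oid) for oid in truth.per_orf["orf_id"]
    ]
    return new_ann, truth


def _add_boundary_violations(
    annotation: GenomeAnnotation, truth: SimulationTruth, rng: np.random.Generator,
    stem: int,
) -> None:
    """One stem per operon crossing the first internal start codon: the 5'
    arm sits at the end of the upstream ORF, the 3' arm just inside the
    downstream ORF."""
    seqs = {rep: np.array(list(s)) for rep, s in annotation.sequences.items()}
    done = set()
    for up, down in annotation.adjacent_pairs():
        if up.operon in done:
            continue
        done.add(up.operon)
        arm1 = rng.choice(AC, size=stem)
        arm2 = np.array(list(reverse_complement("".join(arm1))))
        # transcript offsets: arm1 ends 6 nt before the upstream stop codon;
        # arm2 starts 30 nt into the downstream ORF
        up_off = up.length - 3 - 6 - stem
        down_off = 30
        _write_transcript(seqs, up, up_off, arm1)
        _write_transcript(seqs, down, down_off, arm2)
        _label_transcript(truth.paired, up, up_off, stem)
        _label_transcript(truth.paired, down, down_off, stem)
    annotation.sequences = {rep: "".join(a) for rep, a in seqs.items()}


def _write_transcript(
    seqs: dict[str, np.ndarray], orf: Orf, offset: int, block: np.ndarray
) -> None:
    if orf.strand == "+":
        seqs[orf.replicon][orf.start + offset : orf.start + offset + block.size] = block
    else:
        rc = np.array(list(reverse_complement("".join(block))))
        hi = orf.end - offset
        seqs[orf.replicon][hi - block.size : hi] = rc


def _label_transcript(
    paired: dict[tuple[str, str], np.ndarray], orf: Orf, offset: int, n: int
) -> None:
    if orf.strand == "+":
        paired[(orf.replicon, "+")][orf.start + offset : orf.start + offset + n] = True
    else:
        hi = orf.end - offset
        paired[(orf.replicon, "-")][hi - n : hi] = True


# ---------------------------------------------------------------------------
# Count simulation


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Poisson-gamma draw: variance = mean * (1 + dispersion * mean)."""
    mean = np.clip(mean, 0.0, None)
    if dispersion <= 1e-12:
        return rng.poisson(mean).astype(float)
    shape = 1.0 / dispersion
    lam = mean * rng.gamma(shape, 1.0 / shape, size=mean.shape)
    return rng.poisson(lam).astype(float)


def _transcription_units(
    annotation: GenomeAnnotation, pairs: pd.DataFrame
) -> list[list[Orf]]:
    """Runs of ORFs joined by same_message junctions (per operon)."""
    same = {
        (r.upstream_id, r.downstream_id): bool(r.same_message)
        for r in pairs.itertuples()
    }
    units: list[list[Orf]] = []
    for members in annotation.operons().values():
        if members and members[0].strand == "-":
            members = members[::-1]
        unit = [members[0]]
        for up, down in zip(members[:-1], members[1:]):
            if same.get((up.id, down.id), True):
                unit.append(down)
            else:
                units.append(unit)
                unit = [down]
        units.append(unit)
    return units


def _unit_span(unit: list[Orf]) -> tuple[int, int]:
    return min(o.start for o in unit), max(o.end for o in unit)


def dms_rate_profile(
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    orf: Orf,
    paired_leak: float = DEFAULT_PAIRED_LEAK,
    gu_background: float = DEFAULT_GU_BACKGROUND,
) -> np.ndarray:
    """Relative DMS rate per transcript position of one ORF."""
    seq = np.array(list(annotation.orf_sequence(orf)))
    ac = (seq == "A") | (seq == "C")
    lab = truth.orf_paired(annotation, orf)
    rate = np.where(ac, np.where(lab, paired_leak, 1.0), gu_background)
    return rate


def expected_dms_means(
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    orf: Orf,
    depth: float,
    paired_leak: float = DEFAULT_PAIRED_LEAK,
    gu_background: float = DEFAULT_GU_BACKGROUND,
) -> tuple[np.ndarray, float]:
    """(per-position expected counts, k) for one ORF.

    k scales relative rates so the ORF-mean count equals ``depth``; the
    expected count at an unpaired A/C is depth * k.
    """
    rate = dms_rate_profile(annotation, truth, orf, paired_leak, gu_background)
    k = orf.length / rate.sum()
    return depth * k * rate, k


def simulate_dms_counts(
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    depth: float = 30.0,
    dispersion: float = 0.2,
    paired_leak: float = DEFAULT_PAIRED_LEAK,
    gu_background: float = DEFAULT_GU_BACKGROUND,
    depth_sigma: float = 0.0,
    depth_seed: int | None = None,
    seed: int = 0,
    sample_id: str = "dms",
) -> CountTrack:
    """DMS-seq 5'-end count track over all transcribed regions.

    ``depth`` is the target mean reads/nt over each ORF body; per-ORF rates
    are scaled so this holds in expectation regardless of structure content.
    ``depth_sigma`` adds per-ORF lognormal depth variation (expression
    spread), which coverage filters then act on; give replicates the same
    ``depth_seed`` so they share per-ORF abundances.  Transcribed intergenic
    positions use the operon-average scale.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    depth_rng = np.random.default_rng(seed if depth_seed is None else depth_seed)
    mult = {
        o.id: math.exp(depth_rng.normal(0.0, depth_sigma)) if depth_sigma > 0 else 1.0
        for o in annotation.orfs
    }
    track = CountTrack.from_annotation(sample_id, annotation)
    for members in annotation.operons().values():
        strand = members[0].strand
        rep = members[0].replicon
        span = _unit_span(members)
        arr = track.array(rep, strand)
        seq = np.array(list(annotation.sequences[rep][span[0] : span[1]]))
        if strand == "-":
            seq = np.array(list(reverse_complement("".join(seq))))[::-1]
        # seq is now the transcript base at each genome position
        ac = (seq == "A") | (seq == "C")
        lab = truth.paired[(rep, strand)][span[0] : span[1]]
        rate = np.where(ac, np.where(lab, paired_leak, 1.0), gu_background)
        k = np.empty(span[1] - span[0])
        k[:] = np.nan
        for o in members:
            sl = slice(o.start - span[0], o.end - span[0])
            k[sl] = mult[o.id] * o.length / rate[sl].sum()
        # transcribed gaps between ORFs take the operon-average scale
        k = pd.Series(k).ffill().bfill().to_numpy()
        mean = depth * k * rate
        arr[span[0] : span[1]] += _nb_sample(rng, mean, dispersion)
    return track


def simulate_expression(
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    te_model: tuple[float, float, float] = (0.0, 4.0, 0.3),
    mrna_depth: float = 50.0,
    ribo_depth: float = 50.0,
    dispersion: float = 0.2,
    break_fraction: float = 0.0,
    break_fold_range: tuple[float, float] = (2.5, 8.0),
    level_sigma: float = 0.5,
    ramp: tuple[float, int] | None = None,
    codon_pause: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[CountTrack, CountTrack]:
    """mRNA-seq and ribosome-footprint tracks from the latent TE model.

    ln(TE) = a - b * paired_fraction + Normal(0, sigma) per ORF.  Same-
    message stretches of an operon share one mRNA level (uniform coverage
    across member ORFs and their intergenic gaps); a ``break_fraction`` of
    junctions receives an internal promoter or terminator, which multiplies
    the downstream unit's level by a log-uniform fold (up or down) and
    leaves the junction's intergenic gap uncovered.  Ribosome counts are
    proportional to mRNA level times TE, with an optional constant ramp
    multiplier over the first ``ramp[1]`` codons and optional per-codon
    pause factors.  Returns (ribo_track, mrna_track).
    """
    a, b, sigma = te_model
    if b < 0:
        raise ValueError("te_model slope b must be >= 0")
    rng = np.random.default_rng(seed)
    per_orf = truth.per_orf.set_index("orf_id")
    pf = per_orf["realized_paired_fraction"]
    true_te = np.exp(a - b * pf + rng.normal(0.0, sigma, size=len(pf)))
    per_orf["true_te"] = true_te

    # internal promoter/terminator breaks
    is_break = rng.random(len(truth.pairs)) < break_fraction
    truth.pairs["same_message"] = ~is_break
    break_fold = {}
    lo, hi = np.log(break_fold_range[0]), np.log(break_fold_range[1])
    for row, brk in zip(truth.pairs.itertuples(), is_break):
        if brk:
            fold = math.exp(rng.uniform(lo, hi))
            direction = 1.0 if rng.random() < 0.5 else -1.0
            break_fold[(row.upstream_id, row.downstream_id)] = fold**direction

    units = _transcription_units(annotation, truth.pairs)
    operon_level = {
        op: math.exp(rng.normal(0.0, level_sigma))
        for op in annotation.operons()
    }
    # propagate break folds cumulatively along each operon
    unit_level: dict[int, float] = {}
    level_by_orf: dict[str, float] = {}
    prev_last: Orf | None = None
    running = 1.0
    for idx, unit in enumerate(units):
        op = unit[0].operon
        if prev_last is None or prev_last.operon != op:
            running = operon_level[op]
        else:
            running *= break_fold.get((prev_last.id, unit[0].id), 1.0)
        unit_level[idx] = running
        for o in unit:
            level_by_orf[o.id] = running
        prev_last = unit[-1]
    per_orf["mrna_level"] = pd.Series(level_by_orf)

    mrna = CountTrack.from_annotation("mrna", annotation)
    for idx, unit in enumerate(units):
        rep, strand = unit[0].replicon, unit[0].strand
        span = _unit_span(unit)
        mean = np.full(span[1] - span[0], mrna_depth * unit_level[idx])
        mrna.array(rep, strand)[span[0] : span[1]] += _nb_sample(rng, mean, dispersion)

    # ribosome footprints: per-ORF density proportional to level * TE,
    # cohort-scaled so the average ORF sits near ribo_depth reads/nt
    weights = {o.id: level_by_orf[o.id] * per_orf.loc[o.id, "true_te"]
               for o in annotation.orfs}
    scale = ribo_depth / np.mean(list(weights.values()))
    ribo = CountTrack.from_annotation("ribo", annotation)
    for orf in annotation.orfs:
        mean = np.full(orf.length, scale * weights[orf.id])
        if ramp is not None:
            factor, n_codons = ramp
            mean[: 3 * n_codons] *= factor
        if codon_pause:
            seq = annotation.orf_sequence(orf)
            for ci in range(orf.n_codons):
                f = codon_pause.get(seq[3 * ci : 3 * ci + 3])
                if f is not None:
                    mean[3 * ci : 3 * ci + 3] *= f
        counts = _nb_sample(rng, mean, dispersion)
        arr = ribo.array(orf.replicon, orf.strand)
        if orf.strand == "+":
            arr[orf.start : orf.end] += counts
        else:
            arr[orf.start : orf.end] += counts[::-1]
    truth.per_orf = per_orf.reset_index()
    return ribo, mrna


def truth_reactivity(
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    orf: Orf | str,
    paired_leak: float = DEFAULT_PAIRED_LEAK,
) -> ReactivityProfile:
    """Noiseless normalized reactivity of one ORF from the ground truth:
    1.0 at unpaired A/C, the leak at paired A/C, 0 at G/U."""
    if isinstance(orf, str):
        orf = annotation.orf(orf)
    seq = annotation.orf_sequence(orf)
    b = np.array(list(seq))
    ac = (b == "A") | (b == "C")
    lab = truth.orf_paired(annotation, orf)
    values = np.where(ac, np.where(lab, paired_leak, 1.0), 0.0)
    return ReactivityProfile(values=values, bases=seq, coverage=math.inf)


# ---------------------------------------------------------------------------
# Fixture bundles


@dataclass
class FixtureBundle:
    annotation: GenomeAnnotation
    truth: SimulationTruth
    tracks: dict[str, CountTrack]


def make_dataset(
    seed: int = 0,
    n_operons: int = 40,
    paired_fraction: float | tuple[float, float] | dict[str, float] = (0.0, 0.8),
    dms_depth: float = 30.0,
    mrna_depth: float = 50.0,
    ribo_depth: float = 50.0,
    dispersion: float = 0.2,
    te_model: tuple[float, float, float] = (0.0, 4.0, 0.3),
    break_fraction: float = 0.0,
    n_dms_replicates: int = 1,
    **genome_kw,
) -> FixtureBundle:
    """End-to-end simulated dataset with one seed controlling every stage."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 + n_dms_replicates)]
    ann0 = make_genome(n_operons, seed=seeds[0], **genome_kw)
    ann, truth = make_structures(ann0, paired_fraction, seed=seeds[1])
    ribo, mrna = simulate_expression(
        ann, truth, te_model=te_model, mrna_depth=mrna_depth, ribo_depth=ribo_depth,
        dispersion=dispersion, break_fraction=break_fraction, seed=seeds[2],
    )
    tracks = {"ribo": ribo, "mrna": mrna}
    for r in range(n_dms_replicates):
        name = "dms" if r == 0 else f"dms_rep{r + 1}"
        tracks[name] = simulate_dms_counts(
            ann, truth, depth=dms_depth, dispersion=dispersion,
            seed=seeds[4 + r], sample_id=name,
        )
    return FixtureBundle(annotation=ann, truth=truth, tracks=tracks)


def write_fixture(bundle: FixtureBundle, directory: str | Path) -> None:
    """Serialize a bundle to the package's on-disk formats plus truth TSVs."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    oio.write_annotation(bundle.annotation, d / "annotation.gff3", d / "genome.fasta")
    for name, track in bundle.tracks.items():
        oio.write_track(track, d / name)
    bundle.truth.per_orf.to_csv(d / "truth.tsv", sep="\t", index=False)
    bundle.truth.pairs.to_csv(d / "truth_pairs.tsv", sep="\t", index=False)
    paired_meta = {}
    for (rep, strand), arr in bundle.truth.paired.items():
        key = f"paired_{rep}_{'plus' if strand == '+' else 'minus'}"
        idx = np.flatnonzero(arr)
        paired_meta[key] = idx.tolist()
    with open(d / "truth_paired.json", "w") as fh:
        json.dump(paired_meta, fh)


def read_fixture(directory: str | Path) -> FixtureBundle:
    d = Path(directory)
    annotation = oio.read_annotation(d / "annotation.gff3", d / "genome.fasta")
    tracks = {}
    for libsize in sorted(d.glob("*.libsize.json")):
        name = libsize.name[: -len(".libsize.json")]
        tracks[name] = oio.read_track_bundle(annotation, d / name)
    per_orf = pd.read_csv(d / "truth.tsv", sep="\t")
    pairs = pd.read_csv(d / "truth_pairs.tsv", sep="\t")
    paired = {
        (rep, strand): np.zeros(len(s), dtype=bool)
        for rep, s in annotation.sequences.items()
        for strand in ("+", "-")
    }
    with open(d / "truth_paired.json") as fh:
        meta = json.load(fh)
    for key, idx in meta.items():
        _, rep, strand_name = key.split("_", 2)
        strand = "+" if strand_name == "plus" else "-"
        paired[(rep, strand)][np.asarray(idx, dtype=int)] = True
    truth = SimulationTruth(per_orf=per_orf, paired=paired, pairs=pairs)
    return FixtureBundle(annotation=annotation, truth=truth, tracks=tracks)
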