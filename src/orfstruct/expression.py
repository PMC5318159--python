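"""mRNA abundance, corrected ribosome footprint density, and translation
efficiency.

TE of an ORF is its average ribosome footprint density (reads/nt after
corrections) divided by its mRNA abundance (RPKM).  Footprint densities are
corrected in a fixed order: (1) the first and last five codons are masked
(initiation/termination artifacts); (2) the elevated density over the early
elongation ramp (first 50-100 codons) is divided out using a dataset-wide
per-codon-position profile; (3) an optional per-site anti-Shine-Dalgarno
weight is divided out; (4) remaining pause outliers are blunted by 90%
Winsorization (both tails capped at the 5th/95th percentiles).  Genes with
fewer than 128 footprint reads, or on the excluded-gene list
(selenoproteins, near-identical paralogs), carry QC flags instead of TE
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import CountTrack, GenomeAnnotation, Orf, orf_profile, spacing

#: unconventional-translation gene names excluded from TE analysis:
#: selenoproteins and near-identical paralog families
DEFAULT_EXCLUDED_GENES = (
    "fdhF", "fdoG", "fdnG",
    "gadA", "gadB", "ynaE", "ydfK", "ldrA", "ldrC",
    "ybfD", "yhhI", "tfaR", "tfaQ", "rzoD", "rzoR", "pinR", "pinQ",
)


@dataclass
class CorrectionConfig:
    """Knobs of the footprint-density correction cascade."""

    edge_codons_excluded: int = 5
    ramp_codons: int = 100  # extent of the early-elongation ramp correction
    asd_weights: np.ndarray | None = None  # per-position divisors, or off
    winsor_central: float = 0.90  # central fraction kept uncapped
    min_reads: int = 128
    excluded_genes: tuple[str, ...] = field(default=DEFAULT_EXCLUDED_GENES)

    def __post_init__(self) -> None:
        if not 0.0 < self.winsor_central <= 1.0:
            raise ValueError("winsor_central must be in (0, 1]")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")


def winsorize_two_sided(values: np.ndarray, central: float = 0.90) -> np.ndarray:
    """Cap both tails at the (1-central)/2 and 1-(1-central)/2 quantiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or central >= 1.0:
        return v.copy()
    tail = (1.0 - central) / 2.0
    lo, hi = np.quantile(v, [tail, 1.0 - tail])
    return np.clip(v, lo, hi)


def center_weighted_track(
    reads: list[tuple[str, str, int, int]],
    annotation: GenomeAnnotation,
    sample_id: str = "ribo",
    min_margin: int = 12,
) -> CountTrack:
    """Center-assignment transform for raw footprint intervals.

    Each read (replicon, strand, start, end) contributes a score of 1/N to
    each of the N center residues lying at least ``min_margin`` nt from
    either read end; reads too short to have a center are dropped.
    """
    track = CountTrack.from_annotation(sample_id, annotation)
    for rep, strand, start, end in reads:
        lo, hi = start + min_margin, end - min_margin
        if hi > lo:
            track.add(rep, strand, lo, hi, 1.0 / (hi - lo))
    return track


def mrna_rpkm(
    track: CountTrack, orf: Orf, library_size: float | None = None
) -> float:
    """mRNA abundance: Winsorized read count per kb per million library reads.

    Per-base counts over the ORF are 90% Winsorized (top and bottom 5%
    capped), summed, and scaled by 1e9 / (length * library size).
    """
    if orf.length <= 0:
        raise ValueError("zero-length ORF")
    lib = track.total_assigned if library_size is None else library_size
    if lib <= 0:
        raise ValueError("library size must be positive")
    counts = winsorize_two_sided(orf_profile(track, orf), 0.90)
    return float(counts.sum() * 1e9 / (orf.length * lib))


def estimate_ramp_profile(
    track: CountTrack,
    annotation: GenomeAnnotation,
    cfg: CorrectionConfig | None = None,
    min_mean: float = 1.0,
) -> np.ndarray:
    """Dataset-wide early-elongation ramp: mean relative density per codon
    position, normalized so the post-ramp plateau is 1.

    For each gene long enough to have a plateau, per-codon densities are
    divided by the gene's own plateau mean; the across-gene mean per codon
    position over the first ``ramp_codons`` codons is returned (floored at
    a small positive value so division is safe).
    """
    cfg = cfg or CorrectionConfig()
    edge, span = cfg.edge_codons_excluded, cfg.ramp_codons
    acc = np.zeros(span)
    n = np.zeros(span)
    for orf in annotation.orfs:
        nc = orf.n_codons
        if nc <= span + edge + 10:
            continue
        prof = orf_profile(track, orf)[: nc * 3].reshape(nc, 3).sum(axis=1)
        plateau = prof[span : nc - edge]
        if plateau.mean() < min_mean * 3:
            continue
        rel = prof[:span] / plateau.mean()
        acc += rel
        n += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(n > 0, acc / np.maximum(n, 1), 1.0)
    return np.maximum(profile, 1e-6)


def footprint_density(
    track: CountTrack,
    orf: Orf,
    cfg: CorrectionConfig | None = None,
    ramp_profile: np.ndarray | None = None,
) -> float:
    """Corrected average footprint density (reads/nt) of one ORF.

    Correction order is fixed: edge-codon masking, ramp division, optional
    aSD division, then 90% Winsorization; density is the corrected sum over
    the corrected length.
    """
    cfg = cfg or CorrectionConfig()
    prof = orf_profile(track, orf).astype(float)
    nc = orf.n_codons
    edge = cfg.edge_codons_excluded
    if nc <= 2 * edge + 1:
        return float("nan")
    prof = prof[: nc * 3].copy()
    if ramp_profile is not None:
        span = min(ramp_profile.size, nc)
        per_codon = np.repeat(ramp_profile[:span], 3)
        prof[: span * 3] /= per_codon
    if cfg.asd_weights is not None:
        w = np.asarray(cfg.asd_weights, dtype=float)
        if w.size < prof.size:
            w = np.pad(w, (0, prof.size - w.size), constant_values=1.0)
        prof = prof / w[: prof.size]
    body = prof[edge * 3 : (nc - edge) * 3]
    if body.size < 3:
        return float("nan")
    body = winsorize_two_sided(body, cfg.winsor_central)
    return float(body.sum() / body.size)


def expression_table(
    ribo: CountTrack,
    mrna: CountTrack,
    annotation: GenomeAnnotation,
    cfg: CorrectionConfig | None = None,
    apply_ramp: bool = True,
) -> pd.DataFrame:
    """Per-ORF RPKM, corrected density, TE, and QC flags.

    TE is defined only for genes with positive RPKM, at least
    ``cfg.min_reads`` footprint reads, and no exclusion flag; other genes
    keep NaN TE plus the reason in the flag columns.
    """
    cfg = cfg or CorrectionConfig()
    ramp = estimate_ramp_profile(ribo, annotation, cfg) if apply_ramp else None
    lib = mrna.total_assigned
    rows = []
    for orf in annotation.orfs:
        raw_reads = float(orf_profile(ribo, orf).sum())
        rpkm = mrna_rpkm(mrna, orf, lib)
        density = footprint_density(ribo, orf, cfg, ramp)
        low_reads = raw_reads < cfg.min_reads
        excluded = orf.id in cfg.excluded_genes
        ok = (not low_reads) and (not excluded) and rpkm > 0 and np.isfinite(density)
        rows.append(
            {
                "orf_id": orf.id, "operon": orf.operon, "length": orf.length,
                "fp_reads": raw_reads, "rpkm": rpkm, "density": density,
                "te": density / rpkm if ok else np.nan,
                "low_reads": low_reads, "excluded_gene": excluded,
                "zero_rpkm": rpkm <= 0,
            }
        )
    return pd.DataFrame(rows)


def adjacent_te_ratios(
    pairs: pd.DataFrame, table: pd.DataFrame
) -> tuple[pd.DataFrame, float, float]:
    """Downstream/upstream TE ratios for adjacent pairs, split by overlap.

    Pairs missing either TE are dropped.  Returns the per-pair table plus
    the two-sample Kolmogorov-Smirnov statistic and p-value comparing the
    log-ratio distributions of overlapping (spacing <= 0) versus
    non-overlapping pairs (NaN when either class is empty).
    """
    te = table.set_index("orf_id")["te"]
    rows = []
    for r in pairs.itertuples():
        t_up, t_down = te.get(r.upstream_id, np.nan), te.get(r.downstream_id, np.nan)
        if not (np.isfinite(t_up) and np.isfinite(t_down)) or t_up <= 0:
            continue
        rows.append(
            {
                "upstream_id": r.upstream_id, "downstream_id": r.downstream_id,
                "spacing": r.spacing,
                "overlap_class": "overlapping" if r.spacing <= 0 else "non_overlapping",
                "te_ratio": t_down / t_up,
            }
        )
    df = pd.DataFrame(
        rows, columns=["upstream_id", "downstream_id", "spacing", "overlap_class", "te_ratio"]
    )
    ov = np.log(df.loc[df.overlap_class == "overlapping", "te_ratio"])
    non = np.log(df.loc[df.overlap_class == "non_overlapping", "te_ratio"])
    if len(ov) and len(non):
        ks = sps.ks_2samp(ov, non)
        return df, float(ks.statistic), float(ks.pvalue)
    return df, float("nan"), float("nan")


def te_pairs_from_annotation(annotation: GenomeAnnotation) -> pd.DataFrame:
    """Adjacent-pair skeleton (ids + spacing) straight from the annotation."""
    rows = [
        {"upstream_id": up.id, "downstream_id": down.id, "operon": up.operon,
         "spacing": spacing(up, down)}
        for up, down in annotation.adjacent_pairs()
    ]
    return pd.DataFrame(rows, columns=["upstream_id", "downstream_id", "operon", "spacing"])


def codon_occupancy(
    track: CountTrack,
    annotation: GenomeAnnotation,
    codon: str,
    control: float | None = None,
) -> float:
    """Mean relative ribosome occupancy at one codon.

    Occupancy of a codon instance is its mean footprint signal divided by
    the ORF-mean signal; instances are averaged within each ORF and then
    across ORFs.  ORFs without signal are skipped.  When ``control`` is
    given (the same statistic from a control sample), the ratio to it is
    returned.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3:
        raise ValueError("codon must be a triplet")
    per_orf = []
    for orf in annotation.orfs:
        prof = orf_profile(track, orf)
        mean = prof[: orf.n_codons * 3].mean()
        if mean <= 0:
            continue
        seq = annotation.orf_sequence(orf)
        occs = [
            prof[3 * ci : 3 * ci + 3].mean() / mean
            for ci in range(orf.n_codons)
            if seq[3 * ci : 3 * ci + 3] == codon
        ]
        if occs:
            per_orf.append(float(np.mean(occs)))
    if not per_orf:
        return float("nan")
    value = float(np.mean(per_orf))
    return value / control if control else value
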